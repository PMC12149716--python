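"""Smooth parametrizations of reading ratios and kQ versus field size.

Corrected reading ratios M(Sclin) follow a saturation-plus-buildup form
(Sauer & Wilbert):

    M_raw_model(S) = Pinf * S^n / (l^n + S^n) + Sinf * (1 - exp(-b S)),

normalized to unity at S = 10 cm.  Output correction factors follow the
TRS-483 sigmoid-plus-linear form

    kQ(S) = (1 + q4 exp(-(10 - q1)/q2)) / (1 + q4 exp(-(S - q1)/q2)) + q3 (S - 10),

which is exactly 1 at S = 10 cm for any parameters.  (The sigmoid parameters
are named q1..q4 here to avoid clashing with the profile-model polynomial
coefficients.)  Fits use bounded trust-region-reflective nonlinear least
squares with optional per-point weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import InvalidInputError

__all__ = [
    "OFFitParams",
    "KQFitParams",
    "FitResult",
    "of_model",
    "kq_model",
    "fit_bounded",
    "fit_of_curve",
    "fit_kq_curve",
    "fit_reference_kq_polynomial",
    "DEFAULT_OF_BOUNDS",
    "DEFAULT_KQ_BOUNDS",
]


@dataclass(frozen=True)
class OFFitParams:
    l: float
    n: float
    b: float
    P_inf: float
    S_inf: float

    def as_array(self):
        return np.array([self.l, self.n, self.b, self.P_inf, self.S_inf])


@dataclass(frozen=True)
class KQFitParams:
    q1: float
    q2: float
    q3: float
    q4: float

    def as_array(self):
        return np.array([self.q1, self.q2, self.q3, self.q4])


# all OF parameters positive; sigmoid width positive, slope and amplitude bounded
DEFAULT_OF_BOUNDS = (np.array([1e-6, 1e-6, 1e-6, 1e-6, 0.0]),
                     np.array([50.0, 10.0, 5.0, 10.0, 10.0]))
DEFAULT_KQ_BOUNDS = (np.array([-20.0, 1e-3, -0.05, -10.0]),
                     np.array([20.0, 50.0, 0.05, 10.0]))


def _of_raw(S, p):
    l, n, b, P_inf, S_inf = p
    S = np.asarray(S, dtype=float)
    return P_inf * S**n / (l**n + S**n) + S_inf * (1.0 - np.exp(-b * S))


def of_model(S, params: OFFitParams | np.ndarray):
    """Reading-ratio model normalized so that its value at S = 10 cm is 1."""
    p = params.as_array() if isinstance(params, OFFitParams) else np.asarray(params, float)
    return _of_raw(S, p) / _of_raw(10.0, p)


def kq_model(S, params: KQFitParams | np.ndarray):
    """Sigmoid-plus-linear kQ(S); identically 1 at S = 10 cm."""
    p = params.as_array() if isinstance(params, KQFitParams) else np.asarray(params, float)
    q1, q2, q3, q4 = p
    S = np.asarray(S, dtype=float)
    num = 1.0 + q4 * np.exp(-(10.0 - q1) / q2)
    den = 1.0 + q4 * np.exp(-(S - q1) / q2)
    return num / den + q3 * (S - 10.0)


@dataclass
class FitResult:
    params: np.ndarray
    covariance: np.ndarray
    success: bool
    message: str
    residual_rms: float
    bounds: tuple = field(default=None, repr=False)

    def param_sigmas(self):
        return np.sqrt(np.diag(self.covariance))


def fit_bounded(model, S_values, y_values, sigma=None, bounds=None, p0=None,
                seed=None) -> FitResult:
    """Weighted bounded nonlinear least squares (trust-region reflective).

    ``model(S, params)`` is any curve taking a parameter vector.  ``sigma``
    weights the residuals (1/sigma); when absent the fit is unweighted.
    Non-convergence is reported in the result, never silently; degenerate
    designs (all S equal, fewer points than parameters) raise.
    """
    S = np.asarray(S_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if p0 is None:
        raise InvalidInputError("an initial parameter vector p0 is required")
    p0 = np.asarray(p0, dtype=float)
    if S.size < p0.size:
        raise InvalidInputError(f"need at least {p0.size} points, got {S.size}")
    if np.ptp(S) == 0:
        raise InvalidInputError("all field sizes identical: rank-deficient design")
    w = np.ones_like(y) if sigma is None else 1.0 / np.asarray(sigma, dtype=float)
    lo, hi = bounds if bounds is not None else (-np.inf, np.inf)
    if seed is not None:
        rng = np.random.default_rng(seed)
        span = np.where(np.isfinite(np.atleast_1d(hi - lo)), 1.0, 1.0)
        p0 = p0 * (1.0 + 1e-3 * rng.standard_normal(p0.size) * span)
        p0 = np.clip(p0, lo, hi)

    def resid(p):
        return (model(S, p) - y) * w

    res = least_squares(resid, p0, bounds=(lo, hi), method="trf")
    dof = max(S.size - p0.size, 1)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    # covariance from the Jacobian pseudo-inverse, scaled by residual variance
    # when the fit is unweighted (standard Gauss-Markov estimate)
    JTJ = res.jac.T @ res.jac
    try:
        cov = np.linalg.pinv(JTJ)
    except np.linalg.LinAlgError:
        cov = np.full((p0.size, p0.size), np.nan)
    if sigma is None:
        cov = cov * np.sum(res.fun**2) / dof
    return FitResult(params=res.x, covariance=cov, success=bool(res.success),
                     message=res.message, residual_rms=rms, bounds=(lo, hi))


def fit_of_curve(S_values, y_values, sigma=None, seed=None) -> FitResult:
    """Fit the normalized reading-ratio model with default positivity bounds."""
    p0 = np.array([1.5, 1.5, 0.1, 1.0, 0.1])
    return fit_bounded(lambda S, p: of_model(S, p), S_values, y_values,
                       sigma=sigma, bounds=DEFAULT_OF_BOUNDS, p0=p0, seed=seed)


def fit_kq_curve(S_values, y_values, sigma=None, seed=None) -> FitResult:
    """Fit the sigmoid-plus-linear kQ model with default bounds."""
    p0 = np.array([1.0, 2.0, 0.0, 0.01])
    return fit_bounded(lambda S, p: kq_model(S, p), S_values, y_values,
                       sigma=sigma, bounds=DEFAULT_KQ_BOUNDS, p0=p0, seed=seed)


def fit_reference_kq_polynomial(S_values, kQ_values, sigma=None):
    """Weighted second-degree polynomial for the reference detector's kQ.

    Used only to interpolate the reference probe's nearly flat kQ(S) at
    arbitrary field sizes.  The quadratic is taken in log(S): field sizes are
    sampled log-uniformly over almost two decades and the flat curve is then
    representable within the tabulated rounding.  Returns ``(coeffs,
    predict)`` where coeffs are in increasing powers of log(S) and
    ``predict(S)`` warns outside the fitted range.
    """
    S = np.asarray(S_values, dtype=float)
    y = np.asarray(kQ_values, dtype=float)
    if S.size < 3:
        raise InvalidInputError("need at least 3 points for a quadratic")
    if np.any(S <= 0):
        raise InvalidInputError("field sizes must be positive")
    w = None if sigma is None else 1.0 / np.asarray(sigma, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(np.log(S), y, 2, w=w)
    smin, smax = S.min(), S.max()

    def predict(s):
        import warnings

        s = np.asarray(s, dtype=float)
        if np.any(s < smin) or np.any(s > smax):
            warnings.warn(
                f"extrapolating the reference kQ polynomial outside [{smin:g}, {smax:g}] cm",
                RuntimeWarning,
                stacklevel=2,
            )
        return np.polynomial.polynomial.polyval(np.log(s), coeffs)

    return coeffs, predict
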