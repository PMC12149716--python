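"""Field geometry: profile fitting, 11-point centering and equivalent square field size.

Small photon fields are characterised by their full width at half maximum
(FWHM) rather than the nominal collimator setting, because source occlusion
and penumbra overlap broaden the dosimetric field.  This module provides

* a separable quadratic model of the 2-D relative dose near the central axis,
  ``D(x, y) = f(x) g(y)`` with ``f`` and ``g`` second-order polynomials, which
  is the input of the volume-averaging / positioning convolutions in
  :mod:`smallfield.response`;
* the 11-point step-and-shoot centering technique that locates the field
  centre and measures the FWHM on both axes from four penumbra samples per
  axis plus normalization readings;
* the equivalent square field size ``S_clin = sqrt(FSx * FSy)`` and its
  first-order uncertainty propagation.

Axis convention: positions are in mm with the origin on the beam axis;
cross-line is ``x`` and in-line is ``y``.  Field sizes are in cm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BracketingError, InvalidInputError

__all__ = [
    "DoseProfileModel",
    "FieldSize",
    "CenteringResult",
    "fit_quadratic_profile",
    "eleven_point_centering",
    "equivalent_square",
]

# z-offset (in units of the penumbra sigma) of a Gaussian-blurred field edge
# at which the profile passes 30% / 70% of the plateau value.
_PENUMBRA_LEVEL_Z = 0.5244005127080409  # Phi^-1(0.70)


@dataclass(frozen=True)
class DoseProfileModel:
    """Separable quadratic relative dose ``D(x,y) = f(x) g(y)`` near the axis.

    ``f(x) = pa0 + pa1 x + pa2 x**2`` (x in mm) and likewise ``g`` with the
    ``pb`` coefficients.  The model is only meaningful inside
    ``|x - xmax|, |y - ymax| <= valid_halfwidth`` where it stays positive and
    concave.  The overall scale is a gauge choice (only per-axis coefficient
    ratios enter the correction factors).
    """

    pa0: float
    pa1: float
    pa2: float
    pb0: float
    pb1: float
    pb2: float
    valid_halfwidth: float  # mm
    concave: bool = True
    residual_rms: float = 0.0

    def f(self, x):
        x = np.asarray(x, dtype=float)
        return self.pa0 + self.pa1 * x + self.pa2 * x * x

    def g(self, y):
        y = np.asarray(y, dtype=float)
        return self.pb0 + self.pb1 * y + self.pb2 * y * y

    def dose(self, x, y):
        """Relative dose D(x, y) = f(x) g(y)."""
        return self.f(x) * self.g(y)

    @property
    def xmax(self) -> float:
        """Location of the maximum of f (mm); 0 for a flat axis."""
        return 0.0 if self.pa2 == 0.0 else -self.pa1 / (2.0 * self.pa2)

    @property
    def ymax(self) -> float:
        return 0.0 if self.pb2 == 0.0 else -self.pb1 / (2.0 * self.pb2)


@dataclass(frozen=True)
class FieldSize:
    """Measured field sizes (cm) and the equivalent square, with sigmas in mm."""

    FSx: float
    FSy: float
    Sclin: float
    sigma_FSx: float = 0.0
    sigma_FSy: float = 0.0
    sigma_Sclin: float = 0.0


@dataclass
class CenteringResult:
    """Output of the 11-point centering / field-size measurement.

    ``center`` is the located field centre (mm); FSx/FSy are FWHMs in cm;
    ``normalization`` is the reading at the final 2-D centre; ``samples``
    lists the 11 acquired ``(x_mm, y_mm, reading)`` triples in order.
    """

    center: tuple[float, float]
    FSx: float
    FSy: float
    normalization: float
    samples: list[tuple[float, float, float]] = field(default_factory=list)


def _fit_axis(pos, val, center, halfwidth):
    mask = np.abs(pos - center) <= halfwidth
    if mask.sum() < 5:
        raise InvalidInputError(
            f"need >= 5 points inside the fit halfwidth ({halfwidth} mm), got {mask.sum()}"
        )
    coeffs = np.polynomial.polynomial.polyfit(pos[mask], val[mask], 2)
    resid = val[mask] - np.polynomial.polynomial.polyval(pos[mask], coeffs)
    return coeffs, float(np.sqrt(np.mean(resid**2)))


def _as_profile_arrays(profile):
    if isinstance(profile, pd.DataFrame):
        return profile["position_mm"].to_numpy(float), profile["value"].to_numpy(float)
    arr = np.asarray(profile, dtype=float)
    return arr[:, 0], arr[:, 1]


def _estimate_fwhm(pos, val):
    """Crude (FWHM, centre) of a sampled peaked profile by 50%-crossing interpolation.

    The centre is the midpoint of the two crossings — robust on flat-topped
    profiles where the sample argmax can sit anywhere on the plateau.
    """
    half = 0.5 * val.max()
    above = val >= half
    idx = np.flatnonzero(above)
    if idx.size == 0 or idx[0] == 0 or idx[-1] == len(pos) - 1:
        raise InvalidInputError("profile does not fall below 50% of its maximum on both sides")
    i, j = idx[0], idx[-1]
    xl = np.interp(half, [val[i - 1], val[i]], [pos[i - 1], pos[i]])
    xr = np.interp(half, [val[j + 1], val[j]], [pos[j + 1], pos[j]])
    return xr - xl, 0.5 * (xl + xr)


def fit_quadratic_profile(cross_profile, inline_profile, fit_halfwidth=None) -> DoseProfileModel:
    """Least-squares fit of the separable quadratic dose model to two profiles.

    Parameters
    ----------
    cross_profile, inline_profile
        DataFrames with ``position_mm``/``value`` columns, or (n, 2) arrays.
        The cross-line profile samples D(x, y=const) and the in-line profile
        D(x=const, y); constant transverse offsets are absorbed in the gauge.
    fit_halfwidth
        Half-width (mm) of the window around the profile maximum used in the
        fit.  Default: 15% of the estimated FWHM on each axis (a window of
        30% of the FWHM around the centre), which keeps the quadratic
        approximation well inside the penumbrae.

    Returns
    -------
    DoseProfileModel
        with ``concave=False`` (and a warning) if either fitted second-order
        coefficient is positive over a peaked profile.
    """
    xs, fx = _as_profile_arrays(cross_profile)
    ys, gy = _as_profile_arrays(inline_profile)

    coeffs = []
    rms_tot = 0.0
    halfwidths = []
    for pos, val in ((xs, fx), (ys, gy)):
        try:
            fwhm, c0 = _estimate_fwhm(pos, val)
        except InvalidInputError:
            # profile sampled only over the peak region: centre on the argmax
            if fit_halfwidth is None:
                raise
            fwhm, c0 = np.ptp(pos), pos[np.argmax(val)]
        hw = fit_halfwidth if fit_halfwidth is not None else 0.15 * fwhm
        cf, rms = _fit_axis(pos, val, c0, hw)
        coeffs.append(cf)
        rms_tot += rms**2
        halfwidths.append(hw)

    (a0, a1, a2), (b0, b1, b2) = coeffs
    concave = True
    hw2 = float(min(halfwidths)) ** 2
    # positive curvature below roundoff scale is a flat axis, not a defect
    if a2 * hw2 > 1e-12 * abs(a0) or b2 * hw2 > 1e-12 * abs(b0):
        concave = False
        warnings.warn(
            "non-concave quadratic fit over a peaked profile (pa2 or pb2 > 0)",
            RuntimeWarning,
            stacklevel=2,
        )
    return DoseProfileModel(
        pa0=a0, pa1=a1, pa2=a2, pb0=b0, pb1=b1, pb2=b2,
        valid_halfwidth=float(min(halfwidths)),
        concave=concave,
        residual_rms=float(np.sqrt(rms_tot / 2.0)),
    )


def _interp_crossing(p_lo, v_lo, p_hi, v_hi, level):
    """Linear interpolation of the position where the reading equals *level*."""
    if v_lo == v_hi or not (min(v_lo, v_hi) <= level <= max(v_lo, v_hi)):
        raise BracketingError(
            f"penumbra samples ({v_lo:.4g}, {v_hi:.4g}) do not bracket level {level:.4g}"
        )
    return p_lo + (level - v_lo) * (p_hi - p_lo) / (v_hi - v_lo)


def _center_one_axis(sample, center0, side_mm, step, samples_log):
    """Four penumbra samples + normalization reading on one axis.

    Returns (center, fwhm_mm, normalization).  ``sample`` maps an axis
    position to a reading (the orthogonal coordinate is frozen by the caller).
    """
    lo_edge = center0 - 0.5 * side_mm
    hi_edge = center0 + 0.5 * side_mm
    # ~30% / 70% sample positions on each edge
    p = [lo_edge - step, lo_edge + step, hi_edge - step, hi_edge + step]
    v = [sample(q) for q in p]
    for q, r in zip(p, v):
        samples_log.append((q, r))

    # provisional centre assuming linear penumbra slopes; the mean of the four
    # readings is a level both chords cross, and makes the midpoint exact for
    # symmetric fields
    lev = float(np.mean(v))
    x_lo = _interp_crossing(p[0], v[0], p[1], v[1], lev)
    x_hi = _interp_crossing(p[3], v[3], p[2], v[2], lev)
    c_prov = 0.5 * (x_lo + x_hi)

    norm = sample(c_prov)
    samples_log.append((c_prov, norm))

    half = 0.5 * norm
    x_lo = _interp_crossing(p[0], v[0], p[1], v[1], half)
    x_hi = _interp_crossing(p[3], v[3], p[2], v[2], half)
    return 0.5 * (x_lo + x_hi), x_hi - x_lo, norm


def eleven_point_centering(
    profile_sampler,
    initial_center=(0.0, 0.0),
    nominal_side=1.0,
    penumbra_sigma_guess=2.0,
    target_levels=(0.3, 0.7),
) -> CenteringResult:
    """Locate the field centre and measure FSx/FSy with 11 point readings.

    Per axis, two readings are taken on each side of the field at positions
    where the dose is expected near 30% and 70% of the plateau (for a
    Gaussian-blurred edge of width ``penumbra_sigma_guess``).  Assuming
    linear penumbra slopes, the two 50%-crossings of a fifth, central
    normalization reading give the axis centre (their midpoint) and the FWHM
    (their distance).  The in-line axis is processed after re-centering
    cross-line, and an eleventh reading at the final 2-D centre is returned
    as the normalization signal.

    Parameters
    ----------
    profile_sampler
        Callable ``(x_mm, y_mm) -> reading``; synthetic generator or an
        interpolator over measured data.
    initial_center
        Visual centering estimate (mm).
    nominal_side
        Nominal square field side (cm).
    penumbra_sigma_guess
        Assumed penumbra width (mm) used only to place the 30%/70% samples.
    target_levels
        Penumbra dose levels aimed at by the sampling positions; only their
        spread matters, via the Gaussian quantile of the upper level.
    """
    from scipy.stats import norm as _norm

    side_mm = 10.0 * nominal_side
    if side_mm <= 0:
        raise InvalidInputError("nominal_side must be positive")
    step = penumbra_sigma_guess * float(_norm.ppf(max(target_levels)))
    cx, cy = (float(c) for c in initial_center)

    samples: list[tuple[float, float, float]] = []

    log_x: list[tuple[float, float]] = []
    cx, fwhm_x, _ = _center_one_axis(lambda q: profile_sampler(q, cy), cx, side_mm, step, log_x)
    samples.extend((q, cy, r) for q, r in log_x)

    log_y: list[tuple[float, float]] = []
    cy, fwhm_y, _ = _center_one_axis(lambda q: profile_sampler(cx, q), cy, side_mm, step, log_y)
    samples.extend((cx, q, r) for q, r in log_y)

    norm11 = profile_sampler(cx, cy)
    samples.append((cx, cy, norm11))

    return CenteringResult(
        center=(cx, cy),
        FSx=fwhm_x / 10.0,
        FSy=fwhm_y / 10.0,
        normalization=norm11,
        samples=samples,
    )


def equivalent_square(FSx, FSy, sigma_FSx=0.0, sigma_FSy=0.0) -> FieldSize:
    """Equivalent square field size ``Sclin = sqrt(FSx * FSy)`` with propagation.

    ``FSx``/``FSy`` are the measured FWHMs in cm; the sigmas are in mm.
    First-order propagation of the square-root-of-product definition gives

    ``sigma_Sclin = 1/2 sqrt( (FSy/FSx) sigma_FSx**2 + (FSx/FSy) sigma_FSy**2 )``.
    """
    if FSx <= 0 or FSy <= 0:
        raise InvalidInputError("field sizes must be positive")
    if sigma_FSx < 0 or sigma_FSy < 0:
        raise InvalidInputError("sigmas must be non-negative")
    sclin = float(np.sqrt(FSx * FSy))
    sig = 0.5 * float(
        np.sqrt((FSy / FSx) * sigma_FSx**2 + (FSx / FSy) * sigma_FSy**2)
    )
    return FieldSize(
        FSx=float(FSx), FSy=float(FSy), Sclin=sclin,
        sigma_FSx=float(sigma_FSx), sigma_FSy=float(sigma_FSy), sigma_Sclin=sig,
    )
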