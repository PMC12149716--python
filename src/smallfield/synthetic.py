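"""Synthetic study generator: profiles, measurement sessions, spectra, fixtures.

Everything the output-factor pipeline consumes can be generated here with a
known ground truth, so that end-to-end recovery is testable:

* **Profiles** — square small fields modelled as differences of two
  Gaussian-blurred edges (erf penumbras) of width ``penumbra_sigma`` centred
  at +/- side/2, normalized to 1 at the maximum; the standard analytic
  penumbra model, chosen because its FWHM is available in closed form for
  oracles.
* **Sessions** — raw readings per field size, polarity and repeat, with an
  injected polarity curve, a dose-per-pulse recombination effect driven by
  the parameter B (made self-consistent with the linear kion-ratio model so
  that the analysis-side correction inverts it exactly at zero noise) and
  multiplicative Gaussian reading noise.  The type-I-corrected reading-ratio
  ground truth follows a saturation-plus-buildup curve with defaults tuned
  to a flattened 6 MV jaw-collimated beam.
* **Scaled-reference-field (msr') sessions** — the recombination calibration
  experiment: the reference field is rescaled at several SSDs so the field
  size at the detector stays constant while the dose per pulse follows the
  inverse square law; two-voltage readings are emitted so the Boag method
  recovers the injected recombination.
* **Spectra** — per-field electron energy-deposition interval lists with a
  hard (~MeV) and a soft (tens of keV) component; the soft weight grows with
  field size, emulating the increased low-energy scatter of large fields
  that drives the quenching correction away from unity by a few tenths of a
  percent.
* **Perturbation fixtures** — smooth Pwall/Pscint tables of the magnitude
  seen for a water-matched scintillator probe, with Pscint chosen to largely
  offset the quenching ratio.

All randomness flows through a single integer seed (default 20240101).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import ndtr  # Gaussian CDF

from .errors import InvalidSpecError
from .fitting import of_model
from .quenching import QuenchingInput

__all__ = [
    "DEFAULT_SEED",
    "FIELD_SIDES_CM",
    "OF_TRUTH_PARAMS",
    "SyntheticFieldSpec",
    "SyntheticSessionSpec",
    "axis_profile",
    "dose_sampler",
    "analytic_fwhm",
    "make_profile",
    "make_session",
    "make_msr_prime_session",
    "make_spectra",
    "make_perturbation_table",
    "default_soft_fraction",
    "field_spec_to_yaml",
    "field_spec_from_yaml",
]

DEFAULT_SEED = 20240101

# the twelve jaw-delimited square field sides of the study conditions (cm)
FIELD_SIDES_CM = (0.6, 0.8, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 30.0)

# saturation-plus-buildup reading-ratio truth (l, n, b, P_inf, S_inf),
# tuned once to typical flattened 6 MV jaw output factors
# (0.67 at 0.66 cm, 0.80 at ~1 cm, 1.06 at 30 cm)
OF_TRUTH_PARAMS = np.array([0.38991605, 1.96935665, 0.09533685, 6.88524083, 1.37749442])


def of_truth(S):
    """Ground-truth type-I-corrected reading ratio at equivalent square size S (cm)."""
    return of_model(S, OF_TRUTH_PARAMS)


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """A square field: nominal side (cm), penumbra sigma (mm), centre offset (mm)."""

    nominal_side: float
    penumbra_sigma: float = 2.0
    center_offset: tuple[float, float] = (0.0, 0.0)
    msr_side: float = 10.0

    def __post_init__(self):
        if self.nominal_side <= 0:
            raise InvalidSpecError("nominal_side must be positive")
        if self.penumbra_sigma <= 0:
            raise InvalidSpecError("penumbra_sigma must be positive")


@dataclass(frozen=True)
class SyntheticSessionSpec:
    """Measurement-session nuisance model.

    ``true_B`` is the dose-per-pulse recombination parameter;
    ``true_kpol_curve`` maps the field side (cm) to the polarity factor
    (None means unity); noise is multiplicative and i.i.d. per reading.
    The default noise level matches short-term readout/machine
    reproducibility of about 0.1%.
    """

    detector_id: str = "det-1"
    true_B: float = 0.0
    true_kpol_curve: object = None
    reading_noise_rel: float = 0.001
    n_repeats: int = 3
    rng_seed: int = DEFAULT_SEED

    def __post_init__(self):
        if not -0.02 <= self.true_B <= 0.02:
            raise InvalidSpecError("true_B outside the plausible [-0.02, 0.02] range")
        if self.reading_noise_rel < 0:
            raise InvalidSpecError("reading_noise_rel must be >= 0")
        if self.n_repeats < 1:
            raise InvalidSpecError("n_repeats must be >= 1")

    def kpol(self, side_cm: float) -> float:
        if self.true_kpol_curve is None:
            return 1.0
        if callable(self.true_kpol_curve):
            return float(self.true_kpol_curve(side_cm))
        return float(self.true_kpol_curve[side_cm])


def axis_profile(x_mm, side_cm: float, sigma_mm: float, center_mm: float = 0.0):
    """Normalized 1-D erf-difference field profile (max = 1 at the centre)."""
    x = np.asarray(x_mm, dtype=float)
    half = 5.0 * side_cm  # cm -> mm, half side
    lo = (x - center_mm + half) / sigma_mm
    hi = (x - center_mm - half) / sigma_mm
    peak = 2.0 * ndtr(half / sigma_mm) - 1.0
    return (ndtr(lo) - ndtr(hi)) / peak


def dose_sampler(spec: SyntheticFieldSpec, noise_rel: float = 0.0, rng=None):
    """2-D relative dose D(x, y) for a square field; optionally noisy readings."""
    dx, dy = spec.center_offset
    if noise_rel > 0 and rng is None:
        rng = np.random.default_rng(DEFAULT_SEED)

    def sample(x, y):
        val = (axis_profile(x, spec.nominal_side, spec.penumbra_sigma, dx)
               * axis_profile(y, spec.nominal_side, spec.penumbra_sigma, dy))
        if noise_rel > 0:
            val = val * (1.0 + noise_rel * rng.standard_normal(np.shape(val) or None))
        return val

    return sample


def analytic_fwhm(spec: SyntheticFieldSpec) -> float:
    """Closed-form-root FWHM (mm) of the erf-difference axis profile."""
    f = lambda x: axis_profile(x, spec.nominal_side, spec.penumbra_sigma) - 0.5
    half = 5.0 * spec.nominal_side
    hi = half + 10.0 * spec.penumbra_sigma
    x_r = brentq(f, 0.0, hi, xtol=1e-12)
    return 2.0 * x_r


def measured_equiv_square(spec: SyntheticFieldSpec) -> float:
    """Ground-truth equivalent square size (cm): the analytic FWHM of a square field."""
    return analytic_fwhm(spec) / 10.0


def make_profile(spec: SyntheticFieldSpec, axis: str = "cross-line", n_points: int = 201,
                 rng_seed=None, noise_rel: float = 0.0, span_mm: float | None = None) -> pd.DataFrame:
    """Sample one axis profile as a (position_mm, value) table.

    The span covers the field plus four penumbra sigmas by default.  Noise is
    multiplicative i.i.d. Gaussian; zero noise is exactly deterministic.
    """
    if axis not in ("cross-line", "in-line"):
        raise InvalidSpecError(f"unknown axis {axis!r}")
    if n_points < 11:
        raise InvalidSpecError("need at least 11 profile points")
    offset = spec.center_offset[0] if axis == "cross-line" else spec.center_offset[1]
    if span_mm is None:
        span_mm = 5.0 * spec.nominal_side + 4.0 * spec.penumbra_sigma + abs(offset)
    x = np.linspace(-span_mm, span_mm, n_points) + offset
    v = axis_profile(x, spec.nominal_side, spec.penumbra_sigma, offset)
    if noise_rel > 0:
        rng = np.random.default_rng(rng_seed if rng_seed is not None else DEFAULT_SEED)
        v = v * (1.0 + noise_rel * rng.standard_normal(v.size))
    return pd.DataFrame({"position_mm": x, "value": v})


def _self_consistent_raw_ratio(of_corrected: float, B: float) -> float:
    """Raw*kpol reading ratio r solving r / (1 + B (1 - r)) = of_corrected."""
    return of_corrected * (1.0 + B) / (1.0 + of_corrected * B)


@dataclass
class SessionData:
    """Raw readings plus the generating ground truth."""

    readings: pd.DataFrame
    truth: pd.DataFrame
    spec: SyntheticSessionSpec


def make_session(field_specs, session_spec: SyntheticSessionSpec,
                 base_reading: float = 100.0) -> SessionData:
    """Generate a bias-paired measurement session over the given fields.

    Raw readings equal the ground-truth corrected ratio divided by the
    injected polarity and recombination effects, times noise; both bias
    polarities are emitted so the analysis can recover kpol, and the truth
    table stores every injected quantity per field.
    """
    rng = np.random.default_rng(session_spec.rng_seed)
    rows, truth_rows = [], []
    msr_sides = {s.msr_side for s in field_specs}
    if len(msr_sides) != 1:
        raise InvalidSpecError("all field specs must share the msr side")
    msr_side = msr_sides.pop()
    kpol_msr = session_spec.kpol(msr_side)
    B = session_spec.true_B

    for spec in field_specs:
        s_meas = measured_equiv_square(spec)
        s_msr_meas = measured_equiv_square(
            SyntheticFieldSpec(msr_side, spec.penumbra_sigma))
        of = float(of_truth(s_meas) / of_truth(s_msr_meas))
        kpol = session_spec.kpol(spec.nominal_side)
        r = _self_consistent_raw_ratio(of, B)  # raw*kpol ratio vs msr
        kion_r = 1.0 / (1.0 + B * (1.0 - r))
        m_op = base_reading * r * kpol_msr / kpol
        for rep in range(session_spec.n_repeats):
            eps_p = session_spec.reading_noise_rel * rng.standard_normal()
            eps_m = session_spec.reading_noise_rel * rng.standard_normal()
            rows.append((session_spec.detector_id, spec.nominal_side, 90.0, 300.0,
                         "+", m_op * (1.0 + eps_p), rep))
            rows.append((session_spec.detector_id, spec.nominal_side, 90.0, 300.0,
                         "-", -(2.0 * kpol - 1.0) * m_op * (1.0 + eps_m), rep))
        truth_rows.append((spec.nominal_side, s_meas, of, kpol, kion_r, r))

    readings = pd.DataFrame(rows, columns=[
        "detector_id", "field_side_cm", "SSD_cm", "bias_V", "polarity",
        "reading", "repeat_index"])
    truth = pd.DataFrame(truth_rows, columns=[
        "field_side_cm", "S_meas_cm", "of_true", "kpol_true",
        "kion_ratio_true", "raw_kpol_ratio_true"])
    return SessionData(readings=readings, truth=truth, spec=session_spec)


def make_msr_prime_session(session_spec: SyntheticSessionSpec,
                           SSDs=(80.0, 90.0, 100.0, 110.0), msr_side: float = 10.0,
                           detector_depth: float = 10.0, kion_msr: float = 1.002,
                           base_reading: float = 100.0) -> SessionData:
    """Scaled-reference-field recombination calibration data.

    At each SSD the reference field side is rescaled to keep the field size
    constant at the detector plane while the dose per pulse follows the
    inverse square of the source-detector distance; readings at the full and
    half bias are generated so the two-voltage method recovers the injected
    recombination exactly (up to noise).
    """
    rng = np.random.default_rng(session_spec.rng_seed + 1)
    B = session_spec.true_B
    rows, truth_rows = [], []
    for ssd in SSDs:
        side = msr_side * 100.0 / (ssd + detector_depth)
        d = (100.0 / (ssd + detector_depth)) ** 2  # dose-per-pulse ratio vs msr
        r = _self_consistent_raw_ratio(d, B)
        kion_ratio_true = 1.0 / (1.0 + B * (1.0 - r))
        kion_abs = kion_msr * kion_ratio_true  # condition-level correction
        kpol = session_spec.kpol(side)
        # raw reading at the operating (full) bias, normalized so the
        # raw*kpol ratio against the SSD-90 reference record equals r
        m_h = base_reading * r * session_spec.kpol(msr_side) / kpol
        m_l = m_h / (2.0 - 1.0 / kion_abs)  # exact Boag inversion at V_H/V_L = 2
        for rep in range(session_spec.n_repeats):
            for bias, pol, val in ((300.0, "+", m_h),
                                   (300.0, "-", -(2.0 * kpol - 1.0) * m_h),
                                   (150.0, "+", m_l)):
                eps = session_spec.reading_noise_rel * rng.standard_normal()
                rows.append((session_spec.detector_id, side, ssd, bias, pol,
                             val * (1.0 + eps), rep))
        truth_rows.append((ssd, side, d, r, kion_ratio_true, kion_abs, kpol))
    readings = pd.DataFrame(rows, columns=[
        "detector_id", "field_side_cm", "SSD_cm", "bias_V", "polarity",
        "reading", "repeat_index"])
    truth = pd.DataFrame(truth_rows, columns=[
        "SSD_cm", "field_side_cm", "dose_ratio", "raw_kpol_ratio_true",
        "kion_ratio_true", "kion_abs_true", "kpol_true"])
    return SessionData(readings=readings, truth=truth, spec=session_spec)


def default_soft_fraction(S):
    """Default soft-electron energy fraction, growing with field side (cm)."""
    S = np.asarray(S, dtype=float)
    return 0.03 + 0.05 * S / (S + 5.0)


def make_spectra(field_sides, soft_fraction_curve=default_soft_fraction,
                 rng_seed: int = DEFAULT_SEED, n_hard: int = 60, n_soft: int = 40) -> dict:
    """Per-field energy-deposition interval lists with a two-component spectrum.

    A single set of hard (~0.1-1.7 MeV) and soft (~10-60 keV) electron
    intervals is drawn once and shared by all fields; only the relative
    energy weight of the soft component varies with field side, following
    ``soft_fraction_curve`` (which must be non-decreasing).  A constant
    curve therefore yields identical spectra — and a quenching ratio of
    exactly one — for every field pair.
    """
    sides = np.asarray(list(field_sides), dtype=float)
    sf = np.asarray([float(soft_fraction_curve(s)) for s in sides])
    if np.any(np.diff(sf[np.argsort(sides)]) < -1e-12):
        raise InvalidSpecError("soft fraction must be non-decreasing with field side")

    rng = np.random.default_rng(rng_seed)
    hard_lo = 0.05 + 0.10 * rng.random(n_hard)
    hard = np.column_stack([hard_lo, hard_lo + 0.2 + 1.5 * rng.random(n_hard)])
    soft_lo = 0.002 + 0.003 * rng.random(n_soft)
    soft = np.column_stack([soft_lo, soft_lo + 0.01 + 0.05 * rng.random(n_soft)])
    len_hard = float(np.sum(hard[:, 1] - hard[:, 0]))
    len_soft = float(np.sum(soft[:, 1] - soft[:, 0]))

    particles = tuple(map(tuple, np.vstack([hard, soft])))
    out = {}
    for side, frac in zip(sides, sf):
        w_hard = (1.0 - frac) / len_hard
        w_soft = frac / len_soft
        weights = tuple([w_hard] * n_hard + [w_soft] * n_soft)
        out[float(side)] = QuenchingInput(field_side=float(side),
                                          particles=particles, weights=weights)
    return out


def make_perturbation_table(field_sides) -> pd.DataFrame:
    """Smooth synthetic Pwall/Pscint tables of water-matched-probe magnitude.

    Pwall stays within 0.1% of unity; Pscint rises by ~0.2% toward small
    fields so that, combined with the quenching ratio of the default
    spectra, the assembled output correction factor remains within a few
    tenths of a percent of one — the behaviour the probe is designed for.
    """
    S = np.asarray(list(field_sides), dtype=float)
    pwall = 1.0 + 0.001 * np.exp(-S / 4.0)
    pscint = 1.0 + 0.004 * (5.0 / (S + 5.0) - 5.0 / 15.0)
    return pd.DataFrame({
        "field_side_cm": S, "Pwall": pwall, "Pwall_u": 0.001,
        "Pscint": pscint, "Pscint_u": 0.001,
    })


# --- YAML round-trips for specs --------------------------------------------

def field_spec_to_yaml(specs) -> str:
    docs = [
        {"nominal_side": s.nominal_side, "penumbra_sigma": s.penumbra_sigma,
         "center_offset": list(s.center_offset), "msr_side": s.msr_side}
        for s in specs
    ]
    return yaml.safe_dump(docs, sort_keys=False)


def field_spec_from_yaml(text: str):
    docs = yaml.safe_load(text)
    return [SyntheticFieldSpec(nominal_side=d["nominal_side"],
                               penumbra_sigma=d.get("penumbra_sigma", 2.0),
                               center_offset=tuple(d.get("center_offset", (0.0, 0.0))),
                               msr_side=d.get("msr_side", 10.0))
            for d in docs]
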