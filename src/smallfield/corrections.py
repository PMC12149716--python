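"""Reading corrections: polarity, ion recombination and the other type I factors.

A raw detector reading is converted into a signal proportional to the dose in
the sensitive volume by a product of correction factors.  "Type I" factors
(temperature/pressure, humidity, electrometer, polarity, recombination,
drift, background, stem, positioning) are independent of the small beam
quality change between the reference (msr) and the clinical field, and are
applied directly to the reading; "type II" factors (for these detectors only
the scintillator quenching ratio) live inside the output correction factor
instead.  The applicable factor set depends on the detector class:

* IC  (ionization chamber):  kTP kH kelec kpol kion kdrift kbg kstem kpos
* SS  (solid state):         kT kelec kion kdrift kbg kstem kpos
* PSD (plastic scintillator): kT kread kdrift kbg kstem kpos

Recombination is corrected with the Boag two-voltage method in pulsed beams
and, across field sizes, with a linear dose-per-pulse model parametrised by a
single detector constant B fitted on scaled-reference-field (msr')
measurements at several source-to-surface distances:

    kion ratio (clin/msr) = 1 / (1 + B * (1 - raw*kpol*kpos reading ratio)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np

from .errors import InvalidCorrectionError, InvalidInputError

__all__ = [
    "TypeIFactors",
    "CorrectedReading",
    "RecombinationModel",
    "CLASS_FACTORS",
    "apply_type1",
    "reading_ratio",
    "kpol_from_bias_pair",
    "boag_two_voltage",
    "kion_ratio",
    "scale_msr_prime",
    "transfer_kion_to_SS",
    "fit_B",
]

CLASS_FACTORS = {
    "IC": ("kTP", "kH", "kelec", "kpol", "kion", "kdrift", "kbg", "kstem", "kpos"),
    "SS": ("kT", "kelec", "kion", "kdrift", "kbg", "kstem", "kpos"),
    "PSD": ("kT", "kread", "kdrift", "kbg", "kstem", "kpos"),
}


@dataclass(frozen=True)
class TypeIFactors:
    """All type I correction factors, defaulting to unity."""

    kTP: float = 1.0
    kH: float = 1.0
    kelec: float = 1.0
    kpol: float = 1.0
    kion: float = 1.0
    kdrift: float = 1.0
    kbg: float = 1.0
    kstem: float = 1.0
    kpos: float = 1.0
    kT: float = 1.0
    kread: float = 1.0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class CorrectedReading:
    Mraw: float
    factors: TypeIFactors
    M: float
    detector_class: str


def apply_type1(Mraw: float, factors: TypeIFactors, detector_class: str) -> CorrectedReading:
    """Apply the class-specific product of type I factors to a raw reading.

    Factors outside the detector class's equation must remain at unity; a
    non-unit inapplicable factor is rejected rather than silently ignored.
    """
    if detector_class not in CLASS_FACTORS:
        raise InvalidInputError(f"unknown detector class {detector_class!r}")
    applicable = CLASS_FACTORS[detector_class]
    d = factors.as_dict()
    for name, val in d.items():
        if val <= 0:
            raise InvalidCorrectionError(f"{name} must be positive, got {val}")
        if name not in applicable and val != 1.0:
            raise InvalidCorrectionError(
                f"{name} is not applicable to detector class {detector_class}"
            )
    prod = 1.0
    for name in applicable:
        prod *= d[name]
    return CorrectedReading(Mraw=float(Mraw), factors=factors,
                            M=float(Mraw) * prod, detector_class=detector_class)


def reading_ratio(clin: CorrectedReading, msr: CorrectedReading):
    """Ratio of two corrected readings, tracking factor ratios assumed unity.

    Returns ``(ratio, assumed_unity)`` where the second element lists the
    applicable factors whose clin and msr values coincide — these contribute
    a type B uncertainty allowance but no value to the ratio.
    """
    if clin.detector_class != msr.detector_class:
        raise InvalidInputError("cannot ratio readings from different detector classes")
    if msr.M == 0:
        raise InvalidInputError("reference corrected reading is zero")
    dc, dm = clin.factors.as_dict(), msr.factors.as_dict()
    assumed = [n for n in CLASS_FACTORS[clin.detector_class] if dc[n] == dm[n]]
    return clin.M / msr.M, assumed


def kpol_from_bias_pair(M_plus: float, M_minus: float, M_operating: float) -> float:
    """Polarity correction from paired-bias readings.

    kpol = (|M+| + |M-|) / (2 |M_operating|), with the operating reading one
    of the pair.  Same-sign raw inputs (charge not reversing with bias) are
    flagged as suspicious.
    """
    if M_operating == 0:
        raise InvalidInputError("operating-polarity reading is zero")
    if M_plus * M_minus > 0:
        raise InvalidCorrectionError(
            "bias-pair readings have the same sign; expected opposite-polarity charges"
        )
    return (abs(M_plus) + abs(M_minus)) / (2.0 * abs(M_operating))


def boag_two_voltage(M_H: float, M_L: float, V_H: float, V_L: float) -> float:
    """Boag two-voltage recombination correction at V_H for pulsed beams.

    kion(V_H) = (1 - V_H/V_L) / (M_H/M_L - V_H/V_L).
    """
    if not (V_H > V_L > 0):
        raise InvalidInputError("need V_H > V_L > 0")
    if M_H <= 0 or M_L <= 0:
        raise InvalidInputError("readings must be positive")
    vr = V_H / V_L
    mr = M_H / M_L
    if mr == vr:
        raise InvalidInputError("M_H/M_L equals V_H/V_L: singular two-voltage inversion")
    return (1.0 - vr) / (mr - vr)


def kion_ratio(B: float, corrected_raw_ratio: float) -> float:
    """Dose-per-pulse recombination ratio: 1 / (1 + B (1 - ratio)).

    ``corrected_raw_ratio`` is the raw*kpol*kpos reading ratio between the
    clinical and reference fields (the dose-per-pulse proxy).
    """
    if corrected_raw_ratio <= 0:
        raise InvalidInputError("reading ratio must be positive")
    return 1.0 / (1.0 + B * (1.0 - corrected_raw_ratio))


def scale_msr_prime(fmsr_side: float, SSD: float, detector_depth: float = 10.0) -> float:
    """Scaled reference field side keeping the field size constant at the detector.

    fmsr' = fmsr * 100 / (SSD + depth): the 100 cm is the reference
    source-to-detector distance (SSD 90 cm + 10 cm depth).
    """
    if SSD <= 0:
        raise InvalidInputError("SSD must be positive")
    return fmsr_side * 100.0 / (SSD + detector_depth)


def transfer_kion_to_SS(ic_raw_ratio: float, ss_raw_ratio: float,
                        ic_kion_ratio: float, ic_kpol_ratio: float) -> float:
    """Approximate a solid-state detector's kion ratio from chamber data.

    For matched msr -> msr' geometries where the beam quality is unchanged,
    (kion)_SS = (Mraw_IC / Mraw_SS) * (kion * kpol)_IC.
    """
    if ss_raw_ratio == 0:
        raise InvalidInputError("solid-state raw ratio is zero")
    return (ic_raw_ratio / ss_raw_ratio) * ic_kion_ratio * ic_kpol_ratio


@dataclass(frozen=True)
class RecombinationModel:
    """Fitted dose-per-pulse parameter B with its spread-based uncertainty.

    ``B_uncertainty`` is absolute (same scale as B); ``B_rel_uncertainty``
    is the max-spread-over-mean ratio across all source records, which are
    kept for provenance.
    """

    B: float
    B_uncertainty: float
    B_rel_uncertainty: float
    records: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if abs(self.B) >= 0.1:
            raise InvalidInputError(f"|B| = {abs(self.B):.3g} is implausibly large (>= 0.1)")


def fit_B(records: Sequence[dict]) -> RecombinationModel:
    """Invert the dose-per-pulse model per msr' record and average B.

    Each record needs keys ``SSD`` (cm), ``kion_ratio`` and ``raw_ratio``
    (the raw*kpol*kpos reading ratio msr'/msr).  Per record
    B = (1/kion_ratio - 1) / (1 - raw_ratio); records with raw_ratio == 1
    are excluded (singular inversion).  The reported B averages the 80 cm
    and 110 cm SSD inversions (the extremes of the dose-per-pulse lever
    arm); its uncertainty is the maximal variation among all SSDs over the
    mean.
    """
    if len(records) < 2:
        raise InvalidInputError("need at least two msr' records to fit B")
    inversions = []
    for rec in records:
        ratio = rec["raw_ratio"]
        if ratio == 1.0:
            continue  # no dose-per-pulse lever; would divide by zero
        b = (1.0 / rec["kion_ratio"] - 1.0) / (1.0 - ratio)
        inversions.append((rec["SSD"], b))
    if len(inversions) < 2:
        raise InvalidInputError("fewer than two usable msr' records (raw_ratio != 1)")

    ssds = np.array([s for s, _ in inversions])
    bs = np.array([b for _, b in inversions])
    extremes = [bs[np.argmin(np.abs(ssds - s))] for s in (80.0, 110.0)]
    B = float(np.mean(extremes))
    spread = float(bs.max() - bs.min())
    rel = spread / abs(np.mean(bs)) if np.mean(bs) != 0 else np.inf
    return RecombinationModel(B=B, B_uncertainty=spread, B_rel_uncertainty=float(rel),
                              records=tuple((s, float(b)) for s, b in inversions))
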