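"""Assembly of the output correction factor kQclin,Qmsr and field output factors.

For the scintillator probe the dose to water at a point relates to the mean
dose in the detector through a chain of perturbation factors,

    Dw = kvol * Pscint * Pwall * D_det,

where Pwall covers the extracameral components (jacket, fiber, wall), Pscint
the density/composition difference between scintillator and water, and kvol
the volume averaging over the sensitive volume.  Expressed as clin/msr
ratios and including the quenching ratio kioq (the only beam-quality
dependent reading correction), the field output correction factor is

    kQclin,Qmsr = (kvol * Pscint * Pwall * kioq) clin/msr ,

and the field output factor follows from the corrected reading ratio,
Omega = M_ratio * kQ.  A detector with known kQ transfers it to another
detector measured in the same fields:  kQ(det2) = M_ratio(det1) * kQ(det1)
/ M_ratio(det2).

Pwall and Pscint are Monte-Carlo products consumed here as per-field-size
fixtures (CSV columns: field_side_cm, Pwall, Pwall_u, Pscint, Pscint_u and
optionally the four chain doses Ddet, Dscint, Dscint_w, Dw); interpolation
between tabulated sides is linear in log field side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FixtureSchemaError, InvalidInputError

__all__ = [
    "PerturbationFixture",
    "CorrectionChainResult",
    "OutputFactorResult",
    "chain_from_doses",
    "assemble_kQ",
    "output_factor",
    "transfer_kQ",
]

_REQUIRED_COLS = ("field_side_cm", "Pwall", "Pscint")
_DOSE_COLS = ("Ddet", "Dscint", "Dscint_w", "Dw")


@dataclass
class PerturbationFixture:
    """Per-field-size Monte-Carlo perturbation factors with uncertainties."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _REQUIRED_COLS if c not in self.table.columns]
        if missing:
            raise FixtureSchemaError(f"fixture missing columns: {missing}")
        self.table = self.table.sort_values("field_side_cm").reset_index(drop=True)
        if (self.table[list(_REQUIRED_COLS)] <= 0).any().any():
            raise FixtureSchemaError("field sides and perturbation factors must be positive")

    @classmethod
    def from_csv(cls, path) -> "PerturbationFixture":
        return cls(pd.read_csv(path, comment="#"))

    def interpolate(self, field_side, column: str):
        """Value at arbitrary field side, linear in log(side)."""
        s = np.log(np.asarray(field_side, dtype=float))
        grid = np.log(self.table["field_side_cm"].to_numpy())
        return np.interp(s, grid, self.table[column].to_numpy())


def chain_from_doses(fixture: PerturbationFixture) -> pd.DataFrame:
    """Perturbation factors from the four chain doses.

    Pscint = Dscint_w / Dscint (water-equivalent vs actual scintillator
    composition) and Pwall = Dscint / Ddet (bare sensitive volume vs full
    detector).  Requires all four dose columns.
    """
    t = fixture.table
    missing = [c for c in _DOSE_COLS if c not in t.columns]
    if missing:
        raise FixtureSchemaError(f"chain doses missing columns: {missing}")
    out = pd.DataFrame({
        "field_side_cm": t["field_side_cm"],
        "Pscint": t["Dscint_w"] / t["Dscint"],
        "Pwall": t["Dscint"] / t["Ddet"],
    })
    return out


@dataclass(frozen=True)
class CorrectionChainResult:
    """kQclin,Qmsr with its factor decomposition (all as clin/msr ratios)."""

    kvol: float
    Pscint: float
    Pwall: float
    kioq: float
    kQ: float
    uncertainties_pct: dict = field(default_factory=dict)


@dataclass(frozen=True)
class OutputFactorResult:
    M_ratio: float
    kQ: float
    Omega: float
    combined_uncertainty_pct: float = float("nan")


def assemble_kQ(kvol_ratio: float, Pscint_ratio: float, Pwall_ratio: float,
                kioq_ratio: float, uncertainties_pct: dict | None = None) -> CorrectionChainResult:
    """Output correction factor kQ = kvol * Pscint * Pwall * kioq (clin/msr ratios)."""
    for name, v in (("kvol", kvol_ratio), ("Pscint", Pscint_ratio),
                    ("Pwall", Pwall_ratio), ("kioq", kioq_ratio)):
        if v <= 0:
            raise InvalidInputError(f"{name} ratio must be positive")
    return CorrectionChainResult(
        kvol=float(kvol_ratio), Pscint=float(Pscint_ratio), Pwall=float(Pwall_ratio),
        kioq=float(kioq_ratio),
        kQ=float(kvol_ratio * Pscint_ratio * Pwall_ratio * kioq_ratio),
        uncertainties_pct=dict(uncertainties_pct or {}),
    )


def output_factor(M_ratio: float, kQ: float,
                  combined_uncertainty_pct: float = float("nan")) -> OutputFactorResult:
    """Field output factor Omega = M_ratio * kQ."""
    if M_ratio <= 0 or kQ <= 0:
        raise InvalidInputError("M_ratio and kQ must be positive")
    return OutputFactorResult(M_ratio=float(M_ratio), kQ=float(kQ),
                              Omega=float(M_ratio * kQ),
                              combined_uncertainty_pct=combined_uncertainty_pct)


def transfer_kQ(det1_M_ratio: float, det1_kQ: float, det2_M_ratio: float) -> float:
    """Transfer the output correction factor from a characterized detector.

    kQ(det2) = M_ratio(det1) * kQ(det1) / M_ratio(det2): both detectors see
    the same dose ratio, so det2's correction absorbs the reading difference.
    """
    if det2_M_ratio == 0:
        raise InvalidInputError("det2 reading ratio is zero")
    return det1_M_ratio * det1_kQ / det2_M_ratio
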