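"""Uncertainty budgets, field-size propagation and the fit-resampling band.

All uncertainty bookkeeping is at one standard deviation (k = 1), expressed
as relative percentages, and combined in quadrature (components are treated
as uncorrelated).  Three tools cover the needs of the output-factor
workflow:

* quadrature combination of labelled type A/B components per field size,
  mirroring the structure of published measurement-scenario budget tables;
* the field-size contribution: the derivative of a fitted reading-ratio (or
  kQ) curve times the equivalent-square-size determination uncertainty;
* a two-level Monte-Carlo resampler for the uncertainty band of a fitted
  kQ(S) curve, drawing one shared (systematic) relative deviation per
  iteration plus independent (random) per-point deviations, refitting, and
  taking the standard deviation of the refitted curves on a dense S grid.

Module constants carry the reference measurement-scenario component tables
for the scintillator probe (kQ determination and output-factor measurement
at 0.6x0.6, 1x1 and 2x2 cm^2) used by the reproduction tests; values are in
percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .fitting import fit_kq_curve, kq_model

__all__ = [
    "BudgetComponent",
    "Budget",
    "combine_quadrature",
    "fieldsize_contribution",
    "resample_fit_uncertainty",
    "build_budget_tables",
    "PSD_KQ_BUDGET_COMPONENTS",
    "PSD_OF_BUDGET_COMPONENTS",
]


@dataclass(frozen=True)
class BudgetComponent:
    label: str
    type: str  # "A" (statistical) or "B" (systematic estimate)
    value_pct: float
    applies_to: str = "all"

    def __post_init__(self):
        if self.type not in ("A", "B"):
            raise InvalidInputError("component type must be 'A' or 'B'")
        if self.value_pct < 0:
            raise InvalidInputError("uncertainty must be non-negative")


@dataclass
class Budget:
    """Labelled uncertainty components with their quadrature combination."""

    components: list[BudgetComponent] = field(default_factory=list)

    @property
    def combined_pct(self) -> float:
        return combine_quadrature([c.value_pct for c in self.components])

    @property
    def combined_pct_rounded(self) -> float:
        return round(self.combined_pct, 2)

    def to_rows(self):
        rows = [(c.label, c.type, c.value_pct) for c in self.components]
        rows.append(("Combined uncertainty (k=1)", "", self.combined_pct_rounded))
        return rows


def combine_quadrature(components) -> float:
    """Root-sum-square of relative uncertainties (all in percent)."""
    arr = np.asarray(list(components), dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cannot combine an empty component list")
    if np.any(arr < 0):
        raise InvalidInputError("components must be non-negative")
    return float(np.sqrt(np.sum(arr**2)))


def fieldsize_contribution(fit_curve, S: float, sigma_S: float, h: float | None = None) -> float:
    """Relative contribution (%) of the field-size uncertainty to a fitted curve.

    |d curve / dS| * sigma_S / curve(S) * 100, with the derivative taken
    numerically (central difference, step ``h`` defaulting to max(1e-4,
    1e-4*S) cm).  ``sigma_S`` is in cm.
    """
    if h is None:
        h = max(1e-4, 1e-4 * S)
    c0 = float(fit_curve(S))
    if c0 == 0:
        raise InvalidInputError("curve value is zero at S")
    deriv = (float(fit_curve(S + h)) - float(fit_curve(S - h))) / (2.0 * h)
    return abs(deriv) * sigma_S / abs(c0) * 100.0


def resample_fit_uncertainty(S_values, kQ_values, sigmas_random, sigma_systematic,
                             n_iter: int = 1000, seed=None, grid=None,
                             fit=fit_kq_curve, model=kq_model):
    """Two-level Monte-Carlo uncertainty band of the fitted kQ(S) curve.

    Per iteration a single standard-normal draw scales the shared relative
    systematic sigma (shifting every point together) and independent draws
    scale the per-point random sigmas; the perturbed points are refitted and
    the band is the standard deviation of the fitted curves evaluated on
    ``grid`` (default: 0.05 cm spacing over S in [0.5, 40] cm).
    Non-convergent iterations are dropped and counted; more than 5% dropped
    is a failure.

    Returns a dict with ``S_grid``, ``band`` (absolute, same units as kQ),
    ``n_dropped`` and the central fit.
    """
    S = np.asarray(S_values, dtype=float)
    y = np.asarray(kQ_values, dtype=float)
    sr = np.broadcast_to(np.asarray(sigmas_random, dtype=float), y.shape)
    if np.any(sr < 0) or sigma_systematic < 0:
        raise InvalidInputError("sigmas must be non-negative")
    if grid is None:
        grid = np.arange(0.5, 40.0 + 1e-9, 0.05)
    rng = np.random.default_rng(seed)

    central = fit(S, y)
    curves = []
    n_dropped = 0
    for _ in range(int(n_iter)):
        shared = rng.standard_normal() * sigma_systematic
        noise = rng.standard_normal(y.size) * sr
        y_i = y * (1.0 + shared + noise)
        res = fit(S, y_i)
        if not res.success:
            n_dropped += 1
            continue
        curves.append(model(grid, res.params))
    if n_dropped > 0.05 * n_iter:
        raise RuntimeError(f"{n_dropped}/{n_iter} resampling fits failed to converge")
    if curves:
        arr = np.asarray(curves)
        band = np.std(arr, axis=0, ddof=1)
        band[np.ptp(arr, axis=0) == 0.0] = 0.0  # identical refits: exactly zero
    else:
        band = np.zeros_like(grid)
    return {"S_grid": grid, "band": band, "n_dropped": n_dropped, "central_fit": central}


# --- reference measurement-scenario component tables (percent, k=1) --------
#
# kQ determination with the scintillator probe: Monte-Carlo statistical
# components for Pwall/Pscint/kioq, type B allowances for cross-sections and
# for geometry & density, and the experimental kvol statistics/geometry.
PSD_KQ_BUDGET_COMPONENTS: dict[str, list[tuple[str, str, float]]] = {
    "0.6": [
        ("Statistical Pwall", "A", 0.08), ("Statistical Pscint", "A", 0.07),
        ("Statistical kioq", "A", 0.36), ("Cross-section", "B", 0.2),
        ("Geometry and density", "B", 0.3),
        ("Statistical kvol (7 dets)", "A", 0.026), ("Geometry kvol", "B", 0.03),
    ],
    "1": [
        ("Statistical Pwall", "A", 0.09), ("Statistical Pscint", "A", 0.08),
        ("Statistical kioq", "A", 0.32), ("Cross-section", "B", 0.2),
        ("Geometry and density", "B", 0.3),
        ("Statistical kvol (7 dets)", "A", 0.009), ("Geometry kvol", "B", 0.005),
    ],
    "2": [
        ("Statistical Pwall", "A", 0.09), ("Statistical Pscint", "A", 0.08),
        ("Statistical kioq", "A", 0.30), ("Cross-section", "B", 0.2),
        ("Geometry and density", "B", 0.3),
        ("Statistical kvol (7 dets)", "A", 0.002), ("Geometry kvol", "B", 0.001),
    ],
}

# Output-factor measurement with the scintillator probe.  Top-level
# composition: the probe's kQ, the statistical reading-ratio component for
# the scenario, 0.1% stem and 0.1% other type B allowances, and the
# field-size determination contribution (derivative of the reading-ratio
# curve times sigma_Sclin).  Scenarios: "single" = one measurement with one
# detector; "multi" = seven detectors with two measurements each.
PSD_OF_BUDGET_COMPONENTS: dict[str, dict[str, list[tuple[str, str, float]]]] = {
    "single": {
        "0.6": [("kQ (PSD)", "B", 0.52), ("Statistical Mraw (1 meas)", "A", 0.29),
                ("kstem", "B", 0.1), ("kother", "B", 0.1),
                ("Sclin (1 centering)", "A", 0.75)],
        "1": [("kQ (PSD)", "B", 0.50), ("Statistical Mraw (1 meas)", "A", 0.16),
              ("kstem", "B", 0.1), ("kother", "B", 0.1),
              ("Sclin (1 centering)", "A", 0.22)],
        "2": [("kQ (PSD)", "B", 0.48), ("Statistical Mraw (1 meas)", "A", 0.11),
              ("kstem", "B", 0.1), ("kother", "B", 0.1),
              ("Sclin (1 centering)", "A", 0.05)],
    },
    "multi": {
        "0.6": [("kQ (PSD)", "B", 0.52), ("Statistical Mraw (7 dets x 2 meas)", "A", 0.08),
                ("kstem", "B", 0.1), ("kother", "B", 0.1),
                ("Sclin (7 centerings)", "A", 0.57)],
        "1": [("kQ (PSD)", "B", 0.50), ("Statistical Mraw (7 dets x 2 meas)", "A", 0.04),
              ("kstem", "B", 0.1), ("kother", "B", 0.1),
              ("Sclin (7 centerings)", "A", 0.16)],
        "2": [("kQ (PSD)", "B", 0.48), ("Statistical Mraw (7 dets x 2 meas)", "A", 0.03),
              ("kstem", "B", 0.1), ("kother", "B", 0.1),
              ("Sclin (7 centerings)", "A", 0.04)],
    },
}


def build_budget_tables(results: dict, scenario: str = "single_measurement",
                        kstem_pct: float = 0.1, kother_pct: float = 0.1) -> dict[str, Budget]:
    """Assemble per-field-size output-factor budgets from pipeline results.

    ``results`` maps a field-size label to a dict with keys ``kq_pct``
    (combined kQ uncertainty), ``mraw_stat_pct`` (statistical reading-ratio
    component for the chosen scenario) and ``fieldsize_pct`` (Sclin
    contribution via the curve derivative); optional ``extra`` holds
    additional (label, type, pct) triples.  The stem and "other influence
    quantities" allowances default to 0.1% each.  Composition rule: these
    five top-level terms combine in quadrature; per-measurement
    sub-components (readout reproducibility, jaw repositioning, positioning
    window) are already folded into the statistical terms and are reported
    only informationally by callers.
    """
    if scenario not in ("single_measurement", "multi_detector"):
        raise InvalidInputError(f"unknown scenario {scenario!r}")
    if not results:
        raise InvalidInputError("no field sizes provided")
    tag = "1 meas" if scenario == "single_measurement" else "multi det"
    out = {}
    for label, r in results.items():
        comps = [
            BudgetComponent("kQ", "B", float(r["kq_pct"])),
            BudgetComponent(f"Statistical Mraw ({tag})", "A", float(r["mraw_stat_pct"])),
            BudgetComponent("kstem", "B", kstem_pct),
            BudgetComponent("kother", "B", kother_pct),
            BudgetComponent("Field size (Sclin)", "A", float(r["fieldsize_pct"])),
        ]
        for extra in r.get("extra", ()):
            comps.append(BudgetComponent(*extra))
        out[label] = Budget(components=comps)
    return out
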