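"""Birks-law light yield and the ionization quenching correction factor.

Scintillation light production is reduced where the local ionization density
is high; the empirical Birks law writes the light yield of a charged particle
slowing from Emax to Emin inside the sensitive volume as

    L = sum_n integral_{Emin,n}^{Emax,n}  A / (1 + kB * L_Delta(E)) dE,

with A the scintillation efficiency (arbitrary units, cancelling in ratios),
kB the quenching strength (cm/MeV) and L_Delta the restricted linear
electronic stopping power of the scintillator with cutoff Delta (default
1 keV).  Low-energy secondary electrons — more abundant in large fields —
have higher stopping power and quench more, so the quenching correction

    kioq = [L_ideal / L_quenched]_clin / [L_ideal / L_quenched]_msr

depends on field size; it is the only beam-quality-dependent ("type II")
correction of the scintillator probe and enters the output correction factor.
The clin/msr ratio convention follows the factor's subscripts.

The default quenching strength is kB = 0.019 cm/MeV for polystyrene-based
scintillators, with 0.01 cm/MeV used for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator

from .errors import InvalidInputError

__all__ = [
    "QuenchingInput",
    "StoppingPowerTable",
    "BirksParameters",
    "light_yield",
    "kioq_ratio",
    "kB_sensitivity",
    "load_stopping_power",
    "synthetic_polystyrene_table",
]

DEFAULT_KB = 0.019  # cm/MeV
SENSITIVITY_KB = 0.01  # cm/MeV


@dataclass(frozen=True)
class BirksParameters:
    """Quenching strength kB (cm/MeV) and scintillation efficiency A."""

    kB: float = DEFAULT_KB
    A: float = 1.0

    def __post_init__(self):
        if self.kB < 0:
            raise InvalidInputError("kB must be non-negative")


@dataclass(frozen=True)
class QuenchingInput:
    """Per-field energy-deposition intervals of the charged particles.

    ``particles`` is an (N, 2) array of (Emin, Emax) in MeV — the energies at
    which each particle enters and leaves the sensitive volume — with
    optional multiplicities ``weights``.
    """

    field_side: float
    particles: tuple
    weights: tuple | None = None

    def arrays(self):
        p = np.asarray(self.particles, dtype=float).reshape(-1, 2)
        w = (np.ones(len(p)) if self.weights is None
             else np.asarray(self.weights, dtype=float))
        if len(w) != len(p):
            raise InvalidInputError("weights and particles length mismatch")
        if np.any(p[:, 1] <= p[:, 0]):
            raise InvalidInputError("every interval needs Emax > Emin")
        return p, w


class StoppingPowerTable:
    """Restricted linear electronic stopping power L_Delta(E) on an energy grid.

    Interpolation is monotone-preserving (PCHIP) in log-energy, so a
    monotone tabulation never yields spurious oscillations or negative
    values between grid points.
    """

    def __init__(self, energy_mev, l_delta_mev_per_cm, delta: float = 0.001):
        e = np.asarray(energy_mev, dtype=float)
        s = np.asarray(l_delta_mev_per_cm, dtype=float)
        if e.ndim != 1 or e.shape != s.shape:
            raise InvalidInputError("energy grid and stopping powers must be 1-D and matched")
        if np.any(np.diff(e) <= 0):
            raise InvalidInputError("energy grid must be strictly increasing")
        if np.any(s <= 0) or np.any(e <= 0):
            raise InvalidInputError("energies and stopping powers must be positive")
        self.energy = e
        self.l_delta = s
        self.delta = float(delta)
        self._interp = PchipInterpolator(np.log(e), s, extrapolate=False)

    def __call__(self, energy):
        energy = np.asarray(energy, dtype=float)
        out = self._interp(np.log(energy))
        if np.any(np.isnan(out)):
            raise InvalidInputError(
                f"energy outside table range [{self.energy[0]:g}, {self.energy[-1]:g}] MeV"
            )
        return out


def light_yield(qin: QuenchingInput, table: StoppingPowerTable,
                params: BirksParameters, quenched: bool = True) -> float:
    """Total Birks light yield of the recorded particles (arbitrary units).

    With ``quenched=False`` (or kB = 0) the integrand is the constant A and
    the yield reduces to A * sum of weighted interval lengths — the ideal,
    quenching-free yield.  Integration is adaptive in log-energy.
    """
    p, w = qin.arrays()
    if not quenched or params.kB == 0.0:
        return float(params.A * np.sum(w * (p[:, 1] - p[:, 0])))

    kB, A = params.kB, params.A

    def integrand(t):  # t = ln E
        e = np.exp(t)
        return e * A / (1.0 + kB * table(e))

    total = 0.0
    for (emin, emax), wt in zip(p, w):
        val, _ = quad(integrand, np.log(emin), np.log(emax), epsabs=0.0, epsrel=1e-9, limit=200)
        total += wt * val
    return float(total)


def kioq_ratio(clin: QuenchingInput, msr: QuenchingInput,
               table: StoppingPowerTable, params: BirksParameters) -> float:
    """Quenching correction kioq = (ideal/quenched)_clin / (ideal/quenched)_msr.

    Equal to 1 for identical spectra or kB = 0; independent of A.
    """
    ideal = BirksParameters(kB=0.0, A=params.A)
    num = light_yield(clin, table, ideal) / light_yield(clin, table, params)
    den = light_yield(msr, table, ideal) / light_yield(msr, table, params)
    return num / den


def kB_sensitivity(clin: QuenchingInput, msr: QuenchingInput, table: StoppingPowerTable,
                   kB_values=(DEFAULT_KB, SENSITIVITY_KB)) -> dict:
    """kioq for each candidate quenching strength, with the maximal spread."""
    values = {kb: kioq_ratio(clin, msr, table, BirksParameters(kB=kb)) for kb in kB_values}
    vals = list(values.values())
    return {"kioq": values, "max_spread": max(vals) - min(vals)}


# --- synthetic stopping-power fixture -------------------------------------

_ELECTRON_REST_MEV = 0.5109989461
# polystyrene (C8H8)n bulk properties
_PS_Z_OVER_A = 0.53768
_PS_I_MEV = 68.7e-6
_PS_DENSITY = 1.06  # g/cm^3


def synthetic_polystyrene_table(delta: float = 0.001, e_min: float = 0.001,
                                e_max: float = 10.0, n: int = 120) -> StoppingPowerTable:
    """Synthetic restricted collision stopping power of polystyrene.

    Computed from the standard restricted Moller (ICRU-form) collision
    stopping-power formula for electrons with Z/A = 0.53768, I = 68.7 eV and
    density 1.06 g/cm^3, cutoff Delta (default 1 keV); the density-effect
    term is omitted (a few-percent effect above ~1 MeV, immaterial for a
    synthetic fixture).  This is a physics-based stand-in generated by the
    package, not a transcription of a published tabulation.
    """
    e = np.geomspace(max(e_min, delta * (1 + 1e-9)), e_max, n)
    tau = e / _ELECTRON_REST_MEV
    beta2 = 1.0 - 1.0 / (1.0 + tau) ** 2
    eta = np.minimum(delta / e, 0.5)  # max transferable fraction is 1/2
    ln_term = np.log(tau**2 * (tau + 2.0) / (2.0 * (_PS_I_MEV / _ELECTRON_REST_MEV) ** 2))
    g = (-1.0 - beta2 + np.log(4.0 * (1.0 - eta) * eta) + 1.0 / (1.0 - eta)
         + (1.0 - beta2) * (tau**2 * eta**2 / 2.0 + (2.0 * tau + 1.0) * np.log(1.0 - eta)))
    mass_sp = 0.1535 * _PS_Z_OVER_A / beta2 * (ln_term + g)  # MeV cm^2 / g
    lin_sp = mass_sp * _PS_DENSITY  # MeV / cm
    if np.any(lin_sp <= 0):
        raise InvalidInputError("non-physical stopping power in requested range")
    return StoppingPowerTable(e, lin_sp, delta=delta)


def load_stopping_power(path=None, delta: float = 0.001) -> StoppingPowerTable:
    """Load a stopping-power CSV (columns energy_MeV, L_delta_MeV_per_cm).

    Without a path, the packaged synthetic polystyrene fixture is used.
    """
    if path is None:
        ref = resources.files("smallfield.data") / "polystyrene_restricted_stopping_power_synthetic.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    return StoppingPowerTable(df["energy_MeV"].to_numpy(),
                              df["L_delta_MeV_per_cm"].to_numpy(), delta=delta)
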