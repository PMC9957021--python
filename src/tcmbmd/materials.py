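"""Tabulated X-ray mass-attenuation curves for the phantom materials.

The package ships a small frozen table (``data/mass_attenuation.csv``,
10-150 keV on a 1 keV grid) for water, K2HPO4 salt and aluminum,
generated once from a two-basis parameterization of the elemental
compositions: a photoelectric term proportional to Z^4.62 / E^3 plus the
Klein-Nishina incoherent cross section, with the photoelectric constant
anchored to the reference water value at 30 keV.  The two-compartment
model cancels absolute attenuation scale, so a physically plausible
energy dependence is all the simulation requires.

K2HPO4 solutions are modelled additively: the salt adds attenuation on
top of water without displacing it,

    mu_sol(E) = mu_water(E) + c * m_salt(E)

with c the concentration (g/cm3) and m_salt the salt mass attenuation
(cm2/g).  This keeps the theoretical vBMD of a solution identical to
its concentration — the convention the phantom validation relies on —
at the cost of ignoring real water displacement (a fidelity limit, not
a correctness issue for the model's own consistency checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "MaterialAttenuation",
    "load_attenuation_table",
    "water",
    "k2hpo4_salt",
    "aluminum",
    "solution_attenuation",
]

_TABLE_CACHE: dict[str, np.ndarray] = {}


def load_attenuation_table() -> dict[str, np.ndarray]:
    """Load the frozen mass-attenuation table (cm2/g vs keV)."""
    if not _TABLE_CACHE:
        with resources.files("tcmbmd.data").joinpath("mass_attenuation.csv").open("rb") as fh:
            raw = np.genfromtxt(fh, delimiter=",", names=True)
        for name in raw.dtype.names:
            _TABLE_CACHE[name] = np.asarray(raw[name], dtype=float)
    return _TABLE_CACHE


@dataclass(frozen=True)
class MaterialAttenuation:
    """Energy-dependent linear attenuation of a homogeneous material.

    ``mass_atten`` is tabulated mass attenuation (cm2/g) on ``energies``
    (keV); ``density`` converts to linear attenuation (1/cm).
    """

    name: str
    energies: np.ndarray = field(repr=False)
    mass_atten: np.ndarray = field(repr=False)
    density: float = 1.0  # g/cm3

    def mu(self, energy_kev):
        """Linear attenuation coefficient (1/cm) at the given energies."""
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self.energies[0], self.energies[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(f"energy outside tabulated range [{lo}, {hi}] keV")
        return self.density * np.interp(e, self.energies, self.mass_atten)


def _material(column: str, name: str, density: float) -> MaterialAttenuation:
    tab = load_attenuation_table()
    return MaterialAttenuation(
        name=name, energies=tab["energy_kev"], mass_atten=tab[column], density=density
    )


def water() -> MaterialAttenuation:
    return _material("water", "water", 1.0)


def k2hpo4_salt() -> MaterialAttenuation:
    """The dissolved salt's mass attenuation at unit (1 g/cm3) density.

    Used only through the additive solution model; the nominal density
    of 1.0 means ``mu(E)`` returns the per-unit-concentration term.
    """
    return _material("k2hpo4", "K2HPO4", 1.0)


def aluminum() -> MaterialAttenuation:
    return _material("aluminum", "aluminum", 2.699)


def solution_attenuation(concentration: float, energy_kev) -> np.ndarray | float:
    """Linear attenuation (1/cm) of a K2HPO4 solution, additive-salt model.

    Linear in concentration at every energy; concentration 0 returns the
    attenuation of pure water.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    return water().mu(energy_kev) + concentration * k2hpo4_salt().mu(energy_kev)
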