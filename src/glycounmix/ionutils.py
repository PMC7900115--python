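"""Ion-chemistry bookkeeping: monoisotopic mass, adduct m/z, Mason-Schamp CCS.

These are the small exact computations that accompany IM-MS workflows:
summing most-abundant-isotope masses over an elemental formula, adding a
charge-carrier mass for [M+H]+, [M+Na]+ or [M+Ag]+ adducts, and converting
a reduced ion mobility K0 into an orientation-averaged collision cross
section via the Mason-Schamp equation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from scipy import constants as _const

__all__ = [
    "ElementalFormula",
    "AdductSpec",
    "MobilityConditions",
    "ADDUCTS",
    "GAS_MASSES",
    "monoisotopic_mass",
    "adduct_mz",
    "ccs_mason_schamp",
]

#: Most-abundant-isotope masses, Da.
ISOTOPE_MASSES: dict[str, float] = {
    "C": 12.000000,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "Na": 22.989770,
    "Ag": 106.905092,  # 107Ag
    "P": 30.973762,
    "S": 31.972071,
}

#: Buffer-gas masses, Da.
GAS_MASSES: dict[str, float] = {"He": 4.002602, "N2": 28.013406}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map, e.g. ElementalFormula.parse('C48H91NO8')."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for element, count in self.counts:
            if element not in ISOTOPE_MASSES:
                raise ValueError(f"unsupported element {element!r}")
            if count < 0 or int(count) != count:
                raise ValueError("element counts must be non-negative integers")

    @classmethod
    def parse(cls, formula: str) -> "ElementalFormula":
        pos = 0
        counts: dict[str, int] = {}
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos or not m.group(0):
                break
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(tuple(sorted(counts.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)


@dataclass(frozen=True)
class AdductSpec:
    """Singly charged adduct: name plus charge-carrier mass delta (Da).

    Deltas are cation masses (electron mass already removed), which is what
    makes computed m/z match printed 1-decimal values.
    """

    name: str
    mass_delta: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ValueError("only singly charged adducts are supported")


ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", 1.007276),
    "[M+Na]+": AdductSpec("[M+Na]+", 22.989218),
    "[M+Ag]+": AdductSpec("[M+Ag]+", 106.904548),  # 107Ag+
}


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Sum of most-abundant-isotope masses over the formula, Da."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    return sum(ISOTOPE_MASSES[el] * n for el, n in formula.counts)


def adduct_mz(mass: float, adduct: AdductSpec | str) -> float:
    """m/z of an adduct ion: (neutral mass + carrier mass) / charge."""
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ValueError(f"unknown adduct {adduct!r}") from None
    if mass <= 0:
        raise ValueError("mass must be positive")
    return round((mass + adduct.mass_delta) / adduct.charge, 4)


@dataclass(frozen=True)
class MobilityConditions:
    """Inputs for the Mason-Schamp conversion.

    k0 is the reduced mobility in cm^2 V^-1 s^-1 (referenced to 273.15 K
    and 760 Torr); temperature in K; gas and ion masses in Da.
    """

    k0: float
    temperature: float
    gas_mass: float
    ion_mass: float
    charge: int = 1

    def __post_init__(self) -> None:
        for name in ("k0", "temperature", "gas_mass", "ion_mass", "charge"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def ccs_mason_schamp(cond: MobilityConditions) -> float:
    """Collision cross section (A^2) from reduced mobility.

    Omega = 3 z e / (16 N0) * sqrt(2 pi / (mu kB T)) / K0, with mu the
    ion-gas reduced mass and N0 the buffer-gas number density at standard
    conditions (273.15 K, 760 Torr). Exactly inverse-proportional to K0.
    """
    amu = _const.atomic_mass
    mu = (cond.ion_mass * cond.gas_mass / (cond.ion_mass + cond.gas_mass)) * amu
    n0 = _const.atm / (_const.k * 273.15)  # Loschmidt constant, m^-3
    k0_si = cond.k0 * 1e-4  # cm^2/(V s) -> m^2/(V s)
    omega_m2 = (
        (3.0 * cond.charge * _const.e)
        / (16.0 * n0)
        * math.sqrt(2.0 * math.pi / (mu * _const.k * cond.temperature))
        / k0_si
    )
    return omega_m2 / 1e-20  # m^2 -> A^2
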