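"""Equilibrium SPME extraction calculator.

At equilibrium the analyte partitions between the fibre coating and the
aqueous sample with coating-matrix partition coefficient Kfs = Cf/Cs, and
the mass balance Co·Vs = Cf·Vf + Cs·Vs gives the extracted mass

    Mf = Kfs·Co·Vs·Vf / (Kfs·Vf + Vs)

Units are the caller's responsibility but must be self-consistent
(volumes in one unit, concentration in mass per that unit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

__all__ = ["ExtractionSystem", "ExtractionResult", "extracted_mass", "fraction_extracted"]


@dataclass(frozen=True)
class ExtractionSystem:
    """Two-phase coating/water system at sorption equilibrium.

    kfs : dimensionless coating-water partition coefficient (>= 0)
    c0 : initial aqueous concentration (mass/volume, >= 0)
    vf : coating volume (> 0)
    vs : sample volume (> 0, same unit as vf)
    """

    kfs: float
    c0: float
    vf: float
    vs: float

    def __post_init__(self):
        if self.kfs < 0:
            raise ValueError("kfs must be non-negative")
        if self.c0 < 0:
            raise ValueError("c0 must be non-negative")
        if self.vf <= 0 or self.vs <= 0:
            raise ValueError("vf and vs must be positive")


class ExtractionResult(NamedTuple):
    mf: float  # mass sorbed by the coating
    cf: float  # equilibrium coating concentration
    cs: float  # residual aqueous concentration


def extracted_mass(system: ExtractionSystem) -> ExtractionResult:
    """Equilibrium extracted mass and phase concentrations.

    Closed form of the linear-isotherm mass balance; satisfies
    Cf·Vf + Cs·Vs = Co·Vs to floating-point tolerance.
    """
    denom = system.kfs * system.vf + system.vs
    cs = system.c0 * system.vs / denom
    cf = system.kfs * cs
    mf = cf * system.vf
    return ExtractionResult(mf=mf, cf=cf, cs=cs)


def fraction_extracted(system: ExtractionSystem) -> float:
    """Fraction of the total analyte mass sorbed by the coating.

    Kfs·Vf / (Kfs·Vf + Vs): increasing in Kfs and Vf, decreasing in Vs.
    """
    return system.kfs * system.vf / (system.kfs * system.vf + system.vs)
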