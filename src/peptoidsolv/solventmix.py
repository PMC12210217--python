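"""THF/water composition conventions and the virtual solvent unit.

Experimental and simulated mixed-solvent systems are described in several
interchangeable conventions — THF mass fraction, THF molarity (moles of THF
per litre of water), THF volume fraction — all of which reduce to a single
dimensionless THF/water molar ratio. The assembly-energy bookkeeping treats
one THF molecule plus the composition-matched number of water molecules as a
single "virtual" solvent unit, so that solvent boxes of different
compositions can be compared on an equal per-unit footing.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import MW_THF, MW_WATER, RHO_THF, RHO_WATER, WATER_MOLARITY

__all__ = [
    "SolventComposition",
    "VirtualUnit",
    "molar_ratio_from_mass_fraction",
    "molar_ratio_from_molarity",
    "molar_ratio_from_volume_fraction",
    "virtual_unit",
    "composition_record",
]


@dataclass(frozen=True)
class SolventComposition:
    """A THF/water mixture identified by its THF/water molar ratio.

    ``thf_water_molar_ratio`` is 0 for pure water and ``math.inf`` for pure
    THF; any nonnegative value in between is a mixture.
    """

    thf_water_molar_ratio: float
    label: str = ""

    def __post_init__(self) -> None:
        r = self.thf_water_molar_ratio
        if math.isnan(r) or r < 0:
            raise ValueError(f"molar ratio must be >= 0 or inf, got {r}")

    @property
    def is_pure_water(self) -> bool:
        return self.thf_water_molar_ratio == 0

    @property
    def is_pure_thf(self) -> bool:
        return math.isinf(self.thf_water_molar_ratio)


@dataclass(frozen=True)
class VirtualUnit:
    """Composition of one virtual solvent unit.

    For any mixture containing THF the unit holds one THF molecule and
    ``1/ratio`` water molecules (fractional counts are intentional); pure
    water uses one water molecule per unit.
    """

    n_thf: int
    n_water: float


def _check_fraction(x: float, name: str) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")


def molar_ratio_from_mass_fraction(w_thf: float) -> float:
    """THF/water molar ratio from the THF mass fraction.

    r = (w/MW_THF) / ((1-w)/MW_water). Returns ``inf`` for w=1 (pure THF).
    """
    _check_fraction(w_thf, "mass fraction")
    if w_thf == 1.0:
        return math.inf
    return (w_thf / MW_THF) / ((1.0 - w_thf) / MW_WATER)


def mass_fraction_from_molar_ratio(ratio: float) -> float:
    """Inverse of :func:`molar_ratio_from_mass_fraction`."""
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if math.isinf(ratio):
        return 1.0
    m_thf = ratio * MW_THF
    return m_thf / (m_thf + MW_WATER)


def molar_ratio_from_molarity(c_thf: float) -> float:
    """THF/water molar ratio from moles of THF per litre of water.

    The denominator is the molarity of pure water computed from the
    constants table (1000 * rho_water / MW_water ~ 55.34 mol/L).
    """
    if c_thf < 0:
        raise ValueError(f"molarity must be >= 0, got {c_thf}")
    return c_thf / WATER_MOLARITY


def molar_ratio_from_volume_fraction(phi_thf: float) -> float:
    """THF/water molar ratio from the THF volume fraction (ideal mixing)."""
    _check_fraction(phi_thf, "volume fraction")
    if phi_thf == 1.0:
        return math.inf
    return (phi_thf * RHO_THF / MW_THF) / ((1.0 - phi_thf) * RHO_WATER / MW_WATER)


def virtual_unit(comp: SolventComposition) -> VirtualUnit:
    """The virtual solvent unit for a composition.

    Mixtures with ratio r > 0 map to (1 THF, 1/r water); pure water to
    (0, 1); pure THF to (1, 0).
    """
    if comp.is_pure_water:
        return VirtualUnit(0, 1.0)
    if comp.is_pure_thf:
        return VirtualUnit(1, 0.0)
    return VirtualUnit(1, 1.0 / comp.thf_water_molar_ratio)


def composition_record(
    mass_fraction: float | None = None,
    molarity: float | None = None,
    volume_fraction: float | None = None,
    label: str = "",
) -> dict:
    """All-conventions record for a composition given in any one convention.

    Exactly one of the three inputs must be provided. Returns a plain dict
    (JSON-serialisable apart from ``inf`` for pure THF).
    """
    given = [x is not None for x in (mass_fraction, molarity, volume_fraction)]
    if sum(given) != 1:
        raise ValueError("provide exactly one of mass_fraction, molarity, volume_fraction")
    if mass_fraction is not None:
        ratio = molar_ratio_from_mass_fraction(mass_fraction)
    elif molarity is not None:
        ratio = molar_ratio_from_molarity(molarity)
    else:
        ratio = molar_ratio_from_volume_fraction(volume_fraction)
    comp = SolventComposition(ratio, label=label)
    unit = virtual_unit(comp)
    return {
        "label": label,
        "thf_water_molar_ratio": ratio,
        "mass_fraction_thf": mass_fraction_from_molar_ratio(ratio),
        "virtual_unit": {"n_thf": unit.n_thf, "n_water": unit.n_water},
    }
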