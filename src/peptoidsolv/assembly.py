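"""Per-molecule assembly-energy statistic and stability profiles.

The stability of a peptoid nanostructure in a solvent is scored by the
per-molecule assembly energy

    e(A in S) = [E(N*A in M*S) - M*e(S)] / N

where E(N*A in M*S) is the potential energy of N peptoid molecules immersed
in M virtual solvent units and e(S) is the per-unit potential energy of the
equilibrated solvent-only box. Lower values mean a more stable assembly.
The statistic is gauge-invariant: shifting the per-unit solvent energy by a
constant (and the system energy by M times that constant) leaves it
unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnergyRecord",
    "SolventReference",
    "solvent_reference",
    "assembly_energy",
    "assembly_profile",
    "block_average",
]


@dataclass(frozen=True)
class EnergyRecord:
    """Time-averaged potential energy of a peptoid-in-solvent system.

    Parameters
    ----------
    label : structure class, e.g. "isolated", "6-mer stack", "nanosheet".
    solvent_label : solvent the system was simulated in.
    n_peptoid : number of peptoid molecules N (>= 1).
    m_units : number of virtual solvent units M in the box (> 0).
    e_total : potential energy E(N*A in M*S), kJ/mol.
    """

    label: str
    solvent_label: str
    n_peptoid: int
    m_units: float
    e_total: float

    def __post_init__(self) -> None:
        if self.n_peptoid < 1:
            raise ValueError("n_peptoid must be >= 1")
        if self.m_units <= 0:
            raise ValueError(
                "m_units must be > 0; the statistic is defined relative to "
                "solvent and vacuum systems are rejected"
            )


@dataclass(frozen=True)
class SolventReference:
    """Per-unit potential energy e(S) of an equilibrated solvent-only box."""

    e_per_unit: float
    solvent_label: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.e_per_unit):
            raise ValueError("e_per_unit must be finite")


def solvent_reference(e_box: float, m_units: float, solvent_label: str = "") -> SolventReference:
    """e(S) from the total energy of a solvent-only box of M virtual units."""
    if m_units <= 0:
        raise ValueError(f"m_units must be > 0, got {m_units}")
    return SolventReference(e_per_unit=e_box / m_units, solvent_label=solvent_label)


def assembly_energy(rec: EnergyRecord, ref: SolventReference) -> float:
    """Per-molecule assembly energy of one system, kJ/mol.

    Raises ``ValueError`` if the record and reference solvent labels differ.
    """
    if rec.solvent_label != ref.solvent_label:
        raise ValueError(
            f"solvent mismatch: record is {rec.solvent_label!r}, "
            f"reference is {ref.solvent_label!r}"
        )
    return (rec.e_total - rec.m_units * ref.e_per_unit) / rec.n_peptoid


def assembly_profile(
    records: Iterable[EnergyRecord],
    refs: Mapping[str, SolventReference],
    class_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assembly-energy profile across structure classes and solvents.

    Returns a tidy frame with one row per (structure class, solvent):
    columns ``label``, ``solvent_label``, ``n_peptoid``, ``assembly_energy``
    and ``delta_from_previous`` (the energy change from the previous
    structure class in ``class_order`` within the same solvent; NaN for the
    first class). ``class_order`` defaults to first-appearance order of the
    input records; the output does not depend on input record order beyond
    that default.
    """
    records = list(records)
    for rec in records:
        if rec.solvent_label not in refs:
            raise ValueError(f"no solvent reference for {rec.solvent_label!r}")
    rows = [
        {
            "label": rec.label,
            "solvent_label": rec.solvent_label,
            "n_peptoid": rec.n_peptoid,
            "assembly_energy": assembly_energy(rec, refs[rec.solvent_label]),
        }
        for rec in records
    ]
    df = pd.DataFrame(rows)
    if class_order is None:
        class_order = list(dict.fromkeys(df["label"]))
    df["label"] = pd.Categorical(df["label"], categories=class_order, ordered=True)
    df = df.sort_values(["solvent_label", "label"]).reset_index(drop=True)
    df["delta_from_previous"] = df.groupby("solvent_label", observed=True)[
        "assembly_energy"
    ].diff()
    return df


def block_average(series: np.ndarray, n_blocks: int = 5) -> tuple[float, float]:
    """Mean and standard error of a per-frame energy series by block averaging.

    The series is split into ``n_blocks`` equal contiguous blocks (a trailing
    remainder is dropped); the standard error is std(block means)/sqrt(n).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < n_blocks:
        raise ValueError(f"need a 1-D series with at least {n_blocks} frames")
    usable = (len(series) // n_blocks) * n_blocks
    blocks = series[:usable].reshape(n_blocks, -1)
    means = blocks.mean(axis=1)
    return float(series.mean()), float(means.std(ddof=1) / np.sqrt(n_blocks))
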