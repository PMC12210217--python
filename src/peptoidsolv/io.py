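"""Readers and writers for the formats the analysis modules consume.

Coordinate files (PDB/GRO/XYZ, single- or multi-frame) go through
MDAnalysis; tabular inputs through pandas. Umbrella-sampling input follows
the common "metadata file" layout: one line per window with the time-series
path, window center (nm) and optionally the force constant, each series
file holding two whitespace-separated columns (time, CV).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assembly import EnergyRecord, SolventReference
from .conformation import Conformation
from .pmf import DEFAULT_FORCE_CONSTANT, PMFResult, UmbrellaWindow
from .solvation import DensityMap

__all__ = [
    "read_conformations",
    "write_conformation_pdb",
    "read_energy_records",
    "read_solvent_references",
    "read_umbrella_metadata",
    "write_pmf_tsv",
    "write_density_grid",
    "write_density_dx",
    "write_json",
]

HEAVY_ATOMS = "not name H* and not name 1H* and not name 2H* and not name 3H*"


def read_conformations(
    path: str | Path,
    selection: str = HEAVY_ATOMS,
    label: str = "",
    solvent_label: str = "",
) -> list[Conformation]:
    """One :class:`Conformation` per frame of a PDB/GRO/XYZ file.

    ``selection`` is an MDAnalysis selection string choosing the backbone
    heavy atoms (all heavy atoms by default; XYZ files carry no residue
    information, so use name-based selections there).
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    try:
        atoms = u.select_atoms(selection)
    except Exception:
        atoms = u.atoms
    if len(atoms) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms in {path}")
    out = []
    for i, _ in enumerate(u.trajectory):
        out.append(
            Conformation(
                atoms.positions.astype(float),
                label=label or f"{Path(path).stem}_{i}",
                solvent_label=solvent_label,
            )
        )
    return out


def write_conformation_pdb(conf: Conformation, path: str | Path,
                           element: str = "C") -> None:
    """Write a conformation as a minimal single-chain PDB."""
    import MDAnalysis as mda

    n = conf.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", [f"{element}{i+1}" for i in range(n)])
    u.add_TopologyAttr("elements", [element] * n)
    u.add_TopologyAttr("resnames", ["PEP"])
    u.atoms.positions = conf.coords
    u.atoms.write(str(path))


def read_energy_records(path: str | Path) -> list[EnergyRecord]:
    """Energy records from a CSV with columns label, solvent_label,
    n_peptoid, m_units, e_total."""
    df = pd.read_csv(path)
    required = {"label", "solvent_label", "n_peptoid", "m_units", "e_total"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        EnergyRecord(
            label=str(r.label),
            solvent_label=str(r.solvent_label),
            n_peptoid=int(r.n_peptoid),
            m_units=float(r.m_units),
            e_total=float(r.e_total),
        )
        for r in df.itertuples()
    ]


def read_solvent_references(path: str | Path) -> dict[str, SolventReference]:
    """Solvent references from a CSV with columns solvent_label and either
    e_per_unit or (e_box, m_units)."""
    df = pd.read_csv(path)
    refs = {}
    for r in df.itertuples():
        if hasattr(r, "e_per_unit") and np.isfinite(getattr(r, "e_per_unit")):
            e = float(r.e_per_unit)
        else:
            e = float(r.e_box) / float(r.m_units)
        refs[str(r.solvent_label)] = SolventReference(e, str(r.solvent_label))
    return refs


def read_umbrella_metadata(meta_path: str | Path,
                           default_force_constant: float = DEFAULT_FORCE_CONSTANT
                           ) -> list[UmbrellaWindow]:
    """Umbrella windows from a metadata file.

    Each non-comment line: ``series_path center [force_constant]``; paths
    are resolved relative to the metadata file. Series files have two
    whitespace-separated columns (time, CV in nm).
    """
    meta_path = Path(meta_path)
    windows = []
    for line in meta_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        series = meta_path.parent / parts[0]
        center = float(parts[1])
        k = float(parts[2]) if len(parts) > 2 else default_force_constant
        data = np.loadtxt(series)
        cv = data[:, 1] if data.ndim == 2 else np.atleast_1d(data)
        windows.append(UmbrellaWindow(center=center, samples=cv, force_constant=k,
                                      meta={"series": str(series)}))
    if not windows:
        raise ValueError(f"{meta_path}: no windows found")
    return windows


def write_pmf_tsv(result: PMFResult, path: str | Path,
                  std: np.ndarray | None = None) -> None:
    """PMF as TSV: bin center (nm), free energy (kJ/mol), optional std."""
    df = result.summary()
    if std is not None:
        df["pmf_std"] = std
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_density_grid(dmap: DensityMap, path: str | Path) -> None:
    """Plain-text density grid: header lines then one voxel per row."""
    nx, ny, nz = dmap.density.shape
    with open(path, "w") as fh:
        fh.write(f"# species {dmap.species} g/cm^3, grid {nx} {ny} {nz}\n")
        fh.write("# voxel_lengths_A "
                 + " ".join(f"{v:.6g}" for v in dmap.voxel_lengths) + "\n")
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    fh.write(f"{i} {j} {k} {dmap.density[i, j, k]:.6g}\n")


def write_density_dx(dmap: DensityMap, path: str | Path) -> None:
    """OpenDX scalar-field export for visualization tools."""
    nx, ny, nz = dmap.density.shape
    dx, dy, dz = dmap.voxel_lengths
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {dx/2:.6g} {dy/2:.6g} {dz/2:.6g}",
        f"delta {dx:.6g} 0 0",
        f"delta 0 {dy:.6g} 0",
        f"delta 0 0 {dz:.6g}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx*ny*nz} data follows",
    ]
    flat = dmap.density.ravel()
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6g}" for v in flat[i:i + 3]))
    lines.append('object "density" class field')
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path: str | Path) -> None:
    """JSON writer tolerant of numpy scalars/arrays."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
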