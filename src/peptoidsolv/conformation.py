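"""Backbone conformational metrics and internal-distance featurization.

A :class:`Conformation` is an ordered list of backbone heavy-atom positions
(N-terminus first, Angstrom). The landscape pipeline featurizes each
conformation as its internal distance matrix — the distances from every atom
to the first three ("anchor") atoms — which is exactly invariant under rigid
motions, embeds the features with UMAP, clusters the 2-D landscape, and
reconstructs an average conformation per cluster by trilateration from the
mean feature (see :mod:`peptoidsolv.landscape`).

Distances to three anchors cannot encode chirality, so reconstruction is
defined up to a global mirror; the trilateration sign is resolved by
backbone bond-length continuity (target 1.5 A).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import BACKBONE_BOND

__all__ = [
    "Conformation",
    "rmsd",
    "kabsch_rotation",
    "radius_of_gyration",
    "end_to_end",
    "featurize",
    "reconstruct",
    "rmsd_histogram",
    "aggregate_rg_series",
]

SOURCES = ("isolated", "dimer_C", "dimer_O", "fiber_C", "sheet")


@dataclass
class Conformation:
    """Ordered backbone heavy-atom coordinates with provenance labels."""

    coords: np.ndarray  # (n_atoms, 3), Angstrom
    label: str = ""
    source: str = "isolated"
    solvent_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(self.coords) < 4:
            raise ValueError("a conformation needs at least 4 atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


def _as_coords(obj) -> np.ndarray:
    if isinstance(obj, Conformation):
        return obj.coords
    return np.asarray(obj, dtype=float)


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation (det = +1) minimising ||R P - Q|| for centred P, Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def rmsd(conf, ref) -> float:
    """Minimum RMSD between two equal-length conformations, Angstrom.

    Minimised over translations and proper rotations only (Kabsch);
    reflections are excluded so mirror images give a nonzero value.
    """
    P = _as_coords(conf)
    Q = _as_coords(ref)
    if P.shape != Q.shape:
        raise ValueError(f"atom-count mismatch: {P.shape} vs {Q.shape}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    R = kabsch_rotation(Pc, Qc)
    diff = Pc @ R.T - Qc
    return float(np.sqrt((diff**2).sum() / len(P)))


def radius_of_gyration(coords, masses=None) -> float:
    """Mass-weighted radius of gyration, Angstrom.

    ``masses`` defaults to uniform weights. All masses must be positive.
    """
    r = _as_coords(coords)
    if r.ndim != 2 or len(r) < 1:
        raise ValueError("need at least one atom")
    if masses is None:
        m = np.ones(len(r))
    else:
        m = np.asarray(masses, dtype=float)
        if m.shape != (len(r),) or np.any(m <= 0):
            raise ValueError("masses must be positive, one per atom")
    com = (m[:, None] * r).sum(axis=0) / m.sum()
    sq = ((r - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * sq).sum() / m.sum()))


def end_to_end(conf) -> float:
    """Distance between the first and last backbone heavy atoms, Angstrom."""
    r = _as_coords(conf)
    if len(r) < 2:
        raise ValueError("need at least 2 atoms")
    return float(np.linalg.norm(r[-1] - r[0]))


def featurize(conf) -> np.ndarray:
    """Internal distance matrix: distances of every atom to the first three.

    Returns an (n_atoms, 3) array whose (i, j) entry is |r_i - r_j| for
    anchor j in {0, 1, 2}. Includes the anchor rows themselves, so the
    feature is self-contained for reconstruction. Invariant under rigid
    motions. If the three anchors are collinear (within 1e-6 A of a line) a
    warning is emitted; featurization still proceeds.
    """
    r = _as_coords(conf)
    if len(r) < 4:
        raise ValueError("need at least 4 atoms")
    anchors = r[:3]
    cross = np.cross(anchors[1] - anchors[0], anchors[2] - anchors[0])
    base = np.linalg.norm(anchors[1] - anchors[0])
    if base > 0 and np.linalg.norm(cross) / base < 1e-6:
        warnings.warn("anchor atoms 1-3 are nearly collinear; reconstruction "
                      "from this feature will be ill-conditioned")
    diff = r[:, None, :] - anchors[None, :, :]
    return np.linalg.norm(diff, axis=2)


def reconstruct(mean_feature: np.ndarray, bond_target: float = BACKBONE_BOND,
                tol: float = 1e-6) -> Conformation:
    """Rebuild a conformation from an internal distance matrix.

    Atom 1 is placed at the origin, atom 2 on +x, atom 3 in the xy-plane
    with y > 0; every later atom is trilaterated from its distances to the
    three anchors. The sign of z (the mirror ambiguity of trilateration) is
    chosen to bring the bond to the previous atom closest to ``bond_target``,
    with z >= 0 on ties. Slightly infeasible distances (squared-z below zero
    by more than ``tol``) are clamped to the plane and flagged in
    ``meta["reconstruction_flags"]``.
    """
    F = np.asarray(mean_feature, dtype=float)
    if F.ndim != 2 or F.shape[1] != 3 or F.shape[0] < 4:
        raise ValueError("feature must have shape (n_atoms >= 4, 3)")
    n = F.shape[0]
    d21 = F[1, 0]
    d31, d32 = F[2, 0], F[2, 1]
    coords = np.zeros((n, 3))
    coords[1] = [d21, 0.0, 0.0]
    if d21 <= 0:
        raise ValueError("anchor atoms 1 and 2 coincide; cannot reconstruct")
    x3 = (d31**2 - d32**2 + d21**2) / (2 * d21)
    y3_sq = d31**2 - x3**2
    if y3_sq <= 0:
        raise ValueError("anchor distances are collinear or infeasible")
    coords[2] = [x3, np.sqrt(y3_sq), 0.0]
    y3 = coords[2, 1]
    flags: list[int] = []
    for i in range(3, n):
        d1, d2, d3 = F[i]
        x = (d1**2 - d2**2 + d21**2) / (2 * d21)
        y = (d1**2 - d3**2 + x3**2 + y3**2 - 2 * x * x3) / (2 * y3)
        z_sq = d1**2 - x**2 - y**2
        # cancellation noise floor of the squared-distance arithmetic: below
        # it z is indistinguishable from 0 and snapping keeps planar inputs
        # exactly planar
        noise_floor = 100 * np.finfo(float).eps * (d1**2 + x**2 + y**2)
        if z_sq < -tol:
            flags.append(i)
            z = 0.0
        elif z_sq < noise_floor:
            z = 0.0
        else:
            z = np.sqrt(z_sq)
        # resolve the mirror ambiguity by backbone bond continuity
        prev = coords[i - 1]
        b_plus = np.linalg.norm([x - prev[0], y - prev[1], z - prev[2]])
        b_minus = np.linalg.norm([x - prev[0], y - prev[1], -z - prev[2]])
        if abs(b_minus - bond_target) < abs(b_plus - bond_target):
            z = -z
        coords[i] = [x, y, z]
    meta = {"reconstruction_flags": flags, "mirror_ambiguous": True}
    return Conformation(coords, label="reconstructed", meta=meta)


def rmsd_histogram(
    confs: Iterable[Conformation],
    ref: Conformation,
    bin_width: float = 0.5,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Normalized RMSD-to-reference histograms grouped by solvent label.

    Bins are left-closed right-open with the given width starting at 0.
    Returns ``{solvent_label: (bin_edges, density)}`` with densities
    integrating to 1.
    """
    confs = list(confs)
    by_solvent: dict[str, list[float]] = {}
    for c in confs:
        by_solvent.setdefault(c.solvent_label, []).append(rmsd(c, ref))
    out = {}
    for solvent, values in by_solvent.items():
        vmax = max(values)
        n_bins = max(1, int(np.floor(vmax / bin_width)) + 1)
        edges = np.arange(n_bins + 1) * bin_width
        density, edges = np.histogram(values, bins=edges, density=True)
        out[solvent] = (edges, density)
    return out


def aggregate_rg_series(
    frames: Sequence[np.ndarray], masses=None
) -> tuple[np.ndarray, float, float]:
    """Per-frame radius of gyration of all pooled atoms, with mean and std.

    ``frames`` is a sequence of (n_atoms, 3) coordinate arrays (one array of
    every peptoid atom in the agglomerate per frame). Returns (series, mean,
    std) with std over frames (population std, ddof=0).
    """
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    series = np.array([radius_of_gyration(f, masses) for f in frames])
    return series, float(series.mean()), float(series.std())
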