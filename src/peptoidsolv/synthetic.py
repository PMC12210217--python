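"""Synthetic inputs with known ground truth for every analysis module.

Real inputs to this package come from long explicit-solvent MD runs; the
generators here replace them with geometric and statistical idealizations
whose planted parameters the analysis modules must recover:

* backbone conformational families interpolating between a coiled C-shape
  (a 300 degree circular arc), a semi-open arc (150 degrees) and a fully
  extended planar zig-zag, with isotropic Gaussian positional noise;
* multi-chain agglomerates for radius-of-gyration trends;
* solvated frames in which water fills the box uniformly while THF carries
  a planted distance-dependent surface enhancement;
* biased collective-variable samples drawn by Metropolis Monte Carlo from
  analytic 1-D potentials under harmonic window restraints;
* assembly-energy tables with an exact planted per-molecule energy.

All generators are deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assembly import EnergyRecord, SolventReference
from .constants import BACKBONE_BOND, MW_THF, MW_WATER, kT
from .conformation import Conformation, end_to_end
from .pmf import DEFAULT_FORCE_CONSTANT, UmbrellaWindow
from .solvation import SolvatedFrame, surface_distances

__all__ = [
    "make_backbone",
    "make_conformation_set",
    "make_agglomerate_frames",
    "make_solvated_frame",
    "Flat",
    "Linear",
    "DoubleWell",
    "sample_umbrella",
    "make_energy_table",
]

SHAPES = ("coiled_C", "semi_open", "extended")
_ARC_DEGREES = {"coiled_C": 300.0, "semi_open": 150.0}


def _arc_chain(n_atoms: int, arc_deg: float, bond: float) -> np.ndarray:
    """Planar circular arc with equal chord lengths between atoms."""
    theta = np.radians(arc_deg)
    seg = theta / (n_atoms - 1)
    radius = bond / (2.0 * np.sin(seg / 2.0))
    angles = seg * np.arange(n_atoms)
    xy = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    return np.column_stack([xy, np.zeros(n_atoms)])


def _zigzag_chain(n_atoms: int, bond: float, angle_deg: float = 120.0) -> np.ndarray:
    """Planar zig-zag with the given backbone bond angle."""
    half = np.radians(180.0 - angle_deg) / 2.0
    dx, dy = bond * np.cos(half), bond * np.sin(half)
    x = dx * np.arange(n_atoms)
    y = dy * (np.arange(n_atoms) % 2)
    return np.column_stack([x, y, np.zeros(n_atoms)])


def make_backbone(
    n_atoms: int = 20,
    shape: str = "coiled_C",
    target_end_to_end: float | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> Conformation:
    """One idealized backbone conformation.

    ``target_end_to_end`` rescales the template uniformly so the noise-free
    end-to-end distance hits the target exactly (e.g. 26 A for the maximally
    extended decyl-block backbone).
    """
    if n_atoms < 4:
        raise ValueError("need at least 4 atoms")
    if shape in _ARC_DEGREES:
        coords = _arc_chain(n_atoms, _ARC_DEGREES[shape], BACKBONE_BOND)
    elif shape == "extended":
        coords = _zigzag_chain(n_atoms, BACKBONE_BOND)
    else:
        raise ValueError(f"unknown shape {shape!r}; choose from {SHAPES}")
    if target_end_to_end is not None:
        e2e = end_to_end(coords)
        if target_end_to_end <= 0 or e2e == 0:
            raise ValueError(f"unreachable target end-to-end {target_end_to_end}")
        coords = coords * (target_end_to_end / e2e)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
    return Conformation(
        coords,
        label=label or shape,
        meta={"shape": shape, "seed": seed, "noise_sigma": noise_sigma},
    )


def make_conformation_set(
    families: Sequence[tuple], seed: int = 0
) -> list[Conformation]:
    """Labelled set of noisy conformations from several template families.

    Each family is ``(template, count, noise_sigma)`` where template is a
    shape name or a :class:`Conformation`. The planted family index is
    stored in ``meta["family"]`` for downstream clustering scores.
    """
    rng = np.random.default_rng(seed)
    out: list[Conformation] = []
    for fam_idx, (template, count, sigma) in enumerate(families):
        if count < 1:
            raise ValueError("family counts must be >= 1")
        if isinstance(template, Conformation):
            base = template.coords
            name = template.label or f"family{fam_idx}"
        else:
            base = make_backbone(shape=template).coords
            name = template
        for j in range(count):
            coords = base + rng.normal(0.0, sigma, base.shape) if sigma > 0 else base.copy()
            out.append(
                Conformation(
                    coords,
                    label=f"{name}_{j}",
                    meta={"family": fam_idx, "family_name": name, "seed": seed},
                )
            )
    return out


def make_agglomerate_frames(
    n_chains: int = 6,
    n_frames: int = 10,
    scale: float = 1.0,
    noise_sigma: float = 0.3,
    seed: int = 0,
) -> list[np.ndarray]:
    """Frames of a multi-chain agglomerate for radius-of-gyration analysis.

    Chains are coiled backbones placed on a sphere of radius proportional to
    ``scale``; tighter agglomerates (smaller scale) have smaller Rg.
    """
    rng = np.random.default_rng(seed)
    base = make_backbone(shape="coiled_C").coords
    centers = rng.normal(size=(n_chains, 3))
    centers *= 10.0 * scale / np.linalg.norm(centers, axis=1, keepdims=True)
    frames = []
    for _ in range(n_frames):
        coords = np.concatenate(
            [base + c + rng.normal(0.0, noise_sigma, base.shape) for c in centers]
        )
        frames.append(coords)
    return frames


def make_solvated_frame(
    solute: Conformation,
    n_thf: int = 648,
    n_water: int = 9000,
    box: float | Sequence[float] = 60.0,
    enhancement: tuple[float, float] | None = None,
    seed: int = 0,
    contact_distance: float = 2.0,
) -> SolvatedFrame:
    """A solvated frame with an optional planted THF surface enhancement.

    Water centers fill the box uniformly outside the solute's excluded
    volume (no solvent center closer than ``contact_distance`` to a solute
    atom, emulating van der Waals contact). Without ``enhancement`` THF
    does too; with ``enhancement=(factor, decay)`` THF positions are
    accepted by rejection sampling with weight
    1 + (factor-1) * exp(-d/decay), d being the minimal periodic distance
    to the solute surface, so the local THF/water molar ratio at distance
    d >= contact_distance is bulk_ratio * that weight.
    """
    box_arr = np.broadcast_to(np.asarray(box, float), (3,)).copy()
    volume = float(np.prod(box_arr))
    if (n_thf + n_water) > 0.05 * volume:  # liquid water is ~0.033 mol/A^3
        raise ValueError("box overfilled for point-center solvent placement")
    rng = np.random.default_rng(seed)
    solute_wrapped = np.mod(solute.coords, box_arr)
    probe = SolvatedFrame(
        solute_coords=solute_wrapped,
        solvent_centers=np.zeros((1, 3)),
        species=np.array(["THF"]),
        masses=np.array([MW_THF]),
        box=box_arr,
    )

    def _distances(pos: np.ndarray) -> np.ndarray:
        probe.solvent_centers = pos
        probe.species = np.full(len(pos), "THF")
        probe.masses = np.full(len(pos), MW_THF)
        return surface_distances(probe)

    def _draw(n: int, weight=None) -> np.ndarray:
        accepted: list[np.ndarray] = []
        while len(accepted) < n:
            n_draw = max(4 * (n - len(accepted)), 64)
            pos = rng.uniform(0.0, 1.0, (n_draw, 3)) * box_arr
            d = _distances(pos)
            keep = d >= contact_distance
            if weight is not None:
                w, w_max = weight(d)
                keep &= rng.uniform(0.0, w_max, n_draw) < w
            accepted.extend(pos[keep])
        return np.array(accepted[:n])

    water = _draw(n_water)
    if enhancement is None or n_thf == 0:
        thf = _draw(n_thf) if n_thf > 0 else np.empty((0, 3))
    else:
        factor, decay = enhancement
        if factor < 1 or decay <= 0:
            raise ValueError("enhancement needs factor >= 1 and decay > 0")
        thf = _draw(
            n_thf,
            weight=lambda d: (1.0 + (factor - 1.0) * np.exp(-d / decay), factor),
        )

    centers = np.vstack([thf, water]) if len(thf) else water
    species = np.array(["THF"] * len(thf) + ["water"] * n_water)
    masses = np.array([MW_THF] * len(thf) + [MW_WATER] * n_water)
    return SolvatedFrame(
        solute_coords=solute_wrapped,
        solvent_centers=centers,
        species=species,
        masses=masses,
        box=box_arr,
        meta={"seed": seed, "enhancement": enhancement},
    )


@dataclass(frozen=True)
class Flat:
    """Zero potential everywhere (null landscape)."""

    def __call__(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class Linear:
    """U(x) = slope * x, kJ/mol."""

    slope: float

    def __call__(self, x):
        return self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class DoubleWell:
    """Symmetric quartic double well with barrier height exactly ``dg``.

    U(x) = 16*dg*(u^2 - u)^2 with u = (x - a)/L: minima at x = a and
    x = a + L (U = 0), barrier dg at the midpoint.
    """

    dg: float
    a: float = 0.5
    L: float = 1.0

    def __call__(self, x):
        u = (np.asarray(x, dtype=float) - self.a) / self.L
        return 16.0 * self.dg * (u * u - u) ** 2

    @property
    def barrier_position(self) -> float:
        return self.a + 0.5 * self.L


def sample_umbrella(
    potential,
    windows: Sequence[float],
    force_constant: float = DEFAULT_FORCE_CONSTANT,
    n_per_window: int = 5000,
    temperature: float = 300.0,
    seed: int = 0,
    target_acceptance: tuple[float, float] = (0.3, 0.5),
    thin: int = 10,
) -> list[UmbrellaWindow]:
    """Metropolis samples of exp[-(U + w_k)/kT] for each harmonic window.

    All window chains advance in lockstep (vectorized proposals). The step
    size is adapted per window during the burn-in (10% of the chain,
    discarded) toward the target acceptance band; the realised acceptance
    rate over the production phase is recorded in each window's metadata.
    Chains are thinned by ``thin`` steps between kept samples to reduce
    autocorrelation. CV values are kept strictly positive.
    """
    if n_per_window < 100:
        raise ValueError("need at least 100 samples per window")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    centers = np.asarray(windows, dtype=float)
    rng = np.random.default_rng(seed)
    kt = kT(temperature)
    n_burn = int(np.ceil(n_per_window / 9.0))  # 10% of the total chain

    def energy(x):
        return potential(x) + 0.5 * force_constant * (x - centers) ** 2

    x = centers.copy()
    e = energy(x)
    step = np.full(len(centers), np.sqrt(kt / force_constant))
    accepted = np.zeros(len(centers))
    samples = np.empty((n_per_window, len(centers)))
    lo_acc, hi_acc = target_acceptance
    window_acc = np.zeros(len(centers))
    n_prod = n_per_window * thin
    for i in range(n_burn + n_prod):
        prop = x + rng.normal(0.0, 1.0, len(centers)) * step
        valid = prop > 0
        e_prop = np.where(valid, energy(np.where(valid, prop, x)), np.inf)
        accept = valid & (rng.uniform(size=len(centers)) < np.exp(
            np.clip((e - e_prop) / kt, -700, 0)
        ))
        x = np.where(accept, prop, x)
        e = np.where(accept, e_prop, e)
        if i < n_burn:
            window_acc += accept
            if (i + 1) % 50 == 0:  # crude Robbins-Monro step tuning
                rate = window_acc / 50.0
                step *= np.where(rate < lo_acc, 0.7, np.where(rate > hi_acc, 1.4, 1.0))
                window_acc[:] = 0.0
        else:
            accepted += accept
            j, rem = divmod(i - n_burn + 1, thin)
            if rem == 0:
                samples[j - 1] = x
    rates = accepted / n_prod
    if np.any(rates == 0):
        raise ValueError("zero Metropolis acceptance in at least one window")
    return [
        UmbrellaWindow(
            center=float(c),
            samples=samples[:, k],
            force_constant=force_constant,
            meta={"acceptance": float(rates[k]), "seed": seed,
                  "temperature": temperature},
        )
        for k, c in enumerate(centers)
    ]


def make_energy_table(
    epsilon_per_molecule: float,
    e_solvent_unit: float,
    systems: Sequence[tuple[int, float]],
    solvent_label: str = "synthetic",
    labels: Sequence[str] | None = None,
) -> tuple[list[EnergyRecord], SolventReference]:
    """Energy records with an exact planted per-molecule assembly energy.

    Each (N, M) system gets e_total = N*epsilon + M*e_solvent_unit, so the
    assembly-energy statistic recovers epsilon exactly for every system.
    """
    if labels is None:
        labels = [f"system_{n}x{m:g}" for n, m in systems]
    records = [
        EnergyRecord(
            label=lab,
            solvent_label=solvent_label,
            n_peptoid=n,
            m_units=m,
            e_total=n * epsilon_per_molecule + m * e_solvent_unit,
        )
        for lab, (n, m) in zip(labels, systems)
    ]
    ref = SolventReference(e_per_unit=e_solvent_unit, solvent_label=solvent_label)
    return records, ref
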