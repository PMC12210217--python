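# Methods

`peptoidsolv` implements the post-simulation analyses used to characterise
evaporation-induced self-assembly of an amphiphilic diblock polypeptoid
(acetyl-capped Ndc10-Nte10: a crystalline poly(N-decylglycine) block and an
amorphous oligo-ether-substituted block) in THF/water mixtures. Real inputs
are long explicit-solvent MD trajectories; the package ships synthetic-data
generators with planted ground truth so every analysis can be validated
end-to-end without them. This note records the models, the parameters that
matter, the numerical choices, and what validation on synthetic data does
and does not establish.

## Solvent composition and the virtual solvent unit

A THF/water mixture is reduced to the dimensionless THF/water molar ratio
`r` (0 = pure water, ∞ = pure THF). Conversions from mass fraction,
molarity and volume fraction assume ideal mixing and use one constants
table: MW(THF) = 72.11, MW(water) = 18.015 g/mol; ρ(THF) = 0.889,
ρ(water) = 0.997 g/mL at 25 °C. Molarity is interpreted as moles of THF
per litre of **water**, divided by the molarity of pure water computed
from the same constants (1000·0.997/18.015 ≈ 55.34 mol/L); the per-litre-
of-solution reading would give ≈ 0.107 for 4 M instead of the 0.072 this
convention (and the reference compositions 0.25 / 0.072 / 0.012 for
~50 wt% / 4 M / 5 vol%) yields.

For energy bookkeeping across compositions, one THF molecule plus `1/r`
water molecules form a single *virtual solvent unit*; pure water uses one
water molecule per unit. Water counts per unit are deliberately fractional
— no rounding is applied anywhere.

## Assembly energy

The stability score of a nanostructure of N peptoid molecules in a box of
M virtual solvent units with total potential energy E is

    e(A in S) = [E − M·e(S)] / N        (kJ/mol per molecule)

where e(S) is the per-unit energy of an equilibrated solvent-only box.
The statistic is exactly gauge-invariant under a constant shift per
solvent unit and scale-invariant in N; both properties are tested to
machine precision. Vacuum systems (M = 0) are rejected: the statistic is
defined relative to solvent. When a per-frame energy series is supplied,
block averaging (5 equal contiguous blocks) attaches a standard error;
time-averaged inputs are accepted as-is. Profiles across structure classes
(isolated → stacks → nanofibers → nanosheet) report the class-to-class
energy change per solvent, e.g. the nanofiber → nanosheet drop.

## Conformational metrics and the landscape pipeline

Backbone conformations are ordered heavy-atom coordinate lists (N-terminus
first, Å). RMSD minimises over translations and **proper** rotations only
(Kabsch with the determinant correction); reflections are excluded so a
mirror image scores nonzero — chirality changes are not faked away.
Radius of gyration is mass-weighted; end-to-end distance is the first-to-
last-atom distance (the coiled C-shaped backbone sits near ~9 Å, the
maximally extended decyl-block backbone near 26 Å).

**Featurization.** Each conformation maps to its internal distance matrix:
the (n × 3) array of distances from every atom to the first three atoms.
This is exactly invariant under rigid motions. The three anchor rows are
included, making the feature self-contained for reconstruction (the
alternative of dropping them loses nothing but breaks invertibility).
Anchor collinearity (within 1e-6 Å of a line) is warned about, not fatal.

**Reconstruction.** Atom 1 at the origin, atom 2 on +x, atom 3 in the
xy-plane (y > 0); each later atom is trilaterated from its three anchor
distances. Distances to three anchors cannot encode chirality, so the
sign of z is ambiguous per atom; it is resolved by bond-length continuity
(choose the sign whose bond to the previous atom is closer to the 1.5 Å
idealised backbone bond, z ≥ 0 on ties), which yields the original or its
global mirror for consistent chains. Two numerical guards matter: (i) a
z² more negative than 1e-6 (infeasible distances, e.g. from averaging
incompatible features) is clamped to the plane and flagged in the output
metadata; (ii) |z²| below the cancellation noise floor of the squared-
distance arithmetic (100·eps·d²) is snapped to exactly 0, which keeps
planar inputs planar and makes the featurize→reconstruct roundtrip exact
to ~1e-13 Å RMSD instead of ~1e-7.

**Embedding and clustering.** Features are flattened and embedded in 2-D
with UMAP (15 neighbours, min_dist 0.0); the embedding is clustered with
HDBSCAN (minimum cluster size 10, minimum core-point neighbours 3, merge
distance 0.2, noise label −1). The embedding seed (default 42) is recorded
in the result; UMAP layouts differ across library versions, so all
comparisons are made within a single run. Cluster population fractions
use **all** samples — noise included — as the denominator, so fractions
plus the noise fraction sum to 1. Each cluster is summarised by the
conformation reconstructed from its mean feature and that conformation's
end-to-end distance.

## Preferential solvation

The "peptoid surface" is the nearest selected solute heavy atom under
minimum-image periodic wrapping — the same convention as the umbrella-
sampling collective variable, so the two analyses agree about what
"distance from the surface" means. Solvent molecules are binned by that
distance (1 Å bins by default) into left-closed right-open shells up to a
bulk cutoff (20 Å default); everything beyond the cutoff defines the bulk
THF/water ratio, and per-shell enhancement is shell ratio over bulk ratio.
Only orthorhombic boxes are supported.

Because a histogram reports bin averages, the raw first-bin enhancement of
an exponentially decaying profile is biased low by the decay within the
bin (≈ 3.1 observed for a planted surface factor of 3.5 decaying over
3 Å). The surface amplitude is therefore recovered by fitting the
analytically bin-averaged model 1 + (A − 1)·exp(−d/λ) to the measured
per-shell enhancements, weighted by Poisson errors; the fit returns A and
λ directly and is unbiased at the tested sizes.

Density maps deposit each solvent center's molecular mass into the voxel
containing it (grid chosen as round(box/voxel) per axis so per-frame mass
is conserved exactly), average over frames, and convert amu/Å³ → g/cm³.
Isolevel masks at 0.5/0.3/0.2/0.1 g/cm³ are nested by construction.

## Umbrella sampling and WHAM

The adsorption collective variable is the smooth minimum distance
s = β / ln Σᵢ exp(β/sᵢ) with β = 100 over the THF–Ndc atom distances. It
reduces exactly to s₁ for a single distance and converges to the true
minimum from below, monotonically in β. (A published variant with β·sᵢ
inside the exponential is dimensionally inconsistent and does not reduce
correctly for one distance; this package uses the standard smooth-minimum
convention.)

The production window schedule is 0.35–4.4 nm in 0.05 nm steps under the
half-open convention — 81 windows — with force constant 3000 kJ/mol/nm².
The WHAM solver iterates the standard self-consistent equations on
histogram counts (Jacobi simultaneous update of the window free energies
f_k, log-space accumulation throughout, f₀ pinned to 0 each sweep) until
max|Δf_k| < tol·kT with tol = 1e-8; k_B = 0.0083144621 kJ/mol/K. Bins
with zero samples stay NaN. The PMF −kT·ln p is anchored to zero at its
minimum over the adsorbed region (CV ≤ 1 nm by default), matching how a
desorption cost is read off; the desorption cost is the mean over the
last 0.5 nm of defined bins (the bulk plateau, with a 1 kT/nm slope
warning when no plateau exists) minus that adsorbed minimum. Replicate
uncertainty re-anchors each replicate before aggregating, so constant
offsets (the gauge freedom of a free-energy profile) do not inflate the
spread. Empty windows are dropped with a warning; non-overlapping
adjacent windows trigger a gap report.

## Synthetic data: what it emulates and what it does not

* **Backbones** are geometric idealizations: the coiled C-shape is a 300°
  circular arc, the semi-open form a 150° arc, the extended form a planar
  zig-zag with 1.5 Å bonds (uniformly rescaled when a target end-to-end
  distance such as 26 Å is requested), plus isotropic Gaussian noise.
  They exercise featurization, embedding, clustering, reconstruction and
  the metrics — they are not force-field minimised structures, carry no
  side chains, and their family separation is cleaner than a real REST2
  ensemble's. A passing landscape test shows the pipeline recovers
  planted structure at realistic noise (σ = 0.3 Å), not that real
  conformational families are this well separated.
* **Solvated frames** place point-center solvent molecules (THF 72.11,
  water 18.015 amu, no internal geometry) uniformly outside a 2 Å
  excluded-volume contact shell around the solute, in a 60 Å cubic box at
  near-liquid number density (9000 water + 648 THF, bulk ratio 0.072 — the
  4 M composition). The planted enhancement multiplies the THF acceptance
  probability by 1 + (factor − 1)·exp(−d/decay). Recovery tests use a
  factor of 3.5 (the observed-scale surface enrichment) with a 6 Å decay,
  400 frames for the planted fit and 600 for the uniform null; these sizes
  put every populated shell's Poisson error well below the ±0.1 band the
  null check uses. Real solvent structuring (orientation, hydrogen
  bonding, layering oscillations) is not emulated.
* **Biased CV samples** come from vectorised Metropolis chains sampling
  exp[−(U + ½K(ξ−c)²)/kT], step size adapted to 30–50 % acceptance during
  a discarded 10 % burn-in, thinned by 10 steps between kept samples to
  suppress autocorrelation, ξ kept strictly positive, acceptance rates
  recorded. The analytic double well U = 16·ΔG·(u²−u)², u = (ξ−a)/L, has
  barrier height exactly ΔG. The WHAM benchmark uses 10 windows spanning
  0.35–1.65 nm with K = 200 kJ/mol/nm² (≈1.3 σ window spacing, chosen for
  healthy histogram overlap at this coarser spacing; the production
  K = 3000 pairs with the finer 0.05 nm spacing) and 5000 samples per
  window. At these sizes a planted 5 kJ/mol barrier is recovered to
  ≲0.1 kJ/mol and a flat potential reconstructs flat to ≲0.15 kT.
* **Energy tables** plant e_total = N·ε + M·e(S) exactly, so the assembly
  statistic must return ε to machine precision for every (N, M).

All generators are bit-reproducible given their seed.

## Problem sizes

The shipped tests and the reproduction script run at desk scale: 10
umbrella windows × 5000 samples × 3 seeds, 180-conformation landscapes
over 3–5 seeds, 400/600 solvated frames. These sizes were chosen so each
recovery's sampling error sits comfortably inside its stated tolerance;
all are parameters, and larger runs only tighten the estimates.

## Known limitations

* WHAM evaluates the bias at bin centers; with very stiff springs and
  coarse bins this discretisation biases the PMF (visible above
  K·σ·Δbin ≈ kT). Choose bins accordingly; no MBAR estimator is provided.
* Reconstruction from three anchors is blind to chirality (global mirror
  returned for chiral inputs) and degrades when anchors are nearly
  collinear.
* The enhancement fit assumes the single-exponential decay form; layered
  (oscillatory) solvation shells would need a different model.
* Triclinic boxes, per-atom solvent binning beyond the provided option,
  autocorrelation-aware PMF error bars, and torsion-space analyses are
  out of scope.
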