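# Methods

This note documents the models, conventions and numerical choices behind
`allosite`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate conventions and superposition

All coordinates are in Å; residues are addressed as `(chain_id,
residue_seq)` with numbering taken verbatim from the input file.  Hydrogens
are kept on read but excluded from every "heavy atom" operation.  Backbone
is `{N, CA, C, O}`; CB counts as side chain.

Frames from all conditions are concatenated into one receptor-only super
trajectory (ligand atoms are dropped from the shared topology, since not
every condition carries them) and superposed by the Kabsch algorithm with
the SVD sign correction, guaranteeing a proper rotation.  The fitting frame
is an *invariant core* found iteratively: superpose all frames on the mean
structure of the current candidate residues (three mean-refit sweeps),
compute each residue's mean positional variance over its backbone atoms,
drop the most mobile residue, and repeat until either every survivor's
variance is below a threshold (default 0.1 Ų, i.e. ≈0.3 Å RMS) or a floor
of `ceil(target_fraction · n_residues)` residues (default fraction 0.5) is
reached.  Ties break toward keeping the lower residue number, so the result
is deterministic.  The original core-identification method's exact stopping
parameters are not published alongside the rest of the protocol; both knobs
are therefore explicit configuration, and the defaults make no claim to
match any particular earlier analysis.

Distances, contact counts and re-centred pocket volumes are invariant under
rigid motions, so the pipeline computes them on aligned coordinates purely
for consistency; only the PCA genuinely requires the shared frame.

## Site definition

A residue belongs to the agonist site when at least one of its heavy atoms
lies strictly within the cutoff (default 4.5 Å) of any ligand heavy atom.
Heavy atoms are used on both sides because crystallographic inputs commonly
lack hydrogens; the boundary is open (`< cutoff`), so an atom pair at
exactly 4.5 Å does not qualify.  Both choices are tested, including exact
agreement with a brute-force all-pairs scan.

## Site PCA

The covariance of the 3N Cartesian coordinates of the site's heavy atoms
(side chains included, no mass weighting) is computed over all frames of
the aligned super trajectory with the sample convention (ddof = 1) and
diagonalised with a symmetric eigensolver.  Fitting on the concatenation —
never per condition — puts all conditions in one shared component space.
Eigenvalues are clipped at zero; eigenvector signs follow a deterministic
convention (largest-magnitude component positive).  Per-condition spread in
PC1–PC2 is summarised by the convex-hull area of the projections.

## Pocket volume

The region of interest (ROI) is a sphere of radius 10 Å centred on the
unweighted mean of the site residues' heavy-atom coordinates, re-centred
every frame so the estimate tracks the site's own cavity (a fixed centre is
available as configuration).  A cubic grid (default spacing 0.5 Å) spans
the ROI bounding box; a cell is free iff its centre is inside the sphere
and strictly farther than the element's van der Waals radius (Bondi-style:
C 1.70, N 1.55, O 1.52, S/P 1.80 Å, default 1.70 Å) from every heavy atom,
ligand atoms included — so an occupied pocket yields the smallest volumes.
No solvent-probe inflation is applied by default.  The cell-centre test
converges cleanly: halving the spacing changes the volume by ≈0.1 % on the
synthetic receptor, and the analytic empty-sphere and single-atom cases
agree within 1 % at 0.25 Å spacing.  An independent Monte-Carlo
rejection-sampling estimator (uniform points in the ball, direct distance
test) provides a cross-check; grid and MC agree within 3 standard errors at
10⁶ samples.  Volume distributions are summarised by a Gaussian KDE with
Scott's-rule bandwidth on a grid extending four bandwidths past the sample
range.

## Geometric states

Two observables summarise the pocket per frame: the perimeter of a triangle
spanned by one Cα and two side-chain atoms across the pocket, and one
Cα–Cα distance between two site residues.  Labels use strict inequalities —
closed: perimeter < 16 Å and distance < 8 Å; open: > 21 Å and > 13 Å;
anything else, boundaries included, is intermediate.  Side-chain distances
are minima over heavy-atom pairs excluding the backbone; glycine has no
side-chain heavy atom and is rejected in side-chain mode rather than
silently substituted.

Correlation scans report plain Pearson r between every site residue-pair
distance (both modes) and the per-frame volume, sorted by |r|; pairs with
zero variance are skipped.  Contact frequencies for user-supplied residue
pairs use the closest heavy atoms of the *whole* residues (backbone
included), matching the consensus-contact convention, again with a strict
4.5 Å cutoff.

## Protein structure networks

For residues i, j the interaction strength is `I_ij = 100 · n_ij /
√(N_i·N_j)` (percent), with `n_ij` the number of side-chain heavy-atom
pairs strictly closer than 4.5 Å and `N` residue-type normalization values.
Residues three or fewer sequence positions apart in the same chain are
"adjacent" and skipped; inter-chain pairs never are.  The shipped
normalization table (`allosite/data/psn_normalization.tsv`) carries the
residue-type values distributed with the Wordom implementation of the
method; because analyses depend on these values only up to this table, a
`uniform` mode (all N equal) exists for method-independent testing, and the
table is user-replaceable.  Per-frame matrices are averaged over a
trajectory, optionally restricted to frames in a given conformational
state; differences of two averages are reported as signed matrices plus an
edge list ranked by |ΔI|.

Matrix PCA flattens each condition's symmetric matrix to its strict upper
triangle, centres across conditions, and decomposes by SVD.  All components
are kept by default, so Euclidean distances between condition scores equal
distances between the raw flattened matrices (a 2-PC mode exists for
plotting).  Conditions are grouped by agglomerative single linkage; with
four conditions the package reports k = 2 clusters.

## The synthetic-data generator

The generator emulates the statistical structure of a four-condition
receptor study at desk scale.  The receptor is a ring of seven ideal
helices (radius 11 Å, eight residues each, rise 1.5 Å, twist 100°, Cα helix
radius 2.3 Å) with 1–4 pseudo side-chain heavy atoms per residue carrying
real residue names, so the normalization table, glycine handling and
side-chain selection logic are all exercised.  Two anchor conformations
share one topology:

* **closed** — three marker atoms (Cα of a threonine; the CH2 of a
  tryptophan and CD2 of a histidine, i.e. the classic pocket-floor
  aromatic/imidazole pair) form an equilateral 15 Å-perimeter triangle, and
  two marker Cαs sit 7 Å apart;
* **open** — one designated helix (the "TM2-like" mobile element, residues
  9–16) is displaced 7 Å outward along its radial direction and the two
  rotamer tips swing 3 Å outward, giving a ≈25.7 Å perimeter, a 14 Å pair
  distance, and a strictly larger pocket volume.

Margins to the classification thresholds are ≥1 Å, so with the default
coordinate noise (σ = 0.1–0.15 Å per coordinate; distance noise ≈ σ√2) the
planted label is recovered in ≥99 % of frames.  Hidden states follow a
two-state Markov chain with stationary open probability `p_open` and a
persistence parameter (default 0.8) so state-conditioned averaging operates
on contiguous segments, as it would on correlated simulation frames; an
`intermediate_fraction` of frames is replaced by linear interpolations at
λ ∈ (0.3, 0.7), which land in the intermediate band of both observables.
`build_anchors` verifies the planted classification of both anchors and
fails loudly on construction errors.

The four suite conditions are: `free` (p_open = 0.3, σ = 0.15,
10 % intermediates — the largest motion amplitude), `miniG` and `alpha5`
(pinned closed, σ = 0.10, 5 % intermediates, and a shared planted rewiring
of five intracellular contact pairs whose side chains are repositioned into
4-atom-pair contact blocks), and `miniG_agonist` (pinned closed, σ = 0.08,
no intermediates, pocket occluded by an 11-atom elongated ligand analogue).
Two construction choices keep the planted truths cleanly recoverable and
are deliberate stylisations: the bottom helix layer is glycine-rich so
nothing but the planted pairs contributes contacts in the rewiring zone,
and the agonist condition carries the ligand but *not* the partner
rewiring pattern — each suite condition isolates one mechanistic
ingredient, which is what lets k = 2 clustering isolate exactly the two
pattern-sharing conditions.  The marker residues are placed by direct
coordinate override, so their bond geometry is schematic.

A separate correlation benchmark plants a known distance–volume coupling:
a standard-normal latent coordinate moves the two marker residues apart
along their separation axis (amplitude b = 1 Å) over coordinate noise
σ = 0.35 Å, and drives a synthetic volume series with independent Gaussian
noise solved from `r = b·c / (√(b² + 2σ²)·√(c² + s²))` so the population
correlation of the planted pair is exactly the target (0.7).  Because the
measurement noise is non-negligible, partially coupled pairs correlate
strictly weaker (≈0.56 at best), and the planted pair ranks first in the
scan.  The volume series here is synthesised, not grid-computed: the
benchmark isolates the correlation-scan estimator from the volume
estimator, which has its own analytic and Monte-Carlo checks.

### What the synthetic benchmarks do not show

The generator plants geometric and statistical structure, not physics: no
excluded-volume enforcement between residues, no realistic backbone
geometry at the marker overrides, harmonic-free white coordinate noise
rather than correlated thermal motion, and per-frame states rather than
kinetics.  Passing tests demonstrate that the estimators recover planted
truth at the stated sizes and tolerances — not that any particular real
receptor behaves this way, and not that results on μs-scale membrane
simulations would be statistically converged.

## Problem sizes and tolerances

The shipped test suite and the acceptance script use: 120–300 frames per
suite condition (states, volumes, hulls, networks, clustering), 2000 frames
for state-occupancy recovery (±0.03 on the open fraction) and for the
correlation benchmark (±0.05 on r), 10⁶ Monte-Carlo samples (3-SE
agreement), 0.25 Å grids for the analytic volume checks (1 %), and 20
random frames of 20–50 residues for exact (≤1e-9) PSN agreement with a
quadruple-loop reference.  Determinism is exact: a fixed seed reproduces
trajectories bit-for-bit, and two pipeline runs on the same inputs produce
byte-identical summaries.
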