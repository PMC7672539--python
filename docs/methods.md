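# Methods

This note documents the models, conventions and design choices behind
ensdyn in enough detail to reproduce or audit any number the package
prints. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate handling and superposition

Ensembles are stored as a flat atom table plus an `(n_models, n_atoms, 3)`
coordinate stack in Angstrom. Atomic masses and van der Waals radii come
from a fixed internal element table (IUPAC 2021 masses; Bondi radii with
the Rowland–Taylor value 1.10 Å for H), so results are reproducible
bit-for-bit with no external parameter source. Alternate locations keep
the highest-occupancy conformer; insertion codes are rejected. Replica
identifiers travel in `REMARK 299` header lines or a sidecar JSON.

All covariance-based quantities are computed after iterative superposition:
each model is Kabsch-fitted (proper rotations only) to the mean of a fit
group, the mean is recomputed, and iteration stops when the mean moves less
than 1e-6 Å RMS (max 100 iterations; non-convergence is a warning, not an
error). The iteration is seeded with the raw coordinate mean, which makes
fitting idempotent; if that mean is rank-deficient (models carrying
arbitrary rigid transforms can average out), the first model seeds instead.
Fit groups: backbone atoms for entropy (mass-weighted fit), the Cα
selection itself for mode analysis (unweighted). The consensus frame of an
iterative fit is defined only up to a global rotation; all reported
quantities are invariant to it.

## Order parameters

S² is the second-moment expression over the ensemble-averaged dyadic of
the unit bond vector. It is exact for rigid vectors (S² = 1), invariant
under μ → −μ, and for vectors uniformly distributed on a cone rim of
semi-angle θ has the closed form S² = 3/2 (sin⁴θ/2 + cos⁴θ) − 1/2, which
the synthetic generator uses as its analytic ground truth. Methyl-group
dynamics are represented by the symmetry-axis vector (heavy-atom neighbour
→ methyl carbon); no proton-geometry scaling is applied by default because
published side-chain comparisons do not always state their convention —
`methyl_axis_scale` (e.g. 0.111) exposes the alternative. Vectors
unresolvable in a residue (no amide proton, no methyl) are absent rows,
not errors. Comparisons against experimental tables are computed per
vector class: Pearson r, RMSD, n and per-residue residuals, requiring at
least 3 shared keys.

## Conformational entropy

The covariance is the population (1/N) covariance of the fitted
heavy-atom coordinates — the normalization matters because Schlitter
values depend on it, so it is fixed and echoed into reports. Both
estimators operate on the eigenvalues λ_i (amu Å², converted to SI
internally) of M^½ σ M^½:

* Schlitter: S = (k_B/2) Σ ln(1 + k_B T e² λ_i/ħ²), an upper bound that
  exceeds the quasi-harmonic value mode by mode;
* quasi-harmonic: each mode is a quantum harmonic oscillator with
  ω_i = √(k_B T/λ_i).

Eigenvalues below 1e-12 amu Å² are skipped (numerical noise or sample-rank
deficiency; a vanishing variance contributes no entropy either way).
Temperature defaults to 300 K and is configurable; values are reported per
mole (J mol⁻¹ K⁻¹), with J/K available. The binding-entropy ratio
(S_cd − S_fd)/(S_cf − S_ff) uses Schlitter by default (the quasi-harmonic
route is a flag) and is traced over prefixes of 10%, 20%, …, 100% of each
state's models in stored order — the order is provenance-defined (replica
blocks, matching concatenated-trajectory practice). A denominator below a
configurable tolerance is a hard "degenerate" error.

With n models and 3N coordinate dimensions of similar magnitude, sample
covariance eigen-spectra are strongly biased and absolute entropies are
systematically underestimated; the *ratio* is far more robust because the
spectrum distortion largely cancels between states that differ mainly by a
covariance scale. This is why the designed ratio is recovered within a few
percent at n = 808 while per-state entropies sit ~13% below their analytic
values, and why the ratio — not absolute entropies — is the validated
statistic.

## Modes and state partition

PCA is performed on pooled Cα coordinates (ProDy-style convention;
selection configurable) after fitting the pooled set to its own mean.
Modes with eigenvalue ≤ 1e-9 Å² are dropped. Eigenvector signs are
arbitrary, so each mode is oriented such that the reference ensembles
(default: state labels starting with "c", i.e. the complex states) have
non-positive mean projection; the positive sides of modes 1 and 2 are then
named "open" and "narrow". Conformers are labelled by the sign of their
projection against a per-mode threshold (default 0 Å); a projection exactly
at the threshold goes to the negative side (deterministic tie-break).

Co-occurrence of the two binary states has no canonical definition; we
report

    co = max( P(open∧narrow) + P(closed∧wide),
              P(open∧wide) + P(closed∧narrow) )

— the heavier diagonal of the joint 2×2 table, a symmetric matching
coefficient in [0.5−ε, 1] for balanced marginals — and always emit the
full joint table so any alternative convention can be applied downstream.

Subspace similarity uses O_ij = |u_i·v_j| and
RMSIP(k) = √(Σ_{i,j≤k}(u_i·v_j)²/k). External conformers are projected by
fitting each onto the mode-space mean; because the stored projections come
from an iterative fit converged to 1e-6 Å, re-projected pooled conformers
match their stored values to about that precision, not machine epsilon.

## Contacts and network

The default contact metric is a solvent-probe-augmented soft-sphere
overlap: area(i,j) = Σ_ab π max(0, r_a + r_b + 2r_w − d_ab)² over heavy
atom pairs, r_w = 1.4 Å, with sequence neighbours (|i−j| ≤ 1, same chain)
excluded. It is monotone in proximity but **not numerically comparable to
Voronoi tessellation areas**; the discriminative criterion and network
stages are metric-agnostic and a `precomputed` reader ingests genuine
tessellation output. For speed, candidate atom pairs are prescreened on
the mean structure with a 10 Å margin over the maximal reach — exact as
long as atoms fluctuate less than the margin (configurable).

Contact statistics are population mean/SD per residue pair, with absent
(model, pair) combinations counted as zero area; grouping can be by
ensemble label or by any partition of conformers (e.g. PCA regions). A
pair is discriminative when |mean_A − mean_B| > sd_A + sd_B — a strict
inequality — for at least one examined state pair. The selected pairs form
an undirected unweighted graph; components are reported by size, and
betweenness centrality both raw and normalized (×2/((n−1)(n−2))).

## Core mapping

Alignment blocks (aligned FASTA plus a residue-number track; sequential
numbering is assumed when no track is given) are concatenated through a
pivot structure present in every block: the pivot's residues define the
common column coordinate, and columns in which the pivot is gapped cannot
be reconciled across blocks — they are dropped and logged. The core is the
set of columns ungapped in *every* sequence, renumbered 1..K; `apply_core`
rewrites any ensemble to core-only Cα atoms with that consensus numbering,
which makes ensembles of different domains directly poolable in one PCA.
Tandem-domain entries must be split by the caller; the tool operates per
chain.

## The synthetic study (what a green test establishes)

The generator emulates the statistical structure the analysis assumes —
not protein physics. The scaffold is a smooth superhelical Cα trace with
backbone N (+ amide H) and two pseudo side-chain atoms (CB, CG) per
residue, carrying real masses and radii. Each conformer is
scaffold + a₁u₁ + a₂u₂ + ε:

* u₁, u₂ are smooth, block-localized displacement fields with rigid-body
  content projected out (so superposition cannot absorb or distort them),
  orthonormalized;
* a₁, a₂ are drawn from per-state two-component Gaussian mixtures. Defaults
  (means ±3 Å and ±2 Å, SDs 0.7 and 0.6 Å; open weights ff 0.95, fd 0.50,
  cf 0.10, cd 0.10; narrow weights ff 0.87, fd 0.30, cf 0.50, cd 0.31)
  follow the qualitative pattern of the motivating domain: bound states
  predominantly closed, the free truncated form bimodal, the free
  full-length form open and narrow. Components are separated by ≥ 4 SD so
  the threshold-0 partition is meaningful;
* ε is isotropic Gaussian noise with per-state scale (ff 0.60, fd 0.75,
  cf 0.50 Å); the cd scale is solved by root finding so that the analytic
  Schlitter entropies of the designed covariances give a binding-entropy
  ratio of exactly 4.0, with the free truncated state most disordered;
* N–H and CB–CG vectors wobble on cone rims with per-residue semi-angles
  (smooth 12–20°/18–32° profiles, frayed termini at 45°), giving exact
  analytic S² values; the proton and methyl carbon are *derived* atoms, so
  coordinate noise does not contaminate the designed S²;
* one residue pair (chosen so its CB–CB scaffold distance is ≈10 Å) has
  both side chains displaced 3 Å toward each other in the complex states —
  a planted discriminative contact far above the noise;
* models are grouped into 8 equal replica blocks of 101 (n = 808).

Because the per-state mixture means are correlated *across* states, the
pooled population covariance's principal axes are rotated within the
planted-mode plane relative to the raw u₁, u₂ (about 15° at the defaults).
The manifest therefore records, as ground truth, the **population
principal axes** (a closed-form 2×2 eigenproblem in that plane) and the
exact occupancies along them (mixture CDFs including the pooled-mean
shift), alongside the raw planted fields. Validated tolerances:
occupancies ±5%, S² ±0.03, entropy ratio ±10%, mode cosines ≥ 0.95,
planted contact always selected.

What the generator does *not* emulate: temporal autocorrelation within
replicas (models are i.i.d.), anisotropic or sequence-dependent noise,
real side-chain rotamer structure, and any force-field physics. A green
test therefore establishes the correctness of the estimators and the
pipeline plumbing — not the realism of any particular molecular system.
Convergence of the prefix-traced ratio approaches its plateau in
expectation; individual prefixes fluctuate ~1/√n, so plateau checks are
made on averages over seeds.

## Determinism and limitations

All randomness flows from a single integer seed through one generator;
identical seeds give byte-identical PDB output and identical reports (up
to timestamps). Known limitations: no mmCIF or trajectory formats (the
ensemble contract admits them later); no structural aligner (alignments
are inputs); Voronoi contact areas are consumed, not computed; absolute
entropies at n ≈ 3N are biased low (see above) — compare ratios or equal-n
states only.
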