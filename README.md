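# ensdyn

Comparative analysis of protein conformational ensembles, built for studies
of dynamic allostery in small interaction domains (the motivating case is a
PDZ domain observed free and ligand-bound, with and without a C-terminal
modulator helix). Given multi-model coordinate ensembles of several states
of one domain — or of several homologous domains — the package answers:

* Do the ensembles reproduce experimental NMR **S² order parameters**?
* How does **conformational entropy** change upon ligand binding, and how
  does that change depend on the modulator?
* What **collective motions** distinguish the states, and how are the
  resulting conformational sub-states populated?
* Which **residue–residue contacts** discriminate the states, and what
  network do they form?
* How do these motions map onto a **common structural core** of a whole
  domain family?

Because the restrained-MD ensembles behind such studies are rarely
deposited, ensdyn ships a first-class synthetic-study generator with an
exact ground-truth manifest, so every stage of the pipeline is validated
against closed-form oracles without downloads.

## Methods at a glance

**Order parameters.** For a bond unit vector μ averaged over conformers,

    S² = 3/2 (⟨μx²⟩² + ⟨μy²⟩² + ⟨μz²⟩² + 2⟨μxμy⟩² + 2⟨μxμz⟩² + 2⟨μyμz⟩²) − 1/2

computed after iterative least-squares superposition, for backbone N–H
vectors and side-chain methyl symmetry axes, and compared per vector class
(Pearson r, RMSD) to experimental tables.

**Entropy.** From the mass-weighted covariance σ of the fitted heavy-atom
coordinates, Schlitter's bound

    S = (k_B/2) ln det[ 1 + (k_B T e²/ħ²) M^½ σ M^½ ]

and the quasi-harmonic estimate with mode frequencies ω_i = √(k_B T/λ_i).
The headline statistic is the binding-entropy ratio
**(S_cd − S_fd)/(S_cf − S_ff)** across the four states (free/complex ×
full-length/truncated), traced over growing ensemble prefixes for
convergence.

**Modes.** PCA of the pooled, superposed Cα coordinates of all states;
conformers are partitioned open/closed (PC1) and narrow/wide (PC2) by a
threshold at 0, giving per-ensemble (and per-replica) occupancies and a
co-occurrence coefficient. Subspaces are compared by RMSIP; external PDB
conformers can be projected into an existing mode space.

**Contacts.** Per-conformer residue-pair contact areas (soft-sphere overlap
proxy, or precomputed tessellation areas); a pair is *discriminative*
between two states when |mean_A − mean_B| > sd_A + sd_B. Selected pairs
form an unweighted residue graph summarised by connected components and
Brandes betweenness centrality.

**Core mapping.** Multiple structure alignments are concatenated through a
pivot structure, the columns ungapped in every sequence define the common
core, and ensembles are rewritten to core-only Cα atoms with consensus
numbering — making ensembles of different domains directly poolable.

## Worked example

```sh
ensdyn run --out results/demo
```

runs the default synthetic study (four states × 808 conformers, 8 replicas
each, seed 0 — or `ensdyn run --seed N`). With `--seed 1` the report
contains, among others:

```
entropy ratio        3.937        # designed ground truth: 4.0
pc1 share of PCs1-10 0.390
S2 Pearson r (ff)    backbone 1.000, methyl axis 1.000
open occupancy       ff 0.95  fd 0.50  cf 0.13  cd 0.11
narrow occupancy     ff 0.31  fd 0.66  cf 0.45  cd 0.64
co-occurrence        ff 0.65  fd 0.56  cf 0.54  cd 0.61
contacts             5 discriminative pairs, 1 component of 5 residues,
                     2 residues with nonzero betweenness
```

Reading: the Schlitter-based binding-entropy ratio recovers the designed
value within 2%; the free full-length state sits almost entirely on the
open side of mode 1 while the bound states are closed; the planted
side-chain contact change is picked up by the discriminative-contact rule
and seeds a small residue network. The same commands accept real
multi-model PDBs per state (see `ensdyn run --config study.yaml` with an
`inputs:` mapping).

The library API mirrors the CLI: `ensdyn.synthetic.generate_study`,
`ensdyn.order_parameters.back_calculate_s2`,
`ensdyn.entropy.binding_entropy_ratio`, `ensdyn.modes.combined_pca`,
`ensdyn.contacts_network.discriminative_contacts`,
`ensdyn.core_mapping.extract_core`, …

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the complete default study from scratch with the given seed —
ensemble generation, S² validation, entropy ratio with convergence trace,
pooled PCA with occupancies and co-occurrence, and the discriminative
contact network — writing the results JSON to `--out` and the full study
report alongside it.

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical conventions.
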