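# Methods

## Interface model

A complex is exactly two chains of atoms read from PDB ATOM records
(HETATM, waters, and all but the first MODEL are dropped; altloc ' '/'A'
kept; insertion codes are appended to the residue number as a composite
identifier). A residue is an *interface residue* when any of its atoms is
within the interface cutoff (default 5.5 Å, inclusive) of any atom of the
other chain. The boundary is inclusive by convention, matching the ≤ rule
used for the iRMSD hit label. Hydrogens participate if present in the
file; the synthetic fixtures are heavy-atom only.

The receptor is the chain with more residues (ties broken by the
lexicographically smaller chain id); the other chain is the ligand. This
convention fixes which chain is superposed for lRMSD and which chain the
decoy generator perturbs.

## Features

All features are emitted as *(position, value, σ)* points and only then
mapped to the lattice, so every feature shares one mapping code path.

* **Element densities** (8 channels): one unit point per interface-residue
  heavy atom, split by element {C, N, O, S} and chain; σ is the element's
  van der Waals radius (C 1.70, N 1.55, O 1.52, S 1.80 Å; other elements
  are skipped). Eight density channels make the default set total 36.
* **Atomic charge** (2): partial charges from a reduced, user-replaceable
  parameter table shipped as plain text. The table covers N/CA/C/O/CB of
  the 20 amino acids with the classic amide four-point pattern
  (N −0.50, CA +0.14, C +0.50, O −0.50) and formal side-chain charges of
  Asp/Glu (−1) and Lys/Arg (+1) lumped onto CB. Unknown (residue, atom)
  keys fall back to charge 0 with a counted warning.
* **Intermolecular Coulomb and Lennard-Jones energies** (2 + 2): for atom
  k, v_k = Σ_l v_kl over cross-chain partners within a hard 8.5 Å cutoff,
  constant dielectric ε_r = 1, Coulomb constant 332.0636 kcal·Å/(mol·e²);
  LJ uses element-level parameters (C: ε 0.10, σ 3.40; N: 0.17/3.25;
  O: 0.21/2.96; S: 0.25/3.56) with Lorentz–Berthelot combining. Each pair
  term is clamped to ±1000 kcal/mol so steric clashes in rigid-body decoys
  cannot dominate a grid. The cutoff and dielectric are deliberate,
  documented simplifications — the feature pipeline, not the force field,
  is the point; the table file is an external interface.
* **Buried surface area** (2): BSA = (ASA_A + ASA_B − ASA_complex)/2 with
  Shrake–Rupley accessible areas (probe 1.4 Å, 960 Fibonacci sphere points
  per atom, via biotite with the package's radius table). The per-residue
  burial (isolated-chain ASA minus in-complex ASA, floored at 0) maps at
  the Cα with σ = 1.70 Å. At 960 points the quadrature carries ≈1%
  orientation sensitivity; totals converge to <1% when the point count is
  doubled.
* **PSSM** (20 shared channels): per interface residue, the 20 log-odds
  scores map at the Cα (σ = 1.70 Å); both chains write into the same 20
  channels. The file dialect is tab-separated with header
  `resnum resname A R N D C Q E G H I L K M F P S T W Y V IC`.
* **Residue contact counts** (opt-in, 6 channels): cross-chain
  residue-contact counts split by partner class, with charged = {D,E,K,R},
  polar = {C,H,N,Q,S,T,W,Y}, apolar = {A,F,G,I,L,M,P,V} (configurable).
  Excluded from the default 36-channel set.

## Gaussian grid mapping

The grid is a regular lattice centered on the mean position of the
interface heavy atoms, n = round(size/resolution) points per axis,
symmetric about the center. Defaults: 30×30×30 Å at 1 Å; a coarse
10×10×10 Å / 3 Å setting suits residue-level features. Each feature point
adds v·exp(−d²/2σ²) to every node, truncated beyond 4σ (the neglected tail
is < 3.4·10⁻⁴ of the peak). No Gaussian normalization is applied, so a
node coinciding with a point reproduces v exactly. Rotation augmentation
rotates the coordinates (not the grid) about the complex centroid with
rotations drawn uniformly from SO(3) via a seeded generator.

## Docking-quality targets

* **Superposition**: Kabsch via `scipy` `Rotation.align_vectors`
  (proper rotation guaranteed); inputs with < 3 points or collinear
  geometry are rejected.
* **lRMSD**: superpose on receptor backbone {N, CA, C, O}, report the
  ligand backbone RMSD without re-fitting. Atoms missing from either
  structure (e.g. terminal O) are dropped from both.
* **iRMSD**: interface residues defined on the *reference* at a 10 Å
  heavy-atom contact cutoff; the model is superposed on those residues'
  backbone atoms and that fit's RMSD is reported. Backbone (not all-atom)
  superposition is the documented choice.
* **FNAT**: native contacts are cross-chain residue pairs with any
  heavy-atom distance ≤ 5 Å in the reference; FNAT is the preserved
  fraction.
* **DockQ** = (FNAT + 1/(1+(iRMSD/1.5)²) + 1/(1+(lRMSD/8.5)²)) / 3.
* **CAPRI class** from the conventional inclusive threshold table;
  **hit label**: near-native ⇔ iRMSD ≤ 4 Å.

## Dataset store and splits

One HDF5 group per model: `mapped_features/<channel>` (gzip-compressed 3D
arrays), `grid_points/{x,y,z}` stored per model so mixed grid specs remain
valid, `targets/<name>`, and attributes (case id, seed, config hash).
Streaming is in sorted-model-id order — independent of write order — with
channel subsetting and `(target, comparator, value)` filters.

Cross-validation is grouped at the complex level: cases are shuffled by
seed and cut into k equal test blocks of ⌊n/k⌋; leftover cases are never
tested; validation cases are drawn per fold from the non-test cases. With
142 cases and k = 10 this reproduces the 114/14/14 train/validation/test
pattern in which 140 distinct cases are tested.

## Network

Torch is deliberately not a dependency: the CNN is a self-contained numpy
implementation with manual backpropagation, which keeps the training loop
fully deterministic given (seed, data, config) and auditable in one file.
Convolutions are stride-1 valid 3D correlations computed as chunked
im2col matmuls with a ~200 MB patch-memory bound; max-pooling routes
gradients through recorded argmaxes; batch normalization keeps running
statistics for inference.

Default architecture: two conv blocks (8 then 16 filters, kernel 3,
batch-norm, ReLU, 2³ max-pool), one hidden FC layer of width 84, and a
linear head (2 logits for classification, 1 value for regression). It
accepts any channel count and any grid of at least 12³ voxels (smaller
grids raise a configuration error rather than collapsing silently).

Two shipped presets mirror the published hyperparameter sets: an SGD
preset (lr 5·10⁻⁴, momentum 0.9, weight decay 10⁻³, batch 8,
cross-entropy over log-softmax) and an Adam preset (lr 10⁻³, batch 100,
automatic class weights). Class weights follow the opposite-fraction rule
— w_neg = fraction of positives, w_pos = fraction of negatives — so a
7.1%-positive corpus yields (0.071, 0.929) and expected penalties
balance. Early stopping monitors validation loss (patience 10) and the
best-epoch weights are restored. The ranking score is the raw wrong-class
log-softmax output (any monotone transform gives identical rankings).

## Ranking evaluation

Models are sorted by ascending score, ties broken by model id for
determinism. Hit Rate(K) = n_hits(K)/M per case; cases with M = 0 are
excluded from hit-rate statistics (the curve is undefined) and count as
failures in the success rate. Cross-case medians and 25/75% quantiles are
reported only up to N_min, the smallest model count among cases. The
HADDOCK reference scores use the stage coefficients
it0 = 0.01·E_vdw + E_elec + E_desol − 0.01·BSA,
it1 = E_vdw + E_elec + E_desol − 0.01·BSA,
itw = E_vdw + 0.2·E_elec + E_desol; desolvation energy is an input only,
never computed, and restraint-energy terms are omitted.

## Synthetic fixtures — what they do and do not show

* **Toy dimers**: two idealized backbone traces (N/CA/C/O, 3.8 Å Cα
  spacing, small seeded jitter) placed ~4.2 Å apart so an interface exists
  by construction. They exercise every feature and metric path but carry
  no real fold geometry, side chains, or sequence–structure correlation.
* **Decoys**: the ligand chain is rigidly rotated (≤ 80°) and translated
  (≤ 20 Å), both scaled by one shared uniform draw so qualities span
  near-native to wrong; candidates are rejection-resampled until requested
  counts of hits (iRMSD ≤ 4 Å) and non-hits exist. These mimic rigid-body
  docking diversity only — no conformational change upon binding. Wide
  perturbations can destroy the 5.5 Å interface entirely; featurization
  then skips the decoy with a log entry, which batch tooling treats as
  normal attrition.
* **Synthetic PSSMs**: integer log-odds uniform in [−5, 8] with the
  residue's own column biased +4 and IC uniform in [0, 2] — self-consistent
  but carrying no real evolutionary signal.
* **Planted-signal grids**: unit-variance noise in all 36 channels, with
  positives carrying an additive centered Gaussian blob (width 3 grid
  units) of amplitude `snr` in one density channel. At snr 5 the classes
  are linearly separable by channel mean, so a network failing to reach
  high validation accuracy indicates a training defect, not a hard
  problem. Passing these tests demonstrates the pipeline's correctness,
  not transferability to real docking corpora.

Desk-scale problem sizes used by the test suite and the acceptance script:
5–8 residues per chain, 50-decoy sets, 12³ planted grids with 100
entries per class (with batch 100, an epoch of the Adam preset is then two
full-batch steps, enough for reliable convergence within 20 epochs).

## Numerical notes and limitations

* SASA quadrature (960 sphere points) is orientation-dependent at the ~1%
  level; all other feature values are exactly invariant under rigid
  motions, and the Gaussian mapping conserves each channel's total mass
  under rotation up to lattice discretization (< 1% observed, consistent
  with the 4σ truncation and Riemann-sum error). For signed channels
  (charge, PSSM) whose grid sums can nearly cancel, rotation deviation is
  measured against the channel's absolute Gaussian mass, the only scale on
  which "within 1%" is well defined.
* Per-pair energy clamping (±1000 kcal/mol) bounds r → 0 divergences;
  exactly coincident atoms raise a degenerate-geometry error instead.
* Grid channel order is fixed and recorded; the HDF5 reader's default
  stacking order is sorted channel names, and training/prediction must use
  the same selection (a mismatch raises a configuration error).
* Only two-chain complexes are supported; mmCIF, multi-model ensembles
  beyond the first MODEL, binding-affinity targets, and desolvation-energy
  calculation are out of scope.
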