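# Methods

This note documents the models and procedures implemented in `rinvar`, the
parameters that matter, the numerical choices, and the limits of what the
synthetic experiments demonstrate.

## Probe-sphere contact model

Interactions are detected by rolling a virtual probe sphere (radius
`probe_radius`, default 0.25 Å) over the van der Waals surface of every
atom. For an atom pair at centre distance *d* with radii *rᵢ*, *rⱼ*, the
surface gap is *g = d − rᵢ − rⱼ* and the pair is classified as:

* **contact** for 0 ≤ *g* ≤ 2·`probe_radius`. The score is a surface
  integral approximated on a deterministic Fibonacci-spiral dot lattice of
  `dot_density` (default 16) dots/Å²: each dot on atom *i* whose gap to
  atom *j*'s surface lies in [0, 2·`probe_radius`] contributes a weight
  falling linearly from 1 at gap 0 to 0 at the probe diameter. The weighted
  sum is divided by the dot density, giving an area-like score (Å²) that is
  stable under density refinement; the emitted score is the mean of the two
  per-atom directions. For scoring, the lattice pole is oriented along the
  pair axis — the gap then depends only on the polar angle and the
  uniform-z spiral integrates it midpoint-style, which is what keeps the
  default density within a few percent of a 16×-density evaluation.
* **overlap** for *g* < 0, scored by the closed-form sphere–sphere lens
  (interpenetration) volume, reported as a positive magnitude.
* **hydrogen bond**: a donor/acceptor-eligible pair (built-in per-residue
  heavy-atom templates: backbone N donors except proline, backbone O/OXT
  acceptors, the usual side-chain N/O donors and acceptors) with
  heavy-atom distance ≤ `hbond_heavy_cutoff` (default 3.5 Å) is
  reclassified from contact/overlap to hbond and scored by the overlap
  volume of the two spheres inflated by the probe radius. No explicit
  hydrogen geometry is tested; AlphaFold-style models carry no reliable
  hydrogens, so the criterion is heavy-atom only.

Covalent bonds are inferred from distance < 0.6·(rᵢ + rⱼ) using
element-table vdW radii (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å). With
these radii the 0.6 factor cleanly separates bonded distances (C–C 1.54 Å
< 2.04 Å) from 1–3 distances (≥ 2.3 Å). Element-table rather than per-atom
radii are used here deliberately: perturbing an atom's scoring sphere (as
the synthetic generator does) must never rewire the bond graph. Pairs
connected by ≤ `covalent_exclusion_bonds` (default 3) bonds and intra-
residue pairs are excluded from scoring. A k-d tree prunes candidate pairs;
the brute-force all-pairs path is kept and tested to produce identical
output.

All dot lattices are deterministic (no RNG), so scores are bit-reproducible.

## Residue interaction network and matrix encoding

Atomic scores aggregate per residue pair into typed, subtyped, weighted
edges. Subtypes follow the atoms' segments: main chain = {N, CA, C, O,
OXT}, everything else side chain (glycine has none); `mc_sc` covers both
orientations. The `combi` edge is w_cnt·Σcnt + w_hbond·Σhbond + w_ovl·Σovl
over all subtypes, defaults all 1.0 — the combination weights are exposed
as configuration because no canonical values exist; the defaults make
`combi` the plain sum. Zero-weight edges are omitted.

Networks serialize to Cytoscape SIF (topology; isolated nodes as bare
lines so node count round-trips) and 2.x-style NA edge-attribute files
(one per edge type, weights to 6 significant digits). Node labels are
`chain:resnum:name3`.

The encoder maps edges to a symmetric L×L×7 tensor with a fixed channel
map: 1 cnt (mc_mc + sc_sc), 2 cnt (mc_sc), 3 hbond (mc_mc + sc_sc),
4 hbond (mc_sc), 5 combi (all_all), 6 ovl (mc_mc + sc_sc), 7 ovl (mc_sc).
Values are stored raw; optional per-channel max-normalization exists but
defaults off (batch normalization in the classifier absorbs scale).
Datasets are HDF5 files (`/matrices`, `/labels`, `/variant_ids`) with the
channel semantics as metadata and timestamp tracking disabled so identical
inputs give byte-identical files.

## Base classifier and ensemble

The base classifier is a ResNet18-style 2D CNN: 7×7 stem convolution to
the first stage width (stride 2), BN + LeakyReLU, 3×3 max pool (stride 2),
four stages of two residual blocks (3×3 kernels, BN + LeakyReLU per
convolution, stride-2 first block with 1×1 projection shortcut in stages
2–4), global average pooling, dense 2-class head, softmax cross-entropy.
Convolution biases are enabled and batch norm contributes two trainable
parameters per channel: this is the unique standard reading under which
the canonical widths (64/128/256/512) at 7 input channels and 2 classes
give exactly 11,194,882 trainable parameters (independently confirmed by
layer-wise arithmetic: the 3-channel/1000-class variant totals 11,689,512
weights + 4,800 conv biases = 11,694,312). The parameter count is
independent of L because the network is fully convolutional up to the
global pooling. LeakyReLU slope defaults to 0.3.

The framework behind it (`rinvar.nn`) is a compact numpy implementation —
im2col convolution, manual backprop, float64 throughout for run-to-run
bit-reproducibility — validated against numeric gradients in the tests.

Class imbalance is handled with EasyEnsemble undersampling: T (default 3)
training sets, each all |P| positives plus |P| negatives drawn without
replacement, independently per set, from a seeded generator. One base
classifier trains per set; the ensemble score is the arithmetic mean of
the class-1 probabilities with decision threshold 0.5. The integration
rule is pluggable — averaging probabilities was chosen over majority vote
because it preserves confidence information; only "use the probabilities,
not the sign function" is prescribed.

Training: Adadelta in its original accumulated-gradient/accumulated-update
form (lr 1.0, ρ 0.95, ε 1e-6 — the method adapts its own step size, so
the base step stays at the classic 1.0 and is recorded in every model
sidecar), batch size 26, up to 200 epochs, early stopping on validation
loss with patience 10 and best-weights restore. The validation split is a
stratified seeded 10% — stratification matters because an unstratified 10%
of a 520-sample balanced subset could starve a class. Non-finite loss
aborts with a diagnostic rather than training through NaNs. Models persist
as `.npz` weights plus a JSON sidecar (parameters, classes, history,
subset indices); save → load → predict is bit-stable.

A cross-training filter flags suspected label errors: a model trained on
an independent probe set scores the training set, and samples misclassified
with wrong-class probability ≥ `extreme_cut` (default 0.95) are removed —
capped at 5% of the training set (most extreme first) so the filter can
never hollow out the data; a cut of 1.0 is vacuous by definition (floating-
point softmax can saturate at exactly 1.0).

## Evaluation and external-score combination

Reports contain per-class and overall accuracies at threshold 0.5 and
ROC/PR curves from a threshold sweep over the unique scores
(scikit-learn's curve construction), both integrated by trapezoid. PR AUC
is trapezoidal on the recall-sorted curve, not average precision — a
documented choice since no estimator is canonical; the ROC AUC is verified
in tests against brute-force concordant-pair counting with tie correction.
With a single label class, accuracies are still reported and AUCs are NaN.

Feature ablation retrains the same estimator configuration (same seeds,
hence identical undersampling and validation splits) with non-selected
channels zeroed in train and test: `cnt` → channels 1–2, `hbond` → 3–4,
`combi` → 5, `ovl` → 6–7, `all` → 1–7.

The combination rule treats an external pathogenicity score in [0, 1]
(threshold 0.611) as decisive outside the uncertainty band [0.45, 0.772]
and defers to the structural model inside it. Band endpoints are
inclusive — the closed reading of a stated range, affecting only scores
exactly on the boundary. Ranked curves for combined calls use the deciding
source's score, a documented choice among defensible alternatives.

## Structure handling

PDB input is parsed by a strict fixed-column ATOM reader: malformed
records raise an error naming the line, HETATM-only files are rejected,
the first chain is taken (with a warning) when several are present, first
altlocs win, and unknown elements without a vdW radius entry are an error
naming the atom. B-factors are kept per atom and interpreted as pLDDT for
AlphaFold-style models; the per-residue pLDDT is read from the Cα B-factor
(AlphaFold writes identical per-residue values to all atoms, so this is
lossless there). Cα RMSD uses Kabsch superposition via
`scipy.spatial.transform.Rotation.align_vectors` on 1:1 residue
correspondence by sequence index; tests cross-check it against an
independent numeric rotation optimizer. HGVS protein substitutions
(`p.Ala1708Glu`) apply to sequences through an author-numbering offset
(index = position − offset; e.g. a domain fragment starting at author
residue 1646 uses offset 1646).

## Synthetic study conditions

The generator builds an ideal α-helix from standard internal coordinates
(φ = −57°, ψ = −47°, ω = 180°; N–CA 1.458, CA–C 1.525, C–N 1.329,
C=O 1.231 Å), which reproduces the canonical helix geometry: 3.8 Å
consecutive Cα–Cα distance, ~1.5 Å rise and ~100° turn per residue,
~2.3 Å Cα radius, and i → i+4 backbone O···N pairs near 3.1 Å that the
contact engine classifies as hydrogen bonds. Each non-glycine residue
carries one side-chain pseudo-atom on the ideal CB direction at
1.5 + 0.25·√k Å from CA with sphere radius 1.6 + 0.12·k Å (k = side-chain
heavy-atom count) — a unified side chain that moves packing signal without
rotamer modeling. B-factors emulate high-confidence pLDDT (88–98, seeded).

A variant is a point perturbation at one residue: enlarge the side-chain
sphere by a factor (1 + magnitude), displace it outward by magnitude Å, or
delete it. The label rule is deterministic: pathogenic iff magnitude ≥
`label_cutoff` (default 0.5) at a designated core position (default: the
middle third of the chain). The default study conditions are L = 60,
30 positives at magnitude 1.0 against 90 negatives with magnitudes below
0.3·cutoff at arbitrary positions (1:3 imbalance), plus 0.02 Å seeded
coordinate jitter on every structure to emulate prediction noise. At these
settings the classes are linearly separable in the channel-5 row mean of
the perturbed residue (asserted in the tests), which is precisely why the
CNN-recovery tests demand held-out accuracy ≥ 0.9.

Desk-scale training in the test suite uses the `tiny` width preset
(8/16/32/64) and a 30-epoch cap — sized so a full ensemble trains in under
a minute on one CPU; the full-width architecture is still built (never
trained) for the parameter-count identity, which is width-dependent but
training-free.

What passing these tests shows: the pipeline propagates localized
structural perturbations into the designated matrix channels, and the
ensemble recovers a planted, separable signal while collapsing to chance
on shuffled labels. What it does not show: performance on real predicted
mutant structures, whose signal is weaker, noisier, and entangled with
prediction error — the synthetic helix has no tertiary packing beyond the
helix itself, no rotamers, and no correlation between perturbation and
sequence context.

## Known limitations

* Single-chain structures only; no mmCIF; no hydrogen placement; no
  aromatic/salt-bridge typing. The probe-score weighting and H-bond
  criteria are config-exposed readings of a dot-based contact scheme, not
  a reimplementation of any specific legacy tool's internal constants.
* The Adadelta learning rate, combi weights, ensemble integration rule,
  and PR-AUC estimator are package choices where no canonical value is
  published; all are recorded in sidecars and overridable.
* The numpy CNN trains small models comfortably but is not a GPU
  framework; the full-width network is practical to build and score, not
  to train at scale.
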