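# rinvar

Residue interaction networks from protein tertiary structures, and an
under-sampled ensemble of 2D convolutional classifiers that recognizes the
pathogenicity of missense variants from those networks.

## The problem

Most missense variants in clinically important genes (the motivating case is
the BRCT domain of BRCA1) are variants of uncertain significance. Sequence-
based predictors ignore the tertiary structure, yet a single amino-acid
substitution perturbs the local atomic packing in ways a predicted structure
can expose. `rinvar` implements a structure-native pipeline:

1. **Structure → atomic contacts.** A virtual probe sphere of radius 0.25 Å
   rolls over the van der Waals surface of every atom. For a pair at centre
   distance *d* with radii *rᵢ*, *rⱼ* the surface gap is
   *g = d − rᵢ − rⱼ*: pairs with 0 ≤ *g* ≤ 0.5 Å are **contacts**, scored by
   a deterministic surface-dot lattice with a weight falling linearly from 1
   at *g* = 0 to 0 at the probe diameter; pairs with *g* < 0 are
   **overlaps**, scored by the analytic sphere–sphere lens volume;
   donor/acceptor pairs within 3.5 Å are reclassified as **hydrogen bonds**
   and scored by the overlap volume of probe-inflated spheres. Covalently
   connected pairs (≤ 3 bonds) and intra-residue pairs are excluded.
2. **Contacts → residue interaction network (AAN/RIN).** Atomic scores are
   summed per residue pair into typed edges — `cnt`, `hbond`, `ovl`, and
   their weighted sum `combi` — with main-chain/side-chain subtypes
   (`mc_mc`, `mc_sc`, `sc_sc`). Networks serialize to Cytoscape SIF
   (topology) and NA (weights) files.
3. **Network → interaction matrix.** Each network becomes a symmetric
   L×L×7 tensor. Channels 1–7 hold: cnt (mc_mc + sc_sc), cnt (mc_sc),
   hbond (mc_mc + sc_sc), hbond (mc_sc), combi (all_all),
   ovl (mc_mc + sc_sc), ovl (mc_sc).
4. **Matrices → classifier.** The base model is a ResNet18-style 2D CNN
   (7×7 stem → 64 channels, four stages of two residual blocks at widths
   64/128/256/512, batch norm + LeakyReLU, global average pooling, 2-class
   head; **11,194,882 trainable parameters** at 7 input channels). Class
   imbalance is handled EasyEnsemble-style: T = 3 balanced training sets
   (all positives + equal-sized negative draws), one classifier per set,
   and the mean class-1 probability as the ensemble score. Training uses
   Adadelta, batch size 26, up to 200 epochs with early stopping
   (patience 10) on a stratified 10% validation split.
5. **Combination with an external predictor.** An external pathogenicity
   score in [0, 1] with threshold 0.611 decides a variant outright unless
   it falls in the uncertainty band [0.45, 0.772], where the structural
   model's call takes over.

The CNN stack (convolution, batch norm, pooling, Adadelta, backprop) is
implemented in numpy inside `rinvar.nn`; classifiers are scikit-learn
estimators (`ResNetClassifier2D`, `UndersampleEnsembleClassifier`) that
compose with sklearn model selection.

A synthetic-fixtures module generates ideal α-helix structures with
single-sphere side chains and planted, labeled perturbations, so the whole
pipeline trains and evaluates in minutes on one CPU with no downloads.

## Worked example

End-to-end on synthetic data (simulate → train → evaluate):

```bash
cat > config.json <<'JSON'
{
  "synthetic": {"n_residues": 60, "rng_seed": 0, "magnitude": 1.0},
  "train": {"epochs": 30, "widths": "tiny", "n_estimators": 3, "rng_seed": 0},
  "n_pos": 30, "n_neg": 90, "n_test_pos": 20, "n_test_neg": 20
}
JSON
rinvar pipeline --config config.json --outdir run
```

Output (about a minute on one CPU):

```
rinvar INFO pipeline/simulate: 120 train + 40 test matrices (21.4s)
rinvar INFO pipeline/train: T=3 (40.3s)
rinvar INFO pipeline/evaluate: acc=1.000 roc_auc=1.000
{
  "n_pos": 20,
  "n_neg": 20,
  "overall_accuracy": 1.0,
  "tpr_accuracy": 1.0,
  "tnr_accuracy": 1.0,
  "roc_auc": 1.0,
  "pr_auc": 1.0
}
```

The training set is 120 interaction matrices (L = 60, 25% positive, the
positives carrying a strong planted side-chain perturbation at core
positions); the report shows the ensemble's accuracy on positives
(`tpr_accuracy`), negatives (`tnr_accuracy`), overall, and the trapezoidal
ROC/PR AUCs of the pathogenicity ranking on an independently seeded test
set. Perfect recovery is expected here — the planted signal is linearly
separable by construction; see `docs/methods.md` for what this does and
does not demonstrate.

Individual stages are also exposed (`rinvar simulate`, `build-network`,
`encode`, `train`, `predict`, `evaluate`, `ablate`, `combine`, `rmsd`), and
everything is importable as a library:

```python
from rinvar import (ProbeConfig, detect_contacts, build_rin, encode,
                    UndersampleEnsembleClassifier)
```

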