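# Methods

## Problem and model

Protein function prediction is cast as multi-label classification: a protein
`x` (an amino-acid sequence, or a precomputed feature vector) is mapped to an
assignment vector `y ∈ {0,1}^c` over `c` Gene Ontology (GO) terms of one
namespace (BP, MF or CC).  GO terms live in an `is_a` DAG and obey the
true-path rule: a term's ancestors must annotate every protein the term
annotates.  Beyond the DAG, term usage carries co-occurrence structure — some
pairs of functions co-occur in the same proteins, others are mutually
exclusive — that a per-term loss cannot see.

The package trains a conditional Wasserstein GAN to exploit that structure:

* **Generator (the annotator).**  Sequence mode: one-hot trigrams →
  128-dim embedding → dropout 0.2 → 32 one-dimensional convolutions →
  LeakyReLU → average pooling (window 64, stride 32) → two dense LeakyReLU
  layers → dense layer of width `c` with `tanh`, affinely rescaled to
  `[0,1]` by `(t+1)/2`.  Feature mode replaces the front end by three dense
  LeakyReLU layers.
* **Critic.**  Scores `(x, y)` pairs with an unbounded scalar: a dense
  label branch over `y`, concatenated with condition features of `x`
  (a private copy of the generator front-end shape), then five dense
  LeakyReLU layers and a single linear neuron.
* **Losses.**  Generator: `BCE(y, G(x)) − λ1·D(x, G(x))`.  Critic:
  `D(x, G(x)) − D(x, y) + λ2·(‖∇_ŷ D(x, ŷ)‖₂ − 1)²` with `ŷ` a per-sample
  uniform interpolate between the real and generated assignment vectors;
  the gradient is taken with respect to `ŷ` only, since real and generated
  pairs share the condition `x`.
* **Schedule.**  Ten critic updates per generator update, Adam for both
  networks, an 80/20 train/validation split, checkpointing at the epoch
  with the best validation Fmax.  The ablation **PFP-S** omits the critic
  and trains the generator on BCE alone.

## Defaults and units

| parameter | default | notes |
|---|---|---|
| λ1 (Wasserstein weight) | 0.03 | sequence experiments; 1e-5 for the feature-vector setting |
| λ2 (gradient penalty) | 10 | both settings |
| critic ratio | 10 | critic updates per generator update |
| learning rate | 1e-5 | full-scale default; desk-scale runs use 1e-3 (below) |
| Adam β1, β2 | 0.9, 0.999 | library-standard, logged for reproducibility |
| batch size | 32 | unstated in the source setting; fixed here |
| validation fraction | 0.2 | |
| sequence filter | length > 1002 or ambiguous codes dropped | B, J, O, U, X, Z count as ambiguous |
| term filter | ≥ 250 / 50 / 50 positives (BP/MF/CC) | counts on the propagated matrix |
| trigram code | base-20 positional, alphabetical letter order | bijective onto 1..8000; 0 is padding |
| MCC threshold | 0.5 | the source defers the definition; configurable |

## Numerical and design choices

* **No deep-learning framework.**  The networks, both losses and Adam run
  on a small reverse-mode autodiff core (`pfpwgan.autodiff`) written for
  this package.  Its vector-Jacobian products are themselves composed of
  primitive operations, so the gradient penalty — a function of
  `∇_ŷ D` — is differentiated exactly with respect to the critic
  parameters (activation masks are treated as constants, which equals the
  almost-everywhere second derivative of piecewise-linear activations).
  First-order gradients are verified against finite differences, the
  penalty against the closed form of a linear critic.
* **Fused front end.**  A one-hot trigram times the embedding matrix is a
  row lookup, and the convolution over embedded trigrams is a sum of
  per-offset lookups into `E·W`.  Both are expressed as constant sparse
  matrices applied to parameter-dependent dense matrices; this is an exact
  reformulation, chosen for CPU speed.  Right-edge convolution positions
  read the trainable padding embedding (row 0, initialized at zero), the
  same code short sequences are padded with.
* **Dropout granularity.**  The stochastic-generator dropout (rate 0.2)
  zeroes whole trigram-position embedding vectors (SpatialDropout style)
  rather than single activations; this composes with the fused front end
  and serves the same purpose.  The critic's condition branch runs without
  dropout: the critic is regularized by the gradient penalty, and a
  deterministic critic makes the Wasserstein estimate less noisy.
  Dropout is off at prediction time; repeated predictions are identical.
* **Output scale.**  `tanh` outputs in `[−1,1]` are rescaled to `[0,1]`
  so the BCE term is well defined; the critic sees the rescaled vector as
  the generated assignment and `{0,1}` vectors as real ones.  BCE clips
  predictions to `[1e-7, 1−1e-7]`.
* **Precision/recall conventions.**  0/0 is defined as 0 and every protein
  counts in the protein averages (the CAFA refinement — precision averaged
  only over predicting proteins — is available behind a flag).  Thresholds
  are a 100-point grid on `[0,1]`, prediction = score ≥ t.  Term-centric
  measures are undefined for terms without positives and excluded from
  macro averages.  AUPR integrates the PR curve trapezoidally over unique
  score cut points, anchored at recall 0.
* **Term height** (for the per-height F1 report) is the longest `is_a`
  path from the term up to its namespace root, root = 0; longest-path is
  stable under shortcut edges, which depth-from-root is not.
* **Hierarchy = `is_a` only.**  Other OBO relations are ignored; the
  true-path closure and the ancestor sets of the conflict score are
  defined on the parent relation alone.  The conflict (TPR) score
  restricts ancestor sets to the evaluated term set.
* **Binarization for the co-occurrence heatmap** uses the validation
  Fmax-maximizing threshold — the only threshold the pipeline has already
  distinguished; configurable.
* **Randomness.**  One master seed is split into independent streams
  (split, per-network init, generator dropout, critic-side dropout,
  interpolation draws, generator batches, critic batches).  Because the
  generator-side streams do not touch critic machinery, a run with λ1 = 0
  updates the generator exactly as the PFP-S ablation does under the same
  seed — a tested invariant.

## Synthetic benchmark

The generator of desk-scale data emulates what the method needs from real
annotation corpora:

* a single-rooted `is_a` DAG (default 40 terms, depth 4; every non-root
  term has one parent on the level above, so its height equals its level,
  plus an optional shortcut parent);
* leaf terms carry distinct exact 6-mer motifs; a protein (default 2000
  per dataset) draws 1–3 leaves, its sequence (uniform background,
  length 50–400) contains each drawn leaf's motif at non-overlapping
  positions, and annotations are closed under the true-path rule;
* planted pair constraints on leaves: three forced co-occurrence pairs
  (either member implies both) and three mutual-exclusion pairs (never
  jointly annotated) by default — co-occurrence structure beyond the DAG,
  which is exactly what the critic is meant to learn;
* a feature-vector variant sums per-leaf prototype vectors plus isotropic
  noise (default dimension 64).

What the benchmark does **not** emulate: realistic amino-acid composition,
homology between proteins, degenerate motifs, annotation incompleteness.
Passing results show the machinery works end-to-end and that the
adversarial term helps recover planted label structure at desk scale; they
do not certify performance on SwissProt-scale corpora.

## Desk-scale study conditions

CPU-scale runs (`pfpwgan.benchmark`) shrink widths, not the procedure:
embedding 32, 8 convolution filters, generator dense layers (64, 32),
label branch 32, critic trunk (64, 48, 32, 24, 16), 10 epochs on 2000
proteins with batch 32.  The learning rate is 1e-3 here: the full-scale
1e-5 cannot leave initialization within a 10-epoch desk run.  λ1 = 0.03,
λ2 = 10 and the 10:1 schedule are kept.  The correlation analysis trains
the adversarial model and PFP-S on the same data and seed, binarizes each
model's held-out (validation-split) predictions at the Fmax-maximizing
threshold of that evaluation run, builds the co-occurrence heatmaps, and
compares each against the ground-truth heatmap of the training-split
annotations by MSE, median over five seeds.

## Known limitations

* CPU-bound: full-scale (≈1000-term, 60k-protein) training is out of reach
  of the numpy core; the package is exercised at desk scale.
* The OBO reader handles the minimal dialect (`id`, `name`, `namespace`,
  `is_a`, `is_obsolete`); cross-products, typedefs and `part_of` semantics
  are out of scope.
* Exact hidden widths and the convolution kernel size of the original
  networks are not published; the defaults here are configurable choices
  (kernel 8, 'same' length).
* The critic trunk is read as five hidden layers plus the scalar output
  neuron; the source wording would also admit four hidden layers and the
  output as the fifth.
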