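# Methods

## Task and data model

The unit of learning is a *blinded instance*: one sentence, one ordered
candidate drug pair, one gold label from {negative, effect, mechanism,
advice, int}. Corpora arrive pre-sentencized in the DDIExtraction2013 XML
dialect (`document → sentence → entity/pair`); character offsets are 0-based
inclusive and may be discontinuous (semicolon-separated), in which case the
mention collapses to a single blinded token at its first span. Blinding is
applied before any other normalisation so entity surface forms never leak
into the token stream; normalisation then lowercases, strips punctuation,
removes a configurable stop-word list and maps digit-only tokens to `dnum`.

Two corpus-cleaning rules remove candidate pairs whose two surface names
denote the same substance: **R1** — names equal after case-folding and
whitespace collapsing; **R2** — one name is (i) a parenthesised alias inside
the other, (ii) a whole-token contiguous substring of the other, or (iii)
the initials of the other's tokens. R2 is a deliberately conservative,
testable realisation of the informal "abbreviation or special case"
criterion. Instances flagged by either rule are removed *regardless of
label* when building the filtered dataset variants, because flagged positive
pairs are ambiguous annotations. The four variants are: dataset-1 (all),
dataset-2 (filtered), dataset-3 (all minus negatives), dataset-4 (filtered
minus negatives). Filtering is idempotent and variant instance-id sets are
nested (4 ⊆ 2 ⊆ 1, 4 ⊆ 3 ⊆ 1). Whether filtering should apply to evaluation
folds as well as training is not fixed by the corpus convention; it is
applied corpus-wide here, before any fold assignment.

## Modalities and fusion

* **Tokens** — a contextual provider maps the blinded token sequence to a
  (T × d_w) matrix. When a provider exposes layers, the mean of its last
  four is used; sub-token rows are mean-pooled to instance tokens and
  boundary markers dropped. The built-in provider hashes each token with a
  seed into a deterministic Gaussian vector: it is a *stand-in for* but not
  an approximation of a pretrained encoder, and real encoders plug in
  behind the same provider contract.
* **Descriptions** — one document vector (d_d) per drug; empty or missing
  descriptions fall back to a zero vector with a warning, since not every
  drug has a curated description.
* **Structures** — SMILES strings are parsed by a small organic-subset
  reader (atoms B/C/N/O/P/S/F/Cl/Br/I, aromatic lowercase, branches, ring
  closures including `%nn`, explicit bond orders; no charges, isotopes or
  stereochemistry). Aromatic–aromatic bonds carry the order tag `"ar"`;
  hydrogens stay implicit; parse errors report the character position.
  The built-in graph provider hashes the multiset of local signatures
  (element, sorted neighbour elements), so graphs identical up to atom
  reordering — e.g. `CCO` vs `OCC` — embed identically. This one-round
  signature is not a complete isomorphism invariant in general, but the
  test suite verifies it coincides with brute-force isomorphism on the
  structure panel used here.

Fusion tiles the two per-drug vectors across all token positions and
concatenates on the feature axis, giving (T × (d_w+d_d+d_g)) per drug. The
sequence form is required by the recurrent encoder's time index; an
alternative `append` mode (description and graph vectors as pseudo-token
rows in disjoint feature slices) is available by config. The token block is
shared between the two drugs' fused sequences; a config flag allows
recomputation per drug for providers that condition on the target pair.

## Network

Defaults (the published operating point): d_w/d_d/d_g = 400/200/100,
3 BiGRU layers with 128 hidden units per direction (encoded width
Gd = 256), head width 32 with Gd/32 = 8 heads, dropout 0.01, Adam at
learning rate 1e-3, mini-batch 30, 3000 iterations. The mini-batch of 30 is
the gradient-step batch; 1024 is the inference/eval batch cap.

* One **shared BiGRU** encodes both drugs' sequences (`tied_encoder: false`
  unties it). The GRU uses the standard update/reset gating with
  `h' = (1−z)·n + z·h`; at zero weights and zero input the encoding is
  exactly zero.
* **Cross-attention** draws queries from one drug's encoding and keys/values
  from the other, with a single shared set of per-head projections W_q, W_k,
  W_v and output map W_Z for both directions. This weight sharing makes the
  swap symmetry exact, which the tests exploit.
* Residual averaging `(Z+U)/2`, then column-wise max-pooling over time.
* **Link attention**: the written form `Wᵀ ReLU(W_12 [F1;F2] + b)` is
  dimensionally underdetermined if read as a scalar product, while the
  following softmax is indexed per coordinate d = 1..D. It is therefore
  realised as a dense map ℝ^{2D}→ℝ^{D} with ReLU followed by elementwise
  scaling by the vector W, giving a length-D pre-activation. The link
  embedding is `F12 = a12 ⊙ F1 ⊙ F2`.
* A softmax applied directly to the D-dimensional F12 cannot produce 5
  class probabilities, so a trainable affine map D → n_classes precedes the
  softmax — the minimal repair consistent with a distribution over classes.
* **Batch normalisation** is stated without a location; it is placed once on
  the encoded features before cross-attention (statistics pooled over both
  drugs' valid positions, keeping the swap symmetry) and once on F12 before
  the classifier; both are removable by config. **Dropout** 0.01 (the
  printed default, unusually small, preserved verbatim) is applied
  elementwise to the fused input sequences and to F12 in training mode.
* Variable-length batches are padded to the batch maximum; attention
  softmaxes mask padded keys and the max-pool masks padded rows, so a pair's
  output is identical alone or inside a longer-padded batch (tested).

All parameters are initialised by a scaled-uniform fan-in scheme from the
config seed; every source of randomness (init, dropout, shuffling, splits)
flows from explicit seeds, making checkpoints and predictions
bit-reproducible. Checkpoints are `.npz` archives written with pinned zip
timestamps so identical runs produce identical bytes.

## Training and evaluation

The loss is categorical cross-entropy (the binary form is the special case
n_classes = 2). The public `cross_entropy_loss` operates on probabilities
with sum reduction by default (mean by flag) and clamps zero probabilities
at 1e-12 with a warning; the training path computes the same quantity from
logits via log-softmax for numerical stability and averages over the batch
so the step size is batch-size invariant (Adam's moment normalisation makes
this equivalent to the summed form up to the learning-rate scale).
Optional inverse-frequency class weighting addresses the corpus's extreme
class imbalance; early stopping exists behind a flag but is off by default
(training runs the fixed iteration budget).

Metrics follow the DDI-corpus convention: micro-averaged precision, recall
and F1 from per-class TP/FP/FN sums over the four positive classes
(all-classes scope available, in which case micro-P = R = F1 = accuracy for
single-label data); accuracy is always computed over all instances.
Cross-validation uses stratified folds with a fixed seed; classes with
fewer than k members are merged into the nearest-size stratum for fold
assignment only, with a warning.

## Synthetic studies: what they do and do not show

The synthetic generator emits the same formats the real pipeline consumes.
Sentences are template-generated ("coadministration of A, B and C VERB
PHRASE"); entity names are distinct within a sentence except where an R1
(duplicate name) or R2 (parenthesised abbreviation) violation is planted
deliberately, so the filter rules can be checked for *exact* removal.
Labels are sampled from configurable class priors (balanced by default).

Planted-signal embeddings draw every modality vector of a class-c instance
from a Gaussian centred at `mu · u_c` (u_c a fixed unit direction per class
and modality, scaled per modality so ablation toggles have measurable
effect) with noise sd `sigma = 1`. At `mu = 0` the classes are
indistinguishable by construction; at `mu = 5` they are linearly separable,
which an independent linear probe confirms in the tests. The reference
study uses desk-scale problem sizes chosen once for this package: embedding
widths 32/16/8, one BiGRU layer with 16 hidden units per direction, four
8-wide heads, 500 Adam steps, 500 training and 200 held-out pairs, seed 7
in the test suite (the analysis script takes its seed on the command line).
Passing these studies shows the implementation can recover a known planted
signal and does not hallucinate one from noise; it says nothing about
performance on real biomedical text, which depends on pretrained encoders
and corpus phenomena (sub-token segmentation, long sentences, heavy class
imbalance, annotation noise) the generator deliberately does not emulate.

## Numerical and design notes

* Gradients come from a minimal in-repo reverse-mode autodiff over NumPy;
  the full forward+loss is finite-difference checked at 1e-4 relative
  tolerance on a miniature configuration.
* Softmaxes are max-shifted; the max-pool routes gradient to the first
  maximal element (a valid subgradient at ties); masked positions receive
  additive −1e30 before softmax/pooling.
* Batch-norm uses eps 1e-5 and momentum 0.1 for running statistics; eval
  mode uses running statistics, so an untrained model's eval BN is the
  identity up to the affine parameters.
* The learning-rate config enforces the documented range (1e-4, 0.1); the
  invariant "zero learning rate leaves parameters unchanged" is guaranteed
  by the optimiser itself and tested at the optimiser level.
* Known limitations: no GPU path; the contextual/document/graph providers
  shipped are deterministic hashes, not learned encoders; the SMILES subset
  excludes bracket atoms; attention head count defaults to Gd/head_dim
  (head width is fixed by config, head count is not).
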