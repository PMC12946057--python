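# Methods

This note documents the models, the synthetic benchmark, the numerical
choices and the known limitations of the package. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model and losses

The backbone is a standard pre-norm Vision Transformer: patch embedding
with a learned positional term and optional class token, then blocks of
multi-head self-attention and a GELU MLP with residual connections and a
final layer norm. Unusually, every MHSA layer stores its per-head Q/K/V
projection blocks separately, so per-head attention maps `A_h` (the full
`n_tokens × n_tokens` post-softmax matrix, class token included when
enabled) and per-head outputs `Z_h` are first-class objects, and heads can
be masked or physically removed.

**Domain alignment loss.** `DAL_h` is the KL divergence between the frozen
source model's and the live model's attention maps *on the same target
image*. Since each post-softmax row is a probability distribution over
keys, KL is taken row-wise and averaged over query rows and over the
batch, with additive `ε = 1e-8` smoothing inside both logarithms. The
direction matters and is fixed: the frozen source map is the reference
(first) argument. On generic maps KL is asymmetric, and the tests assert
this.

**Phenotypic consistency.** `PCC` is the mean squared L2 distance between
`f_MLP(Z_i)` and *standardized one-hot* labels: one-hot vectors whose
columns are z-scored over the labeled set. A squared-error loss against
standardized targets (rather than cross-entropy) keeps the constraint in
the same least-squares family as the correlation used for scoring and
makes the "perfect prediction → 0" contract exact. `Z_i` pools each
head's output by token-mean and concatenates heads in fixed (layer, head)
order. Only labeled target samples contribute; an all-unlabeled batch is
an error, not a silent zero.

**Head scoring.** `HTS_h = α·exp(−DAL_h) + (1−α)·Corr(Z_h, y)` with
α = 0.6. The correlation reduction for a multivariate head output against
a categorical label is: token-mean pool per sample, Pearson-correlate
every feature dimension with every standardized one-hot column, take
|r|, max over columns, mean over dimensions. This yields a value in
[0, 1] (constant dimensions contribute 0), matching the score's implied
positive range; it is isolated in one function so alternative reductions
are swappable.

**Threshold and selection.** `τ = mean(HTS) − β·std(HTS)` with β = 1.5
and the *population* standard deviation — the head set is the entire
population being thresholded, not a sample from one. τ is computed over
the global pool of all retained heads (per-layer pooling is available via
an argument); ties at τ are retained; every layer keeps at least
`min_heads_per_layer` (default 1) heads, with floor-forced retentions
flagged in the mask. Note a structural property of this rule: for any
one-shot score distribution, at most a small tail lies below μ − 1.5σ, so
large cumulative reductions arise only through *iteration* — each outer
iteration removes the extreme tail, the distribution re-tightens, and the
threshold climbs.

**Surgery.** Pruning deletes the Q/K/V blocks of removed heads and the
matching `d_v`-row blocks of `W_O`, producing `W_O′`. Because the deleted
rows are exactly the rows that multiplied the deleted concatenation
slices, the compact forward pass is algebraically identical to the
zero-masked original; the suite verifies this within 1e-6 over random
models and masks, and verifies that all-retain pruning is a bitwise
no-op. Head width `d_k` never changes after pruning; biases follow their
head; layer norms and MLPs are untouched.

## The training engine

Models are trained with a compact reverse-mode automatic-differentiation
engine over numpy arrays (`taha.autodiff`), implementing exactly the
operations the transformer needs, with float64 accumulation and an Adam
optimizer. The models in this package are small enough (tens of
thousands of parameters) that this keeps the whole stack inspectable and
bitwise reproducible; it is not intended for large-scale training.

## Iterative procedure

Each outer iteration: (1) alignment steps on `mean_h DAL_h + λ·PCC`
against the frozen snapshot; (2) head scoring (DAL on a held target
batch, correlation on the labeled target subset — the only place labels
exist); (3) threshold + surgery on both the live model and the frozen
reference (whose parameters are never *updated*; a hash check in the
tests guards this); (4) supervised fine-tuning of the remaining heads and
classifier on the labeled target fraction. Optimizer state is rebuilt
after surgery because parameter shapes change.

Convergence: the loop stops when an outer iteration prunes nothing, but
only after at least `min_outer_iters = 2` iterations — at iteration 1,
λ is still on warmup and no fine-tuning pass has occurred, so a
prune-free first iteration is not yet evidence of convergence. A hard cap
`max_outer_iters = 5` bounds the loop. Pruning is the only irreversible
state change, which is why a prune-free (post-warmup) iteration is the
natural stopping signal.

λ warms up linearly from 0.1 to 1.0 over 50 steps and stays constant
afterwards, so alignment dominates early and phenotype preservation
dominates late.

**Learning rates.** The default alignment rate is Adam 3e-3 and the
pre-train/fine-tune rate 1e-3. These are calibrated to the package's
step budgets (a few hundred steps on a 2-layer backbone): at rates
appropriate for a 86M-parameter backbone trained for many epochs (3e-5),
a few hundred steps move the per-head alignment loss by less than 1e-2
and the dynamic threshold never fires. Batch size is 32.

**Seeding.** One master seed derives per-stage seeds (data generation,
initialization, batching, per-iteration fine-tuning) by fixed offsets;
two runs with the same config are bitwise identical on one machine.

## Synthetic benchmark

The generator emulates a cross-species transfer pair:

* **Shared morphology (class signal):** an elliptical leaf blob whose
  axis lengths are drawn from disjoint per-class ranges, crossed by a
  class-dependent number of darker vein lines. The blob sits in the
  lower-right interior of the frame. Both domains use identical shape
  parameters — the "shared trait" assumption.
* **Species texture (domain signal):** background intensity, pixel
  noise, and a high-frequency diagonal grating whose amplitude is
  `0.25·shift_magnitude`, present only in the target. The band-pass
  spectral discrepancy between domains is monotone in `shift_magnitude`
  (a tested invariant).
* **Planted non-transferable cue:** in the source domain only, a bright
  8-px top-left corner marker ("glyph") appears for half of the classes,
  i.e. a presence/absence code. Reading it requires attention anchored to
  that corner. In the target domain the same corner carries *clutter* —
  a per-image random brightness uncorrelated with the label — so heads
  that learned to read the corner inject pure noise into prediction.
  This gives the pruning experiments a controllable ground truth: a head
  is called *glyph-attending* when its class-token attention row puts
  more than twice the uniform share of mass on glyph tokens, measured on
  glyph-carrying source images with the source-pretrained model.

Default study conditions: 4 classes, 32×32 RGB images, 320 source / 400
target images, 12.5 % of the target labeled (stratified so every class is
represented), `shift_magnitude = 1.0`. The default backbone is 2 layers ×
4 heads, embedding 32, 16-px patches (5 tokens including the class
token).

Two generator-design points deserve explanation. First, the 16-px patch
choice: both spec-level reductions — row-averaged KL and token-mean
pooling — average per-head signals over all query rows/tokens, so any
cue expressed in a single attention row is diluted by the token count. At
5 tokens a corner-anchored head's behavior remains visible in its scores;
at 17+ tokens it vanishes into the average. Second, the corner clutter:
a glyph that is merely *absent* in the target makes glyph heads useless
but harmless — they receive no gradient, never drift from the frozen
reference, and are invisible to both HTS terms. The label-independent
clutter makes them actively noisy, which lowers their correlation and
creates the restructuring pressure that raises their alignment loss.

**What passing tests do and do not show.** The benchmark demonstrates the
mechanics of alignment, scoring and surgery under a controlled shift with
known ground truth. It does not model photorealistic plants, intra-class
morphological diversity, illumination, occlusion, or label noise, and the
tiny backbone has little of the head redundancy of a 12×12 ViT — so
quantitative pruning rates here do not predict rates on real phenotyping
data. Per-head attribution at this scale is intrinsically noisy: with
eight heads, residual mixing spreads class information across all heads,
and the correlation term separates planted from transferable heads only
partially. In the 10-seed recovery experiment the acceptance script
reports, the run-level clauses (some head pruned; accuracy within 5
points of the unpruned control) hold in nearly all runs, while the
glyph-targeting clause (a glyph-attending head among the pruned) holds in
most but not all runs — the honest operating point of the method at this
scale.

## Cost accounting

Parameter counts are exact closed forms per configuration (patch
embedding, positions, class token, per-layer QKV/W_O′/norms/MLP, final
norm; classifier excluded by default) and are tested against
instantiation. MAC counts use the vision-community convention
1 MAC = 1 reported "FLOP", include the patch-embedding projection and
all projection/attention/MLP matmuls, and exclude softmax, norms, GELU
and the classifier — the convention under which the 12-layer, 12-head,
768-dim backbone at 224×224 with 16-px patches costs 17.6 G (3
significant figures), matching the published scale for that
architecture. Attention MACs are exactly linear in head count at fixed
token count and head width. Percent reductions are `100·(1 − pruned/full)`
rounded half-up to one decimal; giga-scale counts are shown to 3
significant figures.

## Numerical choices

* Softmax and log-softmax subtract the row maximum (a constant under
  differentiation) before exponentiation.
* KL smoothing `ε = 1e-8` added inside both logarithms; DAL of identical
  maps is below 1e-6 rather than exactly 0.
* Layer norm uses `ε = 1e-6`; GELU is the exact erf form.
* z-scoring (labels, correlation columns) treats zero-variance columns as
  zero contribution rather than dividing by zero.
* All gradients accumulate in float64.
* Ties at the pruning threshold are retained (`HTS ≥ τ`).
* Glorot-uniform initialization throughout; positional terms and class
  token start at N(0, 0.02).

## Limitations

* The MLP head and the patch embedding update policy during alignment is
  a config switch (`update_patch_embed`, default off); the attention
  parameters and the MLP head always update.
* λ_max and the warmup length are package defaults (1.0, 50 steps), not
  externally fixed constants.
* No GPU path, mixed precision, pretrained-checkpoint loading, token
  pruning or quantization; no adversarial (DANN-style) alignment.
* The pruned-model absolute costs of a 12×12 backbone reported in the
  transfer-learning literature are not reachable by attention-head
  removal alone (MLP blocks dominate and are untouched); the accounting
  module reproduces reduction *arithmetic* and full-model counts, and
  computes true costs for its own pruned configurations.
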