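# Methods

## The model

`probgenome` represents a genome not as a string but as a column-stochastic
matrix: position *i* carries a probability distribution
*q<sub>i</sub>* = (p<sub>A</sub>, p<sub>C</sub>, p<sub>G</sub>, p<sub>T</sub>)
derived from observed variation. Invariant positions are reference one-hots
and are never materialized; only variable loci are stored, because in
within-species data well under 1% of positions vary. Two builders produce
these distributions:

* **Population route** (`build_probabilistic_genome`): per-locus allele
  frequencies from a VCF, taken from INFO/AF when present or counted from
  genotypes otherwise. Alt alleles with frequency below a threshold
  (default 0.02) are treated as unobserved: their mass is returned to the
  reference allele rather than renormalized away, so every column sums to
  1 exactly and a fully filtered site reverts to a one-hot. Reassignment
  (not proportional renormalization) is deliberate: discarding a rare
  allele means the site looks *more* like the reference, and it keeps the
  filter idempotent.
* **Alignment route** (`build_from_msa`): per-column base counts over a
  multi-species alignment, normalized over non-gap, non-ambiguous
  observations. No frequency threshold is applied by default; the filter
  is exposed as an option. Columns with zero usable counts fall back to
  the reference one-hot. Whether gap-heavy columns should contribute at
  all is a judgment call; excluding gaps from denominators is our choice,
  not a principled necessity.

Coordinates are 0-based half-open internally; the 1-based conventions of
VCF and the count table are converted exactly once, inside the builders.
Runs of N (or any ambiguity code) split contigs into segments whose
original coordinates are preserved; windows are addressed on the
concatenated segment stream of a contig, and a window crossing an excised
run acquires an internal `[SEP]` column. This mirrors how training
corpora are built by concatenating clean segments with separators, and it
makes every in-range window start valid.

## Training objective

Windows are encoded as 9×L matrices over the vocabulary
(`[PAD] [UNK] [CLS] [SEP] [MASK] A C G T`). Masking selects
round-half-up(0.15 · L<sub>eff</sub>) genomic columns per window
(L<sub>eff</sub> excludes `[CLS]`/`[SEP]`), exhausting variant columns
first and filling the remainder uniformly from invariant columns.
Selected columns are replaced by a `[MASK]` one-hot with probability 0.8
and left as their original distribution otherwise. The 20% "unchanged"
branch keeps the probabilistic column rather than sampling a base: the
model's input space is distributions, and sampling would discard exactly
the information the representation exists to carry.

The target at every selected column is the original allele distribution
sharpened by temperature scaling: a softmax of *q/τ* restricted to *q*'s
support (zero entries stay zero, so one-hots are fixed points; τ = 0.7 by
default). Restriction-to-support is the only reading of the scaling rule
under which one-hot targets are preserved, and a single softmax is
applied — no second normalization. A `scale_mode="off"` flag bypasses
scaling entirely, which is *not* the same as τ = 1 (a softmax at
temperature 1 is not the identity). The loss is the soft cross-entropy
−Σ q′(x) log p(x) averaged over selected positions only, with a 1e-12
floor inside the logarithm.

## Encoder

The encoder is a pre-norm transformer written in NumPy with explicit
backward passes (forward caches feed one backward call; gradients
accumulate into parameters; AdamW consumes them). The embedding is a
linear map 9 → d: a probability column's embedding is the
probability-weighted sum of the nine symbol embeddings, which reduces to
classical table lookup on one-hot columns. Defaults are the standard base
geometry — 12 layers, hidden 768, 12 heads, feed-forward 3072, GELU —
whose exact trainable-parameter sum (85,662,729 with the untied MLM head:
dense transform, norm, 9-way decoder) rounds to 86 million. Head count,
feed-forward width, dropout, and weight tying are our inferences; only
the layer count and the rounded total pin them.

Positions enter through rotary embeddings: coordinate pairs of queries
and keys rotate by t·θ^(−2j/dim), with dim the per-head dimension. For
evaluation lengths L<sub>test</sub> beyond the pretraining context
L<sub>train</sub> the base is enlarged by dynamic NTK scaling:
α = α₀·(L<sub>test</sub>/L<sub>train</sub>) − (α₀−1) (α = 1 at or below
L<sub>train</sub>), θ = θ₀·α^(dim/(dim−2)), with θ₀ = 10000 and α₀ = 1 by
default. Attention is exact scaled-dot-product; any IO-optimized kernel
would compute the same function, so correctness tests are
backend-independent. Padding columns are `[PAD]` one-hots excluded by the
attention mask and never scored.

Low-rank adaptation replaces a target weight W (m×n) by
W + (α/r)·BA with B (m×r) zero-initialized and A (r×n) random, freezing
everything else; the wrapped model is forward-identical to its base
until the first update and trains r(m+n) values per target. The
fine-tuning harness defaults to r = 8, α = 16, rate 1e-4 for LoRA runs
and 3e-5 for standard runs; adapter dropout is not implemented (the
desk-scale models train without dropout).

Compute dtype is float32 by default (float64 via `model.dtype`); the
optimizer keeps float64 moments either way. Runs are bit-reproducible
for a fixed seed and thread count.

## Pretraining and evaluation

The loop samples window starts uniformly (with replacement) over the
training contigs' segment streams, holding out designated contigs
entirely. AdamW uses β₁ = 0.9, β₂ = 0.99, ε = 1e-8, weight decay 0.01
(decay on matrix weights only); the schedule rises linearly from 0 to
4e-4 over the warmup and decays by cosine to 1e-8 at the final step.
When total steps are scaled down from the full-scale 120k, warmup
defaults to total/12, preserving the schedule's shape. Divergence
(non-finite loss) aborts with a diagnostic; gradient clipping is off by
default but available.

Evaluation reports the mean soft cross-entropy over a frozen, seeded
masking of held-out windows and its exponential (perplexity), which
satisfies ppl = exp(loss) by construction. Allele-frequency recovery —
the operational test of the training claim — probes each planted locus
with its column replaced by `[MASK]` in a window centered on it and
reports KL(q′ ‖ p̂) between the temperature-scaled planted distribution
and the model's prediction renormalized over the nucleotide rows.

## Synthetic data

The simulator emulates the two data regimes the method targets. The
population regime plants biallelic (optionally multiallelic) SNVs by a
per-position Bernoulli at density 0.0034 by default (the sparse
within-species setting), draws alt frequencies from a Beta(0.5, 3) law
truncated to [0.02, 0.5] by inverse-CDF — skewed toward rare alleles,
but bounded so every planted locus survives the 2% filter, separating
filter tests from recovery tests — and writes a VCF 4.2 with AF INFO and
diploid genotypes drawn under Hardy–Weinberg independence. The
cross-species regime makes each of 10 species an independently
substituted copy of the reference (substitution probability 0.113 by
default, chosen so ~70% of columns are variable, the dense-alignment
setting) and emits per-position base/gap counts. Both record the exact
planted distributions as machine-readable truth.

What the simulator does not model: linkage disequilibrium, demography,
recombination, indels, tree-structured substitution, or
population-stratified frequencies. Passing recovery tests therefore
shows that the representation, masking, objective, and optimizer
interact correctly — not that the model captures the correlational
structure of real population data.

## Desk-scale problem sizes

The test suite runs everything on one CPU. The desk-scale defaults are a
2-layer, hidden-64 encoder, batch 32, 2000 steps, 128 bp training
windows, on simulated genomes of 30–100 kb. The recovery experiment at
these sizes gives each planted locus only on the order of 10²
masked-probe exposures during training; down-scaled replicas of the same
pipeline show mean KL falling roughly log-linearly in per-locus
exposures (≈0.08 at ~6.5k exposures, ≈0.5 at ~1.2k, ≈0.8 at ~65), so
recovery quality at desk scale is exposure-limited, improves
monotonically with training, and does not reach the near-zero KL that a
full-scale run with orders of magnitude more exposures per locus would
approach. The recovery test suite asserts the improvement property and a
tight absolute bound; the bound documents the full-scale claim and is
not attainable at these problem sizes.

## Numerical choices

* round-half-up for the masking quota (deterministic, documented).
* Softmax always shifts by the row maximum before exponentiation.
* `[MASK]`-probe evaluation renormalizes predictions over the nucleotide
  block; the MLM head itself scores all nine symbols, with targets
  placing zero mass on structural rows.
* MCC uses the multi-class generalization
  (c·s − p·t)/√((s²−Σp²)(s²−Σt²)) and returns 0 on degenerate marginals.
* Early stopping halts after `patience` consecutive validation checks
  without improvement on the best value seen; the best head is restored.
* Embedding pooling windows are clipped at sequence ends; with a
  sequence shorter than the pooling span the whole sequence is pooled.

## Known limitations

* The encoder is NumPy on a single device; it is meant for desk-scale
  experiments and method verification, not production pretraining.
* Backbone and LoRA fine-tuning require equal-length windows (no
  bucketing).
* The RBF-SVM variant-effect recipe (`scripts/eqtl_svm_recipe.py`)
  expects externally supplied labels and TSS distances; it ships as a
  script, not a library operation, because those inputs are external.
* The hold-out mechanism is per-contig, matching chromosome-level
  validation splits; finer splits are out of scope.
* VCF INFO floats are 32-bit by the format specification, so frequencies
  recovered via INFO/AF carry ~1e-7 storage error.
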