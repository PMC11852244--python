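# Methods

`sebird` classifies human regulatory elements as super-enhancers (SE) or
typical enhancers (TE) from DNA sequence alone. This note records the
model, the data-construction procedure, the synthetic study conditions,
the numerical choices, and the limitations of what the desk-scale tests
demonstrate.

## The classification problem and the length leak

SEs are clusters of enhancer elements spanning many kilobases; TEs are
single elements usually a few hundred bp long. Any classifier given raw
intervals could therefore separate the classes from length alone without
reading a single base — a data leak that would make reported accuracy
meaningless as evidence of sequence-encoded signal. The preprocessing
pipeline removes the leak before the model ever sees a sequence:

1. **SE length filtering.** SEs shorter than 2,500 bp are discarded;
   SEs longer than 25,000 bp are trimmed to exactly 25,000 bp. Trimming
   is symmetric about the interval midpoint — the trimming side is a
   free choice, and keeping the centre preserves the presumed SE core
   rather than an arbitrary end.
2. **TE flank augmentation.** The SE length distribution is cut into
   M bins of 50 bp; TE lengths are cut into M equal-width bins over the
   TE range and paired with the SE bins by index. Each TE of length *l*
   at (*s*, *e*) draws a new length *new_l* uniformly from the actual SE
   lengths (≥ *l*) in its paired bin — an empirical draw, which
   preserves the SE length distribution exactly rather than smearing it
   uniformly over the bin — and a new start uniformly in
   [*s* − (*new_l* − *l*), *s*], so the extended window always contains
   the source TE. If the paired bin holds no candidate, the nearest
   non-empty bin is used; if no SE is as long as the TE, the TE is left
   unchanged. Windows that would cross a chromosome boundary are shifted
   inward with their length preserved.
3. **Overlap exclusion.** After augmentation, any window overlapping the
   exclusion annotation (ORFs, other regulatory elements) or an
   already-retained window is dropped (first kept wins, in input order).
   Running this after augmentation matters: the flanks are new sequence
   and can swallow foreign elements. Exclusion is applied across both
   classes, the strictest reading of "do not overlap with each other".
4. **Token-length balancing.** Sequences are BPE-tokenized and binned by
   token count in 50-token bins; in every bin the over-represented class
   is subsampled uniformly at random to the smaller count, so per-bin
   and total class counts match exactly.
5. **Split.** A random 3:1 train/test partition (train receives the
   extra example on odd sizes — arbitrary but documented). Exact
   duplicate sequences are removed before splitting, and a source-id
   check guarantees no interval contributes to both sides.

Distribution matching is verifiable: the two-sample Kolmogorov–Smirnov
statistic between TE and SE lengths drops from ≈1.0 before augmentation
to ≈0.1 after (computed live by `scripts/acceptance.py`).

## Tokenization

DNA has no words, so byte-pair encoding runs on the whole sequence: the
most frequent adjacent token pair is merged repeatedly, starting from
{A, C, G, T, N}, until the vocabulary reaches its target size. Count
ties break lexicographically on the (left, right) strings, making
training deterministic. `N` is inert — no merge rule may touch a token
containing it — so ambiguous runs stay as single characters. The
production vocabulary size for this model family is 32,000; the
desk-scale default is 512, which on synthetic genomes gives ≈4 bp per
token. Encoding applies merges in learned priority order with a
heap over a linked token list (O(n log n)), tracks per-token (start,
end) bp offsets, prepends a [CLS] token with a zero-width offset, and
truncates from the 3' end when a limit applies (the 5' end is kept; the
truncation side is a free choice, fixed and documented).

## Model

A BigBird-style encoder: learned token embeddings plus learned absolute
position embeddings, layer-normalised; then N identical layers of
block-sparse multi-head self-attention and a GELU feed-forward block,
each with residual connection and post-layer-norm. Attention over
token blocks of `block_size` is restricted to the union of (i) global
blocks (the first `n_global_blocks`, which attend to and from all),
(ii) a sliding window of `n_window_blocks` nearest neighbours, and
(iii) `n_random_blocks` uniformly drawn partner blocks per block, drawn
once per model instantiation from a recorded seed. At desk scale the
sparsity is a boolean mask over dense attention — mathematically
identical to blocked kernels, verified against an independently written
dense forward pass. The classification head reads the [CLS] hidden
state through dropout → linear → GELU (tanh approximation) → dropout →
linear, yielding a (1, 2) logit row.

Two presets ship with the package:

| preset | layers | heads | hidden | block | random/global/window | positions | vocab |
|--------|-------:|------:|-------:|------:|:--------------------:|----------:|------:|
| full   | 12     | 12    | 768    | 64    | 3 / 2 / 3            | 4096      | 32000 |
| tiny   | 2      | 2     | 32     | 16    | 1 / 1 / 3            | 256       | 512   |

The full preset is the production geometry (≈112 M parameters by the
analytic count); every test and the acceptance script run the tiny
preset, whose 256-position window sees roughly the first kilobase of
each sequence.

All forward/backward computation runs on a small reverse-mode autodiff
engine over numpy (`sebird.autograd`), verified against central finite
differences. Masked-language-model pre-training (masking 15% of
non-special tokens and predicting them) is available at desk scale via
`pretrain_mlm`; classification fine-tuning does not require it.

## Training

Two stages with cross-entropy loss and AdamW: first the head alone for
5 epochs with every encoder parameter frozen (bit-exact: the optimizer
simply never touches them), then all parameters for 10 more epochs.
The validation curve uses the held-out test split; there is no third
split and no early stopping. Default learning rates are 1e-3 (head) and
3e-4 (full) with batch size 8 and weight decay 0.01. These defaults
suit the from-scratch tiny configuration this package actually trains;
fine-tuning a large pretrained encoder would conventionally use rates
one to two orders of magnitude lower, and all of this is exposed in
`TrainSchedule`. Batches shuffle each epoch, then group examples of
similar token length to limit padding waste; everything is
bit-reproducible under a fixed seed.

## Evaluation and statistics

Six metrics — accuracy, F1, precision, recall, ROC AUC, MCC — with
precision/recall/F1 macro-averaged over the two classes (macro
averaging is what makes F1 differ slightly from accuracy on nearly
balanced test sets). ROC AUC is reported as NaN when only one class is
present. Model-vs-random comparison uses McNemar's test on the
discordant counts b (model right, coin wrong) and c (model wrong, coin
right): exact binomial when b + c < 25, otherwise chi-square with
continuity correction clamped at zero (so b = c gives statistic 0,
p = 1). The random baseline is a fair coin with a recorded seed.
Negative controls are 50 random genomic windows of 2,500–5,000 bp;
the model's class-1 scores on them are compared with a no-information
score sample (uniform on [0, 1]) by the two-sample Kolmogorov–Smirnov
test with asymptotic p-value.

## Interpretation

Integrated gradients attributes the class-1 logit to input tokens by
integrating gradients along the straight path from a baseline embedding
to the input embedding (midpoint rule, default 50 steps; 200 steps
brings the completeness identity — attributions summing to
logit(input) − logit(baseline) — within 2%). The baseline is the [PAD]
token embedding at every position, a standard neutral reference;
position embeddings are shared by both endpoints. Per-token scores are
summed over embedding dimensions (the only granularity compatible with
per-token browser tracks). For display, scores are multiplied by
1000 / max|score| and rounded, so the strongest token scores exactly
±1000; positive (SE-supporting) and negative (TE-supporting) tokens go
to separate BED6 files, the negative file storing absolute values with
the sign in the name field because browser grayscale shading requires
scores in 0–1000. Attribution covers the model-visible prefix of a
sequence (the position window); tokens beyond it receive no score.
Layer-conductance attribution is not implemented; integrated gradients
is the single supported backend.

## Synthetic study conditions

The generator emulates the statistical structure of real SE/TE
collections with zero downloads. Defaults, chosen once:

- Genome: one 12 Mb chromosome, i.i.d. bases at GC 0.41 (the human
  genome-wide value). The length and the 3 kb minimum inter-region gap
  give flank-augmented TE windows (median ≈8 kb) room to avoid
  colliding with neighbouring planted regions.
- 200 SE regions with log-normal lengths (median 8 kb, σ = 0.55,
  clipped to 2.5–25 kb) and 200 TE regions (median 800 bp, σ = 0.45).
- Class signal is a motif-density difference: TFBS-like 8-mers written
  into SE regions at 10/kb and different 8-mers into TE regions at
  2/kb — a 5:1 ratio, biologically motivated by the TFBS enrichment
  observed in high-attention SE subsequences, at a level a tiny model
  can learn from ~150 training examples. `SyntheticSpec.null_signal()`
  equalises the densities, removing all sequence signal.
- 20 ORF decoys (ATG + stop-free codons + stop), half placed just
  downstream of TEs so that flank extension runs into them, exercising
  the annotation-exclusion path.

After preprocessing this yields ≈165 train / ≈55 test examples, a
deliberate desk-scale regime. One spec is one synthetic "cell line";
multi-line pooling (800 per line pooled, 2,500 sampled — or smaller
desk-scale numbers) is exercised with fixtures differing in seed.

What the synthetic conditions do **not** emulate: repeat structure,
isochores and local GC heterogeneity, real TFBS motif degeneracy
(PWM-like variation), chromatin context, and assembly artefacts. A
passing suite therefore shows the pipeline and model are correct and
can learn a planted sequence signal — not that the tiny configuration
would reach any particular accuracy on real cell-line data.

## Behaviour on the null fixture

On the no-signal fixture the fitted model's test accuracy sits at
chance and McNemar against the random coin is non-significant, as the
negative-control logic requires. One caveat is worth stating plainly:
the null model's *scores* on negative controls are not random — 
cross-entropy training on an unlearnable task converges to the class
prior, so the model emits nearly the same probability (~0.5) for every
input. A two-sample KS test between that near-constant sample and any
non-degenerate random-score sample is therefore significant even though
the model knows nothing. Score-distribution KS comparisons against a
random baseline are meaningful for models with genuine score spread;
for degenerate-score models the prediction-level McNemar comparison is
the informative negative control, and that is the one the package's
null check relies on.

## Numerical choices and edge cases

- Coordinates are 0-based half-open everywhere (BED convention);
  touching intervals do not overlap. Strand is ignored.
- Attention masking adds −1e9 to disallowed logits before softmax;
  padding tokens are masked as keys, so right-padding a batch never
  changes any logit (asserted to 1e-9).
- Layer-norm ε is 1e-12; parameter init is N(0, 0.02²); float64
  throughout — determinism across runs on the same platform is exact.
- BPE training stops early if no pair occurs twice; the vocabulary may
  then be smaller than its target (never larger).
- `filter_se` with an empty result, single-class metric vectors
  (NaN AUC), b + c = 0 in McNemar (p = 1), all-zero attribution tracks
  (two empty BEDs) are all handled and tested.

## Problem sizes

Tests and the acceptance script use the tiny preset on the default
synthetic conditions: ~330 sequences per fixture before balancing,
256-token model window, 5 + 10 epochs. The full acceptance script
(two complete pipelines plus attribution) completes in a few minutes on
one CPU core; the dense-oracle, augmentation (1,000 seeded runs) and
tokenizer (1,000 round-trips) batteries each run in seconds.
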