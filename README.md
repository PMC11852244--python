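# sebird

Sequence-only classification of **super-enhancers (SE)** versus
**typical enhancers (TE)** in genomic DNA, using a block-sparse-attention
transformer over byte-pair-encoded nucleotide sequence.

Super-enhancers are clusters of enhancer elements spanning many
kilobases with exceptionally high transcription-factor and chromatin-mark
enrichment; typical enhancers are single, much shorter elements.
Distinguishing them from sequence alone is confounded by an obvious
leak: the classes differ grossly in length. `sebird` implements the
full leakage-aware pipeline — SE length filtering and trimming, TE
**flank augmentation** that matches the TE length distribution to the
SE distribution bin-by-bin, exclusion of windows overlapping ORFs or
other elements, per-token-length-bin class balancing, and a 3:1 split —
followed by DNA BPE tokenization, two-stage fine-tuning (classifier
head first, then all layers) of a BigBird-style encoder with
random/window/global block attention, the standard six-metric
evaluation battery with McNemar and Kolmogorov–Smirnov comparisons
against a random classifier, and integrated-gradients token
attributions exported as genome-browser BED tracks.

The package is aimed at regulatory-genomics researchers who want to
(a) build honest SE/TE sequence datasets from BED + FASTA inputs,
(b) probe what a sequence model can learn at desk scale on synthetic
genomes with planted, controllable signal, and (c) inspect *where* in a
sequence a trained model finds SE-like content.

## The model

Token embeddings plus learned absolute position embeddings feed an
encoder whose attention is restricted, over token blocks of size *b*,
to the union of **global** blocks (attending to and from everything),
a sliding **window** of neighbouring blocks, and a few **random**
partner blocks per block — approximating full attention at a fraction
of the cost, which is what makes 4,096-token (~36 kb) inputs tractable.
The `[CLS]` state passes through a dropout → linear → GELU → dropout →
linear head to a 2-class logit. Training minimises cross-entropy in
two stages (head-only with a frozen encoder, then all parameters); the
production geometry (12 layers, 12 heads, hidden 768, block 64,
3 random / 2 global / 3 window blocks) ships as the `full` preset, and
a 2-layer `tiny` preset drives all tests. The transformer, its
training loop, the BPE tokenizer and integrated gradients are
implemented on a small numpy reverse-mode autodiff engine included in
the package — no deep-learning framework required.

See `docs/methods.md` for the complete methodological account.

## Worked example

```python
from sebird import SyntheticSpec, make_fixture, SuperEnhancerClassifier

fixture = make_fixture(SyntheticSpec(seed=1))   # 12 Mb genome, 200 SE + 200 TE planted
clf = SuperEnhancerClassifier.from_fixture(fixture, seed=1)
result = clf.fit(seed=1)
print(result.summary())
```

```
Super-enhancer sequence classifier — fit summary
========================================================
Train examples:             165
Test examples:              55
Vocabulary size:            512
Encoder:                    2 layers, 2 heads, hidden 32
Attention blocks:           size 16, 1 random / 1 global / 3 window
Parameters:                 51,170
Schedule:                   5 head + 10 full epochs, batch 8, seed 1
--------------------------------------------------------
Final train loss:           0.1374
Final validation loss:      0.0767
--------------------------------------------------------
Accuracy:   1.0000    F1:       1.0000
Precision:  1.0000    Recall:   1.0000
ROC AUC:    1.0000    MCC:      1.0000
Confusion (TP/FP/FN/TN): 24/0/0/31
========================================================
```

The synthetic cell line plants TFBS-like motifs at 10/kb in SEs versus
2/kb in TEs; after flank augmentation both classes have SE-like
lengths, so the only separating signal is sequence content — which the
tiny model finds (here perfectly, on 55 held-out sequences). The
comparison battery and attribution hang off the same result object:

```python
result.mcnemar_vs_random(seed=2)
# PairedTestResult(statistic=31.03, p_value=2.5e-08, method='mcnemar_chi2', b=33, c=0)

tracks = result.attribute_top(k=5, steps=50, outdir="tracks/")
# writes se_top1_positive.bed / se_top1_negative.bed, ... with scores
# scaled by 1000/max|score|; the strongest token scores exactly ±1000
```

A no-signal control is one call away — `SyntheticSpec(seed=1).null_signal()`
equalises the motif densities; the fitted model then sits at chance
accuracy and McNemar against a fair coin is non-significant.

## Command line

Every stage is also a subcommand of `sebird`:

```bash
sebird make-fixture --seed 1 --out fx/            # genome.fa, se.bed, te.bed, annotation.bed
sebird build-dataset --se fx/se.bed --te fx/te.bed --genome fx/genome.fa \
    --annotation fx/annotation.bed --seed 1 --out ds/
sebird train --tokenizer ds/tokenizer --train ds/train.fa --test ds/test.fa \
    --seed 1 --out ckpt/
sebird evaluate --ckpt ckpt/ --tokenizer ds/tokenizer --test ds/test.fa --out metrics.json
sebird attribute --ckpt ckpt/ --tokenizer ds/tokenizer --test ds/test.fa \
    --k 5 --steps 200 --out tracks/
```

`train-tokenizer` and `tokenize` expose the BPE tokenizer on its own.

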