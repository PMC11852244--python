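"""Integrated-gradients token attribution, mapped to genome-browser tracks.

Integrated gradients attributes a prediction to its inputs by
integrating the gradient of the target logit along the straight path
from a neutral baseline embedding (here: the [PAD] token embedding at
every position) to the actual input embedding. The per-token score is
the sum over embedding dimensions of (input - baseline) * average
gradient; by the completeness property, the token scores sum to
logit(input) - logit(baseline).

Positive scores push the sequence toward class 1 (super-enhancer),
negative toward class 0 (typical enhancer). For browser display the
scores are rescaled by 1000 / max|score| and rounded, so the strongest
token in a track always scores +/-1000; positive and negative tokens
are written to two separate BED files (scores stored as absolute values
with the sign recorded in the name field, since BED grayscale shading
requires scores in 0-1000).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .autograd import Tensor
from .bpe import PAD_ID, TokenizedExample
from .intervals import GenomicInterval
from .model import SparseTransformerClassifier


def integrated_gradients(
    model: SparseTransformerClassifier,
    example: TokenizedExample,
    target_class: int = 1,
    steps: int = 50,
) -> np.ndarray:
    """Per-token attribution scores for ``target_class`` (midpoint-rule
    path integral with ``steps`` points). Returns one score per token,
    including the zero-width [CLS] token at index 0."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    was_training = model.training
    model.eval_mode()
    example = example.truncated(model.config.max_positions)
    ids = np.asarray(example.ids, dtype=int)[None, :]
    pad_mask = ids != PAD_ID
    input_emb = model.embed(ids).data  # includes position embeddings
    n_pos = ids.shape[1]
    baseline_ids = np.full_like(ids, PAD_ID)
    baseline_emb = model.embed(baseline_ids).data
    delta = input_emb - baseline_emb

    total_grad = np.zeros_like(input_emb)
    for k in range(steps):
        alpha = (k + 0.5) / steps
        point = Tensor(baseline_emb + alpha * delta, requires_grad=True)
        logits = model.forward_from_embeddings(point, pad_mask)
        logits[0, target_class].backward()
        total_grad += point.grad
    from .autograd import parameters_zero_grad

    parameters_zero_grad(model.params.values())
    model.training = was_training
    avg_grad = total_grad / steps
    scores = (delta * avg_grad).sum(axis=-1)[0]  # sum over embedding dims
    assert scores.shape == (n_pos,)
    return scores


def attribution_completeness_gap(
    model: SparseTransformerClassifier,
    example: TokenizedExample,
    scores: np.ndarray,
    target_class: int = 1,
) -> tuple[float, float]:
    """(sum of attributions, logit(input) - logit(baseline)) — equal in
    the limit of infinitely many integration steps."""
    example = example.truncated(model.config.max_positions)
    ids = np.asarray(example.ids, dtype=int)[None, :]
    pad_mask = ids != PAD_ID
    model.eval_mode()
    logit_in = model.forward_from_embeddings(model.embed(ids), pad_mask)
    logit_base = model.forward_from_embeddings(
        model.embed(np.full_like(ids, PAD_ID)), pad_mask
    )
    diff = float(logit_in.data[0, target_class] - logit_base.data[0, target_class])
    return float(scores.sum()), diff


def top_ranked_examples(
    examples: Sequence[TokenizedExample],
    class1_scores: Sequence[float],
    k: int = 5,
) -> list[int]:
    """Indices of the k true-class-1 examples with the highest class-1
    score; ties and ranking resolve toward earlier input order. If fewer
    than k class-1 examples exist, all are returned."""
    candidates = [i for i, ex in enumerate(examples) if ex.label == 1]
    # stable sort on negated score keeps earlier inputs first on ties
    order = sorted(candidates, key=lambda i: -float(class1_scores[i]))
    if len(candidates) < k:
        import warnings

        warnings.warn(
            f"only {len(candidates)} class-1 examples available (k={k})",
            stacklevel=2,
        )
    return order[:k]


@dataclass
class AttributionTrack:
    """Raw and browser-scaled attribution scores for one sequence."""

    source: GenomicInterval
    raw_scores: np.ndarray  # per content token (CLS excluded)
    offsets: tuple[tuple[int, int], ...]  # bp spans within the source interval

    def __post_init__(self) -> None:
        if len(self.raw_scores) != len(self.offsets):
            raise ValueError("one raw score per token offset required")

    @property
    def scale_factor(self) -> float:
        peak = float(np.max(np.abs(self.raw_scores))) if len(self.raw_scores) else 0.0
        return 0.0 if peak == 0.0 else 1000.0 / peak

    @property
    def scaled_scores(self) -> np.ndarray:
        return np.round(self.raw_scores * self.scale_factor).astype(int)

    @classmethod
    def from_example(
        cls,
        example: TokenizedExample,
        source: GenomicInterval,
        token_scores: np.ndarray,
    ) -> "AttributionTrack":
        """Drop zero-width special-token spans (e.g. [CLS]) and keep the
        content tokens whose offsets tile the attributed sequence."""
        keep = [i for i, (s, e) in enumerate(example.offsets) if e > s]
        return cls(
            source=source,
            raw_scores=np.asarray(token_scores, dtype=float)[keep],
            offsets=tuple(example.offsets[i] for i in keep),
        )


def to_bed_tracks(
    track: AttributionTrack,
    positive_path: str | Path,
    negative_path: str | Path,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Split scaled scores into SE-supporting (positive) and
    TE-supporting (negative) BED tracks in genomic coordinates."""
    positive: list[GenomicInterval] = []
    negative: list[GenomicInterval] = []
    base = track.source.start
    chrom = track.source.chrom
    for i, ((s, e), score) in enumerate(zip(track.offsets, track.scaled_scores)):
        if score == 0:
            continue
        iv = GenomicInterval(
            chrom, base + s, base + e,
            name=f"tok{i}:{'+' if score > 0 else '-'}",
            score=int(abs(score)),
        )
        (positive if score > 0 else negative).append(iv)
    from .intervals import write_bed

    write_bed(positive, positive_path)
    write_bed(negative, negative_path)
    return positive, negative
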