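"""Leakage-aware SE/TE dataset construction.

Raw super-enhancer (SE) and typical-enhancer (TE) calls differ grossly in
length (SEs span tens of kb, TEs hundreds of bp), so a classifier could
separate the classes from length alone — a data leak. The pipeline here
removes that leak and builds balanced train/test sets:

1. SEs shorter than 2,500 bp are dropped; SEs longer than 25,000 bp are
   trimmed (symmetrically about their midpoint) to exactly 25,000 bp.
2. Each TE is extended with random flanking sequence so that the TE
   length distribution matches the SE length distribution: SE lengths
   are binned at 50 bp, TE lengths into the same number of equal-width
   bins, bins are paired by index, and each TE draws its new length
   uniformly from the SE lengths in its paired bin. The new window is
   positioned uniformly among all placements that still contain the
   original TE.
3. Windows overlapping annotated ORFs/regulatory elements — or each
   other — are excluded (flanks included, since the extension step can
   pull foreign elements into a window).
4. Sequences are balanced per 50-token length bin (each bin keeps the
   smaller of the two class counts, subsampled at random) and split
   3:1 into train and test.

All randomness flows through an explicit ``numpy.random.Generator`` so
every step is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .intervals import Genome, GenomicInterval

SE_MIN_LEN = 2_500
SE_MAX_LEN = 25_000


@dataclass(frozen=True)
class LengthBinning:
    """Equal-width binning of lengths, in bp or tokens."""

    step: float
    edges: tuple[float, ...]
    unit: str  # "bp" | "tokens"

    def __post_init__(self) -> None:
        diffs = np.diff(self.edges)
        if len(self.edges) < 2 or not np.all(diffs > 0):
            raise ValueError("edges must be strictly increasing")
        if self.unit not in ("bp", "tokens"):
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @classmethod
    def from_step(cls, values: Sequence[float], step: float, unit: str) -> "LengthBinning":
        """Bins of width ``step`` aligned to multiples of ``step``."""
        lo = float(np.floor(min(values) / step) * step)
        hi = float(np.ceil((max(values) + 1) / step) * step)
        edges = tuple(np.arange(lo, hi + step / 2, step))
        return cls(step=step, edges=edges, unit=unit)

    @classmethod
    def from_count(cls, values: Sequence[float], n_bins: int, unit: str) -> "LengthBinning":
        """``n_bins`` equal-width bins spanning the value range."""
        lo, hi = float(min(values)), float(max(values)) + 1.0
        edges = tuple(np.linspace(lo, hi, n_bins + 1))
        return cls(step=(hi - lo) / n_bins, edges=edges, unit=unit)

    def assign(self, value: float) -> int:
        """Bin index of ``value``; values at the top edge go to the last bin."""
        idx = int(np.searchsorted(self.edges, value, side="right")) - 1
        return min(max(idx, 0), self.n_bins - 1)


@dataclass(frozen=True)
class LabeledSequence:
    """A nucleotide sequence with its class label and provenance."""

    seq: str
    label: int
    source: GenomicInterval
    cell_line: str | None = None
    n_tokens: int | None = None

    @property
    def source_id(self) -> str:
        iv = self.source
        base = f"{iv.chrom}:{iv.start}-{iv.end}"
        return f"{self.cell_line}|{base}" if self.cell_line else base


@dataclass
class DatasetSplit:
    train: list[LabeledSequence]
    test: list[LabeledSequence]
    seed: int

    def __post_init__(self) -> None:
        train_ids = {s.source_id for s in self.train}
        test_ids = {s.source_id for s in self.test}
        if train_ids & test_ids:
            raise ValueError("train/test leakage: shared source intervals")


def filter_se(
    se_intervals: Iterable[GenomicInterval],
    min_len: int = SE_MIN_LEN,
    max_len: int = SE_MAX_LEN,
) -> list[GenomicInterval]:
    """Drop SEs shorter than ``min_len``; centre-trim longer than ``max_len``.

    Trimming is symmetric about the interval midpoint, keeping the
    presumed SE core; the trimmed interval has length exactly ``max_len``.
    """
    out: list[GenomicInterval] = []
    for iv in se_intervals:
        n = iv.length()
        if n < min_len:
            continue
        if n > max_len:
            excess = n - max_len
            new_start = iv.start + excess // 2
            iv = iv.shifted(new_start, new_start + max_len)
        out.append(iv)
    return out


def exclude_overlaps(
    intervals: Sequence[GenomicInterval],
    annotation: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Keep intervals with zero-bp overlap with the annotation and with
    any already-retained interval (first kept wins, in input order)."""
    ann_trees: dict[str, IntervalTree] = {}
    for iv in annotation:
        ann_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    kept_trees: dict[str, IntervalTree] = {}
    out: list[GenomicInterval] = []
    for iv in intervals:
        if iv.chrom in ann_trees and ann_trees[iv.chrom].overlap(iv.start, iv.end):
            continue
        tree = kept_trees.setdefault(iv.chrom, IntervalTree())
        if tree.overlap(iv.start, iv.end):
            continue
        tree.addi(iv.start, iv.end)
        out.append(iv)
    return out


def augment_te_lengths(
    te_intervals: Sequence[GenomicInterval],
    se_lengths: Sequence[int],
    chrom_lengths: Mapping[str, int],
    rng: np.random.Generator,
    step: int = 50,
) -> list[GenomicInterval]:
    """Extend each TE with flanking sequence to an SE-like length.

    SE lengths are binned at ``step`` bp into M bins; TE lengths into M
    equal-width bins over the TE range, paired by index. Each TE of
    length l draws new_l uniformly from the SE lengths (>= l) in its
    paired bin — nearest non-empty bin as fallback — then a new start
    uniformly in [s - (new_l - l), s], so the window always contains the
    source TE. Windows crossing a chromosome boundary are shifted inward
    with length preserved.
    """
    if len(se_lengths) == 0:
        raise ValueError("se_lengths must be non-empty")
    se_lengths_arr = np.asarray(se_lengths, dtype=int)
    se_binning = LengthBinning.from_step(se_lengths_arr, step, unit="bp")
    m = se_binning.n_bins
    te_lens = [iv.length() for iv in te_intervals]
    te_binning = LengthBinning.from_count(te_lens, m, unit="bp")

    bin_contents: list[np.ndarray] = [
        se_lengths_arr[
            (se_lengths_arr >= se_binning.edges[i])
            & (se_lengths_arr < se_binning.edges[i + 1])
        ]
        for i in range(m)
    ]
    non_empty = [i for i, c in enumerate(bin_contents) if len(c)]

    out: list[GenomicInterval] = []
    for iv in te_intervals:
        l = iv.length()
        idx = te_binning.assign(l)
        new_l = _draw_new_length(bin_contents, non_empty, idx, l, rng)
        chrom_len = chrom_lengths[iv.chrom]
        if new_l > chrom_len:
            raise ValueError(
                f"chromosome {iv.chrom} ({chrom_len} bp) shorter than "
                f"augmented length {new_l}"
            )
        new_s = int(rng.integers(iv.start - (new_l - l), iv.start + 1))
        new_e = new_s + new_l
        if new_s < 0:  # shift right, preserving length and containment
            new_s, new_e = 0, new_l
        if new_e > chrom_len:  # shift left
            new_s, new_e = chrom_len - new_l, chrom_len
        aug = iv.shifted(new_s, new_e)
        assert aug.contains(iv), "augmented window must contain its source TE"
        out.append(aug)
    return out


def _draw_new_length(
    bin_contents: list[np.ndarray], non_empty: list[int], idx: int, l: int,
    rng: np.random.Generator,
) -> int:
    """Uniform draw among SE lengths >= l, from the paired bin or the
    nearest bin holding a candidate; falls back to l if every SE is shorter."""
    order = sorted(non_empty, key=lambda i: (abs(i - idx), i))
    for i in order:
        candidates = bin_contents[i][bin_contents[i] >= l]
        if len(candidates):
            return int(candidates[rng.integers(len(candidates))])
    return l


def balance_bins(
    se_seqs: Sequence[LabeledSequence],
    te_seqs: Sequence[LabeledSequence],
    rng: np.random.Generator,
    step: int = 50,
) -> tuple[list[LabeledSequence], list[LabeledSequence]]:
    """Equalise per-token-length-bin class counts by random subsampling.

    Every sequence must carry ``n_tokens``. For each 50-token bin the
    over-represented class is subsampled uniformly at random down to the
    smaller count, so per-bin and total counts match exactly.
    """
    for s in list(se_seqs) + list(te_seqs):
        if s.n_tokens is None:
            raise ValueError("balance_bins requires token lengths (n_tokens)")
    all_tokens = [s.n_tokens for s in se_seqs] + [s.n_tokens for s in te_seqs]
    binning = LengthBinning.from_step(all_tokens, step, unit="tokens")

    def _group(seqs: Sequence[LabeledSequence]) -> dict[int, list[int]]:
        groups: dict[int, list[int]] = {}
        for i, s in enumerate(seqs):
            groups.setdefault(binning.assign(s.n_tokens), []).append(i)
        return groups

    se_groups, te_groups = _group(se_seqs), _group(te_seqs)
    se_keep: list[int] = []
    te_keep: list[int] = []
    for b in range(binning.n_bins):
        se_idx = se_groups.get(b, [])
        te_idx = te_groups.get(b, [])
        k = min(len(se_idx), len(te_idx))
        if k == 0:
            continue
        se_keep.extend(_subsample(se_idx, k, rng))
        te_keep.extend(_subsample(te_idx, k, rng))
    return (
        [se_seqs[i] for i in sorted(se_keep)],
        [te_seqs[i] for i in sorted(te_keep)],
    )


def _subsample(idx: list[int], k: int, rng: np.random.Generator) -> list[int]:
    if k == len(idx):
        return idx
    chosen = rng.choice(len(idx), size=k, replace=False)
    return [idx[i] for i in chosen]


def split_train_test(
    examples: Sequence[LabeledSequence],
    rng: np.random.Generator,
    seed: int = 0,
    ratio: tuple[int, int] = (3, 1),
) -> DatasetSplit:
    """Random 3:1 partition; with odd sizes the train side gets the extra."""
    n = len(examples)
    if n < sum(ratio):
        raise ValueError(f"need at least {sum(ratio)} examples, got {n}")
    n_test = n * ratio[1] // sum(ratio)
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [examples[i] for i in range(n) if i not in test_idx]
    test = [examples[i] for i in range(n) if i in test_idx]
    return DatasetSplit(train=train, test=test, seed=seed)


def build_integrative(
    per_line_datasets: Mapping[str, Sequence[LabeledSequence]],
    rng: np.random.Generator,
    per_line_n: int = 800,
    total_n: int = 2_500,
) -> list[LabeledSequence]:
    """Pool ``per_line_n`` sequences from each cell line, then draw
    ``total_n`` without replacement from the pool."""
    pool: list[LabeledSequence] = []
    for line in sorted(per_line_datasets):
        seqs = per_line_datasets[line]
        if len(seqs) < per_line_n:
            raise ValueError(
                f"cell line {line!r} has {len(seqs)} sequences, "
                f"fewer than per_line_n={per_line_n}"
            )
        chosen = rng.choice(len(seqs), size=per_line_n, replace=False)
        pool.extend(seqs[i] for i in chosen)
    if len(pool) < total_n:
        raise ValueError(f"pooled {len(pool)} sequences < total_n={total_n}")
    chosen = rng.choice(len(pool), size=total_n, replace=False)
    return [pool[i] for i in chosen]


def make_negative_controls(
    genome: Genome,
    rng: np.random.Generator,
    n: int = 50,
    min_len: int = 2_500,
    max_len: int = 5_000,
) -> list[GenomicInterval]:
    """``n`` unlabeled random genomic windows with uniform lengths in
    [min_len, max_len], positioned uniformly over all valid starts."""
    chrom_lengths = genome.chrom_lengths()
    out: list[GenomicInterval] = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        valid = {c: cl - length + 1 for c, cl in chrom_lengths.items() if cl >= length}
        if not valid:
            raise ValueError(f"no chromosome can hold a {length} bp window")
        chroms = sorted(valid)
        weights = np.array([valid[c] for c in chroms], dtype=float)
        chrom = chroms[int(rng.choice(len(chroms), p=weights / weights.sum()))]
        start = int(rng.integers(0, valid[chrom]))
        out.append(GenomicInterval(chrom, start, start + length, label=None))
    return out


@dataclass
class BuiltDataset:
    """Output of the end-to-end preprocessing pipeline."""

    split: DatasetSplit
    se_final: list[LabeledSequence] = field(default_factory=list)
    te_final: list[LabeledSequence] = field(default_factory=list)
    provenance: list[tuple[GenomicInterval, GenomicInterval]] = field(default_factory=list)
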