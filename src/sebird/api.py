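"""Model/Results front end for the SE-vs-TE classification pipeline.

``SuperEnhancerClassifier`` is constructed from data (either a planted
synthetic fixture or BED + FASTA files), runs the full leakage-aware
preprocessing — SE filtering, TE flank augmentation, overlap exclusion,
BPE tokenization, per-token-bin balancing, 3:1 split — and its
``fit()`` trains the block-sparse transformer with the two-stage
schedule, returning a ``ClassifierResults`` with the trained weights,
training curves, the test-set metric battery, and hooks for the
statistical comparisons and token attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import bpe, datasets, evaluation
from .attribution import (
    AttributionTrack,
    integrated_gradients,
    to_bed_tracks,
    top_ranked_examples,
)
from .datasets import DatasetSplit, LabeledSequence
from .intervals import Genome, GenomicInterval, read_bed
from .model import SparseAttentionConfig, SparseTransformerClassifier, load_preset
from .synthetic import PlantedFixture
from .training import TrainLog, TrainSchedule, fine_tune

DEFAULT_MAX_TOKENS = 4096
DEFAULT_VOCAB_SIZE = 512
_TOKENIZER_CORPUS_CAP = 400_000  # bp of corpus used to train the tokenizer


@dataclass
class PreparedData:
    """Everything the model needs after preprocessing."""

    split: DatasetSplit
    vocab: bpe.BpeVocab
    tokenized: dict[str, bpe.TokenizedExample]
    sources: dict[str, GenomicInterval]
    provenance: list[tuple[GenomicInterval, GenomicInterval]] = field(default_factory=list)

    def examples(self, which: str) -> list[bpe.TokenizedExample]:
        seqs = self.split.train if which == "train" else self.split.test
        return [self.tokenized[s.source_id] for s in seqs]


def build_dataset(
    genome: Genome,
    se_intervals: Sequence[GenomicInterval],
    te_intervals: Sequence[GenomicInterval],
    annotation: Sequence[GenomicInterval],
    rng: np.random.Generator,
    vocab: bpe.BpeVocab | None = None,
    vocab_size: int = DEFAULT_VOCAB_SIZE,
    max_tokens: int = DEFAULT_MAX_TOKENS,
    seed: int = 0,
    cell_line: str | None = None,
) -> PreparedData:
    """Run the preprocessing pipeline on interval inputs.

    Filtering -> TE flank augmentation -> overlap exclusion (after
    augmentation, so flank-acquired ORF overlaps are caught) -> sequence
    extraction -> tokenizer training (if no vocabulary given) ->
    per-50-token-bin balancing -> 3:1 train/test split.
    """
    from .intervals import LABEL_SE, LABEL_TE, extract_sequence

    se_f = datasets.filter_se(se_intervals)
    if not se_f:
        raise ValueError("no super-enhancers survive length filtering")
    aug_te = datasets.augment_te_lengths(
        te_intervals,
        [iv.length() for iv in se_f],
        genome.chrom_lengths(),
        rng,
    )
    provenance = list(zip(te_intervals, aug_te))
    kept = datasets.exclude_overlaps(list(se_f) + aug_te, annotation)
    se_kept = [iv for iv in kept if iv.label == LABEL_SE]
    te_kept = [iv for iv in kept if iv.label == LABEL_TE]

    def to_seqs(ivs: Sequence[GenomicInterval], label: int) -> list[LabeledSequence]:
        out = []
        seen: set[str] = set()
        for iv in ivs:
            seq = extract_sequence(genome, iv)
            if seq in seen:
                continue
            seen.add(seq)
            out.append(LabeledSequence(seq=seq, label=label, source=iv,
                                       cell_line=cell_line or iv.cell_line))
        return out

    se_seqs = to_seqs(se_kept, LABEL_SE)
    te_seqs = to_seqs(te_kept, LABEL_TE)

    if vocab is None:
        corpus: list[str] = []
        total = 0
        for s in se_seqs + te_seqs:
            corpus.append(s.seq)
            total += len(s.seq)
            if total >= _TOKENIZER_CORPUS_CAP:
                break
        vocab = bpe.train_bpe(corpus, target_size=vocab_size)

    tokenized: dict[str, bpe.TokenizedExample] = {}
    sources: dict[str, GenomicInterval] = {}

    def tokenize_all(seqs: list[LabeledSequence]) -> list[LabeledSequence]:
        out = []
        for s in seqs:
            ex = bpe.encode(vocab, s.seq, max_tokens=max_tokens, label=s.label,
                            source_id=s.source_id)
            tokenized[s.source_id] = ex
            sources[s.source_id] = s.source
            out.append(replace(s, n_tokens=ex.n_tokens))
        return out

    se_seqs = tokenize_all(se_seqs)
    te_seqs = tokenize_all(te_seqs)
    se_bal, te_bal = datasets.balance_bins(se_seqs, te_seqs, rng)
    split = datasets.split_train_test(list(se_bal) + list(te_bal), rng, seed=seed)
    return PreparedData(split=split, vocab=vocab, tokenized=tokenized,
                        sources=sources, provenance=provenance)


class SuperEnhancerClassifier:
    """SE-vs-TE sequence classifier (model object).

    Build from data with :meth:`from_fixture` (synthetic cell line) or
    :meth:`from_bed` (BED + FASTA inputs), then call :meth:`fit`.
    """

    def __init__(
        self,
        data: PreparedData,
        genome: Genome | None = None,
        config: SparseAttentionConfig | None = None,
        schedule: TrainSchedule | None = None,
    ):
        if config is None:
            config = load_preset("tiny")
        if len(data.vocab) > config.vocab_size:
            config = replace(config, vocab_size=len(data.vocab))
        self.data = data
        self.genome = genome
        self.config = config
        self.schedule = schedule if schedule is not None else TrainSchedule()

    # ---- constructors ----------------------------------------------------

    @classmethod
    def from_fixture(
        cls,
        fixture: PlantedFixture,
        seed: int = 0,
        config: SparseAttentionConfig | None = None,
        schedule: TrainSchedule | None = None,
        vocab_size: int = DEFAULT_VOCAB_SIZE,
    ) -> "SuperEnhancerClassifier":
        rng = np.random.default_rng(seed)
        data = build_dataset(
            fixture.genome, fixture.se_intervals, fixture.te_intervals,
            fixture.annotation, rng, vocab_size=vocab_size, seed=seed,
        )
        return cls(data, genome=fixture.genome, config=config, schedule=schedule)

    @classmethod
    def from_bed(
        cls,
        se_bed: str | Path,
        te_bed: str | Path,
        genome_fasta: str | Path,
        annotation_bed: str | Path | None = None,
        seed: int = 0,
        config: SparseAttentionConfig | None = None,
        schedule: TrainSchedule | None = None,
        vocab_size: int = DEFAULT_VOCAB_SIZE,
    ) -> "SuperEnhancerClassifier":
        genome = Genome.from_fasta(genome_fasta)
        annotation = read_bed(annotation_bed) if annotation_bed else []
        rng = np.random.default_rng(seed)
        data = build_dataset(
            genome, read_bed(se_bed), read_bed(te_bed), annotation, rng,
            vocab_size=vocab_size, seed=seed,
        )
        return cls(data, genome=genome, config=config, schedule=schedule)

    # ---- fitting ---------------------------------------------------------

    def fit(self, seed: int = 0) -> "ClassifierResults":
        schedule = replace(self.schedule, seed=seed)
        model = SparseTransformerClassifier(self.config, seed=seed)
        train = self.data.examples("train")
        test = self.data.examples("test")
        weights, log = fine_tune(model, train, test, schedule)
        probs = model.predict_proba(test)
        labels = np.array([ex.label for ex in test])
        preds = probs.argmax(axis=1)
        metrics = evaluation.compute_metrics(labels, preds, probs[:, 1])
        return ClassifierResults(
            model=model, weights=weights, train_log=log, schedule=schedule,
            data=self.data, genome=self.genome, probabilities=probs,
            predictions=preds, labels=labels, metrics=metrics,
        )


@dataclass
class ClassifierResults:
    """Fitted model, curves, test-set predictions and metric battery."""

    model: SparseTransformerClassifier
    weights: dict[str, np.ndarray]
    train_log: TrainLog
    schedule: TrainSchedule
    data: PreparedData
    genome: Genome | None
    probabilities: np.ndarray
    predictions: np.ndarray
    labels: np.ndarray
    metrics: evaluation.MetricsReport

    # ---- statistical comparisons ----------------------------------------

    def mcnemar_vs_random(self, seed: int = 0) -> evaluation.PairedTestResult:
        rng = np.random.default_rng(seed)
        return evaluation.mcnemar_vs_random(self.labels, self.predictions, rng)

    def score_negative_controls(
        self, seed: int = 0, n: int = 50, min_len: int = 2_500, max_len: int = 5_000
    ) -> np.ndarray:
        """Class-1 scores on fresh random genomic windows (no class
        content by construction)."""
        if self.genome is None:
            raise ValueError("no genome attached; pass negative scores directly")
        from .intervals import extract_sequence

        rng = np.random.default_rng(seed)
        controls = datasets.make_negative_controls(
            self.genome, rng, n=n, min_len=min_len, max_len=max_len
        )
        examples = [
            bpe.encode(self.data.vocab, extract_sequence(self.genome, iv))
            for iv in controls
        ]
        return self.model.predict_proba(examples)[:, 1]

    def ks_negative_control(self, seed: int = 0, n: int = 50) -> evaluation.PairedTestResult:
        model_scores = self.score_negative_controls(seed=seed, n=n)
        rng = np.random.default_rng(seed + 1)
        random_scores = rng.random(n)
        return evaluation.ks_negative_control(model_scores, random_scores)

    # ---- interpretation --------------------------------------------------

    def attribute_top(
        self, k: int = 5, steps: int = 50, outdir: str | Path | None = None
    ) -> list[AttributionTrack]:
        """Integrated-gradients tracks for the k top-ranked true SEs in
        the test set; optionally writes positive/negative BED pairs."""
        test_seqs = self.data.split.test
        examples = self.data.examples("test")
        idx = top_ranked_examples(examples, self.probabilities[:, 1], k=k)
        tracks = []
        for rank, i in enumerate(idx):
            ex = examples[i].truncated(self.model.config.max_positions)
            scores = integrated_gradients(self.model, ex, target_class=1, steps=steps)
            track = AttributionTrack.from_example(
                ex, self.data.sources[test_seqs[i].source_id], scores
            )
            if outdir is not None:
                outdir = Path(outdir)
                outdir.mkdir(parents=True, exist_ok=True)
                to_bed_tracks(
                    track,
                    outdir / f"se_top{rank + 1}_positive.bed",
                    outdir / f"se_top{rank + 1}_negative.bed",
                )
            tracks.append(track)
        return tracks

    def export_embeddings(self, path: str | Path | None = None):
        return evaluation.export_embeddings(
            self.model, self.data.examples("test"), path
        )

    # ---- presentation ----------------------------------------------------

    def plot_training(self, path: str | Path | None = None):
        """Loss/accuracy curves with the stage-2 start marked."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        log = self.train_log
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
        ax1.plot(log.epochs, log.train_loss, label="train loss")
        ax1.plot(log.epochs, log.val_loss, label="validation loss")
        ax2.plot(log.epochs, log.val_accuracy, label="validation accuracy")
        for ax in (ax1, ax2):
            if log.stage_boundary:
                ax.axvline(log.stage_boundary + 0.5, color="red", lw=1,
                           label="full fine-tuning starts")
            ax.set_xlabel("epoch")
            ax.legend(fontsize=8)
        ax1.set_ylabel("cross-entropy loss")
        ax2.set_ylabel("accuracy")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def summary(self) -> str:
        m = self.metrics
        cfg = self.model.config
        lines = [
            "Super-enhancer sequence classifier — fit summary",
            "=" * 56,
            f"{'Train examples:':<28}{len(self.data.split.train)}",
            f"{'Test examples:':<28}{len(self.data.split.test)}",
            f"{'Vocabulary size:':<28}{len(self.data.vocab)}",
            f"{'Encoder:':<28}{cfg.n_layers} layers, {cfg.n_heads} heads, "
            f"hidden {cfg.hidden_size}",
            f"{'Attention blocks:':<28}size {cfg.block_size}, "
            f"{cfg.n_random_blocks} random / {cfg.n_global_blocks} global / "
            f"{cfg.n_window_blocks} window",
            f"{'Parameters:':<28}{self.model.n_parameters():,}",
            f"{'Schedule:':<28}{self.schedule.head_epochs} head + "
            f"{self.schedule.full_epochs} full epochs, batch "
            f"{self.schedule.batch_size}, seed {self.schedule.seed}",
            "-" * 56,
            f"{'Final train loss:':<28}{self.train_log.train_loss[-1]:.4f}"
            if self.train_log.train_loss else f"{'Final train loss:':<28}n/a",
            f"{'Final validation loss:':<28}{self.train_log.val_loss[-1]:.4f}"
            if self.train_log.val_loss else f"{'Final validation loss:':<28}n/a",
            "-" * 56,
            f"{'Accuracy:':<12}{m.accuracy:.4f}    {'F1:':<10}{m.f1:.4f}",
            f"{'Precision:':<12}{m.precision:.4f}    {'Recall:':<10}{m.recall:.4f}",
            f"{'ROC AUC:':<12}{m.roc_auc:.4f}    {'MCC:':<10}{m.mcc:.4f}",
            f"Confusion (TP/FP/FN/TN): {m.tp}/{m.fp}/{m.fn}/{m.tn}",
            "=" * 56,
        ]
        return "\n".join(lines)


def build_integrative_classifier(
    fixtures: Mapping[str, PlantedFixture],
    seed: int = 0,
    per_line_n: int = 800,
    total_n: int = 2_500,
    config: SparseAttentionConfig | None = None,
    schedule: TrainSchedule | None = None,
) -> SuperEnhancerClassifier:
    """Multi-cell-line pooling: preprocess each synthetic 'cell line',
    pool per_line_n sequences from each, sample total_n, and build one
    classifier over the pooled set (shared tokenizer from the first line)."""
    rng = np.random.default_rng(seed)
    per_line: dict[str, list[LabeledSequence]] = {}
    vocab = None
    tokenized: dict[str, bpe.TokenizedExample] = {}
    sources: dict[str, GenomicInterval] = {}
    genome = None
    for line, fixture in sorted(fixtures.items()):
        data = build_dataset(
            fixture.genome, fixture.se_intervals, fixture.te_intervals,
            fixture.annotation, rng, vocab=vocab, seed=seed, cell_line=line,
        )
        vocab = data.vocab
        tokenized.update(data.tokenized)
        sources.update(data.sources)
        genome = fixture.genome
        per_line[line] = data.split.train + data.split.test
    pooled = datasets.build_integrative(per_line, rng, per_line_n=per_line_n,
                                        total_n=total_n)
    split = datasets.split_train_test(pooled, rng, seed=seed)
    data = PreparedData(split=split, vocab=vocab, tokenized=tokenized,
                        sources=sources)
    return SuperEnhancerClassifier(data, genome=genome, config=config,
                                   schedule=schedule)
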