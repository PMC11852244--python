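"""Classification metrics and the statistical comparison battery.

The metric set is the standard six for binary genomics classifiers:
accuracy, macro-averaged F1 / precision / recall, ROC AUC and the
Matthews correlation coefficient, all derivable from the confusion
table plus the score ranking. Model-vs-random-classifier comparison
uses McNemar's paired test on discordant counts; negative-control
score distributions are compared with the two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as _skm
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    f1: float
    precision: float
    recall: float
    roc_auc: float  # NaN when undefined (single-class labels)
    mcc: float
    tp: int
    fp: int
    fn: int
    tn: int

    def as_dict(self) -> dict[str, float | int]:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "roc_auc": self.roc_auc,
            "mcc": self.mcc,
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
        }


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    method: str  # mcnemar_exact | mcnemar_chi2 | ks_two_sample
    b: int | None = None  # model right, baseline wrong
    c: int | None = None  # model wrong, baseline right


def compute_metrics(
    labels: Sequence[int],
    predictions: Sequence[int],
    scores: Sequence[float] | None = None,
) -> MetricsReport:
    """Six-metric report; precision/recall/F1 are macro-averaged over the
    two classes. ROC AUC needs class-1 scores and both classes present,
    otherwise it is reported as NaN."""
    y = np.asarray(labels, dtype=int)
    yhat = np.asarray(predictions, dtype=int)
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions must have equal length")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    if scores is not None and len(np.unique(y)) == 2:
        roc_auc = float(_skm.roc_auc_score(y, np.asarray(scores, dtype=float)))
    else:
        roc_auc = float("nan")
    return MetricsReport(
        accuracy=float(_skm.accuracy_score(y, yhat)),
        f1=float(_skm.f1_score(y, yhat, average="macro", zero_division=0)),
        precision=float(_skm.precision_score(y, yhat, average="macro", zero_division=0)),
        recall=float(_skm.recall_score(y, yhat, average="macro", zero_division=0)),
        roc_auc=roc_auc,
        mcc=float(_skm.matthews_corrcoef(y, yhat)),
        tp=tp, fp=fp, fn=fn, tn=tn,
    )


def random_classifier_predictions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Fair-coin baseline predictions (class probabilities 1/2, 1/2)."""
    return rng.integers(0, 2, size=n)


def mcnemar_test(b: int, c: int, exact_threshold: int = 25) -> PairedTestResult:
    """McNemar's test from the two discordant counts.

    Exact binomial when b + c < exact_threshold, otherwise chi-square
    with continuity correction (clamped at zero, so b = c gives
    statistic 0 and p = 1). b + c = 0 gives p = 1 by convention.
    """
    n_discordant = b + c
    if n_discordant == 0:
        return PairedTestResult(0.0, 1.0, "mcnemar_exact", b=b, c=c)
    if n_discordant < exact_threshold:
        res = _sm_mcnemar(np.array([[0, b], [c, 0]]), exact=True)
        return PairedTestResult(float(res.statistic),
                                min(float(res.pvalue), 1.0),
                                "mcnemar_exact", b=b, c=c)
    statistic = max(abs(b - c) - 1, 0) ** 2 / n_discordant
    p_value = float(stats.chi2.sf(statistic, df=1))
    return PairedTestResult(float(statistic), p_value, "mcnemar_chi2", b=b, c=c)


def mcnemar_vs_random(
    labels: Sequence[int],
    model_predictions: Sequence[int],
    rng: np.random.Generator,
) -> PairedTestResult:
    """Compare the model against a seeded fair-coin random classifier on
    the same examples, via McNemar's test on the discordant counts."""
    y = np.asarray(labels, dtype=int)
    yhat = np.asarray(model_predictions, dtype=int)
    baseline = random_classifier_predictions(len(y), rng)
    model_right = yhat == y
    baseline_right = baseline == y
    b = int(np.sum(model_right & ~baseline_right))
    c = int(np.sum(~model_right & baseline_right))
    return mcnemar_test(b, c)


def ks_negative_control(
    model_scores: Sequence[float],
    random_scores: Sequence[float],
) -> PairedTestResult:
    """Two-sample Kolmogorov-Smirnov test (D = sup|F1 - F2|, asymptotic
    p-value) between model scores and random-classifier scores on the
    same negative-control set."""
    a = np.asarray(model_scores, dtype=float)
    b = np.asarray(random_scores, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("score samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return PairedTestResult(float(res.statistic), float(res.pvalue), "ks_two_sample")


def export_embeddings(model, examples, path: str | Path | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Pooled ([CLS]) representation per example, plus labels.

    Written as a tab-separated table (one row per example, hidden
    dimensions then label) for downstream t-SNE/UMAP projection.
    """
    was_training = model.training
    model.eval_mode()
    pooled_rows = []
    for start in range(0, len(examples), 16):
        batch = list(examples[start : start + 16])
        pooled_rows.append(model.forward_classify(batch).pooled)
    model.training = was_training
    pooled = np.concatenate(pooled_rows, axis=0)
    labels = np.array([ex.label if ex.label is not None else -1 for ex in examples])
    if path is not None:
        header = "\t".join(
            [f"h{i}" for i in range(pooled.shape[1])] + ["label"]
        )
        table = np.column_stack([pooled, labels])
        np.savetxt(path, table, delimiter="\t", header=header, comments="")
    return pooled, labels
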