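"""Two-stage fine-tuning with cross-entropy loss.

Stage 1 trains only the classification head with the encoder frozen
(head_epochs); stage 2 unfreezes everything (full_epochs). The frozen
stage is exact: encoder parameters are bit-identical before and after.
The optimizer is AdamW (decoupled weight decay). An optional
masked-language-model pre-training pass on raw sequences is available
for desk-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .autograd import Tensor, parameters_zero_grad
from .bpe import TokenizedExample
from .model import SparseTransformerClassifier, mask_for_mlm, pad_batch


@dataclass(frozen=True)
class TrainSchedule:
    """Two-stage schedule. Learning-rate defaults suit training the tiny
    from-scratch configuration; fine-tuning a large pretrained encoder
    would typically use rates one to two orders of magnitude lower."""

    head_epochs: int = 5
    full_epochs: int = 10
    batch_size: int = 8
    lr_head: float = 1e-3
    lr_full: float = 3e-4
    weight_decay: float = 0.01
    seed: int = 0

    @property
    def total_epochs(self) -> int:
        return self.head_epochs + self.full_epochs


@dataclass
class TrainLog:
    """Per-epoch curves; ``stage_boundary`` marks the epoch at which
    full-model fine-tuning begins (the 'red line' on loss plots)."""

    epochs: list[int] = field(default_factory=list)
    stages: list[str] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stage_boundary: int | None = None

    def append(self, epoch: int, stage: str, tr: float, vl: float, va: float) -> None:
        self.epochs.append(epoch)
        self.stages.append(stage)
        self.train_loss.append(tr)
        self.val_loss.append(vl)
        self.val_accuracy.append(va)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,stage,train_loss,val_loss,val_accuracy\n")
            for row in zip(
                self.epochs, self.stages, self.train_loss, self.val_loss,
                self.val_accuracy,
            ):
                fh.write(",".join(str(x) for x in row) + "\n")


class AdamW:
    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            m_hat = self.m[name] / (1 - self.b1**self.t)
            v_hat = self.v[name] / (1 - self.b2**self.t)
            p.data -= self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data
            )


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (B, 2) logits against integer labels."""
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(len(labels)), labels]
    return -picked.mean()


def _batches(
    examples: Sequence[TokenizedExample], batch_size: int, rng: np.random.Generator
) -> list[list[TokenizedExample]]:
    # shuffle, then group nearby lengths to limit padding waste
    order = rng.permutation(len(examples))
    chunk = batch_size * 8
    ordered: list[TokenizedExample] = []
    for s in range(0, len(order), chunk):
        block = sorted(order[s : s + chunk], key=lambda i: examples[i].n_tokens)
        ordered.extend(examples[i] for i in block)
    return [ordered[s : s + batch_size] for s in range(0, len(ordered), batch_size)]


def evaluate_loss_accuracy(
    model: SparseTransformerClassifier,
    examples: Sequence[TokenizedExample],
    batch_size: int = 16,
) -> tuple[float, float]:
    probs = model.predict_proba(examples, batch_size=batch_size)
    labels = np.array([ex.label for ex in examples])
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + eps)))
    accuracy = float(np.mean(probs.argmax(axis=1) == labels))
    return loss, accuracy


def fine_tune(
    model: SparseTransformerClassifier,
    train_set: Sequence[TokenizedExample],
    validation_set: Sequence[TokenizedExample],
    schedule: TrainSchedule,
) -> tuple[dict[str, np.ndarray], TrainLog]:
    """Run the two-stage schedule; returns final weights and the log."""
    if len(train_set) == 0 or len(validation_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(schedule.seed)
    log = TrainLog(stage_boundary=schedule.head_epochs)
    head_names = model.head_parameter_names()

    stages = [
        ("head", schedule.head_epochs, {k: model.params[k] for k in head_names},
         schedule.lr_head),
        ("full", schedule.full_epochs, dict(model.params), schedule.lr_full),
    ]
    epoch = 0
    for stage_name, n_epochs, trainable, lr in stages:
        if n_epochs == 0:
            continue
        optimizer = AdamW(trainable, lr=lr, weight_decay=schedule.weight_decay)
        for _ in range(n_epochs):
            epoch += 1
            model.train_mode()
            losses = []
            for batch in _batches(train_set, schedule.batch_size, rng):
                ids, pad_mask = pad_batch(batch, model.config.max_positions)
                labels = np.array([ex.label for ex in batch])
                parameters_zero_grad(model.params.values())
                loss = cross_entropy(model.forward_logits(ids, pad_mask), labels)
                loss.backward()
                if stage_name == "head":
                    for name in model.encoder_parameter_names():
                        model.params[name].grad = None
                optimizer.step()
                losses.append(float(loss.data))
            model.eval_mode()
            val_loss, val_acc = evaluate_loss_accuracy(model, validation_set)
            log.append(epoch, stage_name, float(np.mean(losses)), val_loss, val_acc)
    model.eval_mode()
    return model.state_dict(), log


def pretrain_mlm(
    model: SparseTransformerClassifier,
    sequences: Sequence[TokenizedExample],
    n_epochs: int = 1,
    batch_size: int = 8,
    lr: float = 1e-3,
    rate: float | None = None,
    seed: int = 0,
) -> list[float]:
    """Optional desk-scale masked-language-model pre-training.

    Masks ``rate`` (default: config.mlm_mask_rate) of non-special tokens
    and minimises cross-entropy of the original ids at masked positions.
    Returns per-epoch mean losses.
    """
    if rate is None:
        rate = model.config.mlm_mask_rate
    rng = np.random.default_rng(seed)
    _ = model.mlm_logits(np.array([[0]]))  # init MLM head
    trainable = dict(model.params)
    trainable.update(model._mlm_params)
    optimizer = AdamW(trainable, lr=lr)
    losses_per_epoch: list[float] = []
    for _ in range(n_epochs):
        model.train_mode()
        losses = []
        for batch in _batches(sequences, batch_size, rng):
            ids, pad_mask = pad_batch(batch, model.config.max_positions)
            masked = np.empty_like(ids)
            targets: list[tuple[int, int, int]] = []
            for b in range(ids.shape[0]):
                row, pos = mask_for_mlm(ids[b][pad_mask[b]], rng, rate=rate)
                masked[b] = ids[b]
                masked[b, : len(row)] = row
                targets.extend((b, int(p), int(ids[b, p])) for p in pos)
            if not targets:
                continue
            parameters_zero_grad(trainable.values())
            logits = model.mlm_logits(masked, pad_mask)
            bi = np.array([t[0] for t in targets])
            pi = np.array([t[1] for t in targets])
            yi = np.array([t[2] for t in targets])
            logp = logits[bi, pi].log_softmax(axis=-1)
            loss = -logp[np.arange(len(yi)), yi].mean()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        losses_per_epoch.append(float(np.mean(losses)))
    model.eval_mode()
    return losses_per_epoch
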