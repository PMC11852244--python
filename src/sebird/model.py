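"""A BigBird-style encoder for long DNA sequences, with classifier head.

Attention is block-sparse: the token axis is cut into blocks of
``block_size`` tokens and each block attends only to (i) a sliding
window of its nearest block neighbours, (ii) a fixed set of global
blocks that attend to and from everything, and (iii) a few random
partner blocks per block. At desk scale the sparsity is realised as a
boolean mask over a dense attention matrix, which is mathematically
identical to the blocked kernels used at production scale.

The classification head follows the BERT-family sequence-classification
pattern: the first-token ([CLS]) hidden state goes through
dropout -> linear -> GELU (tanh approximation) -> dropout -> linear,
producing a (1, 2) logit row per sequence.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .autograd import Tensor, gelu, layer_norm
from .bpe import CLS_ID, MASK_ID, PAD_ID, SEP_ID, UNK_ID, TokenizedExample

_SPECIAL_IDS = frozenset({PAD_ID, UNK_ID, CLS_ID, SEP_ID, MASK_ID})
_NEG_INF = -1e9


@dataclass(frozen=True)
class SparseAttentionConfig:
    """Model geometry; the full-scale preset and a tiny test-scale preset
    are shipped as config files and available via :func:`load_preset`."""

    n_layers: int = 12
    n_heads: int = 12
    hidden_size: int = 768
    intermediate_size: int = 3072
    block_size: int = 64
    n_random_blocks: int = 3
    n_global_blocks: int = 2
    n_window_blocks: int = 3
    max_positions: int = 4096
    vocab_size: int = 32000
    dropout: float = 0.1
    mlm_mask_rate: float = 0.15
    attention_seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size % self.n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")
        if self.n_window_blocks % 2 != 1:
            raise ValueError("n_window_blocks must be odd (centered window)")

    @property
    def head_dim(self) -> int:
        return self.hidden_size // self.n_heads

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                fh.write(f"{key} = {value}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SparseAttentionConfig":
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, value = (part.strip() for part in line.split("=", 1))
            kwargs[key] = float(value) if "." in value else int(value)
        return cls(**kwargs)


def load_preset(name: str) -> SparseAttentionConfig:
    """Load a shipped preset: ``"full"`` (production scale) or ``"tiny"``."""
    path = Path(__file__).parent / "presets" / f"{name}.cfg"
    if not path.exists():
        raise KeyError(f"no preset named {name!r}")
    return SparseAttentionConfig.from_file(path)


@dataclass
class ClassifierOutput:
    logits: np.ndarray  # (B, 2)
    pooled: np.ndarray  # (B, hidden)
    per_layer_hidden: list[np.ndarray] | None = None


def sparse_attention_mask(
    config: SparseAttentionConfig,
    n_tokens: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Boolean (n_tokens, n_tokens) allowed-attention matrix.

    Block-level structure: the first ``n_global_blocks`` blocks attend to
    and from all blocks; every block attends to its ``n_window_blocks``
    nearest neighbours (symmetric window); each block additionally
    attends to ``n_random_blocks`` uniformly drawn non-window, non-global
    partner blocks (seeded, not symmetrised).
    """
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.attention_seed)
    bs = config.block_size
    n_blocks = int(np.ceil(n_tokens / bs))
    block = np.zeros((n_blocks, n_blocks), dtype=bool)

    half = (config.n_window_blocks - 1) // 2
    idx = np.arange(n_blocks)
    block |= np.abs(idx[:, None] - idx[None, :]) <= half

    n_global = min(config.n_global_blocks, n_blocks)
    block[:n_global, :] = True
    block[:, :n_global] = True

    if config.n_random_blocks > 0:
        for i in range(n_blocks):
            candidates = np.where(~block[i])[0]
            if len(candidates) == 0:
                continue
            k = min(config.n_random_blocks, len(candidates))
            block[i, rng.choice(candidates, size=k, replace=False)] = True

    token_mask = np.kron(block, np.ones((bs, bs), dtype=bool))
    return token_mask[:n_tokens, :n_tokens]


def mask_for_mlm(
    ids: Sequence[int],
    rng: np.random.Generator,
    rate: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace round(rate * n) non-special positions with [MASK].

    Returns (masked ids, masked position indices); the original ids at
    those positions are the MLM prediction targets.
    """
    ids_arr = np.asarray(ids, dtype=int)
    if ids_arr.size == 0:
        raise ValueError("cannot mask an empty sequence")
    eligible = np.array([i for i, t in enumerate(ids_arr) if int(t) not in _SPECIAL_IDS])
    n_mask = int(round(rate * len(eligible)))
    if n_mask == 0:
        return ids_arr.copy(), np.array([], dtype=int)
    chosen = np.sort(rng.choice(eligible, size=n_mask, replace=False))
    masked = ids_arr.copy()
    masked[chosen] = MASK_ID
    return masked, chosen


def _init_params(config: SparseAttentionConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    h, ffn, v = config.hidden_size, config.intermediate_size, config.vocab_size
    std = 0.02

    def w(*shape: int) -> Tensor:
        return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)

    def zeros(*shape: int) -> Tensor:
        return Tensor(np.zeros(shape), requires_grad=True)

    def ones(*shape: int) -> Tensor:
        return Tensor(np.ones(shape), requires_grad=True)

    params: dict[str, Tensor] = {
        "tok_emb": w(v, h),
        "pos_emb": w(config.max_positions, h),
        "emb_ln_g": ones(h),
        "emb_ln_b": zeros(h),
        "head_w1": w(h, h),
        "head_b1": zeros(h),
        "head_w2": w(h, 2),
        "head_b2": zeros(2),
    }
    for i in range(config.n_layers):
        params.update(
            {
                f"l{i}.wq": w(h, h),
                f"l{i}.bq": zeros(h),
                f"l{i}.wk": w(h, h),
                f"l{i}.bk": zeros(h),
                f"l{i}.wv": w(h, h),
                f"l{i}.bv": zeros(h),
                f"l{i}.wo": w(h, h),
                f"l{i}.bo": zeros(h),
                f"l{i}.ln1_g": ones(h),
                f"l{i}.ln1_b": zeros(h),
                f"l{i}.ffn_w1": w(h, ffn),
                f"l{i}.ffn_b1": zeros(ffn),
                f"l{i}.ffn_w2": w(ffn, h),
                f"l{i}.ffn_b2": zeros(h),
                f"l{i}.ln2_g": ones(h),
                f"l{i}.ln2_b": zeros(h),
            }
        )
    return params


class SparseTransformerClassifier:
    """Encoder + binary-classification head, trained with the autodiff
    engine in :mod:`sebird.autograd`. Also exposes an MLM head for
    optional small-scale masked-language-model pre-training."""

    def __init__(self, config: SparseAttentionConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params = _init_params(config, rng)
        self._mask_cache: dict[int, np.ndarray] = {}
        self._mask_rng_seed = config.attention_seed
        self.training = False
        self._dropout_rng = np.random.default_rng(seed + 1)
        self._mlm_params: dict[str, Tensor] | None = None

    # ---- modes -----------------------------------------------------------

    def train_mode(self) -> None:
        self.training = True

    def eval_mode(self) -> None:
        self.training = False

    # ---- parameter bookkeeping -------------------------------------------

    def head_parameter_names(self) -> list[str]:
        return ["head_w1", "head_b1", "head_w2", "head_b2"]

    def encoder_parameter_names(self) -> list[str]:
        head = set(self.head_parameter_names())
        return [name for name in self.params if name not in head]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, value in state.items():
            if name not in self.params:
                raise KeyError(f"unexpected parameter {name!r}")
            if self.params[name].data.shape != value.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: config expects "
                    f"{self.params[name].data.shape}, checkpoint has {value.shape}"
                )
            self.params[name].data = value.astype(np.float64).copy()

    def save_checkpoint(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.state_dict())
        self.config.save(directory / "config.cfg")
        manifest = {
            "format": "sebird-checkpoint-v1",
            "n_parameters": self.n_parameters(),
            "seed": self.seed,
            "parameters": {k: list(v.shape) for k, v in self.state_dict().items()},
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load_checkpoint(cls, directory: str | Path) -> "SparseTransformerClassifier":
        directory = Path(directory)
        config = SparseAttentionConfig.from_file(directory / "config.cfg")
        model = cls(config)
        with np.load(directory / "weights.npz") as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        return model

    # ---- forward pass ------------------------------------------------------

    def _attention_mask(self, n_tokens: int) -> np.ndarray:
        if n_tokens not in self._mask_cache:
            rng = np.random.default_rng(self._mask_rng_seed)
            self._mask_cache[n_tokens] = sparse_attention_mask(
                self.config, n_tokens, rng
            )
        return self._mask_cache[n_tokens]

    def _dropout(self, x: Tensor) -> Tensor:
        p = self.config.dropout
        if not self.training or p <= 0.0:
            return x
        keep = (self._dropout_rng.random(x.shape) >= p).astype(np.float64)
        return x * Tensor(keep / (1.0 - p))

    def embed(self, ids: np.ndarray) -> Tensor:
        """Token embedding + learned absolute position embedding, (B,T,H)."""
        if ids.shape[-1] > self.config.max_positions:
            raise ValueError(
                f"sequence length {ids.shape[-1]} exceeds max_positions "
                f"{self.config.max_positions}"
            )
        tok = self.params["tok_emb"].take_rows(ids)
        pos = self.params["pos_emb"][np.arange(ids.shape[-1])]
        return tok + pos

    def _encode(self, x: Tensor, pad_mask: np.ndarray) -> list[Tensor]:
        """Run the encoder stack; ``pad_mask`` is (B, T) True at real tokens."""
        B, T, H = x.shape
        cfg = self.config
        allowed = self._attention_mask(T)  # (T, T)
        bias = np.where(allowed[None, None], 0.0, _NEG_INF)
        key_bias = np.where(pad_mask[:, None, None, :], 0.0, _NEG_INF)
        attn_bias = Tensor(bias + key_bias)  # (B, 1, T, T)

        x = layer_norm(x, self.params["emb_ln_g"], self.params["emb_ln_b"])
        x = self._dropout(x)
        hidden: list[Tensor] = []
        scale = 1.0 / np.sqrt(cfg.head_dim)
        for i in range(cfg.n_layers):
            p = self.params

            def heads(t: Tensor) -> Tensor:
                return t.reshape(B, T, cfg.n_heads, cfg.head_dim).transpose(0, 2, 1, 3)

            q = heads(x @ p[f"l{i}.wq"] + p[f"l{i}.bq"])
            k = heads(x @ p[f"l{i}.wk"] + p[f"l{i}.bk"])
            v = heads(x @ p[f"l{i}.wv"] + p[f"l{i}.bv"])
            scores = (q @ k.transpose(0, 1, 3, 2)) * scale + attn_bias
            attn = self._dropout(scores.softmax(axis=-1))
            ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, H)
            attn_out = self._dropout(ctx @ p[f"l{i}.wo"] + p[f"l{i}.bo"])
            x = layer_norm(x + attn_out, p[f"l{i}.ln1_g"], p[f"l{i}.ln1_b"])
            ffn = gelu(x @ p[f"l{i}.ffn_w1"] + p[f"l{i}.ffn_b1"])
            ffn = self._dropout(ffn @ p[f"l{i}.ffn_w2"] + p[f"l{i}.ffn_b2"])
            x = layer_norm(x + ffn, p[f"l{i}.ln2_g"], p[f"l{i}.ln2_b"])
            hidden.append(x)
        return hidden

    def forward_logits(
        self, ids: np.ndarray, pad_mask: np.ndarray | None = None
    ) -> Tensor:
        ids = np.atleast_2d(np.asarray(ids, dtype=int))
        if pad_mask is None:
            pad_mask = ids != PAD_ID
        return self.forward_from_embeddings(self.embed(ids), pad_mask)

    def forward_from_embeddings(self, embeddings: Tensor, pad_mask: np.ndarray) -> Tensor:
        """Classifier logits from pre-computed token embeddings (used both
        by the normal forward pass and by integrated gradients, whose
        interpolation path lives in embedding space)."""
        hidden = self._encode(embeddings, pad_mask)
        pooled = hidden[-1][:, 0, :]  # [CLS]
        p = self.params
        x = self._dropout(pooled)
        x = gelu(x @ p["head_w1"] + p["head_b1"])
        x = self._dropout(x)
        return x @ p["head_w2"] + p["head_b2"]

    def forward_classify(
        self,
        example: TokenizedExample | Sequence[TokenizedExample],
        return_hidden: bool = False,
    ) -> ClassifierOutput:
        examples = [example] if isinstance(example, TokenizedExample) else list(example)
        ids, pad_mask = pad_batch(examples, self.config.max_positions)
        embeddings = self.embed(ids)
        hidden = self._encode(embeddings, pad_mask)
        pooled_t = hidden[-1][:, 0, :]
        p = self.params
        x = self._dropout(pooled_t)
        x = gelu(x @ p["head_w1"] + p["head_b1"])
        x = self._dropout(x)
        logits = x @ p["head_w2"] + p["head_b2"]
        return ClassifierOutput(
            logits=logits.data.copy(),
            pooled=pooled_t.data.copy(),
            per_layer_hidden=[h.data.copy() for h in hidden] if return_hidden else None,
        )

    def predict_proba(self, examples: Sequence[TokenizedExample], batch_size: int = 16) -> np.ndarray:
        """Class probabilities, (n, 2), in evaluation mode."""
        was_training = self.training
        self.eval_mode()
        probs = []
        for start in range(0, len(examples), batch_size):
            batch = examples[start : start + batch_size]
            logits = self.forward_classify(batch).logits
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            probs.append(e / e.sum(axis=1, keepdims=True))
        self.training = was_training
        return np.concatenate(probs, axis=0)

    # ---- optional MLM head -------------------------------------------------

    def mlm_logits(self, ids: np.ndarray, pad_mask: np.ndarray | None = None) -> Tensor:
        if self._mlm_params is None:
            rng = np.random.default_rng(self.seed + 7)
            h, v = self.config.hidden_size, self.config.vocab_size
            self._mlm_params = {
                "mlm_w": Tensor(rng.normal(0, 0.02, size=(h, v)), requires_grad=True),
                "mlm_b": Tensor(np.zeros(v), requires_grad=True),
            }
        ids = np.atleast_2d(np.asarray(ids, dtype=int))
        if pad_mask is None:
            pad_mask = ids != PAD_ID
        hidden = self._encode(self.embed(ids), pad_mask)
        return hidden[-1] @ self._mlm_params["mlm_w"] + self._mlm_params["mlm_b"]


def pad_batch(
    examples: Sequence[TokenizedExample], max_positions: int
) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad a batch with [PAD]; returns (ids (B,T), pad_mask (B,T))."""
    lengths = [min(ex.n_tokens, max_positions) for ex in examples]
    T = max(lengths)
    B = len(examples)
    ids = np.full((B, T), PAD_ID, dtype=int)
    pad_mask = np.zeros((B, T), dtype=bool)
    for b, ex in enumerate(examples):
        ids[b, : lengths[b]] = ex.ids[: lengths[b]]
        pad_mask[b, : lengths[b]] = True
    return ids, pad_mask


def analytic_parameter_count(config: SparseAttentionConfig) -> int:
    """Closed-form parameter count for a given geometry (embeddings,
    per-layer attention + FFN + two layer norms, and the head)."""
    h, f = config.hidden_size, config.intermediate_size
    embeddings = config.vocab_size * h + config.max_positions * h + 2 * h
    per_layer = 4 * (h * h + h) + 2 * h + (h * f + f) + (f * h + h) + 2 * h
    head = (h * h + h) + (h * 2 + 2)
    return embeddings + config.n_layers * per_layer + head
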