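"""Byte-pair-encoding tokenization of DNA.

BPE starts from the single-nucleotide alphabet {A, C, G, T, N} and
repeatedly merges the most frequent adjacent token pair into a new
token, until the vocabulary reaches a target size. On DNA there are no
words, so the whole sequence is one token stream (no pre-tokenizer).
Frequency ties are broken lexicographically on the (left, right) token
strings so training is deterministic. 'N' is kept inert: no merge rule
ever touches a token containing 'N', so runs of ambiguous bases stay as
single-character tokens.

Encoding applies the learned merges in priority order via a heap over a
doubly-linked token list, which is O(n log n) in sequence length, and
tracks per-token (start, end) bp offsets so attributions can be mapped
back to genomic coordinates.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

SPECIAL_TOKENS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]")
BASE_ALPHABET = ("A", "C", "G", "T", "N")
PAD_ID, UNK_ID, CLS_ID, SEP_ID, MASK_ID = range(5)


@dataclass
class BpeVocab:
    """Learned vocabulary: token strings plus the ordered merge rules."""

    tokens: list[str]
    merges: list[tuple[str, str]]
    target_size: int
    token_to_id: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.token_to_id = {t: i for i, t in enumerate(self.tokens)}
        if len(self.token_to_id) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def rank(self) -> dict[tuple[str, str], int]:
        return {pair: k for k, pair in enumerate(self.merges)}

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "tokens.txt").write_text(
            "\n".join(self.tokens) + "\n"
        )
        (directory / "merges.txt").write_text(
            "".join(f"{l} {r}\n" for l, r in self.merges)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "BpeVocab":
        directory = Path(directory)
        tokens = (directory / "tokens.txt").read_text().splitlines()
        merges = [
            tuple(line.split(" "))
            for line in (directory / "merges.txt").read_text().splitlines()
            if line
        ]
        return cls(tokens=tokens, merges=merges, target_size=len(tokens))


@dataclass(frozen=True)
class TokenizedExample:
    """Token ids + per-token bp offsets into the source sequence."""

    ids: tuple[int, ...]
    offsets: tuple[tuple[int, int], ...]
    label: int | None = None
    source_id: str | None = None

    @property
    def n_tokens(self) -> int:
        return len(self.ids)

    def truncated(self, max_tokens: int) -> "TokenizedExample":
        """3'-truncated copy (identity when already short enough)."""
        if self.n_tokens <= max_tokens:
            return self
        return TokenizedExample(
            ids=self.ids[:max_tokens], offsets=self.offsets[:max_tokens],
            label=self.label, source_id=self.source_id,
        )


def train_bpe(corpus: Iterable[str], target_size: int) -> BpeVocab:
    """Learn BPE merges by greedy highest-frequency pair merging.

    Stops when the vocabulary reaches ``target_size`` or no adjacent
    pair occurs at least twice. Deterministic: count ties are broken by
    lexicographic order of the pair.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus must be non-empty")
    n_fixed = len(SPECIAL_TOKENS) + len(BASE_ALPHABET)
    if target_size < n_fixed:
        raise ValueError(
            f"target_size={target_size} smaller than specials+alphabet ({n_fixed})"
        )
    alphabet = set(BASE_ALPHABET)
    for seq in corpus:
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(f"corpus contains non-ACGTN characters: {sorted(bad)}")

    # linked-list representation per sequence
    syms: list[list[str]] = [list(seq) for seq in corpus]
    nxt: list[list[int]] = [list(range(1, len(s) + 1)) for s in syms]
    alive: list[list[bool]] = [[True] * len(s) for s in syms]
    prv: list[list[int]] = [list(range(-1, len(s) - 1)) for s in syms]

    counts: dict[tuple[str, str], int] = {}
    positions: dict[tuple[str, str], set[tuple[int, int]]] = {}

    def _mergeable(pair: tuple[str, str]) -> bool:
        return "N" not in pair[0] and "N" not in pair[1]

    def _add(pair: tuple[str, str], pos: tuple[int, int]) -> None:
        if not _mergeable(pair):
            return
        counts[pair] = counts.get(pair, 0) + 1
        positions.setdefault(pair, set()).add(pos)

    def _remove(pair: tuple[str, str], pos: tuple[int, int]) -> None:
        if not _mergeable(pair):
            return
        if pos in positions.get(pair, ()):
            positions[pair].discard(pos)
            counts[pair] -= 1
            if counts[pair] == 0:
                del counts[pair], positions[pair]

    for si, s in enumerate(syms):
        for i in range(len(s) - 1):
            _add((s[i], s[i + 1]), (si, i))

    merges: list[tuple[str, str]] = []
    vocab_size = n_fixed
    while vocab_size < target_size and counts:
        best_count = max(counts.values())
        if best_count < 2:
            break
        best = min(p for p, c in counts.items() if c == best_count)
        l, r = best
        merged = l + r
        merges.append(best)
        vocab_size += 1
        for si, i in sorted(positions.get(best, set())):
            if not alive[si][i] or syms[si][i] != l:
                continue
            j = nxt[si][i]
            if j >= len(syms[si]) or not alive[si][j] or syms[si][j] != r:
                continue
            p = prv[si][i]
            k = nxt[si][j]
            if p >= 0:
                _remove((syms[si][p], l), (si, p))
            _remove((l, r), (si, i))
            if k < len(syms[si]):
                _remove((r, syms[si][k]), (si, j))
            syms[si][i] = merged
            alive[si][j] = False
            nxt[si][i] = k
            if k < len(syms[si]):
                prv[si][k] = i
            if p >= 0:
                _add((syms[si][p], merged), (si, p))
            if k < len(syms[si]):
                _add((merged, syms[si][k]), (si, i))

    tokens = list(SPECIAL_TOKENS) + list(BASE_ALPHABET) + [l + r for l, r in merges]
    return BpeVocab(tokens=tokens, merges=merges, target_size=target_size)


def encode(
    vocab: BpeVocab,
    seq: str,
    max_tokens: int = 4096,
    label: int | None = None,
    source_id: str | None = None,
    add_cls: bool = True,
) -> TokenizedExample:
    """Tokenize ``seq``, prepending [CLS] and truncating the 3' end.

    Offsets are half-open bp spans into ``seq``; the [CLS] token carries
    the zero-width span (0, 0) so the offsets still tile the prefix of
    the sequence covered after truncation.
    """
    bad = set(seq) - set(BASE_ALPHABET)
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    rank = vocab.rank
    n = len(seq)
    sym = list(seq)
    start = list(range(n))
    nxt = list(range(1, n + 1))
    prv = list(range(-1, n - 1))
    alive = [True] * n

    heap: list[tuple[int, int, str, str]] = []
    for i in range(n - 1):
        pair = (sym[i], sym[i + 1])
        if pair in rank:
            heap.append((rank[pair], i, pair[0], pair[1]))
    heapq.heapify(heap)
    while heap:
        _, i, l, r = heapq.heappop(heap)
        if not alive[i] or sym[i] != l:
            continue
        j = nxt[i]
        if j >= n or not alive[j] or sym[j] != r:
            continue
        sym[i] = l + r
        alive[j] = False
        k = nxt[j]
        nxt[i] = k
        if k < n:
            prv[k] = i
        p = prv[i]
        if p >= 0:
            pair = (sym[p], sym[i])
            if pair in rank:
                heapq.heappush(heap, (rank[pair], p, pair[0], pair[1]))
        if k < n:
            pair = (sym[i], sym[k])
            if pair in rank:
                heapq.heappush(heap, (rank[pair], i, pair[0], pair[1]))

    ids: list[int] = [CLS_ID] if add_cls else []
    offsets: list[tuple[int, int]] = [(0, 0)] if add_cls else []
    i = 0
    while i < n:
        if alive[i]:
            tok = sym[i]
            ids.append(vocab.token_to_id[tok])
            offsets.append((start[i], start[i] + len(tok)))
        i = nxt[i] if alive[i] else i + 1
    if len(ids) > max_tokens:
        ids = ids[:max_tokens]
        offsets = offsets[:max_tokens]
    return TokenizedExample(
        ids=tuple(ids), offsets=tuple(offsets), label=label, source_id=source_id
    )


def decode(vocab: BpeVocab, ids: Sequence[int]) -> str:
    """Concatenate token strings, dropping special tokens."""
    out: list[str] = []
    for i in ids:
        if not (0 <= int(i) < len(vocab.tokens)):
            raise KeyError(f"unknown token id {i}")
        if int(i) < len(SPECIAL_TOKENS):
            continue
        out.append(vocab.tokens[int(i)])
    return "".join(out)


def token_lengths(vocab: BpeVocab, seqs: Sequence[str], max_tokens: int = 4096) -> np.ndarray:
    return np.array([encode(vocab, s, max_tokens=max_tokens).n_tokens for s in seqs])
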