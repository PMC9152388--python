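"""Per-character input vectors: token + segment + position embeddings.

The input representation of a character is the sum of three parts: a token
embedding looked up in a trainable table, a segment embedding (degenerate for
single-sentence inputs, where every position is segment 0), and a position
embedding.  Positions use the fixed sinusoidal encoding

    PE(pos, 2i)   = sin(pos / 10000^(2i/d_model))
    PE(pos, 2i+1) = cos(pos / 10000^(2i/d_model))

by default, with a learned position table available by configuration.

A pretrained contextual embedder (for example an ALBERT encoder) can replace
the trainable table through :class:`ExternalEmbedderAdapter`; the pretraining
machinery itself is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

PAD_ID = 0
UNK_ID = 1
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"


class Vocabulary:
    """Character <-> id bijection with reserved padding (0) and unknown (1)."""

    def __init__(self, chars: Sequence[str] = ()):
        self._chars: list[str] = [PAD_TOKEN, UNK_TOKEN]
        self._ids: dict[str, int] = {PAD_TOKEN: PAD_ID, UNK_TOKEN: UNK_ID}
        for ch in chars:
            self.add(ch)

    def add(self, ch: str) -> int:
        if ch not in self._ids:
            self._ids[ch] = len(self._chars)
            self._chars.append(ch)
        return self._ids[ch]

    @classmethod
    def from_corpus(cls, sentences: Sequence) -> "Vocabulary":
        vocab = cls()
        for sent in sentences:
            for ch in getattr(sent, "chars", sent):
                vocab.add(ch)
        return vocab

    def __len__(self) -> int:
        return len(self._chars)

    def __contains__(self, ch: str) -> bool:
        return ch in self._ids

    def char_to_id(self, ch: str) -> int:
        return self._ids.get(ch, UNK_ID)

    def id_to_char(self, idx: int) -> str:
        return self._chars[idx]

    def encode(self, text: Sequence[str]) -> np.ndarray:
        return np.array([self.char_to_id(ch) for ch in text], dtype=np.int64)

    def save(self, path: str | Path) -> None:
        # one character per line; id = line number
        with open(path, "w", encoding="utf-8") as fh:
            for ch in self._chars:
                fh.write(ch + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        with open(path, encoding="utf-8") as fh:
            chars = [line.rstrip("\n") for line in fh]
        if chars[:2] != [PAD_TOKEN, UNK_TOKEN]:
            raise ValueError(f"{path}: missing reserved {PAD_TOKEN}/{UNK_TOKEN} rows")
        vocab = cls()
        for ch in chars[2:]:
            vocab.add(ch)
        return vocab


@dataclass(frozen=True)
class EmbeddingConfig:
    d_model: int = 128
    position_mode: str = "sinusoidal"  # or "learned"
    max_len: int = 128

    def __post_init__(self) -> None:
        if self.d_model <= 0:
            raise ValueError("d_model must be positive")
        if self.position_mode not in ("sinusoidal", "learned"):
            raise ValueError(f"unknown position_mode {self.position_mode!r}")
        if self.position_mode == "sinusoidal" and self.d_model % 2:
            raise ValueError("sinusoidal positions require even d_model")


def positional_encoding(pos: int, dim_index: int, d_model: int) -> float:
    """Scalar sinusoidal position encoding at one coordinate."""
    if not 0 <= dim_index < d_model:
        raise ValueError(f"dim_index {dim_index} out of range for d_model {d_model}")
    i = dim_index // 2
    angle = pos / 10000.0 ** (2 * i / d_model)
    return float(np.sin(angle) if dim_index % 2 == 0 else np.cos(angle))


def sinusoidal_table(max_len: int, d_model: int) -> np.ndarray:
    """(max_len, d_model) table of the sinusoidal encoding."""
    pos = np.arange(max_len)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angles = pos / 10000.0 ** (2 * i / d_model)
    table = np.empty((max_len, d_model))
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles)
    return table


class EmbeddingLayer:
    """Trainable token + segment tables plus position encoding.

    Forward maps ``(B, T)`` int arrays of character ids and segment ids to
    ``(B, T, d_model)`` vectors; padding positions (id 0) yield zero vectors.
    """

    def __init__(self, vocab_size: int, config: EmbeddingConfig, rng: np.random.Generator):
        self.config = config
        d = config.d_model
        # token rows are sized to compete with the unit-magnitude sinusoidal
        # position encoding; tiny BERT-style 0.02 init drowns character
        # identity in position signal for a from-scratch embedder
        self.params: dict[str, np.ndarray] = {
            "token_table": rng.normal(0.0, 1.0 / np.sqrt(d), size=(vocab_size, d)),
            "segment_table": np.zeros((2, d)),
        }
        self.params["token_table"][PAD_ID] = 0.0
        if config.position_mode == "learned":
            self.params["pos_table"] = rng.normal(0.0, 0.02, size=(config.max_len, d))
        else:
            self._pe = sinusoidal_table(config.max_len, d)
        self.grads: dict[str, np.ndarray] = {}
        self._cache: tuple | None = None

    def position_table(self, length: int) -> np.ndarray:
        if length > self.config.max_len:
            raise ValueError(f"sequence length {length} exceeds max_len {self.config.max_len}")
        if self.config.position_mode == "learned":
            return self.params["pos_table"][:length]
        return self._pe[:length]

    def forward(self, char_ids: np.ndarray, segment_ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        vocab_size = self.params["token_table"].shape[0]
        if char_ids.min() < 0 or char_ids.max() >= vocab_size:
            raise ValueError("character id out of vocabulary range")
        if segment_ids.min() < 0 or segment_ids.max() >= 2:
            raise ValueError("segment id out of range")
        T = char_ids.shape[1]
        out = (
            self.params["token_table"][char_ids]
            + self.params["segment_table"][segment_ids]
            + self.position_table(T)[None, :, :]
        )
        out = out * mask[:, :, None]
        self._cache = (char_ids, segment_ids, mask)
        return out

    def backward(self, grad_out: np.ndarray) -> None:
        char_ids, segment_ids, mask = self._cache
        g = grad_out * mask[:, :, None]
        gt = np.zeros_like(self.params["token_table"])
        np.add.at(gt, char_ids, g)
        gt[PAD_ID] = 0.0
        gs = np.zeros_like(self.params["segment_table"])
        np.add.at(gs, segment_ids, g)
        self.grads = {"token_table": gt, "segment_table": gs}
        if self.config.position_mode == "learned":
            gp = np.zeros_like(self.params["pos_table"])
            gp[: g.shape[1]] = g.sum(axis=0)
            self.grads["pos_table"] = gp


def embed_sequence(
    char_ids: np.ndarray,
    segment_ids: np.ndarray,
    config: EmbeddingConfig,
    token_table: np.ndarray,
    segment_table: np.ndarray,
    pos_table: np.ndarray | None = None,
) -> np.ndarray:
    """Functional single-sequence embedding: token + segment + position.

    ``char_ids``/``segment_ids`` are 1-D; returns ``(T, d_model)``.
    """
    char_ids = np.asarray(char_ids)
    segment_ids = np.asarray(segment_ids)
    if char_ids.shape != segment_ids.shape:
        raise ValueError("char_ids and segment_ids must have equal length")
    if char_ids.size and (char_ids.min() < 0 or char_ids.max() >= token_table.shape[0]):
        raise ValueError("character id out of vocabulary range")
    T = char_ids.shape[0]
    if pos_table is None:
        pos_table = sinusoidal_table(max(T, 1), config.d_model)
    return token_table[char_ids] + segment_table[segment_ids] + pos_table[:T]


class ExternalEmbedderAdapter:
    """Wrap an external per-character vector provider as an embedder.

    ``provider`` maps a character sequence to a ``(T, provider_dim)`` array.
    When ``provider_dim != d_model`` a linear projection (fixed, seeded) maps
    the vectors to ``d_model``.  A provider that merges or splits characters
    violates the one-vector-per-character contract and is rejected.
    """

    def __init__(
        self,
        provider: Callable[[Sequence[str]], np.ndarray],
        provider_dim: int,
        d_model: int,
        seed: int = 0,
    ):
        self.provider = provider
        self.provider_dim = provider_dim
        self.d_model = d_model
        if provider_dim == d_model:
            self.projection = None
        else:
            rng = np.random.default_rng(seed)
            self.projection = rng.normal(
                0.0, 1.0 / np.sqrt(provider_dim), size=(provider_dim, d_model)
            )

    def __call__(self, chars: Sequence[str]) -> np.ndarray:
        vectors = np.asarray(self.provider(chars), dtype=float)
        if vectors.ndim != 2 or vectors.shape[0] != len(chars):
            raise ValueError(
                f"provider returned {vectors.shape[0] if vectors.ndim == 2 else '?'} "
                f"vectors for {len(chars)} characters (tokenizer mismatch)"
            )
        if vectors.shape[1] != self.provider_dim:
            raise ValueError(
                f"provider dimension {vectors.shape[1]} != declared {self.provider_dim}"
            )
        if self.projection is None:
            return vectors
        return vectors @ self.projection
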