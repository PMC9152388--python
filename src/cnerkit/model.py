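"""End-to-end character-level tagger: embeddings -> dropout -> IDCNN -> MHA
-> linear emission layer -> CRF.

:class:`NerTagger` is a scikit-learn-style estimator: ``fit(X, y)`` takes
character sequences and aligned BIO tag sequences, ``predict(X)`` returns
tag sequences decoded by Viterbi (with hard BIO constraints by default) and
repaired into well-formed spans, and ``score(X, y)`` is strict entity-level
micro-F1.  All randomness (initialization, shuffling, dropout) flows from
``seed``, so runs are reproducible on one thread.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import crf as crf_mod
from .attention import MhaConfig, MultiHeadAttention
from .embeddings import EmbeddingConfig, EmbeddingLayer, PAD_ID, Vocabulary
from .idcnn import IdcnnConfig, IdcnnEncoder
from .metrics import strict_match_eval
from .optim import create_optimizer
from .tagging import (
    DEFAULT_SCHEMA,
    LabeledSentence,
    TagSchema,
    decode_tags,
)


@dataclass
class EpochRecord:
    epoch: int
    loss: float
    dev_precision: float | None
    dev_recall: float | None
    dev_f1: float | None
    seconds: float


@dataclass
class TrainReport:
    epochs: list[EpochRecord] = dc_field(default_factory=list)
    best_epoch: int | None = None

    @property
    def losses(self) -> list[float]:
        return [e.loss for e in self.epochs]

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for e in self.epochs:
                fh.write(json.dumps(e.__dict__) + "\n")


class _Linear:
    """Plain affine layer (used for the emission scores)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.params = {
            "W": rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, d_out)),
            "b": np.zeros(d_out),
        }
        self.grads: dict[str, np.ndarray] = {}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        self.grads = {
            "W": x.reshape(-1, x.shape[-1]).T @ g.reshape(-1, g.shape[-1]),
            "b": g.sum(axis=(0, 1)),
        }
        return g @ self.params["W"].T


class Network:
    """The trainable stack producing emission scores and the CRF on top."""

    def __init__(
        self,
        vocab_size: int,
        schema: TagSchema,
        emb_cfg: EmbeddingConfig,
        idcnn_cfg: IdcnnConfig,
        mha_cfg: MhaConfig | None,
        dropout: float,
        seed: int,
    ):
        if mha_cfg is not None and mha_cfg.d_model != idcnn_cfg.filters:
            raise ValueError(
                f"MHA d_model {mha_cfg.d_model} must equal IDCNN filters "
                f"{idcnn_cfg.filters}"
            )
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        rng = np.random.default_rng(seed)
        self.schema = schema
        self.dropout = dropout
        self.embedding = EmbeddingLayer(vocab_size, emb_cfg, rng)
        self.idcnn = IdcnnEncoder(emb_cfg.d_model, idcnn_cfg, rng)
        self.mha = MultiHeadAttention(mha_cfg, rng) if mha_cfg else None
        self.emission = _Linear(idcnn_cfg.filters, schema.n_tags, rng)
        self.crf = crf_mod.LinearChainCrf(schema.n_tags, rng)
        self._drop_mask: np.ndarray | None = None

    # -- parameter registry -------------------------------------------------
    def _layers(self):
        layers = [self.embedding, self.idcnn]
        if self.mha is not None:
            layers.append(self.mha)
        layers += [self.emission, self.crf]
        return layers

    def parameters(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for i, layer in enumerate(self._layers()):
            for name, p in sorted(layer.params.items()):
                out.append((f"{type(layer).__name__}{i}.{name}", p))
        return out

    def gradients(self) -> list[np.ndarray]:
        grads = []
        for layer in self._layers():
            for name, p in sorted(layer.params.items()):
                grads.append(layer.grads.get(name, np.zeros_like(p)))
        return grads

    def get_flat_params(self) -> np.ndarray:
        return np.concatenate([p.ravel() for _, p in self.parameters()])

    def set_flat_params(self, flat: np.ndarray) -> None:
        pos = 0
        for _, p in self.parameters():
            p[...] = flat[pos : pos + p.size].reshape(p.shape)
            pos += p.size

    def get_flat_grads(self) -> np.ndarray:
        return np.concatenate([g.ravel() for g in self.gradients()])

    # -- forward / backward -------------------------------------------------
    def emissions(
        self,
        char_ids: np.ndarray,
        mask: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        segment_ids = np.zeros_like(char_ids)
        h = self.embedding.forward(char_ids, segment_ids, mask)
        if train and self.dropout > 0.0:
            keep = 1.0 - self.dropout
            self._drop_mask = (rng.random(h.shape) < keep) / keep
            h = h * self._drop_mask
        else:
            self._drop_mask = None
        h = self.idcnn.forward(h, mask, train)
        if self.mha is not None:
            h = self.mha.forward(h, mask, train)
        return self.emission.forward(h)

    def loss(
        self,
        char_ids: np.ndarray,
        tags: np.ndarray,
        mask: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> float:
        P = self.emissions(char_ids, mask, train, rng)
        return self.crf.nll(P, tags, mask)

    def backward(self) -> None:
        g = self.crf.backward()
        g = self.emission.backward(g)
        if self.mha is not None:
            g = self.mha.backward(g)
        g = self.idcnn.backward(g)
        if self._drop_mask is not None:
            g = g * self._drop_mask
        self.embedding.backward(g)


def _pad_batch(
    sentences: list[np.ndarray], tag_rows: list[np.ndarray] | None
):
    B = len(sentences)
    T = max(len(s) for s in sentences)
    char_ids = np.full((B, T), PAD_ID, dtype=np.int64)
    mask = np.zeros((B, T))
    tags = np.zeros((B, T), dtype=np.int64)
    for b, ids in enumerate(sentences):
        char_ids[b, : len(ids)] = ids
        mask[b, : len(ids)] = 1.0
        if tag_rows is not None:
            tags[b, : len(ids)] = tag_rows[b]
    return char_ids, tags, mask


class NerTagger(BaseEstimator):
    """Character-level clinical NER tagger with CRF decoding.

    Parameters mirror the reference configuration of the architecture:
    128-dimensional embeddings, 128 convolution filters with dilation
    schedule (1, 1, 2) iterated 4 times, 4 attention heads, dropout 0.5 and
    batch size 20.  The default learning rate is 1e-3 for the from-scratch
    trainable embedder; 3e-5 is the conventional choice when fine-tuning a
    pretrained contextual embedder through the adapter.

    Attributes ending in ``_`` are set by :meth:`fit`: ``vocab_``,
    ``schema_``, ``network_``, ``report_``, ``n_iter_``.
    """

    def __init__(
        self,
        d_model: int = 128,
        filters: int = 128,
        kernel_size: int = 3,
        dilations: tuple[int, ...] = (1, 1, 2),
        iterations: int = 4,
        heads: int = 4,
        use_mha: bool = True,
        residual: bool = False,
        position_mode: str = "sinusoidal",
        dropout: float = 0.5,
        optimizer: str = "adam",
        learning_rate: float = 1e-3,
        batch_size: int = 20,
        epochs: int = 30,
        patience: int = 5,
        max_len: int = 128,
        constrained_decode: bool = True,
        seed: int = 0,
        verbose: int = 0,
    ):
        self.d_model = d_model
        self.filters = filters
        self.kernel_size = kernel_size
        self.dilations = dilations
        self.iterations = iterations
        self.heads = heads
        self.use_mha = use_mha
        self.residual = residual
        self.position_mode = position_mode
        self.dropout = dropout
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.max_len = max_len
        self.constrained_decode = constrained_decode
        self.seed = seed
        self.verbose = verbose

    # -- helpers ------------------------------------------------------------
    @staticmethod
    def _coerce(X, y) -> list[LabeledSentence]:
        if y is None:
            return list(X)
        return [
            LabeledSentence("".join(chars), tuple(tags))
            for chars, tags in zip(X, y)
        ]

    def _encode_sentences(self, sentences) -> tuple[list[np.ndarray], list[np.ndarray]]:
        ids = [self.vocab_.encode(s.chars) for s in sentences]
        tags = [np.array(self.schema_.encode(s.tags), dtype=np.int64) for s in sentences]
        return ids, tags

    def build_network(self, vocab_size: int, schema: TagSchema) -> Network:
        emb_cfg = EmbeddingConfig(
            d_model=self.d_model, position_mode=self.position_mode, max_len=self.max_len
        )
        idcnn_cfg = IdcnnConfig(
            filters=self.filters,
            kernel_size=self.kernel_size,
            dilations=tuple(self.dilations),
            iterations=self.iterations,
        )
        mha_cfg = (
            MhaConfig(d_model=self.filters, heads=self.heads, residual=self.residual)
            if self.use_mha
            else None
        )
        return Network(
            vocab_size, schema, emb_cfg, idcnn_cfg, mha_cfg, self.dropout, self.seed
        )

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y=None, dev_data=None, schema: TagSchema = DEFAULT_SCHEMA):
        """Train on character sequences ``X`` with BIO tag sequences ``y``.

        ``X`` may also be a list of :class:`LabeledSentence` (then ``y`` is
        omitted).  ``dev_data`` is an optional held-out sentence list used
        for per-epoch entity-F1 evaluation and early stopping; without it,
        training runs for ``epochs`` epochs and keeps the final weights.
        """
        train_sents = self._coerce(X, y) if y is not None else list(X)
        if not train_sents:
            raise ValueError("empty training set")
        for s in train_sents:
            if len(s) > self.max_len:
                raise ValueError(
                    f"sentence of length {len(s)} exceeds max_len {self.max_len}; "
                    "split documents first (corpus_io.split_document)"
                )
        self.schema_ = schema
        self.vocab_ = Vocabulary.from_corpus(train_sents)
        self.network_ = self.build_network(len(self.vocab_), schema)
        ids, tags = self._encode_sentences(train_sents)

        opt = create_optimizer(self.optimizer, self.learning_rate)
        rng = np.random.default_rng((self.seed, 0xD0))
        params = [p for _, p in self.network_.parameters()]
        report = TrainReport()
        best_f1, best_flat, bad_epochs = -1.0, None, 0
        n = len(ids)
        self.n_iter_ = 0
        for epoch in range(1, self.epochs + 1):
            t0 = time.perf_counter()
            order = rng.permutation(n)
            total_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                char_ids, tag_ids, mask = _pad_batch(
                    [ids[i] for i in idx], [tags[i] for i in idx]
                )
                loss = self.network_.loss(char_ids, tag_ids, mask, train=True, rng=rng)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch {start // self.batch_size} "
                        f"(lr={self.learning_rate}, optimizer={self.optimizer})"
                    )
                self.network_.backward()
                opt.step(params, self.network_.gradients())
                self.n_iter_ += 1
                total_loss += loss * len(idx)
            rec = EpochRecord(
                epoch=epoch,
                loss=total_loss / n,
                dev_precision=None,
                dev_recall=None,
                dev_f1=None,
                seconds=0.0,
            )
            if dev_data is not None:
                res = strict_match_eval(
                    [s.mentions(self.schema_) for s in dev_data],
                    self.predict_mentions([s.chars for s in dev_data]),
                    self.schema_,
                )
                rec.dev_precision = round(res.precision, 2)
                rec.dev_recall = round(res.recall, 2)
                rec.dev_f1 = round(res.f1, 2)
                if res.f1 > best_f1:
                    best_f1 = res.f1
                    best_flat = self.network_.get_flat_params()
                    report.best_epoch = epoch
                    bad_epochs = 0
                else:
                    bad_epochs += 1
            rec.seconds = round(time.perf_counter() - t0, 3)
            report.epochs.append(rec)
            if self.verbose:
                msg = f"epoch {epoch}: loss {rec.loss:.4f}"
                if rec.dev_f1 is not None:
                    msg += f", dev F1 {rec.dev_f1:.2f}%"
                print(msg + f" ({rec.seconds:.1f}s)")
            if dev_data is not None and bad_epochs > self.patience:
                break
        if best_flat is not None:
            self.network_.set_flat_params(best_flat)
        self.report_ = report
        return self

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("this NerTagger instance is not fitted yet")

    def predict(self, X) -> list[list[str]]:
        """Viterbi-decode tag sequences for character sequences ``X``."""
        self._check_fitted()
        X = list(X)
        if not X:
            return []
        for s in X:
            if len(s) > self.max_len:
                raise ValueError(
                    f"sentence of length {len(s)} exceeds max_len {self.max_len}; "
                    "split documents first (corpus_io.split_document)"
                )
        ids = [self.vocab_.encode(getattr(s, "chars", s)) for s in X]
        out: list[list[str]] = []
        schema = self.schema_ if self.constrained_decode else None
        for start in range(0, len(ids), self.batch_size):
            chunk = ids[start : start + self.batch_size]
            char_ids, _, mask = _pad_batch(chunk, None)
            P = self.network_.emissions(char_ids, mask, train=False)
            for path in self.network_.crf.decode(P, mask, schema):
                out.append(self.schema_.decode(path))
        return out

    def predict_mentions(self, X) -> list[list]:
        """Predicted entity spans per sentence (repair policy for ill-formed
        tag runs)."""
        return [
            decode_tags(tags, self.schema_, policy="repair") for tags in self.predict(X)
        ]

    def score(self, X, y=None) -> float:
        """Strict entity-level micro-F1 (in percent) against gold tags."""
        gold = self._coerce(X, y) if y is not None else list(X)
        res = strict_match_eval(
            [s.mentions(self.schema_) for s in gold],
            self.predict_mentions([s.chars for s in gold]),
            self.schema_,
        )
        return res.f1

    # -- persistence --------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Checkpoint config + vocabulary + schema + weights (self-contained)."""
        self._check_fitted()
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "config.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"params": self.get_params(), "types": list(self.schema_.types)},
                fh,
                indent=2,
            )
        self.vocab_.save(directory / "vocab.txt")
        np.savez(
            directory / "weights.npz",
            **{name: p for name, p in self.network_.parameters()},
        )

    @classmethod
    def load(cls, directory: str | Path) -> "NerTagger":
        directory = Path(directory)
        with open(directory / "config.json", encoding="utf-8") as fh:
            saved = json.load(fh)
        params = saved["params"]
        params["dilations"] = tuple(params["dilations"])
        est = cls(**params)
        est.schema_ = TagSchema(tuple(saved["types"]))
        est.vocab_ = Vocabulary.load(directory / "vocab.txt")
        est.network_ = est.build_network(len(est.vocab_), est.schema_)
        with np.load(directory / "weights.npz") as data:
            for name, p in est.network_.parameters():
                p[...] = data[name]
        est.report_ = TrainReport()
        est.n_iter_ = 0
        return est
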