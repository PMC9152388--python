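"""Corpus readers/writers and sentence windowing for clinical records.

Two on-disk carriers are supported:

* CoNLL-style token-per-line files: one character, whitespace, one BIO label
  per line; blank line between sentences.
* Span-annotated documents as line-delimited JSON records with fields
  ``originalText`` and ``entities`` ``[{start_pos, end_pos, label_type}]``
  (the CCKS-style layout).

Clinical records hold many sentences, so documents are cut at the ideographic
full stop ``。`` and anything still longer than ``max_len`` (default 128) is
hard-split, backing off to gaps between mentions so gold spans survive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .tagging import (
    DEFAULT_SCHEMA,
    EntityMention,
    LabeledSentence,
    TagSchema,
    _check_mentions,
    encode_tags,
)

PERIOD = "。"  # 。
DEFAULT_MAX_LEN = 128

#: CCKS-2019 category names -> type codes; identity codes also accepted.
DEFAULT_TYPE_NAMES: dict[str, str] = {
    "疾病和诊断": "DIS",
    "影像检查": "EXA",
    "实验室检验": "TES",
    "手术": "OPE",
    "药物": "DRU",
    "解剖部位": "ANA",
    **{c: c for c in DEFAULT_SCHEMA.types},
}


class CorpusError(ValueError):
    """Malformed corpus file or annotation."""


@dataclass(frozen=True)
class RawDocument:
    """A clinical record: full text plus document-level entity spans."""

    doc_id: str
    text: str
    annotations: tuple[EntityMention, ...] = ()

    def __post_init__(self) -> None:
        try:
            ms = _check_mentions(self.annotations, len(self.text), DEFAULT_SCHEMA)
        except Exception as e:
            raise CorpusError(f"document {self.doc_id}: {e}") from e
        object.__setattr__(self, "annotations", tuple(ms))


@dataclass(frozen=True)
class SentenceWindow:
    """One model-sized slice of a document, with window-local tags.

    ``doc_offset`` maps window position ``i`` back to document position
    ``doc_offset + i``.  ``flags`` records lossy events (a mention split by a
    hard length cut).
    """

    doc_id: str
    sentence_index: int
    doc_offset: int
    chars: str
    tags: tuple[str, ...]
    flags: tuple[str, ...] = ()

    def to_sentence(self) -> LabeledSentence:
        return LabeledSentence(self.chars, self.tags, doc_id=self.doc_id)


def _sentence_spans(text: str) -> list[tuple[int, int]]:
    """Half-open spans cut after each ``。`` (period stays with its sentence)."""
    spans, start = [], 0
    for i, ch in enumerate(text):
        if ch == PERIOD:
            spans.append((start, i + 1))
            start = i + 1
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def _hard_cuts(
    length: int, mentions: Sequence[EntityMention], max_len: int
) -> tuple[list[int], list[str]]:
    """Cut points for a sentence longer than ``max_len``.

    Prefers the largest cut <= max_len that falls in a gap between mentions;
    a mention longer than max_len is cut at max_len and flagged.
    """
    cuts, flagged, pos = [], [], 0
    while length - pos > max_len:
        limit = pos + max_len
        cut = limit
        inside = [m for m in mentions if m.start < cut < m.end]
        if inside:
            m = inside[0]
            if m.start > pos:
                cut = m.start  # back off to the gap before the mention
            else:
                flagged.append((cut, m))
        cuts.append(cut)
        pos = cut
    return cuts, flagged


def split_document(
    doc: RawDocument,
    max_len: int = DEFAULT_MAX_LEN,
    schema: TagSchema = DEFAULT_SCHEMA,
) -> list[SentenceWindow]:
    """Cut a document into tagged windows of at most ``max_len`` characters.

    Raises :class:`CorpusError` if an annotation straddles a period boundary.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    windows: list[SentenceWindow] = []
    for s_start, s_end in _sentence_spans(doc.text):
        local = []
        for m in doc.annotations:
            if m.end <= s_start or m.start >= s_end:
                continue
            if m.start < s_start or m.end > s_end:
                raise CorpusError(
                    f"document {doc.doc_id}: mention {tuple(m)} crosses the "
                    f"sentence boundary at [{s_start}, {s_end})"
                )
            local.append(EntityMention(m.start - s_start, m.end - s_start, m.type))
        cuts, flagged = _hard_cuts(s_end - s_start, local, max_len)
        bounds = [0, *cuts, s_end - s_start]
        for w_start, w_end in zip(bounds, bounds[1:]):
            w_mentions = [
                EntityMention(
                    max(m.start, w_start) - w_start,
                    min(m.end, w_end) - w_start,
                    m.type,
                )
                for m in local
                if m.start < w_end and m.end > w_start
            ]
            flags = tuple(
                f"mention {tuple(m)} split at {cut}"
                for cut, m in flagged
                if m.start < w_end and m.end > w_start
            )
            windows.append(
                SentenceWindow(
                    doc_id=doc.doc_id,
                    sentence_index=len(windows),
                    doc_offset=s_start + w_start,
                    chars=doc.text[s_start + w_start : s_start + w_end],
                    tags=tuple(encode_tags(w_mentions, w_end - w_start, schema)),
                    flags=flags,
                )
            )
    return windows


# ---------------------------------------------------------------------------
# CoNLL-style token-per-line format
# ---------------------------------------------------------------------------

def write_conll(sentences: Iterable[LabeledSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            for ch, tag in zip(sent.chars, sent.tags):
                fh.write(f"{ch}\t{tag}\n")
            fh.write("\n")


def read_conll(
    path: str | Path, schema: TagSchema = DEFAULT_SCHEMA
) -> list[LabeledSentence]:
    sentences: list[LabeledSentence] = []
    chars: list[str] = []
    tags: list[str] = []

    def flush() -> None:
        if chars:
            sentences.append(LabeledSentence("".join(chars), tuple(tags)))
            chars.clear()
            tags.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            parts = line.split()
            if len(parts) != 2 or len(parts[0]) != 1:
                raise CorpusError(f"{path}:{lineno}: ragged line {line!r}")
            ch, tag = parts
            if tag not in schema.tags:
                raise CorpusError(f"{path}:{lineno}: unknown label {tag!r}")
            chars.append(ch)
            tags.append(tag)
    flush()
    if not sentences:
        raise CorpusError(f"{path}: empty corpus")
    return sentences


# ---------------------------------------------------------------------------
# Span-annotated documents (line-delimited JSON)
# ---------------------------------------------------------------------------

def write_span_json(docs: Iterable[RawDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            rec = {
                "doc_id": doc.doc_id,
                "originalText": doc.text,
                "entities": [
                    {"start_pos": m.start, "end_pos": m.end, "label_type": m.type}
                    for m in doc.annotations
                ],
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_span_json(
    path: str | Path,
    type_names: dict[str, str] | None = None,
    end_exclusive: bool = True,
) -> list[RawDocument]:
    """Read line-delimited span-annotated records.

    ``type_names`` maps dataset category names to type codes (defaults to the
    CCKS-2019 Chinese names plus identity on the codes).  ``end_exclusive``
    declares the offset dialect of ``end_pos``.
    """
    mapping = DEFAULT_TYPE_NAMES if type_names is None else type_names
    docs: list[RawDocument] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rec = json.loads(line)
            doc_id = str(rec.get("doc_id", lineno))
            mentions = []
            for ent in rec.get("entities", []):
                name = ent["label_type"]
                if name not in mapping:
                    raise CorpusError(
                        f"document {doc_id}: unmapped entity type {name!r}"
                    )
                end = ent["end_pos"] if end_exclusive else ent["end_pos"] + 1
                mentions.append(EntityMention(ent["start_pos"], end, mapping[name]))
            docs.append(RawDocument(doc_id, rec["originalText"], tuple(mentions)))
    return docs


def documents_to_sentences(
    docs: Iterable[RawDocument],
    max_len: int = DEFAULT_MAX_LEN,
    schema: TagSchema = DEFAULT_SCHEMA,
) -> list[LabeledSentence]:
    """Split every document and return the windows as labeled sentences."""
    return [
        w.to_sentence() for doc in docs for w in split_document(doc, max_len, schema)
    ]
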