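"""BIO tag schema over clinical entity types and span<->tag conversion.

Clinical mentions are annotated per character with ``B-X`` (begin), ``I-X``
(inside) and ``O`` (outside) labels, where ``X`` ranges over six entity-type
codes: disease (DIS), exam (EXA), test (TES), operation (OPE), drug (DRU)
and anatomy (ANA).  Spans use 0-based half-open offsets ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

DEFAULT_TYPES: tuple[str, ...] = ("DIS", "EXA", "TES", "OPE", "DRU", "ANA")

O_TAG = "O"


class TaggingError(ValueError):
    """Invalid tag sequence, mention set, or label."""


class EntityMention(NamedTuple):
    """A typed character span, half-open: ``chars[start:end]``."""

    start: int
    end: int
    type: str


@dataclass(frozen=True)
class TagSchema:
    """Closed label inventory: ``O`` first (index 0), then B-X/I-X per type."""

    types: tuple[str, ...] = DEFAULT_TYPES
    tags: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.types)) != len(self.types):
            raise TaggingError(f"duplicate entity types: {self.types}")
        tags = [O_TAG]
        for t in self.types:
            tags.append(f"B-{t}")
            tags.append(f"I-{t}")
        object.__setattr__(self, "types", tuple(self.types))
        object.__setattr__(self, "tags", tuple(tags))

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    def tag_to_id(self, tag: str) -> int:
        try:
            return self.tags.index(tag)
        except ValueError:
            raise TaggingError(f"unknown label {tag!r}") from None

    def id_to_tag(self, idx: int) -> str:
        return self.tags[idx]

    def encode(self, tags: Sequence[str]) -> list[int]:
        return [self.tag_to_id(t) for t in tags]

    def decode(self, ids: Sequence[int]) -> list[str]:
        return [self.tags[i] for i in ids]

    def split_tag(self, tag: str) -> tuple[str, str | None]:
        """Return (prefix, type): ("O", None) or ("B"/"I", code)."""
        if tag == O_TAG:
            return O_TAG, None
        if len(tag) > 2 and tag[1] == "-" and tag[0] in "BI":
            prefix, code = tag[0], tag[2:]
            if code in self.types:
                return prefix, code
        raise TaggingError(f"unknown label {tag!r}")


DEFAULT_SCHEMA = TagSchema()


def _check_mentions(
    mentions: Iterable[EntityMention], length: int, schema: TagSchema
) -> list[EntityMention]:
    ms = sorted(EntityMention(*m) for m in mentions)
    for m in ms:
        if m.type not in schema.types:
            raise TaggingError(f"unknown entity type {m.type!r} in {m}")
        if not (0 <= m.start < m.end <= length):
            raise TaggingError(f"span {m} out of range for length {length}")
    for a, b in zip(ms, ms[1:]):
        if b.start < a.end:
            raise TaggingError(f"overlapping mentions {a} and {b}")
    return ms


def encode_tags(
    mentions: Iterable[EntityMention],
    length: int,
    schema: TagSchema = DEFAULT_SCHEMA,
) -> list[str]:
    """Encode non-overlapping mentions as a BIO label sequence of ``length``."""
    tags = [O_TAG] * length
    for m in _check_mentions(mentions, length, schema):
        tags[m.start] = f"B-{m.type}"
        for i in range(m.start + 1, m.end):
            tags[i] = f"I-{m.type}"
    return tags


def decode_tags(
    tags: Sequence[str],
    schema: TagSchema = DEFAULT_SCHEMA,
    policy: str = "strict",
) -> list[EntityMention]:
    """Recover mentions from a BIO label sequence.

    ``policy="strict"`` rejects an ``I-X`` that does not continue a ``B-X``/
    ``I-X`` of the same type; ``policy="repair"`` treats it as ``B-X``
    (prediction-time decoding, where sequences may be ill-formed).
    """
    if policy not in ("strict", "repair"):
        raise ValueError(f"unknown policy {policy!r}")
    mentions: list[EntityMention] = []
    open_start: int | None = None
    open_type: str | None = None

    def close(end: int) -> None:
        nonlocal open_start, open_type
        if open_start is not None:
            mentions.append(EntityMention(open_start, end, open_type))
            open_start = open_type = None

    for i, tag in enumerate(tags):
        prefix, code = schema.split_tag(tag)
        if prefix == O_TAG:
            close(i)
        elif prefix == "B":
            close(i)
            open_start, open_type = i, code
        else:  # I
            if open_type == code:
                continue
            if policy == "strict":
                raise TaggingError(
                    f"illegal {tag} at position {i}: not preceded by "
                    f"B-{code}/I-{code}"
                )
            close(i)
            open_start, open_type = i, code
    close(len(tags))
    return mentions


def legal_transition(
    from_tag: str, to_tag: str, schema: TagSchema = DEFAULT_SCHEMA
) -> bool:
    """True iff ``to_tag`` may immediately follow ``from_tag`` under BIO.

    ``O`` and any ``B-X`` may follow anything; ``I-X`` requires the previous
    label to be ``B-X`` or ``I-X`` of the same type.
    """
    fp, fc = schema.split_tag(from_tag)
    tp, tc = schema.split_tag(to_tag)
    if tp in (O_TAG, "B"):
        return True
    return fp in ("B", "I") and fc == tc


def legal_start(tag: str, schema: TagSchema = DEFAULT_SCHEMA) -> bool:
    """True iff a sequence may begin with ``tag`` (``O`` or any ``B-X``)."""
    prefix, _ = schema.split_tag(tag)
    return prefix in (O_TAG, "B")


@dataclass(frozen=True)
class LabeledSentence:
    """A character sequence with aligned BIO tags.

    ``mentions`` is derived by strict decoding, so constructing a
    ``LabeledSentence`` validates that the tags are well-formed gold data.
    """

    chars: str
    tags: tuple[str, ...]
    doc_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tags", tuple(self.tags))
        if len(self.chars) != len(self.tags):
            raise TaggingError(
                f"length mismatch: {len(self.chars)} chars vs "
                f"{len(self.tags)} tags"
            )

    def mentions(self, schema: TagSchema = DEFAULT_SCHEMA) -> list[EntityMention]:
        return decode_tags(self.tags, schema, policy="strict")

    @classmethod
    def from_mentions(
        cls,
        chars: str,
        mentions: Iterable[EntityMention],
        schema: TagSchema = DEFAULT_SCHEMA,
        doc_id: str | None = None,
    ) -> "LabeledSentence":
        return cls(chars, tuple(encode_tags(mentions, len(chars), schema)), doc_id)

    def __len__(self) -> int:
        return len(self.chars)
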