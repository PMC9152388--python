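"""Deterministic generator of synthetic EMR-like labeled corpora.

The generator emulates the statistical structure a clinical tagger must
exploit, without any real patient text: sentences of characters from a
finite alphabet, six entity types with heterogeneous lengths, and three
confusion phenomena observed in real clinical notes:

* ``p_nested_lookalike`` — an operation string that extends a disease string
  by a fixed suffix (the gastric-cancer / radical-gastrectomy pattern), so
  type decisions require context beyond the shared prefix;
* ``p_parenthetical`` — supplementary text in full-width brackets around a
  long entity, stressing boundary decisions;
* ``p_cooccur`` — a disease and its dependent operation placed in one
  sentence at least ``cooccur_min_gap`` characters apart, rewarding
  long-range attention.

Background (non-entity) characters and entity characters are drawn from
disjoint blocks of the Unicode private-use area by default, so tests cannot
accidentally depend on real Chinese lexical statistics; a readable ASCII
mode (single Latin characters, preserving the one-code-point-per-token
contract) exists for documentation examples.  All randomness
flows from the :class:`GeneratorSpec` seed; splits use disjoint seed offsets,
never a shuffled common pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import PERIOD, RawDocument
from .tagging import (
    DEFAULT_SCHEMA,
    EntityMention,
    LabeledSentence,
    TagSchema,
)

_PUA = 0xE000  # private-use area base

_ASCII_BG = "abcdefghijklmnopqrstuvwxyz0123456789.,;:-+*/"
_ASCII_ENT = "ABCDEFGHIJKLMNOPQRSTUVWXYZ" + "".join(chr(0xC0 + i) for i in range(24))


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic corpus."""

    seed: int = 0
    background_chars: int = 40
    entity_chars: int = 40
    lexicon_sizes: dict = field(
        default_factory=lambda: {
            "DIS": 25, "EXA": 18, "TES": 18, "OPE": 25, "DRU": 18, "ANA": 20,
        }
    )
    length_ranges: dict = field(
        default_factory=lambda: {
            "DIS": (2, 6), "EXA": (2, 4), "TES": (2, 4),
            "OPE": (3, 7), "DRU": (2, 4), "ANA": (2, 5),
        }
    )
    sentence_length: tuple[int, int] = (20, 60)
    entity_density: float = 3.0  # mean entities per sentence
    p_nested_lookalike: float = 0.3
    p_parenthetical: float = 0.15
    p_cooccur: float = 0.2
    cooccur_min_gap: int = 10
    char_mode: str = "private_use"  # or "ascii" (readable docs/examples)

    def __post_init__(self) -> None:
        for name in ("p_nested_lookalike", "p_parenthetical", "p_cooccur"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.char_mode not in ("private_use", "ascii"):
            raise ValueError(f"unknown char_mode {self.char_mode!r}")


def _alphabets(spec: GeneratorSpec) -> tuple[list[str], list[str]]:
    """Disjoint background and entity character pools (one code point per
    token throughout)."""
    if spec.char_mode == "ascii":
        bg = list(_ASCII_BG[: min(spec.background_chars, len(_ASCII_BG))])
        ent = list(_ASCII_ENT[: min(spec.entity_chars, len(_ASCII_ENT))])
        return bg, ent
    bg = [chr(_PUA + i) for i in range(spec.background_chars)]
    ent = [chr(_PUA + spec.background_chars + i) for i in range(spec.entity_chars)]
    return bg, ent


#: fixed operation suffix appended to a disease string to form a look-alike
_OPE_SUFFIX_LEN = 2


def build_lexicons(
    spec: GeneratorSpec, schema: TagSchema = DEFAULT_SCHEMA
) -> dict[str, list[str]]:
    """Seeded per-type entity lexicons.

    With probability ``p_nested_lookalike`` an operation entry is a disease
    entry plus a fixed suffix; at 0 no operation entry has a full disease
    entry as a prefix.  Entries are unique across types apart from the
    deliberate prefix nesting.
    """
    rng = np.random.default_rng(spec.seed)
    _, ent_pool = _alphabets(spec)
    suffix = "".join(rng.choice(ent_pool, size=_OPE_SUFFIX_LEN))
    lexicons: dict[str, list[str]] = {}
    taken: set[str] = set()

    def sample_entry(lo: int, hi: int) -> str:
        for _ in range(1000):
            n = int(rng.integers(lo, hi + 1))
            s = "".join(rng.choice(ent_pool, size=n))
            if s not in taken:
                return s
        raise RuntimeError("lexicon sampling failed; enlarge entity_chars")

    for t in schema.types:
        lo, hi = spec.length_ranges[t]
        entries: list[str] = []
        for _ in range(spec.lexicon_sizes[t]):
            if t == "OPE" and rng.random() < spec.p_nested_lookalike and lexicons.get("DIS"):
                bases = [d for d in lexicons["DIS"] if d + suffix not in taken]
                if bases:
                    s = str(rng.choice(bases)) + suffix
                else:
                    s = sample_entry(lo, hi)
            else:
                s = sample_entry(lo, hi)
                if t == "OPE" and spec.p_nested_lookalike == 0.0:
                    while any(s.startswith(d) for d in lexicons.get("DIS", [])):
                        s = sample_entry(lo, hi)
            entries.append(s)
            taken.add(s)
        lexicons[t] = entries
    return lexicons


def _cooccur_pairs(lexicons: dict[str, list[str]]) -> list[tuple[str, str]]:
    """(disease, operation) pairs where the operation extends the disease."""
    return [
        (d, o)
        for o in lexicons["OPE"]
        for d in lexicons["DIS"]
        if o.startswith(d) and len(o) > len(d)
    ]


def generate_corpus(
    spec: GeneratorSpec,
    n_sentences: int,
    schema: TagSchema = DEFAULT_SCHEMA,
    seed_offset: int = 0,
) -> list[LabeledSentence]:
    """Generate ``n_sentences`` labeled sentences, each ending in ``。``.

    ``seed_offset`` derives an independent stream from the same spec (used
    for disjoint train/dev/test splits).  Entity placement is sequential, so
    mentions never overlap; gold tags come from span encoding and pass
    strict decoding by construction.
    """
    if n_sentences < 1:
        raise ValueError("n_sentences must be >= 1")
    lo, hi = spec.sentence_length
    for t, (elo, ehi) in spec.length_ranges.items():
        if ehi + 2 > hi:
            raise ValueError(
                f"entity type {t} (length up to {ehi}) cannot fit a sentence of "
                f"maximum length {hi}"
            )
    rng = np.random.default_rng((spec.seed, seed_offset))
    lexicons = build_lexicons(spec, schema)
    pairs = _cooccur_pairs(lexicons)
    bg_pool, _ = _alphabets(spec)

    sentences = []
    for _ in range(n_sentences):
        target = int(rng.integers(lo, hi + 1))
        chars: list[str] = []
        mentions: list[EntityMention] = []

        def add_background(n: int) -> None:
            chars.extend(rng.choice(bg_pool, size=n))

        def add_entity(text: str, etype: str, parenthetical: bool = False) -> None:
            if parenthetical:
                pre = "".join(rng.choice(bg_pool, size=int(rng.integers(1, 3))))
                chars.extend("（" + pre + "）")
            start = len(chars)
            chars.extend(text)
            mentions.append(EntityMention(start, start + len(text), etype))

        add_background(int(rng.integers(1, 4)))
        if pairs and rng.random() < spec.p_cooccur:
            dis, ope = pairs[int(rng.integers(len(pairs)))]
            add_entity(dis, "DIS")
            add_background(max(spec.cooccur_min_gap, int(rng.integers(spec.cooccur_min_gap, spec.cooccur_min_gap + 8))))
            add_entity(ope, "OPE")
            add_background(int(rng.integers(1, 4)))
        # Bernoulli thinning of slots to hit the target density on average
        while len(chars) < target - 1:
            room = target - 1 - len(chars)
            if spec.entity_density > 0 and rng.random() < min(
                0.5, spec.entity_density / 8.0
            ):
                etype = schema.types[int(rng.integers(len(schema.types)))]
                text = str(rng.choice(lexicons[etype]))
                if len(text) + 1 <= room:
                    long_entity = len(text) >= 4
                    add_entity(
                        text,
                        etype,
                        parenthetical=long_entity
                        and rng.random() < spec.p_parenthetical
                        and len(text) + 6 <= room,
                    )
                    add_background(1)
                    continue
            add_background(min(room, int(rng.integers(1, 5))))
        chars.append(PERIOD)
        sentences.append(
            LabeledSentence.from_mentions("".join(chars), mentions, schema)
        )
    return sentences


def generate_splits(
    spec: GeneratorSpec,
    n_train: int,
    n_dev: int,
    n_test: int = 0,
    schema: TagSchema = DEFAULT_SCHEMA,
) -> tuple[list[LabeledSentence], ...]:
    """Disjoint train/dev(/test) corpora from independent seed offsets."""
    out = [
        generate_corpus(spec, n, schema, seed_offset=i + 1)
        for i, n in enumerate((n_train, n_dev, n_test))
        if n > 0
    ]
    return tuple(out)


def sentences_to_documents(
    sentences: Sequence[LabeledSentence], per_doc: int = 5
) -> list[RawDocument]:
    """Concatenate sentences into span-annotated documents (for round-trip
    tests of the document pipeline)."""
    docs = []
    for d in range(0, len(sentences), per_doc):
        group = sentences[d : d + per_doc]
        text = "".join(s.chars for s in group)
        anns: list[EntityMention] = []
        offset = 0
        for s in group:
            anns.extend(
                EntityMention(m.start + offset, m.end + offset, m.type)
                for m in s.mentions()
            )
            offset += len(s.chars)
        docs.append(RawDocument(f"doc{d // per_doc}", text, tuple(anns)))
    return docs
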