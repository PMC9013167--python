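"""Dictionary-based named entity recognition for lncRNA and protein names.

Matching is a greedy longest-match, left-to-right scan over raw tokens.
Surface variation is absorbed by a normalization policy: matching is
case-insensitive and hyphen/space-insensitive, so the lexicon entry
"NF-kB" matches the token sequences "NF-kB", "NF kB" and "nfkb".

A statistical sequence tagger can be plugged in through the ``Tagger``
protocol; its mentions are reported separately (``method == "tagger"``)
and never merged with dictionary mentions. No tagger is trained here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Protocol, runtime_checkable

from .preprocess import TokenizedSentence

__all__ = [
    "LNCRNA",
    "PROTEIN",
    "ENTITY_TYPES",
    "normalize_name",
    "Lexicon",
    "EntityMention",
    "CandidatePair",
    "load_lexicon",
    "find_mentions",
    "pair_candidates",
    "Tagger",
    "tag_with",
]

logger = logging.getLogger(__name__)

LNCRNA = "lncRNA"
PROTEIN = "protein"
ENTITY_TYPES = (LNCRNA, PROTEIN)

_NORM_STRIP_RE = re.compile(r"[\s\-]+")


def normalize_name(name: str) -> str:
    """Matching key: lowercase with spaces and hyphens removed."""
    return _NORM_STRIP_RE.sub("", name).lower()


@dataclass
class Lexicon:
    """Per-type name inventories with a normalization-keyed match index.

    Entries are deduplicated under the normalization policy — a name seen
    in several surface variants is only counted once. The two entity types
    are independent namespaces: the same name may be both a lncRNA and a
    protein entry.
    """

    entries: dict[str, dict[str, str]] = field(default_factory=dict)
    policy: str = "casefold-dehyphenate"

    def __post_init__(self) -> None:
        for etype in ENTITY_TYPES:
            self.entries.setdefault(etype, {})

    def add(self, entity_type: str, name: str) -> None:
        if entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {entity_type!r}")
        name = name.strip()
        if not name:
            raise ValueError("empty entity name")
        key = normalize_name(name)
        if not key:
            raise ValueError(f"name {name!r} normalizes to nothing")
        # first surface form seen becomes the canonical spelling
        self.entries[entity_type].setdefault(key, name)

    def names(self, entity_type: str) -> set[str]:
        return set(self.entries[entity_type].values())

    def size(self, entity_type: str) -> int:
        return len(self.entries[entity_type])

    def max_key_length(self, entity_type: str) -> int:
        keys = self.entries[entity_type]
        return max((len(k) for k in keys), default=0)


def load_lexicon(
    lncrna_paths: Iterable[str] = (),
    protein_paths: Iterable[str] = (),
) -> Lexicon:
    """Load per-type lexicon files (one name per line, UTF-8).

    Raises if a file is missing or the combined lexicon is empty; an empty
    single type only warns.
    """
    lex = Lexicon()
    for etype, paths in ((LNCRNA, lncrna_paths), (PROTEIN, protein_paths)):
        for path in paths:
            with open(path, encoding="utf-8") as fh:
                for line in fh:
                    name = line.strip()
                    if name:
                        lex.add(etype, name)
    total = sum(lex.size(t) for t in ENTITY_TYPES)
    if total == 0:
        raise ValueError("lexicon is empty: no names loaded for any type")
    for etype in ENTITY_TYPES:
        if lex.size(etype) == 0:
            logger.warning("lexicon has zero %s entries", etype)
        else:
            logger.info("loaded %d %s names", lex.size(etype), etype)
    return lex


@dataclass(frozen=True)
class EntityMention:
    entity_type: str
    surface: str
    canonical: str
    token_span: tuple[int, int]  # [start, end) over raw_tokens
    method: str = "dictionary"

    def overlaps(self, other: "EntityMention") -> bool:
        return self.token_span[0] < other.token_span[1] and \
            other.token_span[0] < self.token_span[1]


@dataclass(frozen=True)
class CandidatePair:
    """An in-sentence lncRNA x protein pair — the unit of classification."""

    sentence: TokenizedSentence
    lnc: EntityMention
    prot: EntityMention

    def __post_init__(self) -> None:
        if self.lnc.entity_type != LNCRNA or self.prot.entity_type != PROTEIN:
            raise ValueError("pair must hold one lncRNA and one protein mention")
        if self.lnc.overlaps(self.prot):
            raise ValueError("mention spans overlap")


def _surface(sentence: TokenizedSentence, start: int, end: int) -> str:
    cs = sentence.offsets[start][0]
    ce = sentence.offsets[end - 1][1]
    return sentence.raw_text[cs:ce]


def find_mentions(sentence: TokenizedSentence, lexicon: Lexicon) -> list[EntityMention]:
    """Greedy longest-match dictionary NER over the raw token stream.

    At each start position the longest matching token span is taken for
    each entity type; the scan then advances past the longest match, so
    no reported mention of a type is a strict sub-span of another.
    """
    tokens = sentence.raw_tokens
    n = len(tokens)
    max_key = max(lexicon.max_key_length(t) for t in ENTITY_TYPES)
    mentions: list[EntityMention] = []
    i = 0
    while i < n:
        best_per_type: dict[str, tuple[int, str]] = {}
        key = ""
        j = i
        while j < n:
            key += normalize_name(tokens[j])
            j += 1
            if len(key) > max_key:
                break
            if not key:  # pure-punctuation token contributed nothing
                continue
            for etype in ENTITY_TYPES:
                canonical = lexicon.entries[etype].get(key)
                if canonical is not None:
                    best_per_type[etype] = (j, canonical)
        if best_per_type:
            furthest = i + 1
            for etype in ENTITY_TYPES:
                if etype in best_per_type:
                    end, canonical = best_per_type[etype]
                    mentions.append(EntityMention(
                        entity_type=etype,
                        surface=_surface(sentence, i, end),
                        canonical=canonical,
                        token_span=(i, end),
                        method="dictionary",
                    ))
                    furthest = max(furthest, end)
            i = furthest
        else:
            i += 1
    mentions.sort(key=lambda m: (m.token_span, m.entity_type))
    return mentions


def pair_candidates(
    mentions: Iterable[EntityMention],
    sentence: TokenizedSentence,
) -> list[CandidatePair]:
    """Cartesian product of lncRNA and protein mentions, minus overlapping
    spans, in deterministic (lnc span, prot span) order."""
    lncs = sorted((m for m in mentions if m.entity_type == LNCRNA),
                  key=lambda m: m.token_span)
    prots = sorted((m for m in mentions if m.entity_type == PROTEIN),
                   key=lambda m: m.token_span)
    return [
        CandidatePair(sentence=sentence, lnc=l, prot=p)
        for l in lncs for p in prots if not l.overlaps(p)
    ]


@runtime_checkable
class Tagger(Protocol):
    """Contract for an optional statistical NER tagger."""

    def tag(self, sentence: TokenizedSentence) -> list[EntityMention]:
        ...


def tag_with(tagger: Tagger | None, sentence: TokenizedSentence) -> list[EntityMention]:
    """Run the registered tagger, forcing ``method == "tagger"`` on its
    output; with no tagger registered, return nothing (dictionary-only)."""
    if tagger is None:
        logger.debug("no tagger registered; dictionary-only NER")
        return []
    out = []
    for m in tagger.tag(sentence):
        if m.method != "tagger":
            m = EntityMention(m.entity_type, m.surface, m.canonical,
                              m.token_span, method="tagger")
        out.append(m)
    return out
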