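"""Rule-based labeling of candidate pairs for corpus construction.

A candidate pair is labeled *positive* when its (lncRNA, protein) names
match a reference set of experimentally validated interactions. Pairs
absent from the reference set are labeled *negative* under one of two
conditions:

condition 1
    The sentence contains no interaction keyword; the presence of a
    negation word is irrelevant to this condition.
condition 2
    The sentence contains at least one interaction keyword AND at least
    one negation word.

A non-reference pair whose sentence carries a keyword but no negation is
ambiguous and is dropped rather than auto-labeled. Interaction keywords
are the verb and noun forms of associate, correlate, bind, interact and
enrich; the negation inventory is configurable since no canonical list
exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .ner import (CandidatePair, Lexicon, find_mentions, normalize_name,
                  pair_candidates)
from .preprocess import (RawDocument, TokenizedSentence, analyze_sentence,
                         clean_text, segment_sentences)

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "InteractionKeywordSet",
    "NegationLexicon",
    "ReferenceInteractionSet",
    "LabeledExample",
    "LabeledCorpus",
    "find_interaction_keywords",
    "find_negations",
    "label_positive",
    "label_negative",
    "build_corpus",
    "pair_from_example",
    "read_corpus",
    "write_corpus",
]

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
LABELS = (POSITIVE, NEGATIVE)
PROVENANCES = ("reference_match", "neg_condition_1", "neg_condition_2", "manual")


@dataclass(frozen=True)
class InteractionKeywordSet:
    """Base interaction lemmas plus their derivational noun forms."""

    bases: frozenset[str] = frozenset(
        {"associate", "correlate", "bind", "interact", "enrich"})
    noun_map: dict[str, str] = field(default_factory=lambda: {
        "association": "associate",
        "correlation": "correlate",
        "binding": "bind",
        "interaction": "interact",
        "enrichment": "enrich",
    })

    def matches(self, lemma: str) -> bool:
        return lemma in self.bases or lemma in self.noun_map


@dataclass(frozen=True)
class NegationLexicon:
    """Negation cue lemmas. The default inventory is the package's own
    choice and is fully configurable; corpus reproduction depends on it."""

    lemmas: frozenset[str] = frozenset(
        {"no", "not", "without", "neither", "nor", "lack", "absence",
         "fail", "unable", "never", "cannot"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "lemmas",
                           frozenset(w.lower() for w in self.lemmas))


class ReferenceInteractionSet:
    """Known (lncRNA, protein) interaction pairs, matched under the same
    normalization policy as the lexicon (case/hyphen/space-insensitive)."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._pairs: set[tuple[str, str]] = set()
        for lnc, prot in pairs:
            self.add(lnc, prot)

    def add(self, lnc: str, prot: str) -> None:
        if not lnc.strip() or not prot.strip():
            raise ValueError("reference pair names must be non-empty")
        self._pairs.add((normalize_name(lnc), normalize_name(prot)))

    def contains(self, lnc: str, prot: str) -> bool:
        return (normalize_name(lnc), normalize_name(prot)) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    @classmethod
    def from_tsv(cls, path: str) -> "ReferenceInteractionSet":
        ref = cls()
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}:{i}: expected 2 tab-separated columns")
                ref.add(parts[0], parts[1])
        return ref

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for lnc, prot in sorted(self._pairs):
                fh.write(f"{lnc}\t{prot}\n")


@dataclass(frozen=True)
class LabeledExample:
    sentence_text: str
    lncrna: str
    protein: str
    label: str
    provenance: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        consistent = (self.label == POSITIVE) == (
            self.provenance in ("reference_match", "manual"))
        if self.provenance != "manual" and not consistent:
            raise ValueError(
                f"provenance {self.provenance!r} inconsistent with label")

    def key(self) -> tuple[str, str, str, str, str]:
        return (self.sentence_text, self.lncrna, self.protein,
                self.label, self.provenance)


@dataclass
class LabeledCorpus:
    examples: list[LabeledExample] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ex in self.examples:
            out[ex.provenance] = out.get(ex.provenance, 0) + 1
        return out

    def labels(self) -> list[str]:
        return [ex.label for ex in self.examples]

    def __len__(self) -> int:
        return len(self.examples)

    def __iter__(self):
        return iter(self.examples)


# --------------------------------------------------------------------------
# Sentence-level cue detection
# --------------------------------------------------------------------------

def find_interaction_keywords(
    sentence: TokenizedSentence,
    kws: InteractionKeywordSet = InteractionKeywordSet(),
) -> list[str]:
    """Raw tokens whose lemma is an interaction base or derived noun."""
    return [tok for tok, lem in zip(sentence.raw_tokens, sentence.lemmas)
            if kws.matches(lem)]


def find_negations(
    sentence: TokenizedSentence,
    neg: NegationLexicon = NegationLexicon(),
) -> list[str]:
    """Raw tokens whose lemma is a negation cue."""
    return [tok for tok, lem in zip(sentence.raw_tokens, sentence.lemmas)
            if lem in neg.lemmas]


# --------------------------------------------------------------------------
# Labeling rules
# --------------------------------------------------------------------------

def label_positive(pair: CandidatePair, ref: ReferenceInteractionSet) -> bool:
    """True iff the pair's canonical names are in the reference set."""
    return ref.contains(pair.lnc.canonical, pair.prot.canonical)


def label_negative(
    pair: CandidatePair,
    ref: ReferenceInteractionSet,
    kws: InteractionKeywordSet = InteractionKeywordSet(),
    neg: NegationLexicon = NegationLexicon(),
) -> str | None:
    """Negative-sample provenance for a non-reference pair, or None.

    Returns ``neg_condition_1`` (no keyword in the sentence),
    ``neg_condition_2`` (keyword and negation both present), or None
    (keyword without negation: excluded from the corpus). Reference
    matches take precedence — negatives must not be in the reference set.
    """
    if label_positive(pair, ref):
        return None
    has_kw = bool(find_interaction_keywords(pair.sentence, kws))
    if not has_kw:
        return "neg_condition_1"
    if find_negations(pair.sentence, neg):
        return "neg_condition_2"
    return None


# --------------------------------------------------------------------------
# Corpus construction
# --------------------------------------------------------------------------

def candidate_pairs_of(
    doc: RawDocument,
    lexicon: Lexicon,
    stopwords: Iterable[str] | None = None,
) -> list[CandidatePair]:
    """All candidate pairs across a document's sentences."""
    pairs: list[CandidatePair] = []
    text = clean_text(doc.text)
    for si, sent_text in enumerate(segment_sentences(text)):
        sent = analyze_sentence(sent_text, f"{doc.doc_id}:s{si}", stopwords)
        mentions = find_mentions(sent, lexicon)
        pairs.extend(pair_candidates(mentions, sent))
    return pairs


def build_corpus(
    documents: Sequence[RawDocument],
    lexicon: Lexicon,
    ref: ReferenceInteractionSet,
    kws: InteractionKeywordSet = InteractionKeywordSet(),
    neg: NegationLexicon = NegationLexicon(),
) -> LabeledCorpus:
    """Label every candidate pair in every sentence of the documents.

    Each pair becomes a positive (reference match), a negative (condition
    1 or 2), or is dropped. Per-provenance counts are logged.
    """
    corpus = LabeledCorpus()
    n_pairs = 0
    for doc in documents:
        for pair in candidate_pairs_of(doc, lexicon):
            n_pairs += 1
            if label_positive(pair, ref):
                label, prov = POSITIVE, "reference_match"
            else:
                cond = label_negative(pair, ref, kws, neg)
                if cond is None:
                    continue
                label, prov = NEGATIVE, cond
            corpus.examples.append(LabeledExample(
                sentence_text=pair.sentence.raw_text,
                lncrna=pair.lnc.canonical,
                protein=pair.prot.canonical,
                label=label,
                provenance=prov,
            ))
    if not corpus.examples:
        logger.warning("no labeled examples produced from %d documents",
                       len(documents))
    logger.info("labeled %d of %d candidate pairs: %s",
                len(corpus), n_pairs, corpus.counts)
    return corpus


def pair_from_example(
    ex: LabeledExample,
    stopwords: Iterable[str] | None = None,
) -> CandidatePair:
    """Reconstruct the CandidatePair of a stored corpus row by locating
    the named entities in its sentence text."""
    from .ner import LNCRNA, PROTEIN  # local to avoid import cycle noise

    sent = analyze_sentence(ex.sentence_text, stopwords=stopwords)
    lex = Lexicon()
    lex.add(LNCRNA, ex.lncrna)
    lex.add(PROTEIN, ex.protein)
    pairs = pair_candidates(find_mentions(sent, lex), sent)
    if not pairs:
        raise ValueError(
            f"could not locate ({ex.lncrna!r}, {ex.protein!r}) in "
            f"{ex.sentence_text!r}")
    return pairs[0]


# --------------------------------------------------------------------------
# TSV serialization
# --------------------------------------------------------------------------

_HEADER = ["sentence", "lncrna", "protein", "label", "provenance"]


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(s: str) -> str:
    out, i = [], 0
    while i < len(s):
        c = s[i]
        if c == "\\" and i + 1 < len(s):
            nxt = s[i + 1]
            out.append({"\\": "\\", "t": "\t", "n": "\n"}.get(nxt, "\\" + nxt))
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


def write_corpus(corpus: LabeledCorpus, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for ex in corpus:
            fh.write("\t".join(_escape(v) for v in ex.key()) + "\n")


def read_corpus(path: str) -> LabeledCorpus:
    corpus = LabeledCorpus()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise ValueError(f"{path}:1: expected header {_HEADER}")
        for i, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = [_unescape(p) for p in line.split("\t")]
            if len(parts) != 5:
                raise ValueError(f"{path}:{i}: expected 5 columns, "
                                 f"got {len(parts)}")
            try:
                corpus.examples.append(LabeledExample(*parts))
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: {exc}") from exc
    return corpus
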