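"""Text preprocessing for biomedical relation extraction.

Turns raw abstracts into sentence units carrying three aligned streams —
raw tokens (with character offsets), lowercase lemmas, and Penn-style POS
tags — plus the indices of content tokens that survive stopword and
punctuation removal.

Two views of every sentence are kept deliberately. The *raw* stream is what
named-entity matching, context windows and dependency parsing consume:
function words such as "to" and "with" are legitimate context words and
parse nodes and must not be deleted. The *normalized* view (lemmas at
``content_indices``) is what semantic pooling consumes.

The tokenizer, lemmatizer and POS tagger are lightweight deterministic
rule systems shipped with the package so that every downstream feature is
bit-reproducible across environments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "RawDocument",
    "SourceKind",
    "TokenizedSentence",
    "clean_text",
    "segment_sentences",
    "tokenize",
    "lemmatize",
    "pos_tag",
    "analyze_sentence",
    "load_stopwords",
    "DEFAULT_ABBREVIATIONS",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

class SourceKind(str, Enum):
    """Provenance of a document. Only ``text`` is produced locally; the
    pmid/pmcid kinds exist so the result schema's source column can
    represent externally fetched documents."""

    TEXT = "text"
    PMID = "pmid"
    PMCID = "pmcid"


@dataclass(frozen=True)
class RawDocument:
    doc_id: str
    text: str
    source_kind: SourceKind = SourceKind.TEXT


@dataclass
class TokenizedSentence:
    """A sentence with aligned raw-token, lemma and POS streams.

    Invariants: the three streams have identical length; offsets are
    ordered and non-overlapping; every lemma is lowercase;
    ``content_indices`` is a subset of the raw token indices.
    """

    sentence_id: str
    raw_text: str
    raw_tokens: list[str]
    offsets: list[tuple[int, int]]
    lemmas: list[str]
    pos_tags: list[str]
    content_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.raw_tokens)
        if not (len(self.lemmas) == len(self.pos_tags) == len(self.offsets) == n):
            raise ValueError("token, lemma, POS and offset streams must align")
        prev_end = -1
        for (s, e), tok in zip(self.offsets, self.raw_tokens):
            if s < prev_end or e <= s:
                raise ValueError("offsets must be ordered and non-overlapping")
            if self.raw_text[s:e] != tok:
                raise ValueError("offset does not recover its token")
            prev_end = e
        if any(i < 0 or i >= n for i in self.content_indices):
            raise ValueError("content_indices out of range")
        if any(l != l.lower() for l in self.lemmas):
            raise ValueError("lemmas must be lowercase")

    def __len__(self) -> int:
        return len(self.raw_tokens)

    @property
    def content_lemmas(self) -> list[str]:
        return [self.lemmas[i] for i in self.content_indices]


# --------------------------------------------------------------------------
# Character-level cleaning
# --------------------------------------------------------------------------

# Letters, digits, whitespace and common punctuation survive; everything
# else (symbols, dingbats, non-Latin scripts) is dropped.
_DISALLOWED_RE = re.compile(r"[^A-Za-z0-9\s.,;:!?()\[\]\-'\"/%+]+")
_WS_RE = re.compile(r"\s+")


def clean_text(text: str) -> str:
    """Remove special characters and collapse whitespace runs.

    Idempotent; may return the empty string.
    """
    cleaned = _DISALLOWED_RE.sub(" ", text)
    return _WS_RE.sub(" ", cleaned).strip()


# --------------------------------------------------------------------------
# Sentence segmentation
# --------------------------------------------------------------------------

#: Abbreviations (dots stripped, lowercase) that never end a sentence.
DEFAULT_ABBREVIATIONS = frozenset(
    {"fig", "figs", "et", "al", "eg", "ie", "dr", "vs", "ref", "refs",
     "approx", "ca", "cf", "resp", "inc", "spp"}
)

_BOUNDARY_RE = re.compile(r"[.!?]+")
_TRAILING_WORD_RE = re.compile(r"([A-Za-z][A-Za-z.]*)$")


def segment_sentences(
    doc: RawDocument | str,
    abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS,
) -> list[str]:
    """Split a cleaned document into sentences.

    A run of ``.!?`` ends a sentence when it is followed by whitespace and
    an uppercase letter or digit (or end of text), unless the word before
    it is a known abbreviation ("Fig.", "et al.", "e.g."). The
    concatenation of the output equals the input up to whitespace.
    """
    text = doc.text if isinstance(doc, RawDocument) else doc
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        rest = text[end:]
        nxt = rest.lstrip()
        if nxt and not (nxt[0].isupper() or nxt[0].isdigit()):
            continue
        before = _TRAILING_WORD_RE.search(text[start:m.start()])
        if before and before.group(1).replace(".", "").lower() in abbreviations:
            continue
        sent = text[start:end].strip()
        if sent:
            sentences.append(sent)
        start = end
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# --------------------------------------------------------------------------
# Tokenization
# --------------------------------------------------------------------------

# Alphanumeric runs, optionally joined by hyphens or apostrophes ("NF-kB",
# "doesn't" stay single tokens); any other non-space character is its own
# punctuation token.
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-'][A-Za-z0-9]+)*|[^\sA-Za-z0-9]")


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Tokenize into (token, start, end) triples with character offsets."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def is_punctuation(token: str) -> bool:
    return not any(c.isalnum() for c in token)


# --------------------------------------------------------------------------
# Lemmatization (rule-based English inflection stripper)
# --------------------------------------------------------------------------

_IRREGULAR_LEMMAS = {
    "is": "be", "are": "be", "was": "be", "were": "be", "been": "be",
    "being": "be", "am": "be",
    "has": "have", "had": "have", "having": "have",
    "does": "do", "did": "do", "done": "do",
    "found": "find", "bound": "bind", "shown": "show", "showed": "show",
    "made": "make", "gave": "give", "given": "give", "taken": "take",
    "took": "take", "seen": "see", "saw": "see", "led": "lead",
    "mice": "mouse", "children": "child", "analyses": "analysis",
}

_DOUBLE_UNDOUBLE = set("bdfgkmnprt")


def _fix_verb_stem(stem: str) -> str:
    """Repair a stem left after removing -ed/-ing (Porter step-1b style)."""
    if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] in _DOUBLE_UNDOUBLE:
        return stem[:-1]
    if stem.endswith(("at", "bl", "iz")):
        return stem + "e"
    return stem


def lemmatize(word: str) -> str:
    """Lowercase lemma of a single token.

    Handles a table of irregular forms plus regular -s/-es/-ies, -ed and
    -ing inflections; tokens without letters are returned lowercased.
    """
    w = word.lower()
    if not any(c.isalpha() for c in w):
        return w
    if w in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[w]
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith(("ches", "shes", "xes", "zes", "oes")) and len(w) > 4:
        return w[:-2]
    if w.endswith("s") and not w.endswith(("ss", "us", "is")) and len(w) > 3:
        w = w[:-1]
    if w.endswith("ied") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("ing") and len(w) > 5:
        return _fix_verb_stem(w[:-3])
    if w.endswith("ed") and len(w) > 4:
        return _fix_verb_stem(w[:-2])
    return w


# --------------------------------------------------------------------------
# POS tagging (deterministic lexicon + suffix heuristics, Penn tagset)
# --------------------------------------------------------------------------

_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those", "each",
                "every", "some", "any", "no", "all", "both", "another"}
_PREPOSITIONS = {"in", "on", "at", "by", "for", "with", "from", "of",
                 "between", "into", "through", "during", "without", "within",
                 "under", "over", "about", "after", "before", "against",
                 "among", "via", "upon", "as", "than"}
_CONJUNCTIONS = {"and", "or", "but", "nor", "whereas", "while", "although",
                 "because", "if", "whether"}
_PRONOUNS = {"we", "it", "they", "he", "she", "i", "you", "its", "their",
             "our", "his", "her", "them", "us", "itself", "themselves"}
_MODALS = {"can", "could", "may", "might", "must", "shall", "should",
           "will", "would"}
_AUX_TAGS = {
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "am": "VBP",
    "has": "VBZ", "have": "VBP", "had": "VBD",
    "does": "VBZ", "do": "VBP", "did": "VBD",
}
#: Base forms the tagger recognizes as verbs (after lemmatization).
VERB_BASES = {
    "associate", "bind", "interact", "correlate", "enrich", "regulate",
    "express", "inhibit", "activate", "promote", "suppress", "induce",
    "measure", "find", "show", "observe", "indicate", "suggest", "contain",
    "affect", "increase", "decrease", "modulate", "mediate", "target",
    "repress", "silence", "detect", "reveal", "demonstrate", "play",
    "remain", "require", "involve", "identify", "predict", "compare",
    "report", "confirm", "reduce", "enhance", "lack", "fail", "hold",
    "recruit", "stabilize", "localize", "colocalize", "sequester",
}
_ADVERBS = {"very", "highly", "significantly", "strongly", "directly",
            "also", "however", "thus", "therefore", "together", "further"}
_ADJECTIVES = {"significant", "high", "low", "novel", "specific", "new",
               "important", "essential", "long", "short", "human", "present"}
_ADJ_SUFFIXES = ("al", "ous", "ive", "able", "ible", "ary")
_NUMBER_RE = re.compile(r"^\d+([.,]\d+)*$")


def _tag_token(token: str, lemma: str) -> str:
    if is_punctuation(token):
        return token[0] if token else "."
    w = token.lower()
    if _NUMBER_RE.match(w):
        return "CD"
    if w in _DETERMINERS:
        return "DT"
    if w == "to":
        return "TO"
    if w in _PREPOSITIONS:
        return "IN"
    if w in _CONJUNCTIONS:
        return "CC"
    if w in _PRONOUNS:
        return "PRP"
    if w in _MODALS:
        return "MD"
    if w in _AUX_TAGS:
        return _AUX_TAGS[w]
    if lemma in VERB_BASES:
        if w == lemma:
            return "VB"
        if w.endswith("ing"):
            return "VBG"
        if w.endswith(("ed", "en")) or w in _IRREGULAR_LEMMAS:
            return "VBD"
        if w.endswith("s"):
            return "VBZ"
        return "VB"
    if w in _ADVERBS or (w.endswith("ly") and len(w) > 3):
        return "RB"
    if w in _ADJECTIVES or w.endswith(_ADJ_SUFFIXES):
        return "JJ"
    # biomedical symbol-like names (BC1, Eif4a1, NF-kB) read as proper nouns
    if any(c.isdigit() for c in token) or token.isupper() or any(
            c.isupper() for c in token[1:]):
        return "NNP"
    if token.istitle():
        return "NNP"
    if w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return "NNS"
    return "NN"


def pos_tag(tokens: Sequence[str], lemmas: Sequence[str]) -> list[str]:
    """One Penn-style tag per token."""
    return [_tag_token(t, l) for t, l in zip(tokens, lemmas)]


# --------------------------------------------------------------------------
# Stopwords and full analysis
# --------------------------------------------------------------------------

def load_stopwords(path: str | None = None) -> frozenset[str]:
    """Load the stopword inventory (packaged default, or a custom file)."""
    if path is None:
        text = (resources.files("lpitext.data") / "stopwords.txt").read_text(
            encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    words = {ln.strip().lower() for ln in text.splitlines()
             if ln.strip() and not ln.startswith("#")}
    return frozenset(words)


_DEFAULT_STOPWORDS: frozenset[str] | None = None


def _default_stopwords() -> frozenset[str]:
    global _DEFAULT_STOPWORDS
    if _DEFAULT_STOPWORDS is None:
        _DEFAULT_STOPWORDS = load_stopwords()
    return _DEFAULT_STOPWORDS


def analyze_sentence(
    sentence: str,
    sentence_id: str = "s0",
    stopwords: Iterable[str] | None = None,
) -> TokenizedSentence:
    """Produce the aligned token/lemma/POS streams for one sentence.

    Stopword and punctuation removal only selects ``content_indices``; the
    raw token stream is preserved untouched.
    """
    if not sentence.strip():
        raise ValueError("sentence must be non-empty")
    stop = frozenset(stopwords) if stopwords is not None else _default_stopwords()
    triples = tokenize(sentence)
    tokens = [t for t, _, _ in triples]
    offsets = [(s, e) for _, s, e in triples]
    lemmas = [lemmatize(t) for t in tokens]
    tags = pos_tag(tokens, lemmas)
    content = [
        i for i, (tok, lem) in enumerate(zip(tokens, lemmas))
        if not is_punctuation(tok) and tok.lower() not in stop and lem not in stop
    ]
    return TokenizedSentence(
        sentence_id=sentence_id,
        raw_text=sentence,
        raw_tokens=tokens,
        offsets=offsets,
        lemmas=lemmas,
        pos_tags=tags,
        content_indices=content,
    )
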