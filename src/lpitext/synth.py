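"""Synthetic fixtures: deterministic embeddings, template corpora with
planted interactions, and registered dependency-tree fixtures.

The generator emulates the structure of a rule-labeled interaction
corpus: positive sentences co-mention a reference (lncRNA, protein) pair
together with an interaction keyword; condition-1 negatives co-mention a
non-reference pair without any keyword; condition-2 negatives carry both
a keyword and a negation cue. Reference pairs and negative pairs are
drawn from disjoint slices of the name-pair space, so the rule engine
must recover the planted labels exactly.

Class separability is controlled by ``signal``: each class draws filler
words from its own pool, and pool word vectors are shifted by
``+/- signal/2`` along the first embedding axis, so the separation of
the class-conditional mean embeddings is ``signal``. At signal 0 the two
pools are exchangeable draws from the same vector distribution.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_rules import LabeledCorpus, LabeledExample, \
    ReferenceInteractionSet, pair_from_example
from .features import (DependencyTree, EmbeddingChain, EmbeddingProvider,
                       FeatureConfig, featurize_pairs)
from .model import FeatureMatrix
from .ner import LNCRNA, PROTEIN, Lexicon
from .preprocess import RawDocument, analyze_sentence

__all__ = [
    "SynthConfig",
    "SynthBundle",
    "make_toy_embedding",
    "generate_corpus",
    "feature_matrix",
    "fixture_tree",
    "FIXTURE_TREES",
    "DEFAULT_LNC_POOL",
    "DEFAULT_PROT_POOL",
]

#: Entity name pools mixing well-known names (so worked examples run
#: verbatim) with plausible synthetic ones.
DEFAULT_LNC_POOL = (
    "BC1", "H19", "MALAT1", "NEAT1", "XIST", "HOTAIR", "TUG1", "GAS5",
    "PVT1", "LINC00115", "LINC00473", "SNHG1",
)
DEFAULT_PROT_POOL = (
    "Pura", "Eif4a1", "Igf2", "EZH2", "PTBP1", "STAU1", "FUS", "AUF1",
    "IGF2BP1", "SRSF1", "TDP43", "HNRNPK",
)

_TISSUES = ("brain", "liver", "tumor", "serum", "muscle", "kidney",
            "plasma", "cortex")
_KW_VERB = ("binds", "interacts with", "associates with", "correlates with")
_KW_BASE = ("bind", "interact with", "associate with", "correlate with")
_KW_NOUN = ("association", "correlation", "interaction", "binding")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; ``generate_corpus`` is a pure function of this."""

    seed: int = 0
    dim: int = 16
    n_pos: int = 20
    n_neg: int = 15
    signal: float = 0.0
    neg2_fraction: float = 0.5
    sentences_per_doc: int = 5
    n_filler: int = 30
    embed_entities: bool = False
    #: restrict both classes to lexically matched sentence templates
    #: (keyword-bearing positives vs negated keyword-bearing negatives),
    #: for calibration experiments where only the filler pools may differ
    matched_templates: bool = False
    lnc_pool: tuple[str, ...] = DEFAULT_LNC_POOL
    prot_pool: tuple[str, ...] = DEFAULT_PROT_POOL

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("n_pos and n_neg must be >= 0")
        if self.signal < 0:
            raise ValueError("signal must be >= 0")
        if not (0.0 <= self.neg2_fraction <= 1.0):
            raise ValueError("neg2_fraction must be in [0, 1]")


@dataclass
class SynthBundle:
    config: SynthConfig
    documents: list[RawDocument]
    lexicon: Lexicon
    reference: ReferenceInteractionSet
    expected: LabeledCorpus
    provider: EmbeddingProvider


# --------------------------------------------------------------------------
# Deterministic embeddings
# --------------------------------------------------------------------------

def _word_rng(word: str, seed: int) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}:{word}".encode("utf-8")).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


def make_toy_embedding(vocab: Sequence[str], dim: int,
                       seed: int = 0) -> EmbeddingProvider:
    """Unit-norm vectors derived from a hash of (word, seed): identical
    across runs and platforms, independent of vocabulary order."""
    if not vocab:
        raise ValueError("vocab must be non-empty")
    prov = EmbeddingProvider(f"toy(dim={dim},seed={seed})", dim)
    for word in vocab:
        v = _word_rng(word, seed).standard_normal(dim)
        prov.add(word, v / np.linalg.norm(v))
    return prov


# --------------------------------------------------------------------------
# Corpus generation
# --------------------------------------------------------------------------

def _pick(rng: np.random.Generator, items: Sequence[str]) -> str:
    return items[int(rng.integers(len(items)))]


def _make_sentence(kind: str, lnc: str, prot: str, fillers: Sequence[str],
                   rng: np.random.Generator, matched: bool = False) -> str:
    t = _pick(rng, _TISSUES)
    f1, f2 = _pick(rng, fillers), _pick(rng, fillers)
    variant = 0 if matched else int(rng.integers(2))
    if kind == "pos":
        kw = _pick(rng, _KW_VERB)
        if variant == 0:
            return f"{lnc} {kw} {prot} in {t} {f1} {f2} samples"
        return f"Analysis of {f1} {f2} revealed that {lnc} {kw} {prot}"
    if kind == "neg1":
        if variant == 0:
            return f"{lnc} and {prot} were measured in {t} {f1} {f2} samples"
        return f"Levels of {lnc} and {prot} were detected in {t} {f1} {f2}"
    if kind == "neg2":
        if variant == 0:
            kw = _pick(rng, _KW_BASE)
            return f"{lnc} does not {kw} {prot} in {t} {f1} {f2} samples"
        kw = _pick(rng, _KW_NOUN)
        return f"We found no {kw} between {lnc} and {prot} in {t} {f1} {f2}"
    raise ValueError(kind)


def generate_corpus(config: SynthConfig) -> SynthBundle:
    """Build documents, lexicons, a reference set and the expected labeled
    corpus, such that running NER + the labeling rules over the documents
    reproduces the expected corpus exactly."""
    rng = np.random.default_rng(config.seed)
    combos = [(l, p) for l in config.lnc_pool for p in config.prot_pool]
    order = rng.permutation(len(combos))
    combos = [combos[i] for i in order]
    n_ref = max(1, min(len(combos) // 2, config.n_pos)) if config.n_pos else 0
    ref_pairs = combos[:n_ref]
    neg_pairs = combos[n_ref:]
    if config.n_neg and not neg_pairs:
        raise ValueError("name pools too small to host negative pairs")

    # at zero signal the class-conditional embedding distributions must
    # coincide, so both classes share one filler pool; with signal the
    # pools are disjoint and their vectors shifted apart
    pos_fillers = tuple(f"signalpos{i}" for i in range(config.n_filler))
    if config.signal == 0:
        neg_fillers = pos_fillers
    else:
        neg_fillers = tuple(f"signalneg{i}" for i in range(config.n_filler))

    kinds = ["pos"] * config.n_pos
    n_neg2 = int(round(config.n_neg * config.neg2_fraction))
    kinds += ["neg2"] * n_neg2 + ["neg1"] * (config.n_neg - n_neg2)

    records: list[tuple[str, LabeledExample]] = []
    for i, kind in enumerate(kinds):
        if kind == "pos":
            lnc, prot = ref_pairs[i % len(ref_pairs)]
            fillers = pos_fillers
            label, prov = "positive", "reference_match"
        else:
            lnc, prot = neg_pairs[i % len(neg_pairs)]
            fillers = neg_fillers
            label = "negative"
            prov = "neg_condition_1" if kind == "neg1" else "neg_condition_2"
        sent = _make_sentence(kind, lnc, prot, fillers, rng,
                              matched=config.matched_templates)
        records.append((sent, LabeledExample(
            sentence_text=sent + ".", lncrna=lnc, protein=prot,
            label=label, provenance=prov)))

    # shuffle sentences into documents
    perm = rng.permutation(len(records)) if records else np.array([], int)
    shuffled = [records[i] for i in perm]
    documents = []
    for d in range(0, len(shuffled), config.sentences_per_doc):
        chunk = shuffled[d:d + config.sentences_per_doc]
        text = " ".join(sent + "." for sent, _ in chunk)
        documents.append(RawDocument(doc_id=f"doc{d // config.sentences_per_doc}",
                                     text=text))
    expected = LabeledCorpus(examples=[ex for _, ex in shuffled])

    lexicon = Lexicon()
    for name in config.lnc_pool:
        lexicon.add(LNCRNA, name)
    for name in config.prot_pool:
        lexicon.add(PROTEIN, name)
    reference = ReferenceInteractionSet(ref_pairs)

    provider = _signal_provider(config, [sent for sent, _ in shuffled],
                                pos_fillers, neg_fillers)
    return SynthBundle(config=config, documents=documents, lexicon=lexicon,
                       reference=reference, expected=expected,
                       provider=provider)


def _signal_provider(config: SynthConfig, sentences: Sequence[str],
                     pos_fillers: Sequence[str],
                     neg_fillers: Sequence[str]) -> EmbeddingProvider:
    vocab: set[str] = set(pos_fillers) | set(neg_fillers)
    for sent in sentences:
        analyzed = analyze_sentence(sent)
        vocab.update(t.lower() for t in analyzed.raw_tokens)
        vocab.update(analyzed.lemmas)
    if not config.embed_entities:
        entity_keys = {n.lower() for n in config.lnc_pool} | \
            {n.lower() for n in config.prot_pool}
        vocab -= entity_keys
    if not vocab:
        vocab = {"placeholder"}
    prov = make_toy_embedding(sorted(vocab), config.dim, config.seed)
    shift = np.zeros(config.dim)
    shift[0] = config.signal / 2.0
    for w in pos_fillers:
        if w in prov:
            prov.add(w, prov.vectors[w] + shift)
    for w in neg_fillers:
        if w in prov:
            prov.add(w, prov.vectors[w] - shift)
    return prov


def feature_matrix(
    bundle: SynthBundle,
    groups: Sequence[str] | None = None,
    pooling: str = "mean",
) -> FeatureMatrix:
    """Featurize the bundle's expected corpus with its own embeddings."""
    config = FeatureConfig(
        groups=tuple(groups) if groups else ("semantic", "syntactic",
                                             "distance", "pos"),
        dim=bundle.config.dim, pooling=pooling)
    pairs = [pair_from_example(ex) for ex in bundle.expected]
    chain = EmbeddingChain([bundle.provider])
    blocks = featurize_pairs(pairs, chain, config)
    return FeatureMatrix(blocks=blocks,
                         labels=np.array(bundle.expected.labels()),
                         config=config)


# --------------------------------------------------------------------------
# Dependency-tree fixtures
# --------------------------------------------------------------------------

#: Registered trees: name -> (tokens, parents). The bc1_pura tree is the
#: worked five-token example whose DFS traversal reads
#: "associates RNA Bc1 Pura with".
FIXTURE_TREES: dict[str, tuple[tuple[str, ...], tuple[int, ...]]] = {
    "bc1_pura": (("Bc1", "RNA", "associates", "with", "Pura"),
                 (1, 2, -1, 4, 2)),
    "single": (("X",), (-1,)),
    "chain3": (("a", "b", "c"), (-1, 0, 1)),
    "star4": (("hub", "a", "b", "c"), (-1, 0, 0, 0)),
}


def fixture_tree(name: str) -> DependencyTree:
    """Return a registered dependency tree by name."""
    if name not in FIXTURE_TREES:
        raise KeyError(
            f"unknown fixture tree {name!r}; registry: "
            f"{sorted(FIXTURE_TREES)}")
    tokens, parents = FIXTURE_TREES[name]
    return DependencyTree(tokens, parents)
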