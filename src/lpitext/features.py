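"""Sentence-pair feature extraction.

A candidate lncRNA-protein pair is represented by four concatenated
blocks:

semantic
    Word embeddings of the sentence's content lemmas, pooled to a fixed
    length. Embeddings come from a fallback chain of providers (a locally
    retrained table first, then a general biomedical table); a word found
    in no provider embeds to the all-zeros vector.
syntactic
    The same embeddings, but over the sentence's tokens re-ordered by a
    depth-first traversal of its dependency parse, so that syntactically
    adjacent words become sequence-adjacent. All raw tokens participate,
    stopwords included.
distance
    Cosine distances between each entity's embedding and its three
    nearest raw tokens on each side (12 slots; absent context words and
    zero-vector words contribute the sentinel 0).
pos
    One-hot part-of-speech codes of the two entity head tokens over a
    fixed 11-category inventory (22 binary slots).

Under the defaults (embedding dimension 200, mean pooling) the full
vector has 200 + 200 + 12 + 22 = 434 dimensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .ner import CandidatePair, EntityMention
from .preprocess import (TokenizedSentence, clean_text, is_punctuation,
                         segment_sentences, tokenize)

__all__ = [
    "EmbeddingProvider",
    "EmbeddingChain",
    "embed_word",
    "read_word2vec_text",
    "write_word2vec_text",
    "EmbeddingTrainerConfig",
    "train_embeddings",
    "DependencyTree",
    "HeuristicParser",
    "parse_dependencies",
    "dfs_order",
    "semantic_vector",
    "syntactic_vector",
    "context_words",
    "cosine_distance",
    "distance_vector",
    "POS_CATEGORIES",
    "PENN_TO_CATEGORY",
    "pos_onehot",
    "pos_vector",
    "FeatureConfig",
    "FeatureVector",
    "assemble_features",
    "featurize_pairs",
    "FEATURE_GROUPS",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Embedding providers and the fallback chain
# --------------------------------------------------------------------------

class EmbeddingProvider:
    """A named word -> vector table of fixed dimension."""

    def __init__(self, name: str, dimension: int,
                 vectors: dict[str, np.ndarray] | None = None):
        if dimension <= 0:
            raise ValueError("dimension must be positive")
        self.name = name
        self.dimension = int(dimension)
        self.vectors: dict[str, np.ndarray] = {}
        if vectors:
            for w, v in vectors.items():
                self.add(w, v)

    def add(self, word: str, vector: np.ndarray) -> None:
        v = np.asarray(vector, dtype=np.float64)
        if v.shape != (self.dimension,):
            raise ValueError(
                f"vector for {word!r} has shape {v.shape}, "
                f"expected ({self.dimension},)")
        self.vectors[word] = v

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def get(self, word: str) -> np.ndarray | None:
        return self.vectors.get(word)


class EmbeddingChain:
    """Ordered fallback chain: the first provider containing a word wins;
    a word in no provider embeds to the zero vector."""

    def __init__(self, providers: Sequence[EmbeddingProvider]):
        if not providers:
            raise ValueError("chain must contain at least one provider")
        dims = {p.dimension for p in providers}
        if len(dims) != 1:
            raise ValueError(f"providers disagree on dimension: {sorted(dims)}")
        self.providers = list(providers)
        self.dimension = providers[0].dimension

    def embed(self, word: str) -> np.ndarray:
        for p in self.providers:
            v = p.get(word)
            if v is not None:
                return v
        return np.zeros(self.dimension)


def embed_word(word: str, chain: EmbeddingChain) -> np.ndarray:
    return chain.embed(word)


def read_word2vec_text(path: str, name: str | None = None) -> EmbeddingProvider:
    """Read a table in word2vec text format ("vocab dim" header, then one
    "word v1 ... vd" line per word)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        vocab_size, dim = int(header[0]), int(header[1])
        prov = EmbeddingProvider(name or path, dim)
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"{path}: bad vector line for {parts[0]!r}")
            prov.add(parts[0], np.array([float(x) for x in parts[1:]]))
    if len(prov) != vocab_size:
        logger.warning("%s: header says %d words, read %d",
                       path, vocab_size, len(prov))
    return prov


def write_word2vec_text(provider: EmbeddingProvider, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(provider)} {provider.dimension}\n")
        for word in sorted(provider.vectors):
            vec = " ".join(repr(float(x)) for x in provider.vectors[word])
            fh.write(f"{word} {vec}\n")


# --------------------------------------------------------------------------
# Skip-gram embedding training (numpy, negative sampling)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbeddingTrainerConfig:
    """Skip-gram training settings. The defaults mirror the biomedical
    word2vec convention: 200 dimensions, window 5, frequent-word
    subsampling threshold 0.001."""

    dim: int = 200
    window: int = 5
    subsample: float = 1e-3
    skipgram: bool = True
    min_count: int = 1
    negative: int = 5
    epochs: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    seed: int = 0


def _corpus_sentences(corpus_text: str | Iterable[str]) -> list[list[str]]:
    if isinstance(corpus_text, str):
        sentences = segment_sentences(clean_text(corpus_text))
    else:
        sentences = list(corpus_text)
    out = []
    for s in sentences:
        toks = [t.lower() for t, _, _ in tokenize(s) if not is_punctuation(t)]
        if toks:
            out.append(toks)
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_embeddings(
    corpus_text: str | Iterable[str],
    config: EmbeddingTrainerConfig = EmbeddingTrainerConfig(),
) -> EmbeddingProvider:
    """Train skip-gram word embeddings with negative sampling.

    Deterministic for a fixed corpus and seed. Every word at or above
    ``min_count`` receives a vector of length ``config.dim``.
    """
    if not config.skipgram:
        raise NotImplementedError("only the skip-gram objective is provided")
    sentences = _corpus_sentences(corpus_text)
    counts: dict[str, int] = {}
    for s in sentences:
        for w in s:
            counts[w] = counts.get(w, 0) + 1
    total = sum(counts.values())
    if total < config.window:
        raise ValueError(
            f"corpus has {total} tokens, smaller than window {config.window}")
    vocab = sorted((w for w, c in counts.items() if c >= config.min_count),
                   key=lambda w: (-counts[w], w))
    if not vocab:
        raise ValueError("no word reaches min_count")
    index = {w: i for i, w in enumerate(vocab)}
    freq = np.array([counts[w] for w in vocab], dtype=np.float64)
    noise = freq ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())
    if config.subsample > 0:
        f = freq / total
        keep = np.minimum(1.0, (np.sqrt(f / config.subsample) + 1)
                          * config.subsample / f)
    else:
        keep = np.ones(len(vocab))

    rng = np.random.default_rng(config.seed)
    V, D = len(vocab), config.dim
    W = (rng.random((V, D)) - 0.5) / D   # input (word) vectors
    C = np.zeros((V, D))                 # output (context) vectors

    n_updates = max(1, config.epochs * total)
    done = 0
    for _ in range(config.epochs):
        for sent in sentences:
            ids = [index[w] for w in sent if w in index]
            ids = [i for i in ids if rng.random() < keep[i]]
            for pos, center in enumerate(ids):
                done += 1
                b = int(rng.integers(1, config.window + 1))
                ctx = ids[max(0, pos - b):pos] + ids[pos + 1:pos + 1 + b]
                if not ctx:
                    continue
                lr = max(config.min_alpha,
                         config.alpha * (1 - done / n_updates))
                negs = np.searchsorted(
                    noise_cdf, rng.random(config.negative * len(ctx)))
                targets = np.concatenate([np.array(ctx, dtype=np.int64), negs])
                labels = np.zeros(len(targets))
                labels[:len(ctx)] = 1.0
                h = W[center]
                g = (_sigmoid(C[targets] @ h) - labels) * lr
                dh = g @ C[targets]
                C[targets] -= np.outer(g, h)
                W[center] -= dh
    return EmbeddingProvider(
        name=f"skipgram(dim={D},seed={config.seed})",
        dimension=D,
        vectors={w: W[index[w]].copy() for w in vocab},
    )


# --------------------------------------------------------------------------
# Dependency trees, pluggable parsing, DFS ordering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DependencyTree:
    """One node per raw token; ``parents[i]`` is the head index of token
    i, with -1 marking the single root. Children are always visited in
    sentence order."""

    tokens: tuple[str, ...]
    parents: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "parents", tuple(self.parents))
        n = len(self.tokens)
        if len(self.parents) != n or n == 0:
            raise ValueError("parents must align with a non-empty token list")
        roots = [i for i, p in enumerate(self.parents) if p == -1]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        for i, p in enumerate(self.parents):
            if p != -1 and not (0 <= p < n):
                raise ValueError(f"parent index {p} out of range")
        # connectivity / acyclicity: every node must reach the root
        for i in range(n):
            seen, j = set(), i
            while j != -1:
                if j in seen:
                    raise ValueError("cycle detected in dependency tree")
                seen.add(j)
                j = self.parents[j]

    @property
    def root(self) -> int:
        return self.parents.index(-1)

    def children(self, i: int) -> list[int]:
        return [j for j, p in enumerate(self.parents) if p == i]


class HeuristicParser:
    """Deterministic fallback parser: the first verb-tagged token becomes
    the root; tokens to its left form a chain headed rightward toward the
    root and tokens to its right a chain headed leftward. A crude but
    reproducible stand-in for a trained dependency parser, adequate for
    generating valid trees on synthetic text."""

    _VERB_TAGS = {"VB", "VBP", "VBZ", "VBD", "VBN", "VBG", "MD"}

    def parse(self, tokens: Sequence[str],
              pos_tags: Sequence[str]) -> tuple[list[int], int]:
        n = len(tokens)
        root = next((i for i, t in enumerate(pos_tags)
                     if t in self._VERB_TAGS), None)
        if root is None:
            root = next((i for i, t in enumerate(tokens)
                         if not is_punctuation(t)), 0)
        parents = []
        for i in range(n):
            if i < root:
                parents.append(i + 1)
            elif i == root:
                parents.append(-1)
            else:
                parents.append(i - 1)
        return parents, root


#: Parser plug-in contract: (tokens, pos_tags) -> (parents, root_index).
ParserFn = Callable[[Sequence[str], Sequence[str]], tuple[Sequence[int], int]]

_DEFAULT_PARSER = HeuristicParser()


def parse_dependencies(
    sentence: TokenizedSentence,
    parser: ParserFn | HeuristicParser | None = None,
) -> DependencyTree:
    """Parse a sentence into a DependencyTree via the plug-in contract.

    A failing parser degrades to a linear chain (each token headed by its
    left neighbour), which makes the DFS order coincide with sentence
    order; the degradation is logged.
    """
    if parser is None:
        parser = _DEFAULT_PARSER
    fn = parser.parse if hasattr(parser, "parse") else parser
    try:
        parents, root = fn(sentence.raw_tokens, sentence.pos_tags)
        tree = DependencyTree(tuple(sentence.raw_tokens), tuple(parents))
        if tree.root != root:
            raise ValueError("parser root inconsistent with parent array")
        return tree
    except Exception as exc:  # noqa: BLE001 - any parser failure degrades
        logger.warning("parser failed (%s); falling back to linear order", exc)
        n = len(sentence.raw_tokens)
        return DependencyTree(tuple(sentence.raw_tokens),
                              tuple([-1] + list(range(n - 1))))


def dfs_order(tree: DependencyTree) -> list[str]:
    """Pre-order depth-first traversal from the root, children in
    sentence order; a permutation of the tree's tokens."""
    out: list[str] = []
    stack = [tree.root]
    while stack:
        i = stack.pop()
        out.append(tree.tokens[i])
        stack.extend(reversed(tree.children(i)))
    return out


# --------------------------------------------------------------------------
# Semantic and syntactic blocks
# --------------------------------------------------------------------------

def _pool(words: Sequence[str], chain: EmbeddingChain,
          pooling: str = "mean", max_len: int = 20) -> np.ndarray:
    """Reduce a word sequence to a fixed-length vector.

    ``mean``: arithmetic mean of the word vectors (order-free);
    ``pad_concat``: concatenation of the first ``max_len`` vectors,
    zero-padded, which preserves order at dimension ``dim * max_len``.
    """
    if pooling == "mean":
        if not words:
            return np.zeros(chain.dimension)
        return np.mean([chain.embed(w) for w in words], axis=0)
    if pooling == "pad_concat":
        out = np.zeros(chain.dimension * max_len)
        for i, w in enumerate(words[:max_len]):
            out[i * chain.dimension:(i + 1) * chain.dimension] = chain.embed(w)
        return out
    raise ValueError(f"unknown pooling mode {pooling!r}")


def semantic_vector(sentence: TokenizedSentence,
                    chain: EmbeddingChain) -> np.ndarray:
    """Mean-pooled embedding of the sentence's content lemmas."""
    return _pool(sentence.content_lemmas, chain, "mean")


def syntactic_vector(
    sentence: TokenizedSentence,
    chain: EmbeddingChain,
    parser: ParserFn | None = None,
    pooling: str = "mean",
    max_len: int = 20,
    sdp_only: bool = False,
    entity_spans: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> np.ndarray:
    """Embedding of the DFS-ordered parse tokens, pooled to fixed length.

    By default the full tree is traversed (the worked traversal of
    "Bc1 RNA associates with Pura" visits all five tokens). With
    ``sdp_only`` the sequence is restricted to the shortest dependency
    path between the two entity head tokens, an alternative reading of
    the method that is exposed but not the default.
    """
    tree = parse_dependencies(sentence, parser)
    seq = dfs_order(tree)
    if sdp_only:
        if entity_spans is None:
            raise ValueError("sdp_only requires the two entity spans")
        keep = set(_shortest_path(tree, entity_spans[0][1] - 1,
                                  entity_spans[1][1] - 1))
        order = _dfs_indices(tree)
        seq = [tree.tokens[i] for i in order if i in keep]
    return _pool([w.lower() for w in seq], chain, pooling, max_len)


def _dfs_indices(tree: DependencyTree) -> list[int]:
    out: list[int] = []
    stack = [tree.root]
    while stack:
        i = stack.pop()
        out.append(i)
        stack.extend(reversed(tree.children(i)))
    return out


def _shortest_path(tree: DependencyTree, a: int, b: int) -> list[int]:
    def ancestors(i: int) -> list[int]:
        path = [i]
        while tree.parents[path[-1]] != -1:
            path.append(tree.parents[path[-1]])
        return path

    pa, pb = ancestors(a), ancestors(b)
    sb = set(pb)
    lca = next(i for i in pa if i in sb)
    up = pa[:pa.index(lca) + 1]
    down = pb[:pb.index(lca)]
    return up + list(reversed(down))


# --------------------------------------------------------------------------
# Distance block
# --------------------------------------------------------------------------

def context_words(sentence: TokenizedSentence, mention: EntityMention,
                  k: int = 3) -> tuple[list[str], list[str]]:
    """Up to k raw tokens immediately left and right of the mention span,
    in sentence order, truncated at the sentence boundaries."""
    start, end = mention.token_span
    left = sentence.raw_tokens[max(0, start - k):start]
    right = sentence.raw_tokens[end:end + k]
    return left, right


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v), in [0, 2]; the sentinel 0 if either vector is zero
    (out-of-vocabulary words embed to zero, leaving the angle undefined)."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.clip(1.0 - float(u @ v) / (nu * nv), 0.0, 2.0))


def _mention_vector(sentence: TokenizedSentence, mention: EntityMention,
                    chain: EmbeddingChain) -> np.ndarray:
    start, end = mention.token_span
    toks = [t.lower() for t in sentence.raw_tokens[start:end]]
    return _pool(toks, chain, "mean")


def distance_vector(pair: CandidatePair, chain: EmbeddingChain,
                    k: int = 3) -> np.ndarray:
    """12 slots (with k=3): for each entity in (lncRNA, protein) order,
    cosine distances of its left then right context words to the entity
    embedding, padded with the sentinel 0 where fewer than k words exist."""
    out = np.zeros(4 * k)
    slot = 0
    for mention in (pair.lnc, pair.prot):
        evec = _mention_vector(pair.sentence, mention, chain)
        left, right = context_words(pair.sentence, mention, k)
        for side in (left, right):
            for i, word in enumerate(side):
                out[slot + i] = cosine_distance(chain.embed(word.lower()), evec)
            slot += k
    return out


# --------------------------------------------------------------------------
# Part-of-speech block
# --------------------------------------------------------------------------

#: The 11 coarse POS categories, in fixed order. NN sits at index 1 so the
#: singular-noun one-hot code is [0,1,0,0,0,0,0,0,0,0,0].
POS_CATEGORIES = (
    "proper-noun",        # NNP, NNPS
    "noun-singular",      # NN
    "noun-plural",        # NNS
    "verb-base",          # VB, VBP, VBG
    "verb-3sg",           # VBZ
    "verb-past",          # VBD, VBN
    "adjective",          # JJ, JJR, JJS
    "adverb",             # RB, RBR, RBS
    "preposition",        # IN, TO
    "determiner",         # DT
    "closed-class",       # CC, PRP, MD, CD, ...
)

PENN_TO_CATEGORY: dict[str, int] = {
    "NNP": 0, "NNPS": 0,
    "NN": 1,
    "NNS": 2,
    "VB": 3, "VBP": 3, "VBG": 3,
    "VBZ": 4,
    "VBD": 5, "VBN": 5,
    "JJ": 6, "JJR": 6, "JJS": 6,
    "RB": 7, "RBR": 7, "RBS": 7,
    "IN": 8, "TO": 8,
    "DT": 9,
    "CC": 10, "PRP": 10, "PRP$": 10, "MD": 10, "CD": 10, "EX": 10,
    "WDT": 10, "POS": 10,
}


def pos_onehot(tag: str) -> np.ndarray:
    """11-slot one-hot code of a Penn tag's coarse category; a tag outside
    the inventory (e.g. FW, punctuation) encodes to all zeros."""
    vec = np.zeros(len(POS_CATEGORIES))
    idx = PENN_TO_CATEGORY.get(tag)
    if idx is None:
        logger.debug("POS tag %r outside the 11-category inventory", tag)
    else:
        vec[idx] = 1.0
    return vec


def pos_vector(pair: CandidatePair) -> np.ndarray:
    """22 binary slots: one-hot codes of the lncRNA and protein head
    tokens (the last token of each mention span)."""
    tags = pair.sentence.pos_tags
    lnc_tag = tags[pair.lnc.token_span[1] - 1]
    prot_tag = tags[pair.prot.token_span[1] - 1]
    return np.concatenate([pos_onehot(lnc_tag), pos_onehot(prot_tag)])


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------

FEATURE_GROUPS = ("semantic", "syntactic", "distance", "pos")


@dataclass(frozen=True)
class FeatureConfig:
    """Which blocks are enabled and how they are sized.

    ``dim`` is the embedding dimension (200 under the reference settings,
    smaller for test-scale runs); ``context_k`` the one-sided context
    width of the distance block; ``pooling`` applies to the semantic and
    syntactic blocks.
    """

    groups: tuple[str, ...] = FEATURE_GROUPS
    dim: int = 200
    context_k: int = 3
    pooling: str = "mean"
    pad_max_len: int = 20
    sdp_only: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(FEATURE_GROUPS)
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")
        if not self.groups:
            raise ValueError("at least one feature group must be enabled")
        order = [g for g in FEATURE_GROUPS if g in self.groups]
        object.__setattr__(self, "groups", tuple(order))

    def block_size(self, group: str) -> int:
        pooled = self.dim if self.pooling == "mean" else self.dim * self.pad_max_len
        return {
            "semantic": pooled,
            "syntactic": pooled,
            "distance": 4 * self.context_k,
            "pos": 2 * len(POS_CATEGORIES),
        }[group]

    @property
    def total_dim(self) -> int:
        return sum(self.block_size(g) for g in self.groups)

    def with_groups(self, groups: Sequence[str]) -> "FeatureConfig":
        return replace(self, groups=tuple(groups))


@dataclass(frozen=True)
class FeatureVector:
    """Per-pair feature blocks plus the config they were computed under."""

    blocks: dict[str, np.ndarray]
    config: FeatureConfig

    def __post_init__(self) -> None:
        for g in self.config.groups:
            got = self.blocks[g].shape
            want = (self.config.block_size(g),)
            if got != want:
                raise ValueError(f"block {g!r} has shape {got}, expected {want}")

    def concat(self) -> np.ndarray:
        return np.concatenate([self.blocks[g] for g in self.config.groups])

    def __len__(self) -> int:
        return self.config.total_dim


def assemble_features(
    pair: CandidatePair,
    chain: EmbeddingChain,
    config: FeatureConfig = FeatureConfig(),
    parser: ParserFn | None = None,
) -> FeatureVector:
    """Compute the enabled blocks for one candidate pair, in the fixed
    semantic | syntactic | distance | pos order."""
    if chain.dimension != config.dim:
        raise ValueError(
            f"chain dimension {chain.dimension} != config dim {config.dim}")
    sent = pair.sentence
    blocks: dict[str, np.ndarray] = {}
    for g in config.groups:
        if g == "semantic":
            blocks[g] = _pool(sent.content_lemmas, chain,
                              config.pooling, config.pad_max_len)
        elif g == "syntactic":
            blocks[g] = syntactic_vector(
                sent, chain, parser, config.pooling, config.pad_max_len,
                sdp_only=config.sdp_only,
                entity_spans=(pair.lnc.token_span, pair.prot.token_span))
        elif g == "distance":
            blocks[g] = distance_vector(pair, chain, config.context_k)
        elif g == "pos":
            blocks[g] = pos_vector(pair)
    return FeatureVector(blocks=blocks, config=config)


def featurize_pairs(
    pairs: Sequence[CandidatePair],
    chain: EmbeddingChain,
    config: FeatureConfig = FeatureConfig(),
    parser: ParserFn | None = None,
) -> dict[str, np.ndarray]:
    """Stack per-pair blocks into one (n, block_size) matrix per group."""
    mats = {g: np.zeros((len(pairs), config.block_size(g)))
            for g in config.groups}
    for i, pair in enumerate(pairs):
        fv = assemble_features(pair, chain, config, parser)
        for g in config.groups:
            mats[g][i] = fv.blocks[g]
    return mats
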