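import numpy as np
import pytest

from lpitext.features import EmbeddingChain, EmbeddingProvider
from lpitext.ner import LNCRNA, PROTEIN, EntityMention, Lexicon
from lpitext.preprocess import analyze_sentence


@pytest.fixture
def example_sentence():
    """The worked distance-vector sentence."""
    return analyze_sentence("Bc1 RNA binds to Eif4a1 with high affinity")


@pytest.fixture
def example_lexicon():
    lex = Lexicon()
    lex.add(LNCRNA, "Bc1")
    lex.add(LNCRNA, "BC1")  # dedups with Bc1 under normalization
    lex.add(LNCRNA, "H19")
    lex.add(LNCRNA, "MALAT1")
    lex.add(PROTEIN, "Pura")
    lex.add(PROTEIN, "Eif4a1")
    lex.add(PROTEIN, "Igf2")
    return lex


@pytest.fixture
def toy_chain(example_sentence):
    """Deterministic unit vectors covering the example sentence's words."""
    from lpitext.synth import make_toy_embedding
    vocab = sorted({t.lower() for t in example_sentence.raw_tokens}
                   | set(example_sentence.lemmas))
    return EmbeddingChain([make_toy_embedding(vocab, 16, seed=1)])


def make_pair(sentence, lnc_span, prot_span, lnc_name=None, prot_name=None):
    """Build a CandidatePair directly from token spans."""
    from lpitext.ner import CandidatePair

    def mention(etype, span, name):
        cs = sentence.offsets[span[0]][0]
        ce = sentence.offsets[span[1] - 1][1]
        surface = sentence.raw_text[cs:ce]
        return EntityMention(etype, surface, name or surface, tuple(span))

    return CandidatePair(
        sentence=sentence,
        lnc=mention(LNCRNA, lnc_span, lnc_name),
        prot=mention(PROTEIN, prot_span, prot_name),
    )


def random_tree(rng: np.random.Generator, n: int):
    """Uniformly random labeled rooted tree on n nodes."""
    from lpitext.features import DependencyTree

    parents = [-1] + [int(rng.integers(0, i)) for i in range(1, n)]
    perm = rng.permutation(n)
    relabeled = [0] * n
    for i, p in enumerate(parents):
        relabeled[perm[i]] = -1 if p == -1 else int(perm[p])
    return DependencyTree(tuple(f"t{i}" for i in range(n)), tuple(relabeled))
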