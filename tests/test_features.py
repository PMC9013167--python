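import numpy as np
import pytest

from conftest import make_pair, random_tree
from lpitext.features import (DependencyTree, EmbeddingChain,
                              EmbeddingProvider, EmbeddingTrainerConfig,
                              FeatureConfig, assemble_features, context_words,
                              cosine_distance, dfs_order, distance_vector,
                              parse_dependencies, pos_onehot, pos_vector,
                              read_word2vec_text, semantic_vector,
                              syntactic_vector, train_embeddings,
                              write_word2vec_text, POS_CATEGORIES,
                              PENN_TO_CATEGORY)
from lpitext.preprocess import analyze_sentence
from lpitext.synth import fixture_tree, make_toy_embedding


def _provider(name, dim, table):
    return EmbeddingProvider(name, dim, {w: np.asarray(v, float)
                                         for w, v in table.items()})


class TestEmbeddingChain:
    def test_fallback_priority(self):
        p1 = _provider("retrained", 2, {"bind": [1, 0]})
        p2 = _provider("general", 2, {"bind": [9, 9], "rna": [0, 1]})
        chain = EmbeddingChain([p1, p2])
        assert np.allclose(chain.embed("bind"), [1, 0])   # first wins
        assert np.allclose(chain.embed("rna"), [0, 1])    # falls through
        assert np.allclose(chain.embed("novelword"), [0, 0])  # zero for OOV

    def test_dimension_mismatch_is_hard_error(self):
        p1 = _provider("a", 2, {"x": [1, 0]})
        p2 = _provider("b", 3, {"y": [1, 0, 0]})
        with pytest.raises(ValueError, match="dimension"):
            EmbeddingChain([p1, p2])

    def test_later_provider_never_changes_covered_words(self):
        p1 = make_toy_embedding(["alpha", "beta"], 8, seed=0)
        chain1 = EmbeddingChain([p1])
        p2 = make_toy_embedding(["alpha", "beta", "gamma"], 8, seed=5)
        chain2 = EmbeddingChain([p1, p2])
        for w in ("alpha", "beta"):
            assert np.array_equal(chain1.embed(w), chain2.embed(w))


class TestTrainEmbeddings:
    CORPUS = [f"gene{i} binds protein{i % 3} in cells" for i in range(40)]

    def test_dimension_passthrough_and_coverage(self):
        cfg = EmbeddingTrainerConfig(dim=16, epochs=1, seed=0)
        prov = train_embeddings(self.CORPUS, cfg)
        assert prov.dimension == 16
        assert "binds" in prov and "gene3" in prov
        assert prov.get("binds").shape == (16,)

    def test_seeded_determinism(self):
        cfg = EmbeddingTrainerConfig(dim=8, epochs=2, seed=3)
        a = train_embeddings(self.CORPUS, cfg)
        b = train_embeddings(self.CORPUS, cfg)
        assert sorted(a.vectors) == sorted(b.vectors)
        for w in a.vectors:
            assert np.array_equal(a.vectors[w], b.vectors[w])

    def test_corpus_smaller_than_window_is_error(self):
        with pytest.raises(ValueError, match="window"):
            train_embeddings(["tiny one"], EmbeddingTrainerConfig(window=5))


class TestSemanticVector:
    def test_mean_of_fixture_vectors(self):
        u, v = np.array([2.0, 0.0]), np.array([0.0, 4.0])
        chain = EmbeddingChain([_provider("f", 2, {"bc1": u, "bind": v})])
        s = analyze_sentence("BC1 binds")
        assert np.allclose(semantic_vector(s, chain), (u + v) / 2)

    def test_all_oov_gives_zero_vector(self):
        chain = EmbeddingChain([_provider("f", 4, {})])
        s = analyze_sentence("BC1 binds Pura")
        assert np.array_equal(semantic_vector(s, chain), np.zeros(4))

    def test_single_known_token_is_its_vector(self):
        v = np.array([1.0, 2.0, 3.0])
        chain = EmbeddingChain([_provider("f", 3, {"bc1": v})])
        s = analyze_sentence("The BC1 of")  # only BC1 is content
        assert np.allclose(semantic_vector(s, chain), v)


class TestDependencyParsing:
    def test_toy_parser_deterministic_and_valid(self, example_sentence):
        t1 = parse_dependencies(example_sentence)
        t2 = parse_dependencies(example_sentence)
        assert t1 == t2
        assert len(t1.tokens) == len(example_sentence.raw_tokens)
        assert t1.parents.count(-1) == 1

    def test_single_token_tree(self):
        s = analyze_sentence("MALAT1")
        t = parse_dependencies(s)
        assert t.tokens == ("MALAT1",) and t.parents == (-1,)

    def test_failing_parser_degrades_to_linear_order(self, example_sentence):
        def broken(tokens, tags):
            raise RuntimeError("parser crashed")

        t = parse_dependencies(example_sentence, broken)
        assert dfs_order(t) == list(example_sentence.raw_tokens)

    def test_tree_invariants_enforced(self):
        with pytest.raises(ValueError):
            DependencyTree(("a", "b"), (-1, -1))   # two roots
        with pytest.raises(ValueError):
            DependencyTree(("a", "b"), (1, 0))     # cycle, no root


class TestDfsOrder:
    def test_worked_example_traversal(self):
        assert " ".join(dfs_order(fixture_tree("bc1_pura"))) == \
            "associates RNA Bc1 Pura with"

    def test_single_node(self):
        assert dfs_order(fixture_tree("single")) == ["X"]

    def test_chain(self):
        assert dfs_order(fixture_tree("chain3")) == ["a", "b", "c"]

    def test_all_three_node_shapes_by_enumeration(self):
        """Brute force: every labeled rooted tree on 3 nodes yields a
        permutation starting at the root."""
        import itertools
        tokens = ("a", "b", "c")
        n_trees = 0
        for parents in itertools.product((-1, 0, 1, 2), repeat=3):
            try:
                tree = DependencyTree(tokens, parents)
            except ValueError:
                continue
            n_trees += 1
            order = dfs_order(tree)
            assert sorted(order) == sorted(tokens)
            assert order[0] == tokens[tree.root]
        assert n_trees == 9  # 3 roots x 3 shapes over the remaining pair

    def test_permutation_property_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            tree = random_tree(rng, int(rng.integers(1, 15)))
            assert sorted(dfs_order(tree)) == sorted(tree.tokens)


class TestSyntacticVector:
    def test_mean_pooling_equals_linear_order_mean(self, example_sentence,
                                                   toy_chain):
        """Full-tree DFS is a permutation, so mean pooling coincides with
        pooling the tokens in sentence order."""
        v = syntactic_vector(example_sentence, toy_chain)
        linear = np.mean([toy_chain.embed(t.lower())
                          for t in example_sentence.raw_tokens], axis=0)
        assert np.allclose(v, linear)

    def test_pad_concat_pooling_is_order_sensitive(self, toy_chain):
        s = analyze_sentence("Pura binds Bc1")
        v = syntactic_vector(s, toy_chain, pooling="pad_concat", max_len=4)
        assert v.shape == (16 * 4,)
        tree = parse_dependencies(s)
        seq = [w.lower() for w in dfs_order(tree)]
        assert np.allclose(v[:16], toy_chain.embed(seq[0]))

    def test_all_oov_sentence_gives_zero(self):
        chain = EmbeddingChain([_provider("f", 4, {})])
        s = analyze_sentence("BC1 binds Pura")
        assert np.array_equal(syntactic_vector(s, chain), np.zeros(4))


class TestContextWords:
    def test_worked_example_protein_contexts(self, example_sentence):
        pair = make_pair(example_sentence, (0, 1), (4, 5))
        left, right = context_words(example_sentence, pair.prot, k=3)
        assert left == ["RNA", "binds", "to"]
        assert right == ["with", "high", "affinity"]

    def test_sentence_initial_entity_has_no_left_context(self, example_sentence):
        pair = make_pair(example_sentence, (0, 1), (4, 5))
        left, right = context_words(example_sentence, pair.lnc, k=3)
        assert left == []
        assert right == ["RNA", "binds", "to"]

    def test_mention_spanning_whole_sentence(self):
        s = analyze_sentence("MALAT1")
        pair_mention = make_pair(analyze_sentence("MALAT1 x"), (0, 1), (1, 2))
        left, right = context_words(s, pair_mention.lnc, k=3)
        assert (left, right) == ([], [])


class TestCosineDistance:
    @pytest.mark.parametrize("u,v,expected", [
        ([1, 2], [1, 2], 0.0),
        ([1, 0], [0, 1], 1.0),
        ([1, 0], [1, 1], 1 - 1 / np.sqrt(2)),
        ([1, 0], [-1, 0], 2.0),
    ])
    def test_values(self, u, v, expected):
        assert cosine_distance(np.array(u, float), np.array(v, float)) == \
            pytest.approx(expected, abs=1e-12)

    def test_zero_vector_sentinel(self):
        assert cosine_distance(np.zeros(3), np.array([1.0, 0, 0])) == 0.0

    def test_symmetry_scale_invariance_and_range(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            u, v = rng.standard_normal(6), rng.standard_normal(6)
            d = cosine_distance(u, v)
            assert 0.0 <= d <= 2.0
            assert d == pytest.approx(cosine_distance(v, u), abs=1e-12)
            alpha = float(rng.uniform(0.1, 10))
            assert d == pytest.approx(cosine_distance(alpha * u, v), abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cosine_distance(np.zeros(2), np.zeros(3))


class TestDistanceVector:
    def test_worked_example_slot_structure(self, example_sentence, toy_chain):
        pair = make_pair(example_sentence, (0, 1), (4, 5))
        dv = distance_vector(pair, toy_chain)
        assert dv.shape == (12,)
        assert np.array_equal(dv[:3], np.zeros(3))  # Bc1 has no left words
        assert np.all(dv[3:6] != 0)                 # Bc1 right: RNA binds to
        assert np.count_nonzero(dv[6:]) == 6        # Eif4a1: all six words

    def test_two_token_orthogonal_layout(self):
        chain = EmbeddingChain([_provider("f", 2, {"x": [1, 0], "y": [0, 1]})])
        s = analyze_sentence("X Y")
        pair = make_pair(s, (0, 1), (1, 2))
        dv = distance_vector(pair, chain)
        expected = np.zeros(12)
        expected[3] = 1.0   # lnc right context: Y, orthogonal
        expected[6] = 1.0   # prot left context: X, orthogonal
        assert np.allclose(dv, expected)


class TestPosVectors:
    def test_nn_encodes_to_second_basis_vector(self):
        assert pos_onehot("NN").tolist() == [0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0]

    def test_every_category_is_a_distinct_basis_vector(self):
        covered = set()
        for tag, idx in PENN_TO_CATEGORY.items():
            vec = pos_onehot(tag)
            assert vec.sum() == 1 and vec[idx] == 1
            covered.add(idx)
        assert covered == set(range(len(POS_CATEGORIES)))

    def test_unmapped_tag_encodes_to_zeros(self):
        assert pos_onehot("FW").sum() == 0

    def test_pair_vector_concatenates_head_tags(self, example_sentence):
        pair = make_pair(example_sentence, (0, 1), (4, 5))
        pv = pos_vector(pair)
        assert pv.shape == (22,)
        assert pv.sum() <= 2
        # both entity heads tag as proper nouns
        assert pv[0] == 1 and pv[11] == 1


class TestAssembly:
    @pytest.mark.parametrize("groups,length", [
        (("semantic",), 200),
        (("semantic", "syntactic"), 400),
        (("semantic", "syntactic", "distance", "pos"), 434),
    ])
    def test_block_lengths_at_reference_dimension(self, groups, length):
        chain = EmbeddingChain([_provider("empty", 200, {})])
        s = analyze_sentence("BC1 binds Pura")
        pair = make_pair(s, (0, 1), (2, 3))
        cfg = FeatureConfig(groups=groups, dim=200)
        fv = assemble_features(pair, chain, cfg)
        assert fv.concat().shape == (length,)
        assert cfg.total_dim == length

    def test_bit_identical_determinism(self, example_sentence, toy_chain):
        pair = make_pair(example_sentence, (0, 1), (4, 5))
        cfg = FeatureConfig(dim=16)
        a = assemble_features(pair, toy_chain, cfg).concat()
        b = assemble_features(pair, toy_chain, cfg).concat()
        assert a.tobytes() == b.tobytes()

    def test_chain_config_dimension_mismatch(self, example_sentence, toy_chain):
        pair = make_pair(example_sentence, (0, 1), (4, 5))
        with pytest.raises(ValueError, match="dimension"):
            assemble_features(pair, toy_chain, FeatureConfig(dim=200))


def test_word2vec_text_roundtrip(tmp_path):
    prov = make_toy_embedding(["alpha", "beta", "gamma"], 8, seed=2)
    path = tmp_path / "emb.txt"
    write_word2vec_text(prov, str(path))
    back = read_word2vec_text(str(path))
    assert back.dimension == 8 and sorted(back.vectors) == sorted(prov.vectors)
    for w in prov.vectors:
        assert np.array_equal(back.vectors[w], prov.vectors[w])
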