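"""Sequence generation, Levenshtein, k-NN weighting, trees, kernel, ensemble."""

import itertools
import random
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clintemprel.annotation_layer import TreeNode, parse_penn_tree
from clintemprel.semrel_ensemble import (
    MED_REL_TYPES,
    EnsembleConfig,
    ProbabilityVector,
    SemRelEnsemble,
    SemRelInstance,
    downsample_no_relation,
    evaluate_semrel,
    extract_flat_features,
    extract_simple_expansion_tree,
    generate_sequence,
    knn_probability_vector,
    levenshtein,
    render_sequence,
    tree_kernel,
    tree_to_tuple,
)
from clintemprel.synthetic_fixtures import SEMREL_MIX, generate_corpus

from conftest import random_tree


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

TABLE5_EXPECTED = {
    1: "RB VB, test_e1_ RB VBD RB IN problem_e2_",
    2: "ADVP VP ADVP PP",
    3: "postop, test_e1_ only improve slightly in problem_e2_",
    4: "test_e1_ problem_e2_",
    5: "test_e1_—nsubj → prep ← pobj—problem_e2_",
}


@pytest.fixture(scope="module")
def table5():
    corpus = generate_corpus(2, 1, {"table5": 1.0}, sentences_per_doc=1)
    doc, ann = next(iter(corpus.docs.values()))
    inst = corpus.semrel_instances[0]
    return inst, doc, ann


class TestSequenceGeneration:
    @pytest.mark.parametrize("method", [1, 2, 3, 4, 5])
    def test_reference_sentence_reproduces_printed_sequence(self, table5, method):
        inst, doc, ann = table5
        assert render_sequence(generate_sequence(method, inst, doc, ann)) == TABLE5_EXPECTED[method]

    def test_adjacent_entities_give_empty_chunk_sequence(self):
        corpus = generate_corpus(2, 5, {"series": 1.0}, sentences_per_doc=1)
        inst = corpus.semrel_instances[0]  # fever , leukocytosis: only a comma between
        doc, ann = corpus.docs[inst.doc_id]
        assert generate_sequence(2, inst, doc, ann) == []

    def test_invalid_method_rejected(self, table5):
        inst, doc, ann = table5
        with pytest.raises(ValueError):
            generate_sequence(6, inst, doc, ann)


# ---------------------------------------------------------------------------
# Levenshtein
# ---------------------------------------------------------------------------

def _lev_oracle(a, b, memo=None):
    """Exhaustive edit-script recursion, independent of the DP implementation."""
    memo = {} if memo is None else memo
    key = (a, b)
    if key not in memo:
        if not a:
            memo[key] = len(b)
        elif not b:
            memo[key] = len(a)
        else:
            memo[key] = min(
                _lev_oracle(a[1:], b, memo) + 1,
                _lev_oracle(a, b[1:], memo) + 1,
                _lev_oracle(a[1:], b[1:], memo) + (a[0] != b[0]),
            )
    return memo[key]


class TestLevenshtein:
    def test_identical_and_empty_cases(self):
        assert levenshtein(["a", "b"], ["a", "b"]) == 0
        assert levenshtein([], ["x", "y", "z"]) == 3
        assert levenshtein(["x"], []) == 1

    def test_matches_exhaustive_oracle_on_random_pairs(self):
        rng = random.Random(13)
        alphabet = ["a", "b", "c"]
        for _ in range(200):
            a = tuple(rng.choice(alphabet) for _ in range(rng.randint(0, 8)))
            b = tuple(rng.choice(alphabet) for _ in range(rng.randint(0, 8)))
            assert levenshtein(a, b) == _lev_oracle(a, b)

    @given(st.lists(st.sampled_from("abc"), max_size=6),
           st.lists(st.sampled_from("abc"), max_size=6),
           st.lists(st.sampled_from("abc"), max_size=6))
    @settings(derandomize=True, max_examples=100)
    def test_triangle_inequality(self, a, b, c):
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


# ---------------------------------------------------------------------------
# k-NN probability vectors
# ---------------------------------------------------------------------------

class TestKnnWeighting:
    def _bank(self, specs):
        """specs: list of (distance-proxy sequence, label)."""
        return [(seq, label) for seq, label in specs]

    def test_unanimous_bank(self):
        bank = [(("x",) * (i % 3 + 1), "TeRP") for i in range(200)]
        pv = knn_probability_vector(("x",), bank, k=200)
        assert pv["TeRP"] == pytest.approx(1.0)

    def test_nearest_gets_half_rest_split(self):
        bank = [(("q",), "TrIP")] + [(("q", "far", "far"), "TeRP")] * 199
        pv = knn_probability_vector(("q",), bank, k=200)
        assert pv["TrIP"] == pytest.approx(0.5)
        assert pv["TeRP"] == pytest.approx(199 * (0.5 / 199))

    def test_mixed_remainder_hand_arithmetic(self):
        bank = ([(("q",), "TrIP")] + [(("q", "x", "x"), "TeRP")] * 100
                + [(("q", "y", "y"), "PIP")] * 99)
        pv = knn_probability_vector(("q",), bank, k=200)
        assert pv["TrIP"] == pytest.approx(0.5)
        assert pv["TeRP"] == pytest.approx(100 * 0.5 / 199)
        assert pv["PIP"] == pytest.approx(99 * 0.5 / 199)

    def test_small_bank_degrades_with_rescaled_weights(self):
        bank = [(("q",), "TrIP"), (("q", "x"), "TeRP"), (("q", "y"), "TeRP")]
        with pytest.warns(UserWarning):
            pv = knn_probability_vector(("q",), bank, k=200)
        assert pv["TrIP"] == pytest.approx(0.5)
        assert pv["TeRP"] == pytest.approx(0.5)

    def test_probability_vector_validates_sum(self):
        with pytest.raises(ValueError):
            ProbabilityVector(tuple([0.5] + [0.0] * 10))
        ProbabilityVector(tuple([1.0] + [0.0] * 10))  # ok


# ---------------------------------------------------------------------------
# simple expansion trees
# ---------------------------------------------------------------------------

def _entity_over(tokens_text, lo, hi, etype="PROBLEM"):
    from clintemprel.corpus_io import EventAnnotation

    offs, pos = [], 0
    for w in tokens_text:
        offs.append((pos, pos + len(w)))
        pos += len(w) + 1
    return EventAnnotation(id=f"e{lo}", start=offs[lo][0], end=offs[hi][1],
                           text=" ".join(tokens_text[lo:hi + 1]), etype=etype)


def _ann_for_tree(tree):
    from clintemprel.annotation_layer import DocumentAnnotations, Token

    leaves = tree.leaves()
    words = [f"w{i}" for i in range(len(leaves))]
    offs, pos = [], 0
    for w in words:
        offs.append((pos, pos + len(w)))
        pos += len(w) + 1
    tokens = [Token(i, w, w, "NN", "O", offs[i][0], offs[i][1], 0) for i, w in enumerate(words)]
    return DocumentAnnotations(tokens=tokens, trees=[tree]), words


def _oracle_expansion_node_set(tree, n1, n2, relabel):
    """Brute-force definitional construction via graph shortest path:
    path nodes plus their immediate non-leaf children, with the entity
    covering nodes relabeled."""
    import networkx as nx

    g = nx.Graph()
    g.add_node(id(tree))
    for n in tree.descendants():
        for c in n.children:
            g.add_edge(id(n), id(c))
    by_id = {id(n): n for n in tree.descendants()}
    path = nx.shortest_path(g, id(n1), id(n2))
    keep = set(path)
    for nid in path:
        for c in by_id[nid].children:
            if not c.is_leaf:
                keep.add(id(c))
    return Counter(relabel.get(nid, by_id[nid].label) for nid in keep)


class TestSimpleExpansionTree:
    def test_random_trees_match_definitional_oracle(self):
        from clintemprel.annotation_layer import minimal_covering_node

        rng = random.Random(99)
        checked = 0
        while checked < 200:
            tree = random_tree(rng, 12)
            leaves = tree.leaves()
            if len(leaves) < 2:
                continue
            i, j = sorted(rng.sample(range(len(leaves)), 2))
            ann, words = _ann_for_tree(tree)
            e1 = _entity_over(words, i, i)
            e2 = _entity_over(words, j, j)
            ext = extract_simple_expansion_tree(e1, e2, ann)
            n1 = minimal_covering_node(e1, ann)
            n2 = minimal_covering_node(e2, ann)
            relabel = {id(n1): "PROBLEM", id(n2): "PROBLEM"}
            oracle = _oracle_expansion_node_set(tree, n1, n2, relabel)
            got = Counter(n.label for n in ext.descendants())
            assert got == +oracle
            checked += 1

    def test_sibling_entities_keep_parent_and_nonleaf_children(self):
        tree = parse_penn_tree("(S (NP (A x) (B y)) (VP (V z)))")
        ann, words = _ann_for_tree(tree)
        e1 = _entity_over(words, 0, 0)
        e2 = _entity_over(words, 1, 1)
        ext = extract_simple_expansion_tree(e1, e2, ann)
        # path A-NP-B plus NP's non-leaf children (A, B themselves); VP excluded
        assert Counter(n.label for n in ext.descendants()) == Counter(
            {"NP": 1, "PROBLEM": 2})

    def test_attribute_replacement_visible(self):
        tree = parse_penn_tree("(S (NP (N x)) (VP (V y)))")
        ann, words = _ann_for_tree(tree)
        e1 = _entity_over(words, 0, 0, etype="PROBLEM")
        e2 = _entity_over(words, 1, 1, etype="TREATMENT")
        ext = extract_simple_expansion_tree(e1, e2, ann)
        labels = {n.label for n in ext.descendants()}
        assert "PROBLEM" in labels and "TREATMENT" in labels


# ---------------------------------------------------------------------------
# convolution tree kernel
# ---------------------------------------------------------------------------

def _fragments(tree, lam):
    """Fragment enumeration oracle: weight lam per expanded node; single
    matching leaves weigh lam."""
    out = Counter()  # (repr) -> summed weight per occurrence handled separately
    weights = {}

    def rooted(n):
        """All fragments rooted at internal node n: (repr, n_expanded)."""
        options = []
        child_opts = []
        for c in n.children:
            if c.is_leaf:
                child_opts.append([((c.label,), 0)])
            else:
                opts = [((c.label,), 0)]  # frontier: label only
                opts.extend(rooted(c))
                child_opts.append(opts)
        for combo in itertools.product(*child_opts):
            rep = (n.label, tuple(r for r, _ in combo))
            n_exp = 1 + sum(k for _, k in combo)
            options.append((rep, n_exp))
        return options

    frs = Counter()
    for n in tree.descendants():
        if n.is_leaf:
            frs[("LEAF", n.label)] += 1
            weights[("LEAF", n.label)] = 1
        else:
            for rep, n_exp in rooted(n):
                frs[rep] += 1
                weights[rep] = n_exp
    return frs, weights


def _kernel_oracle(t1, t2, lam):
    f1, w1 = _fragments(t1, lam)
    f2, w2 = _fragments(t2, lam)
    total = 0.0
    for rep, c1 in f1.items():
        if rep in f2:
            total += c1 * f2[rep] * lam ** w1[rep]
    return total


class TestTreeKernel:
    def test_symmetry_and_self_positivity(self):
        rng = random.Random(7)
        for _ in range(30):
            t1, t2 = random_tree(rng, 8), random_tree(rng, 8)
            assert tree_kernel(t1, t2) == pytest.approx(tree_kernel(t2, t1))
            assert tree_kernel(t1, t1) > 0

    def test_disjoint_label_alphabets_give_zero(self):
        t1 = parse_penn_tree("(A (B x) (C y))")
        t2 = parse_penn_tree("(D (E p) (F q))")
        assert tree_kernel(t1, t2) == 0.0

    def test_matches_fragment_enumeration_oracle(self):
        rng = random.Random(23)
        for _ in range(60):
            t1, t2 = random_tree(rng, 8), random_tree(rng, 8)
            lam = rng.choice([0.2, 0.4, 1.0])
            assert tree_kernel(t1, t2, lam) == pytest.approx(_kernel_oracle(t1, t2, lam))


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

class TestEnsemble:
    def test_identical_vectors_combine_to_themselves(self):
        p = ProbabilityVector.delta("TrAP")
        combined = ProbabilityVector.combine([(0.4, p), (0.5, p), (0.1, p)])
        assert combined.values == pytest.approx(p.values)

    def test_disagreeing_deltas_argmax_follows_flat_weight(self):
        ptree = ProbabilityVector.delta("TrIP")
        pflat = ProbabilityVector.delta("TeRP")
        pknn = ProbabilityVector.delta("PIP")
        combined = ProbabilityVector.combine([(0.4, ptree), (0.5, pflat), (0.1, pknn)])
        assert combined.argmax() == "TeRP"
        assert combined["TeRP"] == pytest.approx(0.5)
        assert combined["TrIP"] == pytest.approx(0.4)

    def test_default_weights_from_config(self):
        assert EnsembleConfig().weights == (0.4, 0.5, 0.1)

    def test_every_vector_sums_to_one(self, fitted_ensemble):
        ens, corpus = fitted_ensemble
        insts = [i for i in _some_instances(corpus)][:12]
        for inst in insts:
            doc, ann = corpus[inst.doc_id]
            for pv in (ens.flat_vector(inst, doc, ann), ens.tree_vector(inst, doc, ann),
                       ens.knn_vector(inst, doc, ann), ens.combined_vector(inst, doc, ann)):
                assert abs(sum(pv.values) - 1.0) <= 1e-9

    @pytest.mark.parametrize("weights, which", [
        ((1.0, 0.0, 0.0), "tree"), ((0.0, 1.0, 0.0), "flat"), ((0.0, 0.0, 1.0), "knn"),
    ])
    def test_degenerate_weights_reproduce_single_classifier(self, fitted_ensemble, weights, which):
        ens, corpus = fitted_ensemble
        old = ens.config.weights
        try:
            ens.config.weights = weights
            for inst in _some_instances(corpus)[:10]:
                doc, ann = corpus[inst.doc_id]
                label, _ = ens.predict(inst, doc, ann)
                single = getattr(ens, f"{which}_vector")(inst, doc, ann).argmax()
                assert label == single
        finally:
            ens.config.weights = old

    def test_training_set_recovery_beats_each_single_classifier(self, fitted_ensemble,
                                                                semrel_corpora):
        ens, corpus = fitted_ensemble
        train, _ = semrel_corpora
        gold, comb, tree, flat, knn = [], [], [], [], []
        for inst in train.semrel_instances:
            doc, ann = corpus[inst.doc_id]
            gold.append(inst.label)
            comb.append(ens.combined_vector(inst, doc, ann).argmax())
            tree.append(ens.tree_vector(inst, doc, ann).argmax())
            flat.append(ens.flat_vector(inst, doc, ann).argmax())
            knn.append(ens.knn_vector(inst, doc, ann).argmax())

        def acc(pred):
            return np.mean([p == g for p, g in zip(pred, gold)])

        for single in (tree, flat, knn):
            assert acc(comb) >= acc(single)

    def test_downsampling_caps_no_relation_classes(self):
        insts = ([SemRelInstance("d", f"a{i}", f"b{i}", 0, "TrIP") for i in range(10)]
                 + [SemRelInstance("d", f"c{i}", f"d{i}", 0, "NPP") for i in range(100)])
        out = downsample_no_relation(insts, factor=2.0, seed=3)
        labels = Counter(i.label for i in out)
        assert labels["TrIP"] == 10
        assert labels["NPP"] == 20
        # seeded: deterministic
        again = downsample_no_relation(insts, factor=2.0, seed=3)
        assert out == again


def _some_instances(corpus):
    out = []
    for doc_id, (doc, ann) in corpus.items():
        events = sorted(doc.events, key=lambda e: e.start)
        from clintemprel.annotation_layer import head_token
        from clintemprel.feature_extraction import medsem_applicable

        for a, b in zip(events, events[1:]):
            if medsem_applicable(a, b, ann):
                out.append(SemRelInstance(doc_id, a.id, b.id, head_token(a, ann).sent))
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

class TestEvaluateSemrel:
    def test_perfect_predictions(self):
        gold = ["TrIP", "TeRP", "NPP", "PIP"]
        assert evaluate_semrel(gold, gold)["f1"] == 1.0

    def test_all_no_relation_reports_zero_with_warning(self):
        with pytest.warns(UserWarning):
            scores = evaluate_semrel(["NPP", "NPP"], ["NPP", "NPP"])
        assert scores == {"precision": 0.0, "recall": 0.0, "f1": 0.0}

    def test_hand_built_confusion(self):
        gold = ["TrIP", "TrIP", "TeRP", "TeRP", "PIP", "NPP", "NPP", "NTeP", "TrAP", "TrAP"]
        pred = ["TrIP", "TeRP", "TeRP", "NPP", "PIP", "NPP", "TrAP", "NTeP", "TrAP", "TrAP"]
        # positives in gold: 7; predicted positive: 7; correct positive: 5
        scores = evaluate_semrel(pred, gold)
        assert scores["precision"] == pytest.approx(5 / 7)
        assert scores["recall"] == pytest.approx(5 / 7)
        assert scores["f1"] == pytest.approx(5 / 7)
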