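"""Feature families: content checks against independent oracles on fixtures."""

import pytest

from clintemprel.feature_extraction import (
    NULL,
    InstancePair,
    LexicalRelationLexicon,
    between_tokens,
    extract_all,
    extract_baseline,
    extract_discourse,
    extract_lexical_relations,
    extract_medsem,
    extract_pairwise,
    extract_predarg,
    token_distance,
)
from clintemprel.synthetic_fixtures import generate_corpus


def _single_template_instance(template, seed=9, n=20):
    """A corpus of one template; returns (pair, doc, ann, corpus)."""
    corpus = generate_corpus(seed, n, {template: 1.0}, sentences_per_doc=1)
    doc, ann = next(iter(corpus.docs.values()))
    link = doc.tlinks[0]
    pair = InstancePair(doc.id, link.source, link.target, "EE_INTRA", None)
    return pair, doc, ann, corpus


class TestBaseline:
    def test_same_string_flag(self):
        pair, doc, ann, _ = _single_template_instance("series")
        fv = extract_baseline(pair, doc, ann)
        assert fv.features["lex.same_string"] == 0
        # identical strings -> 1
        e = doc.events[0]
        same = InstancePair(doc.id, e.id, e.id, "EE_INTRA", None)
        assert extract_baseline(same, doc, ann).features["lex.same_string"] == 1

    def test_cross_sentence_pair_gets_null_tree_path(self):
        pair, doc, ann, _ = _single_template_instance("restatement")
        fv = extract_baseline(pair, doc, ann)
        assert fv.features["dist.same_sentence"] == 0
        assert fv.features["gram.tree_path"] == NULL

    def test_intra_pair_has_tree_path_and_sentence_flag(self):
        pair, doc, ann, _ = _single_template_instance("pip")
        fv = extract_baseline(pair, doc, ann)
        assert fv.features["dist.same_sentence"] == 1
        assert fv.features["gram.tree_path"] != NULL

    def test_token_distance_matches_offset_walk_oracle(self):
        for template in ("pip", "tecp", "series", "antonym"):
            pair, doc, ann, _ = _single_template_instance(template)
            e1, e2 = doc.entity(pair.e1), doc.entity(pair.e2)
            # oracle: walk tokens and count the ones strictly between the spans
            count = sum(1 for t in ann.tokens if t.start >= e1.end and t.end <= e2.start)
            assert token_distance(e1, e2, ann) == count
            fv = extract_baseline(pair, doc, ann)
            assert fv.features["dist.tokens"] == count

    def test_purity_identical_inputs_identical_vectors(self):
        pair, doc, ann, corpus = _single_template_instance("tecp")
        a = extract_all(pair, doc, ann, thesaurus=corpus.thesaurus, wordnet=corpus.wordnet)
        b = extract_all(pair, doc, ann, thesaurus=corpus.thesaurus, wordnet=corpus.wordnet)
        assert a.features == b.features and a.families == b.families


class TestPairwise:
    def test_quadruple_is_order_sensitive(self):
        pair, doc, ann, _ = _single_template_instance("resolved")
        fv = extract_pairwise(pair, doc, ann)
        quad = fv.features["pw.type_modality_quad"]
        swapped = InstancePair(doc.id, pair.e2, pair.e1, pair.scheme, None)
        quad_swapped = extract_pairwise(swapped, doc, ann).features["pw.type_modality_quad"]
        assert quad != quad_swapped

    def test_preposition_trace_matches_root_walk_oracle(self):
        pair, doc, ann, _ = _single_template_instance("tecp")
        fv = extract_pairwise(pair, doc, ann)

        def walk(entity):
            from clintemprel.annotation_layer import minimal_covering_node

            node, out = minimal_covering_node(entity, ann), []
            while node is not None:
                if node.label == "PP":
                    out.append(ann.tokens[node.leaves()[0].token_index].text.lower())
                node = node.parent
            return out

        e1, e2 = doc.entity(pair.e1), doc.entity(pair.e2)
        expected = "_".join(walk(e1) + walk(e2)) or NULL
        assert fv.features["pw.prep_trace"] == expected
        # the PROBLEM sits inside "for ..." -> its trace contains the preposition
        assert "for" in str(fv.features["pw.prep_trace"])

    def test_entity_at_root_without_pp_gives_empty_trace(self):
        pair, doc, ann, _ = _single_template_instance("trcp")
        fv = extract_pairwise(pair, doc, ann)
        assert fv.features["pw.prep_trace"] == NULL


class TestLexicalRelations:
    def test_antonym_pair_sets_flag(self):
        pair, doc, ann, corpus = _single_template_instance("antonym")
        fv = extract_lexical_relations(pair, doc, ann, corpus.thesaurus, "thes")
        assert fv.features["thes.e1_in_e2_antonyms"] == 1
        assert fv.features["thes.e2_in_e1_antonyms"] == 1

    def test_absent_headword_gives_all_zero(self):
        pair, doc, ann, _ = _single_template_instance("tecp")
        lex = LexicalRelationLexicon.thesaurus()
        fv = extract_lexical_relations(pair, doc, ann, lex, "thes")
        assert all(v == 0 for v in fv.features.values())
        assert len(fv.features) == 8

    def test_flags_match_membership_oracle_on_random_lexicon(self):
        import random

        rng = random.Random(5)
        pair, doc, ann, _ = _single_template_instance("pip")
        from clintemprel.annotation_layer import head_token

        h1 = head_token(doc.entity(pair.e1), ann).text.lower()
        h2 = head_token(doc.entity(pair.e2), ann).text.lower()
        for _ in range(20):
            lex = LexicalRelationLexicon.thesaurus()
            lists2 = [[h1] if rng.random() < 0.5 else [] for _ in range(4)]
            lists1 = [[h2] if rng.random() < 0.5 else [] for _ in range(4)]
            lex.add(h2, *lists2)
            lex.add(h1, *lists1)
            fv = extract_lexical_relations(pair, doc, ann, lex, "thes")
            for k, rel in enumerate(lex.relations):
                assert fv.features[f"thes.e1_in_e2_{rel}"] == int(h1 in lists2[k])
                assert fv.features[f"thes.e2_in_e1_{rel}"] == int(h2 in lists1[k])


class TestPredArg:
    def test_destination_argument_flag(self):
        # "discharged to rehab": the department is the predicate's A4 argument
        pair, doc, ann, _ = _single_template_instance("rehab")
        fv = extract_predarg(pair, doc, ann)
        assert fv.features["srl.pred_e1_arg_A4"] == 1
        assert fv.features["srl.pred_e2_arg_A4"] == 0

    def test_empty_srl_layer_all_zero(self):
        pair, doc, ann, _ = _single_template_instance("series")
        fv = extract_predarg(pair, doc, ann)
        assert set(fv.features.values()) == {0}

    def test_flags_match_frame_scan_oracle(self):
        from clintemprel.annotation_layer import head_token

        for template in ("rehab", "resolved"):
            pair, doc, ann, _ = _single_template_instance(template)
            fv = extract_predarg(pair, doc, ann)
            h1 = head_token(doc.entity(pair.e1), ann)
            h2 = head_token(doc.entity(pair.e2), ann)
            for name, value in fv.features.items():
                _, direction, _, label = name.split("_", 3)
                pred, arg = (h1, h2) if direction == "e1" else (h2, h1)
                expected = any(
                    fr.predicate == pred.index and any(
                        lbl == label and a <= arg.index <= b for lbl, a, b in fr.arguments)
                    for fr in ann.srl)
                assert value == int(expected), name


class TestDiscourse:
    def test_explicit_asynchronous_example(self):
        pair, doc, ann, _ = _single_template_instance("thereafter")
        fv = extract_discourse(pair, doc, ann)
        assert fv.features["disc.explicit_e1_arg1"] == "ASYNCHRONOUS"
        assert fv.features["disc.explicit_e2_arg1"] == NULL

    def test_implicit_restatement_example(self):
        pair, doc, ann, _ = _single_template_instance("restatement")
        fv = extract_discourse(pair, doc, ann)
        assert fv.features["disc.implicit_e1_arg1"] == "RESTATEMENT"
        assert fv.features["disc.explicit_e1_arg1"] == NULL

    def test_both_entities_in_arg1_only_gives_all_null(self):
        # an intra-sentence pair never spans the two argument intervals
        pair, doc, ann, _ = _single_template_instance("pip")
        fv = extract_discourse(pair, doc, ann)
        assert set(fv.features.values()) == {NULL}


class TestMedsem:
    def test_predicted_label_present_for_applicable_pair(self):
        pair, doc, ann, corpus = _single_template_instance("resolved")
        model = corpus.gold_semrel_model()
        fv = extract_medsem(pair, doc, ann, model)
        assert fv.features["medsem.label"] == "TrIP"

    def test_occurrence_pair_gated_to_null(self):
        pair, doc, ann, corpus = _single_template_instance("discharge")
        model = corpus.gold_semrel_model()
        fv = extract_medsem(pair, doc, ann, model)
        assert fv.features == {"medsem.label": NULL}

    def test_feature_agrees_with_direct_model_call(self, fitted_ensemble):
        ens, corpus = fitted_ensemble
        for doc_id, (doc, ann) in list(corpus.items())[:3]:
            events = sorted(doc.events, key=lambda e: e.start)
            for a, b in zip(events, events[1:]):
                pair = InstancePair(doc.id, a.id, b.id, "EE_INTRA", None)
                fv = extract_medsem(pair, doc, ann, ens)
                if fv.features["medsem.label"] != NULL:
                    direct, _ = ens.predict_for_pair(a, b, doc, ann)
                    assert fv.features["medsem.label"] == direct


class TestFamilyInventory:
    def test_each_feature_has_exactly_one_family(self):
        pair, doc, ann, corpus = _single_template_instance("resolved")
        fv = extract_all(pair, doc, ann, thesaurus=corpus.thesaurus, wordnet=corpus.wordnet,
                         medsem_model=corpus.gold_semrel_model())
        assert set(fv.features) == set(fv.families)
        fams = set(fv.families.values())
        assert {"lexical", "grammatical", "entity", "distance", "semantic", "sct",
                "pairwise", "wn", "thes", "predarg", "discourse", "medsem"} <= fams
        # the lexical-relation families carry exactly 8 binary flags each
        assert len(fv.by_family("thes")) == 8
        assert len(fv.by_family("wn")) == 8
        # four discourse features, 20 SRL flags (6 numbered + 4 modifier args, both directions)
        assert len(fv.by_family("discourse")) == 4
        assert len(fv.by_family("predarg")) == 20
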