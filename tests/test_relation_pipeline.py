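"""Instance generation schemes, specialized classifiers, architectures,
identification and threshold tuning."""

import warnings

import numpy as np
import pytest

from clintemprel.annotation_layer import fallback_annotate
from clintemprel.corpus_io import (
    ClinicalDocument,
    EventAnnotation,
    FineRelation,
    NO_RELATION,
    TemporalLink,
    TimeAnnotation,
)
from clintemprel.relation_pipeline import (
    Featurizer,
    PipelineConfig,
    TemporalPipeline,
    build_classification_instances,
    build_identification_instances,
    gold_label_map,
    train_identifier,
    train_specialized,
)
from clintemprel.rule_engine import HAS_RELATION, apply_first
from clintemprel.synthetic_fixtures import generate_corpus


def _toy_doc(sentences, links=()):
    """sentences: list of lists of (word, kind) where kind in {'E','T',None};
    every E/T word becomes a single-token entity."""
    text_parts, events, times = [], [], []
    pos = 0
    n = 0
    for words in sentences:
        for word, kind in words:
            start, end = pos, pos + len(word)
            if kind == "E":
                events.append(EventAnnotation(id=f"E{n}", start=start, end=end, text=word,
                                              etype="OCCURRENCE"))
                n += 1
            elif kind == "T":
                times.append(TimeAnnotation(id=f"T{n}", start=start, end=end, text=word,
                                            ttype="DATE"))
                n += 1
            text_parts.append(word)
            pos = end + 1
        text_parts[-1] += " ."
        pos += 2
    text = " ".join(w for w in " ".join(text_parts).split(" "))
    doc = ClinicalDocument(id="toy", text=text, events=events, times=times,
                           tlinks=[TemporalLink(id=f"L{i}", source=s, target=t,
                                                relation=FineRelation(r))
                                   for i, (s, t, r) in enumerate(links)])
    doc.validate()
    return doc, fallback_annotate(doc)


class TestClassificationInstances:
    def test_intra_adjacency_negatives(self):
        # events A, B, C in one sentence with a gold link only between A and C:
        # positives {(A,C)}, negatives = adjacent unrelated {(A,B), (B,C)}
        doc, ann = _toy_doc([[("alpha", "E"), ("beta", "E"), ("gamma", "E")]],
                            links=[("E0", "E2", "BEFORE")])
        out = build_classification_instances(doc, ann, for_training=True)
        got = {(p.e1, p.e2): p.label for p in out["EE_INTRA"]}
        assert got == {("E0", "E2"): "BEFORE", ("E0", "E1"): NO_RELATION,
                       ("E1", "E2"): NO_RELATION}

    def test_adjacent_sentence_event_time_pairs_excluded(self):
        doc, ann = _toy_doc([[("alpha", "E")], [("yesterday", "T")]],
                            links=[("E0", "T1", "BEFORE")])
        out = build_classification_instances(doc, ann, for_training=True)
        assert out["EE_ADJACENT"] == []
        assert all(p.scheme != "EE_ADJACENT" for plist in out.values() for p in plist)

    def test_coreferent_pair_without_distance_restriction(self):
        sentences = [[("pain", "E")], [("filler", None)], [("filler2", None)],
                     [("filler3", None)], [("filler4", None)], [("pain", "E")]]
        doc, ann = _toy_doc(sentences, links=[("E0", "E1", "OVERLAP")])
        out = build_classification_instances(doc, ann, for_training=True)
        assert {(p.e1, p.e2) for p in out["EE_COREF"]} == {("E0", "E1")}

    def test_test_candidates_mirror_negative_recipe(self):
        doc, ann = _toy_doc([[("alpha", "E"), ("beta", "E"), ("gamma", "E")]],
                            links=[("E0", "E2", "BEFORE")])
        out = build_classification_instances(doc, ann, for_training=False)
        # test candidates: adjacent pairs only, unlabeled
        assert {(p.e1, p.e2) for p in out["EE_INTRA"]} == {("E0", "E1"), ("E1", "E2")}
        assert all(p.label is None for p in out["EE_INTRA"])


class TestIdentificationInstances:
    def test_gold_pair_positive_and_pruning_off_enumerates_all(self):
        doc, ann = _toy_doc([[("alpha", "E"), ("beta", "E"), ("gamma", "E")]],
                            links=[("E0", "E2", "BEFORE")])
        out = build_identification_instances(doc, ann, prune=False)
        labels = {(p.e1, p.e2): p.label for p in out["EE_INTRA"]}
        assert labels[("E0", "E2")] == HAS_RELATION
        assert labels[("E0", "E1")] == NO_RELATION
        assert len(labels) == 3  # all unordered intra pairs

    def test_distant_intra_negative_pruned(self):
        words = [("alpha", "E")] + [(f"w{i}", None) for i in range(40)] + [("omega", "E")]
        doc, ann = _toy_doc([words])
        cfg = PipelineConfig(intra_prune_tokens=30)
        out = build_identification_instances(doc, ann, cfg, prune=True)
        assert out["EE_INTRA"] == []
        out_all = build_identification_instances(doc, ann, cfg, prune=False)
        assert len(out_all["EE_INTRA"]) == 1

    def test_cross_section_pair_beyond_distance_excluded_unless_coreferent(self):
        doc, ann = _toy_doc([[("pain", "E")], [("a", None)], [("b", None)], [("pain", "E")]])
        out = build_identification_instances(doc, ann, prune=True)
        # 3 sentences apart: only the coreferent route keeps the pair
        assert {(p.e1, p.e2) for p in out["EE_COREF"]} == {("E0", "E1")}
        assert out["EE_ADJACENT"] == []


class TestSpecializedTraining:
    def _featurize(self, featurizer):
        return lambda inst: dict(featurizer.features(inst).features)

    def test_single_class_predicts_that_class(self, train_corpus):
        doc_id, (doc, ann) = next(iter(train_corpus.docs.items()))
        feat = Featurizer({doc_id: (doc, ann)})
        pairs = build_classification_instances(doc, ann)["EE_INTRA"]
        one_class = [p for p in pairs if p.label not in (None, NO_RELATION)][:3]
        from dataclasses import replace

        one_class = [replace(p, label="OVERLAP") for p in one_class]
        model = train_specialized(one_class, self._featurize(feat), PipelineConfig(),
                                  "EE_INTRA")
        assert model.predict({"anything": 1}) == "OVERLAP"

    def test_no_positives_warns_and_predicts_no_relation(self):
        with pytest.warns(UserWarning):
            model = train_specialized([], lambda i: {}, PipelineConfig(), "EE_COREF")
        assert model.predict({}) == NO_RELATION

    def test_separable_fixtures_reach_training_accuracy_one(self, fitted_pipeline,
                                                            train_corpus):
        correct = total = 0
        for doc_id, (doc, ann) in train_corpus.docs.items():
            for scheme, pairs in build_classification_instances(doc, ann).items():
                model = fitted_pipeline.models[scheme]
                for p in pairs:
                    if p.label is None:
                        continue
                    feats = dict(fitted_pipeline.featurizer.features(p).features)
                    total += 1
                    correct += model.predict(feats) == p.label
        assert total > 0
        assert correct / total == pytest.approx(1.0)


class TestArchitectures:
    def _pairs(self, pipe, corpus, n=40):
        out = []
        for doc_id, (doc, ann) in corpus.docs.items():
            for scheme, plist in build_classification_instances(doc, ann).items():
                out.extend(p for p in plist if p.label not in (None, NO_RELATION))
        return out[:n]

    def test_all_rules_equals_apply_first_everywhere(self, fitted_pipeline, train_corpus):
        for p in self._pairs(fitted_pipeline, train_corpus):
            lookup = fitted_pipeline.featurizer.lookup(p)
            ruled = apply_first(fitted_pipeline.ruleset_all, lookup)
            got = fitted_pipeline.classify_pair(p, "ALL_RULES")
            if ruled == "NONE_APPLICABLE":
                assert got == fitted_pipeline.models[p.scheme].majority_label
            else:
                assert got == ruled

    def test_hybrid_rule_precedence_and_fallback(self, fitted_pipeline, train_corpus):
        for p in self._pairs(fitted_pipeline, train_corpus):
            lookup = fitted_pipeline.featurizer.lookup(p)
            ruled = apply_first(fitted_pipeline.ruleset_high, lookup)
            got = fitted_pipeline.classify_pair(p, "HYBRID")
            if ruled != "NONE_APPLICABLE":
                assert got == ruled
            else:
                assert got == fitted_pipeline.classify_pair(p, "FEATURES_PLUS_RULE_FEATURES")

    def test_unknown_architecture_rejected(self, fitted_pipeline, train_corpus):
        p = self._pairs(fitted_pipeline, train_corpus, 1)[0]
        with pytest.raises(ValueError):
            fitted_pipeline.classify_pair(p, "NOT_AN_ARCH")


@pytest.fixture(scope="module")
def id_setup(train_corpus):
    corpus = dict(list(train_corpus.docs.items())[:8])
    feat = Featurizer(corpus, thesaurus=train_corpus.thesaurus,
                      wordnet=train_corpus.wordnet,
                      medsem_model=train_corpus.gold_semrel_model())
    instances = []
    for doc_id, (doc, ann) in corpus.items():
        # intra-sentence instances only, so every one has a parse fragment
        built = build_identification_instances(doc, ann)
        instances.extend(built["EE_INTRA"])
    featurize = lambda i: dict(feat.features(i).features)
    return corpus, feat, instances, featurize


class TestIdentifierKernels:
    def _decisions(self, model, instances, featurize, corpus):
        out = []
        for p in instances:
            doc, ann = corpus[p.doc_id]
            out.append(model.decision(featurize(p), p, doc, ann))
        return np.array(out)

    def test_composite_alpha_one_equals_flat(self, id_setup):
        corpus, feat, instances, featurize = id_setup
        flat = train_identifier(instances, featurize, corpus,
                                PipelineConfig(identifier_mode="FLAT"), "EE_INTRA")
        comp = train_identifier(instances, featurize, corpus,
                                PipelineConfig(identifier_mode="COMPOSITE", composite_alpha=1.0),
                                "EE_INTRA")
        d1 = self._decisions(flat, instances, featurize, corpus)
        d2 = self._decisions(comp, instances, featurize, corpus)
        assert np.allclose(d1, d2, atol=1e-8)

    def test_composite_alpha_zero_equals_tree(self, id_setup):
        corpus, feat, instances, featurize = id_setup
        tree = train_identifier(instances, featurize, corpus,
                                PipelineConfig(identifier_mode="TREE"), "EE_INTRA")
        comp = train_identifier(instances, featurize, corpus,
                                PipelineConfig(identifier_mode="COMPOSITE", composite_alpha=0.0),
                                "EE_INTRA")
        d1 = self._decisions(tree, instances, featurize, corpus)
        d2 = self._decisions(comp, instances, featurize, corpus)
        assert np.allclose(d1, d2, atol=1e-8)

    def test_kernel_matrix_symmetric_psd(self, id_setup):
        corpus, feat, instances, featurize = id_setup
        from clintemprel.semrel_ensemble import _TreeKernelCache, extract_simple_expansion_tree

        cache = _TreeKernelCache(0.4)
        keys = []
        for p in instances[:20]:
            doc, ann = corpus[p.doc_id]
            e1, e2 = doc.entity(p.e1), doc.entity(p.e2)
            keys.append(cache.canonical(extract_simple_expansion_tree(e1, e2, ann,
                                                                      attribute_at="parent")))
        K = cache.gram(keys, keys)
        assert np.allclose(K, K.T)
        eig = np.linalg.eigvalsh(K)
        assert eig.min() >= -1e-8


class TestSettings:
    def test_setting1_with_rule_covered_corpus_recovers_gold(self, fitted_pipeline,
                                                             test_corpus):
        from clintemprel.evaluation import score_12class

        pred, gold = [], []
        for doc_id, (doc, ann) in test_corpus.docs.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pred.extend(fitted_pipeline.predict_document(doc, ann, setting=1, arch="HYBRID"))
            gold.extend(TemporalLink(id=f"g{i}", source=a, target=b,
                                     relation=FineRelation(l))
                        for i, ((a, b), l) in enumerate(gold_label_map(doc).items()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert score_12class(pred, gold).micro_f == pytest.approx(1.0)

    def test_setting2_output_subset_of_identified_candidates(self, fitted_pipeline,
                                                             test_corpus):
        for doc_id, (doc, ann) in list(test_corpus.docs.items())[:3]:
            cand = build_identification_instances(doc, ann, fitted_pipeline.cfg)
            cand_pairs = {(p.e1, p.e2) for plist in cand.values() for p in plist}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                links = fitted_pipeline.predict_document(doc, ann, setting=2, arch="HYBRID")
            assert {(l.source, l.target) for l in links} <= cand_pairs

    def test_output_pairs_are_document_candidates(self, fitted_pipeline, test_corpus):
        for doc_id, (doc, ann) in list(test_corpus.docs.items())[:3]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                links = fitted_pipeline.predict_document(doc, ann, setting=1, arch="HYBRID")
            ids = set(doc.entity_map())
            for l in links:
                assert l.source in ids and l.target in ids


class TestThresholds:
    def test_predicted_positive_count_monotone_in_threshold(self, fitted_pipeline,
                                                            test_corpus):
        doc_id, (doc, ann) = next(iter(test_corpus.docs.items()))
        cand = build_identification_instances(doc, ann, fitted_pipeline.cfg)
        ident = fitted_pipeline.identifiers["EE_INTRA"]
        decisions = []
        for p in cand["EE_INTRA"]:
            feats = dict(fitted_pipeline.featurizer.features(p).features)
            decisions.append(ident.decision(feats, p, doc, ann))
        decisions = np.array(decisions)
        counts = [(decisions >= th).sum() for th in (-np.inf, -1, 0, 1, np.inf)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0  # infinite threshold predicts nothing

    def test_tuned_dev_f_at_least_untuned(self, fitted_pipeline, test_corpus):
        from clintemprel.evaluation import score_12class

        dev = dict(list(test_corpus.docs.items())[:4])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # untuned: thresholds 0 everywhere
            for ident in fitted_pipeline.identifiers.values():
                ident.thresholds = {"micro": 0.0, "macro": 0.0}
            pred0, gold = [], []
            for doc_id, (doc, ann) in dev.items():
                pred0.extend(fitted_pipeline.predict_document(doc, ann, setting=2,
                                                              arch="HYBRID"))
                gold.extend(TemporalLink(id=f"g{i}", source=a, target=b,
                                         relation=FineRelation(l))
                            for i, ((a, b), l) in enumerate(gold_label_map(doc).items()))
            f_untuned = score_12class(pred0, gold).micro_f
            fitted_pipeline.tune_thresholds(dev, arch="HYBRID")
            pred1 = []
            for doc_id, (doc, ann) in dev.items():
                pred1.extend(fitted_pipeline.predict_document(doc, ann, setting=2,
                                                              arch="HYBRID"))
            f_tuned = score_12class(pred1, gold).micro_f
        # the searched grid includes 0, so dev F cannot drop
        assert f_tuned >= f_untuned - 1e-12
        for ident in fitted_pipeline.identifiers.values():
            ident.thresholds = {"micro": 0.0, "macro": 0.0}
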