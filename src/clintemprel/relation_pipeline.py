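"""End-to-end temporal relation extraction.

Two evaluation settings: in setting 1 the gold related pairs are given and
only need labeling; in setting 2 a relation *identification* stage first
decides which candidate pairs are related and the classification stage then
labels the survivors.

Classification uses four specialized classifiers, one per instance scheme:
intra-sentence event-event, intra-sentence event-time, adjacent-sentence
event-event (between main events -- the first and last events of a
sentence), and inter-sentence coreferent event pairs (naive coreference:
matching head lemmas).  Negative training instances are restricted to keep
the class skew bounded: intra-sentence negatives come only from adjacent
(no intervening entity) unrelated pairs; inter-sentence negatives from
main-event pairs.  Test candidates are built the same way as negatives.

Five architectures: FEATURES (learner only), ALL_RULES and HIGH_ACC_RULES
(first-match rules only; rule abstentions take the scheme's majority
training label), FEATURES_PLUS_RULE_FEATURES (learner whose feature set
includes every rule's prediction), and HYBRID (rules with accuracy >= 0.75
first, learner with rule features as fallback).
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import SVC, LinearSVC

from .annotation_layer import DocumentAnnotations, head_token
from .corpus_io import (
    ClinicalDocument,
    EventAnnotation,
    FineRelation,
    NO_RELATION,
    TemporalLink,
    TimeAnnotation,
    invert_relation,
)
from .feature_extraction import (
    DEFAULT_FAMILIES,
    FeatureVector,
    InstancePair,
    extract_all,
)
from .rule_engine import (
    HAS_RELATION,
    NONE_APPLICABLE,
    Rule,
    RuleSet,
    apply_first,
    feature_lookup,
    measure_accuracy,
    order_and_filter,
    rules_as_features,
)
from .semrel_ensemble import (
    _TreeKernelCache,
    _csr32,
    extract_simple_expansion_tree,
)

__all__ = [
    "PipelineConfig",
    "ARCHITECTURES",
    "Featurizer",
    "build_classification_instances",
    "build_identification_instances",
    "SpecializedModel",
    "train_specialized",
    "IdentifierModel",
    "TemporalPipeline",
]

ARCHITECTURES = ("FEATURES", "ALL_RULES", "HIGH_ACC_RULES", "FEATURES_PLUS_RULE_FEATURES", "HYBRID")
SCHEMES = ("EE_INTRA", "ET_INTRA", "EE_ADJACENT", "EE_COREF")


@dataclass
class PipelineConfig:
    families: tuple = DEFAULT_FAMILIES
    c_grid: tuple = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0, 10_000.0)
    seed: int = 0
    min_rule_accuracy: float = 0.75
    identifier_mode: str = "FLAT"  # FLAT | TREE | COMPOSITE
    composite_alpha: float = 0.5
    tree_lambda: float = 0.4
    intra_prune_tokens: int = 30  # drop intra-sentence id negatives with farther heads
    max_sentence_distance: int = 1  # beyond this, only coreferent pairs survive pruning
    dev_fraction: float = 0.2


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _sentence_of(entity, ann: DocumentAnnotations) -> int | None:
    try:
        return head_token(entity, ann).sent
    except Exception:
        return None


def gold_label_map(doc: ClinicalDocument) -> dict[tuple[str, str], str]:
    """Text-ordered (e1, e2) id pair -> fine label, orienting each gold link so
    that e1 precedes e2 (inverting the label when the link was stored the
    other way).  Section-time links are excluded."""
    sectimes = {s.id for s in doc.sectimes}
    emap = doc.entity_map()
    out: dict[tuple[str, str], str] = {}
    for link in doc.tlinks:
        if link.source in sectimes or link.target in sectimes:
            continue
        src, tgt = emap[link.source], emap[link.target]
        rel = FineRelation(str(link.relation))
        if src.start <= tgt.start:
            out[(link.source, link.target)] = rel.value
        else:
            out[(link.target, link.source)] = invert_relation(rel).value
    return out


def _main_events(events: list[EventAnnotation]) -> list[EventAnnotation]:
    """The first and last events of a sentence."""
    if not events:
        return []
    return [events[0]] if len(events) == 1 else [events[0], events[-1]]


def _head_lemma(entity, ann) -> str | None:
    try:
        return head_token(entity, ann).lemma.lower()
    except Exception:
        return None


# ---------------------------------------------------------------------------
# instance generation
# ---------------------------------------------------------------------------

def build_classification_instances(
    doc: ClinicalDocument, ann: DocumentAnnotations, for_training: bool = True
) -> dict[str, list[InstancePair]]:
    """Candidate pairs per scheme.

    Training positives are the gold related pairs of each scheme; training
    negatives (and all test candidates) follow the schemes' skew-bounding
    recipes described in the module docstring.
    """
    gold = gold_label_map(doc)
    by_sent_events: dict[int, list[EventAnnotation]] = {}
    by_sent_entities: dict[int, list] = {}
    for ev in sorted(doc.events, key=lambda e: e.start):
        s = _sentence_of(ev, ann)
        if s is not None:
            by_sent_events.setdefault(s, []).append(ev)
            by_sent_entities.setdefault(s, []).append(ev)
    for tm in sorted(doc.times, key=lambda t: t.start):
        s = _sentence_of(tm, ann)
        if s is not None:
            by_sent_entities.setdefault(s, []).append(tm)
    for s in by_sent_entities:
        by_sent_entities[s].sort(key=lambda e: e.start)

    out: dict[str, list[InstancePair]] = {s: [] for s in SCHEMES}
    seen: set[tuple[str, str, str]] = set()

    def add(scheme: str, a, b, label):
        e1, e2 = (a, b) if a.start <= b.start else (b, a)
        key = (scheme, e1.id, e2.id)
        if key in seen:
            return
        seen.add(key)
        out[scheme].append(InstancePair(doc_id=doc.id, e1=e1.id, e2=e2.id, scheme=scheme, label=label))

    # intra-sentence schemes
    for s, entities in by_sent_entities.items():
        n = len(entities)
        for i in range(n):
            for j in range(i + 1, n):
                a, b = entities[i], entities[j]
                kinds = (isinstance(a, EventAnnotation), isinstance(b, EventAnnotation))
                scheme = "EE_INTRA" if all(kinds) else ("ET_INTRA" if any(kinds) else None)
                if scheme is None:
                    continue
                label = gold.get((a.id, b.id))
                adjacent = j == i + 1
                if for_training:
                    if label is not None:
                        add(scheme, a, b, label)
                    elif adjacent:
                        add(scheme, a, b, NO_RELATION)
                elif adjacent:
                    add(scheme, a, b, None)

    # adjacent-sentence event-event scheme
    sents = sorted(by_sent_events)
    for s in sents:
        if s + 1 not in by_sent_events:
            continue
        cur, nxt = by_sent_events[s], by_sent_events[s + 1]
        if for_training:
            for a in cur:
                for b in nxt:
                    label = gold.get((a.id, b.id)) or gold.get((b.id, a.id))
                    if label is not None:
                        add("EE_ADJACENT", a, b, gold.get((a.id, b.id), label))
        for a in _main_events(cur):
            for b in _main_events(nxt):
                label = gold.get((a.id, b.id))
                if for_training:
                    if label is None:
                        add("EE_ADJACENT", a, b, NO_RELATION)
                else:
                    add("EE_ADJACENT", a, b, None)

    # coreferent event pairs (matching head lemmas, any sentence distance)
    all_events = sorted(doc.events, key=lambda e: e.start)
    lemmas = {ev.id: _head_lemma(ev, ann) for ev in all_events}
    sent_idx = {ev.id: _sentence_of(ev, ann) for ev in all_events}
    mains = {ev.id for s, evs in by_sent_events.items() for ev in _main_events(evs)}
    for i in range(len(all_events)):
        for j in range(i + 1, len(all_events)):
            a, b = all_events[i], all_events[j]
            if sent_idx[a.id] == sent_idx[b.id]:
                continue
            if lemmas[a.id] is None or lemmas[a.id] != lemmas[b.id]:
                continue
            label = gold.get((a.id, b.id))
            if for_training:
                if label is not None:
                    add("EE_COREF", a, b, label)
                elif a.id in mains and b.id in mains:
                    add("EE_COREF", a, b, NO_RELATION)
            elif a.id in mains and b.id in mains:
                add("EE_COREF", a, b, None)
    return out


def build_identification_instances(
    doc: ClinicalDocument, ann: DocumentAnnotations, cfg: PipelineConfig | None = None,
    prune: bool = True,
) -> dict[str, list[InstancePair]]:
    """All event-event / event-time candidate pairs, labeled HAS_RELATION /
    NO_RELATION, routed to the scheme that will decide them.

    Negatives are pruned (when *prune*): intra-sentence pairs whose heads are
    more than ``intra_prune_tokens`` apart, and cross-sentence pairs beyond
    ``max_sentence_distance`` sentences unless coreferent.  Unroutable pairs
    (e.g. cross-sentence event-time) are skipped.
    """
    cfg = cfg or PipelineConfig()
    gold = gold_label_map(doc)
    entities = sorted([*doc.events, *doc.times], key=lambda e: e.start)
    sent_idx = {e.id: _sentence_of(e, ann) for e in entities}
    lemmas = {e.id: _head_lemma(e, ann) for e in entities}
    by_sent_events: dict[int, list[EventAnnotation]] = {}
    for ev in sorted(doc.events, key=lambda e: e.start):
        s = sent_idx[ev.id]
        if s is not None:
            by_sent_events.setdefault(s, []).append(ev)
    mains = {ev.id for s, evs in by_sent_events.items() for ev in _main_events(evs)}

    out: dict[str, list[InstancePair]] = {s: [] for s in SCHEMES}
    for i in range(len(entities)):
        for j in range(i + 1, len(entities)):
            a, b = entities[i], entities[j]
            ee = isinstance(a, EventAnnotation) and isinstance(b, EventAnnotation)
            et = isinstance(a, EventAnnotation) != isinstance(b, EventAnnotation)
            if not (ee or et):
                continue
            sa, sb = sent_idx[a.id], sent_idx[b.id]
            if sa is None or sb is None:
                continue
            related = (a.id, b.id) in gold
            label = HAS_RELATION if related else NO_RELATION
            if sa == sb:
                scheme = "EE_INTRA" if ee else "ET_INTRA"
                if prune and not related:
                    try:
                        d = abs(head_token(a, ann).index - head_token(b, ann).index)
                    except Exception:
                        d = 0
                    if d > cfg.intra_prune_tokens:
                        continue
                out[scheme].append(InstancePair(doc.id, a.id, b.id, scheme, label))
            else:
                coref = ee and lemmas[a.id] is not None and lemmas[a.id] == lemmas[b.id]
                dist = abs(sa - sb)
                if coref:
                    out["EE_COREF"].append(InstancePair(doc.id, a.id, b.id, "EE_COREF", label))
                elif ee and dist <= cfg.max_sentence_distance:
                    if related or (a.id in mains and b.id in mains):
                        out["EE_ADJACENT"].append(InstancePair(doc.id, a.id, b.id, "EE_ADJACENT", label))
                elif prune and not related:
                    continue  # beyond pruning distance and not coreferent
    return out


# ---------------------------------------------------------------------------
# featurization with caching
# ---------------------------------------------------------------------------

class Featurizer:
    """Caches per-pair feature vectors over a corpus of (doc, ann) pairs."""

    def __init__(self, corpus: dict, families=DEFAULT_FAMILIES, thesaurus=None,
                 wordnet=None, medsem_model=None, synsets=None):
        self.corpus = corpus
        self.families = families
        self.thesaurus = thesaurus
        self.wordnet = wordnet
        self.medsem_model = medsem_model
        self.synsets = synsets
        self._cache: dict[tuple[str, str, str], FeatureVector] = {}

    def doc_ann(self, doc_id: str):
        return self.corpus[doc_id]

    def features(self, pair: InstancePair) -> FeatureVector:
        key = (pair.doc_id, pair.e1, pair.e2)
        if key not in self._cache:
            doc, ann = self.corpus[pair.doc_id]
            self._cache[key] = extract_all(
                pair, doc, ann, families=self.families, thesaurus=self.thesaurus,
                wordnet=self.wordnet, medsem_model=self.medsem_model, synsets=self.synsets,
            )
        return self._cache[key]

    def lookup(self, pair: InstancePair):
        doc, ann = self.corpus[pair.doc_id]
        return feature_lookup(self.features(pair), pair, doc, ann)


# ---------------------------------------------------------------------------
# specialized classifiers
# ---------------------------------------------------------------------------

def _stringify(d: dict) -> dict:
    return {k: (v if isinstance(v, (int, float)) else str(v)) for k, v in d.items()}


@dataclass
class SpecializedModel:
    scheme: str
    vec: DictVectorizer | None = None
    svc: LinearSVC | None = None
    constant: str | None = None  # single-class / untrained fallback
    majority_label: str = NO_RELATION
    C: float = 1.0

    def predict(self, feats: dict) -> str:
        if self.constant is not None:
            return self.constant
        X = _csr32(self.vec.transform([_stringify(feats)]))
        return str(self.svc.predict(X)[0])


def train_specialized(
    instances: list[InstancePair], featurize, cfg: PipelineConfig, scheme: str,
    extra_features=None,
) -> SpecializedModel:
    """Train one scheme's multiclass SVM; C picked on a 20% held-out split.

    *featurize* maps an instance to a plain feature dict; *extra_features*
    (optional) appends e.g. rules-as-features.
    """
    labeled = [i for i in instances if i.label is not None]
    labels = [i.label for i in labeled]
    pos = [l for l in labels if l != NO_RELATION]
    majority = max(set(labels), key=labels.count) if labels else NO_RELATION
    maj_pos = max(set(pos), key=pos.count) if pos else NO_RELATION
    if not labeled or not pos:
        warnings.warn(f"scheme {scheme}: no positive training instances; predicting NO_RELATION")
        return SpecializedModel(scheme=scheme, constant=NO_RELATION, majority_label=maj_pos)
    if len(set(labels)) == 1:
        return SpecializedModel(scheme=scheme, constant=labels[0], majority_label=maj_pos)

    feats = [featurize(i) for i in labeled]
    if extra_features is not None:
        for f, inst in zip(feats, labeled):
            f.update(extra_features(inst))
    feats = [_stringify(f) for f in feats]

    rng = random.Random(cfg.seed)
    idx = list(range(len(labeled)))
    rng.shuffle(idx)
    n_dev = max(1, int(cfg.dev_fraction * len(idx)))
    dev_idx, train_idx = idx[:n_dev], idx[n_dev:]
    best_c, best_acc = cfg.c_grid[0], -1.0
    if train_idx and len({labels[i] for i in train_idx}) > 1 and len(cfg.c_grid) > 1:
        vec = DictVectorizer(sparse=True)
        Xall = _csr32(vec.fit_transform(feats))
        ytr = [labels[i] for i in train_idx]
        for C in cfg.c_grid:
            m = LinearSVC(C=C, random_state=cfg.seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(Xall[train_idx], ytr)
            acc = float(np.mean(m.predict(Xall[dev_idx]) == np.array([labels[i] for i in dev_idx])))
            if acc > best_acc:
                best_c, best_acc = C, acc
    else:
        best_c = 1.0
    vec = DictVectorizer(sparse=True)
    X = _csr32(vec.fit_transform(feats))
    svc = LinearSVC(C=best_c, random_state=cfg.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svc.fit(X, labels)
    return SpecializedModel(scheme=scheme, vec=vec, svc=svc, majority_label=maj_pos, C=best_c)


# ---------------------------------------------------------------------------
# identification models
# ---------------------------------------------------------------------------

def _normalize_gram(K: np.ndarray, diag_a: np.ndarray, diag_b: np.ndarray) -> np.ndarray:
    denom = np.sqrt(np.outer(np.maximum(diag_a, 1e-12), np.maximum(diag_b, 1e-12)))
    return K / denom


@dataclass
class IdentifierModel:
    scheme: str
    mode: str
    vec: DictVectorizer | None = None
    svc: SVC | None = None
    X_train: object = None  # sparse flat matrix of training instances
    flat_diag: np.ndarray | None = None
    tree_keys: list = field(default_factory=list)
    tree_diag: np.ndarray | None = None
    kernel: _TreeKernelCache | None = None
    alpha: float = 0.5
    constant: str | None = None
    thresholds: dict[str, float] = field(default_factory=lambda: {"micro": 0.0, "macro": 0.0})

    def _tree_key(self, pair, doc, ann):
        e1, e2 = doc.entity(pair.e1), doc.entity(pair.e2)
        try:
            t = extract_simple_expansion_tree(e1, e2, ann, attribute_at="parent")
        except Exception:
            return None
        return self.kernel.canonical(t)

    def decision(self, feats: dict, pair=None, doc=None, ann=None) -> float:
        """Signed distance from the separating hyperplane (positive = related)."""
        if self.constant is not None:
            return 1.0 if self.constant == HAS_RELATION else -1.0
        x = _csr32(self.vec.transform([_stringify(feats)]))
        kf = np.asarray((x @ self.X_train.T).todense())
        diag_x = np.asarray((x.multiply(x)).sum(axis=1)).ravel()
        kf = _normalize_gram(kf, diag_x, self.flat_diag)
        if self.mode == "FLAT":
            K = kf
        else:
            key = self._tree_key(pair, doc, ann) if pair is not None else None
            if key is None:
                # no parse fragment for this instance: flat fallback
                K = kf
            else:
                kt = np.array([[self.kernel.value(key, k2) if k2 is not None else 0.0
                                for k2 in self.tree_keys]])
                diag_t = np.array([self.kernel.value(key, key)])
                kt = _normalize_gram(kt, diag_t, self.tree_diag)
                if self.mode == "TREE":
                    K = kt
                else:
                    K = self.alpha * kf + (1.0 - self.alpha) * kt
        return float(self.svc.decision_function(K)[0])

    def predict(self, feats, pair=None, doc=None, ann=None, objective: str = "micro") -> bool:
        return self.decision(feats, pair, doc, ann) >= self.thresholds.get(objective, 0.0)


def train_identifier(
    instances: list[InstancePair], featurize, corpus: dict, cfg: PipelineConfig, scheme: str,
) -> IdentifierModel:
    mode = cfg.identifier_mode
    kernel = _TreeKernelCache(cfg.tree_lambda)
    labels = [i.label for i in instances]
    if not instances or len(set(labels)) < 2:
        const = labels[0] if labels else NO_RELATION
        warnings.warn(f"identifier {scheme}: degenerate training set; constant {const}")
        return IdentifierModel(scheme=scheme, mode=mode, constant=const, kernel=kernel)
    feats = [_stringify(featurize(i)) for i in instances]
    vec = DictVectorizer(sparse=True)
    X = _csr32(vec.fit_transform(feats))
    Kf = np.asarray((X @ X.T).todense())
    diag_f = Kf.diagonal().copy()
    Kf = _normalize_gram(Kf, diag_f, diag_f)
    model = IdentifierModel(scheme=scheme, mode=mode, vec=vec, X_train=X,
                            flat_diag=diag_f, kernel=kernel, alpha=cfg.composite_alpha)
    if mode in ("TREE", "COMPOSITE"):
        keys = []
        for inst in instances:
            doc, ann = corpus[inst.doc_id]
            keys.append(model._tree_key(inst, doc, ann))
        model.tree_keys = keys
        diag_t = np.array([kernel.value(k, k) if k is not None else 0.0 for k in keys])
        Kt = np.array([[kernel.value(a, b) if a is not None and b is not None else 0.0
                        for b in keys] for a in keys])
        Kt = _normalize_gram(Kt, np.maximum(diag_t, 1e-12), np.maximum(diag_t, 1e-12))
        model.tree_diag = diag_t
        K = Kt if mode == "TREE" else cfg.composite_alpha * Kf + (1 - cfg.composite_alpha) * Kt
    else:
        K = Kf
    y = np.array([1 if l == HAS_RELATION else -1 for l in labels])
    svc = SVC(kernel="precomputed", C=1.0)
    svc.fit(K, y)
    model.svc = svc
    return model


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

class TemporalPipeline:
    """Trains rules, specialized classifiers and identifiers over a corpus and
    predicts per-document temporal links under a chosen architecture."""

    def __init__(self, cfg: PipelineConfig | None = None, featurizer: Featurizer | None = None,
                 rules: list[Rule] | None = None, negative_rules: list[Rule] | None = None):
        self.cfg = cfg or PipelineConfig()
        self.featurizer = featurizer
        self.rules_input = rules or []
        self.negative_rules = negative_rules or []
        self.ruleset_all: RuleSet = RuleSet()
        self.ruleset_high: RuleSet = RuleSet()
        self.models: dict[str, SpecializedModel] = {}
        self.models_rf: dict[str, SpecializedModel] = {}
        self.identifiers: dict[str, IdentifierModel] = {}

    # -- featurization helpers ---------------------------------------------
    def _feat_dict(self, pair: InstancePair) -> dict:
        return dict(self.featurizer.features(pair).features)

    def _rule_feats(self, pair: InstancePair) -> dict:
        lookup = self.featurizer.lookup(pair)
        return rules_as_features(self.ruleset_all, lookup).features

    # -- training -----------------------------------------------------------
    def fit(self, train_corpus: dict) -> "TemporalPipeline":
        """*train_corpus*: doc_id -> (ClinicalDocument, DocumentAnnotations)."""
        if self.featurizer is None:
            self.featurizer = Featurizer(train_corpus)
        per_scheme: dict[str, list[InstancePair]] = {s: [] for s in SCHEMES}
        for doc_id, (doc, ann) in train_corpus.items():
            for scheme, pairs in build_classification_instances(doc, ann, for_training=True).items():
                per_scheme[scheme].extend(pairs)

        # rule accuracies, measured on the gold-related training instances
        positives = [i for pairs in per_scheme.values() for i in pairs if i.label not in (None, NO_RELATION)]
        scored_pairs = [(self.featurizer.lookup(i), i.label) for i in positives]
        scored = [measure_accuracy(r, scored_pairs) for r in self.rules_input]
        self.ruleset_all = order_and_filter(scored, min_accuracy=0.0)
        self.ruleset_high = order_and_filter(scored, min_accuracy=self.cfg.min_rule_accuracy)

        for scheme, pairs in per_scheme.items():
            self.models[scheme] = train_specialized(pairs, self._feat_dict, self.cfg, scheme)
            self.models_rf[scheme] = train_specialized(
                pairs, self._feat_dict, self.cfg, scheme, extra_features=self._rule_feats)

        id_per_scheme: dict[str, list[InstancePair]] = {s: [] for s in SCHEMES}
        for doc_id, (doc, ann) in train_corpus.items():
            for scheme, pairs in build_identification_instances(doc, ann, self.cfg).items():
                id_per_scheme[scheme].extend(pairs)
        for scheme, pairs in id_per_scheme.items():
            self.identifiers[scheme] = train_identifier(
                pairs, self._feat_dict, train_corpus, self.cfg, scheme)
        return self

    # -- classification -----------------------------------------------------
    def classify_pair(self, pair: InstancePair, arch: str) -> str:
        if arch not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {arch!r}")
        model = (self.models if arch == "FEATURES" else self.models_rf).get(pair.scheme)
        if arch in ("FEATURES", "FEATURES_PLUS_RULE_FEATURES", "HYBRID") and model is None:
            raise ValueError(f"no model for scheme {pair.scheme!r}")
        lookup = self.featurizer.lookup(pair)
        if arch in ("ALL_RULES", "HIGH_ACC_RULES"):
            ruleset = self.ruleset_all if arch == "ALL_RULES" else self.ruleset_high
            label = apply_first(ruleset, lookup)
            if label == NONE_APPLICABLE:
                maj = (self.models.get(pair.scheme) or SpecializedModel(pair.scheme)).majority_label
                return maj
            return label
        if arch == "HYBRID":
            label = apply_first(self.ruleset_high, lookup)
            if label != NONE_APPLICABLE:
                return label
        feats = self._feat_dict(pair)
        if arch in ("FEATURES_PLUS_RULE_FEATURES", "HYBRID"):
            feats.update(self._rule_feats(pair))
        return model.predict(feats)

    def classify(self, pairs: list[InstancePair], arch: str) -> list[TemporalLink]:
        links = []
        for n, pair in enumerate(pairs):
            label = self.classify_pair(pair, arch)
            if label in (NO_RELATION, NONE_APPLICABLE):
                continue
            links.append(TemporalLink(id=f"TL{n}", source=pair.e1, target=pair.e2,
                                      relation=FineRelation(label), origin="CLASSIFIER"))
        return links

    # -- identification -----------------------------------------------------
    def identify_pair(self, pair: InstancePair, objective: str = "micro") -> bool:
        """Hybrid identification: positive rules, negative rules, learned fallback."""
        lookup = self.featurizer.lookup(pair)
        if apply_first(self.ruleset_all, lookup) != NONE_APPLICABLE:
            return True
        for rule in self.negative_rules:
            if rule.applies(lookup):
                return False
        ident = self.identifiers.get(pair.scheme)
        if ident is None:
            return False
        doc, ann = self.featurizer.doc_ann(pair.doc_id)
        return ident.predict(self._feat_dict(pair), pair, doc, ann, objective=objective)

    # -- end-to-end ----------------------------------------------------------
    def predict_document(self, doc: ClinicalDocument, ann: DocumentAnnotations,
                         setting: int = 1, arch: str = "HYBRID",
                         objective: str = "micro") -> list[TemporalLink]:
        self.featurizer.corpus.setdefault(doc.id, (doc, ann))
        if setting == 1:
            gold = gold_label_map(doc)
            pairs = []
            for (a, b) in gold:
                ea, eb = doc.entity(a), doc.entity(b)
                pairs.append(InstancePair(doc.id, a, b, self._route(ea, eb, ann), None))
        elif setting == 2:
            cand = build_identification_instances(doc, ann, self.cfg)
            pairs = [InstancePair(p.doc_id, p.e1, p.e2, p.scheme, None)
                     for scheme, plist in cand.items() for p in plist
                     if self.identify_pair(p, objective=objective)]
        else:
            raise ValueError("setting must be 1 or 2")
        return self.classify(pairs, arch)

    def _route(self, e1, e2, ann) -> str:
        s1, s2 = _sentence_of(e1, ann), _sentence_of(e2, ann)
        ee = isinstance(e1, EventAnnotation) and isinstance(e2, EventAnnotation)
        if s1 == s2:
            return "EE_INTRA" if ee else "ET_INTRA"
        if ee and _head_lemma(e1, ann) == _head_lemma(e2, ann):
            return "EE_COREF"
        return "EE_ADJACENT" if ee else "ET_INTRA"

    # -- threshold tuning ----------------------------------------------------
    def tune_thresholds(self, dev_corpus: dict, arch: str = "HYBRID") -> dict[str, dict[str, float]]:
        """Tune each scheme's identification threshold independently to
        maximize downstream classification micro and macro F on a dev split.

        The searched grid is the set of observed dev signed distances (plus
        the default 0), so the tuned dev F is never below the untuned one.
        """
        from .evaluation import score_12class

        cand: dict[str, list[tuple[InstancePair, float]]] = {s: [] for s in SCHEMES}
        gold_links: list[TemporalLink] = []
        rule_pos: dict[tuple, bool] = {}
        for doc_id, (doc, ann) in dev_corpus.items():
            self.featurizer.corpus.setdefault(doc_id, (doc, ann))
            gold = gold_label_map(doc)
            gold_links.extend(
                TemporalLink(id=f"G{i}", source=a, target=b, relation=FineRelation(l))
                for i, ((a, b), l) in enumerate(gold.items()))
            for scheme, plist in build_identification_instances(doc, ann, self.cfg).items():
                for p in plist:
                    lookup = self.featurizer.lookup(p)
                    if apply_first(self.ruleset_all, lookup) != NONE_APPLICABLE:
                        rule_pos[(p.doc_id, p.e1, p.e2)] = True
                        cand[scheme].append((p, np.inf))  # rule-identified regardless of threshold
                        continue
                    if any(r.applies(lookup) for r in self.negative_rules):
                        continue
                    ident = self.identifiers.get(scheme)
                    if ident is None:
                        continue
                    d = ident.decision(self._feat_dict(p), p, doc, ann)
                    cand[scheme].append((p, d))

        labels_cache: dict[tuple, str] = {}

        def links_for(thresholds: dict[str, float]) -> list[TemporalLink]:
            links = []
            n = 0
            for scheme, plist in cand.items():
                th = thresholds[scheme]
                for p, d in plist:
                    if d >= th:
                        key = (p.doc_id, p.e1, p.e2)
                        if key not in labels_cache:
                            labels_cache[key] = self.classify_pair(
                                InstancePair(p.doc_id, p.e1, p.e2, p.scheme, None), arch)
                        label = labels_cache[key]
                        if label not in (NO_RELATION, NONE_APPLICABLE):
                            links.append(TemporalLink(id=f"S{n}", source=p.e1, target=p.e2,
                                                      relation=FineRelation(label)))
                            n += 1
            return links

        out: dict[str, dict[str, float]] = {}
        for objective in ("micro", "macro"):
            current = {s: 0.0 for s in SCHEMES}
            for scheme in SCHEMES:
                grid = sorted({0.0, *[d for _, d in cand[scheme] if np.isfinite(d)]})
                best_th, best_f = 0.0, -1.0
                for th in grid:
                    trial = dict(current)
                    trial[scheme] = th
                    report = score_12class(links_for(trial), gold_links)
                    f = report.micro_f if objective == "micro" else report.macro_f
                    if f > best_f + 1e-12:
                        best_th, best_f = th, f
                current[scheme] = best_th
            out[objective] = current
            for scheme in SCHEMES:
                if scheme in self.identifiers:
                    self.identifiers[scheme].thresholds[objective] = current[scheme]
        return out


def run_pipeline(train_corpus: dict, test_corpus: dict, setting: int = 1, arch: str = "HYBRID",
                 cfg: PipelineConfig | None = None, featurizer: Featurizer | None = None,
                 rules=None, negative_rules=None) -> dict[str, list[TemporalLink]]:
    """Train on one corpus and predict links for every document of another."""
    pipe = TemporalPipeline(cfg=cfg, featurizer=featurizer, rules=rules,
                            negative_rules=negative_rules)
    pipe.fit(train_corpus)
    out = {}
    for doc_id, (doc, ann) in test_corpus.items():
        out[doc_id] = pipe.predict_document(doc, ann, setting=setting, arch=arch)
    return out
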