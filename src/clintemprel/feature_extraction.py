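"""Featurization of candidate temporal-relation instances.

An instance is an ordered entity pair (e1, e2) with e1 preceding e2 in the
text.  The baseline representation has six families -- lexical, grammatical,
entity-attribute, distance, semantic, and section-creation-time features --
and is augmented by six further families: pairwise features, thesaurus and
WordNet-style lexical-relation flags, predicate-argument (SRL) flags,
PDTB-style discourse-sense features, and features derived from a medical
semantic-relation classifier.

Features are named ``family.name`` (set-valued content such as context
n-grams is folded into the name) and are either categorical strings, binary
flags, or counts.  ``NULL`` is a legal categorical value: extractors never
raise on a missing annotation layer, they emit NULL/zero instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation_layer import (
    AlignmentError,
    DocumentAnnotations,
    Token,
    dominates,
    head_token,
    minimal_covering_node,
    tree_path,
)
from .corpus_io import ClinicalDocument, EventAnnotation, TimeAnnotation, map_fine_to_broad

__all__ = [
    "NULL",
    "InstancePair",
    "FeatureVector",
    "LexicalRelationLexicon",
    "extract_baseline",
    "extract_pairwise",
    "extract_lexical_relations",
    "extract_predarg",
    "extract_discourse",
    "extract_medsem",
    "extract_all",
    "between_tokens",
    "token_distance",
]

NULL = "NULL"

SCHEMES = ("EE_INTRA", "ET_INTRA", "EE_ADJACENT", "EE_COREF")


@dataclass(frozen=True)
class InstancePair:
    """A candidate relation instance; e1 precedes e2 in the text."""

    doc_id: str
    e1: str
    e2: str
    scheme: str  # one of SCHEMES
    label: str | None = None  # fine relation name, NO_RELATION, or None (unlabeled)


@dataclass
class FeatureVector:
    features: dict[str, object] = field(default_factory=dict)
    families: dict[str, str] = field(default_factory=dict)

    def set(self, family: str, name: str, value: object) -> None:
        self.features[name] = value
        self.families[name] = family

    def update(self, other: "FeatureVector") -> None:
        self.features.update(other.features)
        self.families.update(other.families)

    def by_family(self, family: str) -> dict[str, object]:
        return {k: v for k, v in self.features.items() if self.families[k] == family}

    def as_dict(self) -> dict[str, object]:
        return dict(self.features)

    def dump(self) -> str:
        """Sparse name:value text for audit."""
        return "\n".join(f"{k}:{self.features[k]}" for k in sorted(self.features))


class LexicalRelationLexicon:
    """Headword -> four relation lists.

    The thesaurus variant carries (synonyms, related, near_antonyms, antonyms);
    the WordNet-style variant carries (hypernyms, hyponyms, troponyms, similar).
    Lookups are case-folded; a missing headword yields four empty lists.
    """

    def __init__(self, relations: tuple[str, str, str, str], entries: dict[str, tuple] | None = None):
        self.relations = relations
        self._entries: dict[str, tuple[frozenset, ...]] = {}
        for head, lists in (entries or {}).items():
            self.add(head, *lists)

    def add(self, headword: str, *lists) -> None:
        assert len(lists) == 4
        self._entries[headword.lower()] = tuple(frozenset(w.lower() for w in lst) for lst in lists)

    def lookup(self, headword: str) -> dict[str, frozenset]:
        lists = self._entries.get(headword.lower(), (frozenset(),) * 4)
        return dict(zip(self.relations, lists))

    @classmethod
    def thesaurus(cls, entries=None) -> "LexicalRelationLexicon":
        return cls(("synonyms", "related", "near_antonyms", "antonyms"), entries)

    @classmethod
    def wordnet(cls, entries=None) -> "LexicalRelationLexicon":
        return cls(("hypernyms", "hyponyms", "troponyms", "similar"), entries)

    @classmethod
    def load(cls, path, variant: str = "thesaurus") -> "LexicalRelationLexicon":
        """One headword per line followed by four tab-separated comma lists."""
        lex = cls.thesaurus() if variant == "thesaurus" else cls.wordnet()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                head, cols = parts[0], parts[1:] + [""] * (5 - len(parts))
                lex.add(head, *[[w for w in col.split(",") if w] for col in cols[:4]])
        return lex


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _entity_tokens(entity, ann: DocumentAnnotations) -> list[Token]:
    return ann.tokens_overlapping(entity.start, entity.end)


def between_tokens(e1, e2, ann: DocumentAnnotations) -> list[Token]:
    """Tokens strictly between the two entity spans, in text order."""
    lo = min(e1.end, e2.end)
    hi = max(e1.start, e2.start)
    return [t for t in ann.tokens if t.start >= lo and t.end <= hi]


def token_distance(e1, e2, ann: DocumentAnnotations) -> int:
    return len(between_tokens(e1, e2, ann))


def _safe_head(entity, ann) -> Token | None:
    try:
        return head_token(entity, ann)
    except AlignmentError:
        return None


def _is_event(entity) -> bool:
    return isinstance(entity, EventAnnotation)


def _window(tok: Token | None, ann: DocumentAnnotations, radius: int) -> list[Token]:
    if tok is None:
        return []
    lo, hi = max(0, tok.index - radius), min(len(ann.tokens), tok.index + radius + 1)
    return [ann.tokens[i] for i in range(lo, hi) if i != tok.index]


def _ngrams(words: list[str], n: int) -> list[str]:
    return ["_".join(words[i : i + n]) for i in range(len(words) - n + 1)]


# ---------------------------------------------------------------------------
# baseline families
# ---------------------------------------------------------------------------

def _sct_relation(entity, doc: ClinicalDocument) -> str:
    """Fine link between the entity and its section's creation time, merged to
    BEFORE/AFTER/OVERLAP; NULL when no such gold link exists."""
    sectime_ids = {s.id for s in doc.sectimes}
    for link in doc.tlinks:
        if link.source == entity.id and link.target in sectime_ids:
            return map_fine_to_broad(link.relation)[0].name.replace("3", "")
        if link.target == entity.id and link.source in sectime_ids:
            broad, inverted = map_fine_to_broad(link.relation)
            name = broad.name.replace("3", "")
            if not inverted:
                # entity is the target: read the assertion from the entity's side
                name = {"BEFORE": "AFTER", "AFTER": "BEFORE", "OVERLAP": "OVERLAP"}[name]
            return name
    return NULL


def extract_baseline(
    pair: InstancePair,
    doc: ClinicalDocument,
    ann: DocumentAnnotations,
    synsets: dict[str, str] | None = None,
) -> FeatureVector:
    """The six baseline feature families."""
    e1, e2 = doc.entity(pair.e1), doc.entity(pair.e2)
    h1, h2 = _safe_head(e1, ann), _safe_head(e2, ann)
    fv = FeatureVector()

    # -- lexical: context n-grams in a +/-2 token window, strings, heads -----
    for tag, ent, head in (("e1", e1, h1), ("e2", e2, h2)):
        ctx = [t.text.lower() for t in _window(head, ann, 2)]
        for n in (1, 2, 3):
            for g in _ngrams(ctx, n):
                fv.set("lexical", f"lex.{tag}_ctx{n}:{g}", 1)
        fv.set("lexical", f"lex.{tag}_string", ent.text.lower())
        fv.set("lexical", f"lex.{tag}_head", head.text.lower() if head else NULL)
    fv.set("lexical", "lex.same_string", int(e1.text.lower() == e2.text.lower()))

    # -- grammatical --------------------------------------------------------
    fv.set("grammatical", "gram.e1_head_pos", h1.pos if h1 else NULL)
    fv.set("grammatical", "gram.e2_head_pos", h2.pos if h2 else NULL)
    for tag, head in (("e1", h1), ("e2", h2)):
        for off, t in enumerate(_window(head, ann, 5)):
            fv.set("grammatical", f"gram.{tag}_ctx_pos:{t.index - head.index}:{t.pos}", 1)
        if head and head.index > 0:
            fv.set("grammatical", f"gram.{tag}_pos_bigram",
                   f"{ann.tokens[head.index - 1].pos}_{head.pos}")
        else:
            fv.set("grammatical", f"gram.{tag}_pos_bigram", NULL)
    fv.set("grammatical", "gram.head_pos_pair",
           f"{h1.pos if h1 else NULL}_{h2.pos if h2 else NULL}")
    for tag, ent, head in (("e1", e1, h1), ("e2", e2, h2)):
        headed_pp, governed_pp, governing_vp = NULL, NULL, NULL
        if head is not None and ann.trees:
            try:
                cover = minimal_covering_node(ent, ann)
                if cover.label == "PP":
                    leaves = cover.leaves()
                    headed_pp = ann.tokens[leaves[0].token_index].text.lower()
                node = cover.parent
                while node is not None:
                    if node.label == "PP" and governed_pp is NULL:
                        leaves = node.leaves()
                        governed_pp = ann.tokens[leaves[0].token_index].text.lower()
                    if node.label == "VP" and governing_vp is NULL:
                        for child in node.children:
                            if child.label.startswith("V") and child.children:
                                governing_vp = child.label
                                break
                        if governing_vp is NULL:
                            governing_vp = "VP"
                    node = node.parent
            except AlignmentError:
                pass
        fv.set("grammatical", f"gram.{tag}_headed_pp", headed_pp)
        fv.set("grammatical", f"gram.{tag}_governed_pp", governed_pp)
        fv.set("grammatical", f"gram.{tag}_governing_vp_pos", governing_vp)
    same_sent = h1 is not None and h2 is not None and h1.sent == h2.sent
    if same_sent and ann.trees:
        fv.set("grammatical", "gram.e1_dominates_e2", int(dominates(e1, e2, ann)))
        try:
            fv.set("grammatical", "gram.tree_path", "/".join(tree_path(e1, e2, ann)))
        except AlignmentError:
            fv.set("grammatical", "gram.tree_path", NULL)
    else:
        fv.set("grammatical", "gram.e1_dominates_e2", 0)
        fv.set("grammatical", "gram.tree_path", NULL)
    for tag, head in (("e1", h1), ("e2", h2)):
        subj = obj = 0
        if head is not None:
            for edge in ann.deps:
                if edge.dep == head.index:
                    if "subj" in edge.label:
                        subj = 1
                    if "obj" in edge.label:
                        obj = 1
        fv.set("grammatical", f"gram.{tag}_dep_subj", subj)
        fv.set("grammatical", f"gram.{tag}_dep_obj", obj)

    # -- entity attributes --------------------------------------------------
    t1 = e1.etype if _is_event(e1) else e1.ttype
    t2 = e2.etype if _is_event(e2) else e2.ttype
    m1 = e1.modality if _is_event(e1) else NULL
    m2 = e2.modality if _is_event(e2) else NULL
    p1 = e1.polarity if _is_event(e1) else NULL
    p2 = e2.polarity if _is_event(e2) else NULL
    fv.set("entity", "ent.e1_type", t1)
    fv.set("entity", "ent.e2_type", t2)
    fv.set("entity", "ent.e1_modality", m1)
    fv.set("entity", "ent.e2_modality", m2)
    fv.set("entity", "ent.e1_polarity", p1)
    fv.set("entity", "ent.e2_polarity", p2)
    fv.set("entity", "ent.type_pair", f"{t1}_{t2}")
    fv.set("entity", "ent.modality_pair", f"{m1}_{m2}")

    # -- distance -----------------------------------------------------------
    fv.set("distance", "dist.tokens", token_distance(e1, e2, ann))
    fv.set("distance", "dist.same_sentence", int(same_sent))

    # -- semantic -----------------------------------------------------------
    for tag, ent, head in (("e1", e1, h1), ("e2", e2, h2)):
        tmp_tok = NULL
        if head is not None:
            for frame in ann.srl:
                for label, a, b in frame.arguments:
                    if label == "TMP" and a <= head.index <= b:
                        tmp_tok = ann.tokens[a].text.lower()
                        break
        fv.set("semantic", f"sem.{tag}_tmp_role_token", tmp_tok)
        syn = NULL
        if synsets and head is not None:
            syn = synsets.get(head.lemma.lower(), NULL)
        fv.set("semantic", f"sem.{tag}_synset", syn)

    # -- section creation time ----------------------------------------------
    s1, s2 = _sct_relation(e1, doc), _sct_relation(e2, doc)
    fv.set("sct", "sct.e1", s1)
    fv.set("sct", "sct.e2", s2)
    fv.set("sct", "sct.differ", int(s1 != s2))
    return fv


# ---------------------------------------------------------------------------
# pairwise features
# ---------------------------------------------------------------------------

def _root_path_collect(entity, ann: DocumentAnnotations, want: str) -> list[str]:
    """Walk from the entity's minimal covering node to the tree root,
    collecting preposition lexemes (want='prep') or verb POS tags (want='verb')."""
    try:
        node = minimal_covering_node(entity, ann)
    except AlignmentError:
        return []
    out: list[str] = []
    while node is not None:
        if want == "prep" and node.label == "PP":
            leaves = node.leaves()
            out.append(ann.tokens[leaves[0].token_index].text.lower())
        if want == "verb" and node.label.startswith("VB") and node.children:
            out.append(node.label)
        node = node.parent
    return out


def extract_pairwise(pair: InstancePair, doc: ClinicalDocument, ann: DocumentAnnotations) -> FeatureVector:
    e1, e2 = doc.entity(pair.e1), doc.entity(pair.e2)
    h1, h2 = _safe_head(e1, ann), _safe_head(e2, ann)
    fv = FeatureVector()
    fv.set("pairwise", "pw.head_pair",
           f"{h1.text.lower() if h1 else NULL}_{h2.text.lower() if h2 else NULL}")

    def pp_lex(ent, mode):
        if not ann.trees:
            return NULL
        try:
            cover = minimal_covering_node(ent, ann)
        except AlignmentError:
            return NULL
        if mode == "headed":
            if cover.label == "PP":
                return ann.tokens[cover.leaves()[0].token_index].text.lower()
            return NULL
        node = cover.parent
        while node is not None:
            if node.label == "PP":
                return ann.tokens[node.leaves()[0].token_index].text.lower()
            node = node.parent
        return NULL

    fv.set("pairwise", "pw.headed_pp_pair", f"{pp_lex(e1, 'headed')}_{pp_lex(e2, 'headed')}")
    fv.set("pairwise", "pw.governed_pp_pair", f"{pp_lex(e1, 'governed')}_{pp_lex(e2, 'governed')}")
    t1 = e1.etype if _is_event(e1) else e1.ttype
    t2 = e2.etype if _is_event(e2) else e2.ttype
    m1 = e1.modality if _is_event(e1) else NULL
    m2 = e2.modality if _is_event(e2) else NULL
    fv.set("pairwise", "pw.type_modality_quad", f"{t1}_{m1}_{t2}_{m2}")
    prep_trace = "_".join(_root_path_collect(e1, ann, "prep") + _root_path_collect(e2, ann, "prep"))
    verb_trace = "_".join(_root_path_collect(e1, ann, "verb") + _root_path_collect(e2, ann, "verb"))
    fv.set("pairwise", "pw.prep_trace", prep_trace or NULL)
    fv.set("pairwise", "pw.verb_trace", verb_trace or NULL)
    return fv


# ---------------------------------------------------------------------------
# lexical-relation (thesaurus / WordNet-style) flags
# ---------------------------------------------------------------------------

def extract_lexical_relations(
    pair: InstancePair,
    doc: ClinicalDocument,
    ann: DocumentAnnotations,
    lexicon: LexicalRelationLexicon,
    prefix: str = "thes",
) -> FeatureVector:
    """8 binary flags: e1-in-e2's four lists, and e2-in-e1's four lists."""
    e1, e2 = doc.entity(pair.e1), doc.entity(pair.e2)
    h1, h2 = _safe_head(e1, ann), _safe_head(e2, ann)
    w1 = h1.text.lower() if h1 else ""
    w2 = h2.text.lower() if h2 else ""
    fv = FeatureVector()
    lists2 = lexicon.lookup(w2)
    lists1 = lexicon.lookup(w1)
    for rel in lexicon.relations:
        fv.set(prefix, f"{prefix}.e1_in_e2_{rel}", int(bool(w1) and w1 in lists2[rel]))
    for rel in lexicon.relations:
        fv.set(prefix, f"{prefix}.e2_in_e1_{rel}", int(bool(w2) and w2 in lists1[rel]))
    return fv


# ---------------------------------------------------------------------------
# predicate-argument (SRL) flags
# ---------------------------------------------------------------------------

NUMBERED_ARGS = ("A0", "A1", "A2", "A3", "A4", "A5")
MODIFIER_ARGS = ("DIR", "MNR", "TMP", "CAU")


def extract_predarg(pair: InstancePair, doc: ClinicalDocument, ann: DocumentAnnotations) -> FeatureVector:
    """One binary per (numbered argument x predicate direction) plus 8 binaries
    for the four modifier relations in both directions.  All zero without SRL."""
    e1, e2 = doc.entity(pair.e1), doc.entity(pair.e2)
    h1, h2 = _safe_head(e1, ann), _safe_head(e2, ann)
    fv = FeatureVector()
    hits: set[tuple[str, str]] = set()
    if h1 is not None and h2 is not None:
        for frame in ann.srl:
            for pred_head, arg_head, direction in ((h1, h2, "p1"), (h2, h1, "p2")):
                if frame.predicate == pred_head.index:
                    for label, a, b in frame.arguments:
                        if a <= arg_head.index <= b:
                            hits.add((direction, label))
    for label in NUMBERED_ARGS:
        fv.set("predarg", f"srl.pred_e1_arg_{label}", int(("p1", label) in hits))
        fv.set("predarg", f"srl.pred_e2_arg_{label}", int(("p2", label) in hits))
    for label in MODIFIER_ARGS:
        fv.set("predarg", f"srl.pred_e1_mod_{label}", int(("p1", label) in hits))
        fv.set("predarg", f"srl.pred_e2_mod_{label}", int(("p2", label) in hits))
    return fv


# ---------------------------------------------------------------------------
# discourse features
# ---------------------------------------------------------------------------

def _in_interval(tok: Token | None, interval: tuple[int, int]) -> bool:
    return tok is not None and interval[0] <= tok.start and tok.end <= interval[1]


def extract_discourse(pair: InstancePair, doc: ClinicalDocument, ann: DocumentAnnotations) -> FeatureVector:
    """Four categorical features: for explicit and implicit relations, the
    sense when (e1 in Arg1, e2 in Arg2) and when (e2 in Arg1, e1 in Arg2).

    An entity "is in" an argument iff its head token's span lies within the
    argument's character interval.
    """
    e1, e2 = doc.entity(pair.e1), doc.entity(pair.e2)
    h1, h2 = _safe_head(e1, ann), _safe_head(e2, ann)
    values = {"disc.explicit_e1_arg1": NULL, "disc.explicit_e2_arg1": NULL,
              "disc.implicit_e1_arg1": NULL, "disc.implicit_e2_arg1": NULL}
    for rel in ann.discourse:
        kind = rel.kind.lower()
        if _in_interval(h1, rel.arg1) and _in_interval(h2, rel.arg2):
            values[f"disc.{kind}_e1_arg1"] = rel.sense
        if _in_interval(h2, rel.arg1) and _in_interval(h1, rel.arg2):
            values[f"disc.{kind}_e2_arg1"] = rel.sense
    fv = FeatureVector()
    for name, val in values.items():
        fv.set("discourse", name, val)
    return fv


# ---------------------------------------------------------------------------
# medical semantic relation features
# ---------------------------------------------------------------------------

_MEDSEM_PAIRS = {
    frozenset({"TREATMENT", "PROBLEM"}),
    frozenset({"TEST", "PROBLEM"}),
    frozenset({"PROBLEM"}),
}


def medsem_applicable(e1, e2, ann: DocumentAnnotations, intra_sentential: bool = True) -> bool:
    if not (_is_event(e1) and _is_event(e2)):
        return False
    if frozenset({e1.etype, e2.etype}) not in _MEDSEM_PAIRS:
        return False
    if intra_sentential:
        h1, h2 = _safe_head(e1, ann), _safe_head(e2, ann)
        if h1 is None or h2 is None or h1.sent != h2.sent:
            return False
    return True


def extract_medsem(
    pair: InstancePair,
    doc: ClinicalDocument,
    ann: DocumentAnnotations,
    model,
    intra_sentential: bool = True,
) -> FeatureVector:
    """Predicted medical semantic relation label plus the classifier's reusable
    flat feature groups.  NULL for pairs outside the TREATMENT-PROBLEM /
    TEST-PROBLEM / PROBLEM-PROBLEM applicability gate.

    *model* provides ``predict_for_pair(e1, e2, doc, ann) -> (label, flat_features)``
    where flat_features may be None.
    """
    e1, e2 = doc.entity(pair.e1), doc.entity(pair.e2)
    fv = FeatureVector()
    if model is None or not medsem_applicable(e1, e2, ann, intra_sentential):
        fv.set("medsem", "medsem.label", NULL)
        return fv
    label, flat = model.predict_for_pair(e1, e2, doc, ann)
    fv.set("medsem", "medsem.label", label if label is not None else NULL)
    if flat:
        for name, value in flat.items():
            fv.set("medsem", f"medsem.{name}", value)
    return fv


# ---------------------------------------------------------------------------
# combined extraction
# ---------------------------------------------------------------------------

DEFAULT_FAMILIES = ("baseline", "pairwise", "wordnet", "thesaurus", "predarg", "discourse", "medsem")


def extract_all(
    pair: InstancePair,
    doc: ClinicalDocument,
    ann: DocumentAnnotations,
    families=DEFAULT_FAMILIES,
    thesaurus: LexicalRelationLexicon | None = None,
    wordnet: LexicalRelationLexicon | None = None,
    medsem_model=None,
    synsets: dict[str, str] | None = None,
) -> FeatureVector:
    """Extract the requested feature families for one instance.

    Pure in its inputs: identical (document, annotations, lexicons, model)
    give identical vectors.
    """
    fv = FeatureVector()
    if "baseline" in families:
        fv.update(extract_baseline(pair, doc, ann, synsets=synsets))
    if "pairwise" in families:
        fv.update(extract_pairwise(pair, doc, ann))
    if "wordnet" in families:
        fv.update(extract_lexical_relations(pair, doc, ann, wordnet or LexicalRelationLexicon.wordnet(), "wn"))
    if "thesaurus" in families:
        fv.update(extract_lexical_relations(pair, doc, ann, thesaurus or LexicalRelationLexicon.thesaurus(), "thes"))
    if "predarg" in families:
        fv.update(extract_predarg(pair, doc, ann))
    if "discourse" in families:
        fv.update(extract_discourse(pair, doc, ann))
    if "medsem" in families:
        fv.update(extract_medsem(pair, doc, ann, medsem_model))
    return fv
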