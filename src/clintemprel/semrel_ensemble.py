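"""Medical semantic-relation classification (11 classes) by a 3-classifier ensemble.

Relations hold between intra-sentence TEST/PROBLEM/TREATMENT concept pairs:
eight substantive types (TrIP, TrWP, TrCP, PIP, TeRP, TrAP, TrNAP, TeCP) and
three "no relation" types (NTrP, NTeP, NPP).  Three classifiers vote:

* a flat-feature linear SVM (37 feature groups in five categories, C=10000),
* a bank of 11 one-vs-rest SVMs over a convolution tree kernel applied to
  "simple expansion trees" (the parse fragment spanned by the shortest
  inter-entity path plus those nodes' immediate non-leaf children, C=100),
* a k-nearest-neighbor classifier over word-lemma sequences compared with
  token-level Levenshtein distance (k=200; the nearest neighbor's vote
  weighs 0.5 and each of the remaining k-1 weighs 0.5/(k-1)).

Each classifier yields an 11-element probability vector; the ensemble
combines them as ``0.4 * P_tree + 0.5 * P_flat + 0.1 * P_knn`` and predicts
the argmax class.
"""

from __future__ import annotations

import random
import re
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import SVC, LinearSVC

from .annotation_layer import DocumentAnnotations, TreeNode, head_token
from .corpus_io import ClinicalDocument, EventAnnotation
from .feature_extraction import NULL, between_tokens

__all__ = [
    "MED_REL_TYPES",
    "POSITIVE_MED_REL_TYPES",
    "SemRelInstance",
    "ProbabilityVector",
    "generate_sequence",
    "render_sequence",
    "levenshtein",
    "knn_probability_vector",
    "extract_simple_expansion_tree",
    "tree_to_tuple",
    "tree_kernel",
    "extract_flat_features",
    "EnsembleConfig",
    "SemRelEnsemble",
    "evaluate_semrel",
    "CONJUNCTION_RE",
]

MED_REL_TYPES = ("TrIP", "TrWP", "TrCP", "PIP", "TeRP", "TrAP", "TrNAP", "TeCP",
                 "NTrP", "NTeP", "NPP")
POSITIVE_MED_REL_TYPES = MED_REL_TYPES[:8]
_CLASS_INDEX = {c: i for i, c in enumerate(MED_REL_TYPES)}


@dataclass(frozen=True)
class SemRelInstance:
    """An intra-sentence TEST/PROBLEM/TREATMENT concept pair."""

    doc_id: str
    e1: str
    e2: str
    sentence: int
    label: str | None = None  # a MED_REL_TYPES name, or None when unlabeled
    assertion1: str = NULL  # assertion attribute of a PROBLEM concept
    assertion2: str = NULL


@dataclass(frozen=True)
class ProbabilityVector:
    """11 non-negative reals over MED_REL_TYPES summing to 1 (tolerance 1e-9)."""

    values: tuple[float, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(MED_REL_TYPES),):
            raise ValueError(f"probability vector must have {len(MED_REL_TYPES)} entries")
        if (v < -1e-12).any() or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must be non-negative and sum to 1, got sum {v.sum()!r}")

    @classmethod
    def from_array(cls, arr) -> "ProbabilityVector":
        return cls(tuple(float(x) for x in arr))

    @classmethod
    def delta(cls, label: str) -> "ProbabilityVector":
        v = [0.0] * len(MED_REL_TYPES)
        v[_CLASS_INDEX[label]] = 1.0
        return cls(tuple(v))

    @classmethod
    def uniform(cls) -> "ProbabilityVector":
        n = len(MED_REL_TYPES)
        return cls(tuple([1.0 / n] * n))

    def __getitem__(self, label: str) -> float:
        return self.values[_CLASS_INDEX[label]]

    def argmax(self) -> str:
        return MED_REL_TYPES[int(np.argmax(self.values))]

    @staticmethod
    def combine(weighted: list[tuple[float, "ProbabilityVector"]]) -> "ProbabilityVector":
        total = sum(w for w, _ in weighted)
        acc = np.zeros(len(MED_REL_TYPES))
        for w, pv in weighted:
            acc += (w / total) * np.asarray(pv.values)
        return ProbabilityVector.from_array(acc)


# ---------------------------------------------------------------------------
# sequence generation (five methods)
# ---------------------------------------------------------------------------

def _placeholder(entity, slot: int) -> str:
    kind = entity.etype if isinstance(entity, EventAnnotation) else entity.ttype
    return f"{kind.lower()}_e{slot}_"


def _entity_token_set(entity, ann: DocumentAnnotations) -> set[int]:
    return {t.index for t in ann.tokens_overlapping(entity.start, entity.end)}


def _chunk_types(tokens) -> list[str]:
    """Collapse BIO chunk tags into a phrase-type sequence."""
    out: list[str] = []
    for t in tokens:
        tag = t.chunk
        if tag in ("O", ""):
            continue
        typ = tag.split("-", 1)[-1]
        if tag.startswith("B") or not out or out[-1] != typ:
            out.append(typ)
    return out


def generate_sequence(method: int, inst: SemRelInstance, doc: ClinicalDocument,
                      ann: DocumentAnnotations) -> list[str]:
    """Generate the token-label sequence for one of the five representation methods.

    1. POS tags of the whole sentence;
    2. phrase-chunk types between the two concepts;
    3. word lemmas from two tokens before the first concept up to and
       including the second token after the second concept;
    4. event-type sequence of all events in the sentence;
    5. the shortest dependency path.
    Both concepts are replaced by ``<type>_e1_`` / ``<type>_e2_`` placeholders.
    """
    if method not in (1, 2, 3, 4, 5):
        raise ValueError(f"sequence generation method must be 1..5, got {method}")
    e1, e2 = doc.entity(inst.e1), doc.entity(inst.e2)
    if e1.start > e2.start:
        e1, e2 = e2, e1
    ph1, ph2 = _placeholder(e1, 1), _placeholder(e2, 2)
    set1, set2 = _entity_token_set(e1, ann), _entity_token_set(e2, ann)
    sent_tokens = ann.sentence_tokens(inst.sentence)

    def substituted(tokens, render) -> list[str]:
        out: list[str] = []
        done1 = done2 = False
        for t in tokens:
            if t.index in set1:
                if not done1:
                    out.append(ph1)
                    done1 = True
            elif t.index in set2:
                if not done2:
                    out.append(ph2)
                    done2 = True
            else:
                out.append(render(t))
        return out

    if method == 1:
        return substituted(sent_tokens, lambda t: t.pos)
    if method == 2:
        return _chunk_types(between_tokens(e1, e2, ann))
    if method == 3:
        first = min(t.index for t in ann.tokens_overlapping(e1.start, e1.end))
        last = max(t.index for t in ann.tokens_overlapping(e2.start, e2.end))
        # the context window stays within the pair's sentence
        sent_lo = sent_tokens[0].index if sent_tokens else 0
        sent_hi = sent_tokens[-1].index if sent_tokens else -1
        lo = max(sent_lo, first - 2)
        hi = min(sent_hi, last + 2)
        window = [ann.tokens[i] for i in range(lo, hi + 1)]
        return substituted(window, lambda t: t.lemma)
    if method == 4:
        sent_span = (sent_tokens[0].start, sent_tokens[-1].end) if sent_tokens else (0, 0)
        out = []
        for ev in sorted(doc.events, key=lambda e: e.start):
            if ev.start >= sent_span[0] and ev.end <= sent_span[1]:
                if ev.id == e1.id:
                    out.append(ph1)
                elif ev.id == e2.id:
                    out.append(ph2)
                else:
                    out.append(ev.etype.lower())
        return out
    return _dependency_path_sequence(e1, e2, ann, ph1, ph2)


def _dependency_path_sequence(e1, e2, ann: DocumentAnnotations, ph1: str, ph2: str) -> list[str]:
    """Shortest dependency path rendered as
    ``e1—lab1 (→|←) lab2 ... labN—e2`` where an arrow after a label is ``→``
    when that edge was traversed dependent-to-head and ``←`` otherwise."""
    try:
        h1, h2 = head_token(e1, ann), head_token(e2, ann)
    except Exception:
        return []
    import networkx as nx

    g = nx.Graph()
    for edge in ann.deps:
        g.add_edge(edge.head, edge.dep, label=edge.label, head=edge.head)
    if h1.index not in g or h2.index not in g:
        return []
    try:
        path = nx.shortest_path(g, h1.index, h2.index)
    except nx.NetworkXNoPath:
        return []
    labels: list[str] = []
    upward: list[bool] = []
    for a, b in zip(path, path[1:]):
        data = g.get_edge_data(a, b)
        labels.append(data["label"])
        upward.append(data["head"] == b)  # moving from dependent up to its head
    if not labels:
        return []
    if len(labels) == 1:
        return [f"{ph1}—{labels[0]}—{ph2}"]
    out = [f"{ph1}—{labels[0]}"]
    for i in range(1, len(labels)):
        out.append("→" if upward[i - 1] else "←")
        out.append(labels[i] if i < len(labels) - 1 else f"{labels[i]}—{ph2}")
    return out


_PUNCT_ONLY = re.compile(r"^[,.;:!?')\]]+$")


def render_sequence(seq: list[str]) -> str:
    """Join sequence elements with spaces, attaching punctuation-only elements
    to the preceding element (detokenization)."""
    out = ""
    for el in seq:
        if out and not _PUNCT_ONLY.match(el):
            out += " "
        out += el
    return out


# ---------------------------------------------------------------------------
# Levenshtein distance at token granularity
# ---------------------------------------------------------------------------

def levenshtein(a, b) -> int:
    """Minimum number of unit-cost insertions/deletions/substitutions turning
    sequence *a* into sequence *b*, at element granularity."""
    a, b = list(a), list(b)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, start=1):
        cur = [i]
        for j, y in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (x != y)))
        prev = cur
    return prev[-1]


class _LevCache:
    def __init__(self):
        self._cache: dict[tuple[tuple, tuple], int] = {}

    def __call__(self, a: tuple, b: tuple) -> int:
        key = (a, b) if a <= b else (b, a)
        if key not in self._cache:
            self._cache[key] = levenshtein(key[0], key[1])
        return self._cache[key]


def knn_probability_vector(query_seq, bank, k: int = 200, lev=None) -> ProbabilityVector:
    """Weighted vote of the k nearest neighbors by Levenshtein distance.

    *bank* is a list of (sequence, label).  The nearest neighbor's vote weighs
    0.5 and each of the remaining k-1 weighs 0.5/(k-1).  Ties are broken by
    (distance, bank index).  A bank smaller than k degrades gracefully: the
    nearest still weighs 0.5 and the remainder split 0.5 evenly.
    """
    if not bank:
        raise ValueError("empty neighbor bank")
    lev = lev or levenshtein
    q = tuple(query_seq)
    ranked = sorted(
        ((lev(q, tuple(seq)), idx, label) for idx, (seq, label) in enumerate(bank)),
        key=lambda t: (t[0], t[1]),
    )
    if len(ranked) < k:
        warnings.warn(f"neighbor bank has {len(ranked)} < k={k} instances; rescaling weights")
    neighbors = ranked[:k]
    votes = np.zeros(len(MED_REL_TYPES))
    votes[_CLASS_INDEX[neighbors[0][2]]] += 0.5
    rest = neighbors[1:]
    if rest:
        w = 0.5 / len(rest)
        for _, _, label in rest:
            votes[_CLASS_INDEX[label]] += w
    else:
        votes[_CLASS_INDEX[neighbors[0][2]]] += 0.5
    return ProbabilityVector.from_array(votes)


# ---------------------------------------------------------------------------
# simple expansion trees and the convolution tree kernel
# ---------------------------------------------------------------------------

def _covering_node(entity, ann: DocumentAnnotations) -> TreeNode:
    from .annotation_layer import minimal_covering_node

    return minimal_covering_node(entity, ann)


def extract_simple_expansion_tree(
    e1, e2, ann: DocumentAnnotations, attribute_at: str = "covering"
) -> TreeNode:
    """Extract the simple expansion tree for an intra-sentence entity pair.

    Retains (i) every node on the shortest tree path between the two entities
    and (ii) each such node's immediate non-leaf children, and nothing else.
    The node spanning each entity (``attribute_at="covering"``) or each
    entity's parent node (``attribute_at="parent"``) has its label replaced by
    the entity's type attribute.
    """
    from .annotation_layer import AlignmentError, _path_to_root

    n1, n2 = _covering_node(e1, ann), _covering_node(e2, ann)
    h1, h2 = head_token(e1, ann), head_token(e2, ann)
    if h1.sent != h2.sent:
        raise AlignmentError("simple expansion tree undefined across sentences")

    up1, up2 = _path_to_root(n1), _path_to_root(n2)
    anc2 = {id(n): i for i, n in enumerate(up2)}
    path_nodes: list[TreeNode] = []
    for i, n in enumerate(up1):
        if id(n) in anc2:
            path_nodes = up1[: i + 1] + up2[: anc2[id(n)]][::-1]
            break
    path_ids = {id(n) for n in path_nodes}
    keep: dict[int, TreeNode] = {id(n): n for n in path_nodes}
    for n in path_nodes:
        for child in n.children:
            if not child.is_leaf:
                keep[id(child)] = child

    relabel: dict[int, str] = {}
    for ent, node in ((e1, n1), (e2, n2)):
        attr = ent.etype if isinstance(ent, EventAnnotation) else ent.ttype
        target = node.parent if attribute_at == "parent" and node.parent is not None else node
        relabel[id(target)] = attr

    def build(node: TreeNode) -> TreeNode:
        new = TreeNode(label=relabel.get(id(node), node.label))
        for child in node.children:
            if id(child) in keep:
                sub = build(child)
                sub.parent = new
                new.children.append(sub)
        return new

    # root of the extracted tree: the unique retained node without a retained parent
    candidates = [n for n in keep.values() if n.parent is None or id(n.parent) not in keep]
    top = candidates[0]
    for c in candidates[1:]:  # pragma: no cover - defensive
        if c in _path_to_root(top):
            top = c
    return build(top)


def tree_to_tuple(node: TreeNode) -> tuple:
    return (node.label, tuple(tree_to_tuple(c) for c in node.children))


def tree_kernel(t1: TreeNode, t2: TreeNode, lam: float = 0.4) -> float:
    """Convolution (shared-subtree-counting) kernel with decay ``lam``.

    Counts common fragments where every fragment node keeps either all or
    none of its children; a fragment with m expanded nodes weighs lam**m, and
    matching leaf labels contribute lam each.  Symmetric, and K(t, t) > 0.
    """
    nodes1, nodes2 = t1.descendants(), t2.descendants()

    def production(n: TreeNode):
        return (n.label, tuple(c.label for c in n.children))

    memo: dict[tuple[int, int], float] = {}

    def delta(a: TreeNode, b: TreeNode) -> float:
        if a.is_leaf or b.is_leaf:
            return 0.0
        if production(a) != production(b):
            return 0.0
        key = (id(a), id(b))
        if key not in memo:
            prod = lam
            for ca, cb in zip(a.children, b.children):
                prod *= 1.0 + delta(ca, cb)
            memo[key] = prod
        return memo[key]

    total = 0.0
    for a in nodes1:
        for b in nodes2:
            if a.is_leaf and b.is_leaf:
                if a.label == b.label:
                    total += lam
            else:
                total += delta(a, b)
    return total


class _TreeKernelCache:
    """Kernel values memoized on canonical tree structure."""

    def __init__(self, lam: float):
        self.lam = lam
        self._trees: dict[tuple, TreeNode] = {}
        self._vals: dict[tuple[tuple, tuple], float] = {}

    def canonical(self, t: TreeNode) -> tuple:
        key = tree_to_tuple(t)
        self._trees.setdefault(key, t)
        return key

    def value(self, k1: tuple, k2: tuple) -> float:
        key = (k1, k2) if k1 <= k2 else (k2, k1)
        if key not in self._vals:
            self._vals[key] = tree_kernel(self._trees[key[0]], self._trees[key[1]], self.lam)
        return self._vals[key]

    def gram(self, keys_a: list[tuple], keys_b: list[tuple]) -> np.ndarray:
        return np.array([[self.value(a, b) for b in keys_b] for a in keys_a])


# ---------------------------------------------------------------------------
# flat features (37 groups, five categories)
# ---------------------------------------------------------------------------

CONJUNCTION_RE = re.compile(r"(,\s*\w[\w\s']*)+(,\s*)?\b(and|or)\b|\b\w+\s*,\s*\w+", re.IGNORECASE)


def extract_flat_features(
    inst: SemRelInstance,
    doc: ClinicalDocument,
    ann: DocumentAnnotations,
    neighbor_banks: dict[int, list[tuple[tuple, str]]] | None = None,
    k: int = 200,
    sentiment: dict[str, str] | None = None,
    wiki_links: dict[str, set[str]] | None = None,
    wiki_categories: dict[str, str] | None = None,
    lev=None,
) -> dict[str, object]:
    """The flat feature groups: Context (13), Similarity (5 x 11 per-class
    neighbor percentages), Single-concept (11), Wikipedia (6), Vicinity (2).

    Absent resources (banks, sentiment lexicon, offline Wikipedia link table)
    yield NULL/zero features, never errors.
    """
    e1, e2 = doc.entity(inst.e1), doc.entity(inst.e2)
    if e1.start > e2.start:
        e1, e2 = e2, e1
    f: dict[str, object] = {}
    bt = between_tokens(e1, e2, ann)

    # Context
    for t in bt:
        f[f"ctx.between_word:{t.text.lower()}"] = 1
        f[f"ctx.between_pos:{t.pos}"] = 1
    for g in zip(bt, bt[1:]):
        f[f"ctx.between_bigram:{g[0].text.lower()}_{g[1].text.lower()}"] = 1
    f["ctx.between_string"] = "_".join(t.text.lower() for t in bt) or NULL
    f["ctx.between_chunks"] = "_".join(_chunk_types(bt)) or NULL
    ev_between = [ev.etype for ev in sorted(doc.events, key=lambda e: e.start)
                  if ev.start >= e1.end and ev.end <= e2.start]
    f["ctx.between_concept_types"] = "_".join(ev_between) or NULL
    toks1 = ann.tokens_overlapping(e1.start, e1.end)
    toks2 = ann.tokens_overlapping(e2.start, e2.end)
    f["ctx.word_before_e1"] = (
        ann.tokens[toks1[0].index - 1].text.lower() if toks1 and toks1[0].index > 0 else NULL)
    f["ctx.word_before_e2"] = (
        ann.tokens[toks2[0].index - 1].text.lower() if toks2 and toks2[0].index > 0 else NULL)
    for tag, toks in (("e1", toks1), ("e2", toks2)):
        if toks:
            for i in range(toks[-1].index + 1, min(toks[-1].index + 4, len(ann.tokens))):
                f[f"ctx.after_{tag}:{ann.tokens[i].text.lower()}"] = 1
    for tag, ent in (("e1", e1), ("e2", e2)):
        preds = set()
        try:
            h = head_token(ent, ann)
            for frame in ann.srl:
                for label, a, b in frame.arguments:
                    if a <= h.index <= b:
                        preds.add(ann.tokens[frame.predicate].lemma)
        except Exception:
            pass
        f[f"ctx.predicates_{tag}"] = "_".join(sorted(preds)) or NULL
    between_str = " ".join(t.text for t in bt)
    f["ctx.conjunction"] = int(bool(CONJUNCTION_RE.search(between_str)))

    # Similarity: per generation method, percentage of the k nearest
    # neighbors in each of the 11 classes
    if neighbor_banks:
        for method, bank in neighbor_banks.items():
            seq = tuple(generate_sequence(method, inst, doc, ann))
            pv = _neighbor_percentages(seq, bank, k, lev=lev)
            for cls, frac in zip(MED_REL_TYPES, pv):
                f[f"sim.m{method}.pct_{cls}"] = frac

    # Single concept
    for tag, ent, toks in (("e1", e1, toks1), ("e2", e2, toks2)):
        for t in toks:
            f[f"con.{tag}_lemma:{t.lemma}"] = 1
        try:
            h = head_token(ent, ann)
            for t in toks:
                if t.index != h.index:
                    f[f"con.{tag}_desc:{t.text.lower()}"] = 1
        except Exception:
            h = None
        f[f"con.{tag}_type"] = ent.etype
        f[f"con.{tag}_string"] = ent.text.lower()
        sent_cat = NULL
        if sentiment and h is not None:
            sent_cat = sentiment.get(h.lemma.lower(), NULL)
        f[f"con.{tag}_sentiment"] = sent_cat
    f["con.assertion_pair"] = f"{inst.assertion1}_{inst.assertion2}"

    # Wikipedia (offline link table)
    def article(ent):
        if not wiki_links and not wiki_categories:
            return None
        titles = set(wiki_links or ()) | set(wiki_categories or ())
        low = ent.text.lower()
        for title in titles:
            if title.lower() in low:
                return title
        return None

    a1, a2 = article(e1), article(e2)
    f["wiki.no_article"] = int(a1 is None and a2 is None)
    links = wiki_links or {}
    l12 = int(a1 is not None and a2 is not None and a2 in links.get(a1, set()))
    l21 = int(a1 is not None and a2 is not None and a1 in links.get(a2, set()))
    f["wiki.link_e1_e2"] = l12
    f["wiki.link_e2_e1"] = l21
    f["wiki.links_both"] = int(l12 and l21)
    f["wiki.links_absent"] = int(a1 is not None and a2 is not None and not (l12 or l21))
    cats = wiki_categories or {}
    f["wiki.same_category"] = int(
        a1 is not None and a2 is not None and a1 in cats and cats.get(a1) == cats.get(a2))

    # Vicinity
    events_sorted = sorted(doc.events, key=lambda e: e.start)
    prev_type = next_type = NULL
    for ev in events_sorted:
        if ev.end <= e1.start:
            prev_type = ev.etype
        if ev.start >= e2.end and next_type is NULL:
            next_type = ev.etype
    f["vic.e1_prev"] = f"{e1.etype}_{prev_type}"
    f["vic.e2_next"] = f"{e2.etype}_{next_type}"
    return f


def _neighbor_percentages(seq: tuple, bank, k: int, lev=None) -> list[float]:
    lev = lev or levenshtein
    ranked = sorted(
        ((lev(seq, tuple(s)), idx, label) for idx, (s, label) in enumerate(bank)),
        key=lambda t: (t[0], t[1]),
    )[:k]
    counts = np.zeros(len(MED_REL_TYPES))
    for _, _, label in ranked:
        counts[_CLASS_INDEX[label]] += 1
    return list(counts / counts.sum()) if counts.sum() else [0.0] * len(MED_REL_TYPES)


# ---------------------------------------------------------------------------
# classifiers and the ensemble
# ---------------------------------------------------------------------------

def _scale_confidences(conf: np.ndarray) -> np.ndarray:
    """Min-max scale to [0,1] then normalize to sum 1; all-equal -> uniform."""
    lo, hi = conf.min(), conf.max()
    if hi - lo < 1e-12:
        return np.full_like(conf, 1.0 / len(conf))
    scaled = (conf - lo) / (hi - lo)
    return scaled / scaled.sum()


@dataclass
class EnsembleConfig:
    weights: tuple[float, float, float] = (0.4, 0.5, 0.1)  # (tree, flat, knn)
    c_flat: float = 10_000.0
    c_tree: float = 100.0
    tree_lambda: float = 0.4
    k: int = 200
    downsample_factor: float = 2.0  # each no-relation class capped at factor x largest positive class
    seed: int = 0
    tree_label_by_max_confidence: bool = False  # alternative tree-bank labeling rule


def downsample_no_relation(instances: list[SemRelInstance], factor: float, seed: int) -> list[SemRelInstance]:
    """Randomly reduce each of the three no-relation classes to
    ``factor`` times the largest positive class size (seeded)."""
    by_class: dict[str, list[SemRelInstance]] = {}
    for inst in instances:
        by_class.setdefault(inst.label, []).append(inst)
    largest_pos = max((len(v) for c, v in by_class.items() if c in POSITIVE_MED_REL_TYPES), default=0)
    cap = max(1, int(round(factor * largest_pos)))
    rng = random.Random(seed)
    out: list[SemRelInstance] = []
    for cls, members in by_class.items():
        if cls in POSITIVE_MED_REL_TYPES or len(members) <= cap:
            out.extend(members)
        else:
            out.extend(rng.sample(members, cap))
    out.sort(key=lambda i: (i.doc_id, i.e1, i.e2))
    return out


class SemRelEnsemble:
    """Trainable 3-classifier ensemble; see the module docstring."""

    def __init__(self, config: EnsembleConfig | None = None):
        self.config = config or EnsembleConfig()
        self._vec: DictVectorizer | None = None
        self._flat: LinearSVC | None = None
        self._flat_classes: list[str] = []
        self._tree_models: dict[str, SVC] = {}
        self._tree_train_keys: list[tuple] = []
        self._kernel = _TreeKernelCache(self.config.tree_lambda)
        self._knn_bank: list[tuple[tuple, str]] = []
        self._banks: dict[int, list[tuple[tuple, str]]] = {}
        self._lev = _LevCache()
        self._resources: dict = {}

    # -- featurization ------------------------------------------------------
    def _flat_dict(self, inst, doc, ann) -> dict:
        return extract_flat_features(
            inst, doc, ann, neighbor_banks=self._banks, k=self.config.k,
            lev=self._lev, **self._resources,
        )

    def _tree_key(self, inst, doc, ann) -> tuple | None:
        e1, e2 = doc.entity(inst.e1), doc.entity(inst.e2)
        try:
            t = extract_simple_expansion_tree(e1, e2, ann)
        except Exception:
            return None
        return self._kernel.canonical(t)

    # -- training -----------------------------------------------------------
    def fit(self, instances: list[SemRelInstance], corpus: dict, resources: dict | None = None):
        """Train all three classifiers.

        *corpus* maps doc_id -> (ClinicalDocument, DocumentAnnotations);
        *resources* may carry sentiment / wiki_links / wiki_categories tables.
        """
        cfg = self.config
        self._resources = resources or {}
        train = downsample_no_relation(
            [i for i in instances if i.label is not None], cfg.downsample_factor, cfg.seed)

        def da(inst):
            return corpus[inst.doc_id]

        # sequence banks (methods 1..5) for similarity features and k-NN
        self._banks = {m: [] for m in range(1, 6)}
        for inst in train:
            doc, ann = da(inst)
            for m in range(1, 6):
                self._banks[m].append((tuple(generate_sequence(m, inst, doc, ann)), inst.label))
        self._knn_bank = self._banks[3]

        # flat classifier
        X = [self._flat_dict(inst, *da(inst)) for inst in train]
        y = [inst.label for inst in train]
        self._vec = DictVectorizer(sparse=True)
        Xv = _csr32(self._vec.fit_transform([_stringify(d) for d in X]))
        self._flat = LinearSVC(C=cfg.c_flat, random_state=cfg.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._flat.fit(Xv, y)
        self._flat_classes = list(self._flat.classes_)
        missing = set(MED_REL_TYPES) - set(self._flat_classes)
        if missing:
            warnings.warn(f"classes absent from flat training data get probability 0: {sorted(missing)}")

        # tree-kernel bank: one binary one-vs-rest SVM per class
        keyed = [(self._tree_key(inst, *da(inst)), inst.label) for inst in train]
        keyed = [(k, lbl) for k, lbl in keyed if k is not None]
        self._tree_train_keys = [k for k, _ in keyed]
        tree_labels = [lbl for _, lbl in keyed]
        if self._tree_train_keys:
            gram = self._kernel.gram(self._tree_train_keys, self._tree_train_keys)
            for cls in MED_REL_TYPES:
                yb = np.array([1 if lbl == cls else -1 for lbl in tree_labels])
                if len(set(yb)) < 2:
                    continue
                model = SVC(kernel="precomputed", C=cfg.c_tree)
                model.fit(gram, yb)
                self._tree_models[cls] = model
        return self

    # -- per-classifier probability vectors ---------------------------------
    def flat_vector(self, inst, doc, ann) -> ProbabilityVector:
        Xv = _csr32(self._vec.transform([_stringify(self._flat_dict(inst, doc, ann))]))
        decision = self._flat.decision_function(Xv)
        decision = np.atleast_2d(decision)
        if decision.shape[1] == 1:  # binary underneath
            decision = np.hstack([-decision, decision])
        conf = np.full(len(MED_REL_TYPES), -np.inf)
        for j, cls in enumerate(self._flat_classes):
            conf[_CLASS_INDEX[cls]] = decision[0, j]
        present = conf > -np.inf
        scaled = np.zeros(len(MED_REL_TYPES))
        scaled[present] = _scale_confidences(conf[present])
        return ProbabilityVector.from_array(scaled)

    def tree_vector(self, inst, doc, ann) -> ProbabilityVector:
        key = self._tree_key(inst, doc, ann)
        if key is None or not self._tree_models:
            return ProbabilityVector.uniform()
        row = self._kernel.gram([key], self._tree_train_keys)
        conf = np.zeros(len(MED_REL_TYPES))
        seen = np.zeros(len(MED_REL_TYPES), dtype=bool)
        for cls, model in self._tree_models.items():
            conf[_CLASS_INDEX[cls]] = model.decision_function(row)[0]
            seen[_CLASS_INDEX[cls]] = True
        scaled = np.zeros(len(MED_REL_TYPES))
        if seen.any():
            scaled[seen] = _scale_confidences(conf[seen])
        return ProbabilityVector.from_array(scaled)

    def tree_label(self, inst, doc, ann) -> str:
        """The tree bank's own decision: class of the binary classifier with the
        maximum signed distance."""
        key = self._tree_key(inst, doc, ann)
        if key is None or not self._tree_models:
            return MED_REL_TYPES[0]
        row = self._kernel.gram([key], self._tree_train_keys)
        best, best_val = None, -np.inf
        for cls, model in self._tree_models.items():
            val = model.decision_function(row)[0]
            if val > best_val:
                best, best_val = cls, val
        return best

    def knn_vector(self, inst, doc, ann) -> ProbabilityVector:
        seq = tuple(generate_sequence(3, inst, doc, ann))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return knn_probability_vector(seq, self._knn_bank, k=self.config.k, lev=self._lev)

    # -- ensemble prediction -------------------------------------------------
    def combined_vector(self, inst, doc, ann) -> ProbabilityVector:
        wt, wf, wk = self.config.weights
        parts = []
        if wt:
            parts.append((wt, self.tree_vector(inst, doc, ann)))
        if wf:
            parts.append((wf, self.flat_vector(inst, doc, ann)))
        if wk:
            parts.append((wk, self.knn_vector(inst, doc, ann)))
        return ProbabilityVector.combine(parts)

    def predict(self, inst: SemRelInstance, doc, ann) -> tuple[str, ProbabilityVector]:
        pv = self.combined_vector(inst, doc, ann)
        wt, wf, wk = self.config.weights
        if self.config.tree_label_by_max_confidence and wt and not (wf or wk):
            return self.tree_label(inst, doc, ann), pv
        return pv.argmax(), pv

    def predict_for_pair(self, e1, e2, doc, ann):
        """Adapter for temporal-relation feature extraction: predicted label +
        reusable flat feature groups for an entity pair."""
        try:
            sent = head_token(e1, ann).sent
        except Exception:
            return None, None
        inst = SemRelInstance(doc_id=doc.id, e1=e1.id, e2=e2.id, sentence=sent)
        label, _ = self.predict(inst, doc, ann)
        flat = self._flat_dict(inst, doc, ann)
        return label, flat


def _stringify(d: dict) -> dict:
    """DictVectorizer one-hot encodes string values and passes numbers through."""
    return {k: (v if isinstance(v, (int, float)) else str(v)) for k, v in d.items()}


def _csr32(X):
    """Downcast sparse indices to int32 (required by liblinear/libsvm)."""
    X = X.tocsr()
    X.indices = X.indices.astype(np.int32)
    X.indptr = X.indptr.astype(np.int32)
    return X


def train_and_classify_ensemble(train, test, corpus, config: EnsembleConfig | None = None):
    """Convenience wrapper: fit on *train*, return (labels, vectors) for *test*."""
    ens = SemRelEnsemble(config)
    ens.fit(train, corpus)
    labels, vectors = [], []
    for inst in test:
        doc, ann = corpus[inst.doc_id]
        lbl, pv = ens.predict(inst, doc, ann)
        labels.append(lbl)
        vectors.append(pv)
    return ens, labels, vectors


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_semrel(pred: list[str], gold: list[str]) -> dict[str, float]:
    """Micro P/R/F over the eight substantive classes; correct no-relation
    predictions are not counted."""
    if len(pred) != len(gold):
        raise ValueError("prediction and gold lists must align")
    pos = set(POSITIVE_MED_REL_TYPES)
    tp = sum(1 for p, g in zip(pred, gold) if p == g and g in pos)
    pred_pos = sum(1 for p in pred if p in pos)
    gold_pos = sum(1 for g in gold if g in pos)
    if gold_pos == 0:
        warnings.warn("no positive-class gold instances; micro F reported as 0")
        return {"precision": 0.0, "recall": 0.0, "f1": 0.0}
    p = tp / pred_pos if pred_pos else 0.0
    r = tp / gold_pos
    f = 2 * p * r / (p + r) if p + r else 0.0
    return {"precision": p, "recall": r, "f1": f}
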