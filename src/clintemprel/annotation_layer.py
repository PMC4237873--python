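"""Linguistic annotation layers consumed by the feature extractors.

Parsers, taggers, semantic role labelers and discourse parsers are consumed
as *data*: a JSON sidecar file per document carries tokens (with lemma, POS,
BIO chunk tag and character span), one Penn-bracketed constituency tree per
sentence, dependency edges, PropBank-style SRL frames, and PDTB-style
discourse relations.  A degraded-mode fallback annotator lets the system run
(with NULL-valued syntax/semantics features) when no sidecar exists.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .corpus_io import ClinicalDocument, EventAnnotation, IntegrityError, TimeAnnotation

__all__ = [
    "Token",
    "TreeNode",
    "DependencyEdge",
    "SRLFrame",
    "DiscourseRelation",
    "DocumentAnnotations",
    "parse_penn_tree",
    "format_penn_tree",
    "load_annotations",
    "annotations_from_dict",
    "annotations_to_dict",
    "fallback_annotate",
    "head_token",
    "tree_path",
    "dominates",
    "AlignmentError",
]


class AlignmentError(ValueError):
    """An annotation layer does not align with the document tokenization/text."""


@dataclass(frozen=True)
class Token:
    index: int  # 0-based, contiguous over the document
    text: str
    lemma: str
    pos: str  # Penn Treebank tag (opaque string)
    chunk: str  # BIO phrase-chunk tag, e.g. B-NP
    start: int
    end: int
    sent: int  # sentence index

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class TreeNode:
    """Node of a constituency tree.  Leaves carry the token index."""

    label: str
    children: list["TreeNode"] = field(default_factory=list)
    token_index: int | None = None  # set on leaves only
    parent: "TreeNode | None" = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def descendants(self) -> list["TreeNode"]:
        out = [self]
        for c in self.children:
            out.extend(c.descendants())
        return out

    def token_range(self) -> tuple[int, int]:
        """(min, max) token index covered; leaves must be indexed."""
        idx = [lf.token_index for lf in self.leaves() if lf.token_index is not None]
        return (min(idx), max(idx))


def parse_penn_tree(s: str) -> TreeNode:
    """Parse a Penn-bracketed tree string, e.g. ``(S (NP (PRP She)) (VP (VBD fell)))``.

    Leaf terminals become leaf nodes whose label is the word; token indices are
    assigned left to right starting at 0 (re-based by the caller to document
    token indices).
    """
    tokens = re.findall(r"\(|\)|[^\s()]+", s)
    pos = 0
    leaf_counter = [0]

    def parse_node() -> TreeNode:
        nonlocal pos
        if tokens[pos] != "(":
            raise ValueError(f"expected '(' at position {pos} of tree {s!r}")
        pos += 1
        label = tokens[pos]
        pos += 1
        node = TreeNode(label=label)
        while pos < len(tokens) and tokens[pos] != ")":
            if tokens[pos] == "(":
                child = parse_node()
            else:
                child = TreeNode(label=tokens[pos], token_index=leaf_counter[0])
                leaf_counter[0] += 1
                pos += 1
            child.parent = node
            node.children.append(child)
        if pos >= len(tokens):
            raise ValueError(f"unbalanced brackets in tree {s!r}")
        pos += 1  # ')'
        return node

    root = parse_node()
    if pos != len(tokens):
        raise ValueError(f"trailing material in tree {s!r}")
    return root


def format_penn_tree(node: TreeNode) -> str:
    if node.is_leaf:
        return node.label
    inner = " ".join(format_penn_tree(c) for c in node.children)
    return f"({node.label} {inner})"


@dataclass(frozen=True)
class DependencyEdge:
    head: int  # token index of the governor
    dep: int  # token index of the dependent
    label: str


@dataclass(frozen=True)
class SRLFrame:
    """A PropBank-style predicate with labeled argument token intervals."""

    predicate: int  # token index
    arguments: tuple[tuple[str, int, int], ...]  # (label, start_tok, end_tok) inclusive


@dataclass(frozen=True)
class DiscourseRelation:
    """PDTB-style (Arg1, sense, Arg2) triple over character intervals."""

    arg1: tuple[int, int]
    arg2: tuple[int, int]
    sense: str
    kind: str  # EXPLICIT | IMPLICIT
    connective: str | None = None


@dataclass
class DocumentAnnotations:
    tokens: list[Token]
    trees: list[TreeNode]  # one per sentence; leaves re-based to document token indices
    deps: list[DependencyEdge] = field(default_factory=list)
    srl: list[SRLFrame] = field(default_factory=list)
    discourse: list[DiscourseRelation] = field(default_factory=list)

    def sentence_tokens(self, sent: int) -> list[Token]:
        return [t for t in self.tokens if t.sent == sent]

    def tokens_overlapping(self, start: int, end: int) -> list[Token]:
        return [t for t in self.tokens if t.start < end and t.end > start]

    def n_sentences(self) -> int:
        return max((t.sent for t in self.tokens), default=-1) + 1

    def validate(self, doc: ClinicalDocument) -> None:
        for i, tok in enumerate(self.tokens):
            if tok.index != i:
                raise AlignmentError(f"token indices not contiguous at position {i}")
            if doc.text[tok.start : tok.end] != tok.text:
                raise AlignmentError(
                    f"token {i} text {tok.text!r} != document substring "
                    f"{doc.text[tok.start:tok.end]!r}"
                )
        n_sent = self.n_sentences()
        if self.trees and len(self.trees) != n_sent:
            raise AlignmentError(f"{len(self.trees)} trees for {n_sent} sentences")
        for s, tree in enumerate(self.trees):
            sent_toks = self.sentence_tokens(s)
            leaves = tree.leaves()
            if len(leaves) != len(sent_toks):
                raise AlignmentError(f"tree {s} has {len(leaves)} leaves for {len(sent_toks)} tokens")
            for leaf, tok in zip(leaves, sent_toks):
                if leaf.token_index != tok.index:
                    raise AlignmentError(f"tree {s} leaf misaligned at token {tok.index}")
        n_tok = len(self.tokens)
        head_of: dict[int, int] = {}
        for e in self.deps:
            if e.head == e.dep:
                raise AlignmentError(f"dependency self-loop at token {e.dep}")
            if not (0 <= e.head < n_tok and 0 <= e.dep < n_tok):
                raise AlignmentError(f"dependency edge {e} out of range")
            if e.dep in head_of and head_of[e.dep] != e.head:
                raise AlignmentError(f"token {e.dep} has two heads")
            head_of[e.dep] = e.head
        for fr in self.srl:
            psent = self.tokens[fr.predicate].sent
            for label, a, b in fr.arguments:
                if not (0 <= a <= b < n_tok):
                    raise AlignmentError(f"SRL argument {label} interval ({a},{b}) out of range")
                if self.tokens[a].sent != psent or self.tokens[b].sent != psent:
                    raise AlignmentError(f"SRL argument {label} crosses the predicate's sentence")
        for rel in self.discourse:
            if rel.kind == "IMPLICIT" and rel.connective:
                raise AlignmentError("implicit discourse relation carries a connective")


# ---------------------------------------------------------------------------
# sidecar I/O
# ---------------------------------------------------------------------------

def annotations_from_dict(data: dict, doc: ClinicalDocument) -> DocumentAnnotations:
    tokens = [
        Token(
            index=t["i"], text=t["text"], lemma=t.get("lemma", t["text"].lower()),
            pos=t.get("pos", "NN"), chunk=t.get("chunk", "O"),
            start=t["start"], end=t["end"], sent=t.get("sent", 0),
        )
        for t in sorted(data.get("tokens", []), key=lambda t: t["i"])
    ]
    trees = []
    offset = 0
    by_sent: dict[int, int] = {}
    for t in tokens:
        by_sent.setdefault(t.sent, t.index)
    for s, tree_str in enumerate(data.get("trees", [])):
        tree = parse_penn_tree(tree_str)
        offset = by_sent.get(s, 0)
        for leaf in tree.leaves():
            leaf.token_index = leaf.token_index + offset
        trees.append(tree)
    deps = [DependencyEdge(head=d["head"], dep=d["dep"], label=d["label"]) for d in data.get("deps", [])]
    srl = [
        SRLFrame(
            predicate=f["pred"],
            arguments=tuple((a["label"], a["start_tok"], a["end_tok"]) for a in f.get("args", [])),
        )
        for f in data.get("srl", [])
    ]
    disc = [
        DiscourseRelation(
            arg1=tuple(r["a1"]), arg2=tuple(r["a2"]), sense=r["sense"],
            kind=r.get("kind", "EXPLICIT"), connective=r.get("conn"),
        )
        for r in data.get("discourse", [])
    ]
    ann = DocumentAnnotations(tokens=tokens, trees=trees, deps=deps, srl=srl, discourse=disc)
    ann.validate(doc)
    return ann


def annotations_to_dict(ann: DocumentAnnotations) -> dict:
    trees_out = []
    for s, tree in enumerate(ann.trees):
        # serialize with words, not document indices; leaf order carries alignment
        trees_out.append(format_penn_tree(tree))
    return {
        "tokens": [
            {"i": t.index, "text": t.text, "lemma": t.lemma, "pos": t.pos,
             "chunk": t.chunk, "start": t.start, "end": t.end, "sent": t.sent}
            for t in ann.tokens
        ],
        "trees": trees_out,
        "deps": [{"head": e.head, "dep": e.dep, "label": e.label} for e in ann.deps],
        "srl": [
            {"pred": f.predicate,
             "args": [{"label": lbl, "start_tok": a, "end_tok": b} for lbl, a, b in f.arguments]}
            for f in ann.srl
        ],
        "discourse": [
            {"a1": list(r.arg1), "a2": list(r.arg2), "sense": r.sense,
             "kind": r.kind, "conn": r.connective}
            for r in ann.discourse
        ],
    }


def load_annotations(path, doc: ClinicalDocument) -> DocumentAnnotations:
    """Load and validate a sidecar annotation file against its document."""
    with open(path) as fh:
        data = json.load(fh)
    return annotations_from_dict(data, doc)


# ---------------------------------------------------------------------------
# fallback annotator (degraded mode; low-fidelity by design)
# ---------------------------------------------------------------------------

_SUFFIX_POS = [
    ("ing", "VBG"), ("ed", "VBD"), ("ly", "RB"), ("ion", "NN"), ("ous", "JJ"),
    ("ive", "JJ"), ("al", "JJ"), ("s", "NNS"),
]


def _heuristic_pos(word: str) -> str:
    if not word[:1].isalnum():
        return word
    if word[:1].isdigit():
        return "CD"
    low = word.lower()
    if low in {"the", "a", "an"}:
        return "DT"
    if low in {"in", "on", "of", "to", "with", "for", "at", "by", "from", "since"}:
        return "IN"
    if low in {"and", "or", "but"}:
        return "CC"
    if low in {"he", "she", "it", "they", "her", "his", "pt", "patient"}:
        return "PRP"
    if low in {"was", "is", "are", "were", "been", "be", "has", "had", "have"}:
        return "VBD"
    for suf, tag in _SUFFIX_POS:
        if low.endswith(suf) and len(low) > len(suf) + 1:
            return tag
    return "NN"


def fallback_annotate(doc: ClinicalDocument) -> DocumentAnnotations:
    """Whitespace/punctuation tokenizer with suffix-rule POS and flat trees.

    Dependency, SRL and discourse layers are empty, so downstream features
    built on them take NULL.  Marked low-fidelity: intended only to keep the
    pipeline runnable without a sidecar.
    """
    tokens: list[Token] = []
    sent = 0
    for m in re.finditer(r"\w+|[^\w\s]", doc.text):
        word = m.group(0)
        tokens.append(
            Token(index=len(tokens), text=word, lemma=word.lower(), pos=_heuristic_pos(word),
                  chunk="O", start=m.start(), end=m.end(), sent=sent)
        )
        if word in {".", "!", "?"} or word == "\n":
            sent += 1
    trees: list[TreeNode] = []
    for s in range(max((t.sent for t in tokens), default=-1) + 1):
        sent_toks = [t for t in tokens if t.sent == s]
        root = TreeNode(label="S")
        for t in sent_toks:
            pre = TreeNode(label=t.pos, parent=root)
            leaf = TreeNode(label=t.text, token_index=t.index, parent=pre)
            pre.children.append(leaf)
            root.children.append(pre)
        trees.append(root)
    ann = DocumentAnnotations(tokens=tokens, trees=trees)
    ann.validate(doc)
    return ann


# ---------------------------------------------------------------------------
# entity-level helpers
# ---------------------------------------------------------------------------

def head_token(entity: EventAnnotation | TimeAnnotation, ann: DocumentAnnotations) -> Token:
    """Deterministic head: rightmost noun/verb/adjective token in the entity span,
    else the last overlapping token."""
    toks = ann.tokens_overlapping(entity.start, entity.end)
    if not toks:
        raise AlignmentError(f"entity {entity.id!r} overlaps no token")
    for t in reversed(toks):
        if t.pos[:1] in {"N", "V", "J"}:
            return t
    return toks[-1]


def _covering_leaf(tok: Token, ann: DocumentAnnotations) -> TreeNode:
    tree = ann.trees[tok.sent]
    for leaf in tree.leaves():
        if leaf.token_index == tok.index:
            return leaf
    raise AlignmentError(f"token {tok.index} not found in its sentence tree")


def _path_to_root(node: TreeNode) -> list[TreeNode]:
    out = [node]
    while out[-1].parent is not None:
        out.append(out[-1].parent)
    return out


def tree_path(e1, e2, ann: DocumentAnnotations) -> list[str]:
    """Label sequence from e1's preterminal through the lowest common ancestor
    to e2's preterminal (endpoints included).

    Raises :class:`AlignmentError` for cross-sentence pairs; callers turn that
    into a NULL feature.
    """
    t1, t2 = head_token(e1, ann), head_token(e2, ann)
    if t1.sent != t2.sent:
        raise AlignmentError("tree path undefined across sentences")
    n1 = _covering_leaf(t1, ann).parent or _covering_leaf(t1, ann)
    n2 = _covering_leaf(t2, ann).parent or _covering_leaf(t2, ann)
    up1 = _path_to_root(n1)
    up2 = _path_to_root(n2)
    anc2 = {id(n): i for i, n in enumerate(up2)}
    for i, n in enumerate(up1):
        if id(n) in anc2:
            j = anc2[id(n)]
            left = [x.label for x in up1[: i + 1]]
            right = [x.label for x in up2[:j][::-1]]
            return left + right
    raise AlignmentError("nodes share no ancestor")  # pragma: no cover - single-rooted trees


def minimal_covering_node(entity, ann: DocumentAnnotations) -> TreeNode:
    """Smallest non-leaf tree node whose leaves cover every token of the
    entity span (the preterminal, for a single-token entity)."""
    toks = ann.tokens_overlapping(entity.start, entity.end)
    if not toks:
        raise AlignmentError(f"entity {entity.id!r} overlaps no token")
    lo, hi = toks[0].index, toks[-1].index
    leaf = _covering_leaf(toks[0], ann)
    node = leaf.parent or leaf
    while node.parent is not None:
        a, b = node.token_range()
        if a <= lo and hi <= b:
            return node
        node = node.parent
    return node


def dominates(e1, e2, ann: DocumentAnnotations) -> bool:
    """True when the minimal node covering e1 also covers e2's head token."""
    t1, t2 = head_token(e1, ann), head_token(e2, ann)
    if t1.sent != t2.sent:
        return False
    node = minimal_covering_node(e1, ann)
    return any(lf.token_index == t2.index for lf in node.leaves())
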