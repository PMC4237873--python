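"""Scoring: 12-class micro/macro F and the closure-based 3-class scorer.

For fine-grained scoring, a predicted link matches a gold link when the
endpoint pair agrees either directly or with both order and label inverted
(the two readings assert the same relation).  Micro F is instance-weighted;
macro F is the unweighted mean of per-class F over the 12 fine types.

The shared-task-style 3-class scorer verifies links against the *temporal
closure* of the other side: system precision counts system links found in
the closure of the gold links, recall counts gold links found in the
closure of the system links.  Closure here augments inverses (Before'/After'
flip; Overlap' is symmetric) and composes Before' (hence After') chains
transitively, iterated to a fixed point -- a deliberately sound (not
complete) rule table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .corpus_io import (
    BroadRelation,
    FineRelation,
    TemporalLink,
    invert_relation,
    map_12_to_3,
)

__all__ = ["ScoreReport", "score_12class", "ClosureGraph", "close", "i2b2_score", "to_broad_assertions"]


@dataclass
class ScoreReport:
    micro_p: float
    micro_r: float
    micro_f: float
    macro_f: float
    per_class: dict[str, dict[str, float]]
    confusion: dict[tuple[str, str], int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "micro_p": self.micro_p, "micro_r": self.micro_r, "micro_f": self.micro_f,
            "macro_f": self.macro_f,
            "per_class": self.per_class,
        }


def _canonical(link: TemporalLink) -> tuple[tuple[str, str], str]:
    """Canonical (pair, fine label): endpoints sorted lexicographically, label
    inverted when the order was swapped."""
    rel = FineRelation(str(link.relation))
    if link.source <= link.target:
        return (link.source, link.target), rel.value
    return (link.target, link.source), invert_relation(rel).value


def _f1(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r else 0.0


def score_12class(pred: list[TemporalLink], gold: list[TemporalLink]) -> ScoreReport:
    """Micro/macro F over the 12 fine relation types.

    Duplicate predictions for one pair are scored once (logged).  A class with
    no gold and no predicted instances contributes F=0 to the macro mean with
    a warning.
    """
    gold_map: dict[tuple[str, str], str] = {}
    for link in gold:
        pair, label = _canonical(link)
        gold_map[pair] = label
    pred_map: dict[tuple[str, str], str] = {}
    for link in pred:
        pair, label = _canonical(link)
        if pair in pred_map:
            warnings.warn(f"duplicate prediction for pair {pair}; scored once")
            continue
        pred_map[pair] = label

    tp = sum(1 for pair, label in pred_map.items() if gold_map.get(pair) == label)
    micro_p = tp / len(pred_map) if pred_map else 0.0
    micro_r = tp / len(gold_map) if gold_map else 0.0
    micro_f = _f1(micro_p, micro_r)

    confusion: dict[tuple[str, str], int] = {}
    for pair, plabel in pred_map.items():
        glabel = gold_map.get(pair, "NO_RELATION")
        confusion[(glabel, plabel)] = confusion.get((glabel, plabel), 0) + 1
    for pair, glabel in gold_map.items():
        if pair not in pred_map:
            confusion[(glabel, "NO_RELATION")] = confusion.get((glabel, "NO_RELATION"), 0) + 1

    per_class: dict[str, dict[str, float]] = {}
    fsum = 0.0
    for cls in FineRelation:
        c = cls.value
        tp_c = sum(1 for pair, lbl in pred_map.items() if lbl == c and gold_map.get(pair) == c)
        np_c = sum(1 for lbl in pred_map.values() if lbl == c)
        ng_c = sum(1 for lbl in gold_map.values() if lbl == c)
        if np_c == 0 and ng_c == 0:
            warnings.warn(f"class {c} absent from predictions and gold; contributes 0 to macro F")
            per_class[c] = {"precision": 0.0, "recall": 0.0, "f1": 0.0}
            continue
        p = tp_c / np_c if np_c else 0.0
        r = tp_c / ng_c if ng_c else 0.0
        f = _f1(p, r)
        per_class[c] = {"precision": p, "recall": r, "f1": f}
        fsum += f
    macro_f = fsum / len(FineRelation)
    return ScoreReport(micro_p=micro_p, micro_r=micro_r, micro_f=micro_f,
                       macro_f=macro_f, per_class=per_class, confusion=confusion)


# ---------------------------------------------------------------------------
# temporal closure and 3-class scoring
# ---------------------------------------------------------------------------

Assertion = tuple[str, str, str]  # (source, target, broad relation name)


def to_broad_assertions(links: list[TemporalLink]) -> set[Assertion]:
    """Map links (fine or broad) to broad-type assertions."""
    out: set[Assertion] = set()
    for link in links:
        rel = link.relation
        if isinstance(rel, BroadRelation):
            out.add((link.source, link.target, rel.name))
        else:
            mapped = map_12_to_3(link)
            out.add((mapped.source, mapped.target, mapped.relation.name))
    return out


@dataclass
class ClosureGraph:
    """Fixed point of a broad-assertion set under inversion and transitivity."""

    assertions: frozenset[Assertion]

    def __contains__(self, assertion: Assertion) -> bool:
        return assertion in self.assertions


def close(seed: set[Assertion]) -> ClosureGraph:
    """Deductive completion: Before'/After' inverses, Overlap' symmetry, and
    transitive Before' (hence After') chains, iterated to a fixed point.

    Contradictory seed assertions are retained: the scorer is containment
    based, not consistency based.
    """
    s: set[Assertion] = set(seed)
    changed = True
    while changed:
        changed = False
        new: set[Assertion] = set()
        before = {(a, b) for a, b, r in s if r == "BEFORE3"}
        for a, b, r in s:
            if r == "BEFORE3":
                new.add((b, a, "AFTER3"))
            elif r == "AFTER3":
                new.add((b, a, "BEFORE3"))
            elif r == "OVERLAP3":
                new.add((b, a, "OVERLAP3"))
        by_source: dict[str, list[str]] = {}
        for a, b in before:
            by_source.setdefault(a, []).append(b)
        for a, b in before:
            for c in by_source.get(b, ()):
                if c != a:
                    new.add((a, c, "BEFORE3"))
        if not new <= s:
            s |= new
            changed = True
    return ClosureGraph(assertions=frozenset(s))


def i2b2_score(system: list[TemporalLink], gold: list[TemporalLink]) -> dict[str, float]:
    """Closure-verified precision / recall / F over broad types.

    P = |system links verified in the gold closure| / |system links|;
    R = |gold links verified in the system closure| / |gold links|.
    """
    sys_a = to_broad_assertions(system)
    gold_a = to_broad_assertions(gold)
    if not sys_a:
        warnings.warn("empty system output; precision reported as 0")
        return {"precision": 0.0, "recall": 0.0, "f1": 0.0}
    gold_closure = close(gold_a)
    sys_closure = close(sys_a)
    p = sum(1 for a in sys_a if a in gold_closure) / len(sys_a)
    r = (sum(1 for a in gold_a if a in sys_closure) / len(gold_a)) if gold_a else 0.0
    return {"precision": p, "recall": r, "f1": _f1(p, r)}
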