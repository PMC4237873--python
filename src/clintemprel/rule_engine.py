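"""Hand-crafted decision rules for temporal relation classification.

A rule pairs a side-effect-free condition over extracted features with an
output relation type (or HAS_RELATION / NO_RELATION for identification
rules).  Rules are scored on labeled training instances -- accuracy =
correct applications / applications -- ordered by decreasing accuracy, and
applied first-match.  They can also be folded back into the learner as
categorical features whose value is the rule's predicted label (NULL when
the rule does not fire).

Condition DSL (one rule per line, ``#`` comments)::

    rule_id := test (& test)* ( | ... ) => LABEL
    test    := NAME = VALUE | NAME != VALUE | NAME ~ REGEX | !test | ( expr )

NAME is a feature name (e.g. ``medsem.label``, ``dist.same_sentence``) or
one of the pseudo-features ``between`` (the inter-entity token string),
``scheme``, ``e1.type``, ``e2.type``, ``e1.head``, ``e2.head``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

from .feature_extraction import NULL, FeatureVector

__all__ = [
    "NONE_APPLICABLE",
    "HAS_RELATION",
    "Rule",
    "RuleSet",
    "parse_rule",
    "parse_rules",
    "load_rules",
    "measure_accuracy",
    "order_and_filter",
    "apply_first",
    "rules_as_features",
    "STARTER_RULES",
    "RuleError",
]

NONE_APPLICABLE = "NONE_APPLICABLE"
HAS_RELATION = "HAS_RELATION"


class RuleError(ValueError):
    """Malformed rule text or a condition that cannot be evaluated."""


# -- condition AST ----------------------------------------------------------

@dataclass(frozen=True)
class _Test:
    name: str
    op: str  # '=', '!=', '~'
    value: str

    def evaluate(self, lookup) -> bool:
        raw = lookup(self.name)
        raw = NULL if raw is None else str(raw)
        if self.op == "=":
            return raw == self.value
        if self.op == "!=":
            return raw != self.value
        if self.op == "~":
            return re.search(self.value, raw) is not None
        raise RuleError(f"unknown operator {self.op!r}")  # pragma: no cover


@dataclass(frozen=True)
class _Not:
    child: object

    def evaluate(self, lookup) -> bool:
        return not self.child.evaluate(lookup)


@dataclass(frozen=True)
class _And:
    children: tuple

    def evaluate(self, lookup) -> bool:
        return all(c.evaluate(lookup) for c in self.children)


@dataclass(frozen=True)
class _Or:
    children: tuple

    def evaluate(self, lookup) -> bool:
        return any(c.evaluate(lookup) for c in self.children)


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lpar>\() | (?P<rpar>\)) | (?P<not>!(?!=)) | (?P<and>&) | (?P<or>\|)
      | (?P<op>!=|=|~)
      | (?P<quoted>"[^"]*")
      | (?P<atom>[^\s()&|!=~"]+)
    )""",
    re.VERBOSE,
)


def _tokenize(s: str) -> list[tuple[str, str]]:
    out, pos = [], 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if not m or m.end() == pos:
            raise RuleError(f"cannot tokenize condition at {s[pos:]!r}")
        pos = m.end()
        for kind, val in m.groupdict().items():
            if val is not None:
                out.append((kind, val.strip('"') if kind == "quoted" else val))
                break
    return out


def _parse_condition(s: str):
    tokens = _tokenize(s)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None)

    def expr():
        nonlocal pos
        terms = [term()]
        while peek()[0] == "or":
            pos += 1
            terms.append(term())
        return terms[0] if len(terms) == 1 else _Or(tuple(terms))

    def term():
        nonlocal pos
        factors = [factor()]
        while peek()[0] == "and":
            pos += 1
            factors.append(factor())
        return factors[0] if len(factors) == 1 else _And(tuple(factors))

    def factor():
        nonlocal pos
        kind, val = peek()
        if kind == "not":
            pos += 1
            return _Not(factor())
        if kind == "lpar":
            pos += 1
            node = expr()
            if peek()[0] != "rpar":
                raise RuleError(f"missing ')' in condition {s!r}")
            pos += 1
            return node
        if kind in ("atom", "quoted"):
            name = val
            pos += 1
            opk, opv = peek()
            if opk != "op":
                raise RuleError(f"expected operator after {name!r} in {s!r}")
            pos += 1
            vk, vv = peek()
            if vk not in ("atom", "quoted"):
                raise RuleError(f"expected value after operator in {s!r}")
            pos += 1
            return _Test(name=name, op=opv, value=vv)
        raise RuleError(f"unexpected token in condition {s!r}")

    node = expr()
    if pos != len(tokens):
        raise RuleError(f"trailing tokens in condition {s!r}")
    return node


@dataclass(frozen=True)
class Rule:
    id: str
    condition: object  # AST with .evaluate(lookup)
    output: str  # fine relation name, HAS_RELATION or NO_RELATION
    source: str = ""
    accuracy: float = 0.0
    applied_count: int = 0

    def applies(self, lookup) -> bool:
        try:
            return bool(self.condition.evaluate(lookup))
        except re.error as exc:
            raise RuleError(f"rule {self.id!r}: bad regex: {exc}") from exc


@dataclass
class RuleSet:
    """Rules sorted by decreasing measured accuracy (ties: applied_count, id)."""

    rules: list[Rule] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rules)

    def __len__(self):
        return len(self.rules)


def parse_rule(line: str) -> Rule:
    m = re.match(r"^\s*(?P<id>[\w.-]+)\s*:=\s*(?P<cond>.+?)\s*=>\s*(?P<label>[\w]+)\s*$", line)
    if not m:
        raise RuleError(f"malformed rule line: {line!r}")
    return Rule(id=m.group("id"), condition=_parse_condition(m.group("cond")),
                output=m.group("label"), source=line.strip())


def parse_rules(text: str) -> list[Rule]:
    rules = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rules.append(parse_rule(line))
    return rules


def load_rules(path) -> list[Rule]:
    with open(path) as fh:
        return parse_rules(fh.read())


# ---------------------------------------------------------------------------
# scoring, ordering, application
# ---------------------------------------------------------------------------

def feature_lookup(fv: FeatureVector, pair=None, doc=None, ann=None):
    """Build the name -> value lookup a rule condition is evaluated against."""
    extras: dict[str, str] = {}
    if pair is not None and doc is not None and ann is not None:
        from .feature_extraction import between_tokens
        from .annotation_layer import head_token
        from .corpus_io import EventAnnotation

        e1, e2 = doc.entity(pair.e1), doc.entity(pair.e2)
        extras["between"] = " ".join(t.text.lower() for t in between_tokens(e1, e2, ann))
        extras["scheme"] = pair.scheme
        for tag, ent in (("e1", e1), ("e2", e2)):
            extras[f"{tag}.type"] = ent.etype if isinstance(ent, EventAnnotation) else ent.ttype
            try:
                extras[f"{tag}.head"] = head_token(ent, ann).text.lower()
            except Exception:
                extras[f"{tag}.head"] = NULL

    def lookup(name: str):
        if name in extras:
            return extras[name]
        return fv.features.get(name, NULL)

    return lookup


def measure_accuracy(rule: Rule, labeled_instances) -> Rule:
    """Score one rule on (lookup, gold_label) pairs.

    accuracy = correct applications / applications; a rule that never applies
    gets accuracy 0 with applied_count 0.  A rule whose condition errors is
    flagged invalid (accuracy -1) and excluded downstream with a warning.
    """
    applied = correct = 0
    for lookup, gold in labeled_instances:
        try:
            fires = rule.applies(lookup)
        except RuleError as exc:
            warnings.warn(f"rule {rule.id!r} invalid and excluded: {exc}")
            return replace(rule, accuracy=-1.0, applied_count=0)
        if fires:
            applied += 1
            if rule.output == gold:
                correct += 1
    acc = correct / applied if applied else 0.0
    return replace(rule, accuracy=acc, applied_count=applied)


def order_and_filter(rules: list[Rule], min_accuracy: float = 0.0) -> RuleSet:
    """Sort by decreasing accuracy (ties: higher applied_count, then id) and
    drop rules under the accuracy threshold (and invalid rules)."""
    kept = [r for r in rules if r.accuracy >= 0 and (min_accuracy <= 0 or r.accuracy >= min_accuracy)]
    kept.sort(key=lambda r: (-r.accuracy, -r.applied_count, r.id))
    return RuleSet(rules=kept)


def apply_first(ruleset: RuleSet, lookup) -> str:
    """Output of the first applicable rule, or NONE_APPLICABLE."""
    for rule in ruleset:
        if rule.applies(lookup):
            return rule.output
    return NONE_APPLICABLE


def rules_as_features(rules, lookup) -> FeatureVector:
    """One categorical feature per rule (ALL rules, regardless of accuracy):
    the rule's predicted label, or NULL when it does not fire."""
    fv = FeatureVector()
    for rule in rules:
        value = rule.output if rule.applies(lookup) else NULL
        fv.set("rules", f"rule.{rule.id}", value)
    return fv


# ---------------------------------------------------------------------------
# starter ruleset
# ---------------------------------------------------------------------------

#: Hand-written rules encoding the motivating feature patterns: antonymous
#: clauses joined by "but" are asynchronous; an entity in a predicate's A4
#: (destination) argument starts there; a RESTATEMENT between same-type
#: PROBLEM sentences overlaps; "thereafter" (ASYNCHRONOUS sense) orders the
#: arguments; medical relations TrIP/TeCP/PIP/TeRP carry characteristic
#: temporal types; unrelated comma-series PROBLEMs overlap.
STARTER_RULES = """
# lexical-relation rules
r_antonym_but := (thes.e1_in_e2_antonyms = 1 | thes.e2_in_e1_antonyms = 1) & between ~ \\bbut\\b & dist.same_sentence = 1 => BEFORE
# predicate-argument rules
r_srl_a4 := srl.pred_e1_arg_A4 = 1 => BEGINS
# discourse rules
r_restatement := disc.implicit_e1_arg1 = RESTATEMENT & ent.type_pair = PROBLEM_PROBLEM => OVERLAP
r_thereafter := disc.explicit_e1_arg1 = ASYNCHRONOUS => BEFORE
# medical semantic relation rules
r_trip := medsem.label = TrIP => ENDED_BY
r_tecp := medsem.label = TeCP => OVERLAP_AFTER
r_pip := medsem.label = PIP => SIMULTANEOUS
r_terp_due := medsem.label = TeRP & between ~ due\\s+to => OVERLAP_AFTER
r_terp := medsem.label = TeRP => OVERLAP_AFTER
r_npp_series := medsem.label = NPP & between = , => OVERLAP
# event-time anchoring
r_on_date := scheme = ET_INTRA & ent.e2_type = DATE & between ~ \\bon$ => SIMULTANEOUS
r_evidential := e1.head = complained & ent.e2_type = PROBLEM & dist.same_sentence = 1 => OVERLAP_AFTER
"""

#: Negative identification rule: a cross-sentence pair with no discourse
#: relation and non-matching strings is very unlikely to be linked.
STARTER_NEGATIVE_RULES = """
n_cross_sentence := dist.same_sentence = 0 & disc.explicit_e1_arg1 = NULL & disc.implicit_e1_arg1 = NULL & disc.explicit_e2_arg1 = NULL & disc.implicit_e2_arg1 = NULL & lex.same_string = 0 => NO_RELATION
"""


def starter_rules() -> list[Rule]:
    return parse_rules(STARTER_RULES)


def starter_negative_rules() -> list[Rule]:
    return parse_rules(STARTER_NEGATIVE_RULES)
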