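"""Seeded generator of synthetic discharge-summary fixtures.

Every template plants a sentence pattern with annotated entities, a gold
temporal link, where applicable a medical semantic-relation label, and a
hand-crafted sidecar recipe (POS tags, constituency tree, dependencies, SRL
frames, discourse relations) consistent with the pattern.  Templates mirror
the motivating constructions the system targets -- event/time anchoring
("discharge ... on postoperative day 3"), antonymous clauses joined by
"but", SRL destination arguments ("discharged to rehab"), implicit
RESTATEMENT and explicit "thereafter" discourse relations, comma-separated
problem series, and treatment/test-problem patterns (TrIP, PIP, TeCP, TeRP
and friends).

All text is synthetic; regeneration from (seed, mix, counts) is
deterministic.  Optional label noise replaces a seeded fraction of gold
fine types with uniformly random different ones, recording each flip in the
corpus manifest.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace

from .annotation_layer import DocumentAnnotations, annotations_from_dict, annotations_to_dict
from .corpus_io import (
    ClinicalDocument,
    EventAnnotation,
    FineRelation,
    Section,
    SectionTime,
    TemporalLink,
    TimeAnnotation,
    write_i2b2_xml,
)
from .feature_extraction import LexicalRelationLexicon
from .semrel_ensemble import SemRelInstance

__all__ = [
    "TemplateInstance",
    "TEMPLATES",
    "DEFAULT_MIX",
    "SEMREL_MIX",
    "FixtureCorpus",
    "generate_corpus",
    "plant_noise",
    "GoldSemrelModel",
    "fixture_thesaurus",
    "fixture_wordnet",
    "write_corpus",
]


# token spec: (text, lemma, pos, chunk)
def _tok(text, pos, lemma=None, chunk="O"):
    return (text, lemma if lemma is not None else text.lower(), pos, chunk)


@dataclass
class TemplateInstance:
    template_id: str
    sentences: list  # list[list[token spec]]
    trees: list  # one Penn bracket string per sentence
    entities: list  # dicts: slot, kind(EVENT|TIMEX), type, sent, lo, hi (template-local token idx)
    gold: tuple  # (slot_a, slot_b, fine label) in text order
    semrel: tuple | None = None  # (slot_a, slot_b, label, assertion1, assertion2)
    deps: list = field(default_factory=list)  # (head, dep, label), template-local indices
    srl: list = field(default_factory=list)  # (pred, [(label, lo, hi)])
    discourse: list = field(default_factory=list)  # (arg1_sent, arg2_sent, sense, kind, conn)


def _ev(slot, etype, sent, lo, hi, polarity="POS", modality="FACTUAL"):
    return {"slot": slot, "kind": "EVENT", "type": etype, "sent": sent, "lo": lo, "hi": hi,
            "polarity": polarity, "modality": modality}


def _tx(slot, ttype, sent, lo, hi, value=""):
    return {"slot": slot, "kind": "TIMEX", "type": ttype, "sent": sent, "lo": lo, "hi": hi,
            "value": value}


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def _t_discharge(rng: random.Random) -> TemplateInstance:
    day = rng.choice(["3", "4", "5", "6"])
    toks = [_tok("He", "PRP", chunk="B-NP"), _tok("was", "VBD", "be", "B-VP"),
            _tok("ready", "JJ", chunk="B-ADJP"), _tok("for", "IN", chunk="B-PP"),
            _tok("discharge", "NN", chunk="B-NP"), _tok("home", "NN", chunk="I-NP"),
            _tok("on", "IN", chunk="B-PP"), _tok("postoperative", "JJ", chunk="B-NP"),
            _tok("day", "NN", chunk="I-NP"), _tok(day, "CD", day, "I-NP"), _tok(".", ".")]
    tree = (f"(S (NP (PRP He)) (VP (VBD was) (ADJP (JJ ready)) (PP (IN for) "
            f"(NP (NN discharge) (NN home))) (PP (IN on) (NP (JJ postoperative) "
            f"(NN day) (CD {day})))) (. .))")
    return TemplateInstance(
        template_id="discharge", sentences=[toks], trees=[tree],
        entities=[_ev("a", "OCCURRENCE", 0, 4, 4),
                  _tx("b", "DATE", 0, 7, 9, value=f"POD{day}")],
        gold=("a", "b", "SIMULTANEOUS"),
        deps=[(1, 0, "nsubj"), (1, 2, "acomp"), (2, 3, "prep"), (3, 4, "pobj"),
              (4, 5, "nn"), (1, 6, "prep"), (6, 8, "pobj"), (8, 7, "amod"), (8, 9, "num")],
    )


def _t_complained(rng: random.Random) -> TemplateInstance:
    prob = rng.choice([("fever", "fever"), ("rash", "rash"), ("cough", "cough")])
    toks = [_tok("She", "PRP", chunk="B-NP"), _tok("has", "VBZ", "have", "B-VP"),
            _tok("not", "RB", chunk="I-VP"), _tok("complained", "VBN", "complain", "I-VP"),
            _tok("of", "IN", chunk="B-PP"), _tok("any", "DT", chunk="B-NP"),
            _tok(prob[0], "NN", prob[1], "I-NP"), _tok(".", ".")]
    tree = (f"(S (NP (PRP She)) (VP (VBZ has) (RB not) (VP (VBN complained) "
            f"(PP (IN of) (NP (DT any) (NN {prob[0]}))))) (. .))")
    return TemplateInstance(
        template_id="complained", sentences=[toks], trees=[tree],
        entities=[_ev("a", "EVIDENTIAL", 0, 3, 3, polarity="NEG"),
                  _ev("b", "PROBLEM", 0, 6, 6, polarity="NEG")],
        gold=("a", "b", "OVERLAP_AFTER"),
        deps=[(3, 0, "nsubj"), (3, 1, "aux"), (3, 2, "neg"), (3, 4, "prep"), (6, 5, "det"),
              (4, 6, "pobj")],
    )


_ANTONYM_PAIRS = [("elevated", "down"), ("high", "low"), ("increased", "decreased")]


def _t_antonym(rng: random.Random) -> TemplateInstance:
    up, dn = rng.choice(_ANTONYM_PAIRS)
    toks = [_tok("Her", "PRP$", chunk="B-NP"), _tok("amylase", "NN", chunk="I-NP"),
            _tok("was", "VBD", "be", "B-VP"), _tok("mildly", "RB", chunk="B-ADJP"),
            _tok(up, "JJ", up, "I-ADJP"), _tok("but", "CC"),
            _tok("has", "VBZ", "have", "B-VP"), _tok("been", "VBN", "be", "I-VP"),
            _tok(dn, "RB", dn, "B-ADVP"), _tok("since", "IN", chunk="B-PP"),
            _tok("then", "NN", chunk="B-NP"), _tok(".", ".")]
    tree = (f"(S (NP (PRP$ Her) (NN amylase)) (VP (VP (VBD was) (ADJP (RB mildly) "
            f"(JJ {up}))) (CC but) (VP (VBZ has) (VP (VBN been) (ADVP (RB {dn})) "
            f"(PP (IN since) (NP (NN then)))))) (. .))")
    return TemplateInstance(
        template_id="antonym", sentences=[toks], trees=[tree],
        entities=[_ev("a", "PROBLEM", 0, 3, 4), _ev("b", "PROBLEM", 0, 8, 8)],
        gold=("a", "b", "BEFORE"),
        semrel=("a", "b", "NPP", "present", "present"),
        deps=[(4, 1, "nsubj"), (4, 2, "cop"), (4, 3, "advmod"), (1, 0, "poss"),
              (4, 8, "conj"), (8, 6, "aux"), (8, 7, "cop"), (8, 9, "prep"), (9, 10, "pobj")],
    )


def _t_rehab(rng: random.Random) -> TemplateInstance:
    dept = rng.choice(["rehab", "radiology"])
    toks = [_tok("She", "PRP", chunk="B-NP"), _tok("was", "VBD", "be", "B-VP"),
            _tok("discharged", "VBN", "discharge", "I-VP"), _tok("to", "TO", chunk="B-PP"),
            _tok(dept, "NN", dept, "B-NP"), _tok(".", ".")]
    tree = (f"(S (NP (PRP She)) (VP (VBD was) (VP (VBN discharged) (PP (TO to) "
            f"(NP (NN {dept}))))) (. .))")
    return TemplateInstance(
        template_id="rehab", sentences=[toks], trees=[tree],
        entities=[_ev("a", "OCCURRENCE", 0, 2, 2), _ev("b", "CLINICAL_DEPT", 0, 4, 4)],
        gold=("a", "b", "BEGINS"),
        deps=[(2, 0, "nsubjpass"), (2, 1, "auxpass"), (2, 3, "prep"), (3, 4, "pobj")],
        srl=[(2, [("A1", 0, 0), ("A4", 4, 4)])],
    )


def _t_resolved(rng: random.Random) -> TemplateInstance:
    drug = rng.choice(["NTG", "morphine", "Tylenol"])
    prob = rng.choice(["pain", "nausea"])
    toks = [_tok("With", "IN", chunk="B-PP"), _tok(drug, "NN", drug.lower(), "B-NP"),
            _tok(",", ","), _tok("the", "DT", chunk="B-NP"), _tok("patient", "NN", chunk="I-NP"),
            _tok("'s", "POS", "'s", "I-NP"), _tok(prob, "NN", prob, "I-NP"),
            _tok("resolved", "VBD", "resolve", "B-VP"), _tok(".", ".")]
    tree = (f"(S (PP (IN With) (NP (NN {drug}))) (, ,) (NP (DT the) (NN patient) "
            f"(POS 's) (NN {prob})) (VP (VBD resolved)) (. .))")
    return TemplateInstance(
        template_id="resolved", sentences=[toks], trees=[tree],
        entities=[_ev("a", "TREATMENT", 0, 1, 1), _ev("b", "PROBLEM", 0, 6, 6)],
        gold=("a", "b", "ENDED_BY"),
        semrel=("a", "b", "TrIP", "NULL", "present"),
        deps=[(7, 0, "prep"), (0, 1, "pobj"), (7, 6, "nsubj"), (6, 3, "det"), (6, 4, "nn"),
              (6, 5, "possessive")],
        srl=[(7, [("A1", 3, 6), ("MNR", 0, 1)])],
    )


def _t_restatement(rng: random.Random) -> TemplateInstance:
    prob = rng.choice(["sepsis", "infection"])
    s0 = [_tok("Hypotension", "NN", chunk="B-NP"), _tok("was", "VBD", "be", "B-VP"),
          _tok("noted", "VBN", "note", "I-VP"), _tok("on", "IN", chunk="B-PP"),
          _tok("the", "DT", chunk="B-NP"), _tok("referral", "NN", chunk="I-NP"),
          _tok("form", "NN", chunk="I-NP"), _tok(".", ".")]
    s1 = [_tok("Initially", "RB", "initially", "B-ADVP"), _tok("there", "EX", chunk="B-NP"),
          _tok("was", "VBD", "be", "B-VP"), _tok("concern", "NN", chunk="B-NP"),
          _tok("for", "IN", chunk="B-PP"), _tok(prob, "NN", prob, "B-NP"), _tok(".", ".")]
    t0 = ("(S (NP (NN Hypotension)) (VP (VBD was) (VP (VBN noted) (PP (IN on) "
          "(NP (DT the) (NN referral) (NN form))))) (. .))")
    t1 = (f"(S (ADVP (RB Initially)) (NP (EX there)) (VP (VBD was) (NP (NN concern) "
          f"(PP (IN for) (NP (NN {prob}))))) (. .))")
    return TemplateInstance(
        template_id="restatement", sentences=[s0, s1], trees=[t0, t1],
        entities=[_ev("a", "PROBLEM", 0, 0, 0), _ev("b", "PROBLEM", 1, 13, 13, modality="POSSIBLE")],
        gold=("a", "b", "OVERLAP"),
        deps=[(2, 0, "nsubjpass"), (2, 1, "auxpass"), (2, 3, "prep"), (3, 6, "pobj"),
              (6, 4, "det"), (6, 5, "nn"),
              (10, 8, "advmod"), (10, 9, "expl"), (10, 11, "nsubj"), (11, 12, "prep"),
              (12, 13, "pobj")],
        discourse=[(0, 1, "RESTATEMENT", "IMPLICIT", None)],
    )


def _t_thereafter(rng: random.Random) -> TemplateInstance:
    s0 = [_tok("The", "DT", chunk="B-NP"), _tok("operation", "NN", chunk="I-NP"),
          _tok("was", "VBD", "be", "B-VP"), _tok("performed", "VBN", "perform", "I-VP"),
          _tok("at", "IN", chunk="B-PP"), _tok("that", "DT", chunk="B-NP"),
          _tok("time", "NN", chunk="I-NP"), _tok(".", ".")]
    s1 = [_tok("The", "DT", chunk="B-NP"), _tok("patient", "NN", chunk="I-NP"),
          _tok("thereafter", "RB", chunk="B-ADVP"), _tok("had", "VBD", "have", "B-VP"),
          _tok("a", "DT", chunk="B-NP"), _tok("benign", "JJ", chunk="I-NP"),
          _tok("convalescence", "NN", chunk="I-NP"), _tok(".", ".")]
    t0 = ("(S (NP (DT The) (NN operation)) (VP (VBD was) (VP (VBN performed) "
          "(PP (IN at) (NP (DT that) (NN time))))) (. .))")
    t1 = ("(S (NP (DT The) (NN patient)) (ADVP (RB thereafter)) (VP (VBD had) "
          "(NP (DT a) (JJ benign) (NN convalescence))) (. .))")
    return TemplateInstance(
        template_id="thereafter", sentences=[s0, s1], trees=[t0, t1],
        entities=[_ev("a", "TREATMENT", 0, 1, 1), _ev("b", "OCCURRENCE", 1, 14, 14)],
        gold=("a", "b", "BEFORE"),
        deps=[(3, 1, "nsubjpass"), (1, 0, "det"), (3, 2, "auxpass"), (3, 4, "prep"),
              (4, 6, "pobj"), (6, 5, "det"),
              (11, 9, "nsubj"), (9, 8, "det"), (11, 10, "advmod"), (11, 14, "dobj"),
              (14, 12, "det"), (14, 13, "amod")],
        discourse=[(0, 1, "ASYNCHRONOUS", "EXPLICIT", "thereafter")],
    )


def _t_series(rng: random.Random) -> TemplateInstance:
    p1, p2, p3 = rng.choice([("fever", "leukocytosis", "azotemia"),
                             ("chills", "bacteremia", "hypoxia")])
    toks = [_tok("The", "DT", chunk="B-NP"), _tok("patient", "NN", chunk="I-NP"),
            _tok("returned", "VBD", "return", "B-VP"), _tok("with", "IN", chunk="B-PP"),
            _tok(p1, "NN", p1, "B-NP"), _tok(",", ","), _tok(p2, "NN", p2, "B-NP"),
            _tok("and", "CC"), _tok(p3, "NN", p3, "B-NP"), _tok(".", ".")]
    tree = (f"(S (NP (DT The) (NN patient)) (VP (VBD returned) (PP (IN with) "
            f"(NP (NN {p1}) (, ,) (NN {p2}) (CC and) (NN {p3})))) (. .))")
    return TemplateInstance(
        template_id="series", sentences=[toks], trees=[tree],
        entities=[_ev("a", "PROBLEM", 0, 4, 4), _ev("b", "PROBLEM", 0, 6, 6),
                  _ev("c", "PROBLEM", 0, 8, 8)],
        gold=("a", "b", "OVERLAP"),
        semrel=("a", "b", "NPP", "present", "present"),
        deps=[(2, 1, "nsubj"), (1, 0, "det"), (2, 3, "prep"), (3, 4, "pobj"),
              (4, 6, "conj"), (4, 8, "conj")],
    )


def _t_pip(rng: random.Random) -> TemplateInstance:
    toks = [_tok("He", "PRP", chunk="B-NP"), _tok("had", "VBD", "have", "B-VP"),
            _tok("anterior", "JJ", chunk="B-NP"), _tok("aphasia", "NN", chunk="I-NP"),
            _tok("with", "IN", chunk="B-PP"), _tok("word", "NN", chunk="B-NP"),
            _tok("finding", "NN", chunk="I-NP"), _tok("difficulties", "NNS", "difficulty", "I-NP"),
            _tok(".", ".")]
    tree = ("(S (NP (PRP He)) (VP (VBD had) (NP (NP (JJ anterior) (NN aphasia)) "
            "(PP (IN with) (NP (NN word) (NN finding) (NNS difficulties))))) (. .))")
    return TemplateInstance(
        template_id="pip", sentences=[toks], trees=[tree],
        entities=[_ev("a", "PROBLEM", 0, 2, 3), _ev("b", "PROBLEM", 0, 5, 7)],
        gold=("a", "b", "SIMULTANEOUS"),
        semrel=("a", "b", "PIP", "present", "present"),
        deps=[(1, 0, "nsubj"), (1, 3, "dobj"), (3, 2, "amod"), (3, 4, "prep"),
              (4, 7, "pobj"), (7, 5, "nn"), (7, 6, "nn")],
    )


def _t_tecp(rng: random.Random) -> TemplateInstance:
    toks = [_tok("He", "PRP", chunk="B-NP"), _tok("had", "VBD", "have", "B-VP"),
            _tok("bone", "NN", chunk="B-NP"), _tok("marrow", "NN", chunk="I-NP"),
            _tok("biopsy", "NN", chunk="I-NP"), _tok("for", "IN", chunk="B-PP"),
            _tok("persistent", "JJ", chunk="B-NP"), _tok("pancytopenia", "NN", chunk="I-NP"),
            _tok(".", ".")]
    tree = ("(S (NP (PRP He)) (VP (VBD had) (NP (NN bone) (NN marrow) (NN biopsy)) "
            "(PP (IN for) (NP (JJ persistent) (NN pancytopenia)))) (. .))")
    return TemplateInstance(
        template_id="tecp", sentences=[toks], trees=[tree],
        entities=[_ev("a", "TEST", 0, 2, 4), _ev("b", "PROBLEM", 0, 6, 7)],
        gold=("a", "b", "OVERLAP_AFTER"),
        semrel=("a", "b", "TeCP", "NULL", "present"),
        deps=[(1, 0, "nsubj"), (1, 4, "dobj"), (4, 2, "nn"), (4, 3, "nn"),
              (1, 5, "prep"), (5, 7, "pobj"), (7, 6, "amod")],
    )


def _t_terp_due(rng: random.Random) -> TemplateInstance:
    toks = [_tok("Her", "PRP$", chunk="B-NP"), _tok("creatinine", "NN", chunk="I-NP"),
            _tok("continued", "VBD", "continue", "B-VP"), _tok("to", "TO", chunk="I-VP"),
            _tok("increase", "VB", chunk="I-VP"), _tok("due", "IN", chunk="B-PP"),
            _tok("to", "IN", chunk="I-PP"), _tok("her", "PRP$", chunk="B-NP"),
            _tok("worsening", "JJ", "worsen", "I-NP"), _tok("liver", "NN", chunk="I-NP"),
            _tok("failure", "NN", chunk="I-NP"), _tok(".", ".")]
    tree = ("(S (NP (PRP$ Her) (NN creatinine)) (VP (VBD continued) (S (VP (TO to) "
            "(VP (VB increase)))) (PP (IN due) (IN to) (NP (PRP$ her) (JJ worsening) "
            "(NN liver) (NN failure)))) (. .))")
    return TemplateInstance(
        template_id="terp_due", sentences=[toks], trees=[tree],
        entities=[_ev("a", "TEST", 0, 1, 1), _ev("b", "PROBLEM", 0, 8, 10)],
        gold=("a", "b", "OVERLAP_AFTER"),
        semrel=("a", "b", "TeRP", "NULL", "present"),
        deps=[(2, 1, "nsubj"), (1, 0, "poss"), (2, 4, "xcomp"), (4, 3, "aux"),
              (2, 5, "prep"), (5, 10, "pobj"), (10, 7, "poss"), (10, 8, "amod"), (10, 9, "nn")],
    )


def _t_table5(rng: random.Random) -> TemplateInstance:
    # POS tags fixed verbatim to the reference tagging of this sentence
    # (the comma's tag is carried as an opaque string)
    toks = [_tok("Postop", "RB", "postop", "B-ADVP"), _tok(",", "VB,", ","),
            _tok("her", "PRP$", chunk="B-NP"), _tok("exam", "NN", chunk="I-NP"),
            _tok("only", "RB", chunk="B-ADVP"), _tok("improved", "VBD", "improve", "B-VP"),
            _tok("slightly", "RB", chunk="B-ADVP"), _tok("in", "IN", chunk="B-PP"),
            _tok("her", "PRP$", chunk="B-NP"), _tok("hyperreflexia", "NN", chunk="I-NP")]
    tree = ("(S (ADVP (RB Postop)) (, ,) (NP (PRP$ her) (NN exam)) (ADVP (RB only)) "
            "(VP (VBD improved) (ADVP (RB slightly)) (PP (IN in) (NP (PRP$ her) "
            "(NN hyperreflexia)))))")
    return TemplateInstance(
        template_id="table5", sentences=[toks], trees=[tree],
        entities=[_ev("a", "TEST", 0, 2, 3), _ev("b", "PROBLEM", 0, 8, 9)],
        gold=("a", "b", "OVERLAP_AFTER"),
        semrel=("a", "b", "TeRP", "NULL", "present"),
        deps=[(5, 3, "nsubj"), (3, 2, "poss"), (5, 0, "advmod"), (5, 1, "punct"),
              (5, 4, "advmod"), (5, 6, "advmod"), (5, 7, "prep"), (7, 9, "pobj"),
              (9, 8, "poss")],
    )


def _t_trwp(rng: random.Random) -> TemplateInstance:
    toks = [_tok("Zofran", "NN", "zofran", "B-NP"), _tok("was", "VBD", "be", "B-VP"),
            _tok("given", "VBN", "give", "I-VP"), _tok("but", "CC"),
            _tok("her", "PRP$", chunk="B-NP"), _tok("nausea", "NN", chunk="I-NP"),
            _tok("worsened", "VBD", "worsen", "B-VP"), _tok(".", ".")]
    tree = ("(S (S (NP (NN Zofran)) (VP (VBD was) (VP (VBN given)))) (CC but) "
            "(S (NP (PRP$ her) (NN nausea)) (VP (VBD worsened))) (. .))")
    return TemplateInstance(
        template_id="trwp", sentences=[toks], trees=[tree],
        entities=[_ev("a", "TREATMENT", 0, 0, 0), _ev("b", "PROBLEM", 0, 5, 5)],
        gold=("a", "b", "OVERLAP"),
        semrel=("a", "b", "TrWP", "NULL", "present"),
        deps=[(2, 0, "nsubjpass"), (2, 1, "auxpass"), (2, 6, "conj"), (6, 5, "nsubj"),
              (5, 4, "poss")],
    )


def _t_trcp(rng: random.Random) -> TemplateInstance:
    toks = [_tok("Transdermal", "JJ", chunk="B-NP"), _tok("nitroglycerin", "NN", chunk="I-NP"),
            _tok("caused", "VBD", "cause", "B-VP"), _tok("a", "DT", chunk="B-NP"),
            _tok("severe", "JJ", chunk="I-NP"), _tok("headache", "NN", chunk="I-NP"),
            _tok(".", ".")]
    tree = ("(S (NP (JJ Transdermal) (NN nitroglycerin)) (VP (VBD caused) (NP (DT a) "
            "(JJ severe) (NN headache))) (. .))")
    return TemplateInstance(
        template_id="trcp", sentences=[toks], trees=[tree],
        entities=[_ev("a", "TREATMENT", 0, 0, 1), _ev("b", "PROBLEM", 0, 3, 5)],
        gold=("a", "b", "BEFORE_OVERLAP"),
        semrel=("a", "b", "TrCP", "NULL", "present"),
        deps=[(2, 1, "nsubj"), (1, 0, "amod"), (2, 5, "dobj"), (5, 3, "det"), (5, 4, "amod")],
    )


def _t_trap(rng: random.Random) -> TemplateInstance:
    toks = [_tok("She", "PRP", chunk="B-NP"), _tok("was", "VBD", "be", "B-VP"),
            _tok("started", "VBN", "start", "I-VP"), _tok("on", "IN", chunk="B-PP"),
            _tok("Decadron", "NN", "decadron", "B-NP"), _tok("to", "TO", chunk="B-VP"),
            _tok("prevent", "VB", chunk="I-VP"), _tok("swelling", "NN", "swell", "B-NP"),
            _tok(".", ".")]
    tree = ("(S (NP (PRP She)) (VP (VBD was) (VP (VBN started) (PP (IN on) "
            "(NP (NN Decadron))) (S (VP (TO to) (VP (VB prevent) (NP (NN swelling))))))) (. .))")
    return TemplateInstance(
        template_id="trap", sentences=[toks], trees=[tree],
        entities=[_ev("a", "TREATMENT", 0, 4, 4), _ev("b", "PROBLEM", 0, 7, 7, modality="HYPOTHETICAL")],
        gold=("a", "b", "OVERLAP"),
        semrel=("a", "b", "TrAP", "NULL", "hypothetical"),
        deps=[(2, 0, "nsubjpass"), (2, 1, "auxpass"), (2, 3, "prep"), (3, 4, "pobj"),
              (2, 6, "xcomp"), (6, 5, "aux"), (6, 7, "dobj")],
    )


def _t_trnap(rng: random.Random) -> TemplateInstance:
    toks = [_tok("Avandia", "NN", "avandia", "B-NP"), _tok("was", "VBD", "be", "B-VP"),
            _tok("discontinued", "VBN", "discontinue", "I-VP"), _tok("secondary", "JJ", chunk="B-ADJP"),
            _tok("to", "IN", chunk="B-PP"), _tok("the", "DT", chunk="B-NP"),
            _tok("side", "NN", chunk="I-NP"), _tok("effects", "NNS", "effect", "I-NP"),
            _tok(".", ".")]
    tree = ("(S (NP (NN Avandia)) (VP (VBD was) (VP (VBN discontinued) (ADJP (JJ secondary) "
            "(PP (IN to) (NP (DT the) (NN side) (NNS effects)))))) (. .))")
    return TemplateInstance(
        template_id="trnap", sentences=[toks], trees=[tree],
        entities=[_ev("a", "TREATMENT", 0, 0, 0), _ev("b", "PROBLEM", 0, 6, 7)],
        gold=("a", "b", "ENDED_BY"),
        semrel=("a", "b", "TrNAP", "NULL", "present"),
        deps=[(2, 0, "nsubjpass"), (2, 1, "auxpass"), (2, 3, "acomp"), (3, 4, "prep"),
              (4, 7, "pobj"), (7, 5, "det"), (7, 6, "nn")],
    )


def _t_ntrp(rng: random.Random) -> TemplateInstance:
    toks = [_tok("The", "DT", chunk="B-NP"), _tok("sutures", "NNS", "suture", "I-NP"),
            _tok("were", "VBD", "be", "B-VP"), _tok("intact", "JJ", chunk="B-ADJP"),
            _tok("with", "IN", chunk="B-PP"), _tok("no", "DT", chunk="B-NP"),
            _tok("erythema", "NN", chunk="I-NP"), _tok("noted", "VBN", "note", "B-VP"),
            _tok(".", ".")]
    tree = ("(S (NP (DT The) (NNS sutures)) (VP (VBD were) (ADJP (JJ intact)) "
            "(PP (IN with) (NP (DT no) (NN erythema))) (VP (VBN noted))) (. .))")
    return TemplateInstance(
        template_id="ntrp", sentences=[toks], trees=[tree],
        entities=[_ev("a", "TREATMENT", 0, 1, 1), _ev("b", "PROBLEM", 0, 6, 6, polarity="NEG")],
        gold=("a", "b", "OVERLAP"),
        semrel=("a", "b", "NTrP", "NULL", "absent"),
        deps=[(3, 1, "nsubj"), (1, 0, "det"), (3, 2, "cop"), (3, 4, "prep"), (4, 6, "pobj"),
              (6, 5, "det"), (3, 7, "partmod")],
    )


def _t_ntep(rng: random.Random) -> TemplateInstance:
    toks = [_tok("His", "PRP$", chunk="B-NP"), _tok("laboratories", "NNS", "laboratory", "I-NP"),
            _tok("remained", "VBD", "remain", "B-VP"), _tok("normal", "JJ", chunk="B-ADJP"),
            _tok("and", "CC"), _tok("his", "PRP$", chunk="B-NP"),
            _tok("pain", "NN", chunk="I-NP"), _tok("was", "VBD", "be", "B-VP"),
            _tok("controlled", "VBN", "control", "I-VP"), _tok(".", ".")]
    tree = ("(S (S (NP (PRP$ His) (NNS laboratories)) (VP (VBD remained) (ADJP (JJ normal)))) "
            "(CC and) (S (NP (PRP$ his) (NN pain)) (VP (VBD was) (VP (VBN controlled)))) (. .))")
    return TemplateInstance(
        template_id="ntep", sentences=[toks], trees=[tree],
        entities=[_ev("a", "TEST", 0, 1, 1), _ev("b", "PROBLEM", 0, 6, 6)],
        gold=("a", "b", "OVERLAP"),
        semrel=("a", "b", "NTeP", "NULL", "present"),
        deps=[(2, 1, "nsubj"), (1, 0, "poss"), (2, 3, "acomp"), (2, 8, "conj"),
              (8, 6, "nsubjpass"), (6, 5, "poss"), (8, 7, "auxpass")],
    )


TEMPLATES = {
    "discharge": _t_discharge, "complained": _t_complained, "antonym": _t_antonym,
    "rehab": _t_rehab, "resolved": _t_resolved, "restatement": _t_restatement,
    "thereafter": _t_thereafter, "series": _t_series, "pip": _t_pip, "tecp": _t_tecp,
    "terp_due": _t_terp_due, "table5": _t_table5, "trwp": _t_trwp, "trcp": _t_trcp,
    "trap": _t_trap, "trnap": _t_trnap, "ntrp": _t_ntrp, "ntep": _t_ntep,
}

#: Rule-covered temporal templates: the default corpus conditions.
DEFAULT_MIX = {tid: 1.0 / 12 for tid in (
    "discharge", "complained", "antonym", "rehab", "resolved", "restatement",
    "thereafter", "series", "pip", "tecp", "terp_due", "table5")}

#: Templates carrying a semantic-relation label for each of the 11 classes.
SEMREL_MIX = {tid: 1.0 / 13 for tid in (
    "resolved", "trwp", "trcp", "pip", "terp_due", "table5", "trap", "trnap",
    "tecp", "ntrp", "ntep", "series", "antonym")}


# ---------------------------------------------------------------------------
# lexicon fixtures
# ---------------------------------------------------------------------------

def fixture_thesaurus() -> LexicalRelationLexicon:
    lex = LexicalRelationLexicon.thesaurus()
    for up, dn in _ANTONYM_PAIRS:
        lex.add(up, ["raised"], ["rising"], [], [dn])
        lex.add(dn, ["reduced"], ["falling"], [], [up])
    lex.add("pain", ["discomfort", "ache"], ["soreness"], [], [])
    return lex


def fixture_wordnet() -> LexicalRelationLexicon:
    lex = LexicalRelationLexicon.wordnet()
    lex.add("fever", ["symptom"], [], [], ["pyrexia"])
    lex.add("sepsis", ["infection"], [], [], [])
    lex.add("infection", [], ["sepsis"], [], [])
    return lex


# ---------------------------------------------------------------------------
# corpus assembly
# ---------------------------------------------------------------------------

@dataclass
class FixtureCorpus:
    docs: dict  # doc_id -> (ClinicalDocument, DocumentAnnotations)
    semrel_instances: list  # SemRelInstance with labels
    thesaurus: LexicalRelationLexicon
    wordnet: LexicalRelationLexicon
    manifest: dict

    def gold_semrel_model(self) -> "GoldSemrelModel":
        return GoldSemrelModel(self.semrel_instances)


class GoldSemrelModel:
    """Oracle stand-in for a trained semantic-relation classifier (synthetic
    fixtures only): returns the planted label for annotated pairs and NPP
    for any other applicable pair."""

    def __init__(self, instances):
        self._labels = {(i.doc_id, frozenset({i.e1, i.e2})): i.label for i in instances}

    def predict_for_pair(self, e1, e2, doc, ann):
        label = self._labels.get((doc.id, frozenset({e1.id, e2.id})), "NPP")
        return label, {}


_HEADER = "Admission Date : {adm} .\nDischarge Date : {dis} .\n"
_HPI = "History of Present Illness :\n"
_COURSE = "Hospital Course :\n"


def _materialize_doc(doc_id: str, instances: list[TemplateInstance]):
    adm, dis = "2020-01-05", "2020-01-12"
    header = _HEADER.format(adm=adm, dis=dis)
    half = max(1, (len(instances) + 1) // 2)

    text_parts = [header, _HPI]
    tokens_json = []
    trees = []
    deps_json = []
    srl_json = []
    disc_json = []
    events, times, tlinks, semrels = [], [], [], []
    pos_char = len(header) + len(_HPI)
    tok_index = 0
    sent_index = 0
    ecount = tcount = lcount = 0

    course_added = False
    for k, inst in enumerate(instances):
        if k == half:
            text_parts.append(_COURSE)
            pos_char += len(_COURSE)
            course_added = True
        tok_offset = tok_index
        sent_offset = sent_index
        local_spans = []  # char span per template-local token
        for sent in inst.sentences:
            sent_start_tok = tok_index
            for text, lemma, pos, chunk in sent:
                start = pos_char
                end = start + len(text)
                tokens_json.append({"i": tok_index, "text": text, "lemma": lemma, "pos": pos,
                                    "chunk": chunk, "start": start, "end": end,
                                    "sent": sent_index})
                local_spans.append((start, end))
                tok_index += 1
                pos_char = end + 1  # single space / newline after
            sent_text = " ".join(t[0] for t in sent) + "\n"
            text_parts.append(sent_text)
            sent_index += 1
        trees.extend(inst.trees)
        for head, dep, label in inst.deps:
            deps_json.append({"head": head + tok_offset, "dep": dep + tok_offset, "label": label})
        for pred, args in inst.srl:
            srl_json.append({"pred": pred + tok_offset,
                             "args": [{"label": l, "start_tok": a + tok_offset,
                                       "end_tok": b + tok_offset} for l, a, b in args]})
        sent_char_spans = []
        ti = tok_offset
        for sent in inst.sentences:
            s0 = tokens_json[ti]["start"]
            s1 = tokens_json[ti + len(sent) - 1]["end"]
            sent_char_spans.append((s0, s1))
            ti += len(sent)
        for a1s, a2s, sense, kind, conn in inst.discourse:
            disc_json.append({"a1": list(sent_char_spans[a1s]), "a2": list(sent_char_spans[a2s]),
                              "sense": sense, "kind": kind, "conn": conn})

        slot_ids = {}
        # template-local token index across its sentences
        flat_local = [t for sent in inst.sentences for t in sent]
        cum = [0]
        for sent in inst.sentences:
            cum.append(cum[-1] + len(sent))
        for ent in inst.entities:
            lo_local = ent["lo"]
            hi_local = ent["hi"]
            start = local_spans[lo_local][0]
            end = local_spans[hi_local][1]
            etext = " ".join(t[0] for t in flat_local[lo_local:hi_local + 1])
            if ent["kind"] == "EVENT":
                eid = f"{doc_id}_E{ecount}"
                ecount += 1
                events.append(EventAnnotation(id=eid, start=start, end=end, text=etext,
                                              etype=ent["type"], polarity=ent["polarity"],
                                              modality=ent["modality"]))
            else:
                eid = f"{doc_id}_T{tcount}"
                tcount += 1
                times.append(TimeAnnotation(id=eid, start=start, end=end, text=etext,
                                            ttype=ent["type"], value=ent.get("value", "")))
            slot_ids[ent["slot"]] = eid
        sa, sb, label = inst.gold
        tlinks.append(TemporalLink(id=f"{doc_id}_TL{lcount}", source=slot_ids[sa],
                                   target=slot_ids[sb], relation=FineRelation(label)))
        lcount += 1
        if inst.semrel is not None:
            ra, rb, rlabel, as1, as2 = inst.semrel
            ent_sent = {e["slot"]: e["sent"] for e in inst.entities}
            semrels.append(SemRelInstance(
                doc_id=doc_id, e1=slot_ids[ra], e2=slot_ids[rb],
                sentence=sent_offset + ent_sent[ra], label=rlabel,
                assertion1=as1, assertion2=as2))

    if not course_added:  # single-instance documents get an empty second section
        text_parts.append(_COURSE)
    text = "".join(text_parts)
    adm_start = text.index(adm)
    dis_start = text.index(dis)
    hpi_start = text.index(_HPI)
    course_start = text.index(_COURSE)
    doc = ClinicalDocument(
        id=doc_id, text=text,
        sections=[Section("HISTORY_OF_PRESENT_ILLNESS", hpi_start, course_start),
                  Section("HOSPITAL_COURSE", course_start, len(text))],
        events=events, times=times,
        sectimes=[SectionTime(id=f"{doc_id}_S0", section="ADMISSION", start=adm_start,
                              end=adm_start + len(adm), value=adm),
                  SectionTime(id=f"{doc_id}_S1", section="DISCHARGE", start=dis_start,
                              end=dis_start + len(dis), value=dis)],
        tlinks=tlinks,
    )
    doc.validate()
    ann = annotations_from_dict(
        {"tokens": tokens_json, "trees": trees, "deps": deps_json, "srl": srl_json,
         "discourse": disc_json}, doc)
    return doc, ann, semrels


def generate_corpus(seed: int, n_docs: int, template_mix: dict | None = None,
                    sentences_per_doc: int = 8, doc_prefix: str = "doc") -> FixtureCorpus:
    """Deterministically generate *n_docs* two-section documents.

    *template_mix* maps template id -> probability (must sum to 1);
    *sentences_per_doc* counts template instances per document (a
    two-sentence template counts as one instance).  *doc_prefix* keeps ids
    disjoint when corpora are merged.
    """
    mix = template_mix or DEFAULT_MIX
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"template mix must sum to 1, got {total}")
    for tid in mix:
        if tid not in TEMPLATES:
            raise ValueError(f"unknown template id {tid!r}")
    rng = random.Random(seed)
    tids = sorted(mix)
    weights = [mix[t] for t in tids]
    docs = {}
    semrels = []
    for d in range(n_docs):
        doc_id = f"{doc_prefix}{d:04d}"
        chosen = rng.choices(tids, weights=weights, k=sentences_per_doc)
        instances = [TEMPLATES[tid](rng) for tid in chosen]
        doc, ann, sr = _materialize_doc(doc_id, instances)
        docs[doc_id] = (doc, ann)
        semrels.extend(sr)
    manifest = {"seed": seed, "n_docs": n_docs, "mix": dict(mix),
                "sentences_per_doc": sentences_per_doc, "flips": []}
    return FixtureCorpus(docs=docs, semrel_instances=semrels,
                         thesaurus=fixture_thesaurus(), wordnet=fixture_wordnet(),
                         manifest=manifest)


def plant_noise(corpus: FixtureCorpus, flip_rate: float, seed: int) -> FixtureCorpus:
    """Replace a Bernoulli(flip_rate) fraction of gold fine labels with a
    uniformly random *different* fine type; flips are recorded in the manifest."""
    if not (0 <= flip_rate < 1):
        raise ValueError("flip_rate must be in [0, 1)")
    rng = random.Random(seed)
    fine = [r.value for r in FineRelation]
    flips = []
    new_docs = {}
    for doc_id, (doc, ann) in corpus.docs.items():
        new_links = []
        for link in doc.tlinks:
            old = str(link.relation)
            if flip_rate > 0 and rng.random() < flip_rate:
                new = rng.choice([r for r in fine if r != old])
                flips.append({"doc": doc_id, "link": link.id, "old": old, "new": new})
                new_links.append(replace(link, relation=FineRelation(new)))
            else:
                new_links.append(link)
        new_doc = ClinicalDocument(id=doc.id, text=doc.text, sections=doc.sections,
                                   events=doc.events, times=doc.times,
                                   sectimes=doc.sectimes, tlinks=new_links)
        new_docs[doc_id] = (new_doc, ann)
    manifest = dict(corpus.manifest)
    manifest["flips"] = flips
    manifest["flip_rate"] = flip_rate
    manifest["flip_seed"] = seed
    return FixtureCorpus(docs=new_docs, semrel_instances=corpus.semrel_instances,
                         thesaurus=corpus.thesaurus, wordnet=corpus.wordnet,
                         manifest=manifest)


def write_corpus(corpus: FixtureCorpus, outdir) -> None:
    """Emit the corpus as XML + sidecar JSON + lexicons + manifest files."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for doc_id, (doc, ann) in corpus.docs.items():
        write_i2b2_xml(doc, os.path.join(outdir, f"{doc_id}.xml"))
        with open(os.path.join(outdir, f"{doc_id}.json"), "w") as fh:
            json.dump(annotations_to_dict(ann), fh, indent=1)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(corpus.manifest, fh, indent=1)
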