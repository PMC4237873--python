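"""Data model and I/O for i2b2-dialect annotated clinical documents.

A discharge summary is plain text with stand-off annotations: clinically
relevant EVENTs (tests, problems, treatments, ...), TIMEX3 time expressions,
the section creation times (admission / discharge date), and TLINKs --
typed temporal relations between pairs of annotated entities.

The temporal taxonomy has 12 fine-grained relation types defined on an
*ordered* pair (e1, e2); reading the pair in the opposite order inverts the
type (e.g. Overlap_After read backwards is Before_Overlap).  The 2012 i2b2
shared task merged the 12 types into 3 broad ones (Before', After',
Overlap'); four of the fine types map into the broad set only after the
pair is inverted.  Both the fine taxonomy and the merge live here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from lxml import etree

__all__ = [
    "FineRelation",
    "BroadRelation",
    "NO_RELATION",
    "invert_relation",
    "map_fine_to_broad",
    "map_12_to_3",
    "EventAnnotation",
    "TimeAnnotation",
    "SectionTime",
    "TemporalLink",
    "Section",
    "ClinicalDocument",
    "TaxonomyError",
    "IntegrityError",
    "parse_i2b2_xml",
    "write_i2b2_xml",
    "EVENT_TYPES",
    "TIME_TYPES",
]


class TaxonomyError(ValueError):
    """An unknown, broad-for-fine, or sentinel relation type where a fine type is required."""


class IntegrityError(ValueError):
    """Document annotations violate a structural invariant (span/text mismatch, dangling id...)."""


class FineRelation(str, enum.Enum):
    """The 12 fine-grained temporal relation types."""

    SIMULTANEOUS = "SIMULTANEOUS"
    OVERLAP = "OVERLAP"
    BEFORE = "BEFORE"
    AFTER = "AFTER"
    BEFORE_OVERLAP = "BEFORE_OVERLAP"
    OVERLAP_AFTER = "OVERLAP_AFTER"
    DURING = "DURING"
    DURING_INV = "DURING_INV"
    BEGINS = "BEGINS"
    BEGUN_BY = "BEGUN_BY"
    ENDS = "ENDS"
    ENDED_BY = "ENDED_BY"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class BroadRelation(str, enum.Enum):
    """The 3 merged shared-task relation types."""

    BEFORE3 = "BEFORE"
    AFTER3 = "AFTER"
    OVERLAP3 = "OVERLAP"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Sentinel used for pipeline-internal "no temporal relation" labels.  Never
#: serialized into TLINK output.
NO_RELATION = "NO_RELATION"

# Inversion is an involution.  Five inverse pairs are fixed by the taxonomy's
# own descriptions; SIMULTANEOUS and OVERLAP are symmetric (self-inverse) --
# for OVERLAP this is a convention, the taxonomy leaves it open.
_INVERSE: dict[FineRelation, FineRelation] = {
    FineRelation.BEFORE: FineRelation.AFTER,
    FineRelation.AFTER: FineRelation.BEFORE,
    FineRelation.BEFORE_OVERLAP: FineRelation.OVERLAP_AFTER,
    FineRelation.OVERLAP_AFTER: FineRelation.BEFORE_OVERLAP,
    FineRelation.DURING: FineRelation.DURING_INV,
    FineRelation.DURING_INV: FineRelation.DURING,
    FineRelation.BEGINS: FineRelation.BEGUN_BY,
    FineRelation.BEGUN_BY: FineRelation.BEGINS,
    FineRelation.ENDS: FineRelation.ENDED_BY,
    FineRelation.ENDED_BY: FineRelation.ENDS,
    FineRelation.SIMULTANEOUS: FineRelation.SIMULTANEOUS,
    FineRelation.OVERLAP: FineRelation.OVERLAP,
}

# Direct merge for the eight fine types that map without inversion.  The
# remaining four (OVERLAP_AFTER, DURING_INV, BEGINS, ENDS) are first inverted
# (swapping the pair) and then merged.
_DIRECT_BROAD: dict[FineRelation, BroadRelation] = {
    FineRelation.OVERLAP: BroadRelation.OVERLAP3,
    FineRelation.SIMULTANEOUS: BroadRelation.OVERLAP3,
    FineRelation.DURING: BroadRelation.OVERLAP3,
    FineRelation.BEFORE: BroadRelation.BEFORE3,
    FineRelation.BEFORE_OVERLAP: BroadRelation.BEFORE3,
    FineRelation.ENDED_BY: BroadRelation.BEFORE3,
    FineRelation.AFTER: BroadRelation.AFTER3,
    FineRelation.BEGUN_BY: BroadRelation.AFTER3,
}


def _coerce_fine(r: FineRelation | str) -> FineRelation:
    if isinstance(r, FineRelation):
        return r
    try:
        return FineRelation(str(r).upper())
    except ValueError:
        raise TaxonomyError(f"not a fine temporal relation type: {r!r}") from None


def invert_relation(r: FineRelation | str) -> FineRelation:
    """Return the type of the pair read in the opposite order.

    An involution over the 12 fine types: ``invert(invert(r)) == r``.
    """
    return _INVERSE[_coerce_fine(r)]


def map_fine_to_broad(r: FineRelation | str) -> tuple[BroadRelation, bool]:
    """Merge a fine type into a broad one.

    Returns ``(broad, inverted)`` where *inverted* says the pair's endpoints
    must be swapped for the broad assertion to hold.
    """
    fine = _coerce_fine(r)
    if fine in _DIRECT_BROAD:
        return _DIRECT_BROAD[fine], False
    return _DIRECT_BROAD[invert_relation(fine)], True


@dataclass(frozen=True)
class EventAnnotation:
    id: str
    start: int
    end: int  # 0-based half-open character interval
    text: str
    etype: str  # TEST / PROBLEM / TREATMENT / CLINICAL_DEPT / EVIDENTIAL / OCCURRENCE
    polarity: str = "POS"
    modality: str = "FACTUAL"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class TimeAnnotation:
    id: str
    start: int
    end: int
    text: str
    ttype: str  # DATE / TIME / DURATION / FREQUENCY
    value: str = ""
    modifier: str = "NA"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


EVENT_TYPES = ("TEST", "PROBLEM", "TREATMENT", "CLINICAL_DEPT", "EVIDENTIAL", "OCCURRENCE")
TIME_TYPES = ("DATE", "TIME", "DURATION", "FREQUENCY")


@dataclass(frozen=True)
class SectionTime:
    """Creation time of a discharge-summary section (admission or discharge date)."""

    id: str
    section: str  # ADMISSION | DISCHARGE
    start: int
    end: int
    value: str  # TIMEX3 date string

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class TemporalLink:
    """A typed temporal relation on an *ordered* entity pair."""

    id: str
    source: str
    target: str
    relation: FineRelation | BroadRelation | str
    origin: str = "GOLD"  # GOLD | RULE | CLASSIFIER


@dataclass(frozen=True)
class Section:
    name: str  # e.g. HISTORY_OF_PRESENT_ILLNESS, HOSPITAL_COURSE
    start: int
    end: int


@dataclass
class ClinicalDocument:
    id: str
    text: str
    sections: list[Section] = field(default_factory=list)
    events: list[EventAnnotation] = field(default_factory=list)
    times: list[TimeAnnotation] = field(default_factory=list)
    sectimes: list[SectionTime] = field(default_factory=list)
    tlinks: list[TemporalLink] = field(default_factory=list)

    # -- lookups -----------------------------------------------------------
    def entity(self, eid: str) -> EventAnnotation | TimeAnnotation:
        ent = self.entity_map().get(eid)
        if ent is None:
            raise IntegrityError(f"{self.id}: no entity with id {eid!r}")
        return ent

    def entity_map(self) -> dict[str, EventAnnotation | TimeAnnotation]:
        if not hasattr(self, "_entity_map") or len(self._entity_map) != len(self.events) + len(self.times):
            self._entity_map = {e.id: e for e in self.events}
            self._entity_map.update({t.id: t for t in self.times})
        return self._entity_map

    def section_of(self, pos: int) -> Section | None:
        for sec in self.sections:
            if sec.start <= pos < sec.end:
                return sec
        return None

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        """Check all structural invariants; raise IntegrityError on the first violation."""
        seen: set[str] = set()
        for ann in [*self.events, *self.times, *self.sectimes]:
            if ann.id in seen:
                raise IntegrityError(f"{self.id}: duplicate annotation id {ann.id!r}")
            seen.add(ann.id)
            if not (0 <= ann.start <= ann.end <= len(self.text)):
                raise IntegrityError(f"{self.id}: span {ann.span} of {ann.id!r} outside text")
            if hasattr(ann, "text") and self.text[ann.start : ann.end] != ann.text:
                raise IntegrityError(
                    f"{self.id}: annotation {ann.id!r} text {ann.text!r} does not match "
                    f"document substring {self.text[ann.start:ann.end]!r}"
                )
        for ev in self.events:
            if ev.etype not in EVENT_TYPES:
                raise IntegrityError(f"{self.id}: event {ev.id!r} has unknown type {ev.etype!r}")
        for tm in self.times:
            if tm.ttype not in TIME_TYPES:
                raise IntegrityError(f"{self.id}: time {tm.id!r} has unknown type {tm.ttype!r}")
        sec_names = [s.section for s in self.sectimes]
        if len(sec_names) != len(set(sec_names)):
            raise IntegrityError(f"{self.id}: more than one SECTIME for a section")
        emap = self.entity_map()
        for link in self.tlinks:
            if link.source == link.target:
                raise IntegrityError(f"{self.id}: TLINK {link.id!r} links an entity to itself")
            for endpoint in (link.source, link.target):
                if endpoint not in emap and not any(s.id == endpoint for s in self.sectimes):
                    raise IntegrityError(f"{self.id}: TLINK {link.id!r} endpoint {endpoint!r} unresolved")
        for a in self.sections:
            for b in self.sections:
                if a is not b and a.start < b.end and b.start < a.end:
                    raise IntegrityError(f"{self.id}: sections {a.name} and {b.name} overlap")


# ---------------------------------------------------------------------------
# taxonomy operations on links
# ---------------------------------------------------------------------------

def map_12_to_3(link: TemporalLink) -> TemporalLink:
    """Merge a fine-typed link into the 3-type shared-task space.

    Types in the inverted group (Overlap_After, During_Inv, Begins, Ends) swap
    their endpoints first, so e.g. ``(e1, e2, Ends)`` becomes
    ``(e2, e1, Before')``.
    """
    broad, inverted = map_fine_to_broad(link.relation)
    src, tgt = (link.target, link.source) if inverted else (link.source, link.target)
    return TemporalLink(id=link.id, source=src, target=tgt, relation=broad, origin=link.origin)


# ---------------------------------------------------------------------------
# XML read / write
# ---------------------------------------------------------------------------

_RELATION_ALIASES = {
    # tolerated spellings seen across corpus variants
    "BEFORE_OVERLAP": FineRelation.BEFORE_OVERLAP,
    "OVERLAP_BEFORE": FineRelation.BEFORE_OVERLAP,
    "AFTER_OVERLAP": FineRelation.OVERLAP_AFTER,
    "OVERLAP_AFTER": FineRelation.OVERLAP_AFTER,
    "DURING_INV": FineRelation.DURING_INV,
    "DURING_INVERSE": FineRelation.DURING_INV,
}


def _parse_relation(s: str) -> FineRelation | BroadRelation:
    canon = s.strip().upper().replace("-", "_").replace(" ", "_")
    if canon in _RELATION_ALIASES:
        return _RELATION_ALIASES[canon]
    try:
        return FineRelation(canon)
    except ValueError:
        raise TaxonomyError(f"unknown temporal relation type {s!r}") from None


def parse_i2b2_xml(path) -> ClinicalDocument:
    """Parse an i2b2-dialect XML file into a :class:`ClinicalDocument`.

    Accepts stand-off TLINKs with either ``fromID``/``toID`` or ``from``/``to``
    attribute spellings.  Spans are checked against the text; a mismatch is an
    :class:`IntegrityError` naming the annotation id.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    text_el = root.find("TEXT")
    text = text_el.text or "" if text_el is not None else ""
    doc = ClinicalDocument(id=root.get("id") or str(path), text=text)

    tags = root.find("TAGS")
    if tags is None:
        tags = root
    for el in tags.iter():
        tag = el.tag.upper() if isinstance(el.tag, str) else ""
        if tag == "EVENT":
            doc.events.append(
                EventAnnotation(
                    id=el.get("id"),
                    start=int(el.get("start")),
                    end=int(el.get("end")),
                    text=el.get("text", ""),
                    etype=el.get("type", "OCCURRENCE"),
                    polarity=el.get("polarity", "POS"),
                    modality=el.get("modality", "FACTUAL"),
                )
            )
        elif tag == "TIMEX3":
            doc.times.append(
                TimeAnnotation(
                    id=el.get("id"),
                    start=int(el.get("start")),
                    end=int(el.get("end")),
                    text=el.get("text", ""),
                    ttype=el.get("type", "DATE"),
                    value=el.get("val", ""),
                    modifier=el.get("mod", "NA"),
                )
            )
        elif tag == "SECTIME":
            doc.sectimes.append(
                SectionTime(
                    id=el.get("id"),
                    section=el.get("type", "ADMISSION"),
                    start=int(el.get("start")),
                    end=int(el.get("end")),
                    value=el.get("dvalue", ""),
                )
            )
        elif tag == "SECTION":
            doc.sections.append(
                Section(name=el.get("name"), start=int(el.get("start")), end=int(el.get("end")))
            )
        elif tag == "TLINK":
            src = el.get("fromID") or el.get("from")
            tgt = el.get("toID") or el.get("to")
            doc.tlinks.append(
                TemporalLink(
                    id=el.get("id"),
                    source=src,
                    target=tgt,
                    relation=_parse_relation(el.get("type", "")),
                )
            )
    doc.validate()
    return doc


def write_i2b2_xml(doc: ClinicalDocument, path) -> None:
    """Serialize a document back to stand-off i2b2-dialect XML.

    The ``origin`` of a link is dropped on output.  A link carrying the
    NO_RELATION sentinel is a programming error and is refused.
    """
    doc.validate()
    for link in doc.tlinks:
        if str(link.relation) == NO_RELATION:
            raise TaxonomyError(f"{doc.id}: TLINK {link.id!r} carries the NO_RELATION sentinel")
    root = etree.Element("ClinicalNarrativeTemporalAnnotation", id=doc.id)
    text_el = etree.SubElement(root, "TEXT")
    text_el.text = etree.CDATA(doc.text)
    tags = etree.SubElement(root, "TAGS")
    for sec in doc.sections:
        etree.SubElement(tags, "SECTION", name=sec.name, start=str(sec.start), end=str(sec.end))
    for ev in doc.events:
        etree.SubElement(
            tags, "EVENT", id=ev.id, start=str(ev.start), end=str(ev.end), text=ev.text,
            type=ev.etype, polarity=ev.polarity, modality=ev.modality,
        )
    for tm in doc.times:
        etree.SubElement(
            tags, "TIMEX3", id=tm.id, start=str(tm.start), end=str(tm.end), text=tm.text,
            type=tm.ttype, val=tm.value, mod=tm.modifier,
        )
    for st in doc.sectimes:
        etree.SubElement(
            tags, "SECTIME", id=st.id, start=str(st.start), end=str(st.end),
            type=st.section, dvalue=st.value,
        )
    for link in doc.tlinks:
        rel = link.relation.value if isinstance(link.relation, enum.Enum) else str(link.relation)
        etree.SubElement(tags, "TLINK", id=link.id, fromID=link.source, toID=link.target, type=rel)
    etree.ElementTree(root).write(str(path), pretty_print=True, encoding="UTF-8", xml_declaration=True)


def invert_link(link: TemporalLink) -> TemporalLink:
    """The same temporal assertion read in the opposite order."""
    return replace(link, source=link.target, target=link.source, relation=invert_relation(link.relation))
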