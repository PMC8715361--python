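"""Note-derived pipelines: numeric-entity extraction and section templating.

Two extraction passes populate NOTE_NLP:

1. pattern-matched numeric mentions of body weight, height, body-mass index
   and left-ventricular ejection fraction, converted to canonical units
   (kg, cm, kg/m2, %) and routed onward to the domain table;
2. section-template harvesting (line-initial short phrases ending in a
   colon, kept when their document frequency exceeds 1%) and note
   segmentation into labeled, non-overlapping spans.

All offsets are 0-based, half-open, character (not byte) offsets, so
``note[offset_begin:offset_end] == snippet`` always holds.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

NLP_SYSTEM = "mimic2omop-regex-1"

LB_TO_KG = 0.453592
IN_TO_CM = 2.54

#: entity name -> (regex, canonical unit, converter keyed by source unit)
_ENTITY_PATTERNS: list[tuple[str, re.Pattern, str]] = [
    ("weight", re.compile(
        r"\b(?:wt|weight)\s*[:.]?\s*"
        r"(?P<q>(?P<num>\d+(?:\.\d+)?)\s*(?P<unit>kgs?|lbs?|pounds))\b",
        re.IGNORECASE), "kg"),
    ("height", re.compile(
        r"\b(?:ht|height)\s*[:.]?\s*"
        r"(?P<q>(?P<num>\d+(?:\.\d+)?)\s*(?P<unit>cm|in(?:ches)?))\b",
        re.IGNORECASE), "cm"),
    ("bmi", re.compile(
        r"\bbmi\s*[:.]?\s*(?P<q>(?P<num>\d+(?:\.\d+)?))",
        re.IGNORECASE), "kg/m2"),
    ("lvef", re.compile(
        r"\b(?:lv\s?ef|ef|ejection fraction(?: of)?)\s*[:.]?\s*"
        r"(?P<q>(?P<num>\d+(?:\.\d+)?)\s*(?P<unit>%))",
        re.IGNORECASE), "%"),
]

#: extracted entity -> standard concept id (all Measurement domain here)
ENTITY_CONCEPTS = {"weight": 3025315, "height": 3036277,
                   "bmi": 3038553, "lvef": 3011863}


@dataclass(frozen=True)
class NumericEntity:
    entity: str           # weight | height | bmi | lvef
    value: float          # canonical units
    unit: str             # kg | cm | kg/m2 | %
    offset_begin: int
    offset_end: int
    snippet: str          # note[offset_begin:offset_end]
    lexical_variant: str  # raw matched text


def _canonical(entity: str, number: float, unit: str | None) -> float:
    u = (unit or "").lower()
    if entity == "weight" and u.startswith(("lb", "pound")):
        return round(number * LB_TO_KG, 2)
    if entity == "height" and u.startswith("in"):
        return round(number * IN_TO_CM, 2)
    return round(number, 2)


def extract_numeric_entities(note: str) -> list[NumericEntity]:
    """All weight/height/BMI/ejection-fraction mentions in one note."""
    out: list[NumericEntity] = []
    if not note:
        return out
    for entity, rx, canon_unit in _ENTITY_PATTERNS:
        for m in rx.finditer(note):
            b, e = m.span("q")
            out.append(NumericEntity(
                entity=entity,
                value=_canonical(entity, float(m.group("num")),
                                 m.groupdict().get("unit")),
                unit=canon_unit, offset_begin=b, offset_end=e,
                snippet=note[b:e], lexical_variant=m.group(0)))
    out.sort(key=lambda x: (x.offset_begin, x.entity))
    return out


# ---------------------------------------------------------------------------
# Section templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SectionTemplate:
    header: str            # normalized (lower-case) header text
    frequency: float       # document frequency in (0, 1]


@dataclass(frozen=True)
class SectionSpan:
    label: str             # normalized header or "preamble"
    offset_begin: int
    offset_end: int
    snippet: str


_HEADER_LINE_RX = re.compile(r"^[ \t]*([A-Za-z][A-Za-z ]*?):",
                             re.MULTILINE)


def _load_stoplist() -> frozenset[str]:
    path = Path(str(resources.files("mimic2omop").joinpath("data"))) \
        / "section_stoplist.csv"
    with open(path, newline="") as fh:
        return frozenset(row["header"].strip().lower()
                         for row in csv.DictReader(fh))


_STOPLIST = _load_stoplist()


def _candidate_headers(note: str) -> set[str]:
    found = set()
    for m in _HEADER_LINE_RX.finditer(note):
        header = " ".join(m.group(1).lower().split())
        if header and len(header.split()) <= 5:
            found.add(header)
    return found


def harvest_section_templates(notes: list[str],
                              min_frequency: float = 0.01
                              ) -> list[SectionTemplate]:
    """Section templates with document frequency above ``min_frequency``.

    Candidates are line-initial phrases of at most five words (letters and
    spaces) ending in a colon, case-normalized; a committed stop-list drops
    known false positives (measurement labels, dates).
    """
    if not notes:
        raise ValueError("cannot harvest section templates from empty corpus")
    counts: dict[str, int] = {}
    for note in notes:
        for header in _candidate_headers(note or ""):
            counts[header] = counts.get(header, 0) + 1
    n = len(notes)
    out = [SectionTemplate(h, c / n) for h, c in counts.items()
           if c / n > min_frequency and h not in _STOPLIST]
    out.sort(key=lambda t: (-t.frequency, t.header))
    return out


def segment_note(note: str,
                 templates: list[SectionTemplate]) -> list[SectionSpan]:
    """Partition one note into labeled section spans.

    Every matched template header opens a section that runs to the next
    header (or end of note); text before the first header is labeled
    ``preamble``. Spans are non-overlapping, ordered and exactly cover the
    note, so concatenating all snippets reproduces the text.
    """
    if not note:
        return []
    known = {t.header for t in templates}
    marks: list[tuple[int, str]] = []
    for m in _HEADER_LINE_RX.finditer(note):
        header = " ".join(m.group(1).lower().split())
        if header in known:
            marks.append((m.start(), header))
    spans: list[SectionSpan] = []
    if not marks or marks[0][0] > 0:
        end = marks[0][0] if marks else len(note)
        spans.append(SectionSpan("preamble", 0, end, note[:end]))
    for i, (begin, header) in enumerate(marks):
        end = marks[i + 1][0] if i + 1 < len(marks) else len(note)
        spans.append(SectionSpan(header, begin, end, note[begin:end]))
    return [s for s in spans if s.offset_end > s.offset_begin]
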