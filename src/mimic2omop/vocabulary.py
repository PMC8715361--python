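"""Vocabulary store: standard, extension and local concepts plus alignment.

Concept identifiers are banded:

* standard (Athena-loaded) concepts: ``concept_id < 2_000_000_000``
* extension concepts (implementer-added, fixed registry):
  ``2_000_000_000 <= concept_id < 2_001_000_000``
* local source concepts: ``concept_id >= 2_001_000_001`` with
  ``vocabulary_id = "MIMIC code"``

Local-to-standard alignment resolves in four ordered cases: the local code
is itself a standard concept; a "Maps to" relationship exists; a manual
mapping-table entry exists; otherwise the best label-similarity candidate is
recorded as a suggestion (standard id stays 0 until confirmed) or the
concept is left unmapped.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

EXTENSION_BAND = (2_000_000_000, 2_001_000_000)
LOCAL_BAND_START = 2_001_000_001
LOCAL_VOCABULARY = "MIMIC code"

ATHENA_CONCEPT_COLUMNS = [
    "concept_id", "concept_name", "domain_id", "vocabulary_id",
    "concept_class_id", "standard_concept", "concept_code",
    "valid_start_date", "valid_end_date", "invalid_reason"]
ATHENA_RELATIONSHIP_COLUMNS = [
    "concept_id_1", "concept_id_2", "relationship_id",
    "valid_start_date", "valid_end_date", "invalid_reason"]

#: OMOP domain -> CDM fact table
DOMAIN_TABLE = {
    "Measurement": "MEASUREMENT",
    "Observation": "OBSERVATION",
    "Condition": "CONDITION_OCCURRENCE",
    "Drug": "DRUG_EXPOSURE",
    "Procedure": "PROCEDURE_OCCURRENCE",
    "Specimen": "SPECIMEN",
}

KNOWN_DOMAINS = set(DOMAIN_TABLE) | {
    "Gender", "Race", "Ethnicity", "Visit", "Type Concept", "Unit",
    "Meas Value", "Metadata", "Note", "Device", "Route", "Relationship"}


class VocabularyFormatError(ValueError):
    """Athena input does not have the expected columns."""


class VocabularyIntegrityError(ValueError):
    """Duplicate or dangling identifiers in vocabulary input."""


class VocabularyLookupError(KeyError):
    """Unknown vocabulary or domain requested."""


class RegistryCapacityError(RuntimeError):
    """Extension registry band exhausted."""


@dataclass(frozen=True)
class Concept:
    concept_id: int
    concept_name: str
    domain_id: str
    vocabulary_id: str
    concept_class_id: str = "Undefined"
    standard_concept: str | None = None  # "S" for standard
    concept_code: str = ""
    valid_start: str = "19700101"
    valid_end: str = "20991231"

    @property
    def is_standard(self) -> bool:
        return self.standard_concept == "S"

    @property
    def band(self) -> str:
        if self.concept_id < EXTENSION_BAND[0]:
            return "standard"
        if self.concept_id < EXTENSION_BAND[1]:
            return "extension"
        return "local"


@dataclass(frozen=True)
class MappingDecision:
    """Outcome of aligning one local concept to the standard vocabulary."""

    local_concept_id: int
    standard_concept_id: int
    case_tag: str  # already_standard | via_relationship | manual | suggested | unmapped
    score: float = 0.0
    comment: str = ""
    all_targets: tuple[int, ...] = ()

    def __post_init__(self):
        if (self.case_tag == "unmapped") != (self.standard_concept_id == 0
                                             and self.case_tag in
                                             ("unmapped", "suggested")):
            pass  # suggested also carries 0; checked below
        if self.case_tag in ("suggested", "unmapped"):
            assert self.standard_concept_id == 0
        else:
            assert self.standard_concept_id != 0


_token_rx = re.compile(r"[^a-z0-9 ]+")


def _tokens(label: str) -> frozenset[str]:
    return frozenset(_token_rx.sub(" ", label.lower()).split())


def label_similarity(a: str, b: str) -> float:
    """Token cosine similarity with a small exact-match bonus, in [0, 1]."""
    ta, tb = _tokens(a), _tokens(b)
    if not ta or not tb:
        return 0.0
    score = len(ta & tb) / (len(ta) * len(tb)) ** 0.5
    norm = lambda s: " ".join(sorted(_tokens(s)))
    if norm(a) == norm(b):
        score = min(score + 0.05, 1.0)
    return min(score, 1.0)


def rank_candidates(local_label: str, candidates: list[Concept],
                    k: int = 5) -> list[tuple[Concept, float]]:
    """Top-``k`` candidates by label similarity, ties broken by ascending id."""
    if not local_label or not local_label.strip():
        raise ValueError("local label must be nonempty")
    if k < 1:
        raise ValueError("k must be >= 1")
    scored = [(c, label_similarity(local_label, c.concept_name))
              for c in candidates]
    scored.sort(key=lambda cs: (-cs[1], cs[0].concept_id))
    return scored[:k]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mimic2omop").joinpath("data"))) / name


class VocabularyStore:
    """Concepts, relationships, manual mappings and the extension registry."""

    def __init__(self):
        self._concepts: dict[int, Concept] = {}
        self._by_code: dict[tuple[str, str], int] = {}
        self._maps_to: dict[int, list[int]] = {}
        self._relationships: list[tuple[int, int, str]] = []
        self._manual: dict[tuple[str, str], tuple[int, float, str]] = {}
        self._registry: dict[str, tuple[int, str]] = {}
        self._local_meta: dict[int, tuple[str, str | None, str | None]] = {}
        self._next_local = LOCAL_BAND_START

    # -- loading ------------------------------------------------------------

    @classmethod
    def load_athena_vocabulary(cls, concept_file: str | Path,
                               relationship_file: str | Path
                               ) -> "VocabularyStore":
        store = cls()
        store._load_concepts(concept_file)
        store._load_relationships(relationship_file)
        store._load_registry(_data_path("extension_registry.csv"))
        store._load_manual(_data_path("manual_concept_map.csv"))
        return store

    @classmethod
    def fixture(cls) -> "VocabularyStore":
        """The packaged synthetic fixture vocabulary."""
        base = _data_path("synthetic_vocabulary")
        return cls.load_athena_vocabulary(base / "CONCEPT.tsv",
                                          base / "CONCEPT_RELATIONSHIP.tsv")

    def _load_concepts(self, path: str | Path) -> None:
        df = pd.read_csv(path, sep="\t", dtype="object",
                         keep_default_na=False)
        missing = [c for c in ATHENA_CONCEPT_COLUMNS if c not in df.columns]
        if missing:
            raise VocabularyFormatError(
                f"{path}: missing columns {missing}")
        for row in df.itertuples(index=False):
            cid = int(row.concept_id)
            if cid in self._concepts:
                raise VocabularyIntegrityError(
                    f"duplicate concept_id {cid} in {path}")
            self._add(Concept(
                concept_id=cid, concept_name=row.concept_name,
                domain_id=row.domain_id, vocabulary_id=row.vocabulary_id,
                concept_class_id=row.concept_class_id,
                standard_concept=row.standard_concept or None,
                concept_code=row.concept_code,
                valid_start=row.valid_start_date,
                valid_end=row.valid_end_date))

    def _load_relationships(self, path: str | Path) -> None:
        df = pd.read_csv(path, sep="\t", dtype="object",
                         keep_default_na=False)
        missing = [c for c in ATHENA_RELATIONSHIP_COLUMNS
                   if c not in df.columns]
        if missing:
            raise VocabularyFormatError(f"{path}: missing columns {missing}")
        for row in df.itertuples(index=False):
            c1, c2 = int(row.concept_id_1), int(row.concept_id_2)
            for c in (c1, c2):
                if c not in self._concepts:
                    raise VocabularyIntegrityError(
                        f"relationship endpoint {c} not in store")
            self._relationships.append((c1, c2, row.relationship_id))
            if row.relationship_id == "Maps to":
                self._maps_to.setdefault(c1, []).append(c2)
        for targets in self._maps_to.values():
            targets.sort()

    def _load_registry(self, path: Path) -> None:
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                self._registry[row["concept_name"]] = (
                    int(row["concept_id"]), row["domain_id"])

    def _load_manual(self, path: Path) -> None:
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                self._manual[(row["source_table"], row["local_code"])] = (
                    int(row["standard_concept_id"]),
                    float(row["score"]), row["comment"])

    def _add(self, concept: Concept) -> None:
        self._concepts[concept.concept_id] = concept
        key = (concept.vocabulary_id, str(concept.concept_code))
        if concept.concept_code:
            if key in self._by_code:
                raise VocabularyIntegrityError(
                    f"duplicate (vocabulary, code) {key}")
            self._by_code[key] = concept.concept_id

    # -- lookups ------------------------------------------------------------

    def get(self, concept_id: int) -> Concept | None:
        return self._concepts.get(int(concept_id))

    def by_code(self, vocabulary: str, code: str) -> Concept | None:
        cid = self._by_code.get((vocabulary, str(code)))
        return self._concepts.get(cid) if cid is not None else None

    def known_vocabularies(self) -> set[str]:
        return {c.vocabulary_id for c in self._concepts.values()}

    def maps_to(self, code: str, vocabulary: str) -> list[int]:
        """Standard targets of "Maps to" relationships, ascending ids."""
        if vocabulary not in self.known_vocabularies():
            raise VocabularyLookupError(f"unknown vocabulary {vocabulary!r}")
        src = self.by_code(vocabulary, code)
        if src is None:
            return []
        return list(self._maps_to.get(src.concept_id, []))

    def standard_concepts(self, domain: str | None = None) -> list[Concept]:
        return [c for c in self._concepts.values() if c.is_standard
                and (domain is None or c.domain_id == domain)]

    def concept_frame(self) -> pd.DataFrame:
        rows = [dict(concept_id=c.concept_id, concept_name=c.concept_name,
                     domain_id=c.domain_id, vocabulary_id=c.vocabulary_id,
                     concept_class_id=c.concept_class_id,
                     standard_concept=c.standard_concept,
                     concept_code=c.concept_code,
                     valid_start_date=pd.to_datetime(c.valid_start,
                                                     format="%Y%m%d"),
                     valid_end_date=pd.to_datetime(c.valid_end,
                                                   format="%Y%m%d"))
                for c in sorted(self._concepts.values(),
                                key=lambda c: c.concept_id)]
        return pd.DataFrame(rows)

    def relationship_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._relationships,
                            columns=["concept_id_1", "concept_id_2",
                                     "relationship_id"])

    # -- registration -------------------------------------------------------

    def register_local_concept(self, name: str, domain: str,
                               source_table: str,
                               code: str | None = None,
                               code_vocabulary: str | None = None) -> Concept:
        """Register one local source concept in the local id band."""
        if not name or not name.strip():
            raise ValueError("local concept name must be nonempty")
        if domain not in KNOWN_DOMAINS:
            raise VocabularyLookupError(f"unknown domain {domain!r}")
        cid = self._next_local
        self._next_local += 1
        concept = Concept(
            concept_id=cid, concept_name=name, domain_id=domain,
            vocabulary_id=LOCAL_VOCABULARY, concept_class_id="Clinical",
            concept_code=code or "")
        self._concepts[cid] = concept  # local codes may repeat across tables
        self._local_meta[cid] = (source_table, code, code_vocabulary)
        return concept

    def register_extension_concept(self, name: str,
                                   domain: str | None = None) -> Concept:
        """Return the registry's stable extension concept for ``name``."""
        if name in self._registry:
            cid, dom = self._registry[name]
        else:
            used = {cid for cid, _ in self._registry.values()}
            cid = EXTENSION_BAND[0]
            while cid in used:
                cid += 1
            if cid >= EXTENSION_BAND[1]:
                raise RegistryCapacityError(
                    "extension registry band exhausted")
            dom = domain or "Metadata"
            self._registry[name] = (cid, dom)
        concept = Concept(concept_id=cid, concept_name=name, domain_id=dom,
                          vocabulary_id="MIMIC Extension",
                          concept_class_id="Extension",
                          standard_concept="S", concept_code=name)
        if cid not in self._concepts:
            self._concepts[cid] = concept
        return self._concepts[cid]

    def extension_id(self, name: str) -> int:
        return self.register_extension_concept(name).concept_id

    # -- alignment ----------------------------------------------------------

    def align_concept(self, local: Concept) -> MappingDecision:
        """Resolve one local concept through the four alignment cases."""
        meta = self._local_meta.get(local.concept_id)
        source_table, code, code_vocab = meta if meta else ("", None, None)

        if code and code_vocab:
            existing = self.by_code(code_vocab, code)
            if existing is not None and existing.is_standard:
                return MappingDecision(
                    local.concept_id, existing.concept_id, "already_standard",
                    1.0, f"local code is standard {code_vocab} {code}",
                    (existing.concept_id,))
            if code_vocab in self.known_vocabularies():
                targets = self.maps_to(code, code_vocab)
                if targets:
                    comment = "via Maps to"
                    if len(targets) > 1:
                        comment += (f" ({len(targets)} targets, lowest id "
                                    "chosen by convention)")
                    return MappingDecision(
                        local.concept_id, targets[0], "via_relationship",
                        1.0, comment, tuple(targets))

        key = (source_table, str(code) if code is not None else local.concept_name)
        if key in self._manual:
            target, score, comment = self._manual[key]
            return MappingDecision(local.concept_id, target, "manual",
                                   score, comment, (target,))

        candidates = self.standard_concepts(
            local.domain_id if local.domain_id in DOMAIN_TABLE else None)
        if candidates:
            ranked = rank_candidates(local.concept_name, candidates, k=1)
            best, score = ranked[0]
            if score > 0:
                return MappingDecision(
                    local.concept_id, 0, "suggested", score,
                    f"suggest {best.concept_id} ({best.concept_name})", ())
        return MappingDecision(local.concept_id, 0, "unmapped", 0.0,
                               "no equivalent found", ())

    def domain_route(self, decision: MappingDecision,
                     source_default: str) -> str:
        """Target fact table for a decision; unmapped falls back to default."""
        if decision.standard_concept_id == 0:
            return source_default
        concept = self.get(decision.standard_concept_id)
        if concept is None or concept.domain_id not in DOMAIN_TABLE:
            raise VocabularyLookupError(
                f"cannot route domain "
                f"{concept.domain_id if concept else '?'!r} of concept "
                f"{decision.standard_concept_id}")
        return DOMAIN_TABLE[concept.domain_id]

    def manual_entries(self) -> dict[tuple[str, str], tuple[int, float, str]]:
        return dict(self._manual)
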