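"""In-memory source database: the 26-table MIMIC-III-schema bundle.

Tables are pandas DataFrames keyed by lower-case table name; the on-disk
form is one ``<TABLE>.csv`` per table (upper-case file names, comma
separator, double-quote quoting, empty string for null).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .schemas import (SOURCE_TABLES, FLAG_DIALECT, coerce_table, empty_table,
                      frames_equal, read_table_csv, write_table_csv)


class SourceIntegrityError(ValueError):
    """A source-database invariant is violated."""


@dataclass
class SourceDatabase:
    """The 26-table source bundle. Every row carries a stable ``row_id``."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self):
        for name, schema in SOURCE_TABLES.items():
            if name not in self.tables:
                self.tables[name] = empty_table(schema)
            else:
                self.tables[name] = coerce_table(self.tables[name], schema)

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]

    def __setitem__(self, name: str, df: pd.DataFrame) -> None:
        if name not in SOURCE_TABLES:
            raise KeyError(f"unknown source table {name!r}")
        self.tables[name] = coerce_table(df, SOURCE_TABLES[name])

    def copy(self) -> "SourceDatabase":
        return SourceDatabase({k: v.copy() for k, v in self.tables.items()})

    # -- persistence --------------------------------------------------------

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, schema in SOURCE_TABLES.items():
            write_table_csv(self.tables[name], schema,
                            path / f"{name.upper()}.csv")
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "SourceDatabase":
        path = Path(path)
        tables = {}
        for name, schema in SOURCE_TABLES.items():
            f = path / f"{name.upper()}.csv"
            if f.exists():
                tables[name] = read_table_csv(f, schema)
        return cls(tables)

    def equals(self, other: "SourceDatabase") -> bool:
        return all(frames_equal(self.tables[n], other.tables[n])
                   for n in SOURCE_TABLES)

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`SourceIntegrityError` on any invariant violation."""
        t = self.tables
        subjects = set(t["patients"]["subject_id"].dropna())
        adm_subjects = set(t["admissions"]["subject_id"].dropna())
        if not adm_subjects <= subjects:
            raise SourceIntegrityError(
                f"admissions reference unknown subjects: "
                f"{sorted(adm_subjects - subjects)[:5]}")
        hadm_ids = set(t["admissions"]["hadm_id"].dropna())
        for name in ("transfers", "services", "chartevents", "labevents",
                     "outputevents", "microbiologyevents", "prescriptions",
                     "inputevents_cv", "inputevents_mv", "procedureevents_mv",
                     "procedures_icd", "diagnoses_icd", "cptevents",
                     "noteevents", "datetimeevents", "drgcodes", "callout",
                     "icustays"):
            refs = set(t[name]["hadm_id"].dropna())
            if not refs <= hadm_ids:
                raise SourceIntegrityError(
                    f"{name} references unknown hadm_id: "
                    f"{sorted(refs - hadm_ids)[:5]}")
        lab_items = set(t["d_labitems"]["itemid"].dropna())
        lab_refs = set(t["labevents"]["itemid"].dropna())
        if not lab_refs <= lab_items:
            raise SourceIntegrityError(
                f"labevents reference unknown itemid: "
                f"{sorted(lab_refs - lab_items)[:5]}")
        # transfers per admission: time-ordered and non-overlapping
        tr = t["transfers"].dropna(subset=["hadm_id", "intime", "outtime"])
        for hadm, grp in tr.groupby("hadm_id", sort=False):
            g = grp.sort_values("intime")
            if (g["outtime"] < g["intime"]).any():
                raise SourceIntegrityError(
                    f"transfer interval reversed in admission {hadm}")
            if (g["intime"].iloc[1:].values <
                    g["outtime"].iloc[:-1].values).any():
                raise SourceIntegrityError(
                    f"overlapping transfers in admission {hadm}")

    def table_flag_counts(self) -> dict[str, int]:
        """Number of error/cancel-flagged rows per flagged table."""
        out = {}
        for name, (col, bad) in FLAG_DIALECT.items():
            out[name] = int((self.tables[name][col] == bad).sum())
        return out


def source_archive_roundtrip(db: SourceDatabase, path: str | Path) -> SourceDatabase:
    """Write ``db`` to ``path`` and read it back (round-trip contract)."""
    db.write_csv(path)
    return SourceDatabase.read_csv(path)
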