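"""Relational mapping of GDM metadata into an extended conceptual schema.

The star schema is centered on Item (one GWAS study file).  Each Item has
exactly one Cohort (the case/control population studied for one trait) and a
Cohort references any number of Ancestry rows (partitions of the population
with geographic/ancestral descriptors).  A CaseStudy groups Items by
publication.  The knowledge-base tables (vocabulary, synonym, reference,
ontology, relationship) live in the same store and are populated by the
enrichment step.

Mapping is declarative: a rules file per source lists
(attribute pattern -> table.column, transform).  Patterns are anchored
regular expressions over metadata attribute names; an optional
``(?P<ordinal>\\d+)`` group routes matches into per-ordinal Ancestry rows.
New sources therefore need configuration, not code.
"""

from __future__ import annotations

import logging
import re
import sqlite3
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .gdm import GdmDataset, GdmSample

logger = logging.getLogger(__name__)


class RuleConflictError(ValueError):
    """Two mapping rules claim the same attribute with different targets."""


class MappingError(ValueError):
    pass


DDL = """
CREATE TABLE IF NOT EXISTS case_study (
    case_study_id INTEGER PRIMARY KEY,
    pubmed_id TEXT,
    source_site TEXT
);
CREATE TABLE IF NOT EXISTS item (
    item_id INTEGER PRIMARY KEY,
    source_id TEXT NOT NULL,
    dataset_name TEXT NOT NULL,
    case_study_id INTEGER REFERENCES case_study(case_study_id),
    UNIQUE (source_id, dataset_name)
);
CREATE TABLE IF NOT EXISTS cohort (
    cohort_id INTEGER PRIMARY KEY,
    item_id INTEGER NOT NULL UNIQUE REFERENCES item(item_id),
    trait_name TEXT,
    trait_name_tid INTEGER REFERENCES vocabulary(tid),
    initial_cases INTEGER, initial_controls INTEGER,
    initial_individuals INTEGER, initial_trios INTEGER,
    replication_cases INTEGER, replication_controls INTEGER,
    replication_individuals INTEGER, replication_trios INTEGER
);
CREATE TABLE IF NOT EXISTS ancestry (
    ancestry_id INTEGER PRIMARY KEY,
    cohort_id INTEGER NOT NULL REFERENCES cohort(cohort_id),
    ordinal INTEGER NOT NULL,
    broad_ancestral_category TEXT,
    country_of_origin TEXT,
    country_of_recruitment TEXT,
    number_of_individuals INTEGER,
    stage TEXT,
    UNIQUE (cohort_id, ordinal)
);
CREATE TABLE IF NOT EXISTS pair_spill (
    item_id INTEGER NOT NULL REFERENCES item(item_id),
    position INTEGER NOT NULL,
    attribute TEXT NOT NULL,
    value TEXT
);
CREATE TABLE IF NOT EXISTS vocabulary (
    tid INTEGER PRIMARY KEY,
    ontology TEXT NOT NULL,
    code TEXT NOT NULL,
    pref_label TEXT,
    description TEXT,
    iri TEXT,
    UNIQUE (ontology, code)
);
CREATE TABLE IF NOT EXISTS synonym (
    tid INTEGER NOT NULL REFERENCES vocabulary(tid),
    label TEXT NOT NULL,
    UNIQUE (tid, label)
);
CREATE TABLE IF NOT EXISTS reference (
    tid INTEGER NOT NULL REFERENCES vocabulary(tid),
    xref TEXT NOT NULL,
    UNIQUE (tid, xref)
);
CREATE TABLE IF NOT EXISTS ontology (
    name TEXT PRIMARY KEY,
    acceptance REAL
);
CREATE TABLE IF NOT EXISTS relationship (
    parent_tid INTEGER NOT NULL REFERENCES vocabulary(tid),
    child_tid INTEGER NOT NULL REFERENCES vocabulary(tid),
    kind TEXT NOT NULL,
    UNIQUE (parent_tid, child_tid, kind)
);
CREATE TABLE IF NOT EXISTS curation_queue (
    cohort_id INTEGER NOT NULL REFERENCES cohort(cohort_id),
    raw_value TEXT NOT NULL,
    suggestions TEXT,
    UNIQUE (cohort_id, raw_value)
);
"""

TABLES = (
    "case_study",
    "item",
    "cohort",
    "ancestry",
    "pair_spill",
    "vocabulary",
    "synonym",
    "reference",
    "ontology",
    "relationship",
    "curation_queue",
)

_TRANSFORMS = {"identity": lambda v: v, "int": None}  # int handled specially (nullable)


@dataclass(frozen=True)
class MappingRule:
    attribute_pattern: str
    target_table: str
    target_column: str
    value_transform: str = "identity"

    def __post_init__(self) -> None:
        if self.value_transform not in _TRANSFORMS:
            raise MappingError(f"unknown transform {self.value_transform!r}")
        re.compile(self.attribute_pattern)

    @property
    def target(self) -> tuple[str, str]:
        return (self.target_table, self.target_column)

    def match(self, attribute: str) -> re.Match | None:
        return re.fullmatch(self.attribute_pattern, attribute)


def load_rules(path_or_source: Path | str) -> list[MappingRule]:
    """Load mapping rules from a YAML file, or by source name for shipped rules."""
    path = Path(path_or_source)
    if not path.exists():
        ref = resources.files("gwaskit") / "rules" / f"{path_or_source}.yaml"
        if not ref.is_file():
            raise FileNotFoundError(f"no rules file or shipped ruleset named {path_or_source!r}")
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(path.read_text())
    return [MappingRule(**entry) for entry in raw]


class RelationalStore:
    """Thin wrapper over a sqlite database holding the mapped schema."""

    def __init__(self, path: Path | str | None = None):
        self.conn = sqlite3.connect(str(path) if path else ":memory:")
        self.conn.executescript(DDL)

    def close(self) -> None:
        self.conn.close()

    def query(self, sql: str, params: tuple = ()) -> list[tuple]:
        return self.conn.execute(sql, params).fetchall()

    def scalar(self, sql: str, params: tuple = ()):
        row = self.conn.execute(sql, params).fetchone()
        return row[0] if row else None

    def counts(self) -> dict[str, int]:
        return {t: self.scalar(f"SELECT COUNT(*) FROM {t}") for t in TABLES}


def _cast_int(value: str, attribute: str) -> int | None:
    try:
        return int(float(value))
    except (TypeError, ValueError):
        logger.warning("attribute %s: cannot cast %r to integer, stored NULL", attribute, value)
        return None


def _route(rules: list[MappingRule], attribute: str) -> tuple[MappingRule, re.Match] | None:
    hits = [(r, m) for r in rules for m in [r.match(attribute)] if m]
    targets = {r.target for r, _ in hits}
    if len(targets) > 1:
        raise RuleConflictError(
            f"attribute {attribute!r} matched by rules with conflicting targets: {sorted(targets)}"
        )
    return hits[0] if hits else None


def map_sample(
    store: RelationalStore, sample: GdmSample, dataset_name: str, rules: list[MappingRule]
) -> int:
    """Map one sample's metadata into the store; returns the new item_id."""
    cur = store.conn.cursor()
    item_values: dict[str, str] = {}
    case_values: dict[str, str] = {}
    cohort_values: dict[str, object] = {}
    ancestry_values: dict[int, dict[str, object]] = {}
    spill: list[tuple[int, str, str]] = []

    for position, (attribute, value) in enumerate(sample.metadata):
        routed = _route(rules, attribute)
        if routed is None:
            spill.append((position, attribute, value))
            continue
        rule, match = routed
        cast = _cast_int(value, attribute) if rule.value_transform == "int" else value
        if rule.target_table == "ancestry":
            ordinal = int(match.group("ordinal"))
            ancestry_values.setdefault(ordinal, {})[rule.target_column] = cast
        elif rule.target_table == "cohort":
            cohort_values[rule.target_column] = cast
        elif rule.target_table == "case_study":
            case_values[rule.target_column] = str(cast)
        elif rule.target_table == "item":
            item_values[rule.target_column] = str(cast)
        else:
            raise MappingError(f"rule targets unknown table {rule.target_table!r}")

    ordinals = sorted(ancestry_values)
    if ordinals and ordinals != list(range(1, len(ordinals) + 1)):
        raise MappingError(
            f"sample {sample.sample_id!r}: ancestry ordinals {ordinals} not contiguous from 1"
        )

    cur.execute(
        "INSERT INTO case_study (pubmed_id, source_site) VALUES (?, ?)",
        (case_values.get("pubmed_id", ""), case_values.get("source_site", dataset_name)),
    )
    case_study_id = cur.lastrowid
    cur.execute(
        "INSERT INTO item (source_id, dataset_name, case_study_id) VALUES (?, ?, ?)",
        (item_values.get("source_id", sample.sample_id), dataset_name, case_study_id),
    )
    item_id = cur.lastrowid

    cohort_cols = ["item_id"] + [c for c in cohort_values]
    cur.execute(
        f"INSERT INTO cohort ({', '.join(cohort_cols)}) VALUES ({', '.join('?' * len(cohort_cols))})",
        (item_id, *cohort_values.values()),
    )
    cohort_id = cur.lastrowid

    for ordinal in ordinals:
        vals = ancestry_values[ordinal]
        cols = ["cohort_id", "ordinal"] + list(vals)
        cur.execute(
            f"INSERT INTO ancestry ({', '.join(cols)}) VALUES ({', '.join('?' * len(cols))})",
            (cohort_id, ordinal, *vals.values()),
        )

    cur.executemany(
        "INSERT INTO pair_spill (item_id, position, attribute, value) VALUES (?, ?, ?, ?)",
        [(item_id, p, a, v) for p, a, v in spill],
    )
    store.conn.commit()
    return item_id


def map_dataset(
    dataset: GdmDataset, rules: list[MappingRule], store: RelationalStore | None = None
) -> RelationalStore:
    """Map a whole GDM dataset: one Item + one Cohort per sample."""
    store = store or RelationalStore()
    for sample in dataset.samples:
        map_sample(store, sample, dataset.name, rules)
    return store


def export_store(store: RelationalStore, directory: Path | str) -> Path:
    """Write portable DDL plus one header-bearing TSV dump per table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "schema.sql").write_text(DDL.strip() + "\n", encoding="utf-8")
    for table in TABLES:
        cur = store.conn.execute(f"SELECT * FROM {table}")
        header = [d[0] for d in cur.description]
        with open(directory / f"{table}.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(header) + "\n")
            for row in cur.fetchall():
                fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")
    return directory


def load_store(directory: Path | str) -> RelationalStore:
    """Reload an exported store; inverse of :func:`export_store` up to row multisets."""
    directory = Path(directory)
    store = RelationalStore()
    store.conn.executescript((directory / "schema.sql").read_text(encoding="utf-8"))
    for table in TABLES:
        path = directory / f"{table}.tsv"
        if not path.exists():
            continue
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                values = [None if v == "" else v for v in line.rstrip("\n").split("\t")]
                store.conn.execute(
                    f"INSERT INTO {table} ({', '.join(header)}) "
                    f"VALUES ({', '.join('?' * len(header))})",
                    values,
                )
    store.conn.commit()
    return store
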