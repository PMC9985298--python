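"""Semantic enrichment of cohort trait names with ontology terms.

For every cohort whose ``trait_name`` is not yet linked, the enricher first
looks the value up in the knowledge base (exact label/synonym match); only
when that fails does it query the configured term source, score every
candidate with the word-alignment match score, rank by annotation score, and
either auto-link (``trait_name_tid``) when the best match reaches the
minimum match score (default 5) or queue the value for manual curation with
ranked suggestions.  Original trait values are never modified — enrichment
only adds links.

Linked terms are materialized in the knowledge-base tables (vocabulary,
synonym, reference, ontology, relationship), with ancestors and descendants
traversed up to a configurable number of ontology levels (default 3),
recording the relation kind (``is_a`` / ``part_of``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .gcm import RelationalStore
from .scoring import (
    DEFAULT_MIN_MATCH,
    AnnotationCandidate,
    ParsedValue,
    annotation_score,
    match_score,
    ontology_scores,
    parse_raw_value,
)
from .terms import TermRecord, TermSource

logger = logging.getLogger(__name__)

DEFAULT_KB_DEPTH = 3


def load_default_acceptance() -> dict[str, float]:
    """Shipped per-ontology acceptance (trust) map; an external configuration input."""
    text = (resources.files("gwaskit") / "data" / "ontology_acceptance.yaml").read_text(
        encoding="utf-8"
    )
    return {str(k): float(v) for k, v in yaml.safe_load(text).items()}


class KnowledgeBase:
    """Vocabulary/synonym/reference/ontology/relationship tables in a relational store."""

    def __init__(self, store: RelationalStore):
        self.store = store

    def tid_of(self, ontology: str, code: str) -> int | None:
        return self.store.scalar(
            "SELECT tid FROM vocabulary WHERE ontology = ? AND code = ?", (ontology, code)
        )

    def lookup_label(self, parsed: str, ontologies: list[str] | None = None) -> int | None:
        """Exact, case-insensitive match of a parsed value against stored labels.

        Preferred-label matches win over synonym matches; ties resolve to the
        smallest tid (insertion order) for determinism.
        """
        onto_clause, params = "", [parsed]
        if ontologies:
            onto_clause = f" AND v.ontology IN ({','.join('?' * len(ontologies))})"
            params += list(ontologies)
        tid = self.store.scalar(
            "SELECT v.tid FROM vocabulary v WHERE lower(v.pref_label) = lower(?)"
            + onto_clause
            + " ORDER BY v.tid LIMIT 1",
            tuple(params),
        )
        if tid is not None:
            return tid
        return self.store.scalar(
            "SELECT s.tid FROM synonym s JOIN vocabulary v ON v.tid = s.tid "
            "WHERE lower(s.label) = lower(?)" + onto_clause + " ORDER BY s.tid LIMIT 1",
            tuple(params),
        )

    def insert_term(self, term: TermRecord) -> int:
        """Insert one term (idempotent); returns its tid."""
        existing = self.tid_of(term.ontology, term.ontology_id)
        if existing is not None:
            return existing
        cur = self.store.conn.cursor()
        cur.execute(
            "INSERT INTO vocabulary (ontology, code, pref_label, description, iri) "
            "VALUES (?, ?, ?, ?, ?)",
            (term.ontology, term.ontology_id, term.pref_label, term.description, term.iri),
        )
        tid = cur.lastrowid
        cur.executemany(
            "INSERT OR IGNORE INTO synonym (tid, label) VALUES (?, ?)",
            [(tid, s) for s in term.synonyms],
        )
        cur.executemany(
            "INSERT OR IGNORE INTO reference (tid, xref) VALUES (?, ?)",
            [(tid, x) for x in term.xrefs],
        )
        cur.execute(
            "INSERT OR IGNORE INTO ontology (name, acceptance) VALUES (?, NULL)", (term.ontology,)
        )
        self.store.conn.commit()
        return tid

    def set_acceptance(self, acceptance: dict[str, float]) -> None:
        self.store.conn.executemany(
            "INSERT INTO ontology (name, acceptance) VALUES (?, ?) "
            "ON CONFLICT(name) DO UPDATE SET acceptance = excluded.acceptance",
            sorted(acceptance.items()),
        )
        self.store.conn.commit()

    def add_relationship(self, parent_tid: int, child_tid: int, kind: str) -> None:
        self.store.conn.execute(
            "INSERT OR IGNORE INTO relationship (parent_tid, child_tid, kind) VALUES (?, ?, ?)",
            (parent_tid, child_tid, kind),
        )
        self.store.conn.commit()


def populate_kb(
    kb: KnowledgeBase,
    term: TermRecord,
    term_source: TermSource,
    levels: int = DEFAULT_KB_DEPTH,
) -> int:
    """Insert a term and its hierarchy up to ``levels`` ontology levels away.

    Ancestors (hyperonyms) and descendants (hyponyms) are traversed
    breadth-first through the term source; dangling references are skipped
    with a warning.  Re-inserting an existing term adds nothing.  Returns the
    tid of the base term.
    """
    if levels < 0:
        raise ValueError("levels must be >= 0")
    tid = kb.insert_term(term)

    def walk(base: TermRecord, base_tid: int, upward: bool) -> None:
        frontier = [(base, base_tid)]
        for _ in range(levels):
            nxt = []
            for node, node_tid in frontier:
                links = node.parents if upward else node.children
                for other_id, kind in links:
                    other = term_source.get(node.ontology, other_id)
                    if other is None:
                        logger.warning(
                            "term %s:%s references missing term %s, relationship skipped",
                            node.ontology,
                            node.ontology_id,
                            other_id,
                        )
                        continue
                    other_tid = kb.insert_term(other)
                    if upward:
                        kb.add_relationship(other_tid, node_tid, kind)
                    else:
                        kb.add_relationship(node_tid, other_tid, kind)
                    nxt.append((other, other_tid))
            frontier = nxt
            if not frontier:
                break

    walk(term, tid, upward=True)
    walk(term, tid, upward=False)
    return tid


@dataclass
class EnrichmentReport:
    linked: list[tuple[int, str, int]] = field(default_factory=list)  # (cohort_id, raw, tid)
    queued: list[tuple[int, str]] = field(default_factory=list)
    kb_hits: int = 0

    @property
    def n_linked(self) -> int:
        return len(self.linked)

    @property
    def n_queued(self) -> int:
        return len(self.queued)


def _best_candidates(
    parsed_values: list[ParsedValue],
    terms: list[TermRecord],
) -> dict[str, list[AnnotationCandidate]]:
    """Best candidate per (parsed value, ontology), grouped by ontology."""
    by_onto: dict[str, dict[tuple[str, str], AnnotationCandidate]] = {}
    for pv in parsed_values:
        for term in terms:
            cand = match_score(pv, term)
            if cand.match_score <= 0:
                continue  # not a partial match; the value is not annotated by this term
            bucket = by_onto.setdefault(term.ontology, {})
            key = (pv.raw, pv.parsed)
            prev = bucket.get(key)
            if prev is None or _cand_order(cand) < _cand_order(prev):
                bucket[key] = cand
    return {onto: list(bucket.values()) for onto, bucket in by_onto.items()}


def _cand_order(c: AnnotationCandidate) -> tuple:
    # Deterministic preference: higher match, preferred-label basis,
    # then ontology name and id.
    return (-c.match_score, 0 if c.basis == "P" else 1, c.term.ontology, c.term.ontology_id)


def enrich(
    store: RelationalStore,
    kb: KnowledgeBase,
    chosen_ontologies: list[str],
    term_source: TermSource,
    acceptance: dict[str, float] | None = None,
    min_match: float = DEFAULT_MIN_MATCH,
    weights: tuple[float, float] | None = None,
    kb_depth: int = DEFAULT_KB_DEPTH,
) -> EnrichmentReport:
    """Annotate every unlinked cohort trait_name; idempotent on rerun.

    Values whose best candidate reaches ``min_match`` are auto-linked and the
    term (plus its hierarchy) lands in the knowledge base; the rest are
    queued for manual curation with ranked suggestions.
    """
    acceptance = acceptance if acceptance is not None else load_default_acceptance()
    kb.set_acceptance({o: acceptance[o] for o in chosen_ontologies if o in acceptance})
    pending = store.query(
        "SELECT cohort_id, trait_name FROM cohort "
        "WHERE trait_name_tid IS NULL AND trait_name IS NOT NULL AND trait_name != '' "
        "ORDER BY cohort_id"
    )
    report = EnrichmentReport()
    if not pending:
        return report

    # Knowledge-base lookup first; values it resolves never reach the term source.
    unresolved: list[tuple[int, str, list[ParsedValue]]] = []
    for cohort_id, raw in pending:
        parsed_values = parse_raw_value(raw)
        tid = None
        for pv in parsed_values:
            tid = kb.lookup_label(pv.parsed, chosen_ontologies)
            if tid is not None:
                break
        if tid is not None:
            _link(store, cohort_id, tid)
            report.linked.append((cohort_id, raw, tid))
            report.kb_hits += 1
        elif parsed_values:
            unresolved.append((cohort_id, raw, parsed_values))
        else:
            _queue(store, cohort_id, raw, [])
            report.queued.append((cohort_id, raw))
    if not unresolved:
        return report

    try:
        terms = term_source.search("", chosen_ontologies)
    except Exception as exc:
        logger.warning("term source unavailable (%s); unresolved values queued", exc)
        for cohort_id, raw, _ in unresolved:
            _queue(store, cohort_id, raw, [])
            report.queued.append((cohort_id, raw))
        return report

    all_parsed = [pv for _, _, pvs in unresolved for pv in pvs]
    by_onto = _best_candidates(all_parsed, terms)
    n_raw = len({raw for _, raw, _ in unresolved})
    scores = ontology_scores(by_onto, n_raw, acceptance)
    suit_by_onto = {s.ontology: s.suitability for s in scores}

    for cohort_id, raw, parsed_values in unresolved:
        candidates: list[AnnotationCandidate] = []
        for onto, anns in by_onto.items():
            candidates.extend(a for a in anns if a.parsed_value.raw == raw)
        if not candidates:
            _queue(store, cohort_id, raw, [])
            report.queued.append((cohort_id, raw))
            continue
        scored = [
            annotation_score(c, suit_by_onto[c.term.ontology], acceptance[c.term.ontology], weights)
            for c in candidates
        ]
        scored.sort(key=lambda s: (-s.annotation_score,) + _cand_order(s.candidate))
        best = scored[0]
        if best.candidate.match_score >= min_match:
            tid = populate_kb(kb, best.candidate.term, term_source, kb_depth)
            _link(store, cohort_id, tid)
            report.linked.append((cohort_id, raw, tid))
        else:
            _queue(store, cohort_id, raw, scored[:5])
            report.queued.append((cohort_id, raw))
    return report


def _link(store: RelationalStore, cohort_id: int, tid: int) -> None:
    store.conn.execute("UPDATE cohort SET trait_name_tid = ? WHERE cohort_id = ?", (tid, cohort_id))
    store.conn.execute("DELETE FROM curation_queue WHERE cohort_id = ?", (cohort_id,))
    store.conn.commit()


def _queue(store: RelationalStore, cohort_id: int, raw: str, suggestions: list) -> None:
    payload = json.dumps(
        [
            {
                "ontology": s.candidate.term.ontology,
                "ontology_id": s.candidate.term.ontology_id,
                "pref_label": s.candidate.term.pref_label,
                "match_score": s.candidate.match_score,
                "annotation_score": s.annotation_score,
            }
            for s in suggestions
        ]
    )
    store.conn.execute(
        "INSERT OR REPLACE INTO curation_queue (cohort_id, raw_value, suggestions) VALUES (?, ?, ?)",
        (cohort_id, raw, payload),
    )
    store.conn.commit()


def export_curation_queue(store: RelationalStore, path: Path | str) -> Path:
    """Write the manual-curation queue as a review-friendly TSV."""
    path = Path(path)
    rows = store.query(
        "SELECT q.cohort_id, q.raw_value, q.suggestions FROM curation_queue q ORDER BY q.cohort_id"
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("cohort_id\traw_value\tsuggestions\n")
        for cohort_id, raw, suggestions in rows:
            fh.write(f"{cohort_id}\t{raw}\t{suggestions}\n")
    return path


def common_concepts(store: RelationalStore) -> dict[tuple[str, str], dict[str, list[str]]]:
    """Terms referenced by cohorts of more than one source dataset.

    Returns {(ontology, code): {dataset_name: [item source_ids]}} for every
    vocabulary term linked from at least two distinct dataset names.
    """
    rows = store.query(
        "SELECT v.ontology, v.code, i.dataset_name, i.source_id "
        "FROM cohort c JOIN item i ON i.item_id = c.item_id "
        "JOIN vocabulary v ON v.tid = c.trait_name_tid "
        "WHERE c.trait_name_tid IS NOT NULL ORDER BY v.ontology, v.code, i.dataset_name, i.source_id"
    )
    by_term: dict[tuple[str, str], dict[str, list[str]]] = {}
    for onto, code, dataset, source_id in rows:
        by_term.setdefault((onto, code), {}).setdefault(dataset, []).append(source_id)
    return {term: groups for term, groups in by_term.items() if len(groups) >= 2}


def common_concepts_from_sets(annotations_by_source: dict[str, set]) -> set:
    """Intersection of referenced term ids across two or more sources."""
    sets = list(annotations_by_source.values())
    if not sets:
        return set()
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out
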