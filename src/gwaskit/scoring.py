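"""Trait-annotation scoring: word alignment, match/suitability/annotation scores.

The annotator measures how well an ontology term label matches a phenotype
trait value with a word-level global alignment in the Needleman-Wunsch
style: the units aligned are whole words, not characters, and the distance
is the minimum total cost over all order-respecting alignments under

    ==========================  ====
    matching word               0
    adjacent-word swap          0.5
    label-only word (insert)    1
    query-only word (delete)    2
    mismatched word             2.5
    ==========================  ====

so the alignment minimizes deletions and prefers swaps to indels or
mismatches.  A term's *match_score* is an initial score of 10 (preferred
label) or 9 (synonym) minus that distance.

Per ontology, *coverage* is the fraction of raw values it annotates and
*suitability* is coverage times the mean match_score of its annotations, so
an ontology scores higher when it matches values with preferred labels
rather than synonyms.  Each annotation's *annotation_score* is its
match_score times a linear combination ``w_suit * suitability +
w_acc * acceptance``, where acceptance is an externally supplied trust score
per ontology.  The default weights are recovered by least squares from the
packaged reference table of scored annotations (they land at 0.08 / 0.20).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .terms import TermRecord

logger = logging.getLogger(__name__)

MATCH_COST = 0.0
SWAP_COST = 0.5
INSERT_COST = 1.0  # label-side extra word
DELETE_COST = 2.0  # query-side extra word
MISMATCH_COST = 2.5

INITIAL_SCORE = {"P": 10.0, "S": 9.0}
DEFAULT_MIN_MATCH = 5.0
DEFAULT_COVERAGE_TARGET = 0.85

_EDGE_PUNCT = re.compile(r"^[^\w]+|[^\w]+$")


def tokenize(text: str) -> tuple[str, ...]:
    """Lowercase, whitespace-split, strip punctuation at token edges.

    Punctuation *inside* a token (hyphens, colons) is part of the word:
    "magnesium:creatinine" and "pre-eclampsia" are single tokens.
    """
    tokens = []
    for word in text.lower().split():
        word = _EDGE_PUNCT.sub("", word)
        if word:
            tokens.append(word)
    return tuple(tokens)


@dataclass(frozen=True)
class ParsedValue:
    raw: str
    parsed: str
    tokens: tuple[str, ...]


def parse_raw_value(raw: str) -> list[ParsedValue]:
    """Split a raw trait value into parsed values (one per comma-separated part).

    Each part is lowercased and whitespace-collapsed; parts that normalize to
    nothing are dropped (an all-punctuation raw value yields an empty list,
    with a warning).
    """
    out: list[ParsedValue] = []
    for segment in raw.split(","):
        tokens = tokenize(segment)
        if tokens:
            out.append(ParsedValue(raw=raw, parsed=" ".join(tokens), tokens=tokens))
    if not out:
        logger.warning("raw value %r contains no words, nothing to annotate", raw)
    return out


def word_distance(query_tokens: tuple[str, ...] | list[str], label_tokens: tuple[str, ...] | list[str]) -> float:
    """Minimum-cost order-respecting alignment distance between two word lists.

    Dynamic programming over (query prefix, label prefix) with a
    Damerau-style extension for adjacent transpositions; word comparison is
    case-insensitive.
    """
    q = [t.lower() for t in query_tokens]
    l = [t.lower() for t in label_tokens]
    m, n = len(q), len(l)
    d = np.empty((m + 1, n + 1))
    d[:, 0] = np.arange(m + 1) * DELETE_COST
    d[0, :] = np.arange(n + 1) * INSERT_COST
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best = min(
                d[i - 1, j] + DELETE_COST,
                d[i, j - 1] + INSERT_COST,
                d[i - 1, j - 1] + (MATCH_COST if q[i - 1] == l[j - 1] else MISMATCH_COST),
            )
            if i >= 2 and j >= 2 and q[i - 1] == l[j - 2] and q[i - 2] == l[j - 1]:
                best = min(best, d[i - 2, j - 2] + SWAP_COST)
            d[i, j] = best
    return float(d[m, n])


@dataclass(frozen=True)
class AnnotationCandidate:
    parsed_value: ParsedValue
    term: TermRecord
    basis: str  # "P" (pref_label) or "S" (synonym)
    matched_label: str
    distance: float
    match_score: float


def match_score(parsed: ParsedValue, term: TermRecord) -> AnnotationCandidate:
    """Best-scoring alignment of a parsed value against a term's labels.

    The preferred label starts from 10, every synonym from 9; the candidate
    with the highest resulting score wins.  Ties prefer the preferred label,
    then the lexicographically smallest label (determinism).
    """
    options: list[tuple[float, int, str, str, float]] = []
    d = word_distance(parsed.tokens, tokenize(term.pref_label))
    options.append((INITIAL_SCORE["P"] - d, 0, term.pref_label, "P", d))
    for syn in term.synonyms:
        d = word_distance(parsed.tokens, tokenize(syn))
        options.append((INITIAL_SCORE["S"] - d, 1, syn, "S", d))
    score, _, label, basis, distance = min(options, key=lambda o: (-o[0], o[1], o[2]))
    return AnnotationCandidate(
        parsed_value=parsed,
        term=term,
        basis=basis,
        matched_label=label,
        distance=distance,
        match_score=score,
    )


@dataclass(frozen=True)
class OntologyScore:
    ontology: str
    coverage: float
    acceptance: float
    suitability: float


def ontology_scores(
    annotations_by_ontology: dict[str, list[AnnotationCandidate]],
    n_raw_values: int,
    acceptance: dict[str, float],
) -> list[OntologyScore]:
    """Per-ontology coverage and suitability over one annotation run.

    Coverage counts *raw* values: a raw value is covered by an ontology if
    any of its parsed values received an annotation there.  Suitability is
    coverage times the mean match_score over all of the ontology's
    annotations.
    """
    out = []
    for onto in sorted(annotations_by_ontology):
        anns = annotations_by_ontology[onto]
        if onto not in acceptance:
            raise KeyError(f"no acceptance score configured for ontology {onto!r}")
        if not anns or n_raw_values == 0:
            out.append(OntologyScore(onto, 0.0, acceptance[onto], 0.0))
            continue
        covered = len({a.parsed_value.raw for a in anns})
        coverage = covered / n_raw_values
        mean_match = sum(a.match_score for a in anns) / len(anns)
        out.append(OntologyScore(onto, coverage, acceptance[onto], coverage * mean_match))
    return out


@dataclass(frozen=True)
class ScoredAnnotation:
    candidate: AnnotationCandidate
    annotation_score: float


def annotation_score(
    candidate: AnnotationCandidate,
    suitability: float,
    acceptance: float,
    weights: tuple[float, float] | None = None,
) -> ScoredAnnotation:
    """match_score x (w_suit * suitability + w_acc * acceptance), to 2 decimals."""
    w_suit, w_acc = weights if weights is not None else default_weights()
    if w_suit < 0 or w_acc < 0:
        raise ValueError("annotation-score weights must be nonnegative")
    score = candidate.match_score * (w_suit * suitability + w_acc * acceptance)
    return ScoredAnnotation(candidate=candidate, annotation_score=round(score, 2))


def fit_weights(rows: list[tuple[float, float, float, float]]) -> tuple[float, float]:
    """Recover (w_suit, w_acc) by least squares from scored-annotation rows.

    Each row is (match_score, suitability, acceptance, annotation_score); the
    model is annotation = match * (w_suit * suit + w_acc * acc).  Raises on a
    rank-deficient system (fewer than two independent rows).
    """
    if len(rows) < 2:
        raise ValueError("need at least two rows to fit two weights")
    a = np.array([[m * s, m * c] for m, s, c, _ in rows], dtype=float)
    b = np.array([y for *_, y in rows], dtype=float)
    if np.linalg.matrix_rank(a) < 2:
        raise ValueError("rank-deficient system: rows are not linearly independent")
    solution, *_ = np.linalg.lstsq(a, b, rcond=None)
    return float(solution[0]), float(solution[1])


def load_reference_annotations() -> list[dict]:
    """Packaged reference table of scored trait annotations (worked examples)."""
    text = (resources.files("gwaskit") / "data" / "trait_annotation_examples.tsv").read_text(
        encoding="utf-8"
    )
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    rows = []
    for line in lines[1:]:
        rec = dict(zip(header, line.split("\t")))
        for col in ("match_score", "onto_suitability", "onto_acceptance", "annotation_score"):
            rec[col] = float(rec[col])
        rows.append(rec)
    return rows


@lru_cache(maxsize=1)
def default_weights() -> tuple[float, float]:
    """Least-squares fit of the linear-combination weights over the reference table."""
    rows = [
        (r["match_score"], r["onto_suitability"], r["onto_acceptance"], r["annotation_score"])
        for r in load_reference_annotations()
    ]
    return fit_weights(rows)


@dataclass(frozen=True)
class OntologySetMetrics:
    ontologies: tuple[str, ...]
    set_coverage: float
    set_score: float
    set_suitability: float


def select_ontology_set(
    raw_values: list[str],
    annotations_by_ontology: dict[str, list[AnnotationCandidate]],
    scores: list[OntologyScore],
    coverage_target: float = DEFAULT_COVERAGE_TARGET,
    rank_by: str = "suitability",
) -> tuple[OntologySetMetrics, list[OntologySetMetrics]]:
    """Greedy selection of a small ontology set reaching the coverage target.

    Ontologies are ranked by ``rank_by`` ("suitability" or "coverage").  The
    top-ranked ontology annotates whatever it can; each following ontology is
    consulted only for the values still unmatched and is added to the set only
    if it covers at least one of them.  Selection stops as soon as the
    cumulative coverage reaches ``coverage_target`` or no further ontology
    makes progress (the unmatched set reaches a fixed point).

    Returns the metrics of the chosen set plus the per-step trajectory (one
    entry per added ontology); coverage is nondecreasing along the trajectory.
    """
    if not scores:
        raise ValueError("no ontologies to select from")
    if rank_by not in {"suitability", "coverage"}:
        raise ValueError(f"unknown ranking criterion {rank_by!r}")
    score_by_onto = {s.ontology: s for s in scores}
    ranked = sorted(scores, key=lambda s: (-getattr(s, rank_by), s.ontology))

    best_by_value: dict[str, dict[str, AnnotationCandidate]] = {}
    for onto, anns in annotations_by_ontology.items():
        per_value: dict[str, AnnotationCandidate] = {}
        for a in anns:
            prev = per_value.get(a.parsed_value.raw)
            if prev is None or a.match_score > prev.match_score:
                per_value[a.parsed_value.raw] = a
        best_by_value[onto] = per_value

    n_values = len(raw_values)
    uncovered = set(raw_values)
    chosen: list[str] = []
    selected: dict[str, AnnotationCandidate] = {}  # value -> annotation from first covering ontology
    trajectory: list[OntologySetMetrics] = []

    def metrics() -> OntologySetMetrics:
        covered = list(selected.values())
        coverage = (n_values - len(uncovered)) / n_values if n_values else 0.0
        if covered:
            set_score = sum(
                a.match_score * score_by_onto[a.term.ontology].acceptance for a in covered
            ) / len(covered)
            set_suit = coverage * (sum(a.match_score for a in covered) / len(covered))
        else:
            set_score = set_suit = 0.0
        return OntologySetMetrics(tuple(chosen), coverage, set_score, set_suit)

    for rank_index, onto_score in enumerate(ranked):
        onto = onto_score.ontology
        newly = {v: a for v, a in best_by_value.get(onto, {}).items() if v in uncovered}
        if rank_index > 0 and not newly:
            continue  # no progress; the first ontology is always consulted
        chosen.append(onto)
        selected.update(newly)
        uncovered -= set(newly)
        trajectory.append(metrics())
        if trajectory[-1].set_coverage >= coverage_target or not uncovered:
            break
    return trajectory[-1], trajectory
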