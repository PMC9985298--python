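"""Word-alignment distance, match/suitability/annotation scores, weight fitting."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from gwaskit.scoring import (
    AnnotationCandidate,
    annotation_score,
    fit_weights,
    load_reference_annotations,
    match_score,
    ontology_scores,
    parse_raw_value,
    select_ontology_set,
    tokenize,
    word_distance,
)
from gwaskit.terms import TermRecord

# ---------------------------------------------------------------- parsing


def test_parse_single_value():
    (pv,) = parse_raw_value("asthma")
    assert pv.parsed == "asthma" and pv.tokens == ("asthma",)


def test_parse_comma_split():
    parts = parse_raw_value("Height, Weight")
    assert [p.parsed for p in parts] == ["height", "weight"]
    assert all(p.raw == "Height, Weight" for p in parts)


def test_parse_keeps_internal_punctuation():
    (pv,) = parse_raw_value("Magnesium:creatinine ratio measurement")
    assert pv.tokens == ("magnesium:creatinine", "ratio", "measurement")


def test_parse_strips_edge_punctuation_and_collapses_space():
    (pv,) = parse_raw_value("  (Pre-eclampsia)   severity. ")
    assert pv.tokens == ("pre-eclampsia", "severity")


def test_parse_all_punctuation_is_empty(caplog):
    with caplog.at_level("WARNING"):
        assert parse_raw_value("--- ,, !!") == []
    assert caplog.messages


# ---------------------------------------------------------------- distance


def brute_force_distance(q, l):
    """Exhaustive minimum over all order-respecting alignments (with swaps).

    Independent of the DP: explores every alignment path recursively.
    """
    best = math.inf

    def rec(i, j, cost):
        nonlocal best
        if cost >= best:
            return
        if i == len(q) and j == len(l):
            best = cost
            return
        if i < len(q) and j < len(l):
            rec(i + 1, j + 1, cost + (0.0 if q[i] == l[j] else 2.5))
            if i + 1 < len(q) and j + 1 < len(l) and q[i] == l[j + 1] and q[i + 1] == l[j]:
                rec(i + 2, j + 2, cost + 0.5)
        if i < len(q):
            rec(i + 1, j, cost + 2.0)
        if j < len(l):
            rec(i, j + 1, cost + 1.0)

    rec(0, 0, 0.0)
    return best


@pytest.mark.parametrize(
    "query, label, expected",
    [
        ("anorexia nervosa", "Anorexia", 2.0),
        ("sneeze", "Peroutka sneeze", 1.0),
        ("fasting blood insulin measurement", "fasting blood glucose measurement", 2.5),
        ("response to vancomycin", "Vancomycin Resistant Enterococcus", 6.0),
        ("a b", "b a", 0.5),
        ("lean body mass", "Lean Body Mass to Total Body Mass Ratio", 5.0),
        ("primary sclerosing", "sclerosing cholangitis", 3.0),
        ("schizophrenia", "Schizophrenia, Paranoid", 1.0),
        ("", "", 0.0),
        ("only query", "", 4.0),
        ("", "only label words", 3.0),
    ],
)
def test_word_distance_examples(query, label, expected):
    assert word_distance(tokenize(query), tokenize(label)) == expected


_words = st.lists(st.sampled_from(["alpha", "beta", "gamma", "delta", "epsilon"]), max_size=5)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(_words, _words)
def test_word_distance_matches_brute_force(q, l):
    assert word_distance(q, l) == brute_force_distance(q, l)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(_words, _words)
def test_zero_distance_iff_equal(q, l):
    d = word_distance(q, l)
    assert (d == 0) == (q == l)
    assert d >= 0 and (2 * d) == int(2 * d)  # nonneg multiple of 0.5


# ---------------------------------------------------------------- match score


def _term(ontology="EFO", code="EFO_1", pref="creatinine measurement", synonyms=()):
    return TermRecord(ontology=ontology, ontology_id=code, pref_label=pref, synonyms=tuple(synonyms))


def test_exact_pref_label_scores_ten():
    (pv,) = parse_raw_value("creatinine measurement")
    cand = match_score(pv, _term(pref="Creatinine Measurement"))
    assert cand.match_score == 10 and cand.basis == "P"


def test_synonym_match_starts_from_nine():
    (pv,) = parse_raw_value("event free survival time")
    term = _term(pref="metastasis free survival", synonyms=["metastasis free survival time"])
    cand = match_score(pv, term)
    assert cand.match_score == 6.5 and cand.basis == "S"
    assert cand.matched_label == "metastasis free survival time"


def test_pref_label_wins_ties():
    (pv,) = parse_raw_value("asthma")
    cand = match_score(pv, _term(pref="asthma extended", synonyms=["asthma extended"]))
    assert cand.basis == "P"


@settings(max_examples=150, deadline=None, derandomize=True)
@given(_words.filter(bool), _words.filter(bool), st.lists(_words.filter(bool), max_size=3))
def test_match_score_bounds(query, pref, synonyms):
    pv = parse_raw_value(" ".join(query))[0]
    term = _term(pref=" ".join(pref), synonyms=[" ".join(s) for s in synonyms])
    cand = match_score(pv, term)
    assert cand.match_score <= 10
    if cand.basis == "S":
        assert cand.match_score <= 9


# ------------------------------------------------------- ontology-level scores


def _cand(raw, score, ontology="EFO", code="X"):
    (pv,) = parse_raw_value(raw)
    return AnnotationCandidate(
        parsed_value=pv, term=_term(ontology=ontology, code=code), basis="P",
        matched_label=raw, distance=10 - score, match_score=score,
    )


def test_full_coverage_perfect_matches_gives_suitability_ten():
    anns = {"EFO": [_cand("a", 10), _cand("b", 10)]}
    (score,) = ontology_scores(anns, 2, {"EFO": 0.32})
    assert score.coverage == 1.0 and score.suitability == 10.0


def test_no_annotations_gives_zero():
    (score,) = ontology_scores({"EFO": []}, 4, {"EFO": 0.32})
    assert score.coverage == 0.0 and score.suitability == 0.0


def test_partial_coverage_product():
    anns = {"EFO": [_cand("a", 10), _cand("b", 9)]}
    (score,) = ontology_scores(anns, 4, {"EFO": 0.32})
    assert score.suitability == pytest.approx(0.5 * 9.5)


def test_unknown_ontology_without_acceptance_errors():
    with pytest.raises(KeyError):
        ontology_scores({"XYZ": [_cand("a", 10, ontology="XYZ")]}, 1, {"EFO": 0.32})


# ---------------------------------------------------------- annotation score


@pytest.mark.parametrize(
    "match, suit, acc, expected",
    [(10, 4.39, 0.86, 5.23), (10, 0.10, 0.25, 0.58), (0, 3.4, 0.9, 0.0)],
)
def test_annotation_score_reference_points(match, suit, acc, expected):
    cand = _cand("x", match)
    assert annotation_score(cand, suit, acc, weights=(0.08, 0.20)).annotation_score == expected


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        annotation_score(_cand("x", 10), 1.0, 1.0, weights=(-0.1, 0.2))


# ---------------------------------------------------------- weight fitting


def test_fit_weights_exact_on_determined_system():
    rows = [(10, 4.39, 0.86, 10 * (0.08 * 4.39 + 0.2 * 0.86)), (10, 0.10, 0.25, 10 * (0.08 * 0.10 + 0.2 * 0.25))]
    w_suit, w_acc = fit_weights(rows)
    assert w_suit == pytest.approx(0.08, abs=1e-9)
    assert w_acc == pytest.approx(0.20, abs=1e-9)


def test_fit_weights_reproduces_reference_table():
    rows = [
        (r["match_score"], r["onto_suitability"], r["onto_acceptance"], r["annotation_score"])
        for r in load_reference_annotations()
    ]
    w_suit, w_acc = fit_weights(rows)
    for match, suit, acc, printed in rows:
        assert abs(round(match * (w_suit * suit + w_acc * acc), 2) - printed) <= 0.01


def test_fit_weights_degenerate_inputs():
    with pytest.raises(ValueError):
        fit_weights([(10, 1.0, 1.0, 2.8)])
    with pytest.raises(ValueError, match="rank"):
        fit_weights([(10, 1.0, 1.0, 2.8), (20, 2.0, 2.0, 5.6)])


# ------------------------------------------------------------- set selection


def _annotation_fixture(gamma_adds_new=False):
    """Three ontologies with engineered coverage over 20 values.

    ALPHA covers half of the values, BETA another 0.3; GAMMA either only
    re-covers BETA's values (coverage fixed point at 0.8) or, with
    ``gamma_adds_new``, contributes one new value (0.85, on the target).
    """
    values = [f"value {i}" for i in range(20)]
    gamma_span = values[16:17] + values[8:10] if gamma_adds_new else values[8:10]
    anns = {
        "ALPHA": [_cand(v, 10, "ALPHA", f"A{i}") for i, v in enumerate(values[:10])],
        "BETA": [_cand(v, 9, "BETA", f"B{i}") for i, v in enumerate(values[8:16])],
        "GAMMA": [_cand(v, 8, "GAMMA", f"G{i}") for i, v in enumerate(gamma_span)],
    }
    acceptance = {"ALPHA": 0.9, "BETA": 0.5, "GAMMA": 0.3}
    scores = ontology_scores(anns, len(values), acceptance)
    return values, anns, scores


def test_single_sufficient_ontology_gives_singleton_set():
    values = ["a", "b"]
    anns = {"EFO": [_cand("a", 10), _cand("b", 10)]}
    scores = ontology_scores(anns, 2, {"EFO": 0.32})
    chosen, trajectory = select_ontology_set(values, anns, scores, coverage_target=0.85)
    assert chosen.ontologies == ("EFO",) and chosen.set_coverage == 1.0


def test_greedy_selection_matches_exhaustive_minimum():
    values, anns, scores = _annotation_fixture()
    chosen, trajectory = select_ontology_set(values, anns, scores, coverage_target=0.85)
    assert chosen.ontologies == ("ALPHA", "BETA")
    assert chosen.set_coverage == pytest.approx(0.8)  # fixed point below target

    # exhaustive check: coverage of every subset, computed by brute force
    import itertools

    def subset_coverage(subset):
        covered = {a.parsed_value.raw for o in subset for a in anns[o]}
        return len(covered & set(values)) / len(values)

    best = max(
        subset_coverage(subset)
        for r in range(1, 4)
        for subset in itertools.combinations(anns, r)
    )
    assert subset_coverage(chosen.ontologies) == best  # greedy reaches the optimum
    for subset in itertools.combinations(anns, len(chosen.ontologies) - 1):
        assert subset_coverage(subset) < best  # and no smaller subset does
    for subset in itertools.combinations(anns, 1):
        assert subset_coverage(subset) < best
    # coverage along the greedy trajectory is monotone nondecreasing
    covs = [m.set_coverage for m in trajectory]
    assert covs == sorted(covs)


def test_greedy_adds_third_ontology_when_it_completes_the_target():
    values, anns, scores = _annotation_fixture(gamma_adds_new=True)
    chosen, trajectory = select_ontology_set(values, anns, scores, coverage_target=0.85)
    assert chosen.ontologies == ("ALPHA", "BETA", "GAMMA")
    assert chosen.set_coverage == pytest.approx(0.85)


def test_target_zero_stops_after_first_ontology():
    values, anns, scores = _annotation_fixture()
    chosen, trajectory = select_ontology_set(values, anns, scores, coverage_target=0.0)
    assert len(trajectory) == 1 and chosen.ontologies == ("ALPHA",)


def test_empty_ontology_list_errors():
    with pytest.raises(ValueError):
        select_ontology_set(["a"], {}, [], 0.85)
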