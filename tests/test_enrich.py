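"""Knowledge-base population, trait auto-annotation, cross-source concepts."""

import pytest

from gwaskit.enrich import (
    KnowledgeBase,
    common_concepts,
    common_concepts_from_sets,
    enrich,
    export_curation_queue,
    populate_kb,
)
from gwaskit.fixtures import ANNOTATABLE_TRAITS, OBSCURE_TRAITS, default_term_corpus
from gwaskit.gcm import RelationalStore
from gwaskit.terms import FixtureTermSource, TermRecord


def _chain_source(depth=5):
    """Linear is_a chain T0 <- T1 <- ... (T0 is the root)."""
    terms = []
    for i in range(depth):
        parents = (("T%d" % (i - 1), "is_a"),) if i > 0 else ()
        children = (("T%d" % (i + 1), "is_a"),) if i < depth - 1 else ()
        terms.append(
            TermRecord("DEMO", f"T{i}", f"term {i}", parents=parents, children=children)
        )
    return FixtureTermSource.from_records(terms)


def _store_with_traits(traits, dataset="ds"):
    store = RelationalStore()
    cur = store.conn.cursor()
    for i, trait in enumerate(traits):
        cur.execute("INSERT INTO case_study (pubmed_id, source_site) VALUES ('', ?)", (dataset,))
        cur.execute(
            "INSERT INTO item (source_id, dataset_name, case_study_id) VALUES (?, ?, ?)",
            (f"{dataset}_{i}", dataset, cur.lastrowid),
        )
        cur.execute("INSERT INTO cohort (item_id, trait_name) VALUES (?, ?)", (cur.lastrowid, trait))
    store.conn.commit()
    return store


ACCEPTANCE = {"DEMO": 0.5, "EFO": 0.32, "NCIT": 0.86, "HP": 0.31}


def test_populate_kb_depth_zero_inserts_term_only():
    source = _chain_source()
    store = RelationalStore()
    kb = KnowledgeBase(store)
    populate_kb(kb, source.get("DEMO", "T4"), source, levels=0)
    assert store.scalar("SELECT COUNT(*) FROM vocabulary") == 1
    assert store.scalar("SELECT COUNT(*) FROM relationship") == 0


def test_populate_kb_walks_three_ancestor_levels():
    source = _chain_source(depth=5)
    store = RelationalStore()
    kb = KnowledgeBase(store)
    populate_kb(kb, source.get("DEMO", "T4"), source, levels=3)
    # T4 plus ancestors T3, T2, T1 — T0 is four levels up and must be absent
    codes = {r[0] for r in store.query("SELECT code FROM vocabulary")}
    assert codes == {"T4", "T3", "T2", "T1"}
    assert store.scalar("SELECT COUNT(*) FROM relationship") == 3


def test_populate_kb_idempotent():
    source = _chain_source()
    store = RelationalStore()
    kb = KnowledgeBase(store)
    for _ in range(2):
        populate_kb(kb, source.get("DEMO", "T4"), source, levels=2)
    assert store.scalar("SELECT COUNT(*) FROM vocabulary") == 3
    assert store.scalar("SELECT COUNT(*) FROM relationship") == 2


def test_populate_kb_skips_dangling_reference(caplog):
    term = TermRecord("DEMO", "X", "x", parents=(("MISSING", "is_a"),))
    source = FixtureTermSource.from_records([term])
    kb = KnowledgeBase(RelationalStore())
    with caplog.at_level("WARNING"):
        populate_kb(kb, term, source, levels=2)
    assert any("MISSING" in m for m in caplog.messages)


class _ExplodingSource(FixtureTermSource):
    def search(self, query, ontologies=None):
        raise AssertionError("term source must not be queried on a KB hit")


def test_kb_hit_short_circuits_term_source():
    store = _store_with_traits(["appendicitis"])
    kb = KnowledgeBase(store)
    kb.insert_term(TermRecord("NCIT", "NCIT_C35145", "Appendicitis"))
    report = enrich(store, kb, ["NCIT"], _ExplodingSource(), acceptance=ACCEPTANCE)
    assert report.n_linked == 1 and report.kb_hits == 1
    assert store.scalar("SELECT trait_name_tid FROM cohort") is not None


def test_threshold_splits_linked_and_queued(term_source, tmp_path):
    traits = list(ANNOTATABLE_TRAITS[:6]) + list(OBSCURE_TRAITS) + ["zz qq ww ee rr"]
    store = _store_with_traits(traits)
    kb = KnowledgeBase(store)
    report = enrich(store, kb, ["EFO", "NCIT", "HP"], term_source, acceptance=ACCEPTANCE)
    assert report.n_linked == 6
    assert report.n_queued == 4
    queue = export_curation_queue(store, tmp_path / "queue.tsv")
    lines = queue.read_text().splitlines()
    assert len(lines) == 1 + 4  # header + queued values with ranked suggestions


def test_enrichment_never_modifies_trait_names(term_source):
    traits = list(ANNOTATABLE_TRAITS[:3])
    store = _store_with_traits(traits)
    enrich(store, KnowledgeBase(store), ["EFO", "NCIT", "HP"], term_source, acceptance=ACCEPTANCE)
    kept = [r[0] for r in store.query("SELECT trait_name FROM cohort ORDER BY cohort_id")]
    assert kept == traits


def test_enrich_is_idempotent(term_source):
    store = _store_with_traits(list(ANNOTATABLE_TRAITS[:4]) + [OBSCURE_TRAITS[0]])
    kb = KnowledgeBase(store)
    enrich(store, kb, ["EFO", "NCIT", "HP"], term_source, acceptance=ACCEPTANCE)
    snapshot = {
        t: store.query(f"SELECT * FROM {t}")
        for t in ("cohort", "vocabulary", "relationship", "curation_queue")
    }
    report = enrich(store, kb, ["EFO", "NCIT", "HP"], term_source, acceptance=ACCEPTANCE)
    assert report.n_linked <= 1  # only the still-queued obscure value is retried
    for table, rows in snapshot.items():
        if table != "curation_queue":
            assert store.query(f"SELECT * FROM {table}") == rows, table


def test_unavailable_term_source_queues_and_continues():
    class Down(FixtureTermSource):
        def search(self, query, ontologies=None):
            raise OSError("service down")

    store = _store_with_traits(["appendicitis"])
    report = enrich(store, KnowledgeBase(store), ["NCIT"], Down(), acceptance=ACCEPTANCE)
    assert report.n_linked == 0 and report.n_queued == 1


def test_common_concepts_require_two_sources(term_source):
    # both sources carry 'appendicitis'; only one carries 'asthma'
    store = _store_with_traits(["appendicitis", "asthma"], dataset="gwas_catalog")
    kb = KnowledgeBase(store)
    cur = store.conn.cursor()
    cur.execute("INSERT INTO case_study (pubmed_id, source_site) VALUES ('', 'finngen')")
    cur.execute(
        "INSERT INTO item (source_id, dataset_name, case_study_id) VALUES ('EP_1', 'finngen', ?)",
        (cur.lastrowid,),
    )
    cur.execute("INSERT INTO cohort (item_id, trait_name) VALUES (?, 'appendicitis')", (cur.lastrowid,))
    store.conn.commit()
    enrich(store, kb, ["EFO", "NCIT", "HP"], term_source, acceptance=ACCEPTANCE)
    shared = common_concepts(store)
    assert ("NCIT", "NCIT_C35145") in shared
    groups = shared[("NCIT", "NCIT_C35145")]
    assert set(groups) == {"gwas_catalog", "finngen"}
    assert all(("asthma" not in k[1].lower()) for k in shared)


def test_common_concepts_set_algebra():
    assert common_concepts_from_sets({"a": {1, 2}, "b": {3}}) == set()
    assert common_concepts_from_sets({"a": {1, 2}, "b": {1, 2}}) == {1, 2}
    assert common_concepts_from_sets({}) == set()


def test_corpus_has_no_duplicate_ids():
    corpus = default_term_corpus()
    keys = [t.key for t in corpus]
    assert len(keys) == len(set(keys))
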