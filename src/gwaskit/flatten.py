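"""Feed mapped and enriched metadata back into GDM attribute-value files.

Flattening rewrites each sample's metadata file as: the original pairs (in
their original order), then the mapped relational values under dotted
``table.column`` keys, then — when the cohort is enriched — the linked term
(``cohort.trait_name_tid``, ontology, id, preferred label).  Dotted keys
cannot collide with source attribute names.  Region files are copied
byte-for-byte: flattening acts on metadata only.  Output is deterministic,
so a second run is byte-identical.
"""

from __future__ import annotations

import shutil
from pathlib import Path

from .gcm import RelationalStore
from .gdm import GdmDataset, write_schema

COHORT_COLUMNS = (
    "trait_name",
    "initial_cases",
    "initial_controls",
    "initial_individuals",
    "initial_trios",
    "replication_cases",
    "replication_controls",
    "replication_individuals",
    "replication_trios",
)
ANCESTRY_COLUMNS = (
    "broad_ancestral_category",
    "country_of_origin",
    "country_of_recruitment",
    "number_of_individuals",
    "stage",
)


class FlattenError(ValueError):
    pass


def _mapped_pairs(store: RelationalStore, item_id: int) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    source_id, dataset_name = store.query(
        "SELECT source_id, dataset_name FROM item WHERE item_id = ?", (item_id,)
    )[0]
    pairs.append(("item.source_id", source_id))
    pairs.append(("item.dataset_name", dataset_name))
    case = store.query(
        "SELECT cs.pubmed_id, cs.source_site FROM case_study cs "
        "JOIN item i ON i.case_study_id = cs.case_study_id WHERE i.item_id = ?",
        (item_id,),
    )
    if case and any(case[0]):
        pubmed, site = case[0]
        if pubmed:
            pairs.append(("case_study.pubmed_id", pubmed))
        if site:
            pairs.append(("case_study.source_site", site))
    cohort = store.query(
        f"SELECT cohort_id, {', '.join(COHORT_COLUMNS)} FROM cohort WHERE item_id = ?", (item_id,)
    )
    if not cohort:
        return pairs
    cohort_id, *values = cohort[0]
    for col, val in zip(COHORT_COLUMNS, values):
        if val is not None and val != "":
            pairs.append((f"cohort.{col}", str(val)))
    for row in store.query(
        f"SELECT ordinal, {', '.join(ANCESTRY_COLUMNS)} FROM ancestry "
        "WHERE cohort_id = ? ORDER BY ordinal",
        (cohort_id,),
    ):
        ordinal, *anc_values = row
        for col, val in zip(ANCESTRY_COLUMNS, anc_values):
            if val is not None and val != "":
                pairs.append((f"ancestry.{col}_{ordinal}", str(val)))
    enriched = store.query(
        "SELECT c.trait_name_tid, v.ontology, v.code, v.pref_label "
        "FROM cohort c JOIN vocabulary v ON v.tid = c.trait_name_tid WHERE c.cohort_id = ?",
        (cohort_id,),
    )
    if enriched:
        tid, ontology, code, pref_label = enriched[0]
        pairs.append(("cohort.trait_name_tid", str(tid)))
        pairs.append(("cohort.trait_ontology", ontology))
        pairs.append(("cohort.trait_ontology_id", code))
        pairs.append(("cohort.trait_pref_label", pref_label))
    return pairs


def flatten(store: RelationalStore, dataset: GdmDataset, out_dir: Path | str) -> Path:
    """Write the flattened dataset (regions untouched, metadata augmented)."""
    out_dir = Path(out_dir) / dataset.name
    out_dir.mkdir(parents=True, exist_ok=True)
    write_schema(dataset.schema, out_dir / "schema.xml")

    item_ids: dict[str, int] = dict(
        store.query("SELECT source_id, item_id FROM item WHERE dataset_name = ?", (dataset.name,))
    )
    missing = [s.sample_id for s in dataset.samples if s.sample_id not in item_ids]
    extra = set(item_ids) - {s.sample_id for s in dataset.samples}
    if missing:
        raise FlattenError(f"samples not present in the mapped store: {sorted(missing)}")
    if extra:
        raise FlattenError(f"store items missing from the dataset: {sorted(extra)}")

    from .gdm import write_sample  # local import avoids cycle at module load

    for sample in dataset.samples:
        pairs = list(sample.metadata) + _mapped_pairs(store, item_ids[sample.sample_id])
        flat = type(sample)(sample.sample_id, sample.regions, pairs)
        write_sample(flat, dataset.schema, out_dir)
    return out_dir


def copy_regions(src_dataset_dir: Path | str, out_dir: Path | str) -> None:
    """Byte-copy region files between dataset directories (no rewriting)."""
    src, dst = Path(src_dataset_dir), Path(out_dir)
    dst.mkdir(parents=True, exist_ok=True)
    for p in sorted(src.glob("*.gdm")):
        shutil.copyfile(p, dst / p.name)
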