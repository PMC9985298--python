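import pytest

from gwaskit.fixtures import (
    default_term_corpus,
    generate_catalog_fixture,
    generate_finngen_fixture,
)
from gwaskit.gcm import RelationalStore, load_rules, map_dataset
from gwaskit.gdm import GdmRegion, GdmSample, RegionSchema
from gwaskit.ingest import read_catalog, read_finngen
from gwaskit.terms import FixtureTermSource
from gwaskit.transform import transform_catalog, transform_finngen


@pytest.fixture()
def demo_schema() -> RegionSchema:
    return RegionSchema(
        name="demo",
        variable_fields=(("gene", "text"), ("score", "float"), ("reads", "integer")),
    )


@pytest.fixture()
def demo_sample(demo_schema) -> GdmSample:
    return GdmSample(
        sample_id="S1",
        regions=[
            GdmRegion("chr1", 100, 200, "+", ("BRCA2", 0.5, 7)),
            GdmRegion("chr2", 5, 6, "*", ("TP53", 1.25, 0)),
            GdmRegion("chrX", 1000, 2500, "-", ("IL21R", -3.0, 12)),
        ],
        metadata=[("assay", "gwas"), ("trait", "asthma"), ("trait", "stroke"), ("n", "1200")],
    )


@pytest.fixture()
def catalog_fixture(tmp_path):
    truth = generate_catalog_fixture(
        seed=1, n_studies=3, n_assoc_per_study=5, n_ancestries_per_study=2,
        frac_missing_chr=0.2, out_dir=tmp_path / "catalog",
    )
    return truth


@pytest.fixture()
def catalog_rows(catalog_fixture):
    f = catalog_fixture["files"]
    return read_catalog(f["Studies.tsv"], f["Ancestry.tsv"], f["Associations.tsv"])


@pytest.fixture()
def catalog_dataset(catalog_rows):
    return transform_catalog(*catalog_rows)


@pytest.fixture()
def finngen_fixture(tmp_path):
    return generate_finngen_fixture(
        seed=1, n_endpoints=2, n_variants=4,
        shared_trait_labels=("appendicitis",), out_dir=tmp_path / "finngen",
    )


@pytest.fixture()
def finngen_dataset(finngen_fixture, tmp_path):
    entries = read_finngen(finngen_fixture["manifest"], tmp_path / "finngen")
    return transform_finngen(entries)


@pytest.fixture()
def catalog_rules():
    return load_rules("gwas_catalog")


@pytest.fixture()
def finngen_rules():
    return load_rules("finngen")


@pytest.fixture()
def mapped_store(catalog_dataset, catalog_rules) -> RelationalStore:
    return map_dataset(catalog_dataset, catalog_rules)


@pytest.fixture()
def term_source() -> FixtureTermSource:
    return FixtureTermSource.from_records(default_term_corpus())
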