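"""GDM containers: invariants and file round-trips."""

import pytest
from hypothesis import given, settings, strategies as st

from gwaskit.gdm import (
    GdmParseError,
    GdmRegion,
    GdmSample,
    RegionSchema,
    SchemaViolation,
    read_sample,
    read_schema,
    write_sample,
    write_schema,
)


def test_region_rejects_bad_coordinates_and_strand():
    with pytest.raises(SchemaViolation):
        GdmRegion("chr1", 10, 10)
    with pytest.raises(SchemaViolation):
        GdmRegion("chr1", 10, 5)
    with pytest.raises(SchemaViolation):
        GdmRegion("chr1", 1, 2, strand="fwd")
    assert GdmRegion("chr1", 1, 2).strand == "*"


def test_schema_rejects_duplicate_names_and_unknown_types():
    with pytest.raises(SchemaViolation):
        RegionSchema("s", (("chrom", "text"),))
    with pytest.raises(SchemaViolation):
        RegionSchema("s", (("x", "text"), ("x", "float")))
    with pytest.raises(SchemaViolation):
        RegionSchema("s", (("x", "varchar"),))


def test_write_read_round_trip(demo_sample, demo_schema, tmp_path):
    region_path, meta_path = write_sample(demo_sample, demo_schema, tmp_path)
    assert region_path.name == "S1.gdm" and meta_path.name == "S1.gdm.meta"
    back = read_sample(region_path, meta_path, demo_schema)
    assert back.sample_id == demo_sample.sample_id
    assert back.regions == demo_sample.regions
    assert back.metadata == demo_sample.metadata


def test_empty_sample_writes_empty_region_file(demo_schema, tmp_path):
    sample = GdmSample("empty", regions=[], metadata=[("k", "v")])
    region_path, meta_path = write_sample(sample, demo_schema, tmp_path)
    assert region_path.read_text() == ""
    assert meta_path.read_text() == "k\tv\n"


def test_written_rows_have_schema_arity(demo_sample, demo_schema, tmp_path):
    region_path, _ = write_sample(demo_sample, demo_schema, tmp_path)
    for line in region_path.read_text().splitlines():
        assert len(line.split("\t")) == demo_schema.n_columns == 7


def test_metadata_multiplicity_and_order_preserved(demo_schema, tmp_path):
    pairs = [("trait", "asthma"), ("trait", "asthma"), ("trait", "stroke")]
    sample = GdmSample("m", [], pairs)
    paths = write_sample(sample, demo_schema, tmp_path)
    assert read_sample(*paths, demo_schema).metadata == pairs


def test_attrs_schema_mismatch_rejected(demo_schema, tmp_path):
    sample = GdmSample("bad", [GdmRegion("chr1", 1, 2, "*", ("only-one",))])
    with pytest.raises(SchemaViolation):
        write_sample(sample, demo_schema, tmp_path)


def test_read_rejects_bad_rows(demo_schema, tmp_path):
    meta = tmp_path / "x.gdm.meta"
    meta.write_text("")
    bad_coord = tmp_path / "x.gdm"
    bad_coord.write_text("chr1\t10\t5\t*\tG\t1.0\t2\n")
    with pytest.raises(SchemaViolation, match="stop"):
        read_sample(bad_coord, meta, demo_schema)
    bad_coord.write_text("chr1\t10\t20\t*\tG\n")
    with pytest.raises(SchemaViolation, match="columns"):
        read_sample(bad_coord, meta, demo_schema)
    bad_coord.write_text("chr1\tten\t20\t*\tG\t1.0\t2\n")
    with pytest.raises(GdmParseError, match=":1"):
        read_sample(bad_coord, meta, demo_schema)


def test_schema_round_trip(demo_schema, tmp_path):
    path = write_schema(demo_schema, tmp_path / "schema.xml")
    assert read_schema(path) == demo_schema
    fixed_only = RegionSchema("bare")
    assert read_schema(write_schema(fixed_only, tmp_path / "bare.xml")) == fixed_only


_names = st.text(alphabet="abcdefgh", min_size=1, max_size=8)
_values = {
    "text": st.text(alphabet="xyz 0123:-", max_size=12),
    "integer": st.integers(-10**6, 10**6),
    "float": st.floats(allow_nan=False, allow_infinity=False, width=32),
}


@st.composite
def _sample_and_schema(draw):
    fields = draw(
        st.lists(
            st.tuples(_names, st.sampled_from(["text", "integer", "float"])),
            max_size=3,
            unique_by=lambda f: f[0],
        ).filter(lambda fs: all(n not in {"chrom", "start", "stop", "strand"} for n, _ in fs))
    )
    schema = RegionSchema("prop", tuple(fields))
    regions = []
    for _ in range(draw(st.integers(0, 4))):
        start = draw(st.integers(0, 10**8))
        regions.append(
            GdmRegion(
                chrom=f"chr{draw(st.integers(1, 22))}",
                start=start,
                stop=start + draw(st.integers(1, 1000)),
                strand=draw(st.sampled_from(["+", "-", "*"])),
                attrs=tuple(draw(_values[dtype]) for _, dtype in fields),
            )
        )
    metadata = draw(st.lists(st.tuples(_names, st.text(alphabet="abc :_/", max_size=10)), max_size=4))
    return GdmSample("prop_sample", regions, metadata), schema


@settings(max_examples=60, deadline=None, derandomize=True)
@given(_sample_and_schema())
def test_round_trip_property(tmp_path_factory, pair):
    sample, schema = pair
    directory = tmp_path_factory.mktemp("rt")
    back = read_sample(*write_sample(sample, schema, directory), schema)
    assert back.regions == sample.regions
    assert back.metadata == sample.metadata
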