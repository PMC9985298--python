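"""Genomic Data Model (GDM) containers and their file serialization.

A GDM *dataset* is a collection of *samples*; each sample pairs a region
table (genomic intervals with a fixed coordinate prefix plus typed,
source-specific attributes) with a free attribute-value metadata list.
Region files and metadata files share the sample identifier stem, which is
the contract that keeps the two halves of a sample linked on disk.

Coordinates are stored exactly as found in the source (no rebasing between
0- and 1-based conventions); the stop coordinate is exclusive by
convention, recorded in the schema document header.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

FIXED_FIELDS = (("chrom", "text"), ("start", "integer"), ("stop", "integer"), ("strand", "text"))
STRANDS = {"+", "-", "*"}
DATATYPES = {"text", "integer", "float"}

REGION_SUFFIX = ".gdm"
META_SUFFIX = ".gdm.meta"


class SchemaViolation(ValueError):
    """A sample, region or schema document breaks a GDM structural rule."""


class GdmParseError(ValueError):
    """A GDM file is syntactically invalid; message names the offending line."""


@dataclass(frozen=True)
class RegionSchema:
    """Declared shape of region rows: fixed coordinates then variable fields."""

    name: str
    variable_fields: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        names = [n for n, _ in FIXED_FIELDS] + [n for n, _ in self.variable_fields]
        if len(set(names)) != len(names):
            raise SchemaViolation(f"duplicate field name in schema {self.name!r}")
        for fname, dtype in self.variable_fields:
            if dtype not in DATATYPES:
                raise SchemaViolation(f"unknown datatype {dtype!r} for field {fname!r}")

    @property
    def all_fields(self) -> tuple[tuple[str, str], ...]:
        return FIXED_FIELDS + tuple(self.variable_fields)

    @property
    def n_columns(self) -> int:
        return len(FIXED_FIELDS) + len(self.variable_fields)


@dataclass(frozen=True)
class GdmRegion:
    """One genomic region: fixed coordinates plus schema-ordered attributes."""

    chrom: str
    start: int
    stop: int
    strand: str = "*"
    attrs: tuple = ()

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise SchemaViolation(
                f"region {self.chrom}:{self.start}-{self.stop}: stop must exceed start"
            )
        if self.strand not in STRANDS:
            raise SchemaViolation(f"invalid strand {self.strand!r}")


# Metadata pairs are plain (attribute, value) tuples; an attribute may repeat
# with several values and order is significant, so a list of tuples (not a
# dict) is the canonical in-memory form.
MetadataPair = tuple[str, str]


@dataclass
class GdmSample:
    sample_id: str
    regions: list[GdmRegion] = field(default_factory=list)
    metadata: list[MetadataPair] = field(default_factory=list)

    def conforms_to(self, schema: RegionSchema) -> bool:
        return all(len(r.attrs) == len(schema.variable_fields) for r in self.regions)


@dataclass
class GdmDataset:
    name: str
    schema: RegionSchema
    samples: list[GdmSample] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise SchemaViolation(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)
            if not s.conforms_to(self.schema):
                raise SchemaViolation(
                    f"sample {s.sample_id!r} does not conform to schema {self.schema.name!r}"
                )


def _clean(value: object) -> str:
    # Tabs are the one reserved character of the format; writers stay total
    # by degrading them to spaces. Sources are tab-free in practice.
    return str(value).replace("\t", " ").replace("\n", " ")


def _typed(token: str, dtype: str, path: Path, lineno: int):
    if dtype == "text":
        return token
    try:
        return int(token) if dtype == "integer" else float(token)
    except ValueError:
        raise GdmParseError(f"{path}:{lineno}: expected {dtype}, got {token!r}") from None


def write_sample(sample: GdmSample, schema: RegionSchema, directory: Path | str) -> tuple[Path, Path]:
    """Write the paired region/metadata files for one sample.

    Returns (region_path, metadata_path); both share the sample_id stem.
    """
    if not sample.conforms_to(schema):
        raise SchemaViolation(
            f"sample {sample.sample_id!r}: region attrs do not match schema "
            f"{schema.name!r} ({len(schema.variable_fields)} variable fields)"
        )
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    region_path = directory / f"{sample.sample_id}{REGION_SUFFIX}"
    meta_path = directory / f"{sample.sample_id}{META_SUFFIX}"
    with open(region_path, "w", encoding="utf-8", newline="\n") as fh:
        for r in sample.regions:
            row = [r.chrom, str(r.start), str(r.stop), r.strand]
            row.extend(_clean(a) for a in r.attrs)
            fh.write("\t".join(row) + "\n")
    with open(meta_path, "w", encoding="utf-8", newline="\n") as fh:
        for attr, value in sample.metadata:
            fh.write(f"{_clean(attr)}\t{_clean(value)}\n")
    return region_path, meta_path


def read_sample(region_path: Path | str, metadata_path: Path | str, schema: RegionSchema) -> GdmSample:
    """Read a sample back from its paired files; inverse of :func:`write_sample`."""
    region_path = Path(region_path)
    metadata_path = Path(metadata_path)
    sample_id = region_path.name
    if sample_id.endswith(REGION_SUFFIX):
        sample_id = sample_id[: -len(REGION_SUFFIX)]
    regions: list[GdmRegion] = []
    with open(region_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != schema.n_columns:
                raise SchemaViolation(
                    f"{region_path}:{lineno}: expected {schema.n_columns} columns, got {len(cols)}"
                )
            start = _typed(cols[1], "integer", region_path, lineno)
            stop = _typed(cols[2], "integer", region_path, lineno)
            if stop <= start:
                raise SchemaViolation(f"{region_path}:{lineno}: stop {stop} <= start {start}")
            attrs = tuple(
                _typed(tok, dtype, region_path, lineno)
                for tok, (_, dtype) in zip(cols[4:], schema.variable_fields)
            )
            regions.append(GdmRegion(cols[0], start, stop, cols[3], attrs))
    metadata: list[MetadataPair] = []
    with open(metadata_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GdmParseError(f"{metadata_path}:{lineno}: expected 2 columns")
            metadata.append((parts[0], parts[1]))
    return GdmSample(sample_id=sample_id, regions=regions, metadata=metadata)


def write_dataset(dataset: GdmDataset, directory: Path | str) -> Path:
    """Write every sample plus the schema document; returns the dataset directory."""
    dataset.validate()
    directory = Path(directory) / dataset.name
    directory.mkdir(parents=True, exist_ok=True)
    write_schema(dataset.schema, directory / "schema.xml")
    for sample in dataset.samples:
        write_sample(sample, dataset.schema, directory)
    return directory


def read_dataset(directory: Path | str, name: str | None = None) -> GdmDataset:
    directory = Path(directory)
    schema = read_schema(directory / "schema.xml")
    samples = [
        read_sample(p, p.with_name(p.name + ".meta"), schema)
        for p in sorted(directory.glob(f"*{REGION_SUFFIX}"))
    ]
    return GdmDataset(name=name or directory.name, schema=schema, samples=samples)


def write_schema(schema: RegionSchema, path: Path | str) -> Path:
    """Serialize the schema as a declarative XML field list (name + type, in order)."""
    path = Path(path)
    root = ET.Element("gdm-schema", name=schema.name, coordinates="stop-exclusive")
    for fname, dtype in schema.all_fields:
        ET.SubElement(root, "field", type=dtype).text = fname
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)
    with open(path, "a", encoding="utf-8") as fh:
        fh.write("\n")
    return path


def read_schema(path: Path | str) -> RegionSchema:
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise GdmParseError(f"{path}: {exc}") from exc
    fields = [((f.text or "").strip(), f.get("type", "")) for f in root.findall("field")]
    fixed, variable = fields[: len(FIXED_FIELDS)], fields[len(FIXED_FIELDS) :]
    if tuple(fixed) != FIXED_FIELDS:
        raise GdmParseError(f"{path}: fixed coordinate fields missing or out of order")
    for fname, dtype in variable:
        if dtype not in DATATYPES:
            raise GdmParseError(f"{path}: unknown datatype token {dtype!r} for {fname!r}")
    return RegionSchema(name=root.get("name", path.stem), variable_fields=tuple(variable))
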