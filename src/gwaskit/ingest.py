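"""Readers for local dumps of the two supported GWAS sources.

The GWAS Catalog ships as three tab-separated files (``Studies``,
``Ancestry``, ``Associations``) joined on ``STUDY ACCESSION``; FinnGen ships
a manifest of endpoints (one per phenotype) plus one summary-statistics TSV
per endpoint.  Downloading is out of scope: a :class:`Fetcher` abstracts
"where files come from" and the default implementation reads a local
directory, so the ingestion surface is identical whether files were staged
by hand or by an external download step.

Header-name matching is case-insensitive and whitespace-insensitive, since
column capitalization varies across releases.  Only the columns used
downstream are mandatory; everything else rides along as opaque text in the
``extra`` map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


class SourceFormatError(ValueError):
    """An input dump is missing a structurally required column or key."""


@dataclass
class CatalogStudyRow:
    study_accession: str
    disease_trait: str
    pubmed_id: str
    extra: dict[str, str] = field(default_factory=dict)


@dataclass
class CatalogAncestryRow:
    study_accession: str
    stage: str  # "initial" or "replication"
    number_of_individuals: int | None
    broad_ancestral_category: str
    country_of_origin: str
    country_of_recruitment: str
    extra: dict[str, str] = field(default_factory=dict)


@dataclass
class CatalogAssociationRow:
    study_accession: str
    chr_id: str | None
    chr_pos: int | None
    strongest_snp_risk_allele: str
    reported_genes: str
    p_value: float | None
    extra: dict[str, str] = field(default_factory=dict)


@dataclass
class FinnGenEndpoint:
    endpoint_name: str
    trait_label: str
    summary_path: Path
    num_cases: int | None = None
    num_controls: int | None = None


@dataclass
class FinnGenVariantRow:
    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str
    pval: float | None
    effects: dict[str, str] = field(default_factory=dict)


class Fetcher:
    """Resolves a source-relative file name to a local path."""

    def fetch(self, name: str) -> Path:  # pragma: no cover - interface
        raise NotImplementedError


class LocalFetcher(Fetcher):
    def __init__(self, directory: Path | str):
        self.directory = Path(directory)

    def fetch(self, name: str) -> Path:
        return self.directory / name


def _norm_header(name: str) -> str:
    return name.strip().lower().replace(" ", "_").replace("-", "_")


def _read_tsv(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [_norm_header(c) for c in df.columns]
    return df


def _require(df: pd.DataFrame, column: str, path: Path | str) -> None:
    if column not in df.columns:
        raise SourceFormatError(f"{path}: required column {column!r} missing")


def _opt_int(value: str, context: str) -> int | None:
    value = value.strip()
    if not value:
        return None
    try:
        n = int(float(value))
    except ValueError:
        logger.warning("%s: unparseable integer %r, treated as missing", context, value)
        return None
    if n < 0:
        logger.warning("%s: negative count %r, treated as missing", context, value)
        return None
    return n


def _opt_float(value: str, context: str) -> float | None:
    value = value.strip()
    if not value:
        return None
    try:
        return float(value)
    except ValueError:
        logger.warning("%s: unparseable number %r, treated as missing", context, value)
        return None


def read_catalog(
    studies_path: Path | str, ancestry_path: Path | str, associations_path: Path | str
) -> tuple[list[CatalogStudyRow], list[CatalogAncestryRow], list[CatalogAssociationRow]]:
    """Parse the three-file dump into typed row lists (one list per file)."""
    studies_df = _read_tsv(studies_path)
    ancestry_df = _read_tsv(ancestry_path)
    assoc_df = _read_tsv(associations_path)
    for df, path in ((studies_df, studies_path), (ancestry_df, ancestry_path), (assoc_df, associations_path)):
        _require(df, "study_accession", path)

    def pop(rec: dict[str, str], key: str, default: str = "") -> str:
        return rec.pop(key, default).strip()

    studies = []
    for rec in studies_df.to_dict("records"):
        studies.append(
            CatalogStudyRow(
                study_accession=pop(rec, "study_accession"),
                disease_trait=pop(rec, "disease/trait") or pop(rec, "disease_trait"),
                pubmed_id=pop(rec, "pubmedid") or pop(rec, "pubmed_id"),
                extra=rec,
            )
        )

    ancestries = []
    for i, rec in enumerate(ancestry_df.to_dict("records")):
        stage = pop(rec, "stage").lower() or "initial"
        if stage not in {"initial", "replication"}:
            logger.warning("%s row %d: unknown stage %r kept verbatim", ancestry_path, i, stage)
        ancestries.append(
            CatalogAncestryRow(
                study_accession=pop(rec, "study_accession"),
                stage=stage,
                number_of_individuals=_opt_int(
                    rec.pop("number_of_individuals", ""), f"{ancestry_path} row {i}"
                ),
                broad_ancestral_category=pop(rec, "broad_ancestral_category"),
                country_of_origin=pop(rec, "country_of_origin"),
                country_of_recruitment=pop(rec, "country_of_recruitment"),
                extra=rec,
            )
        )

    associations = []
    for i, rec in enumerate(assoc_df.to_dict("records")):
        chr_id = pop(rec, "chr_id") or None
        pos = _opt_int(rec.pop("chr_pos", ""), f"{associations_path} row {i}")
        pval = _opt_float(rec.pop("p_value", ""), f"{associations_path} row {i}")
        if pval is not None and pval < 0:
            logger.warning("%s row %d: negative p-value set missing", associations_path, i)
            pval = None
        associations.append(
            CatalogAssociationRow(
                study_accession=pop(rec, "study_accession"),
                chr_id=chr_id,
                chr_pos=pos,
                strongest_snp_risk_allele=pop(rec, "strongest_snp_risk_allele"),
                reported_genes=pop(rec, "reported_gene(s)") or pop(rec, "reported_genes"),
                p_value=pval,
                extra=rec,
            )
        )

    accessions = {s.study_accession for s in studies}
    orphans = sorted({a.study_accession for a in associations} - accessions)
    if orphans:
        logger.warning("associations reference unknown study accessions: %s", ", ".join(orphans))
    return studies, ancestries, associations


def read_finngen(
    manifest_path: Path | str, data_dir: Path | str | Fetcher
) -> list[tuple[FinnGenEndpoint, list[FinnGenVariantRow]]]:
    """Parse a manifest plus per-endpoint summary statistics, in manifest order.

    The manifest may be a TSV with header (``phenocode``, ``phenostring``,
    ``path`` plus optional case/control counts) or a JSON list of objects with
    the same keys.  Endpoints whose summary file is absent are skipped with a
    warning (partial ingestion is allowed); duplicate endpoint names are fatal.
    """
    fetcher = data_dir if isinstance(data_dir, Fetcher) else LocalFetcher(data_dir)
    manifest_path = Path(manifest_path)
    if manifest_path.suffix == ".json":
        entries = json.loads(manifest_path.read_text())
    else:
        entries = _read_tsv(manifest_path).to_dict("records")

    seen: set[str] = set()
    out: list[tuple[FinnGenEndpoint, list[FinnGenVariantRow]]] = []
    for entry in entries:
        name = str(entry.get("phenocode", "")).strip()
        if not name:
            raise SourceFormatError(f"{manifest_path}: manifest entry without phenocode")
        if name in seen:
            raise SourceFormatError(f"{manifest_path}: duplicate endpoint {name!r}")
        seen.add(name)
        path = fetcher.fetch(str(entry.get("path", f"{name}.tsv")))
        endpoint = FinnGenEndpoint(
            endpoint_name=name,
            trait_label=str(entry.get("phenostring", "")).strip(),
            summary_path=path,
            num_cases=_opt_int(str(entry.get("num_cases", "")), name),
            num_controls=_opt_int(str(entry.get("num_controls", "")), name),
        )
        if not path.exists():
            logger.warning("endpoint %s: summary file %s missing, skipped", name, path)
            continue
        out.append((endpoint, _read_variants(path)))
    return out


def _read_variants(path: Path) -> list[FinnGenVariantRow]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [_norm_header(c.lstrip("#")) for c in df.columns]
    _require(df, "chrom", path)
    _require(df, "pos", path)
    rows = []
    for i, rec in enumerate(df.to_dict("records")):
        pos = _opt_int(rec.pop("pos", ""), f"{path} row {i}")
        if pos is None or pos <= 0:
            logger.warning("%s row %d: nonpositive/missing pos, row skipped", path, i)
            continue
        pval = _opt_float(rec.pop("pval", ""), f"{path} row {i}")
        if pval is not None and not (0.0 <= pval <= 1.0):
            logger.warning("%s row %d: p-value %s outside [0,1] set missing", path, i, pval)
            pval = None
        rows.append(
            FinnGenVariantRow(
                chrom=rec.pop("chrom", "").strip(),
                pos=pos,
                ref=rec.pop("ref", "").strip(),
                alt=rec.pop("alt", "").strip(),
                rsid=rec.pop("rsids", "").strip() or rec.pop("rsid", "").strip(),
                pval=pval,
                effects=rec,
            )
        )
    return rows
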