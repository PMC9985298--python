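"""Source-specific conversion of ingested rows into GDM datasets.

Both sources report SNP associations, so every emitted region is a 1-bp
interval (stop = start + 1) on an unknown strand ('*').  Chromosome tokens
are normalized to ``chr``-prefixed form ("13" -> "chr13"); coordinates are
copied from the source without rebasing.

For the GWAS Catalog the sample unit is one Studies entry (one study-trait
pair): its regions are the resolvable Associations sharing the study
accession, and its metadata combines the Studies columns with the Ancestry
columns, the latter suffixed with a 1-based ordinal in file order
(``broad_ancestral_category_1`` ... ``_n``).  For FinnGen the sample unit is
one endpoint.
"""

from __future__ import annotations

import logging
import re

from .gdm import GdmDataset, GdmRegion, GdmSample, MetadataPair, RegionSchema
from .ingest import (
    CatalogAncestryRow,
    CatalogAssociationRow,
    CatalogStudyRow,
    FinnGenEndpoint,
    FinnGenVariantRow,
)

logger = logging.getLogger(__name__)

# Variable attributes are copied verbatim from the source rows, so they are
# declared as text; numeric interpretation is deferred to consumers.
CATALOG_SCHEMA = RegionSchema(
    name="gwas_catalog",
    variable_fields=(
        ("strongest_snp_risk_allele", "text"),
        ("reported_genes", "text"),
        ("p_value", "text"),
    ),
)

FINNGEN_SCHEMA = RegionSchema(
    name="finngen",
    variable_fields=(
        ("ref", "text"),
        ("alt", "text"),
        ("rsids", "text"),
        ("pval", "text"),
        ("beta", "text"),
        ("sebeta", "text"),
    ),
)

_RISK_ALLELE_RE = re.compile(r"^(?:chr)?(\w+):(\d+)$", re.IGNORECASE)

ANCESTRY_ATTRIBUTES = (
    "broad_ancestral_category",
    "country_of_origin",
    "country_of_recruitment",
    "number_of_individuals",
    "stage",
)


def normalize_chrom(token: str) -> str:
    """Normalize a chromosome token to chr-prefixed form; pass-through if already prefixed."""
    token = token.strip()
    if token.lower().startswith("chr"):
        return "chr" + token[3:]
    return f"chr{token}"


def resolve_catalog_coordinates(
    row: CatalogAssociationRow,
) -> tuple[str, int, int, str] | None:
    """Derive (chrom, start, stop, strand) for one association, or None if unresolvable.

    The chromosome comes from CHR_ID when present; otherwise a positional
    token of the form ``chr<N>:<pos>`` is parsed from the part of STRONGEST
    SNP-RISK ALLELE before the first '-'.  Stop is start+1 (SNPs only) and
    strand is always '*'.
    """
    if row.chr_id and row.chr_pos is not None:
        return normalize_chrom(row.chr_id), row.chr_pos, row.chr_pos + 1, "*"
    head = row.strongest_snp_risk_allele.split("-", 1)[0].strip()
    m = _RISK_ALLELE_RE.match(head)
    if m:
        pos = int(m.group(2))
        return normalize_chrom(m.group(1)), pos, pos + 1, "*"
    return None


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def _catalog_metadata(
    study: CatalogStudyRow, ancestries: list[CatalogAncestryRow]
) -> list[MetadataPair]:
    pairs: list[MetadataPair] = [
        ("study_accession", study.study_accession),
        ("disease_trait", study.disease_trait),
        ("pubmed_id", study.pubmed_id),
    ]
    pairs.extend((k, v) for k, v in sorted(study.extra.items()) if v)
    for ordinal, anc in enumerate(ancestries, start=1):
        for attr in ANCESTRY_ATTRIBUTES:
            value = getattr(anc, attr)
            if value is not None and value != "":
                pairs.append((f"{attr}_{ordinal}", _fmt(value)))
    # Stage-wise participant totals: the relational cohort table stores the
    # cardinalities per stage, which the source only provides per ancestry row.
    for stage in ("initial", "replication"):
        counts = [
            a.number_of_individuals
            for a in ancestries
            if a.stage == stage and a.number_of_individuals is not None
        ]
        if counts:
            pairs.append((f"{stage}_individuals", str(sum(counts))))
    return pairs


def transform_catalog(
    studies: list[CatalogStudyRow],
    ancestries: list[CatalogAncestryRow],
    associations: list[CatalogAssociationRow],
    dataset_name: str = "gwas_catalog",
) -> GdmDataset:
    """Build one GDM sample per Studies entry from the three-file dump."""
    anc_by_acc: dict[str, list[CatalogAncestryRow]] = {}
    for anc in ancestries:
        anc_by_acc.setdefault(anc.study_accession, []).append(anc)
    assoc_by_acc: dict[str, list[CatalogAssociationRow]] = {}
    for assoc in associations:
        assoc_by_acc.setdefault(assoc.study_accession, []).append(assoc)

    samples: list[GdmSample] = []
    seen: dict[str, int] = {}
    for study in studies:
        acc = study.study_accession
        seen[acc] = seen.get(acc, 0) + 1
        sample_id = acc if seen[acc] == 1 else f"{acc}__{seen[acc]}"
        if seen[acc] == 2:
            logger.info(
                "accession %s has multiple trait entries; regions replicated per entry", acc
            )
        regions: list[GdmRegion] = []
        for assoc in assoc_by_acc.get(acc, ()):
            coords = resolve_catalog_coordinates(assoc)
            if coords is None:
                logger.warning(
                    "association of %s (%s) lacks positional information, skipped",
                    acc,
                    assoc.strongest_snp_risk_allele or "?",
                )
                continue
            chrom, start, stop, strand = coords
            regions.append(
                GdmRegion(
                    chrom,
                    start,
                    stop,
                    strand,
                    (assoc.strongest_snp_risk_allele, assoc.reported_genes, _fmt(assoc.p_value)),
                )
            )
        if not regions:
            logger.warning("study %s: no resolvable associations, sample has 0 regions", sample_id)
        samples.append(
            GdmSample(
                sample_id=sample_id,
                regions=regions,
                metadata=_catalog_metadata(study, anc_by_acc.get(acc, [])),
            )
        )
    dataset = GdmDataset(name=dataset_name, schema=CATALOG_SCHEMA, samples=samples)
    dataset.validate()
    return dataset


def transform_finngen(
    endpoints_with_rows: list[tuple[FinnGenEndpoint, list[FinnGenVariantRow]]],
    dataset_name: str = "finngen",
) -> GdmDataset:
    """Build one GDM sample per endpoint; one region per variant row."""
    samples: list[GdmSample] = []
    for endpoint, rows in endpoints_with_rows:
        regions: list[GdmRegion] = []
        for row in rows:
            if row.pos <= 0:
                logger.warning("endpoint %s: nonpositive pos %d skipped", endpoint.endpoint_name, row.pos)
                continue
            regions.append(
                GdmRegion(
                    normalize_chrom(row.chrom),
                    row.pos,
                    row.pos + 1,
                    "*",
                    (
                        row.ref,
                        row.alt,
                        row.rsid,
                        _fmt(row.pval),
                        row.effects.get("beta", ""),
                        row.effects.get("sebeta", ""),
                    ),
                )
            )
        metadata: list[MetadataPair] = [
            ("phenocode", endpoint.endpoint_name),
            ("phenostring", endpoint.trait_label),
        ]
        if endpoint.num_cases is not None:
            metadata.append(("num_cases", str(endpoint.num_cases)))
        if endpoint.num_controls is not None:
            metadata.append(("num_controls", str(endpoint.num_controls)))
        samples.append(GdmSample(sample_id=endpoint.endpoint_name, regions=regions, metadata=metadata))
    dataset = GdmDataset(name=dataset_name, schema=FINNGEN_SCHEMA, samples=samples)
    dataset.validate()
    return dataset
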