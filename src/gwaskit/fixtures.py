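"""Deterministic generators of source-shaped inputs and ontology corpora.

Every stage of the pipeline is testable offline: these generators emit
GWAS Catalog-shaped three-file dumps, FinnGen-shaped manifests with
summary-statistics files, and a JSON ontology-term corpus, all as pure
functions of (seed, parameters) — same seed, byte-identical files.  Next to
each fixture a ``*_truth.json`` manifest records the planted ground truth
(row counts, rows with missing coordinates, shared trait labels) so tests
never re-derive it by parsing the fixture.

Only structural realism is attempted: identifiers, coordinates, traits and
counts have source-like shapes, but p-values and effect sizes are not drawn
from realistic GWAS distributions.
"""

from __future__ import annotations

import json
import random
from pathlib import Path

from .terms import TermRecord, term_from_dict, term_to_dict

# Traits resolvable against the default term corpus (exact or near labels) ...
ANNOTATABLE_TRAITS = (
    "appendicitis",
    "asthma",
    "creatinine measurement",
    "survival time",
    "bipolar disorder",
    "stroke",
    "diverticulitis",
    "autoimmune disease",
    "anorexia nervosa",
)
# ... and traits engineered to stay far from every corpus label (match < 5).
OBSCURE_TRAITS = (
    "yearly pollen episode diary count",
    "self reported wellbeing questionnaire total",
    "left handed grip strength percentile change",
)

ANCESTRY_CATEGORIES = ("European", "East Asian", "African", "Hispanic or Latin American", "South Asian")
COUNTRIES = ("U.K.", "Finland", "Japan", "U.S.", "Germany", "China")

CATALOG_FILES = ("Studies.tsv", "Ancestry.tsv", "Associations.tsv")


def _trait_pool() -> tuple[str, ...]:
    return ANNOTATABLE_TRAITS + OBSCURE_TRAITS


def generate_catalog_fixture(
    seed: int,
    n_studies: int,
    n_assoc_per_study: int = 5,
    n_ancestries_per_study: int = 2,
    frac_missing_chr: float = 0.0,
    out_dir: Path | str = ".",
) -> dict:
    """Write a GWAS Catalog-shaped three-file dump plus a ground-truth manifest.

    Exactly ``round(frac_missing_chr * total)`` association rows lack CHR_ID;
    of those, every second one carries a positional risk-allele token (still
    resolvable) and the rest an rs-identifier (unresolvable).
    """
    if not 0.0 <= frac_missing_chr <= 1.0:
        raise ValueError("frac_missing_chr must be in [0, 1]")
    rng = random.Random(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pool = _trait_pool()

    studies_rows, ancestry_rows, assoc_rows = [], [], []
    truth_studies = []
    total_assoc = n_studies * n_assoc_per_study
    n_missing = round(frac_missing_chr * total_assoc)
    missing_slots = set(rng.sample(range(total_assoc), n_missing)) if n_missing else set()
    n_unresolvable = 0
    assoc_index = 0
    missing_seen = 0

    for s in range(n_studies):
        accession = f"GCST{900000 + seed * 1000 + s:06d}"
        trait = pool[(seed + s) % len(pool)]
        pubmed = str(30000000 + rng.randrange(1000000))
        studies_rows.append((accession, trait, pubmed, f"Journal {rng.randrange(50)}"))
        ancestries = []
        for a in range(n_ancestries_per_study):
            stage = "initial" if a == 0 or rng.random() < 0.6 else "replication"
            n_ind = rng.randrange(500, 50000)
            category = ANCESTRY_CATEGORIES[rng.randrange(len(ANCESTRY_CATEGORIES))]
            origin = COUNTRIES[rng.randrange(len(COUNTRIES))]
            recruit = COUNTRIES[rng.randrange(len(COUNTRIES))]
            ancestry_rows.append((accession, stage, str(n_ind), category, origin, recruit))
            ancestries.append({"stage": stage, "number_of_individuals": n_ind})
        n_res = 0
        for _ in range(n_assoc_per_study):
            chrom = str(rng.randrange(1, 23))
            pos = rng.randrange(10_000, 200_000_000)
            pval = f"{rng.randrange(1, 10)}e-{rng.randrange(8, 30)}"
            gene = f"GENE{rng.randrange(1, 500)}"
            if assoc_index in missing_slots:
                if missing_seen % 2 == 0:
                    allele = f"chr{chrom}:{pos}-{rng.choice('ACGT')}"
                    n_res += 1
                else:
                    allele = f"rs{rng.randrange(10**6, 10**8)}-{rng.choice('ACGT')}"
                    n_unresolvable += 1
                missing_seen += 1
                assoc_rows.append((accession, "", "", allele, gene, pval))
            else:
                allele = f"rs{rng.randrange(10**6, 10**8)}-{rng.choice('ACGT')}"
                assoc_rows.append((accession, chrom, str(pos), allele, gene, pval))
                n_res += 1
            assoc_index += 1
        truth_studies.append(
            {
                "accession": accession,
                "trait": trait,
                "pubmed_id": pubmed,
                "n_ancestries": n_ancestries_per_study,
                "ancestries": ancestries,
                "n_associations": n_assoc_per_study,
                "n_resolvable": n_res,
            }
        )

    _write_tsv(
        out_dir / "Studies.tsv",
        ("STUDY ACCESSION", "DISEASE/TRAIT", "PUBMEDID", "JOURNAL"),
        studies_rows,
    )
    _write_tsv(
        out_dir / "Ancestry.tsv",
        (
            "STUDY ACCESSION",
            "STAGE",
            "NUMBER OF INDIVIDUALS",
            "BROAD ANCESTRAL CATEGORY",
            "COUNTRY OF ORIGIN",
            "COUNTRY OF RECRUITMENT",
        ),
        ancestry_rows,
    )
    _write_tsv(
        out_dir / "Associations.tsv",
        ("STUDY ACCESSION", "CHR_ID", "CHR_POS", "STRONGEST SNP-RISK ALLELE", "REPORTED GENE(S)", "P-VALUE"),
        assoc_rows,
    )

    truth = {
        "seed": seed,
        "n_studies": n_studies,
        "n_ancestry_rows": len(ancestry_rows),
        "n_associations": total_assoc,
        "n_missing_chr": n_missing,
        "n_unresolvable": n_unresolvable,
        "n_resolvable": total_assoc - n_unresolvable,
        "studies": truth_studies,
        "files": {name: str(out_dir / name) for name in CATALOG_FILES},
    }
    _write_json(out_dir / "catalog_truth.json", truth)
    return truth


def generate_finngen_fixture(
    seed: int,
    n_endpoints: int,
    n_variants: int = 4,
    shared_trait_labels: tuple[str, ...] = (),
    out_dir: Path | str = ".",
) -> dict:
    """Write a FinnGen-shaped manifest plus one summary-statistics TSV per endpoint.

    The first ``len(shared_trait_labels)`` endpoints reuse those trait strings
    verbatim (to exercise cross-source concept overlap); the rest draw from
    the built-in trait pool.
    """
    rng = random.Random(seed + 7919)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pool = _trait_pool()

    manifest_rows = []
    truth_endpoints = []
    for e in range(n_endpoints):
        if e < len(shared_trait_labels):
            trait = shared_trait_labels[e]
        else:
            trait = pool[(seed + 3 + e) % len(pool)]
        code = f"EP_{trait.upper().replace(' ', '_').replace('-', '_')[:24]}_{e}"
        filename = f"{code}.tsv"
        cases = rng.randrange(100, 20000)
        controls = rng.randrange(10000, 300000)
        manifest_rows.append((code, trait, str(cases), str(controls), filename))
        variant_rows = []
        for _ in range(n_variants):
            chrom = str(rng.randrange(1, 23))
            pos = rng.randrange(10_000, 200_000_000)
            ref = rng.choice("ACGT")
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rsid = f"rs{rng.randrange(10**6, 10**8)}"
            pval = f"{rng.randrange(1, 10)}e-{rng.randrange(8, 30)}"
            beta = f"{rng.uniform(-0.5, 0.5):.4f}"
            sebeta = f"{rng.uniform(0.01, 0.1):.4f}"
            variant_rows.append((chrom, str(pos), ref, alt, rsid, pval, beta, sebeta))
        _write_tsv(
            out_dir / filename,
            ("#chrom", "pos", "ref", "alt", "rsids", "pval", "beta", "sebeta"),
            variant_rows,
        )
        truth_endpoints.append(
            {"phenocode": code, "trait": trait, "n_variants": n_variants, "file": filename}
        )

    _write_tsv(
        out_dir / "manifest.tsv",
        ("phenocode", "phenostring", "num_cases", "num_controls", "path"),
        manifest_rows,
    )
    truth = {
        "seed": seed,
        "n_endpoints": n_endpoints,
        "n_variants_total": n_endpoints * n_variants,
        "shared_trait_labels": list(shared_trait_labels),
        "endpoints": truth_endpoints,
        "manifest": str(out_dir / "manifest.tsv"),
    }
    _write_json(out_dir / "finngen_truth.json", truth)
    return truth


def generate_ontology_fixture(
    seed: int, terms_spec: list[dict], out_path: Path | str
) -> Path:
    """Write a JSON term corpus from a term specification; duplicate ids are fatal."""
    seen: set[tuple[str, str]] = set()
    records = []
    for doc in terms_spec:
        term = term_from_dict(doc)
        if term.key in seen:
            raise ValueError(f"duplicate term id {term.key} in spec")
        seen.add(term.key)
        records.append(term)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(
        json.dumps([term_to_dict(t) for t in records], indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return out_path


def default_term_corpus() -> list[TermRecord]:
    """Built-in toy ontology corpus covering the packaged worked examples.

    Includes the exemplar terms of the reference annotation table, a shared
    'appendicitis' concept reachable from both sources' trait labels, and a
    five-deep NCIT ancestor chain for knowledge-base traversal tests.
    """

    def t(ontology, code, label, synonyms=(), parents=(), children=(), **kw):
        return TermRecord(
            ontology=ontology,
            ontology_id=code,
            pref_label=label,
            synonyms=tuple(synonyms),
            parents=tuple(parents),
            children=tuple(children),
            iri=kw.get("iri", f"http://purl.example.org/{ontology}/{code}"),
            description=kw.get("description", ""),
            xrefs=tuple(kw.get("xrefs", ())),
        )

    return [
        t(
            "NCIT",
            "NCIT_C64547",
            "Creatinine Measurement",
            ["Creatinine", "Creatinine Level"],
            parents=[("NCIT_C25294", "is_a")],
        ),
        t("NCIT", "NCIT_C61048", "Urine Creatinine Measurement", parents=[("NCIT_C64547", "is_a")]),
        t(
            "NCIT",
            "NCIT_C25294",
            "Laboratory Procedure",
            children=[("NCIT_C64547", "is_a")],
            parents=[("NCIT_C25218", "is_a")],
        ),
        t("NCIT", "NCIT_C25218", "Intervention or Procedure", children=[("NCIT_C25294", "is_a")]),
        # appendicitis with a 5-link ancestor chain (for depth-bounded traversal)
        t(
            "NCIT",
            "NCIT_C35145",
            "Appendicitis",
            ["Inflammation of Appendix"],
            parents=[("NCIT_C26726", "is_a")],
            xrefs=["DOID:8337"],
        ),
        t(
            "NCIT",
            "NCIT_C26726",
            "Gastrointestinal Disorder",
            parents=[("NCIT_C2991", "is_a")],
            children=[("NCIT_C35145", "is_a")],
        ),
        t(
            "NCIT",
            "NCIT_C2991",
            "Disease or Disorder",
            parents=[("NCIT_C7057", "is_a")],
            children=[("NCIT_C26726", "is_a")],
        ),
        t(
            "NCIT",
            "NCIT_C7057",
            "Condition",
            parents=[("NCIT_C43431", "is_a")],
            children=[("NCIT_C2991", "is_a")],
        ),
        t("NCIT", "NCIT_C43431", "Activity", children=[("NCIT_C7057", "is_a")]),
        t("HP", "HP_0002039", "Anorexia", ["Anorexia"]),
        t("HP", "HP_0002099", "Asthma", ["Bronchial asthma", "Asthma"]),
        t("EFO", "EFO_0000270", "asthma", ["asthma attack"]),
        t("EFO", "EFO_0000714", "survival time", ["survival", "time of survival"]),
        t("EFO", "EFO_1001460", "diverticulitis", ["digestive tract diverticulum inflammation"]),
        t("EFO", "EFO_0005140", "autoimmune disease", ["autoimmunity"]),
        t("EFO", "EFO_0000289", "bipolar disorder", ["bipolar affective disorder"]),
        t("EFO", "EFO_0000712", "stroke", ["cerebrovascular accident"]),
        t(
            "EFO",
            "EFO_0004919",
            "metastasis free survival",
            ["metastasis free survival time"],
        ),
        t(
            "EFO",
            "EFO_0007887",
            "autosomal dominant compelling helio-ophthalmic outburst syndrome",
            ["photic sneeze reflex", "Peroutka sneeze"],
        ),
        t("EFO", "EFO_0007149", "appendicitis", ["appendicitis NOS"], xrefs=["NCIT:C35145"]),
    ]


def default_term_corpus_spec() -> list[dict]:
    return [term_to_dict(t) for t in default_term_corpus()]


def _write_tsv(path: Path, header: tuple[str, ...], rows: list[tuple]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8")
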