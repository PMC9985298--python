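"""Ontology term records and term-lookup backends.

A :class:`TermRecord` carries everything the annotator needs about one
ontological term: its identifying (ontology, ontology_id) pair, preferred
label, synonyms, description/IRI, cross-references, and typed links to
parents (hyperonyms) and children (hyponyms) with relation kind (``is_a`` or
``part_of``).

Lookup goes through the :class:`TermSource` interface.  The default backend
reads a JSON corpus from disk (the shape mirrors term-search API responses),
which keeps the whole pipeline runnable offline; an HTTP backend with the
same surface can be pointed at a live term-search service.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

RELATION_KINDS = {"is_a", "part_of"}


@dataclass(frozen=True)
class TermRecord:
    ontology: str
    ontology_id: str
    pref_label: str
    synonyms: tuple[str, ...] = ()
    description: str = ""
    iri: str = ""
    xrefs: tuple[str, ...] = ()
    parents: tuple[tuple[str, str], ...] = ()  # (ontology_id, relation kind)
    children: tuple[tuple[str, str], ...] = ()

    @property
    def key(self) -> tuple[str, str]:
        return (self.ontology, self.ontology_id)


def _links(raw: list) -> tuple[tuple[str, str], ...]:
    out = []
    for entry in raw or []:
        if isinstance(entry, dict):
            out.append((entry["id"], entry.get("relation", "is_a")))
        else:
            out.append((str(entry), "is_a"))
    return tuple(out)


def term_from_dict(doc: dict) -> TermRecord:
    return TermRecord(
        ontology=doc["ontology"],
        ontology_id=doc["ontology_id"],
        pref_label=doc.get("pref_label", ""),
        synonyms=tuple(doc.get("synonyms", ())),
        description=doc.get("description", ""),
        iri=doc.get("iri", ""),
        xrefs=tuple(doc.get("xrefs", ())),
        parents=_links(doc.get("parents", [])),
        children=_links(doc.get("children", [])),
    )


def term_to_dict(term: TermRecord) -> dict:
    return {
        "ontology": term.ontology,
        "ontology_id": term.ontology_id,
        "pref_label": term.pref_label,
        "synonyms": list(term.synonyms),
        "description": term.description,
        "iri": term.iri,
        "xrefs": list(term.xrefs),
        "parents": [{"id": i, "relation": k} for i, k in term.parents],
        "children": [{"id": i, "relation": k} for i, k in term.children],
    }


class TermSourceError(RuntimeError):
    pass


class TermSource:
    """Search and resolve ontology terms."""

    def search(self, query: str, ontologies: list[str] | None = None) -> list[TermRecord]:
        raise NotImplementedError

    def get(self, ontology: str, ontology_id: str) -> TermRecord | None:
        raise NotImplementedError


@dataclass
class FixtureTermSource(TermSource):
    """Offline backend over an in-memory corpus (optionally loaded from JSON)."""

    terms: dict[tuple[str, str], TermRecord] = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: Path | str) -> "FixtureTermSource":
        docs = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls.from_records([term_from_dict(d) for d in docs])

    @classmethod
    def from_records(cls, records: list[TermRecord]) -> "FixtureTermSource":
        terms: dict[tuple[str, str], TermRecord] = {}
        for t in records:
            if t.key in terms:
                raise TermSourceError(f"duplicate term id {t.key}")
            terms[t.key] = t
        return cls(terms=terms)

    def search(self, query: str, ontologies: list[str] | None = None) -> list[TermRecord]:
        # The fixture backend returns every term of the requested ontologies
        # and leaves ranking entirely to the scorer; corpora are toy-scale.
        wanted = set(ontologies) if ontologies else None
        return [
            t
            for key, t in sorted(self.terms.items())
            if wanted is None or t.ontology in wanted
        ]

    def get(self, ontology: str, ontology_id: str) -> TermRecord | None:
        return self.terms.get((ontology, ontology_id))


class HttpTermSource(TermSource):  # pragma: no cover - requires a network service
    """Backend for a term-search HTTP API with OLS-style request shape.

    Never exercised by the test suite; provided so a deployment can swap the
    fixture corpus for a live service without touching the enrichment code.
    """

    def __init__(self, base_url: str, field_list: str = "label,synonym,iri,description"):
        self.base_url = base_url.rstrip("/")
        self.field_list = field_list

    def search(self, query: str, ontologies: list[str] | None = None) -> list[TermRecord]:
        import urllib.parse
        import urllib.request

        params = {"q": query, "fieldList": self.field_list}
        if ontologies:
            params["ontology"] = ",".join(o.lower() for o in ontologies)
        url = f"{self.base_url}/search?{urllib.parse.urlencode(params)}"
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                payload = json.load(resp)
        except OSError as exc:
            raise TermSourceError(f"term service unreachable: {exc}") from exc
        out = []
        for doc in payload.get("response", {}).get("docs", []):
            out.append(
                TermRecord(
                    ontology=doc.get("ontology_prefix", doc.get("ontology_name", "")).upper(),
                    ontology_id=doc.get("short_form", ""),
                    pref_label=doc.get("label", ""),
                    synonyms=tuple(doc.get("synonym", ())),
                    description=" ".join(doc.get("description", ())),
                    iri=doc.get("iri", ""),
                )
            )
        return out

    def get(self, ontology: str, ontology_id: str) -> TermRecord | None:
        hits = [t for t in self.search(ontology_id, [ontology]) if t.ontology_id == ontology_id]
        return hits[0] if hits else None
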