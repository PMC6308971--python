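"""Pathway-membership database: GPML parsing, flat tables, SPARQL queries.

A molecular pathway database (WikiPathways-style) is modelled as an index
pathway -> {gene xrefs, metabolite xrefs, ontology tags}. It can be loaded
from a directory of GPML 2013a pathway documents or from a flat membership
table, and queried for gene/metabolite membership. For remote verification
the module also renders the equivalent SPARQL over the WikiPathways RDF
vocabulary; local execution against a Turtle fixture uses rdflib, remote
execution is an explicit opt-in and is never required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, TYPE_CHECKING

import pandas as pd
from lxml import etree

from .errors import FormatError, ParseError

if TYPE_CHECKING:
    from .lexicon import GeneLexicon

logger = logging.getLogger(__name__)

__all__ = [
    "XrefNamespace",
    "PathwayRecord",
    "PathwayMembershipDB",
    "load_pathway_table",
    "parse_gpml",
    "load_gpml_directory",
    "genes_pathway_coverage",
    "GeneCoverage",
    "pathway_ontology_usage",
    "build_sparql_membership_query",
    "run_sparql_on_turtle",
]

GPML_2013A_NS = "http://pathvisio.org/GPML/2013a"
_BIOPAX_NS = "http://www.biopax.org/release/biopax-level3.owl#"

WP_VOCAB = "http://vocabularies.wikipathways.org/wp#"
_PATHWAY_IRI_PREFIX = "http://identifiers.org/wikipathways/"
_IRI_PREFIXES = {
    "ensembl": "http://identifiers.org/ensembl/",
    "hgnc": "http://identifiers.org/hgnc/",
    "hgnc.symbol": "http://identifiers.org/hgnc.symbol/",
    "chebi": "http://identifiers.org/chebi/",
}


class XrefNamespace(str, Enum):
    HGNC_SYMBOL = "HGNC_SYMBOL"
    HGNC_ID = "HGNC_ID"
    ENSEMBL = "ENSEMBL"
    CHEBI = "CHEBI"
    OTHER = "OTHER"


_GENE_NAMESPACES = (XrefNamespace.HGNC_SYMBOL, XrefNamespace.HGNC_ID, XrefNamespace.ENSEMBL)
_ONTOLOGY_SOURCES = ("PW", "CL", "DO")


@dataclass
class PathwayRecord:
    pathway_id: str
    title: str = ""
    gene_xrefs: set[tuple[XrefNamespace, str]] = field(default_factory=set)
    metabolite_xrefs: set[str] = field(default_factory=set)
    ontology_tags: set[tuple[str, str]] = field(default_factory=set)


class PathwayMembershipDB:
    """Index of pathways by gene xref, metabolite xref, and ontology tag."""

    def __init__(self, records: Iterable[PathwayRecord]):
        self.pathways: dict[str, PathwayRecord] = {}
        for rec in records:
            if rec.pathway_id in self.pathways:
                raise FormatError(f"duplicate pathway id {rec.pathway_id!r}")
            self.pathways[rec.pathway_id] = rec
        self._gene_index: dict[tuple[XrefNamespace, str], set[str]] = {}
        self._metabolite_index: dict[str, set[str]] = {}
        for rec in self.pathways.values():
            for xref in rec.gene_xrefs:
                self._gene_index.setdefault(xref, set()).add(rec.pathway_id)
            for chebi in rec.metabolite_xrefs:
                self._metabolite_index.setdefault(chebi, set()).add(rec.pathway_id)

    def __len__(self) -> int:
        return len(self.pathways)

    def pathways_with_gene(self, namespace: XrefNamespace, identifier: str) -> frozenset[str]:
        return frozenset(self._gene_index.get((namespace, identifier), set()))

    def pathways_with_any_gene_id(self, identifier: str) -> frozenset[str]:
        """Membership lookup of an identifier across all gene namespaces."""
        hits: set[str] = set()
        for ns in _GENE_NAMESPACES:
            hits |= self._gene_index.get((ns, identifier), set())
        return frozenset(hits)

    def pathways_with_metabolite(self, chebi_id: str) -> frozenset[str]:
        return frozenset(self._metabolite_index.get(chebi_id, set()))


_TABLE_COLUMNS = ("pathway_id", "title", "xref_namespace", "xref_id")


def load_pathway_table(path: str | Path) -> PathwayMembershipDB:
    """Load a flat pathway-membership table (a local stand-in for a SPARQL
    endpoint).

    Tab-separated with columns ``pathway_id``, ``title``, ``xref_namespace``,
    ``xref_id``. Gene rows use namespaces HGNC_SYMBOL / HGNC_ID / ENSEMBL /
    OTHER, metabolite rows CHEBI, and ontology-tag rows PW / CL / DO. An
    unknown namespace raises naming the offending value.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"pathway table not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(
            f"pathway table {path} is missing required column(s): {', '.join(sorted(missing))}"
        )
    records: dict[str, PathwayRecord] = {}
    for row in table.itertuples(index=False):
        rec = records.setdefault(
            row.pathway_id, PathwayRecord(pathway_id=row.pathway_id, title=row.title)
        )
        ns = row.xref_namespace.strip()
        xref = row.xref_id.strip()
        if not xref:
            continue
        if ns in _ONTOLOGY_SOURCES:
            rec.ontology_tags.add((ns, xref))
        elif ns == XrefNamespace.CHEBI.value:
            rec.metabolite_xrefs.add(xref)
        elif ns in XrefNamespace.__members__:
            rec.gene_xrefs.add((XrefNamespace[ns], xref))
        else:
            raise FormatError(f"unknown xref namespace {ns!r} in {path}")
    return PathwayMembershipDB(records.values())


_GPML_DB_TO_NS = {
    "Ensembl": XrefNamespace.ENSEMBL,
    "HGNC": XrefNamespace.HGNC_SYMBOL,
    "HGNC ID": XrefNamespace.HGNC_ID,
}


def parse_gpml(path: str | Path) -> PathwayRecord:
    """Parse one GPML 2013a pathway document into a :class:`PathwayRecord`.

    GeneProduct/Protein data nodes contribute gene xrefs (Ensembl and HGNC
    databases normalized, anything else recorded as OTHER); Metabolite nodes
    with a ChEBI xref contribute metabolite xrefs; BioPAX open controlled
    vocabulary elements contribute ontology tags keyed by their term prefix.
    The GPML document itself carries no pathway identifier, so the id is taken
    from the file stem (``WP42.gpml`` -> ``WP42``). Documents in a GPML
    namespace other than 2013a are rejected.
    """
    path = Path(path)
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed GPML in {path}: {exc}") from exc
    ns = root.tag[1:].split("}", 1)[0] if root.tag.startswith("{") else ""
    if ns != GPML_2013A_NS:
        raise ParseError(
            f"unsupported GPML dialect {ns!r} in {path}; only {GPML_2013A_NS} is supported"
        )
    rec = PathwayRecord(pathway_id=path.stem, title=root.get("Name", ""))
    for node in root.findall(f"{{{ns}}}DataNode"):
        node_type = node.get("Type", "")
        xref = node.find(f"{{{ns}}}Xref")
        if xref is None or not xref.get("ID"):
            logger.warning("skipping DataNode without Xref in %s", path.name)
            continue
        database = xref.get("Database", "")
        identifier = xref.get("ID", "").strip()
        if node_type in ("GeneProduct", "Protein"):
            namespace = _GPML_DB_TO_NS.get(database, XrefNamespace.OTHER)
            rec.gene_xrefs.add((namespace, identifier))
        elif node_type == "Metabolite" and database == "ChEBI":
            if not identifier.startswith("CHEBI:"):
                identifier = f"CHEBI:{identifier}"
            rec.metabolite_xrefs.add(identifier)
    for vocab in root.iter(f"{{{_BIOPAX_NS}}}openControlledVocabulary"):
        term_elem = vocab.find(f"{{{_BIOPAX_NS}}}ID")
        if term_elem is None or not term_elem.text:
            continue
        term_id = term_elem.text.strip()
        prefix = term_id.split(":", 1)[0]
        source = {"PW": "PW", "CL": "CL", "DO": "DO", "DOID": "DO"}.get(prefix, "OTHER")
        rec.ontology_tags.add((source, term_id))
    return rec


def load_gpml_directory(directory: str | Path) -> PathwayMembershipDB:
    """Load every ``*.gpml`` file under a directory into one membership DB."""
    directory = Path(directory)
    files = sorted(directory.glob("*.gpml"))
    if not files:
        raise FormatError(f"no .gpml files found in {directory}")
    return PathwayMembershipDB(parse_gpml(f) for f in files)


@dataclass
class GeneCoverage:
    """Which of a set of genes appear in at least one pathway."""

    covered: frozenset[str]
    per_gene_pathways: dict[str, frozenset[str]]
    #: which identifier namespaces produced each gene's hits
    per_gene_namespaces: dict[str, frozenset[XrefNamespace]]
    fraction: float | None


def genes_pathway_coverage(
    gene_ids: Iterable[str], db: PathwayMembershipDB, lexicon: "GeneLexicon"
) -> GeneCoverage:
    """Resolve lexicon gene ids against pathway gene xrefs across namespaces.

    A gene is covered iff any of its identifiers — HGNC id, approved symbol,
    or Ensembl id, all supplied by the lexicon — appears among any pathway's
    gene xrefs. The fraction is ``|covered| / |gene_ids|``, or None when the
    query set is empty.
    """
    gene_ids = set(gene_ids)
    covered: set[str] = set()
    per_gene_pathways: dict[str, frozenset[str]] = {}
    per_gene_namespaces: dict[str, frozenset[XrefNamespace]] = {}
    for gene_id in sorted(gene_ids):
        hits: set[str] = set()
        namespaces: set[XrefNamespace] = set()
        for identifier in lexicon.identifiers_for(gene_id):
            for ns in _GENE_NAMESPACES:
                found = db.pathways_with_gene(ns, identifier)
                if found:
                    hits |= found
                    namespaces.add(ns)
        per_gene_pathways[gene_id] = frozenset(hits)
        per_gene_namespaces[gene_id] = frozenset(namespaces)
        if hits:
            covered.add(gene_id)
    fraction = len(covered) / len(gene_ids) if gene_ids else None
    return GeneCoverage(
        covered=frozenset(covered),
        per_gene_pathways=per_gene_pathways,
        per_gene_namespaces=per_gene_namespaces,
        fraction=fraction,
    )


def pathway_ontology_usage(db: PathwayMembershipDB) -> dict[str, int]:
    """Pathway-annotation audit: total pathways and, per ontology source
    (pathway ontology PW, cell ontology CL, disease ontology DO), the number
    of pathways carrying at least one tag (each pathway counted once per
    source)."""
    counts = {src: 0 for src in _ONTOLOGY_SOURCES}
    for rec in db.pathways.values():
        sources = {src for src, _ in rec.ontology_tags}
        for src in _ONTOLOGY_SOURCES:
            if src in sources:
                counts[src] += 1
    return {
        "pathways_total": len(db.pathways),
        "with_pw": counts["PW"],
        "with_cl": counts["CL"],
        "with_do": counts["DO"],
    }


def _gene_id_to_iri(identifier: str) -> str:
    if identifier.startswith("ENSG"):
        return _IRI_PREFIXES["ensembl"] + identifier
    if identifier.startswith("HGNC:"):
        return _IRI_PREFIXES["hgnc"] + identifier
    return _IRI_PREFIXES["hgnc.symbol"] + identifier


def iri_to_identifier(iri: str) -> str:
    """Strip a known identifiers.org (or pathway) prefix from an IRI."""
    for prefix in (_PATHWAY_IRI_PREFIX, *_IRI_PREFIXES.values()):
        if iri.startswith(prefix):
            return iri[len(prefix):]
    return iri


def build_sparql_membership_query(ids: Iterable[str], id_kind: str) -> str:
    """Render a SPARQL SELECT retrieving (pathway, id) membership pairs.

    ``id_kind`` is ``"gene"`` (ids are HGNC symbols, ``HGNC:<n>`` ids, or
    Ensembl gene ids — matched through the corresponding bridge predicates)
    or ``"metabolite"`` (ids are ``CHEBI:<n>``). The VALUES clause lists the
    ids in sorted order so the query string is reproducible byte-for-byte.
    """
    ids = sorted(set(ids))
    if not ids:
        raise ValueError("id set must be non-empty")
    if id_kind == "metabolite":
        iris = [_IRI_PREFIXES["chebi"] + i for i in ids]
        predicate = "wp:bdbChEBI"
    elif id_kind == "gene":
        iris = [_gene_id_to_iri(i) for i in ids]
        predicate = "(wp:bdbHgncSymbol|wp:bdbHgnc|wp:bdbEnsembl)"
    else:
        raise ValueError(f"unknown id_kind {id_kind!r}; expected 'gene' or 'metabolite'")
    values = "\n    ".join(f"<{iri}>" for iri in iris)
    return (
        f"PREFIX wp: <{WP_VOCAB}>\n"
        "PREFIX dcterms: <http://purl.org/dc/terms/>\n"
        "SELECT DISTINCT ?pathway ?xref WHERE {\n"
        "  VALUES ?xref {\n"
        f"    {values}\n"
        "  }\n"
        f"  ?node {predicate} ?xref ;\n"
        "        dcterms:isPartOf ?pathway .\n"
        "  ?pathway a wp:Pathway .\n"
        "}\n"
    )


def run_sparql_on_turtle(query: str, turtle_path: str | Path) -> frozenset[tuple[str, str]]:
    """Execute a membership query against a local Turtle rendering of the
    pathway database, returning (pathway_id, identifier) pairs.

    This is the in-process counterpart of a remote endpoint; it is the oracle
    used to verify that queries and table lookups agree.
    """
    import rdflib

    graph = rdflib.Graph()
    graph.parse(str(turtle_path), format="turtle")
    return frozenset(
        (iri_to_identifier(str(row.pathway)), iri_to_identifier(str(row.xref)))
        for row in graph.query(query)
    )


def run_sparql_remote(query: str, endpoint: str, timeout: float = 60.0) -> list[dict]:
    """Execute a query against a remote SPARQL endpoint (explicit opt-in only).

    Posts the query with an SPARQL-JSON accept header using the standard
    library; returns the parsed bindings. Never called unless the caller
    passes an endpoint explicitly.
    """
    import json
    import urllib.parse
    import urllib.request

    payload = urllib.parse.urlencode({"query": query}).encode()
    request = urllib.request.Request(
        endpoint,
        data=payload,
        headers={
            "Accept": "application/sparql-results+json",
            "Content-Type": "application/x-www-form-urlencoded",
        },
    )
    with urllib.request.urlopen(request, timeout=timeout) as response:
        body = json.load(response)
    return body.get("results", {}).get("bindings", [])
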