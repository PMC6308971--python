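"""Pathway membership: tables, GPML, coverage, ontology audit, SPARQL."""

import pytest

from aoplink import (
    FormatError,
    ParseError,
    build_sparql_membership_query,
    genes_pathway_coverage,
    load_gpml_directory,
    load_pathway_table,
    parse_gpml,
    pathway_ontology_usage,
    run_sparql_on_turtle,
)
from aoplink.lexicon import FormClass, GeneEntry, GeneLexicon
from aoplink.pathways import XrefNamespace

GPML = """<?xml version="1.0" encoding="UTF-8"?>
<Pathway xmlns="http://pathvisio.org/GPML/2013a"
         xmlns:bp="http://www.biopax.org/release/biopax-level3.owl#"
         Name="demo pathway" Version="1" Organism="Homo sapiens">
  <DataNode TextLabel="g1" GraphId="n1" Type="GeneProduct">
    <Xref Database="Ensembl" ID="ENSG00000141510"/>
  </DataNode>
  <DataNode TextLabel="g2" GraphId="n2" Type="Protein">
    <Xref Database="Ensembl" ID="ENSG00000121691"/>
  </DataNode>
  <DataNode TextLabel="m1" GraphId="n3" Type="Metabolite">
    <Xref Database="ChEBI" ID="CHEBI:16842"/>
  </DataNode>
  <DataNode TextLabel="skipme" GraphId="n4" Type="GeneProduct"/>
  <Biopax>
    <bp:openControlledVocabulary>
      <bp:TERM>demo process</bp:TERM>
      <bp:ID>PW:0000013</bp:ID>
      <bp:Ontology>Pathway Ontology</bp:Ontology>
    </bp:openControlledVocabulary>
  </Biopax>
</Pathway>
"""


def _lexicon():
    return GeneLexicon(
        [
            GeneEntry(
                "HGNC:11998",
                "ENSG00000141510",
                "TP53",
                (("TP53", FormClass.APPROVED_SYMBOL),),
            ),
            GeneEntry("HGNC:1100", "", "BRCA2", (("BRCA2", FormClass.APPROVED_SYMBOL),)),
        ]
    )


class TestLoadPathwayTable:
    def test_gene_and_metabolite_rows(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "pathway_id\ttitle\txref_namespace\txref_id\n"
            "WP1\tt\tHGNC_SYMBOL\tTP53\nWP1\tt\tCHEBI\tCHEBI:16842\n"
        )
        db = load_pathway_table(path)
        assert len(db) == 1
        rec = db.pathways["WP1"]
        assert rec.gene_xrefs == {(XrefNamespace.HGNC_SYMBOL, "TP53")}
        assert rec.metabolite_xrefs == {"CHEBI:16842"}

    def test_empty_table_empty_lookups(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("pathway_id\ttitle\txref_namespace\txref_id\n")
        db = load_pathway_table(path)
        assert len(db) == 0
        assert db.pathways_with_gene(XrefNamespace.HGNC_SYMBOL, "TP53") == frozenset()
        assert db.pathways_with_metabolite("CHEBI:1") == frozenset()

    def test_unknown_namespace_named_in_error(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("pathway_id\ttitle\txref_namespace\txref_id\nWP1\tt\tBOGUS\tX\n")
        with pytest.raises(FormatError, match="BOGUS"):
            load_pathway_table(path)

    def test_fixture_pathway_count_matches_manifest(self, loaded42):
        assert len(loaded42["pathway_db"]) == len(loaded42["manifest"]["pathways"])


class TestParseGpml:
    def test_gene_metabolite_and_tag_extraction(self, tmp_path):
        path = tmp_path / "WP77.gpml"
        path.write_text(GPML)
        rec = parse_gpml(path)
        assert rec.pathway_id == "WP77"
        assert rec.title == "demo pathway"
        assert rec.gene_xrefs == {
            (XrefNamespace.ENSEMBL, "ENSG00000141510"),
            (XrefNamespace.ENSEMBL, "ENSG00000121691"),
        }
        assert rec.metabolite_xrefs == {"CHEBI:16842"}
        assert ("PW", "PW:0000013") in rec.ontology_tags

    def test_empty_pathway(self, tmp_path):
        path = tmp_path / "WP1.gpml"
        path.write_text(
            '<?xml version="1.0"?><Pathway xmlns="http://pathvisio.org/GPML/2013a" Name="e"/>'
        )
        rec = parse_gpml(path)
        assert rec.gene_xrefs == set() and rec.metabolite_xrefs == set()

    def test_other_gpml_dialect_rejected(self, tmp_path):
        path = tmp_path / "WP1.gpml"
        path.write_text(
            '<?xml version="1.0"?><Pathway xmlns="http://pathvisio.org/GPML/2010a" Name="e"/>'
        )
        with pytest.raises(ParseError, match="2010a"):
            parse_gpml(path)

    def test_gpml_directory_equals_table_rendering(self, loaded42):
        """The GPML and flat-table renderings of the same bundle agree."""
        db_gpml = load_gpml_directory(loaded42["paths"]["gpml_dir"])
        db_table = loaded42["pathway_db"]
        assert set(db_gpml.pathways) == set(db_table.pathways)
        for pid, rec in db_gpml.pathways.items():
            assert rec.gene_xrefs == db_table.pathways[pid].gene_xrefs
            assert rec.metabolite_xrefs == db_table.pathways[pid].metabolite_xrefs
            assert rec.ontology_tags == db_table.pathways[pid].ontology_tags


class TestGeneCoverage:
    def test_half_covered(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "pathway_id\ttitle\txref_namespace\txref_id\nWP1\tt\tHGNC_SYMBOL\tTP53\n"
        )
        db = load_pathway_table(path)
        cov = genes_pathway_coverage({"HGNC:11998", "HGNC:1100"}, db, _lexicon())
        assert cov.covered == {"HGNC:11998"}
        assert cov.fraction == 0.5
        assert cov.per_gene_namespaces["HGNC:11998"] == {XrefNamespace.HGNC_SYMBOL}

    def test_ensembl_namespace_bridges_through_lexicon(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "pathway_id\ttitle\txref_namespace\txref_id\nWP1\tt\tENSEMBL\tENSG00000141510\n"
        )
        cov = genes_pathway_coverage({"HGNC:11998"}, load_pathway_table(path), _lexicon())
        assert cov.covered == {"HGNC:11998"}
        assert cov.per_gene_namespaces["HGNC:11998"] == {XrefNamespace.ENSEMBL}

    def test_empty_query_fraction_is_null(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("pathway_id\ttitle\txref_namespace\txref_id\n")
        cov = genes_pathway_coverage(set(), load_pathway_table(path), _lexicon())
        assert cov.covered == frozenset() and cov.fraction is None

    def test_monotone_in_added_pathways(self, tmp_path):
        small = "pathway_id\ttitle\txref_namespace\txref_id\nWP1\tt\tHGNC_SYMBOL\tTP53\n"
        big = small + "WP2\tt\tHGNC_SYMBOL\tBRCA2\n"
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        p1.write_text(small)
        p2.write_text(big)
        genes = {"HGNC:11998", "HGNC:1100"}
        c1 = genes_pathway_coverage(genes, load_pathway_table(p1), _lexicon())
        c2 = genes_pathway_coverage(genes, load_pathway_table(p2), _lexicon())
        assert c1.covered <= c2.covered
        assert c2.fraction >= c1.fraction

    def test_planted_coverage_matches_manifest_target(self, loaded42):
        manifest = loaded42["manifest"]
        expected = manifest["expected_report"]
        ke_genes = {
            g
            for k in manifest["key_events"]
            if k["level"] in {"molecular", "cellular", "tissue", "organ"}
            for g in k["planted_genes"]
        }
        cov = genes_pathway_coverage(ke_genes, loaded42["pathway_db"], loaded42["lexicon"])
        assert len(cov.covered) == expected["genes_in_kes_covered"]


class TestPathwayOntologyUsage:
    def test_counts_once_per_source(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "pathway_id\ttitle\txref_namespace\txref_id\n"
            "WP1\tt\tPW\tPW:1\nWP1\tt\tPW\tPW:2\nWP1\tt\tDO\tDOID:3\n"
            "WP2\tt\tHGNC_SYMBOL\tTP53\nWP3\tt\tHGNC_SYMBOL\tCAT\n"
        )
        usage = pathway_ontology_usage(load_pathway_table(path))
        assert usage == {"pathways_total": 3, "with_pw": 1, "with_cl": 0, "with_do": 1}

    def test_fixture_matches_manifest(self, loaded42):
        usage = pathway_ontology_usage(loaded42["pathway_db"])
        manifest_pathways = loaded42["manifest"]["pathways"]
        assert usage["pathways_total"] == len(manifest_pathways)
        for source, key in (("PW", "with_pw"), ("CL", "with_cl"), ("DO", "with_do")):
            expected = sum(
                1 for rec in manifest_pathways if any(s == source for s, _ in rec["ontology_tags"])
            )
            assert usage[key] == expected


class TestSparql:
    def test_metabolite_query_structure(self):
        query = build_sparql_membership_query({"CHEBI:16842"}, "metabolite")
        assert "http://identifiers.org/chebi/CHEBI:16842" in query
        assert "wp:Pathway" in query and "dcterms:isPartOf" in query

    def test_sorted_ids_determinism(self):
        a = build_sparql_membership_query(["B2X", "A1X", "C3X"], "gene")
        b = build_sparql_membership_query(["C3X", "A1X", "B2X"], "gene")
        assert a == b

    def test_empty_id_set_rejected(self):
        with pytest.raises(ValueError):
            build_sparql_membership_query(set(), "gene")

    def test_local_rdf_equals_table_lookup(self, loaded42):
        """Membership pairs from SPARQL over the Turtle rendering equal the
        table lookup on the equivalent TSV — the remote/local equivalence
        contract on a fixture."""
        manifest, db = loaded42["manifest"], loaded42["pathway_db"]
        gene_ids = {x for rec in manifest["pathways"] for _, x in rec["gene_xrefs"]}
        query = build_sparql_membership_query(gene_ids, "gene")
        sparql_pairs = run_sparql_on_turtle(query, loaded42["paths"]["turtle"])
        table_pairs = {
            (pw, i) for i in gene_ids for pw in db.pathways_with_any_gene_id(i)
        }
        assert sparql_pairs == table_pairs

        chebis = {c for rec in manifest["pathways"] for c in rec["metabolite_xrefs"]}
        if chebis:
            mq = build_sparql_membership_query(chebis, "metabolite")
            sp = run_sparql_on_turtle(mq, loaded42["paths"]["turtle"])
            tp = {(pw, c) for c in chebis for pw in db.pathways_with_metabolite(c)}
            assert sp == tp
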