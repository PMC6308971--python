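{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "CoverageReport",
  "type": "object",
  "required": [
    "stressors", "chemicals", "cas_numbers", "cas_mapped",
    "chebi_ids", "chebi_in_pathways", "chem_pathways_hit",
    "kes_total", "kes_with_genes", "genes_in_kes", "genes_in_kes_covered",
    "kers_total", "kers_with_genes", "genes_in_kers", "genes_in_kers_covered",
    "percents", "raw", "provenance"
  ],
  "properties": {
    "stressors": {"type": "integer", "minimum": 0},
    "chemicals": {"type": "integer", "minimum": 0},
    "cas_numbers": {"type": "integer", "minimum": 0},
    "cas_mapped": {"type": "integer", "minimum": 0},
    "chebi_ids": {"type": "integer", "minimum": 0},
    "chebi_in_pathways": {"type": "integer", "minimum": 0},
    "chem_pathways_hit": {"type": "integer", "minimum": 0},
    "kes_total": {"type": "integer", "minimum": 0},
    "kes_with_genes": {"type": "integer", "minimum": 0},
    "genes_in_kes": {"type": "integer", "minimum": 0},
    "genes_in_kes_covered": {"type": "integer", "minimum": 0},
    "kers_total": {"type": "integer", "minimum": 0},
    "kers_with_genes": {"type": "integer", "minimum": 0},
    "genes_in_kers": {"type": "integer", "minimum": 0},
    "genes_in_kers_covered": {"type": "integer", "minimum": 0},
    "percents": {
      "type": "object",
      "required": [
        "pct_ke_genes_covered", "pct_ker_genes_covered",
        "pct_cas_mapped", "pct_chebi_in_pathways"
      ],
      "properties": {
        "pct_ke_genes_covered": {"anyOf": [{"type": "integer"}, {"type": "null"}]},
        "pct_ker_genes_covered": {"anyOf": [{"type": "integer"}, {"type": "null"}]},
        "pct_cas_mapped": {"anyOf": [{"type": "integer"}, {"type": "null"}]},
        "pct_chebi_in_pathways": {"anyOf": [{"type": "integer"}, {"type": "null"}]}
      }
    },
    "raw": {
      "type": "object",
      "required": [
        "ke_gene_coverage", "ker_gene_coverage", "cas_mapped_fraction",
        "chem_coverage_of_chebi", "chem_coverage_of_cas",
        "chem_coverage_of_mapped_cas"
      ],
      "properties": {
        "ke_gene_coverage": {"anyOf": [{"type": "number"}, {"type": "null"}]},
        "ker_gene_coverage": {"anyOf": [{"type": "number"}, {"type": "null"}]},
        "cas_mapped_fraction": {"anyOf": [{"type": "number"}, {"type": "null"}]},
        "chem_coverage_of_chebi": {"anyOf": [{"type": "number"}, {"type": "null"}]},
        "chem_coverage_of_cas": {"anyOf": [{"type": "number"}, {"type": "null"}]},
        "chem_coverage_of_mapped_cas": {"anyOf": [{"type": "number"}, {"type": "null"}]}
      }
    },
    "provenance": {"type": "object"}
  }
}
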