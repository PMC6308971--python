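"""Hard linkage: CAS numbers -> ChEBI identifiers -> pathway membership.

Each stressor chemical's CAS registry number is validated, joined against a
CAS->ChEBI mapping table, and the resulting ChEBI identifiers are looked up
in the pathway database's metabolite xrefs.
"""

import tempfile

from aoplink import (
    extract_chemicals,
    load_cas_chebi_map,
    load_pathway_table,
    map_chemicals,
    parse_aopwiki_xml,
    validate_cas,
)
from aoplink.synth import SyntheticConfig, generate_bundle

print(f"7732-18-5 (water): {validate_cas('7732-18-5').value}")
print(f"50-00-1 (corrupted check digit): {validate_cas('50-00-1').value}")

with tempfile.TemporaryDirectory() as td:
    paths, _ = generate_bundle(SyntheticConfig(seed=42), td)
    dataset = parse_aopwiki_xml(paths["xml"])
    mapper = load_cas_chebi_map(paths["cas_chebi"])
    db = load_pathway_table(paths["pathways"])

    result = map_chemicals(mapper, extract_chemicals(dataset).records, db)
    print(f"CAS numbers: {result.n_cas_in}, mapped to ChEBI: {result.n_cas_mapped}")
    print(f"ChEBI ids: {len(result.chebi_ids)}, found in pathways: "
          f"{len(result.chebi_in_pathways)} (across {len(result.pathways_hit)} pathways)")
    # a low in-pathway fraction is expected: stressors are mostly exogenous
    # toxicants while pathway databases hold endogenous metabolites.
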