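import json
from pathlib import Path

import pytest

from aoplink import (
    load_cas_chebi_map,
    load_gene_lexicon,
    load_pathway_table,
    parse_aopwiki_xml,
)
from aoplink.synth import SyntheticConfig, generate_bundle

AOPWIKI_NS = "http://www.aopkb.org/aop-xml"


def make_dump(body: str) -> str:
    """Wrap entity elements in a minimal knowledge-base dump document."""
    return f'<?xml version="1.0" encoding="UTF-8"?>\n<data xmlns="{AOPWIKI_NS}">\n{body}\n</data>\n'


@pytest.fixture
def write_dump(tmp_path):
    def _write(body: str, name: str = "dump.xml") -> Path:
        path = tmp_path / name
        path.write_text(make_dump(body))
        return path

    return _write


@pytest.fixture(scope="session")
def bundle42(tmp_path_factory):
    """The default synthetic fixture bundle, generated once per session."""
    out = tmp_path_factory.mktemp("bundle42")
    paths, manifest = generate_bundle(SyntheticConfig(seed=42), out)
    return paths, manifest


@pytest.fixture(scope="session")
def loaded42(bundle42):
    """The seed-42 bundle loaded through every pipeline loader."""
    paths, manifest = bundle42
    return {
        "paths": paths,
        "manifest": manifest,
        "dataset": parse_aopwiki_xml(paths["xml"]),
        "lexicon": load_gene_lexicon(paths["lexicon"]),
        "mapper": load_cas_chebi_map(paths["cas_chebi"]),
        "pathway_db": load_pathway_table(paths["pathways"]),
    }


@pytest.fixture
def tiny_lexicon(tmp_path):
    """Hand-written four-gene lexicon exercising every form class."""
    rows = [
        "hgnc_id\tapproved_symbol\tapproved_name\tprevious_symbols\tsynonyms\tensembl_id",
        "HGNC:11998\tTP53\ttumor protein p53\tTRP53\tp53\tENSG00000141510",
        "HGNC:1884\tCAT\tcatalase\t\t\tENSG00000121691",
        "HGNC:2595\tCYP1A1\tcytochrome P450 family 1 member A1\t\t\tENSG00000140465",
        "HGNC:2596\tCYP1A2\tcytochrome P450 family 1 member A2\t\t\tENSG00000140505",
        "HGNC:6018\tIL6\tinterleukin 6\tIFNB2\tIL-6\tENSG00000136244",
    ]
    path = tmp_path / "lexicon.tsv"
    path.write_text("\n".join(rows) + "\n")
    return load_gene_lexicon(path)
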