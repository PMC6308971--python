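"""Soft linkage: dictionary-based gene-mention recognition in free text.

Builds a tiny HGNC-style lexicon and recognizes gene vocabulary in a
key-event description, showing the case-sensitivity and whole-token rules.
"""

import tempfile
from pathlib import Path

from aoplink import find_gene_mentions, load_gene_lexicon

ROWS = [
    "hgnc_id\tapproved_symbol\tapproved_name\tprevious_symbols\tsynonyms\tensembl_id",
    "HGNC:11998\tTP53\ttumor protein p53\tTRP53\tp53\tENSG00000141510",
    "HGNC:1884\tCAT\tcatalase\t\t\tENSG00000121691",
    "HGNC:6018\tIL6\tinterleukin 6\tIFNB2\tIL-6\tENSG00000136244",
]

with tempfile.TemporaryDirectory() as td:
    path = Path(td) / "lexicon.tsv"
    path.write_text("\n".join(ROWS) + "\n")
    lexicon = load_gene_lexicon(path)

    text = ("Activation of TP53 triggers apoptosis while the cat sat on the mat; "
            "IL-6 release and Tumor Protein P53 accumulation follow.")
    for m in find_gene_mentions(text, lexicon):
        print(f"{m.gene_id:<12} {m.form_class.value:<16} '{text[m.start:m.end]}' @ {m.start}")
    # note: 'cat' does not match the symbol CAT (symbols are case-sensitive),
    # 'IL-6' matches as one hyphenated token, and the multi-word approved name
    # matches case-insensitively.
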