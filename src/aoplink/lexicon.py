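"""Gene lexicon compilation and dictionary-based gene-mention recognition.

The "soft linkage" route joins a knowledge base to a pathway database
indirectly: human gene vocabulary (approved symbols, approved names, previous
symbols, synonyms from an HGNC-style table) is recognized in the free-text
descriptions of key events and key-event relationships, and the recognized
genes are then resolved against pathway membership.

Matching rules
--------------
Tokenization splits on transitions between word characters (letters, digits,
hyphen — so ``IL-6`` is one token) and everything else. Symbol-class surface
forms (approved symbols, previous symbols, single-token synonyms) match
case-sensitively as whole tokens, which suppresses English-word false
positives (``cat`` never matches the symbol ``CAT``). Multi-token forms
(approved names, multi-word synonyms) match case-insensitively as whole-token
sequences. Overlapping candidates resolve longest-match-first, ties broken by
leftmost start and then by form-class priority (approved symbol > previous
symbol > synonym > approved name); a matched span is consumed, so no nested
matches. A surface form claimed by two or more genes emits one mention per
claiming gene, flagged ambiguous. Single-character forms are ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .aopwiki import KeyEvent, KeyEventRelationship
from .errors import FormatError

__all__ = [
    "FormClass",
    "GeneEntry",
    "GeneLexicon",
    "GeneMention",
    "load_gene_lexicon",
    "find_gene_mentions",
    "map_genes_in_key_events",
    "map_genes_in_kers",
    "GeneMappingResult",
]


class FormClass(str, Enum):
    APPROVED_SYMBOL = "approved_symbol"
    APPROVED_NAME = "approved_name"
    PREVIOUS_SYMBOL = "previous_symbol"
    SYNONYM = "synonym"


_CLASS_PRIORITY = {
    FormClass.APPROVED_SYMBOL: 0,
    FormClass.PREVIOUS_SYMBOL: 1,
    FormClass.SYNONYM: 2,
    FormClass.APPROVED_NAME: 3,
}

_TOKEN_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9-]*")
_MIN_FORM_LEN = 2  # single-character forms are alphabet-letter false positives


@dataclass(frozen=True)
class GeneEntry:
    gene_id: str
    ensembl_id: str
    approved_symbol: str
    surface_forms: tuple[tuple[str, FormClass], ...]


@dataclass
class GeneMention:
    """One recognized gene mention; offsets are 0-based half-open into the
    normalized text."""

    gene_id: str
    matched_form: str
    form_class: FormClass
    start: int
    end: int
    ambiguous: bool = False


def _tokenize(text: str) -> list[tuple[str, int, int]]:
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _is_symbol_class(form_tokens: Sequence[str], form_class: FormClass) -> bool:
    """Case-sensitive whole-token rule applies to symbols and single-token
    synonyms; multi-token forms and approved names match case-insensitively."""
    if form_class in (FormClass.APPROVED_SYMBOL, FormClass.PREVIOUS_SYMBOL):
        return True
    return form_class is FormClass.SYNONYM and len(form_tokens) == 1


class GeneLexicon:
    """Surface-form -> gene dictionary compiled from an HGNC-style table.

    Entries are keyed by a unique gene identifier; every entry has exactly one
    approved symbol. The compiled matching indexes are built once and shared
    by all mention searches.
    """

    def __init__(self, entries: Iterable[GeneEntry]):
        self.entries: dict[str, GeneEntry] = {}
        for entry in entries:
            if entry.gene_id in self.entries:
                raise FormatError(f"duplicate gene id {entry.gene_id!r} in lexicon")
            self.entries[entry.gene_id] = entry
        # matching indexes: key -> list of (gene_id, form, form_class)
        self._exact: dict[str, list[tuple[str, str, FormClass]]] = {}
        self._folded: dict[tuple[str, ...], list[tuple[str, str, FormClass]]] = {}
        for entry in self.entries.values():
            for form, cls in entry.surface_forms:
                tokens = [t for t, _, _ in _tokenize(form)]
                if not tokens:
                    continue
                if _is_symbol_class(tokens, cls) and len(tokens) == 1:
                    self._exact.setdefault(tokens[0], []).append((entry.gene_id, form, cls))
                else:
                    key = tuple(t.casefold() for t in tokens)
                    self._folded.setdefault(key, []).append((entry.gene_id, form, cls))
        self._max_folded_len = max((len(k) for k in self._folded), default=0)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    def identifiers_for(self, gene_id: str) -> frozenset[str]:
        """All identifiers of a gene usable for cross-namespace pathway lookup:
        the gene id itself (HGNC id), the approved symbol, and the Ensembl id."""
        entry = self.entries[gene_id]
        ids = {entry.gene_id, entry.approved_symbol}
        if entry.ensembl_id:
            ids.add(entry.ensembl_id)
        return frozenset(ids)

    @property
    def ambiguity_index(self) -> dict[str, frozenset[str]]:
        """Surface forms (by matching key) claimed by two or more genes."""
        out: dict[str, frozenset[str]] = {}
        for key, claims in self._exact.items():
            genes = {g for g, _, _ in claims}
            if len(genes) > 1:
                out[key] = frozenset(genes)
        for key, claims in self._folded.items():
            genes = {g for g, _, _ in claims}
            if len(genes) > 1:
                out[" ".join(key)] = frozenset(genes)
        return out


_REQUIRED_COLUMNS = (
    "hgnc_id",
    "approved_symbol",
    "approved_name",
    "previous_symbols",
    "synonyms",
    "ensembl_id",
)
_MULTI_SEP = re.compile(r"[,|]")


def load_gene_lexicon(path: str | Path) -> GeneLexicon:
    """Load an HGNC-style gene nomenclature table into a :class:`GeneLexicon`.

    The table is tab-separated with header columns ``hgnc_id``,
    ``approved_symbol``, ``approved_name``, ``previous_symbols``, ``synonyms``,
    ``ensembl_id``; the multi-valued columns are comma- or pipe-separated.
    Surface forms are stored verbatim (case preserved); empty and
    single-character forms are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"gene lexicon not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(
            f"lexicon {path} is missing required column(s): {', '.join(sorted(missing))}"
        )
    entries = []
    for row in table.itertuples(index=False):
        gene_id = row.hgnc_id.strip()
        symbol = row.approved_symbol.strip()
        if not gene_id or not symbol:
            raise FormatError(f"lexicon row with empty hgnc_id or approved_symbol in {path}")
        forms: list[tuple[str, FormClass]] = [(symbol, FormClass.APPROVED_SYMBOL)]
        name = row.approved_name.strip()
        if len(name) >= _MIN_FORM_LEN:
            forms.append((name, FormClass.APPROVED_NAME))
        for raw, cls in (
            (row.previous_symbols, FormClass.PREVIOUS_SYMBOL),
            (row.synonyms, FormClass.SYNONYM),
        ):
            for part in _MULTI_SEP.split(raw):
                part = part.strip()
                if len(part) >= _MIN_FORM_LEN:
                    forms.append((part, cls))
        entries.append(
            GeneEntry(
                gene_id=gene_id,
                ensembl_id=row.ensembl_id.strip(),
                approved_symbol=symbol,
                surface_forms=tuple(forms),
            )
        )
    return GeneLexicon(entries)


def find_gene_mentions(text: str, lexicon: GeneLexicon) -> list[GeneMention]:
    """Recognize gene mentions in normalized plain text.

    Returns mentions in document order. See the module docstring for the
    matching and overlap-resolution rules. Deterministic: identical
    (text, lexicon) inputs yield an identical mention list.
    """
    if not text:
        return []
    tokens = _tokenize(text)
    # candidate groups: one per (span, matching key), carrying all claims
    groups: list[tuple[int, int, list[tuple[str, str, FormClass]]]] = []
    for i, (tok, start, end) in enumerate(tokens):
        if len(tok) >= _MIN_FORM_LEN and tok in lexicon._exact:
            groups.append((start, end, lexicon._exact[tok]))
        for length in range(1, lexicon._max_folded_len + 1):
            if i + length > len(tokens):
                break
            key = tuple(t.casefold() for t, _, _ in tokens[i : i + length])
            claims = lexicon._folded.get(key)
            if claims:
                groups.append((start, tokens[i + length - 1][2], claims))
    # longest-match-first; ties: leftmost start, then best form-class priority
    groups.sort(
        key=lambda g: (
            -(g[1] - g[0]),
            g[0],
            min(_CLASS_PRIORITY[c] for _, _, c in g[2]),
        )
    )
    consumed: list[tuple[int, int]] = []
    mentions: list[GeneMention] = []
    for start, end, claims in groups:
        if any(start < e and s < end for s, e in consumed):
            continue
        consumed.append((start, end))
        # one mention per claiming gene; per gene keep its best form class
        best: dict[str, tuple[str, FormClass]] = {}
        for gene_id, form, cls in claims:
            if gene_id not in best or _CLASS_PRIORITY[cls] < _CLASS_PRIORITY[best[gene_id][1]]:
                best[gene_id] = (form, cls)
        ambiguous = len(best) > 1
        for gene_id in sorted(best):
            form, cls = best[gene_id]
            mentions.append(
                GeneMention(
                    gene_id=gene_id,
                    matched_form=text[start:end],
                    form_class=cls,
                    start=start,
                    end=end,
                    ambiguous=ambiguous,
                )
            )
    mentions.sort(key=lambda m: (m.start, m.gene_id))
    return mentions


@dataclass
class GeneMappingResult:
    """Gene recognition aggregated over a collection of documents."""

    per_doc: dict[str, frozenset[str]]
    genes_total: frozenset[str]
    n_docs_with_genes: int
    mentions: dict[str, list[GeneMention]] = field(default_factory=dict)


def map_genes_in_key_events(
    kes: Iterable[KeyEvent], lexicon: GeneLexicon
) -> GeneMappingResult:
    """Recognize genes in key-event descriptions.

    The caller pre-filters key events to the desired biological levels.
    Per-event gene sets deduplicate by gene id; ``genes_total`` is the union.
    """
    per_doc: dict[str, frozenset[str]] = {}
    mentions: dict[str, list[GeneMention]] = {}
    for ke in kes:
        found = find_gene_mentions(ke.description, lexicon)
        per_doc[ke.ke_id] = frozenset(m.gene_id for m in found)
        mentions[ke.ke_id] = found
    union = frozenset().union(*per_doc.values()) if per_doc else frozenset()
    return GeneMappingResult(
        per_doc=per_doc,
        genes_total=union,
        n_docs_with_genes=sum(1 for v in per_doc.values() if v),
        mentions=mentions,
    )


def map_genes_in_kers(
    kers: Iterable[KeyEventRelationship], lexicon: GeneLexicon
) -> GeneMappingResult:
    """Recognize genes in key-event-relationship texts.

    Each relationship's three text fields (description, biological
    plausibility, empirical support) are searched independently and the gene
    sets unioned. The caller restricts relationships to those connecting
    in-scope key events.
    """
    per_doc: dict[str, frozenset[str]] = {}
    mentions: dict[str, list[GeneMention]] = {}
    for ker in kers:
        genes: set[str] = set()
        found_all: list[GeneMention] = []
        for text in ker.texts():
            found = find_gene_mentions(text, lexicon)
            genes.update(m.gene_id for m in found)
            found_all.extend(found)
        per_doc[ker.ker_id] = frozenset(genes)
        mentions[ker.ker_id] = found_all
    union = frozenset().union(*per_doc.values()) if per_doc else frozenset()
    return GeneMappingResult(
        per_doc=per_doc,
        genes_total=union,
        n_docs_with_genes=sum(1 for v in per_doc.values() if v),
        mentions=mentions,
    )
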