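"""Chemical identifier mapping: CAS validation and CAS -> ChEBI joins.

The "hard linkage" route between the knowledge base and a pathway database
joins the two through shared formal identifiers: stressor chemicals annotated
with CAS registry numbers are mapped to ChEBI identifiers via a mapping table
(BridgeDb-style export, Wikidata dump, or synthetic fixture — any two-column
TSV), and the ChEBI identifiers are then resolved against the pathway
database's metabolite xrefs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, TYPE_CHECKING

import pandas as pd

from .aopwiki import StressorChemical, normalize_cas
from .errors import FormatError

if TYPE_CHECKING:
    from .pathways import PathwayMembershipDB

logger = logging.getLogger(__name__)

__all__ = [
    "CasStatus",
    "validate_cas",
    "cas_check_digit",
    "IdentifierMapper",
    "load_cas_chebi_map",
    "ChemicalMappingResult",
    "map_chemicals",
]


class CasStatus(str, Enum):
    VALID = "valid"
    BAD_CHECKSUM = "bad_checksum"
    MALFORMED = "malformed"


_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")
_CHEBI_RE = re.compile(r"^CHEBI:\d+$")


def cas_check_digit(body_digits: str) -> int:
    """Check digit of a CAS number from its non-check digits.

    Digits are numbered right to left (excluding the check digit itself) and
    the check digit is ``(sum_i i * d_i) mod 10``.
    """
    total = sum(i * int(d) for i, d in enumerate(reversed(body_digits), start=1))
    return total % 10


def validate_cas(cas: str) -> CasStatus:
    """Syntactic + checksum validation of a CAS registry number.

    ``malformed`` unless the string is 2-7 digits, hyphen, 2 digits, hyphen,
    1 digit; otherwise ``valid`` iff the mod-10 weighted checksum over the
    leading digits equals the final digit, else ``bad_checksum``.
    """
    match = _CAS_RE.match(cas or "")
    if not match:
        return CasStatus.MALFORMED
    body = match.group(1) + match.group(2)
    if cas_check_digit(body) == int(match.group(3)):
        return CasStatus.VALID
    return CasStatus.BAD_CHECKSUM


@dataclass
class IdentifierMapper:
    """Multimap from normalized CAS string to sets of ChEBI identifiers.

    Lookups of absent keys return the empty set, never an error. Keys pass
    CAS syntactic validation (bad checksums are tolerated — diagnostic only);
    values match the ``CHEBI:<digits>`` pattern.
    """

    cas_to_chebi: dict[str, frozenset[str]] = field(default_factory=dict)
    n_rows_skipped: int = 0

    def lookup(self, cas: str) -> frozenset[str]:
        return self.cas_to_chebi.get(normalize_cas(cas), frozenset())

    def __len__(self) -> int:
        return len(self.cas_to_chebi)

    def __contains__(self, cas: str) -> bool:
        return normalize_cas(cas) in self.cas_to_chebi


def load_cas_chebi_map(path: str | Path) -> IdentifierMapper:
    """Load a tab-separated CAS -> ChEBI mapping table.

    Expects a header with columns ``cas`` and ``chebi``, one pair per row;
    duplicate rows collapse into the multimap. Rows with a syntactically
    malformed CAS or a non-ChEBI value are skipped with a logged warning and
    counted in ``n_rows_skipped``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mapping table not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"cas", "chebi"} - set(table.columns)
    if missing:
        raise FormatError(
            f"mapping table {path} is missing required column(s): {', '.join(sorted(missing))}"
        )
    pairs: dict[str, set[str]] = {}
    skipped = 0
    for cas, chebi in zip(table["cas"], table["chebi"]):
        cas = normalize_cas(cas)
        chebi = chebi.strip()
        if validate_cas(cas) is CasStatus.MALFORMED:
            logger.warning("skipping mapping row with malformed CAS %r", cas)
            skipped += 1
            continue
        if not _CHEBI_RE.match(chebi):
            logger.warning("skipping mapping row with non-ChEBI value %r", chebi)
            skipped += 1
            continue
        pairs.setdefault(cas, set()).add(chebi)
    return IdentifierMapper(
        cas_to_chebi={k: frozenset(v) for k, v in pairs.items()},
        n_rows_skipped=skipped,
    )


@dataclass
class ChemicalMappingResult:
    """Outcome of the hard-linkage route for one set of stressor chemicals.

    Counts are cardinalities over unique CAS / unique ChEBI identifiers, not
    stressor multiplicity.
    """

    per_cas: dict[str, frozenset[str]]
    n_cas_in: int
    n_cas_mapped: int
    chebi_ids: frozenset[str]
    chebi_in_pathways: frozenset[str]
    pathways_hit: frozenset[str]

    def to_dict(self) -> dict:
        return {
            "cas_total": self.n_cas_in,
            "cas_mapped": self.n_cas_mapped,
            "chebi_total": len(self.chebi_ids),
            "chebi_in_pathways": len(self.chebi_in_pathways),
            "pathways_hit": len(self.pathways_hit),
        }


def map_chemicals(
    mapper: IdentifierMapper,
    chemicals: Iterable[StressorChemical],
    pathways: "PathwayMembershipDB | None" = None,
) -> ChemicalMappingResult:
    """Map unique CAS numbers to ChEBI identifiers and resolve them in pathways.

    CAS numbers with a bad checksum are still looked up (warned, not dropped);
    an all-unmapped outcome is legal. When ``pathways`` is None the pathway
    resolution fields stay empty.
    """
    unique_cas = sorted(
        {normalize_cas(c.cas) for c in chemicals if normalize_cas(c.cas)}
    )
    per_cas: dict[str, frozenset[str]] = {}
    for cas in unique_cas:
        if validate_cas(cas) is CasStatus.BAD_CHECKSUM:
            logger.warning("CAS %s fails its checksum; looking it up anyway", cas)
        per_cas[cas] = mapper.lookup(cas)
    chebi_ids = frozenset().union(*per_cas.values()) if per_cas else frozenset()
    chebi_in_pathways: set[str] = set()
    pathways_hit: set[str] = set()
    if pathways is not None:
        for chebi in chebi_ids:
            hits = pathways.pathways_with_metabolite(chebi)
            if hits:
                chebi_in_pathways.add(chebi)
                pathways_hit.update(hits)
    return ChemicalMappingResult(
        per_cas=per_cas,
        n_cas_in=len(unique_cas),
        n_cas_mapped=sum(1 for v in per_cas.values() if v),
        chebi_ids=chebi_ids,
        chebi_in_pathways=frozenset(chebi_in_pathways),
        pathways_hit=frozenset(pathways_hit),
    )
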