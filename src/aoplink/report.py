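"""The headline coverage report assembling every linkage stage.

The report is the machine-readable summary of how much of the knowledge base
can be linked to the pathway database: stressor-chemical counts and their
CAS -> ChEBI -> pathway resolution (hard linkage), and gene recognition in
key-event and relationship texts with pathway coverage of the recognized
genes (soft linkage). Percent fields are display values, recomputed from the
raw counts with round-half-up (296/417 -> 71); the raw ratios are always
retained alongside.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

from .aopwiki import AopWikiDataset, IN_SCOPE_LEVELS, extract_chemicals, filter_key_events, in_scope_kers
from .chemlink import IdentifierMapper, map_chemicals
from .errors import AoplinkError, FormatError, StageError
from .lexicon import GeneLexicon, map_genes_in_key_events, map_genes_in_kers
from .pathways import PathwayMembershipDB, genes_pathway_coverage

__all__ = [
    "CoverageReport",
    "build_coverage_report",
    "write_report",
    "read_report",
    "round_half_up_percent",
    "validate_report_dict",
]


def round_half_up_percent(numerator: int, denominator: int) -> int | None:
    """Integer percent with half-up rounding; None on a zero denominator."""
    if denominator == 0:
        return None
    value = Decimal(100 * numerator) / Decimal(denominator)
    return int(value.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


_COUNT_FIELDS = (
    "stressors",
    "chemicals",
    "cas_numbers",
    "cas_mapped",
    "chebi_ids",
    "chebi_in_pathways",
    "chem_pathways_hit",
    "kes_total",
    "kes_with_genes",
    "genes_in_kes",
    "genes_in_kes_covered",
    "kers_total",
    "kers_with_genes",
    "genes_in_kers",
    "genes_in_kers_covered",
)


@dataclass
class CoverageReport:
    """Counts of every linkage stage; percents and ratios are derived.

    Every ``*_covered`` count is bounded by its identified counterpart, and
    every percent is recomputed from the counts at serialization time, never
    stored independently.
    """

    stressors: int = 0
    chemicals: int = 0
    cas_numbers: int = 0
    cas_mapped: int = 0
    chebi_ids: int = 0
    chebi_in_pathways: int = 0
    chem_pathways_hit: int = 0
    kes_total: int = 0
    kes_with_genes: int = 0
    genes_in_kes: int = 0
    genes_in_kes_covered: int = 0
    kers_total: int = 0
    kers_with_genes: int = 0
    genes_in_kers: int = 0
    genes_in_kers_covered: int = 0
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for covered, identified in (
            ("cas_mapped", "cas_numbers"),
            ("chebi_in_pathways", "chebi_ids"),
            ("genes_in_kes_covered", "genes_in_kes"),
            ("genes_in_kers_covered", "genes_in_kers"),
            ("kes_with_genes", "kes_total"),
        ):
            if getattr(self, covered) > getattr(self, identified):
                raise ValueError(f"{covered} exceeds {identified}")

    @property
    def pct_ke_genes_covered(self) -> int | None:
        return round_half_up_percent(self.genes_in_kes_covered, self.genes_in_kes)

    @property
    def pct_ker_genes_covered(self) -> int | None:
        return round_half_up_percent(self.genes_in_kers_covered, self.genes_in_kers)

    @property
    def pct_cas_mapped(self) -> int | None:
        return round_half_up_percent(self.cas_mapped, self.cas_numbers)

    @property
    def pct_chebi_in_pathways(self) -> int | None:
        return round_half_up_percent(self.chebi_in_pathways, self.chebi_ids)

    def _ratio(self, num: int, den: int) -> float | None:
        return num / den if den else None

    def to_dict(self) -> dict:
        counts = {name: getattr(self, name) for name in _COUNT_FIELDS}
        percents = {
            "pct_ke_genes_covered": self.pct_ke_genes_covered,
            "pct_ker_genes_covered": self.pct_ker_genes_covered,
            "pct_cas_mapped": self.pct_cas_mapped,
            "pct_chebi_in_pathways": self.pct_chebi_in_pathways,
        }
        # the chemical-overlap denominator is contested in the literature the
        # inputs come from, so all candidate ratios are exposed side by side
        raw = {
            "ke_gene_coverage": self._ratio(self.genes_in_kes_covered, self.genes_in_kes),
            "ker_gene_coverage": self._ratio(self.genes_in_kers_covered, self.genes_in_kers),
            "cas_mapped_fraction": self._ratio(self.cas_mapped, self.cas_numbers),
            "chem_coverage_of_chebi": self._ratio(self.chebi_in_pathways, self.chebi_ids),
            "chem_coverage_of_cas": self._ratio(self.chebi_in_pathways, self.cas_numbers),
            "chem_coverage_of_mapped_cas": self._ratio(self.chebi_in_pathways, self.cas_mapped),
        }
        return {**counts, "percents": percents, "raw": raw, "provenance": dict(self.provenance)}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CoverageReport":
        kwargs = {name: int(payload[name]) for name in _COUNT_FIELDS}
        return cls(**kwargs, provenance=dict(payload.get("provenance", {})))


DEFAULT_LEVELS = IN_SCOPE_LEVELS


def build_coverage_report(
    dataset: AopWikiDataset,
    mapper: IdentifierMapper,
    lexicon: GeneLexicon,
    pathway_db: PathwayMembershipDB,
    levels: Iterable = DEFAULT_LEVELS,
    provenance: Mapping | None = None,
) -> CoverageReport:
    """Run every linkage stage and assemble the coverage report.

    Stages: chemical extraction -> CAS/ChEBI mapping -> pathway resolution;
    key-event filtering -> gene recognition -> pathway coverage; relationship
    restriction (both endpoints at in-scope levels) -> gene recognition ->
    pathway coverage. Deterministic given its inputs. Stage failures are
    re-raised as :class:`StageError` naming the stage.
    """
    levels = frozenset(levels)

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except AoplinkError as exc:
            raise StageError(name, str(exc)) from exc

    chem_summary = _stage("extract_chemicals", extract_chemicals, dataset)
    chem_result = _stage(
        "map_chemicals", map_chemicals, mapper, chem_summary.records, pathway_db
    )
    kes = _stage("filter_key_events", filter_key_events, dataset, levels)
    ke_genes = _stage("map_genes_in_key_events", map_genes_in_key_events, kes, lexicon)
    ke_cov = _stage(
        "genes_pathway_coverage", genes_pathway_coverage, ke_genes.genes_total, pathway_db, lexicon
    )
    kers = _stage("in_scope_kers", in_scope_kers, dataset, levels)
    ker_genes = _stage("map_genes_in_kers", map_genes_in_kers, kers, lexicon)
    ker_cov = _stage(
        "genes_pathway_coverage", genes_pathway_coverage, ker_genes.genes_total, pathway_db, lexicon
    )
    return CoverageReport(
        stressors=chem_summary.n_stressors,
        chemicals=chem_summary.n_unique_chemicals,
        cas_numbers=chem_summary.n_unique_cas,
        cas_mapped=chem_result.n_cas_mapped,
        chebi_ids=len(chem_result.chebi_ids),
        chebi_in_pathways=len(chem_result.chebi_in_pathways),
        chem_pathways_hit=len(chem_result.pathways_hit),
        kes_total=len(kes),
        kes_with_genes=ke_genes.n_docs_with_genes,
        genes_in_kes=len(ke_genes.genes_total),
        genes_in_kes_covered=len(ke_cov.covered),
        kers_total=len(kers),
        kers_with_genes=ker_genes.n_docs_with_genes,
        genes_in_kers=len(ker_genes.genes_total),
        genes_in_kers_covered=len(ker_cov.covered),
        provenance=dict(provenance or {}),
    )


_TSV_ORDER = _COUNT_FIELDS + (
    "pct_ke_genes_covered",
    "pct_ker_genes_covered",
    "pct_cas_mapped",
    "pct_chebi_in_pathways",
)


def write_report(report: CoverageReport, path: str | Path, fmt: str = "json") -> Path:
    """Serialize a report as schema-valid JSON or a fixed-order metric/value TSV."""
    path = Path(path)
    if fmt == "json":
        payload = report.to_dict()
        validate_report_dict(payload)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif fmt == "tsv":
        payload = report.to_dict()
        lines = ["metric\tvalue"]
        for name in _TSV_ORDER:
            value = payload.get(name, payload["percents"].get(name))
            lines.append(f"{name}\t{'' if value is None else value}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path


def read_report(path: str | Path) -> CoverageReport:
    """Read back a JSON report written by :func:`write_report`."""
    payload = json.loads(Path(path).read_text())
    validate_report_dict(payload)
    return CoverageReport.from_dict(payload)


def file_provenance(paths: Mapping[str, str | Path], tool_version: str) -> dict:
    """Provenance block: input file identities (SHA-256), tool version, timestamp."""
    inputs = {}
    for label, p in paths.items():
        p = Path(p)
        digest = hashlib.sha256(p.read_bytes()).hexdigest() if p.is_file() else None
        inputs[label] = {"path": str(p), "sha256": digest}
    return {
        "inputs": inputs,
        "tool_version": tool_version,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
    }


# --- minimal JSON-schema validation -----------------------------------------
# The shipped schema uses a small subset of JSON Schema (type/properties/
# required/enum/anyOf); this validator covers exactly that subset.

_SCHEMA_PATH = Path(__file__).parent / "schemas" / "coverage_report.schema.json"
_TYPE_CHECKS = {
    "object": lambda v: isinstance(v, dict),
    "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
    "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
    "string": lambda v: isinstance(v, str),
    "null": lambda v: v is None,
}


def _check(value, schema, where: str) -> None:
    if "anyOf" in schema:
        errors = []
        for option in schema["anyOf"]:
            try:
                _check(value, option, where)
                return
            except FormatError as exc:
                errors.append(str(exc))
        raise FormatError(f"{where}: no anyOf branch matched ({'; '.join(errors)})")
    stype = schema.get("type")
    if stype is not None and not _TYPE_CHECKS[stype](value):
        raise FormatError(f"{where}: expected {stype}, got {type(value).__name__}")
    if stype == "object":
        for key in schema.get("required", []):
            if key not in value:
                raise FormatError(f"{where}: missing required key {key!r}")
        props = schema.get("properties", {})
        for key, sub in props.items():
            if key in value:
                _check(value[key], sub, f"{where}.{key}")
    if "minimum" in schema and value is not None and value < schema["minimum"]:
        raise FormatError(f"{where}: {value} below minimum {schema['minimum']}")


def validate_report_dict(payload: Mapping) -> None:
    """Validate a serialized report against the shipped JSON schema subset."""
    schema = json.loads(_SCHEMA_PATH.read_text())
    _check(payload, schema, "report")
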