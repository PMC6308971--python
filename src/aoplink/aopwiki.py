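"""Parsing and auditing of AOP knowledge-base XML dumps.

An adverse outcome pathway (AOP) is a causal chain of measurable biological
events — key events (KEs) — connecting a molecular initiating event to an
adverse outcome, with key event relationships (KERs) as the directed links and
stressor chemicals as the triggers. The knowledge base publishes its content as
a quarterly XML dump; this module parses one dump into a typed in-memory
dataset and audits its ontology annotations.

The dialect is the 1.0 dump schema: a single XML namespace (read from the
document root, not hard-coded, so dumps of different dates parse alike), with
entity elements for chemicals, stressors, key events and key-event
relationships. Description fields are stripped of markup at parse time; the
normalized plain text is the substrate for all downstream text matching.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from lxml import etree

from ._text import strip_markup
from .errors import ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "BiologicalLevel",
    "OntologyComponent",
    "OntologyAnnotation",
    "KeyEvent",
    "KeyEventRelationship",
    "StressorChemical",
    "AopWikiDataset",
    "ChemicalSummary",
    "parse_aopwiki_xml",
    "filter_key_events",
    "extract_chemicals",
    "ontology_usage_summary",
    "IN_SCOPE_LEVELS",
    "KNOWN_ONTOLOGY_SOURCES",
]


class BiologicalLevel(str, Enum):
    """Level of biological organization of a key event."""

    MOLECULAR = "molecular"
    CELLULAR = "cellular"
    TISSUE = "tissue"
    ORGAN = "organ"
    INDIVIDUAL = "individual"
    POPULATION = "population"
    UNSPECIFIED = "unspecified"


#: The four levels whose key events carry molecular-pathway-relevant biology.
IN_SCOPE_LEVELS = frozenset(
    {
        BiologicalLevel.MOLECULAR,
        BiologicalLevel.CELLULAR,
        BiologicalLevel.TISSUE,
        BiologicalLevel.ORGAN,
    }
)

ALL_LEVELS = frozenset(BiologicalLevel) - {BiologicalLevel.UNSPECIFIED}


class OntologyComponent(str, Enum):
    """Which facet of a key event an ontology annotation describes."""

    BIOLOGICAL_PROCESS = "biological_process"
    BIOLOGICAL_OBJECT = "biological_object"
    CELL_TERM = "cell_term"
    ORGAN_TERM = "organ_term"


#: Ontology source codes recognized from term-identifier prefixes.
KNOWN_ONTOLOGY_SOURCES = frozenset(
    {"GO", "CHEBI", "PR", "MI", "CL", "UBERON", "FMA", "VT", "HP", "MP", "WIKI", "MESH"}
)


def ontology_source_from_term(term_id: str) -> str:
    """Derive the ontology source code from a term identifier's prefix.

    ``GO:0006915`` -> ``GO``; unrecognized prefixes map to ``OTHER`` (never
    discarded), so the audit reports the full annotation landscape.
    """
    prefix = term_id.split(":", 1)[0].strip().upper() if term_id else ""
    return prefix if prefix in KNOWN_ONTOLOGY_SOURCES else "OTHER"


@dataclass(frozen=True)
class OntologyAnnotation:
    component: OntologyComponent
    source: str
    term_id: str
    term_label: str = ""


@dataclass
class KeyEvent:
    """A measurable biological event within an adverse outcome pathway."""

    ke_id: str
    title: str = ""
    level: BiologicalLevel = BiologicalLevel.UNSPECIFIED
    description: str = ""
    annotations: list[OntologyAnnotation] = field(default_factory=list)


@dataclass
class KeyEventRelationship:
    """Directed link between two key events with its evidence texts."""

    ker_id: str
    upstream_ke: str
    downstream_ke: str
    description: str = ""
    biological_plausibility: str = ""
    empirical_support: str = ""

    def texts(self) -> tuple[str, str, str]:
        return (self.description, self.biological_plausibility, self.empirical_support)


@dataclass(frozen=True)
class StressorChemical:
    """One (stressor, chemical) pair; chemical fields empty when the stressor
    carries no chemical annotation."""

    stressor_id: str
    stressor_name: str
    chemical_name: str = ""
    cas: str = ""


@dataclass
class AopWikiDataset:
    """Typed in-memory image of one knowledge-base XML dump."""

    key_events: list[KeyEvent] = field(default_factory=list)
    kers: list[KeyEventRelationship] = field(default_factory=list)
    stressors: list[StressorChemical] = field(default_factory=list)
    source_version: str = ""
    #: (ker_id, missing_ke_id) pairs whose endpoint did not resolve — recorded,
    #: never silently dropped.
    unresolved_references: list[tuple[str, str]] = field(default_factory=list)

    def key_event_index(self) -> dict[str, KeyEvent]:
        return {ke.ke_id: ke for ke in self.key_events}


@dataclass(frozen=True)
class ChemicalSummary:
    """Stressor-chemical records plus deduplicated summary counts."""

    records: tuple[StressorChemical, ...]
    n_stressors: int
    n_unique_chemicals: int
    n_unique_cas: int


def normalize_cas(cas: str | None) -> str:
    """Trim whitespace, keep the hyphenated canonical form."""
    return (cas or "").strip()


_GZIP_MAGIC = b"\x1f\x8b"


def _read_maybe_gzip(path: str | Path) -> bytes:
    path = Path(path)
    raw = path.read_bytes()
    if raw[:2] == _GZIP_MAGIC:
        raw = gzip.decompress(raw)
    return raw


def _localname(tag) -> str:
    if not isinstance(tag, str):
        return ""
    return tag.rsplit("}", 1)[-1]


def _namespace(tag: str) -> str:
    if tag.startswith("{"):
        return tag[1:].split("}", 1)[0]
    return ""


_LEVEL_ALIASES = {lvl.value: lvl for lvl in BiologicalLevel}


def _parse_level(text: str | None, ke_id: str) -> BiologicalLevel:
    if not text or not text.strip():
        return BiologicalLevel.UNSPECIFIED
    level = _LEVEL_ALIASES.get(text.strip().lower())
    if level is None:
        logger.warning("key event %s: unknown biological level %r -> unspecified", ke_id, text)
        return BiologicalLevel.UNSPECIFIED
    return level


_COMPONENT_TAGS = {
    "biological-process": OntologyComponent.BIOLOGICAL_PROCESS,
    "biological-object": OntologyComponent.BIOLOGICAL_OBJECT,
    "cell-term": OntologyComponent.CELL_TERM,
    "organ-term": OntologyComponent.ORGAN_TERM,
}


def _child_text(elem, ns: str, name: str) -> str:
    child = elem.find(f"{{{ns}}}{name}")
    if child is None or child.text is None:
        return ""
    return child.text


def parse_aopwiki_xml(path: str | Path) -> AopWikiDataset:
    """Parse a knowledge-base XML dump into an :class:`AopWikiDataset`.

    Accepts plain or gzip-compressed files (sniffed by magic bytes). Element
    order is preserved; markup inside description fields is stripped to plain
    text with single-space normalization. KER endpoints that do not resolve to
    a parsed key event are recorded in ``unresolved_references``.

    Raises
    ------
    ParseError
        On malformed XML (naming line/column), an unexpected root element
        (naming the namespace found), a duplicate key-event identifier, or a
        missing mandatory identifier on an entity.
    """
    path = Path(path)
    data = _read_maybe_gzip(path)
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:  # carries line/column in its message
        raise ParseError(f"malformed XML in {path}: {exc}") from exc

    if _localname(root.tag) != "data":
        raise ParseError(
            f"unexpected root element <{_localname(root.tag)}> "
            f"(namespace {_namespace(root.tag) or 'none'!r}) in {path}; expected <data>"
        )
    ns = _namespace(root.tag)

    chemicals: dict[str, tuple[str, str]] = {}  # chemical entity id -> (name, cas)
    dataset = AopWikiDataset(source_version=root.get("created", ""))
    seen_ke_ids: set[str] = set()

    for elem in root:
        tag = _localname(elem.tag)
        if tag == "chemical":
            chem_id = elem.get("id")
            if chem_id is None:
                raise ParseError(f"chemical entity without mandatory id in {path}")
            name = _child_text(elem, ns, "preferred-name").strip()
            cas = normalize_cas(_child_text(elem, ns, "casrn"))
            chemicals[chem_id] = (name, cas)
        elif tag == "stressor":
            stressor_id = elem.get("id")
            if stressor_id is None:
                raise ParseError(f"stressor entity without mandatory id in {path}")
            name = _child_text(elem, ns, "name").strip()
            chem_refs: list[tuple[str, str]] = []
            chems = elem.find(f"{{{ns}}}chemicals")
            if chems is not None:
                for initiator in chems.findall(f"{{{ns}}}chemical-initiator"):
                    ref = initiator.get("chemical-id")
                    if ref is not None and ref in chemicals:
                        chem_refs.append(chemicals[ref])
                    elif ref is not None:
                        logger.warning("stressor %s references unknown chemical %s", stressor_id, ref)
            if chem_refs:
                for chem_name, cas in chem_refs:
                    dataset.stressors.append(
                        StressorChemical(stressor_id, name, chem_name, cas)
                    )
            else:
                dataset.stressors.append(StressorChemical(stressor_id, name))
        elif tag == "key-event":
            ke_id = elem.get("id")
            if ke_id is None:
                raise ParseError(f"key-event entity without mandatory id in {path}")
            if ke_id in seen_ke_ids:
                raise ParseError(f"duplicate key-event id {ke_id!r} in {path}")
            seen_ke_ids.add(ke_id)
            annotations = []
            for child in elem:
                comp = _COMPONENT_TAGS.get(_localname(child.tag))
                if comp is None:
                    continue
                term_id = (child.get("source-id") or "").strip()
                annotations.append(
                    OntologyAnnotation(
                        component=comp,
                        source=ontology_source_from_term(term_id),
                        term_id=term_id,
                        term_label=(child.get("name") or "").strip(),
                    )
                )
            dataset.key_events.append(
                KeyEvent(
                    ke_id=ke_id,
                    title=strip_markup(_child_text(elem, ns, "title")),
                    level=_parse_level(
                        _child_text(elem, ns, "biological-organization-level"), ke_id
                    ),
                    description=strip_markup(_child_text(elem, ns, "description")),
                    annotations=annotations,
                )
            )
        elif tag == "key-event-relationship":
            ker_id = elem.get("id")
            if ker_id is None:
                raise ParseError(f"key-event-relationship entity without mandatory id in {path}")
            title = elem.find(f"{{{ns}}}title")
            upstream = downstream = ""
            if title is not None:
                upstream = _child_text(title, ns, "upstream-id").strip()
                downstream = _child_text(title, ns, "downstream-id").strip()
            woe = elem.find(f"{{{ns}}}weight-of-evidence")
            plausibility = support = ""
            if woe is not None:
                plausibility = strip_markup(_child_text(woe, ns, "biological-plausibility"))
                support = strip_markup(_child_text(woe, ns, "empirical-support-linkage"))
            dataset.kers.append(
                KeyEventRelationship(
                    ker_id=ker_id,
                    upstream_ke=upstream,
                    downstream_ke=downstream,
                    description=strip_markup(_child_text(elem, ns, "description")),
                    biological_plausibility=plausibility,
                    empirical_support=support,
                )
            )

    for ker in dataset.kers:
        for endpoint in (ker.upstream_ke, ker.downstream_ke):
            if endpoint and endpoint not in seen_ke_ids:
                dataset.unresolved_references.append((ker.ker_id, endpoint))
    return dataset


def _coerce_levels(levels: Iterable[BiologicalLevel | str]) -> frozenset[BiologicalLevel]:
    coerced = frozenset(BiologicalLevel(lvl) for lvl in levels)
    if not coerced:
        raise ValueError("level set must be non-empty")
    return coerced


def filter_key_events(
    dataset: AopWikiDataset, levels: Iterable[BiologicalLevel | str]
) -> list[KeyEvent]:
    """Key events whose biological level is in ``levels``, in dataset order."""
    wanted = _coerce_levels(levels)
    return [ke for ke in dataset.key_events if ke.level in wanted]


def extract_chemicals(dataset: AopWikiDataset) -> ChemicalSummary:
    """All stressor-chemical records with deduplicated summary counts.

    Stressors are counted as entities; chemicals deduplicate by name and CAS
    numbers by normalized CAS string. Records with an empty CAS are retained
    in the collection but excluded from the CAS count.
    """
    records = tuple(dataset.stressors)
    stressor_ids = {r.stressor_id for r in records}
    chem_names = {r.chemical_name for r in records if r.chemical_name}
    cas_numbers = {normalize_cas(r.cas) for r in records if normalize_cas(r.cas)}
    return ChemicalSummary(
        records=records,
        n_stressors=len(stressor_ids),
        n_unique_chemicals=len(chem_names),
        n_unique_cas=len(cas_numbers),
    )


#: Sentinel source used in the ontology-usage table for key events carrying no
#: annotation for a given component.
UNANNOTATED = "UNANNOTATED"


def ontology_usage_summary(
    dataset: AopWikiDataset,
    levels: Iterable[BiologicalLevel | str] = IN_SCOPE_LEVELS,
) -> pd.DataFrame:
    """Audit ontology usage of key events per (level, component, source).

    Returns a tidy table with columns ``level``, ``component``, ``source``,
    ``n_key_events``: for each (level, component, source) the number of key
    events at that level carrying at least one annotation of that component
    from that source (a key event annotated twice from one source counts
    once), plus ``source == "UNANNOTATED"`` rows counting key events with no
    annotation at all for that component.
    """
    wanted = _coerce_levels(levels)
    counts: Counter[tuple[str, str, str]] = Counter()
    for ke in dataset.key_events:
        if ke.level not in wanted:
            continue
        for comp in OntologyComponent:
            sources = {a.source for a in ke.annotations if a.component is comp}
            if not sources:
                counts[(ke.level.value, comp.value, UNANNOTATED)] += 1
            else:
                for src in sources:
                    counts[(ke.level.value, comp.value, src)] += 1
    rows = [
        {"level": lvl, "component": comp, "source": src, "n_key_events": n}
        for (lvl, comp, src), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["level", "component", "source", "n_key_events"])


def key_events_by_level(dataset: AopWikiDataset) -> dict[str, int]:
    """Count of key events per biological level (all levels, including unspecified)."""
    counts = Counter(ke.level.value for ke in dataset.key_events)
    return {lvl.value: counts.get(lvl.value, 0) for lvl in BiologicalLevel}


def in_scope_kers(
    dataset: AopWikiDataset, levels: Iterable[BiologicalLevel | str] = IN_SCOPE_LEVELS
) -> list[KeyEventRelationship]:
    """KERs whose both endpoints resolve to key events at the given levels."""
    wanted = _coerce_levels(levels)
    index = dataset.key_event_index()
    out = []
    for ker in dataset.kers:
        up = index.get(ker.upstream_ke)
        down = index.get(ker.downstream_ke)
        if up is not None and down is not None and up.level in wanted and down.level in wanted:
            out.append(ker)
    return out
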