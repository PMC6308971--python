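"""Synthetic fixture bundles with exact ground-truth manifests.

Every pipeline stage is tested against generated data whose true content is
known by construction: a knowledge-base XML dump with key events at stated
biological levels containing planted gene mentions inside decoy prose,
stressors with valid/invalid/mappable/unmappable CAS numbers, an HGNC-style
lexicon mixing symbols, multi-word names and synonyms, and a pathway database
(flat table + GPML + Turtle renderings) in which a controlled fraction of the
planted genes and metabolites appear.

The generator certifies its own fixtures: after assembling each text it runs
the mention recognizer and requires the recovered gene set to equal the
planted set (re-drawing surface forms on a collision, which the disjoint
decoy/name vocabularies make vanishingly rare), so manifests are exact
oracles, not approximations. Same seed and config produce byte-identical
bundles.

The manifest is a plain JSON-able dict; :func:`expected_report` recomputes
the full coverage report from the planted structures by brute-force counting,
independent of every pipeline code path.
"""

from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass, field
from pathlib import Path
from random import Random
from typing import Iterable, Mapping

from lxml import etree

from .aopwiki import IN_SCOPE_LEVELS, BiologicalLevel
from .chemlink import cas_check_digit
from .lexicon import FormClass, GeneEntry, GeneLexicon, find_gene_mentions
from .pathways import GPML_2013A_NS, WP_VOCAB, XrefNamespace
from .report import CoverageReport

__all__ = ["SyntheticConfig", "generate_bundle", "expected_report", "BundleError"]

AOPWIKI_NS = "http://www.aopkb.org/aop-xml"


class BundleError(ValueError):
    """A config whose targets are unattainable, or a failed self-check."""


# Vocabulary for approved names and multi-word synonyms. Kept strictly
# disjoint from the decoy/connector vocabulary below so case-insensitive
# multi-token matching cannot fire inside decoy prose.
_NAME_VOCAB = (
    "kinase", "receptor", "transporter", "synthase", "reductase", "oxidase",
    "polymerase", "helicase", "ligase", "phosphatase", "subunit", "homolog",
    "paralog", "alpha", "beta", "gamma", "delta", "epsilon", "interacting",
    "associated",
)

_DEFAULT_DECOYS = (
    "The exposed liver shows marked swelling and gradual loss of its normal role.",
    "Repeated dosing caused visible damage to the outer layer of the skin.",
    "Animals in the treated group moved less and ate smaller amounts of food.",
    "A clear dose response was observed across all tested concentrations.",
    "The change was reversible once the compound was withdrawn from the water.",
    "Histological sections revealed scattered regions of dying cells.",
    "No effect was seen at the lowest concentration tested in this study.",
    "The outcome at the population scale was a decline in reproductive success.",
    "Oxidative stress is a common early response to many toxic compounds.",
    "Swelling of the organ was accompanied by reduced blood flow.",
    "These observations support a causal chain from exposure to outcome.",
    "Measurements were taken at three time points after the initial exposure.",
)

_PLANT_TEMPLATES = (
    "Expression of {form} is strongly increased in treated samples.",
    "Levels of {form} decline steadily after the exposure window.",
    "This event involves {form} and its downstream effects.",
    "Induction of {form} was confirmed in repeated experiments.",
)

_LEVEL_ORDER = (
    BiologicalLevel.MOLECULAR,
    BiologicalLevel.CELLULAR,
    BiologicalLevel.TISSUE,
    BiologicalLevel.ORGAN,
    BiologicalLevel.INDIVIDUAL,
    BiologicalLevel.POPULATION,
)


@dataclass
class SyntheticConfig:
    """Knobs of the fixture generator.

    Defaults are a roughly 1/25-scale image of a real quarterly dump: a few
    dozen key events skewed toward the molecular and cellular levels, most
    stressors carrying CAS-annotated chemicals, ~90% of CAS numbers valid and
    mappable, about two ChEBI ids per mapped CAS, and pathway coverage
    targets of 0.7 for genes and 0.16 for metabolites.
    """

    seed: int
    n_kes_by_level: dict[str, int] = field(
        default_factory=lambda: {
            "molecular": 12, "cellular": 10, "tissue": 6,
            "organ": 4, "individual": 3, "population": 2,
        }
    )
    n_kers: int = 20
    genes_per_ke: int | tuple[int, int] = (0, 3)
    genes_per_ker: int | tuple[int, int] = (0, 3)
    n_lexicon_genes: int = 60
    fraction_forms_multiword: float = 0.4
    n_stressors: int = 30
    n_chemicals: int | None = None
    fraction_chemicals_without_cas: float = 0.05
    fraction_cas_valid: float = 0.9
    fraction_cas_mappable: float = 0.9
    chebi_per_cas: int = 2
    n_pathways: int = 15
    gene_coverage_target: float = 0.7
    metabolite_coverage_target: float = 0.16
    annotation_rate: float = 0.5
    annotation_source_mix: dict[str, float] = field(
        default_factory=lambda: {
            "GO": 0.45, "CHEBI": 0.15, "PR": 0.15, "CL": 0.1, "UBERON": 0.1, "WIKI": 0.05,
        }
    )
    n_ambiguous_synonyms: int = 0
    decoy_sentence_pool: tuple[str, ...] = _DEFAULT_DECOYS

    def __post_init__(self) -> None:
        ratios = {
            "fraction_forms_multiword": self.fraction_forms_multiword,
            "fraction_chemicals_without_cas": self.fraction_chemicals_without_cas,
            "fraction_cas_valid": self.fraction_cas_valid,
            "fraction_cas_mappable": self.fraction_cas_mappable,
            "gene_coverage_target": self.gene_coverage_target,
            "metabolite_coverage_target": self.metabolite_coverage_target,
            "annotation_rate": self.annotation_rate,
        }
        for name, value in ratios.items():
            if not 0.0 <= value <= 1.0:
                raise BundleError(f"{name} must be in [0, 1], got {value}")
        counts = {
            "n_kers": self.n_kers,
            "n_lexicon_genes": self.n_lexicon_genes,
            "n_stressors": self.n_stressors,
            "chebi_per_cas": self.chebi_per_cas,
            "n_pathways": self.n_pathways,
            "n_ambiguous_synonyms": self.n_ambiguous_synonyms,
        }
        for name, value in counts.items():
            if value < 0:
                raise BundleError(f"{name} must be >= 0, got {value}")
        if any(n < 0 for n in self.n_kes_by_level.values()):
            raise BundleError("n_kes_by_level counts must be >= 0")

    def to_jsonable(self) -> dict:
        payload = asdict(self)
        payload["decoy_sentence_pool"] = list(self.decoy_sentence_pool)
        if isinstance(self.genes_per_ke, tuple):
            payload["genes_per_ke"] = list(self.genes_per_ke)
        if isinstance(self.genes_per_ker, tuple):
            payload["genes_per_ker"] = list(self.genes_per_ker)
        return payload


def _draw_count(rng: Random, spec: int | tuple[int, int] | list) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return rng.randint(lo, hi)


def _unique(generator, seen: set[str]) -> str:
    for _ in range(10_000):
        candidate = generator()
        if candidate not in seen:
            seen.add(candidate)
            return candidate
    raise BundleError("exhausted attempts to draw a unique token")


def _make_lexicon(config: SyntheticConfig, rng: Random):
    """Generate lexicon rows; returns (rows, entries, claims_by_form)."""
    used_tokens: set[str] = set()
    used_names: set[str] = set()

    def symbol_like() -> str:
        letters = "".join(rng.choice(string.ascii_uppercase) for _ in range(rng.randint(3, 4)))
        return letters + str(rng.randint(1, 9))

    def multi_word() -> str:
        n = rng.randint(2, 3)
        words = [rng.choice(_NAME_VOCAB) for _ in range(n)]
        return " ".join(words) + f" {rng.randint(1, 99)}"

    rows = []
    for i in range(config.n_lexicon_genes):
        gene_id = f"HGNC:{1000 + i}"
        symbol = _unique(symbol_like, used_tokens)
        name = _unique(multi_word, used_names)
        prev = [_unique(symbol_like, used_tokens)] if rng.random() < 0.5 else []
        synonyms = []
        for _ in range(rng.randint(1, 2)):
            if rng.random() < config.fraction_forms_multiword:
                synonyms.append(_unique(multi_word, used_names))
            else:
                synonyms.append(_unique(symbol_like, used_tokens))
        ensembl = f"ENSG{rng.randrange(10**10, 10**11)}" if rng.random() < 0.9 else ""
        rows.append(
            {
                "hgnc_id": gene_id,
                "approved_symbol": symbol,
                "approved_name": name,
                "previous_symbols": "|".join(prev),
                "synonyms": synonyms,
                "ensembl_id": ensembl,
            }
        )
    # ambiguous synonyms: one extra form shared verbatim by two genes
    for j in range(config.n_ambiguous_synonyms):
        if config.n_lexicon_genes < 2:
            raise BundleError("ambiguous synonyms need at least two lexicon genes")
        shared = _unique(symbol_like, used_tokens)
        a, b = rng.sample(range(config.n_lexicon_genes), 2)
        rows[a]["synonyms"].append(shared)
        rows[b]["synonyms"].append(shared)
    entries = [
        GeneEntry(
            gene_id=row["hgnc_id"],
            ensembl_id=row["ensembl_id"],
            approved_symbol=row["approved_symbol"],
            surface_forms=tuple(
                [(row["approved_symbol"], FormClass.APPROVED_SYMBOL)]
                + [(row["approved_name"], FormClass.APPROVED_NAME)]
                + [(p, FormClass.PREVIOUS_SYMBOL) for p in row["previous_symbols"].split("|") if p]
                + [(s, FormClass.SYNONYM) for s in row["synonyms"]]
            ),
        )
        for row in rows
    ]
    return rows, entries


def _pick_form(rng: Random, entry: GeneEntry) -> str:
    """Pick a surface form to plant, weighted toward symbols."""
    by_class: dict[FormClass, list[str]] = {}
    for form, cls in entry.surface_forms:
        by_class.setdefault(cls, []).append(form)
    roll = rng.random()
    order = (
        FormClass.APPROVED_SYMBOL if roll < 0.6
        else FormClass.PREVIOUS_SYMBOL if roll < 0.75
        else FormClass.SYNONYM if roll < 0.9
        else FormClass.APPROVED_NAME
    )
    forms = by_class.get(order) or by_class[FormClass.APPROVED_SYMBOL]
    return rng.choice(forms)


def _compose_text(
    rng: Random,
    planted_entries: list[GeneEntry],
    lexicon: GeneLexicon,
    decoys: tuple[str, ...],
    markup: bool,
) -> tuple[str, frozenset[str]]:
    """Assemble decoy + planted sentences; certify recovered == planted.

    Returns (raw text as written to XML, expected gene-id set). The expected
    set is the union of lexicon claims of the planted forms, so an ambiguous
    form contributes every claiming gene. On a recognition mismatch the forms
    are re-drawn (deterministically) before giving up.
    """
    for _ in range(10):
        sentences = [rng.choice(decoys) for _ in range(rng.randint(1, 3))]
        planted_forms = [_pick_form(rng, entry) for entry in planted_entries]
        for form in planted_forms:
            template = rng.choice(_PLANT_TEMPLATES)
            sentences.insert(rng.randrange(len(sentences) + 1), template.format(form=form))
        plain = " ".join(sentences)
        expected: set[str] = set()
        for mention in find_gene_mentions(plain, lexicon):
            expected.add(mention.gene_id)
        planted_ids = {e.gene_id for e in planted_entries}
        # expected must contain every planted gene and nothing outside the
        # claims of the planted forms (ambiguity may legitimately add genes)
        if planted_ids <= expected and _claims_only(expected, planted_forms, lexicon):
            if markup:
                raw = "".join(f"<p>{s}</p>" for s in sentences)
            else:
                raw = plain
            return raw, frozenset(expected)
    raise BundleError("could not compose collision-free text after 10 attempts")


def _claims_only(expected: set[str], planted_forms: list[str], lexicon: GeneLexicon) -> bool:
    """True when every recovered gene is a legitimate claimant of a planted form."""
    claims: set[str] = set()
    for form in planted_forms:
        for entry in lexicon.entries.values():
            if any(f == form for f, _ in entry.surface_forms):
                claims.add(entry.gene_id)
    return expected <= claims


def _make_cas(rng: Random, valid: bool, seen: set[str]) -> str:
    def draw() -> str:
        body_len = rng.randint(2, 7)
        seg1 = "".join(rng.choice(string.digits) for _ in range(body_len))
        if seg1[0] == "0":
            seg1 = str(rng.randint(1, 9)) + seg1[1:]
        seg2 = f"{rng.randint(0, 99):02d}"
        check = cas_check_digit(seg1 + seg2)
        if not valid:
            check = (check + 1) % 10
        return f"{seg1}-{seg2}-{check}"

    return _unique(draw, seen)


def _xml_sub(parent, tag: str, text: str | None = None, **attrs):
    elem = etree.SubElement(parent, f"{{{AOPWIKI_NS}}}{tag}", **attrs)
    if text is not None:
        elem.text = text
    return elem


def generate_bundle(config: SyntheticConfig, out_dir: str | Path) -> tuple[dict, dict]:
    """Write a full fixture bundle; return ({file label: path}, manifest).

    Emits ``aopwiki.xml`` (the dump dialect the parser consumes),
    ``lexicon.tsv``, ``cas_chebi.tsv``, ``pathways.tsv``, one GPML per
    pathway under ``gpml/``, ``pathways.ttl`` and ``manifest.json``. The
    manifest embeds the planted structures and the expected coverage report
    recomputed from them. Same seed + config -> byte-identical files.

    Raises :class:`BundleError` before writing anything when a coverage
    target is unattainable (a nonzero target with zero pathways).
    """
    rng = Random(config.seed)
    out_dir = Path(out_dir)

    lex_rows, entries = _make_lexicon(config, rng)
    lexicon = GeneLexicon(entries)
    for sentence in config.decoy_sentence_pool:
        if find_gene_mentions(sentence, lexicon):
            raise BundleError(f"decoy sentence matches a lexicon form: {sentence!r}")
    entry_list = list(lexicon.entries.values())

    # --- key events ---------------------------------------------------------
    key_events = []
    ke_counter = 0
    for level in _LEVEL_ORDER:
        for _ in range(config.n_kes_by_level.get(level.value, 0)):
            ke_counter += 1
            ke_id = f"KE:{ke_counter}"
            n_genes = _draw_count(rng, config.genes_per_ke)
            planted = rng.sample(entry_list, min(n_genes, len(entry_list)))
            raw_text, expected_genes = _compose_text(
                rng, planted, lexicon, config.decoy_sentence_pool, markup=True
            )
            annotations = []
            for component in ("biological_process", "biological_object", "cell_term", "organ_term"):
                if rng.random() < config.annotation_rate:
                    sources = list(config.annotation_source_mix)
                    weights = list(config.annotation_source_mix.values())
                    for _ in range(rng.randint(1, 2)):
                        src = rng.choices(sources, weights=weights, k=1)[0]
                        annotations.append(
                            {
                                "component": component,
                                "source": src,
                                "term_id": f"{src}:{rng.randrange(10**6, 10**7)}",
                            }
                        )
            key_events.append(
                {
                    "ke_id": ke_id,
                    "level": level.value,
                    "title": f"Synthetic key event {ke_counter}",
                    "raw_description": raw_text,
                    "planted_genes": sorted(expected_genes),
                    "annotations": annotations,
                }
            )

    in_scope_ids = [k["ke_id"] for k in key_events if k["level"] in {l.value for l in IN_SCOPE_LEVELS}]
    out_scope_ids = [k["ke_id"] for k in key_events if k["ke_id"] not in set(in_scope_ids)]

    # --- key event relationships -------------------------------------------
    kers = []
    for i in range(config.n_kers):
        ker_id = f"KER:{i + 1}"
        if len(in_scope_ids) >= 2 and (rng.random() < 0.8 or not out_scope_ids):
            upstream, downstream = rng.sample(in_scope_ids, 2)
        elif in_scope_ids and out_scope_ids:
            upstream = rng.choice(in_scope_ids)
            downstream = rng.choice(out_scope_ids)
        elif len(key_events) >= 2:
            upstream, downstream = rng.sample([k["ke_id"] for k in key_events], 2)
        else:
            continue
        in_scope = upstream in set(in_scope_ids) and downstream in set(in_scope_ids)
        n_genes = _draw_count(rng, config.genes_per_ker)
        planted = rng.sample(entry_list, min(n_genes, len(entry_list)))
        fields: dict[str, dict] = {}
        assignment = [rng.choice(["description", "biological_plausibility", "empirical_support"]) for _ in planted]
        for field_name in ("description", "biological_plausibility", "empirical_support"):
            field_entries = [e for e, a in zip(planted, assignment) if a == field_name]
            if not field_entries and rng.random() < 0.3:
                fields[field_name] = {"raw": "", "genes": []}
                continue
            raw_text, expected_genes = _compose_text(
                rng, field_entries, lexicon, config.decoy_sentence_pool, markup=False
            )
            fields[field_name] = {"raw": raw_text, "genes": sorted(expected_genes)}
        kers.append(
            {
                "ker_id": ker_id,
                "upstream": upstream,
                "downstream": downstream,
                "in_scope": in_scope,
                "fields": fields,
            }
        )

    # --- stressors and chemicals -------------------------------------------
    n_chem = config.n_chemicals or max(1, round(0.7 * config.n_stressors))
    seen_cas: set[str] = set()
    chemicals = []
    for i in range(n_chem):
        if rng.random() < config.fraction_chemicals_without_cas:
            cas = ""
            valid = False
        else:
            valid = rng.random() < config.fraction_cas_valid
            cas = _make_cas(rng, valid, seen_cas)
        chemicals.append(
            {"chem_id": f"C:{i + 1}", "name": f"synthetic compound {i + 1}", "cas": cas, "valid": valid}
        )
    stressor_chemicals = []
    for j in range(config.n_stressors):
        stressor_id = f"S:{j + 1}"
        name = f"Synthetic stressor {j + 1}"
        if j < n_chem:
            chem: dict | None = chemicals[j]
        elif j == config.n_stressors - 1 and config.n_stressors > n_chem:
            chem = None  # one stressor with no chemical annotation
        else:
            chem = rng.choice(chemicals)
        stressor_chemicals.append(
            {
                "stressor_id": stressor_id,
                "stressor_name": name,
                "chem_id": chem["chem_id"] if chem else "",
                "chemical_name": chem["name"] if chem else "",
                "cas": chem["cas"] if chem else "",
            }
        )

    # --- CAS -> ChEBI mapping -----------------------------------------------
    chebi_counter = 10_000
    cas_flags: dict[str, dict] = {}
    for chem in chemicals:
        if not chem["cas"]:
            continue
        mappable = rng.random() < config.fraction_cas_mappable
        chebis = []
        if mappable:
            for _ in range(config.chebi_per_cas):
                chebi_counter += 1
                chebis.append(f"CHEBI:{chebi_counter}")
        cas_flags[chem["cas"]] = {"valid": chem["valid"], "mappable": mappable, "chebi": chebis}
    # extra mapping rows for CAS absent from the dump (mapper is a superset)
    extra_rows = []
    for _ in range(5):
        cas = _make_cas(rng, True, seen_cas)
        chebi_counter += 1
        extra_rows.append((cas, f"CHEBI:{chebi_counter}"))

    # --- coverage selection --------------------------------------------------
    ke_gene_union = sorted({g for k in key_events if k["ke_id"] in set(in_scope_ids) for g in k["planted_genes"]})
    ker_gene_union = sorted(
        {g for k in kers if k["in_scope"] for f in k["fields"].values() for g in f["genes"]}
    )
    ker_only = sorted(set(ker_gene_union) - set(ke_gene_union))
    n_cover_ke = round(config.gene_coverage_target * len(ke_gene_union))
    n_cover_ker_only = round(config.gene_coverage_target * len(ker_only))
    chebi_union = sorted({c for flags in cas_flags.values() for c in flags["chebi"]})
    n_cover_chebi = round(config.metabolite_coverage_target * len(chebi_union))
    if (n_cover_ke or n_cover_ker_only or n_cover_chebi) and config.n_pathways == 0:
        raise BundleError(
            "coverage targets require at least one pathway but n_pathways is 0"
        )
    covered_genes = sorted(
        rng.sample(ke_gene_union, n_cover_ke) + rng.sample(ker_only, n_cover_ker_only)
    )
    covered_chebi = sorted(rng.sample(chebi_union, n_cover_chebi))

    # --- pathways -------------------------------------------------------------
    pathways = []
    for p in range(config.n_pathways):
        pathway_id = f"WP{p + 1}"
        tags = []
        if rng.random() < 0.6:
            tags.append(["PW", f"PW:{rng.randrange(10**6, 10**7)}"])
        if rng.random() < 0.2:
            tags.append(["CL", f"CL:{rng.randrange(10**6, 10**7)}"])
        if rng.random() < 0.3:
            tags.append(["DO", f"DOID:{rng.randrange(10**4, 10**5)}"])
        fillers = [
            [XrefNamespace.HGNC_SYMBOL.value, f"ZZZ{p + 1}{string.ascii_uppercase[q]}Q"]
            for q in range(rng.randint(2, 4))
        ]
        pathways.append(
            {
                "pathway_id": pathway_id,
                "title": f"Synthetic pathway {p + 1}",
                "gene_xrefs": fillers,
                "metabolite_xrefs": [],
                "ontology_tags": tags,
            }
        )
    if config.n_pathways:
        for gene_id in covered_genes:
            entry = lexicon.entries[gene_id]
            choices = [XrefNamespace.HGNC_SYMBOL, XrefNamespace.HGNC_ID]
            if entry.ensembl_id:
                choices.append(XrefNamespace.ENSEMBL)
            for target in rng.sample(pathways, rng.randint(1, min(2, len(pathways)))):
                namespace = rng.choice(choices)
                identifier = {
                    XrefNamespace.HGNC_SYMBOL: entry.approved_symbol,
                    XrefNamespace.HGNC_ID: entry.gene_id,
                    XrefNamespace.ENSEMBL: entry.ensembl_id,
                }[namespace]
                xref = [namespace.value, identifier]
                if xref not in target["gene_xrefs"]:
                    target["gene_xrefs"].append(xref)
        for chebi in covered_chebi:
            for target in rng.sample(pathways, rng.randint(1, min(2, len(pathways)))):
                if chebi not in target["metabolite_xrefs"]:
                    target["metabolite_xrefs"].append(chebi)
    for rec in pathways:
        rec["gene_xrefs"].sort()
        rec["metabolite_xrefs"].sort()
        rec["ontology_tags"].sort()

    manifest = {
        "config": config.to_jsonable(),
        "key_events": key_events,
        "kers": kers,
        "stressor_chemicals": stressor_chemicals,
        "cas_flags": cas_flags,
        "pathways": pathways,
        "lexicon": {
            "gene_ids": sorted(lexicon.entries),
            "identifiers": {
                gid: {"symbol": e.approved_symbol, "ensembl": e.ensembl_id}
                for gid, e in sorted(lexicon.entries.items())
            },
        },
    }
    manifest["expected_report"] = expected_report(manifest).to_dict()

    # --- write files -----------------------------------------------------------
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "xml": out_dir / "aopwiki.xml",
        "lexicon": out_dir / "lexicon.tsv",
        "cas_chebi": out_dir / "cas_chebi.tsv",
        "pathways": out_dir / "pathways.tsv",
        "turtle": out_dir / "pathways.ttl",
        "manifest": out_dir / "manifest.json",
        "gpml_dir": out_dir / "gpml",
    }
    _write_xml(paths["xml"], config, manifest, chemicals)
    _write_lexicon_tsv(paths["lexicon"], lex_rows)
    _write_mapping_tsv(paths["cas_chebi"], cas_flags, extra_rows)
    _write_pathway_tsv(paths["pathways"], pathways)
    _write_gpml(paths["gpml_dir"], pathways)
    _write_turtle(paths["turtle"], pathways)
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}, manifest


def _write_xml(path: Path, config: SyntheticConfig, manifest: dict, chemicals: list[dict]) -> None:
    root = etree.Element(f"{{{AOPWIKI_NS}}}data", nsmap={None: AOPWIKI_NS})
    root.set("created", f"synthetic seed={config.seed}")
    for chem in chemicals:
        elem = _xml_sub(root, "chemical", id=chem["chem_id"])
        if chem["cas"]:
            _xml_sub(elem, "casrn", chem["cas"])
        _xml_sub(elem, "preferred-name", chem["name"])
    seen_stressors = set()
    for rec in manifest["stressor_chemicals"]:
        if rec["stressor_id"] in seen_stressors:
            continue
        seen_stressors.add(rec["stressor_id"])
        elem = _xml_sub(root, "stressor", id=rec["stressor_id"])
        _xml_sub(elem, "name", rec["stressor_name"])
        refs = [
            r["chem_id"]
            for r in manifest["stressor_chemicals"]
            if r["stressor_id"] == rec["stressor_id"] and r["chem_id"]
        ]
        if refs:
            chems = _xml_sub(elem, "chemicals")
            for ref in refs:
                etree.SubElement(
                    chems, f"{{{AOPWIKI_NS}}}chemical-initiator", **{"chemical-id": ref}
                )
    for ke in manifest["key_events"]:
        elem = _xml_sub(root, "key-event", id=ke["ke_id"])
        _xml_sub(elem, "title", ke["title"])
        _xml_sub(elem, "biological-organization-level", ke["level"].capitalize())
        _xml_sub(elem, "description", ke["raw_description"])
        tag_by_component = {
            "biological_process": "biological-process",
            "biological_object": "biological-object",
            "cell_term": "cell-term",
            "organ_term": "organ-term",
        }
        for ann in ke["annotations"]:
            etree.SubElement(
                elem,
                f"{{{AOPWIKI_NS}}}{tag_by_component[ann['component']]}",
                **{"source": ann["source"], "source-id": ann["term_id"], "name": "synthetic term"},
            )
    for ker in manifest["kers"]:
        elem = _xml_sub(root, "key-event-relationship", id=ker["ker_id"])
        title = _xml_sub(elem, "title")
        _xml_sub(title, "upstream-id", ker["upstream"])
        _xml_sub(title, "downstream-id", ker["downstream"])
        _xml_sub(elem, "description", ker["fields"]["description"]["raw"])
        woe = _xml_sub(elem, "weight-of-evidence")
        _xml_sub(woe, "biological-plausibility", ker["fields"]["biological_plausibility"]["raw"])
        _xml_sub(woe, "empirical-support-linkage", ker["fields"]["empirical_support"]["raw"])
    path.write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )


def _write_lexicon_tsv(path: Path, rows: list[dict]) -> None:
    lines = ["hgnc_id\tapproved_symbol\tapproved_name\tprevious_symbols\tsynonyms\tensembl_id"]
    for row in rows:
        lines.append(
            "\t".join(
                [
                    row["hgnc_id"],
                    row["approved_symbol"],
                    row["approved_name"],
                    row["previous_symbols"],
                    "|".join(row["synonyms"]),
                    row["ensembl_id"],
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _write_mapping_tsv(path: Path, cas_flags: dict, extra_rows: list[tuple[str, str]]) -> None:
    lines = ["cas\tchebi"]
    for cas in sorted(cas_flags):
        for chebi in cas_flags[cas]["chebi"]:
            lines.append(f"{cas}\t{chebi}")
    if cas_flags:  # one deliberate duplicate row: loaders must collapse it
        first = sorted(c for c in cas_flags if cas_flags[c]["chebi"])
        if first:
            cas = first[0]
            lines.append(f"{cas}\t{cas_flags[cas]['chebi'][0]}")
    for cas, chebi in extra_rows:
        lines.append(f"{cas}\t{chebi}")
    path.write_text("\n".join(lines) + "\n")


def _write_pathway_tsv(path: Path, pathways: list[dict]) -> None:
    lines = ["pathway_id\ttitle\txref_namespace\txref_id"]
    for rec in pathways:
        for ns, xref in rec["gene_xrefs"]:
            lines.append(f"{rec['pathway_id']}\t{rec['title']}\t{ns}\t{xref}")
        for chebi in rec["metabolite_xrefs"]:
            lines.append(f"{rec['pathway_id']}\t{rec['title']}\tCHEBI\t{chebi}")
        for src, term in rec["ontology_tags"]:
            lines.append(f"{rec['pathway_id']}\t{rec['title']}\t{src}\t{term}")
    path.write_text("\n".join(lines) + "\n")


_NS_TO_GPML_DB = {
    "ENSEMBL": "Ensembl",
    "HGNC_SYMBOL": "HGNC",
    "HGNC_ID": "HGNC ID",
    "OTHER": "Entrez Gene",
}
_BIOPAX_NS = "http://www.biopax.org/release/biopax-level3.owl#"


def _write_gpml(gpml_dir: Path, pathways: list[dict]) -> None:
    gpml_dir.mkdir(parents=True, exist_ok=True)
    for rec in pathways:
        nsmap = {None: GPML_2013A_NS, "bp": _BIOPAX_NS}
        root = etree.Element(f"{{{GPML_2013A_NS}}}Pathway", nsmap=nsmap)
        root.set("Name", rec["title"])
        root.set("Version", "synthetic")
        root.set("Organism", "Homo sapiens")
        graph_id = 0
        for ns, xref in rec["gene_xrefs"]:
            graph_id += 1
            node = etree.SubElement(root, f"{{{GPML_2013A_NS}}}DataNode")
            node.set("TextLabel", xref)
            node.set("GraphId", f"n{graph_id}")
            node.set("Type", "GeneProduct")
            x = etree.SubElement(node, f"{{{GPML_2013A_NS}}}Xref")
            x.set("Database", _NS_TO_GPML_DB[ns])
            x.set("ID", xref)
        for chebi in rec["metabolite_xrefs"]:
            graph_id += 1
            node = etree.SubElement(root, f"{{{GPML_2013A_NS}}}DataNode")
            node.set("TextLabel", chebi)
            node.set("GraphId", f"n{graph_id}")
            node.set("Type", "Metabolite")
            x = etree.SubElement(node, f"{{{GPML_2013A_NS}}}Xref")
            x.set("Database", "ChEBI")
            x.set("ID", chebi)
        if rec["ontology_tags"]:
            biopax = etree.SubElement(root, f"{{{GPML_2013A_NS}}}Biopax")
            for _src, term in rec["ontology_tags"]:
                vocab = etree.SubElement(biopax, f"{{{_BIOPAX_NS}}}openControlledVocabulary")
                etree.SubElement(vocab, f"{{{_BIOPAX_NS}}}TERM").text = "synthetic term"
                etree.SubElement(vocab, f"{{{_BIOPAX_NS}}}ID").text = term
                etree.SubElement(vocab, f"{{{_BIOPAX_NS}}}Ontology").text = _src
        (gpml_dir / f"{rec['pathway_id']}.gpml").write_bytes(
            etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
        )


_NS_TO_PREDICATE = {
    "ENSEMBL": "wp:bdbEnsembl",
    "HGNC_SYMBOL": "wp:bdbHgncSymbol",
    "HGNC_ID": "wp:bdbHgnc",
    "OTHER": "wp:bdbEntrezGene",
}
_NS_TO_IRI_PREFIX = {
    "ENSEMBL": "http://identifiers.org/ensembl/",
    "HGNC_SYMBOL": "http://identifiers.org/hgnc.symbol/",
    "HGNC_ID": "http://identifiers.org/hgnc/",
    "OTHER": "http://identifiers.org/ncbigene/",
}


def _write_turtle(path: Path, pathways: list[dict]) -> None:
    """Deterministic line-level Turtle rendering of the membership DB."""
    lines = [
        f"@prefix wp: <{WP_VOCAB}> .",
        "@prefix dcterms: <http://purl.org/dc/terms/> .",
        "",
    ]
    node_counter = 0
    body: list[str] = []
    for rec in pathways:
        pathway_iri = f"<http://identifiers.org/wikipathways/{rec['pathway_id']}>"
        body.append(f"{pathway_iri} a wp:Pathway .")
        for ns, xref in rec["gene_xrefs"]:
            node_counter += 1
            node = f"<http://example.org/node/{node_counter}>"
            xref_iri = f"<{_NS_TO_IRI_PREFIX[ns]}{xref}>"
            body.append(
                f"{node} a wp:GeneProduct ; {_NS_TO_PREDICATE[ns]} {xref_iri} ; "
                f"dcterms:isPartOf {pathway_iri} ."
            )
        for chebi in rec["metabolite_xrefs"]:
            node_counter += 1
            node = f"<http://example.org/node/{node_counter}>"
            body.append(
                f"{node} a wp:Metabolite ; wp:bdbChEBI <http://identifiers.org/chebi/{chebi}> ; "
                f"dcterms:isPartOf {pathway_iri} ."
            )
    path.write_text("\n".join(lines + body) + "\n")


def expected_report(manifest: Mapping) -> CoverageReport:
    """Recompute the full coverage report from planted structures alone.

    Brute-force counting over the manifest dicts — no pipeline code paths —
    so that equality with the pipeline's own report is a genuine two-route
    check.
    """
    in_scope_levels = {l.value for l in IN_SCOPE_LEVELS}
    records = manifest["stressor_chemicals"]
    stressors = {r["stressor_id"] for r in records}
    chemicals = {r["chemical_name"] for r in records if r["chemical_name"]}
    cas_numbers = {r["cas"] for r in records if r["cas"]}

    cas_flags = manifest["cas_flags"]
    mapped = {cas for cas in cas_numbers if cas_flags.get(cas, {}).get("chebi")}
    chebi_ids = {c for cas in mapped for c in cas_flags[cas]["chebi"]}
    pathway_metabolites = {
        rec["pathway_id"]: set(rec["metabolite_xrefs"]) for rec in manifest["pathways"]
    }
    chebi_in_pathways = {
        c for c in chebi_ids if any(c in m for m in pathway_metabolites.values())
    }
    chem_pathways_hit = {
        pid for pid, mets in pathway_metabolites.items() if mets & chebi_in_pathways
    }

    in_scope_kes = [k for k in manifest["key_events"] if k["level"] in in_scope_levels]
    ke_genes = {k["ke_id"]: set(k["planted_genes"]) for k in in_scope_kes}
    genes_in_kes = set().union(*ke_genes.values()) if ke_genes else set()

    in_scope_kers = [k for k in manifest["kers"] if k["in_scope"]]
    ker_genes = {
        k["ker_id"]: {g for f in k["fields"].values() for g in f["genes"]}
        for k in in_scope_kers
    }
    genes_in_kers = set().union(*ker_genes.values()) if ker_genes else set()

    identifiers = manifest["lexicon"]["identifiers"]
    pathway_gene_ids = {
        (ns, xref) for rec in manifest["pathways"] for ns, xref in rec["gene_xrefs"]
    }

    def covered(gene_id: str) -> bool:
        ids = identifiers[gene_id]
        candidates = {("HGNC_ID", gene_id), ("HGNC_SYMBOL", ids["symbol"])}
        if ids["ensembl"]:
            candidates.add(("ENSEMBL", ids["ensembl"]))
        return bool(candidates & pathway_gene_ids)

    return CoverageReport(
        stressors=len(stressors),
        chemicals=len(chemicals),
        cas_numbers=len(cas_numbers),
        cas_mapped=len(mapped),
        chebi_ids=len(chebi_ids),
        chebi_in_pathways=len(chebi_in_pathways),
        chem_pathways_hit=len(chem_pathways_hit),
        kes_total=len(in_scope_kes),
        kes_with_genes=sum(1 for g in ke_genes.values() if g),
        genes_in_kes=len(genes_in_kes),
        genes_in_kes_covered=sum(1 for g in genes_in_kes if covered(g)),
        kers_total=len(in_scope_kers),
        kers_with_genes=sum(1 for g in ker_genes.values() if g),
        genes_in_kers=len(genes_in_kers),
        genes_in_kers_covered=sum(1 for g in genes_in_kers if covered(g)),
        provenance={"source": "synthetic-manifest"},
    )
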