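# Methods

## Data model and parsing

A knowledge-base dump is parsed into a typed dataset of key events (KEs),
key event relationships (KERs) and stressor–chemical records. The dialect is
the 1.0 dump schema: one declared XML namespace, read from the document root
rather than hard-coded, so quarterly dumps of different dates parse alike;
gzip input is sniffed by magic bytes. Chemical entities are referenced from
stressors by id, and each (stressor, chemical) pair yields one record — a
stressor without chemicals yields a single record with empty chemical
fields, so stressor counts are entity counts.

Every description field is normalized at parse time: HTML tags removed
(treated as word separators), character entities decoded, `[[…]]` wiki links
unwrapped to their labels, whitespace runs collapsed to single spaces. This
normalized plain text is the only substrate for downstream text matching, so
matching behaviour does not depend on markup idiosyncrasies. KER endpoints
that do not resolve to a parsed KE are recorded in an unresolved-references
list, never silently dropped; duplicate KE identifiers are a parse error.

Biological levels are matched case-insensitively against the six-member
enum; an absent or unknown level maps to `unspecified` with a logged
warning. The in-scope set for all linkage statistics is {molecular,
cellular, tissue, organ}: events at the individual and population levels do
not describe molecular biology a pathway database could cover. A KER is in
scope iff both endpoints resolve to in-scope KEs.

Ontology annotations keep their component (biological process, biological
object, cell term, organ term) and derive their source code
deterministically from the term-id prefix (GO, CHEBI, PR, MI, CL, UBERON,
FMA, VT, HP, MP, WIKI, MESH); unrecognized prefixes become `OTHER` rather
than being discarded, so the audit reports the full annotation landscape.
The usage table counts, per (level, component, source), KEs with at least
one matching annotation — a KE annotated twice from one source counts once —
plus an `UNANNOTATED` row per (level, component).

## Hard linkage: CAS → ChEBI → pathways

CAS registry numbers are validated syntactically (2–7 digits, 2 digits,
1 check digit) and against the mod-10 weighted checksum: with digits
numbered right to left excluding the check digit, check = (Σᵢ i·dᵢ) mod 10.
Validation is diagnostic only: numbers with a failing checksum are still
looked up (with a warning), because there is no evidence the upstream
curation filtered on checksums. Mapping is a table join against any
two-column `cas`/`chebi` TSV (BridgeDb-style exports, Wikidata dumps and
synthetic fixtures are interchangeable) rather than a live service call, so
the stage is hermetic and testable offline. Rows with malformed CAS or
non-ChEBI values are skipped and counted. All counts are over unique CAS and
unique ChEBI ids, not stressor multiplicity.

Because the natural denominator for "fraction of chemicals found in
pathways" is contested (per ChEBI id, per CAS number, per mapped CAS), the
report's raw block exposes all three ratios side by side instead of choosing
one.

## Soft linkage: dictionary-based gene recognition

The lexicon is compiled from an HGNC-style table (hgnc_id, approved symbol,
approved name, previous symbols, synonyms, Ensembl id; multi-valued columns
comma- or pipe-separated). Matching rules, chosen where the upstream method
description is silent and logged as explicit policy:

* tokenization on transitions between word characters (letters, digits,
  hyphen) and everything else, so `IL-6` is one token;
* symbol-class forms — approved symbols, previous symbols, single-token
  synonyms — match case-sensitively as whole tokens. This suppresses the
  English-word false positives (CAT, SET, MET as lowercase words) that
  dominate error analyses of dictionary NER;
* multi-token forms — approved names, multi-word synonyms — match
  case-insensitively as whole-token sequences;
* overlap resolution is longest-match-first, ties broken by leftmost start,
  then by form-class priority approved symbol > previous symbol > synonym >
  approved name; a matched span is consumed (no nested matches);
* single-character forms are dropped (alphabet-letter false positives);
* a surface form claimed by several genes emits one mention per claiming
  gene, flagged ambiguous — no disambiguation is attempted, and per-document
  gene sets include every claimant.

Gene counting is by unique gene id (not mention count, not per-document
multiplicity). For KERs the three text fields (description, biological
plausibility, empirical support) are searched independently and unioned.

## Pathway membership and coverage

The pathway database loads from a flat membership TSV or a directory of GPML
2013a documents (other GPML dialects are rejected with a clear message; the
2013a document carries no pathway identifier, so it is taken from the file
stem). GeneProduct/Protein data nodes contribute gene xrefs — Ensembl and
HGNC databases normalized, everything else kept as OTHER; Metabolite nodes
with ChEBI xrefs contribute metabolite xrefs; BioPAX open-controlled-
vocabulary terms contribute ontology tags keyed by prefix (PW, CL, DO/DOID).

A gene is covered iff any of its identifiers — HGNC id, approved symbol, or
Ensembl id — appears among any pathway's gene xrefs. Namespace bridging runs
through the lexicon (single source of truth) rather than a second mapping
service, and the coverage result records which namespaces produced each hit.
The coverage fraction is null (not zero) for an empty query set.

For verification against RDF infrastructure, the same membership question is
rendered as SPARQL over the WikiPathways vocabulary (`wp:bdbHgncSymbol`,
`wp:bdbHgnc`, `wp:bdbEnsembl`, `wp:bdbChEBI`, `dcterms:isPartOf`), with a
sorted VALUES clause so the query string is byte-reproducible. Queries are
executed in-process with rdflib against the bundle's Turtle rendering; the
tests require set equality of (pathway, id) pairs with the direct table
lookup. Remote endpoint execution exists behind an explicit opt-in and is
never exercised by the tests.

## Coverage report

The report stores raw counts only; percents are properties recomputed on
serialization with half-up integer rounding (296/417 → 71), never stored,
and raw fractions are kept in a `raw` block. Serialized JSON validates
against the schema shipped in `aoplink/schemas/`; a compact internal
validator covers the schema subset used (types, required keys, enum/anyOf,
minimum). Covered counts are bounded by their identified counterparts at
construction time. The builder wraps stage failures in a `StageError` naming
the failing stage.

## Synthetic fixtures and the oracle

The generator emits, from one integer seed, a complete bundle — dump XML,
lexicon TSV, CAS→ChEBI TSV, pathway TSV + GPML per pathway + Turtle — plus a
manifest of everything planted. Design choices:

* **Scale.** Defaults are a ~1/25-scale image of a real quarterly dump:
  32 in-scope KEs across six levels (plus individual/population events that
  must be filtered out), 20 KERs (some deliberately touching out-of-scope
  KEs), a 60-gene lexicon, 30 stressors sharing ~21 chemicals, 90% of CAS
  numbers valid and 90% mappable at 2 ChEBI ids each, 15 pathways, a 0.7
  gene-coverage target and a 0.16 metabolite-coverage target. These mirror
  the empirical shape of the linkage problem (near-complete CAS mapping, low
  metabolite coverage, ~70% gene coverage) at a size where the whole suite
  runs in seconds.
* **Certified decoys.** Planted gene forms are embedded in decoy prose built
  from a vocabulary strictly disjoint from the name vocabulary, and symbols
  are uppercase-with-digit tokens that the case-sensitivity rule cannot
  confuse with prose. After assembling each text the generator runs the
  recognizer and requires recovered == planted (up to the legitimate extra
  claimants of an ambiguous form), re-drawing forms on a collision — so
  manifests are exact, and planted-recovery precision/recall of 1.0 is a
  meaningful statement about the matcher, not luck.
* **Exact targets.** Coverage targets are enforced by construction: exactly
  round(target · n) of the planted KE genes (and, separately, of the
  KER-only genes) are placed in pathways, each under a randomly chosen
  namespace; exactly round(target · n) of the planted ChEBI ids appear as
  pathway metabolites. Filler xrefs use reserved shapes that cannot collide
  with lexicon identifiers.
* **Checksum-true CAS.** Valid CAS numbers are synthesized digit-wise with
  the checksum formula; invalid ones get an off-by-one check digit, so the
  valid/invalid split is exact.
* **Determinism.** All randomness flows from one `random.Random(seed)`; all
  emitted files are written with deterministic ordering (sorted JSON keys,
  manual Turtle lines, fixed TSV ordering), so identical seed + config yield
  byte-identical bundles.
* `expected_report` recomputes every report field by brute-force counting
  over the manifest dicts, sharing no code path with the pipeline; the
  central test asserts pipeline == oracle field-for-field over 20 randomized
  configurations.

What the generator does **not** emulate: realistic biological prose (decoy
sentences are a fixed pool), the full breadth of the real dump schema (only
elements the parser consumes), species ambiguity, non-human orthologs,
OCR-style noise in text, or the long-tailed pathway-size distribution of a
real database. Passing the oracle tests therefore demonstrates correctness
of the pipeline's logic under controlled conditions, not the field accuracy
of dictionary NER on curated free text — on real descriptions, ambiguity and
vocabulary drift will add false positives and negatives the synthetic
fixtures deliberately exclude.

## Numerical and edge-case conventions

Half-up decimal rounding for integer percents; fractions over empty
denominators are null, never zero. Empty level sets are rejected as
ambiguous intent; empty datasets yield all-zero summaries. Mapper lookups of
absent keys return empty sets. Mention offsets are 0-based half-open into
the normalized text. The full-scale snapshot reproduction (hundreds of KEs,
thousands of lexicon rows) is exercised only when the archived external
inputs are present locally; the shipped suite runs entirely on generated
fixtures, with problem sizes as above.

## Known limitations

* Dictionary NER has no disambiguation; ambiguous forms over-count by
  design and are flagged rather than resolved.
* Multi-token matching ignores intervening punctuation (token sequences are
  matched across sentence boundaries); the generator's self-check makes this
  harmless in fixtures, but on real text it can create rare spurious
  multi-word matches.
* The GPML reader targets the 2013a dialect only and reads gene/metabolite
  xrefs and ontology tags, not graphics, groups or interactions.
* CAS→ChEBI mapping quality is wholly inherited from the supplied table; no
  structure-based reconciliation is attempted.
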