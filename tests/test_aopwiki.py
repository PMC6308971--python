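"""Dump parsing, level filtering, chemical extraction, ontology audit."""

import gzip

import pytest

from aoplink import (
    BiologicalLevel,
    IN_SCOPE_LEVELS,
    ParseError,
    extract_chemicals,
    filter_key_events,
    ontology_usage_summary,
    parse_aopwiki_xml,
)
from aoplink.aopwiki import UNANNOTATED, in_scope_kers, ontology_source_from_term

from conftest import make_dump

THREE_ENTITY_BODY = """
<chemical id="c1"><casrn>50-00-0</casrn><preferred-name>formaldehyde</preferred-name></chemical>
<stressor id="s1"><name>Formaldehyde</name>
  <chemicals><chemical-initiator chemical-id="c1"/></chemicals></stressor>
<key-event id="ke1"><title>Oxidative stress</title>
  <biological-organization-level>Molecular</biological-organization-level>
  <description>&lt;p&gt;Reactive   species increase.&lt;/p&gt;</description>
  <biological-process source="GO" source-id="GO:0006979" name="response to oxidative stress"/>
</key-event>
<key-event id="ke2"><title>Cell death</title>
  <biological-organization-level>Cellular</biological-organization-level>
  <description></description>
</key-event>
<key-event id="ke3"><title>Population decline</title>
  <biological-organization-level>Population</biological-organization-level>
</key-event>
<key-event-relationship id="ker1">
  <title><upstream-id>ke1</upstream-id><downstream-id>ke2</downstream-id></title>
  <description>leads to</description>
  <weight-of-evidence>
    <biological-plausibility>strong</biological-plausibility>
    <empirical-support-linkage>moderate</empirical-support-linkage>
  </weight-of-evidence>
</key-event-relationship>
<key-event-relationship id="ker2">
  <title><upstream-id>ke2</upstream-id><downstream-id>ke3</downstream-id></title>
</key-event-relationship>
"""


@pytest.fixture
def small_dataset(write_dump):
    return parse_aopwiki_xml(write_dump(THREE_ENTITY_BODY))


class TestParsing:
    def test_entity_counts(self, small_dataset):
        assert len(small_dataset.key_events) == 3
        assert len(small_dataset.kers) == 2
        assert len(small_dataset.stressors) == 1

    def test_empty_dump_has_empty_collections(self, write_dump):
        ds = parse_aopwiki_xml(write_dump(""))
        assert ds.key_events == [] and ds.kers == [] and ds.stressors == []

    def test_markup_stripped_and_whitespace_normalized(self, small_dataset):
        ke = small_dataset.key_event_index()["ke1"]
        assert ke.description == "Reactive species increase."

    def test_absent_level_and_description_defaults(self, write_dump):
        ds = parse_aopwiki_xml(write_dump('<key-event id="k"><title>t</title></key-event>'))
        ke = ds.key_events[0]
        assert ke.level is BiologicalLevel.UNSPECIFIED
        assert ke.description == ""

    def test_unknown_level_string_maps_to_unspecified(self, write_dump):
        body = (
            '<key-event id="k"><biological-organization-level>Galactic'
            "</biological-organization-level></key-event>"
        )
        ds = parse_aopwiki_xml(write_dump(body))
        assert ds.key_events[0].level is BiologicalLevel.UNSPECIFIED

    def test_ker_text_fields_never_none(self, small_dataset):
        ker = next(k for k in small_dataset.kers if k.ker_id == "ker2")
        assert ker.description == ""
        assert ker.biological_plausibility == ""
        assert ker.empirical_support == ""

    def test_unresolved_ker_endpoint_recorded_not_dropped(self, write_dump):
        body = (
            '<key-event id="a"/><key-event-relationship id="r">'
            "<title><upstream-id>a</upstream-id><downstream-id>ghost</downstream-id></title>"
            "</key-event-relationship>"
        )
        ds = parse_aopwiki_xml(write_dump(body))
        assert len(ds.kers) == 1
        assert ("r", "ghost") in ds.unresolved_references

    def test_gzip_input_sniffed_by_magic_bytes(self, tmp_path):
        path = tmp_path / "dump.xml.gz"
        path.write_bytes(gzip.compress(make_dump(THREE_ENTITY_BODY).encode()))
        ds = parse_aopwiki_xml(path)
        assert len(ds.key_events) == 3

    def test_parse_is_deterministic(self, write_dump):
        path = write_dump(THREE_ENTITY_BODY)
        assert parse_aopwiki_xml(path) == parse_aopwiki_xml(path)


class TestParseErrors:
    def test_malformed_xml_names_location(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<data><unclosed></data>")
        with pytest.raises(ParseError, match=r"line"):
            parse_aopwiki_xml(path)

    def test_wrong_root_names_namespace(self, tmp_path):
        path = tmp_path / "wrong.xml"
        path.write_text('<pathway xmlns="http://other.example/ns"/>')
        with pytest.raises(ParseError, match="http://other.example/ns"):
            parse_aopwiki_xml(path)

    def test_missing_id_names_entity(self, write_dump):
        with pytest.raises(ParseError, match="key-event"):
            parse_aopwiki_xml(write_dump("<key-event><title>t</title></key-event>"))

    def test_duplicate_ke_id_rejected(self, write_dump):
        with pytest.raises(ParseError, match="duplicate"):
            parse_aopwiki_xml(write_dump('<key-event id="k"/><key-event id="k"/>'))


class TestFilterKeyEvents:
    def test_in_scope_filter(self, small_dataset):
        kept = filter_key_events(small_dataset, IN_SCOPE_LEVELS)
        assert [ke.ke_id for ke in kept] == ["ke1", "ke2"]

    def test_all_levels_is_identity(self, small_dataset):
        all_levels = set(BiologicalLevel) - {BiologicalLevel.UNSPECIFIED}
        kept = filter_key_events(small_dataset, all_levels)
        assert kept == small_dataset.key_events

    def test_empty_level_set_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            filter_key_events(small_dataset, set())

    def test_in_scope_kers_requires_both_endpoints(self, small_dataset):
        assert [k.ker_id for k in in_scope_kers(small_dataset)] == ["ker1"]


class TestExtractChemicals:
    def test_shared_chemical_deduplicates(self, write_dump):
        body = """
        <chemical id="c"><casrn>50-00-0</casrn><preferred-name>formaldehyde</preferred-name></chemical>
        <stressor id="s1"><name>a</name><chemicals><chemical-initiator chemical-id="c"/></chemicals></stressor>
        <stressor id="s2"><name>b</name><chemicals><chemical-initiator chemical-id="c"/></chemicals></stressor>
        """
        summary = extract_chemicals(parse_aopwiki_xml(write_dump(body)))
        assert (summary.n_stressors, summary.n_unique_chemicals, summary.n_unique_cas) == (2, 1, 1)

    def test_chemical_without_cas_counted_in_chemicals_only(self, write_dump):
        body = """
        <chemical id="c"><preferred-name>mystery compound</preferred-name></chemical>
        <stressor id="s"><name>a</name><chemicals><chemical-initiator chemical-id="c"/></chemicals></stressor>
        """
        summary = extract_chemicals(parse_aopwiki_xml(write_dump(body)))
        assert (summary.n_unique_chemicals, summary.n_unique_cas) == (1, 0)

    def test_stressor_without_chemical_yields_empty_record(self, write_dump):
        body = '<stressor id="s"><name>bare</name></stressor>'
        summary = extract_chemicals(parse_aopwiki_xml(write_dump(body)))
        assert summary.n_stressors == 1
        assert summary.records[0].chemical_name == "" and summary.records[0].cas == ""

    def test_empty_dataset_gives_zeros(self, write_dump):
        summary = extract_chemicals(parse_aopwiki_xml(write_dump("")))
        assert (summary.n_stressors, summary.n_unique_chemicals, summary.n_unique_cas) == (0, 0, 0)


class TestOntologyUsage:
    def test_annotated_and_unannotated_partition(self, write_dump):
        body = """
        <key-event id="k1"><biological-organization-level>Molecular</biological-organization-level>
          <biological-process source="GO" source-id="GO:1" name="x"/></key-event>
        <key-event id="k2"><biological-organization-level>Molecular</biological-organization-level></key-event>
        """
        table = ontology_usage_summary(parse_aopwiki_xml(write_dump(body)))
        rows = table[(table.level == "molecular") & (table.component == "biological_process")]
        counts = dict(zip(rows.source, rows.n_key_events))
        assert counts == {"GO": 1, UNANNOTATED: 1}

    def test_two_sources_for_one_component_both_counted_once_per_ke(self, write_dump):
        body = """
        <key-event id="k"><biological-organization-level>Cellular</biological-organization-level>
          <biological-process source="GO" source-id="GO:1" name="x"/>
          <biological-process source="GO" source-id="GO:2" name="y"/>
          <biological-process source="WIKI" source-id="WIKI:3" name="z"/></key-event>
        """
        table = ontology_usage_summary(parse_aopwiki_xml(write_dump(body)))
        rows = table[(table.level == "cellular") & (table.component == "biological_process")]
        counts = dict(zip(rows.source, rows.n_key_events))
        # duplicate GO annotations count the key event once; both sources appear
        assert counts == {"GO": 1, "WIKI": 1}

    def test_unrecognized_prefix_becomes_other(self):
        assert ontology_source_from_term("GO:0006915") == "GO"
        assert ontology_source_from_term("XCUSTOM:1") == "OTHER"
        assert ontology_source_from_term("") == "OTHER"

    def test_row_sums_match_level_population(self, loaded42):
        dataset, manifest = loaded42["dataset"], loaded42["manifest"]
        table = ontology_usage_summary(dataset)
        in_scope = {"molecular", "cellular", "tissue", "organ"}
        ke_per_level = {
            lvl: sum(1 for k in manifest["key_events"] if k["level"] == lvl) for lvl in in_scope
        }
        for (level, component), group in table.groupby(["level", "component"]):
            annotated_kes = {
                k["ke_id"]
                for k in manifest["key_events"]
                if k["level"] == level and any(a["component"] == component for a in k["annotations"])
            }
            unannotated = int(
                group[group.source == UNANNOTATED].n_key_events.sum()
            )
            assert unannotated == ke_per_level[level] - len(annotated_kes)

    def test_summary_matches_generator_manifest(self, loaded42):
        """Every (level, component, source) tally equals the planted annotation mix."""
        dataset, manifest = loaded42["dataset"], loaded42["manifest"]
        table = ontology_usage_summary(dataset)
        observed = {
            (r.level, r.component, r.source): r.n_key_events
            for r in table.itertuples(index=False)
            if r.source != UNANNOTATED
        }
        expected: dict[tuple, int] = {}
        for ke in manifest["key_events"]:
            if ke["level"] not in {"molecular", "cellular", "tissue", "organ"}:
                continue
            for comp_src in {(a["component"], a["source"]) for a in ke["annotations"]}:
                key = (ke["level"], comp_src[0], comp_src[1])
                expected[key] = expected.get(key, 0) + 1
        assert observed == expected
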