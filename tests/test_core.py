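"""Report model, IO dialects, deduplication, cumulative sets, 2x2 tables."""

from __future__ import annotations

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.core import (
    AmbiguousVersionError,
    CaseReport,
    DrugEntry,
    EventEntry,
    ReportSet,
    RowParseError,
    SchemaError,
    build_cumulative_sets,
    contingency_table,
    deduplicate_followups,
    first_report_year,
    observed_terms,
    read_reports,
    restrict_to_suspected,
    write_reports,
)

from conftest import make_report


class TestModelInvariants:
    def test_invalid_role_rejected(self):
        with pytest.raises(ValueError, match="role"):
            DrugEntry("drugA", "prescribed")

    @pytest.mark.parametrize("soc", [0, 33, -1])
    def test_soc_out_of_range_rejected(self, soc):
        with pytest.raises(ValueError, match="soc_code"):
            EventEntry("aeX", soc)

    def test_duplicate_event_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicate ae_term"):
            make_report("c1", events=(("aeX", 1), ("aeX", 2)))

    def test_report_needs_drugs_and_events(self):
        with pytest.raises(ValueError):
            make_report("c1", drugs=())
        with pytest.raises(ValueError):
            make_report("c1", events=())

    def test_reports_outside_window_rejected(self):
        with pytest.raises(ValueError, match="outside study window"):
            ReportSet([make_report("c1", year=2020)], year_range=(2009, 2018))


class TestGenericCsv:
    def test_round_trip_is_field_identical(self, tmp_path, four_report_set):
        path = tmp_path / "reports.csv"
        write_reports(four_report_set, path)
        back = read_reports(path, study_drug="drugA", comparator_drugs=["drugB"])
        assert back.reports == sorted(
            four_report_set.reports, key=lambda r: (r.case_id, r.version)
        )

    def test_rows_group_by_case(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "case_id,version,report_year,gender,age_group,serious,report_type,"
            "source_occupation,source_affiliation,drug_id,drug_role,ae_term,soc_code\n"
            "c1,1,2010,M,30-39,false,spontaneous,physician,manufacturer,dA,suspected,aeX,1\n"
            "c1,1,2010,M,30-39,false,spontaneous,physician,manufacturer,dA,suspected,aeY,2\n"
            "c2,1,2011,F,,true,pms,nurse,rpvc,dB,concomitant,aeX,1\n"
        )
        rs = read_reports(path)
        assert len(rs) == 2
        first, second = rs.reports
        assert first.ae_terms == {"aeX", "aeY"}
        assert first.gender == "male"
        assert second.gender == "female"
        assert second.age_group == "unknown"
        assert second.drugs[0].role == "concomitant"

    def test_unknown_report_type_maps_to_other_with_warning(self, tmp_path, caplog):
        path = tmp_path / "r.csv"
        path.write_text(
            "case_id,version,report_year,gender,age_group,serious,report_type,"
            "source_occupation,source_affiliation,drug_id,drug_role,ae_term,soc_code\n"
            "c1,1,2010,M,30-39,false,registry,physician,manufacturer,dA,suspected,aeX,1\n"
        )
        with caplog.at_level(logging.WARNING, logger="pvsignal"):
            rs = read_reports(path)
        assert rs.reports[0].report_type == "other"
        assert any("registry" in message for message in caplog.messages)

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("case_id,version\nc1,1\n")
        with pytest.raises(SchemaError, match="report_year"):
            read_reports(path)

    def test_unparseable_year_collected(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "case_id,version,report_year,gender,age_group,serious,report_type,"
            "source_occupation,source_affiliation,drug_id,drug_role,ae_term,soc_code\n"
            "c1,1,last year,M,30-39,false,spontaneous,physician,manufacturer,dA,suspected,aeX,1\n"
        )
        with pytest.raises(RowParseError):
            read_reports(path)

    def test_missing_version_defaults_to_one(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "case_id,version,report_year,gender,age_group,serious,report_type,"
            "source_occupation,source_affiliation,drug_id,drug_role,ae_term,soc_code\n"
            "c1,,2010,M,30-39,false,spontaneous,physician,manufacturer,dA,suspected,aeX,1\n"
        )
        assert read_reports(path).reports[0].version == 1


class TestFaersQuarter:
    def _write_quarter(self, directory):
        (directory / "DEMO24Q1.txt").write_text(
            "primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$occp_cod\n"
            "1001$501$2$20150316$45$YR$F$MD\n"
            "1002$502$1$20160210$700$MON$M$CN\n"
            "1003$503$1$20170101$30$YR$$OT\n"
        )
        (directory / "DRUG24Q1.txt").write_text(
            "primaryid$caseid$drug_seq$role_cod$drugname\n"
            "1001$501$1$PS$INFLIXIMAB\n"
            "1001$501$2$C$PREDNISONE\n"
            "1002$502$1$SS$METHOTREXATE\n"
            "1003$503$1$PS$INFLIXIMAB\n"
        )
        (directory / "REAC24Q1.txt").write_text(
            "primaryid$caseid$pt\n"
            "1001$501$Headache\n"
            "1001$501$Nausea\n"
            "1002$502$Rash\n"
            "1003$503$Headache\n"
        )

    def test_minimal_mapping(self, tmp_path):
        self._write_quarter(tmp_path)
        rs = read_reports(
            tmp_path, dialect="faers_quarter", soc_map={"headache": 4, "nausea": 6}
        )
        assert len(rs) == 3
        by_case = {r.case_id: r for r in rs.reports}
        r1 = by_case["501"]
        assert r1.version == 2
        assert r1.report_year == 2015
        assert r1.gender == "female"
        assert r1.age_group == "40-49"
        assert r1.source_occupation == "physician"
        assert {d.role for d in r1.drugs} == {"suspected", "concomitant"}
        assert {e.soc_code for e in r1.events} == {4, 6}
        # fields the dialect cannot carry take their residual values
        assert r1.report_type == "other" and r1.serious is False
        assert by_case["502"].age_group == "50-59"  # 700 months
        assert by_case["503"].gender == "unknown"

    def test_missing_drug_file_is_schema_error(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text("primaryid$caseid\n1$1\n")
        with pytest.raises(SchemaError, match="drug"):
            read_reports(tmp_path, dialect="faers_quarter")


class TestDeduplication:
    @pytest.mark.parametrize(
        "versions, survivor",
        [((1, 2), 2), ((3, 1, 2), 3), ((2, 3, 1), 3), ((1,), 1)],
    )
    def test_latest_version_survives(self, versions, survivor):
        reports = [make_report("c1", version=v) for v in versions]
        reports.append(make_report("c2", version=1))
        rs = deduplicate_followups(ReportSet(reports))
        assert {(r.case_id, r.version) for r in rs} == {("c1", survivor), ("c2", 1)}

    def test_idempotent_on_unique_sets(self, four_report_set):
        once = deduplicate_followups(four_report_set)
        assert deduplicate_followups(once).reports == once.reports

    def test_duplicate_case_version_is_ambiguous(self):
        reports = [make_report("c1", version=1), make_report("c1", version=1)]
        with pytest.raises(AmbiguousVersionError, match="c1"):
            deduplicate_followups(ReportSet(reports))

    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(1, 9)),
            min_size=1, max_size=30, unique=True,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_dedup_keeps_per_case_max_version(self, case_versions):
        reports = [
            make_report(f"c{c}", version=v) for c, v in case_versions
        ]
        rs = deduplicate_followups(ReportSet(reports))
        expected = {}
        for c, v in case_versions:
            expected[f"c{c}"] = max(expected.get(f"c{c}", 0), v)
        assert {(r.case_id, r.version) for r in rs} == set(expected.items())


class TestCumulativeSets:
    def test_sizes_are_cumulative_sums(self):
        reports = (
            [make_report(f"a{i}", year=2009) for i in range(5)]
            + [make_report(f"b{i}", year=2010) for i in range(3)]
            + [make_report(f"c{i}", year=2011) for i in range(2)]
        )
        sets = build_cumulative_sets(ReportSet(reports), 2009, 2011)
        assert [len(s) for s in sets] == [5, 8, 10]

    def test_ten_sets_for_a_ten_year_window(self, small_scenario):
        _, rs, _ = small_scenario
        rs = deduplicate_followups(rs)
        sets = build_cumulative_sets(rs, 2009, 2018)
        assert len(sets) == 10
        assert len(sets[-1]) == len(rs)

    def test_nesting_by_case_id(self, small_scenario):
        _, rs, _ = small_scenario
        sets = build_cumulative_sets(deduplicate_followups(rs), 2009, 2018)
        for earlier, later in zip(sets, sets[1:]):
            assert set(earlier.case_ids()) <= set(later.case_ids())

    def test_single_year_window_is_identity(self):
        rs = ReportSet([make_report("c1", year=2010)])
        sets = build_cumulative_sets(rs, 2010, 2010)
        assert len(sets) == 1 and sets[0].reports == rs.reports

    def test_out_of_window_reports_rejected(self):
        rs = ReportSet([make_report("c1", year=2012)])
        with pytest.raises(ValueError, match="outside"):
            build_cumulative_sets(rs, 2009, 2011)

    def test_empty_input_yields_empty_sets(self, caplog):
        with caplog.at_level(logging.WARNING, logger="pvsignal"):
            sets = build_cumulative_sets(ReportSet([]), 2009, 2011)
        assert [len(s) for s in sets] == [0, 0, 0]


class TestContingency:
    def test_exhaustive_four_report_example(self, four_report_set):
        ct = contingency_table(four_report_set, "drugA", "aeX")
        assert ct.as_tuple() == (1, 1, 1, 1)
        assert ct.N == len(four_report_set)

    def test_absent_term_has_empty_margin(self, four_report_set):
        ct = contingency_table(four_report_set, "drugA", "aeZ")
        assert ct.n11 == ct.n01 == 0
        assert ct.n10 + ct.n00 == ct.N

    def test_concomitant_listing_is_not_exposure(self):
        reports = [
            make_report("c1", drugs=(("drugA", "concomitant"), ("drugB", "suspected")),
                        events=(("aeX", 1),)),
            make_report("c2", drugs=(("drugA", "suspected"),), events=(("aeX", 1),)),
        ]
        rs = ReportSet(reports, study_drug="drugA", comparator_drugs=["drugB"])
        assert contingency_table(rs, "drugA", "aeX").as_tuple() == (1, 0, 1, 0)

    def test_unknown_drug_rejected(self, four_report_set):
        with pytest.raises(ValueError, match="drugC"):
            contingency_table(four_report_set, "drugC", "aeX")

    def test_cells_partition_every_universe(self, small_scenario):
        _, rs, _ = small_scenario
        rs = deduplicate_followups(rs)
        for term in observed_terms(rs)[:8]:
            assert contingency_table(rs, rs.study_drug, term).N == len(rs)


def test_restrict_to_suspected_builds_initial_dataset():
    keep = make_report("c1", drugs=(("drugA", "suspected"),))
    drop = make_report("c2", drugs=(("drugA", "concomitant"),))
    other = make_report("c3", drugs=(("drugC", "suspected"),))
    rs = restrict_to_suspected(ReportSet([keep, drop, other]), ["drugA", "drugB"])
    assert [r.case_id for r in rs] == ["c1"]


def test_first_report_year_respects_exposure():
    reports = [
        make_report("c1", year=2011, drugs=(("drugA", "concomitant"),)),
        make_report("c2", year=2013, drugs=(("drugA", "suspected"),)),
    ]
    rs = ReportSet(reports)
    assert first_report_year(rs, "aeX") == 2011
    assert first_report_year(rs, "aeX", "drugA") == 2013
    assert first_report_year(rs, "missing") is None
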