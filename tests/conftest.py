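"""Shared fixtures: hand-built report sets and a small synthetic study."""

from __future__ import annotations

import pytest

from pvsignal.core import CaseReport, DrugEntry, EventEntry, ReportSet
from pvsignal.reference import LabelHistory
from pvsignal.screening import ScreeningConfig, TermGroup, run_retrospective_screen
from pvsignal.simulate import (
    DEFAULT_CLASS_DRUGS,
    default_scenario,
    generate_label_history,
    generate_reports,
)


def make_report(
    case_id: str,
    version: int = 1,
    year: int = 2010,
    drugs=(("drugA", "suspected"),),
    events=(("aeX", 1),),
    gender: str = "male",
    age_group: str = "30-39",
    serious: bool = False,
    report_type: str = "spontaneous",
    occupation: str = "physician",
    affiliation: str = "manufacturer",
) -> CaseReport:
    """Terse constructor for hand-built reports."""
    return CaseReport(
        case_id=case_id,
        version=version,
        report_year=year,
        gender=gender,
        age_group=age_group,
        serious=serious,
        report_type=report_type,
        source_occupation=occupation,
        source_affiliation=affiliation,
        drugs=tuple(DrugEntry(d, r) for d, r in drugs),
        events=tuple(EventEntry(t, s) for t, s in events),
    )


@pytest.fixture
def four_report_set() -> ReportSet:
    """The exhaustively enumerable 2x2 example: one report per cell."""
    reports = [
        make_report("c1", drugs=(("drugA", "suspected"),), events=(("aeX", 1),)),
        make_report("c2", drugs=(("drugA", "suspected"),), events=(("aeY", 2),)),
        make_report("c3", drugs=(("drugB", "suspected"),), events=(("aeX", 1),)),
        make_report("c4", drugs=(("drugB", "suspected"),), events=(("aeY", 2),)),
    ]
    return ReportSet(reports, study_drug="drugA", comparator_drugs=["drugB"])


@pytest.fixture(scope="session")
def small_scenario():
    """Default synthetic scenario at reduced size, generated once."""
    cfg = default_scenario(seed=11, n_reports=4000)
    rs = generate_reports(cfg)
    lh = generate_label_history(cfg, DEFAULT_CLASS_DRUGS)
    return cfg, rs, lh


@pytest.fixture(scope="session")
def small_screen(small_scenario):
    """One full retrospective screen on the small scenario (shared)."""
    cfg, rs, lh = small_scenario
    targets = [
        TermGroup(s.ae_term, (s.ae_term,))
        for s in cfg.planted
        if s.label_update_year is not None
        and s.label_update_year > s.first_report_year
    ]
    screening_config = ScreeningConfig(seed=5, ic_samples=4000)
    timeline, screens = run_retrospective_screen(
        rs, lh, targets, cfg.year_range,
        config=screening_config,
        class_drugs=DEFAULT_CLASS_DRUGS,
        return_years=True,
    )
    return cfg, timeline, screens
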