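"""Data model and file IO for individual case safety reports (ICSRs).

Spontaneous reporting systems (SRS) such as KAERS and FAERS collect one
structured report per suspected drug-adverse-event occurrence.  A report
carries demographics and provenance (gender, age band, reporter occupation
and affiliation, report type, seriousness), one or more drugs each tagged
with a causality role (suspected / concomitant / drug-drug interaction),
and one or more coded adverse-event terms, each assigned to a system organ
class (SOC).

This module provides:

* the in-memory types :class:`DrugEntry`, :class:`EventEntry`,
  :class:`CaseReport`, :class:`ReportSet` and :class:`ContingencyTable`;
* readers/writers for the canonical ``generic_csv`` interchange layout
  (one row per report-drug-event triple) and a minimal reader for the
  FAERS quarterly ``$``-delimited ASCII layout (DEMO/DRUG/REAC);
* follow-up deduplication (keep the latest version of each case);
* cumulative yearly dataset construction for retrospective screening;
* 2x2 contingency extraction at report level.

Counting conventions
--------------------
A report is *exposed* to a drug iff the drug appears with role
``suspected``; concomitant and interaction listings never define exposure.
A report contributes exactly once to one cell of each pair's 2x2 table,
regardless of how many drug or event rows it spans in a file.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("pvsignal")

__all__ = [
    "DRUG_ROLES",
    "GENDERS",
    "AGE_GROUPS",
    "REPORT_TYPES",
    "OCCUPATIONS",
    "AFFILIATIONS",
    "GENERIC_CSV_COLUMNS",
    "DrugEntry",
    "EventEntry",
    "CaseReport",
    "ReportSet",
    "ContingencyTable",
    "SchemaError",
    "RowParseError",
    "AmbiguousVersionError",
    "read_reports",
    "write_reports",
    "deduplicate_followups",
    "restrict_to_suspected",
    "build_cumulative_sets",
    "contingency_table",
    "observed_terms",
    "first_report_year",
]

# ---------------------------------------------------------------------------
# Controlled vocabularies

DRUG_ROLES = ("suspected", "concomitant", "interaction")
GENDERS = ("male", "female", "unknown")
AGE_GROUPS = ("lt20", "20-29", "30-39", "40-49", "50-59", "60-69", "ge70", "unknown")
REPORT_TYPES = ("spontaneous", "pms", "literature", "other")
OCCUPATIONS = (
    "physician",
    "pharmacist",
    "nurse",
    "consumer",
    "health_professional",
    "other",
    "unknown",
)
AFFILIATIONS = (
    "rpvc",
    "manufacturer",
    "medical_institution",
    "pharmacy",
    "consumer",
    "other",
)

GENERIC_CSV_COLUMNS = (
    "case_id",
    "version",
    "report_year",
    "gender",
    "age_group",
    "serious",
    "report_type",
    "source_occupation",
    "source_affiliation",
    "drug_id",
    "drug_role",
    "ae_term",
    "soc_code",
)

N_SOC_CLASSES = 32


class SchemaError(ValueError):
    """A file does not conform to the declared dialect schema."""


class RowParseError(ValueError):
    """One or more rows of an input file could not be parsed."""

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(message)
        self.rows = list(rows)


class AmbiguousVersionError(ValueError):
    """The same (case_id, version) appears more than once."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class DrugEntry:
    """One drug listed on a report, with its causality role."""

    drug_id: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in DRUG_ROLES:
            raise ValueError(f"drug role {self.role!r} not in {DRUG_ROLES}")
        if not self.drug_id:
            raise ValueError("drug_id must be non-empty")


@dataclass(frozen=True)
class EventEntry:
    """One coded adverse-event term with its ordinal system-organ-class code."""

    ae_term: str
    soc_code: int

    def __post_init__(self) -> None:
        if not self.ae_term:
            raise ValueError("ae_term must be non-empty")
        if not 1 <= int(self.soc_code) <= N_SOC_CLASSES:
            raise ValueError(
                f"soc_code {self.soc_code!r} outside [1, {N_SOC_CLASSES}]"
            )


@dataclass(frozen=True)
class CaseReport:
    """One individual case safety report (one version of one case)."""

    case_id: str
    version: int
    report_year: int
    gender: str
    age_group: str
    serious: bool
    report_type: str
    source_occupation: str
    source_affiliation: str
    drugs: tuple[DrugEntry, ...]
    events: tuple[EventEntry, ...]

    def __post_init__(self) -> None:
        if self.version < 1:
            raise ValueError("version must be >= 1")
        if not self.drugs:
            raise ValueError("a report must list at least one drug")
        if not self.events:
            raise ValueError("a report must list at least one event")
        terms = [e.ae_term for e in self.events]
        if len(set(terms)) != len(terms):
            raise ValueError(f"duplicate ae_term within events of case {self.case_id}")
        for fieldname, value, allowed in (
            ("gender", self.gender, GENDERS),
            ("age_group", self.age_group, AGE_GROUPS),
            ("report_type", self.report_type, REPORT_TYPES),
            ("source_occupation", self.source_occupation, OCCUPATIONS),
            ("source_affiliation", self.source_affiliation, AFFILIATIONS),
        ):
            if value not in allowed:
                raise ValueError(f"{fieldname} {value!r} not in {allowed}")

    # -- convenience accessors -------------------------------------------

    @property
    def suspected_drugs(self) -> frozenset[str]:
        return frozenset(d.drug_id for d in self.drugs if d.role == "suspected")

    @property
    def ae_terms(self) -> frozenset[str]:
        return frozenset(e.ae_term for e in self.events)


@dataclass
class ReportSet:
    """A collection of case reports plus the study frame around them.

    ``study_drug`` / ``comparator_drugs`` name the exposure universe;
    ``year_range`` is the study window governing cumulative assignment.
    """

    reports: list[CaseReport]
    study_drug: str | None = None
    comparator_drugs: list[str] = field(default_factory=list)
    year_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.year_range is None and self.reports:
            years = [r.report_year for r in self.reports]
            self.year_range = (min(years), max(years))
        if self.year_range is not None and self.reports:
            lo, hi = self.year_range
            bad = [r.case_id for r in self.reports if not lo <= r.report_year <= hi]
            if bad:
                raise ValueError(
                    f"{len(bad)} report(s) outside study window {self.year_range}: "
                    f"{bad[:5]}"
                )

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[CaseReport]:
        return iter(self.reports)

    @property
    def drugs_of_interest(self) -> list[str]:
        out = [self.study_drug] if self.study_drug else []
        return out + list(self.comparator_drugs)

    def case_ids(self) -> list[str]:
        return [r.case_id for r in self.reports]

    def _with_reports(self, reports: list[CaseReport]) -> "ReportSet":
        return ReportSet(
            reports=reports,
            study_drug=self.study_drug,
            comparator_drugs=list(self.comparator_drugs),
            year_range=self.year_range,
        )


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 counts for one drug-AE pair.

    ``n11``: drug suspected and AE present; ``n10``: drug suspected, AE
    absent; ``n01``: AE present, drug not suspected; ``n00``: neither.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def N(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n10, self.n01, self.n00)


# ---------------------------------------------------------------------------
# Category normalization for ingestion

_GENDER_ALIASES = {
    "m": "male", "male": "male",
    "f": "female", "female": "female",
    "u": "unknown", "unk": "unknown", "unknown": "unknown", "": "unknown",
}
_AGE_ALIASES = {
    "lt20": "lt20", "<20": "lt20", "0-19": "lt20", "0-20": "lt20",
    "20-29": "20-29", "30-39": "30-39", "40-49": "40-49",
    "50-59": "50-59", "60-69": "60-69",
    "ge70": "ge70", ">=70": "ge70", "70+": "ge70", "≥70": "ge70",
    "unknown": "unknown", "unk": "unknown", "": "unknown",
}
_REPORT_TYPE_ALIASES = {
    "spontaneous": "spontaneous",
    "pms": "pms", "post-marketing surveillance": "pms",
    "post marketing surveillance": "pms",
    "literature": "literature",
    "other": "other", "others": "other", "": "other",
}
_OCCUPATION_ALIASES = {
    "physician": "physician", "md": "physician",
    "pharmacist": "pharmacist", "ph": "pharmacist",
    "nurse": "nurse", "rn": "nurse",
    "consumer": "consumer", "cn": "consumer",
    "health_professional": "health_professional",
    "healthcare professional": "health_professional",
    "health professional": "health_professional", "hp": "health_professional",
    "other": "other", "others": "other", "ot": "other",
    "unknown": "unknown", "unk": "unknown", "": "unknown",
}
_AFFILIATION_ALIASES = {
    "rpvc": "rpvc", "regional pharmacovigilance center": "rpvc",
    "manufacturer": "manufacturer",
    "medical_institution": "medical_institution",
    "medical institution": "medical_institution",
    "pharmacy": "pharmacy",
    "consumer": "consumer",
    "other": "other", "others": "other", "": "other",
}
_ROLE_ALIASES = {
    "suspected": "suspected", "suspect": "suspected", "ps": "suspected",
    "ss": "suspected",
    "concomitant": "concomitant", "c": "concomitant",
    "interaction": "interaction", "i": "interaction",
    "drug-drug interaction": "interaction",
}
_TRUE_TOKENS = {"true", "t", "1", "yes", "y", "serious"}
_FALSE_TOKENS = {"false", "f", "0", "no", "n", "", "not serious"}

# Unmapped tokens fall back to the field's residual category.
_FIELD_ALIASES: dict[str, tuple[Mapping[str, str], str]] = {
    "gender": (_GENDER_ALIASES, "unknown"),
    "age_group": (_AGE_ALIASES, "unknown"),
    "report_type": (_REPORT_TYPE_ALIASES, "other"),
    "source_occupation": (_OCCUPATION_ALIASES, "unknown"),
    "source_affiliation": (_AFFILIATION_ALIASES, "other"),
}


def _normalize_category(fieldname: str, raw: str, warn_counter: Counter) -> str:
    aliases, fallback = _FIELD_ALIASES[fieldname]
    token = str(raw).strip().lower()
    if token in aliases:
        return aliases[token]
    warn_counter[(fieldname, token)] += 1
    return fallback


def _parse_serious(raw: str) -> bool:
    token = str(raw).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ValueError(f"unparseable serious flag {raw!r}")


# ---------------------------------------------------------------------------
# generic_csv reader / writer


def read_reports(
    path: str | Path,
    dialect: str = "generic_csv",
    *,
    study_drug: str | None = None,
    comparator_drugs: Sequence[str] = (),
    year_range: tuple[int, int] | None = None,
    soc_map: Mapping[str, int] | None = None,
) -> ReportSet:
    """Read case reports from ``path``.

    ``dialect='generic_csv'`` expects one row per report-drug-event triple
    with the exact :data:`GENERIC_CSV_COLUMNS` header; rows sharing a
    ``(case_id, version)`` key are grouped into one report.
    ``dialect='faers_quarter'`` expects a directory holding ``$``-delimited
    quarterly ASCII files (DEMO*/DRUG*/REAC*); only the fields of
    :class:`CaseReport` are mapped and ``soc_map`` supplies per-term SOC
    ordinals (unmapped terms default to 1, logged).

    Categorical tokens are case-insensitive; unmapped categories map to the
    field's residual category (``unknown`` or ``other``) with a logged
    warning count.  A missing mandatory column raises :class:`SchemaError`;
    unparseable years/versions are collected and raised as
    :class:`RowParseError`.
    """
    path = Path(path)
    if dialect == "generic_csv":
        reports = _read_generic_csv(path)
    elif dialect == "faers_quarter":
        reports = _read_faers_quarter(path, soc_map or {})
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use generic_csv or faers_quarter")
    return ReportSet(
        reports=reports,
        study_drug=study_drug,
        comparator_drugs=list(comparator_drugs),
        year_range=year_range,
    )


def _read_generic_csv(path: Path) -> list[CaseReport]:
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in GENERIC_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"generic_csv file {path} missing column(s): {missing}")

    warn_counter: Counter = Counter()
    bad_rows: list[int] = []

    def _int_or_flag(raw: str, row: int, default: int | None = None) -> int | None:
        token = str(raw).strip()
        if token == "" and default is not None:
            return default
        try:
            return int(token)
        except ValueError:
            bad_rows.append(row)
            return None

    grouped: dict[tuple[str, int], dict] = {}
    for row_idx, row in enumerate(frame.itertuples(index=False), start=2):
        rec = row._asdict()
        version = _int_or_flag(rec["version"], row_idx, default=1)
        year = _int_or_flag(rec["report_year"], row_idx)
        soc = _int_or_flag(rec["soc_code"], row_idx)
        if version is None or year is None or soc is None:
            continue
        key = (str(rec["case_id"]).strip(), version)
        entry = grouped.setdefault(
            key,
            {
                "report_year": year,
                "gender": _normalize_category("gender", rec["gender"], warn_counter),
                "age_group": _normalize_category("age_group", rec["age_group"], warn_counter),
                "serious": _parse_serious(rec["serious"]),
                "report_type": _normalize_category("report_type", rec["report_type"], warn_counter),
                "source_occupation": _normalize_category(
                    "source_occupation", rec["source_occupation"], warn_counter
                ),
                "source_affiliation": _normalize_category(
                    "source_affiliation", rec["source_affiliation"], warn_counter
                ),
                "drugs": {},
                "events": {},
            },
        )
        role_token = str(rec["drug_role"]).strip().lower()
        if role_token not in _ROLE_ALIASES:
            bad_rows.append(row_idx)
            continue
        drug = DrugEntry(str(rec["drug_id"]).strip(), _ROLE_ALIASES[role_token])
        entry["drugs"][(drug.drug_id, drug.role)] = drug
        term = str(rec["ae_term"]).strip()
        if term and term not in entry["events"]:
            entry["events"][term] = EventEntry(term, soc)

    if bad_rows:
        raise RowParseError(
            f"{len(bad_rows)} unparseable row(s) in {path} "
            f"(file line numbers: {sorted(set(bad_rows))[:10]})",
            sorted(set(bad_rows)),
        )

    for (fieldname, token), count in warn_counter.items():
        logger.warning(
            "read_reports: %d row(s) with unmapped %s token %r mapped to residual category",
            count, fieldname, token,
        )

    reports = [
        CaseReport(
            case_id=case_id,
            version=version,
            report_year=entry["report_year"],
            gender=entry["gender"],
            age_group=entry["age_group"],
            serious=entry["serious"],
            report_type=entry["report_type"],
            source_occupation=entry["source_occupation"],
            source_affiliation=entry["source_affiliation"],
            drugs=tuple(entry["drugs"][k] for k in sorted(entry["drugs"])),
            events=tuple(entry["events"][k] for k in sorted(entry["events"])),
        )
        for (case_id, version), entry in grouped.items()
    ]
    reports.sort(key=lambda r: (r.case_id, r.version))
    logger.info("read_reports: parsed %d report(s) from %s", len(reports), path)
    return reports


def write_reports(rs: ReportSet, path: str | Path) -> None:
    """Write ``rs`` in the generic_csv layout (one row per report-drug-event).

    Row order is deterministic (sorted by case, version, drug, role, term)
    so identical report sets produce byte-identical files.
    """
    path = Path(path)
    rows = []
    for r in sorted(rs.reports, key=lambda r: (r.case_id, r.version)):
        for d in sorted(r.drugs, key=lambda d: (d.drug_id, d.role)):
            for e in sorted(r.events, key=lambda e: e.ae_term):
                rows.append(
                    (
                        r.case_id, r.version, r.report_year, r.gender, r.age_group,
                        "true" if r.serious else "false", r.report_type,
                        r.source_occupation, r.source_affiliation,
                        d.drug_id, d.role, e.ae_term, e.soc_code,
                    )
                )
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(GENERIC_CSV_COLUMNS)
        writer.writerows(rows)


# ---------------------------------------------------------------------------
# FAERS quarterly ASCII reader (minimal field mapping)

_FAERS_ROLE = {"PS": "suspected", "SS": "suspected", "C": "concomitant", "I": "interaction"}
_FAERS_OCC = {
    "MD": "physician", "PH": "pharmacist", "RN": "nurse", "CN": "consumer",
    "HP": "health_professional", "OT": "other", "LW": "other",
}


def _faers_age_group(age: str, age_cod: str) -> str:
    try:
        value = float(str(age).strip())
    except (TypeError, ValueError):
        return "unknown"
    code = str(age_cod).strip().upper()
    if code in ("", "YR"):
        years = value
    elif code == "MON":
        years = value / 12.0
    elif code == "DY":
        years = value / 365.25
    elif code == "DEC":
        years = value * 10.0
    else:
        return "unknown"
    if years < 20:
        return "lt20"
    for lo, hi, band in (
        (20, 30, "20-29"), (30, 40, "30-39"), (40, 50, "40-49"),
        (50, 60, "50-59"), (60, 70, "60-69"),
    ):
        if lo <= years < hi:
            return band
    return "ge70"


def _find_faers_file(directory: Path, prefix: str) -> Path:
    hits = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.name.lower().startswith(prefix)
    )
    if not hits:
        raise SchemaError(f"no {prefix.upper()}* file in {directory}")
    return hits[0]


def _read_faers_quarter(directory: Path, soc_map: Mapping[str, int]) -> list[CaseReport]:
    if not directory.is_dir():
        raise SchemaError(f"faers_quarter expects a directory, got {directory}")
    demo = pd.read_csv(_find_faers_file(directory, "demo"), sep="$", dtype=str,
                       keep_default_na=False, engine="python")
    drug = pd.read_csv(_find_faers_file(directory, "drug"), sep="$", dtype=str,
                       keep_default_na=False, engine="python")
    reac = pd.read_csv(_find_faers_file(directory, "reac"), sep="$", dtype=str,
                       keep_default_na=False, engine="python")
    demo.columns = [c.strip().lower() for c in demo.columns]
    drug.columns = [c.strip().lower() for c in drug.columns]
    reac.columns = [c.strip().lower() for c in reac.columns]
    for name, frame, needed in (
        ("DEMO", demo, ["primaryid"]),
        ("DRUG", drug, ["primaryid", "drugname", "role_cod"]),
        ("REAC", reac, ["primaryid", "pt"]),
    ):
        missing = [c for c in needed if c not in frame.columns]
        if missing:
            raise SchemaError(f"FAERS {name} file missing column(s): {missing}")

    drugs_by_id: dict[str, dict] = defaultdict(dict)
    for row in drug.itertuples(index=False):
        rec = row._asdict()
        role = _FAERS_ROLE.get(str(rec["role_cod"]).strip().upper())
        name = str(rec["drugname"]).strip().lower()
        if role and name:
            drugs_by_id[rec["primaryid"]][(name, role)] = DrugEntry(name, role)

    events_by_id: dict[str, dict] = defaultdict(dict)
    unmapped_soc: Counter = Counter()
    for row in reac.itertuples(index=False):
        rec = row._asdict()
        term = str(rec["pt"]).strip().lower()
        if not term:
            continue
        soc = soc_map.get(term)
        if soc is None:
            unmapped_soc[term] += 1
            soc = 1
        events_by_id[rec["primaryid"]].setdefault(term, EventEntry(term, soc))
    if unmapped_soc:
        logger.warning(
            "faers_quarter: %d term(s) without a SOC mapping defaulted to 1",
            len(unmapped_soc),
        )

    bad_rows: list[int] = []
    reports: list[CaseReport] = []
    warn_counter: Counter = Counter()
    for row_idx, row in enumerate(demo.itertuples(index=False), start=2):
        rec = row._asdict()
        pid = rec["primaryid"]
        if pid not in drugs_by_id or pid not in events_by_id:
            continue  # a valid ICSR needs at least one drug and one event
        date_token = ""
        for date_col in ("fda_dt", "rept_dt", "init_fda_dt", "event_dt"):
            if date_col in rec and str(rec[date_col]).strip():
                date_token = str(rec[date_col]).strip()
                break
        match = re.match(r"^(\d{4})", date_token)
        if not match:
            bad_rows.append(row_idx)
            continue
        year = int(match.group(1))
        try:
            version = int(str(rec.get("caseversion", "")).strip() or 1)
        except ValueError:
            version = 1
        occ_token = str(rec.get("occp_cod", "")).strip().upper()
        occupation = _FAERS_OCC.get(occ_token, "unknown")
        sex = str(rec.get("sex", rec.get("gndr_cod", ""))).strip().lower()
        gender = _GENDER_ALIASES.get(sex, "unknown")
        case_id = str(rec.get("caseid", "")).strip() or str(pid)
        reports.append(
            CaseReport(
                case_id=case_id,
                version=version,
                report_year=year,
                gender=gender,
                age_group=_faers_age_group(rec.get("age", ""), rec.get("age_cod", "")),
                serious=False,  # outcome files are out of scope for this dialect
                report_type="other",  # report type is not identifiable in FAERS
                source_occupation=occupation,
                source_affiliation="other",
                drugs=tuple(drugs_by_id[pid][k] for k in sorted(drugs_by_id[pid])),
                events=tuple(events_by_id[pid][k] for k in sorted(events_by_id[pid])),
            )
        )
    if bad_rows:
        raise RowParseError(
            f"{len(bad_rows)} DEMO row(s) without a parseable year", bad_rows
        )
    reports.sort(key=lambda r: (r.case_id, r.version))
    logger.info("faers_quarter: parsed %d report(s) from %s", len(reports), directory)
    return reports


# ---------------------------------------------------------------------------
# Study-scheme operations


def deduplicate_followups(rs: ReportSet) -> ReportSet:
    """Keep only the latest version of each case.

    Follow-up reports supersede their initial report; for every ``case_id``
    the report with the highest ``version`` survives.  Duplicate
    ``(case_id, version)`` keys raise :class:`AmbiguousVersionError`.
    """
    seen: Counter = Counter((r.case_id, r.version) for r in rs.reports)
    offenders = sorted(key for key, count in seen.items() if count > 1)
    if offenders:
        raise AmbiguousVersionError(
            f"duplicate (case_id, version) pairs: {offenders[:10]}"
        )
    latest: dict[str, CaseReport] = {}
    for report in rs.reports:
        held = latest.get(report.case_id)
        if held is None or report.version > held.version:
            latest[report.case_id] = report
    kept = sorted(latest.values(), key=lambda r: r.case_id)
    if len(kept) < len(rs.reports):
        logger.info(
            "deduplicate_followups: %d -> %d reports", len(rs.reports), len(kept)
        )
    return rs._with_reports(kept)


def restrict_to_suspected(rs: ReportSet, drugs: Sequence[str]) -> ReportSet:
    """Keep reports listing any of ``drugs`` with role suspected.

    This builds the screening "initial dataset": reports naming the study
    drug or a comparator as a suspected drug.
    """
    drugset = set(drugs)
    kept = [r for r in rs.reports if r.suspected_drugs & drugset]
    return rs._with_reports(kept)


def build_cumulative_sets(
    rs: ReportSet, start_year: int, end_year: int
) -> list[ReportSet]:
    """Nested cumulative yearly datasets: set ``k`` holds reports with
    ``report_year <= start_year + k``.

    A 2009-2018 window yields 10 sets, the screening design for a ten-year
    study period.
    """
    if start_year > end_year:
        raise ValueError("start_year must be <= end_year")
    outside = [
        r.case_id for r in rs.reports
        if not start_year <= r.report_year <= end_year
    ]
    if outside:
        raise ValueError(
            f"{len(outside)} report(s) outside [{start_year}, {end_year}]: {outside[:5]}"
        )
    if not rs.reports:
        logger.warning("build_cumulative_sets: empty input report set")
    sets = []
    for year in range(start_year, end_year + 1):
        subset = [r for r in rs.reports if r.report_year <= year]
        cum = rs._with_reports(subset)
        cum.year_range = (start_year, year)
        sets.append(cum)
    return sets


def contingency_table(rs: ReportSet, drug: str, ae_term: str) -> ContingencyTable:
    """Report-level 2x2 table for ``(drug, ae_term)`` over ``rs``.

    Exposure means the drug is listed with role suspected.  Each report
    lands in exactly one cell, so the four cells sum to ``len(rs)``.
    """
    if rs.drugs_of_interest and drug not in rs.drugs_of_interest:
        raise ValueError(
            f"drug {drug!r} is neither the study drug nor a comparator "
            f"({rs.drugs_of_interest})"
        )
    n11 = n10 = n01 = n00 = 0
    for report in rs.reports:
        exposed = drug in report.suspected_drugs
        outcome = ae_term in report.ae_terms
        if exposed and outcome:
            n11 += 1
        elif exposed:
            n10 += 1
        elif outcome:
            n01 += 1
        else:
            n00 += 1
    return ContingencyTable(n11, n10, n01, n00)


def observed_terms(rs: ReportSet) -> list[str]:
    """Sorted distinct AE terms appearing anywhere in ``rs``."""
    terms: set[str] = set()
    for report in rs.reports:
        terms.update(report.ae_terms)
    return sorted(terms)


def first_report_year(
    rs: ReportSet, ae_term: str, drug: str | None = None
) -> int | None:
    """Earliest ``report_year`` in which ``ae_term`` appears.

    With ``drug`` given, only reports listing that drug as suspected count
    (the pair's first appearance with the study drug).
    """
    years = [
        r.report_year
        for r in rs.reports
        if ae_term in r.ae_terms and (drug is None or drug in r.suspected_drugs)
    ]
    return min(years) if years else None
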