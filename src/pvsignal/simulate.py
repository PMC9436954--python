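"""Synthetic spontaneous-report streams with known ground truth.

The generator emulates the structure of a two-drug SRS extract: a study
drug and comparator(s), an AE vocabulary partitioned into at most 32
system organ classes, report covariates drawn from configurable marginal
distributions, *planted* drug-AE associations whose reporting rate on the
study drug is a known multiple of baseline, a label-update schedule, and
follow-up duplicate versions of some cases.

Because every association strength, onset year and label year is chosen by
the configuration, downstream stages (reference standard, features,
disproportionality, classifiers, screening) can be tested for parameter
recovery without access to restricted real data.

Sampling model, per report:

* report year, gender, age band, report type, occupation and affiliation
  are drawn independently from ``covariate_marginals``;
* the suspected drug is the study drug with probability ``p_study_drug``,
  otherwise a comparator (uniform over comparators);
* the number of events is ``1 + Poisson(extra_events_mean)``;
* event terms are drawn without replacement with probability proportional
  to ``baseline_rate``, multiplied by ``rate_multiplier`` when the report's
  suspected drug is the study drug, the term is planted, and the report
  year is at or past the signal's ``first_report_year``.  Planted terms
  have weight zero — on every drug — before their ``first_report_year``;
* the report is serious with probability ``max`` over its events of the
  per-term ``p_serious`` (falling back to ``p_serious_default``);
* with probability ``p_followup`` the case additionally emits a
  superseded version-1 report; the surviving version-2 duplicate may carry
  one extra event.

Weight renormalization means a planted multiplier of ``m`` yields a crude
reporting odds ratio slightly below ``m`` when planted terms make up a
non-negligible share of the study drug's total event weight; see the
methods note.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AFFILIATIONS,
    AGE_GROUPS,
    GENDERS,
    OCCUPATIONS,
    REPORT_TYPES,
    CaseReport,
    DrugEntry,
    EventEntry,
    ReportSet,
)
from .reference import LabelHistory

logger = logging.getLogger("pvsignal")

__all__ = [
    "AeTerm",
    "PlantedSignal",
    "GeneratorConfig",
    "DEFAULT_MARGINALS",
    "generate_reports",
    "generate_label_history",
    "planted_truth",
    "truth_table",
    "default_scenario",
    "null_scenario",
    "DEFAULT_CLASS_DRUGS",
]

# Covariate marginals of a published infliximab report series (n = 4482,
# Korea Adverse Event Reporting System, 2009-2018), re-derived from the
# printed category counts.  They are generator defaults, not assertions
# about any other dataset.
_N_TABLE = 4482
_COUNTS: dict[str, dict[str, int]] = {
    "gender": {"male": 2002, "female": 1929, "unknown": 551},
    "age_group": {
        "lt20": 413, "20-29": 486, "30-39": 735, "40-49": 650,
        "50-59": 666, "60-69": 449, "ge70": 233, "unknown": 850,
    },
    "report_year": {
        "2009": 16, "2010": 77, "2011": 136, "2012": 122, "2013": 264,
        "2014": 521, "2015": 631, "2016": 1608, "2017": 670, "2018": 437,
    },
    "report_type": {"spontaneous": 1244, "pms": 2718, "literature": 404, "other": 116},
    "source_occupation": {
        "physician": 3351, "pharmacist": 67, "nurse": 493, "consumer": 112,
        "health_professional": 6, "other": 80, "unknown": 373,
    },
    "source_affiliation": {
        "rpvc": 632, "manufacturer": 3733, "medical_institution": 37,
        "pharmacy": 1, "consumer": 0, "other": 79,
    },
}
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    fieldname: {cat: count / _N_TABLE for cat, count in cats.items()}
    for fieldname, cats in _COUNTS.items()
}
DEFAULT_P_SERIOUS = 1255 / _N_TABLE
DEFAULT_P_STUDY_DRUG = 4482 / 11376

DEFAULT_CLASS_DRUGS = ("etanercept", "adalimumab", "golimumab")

_FIELD_CATEGORIES = {
    "gender": GENDERS,
    "age_group": AGE_GROUPS,
    "report_type": REPORT_TYPES,
    "source_occupation": OCCUPATIONS,
    "source_affiliation": AFFILIATIONS,
}


@dataclass(frozen=True)
class AeTerm:
    """One vocabulary entry: term, SOC ordinal, baseline reporting weight."""

    term: str
    soc_code: int
    baseline_rate: float = 1.0
    p_serious: float | None = None


@dataclass(frozen=True)
class PlantedSignal:
    """A known drug-AE association injected into the stream.

    ``rate_multiplier`` scales the term's sampling weight on the study drug
    from ``first_report_year`` onward; ``label_update_year`` (if any) is
    the year the term joins the study drug's label.
    """

    ae_term: str
    rate_multiplier: float
    first_report_year: int
    label_update_year: int | None = None

    def __post_init__(self) -> None:
        if self.rate_multiplier <= 0:
            raise ValueError("rate_multiplier must be > 0")
        if (
            self.label_update_year is not None
            and self.label_update_year < self.first_report_year
        ):
            raise ValueError("label_update_year must be >= first_report_year")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic SRS stream."""

    n_reports: int
    year_range: tuple[int, int]
    ae_vocabulary: tuple[AeTerm, ...]
    planted: tuple[PlantedSignal, ...] = ()
    study_drug: str = "infliximab"
    comparator_drugs: tuple[str, ...] = ("methotrexate",)
    p_study_drug: float = DEFAULT_P_STUDY_DRUG
    covariate_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_MARGINALS
    )
    p_serious_default: float = DEFAULT_P_SERIOUS
    p_followup: float = 0.1
    extra_events_mean: float = 1.0
    baseline_labels: tuple[tuple[str, str, int], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if not self.ae_vocabulary:
            raise ValueError("ae_vocabulary must be non-empty")
        if not 0.0 <= self.p_study_drug <= 1.0:
            raise ValueError("p_study_drug must be in [0, 1]")
        if not 0.0 <= self.p_followup <= 1.0:
            raise ValueError("p_followup must be in [0, 1]")
        if self.extra_events_mean < 0:
            raise ValueError("extra_events_mean must be >= 0")
        terms = [a.term for a in self.ae_vocabulary]
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate terms in ae_vocabulary")
        for entry in self.ae_vocabulary:
            if entry.baseline_rate <= 0:
                raise ValueError(f"baseline_rate of {entry.term!r} must be > 0")
            if entry.p_serious is not None and not 0 <= entry.p_serious <= 1:
                raise ValueError(f"p_serious of {entry.term!r} must be in [0, 1]")
        vocab = set(terms)
        lo, hi = self.year_range
        for sig in self.planted:
            if sig.ae_term not in vocab:
                raise ValueError(f"planted term {sig.ae_term!r} not in vocabulary")
            if not lo <= sig.first_report_year <= hi:
                raise ValueError(
                    f"first_report_year of {sig.ae_term!r} outside window {self.year_range}"
                )
            if sig.label_update_year is not None and sig.label_update_year > hi:
                raise ValueError(
                    f"label_update_year of {sig.ae_term!r} past window end {hi}"
                )
        planted_terms = [s.ae_term for s in self.planted]
        if len(set(planted_terms)) != len(planted_terms):
            raise ValueError("duplicate planted terms")
        for fieldname, probs in self.covariate_marginals.items():
            total = float(sum(probs.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"covariate_marginals[{fieldname!r}] sums to {total}, not 1"
                )
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"negative probability in {fieldname!r} marginals")
            if fieldname == "report_year":
                years = {int(y) for y in probs}
                if not years <= set(range(lo, hi + 1)):
                    raise ValueError("report_year marginals outside year_range")
            elif fieldname in _FIELD_CATEGORIES:
                extra = set(probs) - set(_FIELD_CATEGORIES[fieldname])
                if extra:
                    raise ValueError(
                        f"unknown categories in {fieldname!r} marginals: {sorted(extra)}"
                    )
            else:
                raise ValueError(f"unknown covariate field {fieldname!r}")


def _marginal_arrays(
    probs: Mapping[str, float],
) -> tuple[np.ndarray, np.ndarray]:
    cats = np.array(sorted(probs), dtype=object)
    p = np.array([probs[str(c)] for c in cats], dtype=float)
    return cats, p / p.sum()


def _event_weights(
    cfg: GeneratorConfig,
    on_study_drug: bool,
    year: int,
    multipliers: np.ndarray,
    first_years: np.ndarray,
    base: np.ndarray,
) -> np.ndarray:
    w = base.copy()
    active = (first_years < 0) | (year >= first_years)  # -1 = never planted
    w[~active] = 0.0
    if on_study_drug:
        boost = active & (first_years >= 0)
        w[boost] *= multipliers[boost]
    return w


def generate_reports(config: GeneratorConfig) -> ReportSet:
    """Draw a full synthetic report stream (including superseded versions).

    Deterministic for a fixed config (seed included).  The returned set
    contains roughly ``n_reports * (1 + p_followup)`` reports; follow-up
    cases appear twice (version 1 and version 2) and are meant to be passed
    through :func:`pvsignal.core.deduplicate_followups`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    vocab = config.ae_vocabulary
    terms = np.array([a.term for a in vocab], dtype=object)
    socs = np.array([a.soc_code for a in vocab], dtype=int)
    base = np.array([a.baseline_rate for a in vocab], dtype=float)
    p_serious = np.array(
        [
            a.p_serious if a.p_serious is not None else config.p_serious_default
            for a in vocab
        ],
        dtype=float,
    )
    planted_by_term = {s.ae_term: s for s in config.planted}
    multipliers = np.array(
        [planted_by_term[t].rate_multiplier if t in planted_by_term else 1.0
         for t in terms],
        dtype=float,
    )
    first_years = np.array(
        [planted_by_term[t].first_report_year if t in planted_by_term else -1
         for t in terms],
        dtype=int,
    )

    year_cats, year_p = _marginal_arrays(config.covariate_marginals["report_year"])
    years = rng.choice(year_cats, size=n, p=year_p).astype(int)
    on_study = rng.random(n) < config.p_study_drug
    comp_idx = rng.integers(0, len(config.comparator_drugs), size=n)

    covariates: dict[str, np.ndarray] = {}
    for fieldname in (
        "gender", "age_group", "report_type",
        "source_occupation", "source_affiliation",
    ):
        cats, p = _marginal_arrays(config.covariate_marginals[fieldname])
        covariates[fieldname] = rng.choice(cats, size=n, p=p)

    n_events = 1 + rng.poisson(config.extra_events_mean, size=n)

    # Weighted sampling without replacement per report.  Reports sharing a
    # (drug-arm, year) stratum share a weight vector; within a stratum the
    # Efraimidis-Spirakis keys u**(1/w) rank terms, and each report keeps
    # its top n_events terms.
    event_idx: list[np.ndarray] = [np.empty(0, dtype=int)] * n
    strata: dict[tuple[bool, int], list[int]] = {}
    for i in range(n):
        strata.setdefault((bool(on_study[i]), int(years[i])), []).append(i)
    for (is_study, year) in sorted(strata, key=lambda k: (k[0], k[1])):
        rows = np.array(strata[(is_study, year)], dtype=int)
        w = _event_weights(config, is_study, year, multipliers, first_years, base)
        active = np.flatnonzero(w > 0)
        if active.size == 0:
            raise ValueError(f"no active vocabulary terms in year {year}")
        u = rng.random((rows.size, active.size))
        keys = u ** (1.0 / w[active])
        order = np.argsort(-keys, axis=1)
        for pos, i in enumerate(rows):
            k = min(int(n_events[i]), active.size)
            event_idx[i] = active[order[pos, :k]]

    max_p = np.array([p_serious[idx].max() for idx in event_idx])
    serious = rng.random(n) < max_p

    followup = rng.random(n) < config.p_followup
    extra_event_coin = rng.random(n) < 0.5

    reports: list[CaseReport] = []
    n_digits = max(6, len(str(n)))
    for i in range(n):
        drug_id = (
            config.study_drug if on_study[i]
            else config.comparator_drugs[comp_idx[i]]
        )
        base_events = tuple(
            EventEntry(str(terms[j]), int(socs[j])) for j in sorted(event_idx[i])
        )
        common = dict(
            case_id=f"c{i:0{n_digits}d}",
            report_year=int(years[i]),
            gender=str(covariates["gender"][i]),
            age_group=str(covariates["age_group"][i]),
            serious=bool(serious[i]),
            report_type=str(covariates["report_type"][i]),
            source_occupation=str(covariates["source_occupation"][i]),
            source_affiliation=str(covariates["source_affiliation"][i]),
            drugs=(DrugEntry(drug_id, "suspected"),),
        )
        if followup[i]:
            reports.append(CaseReport(version=1, events=base_events, **common))
            events_v2 = base_events
            if extra_event_coin[i]:
                w = _event_weights(
                    config, bool(on_study[i]), int(years[i]),
                    multipliers, first_years, base,
                )
                w[event_idx[i]] = 0.0
                if w.sum() > 0:
                    extra = int(rng.choice(len(vocab), p=w / w.sum()))
                    events_v2 = tuple(
                        sorted(
                            base_events + (EventEntry(str(terms[extra]), int(socs[extra])),),
                            key=lambda e: e.ae_term,
                        )
                    )
            reports.append(CaseReport(version=2, events=events_v2, **common))
        else:
            reports.append(CaseReport(version=1, events=base_events, **common))

    logger.info(
        "generate_reports: %d reports (%d follow-up cases) with seed %d",
        len(reports), int(followup.sum()), config.seed,
    )
    return ReportSet(
        reports=reports,
        study_drug=config.study_drug,
        comparator_drugs=list(config.comparator_drugs),
        year_range=config.year_range,
    )


def generate_label_history(
    config: GeneratorConfig, class_drugs: Sequence[str] = ()
) -> LabelHistory:
    """Label history implied by the configuration.

    Planted signals with a ``label_update_year`` appear for the study drug
    in that year; ``baseline_labels`` contributes explicit
    ``(drug, term, year)`` entries for the study drug and class drugs.
    """
    triples: list[tuple[str, str, int]] = list(config.baseline_labels)
    for sig in config.planted:
        if sig.label_update_year is not None:
            triples.append((config.study_drug, sig.ae_term, sig.label_update_year))
    known_drugs = {config.study_drug, *class_drugs}
    foreign = sorted({d for d, _, _ in triples} - known_drugs)
    if foreign and class_drugs:
        logger.warning(
            "generate_label_history: label entries for drugs outside the "
            "study/class set: %s", foreign,
        )
    return LabelHistory.from_entries(triples)


def planted_truth(config: GeneratorConfig) -> dict[str, bool]:
    """``{ae_term: is_true_signal}`` over the planted signals.

    A planted association is a true signal iff its rate multiplier
    exceeds 1.
    """
    return {s.ae_term: s.rate_multiplier > 1 for s in config.planted}


def truth_table(config: GeneratorConfig) -> dict[str, bool]:
    """Truth over the whole vocabulary (non-planted terms are null)."""
    truth = {a.term: False for a in config.ae_vocabulary}
    truth.update(planted_truth(config))
    return truth


# ---------------------------------------------------------------------------
# Canonical study conditions


def default_scenario(seed: int = 0, n_reports: int = 20_000) -> GeneratorConfig:
    """The package's reference synthetic study.

    Ten-year window (2009-2018), two drug arms, 40 AE terms:

    * ``ae01``-``ae10``: known associations — multiplier 10, reported and
      labeled from 2009 (the Y training pool);
    * ``ae11``-``ae20``: emerging signals — multiplier 10, first reported
      2011-2015, label update three years later (the early-detection
      targets, label lag >= 2 years).  They sit on a same-class drug's
      label from the window start — the typical situation for a class
      effect — so before their own label year they classify as U, the
      pool in which new signals are sought, rather than as spurious
      training negatives;
    * ``ae21``-``ae40``: null terms, multiplier 1, never on the study
      drug's label; ``ae39``/``ae40`` are listed for a class drug only and
      therefore classify as U rather than N;
    * ``ae41``-``ae45``: label-positive for the study drug from 2009 yet
      *not* enriched (multiplier 1) — the legacy label listings every real
      reference standard contains.  They keep the gold standard from being
      perfectly separable, which would otherwise push the AUROC-optimal
      signaling threshold to the extreme of the training scores.

    Planted terms carry ``p_serious`` 0.6 against the 0.28 baseline,
    reflecting that label-worthy reactions skew serious.
    """
    vocab = tuple(
        AeTerm(
            term=f"ae{i:02d}",
            soc_code=((i - 1) % 32) + 1,
            baseline_rate=1.0,
            p_serious=0.6 if i <= 20 else None,
        )
        for i in range(1, 46)
    )
    known = tuple(
        PlantedSignal(f"ae{i:02d}", 10.0, first_report_year=2009,
                      label_update_year=2009)
        for i in range(1, 11)
    )
    emerging_first = (2011, 2011, 2012, 2012, 2013, 2013, 2014, 2014, 2015, 2015)
    emerging = tuple(
        PlantedSignal(f"ae{i:02d}", 10.0, first_report_year=year,
                      label_update_year=year + 3)
        for i, year in zip(range(11, 21), emerging_first)
    )
    baseline_labels = tuple(
        (DEFAULT_CLASS_DRUGS[1], f"ae{i:02d}", 2009) for i in range(11, 21)
    ) + (
        (DEFAULT_CLASS_DRUGS[0], "ae39", 2009),
        (DEFAULT_CLASS_DRUGS[0], "ae40", 2009),
    ) + tuple(
        ("infliximab", f"ae{i:02d}", 2009) for i in range(41, 46)
    )
    return GeneratorConfig(
        n_reports=n_reports,
        year_range=(2009, 2018),
        ae_vocabulary=vocab,
        planted=known + emerging,
        baseline_labels=baseline_labels,
        seed=seed,
    )


def null_scenario(seed: int = 0, n_reports: int = 4_000) -> GeneratorConfig:
    """All-null calibration stream: same frame, no planted associations."""
    vocab = tuple(
        AeTerm(term=f"ae{i:02d}", soc_code=((i - 1) % 32) + 1)
        for i in range(1, 41)
    )
    return GeneratorConfig(
        n_reports=n_reports,
        year_range=(2009, 2018),
        ae_vocabulary=vocab,
        planted=(),
        seed=seed,
    )
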