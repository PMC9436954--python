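"""Retrospective cumulative-yearly screening for early safety signals.

For each cumulative yearly dataset the screen

1. classifies every observed drug-AE pair Y / N / U against the label
   history *as of that year* (no lookahead);
2. trains both ensemble classifiers on the Y/N gold standard (75/25
   split, SMOTE, fivefold stratified CV) and takes each classifier's
   AUROC-optimal probability as its threshold To;
3. scores the U (unknown) pairs with all four methods — classifier
   probabilities, the lower 95% ROR bound (To = 1) and the lower IC
   credible bound (To = 0);
4. puts every method on a common scale via the standardized difference
   d = (score - To) / SD, with SD the dispersion of that method's scores
   across all unknown pairs of the year; d > 0 declares a signal, which
   coincides with each method's native rule whenever SD > 0.

A signal is *early* when its first detection year strictly precedes the
AE's label-update year.  Pre-specified target AEs may be term groups
(clinically equivalent preferred terms): a group is detected in a year
iff any member is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ContingencyTable,
    ReportSet,
    build_cumulative_sets,
    contingency_table,
    deduplicate_followups,
    first_report_year,
)
from .dispro import (
    SeparationError,
    adjusted_ror,
    crude_ror,
    ic_credible_bounds,
)
from .features import FEATURE_COLUMNS, build_features
from .ml import (
    ALGORITHMS,
    score_pairs,
    split_gold_standard,
    tune_and_fit,
)
from .reference import LabelHistory, classification_map, classify_pairs

logger = logging.getLogger("pvsignal")

__all__ = [
    "METHODS",
    "ScreeningConfig",
    "MethodScore",
    "YearScreen",
    "TermGroup",
    "TimelineRow",
    "ScreeningTimeline",
    "standardized_difference",
    "group_terms",
    "screen_year",
    "run_retrospective_screen",
]

METHODS = ("gbm", "rf", "ror025", "ic_bound")


@dataclass(frozen=True)
class ScreeningConfig:
    """Knobs of the yearly screen (defaults mirror the study design)."""

    methods: tuple[str, ...] = METHODS
    train_fraction: float = 0.75
    folds: int = 5
    smote_k: int = 5
    grids: Mapping[str, Sequence[Mapping]] | None = None
    ror_covariates: tuple[str, ...] = ()
    ic_level: float = 0.025
    ic_samples: int = 20_000
    min_class_size: int = 2
    seed: int = 0

    def validate(self) -> None:
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown method(s) {unknown}; allowed {METHODS}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.ic_level not in (0.025, 0.05):
            raise ValueError("ic_level must be 0.025 or 0.05")


@dataclass(frozen=True)
class MethodScore:
    """One method's score for one unknown pair in one screening year."""

    method: str
    ae_term: str
    raw_score: float
    threshold: float
    sd_pool: float
    std_diff: float
    flagged: bool


@dataclass
class YearScreen:
    """Everything computed when screening one cumulative year."""

    year: int
    status: str  # "ok" or "skipped"
    reason: str = ""
    classes: dict[str, str] = field(default_factory=dict)
    scores: list[MethodScore] = field(default_factory=list)
    gold_scores: dict[str, dict[str, float]] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    test_pairs: tuple[str, ...] = ()
    models: dict = field(default_factory=dict)

    def flags_for(self, method: str) -> dict[str, bool]:
        return {
            s.ae_term: s.flagged for s in self.scores if s.method == method
        }


@dataclass(frozen=True)
class TermGroup:
    """A named set of clinically equivalent preferred terms."""

    name: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class TimelineRow:
    target: str
    method: str
    flags: tuple[tuple[int, bool | None], ...]  # (year, flagged/None)
    first_report_year: int | None
    first_detection_year: int | None
    label_update_year: int | None
    early: bool


@dataclass
class ScreeningTimeline:
    """Per-target, per-method detection history across cumulative years."""

    rows: list[TimelineRow]
    years: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            for year, flag in row.flags:
                records.append(
                    {
                        "target": row.target,
                        "method": row.method,
                        "year": year,
                        "flagged": flag,
                    }
                )
        return pd.DataFrame(records)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "target": row.target,
                    "method": row.method,
                    "first_report_year": row.first_report_year,
                    "first_detection_year": row.first_detection_year,
                    "label_update_year": row.label_update_year,
                    "early": row.early,
                }
                for row in self.rows
            ]
        )


def standardized_difference(raw: float, threshold: float, sd_pool: float) -> float:
    """d = (score - threshold) / SD on a method-comparable scale."""
    if sd_pool <= 0:
        raise ValueError("sd_pool must be > 0")
    return (raw - threshold) / sd_pool


def group_terms(target: str, members: Sequence[str]) -> TermGroup:
    """Bundle equivalent preferred terms under one target name."""
    if not members:
        raise ValueError(f"term group {target!r} has no members")
    return TermGroup(name=target, members=tuple(dict.fromkeys(members)))


def _ror_lower_bound(
    rs: ReportSet, drug: str, term: str, covariates: Sequence[str]
) -> float:
    ct = contingency_table(rs, drug, term)
    if not covariates:
        return crude_ror(ct).ci_low
    try:
        return adjusted_ror(rs, drug, term, covariates).ci_low
    except SeparationError:
        logger.warning(
            "screen: separation for (%s, %s); falling back to crude ROR",
            drug, term,
        )
        return crude_ror(ct).ci_low


def _native_threshold(method: str, model_thresholds: Mapping[str, float]) -> float:
    if method == "ror025":
        return 1.0
    if method == "ic_bound":
        return 0.0
    return model_thresholds[method]


def screen_year(
    cumulative_set: ReportSet,
    lh: LabelHistory,
    year: int,
    config: ScreeningConfig,
    class_drugs: Sequence[str],
) -> YearScreen:
    """Screen one cumulative dataset as of ``year``.

    Returns a populated :class:`YearScreen`; if the Y/N gold standard is
    too small to train, the year is skipped with an explicit reason.
    Scores are also recorded for the Y/N pairs (``gold_scores``) so the
    final year can be evaluated against the reference standard.
    """
    config.validate()
    study_drug = cumulative_set.study_drug
    if study_drug is None:
        raise ValueError("cumulative set must carry a study_drug")
    classes = classification_map(
        classify_pairs(cumulative_set, lh, study_drug, class_drugs, year)
    )
    y_terms = sorted(t for t, c in classes.items() if c == "Y")
    n_terms = sorted(t for t, c in classes.items() if c == "N")
    u_terms = sorted(t for t, c in classes.items() if c == "U")
    out = YearScreen(year=year, status="ok", classes=classes)
    if min(len(y_terms), len(n_terms)) < config.min_class_size:
        out.status = "skipped"
        out.reason = (
            f"gold standard too small to train: |Y|={len(y_terms)}, "
            f"|N|={len(n_terms)}"
        )
        logger.warning("screen_year %d: %s", year, out.reason)
        return out
    if not u_terms:
        logger.info("screen_year %d: no unknown pairs to screen", year)

    all_terms = y_terms + n_terms + u_terms
    feats = build_features(cumulative_set, all_terms, study_drug)
    gold_X = feats.loc[y_terms + n_terms]
    gold_y = np.array([classes[t] == "Y" for t in gold_X.index])

    split = split_gold_standard(
        gold_X, gold_y, fraction=config.train_fraction, seed=config.seed
    )
    out.test_pairs = split.test_pairs
    train_X = gold_X.loc[list(split.train_pairs)]
    train_y = np.array([classes[t] == "Y" for t in train_X.index])
    if min(int(train_y.sum()), int((~train_y).sum())) < 2:
        out.status = "skipped"
        out.reason = (
            f"training split too small to cross-validate: "
            f"|Y|={int(train_y.sum())}, |N|={int((~train_y).sum())}"
        )
        logger.warning("screen_year %d: %s", year, out.reason)
        return out

    raw: dict[str, dict[str, float]] = {m: {} for m in config.methods}
    grids = config.grids or {}
    for algo in (m for m in config.methods if m in ALGORITHMS):
        model = tune_and_fit(
            algo, train_X, train_y,
            folds=config.folds,
            grid=grids.get(algo),
            seed=config.seed,
            k_neighbors=config.smote_k,
        )
        out.models[algo] = model
        out.thresholds[algo] = model.threshold
        probs = score_pairs(model, feats)
        raw[algo] = {t: float(probs[t]) for t in all_terms}

    # contingency cells were already computed as the first four features
    tables = {
        t: ContingencyTable(
            *(int(feats.loc[t, c]) for c in ("n11", "n10", "n01", "n00"))
        )
        for t in all_terms
    }
    if "ror025" in config.methods:
        for t in all_terms:
            if config.ror_covariates:
                raw["ror025"][t] = _ror_lower_bound(
                    cumulative_set, study_drug, t, config.ror_covariates
                )
            else:
                raw["ror025"][t] = crude_ror(tables[t]).ci_low
    if "ic_bound" in config.methods:
        for t in all_terms:
            res = ic_credible_bounds(
                tables[t], n_samples=config.ic_samples, seed=config.seed
            )
            raw["ic_bound"][t] = res.ic025 if config.ic_level == 0.025 else res.ic05

    for method in config.methods:
        out.gold_scores[method] = {
            t: raw[method][t] for t in y_terms + n_terms if t in raw[method]
        }
        threshold = _native_threshold(method, out.thresholds)
        u_scores = np.array(
            [raw[method][t] for t in u_terms if np.isfinite(raw[method].get(t, np.nan))]
        )
        sd_pool = float(np.std(u_scores)) if u_scores.size else 0.0
        if u_terms and sd_pool <= 0:
            logger.warning(
                "screen_year %d: degenerate unknown-pair pool for %s "
                "(sd=0); falling back to the native flag rule",
                year, method,
            )
        for t in u_terms:
            score = raw[method].get(t, float("nan"))
            if not np.isfinite(score):
                out.scores.append(
                    MethodScore(method, t, score, threshold, sd_pool,
                                float("nan"), False)
                )
                continue
            if sd_pool > 0:
                d = standardized_difference(score, threshold, sd_pool)
                flagged = d > 0
            else:
                d = float("nan")
                flagged = score > threshold
            out.scores.append(
                MethodScore(method, t, float(score), threshold, sd_pool, d, flagged)
            )
    return out


def run_retrospective_screen(
    rs: ReportSet,
    lh: LabelHistory,
    targets: Sequence[TermGroup | str],
    window: tuple[int, int],
    config: ScreeningConfig = ScreeningConfig(),
    class_drugs: Sequence[str] = (),
    return_years: bool = False,
):
    """Full retrospective screen over nested cumulative yearly datasets.

    ``targets`` are AE terms or term groups whose detection history is
    assembled into a :class:`ScreeningTimeline`; a target is *early* when
    some member is flagged (while unknown) in a year strictly before the
    group's label-update year.  No year's computation sees reports filed
    after it.

    With ``return_years=True`` also returns the per-year
    :class:`YearScreen` list (the last "ok" year carries the material for
    performance evaluation).
    """
    rs = deduplicate_followups(rs)
    groups = [
        t if isinstance(t, TermGroup) else group_terms(t, [t]) for t in targets
    ]
    start, end = window
    cumulative = build_cumulative_sets(rs, start, end)
    years = tuple(range(start, end + 1))
    screens = [
        screen_year(cum, lh, year, config, class_drugs)
        for cum, year in zip(cumulative, years)
    ]

    study_drug = rs.study_drug
    rows: list[TimelineRow] = []
    for group in groups:
        frys = [
            y for y in (
                first_report_year(rs, m, study_drug) for m in group.members
            ) if y is not None
        ]
        fry = min(frys) if frys else None
        label_years = [
            y for y in (lh.label_year(study_drug, m) for m in group.members)
            if y is not None
        ]
        label_year = min(label_years) if label_years else None
        for method in config.methods:
            flags: list[tuple[int, bool | None]] = []
            detection_years: list[int] = []
            for screen in screens:
                member_flags = [
                    s.flagged for s in screen.scores
                    if s.method == method and s.ae_term in group.members
                ]
                if screen.status != "ok" or not member_flags:
                    flags.append((screen.year, None))
                    continue
                hit = any(member_flags)
                flags.append((screen.year, hit))
                if hit:
                    detection_years.append(screen.year)
            first_detection = min(detection_years) if detection_years else None
            early = first_detection is not None and (
                label_year is None or first_detection < label_year
            )
            rows.append(
                TimelineRow(
                    target=group.name,
                    method=method,
                    flags=tuple(flags),
                    first_report_year=fry,
                    first_detection_year=first_detection,
                    label_update_year=label_year,
                    early=early,
                )
            )
    timeline = ScreeningTimeline(rows=rows, years=years)
    return (timeline, screens) if return_years else timeline
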