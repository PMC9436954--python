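"""Disproportionality statistics on 2x2 tables and report-level data.

Conventional SRS signal detection asks whether a drug-AE pair is reported
more often than its margins predict.  This module implements:

* the crude reporting odds ratio (ROR) with a Wald 95% CI, applying the
  Haldane-Anscombe +0.5 correction to all four cells only when some cell
  is zero;
* the covariate-adjusted ROR via report-level logistic regression — the
  outcome is "report lists the AE", the exposure indicator is "report
  lists the drug as suspected", and the exponentiated exposure coefficient
  is the ROR.  Non-convergence and complete separation are surfaced as
  errors, never returned silently;
* the BCPNN information component IC = log2(Pxy / (Px Py)) with plug-in
  proportions, and lower credible bounds from a Monte-Carlo posterior:
  cell probabilities ~ Dirichlet(n + 1) (flat (1,1,1,1) prior), IC
  computed per draw, lower quantiles reported (IC025 = 2.5th percentile,
  IC05 = 5th).  A closed-form normal approximation in the tradition of the
  original BCPNN variance formula is available as an alternative backend;
* the flag rules: ROR signals iff ROR025 > 1, IC signals iff the chosen
  lower bound > 0 (both strict).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .core import ContingencyTable, ReportSet

logger = logging.getLogger("pvsignal")

__all__ = [
    "RorResult",
    "IcResult",
    "SeparationError",
    "ConvergenceError",
    "crude_ror",
    "adjusted_ror",
    "information_component",
    "ic_credible_bounds",
    "signal_flag_ror",
    "signal_flag_ic",
]

ADJUSTMENT_COVARIATES = (
    "report_year",
    "gender",
    "age_group",
    "report_type",
    "source_occupation",
    "source_affiliation",
    "serious",
)

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class SeparationError(RuntimeError):
    """Logistic fit failed due to complete or quasi-complete separation."""


class ConvergenceError(RuntimeError):
    """Logistic fit did not converge."""


@dataclass(frozen=True)
class RorResult:
    """A reporting odds ratio with its Wald 95% confidence bounds."""

    estimate: float
    ci_low: float
    ci_high: float
    adjusted: bool
    covariates_used: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")
        if self.ci_low <= 0:
            raise ValueError("odds-ratio scale values must be positive")


@dataclass(frozen=True)
class IcResult:
    """Information component with lower posterior credible bounds."""

    ic: float
    ic025: float
    ic05: float
    quantiles: tuple[tuple[float, float], ...]
    n_samples: int
    seed: int


def crude_ror(ct: ContingencyTable, correction: float = 0.5) -> RorResult:
    """Cross-product ROR with a Wald 95% CI.

    ``correction`` is added to all four cells iff any cell is zero
    (Haldane-Anscombe); an all-zero table is undefined.
    """
    if ct.N == 0:
        raise ValueError("ROR undefined for an all-zero table")
    cells = np.array(ct.as_tuple(), dtype=float)
    if (cells == 0).any():
        cells = cells + correction
    n11, n10, n01, n00 = cells
    estimate = (n11 * n00) / (n10 * n01)
    se = float(np.sqrt((1.0 / cells).sum()))
    log_est = float(np.log(estimate))
    return RorResult(
        estimate=float(estimate),
        ci_low=float(np.exp(log_est - _Z95 * se)),
        ci_high=float(np.exp(log_est + _Z95 * se)),
        adjusted=False,
    )


def _report_frame(rs: ReportSet, drug: str, ae_term: str) -> pd.DataFrame:
    rows = [
        {
            "outcome": int(ae_term in r.ae_terms),
            "exposed": int(drug in r.suspected_drugs),
            "report_year": r.report_year,
            "gender": r.gender,
            "age_group": r.age_group,
            "report_type": r.report_type,
            "source_occupation": r.source_occupation,
            "source_affiliation": r.source_affiliation,
            "serious": int(r.serious),
        }
        for r in rs.reports
    ]
    return pd.DataFrame(rows)


def adjusted_ror(
    rs: ReportSet,
    drug: str,
    ae_term: str,
    covariates: Sequence[str] = ADJUSTMENT_COVARIATES,
) -> RorResult:
    """Covariate-adjusted ROR by report-level multivariate logistic regression.

    Fits ``outcome ~ exposed + C(covariate) + ...`` over the deduplicated
    reports of ``rs`` and returns the exponentiated exposure coefficient
    with its Wald 95% CI.  With an empty covariate list this is the exact
    maximum-likelihood match of :func:`crude_ror` on tables without zero
    cells.
    """
    unknown = [c for c in covariates if c not in ADJUSTMENT_COVARIATES]
    if unknown:
        raise ValueError(
            f"unknown covariate(s) {unknown}; allowed: {ADJUSTMENT_COVARIATES}"
        )
    frame = _report_frame(rs, drug, ae_term)
    if frame["outcome"].nunique() < 2:
        raise ValueError(
            f"outcome {ae_term!r} does not vary in the report universe"
        )
    if frame["exposed"].nunique() < 2:
        raise ValueError(f"exposure {drug!r} does not vary in the report universe")
    terms = ["exposed"] + [f"C({c})" for c in covariates]
    formula = "outcome ~ " + " + ".join(terms)
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            result = smf.logit(formula, data=frame).fit(disp=0, maxiter=200)
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError,
        ) as err:
            ct = (
                int(((frame.exposed == 1) & (frame.outcome == 1)).sum()),
                int(((frame.exposed == 1) & (frame.outcome == 0)).sum()),
                int(((frame.exposed == 0) & (frame.outcome == 1)).sum()),
                int(((frame.exposed == 0) & (frame.outcome == 0)).sum()),
            )
            raise SeparationError(
                f"separation fitting adjusted ROR for ({drug}, {ae_term}); "
                f"2x2 cells (n11, n10, n01, n00) = {ct}"
            ) from err
    if not result.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"adjusted ROR fit for ({drug}, {ae_term}) did not converge"
        )
    beta = float(result.params["exposed"])
    se = float(result.bse["exposed"])
    return RorResult(
        estimate=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        adjusted=bool(covariates),
        covariates_used=tuple(covariates),
    )


def information_component(ct: ContingencyTable) -> float:
    """Plug-in IC = log2( (n11/N) / ((n11+n10)/N * (n11+n01)/N) ).

    Exactly 0 at independence; invariant to scaling all four cells;
    undefined (error) when ``n11`` is zero.
    """
    if ct.n11 < 1:
        raise ValueError("IC undefined at maximum likelihood when n11 = 0")
    n = ct.N
    pxy = ct.n11 / n
    px = (ct.n11 + ct.n10) / n
    py = (ct.n11 + ct.n01) / n
    return float(np.log2(pxy / (px * py)))


def _ic_normal_approx(
    ct: ContingencyTable, levels: Sequence[float]
) -> dict[float, float]:
    """Closed-form BCPNN bounds (normal approximation on the IC posterior).

    Uses the classical BCPNN prior moments: gamma11 = alpha1 = beta1 = 1,
    alpha = beta = 2, gamma tuned so the prior IC expectation is zero.
    """
    n11, n10, n01, n00 = ct.as_tuple()
    n = ct.N
    nx = n11 + n10
    ny = n11 + n01
    a1 = b1 = g11 = 1.0
    a = b = 2.0
    g = g11 * (n + a) * (n + b) / ((nx + a1) * (ny + b1))
    e_ic = np.log2(
        (n11 + g11) * (n + a) * (n + b) / ((n + g) * (nx + a1) * (ny + b1))
    )
    ln2sq = np.log(2.0) ** 2
    v_ic = (
        (n - n11 + g - g11) / ((n11 + g11) * (1 + n + g))
        + (n - nx + a - a1) / ((nx + a1) * (1 + n + a))
        + (n - ny + b - b1) / ((ny + b1) * (1 + n + b))
    ) / ln2sq
    sd = float(np.sqrt(v_ic))
    return {lv: float(e_ic + stats.norm.ppf(lv) * sd) for lv in levels}


def ic_credible_bounds(
    ct: ContingencyTable,
    levels: Sequence[float] = (0.025, 0.05),
    n_samples: int = 20_000,
    seed: int = 0,
    backend: str = "dirichlet",
) -> IcResult:
    """Lower credible bounds of the IC posterior.

    ``backend='dirichlet'`` (default): draw cell-probability vectors from
    Dirichlet(n11+1, n10+1, n01+1, n00+1) — the flat-prior posterior over
    the four cells — compute the IC per draw and return the requested
    lower quantiles; deterministic for a fixed ``seed``.
    ``backend='normal'``: the closed-form BCPNN normal approximation.

    The ``ic`` field is the plug-in IC when ``n11 >= 1`` and NaN otherwise
    (the bounds remain defined through the prior).
    """
    for lv in levels:
        if not 0.0 < lv < 1.0:
            raise ValueError(f"credible level {lv} outside (0, 1)")
    if n_samples < 1000:
        logger.warning(
            "ic_credible_bounds: n_samples=%d is low; quantiles will be noisy",
            n_samples,
        )
    want = sorted(set(levels) | {0.025, 0.05})
    if backend == "dirichlet":
        rng = np.random.default_rng(seed)
        alpha = np.array(ct.as_tuple(), dtype=float) + 1.0
        draws = rng.dirichlet(alpha, size=n_samples)
        p11 = draws[:, 0]
        px = draws[:, 0] + draws[:, 1]
        py = draws[:, 0] + draws[:, 2]
        ic_draws = np.log2(p11 / (px * py))
        q = {lv: float(np.quantile(ic_draws, lv)) for lv in want}
    elif backend == "normal":
        q = _ic_normal_approx(ct, want)
    else:
        raise ValueError(f"unknown backend {backend!r}; use dirichlet or normal")
    plug_in = information_component(ct) if ct.n11 >= 1 else float("nan")
    return IcResult(
        ic=plug_in,
        ic025=q[0.025],
        ic05=q[0.05],
        quantiles=tuple(sorted((lv, q[lv]) for lv in levels)),
        n_samples=n_samples,
        seed=seed,
    )


def signal_flag_ror(r: RorResult) -> bool:
    """Signal iff the lower 95% bound of the ROR exceeds 1 (strict)."""
    return r.ci_low > 1.0


def signal_flag_ic(bound: float) -> bool:
    """Signal iff the lower IC credible bound exceeds 0 (strict)."""
    return bool(np.isfinite(bound)) and bound > 0.0
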