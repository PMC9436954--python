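"""Per drug-AE-pair feature vectors for the supervised classifiers.

Each (study drug, AE term) pair is summarized by exactly 35 real-valued
features in three blocks:

* statistical — the four report-level 2x2 contingency cells
  ``n11, n10, n01, n00``;
* organ-specific — the term's system-organ-class ordinal (1-32), obtained
  from the 3-4 digit SOC codes 100, 200, ..., 3200 via :func:`soc_ordinal`;
* covariate — proportions of the ``n11`` reports (study drug suspected and
  AE present) falling in each gender (3), age band (8), report type (4),
  reporter occupation (7) and reporter affiliation (6) category, the
  serious proportion, and the pair's first report year min-max normalized
  over the study window.

Classifiers train on pairs, not reports, so report-level covariates are
aggregated to scale-free proportions over the pair's exposed-case reports.
Each proportion block sums to 1 when ``n11 > 0`` and is all-zero for a
never-observed pair (which also gets SOC 0 and a logged warning).

The schema is locked: :data:`FEATURE_COLUMNS` has 35 entries and
:func:`build_features` always emits exactly those columns in that order.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AFFILIATIONS,
    AGE_GROUPS,
    GENDERS,
    OCCUPATIONS,
    REPORT_TYPES,
    ReportSet,
)

logger = logging.getLogger("pvsignal")

__all__ = ["FEATURE_COLUMNS", "soc_ordinal", "build_features", "DEFAULT_SOC_TABLE"]

FEATURE_COLUMNS: tuple[str, ...] = (
    "n11", "n10", "n01", "n00",
    "soc_code",
    *(f"gender_{g}" for g in GENDERS),
    *(f"age_{a}" for a in AGE_GROUPS),
    *(f"rt_{t}" for t in REPORT_TYPES),
    *(f"occ_{o}" for o in OCCUPATIONS),
    *(f"aff_{a}" for a in AFFILIATIONS),
    "serious_prop",
    "first_year_norm",
)
assert len(FEATURE_COLUMNS) == 35

#: 100 -> 1, 200 -> 2, ..., 3200 -> 32
DEFAULT_SOC_TABLE: dict[int, int] = {100 * i: i for i in range(1, 33)}


def soc_ordinal(
    raw_soc: str | int, table: Mapping[int, int] = DEFAULT_SOC_TABLE
) -> int:
    """Map a raw numeric SOC code to its small ordinal.

    The default table sends the 3-4 digit codes 100, 200, ..., 3200 to
    1..32, keeping the feature's numeric range small.  An alternate
    ``table`` may be supplied for other coding systems.
    """
    try:
        code = int(str(raw_soc).strip())
    except (TypeError, ValueError):
        raise ValueError(f"SOC code {raw_soc!r} is not numeric") from None
    if code not in table:
        raise ValueError(f"SOC code {code} not in the configured mapping table")
    return table[code]


def build_features(
    rs: ReportSet,
    pairs: Sequence[str],
    study_drug: str | None = None,
) -> pd.DataFrame:
    """Feature table for ``(study_drug, ae_term)`` pairs over ``rs``.

    ``rs`` must be deduplicated.  Returns one row per term in ``pairs``
    (index = term), with the 35 :data:`FEATURE_COLUMNS`.  Deterministic and
    invariant to report ordering.
    """
    if study_drug is None:
        study_drug = rs.study_drug
    if study_drug is None:
        raise ValueError("study_drug is required (none set on the ReportSet)")
    if rs.year_range is None:
        raise ValueError("ReportSet must carry a year_range")
    y0, y1 = rs.year_range
    span = max(y1 - y0, 1)

    # one pass over reports: exposure flags, inverted term index, SOC lookup
    exposed = np.fromiter(
        (study_drug in r.suspected_drugs for r in rs.reports),
        dtype=bool, count=len(rs.reports),
    )
    soc_by_term: dict[str, int] = {}
    rows_by_term: dict[str, list[int]] = {}
    for i, r in enumerate(rs.reports):
        for e in r.events:
            soc_by_term.setdefault(e.ae_term, e.soc_code)
            rows_by_term.setdefault(e.ae_term, []).append(i)

    n_exposed = int(exposed.sum())
    n_total = len(rs.reports)

    rows = np.zeros((len(pairs), len(FEATURE_COLUMNS)))
    frame = pd.DataFrame(rows, index=pd.Index(pairs, name="ae_term"),
                         columns=list(FEATURE_COLUMNS))

    col = {name: i for i, name in enumerate(FEATURE_COLUMNS)}
    for row_i, term in enumerate(pairs):
        term_rows = np.array(rows_by_term.get(term, ()), dtype=int)
        exposed_rows = term_rows[exposed[term_rows]] if term_rows.size else term_rows
        n11 = int(exposed_rows.size)
        n01 = int(term_rows.size) - n11
        values = rows[row_i]
        values[col["n11"]] = n11
        values[col["n10"]] = n_exposed - n11
        values[col["n01"]] = n01
        values[col["n00"]] = n_total - n_exposed - n01
        values[col["soc_code"]] = soc_by_term.get(term, 0)
        if term not in soc_by_term:
            logger.warning(
                "build_features: pair (%s, %s) never observed; zero-count row",
                study_drug, term,
            )
        if n11 == 0:
            continue  # proportion blocks stay all-zero
        case_reports = [rs.reports[i] for i in exposed_rows]
        values[col["serious_prop"]] = sum(r.serious for r in case_reports) / n11
        first = min(r.report_year for r in case_reports)
        values[col["first_year_norm"]] = (first - y0) / span
        for r in case_reports:
            values[col[f"gender_{r.gender}"]] += 1
            values[col[f"age_{r.age_group}"]] += 1
            values[col[f"rt_{r.report_type}"]] += 1
            values[col[f"occ_{r.source_occupation}"]] += 1
            values[col[f"aff_{r.source_affiliation}"]] += 1
        for block in ("gender_", "age_", "rt_", "occ_", "aff_"):
            block_cols = [i for name, i in col.items() if name.startswith(block)]
            values[block_cols] /= n11

    frame.loc[:, :] = rows
    return frame
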