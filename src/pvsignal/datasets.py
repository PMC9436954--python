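"""Small bundled reference datasets for worked examples and checks.

:func:`infliximab_unknown_ae_screen` returns the published screening
scores of the 27 unknown adverse events flagged for infliximab in the
Korea Adverse Event Reporting System (2009-2018): the GBM and RF
signaling probabilities, the lower 95% bound of the adjusted reporting
odds ratio (ROR025), the lower 90%-interval bound of the information
component (IC05), and the signal calls printed for each method.  Applying
the strict flag rules (ROR025 > 1; IC05 > 0) to the score columns must
reproduce the printed calls row for row — a fixed-point check of the rule
implementations against an independent source.

ROR025 values published as "< 0.01" are stored as 0.005 with
``ror025_censored = True``; the censoring never affects the flag rule,
which only compares against 1.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["infliximab_unknown_ae_screen"]

# term, gbm_signal, gbm_prob, rf_signal, rf_prob, ror_signal, ror025,
# censored, ic_signal, ic05
_UNKNOWN_AE_ROWS = [
    ("acne", True, 0.92, True, 0.74, False, 0.64, False, False, -0.33),
    ("alopecia", True, 0.94, True, 0.77, False, 0.08, False, False, -2.66),
    ("asthenia", True, 1.00, True, 0.95, False, 0.36, False, False, -1.34),
    ("bilirubinaemia", True, 0.93, True, 0.71, False, 0.02, False, False, -4.37),
    ("cytomegalovirus colitis", True, 0.87, True, 0.75, False, 0.20, False, False, -1.07),
    ("death", True, 0.88, True, 0.76, False, 0.01, False, False, -2.89),
    ("drug reaction paradoxical", True, 0.88, True, 0.80, False, 0.005, True, False, -0.17),
    ("epistaxis", True, 0.93, True, 0.81, False, 0.78, False, False, -0.63),
    ("extravasation", True, 0.86, True, 0.73, False, 0.03, False, False, -2.11),
    ("gastroenteritis", True, 0.97, True, 0.76, False, 0.005, True, False, -0.07),
    ("haematuria", True, 0.99, True, 0.82, False, 0.04, False, False, -1.83),
    ("hepatocellular damage", True, 0.88, True, 0.67, False, 0.06, False, False, -3.27),
    ("hypoaesthesia", True, 0.90, True, 0.70, False, 0.14, False, False, -1.39),
    ("liver fatty", True, 0.97, True, 0.79, False, 0.005, True, False, -0.17),
    ("melaena", True, 0.95, True, 0.89, True, 2.79, False, True, 0.62),
    ("mouth dry", True, 0.78, True, 0.65, False, 0.26, False, False, -1.06),
    ("oedema genital", True, 0.90, True, 0.63, False, 0.005, True, False, -1.48),
    ("oedema periorbital", True, 0.88, True, 0.64, False, 0.11, False, False, -1.99),
    ("paraesthesia", True, 0.82, True, 0.83, False, 0.83, False, False, -0.16),
    ("psoriasis", True, 0.87, True, 0.71, False, 0.005, True, True, 0.19),
    ("pulmonary infiltration", True, 0.97, True, 0.82, False, 0.32, False, False, -0.30),
    ("stomatitis ulcerative", True, 0.89, True, 0.78, False, 0.08, False, False, -1.82),
    ("stridor", True, 0.82, True, 0.65, False, 0.005, True, False, -1.48),
    ("stupor", True, 0.84, True, 0.64, False, 0.14, False, False, -3.17),
    ("temperature changed sensation", True, 1.00, True, 0.96, True, 4.23, False, False, -0.08),
    ("tremor", True, 0.85, True, 0.71, False, 0.20, False, False, -0.80),
    ("uveitis", True, 0.66, True, 0.70, False, 0.005, True, True, 0.08),
]


def infliximab_unknown_ae_screen() -> pd.DataFrame:
    """27 unknown-AE screening rows for infliximab (KAERS, 2009-2018).

    Columns: ``ae_term``, per-method printed signal calls
    (``gbm_signal``, ``rf_signal``, ``ror_signal``, ``ic_signal``), the
    classifier probabilities (``gbm_prob``, ``rf_prob``), ``ror025``
    (with ``ror025_censored`` marking values published as "< 0.01"),
    and ``ic05``.
    """
    return pd.DataFrame(
        _UNKNOWN_AE_ROWS,
        columns=[
            "ae_term",
            "gbm_signal", "gbm_prob",
            "rf_signal", "rf_prob",
            "ror_signal", "ror025", "ror025_censored",
            "ic_signal", "ic05",
        ],
    )
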