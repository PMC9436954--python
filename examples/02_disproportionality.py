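"""Score drug-AE pairs with the conventional disproportionality statistics.

Builds report-level 2x2 tables for one planted and one null pair, then
computes the crude ROR with its 95% CI and the BCPNN information component
with Monte-Carlo credible bounds, and applies the strict signal rules.
"""

from pvsignal import (
    contingency_table,
    crude_ror,
    deduplicate_followups,
    default_scenario,
    generate_reports,
    ic_credible_bounds,
    information_component,
    signal_flag_ic,
    signal_flag_ror,
)

config = default_scenario(seed=3, n_reports=8000)
reports = deduplicate_followups(generate_reports(config))

for term, kind in [("ae01", "planted x10"), ("ae25", "null")]:
    ct = contingency_table(reports, config.study_drug, term)
    ror = crude_ror(ct)
    ic = ic_credible_bounds(ct, seed=1)
    print(f"{term} ({kind}): cells={ct.as_tuple()}")
    print(
        f"  ROR {ror.estimate:5.2f} [{ror.ci_low:.2f}, {ror.ci_high:.2f}]"
        f"  -> signal: {signal_flag_ror(ror)}"
    )
    print(
        f"  IC  {information_component(ct):5.2f} (IC025 {ic.ic025:.2f})"
        f"  -> signal: {signal_flag_ic(ic.ic025)}"
    )

# The planted pair's lower ROR bound exceeds 1 and its IC025 exceeds 0, so
# both rules flag it; the null pair's bounds stay below the cut-points.
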