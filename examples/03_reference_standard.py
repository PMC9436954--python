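"""Classify observed drug-AE pairs against the label reference standard.

A pair is Y once the study drug's label lists the AE, N while no label in
the therapeutic class lists it, and U otherwise — the pool in which new
signals are sought.  The classification is year-aware: an AE labeled in
2014 is U (or N) before 2014 and Y afterwards.
"""

from collections import Counter

from pvsignal import (
    build_cumulative_sets,
    classification_map,
    classify_pairs,
    deduplicate_followups,
    default_scenario,
    generate_label_history,
    generate_reports,
)
from pvsignal.simulate import DEFAULT_CLASS_DRUGS

config = default_scenario(seed=5, n_reports=5000)
reports = deduplicate_followups(generate_reports(config))
labels = generate_label_history(config, DEFAULT_CLASS_DRUGS)
cumulative = build_cumulative_sets(reports, 2009, 2018)

for year in (2010, 2013, 2016, 2018):
    classes = classification_map(
        classify_pairs(cumulative[year - 2009], labels, config.study_drug,
                       DEFAULT_CLASS_DRUGS, year)
    )
    counts = Counter(classes.values())
    emerging = classes.get("ae11", "-")
    print(f"{year}: Y={counts['Y']:2d} N={counts['N']:2d} U={counts['U']:2d}"
          f"   ae11 is {emerging}")

# ae11 (first reported 2011, labeled 2014) moves U -> Y at its label year,
# and the U pool shrinks as emerging signals get labeled.
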