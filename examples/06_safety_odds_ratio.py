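"""Weighted grade 3/4 adverse-event comparison via odds ratios.

The index arm's weighted incidence is expressed as fractional effective
events over the Kish effective sample size and compared with the
comparator's published count/total. The two tables below are the published
weighted margins of a melanoma indirect comparison; the first contrasts an
immunotherapy doublet with dabrafenib+trametinib, the second with
vemurafenib+cobimetinib.
"""

import maicsurv as ms

for label, table in [
    ("vs dabrafenib+trametinib", ms.SafetyTable(54.0, 83.3, 101, 211)),
    ("vs vemurafenib+cobimetinib", ms.SafetyTable(60.9, 91.7, 188, 248)),
]:
    res = ms.odds_ratio(table, seed=1)
    print(f"{label}: weighted incidence {res.index_rate:.0%} vs "
          f"{res.comp_rate:.0%}; OR {res.or_point:.2f} "
          f"(95% CrI {res.cri95[0]:.2f}-{res.cri95[1]:.2f})")
# OR > 1 with a CrI above 1 means the index therapy causes significantly
# more severe treatment-related adverse events; a CrI spanning 1 means the
# rates are statistically comparable.
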