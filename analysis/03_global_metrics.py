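#!/usr/bin/env python
"""Compare global network measures between groups.

Computes per-subject global efficiency and mean nodal strength, then runs
the omnibus one-way ANOVA followed by pairwise Welch's t-tests.  Both
disease groups are expected to sit below controls, with no reliable
difference between the two pathologies.
"""

import pandas as pd

from netphase import anova_oneway, cohort_global_measures, welch_t

from _common import RESULTS, load_cohorts


def main() -> None:
    cohorts = load_cohorts()
    measures = {label: cohort_global_measures(c) for label, c in cohorts.items()}
    rows = []
    for name, attr in (("global_efficiency", "global_efficiency"),
                       ("mean_nodal_strength", "mean_nodal_strength")):
        data = {g: [getattr(m, attr) for m in ms] for g, ms in measures.items()}
        res = anova_oneway([data["HC"], data["TAU"], data["TDP"]])
        print(f"{name}: F({int(res.df[0])},{int(res.df[1])}) = "
              f"{res.statistic:.2f}, p = {res.p_value:.2g}")
        rows.append({"measure": name, "test": "anova", "stat": res.statistic,
                     "df": f"{int(res.df[0])},{int(res.df[1])}",
                     "p": res.p_value})
        for a, b in (("HC", "TAU"), ("HC", "TDP"), ("TAU", "TDP")):
            t = welch_t(data[a], data[b])
            print(f"  {a} vs {b}: t({t.df_pooled}) = {t.statistic:.2f}, "
                  f"p = {t.p_value:.2g} (means {t.group_means[0]:.3f} / "
                  f"{t.group_means[1]:.3f})")
            rows.append({"measure": name, "test": f"welch_{a}_vs_{b}",
                         "stat": t.statistic, "df": t.df_pooled,
                         "p": t.p_value})
    pd.DataFrame(rows).to_csv(RESULTS / "global_measures_tests.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
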