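#!/usr/bin/env python
"""Hub detection and lost/gained hub accounting per disease phase.

Derives strength/betweenness hub thresholds (mean + 1 SD across nodes) from
the control cohort, applies them to each disease group, and summarizes lost
and gained hubs within each recovered atrophy phase.
"""

import pandas as pd

from netphase import (cohort_node_measures, compare_hubs, detect_hubs,
                      hub_thresholds, phase_hub_summary)

from _common import RESULTS, load_cohorts, load_phases


def main() -> None:
    cohorts = load_cohorts()
    node_measures = {g: cohort_node_measures(c) for g, c in cohorts.items()}
    criteria = hub_thresholds(node_measures["HC"])
    hubs = {g: detect_hubs(nm, criteria) for g, nm in node_measures.items()}
    print(f"hub thresholds: strength > {criteria.strength_threshold:.3f}, "
          f"betweenness > {criteria.betweenness_threshold:.4f}")
    print(f"hub counts: " + ", ".join(f"{g}={len(h)}" for g, h in hubs.items()))

    rows = []
    for label in ("TAU", "TDP"):
        lost, gained, retained = compare_hubs(hubs["HC"], hubs[label])
        print(f"{label}: lost {len(lost)}, gained {len(gained)}, "
              f"retained {len(retained)}")
        summary = phase_hub_summary(hubs["HC"], hubs[label], load_phases(label))
        for phase, vals in summary.items():
            fmt = {k: ("-" if v is None else f"{v:.0f}%")
                   for k, v in vals.items()}
            print(f"  phase {phase}: HC-hub nodes {fmt['pct_nodes_hub']}, "
                  f"lost {fmt['pct_hubs_lost']}, gained {fmt['pct_hubs_gained']}")
            rows.append({"group": label, "phase": phase, **vals})
    pd.DataFrame(rows).to_csv(RESULTS / "hub_phase_summary.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
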