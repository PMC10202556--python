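#!/usr/bin/env python
"""Edge z-scoring and phase-transition weakened-edge analysis.

Builds the per-edge control reference (mean/SD over controls with the edge
defined), z-scores every patient edge, flags weakened edges at z <= -3, and
compares normalized cross-phase weakened-edge counts between the two
disease groups for epicentre-anchored and sequential phase transitions.
"""

import numpy as np
import pandas as pd

from netphase import (build_edge_reference, edge_zscores, transition_edge_stats,
                      weak_edges, welch_t, whole_brain_mean_z)
from netphase.proximal import EPICENTRE_PAIRS, SEQUENTIAL_PAIRS

from _common import RESULTS, load_cohorts, load_phases


def main() -> None:
    cohorts = load_cohorts()
    ref = build_edge_reference(cohorts["HC"])
    print(f"usable reference edges: {int(np.triu(ref.usable, 1).sum())}")

    weak_sets, mean_z = {}, {}
    for label in ("TAU", "TDP"):
        weak_sets[label], mean_z[label] = [], []
        for s in cohorts[label]:
            z = edge_zscores(s, ref)
            weak_sets[label].append(weak_edges(z))
            mean_z[label].append(whole_brain_mean_z(z))
    t = welch_t(mean_z["TAU"], mean_z["TDP"])
    print(f"whole-brain mean edge z, TAU vs TDP: t({t.df_pooled}) = "
          f"{t.statistic:.2f}, p = {t.p_value:.2g} "
          f"(means {t.group_means[0]:.3f} / {t.group_means[1]:.3f})")

    rows = []
    phases = {g: load_phases(g) for g in ("TAU", "TDP")}
    pairs = list(dict.fromkeys(EPICENTRE_PAIRS + SEQUENTIAL_PAIRS))
    for pair in pairs:
        series = {}
        for g in ("TAU", "TDP"):
            vals = [transition_edge_stats(ws, phases[g], pair)["normalized"]
                    for ws in weak_sets[g]]
            series[g] = [v for v in vals if v is not None]
        entry = {"pair": f"{pair[0]}-{pair[1]}",
                 "tau_mean": np.mean(series["TAU"]) if series["TAU"] else None,
                 "tdp_mean": np.mean(series["TDP"]) if series["TDP"] else None}
        if all(len(v) >= 2 for v in series.values()) and (
                np.std(series["TAU"]) > 0 or np.std(series["TDP"]) > 0):
            t = welch_t(series["TAU"], series["TDP"])
            entry.update(t=t.statistic, df_pooled=t.df_pooled, p=t.p_value)
            mark = "*" if t.p_value < 0.05 else " "
            print(f"  transition {entry['pair']}: normalized weak edges "
                  f"TAU {entry['tau_mean']:.4f} vs TDP {entry['tdp_mean']:.4f}, "
                  f"t({t.df_pooled}) = {t.statistic:.2f}, p = {t.p_value:.2g}{mark}")
        rows.append(entry)
    pd.DataFrame(rows).to_csv(RESULTS / "transition_weak_edges.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
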