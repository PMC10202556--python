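#!/usr/bin/env python
"""Proximal spreading connections per phase transition.

Counts, per subject, pairs of physically adjacent regions spanning an
earlier and a later phase in which the subject shows atrophy at both ends,
normalized by the product of the phase sizes, and compares the two disease
groups.  The proximal-mechanism group is expected to dominate transitions
beyond the epicentre.
"""

import numpy as np
import pandas as pd

from netphase import welch_t
from netphase.proximal import (EPICENTRE_PAIRS, SEQUENTIAL_PAIRS,
                               adjacent_phase_pairs, subject_proximal_stats)
from netphase.staging import AtrophyTable

from _common import RESULTS, load_atrophy, load_cohorts, load_phases


def main() -> None:
    cohorts = load_cohorts()
    adjacency = cohorts["HC"].atlas.adjacency
    rows = []
    data = {}
    for g in ("TAU", "TDP"):
        table, subject_ids = load_atrophy(g)
        data[g] = (AtrophyTable(table=table, subject_ids=subject_ids),
                   load_phases(g))
    pairs = list(dict.fromkeys(EPICENTRE_PAIRS + SEQUENTIAL_PAIRS))
    for pair in pairs:
        series = {}
        for g in ("TAU", "TDP"):
            table, phases = data[g]
            cands = adjacent_phase_pairs(phases, adjacency, pair)
            sizes = phases.phase_sizes()
            vals = [subject_proximal_stats(row, cands, sizes[pair[0]],
                                           sizes[pair[1]])["normalized"]
                    for row in table.table]
            series[g] = [v for v in vals if v is not None]
        entry = {"pair": f"{pair[0]}-{pair[1]}",
                 "tau_mean": np.mean(series["TAU"]) if series["TAU"] else None,
                 "tdp_mean": np.mean(series["TDP"]) if series["TDP"] else None}
        if all(len(v) >= 2 for v in series.values()) and (
                np.std(series["TAU"]) > 0 or np.std(series["TDP"]) > 0):
            t = welch_t(series["TAU"], series["TDP"])
            entry.update(t=t.statistic, df_pooled=t.df_pooled, p=t.p_value)
            mark = "*" if t.p_value < 0.05 else " "
            print(f"  transition {entry['pair']}: normalized proximal spread "
                  f"TAU {entry['tau_mean']:.4f} vs TDP {entry['tdp_mean']:.4f}, "
                  f"t({t.df_pooled}) = {t.statistic:.2f}, p = {t.p_value:.2g}{mark}")
        rows.append(entry)
    pd.DataFrame(rows).to_csv(RESULTS / "proximal_spread.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
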