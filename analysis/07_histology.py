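#!/usr/bin/env python
"""Relate edge integrity to %-area-occupied pathology burden.

For patients with disease duration <= 5 years, pairs each sampled region's
%AO with the subject's mean z-score over the edges incident to that region
and fits a linear regression per tissue (GM, WM) per group.  A negative
slope means heavier pathology where connectivity is more degraded.
"""

import pandas as pd

from netphase import build_edge_reference, edge_zscores, histo_association

from _common import RESULTS, load_cohorts


def main() -> None:
    cohorts = load_cohorts()
    ref = build_edge_reference(cohorts["HC"])
    rows = []
    for g in ("TAU", "TDP"):
        histo = pd.read_csv(RESULTS / f"histology_{g}.tsv", sep="\t")
        zmats = {s.subject_id: edge_zscores(s, ref) for s in cohorts[g]}
        res = histo_association(cohorts[g], zmats, histo)
        for tissue in ("GM", "WM"):
            r = res[tissue]
            if r is None:
                print(f"{g} {tissue}: insufficient pairs")
                continue
            print(f"{g} {tissue}: b = {r.slope:.3f}, p = {r.slope_p:.3g}; "
                  f"r = {r.r:.3f}, p = {r.r_p:.3g} (n = {r.n})")
            rows.append({"group": g, "tissue": tissue, "slope": r.slope,
                         "slope_p": r.slope_p, "r": r.r, "r_p": r.r_p,
                         "n": r.n})
    pd.DataFrame(rows).to_csv(RESULTS / "histology_association.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
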