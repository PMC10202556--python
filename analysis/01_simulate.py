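#!/usr/bin/env python
"""Generate the synthetic study cohorts.

Creates a 100-region atlas and three cohorts at the study's sizes — 27
controls, 28 patients under the distant (long-range edge damage) mechanism
and 13 under the proximal (adjacency spread) mechanism — plus %AO histology
tables, and writes everything under results/ in the package's TSV dialect.
"""

import pandas as pd

from netphase import (GeneratorParams, generate_atlas, generate_disease_cohort,
                      generate_hc_cohort, generate_histology, validate_inputs,
                      write_cohort)

from _common import COHORTS, RESULTS, SEED


def main() -> None:
    params = GeneratorParams()
    atlas = generate_atlas(params.n_regions, SEED)
    hc = generate_hc_cohort(atlas, params, SEED)
    tau, tau_truth = generate_disease_cohort(atlas, params, "distant", SEED)
    tdp, tdp_truth = generate_disease_cohort(atlas, params, "proximal", SEED)

    RESULTS.mkdir(parents=True, exist_ok=True)
    for cohort in (hc, tau, tdp):
        assert validate_inputs(cohort) == [], cohort.label
        write_cohort(cohort, COHORTS / cohort.label)
        print(f"{cohort.label}: {len(cohort)} subjects, "
              f"{atlas.n_regions} regions")

    for label, truth, cohort in (("TAU", tau_truth, tau),
                                 ("TDP", tdp_truth, tdp)):
        pd.DataFrame({
            "region_id": atlas.region_ids,
            "planted_phase": truth.planted_phase,
            "planting_prob": truth.planting_prob,
            "planted_hub": [int(i in truth.planted_hubs)
                            for i in range(atlas.n_regions)],
        }).to_csv(RESULTS / f"truth_{label}.tsv", sep="\t", index=False)
        generate_histology(cohort, truth, params, SEED).to_csv(
            RESULTS / f"histology_{label}.tsv", sep="\t", index=False)
        print(f"{label} truth: {len(truth.planted_weak_edges)} planted weak "
              f"edges ({truth.mechanism} mechanism), "
              f"{(truth.planted_phase == 1).sum()} epicentre regions")


if __name__ == "__main__":
    main()
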