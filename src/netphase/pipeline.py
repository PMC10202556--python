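"""End-to-end pipeline: simulate -> stage -> metrics -> hubs -> edges ->
proximal -> histology statistics, with a JSON summary report.

The report mirrors the structure of the study's group comparisons: global
measures (ANOVA + pairwise Welch), per-phase hub summaries, phase-transition
weakened-edge comparisons, proximal-spread comparisons and the
%AO-vs-edge-integrity regressions.  Given the same config and seed the run
is deterministic and idempotent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import edges as edges_mod
from . import hubs as hubs_mod
from . import metrics as metrics_mod
from . import proximal as proximal_mod
from . import staging as staging_mod
from . import stats as stats_mod
from .model import Cohort, write_cohort
from .synthetic import (GeneratorParams, generate_atlas, generate_disease_cohort,
                        generate_hc_cohort, generate_histology)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration; defaults are the analysis constants
    (W < -0.5, z <= -3, mean + 1 SD hubs, min 5 reference controls,
    duration <= 5 years)."""

    seed: int = 0
    out_dir: str = "results/run"
    n_regions: int = 100
    w_threshold: float = -0.5
    z_threshold: float = -3.0
    hub_sd_multiplier: float = 1.0
    min_obs: int = 5
    max_duration: float = 5.0
    generator: dict[str, Any] = dataclasses.field(default_factory=dict)
    write_cohorts: bool = False

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def generator_params(self) -> GeneratorParams:
        return GeneratorParams(n_regions=self.n_regions, **self.generator)


def _welch_entry(res: stats_mod.TestResult) -> dict:
    return {"t": res.statistic, "df_welch": res.df, "df_pooled": res.df_pooled,
            "p": res.p_value, "means": res.group_means, "n": res.n}


def _transition_comparison(weak_by_group, phases_by_group, pairs, z_threshold):
    """Per-subject normalized cross-phase weak-edge counts + Welch comparison."""
    out = {}
    for pair in pairs:
        per_group = {}
        for g, weak_sets in weak_by_group.items():
            vals = []
            for ws in weak_sets:
                st = edges_mod.transition_edge_stats(ws, phases_by_group[g], pair)
                vals.append(st["normalized"])
            per_group[g] = vals
        key = f"{pair[0]}-{pair[1]}"
        entry = {g: {"mean_normalized": float(np.mean([v for v in vs if v is not None]))
                     if any(v is not None for v in vs) else None}
                 for g, vs in per_group.items()}
        groups = list(per_group)
        if len(groups) == 2:
            a = [v for v in per_group[groups[0]] if v is not None]
            b = [v for v in per_group[groups[1]] if v is not None]
            if len(a) >= 2 and len(b) >= 2 and (np.std(a) > 0 or np.std(b) > 0):
                entry["welch"] = _welch_entry(stats_mod.welch_t(a, b))
        out[key] = entry
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on synthetic cohorts and write TSVs + report.json."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.generator_params()
    seed = config.seed

    logger.info("stage=simulate seed=%d n_regions=%d", seed, config.n_regions)
    atlas = generate_atlas(config.n_regions, seed)
    hc = generate_hc_cohort(atlas, params, seed)
    tau, tau_truth = generate_disease_cohort(atlas, params, "distant", seed)
    tdp, tdp_truth = generate_disease_cohort(atlas, params, "proximal", seed)
    histo = {"TAU": generate_histology(tau, tau_truth, params, seed),
             "TDP": generate_histology(tdp, tdp_truth, params, seed)}
    if config.write_cohorts:
        for c in (hc, tau, tdp):
            write_cohort(c, out / "cohorts" / c.label)

    logger.info("stage=staging n_hc=%d", len(hc))
    wmodel = staging_mod.fit_wscore_model(hc)
    staged = {}
    for cohort in (tau, tdp):
        table, phases, W = staging_mod.stage_cohort(cohort, wmodel,
                                                    config.w_threshold)
        staged[cohort.label] = {"atrophy": table, "phases": phases, "W": W}
        pd.DataFrame({"region_id": atlas.region_ids,
                      "phase": phases.phases,
                      "ratio": phases.ratios}).to_csv(
            out / f"phases_{cohort.label}.tsv", sep="\t", index=False)

    logger.info("stage=metrics")
    glob = {c.label: metrics_mod.cohort_global_measures(c) for c in (hc, tau, tdp)}
    ge = {g: [m.global_efficiency for m in ms] for g, ms in glob.items()}
    mns = {g: [m.mean_nodal_strength for m in ms] for g, ms in glob.items()}
    global_report = {}
    for name, data in (("global_efficiency", ge), ("mean_nodal_strength", mns)):
        global_report[name] = {
            "anova": dataclasses.asdict(
                stats_mod.anova_oneway([data["HC"], data["TAU"], data["TDP"]])),
            "HC_vs_TAU": _welch_entry(stats_mod.welch_t(data["HC"], data["TAU"])),
            "HC_vs_TDP": _welch_entry(stats_mod.welch_t(data["HC"], data["TDP"])),
            "TAU_vs_TDP": _welch_entry(stats_mod.welch_t(data["TAU"], data["TDP"])),
        }
    pd.DataFrame({
        "subject_id": [s.subject_id for c in (hc, tau, tdp) for s in c],
        "group": [c.label for c in (hc, tau, tdp) for _ in c],
        "global_efficiency": [v for g in ("HC", "TAU", "TDP") for v in ge[g]],
        "mean_nodal_strength": [v for g in ("HC", "TAU", "TDP") for v in mns[g]],
    }).to_csv(out / "global_measures.tsv", sep="\t", index=False)

    logger.info("stage=hubs")
    node_measures = {c.label: metrics_mod.cohort_node_measures(c)
                     for c in (hc, tau, tdp)}
    hc_nm = node_measures["HC"]
    crit = hubs_mod.HubCriteria(
        strength_threshold=float(hc_nm.strength.mean()
                                 + config.hub_sd_multiplier * hc_nm.strength.std(ddof=1)),
        betweenness_threshold=float(hc_nm.betweenness.mean()
                                    + config.hub_sd_multiplier * hc_nm.betweenness.std(ddof=1)),
    )
    hub_sets = {g: hubs_mod.detect_hubs(nm, crit) for g, nm in node_measures.items()}
    hub_report = {"n_hubs": {g: len(h) for g, h in hub_sets.items()}}
    for g in ("TAU", "TDP"):
        lost, gained, retained = hubs_mod.compare_hubs(hub_sets["HC"], hub_sets[g])
        hub_report[g] = {
            "lost": sorted(lost), "gained": sorted(gained),
            "retained": sorted(retained),
            "phase_summary": hubs_mod.phase_hub_summary(
                hub_sets["HC"], hub_sets[g], staged[g]["phases"]),
        }
    pd.DataFrame([
        {"group": g, "node": atlas.region_ids[i],
         "reasons": "+".join(sorted(h.reasons[i]))}
        for g, h in hub_sets.items() for i in sorted(h.members)
    ]).to_csv(out / "hubs.tsv", sep="\t", index=False)

    logger.info("stage=edges min_obs=%d", config.min_obs)
    ref = edges_mod.build_edge_reference(hc, min_obs=config.min_obs)
    zmats = {c.label: {s.subject_id: edges_mod.edge_zscores(s, ref) for s in c}
             for c in (tau, tdp)}
    weak_by_group = {
        g: [edges_mod.weak_edges(z, config.z_threshold) for z in zm.values()]
        for g, zm in zmats.items()
    }
    mean_z = {g: [edges_mod.whole_brain_mean_z(z) for z in zm.values()]
              for g, zm in zmats.items()}
    edge_report = {
        "whole_brain_mean_z": {
            g: float(np.mean([v for v in vs if v is not None])) for g, vs in mean_z.items()
        },
        "whole_brain_welch": _welch_entry(stats_mod.welch_t(
            [v for v in mean_z["TAU"] if v is not None],
            [v for v in mean_z["TDP"] if v is not None])),
        "epicentre_transitions": _transition_comparison(
            weak_by_group, {g: staged[g]["phases"] for g in ("TAU", "TDP")},
            proximal_mod.EPICENTRE_PAIRS, config.z_threshold),
        "sequential_transitions": _transition_comparison(
            weak_by_group, {g: staged[g]["phases"] for g in ("TAU", "TDP")},
            proximal_mod.SEQUENTIAL_PAIRS[1:], config.z_threshold),
    }
    hub_frac = {}
    for g in ("TAU", "TDP"):
        rows = []
        for pair in proximal_mod.EPICENTRE_PAIRS:
            vals = [edges_mod.hub_connected_fraction(ws, hub_sets["HC"],
                                                     staged[g]["phases"], pair)
                    for ws in weak_by_group[g]]
            vals = [v for v in vals if v is not None]
            rows.append({"pair": f"{pair[0]}-{pair[1]}",
                         "mean_pct_hub_connected": float(np.mean(vals)) if vals else None})
        hub_frac[g] = rows
    edge_report["hub_connected"] = hub_frac

    logger.info("stage=proximal")
    prox_report = {}
    for family, pairs in (("epicentre", proximal_mod.EPICENTRE_PAIRS),
                          ("sequential", proximal_mod.SEQUENTIAL_PAIRS)):
        fam = {}
        per_group = {
            g: proximal_mod.cohort_proximal_stats(
                staged[g]["atrophy"], staged[g]["phases"], atlas.adjacency, pairs)
            for g in ("TAU", "TDP")
        }
        for pair in pairs:
            key = f"{pair[0]}-{pair[1]}"
            entry = {}
            series = {}
            for g in ("TAU", "TDP"):
                vals = [e["normalized"] for e in per_group[g][pair]
                        if e["normalized"] is not None]
                series[g] = vals
                entry[g] = {"mean_normalized": float(np.mean(vals)) if vals else None}
            if all(len(v) >= 2 for v in series.values()) and any(
                    np.std(v) > 0 for v in series.values()):
                entry["welch"] = _welch_entry(
                    stats_mod.welch_t(series["TAU"], series["TDP"]))
            fam[key] = entry
        prox_report[family] = fam

    logger.info("stage=histology max_duration=%.1f", config.max_duration)
    histo_report = {}
    for g, cohort in (("TAU", tau), ("TDP", tdp)):
        res = stats_mod.histo_association(cohort, zmats[g], histo[g],
                                          max_duration=config.max_duration)
        histo_report[g] = {
            t: None if r is None else dataclasses.asdict(r) for t, r in res.items()
        }
        histo[g].to_csv(out / f"histology_{g}.tsv", sep="\t", index=False)

    report = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "seed": seed,
        "phases": {g: staged[g]["phases"].phase_sizes() for g in ("TAU", "TDP")},
        "global_measures": global_report,
        "hubs": hub_report,
        "edges": edge_report,
        "proximal": prox_report,
        "histology": histo_report,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
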