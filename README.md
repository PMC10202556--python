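# netphase

Phase-staged structural-connectome analysis of spreading neurodegeneration.

Two sporadic frontotemporal lobar degeneration pathologies — FTLD-tau and
FTLD-TDP — are hypothesized to spread through the cerebrum by different
routes: tau along long-range white-matter projections from strongly
connected hub regions ("distant" spread), TDP-43 into physically adjacent
cortex ("proximal" spread). `netphase` implements the antemortem MRI
analysis chain that probes these hypotheses on FA-weighted structural
networks over a cortical parcellation, together with a synthetic cohort
generator that plants each mechanism as ground truth so the whole chain can
be validated end to end without patient data.

The pipeline, for cohorts of healthy controls (HC) and two patient groups:

1. **Atrophy phase staging.** Regional grey-matter volumes are converted to
   W-scores against a control regression, `W = (observed − predicted) /
   residual SD` with age and intracranial volume as covariates, binarized at
   `W < −0.5`, and regions are binned by the atrophy-prevalence ratio
   `N_a(r)/N_m` into phases: ≥ 0.9 → phase 1 (epicentre), [0.8, 0.9) → 2,
   [0.7, 0.8) → 3, [0.6, 0.7) → 4, [0.5, 0.6) → 5, otherwise unstaged.
2. **Network metrics.** Per subject: nodal strength (sum of incident FA
   weights), betweenness centrality (weighted shortest paths on lengths
   `1/w`, normalized), global efficiency and mean nodal strength.
3. **Hubs.** A node is a hub when its cohort-mean strength *or* betweenness
   exceeds the HC across-node mean + 1 SD. HC thresholds applied to disease
   groups define *lost* (HC-only) and *gained* (disease-only) hubs.
4. **Edge degradation.** Each patient edge weight `w` is standardized
   against the control cohort, `z = (w − w̄_HC) / S_HC`; edges with
   `z ≤ −3` are *weakened*. Weakened-edge counts between phase pairs,
   normalized by the product of phase sizes, quantify transition damage.
5. **Proximal spread.** Pairs of physically adjacent regions spanning an
   earlier and a later phase, counted per subject when both ends show
   atrophy and normalized the same way.
6. **Histopathology association.** Per-region %-area-occupied (%AO)
   pathology burden is regressed on the subject's mean edge z of that
   region; a negative slope ties heavier pathology to degraded connectivity.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
cohorts (100 regions; 27 HC, 28 distant-mechanism "TAU", 13
proximal-mechanism "TDP"; seed 1) and write tables under `results/`:

```sh
cd analysis
python 01_simulate.py && python 02_stage.py && python 05_edges.py
```

prints, among other lines:

```
TAU truth: 27 planted weak edges (distant mechanism), 8 epicentre regions
TAU: phase sizes {1: 9, 2: 6, 3: 7, 4: 13, 5: 9}, planted-phase Spearman rho = 0.918, epicentre Jaccard = 0.889
whole-brain mean edge z, TAU vs TDP: t(39) = -3.88, p = 0.00084 (means -0.048 / -0.007)
  transition 1-2: normalized weak edges TAU 0.0364 vs TDP 0.0026, t(39) = 8.70, p = 3.8e-10*
```

Reading: staging recovers the planted five-phase gradient almost perfectly
(rank correlation 0.92); whole-brain edge integrity is significantly lower
in the distant-mechanism group; and the epicentre→phase-2 transition
carries an order of magnitude more weakened edges under distant spread —
the signature separating the two mechanisms. `04_hubs.py` shows the
complementary hub result (every HC hub in the TAU epicentre is lost;
almost none in TDP), `06_proximal.py` the reverse dominance of adjacent
spread in TDP, and `07_histology.py` the negative %AO-vs-z regression
(TAU GM: b = −2.01, r = −0.74).

The same stages are available as a CLI (`netphase simulate|stage|metrics|
hubs|edges|proximal|run`) operating on TSV cohort directories; `netphase
run` executes everything and writes `report.json`.

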