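# Methods

This note documents the models, conventions and design choices behind
`netphase`: what each analysis stage computes, what the synthetic cohort
generator emulates (and deliberately does not), and the numerical decisions
that affect results.

## Data model and file dialect

Cohorts are triples of (region atlas, covariates, per-subject data). The
atlas carries ordered region ids, centroids (mm, arbitrary consistent
space) and a boolean physical-adjacency matrix. Per subject: age (years),
intracranial volume (mm³), disease duration (years, patients only),
per-region grey-matter volumes (mm³), and a symmetric connectivity matrix
with FA-like weights in (0, 1]. A missing edge — no streamlines found — is
NaN and is excluded from every computation rather than treated as zero;
diagonals are never used. On disk everything is tab-separated text with the
literal `NA` for missingness; floats are written with 12 significant digits
so a read–write cycle is an identity for analysis purposes.

## Atrophy staging

W-scores standardize patient volumes against a control regression fitted
per region by ordinary least squares, volume ~ age + ICV, with residual SD
on an n − 3 denominator. Atrophy is the strict inequality `W < −0.5`;
`W = −0.5` exactly is not atrophy. Phases use the exact ratio
`N_a(r)/N_m` (never rounded to integer percent): phase 1 at ratio ≥ 0.9
(closed at 1.0), then half-open bins of width 0.1 down to 0.5; below 0.5 a
region is unstaged. The W-score covariates are age and ICV only — no sex
term — and patients missing a covariate are dropped from staging with a
warning rather than imputed. An all-zero atrophy table is an error: there
is nothing to stage.

## Network measures

Weighted shortest paths use the length map `l = 1/w`, the standard
convention for FA-weighted connectomes (stronger = shorter). Betweenness is
Brandes' algorithm with exact fractional counting of co-minimal paths,
endpoints excluded, normalized so the centre of a star graph scores 1; hub
detection is invariant to this scaling, which merely makes values
comparable across atlas sizes. Global efficiency averages inverse
shortest-path lengths over ordered pairs, with unreachable pairs
contributing zero. Strength sums defined incident weights (missing → 0
contribution). Cohort-level node measures are computed per subject and then
averaged across subjects — robust to per-subject missing edges — rather
than derived from a group-average matrix; this choice is recorded because
the alternative is defensible too.

## Hubs

Thresholds are the HC across-node mean + 1 across-node sample SD (ddof 1)
of the cohort-mean strength and betweenness; a node is a hub when either
measure strictly exceeds its threshold. Zero across-node variance
degenerates the threshold to the mean (logged); under the strict rule no
node is then a hub. HC thresholds applied unchanged to disease cohorts give
lost = HC∖disease and gained = disease∖HC hub sets. Per-phase summaries
report percentages with explicit absent values (never silent zeros) when a
denominator — nodes in a phase, or HC hubs in a phase — is empty.

## Edge z-scores

The control reference stores, per edge, the mean and sample SD over
controls in whom the edge is defined. An edge is usable when at least 5
controls contribute and the SD is positive; otherwise z is undefined (not
±∞). For a patient, `z = (w − w̄_HC)/S_HC` where both the subject edge and
the reference are defined; a reference edge absent in the patient is NaN —
counted and reported separately, never treated as weakened. Weakened means
`z ≤ −3`, inclusive. Phase-transition counts take weakened edges with one
endpoint in each phase of a pair and normalize by the product of the phase
sizes `n_p · n_q`; division by `n_p + n_q` is available as an option since
the normalization phrase admits both readings, and the product matches the
explicitly stated proximal normalization. Transition families: the
epicentre-anchored pairs 1–2 … 1–5 and the sequential pairs 2–3, 3–4, 4–5;
both are always computed, since figure captions and text emphasize
different families.

## Proximal spread

Candidates for a phase pair (p < q) are unordered adjacent region pairs
with one region in each phase. A subject's count requires binarized atrophy
at *both* endpoints (the default reading of spread having occurred along
the pair; an either-end variant is a flag), normalized by `n_p · n_q`.

## Statistics

Welch's t (scipy) is reported with both the Satterthwaite df and the pooled
integer df `n1 + n2 − 2`, because published captions conventionally print
the pooled integer even for Welch's test; outputs label both. One-way ANOVA
has df (k − 1, N − k). Mann–Whitney U uses the asymptotic tie-corrected
normal approximation without continuity correction. Chi-square is Pearson's
without Yates correction. Regressions report the least-squares slope with
its t-test and Pearson's r with the exact t-transform p on n − 2 df (these
p-values coincide for simple regression). All tests are two-sided; no
multiple-comparison correction is applied by default (a Bonferroni option
exists for transition scans via the caller). The histology association
filters patients to disease duration ≤ 5 years (inclusive), pairs each
sampled (subject, region, tissue) %AO with the subject's mean z over edges
incident to the region, and fits one regression per tissue per group; fewer
than 3 pairs yields an absent result with a logged warning.

## Synthetic cohort generator

The generator emulates the study conditions rather than MRI physics. All
randomness derives from one root seed through keyed substreams (subject k's
covariates, volume noise and connectivity do not depend on cohort size).

**Atlas.** Centroids uniform in a 140 × 110 × 60 mm slab; adjacency is
symmetrized 5-nearest-neighbour contiguity, with any residual components
stitched through their closest pair so the graph is always connected.
Hemispheres split at the median x.

**Edges.** A cohort-level skeleton is drawn once per seed: edge (i, j)
exists with probability `exp(−d/60 mm)`. Mean weight decays with distance,
`μ(d) = 0.25 + 0.45·exp(−d/40 mm)`, keeping μ at least 4 SD inside the
clamp range; subject weights are `clip(μ + N(0, σ_w), 0.05, 1)` with
σ_w = 0.05. Edges go missing per subject with probability rising linearly
from 0.05 at distance 0 to 0.35 at the maximum connected distance,
*after* any weakening — so some damaged edges are unobserved, exercising
the NaN policy.

**Volumes.** `v = 2000 − 8·age + 1.5·10⁻³·ICV + N(0, 150)` mm³, ages
uniform 55–80, ICV normal (1.45·10⁶, 1.2·10⁵) mm³ — magnitudes typical of
a ~450-region cortical parcel scaled to 100 regions.

**Phases.** Eight regions per phase (8% of the atlas). The epicentre seeds
phase 1 together with its spatially nearest regions. Under the *distant*
mechanism, each later phase takes the unassigned regions with the strongest
long-range skeleton connections to the previous phase (long-range = above
the 75th percentile of connected-edge distances, the package's
operationalization of "long-distance"); the epicentre is the hub with the
highest long-range degree, matching the mechanism's premise that deep-layer
long-projection neurons drive it. Under the *proximal* mechanism, phases
grow as adjacency rings around a random top-strength hub.

**Atrophy.** The phase prevalences (0.95, 0.85, 0.75, 0.65, 0.55) are the
designed *observed* prevalence gradient. Because W-binarization flips
states at fixed rates (false-positive Φ(−0.5) ≈ 0.31, true-positive
Φ(depth − 0.5) ≈ 0.977 at the default atrophy depth of 2.5 σ_v), planting
probabilities are the confusion-matrix inversion of the targets, and each
region's atrophy count is planted as an exact quota of randomly assigned
subjects. Marginally each subject is atrophied with the planting
probability; the quota removes design-level sampling noise that would
otherwise exceed the 10%-wide phase-bin margins at n = 13–30 and make the
planted gradient itself ill-defined. Atrophy is realized in volumes (a
decrement of 2.5 σ_v before noise), so the full W-score path is exercised.

**Edge damage.** The distant mechanism decrements all long-range skeleton
edges incident to phase-1 hubs by Δ·σ_w with Δ = 4 HC-SD units — beyond
the z ≤ −3 detection threshold with margin for reference-estimation noise;
the proximal mechanism applies at most 10% as many decrements. Δ = 0 is an
explicit degenerate no-damage switch; values in (0, 3] are rejected as
undetectable by design.

**Histology.** A fixed panel of ~9 regions shared by all subjects —
epicentre hubs, one region per phase, and evenly spaced preserved regions —
mirrors standard-region autopsy sampling. Per tissue,
`%AO = clip(α + β·D + N(0, 0.8), 0, 100)` with α = 2, β = 2 and D the
node's mean planted edge decrement in SD units over incident skeleton
edges; since the measured mean edge z at a node is ≈ −D, %AO is negatively
coupled to edge integrity by construction.

**What passing tests do and do not show.** The generator plants clean,
separable mechanisms: no co-pathology, no spatial autocorrelation of
volume noise, no subject-level severity correlation across regions, no
atrophy–connectivity coupling beyond the planted decrements, and Gaussian
edge noise with a stable per-edge SD. Recovery of planted signals therefore
validates the *analysis chain* — that each stage measures what it claims
under its own assumptions — not that real FTLD cohorts satisfy those
assumptions.

## Problem sizes and runtime

Validation suites run at the study's scale: 100 regions with cohorts of
27/28/13 (and n = 30 disease cohorts for phase recovery, staged against a
synthetic normative control cohort of n = 170, mirroring the size of
published W-score reference cohorts); 20 replicate seeds for recovery and
mechanism contrasts, 100 replicates for histology, and a 1000-control
reference with 50 null patients for the z-score calibration. The full test
suite completes in well under a minute of compute for the generators plus
~15 s for exhaustive-oracle comparisons; `scripts/acceptance.py` takes
roughly half a minute.

## Known limitations

Phase recovery at n = 13 (the proximal-mechanism cohort size) is noisy:
ratio bins are 10% wide while one subject is ~8% of the denominator, so
epicentre membership can flip on single subjects — visible as a lower
epicentre Jaccard for the small cohort in the worked example. Global
network measures barely move under the planted mechanisms (damage is
confined to tens of edges), so group differences in global efficiency are
weak by design. The betweenness implementation is exact but O(n·m) per
subject; for atlases of several hundred regions expect minutes per cohort.
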