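"""Generator contracts: determinism, distributions, planted-truth structure."""

import numpy as np
import pytest
from scipy import stats as sps

from netphase.model import validate_inputs
from netphase.synthetic import (GeneratorParams, generate_atlas,
                                generate_disease_cohort, generate_hc_cohort,
                                generate_histology)


class TestAtlas:
    def test_same_seed_identical(self):
        a1 = generate_atlas(40, 5)
        a2 = generate_atlas(40, 5)
        np.testing.assert_array_equal(a1.centroids, a2.centroids)
        np.testing.assert_array_equal(a1.adjacency, a2.adjacency)
        assert a1.region_ids == a2.region_ids

    def test_adjacency_symmetric_false_diagonal(self):
        a = generate_atlas(30, 1)
        assert np.array_equal(a.adjacency, a.adjacency.T)
        assert not np.any(np.diag(a.adjacency))

    def test_adjacency_connected_over_seeds(self):
        """Contiguity graph is connected (breadth-first search oracle)."""
        for seed in range(20):
            a = generate_atlas(100, seed)
            n = a.n_regions
            reach = {0}
            frontier = [0]
            while frontier:
                v = frontier.pop()
                for u in np.flatnonzero(a.adjacency[v]):
                    if u not in reach:
                        reach.add(int(u))
                        frontier.append(int(u))
            assert len(reach) == n

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            generate_atlas(10, 0)


class TestParams:
    def test_prevalences_must_decrease(self):
        with pytest.raises(ValueError, match="strictly decreasing"):
            GeneratorParams(prevalences=(0.9, 0.9, 0.7, 0.6, 0.5))

    def test_delta_between_zero_and_three_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            GeneratorParams(delta=2.0)
        GeneratorParams(delta=0.0)       # degenerate no-weakening switch
        GeneratorParams(delta=4.0)


class TestHCCohort:
    def test_valid_and_deterministic(self):
        a = generate_atlas(30, 2)
        p = GeneratorParams(n_regions=30)
        c1 = generate_hc_cohort(a, p, 2, n_subjects=5)
        c2 = generate_hc_cohort(a, p, 2, n_subjects=5)
        assert validate_inputs(c1) == []
        for s1, s2 in zip(c1, c2):
            np.testing.assert_array_equal(s1.volumes, s2.volumes)
            np.testing.assert_array_equal(s1.connectivity, s2.connectivity)

    def test_subjects_stable_under_cohort_growth(self):
        """Adding subjects never reshuffles earlier subjects' data."""
        a = generate_atlas(30, 2)
        p = GeneratorParams(n_regions=30)
        small = generate_hc_cohort(a, p, 2, n_subjects=3)
        big = generate_hc_cohort(a, p, 2, n_subjects=6)
        for s1, s2 in zip(small, big):
            np.testing.assert_array_equal(s1.connectivity, s2.connectivity)

    def test_zero_weight_noise_gives_identical_defined_weights(self):
        a = generate_atlas(30, 3)
        p = GeneratorParams(n_regions=30, sigma_w=1e-12)
        c = generate_hc_cohort(a, p, 3, n_subjects=4)
        ref = c.subjects[0].connectivity
        for s in c.subjects[1:]:
            both = ~np.isnan(ref) & ~np.isnan(s.connectivity)
            np.testing.assert_allclose(s.connectivity[both], ref[both], atol=1e-9)

    def test_empirical_edge_sd_matches_sigma_w(self):
        a = generate_atlas(25, 4)
        p = GeneratorParams(n_regions=25, miss_base=0.0, miss_slope=0.0)
        c = generate_hc_cohort(a, p, 4, n_subjects=500)
        stack = c.connectivity_stack()
        iu, ju = np.nonzero(np.triu(~np.isnan(stack[0]), 1))
        sds = np.nanstd(stack[:, iu, ju], axis=0, ddof=1)
        # interior edges (no clamping): empirical SD within 10% of sigma_w
        means = np.nanmean(stack[:, iu, ju], axis=0)
        interior = (means > 0.05 + 4 * p.sigma_w) & (means < 1 - 4 * p.sigma_w)
        assert np.median(np.abs(sds[interior] - p.sigma_w)) < 0.1 * p.sigma_w

    def test_volume_regression_recovers_coefficients(self):
        a = generate_atlas(20, 5)
        p = GeneratorParams(n_regions=20)
        c = generate_hc_cohort(a, p, 5, n_subjects=500)
        X = np.column_stack([np.ones(500), [s.age for s in c], [s.icv for s in c]])
        V = c.volumes_matrix()
        coef, _, _, _ = np.linalg.lstsq(X, V, rcond=None)
        resid = V - X @ coef
        sd = np.sqrt((resid ** 2).sum(0) / (500 - 3))
        cov = np.linalg.inv(X.T @ X)
        for j, truth in enumerate((p.vol_intercept, p.vol_age_slope,
                                   p.vol_icv_slope)):
            se = sd * np.sqrt(cov[j, j])
            assert np.all(np.abs(coef[j] - truth) < 3 * se)


class TestDiseaseCohort:
    def test_invalid_mechanism_rejected(self):
        a = generate_atlas(30, 6)
        with pytest.raises(ValueError, match="mechanism"):
            generate_disease_cohort(a, GeneratorParams(n_regions=30), "osmosis", 6)

    def test_deterministic_truth(self):
        a = generate_atlas(40, 7)
        p = GeneratorParams(n_regions=40)
        c1, t1 = generate_disease_cohort(a, p, "distant", 7)
        c2, t2 = generate_disease_cohort(a, p, "distant", 7)
        np.testing.assert_array_equal(t1.planted_phase, t2.planted_phase)
        assert t1.planted_weak_edges == t2.planted_weak_edges
        for s1, s2 in zip(c1, c2):
            np.testing.assert_array_equal(s1.connectivity, s2.connectivity)

    def test_distant_has_many_more_weak_edges_than_proximal(self):
        a = generate_atlas(100, 8)
        p = GeneratorParams()
        _, distant = generate_disease_cohort(a, p, "distant", 8)
        _, proximal = generate_disease_cohort(a, p, "proximal", 8)
        assert len(distant.planted_weak_edges) >= \
            10 * max(len(proximal.planted_weak_edges), 1)

    def test_phase_one_nonempty_and_partition(self):
        a = generate_atlas(60, 9)
        p = GeneratorParams(n_regions=60)
        for mech in ("distant", "proximal"):
            _, truth = generate_disease_cohort(a, p, mech, 9)
            assert (truth.planted_phase == 1).sum() > 0
            assert set(np.unique(truth.planted_phase)) <= {0, 1, 2, 3, 4, 5}

    def test_degenerate_params_atrophy_everywhere_no_weak_edges(self):
        """Near-1 prevalences with delta = 0: full atrophy, no edge damage."""
        a = generate_atlas(40, 10)
        p = GeneratorParams(n_regions=40, delta=0.0,
                            prevalences=(1.0, 0.9999, 0.9998, 0.9997, 0.9996))
        cohort, truth = generate_disease_cohort(a, p, "distant", 10)
        assert len(truth.planted_weak_edges) == 0
        # every planting probability saturates at 1
        staged = truth.planted_phase > 0
        assert np.all(truth.planting_prob[staged] == 1.0)

    def test_atrophy_frequency_matches_planting_probability(self):
        """Quota assignment: per-region planted frequency sits at the centre
        of the binomial 99% CI around the planting probability."""
        a = generate_atlas(50, 11)
        p = GeneratorParams(n_regions=50)
        n = 1000
        cohort, truth = generate_disease_cohort(a, p, "distant", 11, n_subjects=n)
        freq = truth.planted_atrophy.mean(axis=0)
        staged = np.flatnonzero(truth.planted_phase > 0)
        for r in staged:
            lo, hi = sps.binom.interval(0.99, n, truth.planting_prob[r])
            assert lo / n <= freq[r] <= hi / n
        # atrophy is realized in volumes: atrophied subjects sit well below
        # the volume prediction in the epicentre
        r = staged[0]
        pred = np.array([
            p.vol_intercept + p.vol_age_slope * s.age + p.vol_icv_slope * s.icv
            for s in cohort])
        resid = np.array([s.volumes[r] for s in cohort]) - pred
        atro = truth.planted_atrophy[:, r]
        assert resid[atro].mean() < resid[~atro].mean() - p.sigma_v

    def test_planted_weak_edges_lie_on_existing_edges(self):
        a = generate_atlas(60, 12)
        p = GeneratorParams(n_regions=60)
        cohort, truth = generate_disease_cohort(a, p, "distant", 12)
        stack = cohort.connectivity_stack()
        ever_defined = ~np.isnan(stack)
        for (i, j) in truth.planted_weak_edges:
            # the edge exists in the skeleton: some subject realizes it
            assert ever_defined[:, i, j].any()


class TestHistology:
    def _cohort(self, seed=13):
        a = generate_atlas(60, seed)
        p = GeneratorParams(n_regions=60)
        cohort, truth = generate_disease_cohort(a, p, "distant", seed)
        return a, p, cohort, truth

    def test_values_bounded(self):
        _, p, cohort, truth = self._cohort()
        histo = generate_histology(cohort, truth, p, 13)
        assert histo["pct_area_occupied"].between(0, 100).all()
        assert set(histo["tissue"]) == {"GM", "WM"}

    def test_noise_free_undamaged_region_equals_alpha(self):
        a, p0, cohort, truth = self._cohort(14)
        p = GeneratorParams(n_regions=60, histo_noise_sd=1e-12)
        histo = generate_histology(cohort, truth, p, 14)
        damaged = {i for pair in truth.planted_weak_edges for i in pair}
        ids = [cohort.atlas.region_ids[i] for i in range(60) if i not in damaged]
        clean = histo[histo["region_id"].isin(ids)]
        assert not clean.empty
        np.testing.assert_allclose(clean["pct_area_occupied"], p.histo_alpha,
                                   atol=1e-6)

    def test_regression_on_planted_decrement_recovers_beta(self):
        """Pooled regression of %AO on the planted node decrement recovers
        the coupling slope within 2 SE (and %AO falls with edge integrity)."""
        import netphase.synthetic as syn

        xs, ys = [], []
        for seed in range(20, 30):
            a = generate_atlas(60, seed)
            p = GeneratorParams(n_regions=60)
            cohort, truth = generate_disease_cohort(a, p, "distant", seed,
                                                    n_subjects=20)
            histo = generate_histology(cohort, truth, p, seed)
            exists, _, _, _ = syn._edge_skeleton(a, p, seed)
            dec = np.zeros((60, 60))
            for (i, j), d in truth.planted_weak_edges.items():
                dec[i, j] = dec[j, i] = d
            node_dec = dec.sum(1) / np.maximum(exists.sum(1), 1)
            idx = {rid: k for k, rid in enumerate(a.region_ids)}
            gm = histo[histo["tissue"] == "GM"]
            xs += [node_dec[idx[r]] for r in gm["region_id"]]
            ys += gm["pct_area_occupied"].tolist()
        slope, _, _, _, se = sps.linregress(xs, ys)[:5]
        p0 = GeneratorParams()
        assert slope > 0                        # %AO rises with damage
        assert abs(slope - p0.histo_beta) < 2 * se
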