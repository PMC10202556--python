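"""Edge reference construction, z-scoring, weak-edge and transition counts."""

import numpy as np
import pytest

from netphase.edges import (build_edge_reference, edge_zscores,
                            hub_connected_fraction, missing_reference_edges,
                            node_mean_edge_z, transition_edge_stats, weak_edges,
                            whole_brain_mean_z)
from netphase.hubs import HubSet
from netphase.model import Cohort, SubjectRecord
from netphase.staging import PhaseAssignment

from conftest import make_atlas, make_cohort, random_connectivity


def _cohort_from_matrices(mats):
    n = mats[0].shape[0]
    atlas = make_atlas(n)
    subs = [SubjectRecord(subject_id=f"HC{i:03d}", group="HC", age=60.0,
                          icv=1.4e6, volumes=np.full(n, 3000.0),
                          connectivity=m) for i, m in enumerate(mats)]
    return Cohort(label="HC", subjects=subs, atlas=atlas)


class TestEdgeReference:
    def test_zero_variance_edge_unusable(self):
        mats = []
        for _ in range(6):
            m = np.full((6, 6), np.nan)
            m[0, 1] = m[1, 0] = 0.5            # constant across subjects
            m[0, 2] = m[2, 0] = np.random.uniform(0.3, 0.7)
            mats.append(m)
        ref = build_edge_reference(_cohort_from_matrices(mats), min_obs=5)
        assert not ref.usable[0, 1]

    def test_too_few_observations_unusable(self):
        rng = np.random.default_rng(0)
        mats = [random_connectivity(rng, 6, missing_frac=0.0) for _ in range(6)]
        for m in mats[:3]:
            m[2, 3] = m[3, 2] = np.nan         # edge defined in only 3 of 6
        ref = build_edge_reference(_cohort_from_matrices(mats), min_obs=5)
        assert not ref.usable[2, 3]
        assert ref.n_obs[2, 3] == 3

    def test_matches_per_edge_mean_sd_oracle(self):
        rng = np.random.default_rng(1)
        mats = [random_connectivity(rng, 7, missing_frac=0.3) for _ in range(12)]
        ref = build_edge_reference(_cohort_from_matrices(mats), min_obs=5)
        for i in range(7):
            for j in range(i + 1, 7):
                vals = [m[i, j] for m in mats if not np.isnan(m[i, j])]
                if len(vals) >= 5 and np.std(vals, ddof=1) > 0:
                    assert ref.mean[i, j] == pytest.approx(np.mean(vals), abs=1e-12)
                    assert ref.sd[i, j] == pytest.approx(np.std(vals, ddof=1),
                                                         abs=1e-12)
                else:
                    assert not ref.usable[i, j]


def _simple_reference(n=4, mean=0.5, sd=0.05):
    ref_mean = np.full((n, n), mean)
    ref_sd = np.full((n, n), sd)
    np.fill_diagonal(ref_mean, np.nan)
    np.fill_diagonal(ref_sd, np.nan)
    from netphase.edges import EdgeReference
    return EdgeReference(mean=ref_mean, sd=ref_sd,
                         n_obs=np.full((n, n), 10), min_obs=5)


class TestZScores:
    def test_weight_at_reference_mean_gives_zero(self):
        ref = _simple_reference()
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, np.nan)
        z = edge_zscores(w, ref)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(z[off], 0.0, atol=1e-12)

    def test_exact_minus_three_is_weak_inclusive(self):
        ref = _simple_reference(mean=0.5, sd=0.05)
        w = np.full((4, 4), 0.5)
        w[0, 1] = w[1, 0] = 0.35              # z = -3 exactly
        np.fill_diagonal(w, np.nan)
        z = edge_zscores(w, ref)
        assert z[0, 1] == pytest.approx(-3.0, abs=1e-12)
        assert (0, 1) in weak_edges(z)

    def test_missing_subject_edge_excluded_everywhere(self):
        ref = _simple_reference()
        w = np.full((4, 4), 0.2)              # all z = -6
        w[0, 1] = w[1, 0] = np.nan
        np.fill_diagonal(w, np.nan)
        z = edge_zscores(w, ref)
        assert np.isnan(z[0, 1])
        assert (0, 1) not in weak_edges(z)
        assert missing_reference_edges(w, ref) == 1

    def test_symmetry_everywhere_defined(self, rng):
        ref = _simple_reference(6)
        w = random_connectivity(rng, 6)
        z = edge_zscores(w, ref)
        np.testing.assert_array_equal(np.isnan(z), np.isnan(z.T))
        mask = ~np.isnan(z)
        np.testing.assert_allclose(z[mask], z.T[mask], atol=1e-12)

    def test_decreasing_weight_keeps_edge_weak(self, rng):
        """Monotonicity: lowering a defined weight never un-weakens it."""
        ref = _simple_reference(5)
        w = random_connectivity(rng, 5, missing_frac=0.0)
        z = edge_zscores(w, ref)
        before = weak_edges(z)
        w2 = w.copy()
        w2[0, 1] = w2[1, 0] = max(w[0, 1] - 0.2, 0.01)
        after = weak_edges(edge_zscores(w2, ref))
        assert before <= after


class TestWeakEdges:
    def test_no_weak_edges_when_all_zero(self):
        assert weak_edges(np.zeros((5, 5))) == set()

    def test_matches_threshold_oracle(self, rng):
        z = rng.normal(0, 2, (8, 8))
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        expected = {(i, j) for i in range(8) for j in range(i + 1, 8)
                    if z[i, j] <= -3}
        assert weak_edges(z) == expected


class TestTransitionStats:
    def _phases(self, codes):
        codes = np.asarray(codes)
        return PhaseAssignment(phases=codes, ratios=np.zeros(len(codes)))

    def test_empty_weak_set_counts_zero(self):
        st = transition_edge_stats(set(), self._phases([1, 1, 2, 2]), (1, 2))
        assert st["count"] == 0.0 and st["normalized"] == 0.0

    def test_within_phase_edge_excluded(self):
        phases = self._phases([1, 1, 2, 2])
        st = transition_edge_stats({(0, 1)}, phases, (1, 2))
        assert st["count"] == 0.0

    def test_empty_phase_normalization_absent(self):
        phases = self._phases([1, 1, 0, 0])
        st = transition_edge_stats({(0, 2)}, phases, (1, 3))
        assert st["normalized"] is None

    def test_matches_pair_scan_oracle(self, rng):
        for _ in range(20):
            codes = rng.integers(0, 6, 12)
            phases = self._phases(codes)
            weak = {(int(i), int(j))
                    for i, j in zip(*np.triu_indices(12, 1))
                    if rng.random() < 0.3}
            for p, q in [(1, 2), (1, 5), (2, 3)]:
                st = transition_edge_stats(weak, phases, (p, q))
                expected = sum(
                    1 for (i, j) in weak
                    if {codes[i], codes[j]} == {p, q})
                assert st["count"] == expected
                n_p, n_q = (codes == p).sum(), (codes == q).sum()
                if n_p and n_q:
                    assert st["normalized"] == pytest.approx(expected / (n_p * n_q))

    def test_sum_normalization_option(self):
        phases = self._phases([1, 1, 2, 2, 2, 0])
        st = transition_edge_stats({(0, 2)}, phases, (1, 2), normalization="sum")
        assert st["normalized"] == pytest.approx(1 / 5)


class TestHubConnectedFraction:
    def _phases(self, codes):
        return PhaseAssignment(phases=np.asarray(codes), ratios=np.zeros(len(codes)))

    def test_no_hub_endpoints_zero(self):
        hubs = HubSet(members={5}, reasons={5: {"strength"}})
        frac = hub_connected_fraction({(0, 2)}, hubs, self._phases([1, 1, 2, 2, 0, 0]),
                                      (1, 2))
        assert frac == 0.0

    def test_all_edges_touch_hubs_100(self):
        hubs = HubSet(members={0}, reasons={0: {"strength"}})
        frac = hub_connected_fraction({(0, 2), (0, 3)}, hubs,
                                      self._phases([1, 1, 2, 2, 0, 0]), (1, 2))
        assert frac == pytest.approx(100.0)

    def test_absent_when_no_cross_phase_edges(self):
        hubs = HubSet(members={0}, reasons={0: {"strength"}})
        assert hub_connected_fraction(set(), hubs, self._phases([1, 1, 2, 2]),
                                      (1, 2)) is None

    def test_matches_counting_oracle(self, rng):
        codes = rng.integers(0, 4, 10)
        phases = self._phases(codes)
        weak = {(int(i), int(j)) for i, j in zip(*np.triu_indices(10, 1))
                if rng.random() < 0.4}
        hub_set = set(map(int, rng.choice(10, 3, replace=False)))
        hubs = HubSet(members=hub_set, reasons={i: {"strength"} for i in hub_set})
        cross = [(i, j) for (i, j) in weak if {codes[i], codes[j]} == {1, 2}]
        got = hub_connected_fraction(weak, hubs, phases, (1, 2))
        if not cross:
            assert got is None
        else:
            expected = 100 * sum(1 for (i, j) in cross
                                 if i in hub_set or j in hub_set) / len(cross)
            assert got == pytest.approx(expected)


class TestMeanZ:
    def test_constant_matrix_mean(self):
        z = np.full((4, 4), -1.0)
        np.fill_diagonal(z, np.nan)
        assert whole_brain_mean_z(z) == pytest.approx(-1.0)

    def test_node_mean_arithmetic(self):
        z = np.full((3, 3), np.nan)
        z[0, 1] = z[1, 0] = -3.0
        z[0, 2] = z[2, 0] = 1.0
        assert node_mean_edge_z(z, 0) == pytest.approx(-1.0)

    def test_all_missing_absent(self):
        z = np.full((3, 3), np.nan)
        assert whole_brain_mean_z(z) is None
        assert node_mean_edge_z(z, 0) is None

    def test_masked_mean_oracle(self, rng):
        z = rng.normal(0, 1, (7, 7))
        z = (z + z.T) / 2
        z[rng.random((7, 7)) < 0.3] = np.nan
        z = np.where(np.isnan(z) | np.isnan(z.T), np.nan, z)
        np.fill_diagonal(z, np.nan)
        iu = np.triu_indices(7, 1)
        vals = z[iu][~np.isnan(z[iu])]
        if vals.size:
            assert whole_brain_mean_z(z) == pytest.approx(vals.mean())
        for node in range(7):
            row = np.delete(z[node], node)
            row = row[~np.isnan(row)]
            got = node_mean_edge_z(z, node)
            if row.size:
                assert got == pytest.approx(row.mean())
            else:
                assert got is None
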