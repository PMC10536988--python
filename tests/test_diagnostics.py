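import numpy as np
import pytest

from conftest import make_distance_matrix
from oracles import silhouette_brute_force
from trajclust.clustering import ClusterLabels
from trajclust.diagnostics import (
    cluster_center_timeseries,
    population_split,
    select_representatives,
    silhouette,
)
from trajclust.errors import (
    ContractError,
    FeatureUnavailableError,
    ValidationError,
)
from trajclust.trajectory_io import TrajectoryEnsemble
from test_features import fm_from_values


def labels_of(arr, eps=1.0, min_pts=1):
    arr = np.asarray(arr, dtype=int)
    return ClusterLabels(labels=arr, is_core=arr >= 0,
                         eps=eps, min_pts=min_pts)


class TestSilhouette:
    def test_four_point_worked_example(self):
        """C1 = {0, 1}, C2 = {10, 11}: outer points have a=1, b=10.5
        (s = 0.904762); inner points have a=1, b=9.5 (s = 0.894737)."""
        dm = make_distance_matrix([0.0, 1.0, 10.0, 11.0])
        rep = silhouette(dm, labels_of([0, 0, 1, 1]))
        np.testing.assert_allclose(
            rep.s_i, [9.5 / 10.5, 8.5 / 9.5, 8.5 / 9.5, 9.5 / 10.5]
        )
        assert rep.s_avg == pytest.approx(0.899749, abs=1e-6)

    def test_equidistant_point_scores_zero(self):
        # point at 1.0 in C1={0,2,1}: a = mean(1,1) = 1; C2={2} gives b = 1
        dm = make_distance_matrix([0.0, 2.0, 1.0, 2.0])
        rep = silhouette(dm, labels_of([0, 0, 0, 1]))
        i = 2
        assert rep.a_i[i] == pytest.approx(rep.b_i[i])
        assert rep.s_i[i] == pytest.approx(0.0)

    def test_noise_excluded(self):
        dm = make_distance_matrix([0.0, 1.0, 10.0, 11.0, 50.0])
        rep = silhouette(dm, labels_of([0, 0, 1, 1, -1]))
        assert np.isnan(rep.s_i[4])
        assert rep.s_avg == pytest.approx(np.mean(rep.s_i[:4]))

    def test_requires_two_clusters(self):
        dm = make_distance_matrix([0.0, 1.0, 2.0])
        with pytest.raises(ValidationError):
            silhouette(dm, labels_of([0, 0, 0]))

    def test_size_mismatch_rejected(self):
        dm = make_distance_matrix([0.0, 1.0, 2.0])
        with pytest.raises(ContractError):
            silhouette(dm, labels_of([0, 1]))

    def test_singleton_cluster_scores_zero(self):
        dm = make_distance_matrix([0.0, 1.0, 10.0])
        rep = silhouette(dm, labels_of([0, 0, 1]))
        assert rep.s_i[2] == 0.0

    def test_matches_brute_force(self):
        """Full floating-point agreement with naive double loops on random
        labeled instances."""
        rng = np.random.default_rng(31)
        for _ in range(25):
            n = int(rng.integers(6, 25))
            pts = rng.normal(size=(n, 2)) + rng.integers(0, 3, size=(n, 1)) * 4
            dm = make_distance_matrix(pts)
            lab = rng.integers(0, 3, size=n)
            lab[rng.random(n) < 0.15] = -1
            if len(set(lab[lab >= 0])) < 2:
                continue
            # relabel to consecutive ids
            ids = {c: k for k, c in enumerate(sorted(set(lab[lab >= 0])))}
            lab = np.array([ids.get(c, -1) for c in lab])
            rep = silhouette(dm, labels_of(lab))
            s_ref, s_avg_ref = silhouette_brute_force(dm.values, lab)
            np.testing.assert_array_equal(
                np.nan_to_num(rep.s_i, nan=99.0),
                np.nan_to_num(s_ref, nan=99.0),
            )
            assert rep.s_avg == s_avg_ref

    def test_matches_sklearn_without_noise(self):
        from sklearn.metrics import silhouette_samples, silhouette_score

        rng = np.random.default_rng(32)
        pts = np.vstack([rng.normal(size=(8, 2)),
                         rng.normal(size=(8, 2)) + 6])
        dm = make_distance_matrix(pts)
        lab = np.array([0] * 8 + [1] * 8)
        rep = silhouette(dm, labels_of(lab))
        sk = silhouette_samples(dm.values, lab, metric="precomputed")
        np.testing.assert_allclose(rep.s_i, sk, atol=1e-12)
        assert rep.s_avg == pytest.approx(
            silhouette_score(dm.values, lab, metric="precomputed")
        )

    def test_permutation_invariance(self):
        dm = make_distance_matrix([0.0, 1.0, 10.0, 11.0, 20.0, 21.0])
        lab = np.array([0, 0, 1, 1, 2, 2])
        rep1 = silhouette(dm, labels_of(lab))
        perm = np.array([2, 2, 0, 0, 1, 1])
        rep2 = silhouette(dm, labels_of(perm))
        np.testing.assert_allclose(rep1.s_i, rep2.s_i)
        assert rep1.s_avg == rep2.s_avg

    def test_separation_bound(self):
        """For two planted clusters, every s_i >= 1 - m/M with m the max
        intra- and M the min inter-cluster distance."""
        rng = np.random.default_rng(33)
        a = rng.normal(scale=0.3, size=(10, 2))
        b = rng.normal(scale=0.3, size=(10, 2)) + 8
        pts = np.vstack([a, b])
        dm = make_distance_matrix(pts)
        lab = labels_of([0] * 10 + [1] * 10)
        d = dm.values
        intra = max(d[:10, :10].max(), d[10:, 10:].max())
        inter = d[:10, 10:].min()
        rep = silhouette(dm, lab)
        assert np.all(rep.s_i >= 1 - intra / inter - 1e-12)

    def test_literal_denominator_option(self):
        dm = make_distance_matrix([0.0, 1.0, 10.0, 11.0])
        lab = labels_of([0, 0, 1, 1])
        std = silhouette(dm, lab)
        lit = silhouette(dm, lab, intra_denominator="literal")
        # literal |C_I| halves a_i for 2-member clusters
        np.testing.assert_allclose(lit.a_i, std.a_i / 2)
        assert lit.s_avg > std.s_avg

    def test_range_invariant(self):
        rng = np.random.default_rng(34)
        pts = rng.normal(size=(20, 2))
        dm = make_distance_matrix(pts)
        lab = labels_of(rng.integers(0, 3, size=20))
        rep = silhouette(dm, lab)
        defined = ~np.isnan(rep.s_i)
        assert np.all(rep.s_i[defined] >= -1) and np.all(rep.s_i[defined] <= 1)


class TestClusterCenters:
    def test_single_member_cluster(self):
        vals = np.random.default_rng(1).normal(size=(3, 5, 2))
        fm = fm_from_values(vals)
        cc = cluster_center_timeseries(fm, labels_of([0, 1, 1]))
        np.testing.assert_allclose(cc.centers[0], vals[0])
        np.testing.assert_allclose(cc.spreads[0], 0.0)

    def test_symmetric_members_center_on_midline(self):
        mid = np.linspace(0, 1, 5)[None, :, None]
        vals = np.concatenate([mid + 0.3, mid - 0.3, np.zeros_like(mid)])
        fm = fm_from_values(vals)
        cc = cluster_center_timeseries(fm, labels_of([0, 0, 1]))
        np.testing.assert_allclose(cc.centers[0], mid[0], atol=1e-12)
        np.testing.assert_allclose(cc.spreads[0], 0.3, atol=1e-12)

    def test_noise_excluded(self):
        vals = np.random.default_rng(2).normal(size=(4, 5, 1))
        fm = fm_from_values(vals)
        cc = cluster_center_timeseries(fm, labels_of([0, 0, 1, -1]))
        np.testing.assert_allclose(cc.centers[0], vals[:2].mean(axis=0))

    def test_synthetic_centers_converge_to_channel_targets(self, small_spec,
                                                           small_pipeline):
        fm = small_pipeline["fm"]
        truth = small_pipeline["labels"]
        cc = cluster_center_timeseries(fm, labels_of(truth))
        for c, ch in enumerate(small_spec.channels):
            final = cc.centers[c, -1, :]
            for f, target in enumerate(ch.targets):
                tol = 2 * small_spec.noise_sd[f] + ch.osc_amplitude[f] \
                    + abs(target - small_spec.start[f]) * np.exp(
                        -ch.rate * (small_spec.n_time - ch.onset))
                assert abs(final[f] - target) < tol + 1.0

    def test_band_options(self):
        vals = np.random.default_rng(3).normal(size=(6, 4, 1))
        fm = fm_from_values(vals)
        lab = labels_of([0, 0, 0, 1, 1, 1])
        for band in ("std", "percentile", "minmax"):
            cc = cluster_center_timeseries(fm, lab, band=band)
            assert cc.spreads.shape == cc.centers.shape
        with pytest.raises(ValidationError):
            cluster_center_timeseries(fm, lab, band="iqr-ish")


class TestRepresentatives:
    def test_singleton_cluster(self):
        dm = make_distance_matrix([0.0, 5.0, 6.0])
        reps = select_representatives(dm, labels_of([0, 1, 1]), k=1)
        assert reps[0] == [0]

    def test_medoid_of_three(self):
        """Points {0, 1, 10}: totals 11, 10, 19 -> medoid is the middle."""
        dm = make_distance_matrix([0.0, 1.0, 10.0])
        reps = select_representatives(dm, labels_of([0, 0, 0, ]), k=1)
        assert reps[0] == [1]

    def test_k_two_of_three(self):
        dm = make_distance_matrix([0.0, 1.0, 10.0])
        reps = select_representatives(dm, labels_of([0, 0, 0]), k=2)
        assert reps[0] == [1, 0]

    def test_k_truncated_with_warning(self, caplog):
        import logging

        dm = make_distance_matrix([0.0, 1.0])
        with caplog.at_level(logging.WARNING):
            reps = select_representatives(dm, labels_of([0, 0]), k=5)
        assert len(reps[0]) == 2

    def test_tie_broken_by_index(self):
        dm = make_distance_matrix([0.0, 2.0, 1.0, 1.0])
        # points at 1.0 (indices 2, 3) tie on total distance
        reps = select_representatives(dm, labels_of([0, 0, 0, 0]), k=1)
        assert reps[0] == [2]


class TestPopulationSplit:
    def make_ensemble(self, populations):
        populations = np.asarray(populations, dtype=float)
        n_traj, n_time, _ = populations.shape
        return TrajectoryEnsemble(
            times=np.arange(n_time, dtype=float),
            coords=np.zeros((n_traj, n_time, 1, 3)),
            atom_symbols=["C"],
            traj_ids=[f"t{i}" for i in range(n_traj)],
            populations=populations,
        )

    def test_all_ground_state_fraction_one(self):
        pop = np.zeros((3, 4, 2))
        pop[..., 0] = 1.0
        ens = self.make_ensemble(pop)
        scatter, summary = population_split(ens, labels_of([0, 0, 1]), t=3.0)
        assert summary["dominant_a_fraction"].tolist() == [1.0, 1.0]

    def test_tie_on_line_not_dominant(self):
        pop = np.full((2, 3, 2), 0.5)
        ens = self.make_ensemble(pop)
        _, summary = population_split(ens, labels_of([0, 1]), t=2.0)
        assert summary["dominant_a_fraction"].tolist() == [0.0, 0.0]

    def test_missing_populations_error(self):
        ens = self.make_ensemble(np.full((2, 3, 2), 0.5))
        ens = TrajectoryEnsemble(
            times=ens.times, coords=ens.coords,
            atom_symbols=ens.atom_symbols, traj_ids=ens.traj_ids,
        )
        with pytest.raises(FeatureUnavailableError):
            population_split(ens, labels_of([0, 1]), t=2.0)

    def test_nearest_frame_matching(self):
        pop = np.zeros((1, 4, 2))
        pop[0, :, 0] = [0.0, 0.2, 0.8, 1.0]
        pop[0, :, 1] = 1.0 - pop[0, :, 0]
        ens = self.make_ensemble(pop)
        scatter, _ = population_split(ens, labels_of([0]), t=2.2)
        assert scatter["P_a"].iloc[0] == pytest.approx(0.8)

    def test_synthetic_channels_correlate_with_states(self):
        """Ground-state channels show a dominant-S0 fraction above 0.9 at
        the final time; the excited channel stays S1-dominant.  The full
        150 fs window is needed for the population ramp to saturate."""
        from dataclasses import replace

        from trajclust.synthetic import default_spec, generate

        spec = replace(default_spec(seed=13), n_traj=24)
        _, truth, pops = generate(spec)
        ens = self.make_ensemble(pops)
        _, summary = population_split(
            ens, labels_of(truth), t=float(ens.times[-1])
        )
        for c, ch in enumerate(spec.channels):
            frac = summary.loc[summary["cluster"] == c,
                               "dominant_a_fraction"].iloc[0]
            if ch.dominant_state == 0:
                assert frac > 0.9
            else:
                assert frac < 0.1
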