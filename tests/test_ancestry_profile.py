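"""NNLS profile fit against a projected-gradient oracle, bootstrap
mechanics and the bootstrap difference test."""

import numpy as np
import pytest

from hapfine import ancestry_profile as ap
from hapfine import simdata
from hapfine.cluster_eval import ClusterModel
from hapfine.painting import CoancestryMatrix

from conftest import coancestry_from_sim


def row(vals, cluster="c", n=1):
    vals = np.asarray(vals, dtype=float)
    return ap.CharacteristicRow(vals, [f"d{i}" for i in range(len(vals))], cluster, n)


def project_simplex(v):
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1
    rho = np.flatnonzero(u - css / np.arange(1, len(v) + 1) > 0)[-1]
    return np.maximum(v - css[rho] / (rho + 1), 0.0)


def projected_gradient_fit(a, y, n_iter=200_000):
    """Slow simplex-constrained least squares (independent oracle)."""
    beta = np.full(a.shape[1], 1.0 / a.shape[1])
    step = 1.0 / np.linalg.norm(a, 2) ** 2
    for _ in range(n_iter):
        beta = project_simplex(beta - step * a.T @ (a @ beta - y))
    return beta


class TestClusterMeanRow:
    def test_single_recipient_cluster_is_its_row(self, simulated_coancestry):
        total, _, clusters = coancestry_from_sim(simulated_coancestry)
        rid = clusters.members("T0")[0]
        single = ClusterModel({**clusters.assignment, rid: "solo"})
        got = ap.cluster_mean_row(total, single, "solo")
        np.testing.assert_array_equal(
            got.values, total.values[total.recipient_ids.index(rid)])

    def test_mean_of_two_rows(self):
        mat = CoancestryMatrix(np.array([[0.0, 1, 3], [3, 0, 1], [1, 3, 0]]),
                               ["a", "b", "c"])
        clusters = ClusterModel({"a": "g", "b": "g", "c": "h"})
        got = ap.cluster_mean_row(mat, clusters, "g", donor_ids=["c"])
        np.testing.assert_allclose(got.values, [2.0])

    def test_recipient_order_irrelevant_and_empty_rejected(self):
        mat = CoancestryMatrix(np.array([[0.0, 2], [2, 0.0]]), ["a", "b"])
        clusters = ClusterModel({"a": "g", "b": "g"})
        fwd = ap.cluster_mean_row(mat, clusters, "g", donor_ids=["a", "b"]).values
        rev = ap.cluster_mean_row(
            CoancestryMatrix(mat.values[::-1, ::-1], ["b", "a"]), clusters, "g",
            donor_ids=["a", "b"]).values
        np.testing.assert_allclose(fwd, rev)
        with pytest.raises(ValueError, match="empty"):
            ap.cluster_mean_row(mat, clusters, "nope")


class TestFitProfile:
    def test_exact_member_recovers_unit_vector(self):
        rng = np.random.default_rng(1)
        xs = [row(rng.random(8), f"g{i}") for i in range(3)]
        prof = ap.fit_profile(row(xs[1].values, "y"), xs)
        np.testing.assert_allclose(prof.beta, [0, 1, 0], atol=1e-9)

    def test_exact_mixture_recovered(self):
        rng = np.random.default_rng(2)
        xs = [row(rng.random(10), f"g{i}") for i in range(2)]
        y = row(0.3 * xs[0].values + 0.7 * xs[1].values, "y")
        prof = ap.fit_profile(y, xs)
        np.testing.assert_allclose(prof.beta, [0.3, 0.7], atol=1e-6)

    def test_objective_matches_projected_gradient_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.random((12, 5))
        y = rng.random(12)
        prof = ap.fit_profile(row(y, "y"), [row(a[:, g], f"g{g}") for g in range(5)])
        oracle = projected_gradient_fit(a, y)
        obj_oracle = float(np.sum((y - a @ oracle) ** 2))
        assert prof.objective <= obj_oracle + 1e-6
        assert abs(prof.objective - obj_oracle) < 1e-6

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ap.fit_profile(row([1.0, 2.0]), [])
        with pytest.raises(ValueError, match="zero"):
            ap.fit_profile(row([1.0, 2.0]), [row([0.0, 0.0])])


class TestRecovery:
    def test_identity_profile_recovered_at_large_chunk_count(self):
        sim = simdata.simulate_coancestry(
            [20, 20, 20], np.eye(3), 1_000_000, noise_seed=4, n_per_target=10)
        total, _, clusters = coancestry_from_sim(sim)
        xs = [ap.cluster_mean_row(total, clusters, g) for g in sim.donor_labels]
        for t, lab in enumerate(sim.target_labels):
            prof = ap.fit_profile(ap.cluster_mean_row(total, clusters, lab), xs)
            np.testing.assert_allclose(prof.beta, np.eye(3)[t], atol=0.01)

    def test_admixed_profile_recovered(self, simulated_coancestry):
        total, _, clusters = coancestry_from_sim(simulated_coancestry)
        xs = [ap.cluster_mean_row(total, clusters, g)
              for g in simulated_coancestry.donor_labels]
        prof = ap.fit_profile(ap.cluster_mean_row(total, clusters, "T0"), xs)
        assert np.abs(prof.beta - [0.3, 0.7, 0.0]).mean() <= 0.03

    def test_identical_donor_clusters_sum_identified(self):
        # donor clusters 0 and 1 get identical characteristic rows by
        # construction: split one cluster's columns in half
        sim = simdata.simulate_coancestry(
            [30, 30], [[0.6, 0.4]], 100_000, noise_seed=5, n_per_target=20)
        total, _, clusters = coancestry_from_sim(sim)
        xs = [ap.cluster_mean_row(total, clusters, g) for g in sim.donor_labels]
        # duplicate donor cluster 0 as a third, identical signature
        xs.append(ap.CharacteristicRow(xs[0].values.copy(), xs[0].donor_ids,
                                       "D0bis", xs[0].n_recipients))
        prof = ap.fit_profile(ap.cluster_mean_row(total, clusters, "T0"), xs)
        assert prof.beta[0] + prof.beta[2] == pytest.approx(0.6, abs=0.02)
        assert prof.beta[1] == pytest.approx(0.4, abs=0.02)


class TestBootstrap:
    def test_singleton_cluster_gives_constant_profiles(self, simulated_coancestry):
        total, per, clusters = coancestry_from_sim(simulated_coancestry)
        rid = clusters.members("T0")[0]
        single = ClusterModel({**clusters.assignment, rid: "solo"})
        xs = [ap.cluster_mean_row(total, single, g)
              for g in simulated_coancestry.donor_labels]
        boot = ap.bootstrap_profiles([total], single, "solo", xs, 50, seed=1)
        assert np.ptp(boot.samples, axis=0).max() == 0

    def test_fixed_seed_reproducible(self, simulated_coancestry):
        total, per, clusters = coancestry_from_sim(simulated_coancestry)
        xs = [ap.cluster_mean_row(total, clusters, g)
              for g in simulated_coancestry.donor_labels]
        a = ap.bootstrap_profiles([total], clusters, "T0", xs, 30, seed=9)
        b = ap.bootstrap_profiles([total], clusters, "T0", xs, 30, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_replicates_stay_on_simplex(self, simulated_coancestry):
        total, per, clusters = coancestry_from_sim(simulated_coancestry)
        xs = [ap.cluster_mean_row(total, clusters, g)
              for g in simulated_coancestry.donor_labels]
        boot = ap.bootstrap_profiles(per, clusters, "T0", xs, 40, seed=2)
        assert (boot.samples >= -1e-12).all()
        np.testing.assert_allclose(boot.samples.sum(axis=1), 1.0, atol=1e-9)


class TestDifferenceTest:
    def test_null_observed_difference_gives_p_near_one(self):
        rng = np.random.default_rng(0)
        b = rng.normal(0.5, 0.05, 1000)
        g = rng.normal(0.5, 0.05, 1000)
        assert ap.profile_difference_test(0.5, 0.5, b, g) >= 0.8

    def test_tail_count_arithmetic_25_of_1000_gives_005(self):
        # observed difference 0.1; exactly 25 centred replicates at/above it
        d = 0.1
        x = np.concatenate([np.full(25, d + 0.01), np.full(975, 0.0)])
        boot_beta = x + d  # so (boot - 0) - d == x
        boot_gamma = np.zeros(1000)
        assert ap.profile_difference_test(d, 0.0, boot_beta, boot_gamma) == \
            pytest.approx(0.05)

    def test_doubling_capped_at_one_and_floor_flag(self):
        b = np.full(100, 0.0)
        g = np.full(100, 0.0)
        assert ap.profile_difference_test(0.0, 0.0, b, g) == 1.0
        far = ap.profile_difference_test(0.9, 0.0, b + 0.0, g)
        assert far == 0.0
        assert ap.profile_difference_test(0.9, 0.0, b, g, floor=True) == \
            pytest.approx(2 / 100)

    def test_empty_bootstrap_rejected(self):
        with pytest.raises(ValueError):
            ap.profile_difference_test(0, 0, np.array([]), np.array([]))


class TestProfileCI:
    def test_constant_samples_zero_width(self):
        boot = ap.BootstrapProfiles(np.tile([0.2, 0.8], (50, 1)), ["a", "b"],
                                    "t", 0)
        ci = ap.profile_ci(boot)
        np.testing.assert_allclose(ci[:, 0], ci[:, 1])
        np.testing.assert_allclose(ci[:, 0], [0.2, 0.8])

    def test_matches_order_statistic_formula(self):
        vals = np.arange(1, 1001) / 1000.0
        boot = ap.BootstrapProfiles(
            np.column_stack([vals, 1 - vals]), ["a", "b"], "t", 0)
        ci = ap.profile_ci(boot)
        assert ci[0, 0] == pytest.approx(np.quantile(vals, 0.025))
        assert ci[0, 1] == pytest.approx(np.quantile(vals, 0.975))

    def test_intervals_within_simplex_bounds(self, simulated_coancestry):
        total, per, clusters = coancestry_from_sim(simulated_coancestry)
        xs = [ap.cluster_mean_row(total, clusters, g)
              for g in simulated_coancestry.donor_labels]
        boot = ap.bootstrap_profiles(per, clusters, "T0", xs, 40, seed=3)
        ci = ap.profile_ci(boot)
        assert (ci >= -1e-12).all() and (ci <= 1 + 1e-12).all()

    def test_level_validated(self):
        boot = ap.BootstrapProfiles(np.tile([0.5, 0.5], (50, 1)), ["a", "b"],
                                    "t", 0)
        with pytest.raises(ValueError):
            ap.profile_ci(boot, level=1.5)
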