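import numpy as np
import pytest
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

from cmot.matrix import ModalityMatrix
from cmot.transport import (
    barycentric_map,
    cost_matrix,
    flag_outlier_targets,
    induce_labels,
    sinkhorn,
    sinkhorn_label_reg,
    uniform_marginals,
)


def lp_transport_cost(C, a, b):
    """Exact optimum of the transport linear program (independent oracle)."""
    n, m = C.shape
    Aeq = np.zeros((n + m, n * m))
    for i in range(n):
        Aeq[i, i * m : (i + 1) * m] = 1
    for j in range(m):
        Aeq[n + j, j::m] = 1
    res = linprog(
        C.ravel(), A_eq=Aeq, b_eq=np.r_[a, b], bounds=(0, None),
        method="highs",
    )
    assert res.success
    return res.fun


def two_cluster_problem(rng, n_src=20, n_tgt=14, sep=8.0):
    src = np.vstack(
        [rng.normal(0, 0.3, (n_src // 2, 2)), rng.normal(sep, 0.3, (n_src // 2, 2))]
    )
    tgt = np.vstack(
        [rng.normal(0, 0.3, (n_tgt // 2, 2)), rng.normal(sep, 0.3, (n_tgt // 2, 2))]
    )
    C = cdist(src, tgt, "sqeuclidean")
    C /= C.max()
    labels = np.r_[np.zeros(n_src // 2), np.ones(n_src // 2)]
    tgt_cluster = np.r_[np.zeros(n_tgt // 2), np.ones(n_tgt // 2)]
    return C, labels, tgt_cluster


class TestCostMatrix:
    def test_single_identical_cell(self):
        m = ModalityMatrix(np.array([[1.0, 2.0]]))
        np.testing.assert_array_equal(cost_matrix(m, m), [[0.0]])

    def test_hand_computation(self):
        Y = ModalityMatrix(np.array([[0.0], [1.0]]))
        np.testing.assert_allclose(
            cost_matrix(Y, Y), [[0.0, 1.0], [1.0, 0.0]]
        )

    def test_scale_invariance(self, rng):
        v = rng.normal(size=(4, 3))
        Y = ModalityMatrix(v)
        Y3 = ModalityMatrix(3 * v)
        np.testing.assert_allclose(cost_matrix(Y, Y), cost_matrix(Y3, Y3))

    def test_feature_mismatch_rejected(self, rng):
        a = ModalityMatrix(rng.normal(size=(3, 2)), feature_ids=["a", "b"])
        b = ModalityMatrix(rng.normal(size=(3, 2)), feature_ids=["b", "a"])
        with pytest.raises(ValueError, match="feature_ids differ"):
            cost_matrix(a, b)

    def test_nonfinite_rejected(self):
        m = ModalityMatrix(np.array([[np.nan]]))
        with pytest.raises(ValueError, match="non-finite"):
            cost_matrix(m, m)


class TestSinkhorn:
    def test_zero_cost_gives_independence_coupling(self):
        a, b = uniform_marginals(3, 4)
        plan = sinkhorn(np.zeros((3, 4)), a, b, lambda_entropy=10)
        np.testing.assert_allclose(plan.pi, np.outer(a, b), atol=1e-9)

    def test_entropy_dominated_limit(self, rng):
        C = rng.random((4, 4))
        a, b = uniform_marginals(4, 4)
        plan = sinkhorn(C, a, b, epsilon=1e6, max_iter=5000)
        np.testing.assert_allclose(plan.pi, np.outer(a, b), atol=1e-6)

    def test_near_lp_regime_matches_lp_oracle(self, rng):
        C = rng.random((3, 3))
        a, b = uniform_marginals(3, 3)
        plan = sinkhorn(C, a, b, epsilon=1e-3, max_iter=50000, tol=1e-10)
        lp = lp_transport_cost(C, a, b)
        assert plan.transport_cost <= lp * 1.01 + 1e-12

    def test_marginals_conserved(self, rng):
        C = rng.random((6, 5))
        a, b = uniform_marginals(6, 5)
        for lam in (1.0, 100.0, 1000.0):
            plan = sinkhorn(C, a, b, lambda_entropy=lam, max_iter=20000,
                            tol=1e-9)
            assert np.abs(plan.pi.sum(axis=1) - a).max() < 1e-6
            assert np.abs(plan.pi.sum(axis=0) - b).max() < 1e-6
            assert np.all(plan.pi >= 0)

    def test_cost_nonincreasing_in_lambda(self, rng):
        C = rng.random((6, 6))
        costs = [
            sinkhorn(C, lambda_entropy=lam, max_iter=20000).transport_cost
            for lam in (5, 50, 500, 5000)
        ]
        assert all(c2 <= c1 + 1e-9 for c1, c2 in zip(costs, costs[1:]))

    def test_entropy_nondecreasing_in_epsilon(self, rng):
        C = rng.random((6, 6))

        def entropy(pi):
            p = pi[pi > 0]
            return -(p * np.log(p)).sum()

        ents = [
            entropy(sinkhorn(C, epsilon=e, max_iter=20000).pi)
            for e in (1e-3, 1e-2, 1e-1, 1.0)
        ]
        assert all(e2 >= e1 - 1e-9 for e1, e2 in zip(ents, ents[1:]))

    def test_log_domain_switch_small_epsilon(self, rng):
        C = rng.random((4, 4))
        plan = sinkhorn(C, epsilon=1e-4, max_iter=50000)
        assert plan.log_domain
        plan2 = sinkhorn(C, epsilon=1.0)
        assert not plan2.log_domain

    def test_invalid_marginals(self):
        with pytest.raises(ValueError, match="strictly positive"):
            sinkhorn(np.ones((2, 2)), np.array([1.0, 0.0]), np.array([0.5, 0.5]))


class TestLabelRegularization:
    def test_eta_zero_reduces_to_sinkhorn_bitwise(self, rng):
        C = rng.random((5, 5))
        labels = np.array([0, 0, 1, 1, 1])
        a = sinkhorn_label_reg(C, labels=labels, eta=0.0, lambda_entropy=50)
        b = sinkhorn(C, lambda_entropy=50)
        assert np.array_equal(a.pi, b.pi)

    def test_large_eta_concentrates_columns(self, rng):
        C, labels, tgt_cluster = two_cluster_problem(rng)
        plan = sinkhorn_label_reg(
            C, labels=labels, lambda_entropy=100, eta=5.0
        )
        mass0 = plan.pi[labels == 0].sum(axis=0)
        mass1 = plan.pi[labels == 1].sum(axis=0)
        conc = np.maximum(mass0, mass1) / (mass0 + mass1)
        assert np.all(conc > 0.99)
        # concentrated into the matching cluster, not an arbitrary one
        assert np.all((mass1 > mass0) == (tgt_cluster == 1))

    def test_single_class_matches_plain_sinkhorn(self, rng):
        C = rng.random((5, 4))
        labels = np.zeros(5)
        a = sinkhorn_label_reg(C, labels=labels, eta=1.0, lambda_entropy=50)
        b = sinkhorn(C, lambda_entropy=50)
        # one class: the group penalty is constant per column mass
        np.testing.assert_allclose(a.pi, b.pi, atol=1e-9)

    def test_marginals_conserved_over_parameter_grid(self, rng):
        C, labels, _ = two_cluster_problem(rng, n_src=12, n_tgt=10)
        for lam in (100.0, 200.0):
            for eta in (5e-3, 1.0):
                plan = sinkhorn_label_reg(
                    C, labels=labels, lambda_entropy=lam, eta=eta
                )
                assert plan.marginal_violation < 1e-6

    def test_label_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="labels"):
            sinkhorn_label_reg(
                rng.random((4, 4)), labels=np.zeros(3), eta=1.0
            )


class TestInduceLabels:
    def test_planted_partition_recovery(self, rng):
        vals = np.vstack(
            [rng.normal(0, 0.5, (15, 4)), rng.normal(10, 0.5, (15, 4))]
        )
        labels = induce_labels(ModalityMatrix(vals), 2)
        truth = np.r_[np.zeros(15), np.ones(15)]
        agree = max(
            np.mean(labels == truth), np.mean(labels == 1 - truth)
        )
        assert agree == 1.0

    def test_singleton_clusters(self, rng):
        m = ModalityMatrix(rng.normal(size=(5, 2)))
        labels = induce_labels(m, 5)
        assert len(set(labels)) == 5

    def test_too_many_clusters(self, rng):
        with pytest.raises(ValueError):
            induce_labels(ModalityMatrix(rng.normal(size=(3, 2))), 4)


class TestBarycentricMap:
    def _plan(self, pi, Yhat):
        from cmot.transport import TransportPlan

        return TransportPlan(
            pi=pi, cost=np.zeros(pi.shape), a=pi.sum(1), b=pi.sum(0),
            n_iter=0, converged=True,
        )

    def test_identity_coupling_recovers_target(self, rng):
        Yhat = ModalityMatrix(rng.normal(size=(4, 3)))
        plan = self._plan(np.eye(4) / 4, Yhat)
        np.testing.assert_allclose(
            barycentric_map(plan, Yhat).values, Yhat.values
        )

    def test_permutation_coupling(self, rng):
        Yhat = ModalityMatrix(rng.normal(size=(4, 3)))
        perm = np.array([2, 0, 3, 1])
        pi = np.zeros((4, 4))
        pi[np.arange(4), perm] = 0.25
        out = barycentric_map(self._plan(pi, Yhat), Yhat)
        np.testing.assert_allclose(out.values, Yhat.values[perm])

    def test_rows_in_convex_hull(self, rng):
        Yhat = ModalityMatrix(rng.normal(size=(5, 3)))
        pi = rng.random((4, 5))
        out = barycentric_map(self._plan(pi, Yhat), Yhat)
        lo, hi = Yhat.values.min(0), Yhat.values.max(0)
        assert np.all(out.values >= lo - 1e-12)
        assert np.all(out.values <= hi + 1e-12)

    def test_zero_row_rejected(self, rng):
        Yhat = ModalityMatrix(rng.normal(size=(3, 2)))
        pi = np.ones((3, 3)) / 9
        pi[1] = 0.0
        with pytest.raises(ValueError, match="zero-mass"):
            barycentric_map(self._plan(pi, Yhat), Yhat)


class TestOutlierFlagging:
    def _plan_from(self, Y, Yhat, rng_seed=0):
        C = cost_matrix(Y, Yhat)
        return sinkhorn(C, lambda_entropy=100, max_iter=5000)

    def test_clean_targets_few_flags(self, rng):
        vals = rng.normal(size=(40, 5))
        Y = ModalityMatrix(vals)
        Yhat = ModalityMatrix(
            rng.normal(size=(30, 5)), cell_ids=[f"t{i}" for i in range(30)]
        )
        plan = self._plan_from(Y, Yhat)
        report = flag_outlier_targets(plan, contamination=0.1, seed=0)
        assert report.fraction_flagged <= 0.1 + 1e-9

    def test_deterministic_under_seed(self, rng):
        Y = ModalityMatrix(rng.normal(size=(20, 4)))
        Yhat = ModalityMatrix(
            rng.normal(size=(15, 4)), cell_ids=[f"t{i}" for i in range(15)]
        )
        plan = self._plan_from(Y, Yhat)
        r1 = flag_outlier_targets(plan, seed=5)
        r2 = flag_outlier_targets(plan, seed=5)
        np.testing.assert_array_equal(r1.flags, r2.flags)

    def test_tiny_target_set_skipped(self, rng):
        Y = ModalityMatrix(rng.normal(size=(6, 3)))
        Yhat = ModalityMatrix(
            rng.normal(size=(3, 3)), cell_ids=["a", "b", "c"]
        )
        plan = self._plan_from(Y, Yhat)
        with pytest.warns(UserWarning, match="skipped"):
            report = flag_outlier_targets(plan)
        assert report.skipped and not report.flags.any()

    def test_planted_outliers_recovered(self):
        from cmot.synthetic import SyntheticSpec, generate, plant_outliers

        recalls = []
        for seed in range(5):
            data = generate(SyntheticSpec(n_source=120, n_target=80, seed=seed))
            corrupted, mask = plant_outliers(
                data.Yhat, 0.05, amplitude=5.0, seed=seed
            )
            C = cost_matrix(data.Y, corrupted)
            plan = sinkhorn(C, lambda_entropy=100)
            with pytest.warns(UserWarning, match="poorly mapped"):
                report = flag_outlier_targets(plan, seed=seed)
            recalls.append(np.sum(report.flags & mask) / mask.sum())
        assert np.median(recalls) >= 0.8
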