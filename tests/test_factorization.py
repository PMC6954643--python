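"""Objective, multiplicative updates, consensus and dispersion."""

import numpy as np
import pytest

from cnmtf.correction import centering_matrix
from cnmtf.factorization import (
    EPS,
    ConsensusResult,
    FactorSet,
    PenaltyWeights,
    build_phenotype_matrix,
    dispersion,
    fit_consensus,
    fit_once,
    objective,
    split_signed,
    update_step,
)


def brute_force_objective(R, fac, L, Vo, HAH, g):
    """Element-wise loop evaluation of the objective, no matrix identities."""
    n, m = R.shape
    k1, k2 = fac.S.shape
    total = 0.0
    for i in range(n):
        for j in range(m):
            pred = sum(
                fac.U[i, t] * fac.S[t, l] * fac.V[j, l] for t in range(k1) for l in range(k2)
            )
            total += (R[i, j] - pred) ** 2
    if g.gamma1:
        for a in range(k1):
            for i in range(n):
                for j in range(n):
                    total += g.gamma1 * fac.U[i, a] * L[i, j] * fac.U[j, a]
    if g.gamma2:
        total += g.gamma2 * sum(
            (fac.V[j, l] - Vo[j, l]) ** 2 for j in range(m) for l in range(k2)
        )
    if g.gamma3:
        for j in range(m):
            for jj in range(m):
                vvt = sum(fac.V[j, l] * fac.V[jj, l] for l in range(k2))
                total += g.gamma3 * vvt * HAH[jj, j]
    return total


def random_instance(rng, n=10, m=8, k1=3, k2=2):
    R = rng.integers(0, 3, size=(n, m)).astype(float)
    fac = FactorSet(
        rng.uniform(0.1, 1, (n, k1)), rng.uniform(0.1, 1, (k1, k2)), rng.uniform(0.1, 1, (m, k2))
    )
    W = rng.random((n, n)) * (rng.random((n, n)) < 0.3)
    W = np.triu(W, 1)
    W = W + W.T
    L = np.diag(W.sum(1)) - W
    Vo = np.zeros((m, k2))
    Vo[np.arange(m), rng.integers(0, k2, m)] = 1
    A = rng.normal(size=(m, 3))
    A = A @ A.T
    H = centering_matrix(m)
    return R, fac, L, Vo, H @ A @ H


class TestObjective:
    def test_perfect_reconstruction_is_zero(self, rng):
        fac = FactorSet(
            rng.uniform(0, 1, (6, 2)), rng.uniform(0, 1, (2, 2)), rng.uniform(0, 1, (5, 2))
        )
        R = fac.reconstruction()
        assert objective(R, fac) < 1e-10

    def test_constant_u_columns_kill_network_term(self, rng):
        R, fac, L, Vo, HAH = random_instance(rng)
        fac.U[:] = np.ones_like(fac.U) * 0.7  # constant columns: L annihilates them
        g = PenaltyWeights(gamma1=5.0)
        base = objective(R, fac, L=None, gammas=PenaltyWeights())
        with_net = objective(R, fac, L=L, gammas=g)
        assert with_net == pytest.approx(base, abs=1e-8)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            R, fac, L, Vo, HAH = random_instance(rng)
            g = PenaltyWeights(*rng.uniform(0, 2, 3))
            fast = objective(R, fac, L, Vo, HAH, g)
            slow = brute_force_objective(R, fac, L, Vo, HAH, g)
            assert fast == pytest.approx(slow, abs=1e-8 * max(1, abs(slow)))


class TestPhenotypeMatrix:
    def test_one_hot_layout(self):
        Vo = build_phenotype_matrix(["control", "case", "control"])
        assert np.array_equal(Vo, [[1, 0], [0, 1], [1, 0]])

    def test_all_controls_leave_case_column_empty(self):
        Vo = build_phenotype_matrix(["control"] * 4)
        assert Vo[:, 1].sum() == 0
        assert np.array_equal(Vo.sum(axis=1), np.ones(4))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_phenotype_matrix(["control", "maybe"])


class TestUpdateStep:
    def test_preserves_nonnegativity(self, rng):
        R, fac, L, Vo, HAH = random_instance(rng, n=15, m=12)
        Hp, Hn = split_signed(HAH)
        W = np.diag(np.diag(L)) - L
        out = update_step(
            R, fac, np.diag(np.diag(L)), W, Vo, Hp, Hn, PenaltyWeights(0.5, 0.5, 0.5)
        )
        assert out.U.min() >= 0 and out.S.min() >= 0 and out.V.min() >= 0

    @pytest.mark.parametrize("gammas", [(0, 0, 0), (1, 0, 0), (0.5, 1, 0.5)])
    def test_objective_nonincreasing(self, rng, gammas):
        R, fac, L, Vo, HAH = random_instance(rng, n=20, m=30, k1=4)
        g = PenaltyWeights(*gammas)
        _, trace, _ = fit_once(
            R,
            np.diag(np.diag(L)),
            np.diag(np.diag(L)) - L,
            Vo,
            HAH,
            g,
            k1=4,
            k2=2,
            tol=1e-14,
            max_iter=200,
            seed=5,
        )
        rel = np.diff(trace) / np.maximum(np.abs(trace[:-1]), 1e-30)
        assert rel.max() < 1e-9


class TestFitOnce:
    def test_planted_rank2_recovery(self, rng):
        U0 = rng.uniform(0, 1, (30, 2))
        S0 = rng.uniform(0.5, 1.5, (2, 2))
        V0 = rng.uniform(0, 1, (20, 2))
        R = U0 @ S0 @ V0.T
        fac, _, _ = fit_once(R, gammas=PenaltyWeights(), k1=2, k2=2, tol=1e-10,
                             max_iter=3000, seed=0)
        err = np.linalg.norm(R - fac.reconstruction()) / np.linalg.norm(R)
        assert err < 0.01

    def test_infinite_tol_runs_exactly_one_iteration(self, rng):
        R = rng.integers(0, 3, (10, 8)).astype(float)
        _, trace, converged = fit_once(R, gammas=PenaltyWeights(), tol=np.inf, max_iter=50)
        assert len(trace) == 2  # init + one update
        assert converged

    def test_same_seed_gives_identical_traces(self, rng):
        R = rng.integers(0, 3, (15, 12)).astype(float)
        _, t1, _ = fit_once(R, gammas=PenaltyWeights(), k1=3, seed=42, max_iter=50, tol=1e-12)
        _, t2, _ = fit_once(R, gammas=PenaltyWeights(), k1=3, seed=42, max_iter=50, tol=1e-12)
        assert np.array_equal(t1, t2)

    def test_scale_consistency(self, rng):
        # multiplying R by c multiplies the fitted reconstruction error by ~c^2
        R = rng.integers(0, 3, (40, 25)).astype(float) + 0.1
        errs = []
        for c in (1.0, 3.0):
            vals = []
            for seed in range(10):
                fac, tr, _ = fit_once(c * R, gammas=PenaltyWeights(), k1=3,
                                      max_iter=300, tol=1e-8, seed=seed)
                vals.append(tr[-1])
            errs.append(np.median(vals))
        assert errs[1] / errs[0] == pytest.approx(9.0, rel=0.05)


class TestDispersion:
    def test_binary_consensus_is_one(self):
        C = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert dispersion(C) == 1.0

    def test_uniform_half_is_zero(self):
        assert dispersion(np.full((5, 5), 0.5)) == 0.0

    def test_direct_formula_example(self):
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert dispersion(C) == pytest.approx(0.5)

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            m = rng.integers(2, 8)
            C = rng.random((m, m))
            C = (C + C.T) / 2
            slow = sum(4 * (C[i, j] - 0.5) ** 2 for i in range(m) for j in range(m)) / m**2
            assert dispersion(C) == pytest.approx(slow, abs=1e-10)


@pytest.fixture(scope="module")
def block_R():
    rng = np.random.default_rng(7)
    # two well-separated subject blocks
    R = np.zeros((40, 30))
    R[:20, :15] = 2.0
    R[20:, 15:] = 2.0
    return R + rng.uniform(0, 0.05, R.shape)


class TestConsensus:
    def test_separated_blocks_give_unit_dispersion(self, block_R):
        res = fit_consensus(block_R, gammas=PenaltyWeights(), k1=2, n_restarts=10,
                            seed=3, max_iter=100, tol=1e-7)
        assert set(np.unique(np.round(res.consensus_matrix, 6))) <= {0.0, 1.0}
        assert res.dispersion == pytest.approx(1.0)

    def test_single_restart_rejected(self, block_R):
        with pytest.raises(ValueError, match="n_restarts"):
            fit_consensus(block_R, gammas=PenaltyWeights(), n_restarts=1)

    def test_subject_permutation_equivariance(self, block_R):
        perm = np.random.default_rng(1).permutation(block_R.shape[1])
        res1 = fit_consensus(block_R, gammas=PenaltyWeights(), k1=2, n_restarts=5,
                             seed=3, max_iter=80, tol=1e-7)
        res2 = fit_consensus(block_R[:, perm], gammas=PenaltyWeights(), k1=2, n_restarts=5,
                             seed=3, max_iter=80, tol=1e-7)
        assert np.allclose(res2.consensus_matrix, res1.consensus_matrix[np.ix_(perm, perm)])
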