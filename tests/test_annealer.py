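"""Simulated annealing: Metropolis kernel, global-optimum recovery on
exhaustively enumerable instances, lambda sweep, compartment inference."""

import numpy as np
import pytest

from multicd import (
    AnnealSchedule,
    CorrelationMatrix,
    DomainSolution,
    GenomicBinning,
    ObjectiveParams,
    anneal,
    binary_similarity,
    infer_compartments,
    metropolis_sweep,
    objective,
    sweep_lambda,
)
from multicd.annealer import _State
from multicd.synthetic import GroupSignalModel, sample_signals

from conftest import block_correlation, enumerate_partitions


def brute_force_minimum(C, lam):
    n = C.shape[0]
    best = (np.inf, None)
    params = ObjectiveParams(lam)
    for p in enumerate_partitions(n):
        H = objective(DomainSolution(np.array(p) + 1), C, params)
        if H < best[0]:
            best = (H, p)
    return best


class TestMetropolisKernel:
    def test_deterministic_given_seed(self, two_block_corr):
        p = ObjectiveParams(0.0)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            s = DomainSolution(np.arange(1, 9))
            for _ in range(5):
                s, _ = metropolis_sweep(s, two_block_corr, p, 0.5, rng)
            out.append(s.labels.copy())
        np.testing.assert_array_equal(out[0], out[1])

    def test_low_temperature_rejects_uphill(self, two_block_corr, two_block_labels):
        # from the global optimum at tiny T every proposal raises H -> no moves
        p = ObjectiveParams(0.0)
        rng = np.random.default_rng(0)
        s = two_block_labels
        for _ in range(5):
            s, _ = metropolis_sweep(s, two_block_corr, p, 1e-9, rng)
        np.testing.assert_array_equal(np.sort(s.labels), np.sort(two_block_labels.labels))
        assert binary_similarity(s, two_block_labels) == pytest.approx(1.0)

    def test_incremental_matches_full_recompute(self, rng):
        n = 30
        noise = rng.standard_normal((n, n)) * 0.1
        C = np.clip(block_correlation([10, 10, 10], 0.5) + (noise + noise.T) / 2, -0.9, 0.95)
        np.fill_diagonal(C, 1.0)
        state = _State(C, np.arange(n), lam=1.5)
        for T in (2.0, 0.5, 0.1):
            state.sweep(T, rng)
            E_full, K_full = state.recompute()
            assert state.E == pytest.approx(E_full, abs=1e-9)
            assert state.K_gen() == pytest.approx(K_full, abs=1e-9)

    def test_detailed_balance_four_sites(self):
        # long-run partition frequencies must match exp(-H/T) over all 15
        # partitions of 4 sites, within 3 batch-means standard errors
        C = np.array(
            [[1.0, 0.6, 0.1, 0.0],
             [0.6, 1.0, 0.2, 0.1],
             [0.1, 0.2, 1.0, 0.5],
             [0.0, 0.1, 0.5, 1.0]]
        )
        lam, T = 0.3, 1.0
        params = ObjectiveParams(lam)
        parts = list(enumerate_partitions(4))
        w = {
            p: np.exp(-objective(DomainSolution(np.array(p) + 1), C, params) / T)
            for p in parts
        }
        Z = sum(w.values())
        exact = {p: w[p] / Z for p in parts}

        rng = np.random.default_rng(42)
        state = _State(C, np.arange(4), lam=lam)
        n_sweeps, n_burn = 40_000, 2_000
        keys = []
        from multicd.types import canonical_labels

        for it in range(n_sweeps + n_burn):
            state.sweep(T, rng)
            if it >= n_burn:
                keys.append(tuple(canonical_labels(state.labels + 1)))
        canon = {tuple(canonical_labels(np.array(p) + 1)): p for p in parts}
        for key, p in canon.items():
            ind = np.array([k == key for k in keys], dtype=float)
            nb = 20
            bs = len(ind) // nb
            bm = ind[: nb * bs].reshape(nb, bs).mean(axis=1)
            se = bm.std(ddof=1) / np.sqrt(nb)
            assert abs(ind.mean() - exact[p]) <= 3 * max(se, 1e-4), (
                f"partition {p}: freq {ind.mean():.4f} vs exact {exact[p]:.4f}"
            )


class TestAnneal:
    def test_two_block_global_optimum(self, two_block_corr, two_block_labels):
        bestH, _ = brute_force_minimum(two_block_corr.C, 0.0)
        sol = anneal(two_block_corr, ObjectiveParams(0.0), AnnealSchedule(seed=1, n_restarts=3))
        assert sol.objective_value == pytest.approx(bestH, abs=1e-9)
        assert binary_similarity(sol, two_block_labels) == pytest.approx(1.0)

    def test_large_lambda_single_domain(self, two_block_corr):
        lam = 50.0
        bestH, bestp = brute_force_minimum(two_block_corr.C, lam)
        assert len(set(bestp)) == 1  # enumeration itself picks one domain
        sol = anneal(two_block_corr, ObjectiveParams(lam), AnnealSchedule(seed=2, n_restarts=3))
        assert sol.n_domains == 1
        assert sol.objective_value == pytest.approx(bestH, abs=1e-9)

    def test_determinism(self, two_block_corr):
        sched = AnnealSchedule(seed=9, n_restarts=2)
        a = anneal(two_block_corr, ObjectiveParams(0.5), sched)
        b = anneal(two_block_corr, ObjectiveParams(0.5), sched)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.objective_value == b.objective_value

    def test_best_H_non_increasing(self, two_block_corr):
        trace: list = []
        anneal(
            two_block_corr,
            ObjectiveParams(0.5),
            AnnealSchedule(seed=3, n_restarts=1),
            track_best=trace,
        )
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))


@pytest.fixture(scope="module")
def nested_corr():
    rng = np.random.default_rng(7)
    sub = np.repeat(np.arange(1, 21), 5)  # 20 sub-domains of 5 bins
    sup = np.repeat(np.arange(1, 5), 25)  # 4 super-domains of 25 bins
    model = GroupSignalModel(
        sub, np.array([1.0] * 20), u=sup, h_strengths=np.array([2.0] * 4)
    )
    _, Chat = sample_signals(model, 1600, rng)
    C = CorrelationMatrix(
        np.clip(Chat, -1, 1 - 1e-6),
        np.ones(100, dtype=bool),
        GenomicBinning("c", 50_000, 100),
    )
    return C, DomainSolution(sub), DomainSolution(sup)


@pytest.fixture(scope="module")
def two_level():
    N = 120
    rng = np.random.default_rng(1)
    s = np.repeat(np.arange(1, 13), 10)  # local primary domains, 10 bins
    u = (np.arange(N) // 30 % 2) + 1  # alternating A/B blocks -> checkerboard
    model = GroupSignalModel(s, np.array([2.0]), u=u, h_strengths=np.array([1.0]))
    _, Chat = sample_signals(model, 400, rng)
    C = CorrelationMatrix(
        np.clip(Chat, -1, 1 - 1e-6),
        np.ones(N, dtype=bool),
        GenomicBinning("c", 50_000, N),
    )
    return C, DomainSolution(s), DomainSolution(u)


class TestSweepLambda:

    def test_single_lambda_matches_anneal(self, two_block_corr):
        sched = AnnealSchedule(seed=4, n_restarts=2)
        fam = sweep_lambda(two_block_corr, [0.5], sched)
        assert len(fam) == 1
        direct = anneal(two_block_corr, ObjectiveParams(0.5), AnnealSchedule(seed=4, n_restarts=2))
        np.testing.assert_array_equal(fam.entries[0].solution.labels, direct.labels)

    def test_mean_size_monotone(self, nested_corr):
        C, _, _ = nested_corr
        fam = sweep_lambda(C, [0.0, 1.0, 2.0, 4.0, 8.0], AnnealSchedule(seed=5, n_restarts=2))
        means = fam.diagnostic("mean_size_bins")
        from scipy.stats import spearmanr

        assert spearmanr(fam.lambdas(), means).statistic >= 0.9

    def test_two_scale_recovery(self, nested_corr):
        C, sub, sup = nested_corr
        fam = sweep_lambda(C, [0.0, 2.0], AnnealSchedule(seed=6, n_restarts=2))
        assert binary_similarity(fam.entries[0].solution, sub) >= 0.9
        assert binary_similarity(fam.entries[1].solution, sup) >= 0.9

    def test_warm_and_cold_agree(self, nested_corr):
        C, _, _ = nested_corr
        lams = [0.0, 2.0]
        warm = sweep_lambda(C, lams, AnnealSchedule(seed=8, n_restarts=2), warm_start=True)
        cold = sweep_lambda(C, lams, AnnealSchedule(seed=8, n_restarts=2), warm_start=False)
        for w, c in zip(warm.entries, cold.entries):
            assert w.H == pytest.approx(c.H, rel=0.01, abs=0.05)

    def test_unsorted_lambdas_rejected(self, two_block_corr):
        with pytest.raises(ValueError):
            sweep_lambda(two_block_corr, [1.0, 0.5], AnnealSchedule())


class TestInferCompartments:
    def test_band_mode_recovers_checkerboard(self, two_level):
        C, _, truth_u = two_level
        sol = infer_compartments(
            C, 10 * 50_000, ObjectiveParams(2.0), AnnealSchedule(seed=3, n_restarts=3),
            mode="band",
        )
        assert binary_similarity(sol, truth_u) >= 0.8

    def test_residual_mode_recovers_checkerboard(self, two_level):
        C, truth_s, truth_u = two_level
        primary = anneal(C, ObjectiveParams(0.0), AnnealSchedule(seed=4, n_restarts=2))
        assert binary_similarity(primary, truth_s) >= 0.9
        sol = infer_compartments(
            C, 0, ObjectiveParams(2.0), AnnealSchedule(seed=5, n_restarts=3),
            mode="residual", primary=primary,
        )
        assert binary_similarity(sol, truth_u) >= 0.8

    def test_residual_zero_gtilde_equals_plain_anneal(self, two_level):
        C, truth_s, _ = two_level
        sched = AnnealSchedule(seed=6, n_restarts=2)
        plain = anneal(C, ObjectiveParams(0.0), sched)
        res = infer_compartments(
            C, 0, ObjectiveParams(0.0), sched, mode="residual",
            primary=truth_s, g_tilde=np.zeros(truth_s.n_domains),
        )
        np.testing.assert_array_equal(plain.labels, res.labels)

    def test_residual_requires_primary(self, two_level):
        C, _, _ = two_level
        with pytest.raises(ValueError, match="primary"):
            infer_compartments(C, 0, ObjectiveParams(1.0), AnnealSchedule(), mode="residual")
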