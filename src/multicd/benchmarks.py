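"""Self-contained benchmark computations used by the acceptance checks.

Each function regenerates its inputs from the package's own synthetic
module under a caller-supplied seed, runs the method end to end, and
returns the measured quantity together with the problem size.  Problem
sizes are desk-scale versions of the study conditions (see
docs/methods.md for the rationale behind each setting).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from . import annealer, evaluation, group_model, polymer_map, synthetic
from .types import (
    AnnealSchedule,
    CorrelationMatrix,
    DomainSolution,
    GenomicBinning,
    ObjectiveParams,
)

__all__ = [
    "transform_identity",
    "rc_invariance",
    "likelihood_optimality",
    "energy_likelihood_consistency",
    "exhaustive_recovery",
    "parameter_recovery",
    "secondary_recovery",
    "lambda_monotonicity",
    "roundtrip_mad",
]


def _corr(C: np.ndarray, bin_size: int = 50_000) -> CorrelationMatrix:
    n = C.shape[0]
    return CorrelationMatrix(
        np.clip(C, -1.0, 1.0 - 1e-6),
        np.ones(n, dtype=bool),
        GenomicBinning("chrS", bin_size, n),
    )


def transform_identity(n_points: int = 200) -> tuple[float, int]:
    """Max |invert(forward(gamma)) - gamma| over the working stiffness range
    [1e-4, 12] (bounded above by the p = 1 - 1e-6 saturation cap, beyond
    which the forward map is flat to double precision)."""
    gamma = np.logspace(-4, np.log10(12.0), n_points)
    p = polymer_map.contact_probability(gamma)
    back = polymer_map.invert_contact_probability(p)
    return float(np.abs(back - gamma).max()), n_points


def rc_invariance(seed: int, n_bins: int = 60) -> tuple[float, int]:
    """Max deviation between correlation matrices pre-processed with
    r_c = 1 and r_c = 2 on one simulated contact map."""
    rng = np.random.default_rng(seed)
    C = np.zeros((n_bins, n_bins))
    h = n_bins // 2
    C[:h, :h] = 0.5
    C[h:, h:] = 0.5
    np.fill_diagonal(C, 1.0)
    M = synthetic.synth_hic(C, 50_000, rng)
    p1 = synthetic.nearest_neighbor_probability(C)
    C1 = polymer_map.preprocess(M, p1bar=p1, r_c=1.0)
    C2 = polymer_map.preprocess(M, p1bar=p1, r_c=2.0)
    return float(np.nanmax(np.abs(C1.C - C2.C))), n_bins


def likelihood_optimality(seed: int, n_domains: int = 100) -> tuple[float, int]:
    """Worst shortfall of the closed-form g_hat against a dense strength
    grid, over random small domains (0 means g_hat always wins)."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 50.0, 2001)
    worst = 0.0
    for _ in range(n_domains):
        n = int(rng.integers(2, 9))
        X = rng.standard_normal((50, n))
        C = np.corrcoef(X, rowvar=False)
        s = DomainSolution(np.ones(n, dtype=int))
        st = group_model.domain_stats(s, C)
        at_hat = group_model.log_likelihood(s, C, st.g_hat)
        best_grid = max(group_model.log_likelihood(s, C, [g]) for g in grid)
        worst = max(worst, best_grid - at_hat)
    return float(worst), n_domains


def energy_likelihood_consistency(seed: int, n_trials: int = 50) -> tuple[float, int]:
    """Max |E(s|C) + log L(s, g_hat) + N/2| over random instances in which
    every domain sits at an interior strength optimum."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    checked = 0
    while checked < n_trials:
        n = int(rng.integers(6, 13))
        labels = DomainSolution(rng.integers(1, 4, size=n)).canonical()
        base = np.full((n, n), 0.55)
        noise = 0.05 * rng.standard_normal((n, n))
        C = np.clip(base + (noise + noise.T) / 2, -0.95, 0.95)
        np.fill_diagonal(C, 1.0)
        st = group_model.domain_stats(labels, C)
        if np.any(st.g_hat == 0):
            continue
        lhs = group_model.energy(labels, C)
        rhs = -group_model.log_likelihood(labels, C, st.g_hat) - n / 2
        worst = max(worst, abs(lhs - rhs))
        checked += 1
    return float(worst), n_trials


def _enumerate_partitions(n: int):
    def rec(prefix, mx):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for v in range(mx + 2):
            yield from rec(prefix + [v], max(mx, v))

    yield from rec([], -1)


def exhaustive_recovery(
    seed: int, n_seeds: int = 20, lambdas=(0.0, 0.5, 5.0)
) -> tuple[float, int]:
    """Fraction of annealing runs recovering the enumerated global optimum
    of H_lambda on the N = 8 two-block instance (4140 partitions)."""
    N = 8
    C = np.zeros((N, N))
    C[:4, :4] = 0.8
    C[4:, 4:] = 0.8
    np.fill_diagonal(C, 1.0)
    Cm = _corr(C)
    hits, total = 0, 0
    for lam in lambdas:
        params = ObjectiveParams(lam)
        best = min(
            group_model.objective(DomainSolution(np.array(p) + 1), C, params)
            for p in _enumerate_partitions(N)
        )
        for k in range(n_seeds):
            sched = AnnealSchedule(seed=seed + 1000 * total + k, n_restarts=3)
            sol = annealer.anneal(Cm, params, sched)
            hits += abs(sol.objective_value - best) < 1e-9
            total += 1
    return hits / total, total


def parameter_recovery(
    seed: int, n_seeds: int = 10, N: int = 100, K: int = 5, g: float = 2.0,
    n_samples: int = 400,
) -> tuple[float, int]:
    """Mean similarity rho between the annealed solution at lambda = 0 and
    the true K equal contiguous domains, from empirical correlations."""
    labels = np.repeat(np.arange(1, K + 1), N // K)
    truth = DomainSolution(labels)
    rhos = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        model = synthetic.GroupSignalModel(labels, np.full(K, g))
        _, Chat = synthetic.sample_signals(model, n_samples, rng)
        sol = annealer.anneal(
            _corr(Chat), ObjectiveParams(0.0),
            AnnealSchedule(seed=seed + k, n_restarts=2),
        )
        rhos.append(evaluation.binary_similarity(sol, truth))
    return float(np.mean(rhos)), N


def _two_level_instance(seed: int, N: int = 120):
    rng = np.random.default_rng(seed)
    s = np.repeat(np.arange(1, N // 10 + 1), 10)  # local primary, 10 bins each
    u = (np.arange(N) // 30 % 2) + 1  # alternating secondary blocks
    model = synthetic.GroupSignalModel(
        s, np.array([2.0]), u=u, h_strengths=np.array([1.0])
    )
    _, Chat = synthetic.sample_signals(model, 400, rng)
    return _corr(Chat), DomainSolution(s), DomainSolution(u)


def secondary_recovery(seed: int, mode: str, N: int = 120) -> tuple[float, int]:
    """Similarity of band- or residual-mode compartment inference to the
    true secondary labels of a two-level instance (g = 2, h = 1)."""
    C, _, truth_u = _two_level_instance(seed, N)
    params = ObjectiveParams(2.0)
    if mode == "band":
        sol = annealer.infer_compartments(
            C, 10 * 50_000, params, AnnealSchedule(seed=seed + 1, n_restarts=3),
            mode="band",
        )
    else:
        primary = annealer.anneal(
            C, ObjectiveParams(0.0), AnnealSchedule(seed=seed + 2, n_restarts=2)
        )
        sol = annealer.infer_compartments(
            C, 0, params, AnnealSchedule(seed=seed + 3, n_restarts=3),
            mode="residual", primary=primary,
        )
    rho = evaluation.binary_similarity(sol, truth_u)
    return float(rho if rho is not None else 0.0), N


def lambda_monotonicity(seed: int, N: int = 200) -> tuple[float, int]:
    """Spearman correlation between lambda and the mean domain size over a
    lambda grid on nested two-level data (the multi-scale claim)."""
    rng = np.random.default_rng(seed)
    sub = np.repeat(np.arange(1, N // 5 + 1), 5)
    sup = np.repeat(np.arange(1, N // 25 + 1), 25)
    # heterogeneous strengths spread the merge thresholds over the lambda
    # grid, so the size staircase has many small steps instead of long
    # degenerate plateaus
    model = synthetic.GroupSignalModel(
        sub,
        rng.uniform(0.6, 1.4, N // 5),
        u=sup,
        h_strengths=rng.uniform(1.5, 2.5, N // 25),
    )
    _, Chat = synthetic.sample_signals(model, 1600, rng)
    lams = [0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0]
    fam = annealer.sweep_lambda(
        _corr(Chat), lams, AnnealSchedule(seed=seed, n_restarts=2)
    )
    means = fam.diagnostic("mean_size_bins")
    return float(spearmanr(lams, means).statistic), N


def roundtrip_mad(seed: int, n_bins: int = 100, n_reads: int = 100_000) -> tuple[float, int]:
    """Median absolute deviation between a two-block correlation matrix and
    its reconstruction after forward Hi-C simulation and pre-processing."""
    rng = np.random.default_rng(seed)
    C = np.zeros((n_bins, n_bins))
    h = n_bins // 2
    C[:h, :h] = 0.5
    C[h:, h:] = 0.5
    np.fill_diagonal(C, 1.0)
    M = synthetic.synth_hic(C, n_reads, rng)
    rec = polymer_map.preprocess(M, p1bar=synthetic.nearest_neighbor_probability(C))
    off = ~np.eye(n_bins, dtype=bool)
    return float(np.median(np.abs(rec.C[off] - C[off]))), n_bins
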