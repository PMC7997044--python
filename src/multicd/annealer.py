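"""Simulated-annealing minimization of the lambda-penalized group-model
objective, the lambda sweep producing the multi-scale solution family, and
secondary (compartment) inference.

The Markov chain is single-site Metropolis on partitions: each sweep visits
every valid site once in random order and proposes relabeling it to a
uniformly chosen existing domain (other than its own) or to a fresh
singleton domain.  Moves are accepted with probability min(1, exp(-dH/T)).
dH is evaluated incrementally: moving one site touches only two domains'
(n_k, c_k), which are updated from one row sum, and the entropy sum behind
K(s) is maintained in O(1).  The chain is ergodic on the partition space
and satisfies detailed balance at fixed T.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from . import group_model
from .group_model import energy_term, estimate_residual_strength, residual_correlation
from .polymer_map import band_mask
from .types import (
    AnnealSchedule,
    CorrelationMatrix,
    DomainSolution,
    FamilyEntry,
    ObjectiveParams,
    SolutionFamily,
    canonical_labels,
)

__all__ = [
    "metropolis_sweep",
    "anneal",
    "sweep_lambda",
    "infer_compartments",
]


class _State:
    """Mutable annealing state on the compacted valid-bin matrix.

    Maintains per-domain (n_k, c_k), per-domain energy terms, the total
    energy, and sum(n log n) so that K(s) updates in O(1).  Label slots are
    recycled through a free list; ``labels`` holds slot ids (0-based).
    """

    def __init__(self, A: np.ndarray, labels: np.ndarray, lam: float):
        self.A = A
        self.N = A.shape[0]
        self.lam = lam
        cap = self.N + 1
        self.n = np.zeros(cap, dtype=np.int64)
        self.c = np.zeros(cap)
        self.e = np.zeros(cap)
        # compact slot ids from input labels
        uniq, compact = np.unique(labels, return_inverse=True)
        self.labels = compact.astype(np.int64)
        self.free = list(range(cap - 1, len(uniq) - 1, -1))  # stack of unused slots
        self.active = list(range(len(uniq)))
        self.pos = {k: i for i, k in enumerate(self.active)}
        for k in self.active:
            m = self.labels == k
            self.n[k] = int(m.sum())
            self.c[k] = float(A[np.ix_(m, m)].sum())
            self.e[k] = energy_term(float(self.n[k]), self.c[k])
        self.E = float(self.e[self.active].sum()) if self.active else 0.0
        nn = self.n[self.active].astype(float)
        self.sum_nlogn = float((nn * np.log(nn)).sum())

    # -- derived quantities -------------------------------------------------
    def K_gen(self, sum_nlogn: Optional[float] = None) -> float:
        s = self.sum_nlogn if sum_nlogn is None else sum_nlogn
        return math.exp(math.log(self.N) - s / self.N)

    def H(self) -> float:
        return self.E + self.lam * self.K_gen()

    # -- bookkeeping --------------------------------------------------------
    def _activate(self) -> int:
        k = self.free.pop()
        self.pos[k] = len(self.active)
        self.active.append(k)
        return k

    def _deactivate(self, k: int) -> None:
        i = self.pos.pop(k)
        last = self.active.pop()
        if last != k:
            self.active[i] = last
            self.pos[last] = i
        self.free.append(k)

    # -- the elementary move ------------------------------------------------
    def propose_and_apply(
        self, i: int, b: int, T: float, u: float, log_q_ratio: float = 0.0
    ) -> bool:
        """Metropolis-Hastings step moving site i to domain slot b (possibly
        fresh, already activated with n=0).  ``u`` is the uniform variate for
        the acceptance test; ``log_q_ratio`` is log q(s'->s) - log q(s->s'),
        nonzero when the move changes the number of proposal options (domain
        birth/death), so the chain keeps detailed balance w.r.t. exp(-H/T).
        Returns True if accepted (state updated)."""
        a = int(self.labels[i])
        row = self.A[i]
        sums = np.bincount(self.labels, weights=row, minlength=self.n.shape[0])
        na, ca = int(self.n[a]), self.c[a]
        nb, cb = int(self.n[b]), self.c[b]
        # removing i from a: subtract its row twice, add back the diagonal
        ca_new = ca - 2.0 * sums[a] + row[i]
        cb_new = cb + 2.0 * sums[b] + row[i]
        ea_new = energy_term(na - 1.0, ca_new) if na > 1 else 0.0
        eb_new = energy_term(nb + 1.0, cb_new)
        dE = ea_new + eb_new - self.e[a] - self.e[b]

        def nlogn(m: float) -> float:
            return m * math.log(m) if m > 0 else 0.0

        s_new = (
            self.sum_nlogn
            - nlogn(na) - nlogn(nb)
            + nlogn(na - 1) + nlogn(nb + 1)
        )
        dH = dE + self.lam * (self.K_gen(s_new) - self.K_gen())
        log_acc = -dH / T + log_q_ratio
        if log_acc < 0 and u >= math.exp(log_acc):
            return False
        self.labels[i] = b
        self.n[a] -= 1
        self.n[b] += 1
        self.c[a], self.c[b] = ca_new, cb_new
        self.e[a], self.e[b] = ea_new, eb_new
        self.E += dE
        self.sum_nlogn = s_new
        if self.n[a] == 0:
            self.c[a] = 0.0
            self.e[a] = 0.0
            self._deactivate(a)
        return True

    def sweep(self, T: float, rng: np.random.Generator) -> int:
        """One Metropolis sweep: every site once, in random order."""
        accepted = 0
        order = rng.permutation(self.N)
        for i in order:
            a = int(self.labels[i])
            # draw uniformly from {active labels != a} + {fresh}; resample
            # the (rare) draws that hit the current label
            while True:
                j = int(rng.integers(0, len(self.active) + 1))
                if j == len(self.active) or self.active[j] != a:
                    break
            fresh = j == len(self.active)
            m_fwd = len(self.active)  # options: (K-1 existing != a) + fresh
            if fresh:
                if self.n[a] == 1:
                    continue  # singleton -> fresh singleton is the identity move
                b = self._activate()
                m_rev = m_fwd + 1  # domain birth
            else:
                b = self.active[j]
                m_rev = m_fwd - 1 if self.n[a] == 1 else m_fwd  # death / neutral
            u = float(rng.random())
            ok = self.propose_and_apply(
                i, b, T, u, log_q_ratio=math.log(m_fwd / m_rev)
            )
            if ok:
                accepted += 1
            elif fresh:
                self._deactivate(b)
        return accepted

    def recompute(self) -> tuple[float, float]:
        """Full from-scratch (E, K) for verification against the
        incremental bookkeeping (contract: agree within 1e-9)."""
        E = 0.0
        s_nlogn = 0.0
        for k in self.active:
            m = self.labels == k
            n = int(m.sum())
            c = float(self.A[np.ix_(m, m)].sum())
            E += energy_term(float(n), c)
            s_nlogn += n * math.log(n) if n > 0 else 0.0
        K = math.exp(math.log(self.N) - s_nlogn / self.N)
        return E, K


def _labels_for(C: CorrelationMatrix, s: Optional[DomainSolution]) -> np.ndarray:
    idx = np.flatnonzero(C.mask)
    if s is None:
        return np.arange(1, len(idx) + 1)
    lab = s.labels[idx]
    if np.any(lab <= 0):
        raise ValueError("initial solution leaves valid bins unlabeled")
    return lab


def _expand(C: CorrelationMatrix, compact: np.ndarray) -> np.ndarray:
    idx = np.flatnonzero(C.mask)
    full = np.zeros(C.n_bins, dtype=int)
    full[idx] = compact + 1
    return canonical_labels(full, C.mask)


def metropolis_sweep(
    s: DomainSolution,
    C: CorrelationMatrix,
    params: ObjectiveParams,
    T: float,
    rng: np.random.Generator,
) -> tuple[DomainSolution, int]:
    """One Metropolis sweep over all valid sites at temperature T.

    Returns the updated (canonicalized) solution and the acceptance count.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    A, _ = C.effective()
    state = _State(A, _labels_for(C, s), params.lam)
    accepted = state.sweep(T, rng)
    out = DomainSolution(_expand(C, state.labels), C.mask.copy(), params.lam, state.H())
    return out, accepted


def anneal(
    C: CorrelationMatrix,
    params: ObjectiveParams,
    schedule: AnnealSchedule,
    init: Optional[DomainSolution] = None,
    track_best: Optional[list] = None,
) -> DomainSolution:
    """Simulated-annealing minimization of H_lambda on C.

    Each restart starts from all singletons (or ``init``, used for the
    first restart as a warm start), cools geometrically from T0 to T_min,
    and tracks the best state ever visited; the best across restarts is
    returned with its objective value recorded.  Fully deterministic given
    (schedule.seed, schedule, C, lambda).
    """
    A, _ = C.effective()
    temps = schedule.temperatures()
    best_H = np.inf
    best_labels: Optional[np.ndarray] = None
    seeds = np.random.SeedSequence(schedule.seed).spawn(schedule.n_restarts)
    for r in range(schedule.n_restarts):
        rng = np.random.default_rng(seeds[r])
        if r == 0 and init is not None:
            labels0 = _labels_for(C, init)
        else:
            labels0 = np.arange(1, A.shape[0] + 1)
        state = _State(A, labels0, params.lam)
        run_best = state.H()
        if run_best < best_H:
            best_H = run_best
            best_labels = state.labels.copy()
        for T in temps:
            for _ in range(schedule.sweeps_per_T):
                state.sweep(T, rng)
                H = state.H()
                if H < best_H - 1e-12:
                    best_H = H
                    best_labels = state.labels.copy()
                run_best = min(run_best, H)
                if track_best is not None:
                    track_best.append(min(run_best, best_H))
    assert best_labels is not None
    return DomainSolution(_expand(C, best_labels), C.mask.copy(), params.lam, float(best_H))


def sweep_lambda(
    C: CorrelationMatrix,
    lambdas: Sequence[float],
    schedule: AnnealSchedule,
    reference: Optional[np.ndarray] = None,
    warm_start: bool = True,
) -> SolutionFamily:
    """Anneal at each lambda (ascending) and collect the solution family.

    With ``warm_start`` the previous lambda's solution seeds one restart of
    the next.  Diagnostics per entry: mean domain size (bins and Mb), index
    of dispersion D, K(s), and nMI against ``reference`` if supplied.
    """
    from . import evaluation

    lambdas = list(lambdas)
    if any(b <= a for a, b in zip(lambdas, lambdas[1:])):
        raise ValueError("lambdas must be strictly increasing")
    fam = SolutionFamily()
    prev: Optional[DomainSolution] = None
    for li, lam in enumerate(lambdas):
        sched = AnnealSchedule(
            schedule.T0, schedule.alpha, schedule.sweeps_per_T,
            schedule.T_min, schedule.n_restarts, schedule.seed + li,
        )
        sol = anneal(C, ObjectiveParams(lam), sched, init=prev if warm_start else None)
        diag: dict = {"K_gen": group_model.generalized_K(sol)}
        if C.binning is not None:
            st = evaluation.size_stats(sol, C.binning)
            diag["mean_size_bins"] = st.mean_size_bins
            diag["mean_size_mb"] = st.mean_size_mb
            diag["dispersion"] = st.dispersion
        else:
            sizes = np.bincount(sol.labels[sol.mask])
            sizes = sizes[sizes > 0]
            diag["mean_size_bins"] = float(sizes.mean())
        if reference is not None:
            diag["nMI"] = evaluation.nmi(reference, sol)
        fam.entries.append(FamilyEntry(lam, sol, float(sol.objective_value), diag))
        prev = sol
    return fam


def infer_compartments(
    C: CorrelationMatrix,
    band_width: int,
    params: ObjectiveParams,
    schedule: AnnealSchedule,
    mode: str = "band",
    primary: Optional[DomainSolution] = None,
    g_tilde: Optional[Sequence[float]] = None,
) -> DomainSolution:
    """Secondary (compartment) inference.

    mode='band'     anneal on C with the near-diagonal band (width
                    ``band_width`` bp) excluded, hiding the local TAD-like
                    evidence so the non-local checkerboard dominates;
    mode='residual' anneal on the residual correlation after explaining
                    away ``primary`` (strengths ``g_tilde``; estimated by
                    :func:`multicd.group_model.estimate_residual_strength`
                    when not given).

    Non-local (non-contiguous) domains are permitted and expected.
    """
    if mode == "band":
        target = band_mask(C, band_width)
    elif mode == "residual":
        if primary is None:
            raise ValueError("mode='residual' requires the primary solution")
        if g_tilde is None:
            g_tilde = estimate_residual_strength(C, primary)
        target = residual_correlation(C, primary, g_tilde)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return anneal(target, params, schedule)
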