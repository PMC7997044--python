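"""Generators realizing the model's own assumptions, so every stage of the
pipeline is testable without external Hi-C downloads.

* ground-truth partitions (contiguous or non-local);
* latent-signal sampling from the one- and two-level group models, giving
  empirical correlation matrices with known block structure;
* forward Hi-C simulation: a correlation matrix is pushed back through the
  polymer map (correlation -> stiffness -> contact probability) and read
  counts are drawn per pair, producing a raw contact map whose
  pre-processing should recover the input correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .polymer_map import contact_probability
from .types import (
    CorrelationMatrix,
    DomainSolution,
    GenomicBinning,
    RawContactMap,
    canonical_labels,
)

__all__ = [
    "GroupSignalModel",
    "random_partition",
    "two_level_partition",
    "sample_signals",
    "model_correlation_matrix",
    "synth_hic",
    "nearest_neighbor_probability",
]


@dataclass
class GroupSignalModel:
    """Latent-signal model: primary labels s with per-domain strengths g,
    optionally a secondary level (labels u, strengths h).  Single level:

        x_i = sqrt(g/(1+g)) eta_s + sqrt(1/(1+g)) eps_i,

    two levels:

        x_i = (eps_i + sqrt(g) eta_s + sqrt(h) xi_u) / sqrt(1 + g + h),

    with eta, xi, eps i.i.d. standard normal; x_i has unit variance in
    both cases."""

    s: np.ndarray
    g: np.ndarray  # one strength per primary domain label (ascending order)
    u: Optional[np.ndarray] = None
    h_strengths: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=int)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.g < 0):
            raise ValueError("strengths must be non-negative")
        if (self.u is None) != (self.h_strengths is None):
            raise ValueError("secondary labels and strengths go together")
        if self.u is not None:
            self.u = np.asarray(self.u, dtype=int)
            if self.u.shape != self.s.shape:
                raise ValueError("s and u must have the same length")
            self.h_strengths = np.asarray(self.h_strengths, dtype=float)
            if np.any(self.h_strengths < 0):
                raise ValueError("strengths must be non-negative")


def random_partition(
    N: int,
    mean_size: float,
    rng: np.random.Generator,
    contiguous: bool = True,
    n_nonlocal_labels: Optional[int] = None,
) -> DomainSolution:
    """Ground-truth partition generator.

    Contiguous mode places boundaries by a Bernoulli process with rate
    1/mean_size (first bin always a boundary), giving geometric run
    lengths.  Non-contiguous mode additionally maps the runs onto a
    smaller label set so domains occupy several separated blocks."""
    if not (1 <= mean_size <= N):
        raise ValueError("mean_size must be in [1, N]")
    boundary = rng.random(N) < 1.0 / mean_size
    boundary[0] = True
    labels = np.cumsum(boundary)
    if not contiguous:
        K = int(labels[-1])
        n_lab = n_nonlocal_labels or max(2, K // 2)
        run_to_label = rng.integers(1, n_lab + 1, size=K + 1)
        labels = run_to_label[labels]
    return DomainSolution(canonical_labels(labels))


def two_level_partition(
    N: int,
    sub_mean_size: float,
    super_mean_size: float,
    rng: np.random.Generator,
) -> tuple[DomainSolution, DomainSolution]:
    """Nested pair of partitions: contiguous super-domains whose boundaries
    are a subset of the sub-domain boundaries (exact nesting)."""
    if super_mean_size <= sub_mean_size:
        raise ValueError("super domains must be larger than sub domains")
    sub = random_partition(N, sub_mean_size, rng)
    starts = np.flatnonzero(np.diff(sub.labels, prepend=0) != 0)
    # promote each sub-boundary to a super-boundary with matching rate
    promote = rng.random(len(starts)) < sub_mean_size / super_mean_size
    promote[0] = True
    super_lab = np.zeros(N, dtype=int)
    super_lab[starts[promote]] = 1
    super_lab = np.cumsum(super_lab)
    return sub, DomainSolution(canonical_labels(super_lab))


def _strength_per_site(labels: np.ndarray, strengths: np.ndarray) -> np.ndarray:
    uniq = np.unique(labels)
    if len(strengths) == 1:
        strengths = np.repeat(strengths, len(uniq))
    if len(strengths) != len(uniq):
        raise ValueError(f"expected {len(uniq)} strengths, got {len(strengths)}")
    lut = dict(zip(uniq.tolist(), np.asarray(strengths, float).tolist()))
    return np.array([lut[int(l)] for l in labels])


def sample_signals(
    model: GroupSignalModel, n_samples: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_samples`` i.i.d. latent-signal vectors and return
    ``(X, C_hat)`` with X of shape (n_samples, N) and C_hat the empirical
    Pearson correlation of the sites."""
    if n_samples < 2:
        raise ValueError("need at least two samples")
    s = model.s
    N = len(s)
    gs = _strength_per_site(s, model.g)
    s_ids = np.unique(s)
    s_pos = {int(k): i for i, k in enumerate(s_ids)}
    s_idx = np.array([s_pos[int(l)] for l in s])
    eps = rng.standard_normal((n_samples, N))
    eta = rng.standard_normal((n_samples, len(s_ids)))
    if model.u is None:
        X = np.sqrt(gs / (1 + gs)) * eta[:, s_idx] + np.sqrt(1 / (1 + gs)) * eps
    else:
        hu = _strength_per_site(model.u, model.h_strengths)
        u_ids = np.unique(model.u)
        u_pos = {int(k): i for i, k in enumerate(u_ids)}
        u_idx = np.array([u_pos[int(l)] for l in model.u])
        xi = rng.standard_normal((n_samples, len(u_ids)))
        X = (eps + np.sqrt(gs) * eta[:, s_idx] + np.sqrt(hu) * xi[:, u_idx]) / np.sqrt(
            1 + gs + hu
        )
    C_hat = np.corrcoef(X, rowvar=False)
    return X, C_hat


def model_correlation_matrix(model: GroupSignalModel) -> np.ndarray:
    """Expected correlation of the generator: for one level
    g/(1+g) within a primary domain; for two levels
    (g d_ss' + h d_uu')/(1+g+h); diagonal 1."""
    s = model.s
    gs = _strength_per_site(s, model.g)
    same_s = s[:, None] == s[None, :]
    if model.u is None:
        C = np.where(same_s, (gs / (1 + gs))[:, None], 0.0)
    else:
        hu = _strength_per_site(model.u, model.h_strengths)
        same_u = model.u[:, None] == model.u[None, :]
        C = (gs[:, None] * same_s + hu[:, None] * same_u) / (1 + gs + hu)[:, None]
    np.fill_diagonal(C, 1.0)
    return C


def nearest_neighbor_probability(
    C: np.ndarray, sigma_c: float = 0.25, r_c: float = 1.0
) -> float:
    """Mean nearest-neighbor contact probability implied by a correlation
    matrix under the forward polymer map (the natural p1bar anchor when
    pre-processing a simulated map)."""
    C = np.asarray(C, dtype=float)
    nn = np.diag(C, k=1)
    gamma = 1.0 / (4.0 * sigma_c * (1.0 - nn))
    return float(np.mean(contact_probability(gamma, r_c)))


def synth_hic(
    C: np.ndarray,
    n_reads_per_pair: int,
    rng: np.random.Generator,
    sigma_c: float = 0.25,
    r_c: float = 1.0,
    bin_size: int = 50_000,
    chromosome: str = "chrS",
    noise: str = "binomial",
) -> RawContactMap:
    """Forward Hi-C simulation from a correlation matrix.

    Runs the polymer map in reverse -- gamma = 1/(4 sigma_c (1 - C)),
    p from the closed-form contact probability -- and draws the count of
    each pair independently as Binomial(n_reads_per_pair, p) (or
    Poisson(n*p)), symmetrized.  Off-diagonal C == 1 has infinite
    stiffness and is rejected."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(C[off] >= 1.0):
        raise ValueError("off-diagonal correlation of 1 implies infinite stiffness")
    with np.errstate(divide="ignore"):
        gamma = 1.0 / (4.0 * sigma_c * (1.0 - C))
    np.fill_diagonal(gamma, 1.0)  # placeholder; diagonal contact is certain
    p = contact_probability(gamma, r_c)
    np.fill_diagonal(p, 1.0)
    iu = np.triu_indices(n)
    if noise == "binomial":
        draws = rng.binomial(n_reads_per_pair, p[iu])
    elif noise == "poisson":
        draws = rng.poisson(n_reads_per_pair * p[iu])
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    counts = np.zeros((n, n))
    counts[iu] = draws
    counts = counts + counts.T - np.diag(np.diag(counts))
    binning = GenomicBinning(chromosome, bin_size, n)
    return RawContactMap(counts, binning)
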