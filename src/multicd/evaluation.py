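"""Comparison and validation statistics for domain solutions.

Covers: Pearson similarity of binary co-membership matrices, normalized
mutual information against a data matrix, chance-corrected nestedness
between two solutions, domain-size statistics (mean and index of
dispersion), CTCF-style boundary cross-correlation chi(d) with an
exponential correlation length, A/B compartment assignment from contact
profiles, and compartment-track cosine correlations.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .types import (
    BalancedContactMap,
    BoundaryCorrelation,
    DomainSolution,
    GenomicBinning,
    NestednessResult,
    SignalTrack,
    SizeStats,
)

__all__ = [
    "binary_similarity",
    "nmi",
    "nestedness",
    "size_stats",
    "boundary_correlation",
    "assign_AB",
    "compartment_track_correlation",
]


def _comembership(s: DomainSolution, idx: np.ndarray) -> np.ndarray:
    lab = s.labels[idx]
    return (lab[:, None] == lab[None, :]).astype(float)


def binary_similarity(s: DomainSolution, s2: DomainSolution) -> Optional[float]:
    """Pearson correlation of the two binary co-membership matrices over all
    distinct valid pairs (i != j).  Label-permutation invariant.  Returns
    None (with a warning) when either matrix has zero variance, e.g. a
    single-domain solution."""
    if s.labels.shape != s2.labels.shape:
        raise ValueError("solutions must have the same length")
    mask = s.mask & s2.mask
    idx = np.flatnonzero(mask)
    B1 = _comembership(s, idx)
    B2 = _comembership(s2, idx)
    off = ~np.eye(len(idx), dtype=bool)
    x, y = B1[off], B2[off]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("co-membership matrix has zero variance; similarity undefined")
        return None
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def nmi(A: np.ndarray, s: DomainSolution, n_bins: int = 100) -> Optional[float]:
    """Normalized mutual information between a data matrix A (e.g. log10 of
    the balanced Hi-C map, or C_O/E) and the co-membership matrix of s.

    A is discretized into ``n_bins`` equal-width bins over [min, max]; the
    joint distribution runs over valid distinct pairs.  Normalization by
    the geometric mean of the marginal entropies makes the result
    base-invariant and confined to [0, 1]."""
    A = np.asarray(A, dtype=float)
    idx = np.flatnonzero(s.mask)
    sub = A[np.ix_(idx, idx)]
    off = ~np.eye(len(idx), dtype=bool)
    finite = np.isfinite(sub)
    sel = off & finite
    a = sub[sel]
    if a.size == 0 or a.max() == a.min():
        warnings.warn("constant data matrix; nMI undefined")
        return None
    b = _comembership(s, idx)[sel]
    edges = np.linspace(a.min(), a.max(), n_bins + 1)
    ai = np.clip(np.searchsorted(edges, a, side="right") - 1, 0, n_bins - 1)
    joint = np.zeros((n_bins, 2))
    np.add.at(joint, (ai, b.astype(int)), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    I = float((joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])).sum())
    Ha = float(-(pa[pa > 0] * np.log(pa[pa > 0])).sum())
    Hb = float(-(pb[pb > 0] * np.log(pb[pb > 0])).sum())
    if Ha == 0 or Hb == 0:
        warnings.warn("degenerate marginal entropy; nMI undefined")
        return None
    return float(I / np.sqrt(Ha * Hb))


def nestedness(
    s_small: DomainSolution,
    s_large: DomainSolution,
    n_null: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> NestednessResult:
    """How completely the domains of ``s_small`` sit inside the domains of
    ``s_large``: per-domain best-overlap fraction h1, chance level h1_bar
    from ``n_null`` random draws (without replacement) of n_k sites from
    ``s_large``, normalized h1_hat = (h1 - h1_bar)/(1 - h1_bar), and the
    size-weighted total h.  h = 1 means perfect nesting, 0 is chance."""
    if rng is None:
        rng = np.random.default_rng(0)
    mask = s_small.mask & s_large.mask
    idx = np.flatnonzero(mask)
    small = s_small.labels[idx]
    large = s_large.labels[idx]
    N = len(idx)
    per_domain = []
    h_total = 0.0
    for k in np.unique(small):
        members = small == k
        n_k = int(members.sum())
        counts = np.bincount(large[members])
        h1 = float(counts.max() / n_k)
        null = np.empty(n_null)
        for t in range(n_null):
            draw = rng.choice(large, size=n_k, replace=False)
            null[t] = np.bincount(draw).max() / n_k
        h1_bar = float(null.mean())
        if h1_bar >= 1.0:
            warnings.warn(f"domain {k}: chance level is 1 (reference is one domain)")
            per_domain.append((int(k), h1, h1_bar, None))
            continue
        h1_hat = (h1 - h1_bar) / (1.0 - h1_bar)
        per_domain.append((int(k), h1, h1_bar, float(h1_hat)))
        h_total += h1_hat * n_k / N
    return NestednessResult(float(h_total), per_domain, n_null)


def size_stats(
    s: DomainSolution, binning: GenomicBinning, units: str = "mb"
) -> SizeStats:
    """Mean domain size and index of dispersion D = var/mean of the sizes.

    Sizes are counted in bins and reported in Mb; D is computed on sizes in
    Mb by default (``units='bins'`` switches to bin counts)."""
    sizes = np.bincount(s.labels[s.mask])
    sizes = sizes[sizes > 0]
    mb = sizes * binning.bin_size / 1e6
    vals = mb if units == "mb" else sizes.astype(float)
    dispersion = float(vals.var() / vals.mean()) if vals.size else 0.0
    return SizeStats(float(sizes.mean()), float(mb.mean()), dispersion, sizes)


def domain_boundaries(s: DomainSolution) -> np.ndarray:
    """psi indicator: 1 on the first bin of every maximal contiguous run of
    one label (a non-local domain contributes one boundary per run); the
    leftmost valid bin always counts as a boundary."""
    idx = np.flatnonzero(s.mask)
    psi = np.zeros(len(s.labels))
    prev = None
    prev_i = None
    for i in idx:
        if prev is None or s.labels[i] != prev or i != prev_i + 1:
            psi[i] = 1.0
        prev, prev_i = s.labels[i], i
    return psi


def boundary_correlation(
    track: SignalTrack, s: DomainSolution, d_max: int = 40
) -> BoundaryCorrelation:
    """Cross-correlation chi(d) between a genomic signal and domain
    boundaries:

        chi(d) = < dphi(i+d) psi(i) >_i / < psi >,

    with dphi the mean-centered signal, for displacements |d| <= d_max.
    The correlation length comes from an unweighted least-squares fit of
    log|chi| to A exp(-|d|/l) over d in [0, d_max] (positive values only).
    """
    if track.binning.n_bins != len(s.labels):
        raise ValueError("track and solution are on different binnings")
    psi = domain_boundaries(s)
    valid = s.mask & np.isfinite(track.values)
    if psi[valid].sum() == 0:
        raise ValueError("no domain boundaries (single domain?)")
    phi = track.values
    dphi = phi - phi[valid].mean()
    n = len(phi)
    ds = np.arange(-d_max, d_max + 1)
    chi = np.full(len(ds), np.nan)
    psi_mean = psi[valid].mean()
    for a, d in enumerate(ds):
        i = np.arange(max(0, -d), min(n, n - d))
        ok = valid[i] & valid[i + d]
        if ok.any():
            chi[a] = float((dphi[i + d][ok] * psi[i][ok]).mean() / psi_mean)
    # exponential fit on the decaying flank
    pos = ds >= 0
    y = np.abs(chi[pos])
    x = ds[pos].astype(float)
    keep = np.isfinite(y) & (y > 0)
    ell_bp: Optional[float] = None
    if keep.sum() >= 2:
        slope, _ = np.polyfit(x[keep], np.log(y[keep]), 1)
        if slope < 0:
            ell_bp = float(-1.0 / slope * track.binning.bin_size)
    return BoundaryCorrelation(ds, chi, ell_bp, psi)


def intra_domain_contact_profile(
    s: DomainSolution, M: BalancedContactMap, label: int, d_max: Optional[int] = None
) -> np.ndarray:
    """Mean contact vs genomic distance over pairs inside one domain."""
    idx = np.flatnonzero(s.mask & M.mask & (s.labels == label))
    n = M.binning.n_bins
    if d_max is None:
        d_max = n - 1
    prof = np.full(d_max + 1, np.nan)
    if len(idx) < 2:
        return prof
    sub = M.values[np.ix_(idx, idx)]
    dmat = np.abs(idx[:, None] - idx[None, :])
    for d in range(d_max + 1):
        sel = dmat == d
        if sel.any():
            prof[d] = float(np.nanmean(sub[sel]))
    return prof


def assign_AB(
    s: DomainSolution, M: BalancedContactMap, short_range_bins: int = 10
) -> tuple[int, int, dict[int, np.ndarray]]:
    """Label the two largest domains as A/B compartments.

    The domain with the higher mean intra-domain contact at short genomic
    range (1 <= d <= ``short_range_bins``) is the locally compact
    B compartment; the other is A.  Ties resolve by label order with a
    warning.  Returns (A_label, B_label, {label: contact profile})."""
    sizes = np.bincount(s.labels[s.mask])
    order = np.argsort(sizes)[::-1]
    big = [int(k) for k in order if k > 0 and sizes[k] > 0][:2]
    if len(big) < 2:
        raise ValueError("need at least two domains for A/B assignment")
    profiles = {
        k: intra_domain_contact_profile(s, M, k, d_max=max(short_range_bins, 10))
        for k in big
    }
    scores = {
        k: float(np.nanmean(profiles[k][1 : short_range_bins + 1])) for k in big
    }
    k1, k2 = big
    if np.isclose(scores[k1], scores[k2], rtol=0, atol=1e-12):
        warnings.warn("identical short-range profiles; resolving tie by label order")
        b_label, a_label = sorted((k1, k2))
        b_label, a_label = b_label, a_label
    elif scores[k1] > scores[k2]:
        b_label, a_label = k1, k2
    else:
        b_label, a_label = k2, k1
    return a_label, b_label, profiles


def compartment_track_correlation(
    s: DomainSolution, A_label: int, B_label: int, track: SignalTrack
) -> tuple[Optional[float], Optional[float]]:
    """Cosine-style correlation between +/-1 compartment indicator vectors
    and a signal track h:  c_X = (q_X . h) / (|q_X| |h|).  When the
    solution is exactly the two compartments, c_B = -c_A."""
    if A_label == B_label:
        raise ValueError("A_label and B_label must differ")
    valid = s.mask & np.isfinite(track.values)
    h = track.values[valid]
    if np.linalg.norm(h) == 0:
        warnings.warn("zero-norm track; correlation undefined")
        return None, None
    lab = s.labels[valid]
    qa = np.where(lab == A_label, 1.0, -1.0)
    qb = np.where(lab == B_label, 1.0, -1.0)
    cA = float(qa @ h / (np.linalg.norm(qa) * np.linalg.norm(h)))
    cB = float(qb @ h / (np.linalg.norm(qb) * np.linalg.norm(h)))
    return cA, cB
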