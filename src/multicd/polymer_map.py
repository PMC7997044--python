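"""Gaussian polymer-network pre-processing: normalized Hi-C contacts to a
pairwise correlation matrix.

The chromosome is modeled as a Gaussian polymer network in which the
distance between segments i and j follows

    P(r; gamma) = 4*pi * (gamma/pi)^(3/2) * r^2 * exp(-gamma r^2),

so the contact probability within a cutoff r_c has the closed form

    p(gamma) = erf(sqrt(gamma) r_c) - 2 r_c sqrt(gamma/pi) exp(-gamma r_c^2),

a strictly increasing function of gamma.  Inverting it per pair converts
the normalized Hi-C map into stiffnesses, and with a uniform segment
variance sigma_c (set by the median rule) the stiffnesses map onto the
correlation matrix C_ij = 1 - 1/(4 sigma_c gamma_ij).  The cutoff r_c only
rescales gamma, so the final C is independent of it.
"""

from __future__ import annotations

import warnings
from typing import Optional, Union

import numpy as np
from scipy.special import erf

from .hic_io import kr_normalize, mask_low_coverage
from .types import (
    BalancedContactMap,
    ContactProbabilityMatrix,
    CorrelationMatrix,
    RawContactMap,
    StiffnessMatrix,
)

__all__ = [
    "contact_probability",
    "invert_contact_probability",
    "contacts_to_probability",
    "probability_to_stiffness",
    "gamma_to_correlation",
    "preprocess",
    "band_mask",
]

# p == 1 entries (clipped by the min operator) have no finite stiffness;
# they are assigned the stiffness of p = 1 - SATURATION_EPS and flagged.
SATURATION_EPS = 1e-6
_DIAG_EPS = 1e-6  # off-diagonal correlation cap: 1 - _DIAG_EPS


def contact_probability(gamma, r_c: float = 1.0):
    """Closed-form contact probability p(gamma, r_c); depends on gamma only
    through the dimensionless product t = gamma * r_c**2."""
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    g = np.asarray(gamma, dtype=float)
    if np.any(g < 0):
        raise ValueError("gamma must be non-negative")
    t = g * r_c**2
    p = erf(np.sqrt(t)) - 2.0 * np.sqrt(t / np.pi) * np.exp(-t)
    out = np.clip(p, 0.0, 1.0)
    return float(out) if np.isscalar(gamma) else out


# Monotone lookup for the inverse map, built once in the dimensionless
# variable t = gamma * r_c^2 (4096 log-spaced knots) and polished by Newton.
_T_GRID = np.logspace(-12, np.log10(60.0), 4096)
_P_GRID = erf(np.sqrt(_T_GRID)) - 2.0 * np.sqrt(_T_GRID / np.pi) * np.exp(-_T_GRID)


def _invert_t(p: np.ndarray, tol: float) -> np.ndarray:
    """Solve p(t) = p for t >= 0 on the monotone closed form."""
    t = np.interp(p, _P_GRID, _T_GRID)
    t = np.where(p <= _P_GRID[0], _T_GRID[0] * p / max(_P_GRID[0], 1e-300), t)
    for _ in range(60):
        pt = erf(np.sqrt(t)) - 2.0 * np.sqrt(t / np.pi) * np.exp(-t)
        resid = pt - p
        if np.all(np.abs(resid) <= tol):
            break
        dpdt = 2.0 * np.sqrt(t / np.pi) * np.exp(-t)
        step = np.where(dpdt > 0, resid / np.maximum(dpdt, 1e-300), 0.0)
        t = np.clip(t - step, 0.0, None)
    # p = 0 exactly -> t = 0
    t = np.where(p <= 0, 0.0, t)
    return t


def invert_contact_probability(
    p: Union[float, np.ndarray], r_c: float = 1.0, tol: float = 1e-10
):
    """Invert the contact-probability map: gamma such that
    ``contact_probability(gamma, r_c) == p`` within ``tol``.

    ``p`` must lie in [0, 1); p == 1 maps to the saturation cap
    ``invert(1 - SATURATION_EPS)`` with a warning.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p must lie in [0, 1]")
    saturated = arr >= 1.0
    if np.any(saturated):
        warnings.warn("p = 1 entries assigned the saturation stiffness cap")
    q = np.where(saturated, 1.0 - SATURATION_EPS, arr)
    t = _invert_t(q, tol)
    gamma = t / r_c**2
    return float(gamma) if np.isscalar(p) else gamma


def contacts_to_probability(
    M: BalancedContactMap, p1bar: float = 0.9
) -> ContactProbabilityMatrix:
    """Convert the balanced map to contact probabilities by anchoring the
    mean nearest-neighbor probability at ``p1bar``:
    ``p = min(1, (p1bar/mu) * M)`` with ``mu = <M_{i,i+1}>``."""
    if not (0 < p1bar <= 1):
        raise ValueError("p1bar must be in (0, 1]")
    n = M.binning.n_bins
    valid = M.mask
    nn = np.array(
        [M.values[i, i + 1] for i in range(n - 1) if valid[i] and valid[i + 1]]
    )
    if nn.size == 0 or not np.isfinite(nn).any() or np.nanmean(nn) <= 0:
        raise ValueError("no nearest-neighbor signal (mu = 0)")
    mu = float(np.nanmean(nn))
    with np.errstate(invalid="ignore"):
        p = np.minimum(1.0, (p1bar / mu) * M.values)
    off = ~np.eye(n, dtype=bool) & valid[:, None] & valid[None, :]
    sat = float(np.mean((p1bar / mu) * M.values[off] > 1)) if off.any() else 0.0
    if sat > 0.10:
        warnings.warn(
            f"{sat:.1%} of contact probabilities saturated at 1; "
            "the polymer-map inversion is unreliable for these pairs"
        )
    return ContactProbabilityMatrix(p, p1bar, mu, M.binning, valid.copy(), sat)


def probability_to_stiffness(
    P: ContactProbabilityMatrix, r_c: float = 1.0, tol: float = 1e-10
) -> StiffnessMatrix:
    """Elementwise inversion of the contact-probability map over valid pairs."""
    idx = np.flatnonzero(P.mask)
    n = P.p.shape[0]
    gamma = np.full((n, n), np.nan)
    sub = P.p[np.ix_(idx, idx)]
    saturated_sub = sub >= 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gsub = invert_contact_probability(sub, r_c=r_c, tol=tol)
    gamma[np.ix_(idx, idx)] = gsub
    saturated = np.zeros((n, n), dtype=bool)
    saturated[np.ix_(idx, idx)] = saturated_sub
    return StiffnessMatrix(gamma, r_c, P.binning, P.mask.copy(), saturated)


def gamma_to_correlation(G: StiffnessMatrix) -> CorrelationMatrix:
    """Map stiffnesses to correlations via C = 1 - 1/(4 sigma_c gamma) with
    sigma_c the median of 1/(4 gamma) over valid, unsaturated off-diagonal
    entries (balancing positive and negative correlations)."""
    gamma = G.gamma
    n = gamma.shape[0]
    mask = G.mask if G.mask is not None else np.ones(n, dtype=bool)
    off = ~np.eye(n, dtype=bool) & mask[:, None] & mask[None, :]
    sel = off & np.isfinite(gamma) & (gamma > 0)
    if G.saturated is not None:
        sel &= ~G.saturated
    if not sel.any():
        raise ValueError("degenerate contact map: no positive off-diagonal stiffness")
    sigma_c = float(np.median(1.0 / (4.0 * gamma[sel])))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = 1.0 - 1.0 / (4.0 * sigma_c * gamma)
    C = np.clip(C, -1.0, 1.0 - _DIAG_EPS)
    C[~np.isfinite(gamma)] = np.nan
    np.fill_diagonal(C, 1.0)
    C[~mask, :] = np.nan
    C[:, ~mask] = np.nan
    return CorrelationMatrix(C, mask.copy(), G.binning, sigma_c)


def preprocess(
    M_raw: RawContactMap,
    p1bar: float = 0.9,
    r_c: float = 1.0,
    min_nonzero_fraction: float = 0.0,
    kr_tol: float = 1e-6,
    kr_max_iter: int = 100,
) -> CorrelationMatrix:
    """Full pre-processing chain: coverage masking -> KR balancing ->
    contact probabilities -> stiffness inversion -> correlation matrix.

    The result is independent of ``r_c`` (the cutoff only rescales the
    stiffnesses, which the median-sigma_c normalization cancels).
    """
    M = mask_low_coverage(M_raw, min_nonzero_fraction)
    B = kr_normalize(M, tol=kr_tol, max_iter=kr_max_iter)
    P = contacts_to_probability(B, p1bar=p1bar)
    G = probability_to_stiffness(P, r_c=r_c)
    return gamma_to_correlation(G)


def band_mask(C: CorrelationMatrix, band_width: int) -> CorrelationMatrix:
    """Exclude the diagonal band ``|i - j| * bin_size <= band_width`` from
    all likelihood statistics (evidence removal for secondary inference);
    the diagonal itself stays defined as 1."""
    if band_width < 0:
        raise ValueError("band_width must be >= 0")
    if C.binning is None:
        raise ValueError("band_mask requires binning metadata")
    band_bins = int(band_width // C.binning.bin_size)
    n = C.n_bins
    if band_bins >= n - 1:
        raise ValueError("band covers the entire matrix")
    return CorrelationMatrix(
        C.C.copy(), C.mask.copy(), C.binning, C.sigma_c, band_bins
    )
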