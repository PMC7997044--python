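"""Reading, balancing and exporting Hi-C matrices and genomic tracks.

Input dialects
--------------
* sparse triplet text: ``start1 <sep> start2 <sep> count`` per line, where the
  coordinates are bin-start base pairs (the dialect of the GEO GSE63525
  intra-chromosomal dumps);
* dense numeric matrices (whitespace/tab separated).

The two are auto-detected from the number of columns on the first data line
(3 columns -> triplet).  All coordinates are 0-based, half-open; BED output
follows the same convention.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .types import (
    BalancedContactMap,
    CorrelationMatrix,
    DomainSolution,
    GenomicBinning,
    RawContactMap,
    SignalTrack,
    canonical_labels,
)

__all__ = [
    "read_contact_map",
    "mask_low_coverage",
    "kr_normalize",
    "expected_profile",
    "oe_pearson",
    "bin_signal_track",
    "write_domains",
    "read_domains",
]


def read_contact_map(
    path,
    bin_size: int,
    chromosome: str = "chr",
    n_bins: Optional[int] = None,
    start_offset: int = 0,
) -> RawContactMap:
    """Read a contact matrix from a sparse-triplet or dense text file.

    Triplet coordinates are bin-start bp and must be multiples of
    ``bin_size`` (after subtracting ``start_offset``); the matrix size is
    inferred from the largest coordinate unless ``n_bins`` is given.
    """
    with open(path) as fh:
        first = None
        for line in fh:
            if line.strip() and not line.startswith(("#", "track")):
                first = line
                break
    if first is None:
        raise ValueError(f"no records in {path}")
    ncol = len(first.split())

    if ncol == 3:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
        if df.shape[1] != 3:
            raise ValueError(f"inconsistent column count in {path}")
        for col in range(3):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            if bad.any():
                raise ValueError(
                    f"non-numeric field in {path} at data line {int(bad.idxmax()) + 1}"
                )
        coords = df[[0, 1]].to_numpy(dtype=float) - start_offset
        if np.any(coords % bin_size != 0):
            bad_line = int(np.flatnonzero((coords % bin_size != 0).any(axis=1))[0]) + 1
            raise ValueError(
                f"coordinate not a multiple of bin_size={bin_size} at data line {bad_line}"
            )
        ii = (coords[:, 0] // bin_size).astype(int)
        jj = (coords[:, 1] // bin_size).astype(int)
        vv = df[2].to_numpy(dtype=float)
        n = n_bins if n_bins is not None else int(max(ii.max(), jj.max())) + 1
        counts = np.zeros((n, n))
        np.add.at(counts, (ii, jj), vv)
        # mirror across the diagonal; diagonal entries appear once in the file
        counts = counts + counts.T - np.diag(np.diag(counts))
    else:
        counts = np.loadtxt(path)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"dense matrix in {path} is not square: {counts.shape}")
        if np.abs(counts - counts.T).max() > 1e-9:
            raise ValueError(f"dense matrix in {path} is asymmetric beyond 1e-9")
        counts = 0.5 * (counts + counts.T)
        n = counts.shape[0]
        if n_bins is not None and n_bins != n:
            raise ValueError(f"dense matrix has {n} bins, expected {n_bins}")

    binning = GenomicBinning(chromosome, bin_size, n, start_offset)
    return RawContactMap(counts, binning)


def mask_low_coverage(M: RawContactMap, min_nonzero_fraction: float = 0.0) -> RawContactMap:
    """Mark empty or sparse bins invalid: a bin fails if its row sum is 0 or
    its fraction of nonzero entries falls below ``min_nonzero_fraction``.
    Matrix values are left untouched."""
    if not (0 <= min_nonzero_fraction <= 1):
        raise ValueError("min_nonzero_fraction must be in [0, 1]")
    row_sums = M.counts.sum(axis=1)
    nz_frac = (M.counts > 0).mean(axis=1)
    ok = (row_sums > 0) & (nz_frac >= min_nonzero_fraction)
    mask = M.mask & ok
    if not mask.any():
        raise ValueError("no usable bins after coverage masking")
    return RawContactMap(M.counts, M.binning, mask)


def _kr_balance(A: np.ndarray, tol: float, max_outer: int) -> np.ndarray:
    """Knight-Ruiz balancing: find x > 0 with diag(x) A diag(x) e = e.

    Inner-outer Newton iteration with a conjugate-gradient inner solve,
    following Knight & Ruiz (2013, IMA J Numer Anal).
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g_par, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    outer = 0
    while rout > rt:
        outer += 1
        if outer > max_outer:
            raise RuntimeError(
                f"KR balancing did not converge in {max_outer} outer iterations "
                f"(residual {np.sqrt(rout):.3g}); consider stronger masking"
            )
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = np.zeros(n)
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 200:  # CG stagnation guard
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta = g_par * rat
        if g_par * eta**2 > 0.1:
            eta = max(eta, g_par * eta**2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))
    return x


def kr_normalize(M: RawContactMap, tol: float = 1e-6, max_iter: int = 100) -> BalancedContactMap:
    """Knight-Ruiz balance the valid submatrix so every valid row sums to 1.

    Raises if the valid contact graph is disconnected (the balancing vector
    is then not unique) or if the iteration fails to converge.
    """
    idx = np.flatnonzero(M.mask)
    if idx.size == 0:
        raise ValueError("no valid bins to normalize")
    A = M.counts[np.ix_(idx, idx)]
    ncomp, _ = connected_components(csr_matrix(A > 0), directed=False)
    if ncomp > 1:
        raise ValueError(
            f"contact graph on valid bins has {ncomp} components; "
            "apply stronger low-coverage masking first"
        )
    x = _kr_balance(A, tol, max_iter)
    n = M.binning.n_bins
    v = np.full(n, np.nan)
    v[idx] = x
    values = np.full((n, n), np.nan)
    values[np.ix_(idx, idx)] = x[:, None] * x[None, :] * A
    return BalancedContactMap(values, v, M.binning, M.mask.copy())


def expected_profile(
    M: BalancedContactMap,
    smoothing: str = "proportional",
    window_fraction: float = 0.01,
) -> np.ndarray:
    """Distance-dependent expected contact: mean of ``values`` over valid
    pairs at each genomic distance ``d = |i - j|``.

    ``smoothing='proportional'`` averages the raw per-distance means over a
    window that grows with d (``[d - ceil(f*d), d + ceil(f*d)]``);
    ``smoothing='none'`` returns the raw means.  Distances with no valid
    pairs carry the last finite value forward.
    """
    n = M.binning.n_bins
    idx = np.flatnonzero(M.mask)
    A = M.values[np.ix_(idx, idx)]
    dmat = np.abs(idx[:, None] - idx[None, :])
    raw = np.full(n, np.nan)
    sums = np.bincount(dmat.ravel(), weights=np.nan_to_num(A).ravel(), minlength=n)
    cnts = np.bincount(dmat.ravel(), weights=np.isfinite(A).ravel().astype(float), minlength=n)
    with np.errstate(invalid="ignore"):
        raw[: len(sums)] = np.where(cnts[:n] > 0, sums[:n] / np.maximum(cnts[:n], 1), np.nan)
    # carry last finite value forward over empty distances
    last = np.nan
    for d in range(n):
        if np.isfinite(raw[d]):
            last = raw[d]
        else:
            raw[d] = last
    if smoothing == "none":
        return raw
    if smoothing != "proportional":
        raise ValueError(f"unknown smoothing policy {smoothing!r}")
    out = np.empty(n)
    for d in range(n):
        w = int(np.ceil(window_fraction * d))
        lo, hi = max(0, d - w), min(n - 1, d + w)
        out[d] = np.nanmean(raw[lo : hi + 1])
    return out


def oe_pearson(M: BalancedContactMap, expected: Optional[np.ndarray] = None) -> CorrelationMatrix:
    """Observed/expected matrix and its row-wise Pearson correlation C_O/E.

    Rows whose O/E profile has zero variance are masked and their
    correlations set to NaN.  The diagonal is set to 1.
    """
    if expected is None:
        expected = expected_profile(M)
    n = M.binning.n_bins
    idx = np.flatnonzero(M.mask)
    d = np.abs(idx[:, None] - idx[None, :])
    exp_sub = expected[d]
    if np.any(~np.isfinite(exp_sub)) or np.any(exp_sub <= 0):
        raise ValueError("expected profile must be strictly positive where used")
    oe = M.values[np.ix_(idx, idx)] / exp_sub
    sd = oe.std(axis=1)
    good = sd > 1e-12 * max(np.abs(oe).max(), 1.0)  # rounding-level variance is none
    C_full = np.full((n, n), np.nan)
    mask = np.zeros(n, dtype=bool)
    if good.sum() >= 2:
        sub = np.corrcoef(oe[good][:, good])
        keep = idx[good]
        C_full[np.ix_(keep, keep)] = sub
        mask[keep] = True
    if (~good).any():
        warnings.warn(f"{int((~good).sum())} zero-variance O/E rows masked")
    np.fill_diagonal(C_full, 1.0)
    C_full = np.clip(C_full, -1.0, 1.0)
    return CorrelationMatrix(C_full, mask, M.binning)


def bin_signal_track(
    intervals: Iterable[tuple[float, float, float]],
    binning: GenomicBinning,
    name: str = "",
) -> SignalTrack:
    """Average interval signals into bins.

    An interval fully inside one bin contributes its value there; an
    interval overlapping k > 1 bins contributes value/k to each (the
    even-split convention for straddling peaks).  Multiple contributions in
    one bin are averaged.  Bins with no signal are 0.
    """
    sums = np.zeros(binning.n_bins)
    counts = np.zeros(binning.n_bins)
    lo_bp = binning.start_offset
    hi_bp = binning.start_offset + binning.n_bins * binning.bin_size
    for start, end, value in intervals:
        if end <= start:
            raise ValueError(f"empty interval [{start}, {end})")
        if start < lo_bp or end > hi_bp:
            warnings.warn(f"interval [{start}, {end}) clipped to binning range")
            start, end = max(start, lo_bp), min(end, hi_bp)
            if end <= start:
                continue
        b0 = int((start - lo_bp) // binning.bin_size)
        b1 = int((end - 1 - lo_bp) // binning.bin_size)  # inclusive last bin
        nb = b1 - b0 + 1
        for b in range(b0, b1 + 1):
            sums[b] += value / nb
            counts[b] += 1
    values = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return SignalTrack(values, binning, name)


def write_domains(s: DomainSolution, binning: GenomicBinning, path) -> None:
    """Write a domain solution as BED (0-based, half-open).

    Contiguous runs of one label merge into one record; a non-local domain
    yields several records sharing a name; masked bins get name '.'."""
    labels = s.labels
    with open(path, "w") as fh:
        i = 0
        n = binning.n_bins
        while i < n:
            j = i
            while j + 1 < n and labels[j + 1] == labels[i] and s.mask[j + 1] == s.mask[i]:
                j += 1
            name = str(labels[i]) if s.mask[i] else "."
            fh.write(
                f"{binning.chromosome}\t{binning.bin_start(i)}\t{binning.bin_end(j)}\t{name}\n"
            )
            i = j + 1


def read_domains(path, binning: GenomicBinning) -> DomainSolution:
    """Read a BED file written by :func:`write_domains` back into labels."""
    labels = np.zeros(binning.n_bins, dtype=int)
    mask = np.zeros(binning.n_bins, dtype=bool)
    name_map: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, nm = line.split()[:4]
            b0 = (int(start) - binning.start_offset) // binning.bin_size
            b1 = (int(end) - binning.start_offset) // binning.bin_size
            if nm == ".":
                continue
            if nm not in name_map:
                name_map[nm] = len(name_map) + 1
            labels[b0:b1] = name_map[nm]
            mask[b0:b1] = True
    return DomainSolution(canonical_labels(labels, mask), mask)
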