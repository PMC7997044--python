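"""Shared data containers for the Multi-CD pipeline.

Every matrix is stored dense and full-size (``n_bins x n_bins``); bins that
are excluded from analysis (unmappable, low coverage) are tracked with a
boolean ``mask`` (True = valid) and carry NaN in derived matrices rather
than silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "GenomicBinning",
    "RawContactMap",
    "BalancedContactMap",
    "SignalTrack",
    "ContactProbabilityMatrix",
    "StiffnessMatrix",
    "CorrelationMatrix",
    "DomainSolution",
    "DomainStats",
    "ObjectiveParams",
    "AnnealSchedule",
    "FamilyEntry",
    "SolutionFamily",
    "NestednessResult",
    "SizeStats",
    "BoundaryCorrelation",
]


@dataclass(frozen=True)
class GenomicBinning:
    """Uniform binning of one chromosome: bin ``i`` covers the 0-based,
    half-open interval ``[start_offset + i*bin_size, start_offset + (i+1)*bin_size)``.
    """

    chromosome: str
    bin_size: int
    n_bins: int
    start_offset: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")

    def bin_start(self, i: int) -> int:
        return self.start_offset + i * self.bin_size

    def bin_end(self, i: int) -> int:
        return self.start_offset + (i + 1) * self.bin_size


def _check_symmetric(a: np.ndarray, tol: float = 1e-9, what: str = "matrix") -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{what} must be square, got shape {a.shape}")
    finite = np.isfinite(a)
    if not np.array_equal(finite, finite.T):
        raise ValueError(f"{what} has an asymmetric NaN pattern")
    d = np.abs(np.where(finite, a, 0.0) - np.where(finite, a, 0.0).T)
    if d.max(initial=0.0) > tol:
        raise ValueError(f"{what} is not symmetric (max deviation {d.max():.3g})")


@dataclass
class RawContactMap:
    """Symmetric non-negative Hi-C count matrix with binning metadata."""

    counts: np.ndarray
    binning: GenomicBinning
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        _check_symmetric(self.counts, what="contact map")
        if np.nanmin(self.counts) < 0:
            raise ValueError("contact counts must be non-negative")
        if self.counts.shape[0] != self.binning.n_bins:
            raise ValueError("matrix size does not match binning.n_bins")
        if self.mask is None:
            self.mask = np.ones(self.binning.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.binning.n_bins


@dataclass
class BalancedContactMap:
    """KR-balanced matrix ``values[i,j] = v[i] * v[j] * counts[i,j]`` whose
    valid rows each sum to 1."""

    values: np.ndarray
    balance_vector: np.ndarray
    binning: GenomicBinning
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class SignalTrack:
    """Per-bin 1-D genomic signal (CTCF, Repli-seq, histone marks, ...).

    Bins with no data carry NaN, never a silent zero.
    """

    values: np.ndarray
    binning: GenomicBinning
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.binning.n_bins,):
            raise ValueError("track length must equal binning.n_bins")


@dataclass
class ContactProbabilityMatrix:
    """Pairwise contact probabilities ``p = min(1, (p1bar/mu) * M)``."""

    p: np.ndarray
    p1bar: float
    mu: float
    binning: GenomicBinning
    mask: np.ndarray
    saturated_fraction: float = 0.0


@dataclass
class StiffnessMatrix:
    """Harmonic stiffnesses gamma (units of 1/r_c^2) of the polymer network."""

    gamma: np.ndarray
    r_c: float = 1.0
    binning: Optional[GenomicBinning] = None
    mask: Optional[np.ndarray] = None
    saturated: Optional[np.ndarray] = None  # entries where p == 1 hit the gamma cap


@dataclass
class CorrelationMatrix:
    """Symmetric correlation matrix with unit diagonal.

    ``band_bins`` (if set) excludes pairs with ``|i - j| <= band_bins`` from
    all likelihood statistics; the diagonal stays defined as 1.
    """

    C: np.ndarray
    mask: np.ndarray
    binning: Optional[GenomicBinning] = None
    sigma_c: Optional[float] = None
    band_bins: Optional[int] = None

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.C.shape[0]

    def effective(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(A, idx)``: the compacted valid-bin matrix used by the
        likelihood, with band-excluded pairs zeroed (evidence removed) and
        the diagonal forced to 1, plus the original indices of its rows."""
        idx = np.flatnonzero(self.mask)
        A = self.C[np.ix_(idx, idx)].copy()
        A[~np.isfinite(A)] = 0.0
        if self.band_bins is not None:
            d = np.abs(idx[:, None] - idx[None, :])
            A[d <= self.band_bins] = 0.0
        np.fill_diagonal(A, 1.0)
        return A, idx


@dataclass
class DomainSolution:
    """Length-N label vector; valid bins carry labels 1..K (canonical: first
    occurrences in increasing order), masked bins carry 0."""

    labels: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    lambda_used: Optional[float] = None
    objective_value: Optional[float] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.mask is None:
            self.mask = self.labels > 0
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_domains(self) -> int:
        v = self.labels[self.mask]
        return int(len(np.unique(v))) if v.size else 0

    def canonical(self) -> "DomainSolution":
        labels = canonical_labels(self.labels, self.mask)
        return DomainSolution(labels, self.mask.copy(), self.lambda_used, self.objective_value)


def canonical_labels(labels: np.ndarray, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Relabel so first occurrences (over valid bins) appear in increasing order 1..K."""
    labels = np.asarray(labels, dtype=int)
    if mask is None:
        mask = labels > 0
    out = np.zeros_like(labels)
    remap: dict[int, int] = {}
    nxt = 1
    for i in np.flatnonzero(mask):
        lab = labels[i]
        if lab not in remap:
            remap[lab] = nxt
            nxt += 1
        out[i] = remap[lab]
    return out


@dataclass
class DomainStats:
    """Per-domain sufficient statistics of the group model: size ``n_k``,
    intra-domain correlation sum ``c_k`` (diagonal included), and the
    likelihood-optimal strength ``g_hat_k = max(0, (c_k - n_k)/(n_k^2 - c_k))``."""

    labels: np.ndarray  # distinct domain labels, ascending
    n: np.ndarray
    c: np.ndarray
    g_hat: np.ndarray


@dataclass(frozen=True)
class ObjectiveParams:
    """The Lagrange multiplier (negative chemical potential) lambda >= 0
    multiplying the generalized domain count K(s)."""

    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule for simulated annealing."""

    T0: float = 1.0
    alpha: float = 0.9
    sweeps_per_T: int = 20
    T_min: float = 1e-3
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.T0 > self.T_min > 0):
            raise ValueError("require T0 > T_min > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.sweeps_per_T < 1 or self.n_restarts < 1:
            raise ValueError("sweeps_per_T and n_restarts must be >= 1")

    def temperatures(self) -> np.ndarray:
        n = int(np.floor(np.log(self.T_min / self.T0) / np.log(self.alpha))) + 1
        return self.T0 * self.alpha ** np.arange(max(n, 1))


@dataclass
class FamilyEntry:
    lam: float
    solution: DomainSolution
    H: float
    diagnostics: dict


@dataclass
class SolutionFamily:
    """Ordered (by lambda) family of domain solutions with diagnostics."""

    entries: list[FamilyEntry] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def lambdas(self) -> np.ndarray:
        return np.array([e.lam for e in self.entries])

    def diagnostic(self, key: str) -> np.ndarray:
        return np.array([e.diagnostics.get(key, np.nan) for e in self.entries])


@dataclass
class NestednessResult:
    h: float
    per_domain: list  # (label, h1, h1_bar, h1_hat) tuples; h1_hat None if undefined
    n_null: int


@dataclass
class SizeStats:
    mean_size_bins: float
    mean_size_mb: float
    dispersion: float  # variance-to-mean ratio of sizes (in Mb by default)
    sizes: np.ndarray


@dataclass
class BoundaryCorrelation:
    d: np.ndarray  # displacements, bins
    chi: np.ndarray
    correlation_length_bp: Optional[float]
    psi: np.ndarray
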