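"""Comparison statistics between domain solutions and against signal tracks.

Builds two nested partitions and a boundary-enriched signal track, then
computes the similarity, nestedness, size statistics, nMI, and the
boundary cross-correlation chi(d).
"""

import numpy as np

from multicd import (
    DomainSolution,
    GenomicBinning,
    SignalTrack,
    binary_similarity,
    boundary_correlation,
    nestedness,
    nmi,
    size_stats,
)
from multicd.evaluation import domain_boundaries

N = 400
binning = GenomicBinning("chrS", 50_000, N)
sub = DomainSolution((np.arange(N) // 10) + 1)   # 40 domains of 10 bins
sup = DomainSolution((np.arange(N) // 50) + 1)   # 8 domains of 50 bins
rng = np.random.default_rng(0)

print("similarity(sub, sup) =", round(binary_similarity(sub, sup), 3))
res = nestedness(sub, sup, rng=rng)
print("nestedness h(sub -> sup) =", round(res.h, 3), "(1 = perfectly nested)")

st = size_stats(sup, binning)
print(f"super-domains: <n> = {st.mean_size_mb:.2f} Mb, dispersion D = {st.dispersion:.3f}")

B = (sup.labels[:, None] == sup.labels[None, :]).astype(float)
A = B + 0.3 * rng.standard_normal((N, N))
A = (A + A.T) / 2
print("nMI(noisy co-membership, sup) =", round(nmi(A, sup), 3))

# CTCF-like track: unit peaks at sub-domain boundaries plus noise
psi = domain_boundaries(sub)
track = SignalTrack(psi + 0.1 * rng.standard_normal(N), binning, name="ctcf-like")
bc = boundary_correlation(track, sub, d_max=8)
i0 = np.flatnonzero(bc.d == 0)[0]
print(f"chi(0) = {bc.chi[i0]:.2f} (peak at the boundaries), "
      f"chi(+-3) = {bc.chi[i0+3]:.2f}/{bc.chi[i0-3]:.2f}")
# A sharp chi(d) peak at d = 0 means the signal is enriched precisely at
# the inferred domain boundaries.
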