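# multicd

Multi-scale chromatin domain inference from Hi-C contact matrices.

Hi-C measures the contact frequency between all pairs of genomic bins on
a chromosome. The block and checkerboard patterns in these maps reflect
chromatin domains — sub-TADs, TADs, meta-TADs and A/B compartments — at
different genomic scales, but most callers target one scale with
scale-specific heuristics. `multicd` treats all of them in a single
framework, for computational genomicists who want one interpretable model
across scales rather than a different tool per scale:

1. **Pre-processing.** The chromosome is modeled as a Gaussian polymer
   network: the distance between bins *i, j* follows
   P(r; γᵢⱼ) = 4π(γᵢⱼ/π)^{3/2} r² e^{−γᵢⱼ r²}, so the contact probability
   within a cutoff r_c is pᵢⱼ = erf(√γᵢⱼ r_c) − 2r_c√(γᵢⱼ/π) e^{−γᵢⱼ r_c²},
   strictly increasing in the stiffness γᵢⱼ. A KR-balanced Hi-C map,
   anchored so the mean nearest-neighbor contact probability is p̄₁,
   is inverted pair by pair to stiffnesses and then to a correlation
   matrix Cᵢⱼ = 1 − 1/(4σ_c γᵢⱼ), with σ_c set by the median rule. The
   result is independent of r_c.

2. **Inference.** C is assumed to be generated by a *group model*: each
   bin's latent signal mixes a domain-shared Gaussian variable (weight
   g_k ≥ 0) with private noise, xᵢ = √(g/(1+g)) η_{sᵢ} + √(1/(1+g)) εᵢ.
   The partition **s** is found by simulated annealing on

       H_λ(s|C) = E(s|C) + λ·K(s),

   where E is the negative profile log-likelihood (strengths maximized in
   closed form) and K(s) = exp(entropy of domain-size fractions) is the
   generalized domain count. Sweeping the single parameter λ yields the
   whole solution family, from sub-TAD-like fine partitions (λ = 0) to
   coarse ones; A/B compartments emerge as a *secondary* solution after
   masking the near-diagonal band or explaining away the primary solution
   via the residual correlation C_res = (1+g̃)C − g̃δ_{sᵢsⱼ}.

   **λ has no intrinsic biological meaning** — the λ value at which TADs
   or compartments appear depends on resolution, chromosome and cell
   type. Identify named scales from properties of the family
   (conservation across cell types, nMI against the data), not from a
   fixed λ.

Domains may be non-local (non-contiguous): the model clusters bins, not
intervals, which is exactly what lets the same machinery capture the
compartment checkerboard.

The package also implements the evaluation toolbox: co-membership Pearson
similarity, normalized mutual information against the data, a
chance-corrected nestedness score between solutions at two scales, domain
size statistics (mean, index of dispersion), CTCF-boundary
cross-correlation χ(d) with exponential correlation lengths, and A/B
assignment from intra-domain contact profiles with signal-track
correlations.

## Quick start

```python
import numpy as np
from multicd import (AnnealSchedule, CorrelationMatrix, DomainSolution,
                     GenomicBinning, GroupSignalModel, ObjectiveParams,
                     anneal, binary_similarity, sample_signals)

# five equal domains of 20 bins with clustering strength g = 2
truth = np.repeat(np.arange(1, 6), 20)
model = GroupSignalModel(truth, np.full(5, 2.0))
_, C_hat = sample_signals(model, n_samples=400, rng=np.random.default_rng(1))

C = CorrelationMatrix(np.clip(C_hat, -1, 1 - 1e-6), np.ones(100, bool),
                      GenomicBinning("chrS", 50_000, 100))
sol = anneal(C, ObjectiveParams(lam=0.0), AnnealSchedule(seed=1, n_restarts=3))
print(sol.n_domains, binary_similarity(sol, DomainSolution(truth)))
```

Running `examples/02_infer_domains.py` (this script) prints

```
inferred 5 domains (truth: 5), H = -46.283
similarity to ground truth rho = 1.000
```

i.e. the annealer recovers the generating five-domain partition exactly
(ρ is the Pearson correlation of the two co-membership matrices; 1 means
identical partitions up to label names) with objective value −46.28.
`examples/04_compartments.py` shows the secondary inference on two-level
data, where both routes recover the planted compartments:

```
band mode:     K = 2, rho vs true compartments = 1.000
primary (lambda=0): K = 12, rho vs true TAD-like domains = 1.000
residual mode: K = 2, rho vs true compartments = 1.000
```

The other scripts in `examples/` cover pre-processing a simulated raw map
(`01`), the multi-scale λ sweep (`03`) and the evaluation statistics
(`05`); each prints the numbers it computes with a note on their meaning.

## Command line

A thin CLI wraps the library for shell pipelines:

```
multicd simulate hic --n 100 --n-reads 50000 --seed 3 --out hic.txt
multicd preprocess --input hic.txt --bin-size 50000 --out C.tsv
multicd infer --corr C.tsv --lam 10 --seed 1 --out domains.bed
multicd sweep --corr C.tsv --lams 0:10:100 --out family.json
multicd compartments --corr C.tsv --band 2000000 --lam 90 --out comps.bed
multicd eval similarity --bed a.bed --bed b.bed --bin-size 50000 --n-bins 100
```

Raw maps are read as GSE63525-style sparse triplets ("start1 start2
count", bin-start bp) or dense matrices (auto-detected); solutions are
written as BED (0-based, half-open; non-local domains produce multiple
records sharing one name).

## Testing

```
python -m pytest tests/
```

The suite includes unit tests per module, seeded property tests (KR row
sums and scale invariance, inversion identity, detailed balance of the
sampler against exact enumeration, label-permutation invariance) and
end-to-end recovery benchmarks.

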