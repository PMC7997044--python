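# Methods

`multicd` infers chromatin domains (CDs) from intra-chromosomal Hi-C
contact matrices in two stages: a physically motivated *pre-processing*
step that converts raw counts into a pairwise correlation matrix, and a
statistical-mechanics *inference* step that partitions genomic bins into
domains by minimizing a penalized group-model objective with simulated
annealing. This note records the model, its assumptions, the parameters
that matter, and the design choices made where the design was open.

## 1. From Hi-C counts to a correlation matrix

**Model.** The chromosome segment positions are treated as a Gaussian
polymer network: the distance between segments *i* and *j* follows

    P(r; γ_ij) = 4π (γ_ij/π)^{3/2} r² exp(−γ_ij r²),

where γ_ij is the effective harmonic stiffness coupling the pair. The
probability of a contact within cutoff r_c is the closed form

    p(γ) = erf(√γ · r_c) − 2 r_c √(γ/π) · exp(−γ r_c²),

strictly increasing in γ, so each contact probability determines a unique
stiffness. With a uniform per-segment variance σ_c, the stiffnesses map
onto a correlation matrix C via C_ij = 1 − 1/(4 σ_c γ_ij).

**Pipeline** (`polymer_map.preprocess`):

1. *Coverage masking* — bins with zero marginal count (or a nonzero
   fraction below `min_nonzero_fraction`) are excluded; they stay NaN
   throughout, never silent zeros.
2. *KR balancing* — Knight–Ruiz inner–outer Newton iteration (CG inner
   solve) on the valid submatrix, so every valid row sums to 1
   (tolerance 1e-6, max 100 outer iterations). Balancing requires the
   contact graph on valid bins to be connected; otherwise the scaling
   vector is not unique and the call fails with advice to mask harder.
3. *Probability anchor* — the balanced signal is proportional to the
   contact probability; the unknown constant is fixed by anchoring the
   mean nearest-neighbor contact probability at `p1bar` (default 0.9:
   adjacent 50-kb bins are nearly always in contact, but not exactly).
   Entries pushed above 1 are clipped; the clipped fraction is recorded
   and a warning is raised above 10%.
4. *Stiffness inversion* — elementwise numerical inversion of p(γ) via a
   4096-knot monotone lookup in the dimensionless variable t = γ r_c²,
   polished by Newton to |p(t) − p| ≤ 1e-10. Clipped p = 1 entries have
   no finite stiffness; they receive the saturation cap
   γ_max = invert(1 − 1e-6) and are flagged.
5. *Correlation* — σ_c is the median of 1/(4γ) over valid, unsaturated
   off-diagonal entries, which balances the fractions of positive and
   negative correlation. Off-diagonal values are clamped to
   [−1, 1 − 1e-6]; without the upper cap a perfectly correlated pair
   makes the inference energy diverge.

Because p depends on γ only through γ r_c², the cutoff only rescales the
stiffnesses and σ_c cancels it: the final C is exactly independent of
r_c. This is asserted in tests by running the pipeline at r_c = 1 and 2.

**Numerical domain of the inversion.** In double precision the forward
map saturates: for γ r_c² ≳ 20, 1 − p underflows relative to 1 and p
rounds to exactly 1, so no algorithm can invert there. The pipeline never
produces stiffnesses beyond the saturation cap (≈ 11.6 at r_c = 1), and
the inversion identity is guaranteed (to 1e-8) on [1e-4, 12].

## 2. The group model and the inference objective

Each bin *i* carries a latent standardized signal mixing a component
shared by its domain s_i with private noise,

    x_i = √(g/(1+g)) η_{s_i} + √(1/(1+g)) ε_i ,

giving model correlation g/(1+g) within a domain and 0 across domains.
The log-likelihood of a data correlation matrix C given a partition **s**
and strengths g_k depends only on each domain's size n_k and
intra-domain correlation sum c_k (diagonal included), and is maximized in
closed form at ĝ_k = (c_k − n_k)/(n_k² − c_k). Substituting ĝ gives the
energy

    E(s|C) = ½ Σ_k [ ln(c_k/n_k) + (n_k − 1) ln((n_k² − c_k)/(n_k² − n_k)) ],

lower is better. Two boundary conventions matter:

* **g ≥ 0 boundary.** When c_k ≤ n_k (net non-positive intra-domain
  correlation) the likelihood optimum over g ≥ 0 sits at g = 0 and the
  domain's energy contribution is defined as 0, the no-grouping baseline.
  The printed energy formula is symmetric in the sign of the correlations
  and would otherwise *reward* anti-correlated groupings, contradicting
  the generative model.
* **Diagonal.** c_k always includes the i = j terms (1 per member); band
  exclusion (below) removes evidence pairs, not self-correlation.

The objective minimized at a given λ ≥ 0 is

    H_λ(s|C) = E(s|C) + λ K(s),    K(s) = exp(−Σ_k p_k ln p_k),  p_k = n_k/N,

with K(s) the generalized (entropy-based) domain count: equal to the
plain count for equal sizes, smaller when sizes are uneven. λ acts as a
negative chemical potential for domains; sweeping it produces the
multi-scale solution family. Natural logarithms are used throughout
(forced for K(s), adopted uniformly).

**λ carries no intrinsic biological meaning.** The λ value at which
TAD-like or compartment-like solutions appear depends on the data
resolution, the chromosome length, and the cell type; named scales should
be identified from properties of the family (cross-cell-type
conservation, nMI against the data), not from fixed λ values. Because
both E and (at fixed structure) λK(s) are extensive in N, λ ranges scale
roughly proportionally with the number of bins: the desk-scale benchmarks
here (N ≈ 100–200) use grids of order 0–10 where a ~2700-bin chromosome
at 50 kb calls for 0–100.

**A consequence of the g ≥ 0 boundary worth knowing.** Merging groups
with *zero* mutual correlation costs no energy while reducing K(s). At
large λ the optimizer therefore prefers to keep a few strongly correlated
domains intact and pool weakly related bins into large heterogeneous
domains, rather than reproducing a coarse partition whose blocks are
mutually uncorrelated. This is intrinsic to the model (it is the same
mechanism behind the crossover from homogeneous-local to
heterogeneous-non-local solutions as λ grows) and is why the nested
benchmark below gives the super-level most of the correlation mass.

## 3. Simulated annealing

`anneal` minimizes H_λ with a single-site Markov chain: each sweep visits
every valid bin in random order and proposes relabeling it to a uniformly
chosen existing domain or to a fresh singleton. Because the number of
proposal options changes when domains are created or destroyed, the
proposal is asymmetric and the acceptance rule is Metropolis–Hastings,

    min(1, exp(−ΔH/T) · m_fwd/m_rev),

with m the option counts before/after the move; the chain then satisfies
detailed balance w.r.t. exp(−H/T), which a test verifies exactly on a
4-site system against all 15 enumerated partitions.

ΔH is evaluated incrementally: a move touches two domains whose (n_k,
c_k) update from one row sum, and Σ n_k ln n_k is maintained so K(s)
updates in O(1). Incremental and from-scratch recomputation agree to
1e-9 (tested). Empty domains are deleted and labels canonicalized (first
occurrences in increasing order) at sweep ends.

**Schedule.** Geometric cooling T ← αT from T0 = 1.0 with α = 0.9 to
T_min = 1e-3, 20 sweeps per temperature, 5 restarts by default (2–3 in
the benchmarks, which are smaller), each restart starting from all
singletons — unbiased with respect to the domain count, letting the
penalty shrink K. The best-H state ever visited is returned; ties resolve
to the first-visited state. These settings recover the enumerated global
optimum on the 8-bin oracle instances in 100% of seeded runs; they are
configuration, not tuned constants of the method. All randomness flows
from an explicit seed; identical (seed, schedule, C, λ) gives
bit-identical output.

`sweep_lambda` repeats the procedure over an ascending λ grid, optionally
warm-starting one restart of each λ from the previous solution (cold and
warm runs agree within 1% on the benchmarks, which guards against
warm-start lock-in), and collects per-λ diagnostics: mean domain size,
index of dispersion, K(s), and nMI against a reference matrix.

## 4. Secondary (compartment) inference

A/B compartments appear as a *secondary* structure coexisting with the
TAD-like primary family; simply raising λ does not produce them. Two
routes are provided:

* **Band mode** — remove a diagonal band (default 2 Mb, the meta-TAD
  scale) from C before annealing: excluded pairs contribute nothing to
  c_k, hiding the local evidence so the non-local checkerboard dominates.
  The band stays in index space (|i−j| ≤ band/bin_size) and the diagonal
  itself remains 1.
* **Residual mode** — explain away an already inferred primary solution:

      C_res_ij = (1 + g̃_{s_i}) C_ij − g̃_{s_i} δ_{s_i s_j},

  symmetrized by averaging (the printed form is asymmetric whenever the
  two strengths differ), diagonal reset to 1, clamped to [−1, 1]. For
  exactly hierarchical data this equals the single-group model of the
  secondary labels when g̃ = g/(1+h), the primary strength *reduced* by
  the secondary level — not the naive single-group fit ĝ, which absorbs
  the secondary correlation and overshoots. When g̃ is not supplied,
  `estimate_residual_strength` recovers it by moment inversion:
  with a = mean intra-primary correlation and b = the secondary plateau
  (read off the upper population of cross-primary correlations),
  g̃ = (a − b)/(1 − a + b); with no secondary structure b ≈ 0 and the
  estimate reduces to the plain fit a/(1 − a).

Non-local, non-contiguous domains are permitted and expected in both
modes.

## 5. Evaluation statistics

* **Similarity** ρ: Pearson correlation of binary co-membership matrices
  over distinct valid pairs; label-permutation invariant; undefined
  (None + warning) for a single-domain solution.
* **nMI**: the data matrix (log10 balanced counts or the
  observed/expected Pearson matrix C_O/E) is discretized into 100
  equal-width bins, the co-membership bit is the second variable, and
  I/√(H_A H_B) is reported — base-invariant, in [0, 1], equal to 1 for a
  deterministic relation.
* **Nestedness** h: per-domain best-overlap fraction h₁, chance level h̄₁
  from 100 seeded draws without replacement from the coarser solution,
  normalized (h₁−h̄₁)/(1−h̄₁), size-weighted. 1 = perfect nesting, 0 =
  chance.
* **Size statistics**: mean domain size (bins and Mb) and the index of
  dispersion D = σ²/⟨n⟩ computed on sizes in Mb by default (the unit is a
  switch; the variance-to-mean ratio is unit-dependent and the choice of
  Mb puts D ≈ 1 crossovers on the 50-kb genome scale).
* **Boundary correlation** χ(d): cross-correlation between a mean-centered
  signal (e.g. CTCF) and the boundary indicator ψ, normalized by ⟨ψ⟩.
  ψ marks the first bin of every maximal contiguous run of a label (one
  boundary per run for non-local domains; the leftmost valid bin always
  counts). The correlation length comes from unweighted least squares on
  log |χ| over d ∈ [0, d_max] (default 40 bins); the fit is only
  meaningful when boundaries are sparse enough that the centering offset
  is small relative to χ(0).
* **A/B assignment**: of the two largest domains, the one with the higher
  mean intra-domain contact at short range (d ≤ 10 bins, excluding d=0)
  is the locally compact B compartment; ties warn and resolve by label
  order. Compartment–track correlations use ±1 indicator vectors and the
  cosine form q·h/(|q||h|).

## 6. Synthetic data and what the benchmarks show

The generators realize exactly the assumptions of the inference model:
group-model signal sampling (one and two levels, unit variance by
construction), empirical correlation matrices, and forward Hi-C
simulation (correlation → stiffness with σ_c = 0.25 so C = 0 maps to
γ = 1 → closed-form contact probability → Binomial(n_reads, p) counts per
pair, Poisson optional). They emulate the statistical structure the
method assumes — block correlations, binomial sequencing noise — and
deliberately *not* the distance-decay exponents, loops, or mappability
artifacts of real genome-wide Hi-C; passing benchmarks demonstrates
correctness of the machinery, not performance on real chromatin.

Benchmark conditions (in `multicd.benchmarks`, shared by the tests and
`scripts/acceptance.py`):

* *Exhaustive oracle*: N = 8 two-block matrix (intra 0.8), all 4140
  partitions enumerated; 20 annealing seeds at λ ∈ {0, 0.5, 5}.
* *Parameter recovery*: N = 100, five equal contiguous domains, g = 2,
  empirical C from 400 samples, λ = 0, 10 seeds.
* *Secondary recovery*: N = 120, twelve 10-bin primary domains (g = 2),
  alternating 30-bin secondary blocks (h = 1), 400 samples; band mode
  masks 10 bins, residual mode explains away the λ = 0 primary solution;
  λ = 2 for the secondary inference (see the extensivity note above).
* *Multi-scale monotonicity*: N = 200, 5-bin sub-domains nested in
  25-bin super-domains, 1600 samples, λ grid 0–10. The super-level is
  given the larger strength so that coarse solutions are identifiable at
  all (Section 2): sub strengths g_k ~ U(0.6, 1.4), super strengths
  h ~ U(1.5, 2.5). The heterogeneity spreads the merge thresholds across
  the grid so the size staircase has many small steps (with equal
  strengths the few long plateaus leave the rank correlation degenerate
  even though the sequence is perfectly non-decreasing). The mean domain
  size must grow monotonically in λ (Spearman ≥ 0.95); the two-scale
  recovery check (equal strengths g = 1, h = 2) separately verifies that
  the grid ends reproduce sub- and super-domains.
* *Round trip*: 100-bin two-block correlation matrix, 1e5 reads per
  pair, pre-processing anchored at the generator's true nearest-neighbor
  contact probability; median absolute deviation of the recovered
  correlations < 0.05.

These sizes keep the whole suite and the acceptance script to a few
minutes on one core while leaving every statistical margin wide.

## 7. Degenerate inputs and numerical guards

* Disconnected contact graphs, all-zero maps, μ = 0 (no nearest-neighbor
  signal), constant data matrices in nMI, zero-variance O/E rows,
  single-domain solutions in similarity, zero-norm tracks: all are
  explicit errors, warnings, or None results — never silent numbers.
* c_k within 1e-12 of n_k² (possible only if the correlation clamp was
  bypassed) raises instead of returning −∞.
* The nestedness normalization is undefined when the coarse reference is
  a single domain (chance level 1); affected domains are reported with
  h1_hat = None.

## 8. Known limitations

* Single-site moves mix slowly between coarse partitions separated by
  wide barriers; merge/split moves are a natural extension hook. In
  borderline-λ regimes the chain can settle into a slightly fragmented
  local optimum whose H lies within O(0.1) of the global one.
* The residual-strength moment estimator assumes an approximately
  two-plateau correlation structure; heavily heterogeneous strengths per
  secondary domain would need a per-domain estimate.
* The O/E expected profile uses a proportional smoothing window
  (±⌈0.01 d⌉ bins); the exact smoothing used by external Hi-C pipelines
  differs, and the profile is exposed as an argument for that reason.
* D (index of dispersion) depends on the size unit; values are comparable
  only within a fixed unit convention (Mb here).
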