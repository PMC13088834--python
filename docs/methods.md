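# Methods

## The testing problem

Given an n × K table of relative OTU abundances, an optional rooted
phylogeny on the OTUs, variables of interest `X1` (n × p1) and confounders
`X2` (n × p2), the package tests whether community composition is
associated with `X1` after adjusting for `X2`.  The distance-based
(PERMANOVA-style) framing reduces the K-dimensional compositions — usually
K > n, sparse and compositional — to an n × n distance matrix `D` and asks
whether the design explains the between-sample dissimilarity.

## From distances to base statistics

Three complementary distances are built in:

- weighted UniFrac (metric id 1), generalized form with abundance exponent
  α ∈ [0, 1] (default 0.5, the variance-robust middle ground):
  `d_ij = Σ_l b_l (p_il + p_jl)^α |p_il − p_jl| / Σ_l b_l (p_il + p_jl)^α`,
  where `p_il` is the summed relative abundance of the leaves below branch
  `l` and `b_l` its length.  Branches with `p_il + p_jl = 0` drop out of
  both sums (the 0/0 limit of the formula).
- unweighted UniFrac (id 2), presence/absence only, normalized by the
  *total* tree length: `d_ij = Σ_l b_l |I(p_il>0) − I(p_jl>0)| / Σ_l b_l`.
  Note this differs from the classic implementation that normalizes by the
  pairwise union of observed branches; the total-length normalization is
  deliberate and is what the tests' brute-force oracle checks.  Presence
  means strictly positive abundance — no pseudo-count.
- Bray-Curtis (id 3): `d_ij = Σ_k |p_ik − p_jk| / Σ_k (p_ik + p_jk)`, which
  on compositions equals half the L1 distance.

Each distance is turned into a centered kernel by the Gower transform:
`s_ij = −d_ij²/2`, `K = H S H` with `H = I − 11'/n`.  Microbiome distances
are generally not Euclidean-embeddable, so `K` carries negative
eigenvalues (a regression test documents this on simulated data).  The PSD
repair replaces the spectrum by its absolute values, `K* = U |Λ| U'`, and
the base statistic for exponent r > 0 is

    T_{d,r} = tr((H_X − H_{X2}) (K*)^r),   (K*)^r = U |Λ|^r U',

with `H_X`, `H_{X2}` the hat matrices of the full and confounder-only
designs (rank-revealing pseudo-inverse; design columns mean-centered, so
both projectors and their difference `G` are double-centered).  The
exponent reweights the kernel's spectrum: r < 1 flattens it, up-weighting
minor principal coordinates; r > 1 concentrates on the dominant axes.  The
default grid R = {0.125, 0.25, 0.5, 1, 2} is geometric around r = 1 (the
classic pseudo-F weighting); exponents outside [0.125, 2] trigger a
warning because the tail approximation degrades there.

Eigenvalues below 1e-12 × max|λ| are floored to zero before powering —
the centering null vector is an exact zero whose rounding noise r < 1
would otherwise amplify (at r = 0.125, noise of 1e-17 would become ~1e-2).
All powers of one kernel come from a single symmetric eigendecomposition,
so eigenvector sign/order indeterminacy cannot leak into results.

## Exact permutation moments and the Pearson III tail

The null distribution is the permutation distribution of
`T(π) = tr(G P K_r P')` over all n! simultaneous row/column permutations
of the kernel against the fixed design contrast `G`.  Its first three raw
moments are computed in closed form (no sampling) by a partition-lattice
argument: expanding `E[T^m]` over the 2m index slots of the m factors,
the expectation depends only on the equality pattern of the slots, giving

    E[T^m] = Σ_ρ N_ρ(G) N_ρ(K_r) / (n)_{|ρ|}

over set partitions ρ, with `N_ρ(·)` the distinct-index entry-product sums
recovered from unrestricted einsum contractions by Möbius inversion
(for the partition lattice, μ is a product of signed factorials over
merged blocks).  Because both matrices are double-centered, every
contraction whose partition has a singleton block vanishes identically,
leaving 1 + 4 + 41 contractions for m = 1, 2, 3 — a few hundred
matrix operations of cost at most O(n³) per base test.  The normative
check is exhaustive: at n ≤ 7 the closed form must agree with direct
enumeration over all n! permutations to 1e-10 relative error (it does;
see `tests/test_acceptance.py`).  Inputs are tolerance-checked for
centering and then exactly re-projected, so the structural zeros of the
closed form hold to machine precision.

From `E1 = E[T]`, `Var`, `E3 = E[T³]` the permutation skewness is
`γ = (E3 − 3·E1·Var − E1³) / Var^{3/2}`.  The standardized statistic
`t = (T − E1)/√Var` is referred to a Pearson type III distribution with
matching skewness — a shifted gamma with shape `b = 4/γ²`: for γ > 0 the
upper tail is the survival function of Gamma(shape b, scale 1/√b) at
`t + √b`; for γ < 0 the mirrored lower tail.  Pearson III is used instead
of a plain gamma because small exponents (r < 0.5) routinely produce
*negative* skewness.  |γ| < 1e-8 falls back to the standard normal (the
b → ∞ limit).  P-values are clipped to [1e-15, 1 − 1e-15] so the Cauchy
transform stays finite.

The fit's accuracy is direction-dependent.  In the upper tail — small
p-values, the side that decides significance — analytic and permutation
p-values agree to a few 1e-3 at n = 50.  In the body and lower tail the
three-moment fit degrades when the powered spectrum is concentrated: at
r = 2 a single eigenvalue can carry over half of Σ|λ|^2r, the null
skewness reaches γ ≈ 2–3, and the fitted distribution's support cuts off
at −√b̂ = −2/γ standard deviations while the true permutation null keeps
several percent of its mass below that point.  Deviations up to ~0.04
then occur for p-values above ~0.4 (see the permutation-agreement test in
`tests/test_acceptance.py`, which documents this).  None of this affects
rejection decisions at conventional levels.

Degenerate cases: a base test whose null variance is ≤ 1e-14 of its
natural scale (a permutation-invariant statistic) is dropped from the
combination with a logged warning; a design where `X1` lies inside
span(`X2`) (contrast rank v = 0) raises an error.

## Cauchy combination

The D × R base p-values are combined with equal weights through the
Cauchy tail transform, `T = mean_d,r tan((0.5 − p_{d,r})π)`, evaluated via
the stable identity `tan((0.5 − p)π) = 1/tan(pπ)`.  Under the null `T` is
standard Cauchy *regardless of dependence* between base tests, so
`P = 0.5 − arctan(T)/π` (computed with the large-|T| arctan branch to
avoid cancellation; with one base test the combination returns that
p-value to 1e-12).  The heavy tail means any strongly significant base
test dominates the average — the source of the ensemble's robustness
across distances and exponents.  The combination is exact in the tails
but mildly liberal in the body when p-values are strongly dependent; the
ensemble's empirical size at α = 0.05 stays inside [0.033, 0.069] in the
acceptance run, while a Kolmogorov–Smirnov test of global uniformity of
the *ensemble* p-values would reject (the base p-values themselves are
uniform).  The whole analysis path contains no random number generation:
repeated runs produce bit-identical result files.

## Synthetic studies

The generator emulates a sparse 16S/WGS case study rather than any
particular cohort:

- **Phylogeny**: birth-death tree (birth 1, death 0) on K leaves via
  dendropy, shared across replicates of a study (as when all replicates
  derive from one template dataset) unless `share_tree=False`.
- **Abundances**: lognormal base composition (σ = 1.5 — a realistic
  steep rank-abundance curve), per-sample Dirichlet draws with
  concentration θ = 20 × base (strong overdispersion typical of
  microbiome data), multinomial counts at lognormal library sizes
  (median 10⁴ reads, σ = 0.5), then random dropout calibrated so the
  expected zero fraction is 0.80 (each sample's most abundant OTU is
  protected, so rows stay valid compositions).  Under these conditions
  the un-inflated counts are already ~76% zero; the dropout stage tops
  this up to the target.  Defaults: n = 100 samples, K = 330 OTUs.
- **Associated set A**: scenarios S1/S3 cluster the patristic distance
  matrix into 20 average-linkage groups and draw one cluster with
  probability proportional to its mean aggregate abundance (clusters with
  constant aggregate are ineligible — `scale()` would be undefined);
  S2/S4 take the top 10% of OTUs by mean relative abundance.
- **Outcomes**: with `g = scale(Σ_{k∈A} Z_ik)` (zero mean, unit variance),
  continuous `y = 0.5·X1 + 0.5·X2 + β·f(g) + ε`, ε ~ N(0,1), or binary
  via `logit(p) = 0.5·X1 + 0.5·X2 + β·f(g)`.  The link f is the identity
  (S1, S2), the real signed cube root (S3; cbrt(−8) = −2), or the sine
  (S4).  X1 ~ Bernoulli(0.5); X2 is standard normal, independent of the
  table or — in correlated mode — `ρ·g + √(1−ρ²)·noise` with ρ = 0.5.
  β = 0 is the null.

What passing tests on this generator do *not* show: power levels against
a generator fitted to a real cohort (taxon-taxon correlation structure,
realistic phylogenetic signal in abundances, batch effects) can differ
substantially; the desk-scale power checks only establish monotonicity in
β and non-trivial power by β = 2 per scenario.  Null calibration, by
contrast, is generator-agnostic: under β = 0 the table is independent of
the design, so the permutation null is exact regardless of the abundance
model.

Replicate studies derive per-replicate generators from
`numpy.random.SeedSequence(seed).spawn(...)`, so results are reproducible
end-to-end from one integer and replicates are statistically independent.
A pathological replicate (degenerate design or null) is recorded as a
non-rejection with a warning rather than aborting the study.

## Problem sizes used in the shipped checks

The acceptance suite runs 1000 null replicates at the default study
conditions for the size check, 20 datasets at n = 50 with B = 20 000
permutations for the analytic-vs-permutation agreement, 50 enumeration
checks at n = 4..7 for moment exactness, and 300 replicates per effect
size (β ∈ {0, 1, 2}) per scenario for the power curves.

## Known limitations

- The permutation scheme permutes the microbiome block (kernel rows and
  columns) against the fixed design.  Under a sharp null where the
  community is independent of everything this is exact, including with
  confounders; residualization-based schemes (e.g. Freedman–Lane) for
  non-sharp nulls are out of scope.
- The Pearson III fit matches three moments; extreme-tail p-values
  (far below ~1e-8) are extrapolations of the fitted tail, not verified
  against permutation references (which cannot reach them by construction).
- Trees are used exactly as parsed.  An unrooted Newick string is
  indistinguishable from a rooted multifurcation, so no automatic
  re-rooting is attempted; supplying a deliberately rooted tree is the
  caller's responsibility.  Missing branch lengths are treated as zero
  with a warning.
- Input abundances are always renormalized to row compositions; analyses
  of raw counts (library-size effects) are out of scope.
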