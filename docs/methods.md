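# Methods

## Inheritance model

Meiosis is modelled per gamete as a binary vector `J` over the `N`
mapped loci: `J_i = 0` if locus `i` is copied from the first parental
gamete column, 1 otherwise. `J` follows the inheritance distribution
`I(r, alpha0)`: `Pr(J_1 = 0) = alpha0` and
`Pr(J_i != J_{i-1}) = r_{i-1}`, with `r in [0, 0.5]^{N-1}` the
adjacent-locus recombination frequencies. The chain is first-order
Markov by construction, so crossover interference is outside the model,
as are sex-specific maps. A chromosome boundary is encoded as
`r = 0.5` (independent assortment), which keeps the genome a single
ordered vector.

The recursion `phi_1 = 0`, `phi_i = r_{i-1} + (1 - 2 r_{i-1}) phi_{i-1}`
gives the probability that `J_i` differs from `J_1`, hence the marginal
`Pr(J_i = 0) = alpha0 + (1 - 2 alpha0) phi_i(r)`; with `alpha0 = 0.5`
every marginal is exactly 0.5 (Mendelian segregation).

## ECV and PCV

For a candidate pair with trait-oriented genotype matrices `L^1, L^2`,
the grandchild gamete is `g3 = gam([gam(L^1,J^1), gam(L^2,J^2)], J^3)`
with independent chains. The expected cross value is `E[sum_i g3_i]`:

* Mendelian closed form: `0.25 * sum` of the four parental gamete
  entries per locus — map-independent, exact in quarter-integers. All
  selection operates on this form, which is why allele-frequency
  outcomes of ECV selection do not depend on effect sizes or on the
  recombination map.
* General closed form: with `beta_i = Pr(J_i = 1)` the per-locus
  expectation is quadratic in `beta_i`; implemented as stated and
  verified against exhaustive `2^{3N}` enumeration. Note the general
  form is *not* symmetric in the parents when `alpha0 != 0.5`: the
  child's `J^3` chain then favours one parent's gamete column. The
  symmetric behaviour holds exactly at `alpha0 = 0.5`.

The predicted cross value — the probability that `g3` is desirable
everywhere — is computed exactly by a forward dynamic program over the
8 joint states `(J^1_i, J^2_i, J^3_i)`, linear in `N`. It is bounded
above by the smallest per-locus desirability probability (a Fréchet
bound) and is identically zero once any locus lacks a desirable copy in
both parents, which is why the package optimizes the expectation
instead for polygenic targets.

## Genomic relationship and GEBVs

`G` follows VanRaden's first method on neutral-marker dosages:
`Z = X - 2p`, `G = ZZ' / (2 sum p(1-p))`, markers observed monomorphic
excluded, frequencies clipped to `[0.01, 0.99]`. By default `p` is
taken from the supplied genotypes; the simulator instead fixes `p` at
the founder generation's frequencies so that relatedness accumulated by
selection remains visible on a constant scale (with per-generation
centring, the mean relationship of any generation is forced toward
zero and cross-family pairs read negative). Rows of `G` are computed
lazily — the selectors only ever touch pairs that surface during the
search, so the full `K x K` matrix is never materialized for the
10,000-founder panel.

GEBVs come from effects-space ridge-regression BLUP: effects solve
`(X'X + lambda I) u = X'(y - ybar)` with `lambda = sigma_e^2 /
sigma_u^2` estimated by REML, profiled in the SVD basis of the centred
dosage matrix (one-dimensional deterministic optimization; cost
`O(n m^2)` for `m` markers). Constant phenotypes yield zero effects; a
degenerate REML surface falls back to `lambda = m (1 - h^2) / h^2` at
the configured heritability. The model is refit each generation on
that generation's markers and phenotypes — the simplest defensible
training design, since no cross-generation scheme is specified for the
benchmark.

## Selection optimizers

The single-pair problem — maximize ECV subject to `G <= epsilon`,
excluded ("conflict") pairs removed — is solved by three exact routes
that are tested to agree pair-for-pair:

* **ILP**: one binary per admissible pair linked to per-individual
  binaries, solved by HiGHS through `scipy.optimize.milp`. Inadmissible
  pairs are removed from the model rather than constrained to zero.
  The objective is integer-scaled (`4*ECV*(K^2+K+1)` minus the pair's
  lexicographic rank), making the optimum unique and equal to the
  lexicographically smallest maximizing pair — so results are
  solver-independent.
* **Exhaustive**: a vectorized scan of all admissible pairs under the
  `(-ECV, k, k')` order; the semantic oracle, guarded to `K <= 2000`.
* **Fast**: the Mendelian ECV of a pair is `0.25 (c_k + c_k')` with
  `c_k` the individual's desirable-allele count, so the best pair is a
  max-sum search: candidates are visited best-first from a count-sorted
  frontier (a heap), the first feasible visit fixes the optimum, and
  the equal-sum plateau is then scanned in lexicographic order. This
  route handles the 10,000-candidate generation-0 panel, where a
  pair-indexed model (~5x10^7 variables) is out of reach.

Crossing blocks repeat the solve `n_c` times, adding a conflict
constraint for exactly the returned pair after each solve (the same
individual may appear in several pairs); objectives are therefore
non-increasing down the block. Lexicographic multi-trait selection runs
stage `l` with constraints `ECV^i >= (1 - tau_i) * opt_i` for all
earlier stages `i`; in the fast route the stage-1 constraint is
materialized as an explicit pair list via a sorted two-pointer sweep
(cached across block slots) and later stages filter it. Thresholds are
compared with a `1e-9` absolute slack so that exact quarter-integer
ties are never cut by floating-point rounding; all probability
comparisons in tests use `1e-12`.

Baseline pairing (phenotypic and GEBV selection) ranks unordered pairs
by the sum of the two mates' scores with no relatedness cap and no
self-crossing; only the top `n_c + 1` individuals under the strict
`(-score, index)` order can appear in the top `n_c` pairs, so the
enumeration is restricted to them. For multiple traits, scores are
standardized to unit variance within the generation before summing —
otherwise the 70-locus trait dominates the sum.

## Simulated study conditions

The generator emulates a breeding benchmark: 10,000 founders, every
allele an independent fair coin (frequency 0.5 at all 300 loci), 200
QTL + 100 neutral markers. Trait 1 uses the first 40 QTL in map order,
Trait 2 the next 10, and Trait 3 combines 20 loci drawn from Trait 1's
set with flipped desirable orientation (antagonistic pleiotropy,
inducing the negative genetic correlation) plus 50 private loci from
the remainder. Generations advance by simulating both meioses for each
of `progeny_per_cross = 100` offspring per selected pair; scenario
crossing-block sizes are A = (50, 10, 3, 3), B = (50, 10, 5, 5),
C = (50, 25, 5, 5), giving population trajectories such as
5000/1000/500/500 for B.

Conditions the benchmark leaves unstated are fixed once as package
defaults:

* genome: 10 chromosomes x 30 positions interleaved (qtl, qtl, marker),
  `r = 0.1` between adjacent positions — markers sit in linkage with
  QTL so GEBVs and `G` behave non-trivially;
* effects: `|effect| = 1` per desirable copy for every trait locus
  (printed architectures name loci, not magnitudes; equal effects make
  the allele-frequency metrics effect-free);
* heritability 0.5 per trait, with environmental noise calibrated so
  genetic/total variance equals `h^2` in the founder generation and held
  fixed thereafter (consistent environment);
* relatedness cap `epsilon = 0.20` on the VanRaden scale — between
  unrelated (~0) and full sibs (~0.5), consistent with the reported
  mean relatedness of ECV-selected mates (~0.15) under high selection
  intensity;
* lexicographic priority (Trait 1, Trait 3, Trait 2) with the
  per-generation tolerance schedule `tau_1 = (0.17, 0.05, 0.05, 0.05)`
  for the first objective and `tau_2 = (0, 0, 0, 0.05)` for the second
  (the last objective always carries `tau = 0`). The zero tolerance on
  the second objective protects Trait 3 against the antagonistic pull
  of Trait 1 — the configuration that reproduces the benchmark's
  qualitative outcome (Trait 2 improving least, Trait 3 recovering
  despite the shared loci);
* per-replication seeds derive from the master seed by a counter-based
  spawn, so replications are independent and individually re-runnable;
  identical config + seed gives bit-identical results.

## What the synthetic data does and does not show

The generator reproduces the benchmark's genetic *architecture* but not
its unprinted physical scales: real effect-size spectra, heterogeneous
recombination, dominance/epistasis, genotyping error and
environment-by-genotype structure are all absent. Passing tests
therefore demonstrate correctness of the criterion and optimizers and
qualitative faithfulness of the population dynamics, not quantitative
transfer to any real program. Measured at 10 replications, the
final-generation desirable-allele frequencies under multi-trait ECV are
roughly 0.81 / 0.59 / 0.63 for Traits 1/2/3 against reported values of
0.70 / 0.65 / 0.72 — right ordering and direction, with Trait 1
over-improving and Trait 3 under-improving relative to the original,
which we attribute to the unprinted effect sizes, map, heritabilities
and `epsilon`. The mean relatedness of ECV-selected mates in the last
high-intensity generation (~0.14) matches the reported 0.15; GEBV
pairing drives relatedness far past the reported 0.42 here (to ~1.1 on
the founder scale, i.e. beyond repeated full-sib mating), the expected
behaviour of unconstrained GEBV selection when its per-generation
accuracy is high.

## Numerical and degenerate-input choices

Ties everywhere resolve to the smallest `(k, k')` index pair. ECV
values are exact multiples of 0.25 and exposed as rationals where
exactness matters (CLI output). `epsilon = None` disables the
relatedness constraint; an infeasible block raises a partial-plan error
carrying the pairs found so far. Self-crossing is rejected unless
explicitly enabled. All randomness flows through caller-supplied
numpy generators; no global state is used anywhere.
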