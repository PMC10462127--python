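# Methods

## Model

For one experimental group with N biological replicates and T features
(transcripts for bulk data, genes for single-cell data), feature totals
follow a multinomial with per-sample relative abundances ρ_i, and the split
of each feature's reads across splice versions follows a hierarchical
beta-binomial (bulk: spliced/unspliced) or Dirichlet-multinomial
(single-cell: spliced/unspliced/ambiguous) with per-feature hyper-
parameters δ.  δ is reparametrised as the precision δ₊ = Σ_v δ_v,
governing sample-to-sample variability of the splice proportions, and the
group-level proportions π̄ = δ / δ₊.  ρ deliberately has no hierarchy:
overall abundances are easy to estimate and a hierarchy there would mostly
add cost.

The data are equivalence-class counts, so the per-(feature, version) counts
X are latent.  Multi-mapping reads are allocated by a multinomial draw over
the EC's members with probability ∝ ρ_i(feature) · w_i(feature, version),
where the weight w is the per-sample splice proportion π; in the bulk model
it is divided by the version's effective length, so allocation does not
favour long transcripts (rescaling all effective lengths by a common factor
provably leaves allocation probabilities unchanged, and unit lengths
recover the single-cell rule).  Ambiguous single-cell reads (compatible
with both versions of one gene) are their own category end to end: the
probability that such a read is spliced is not identifiable at allocation
time, so they are never re-split between s and u; they only enter the
comparison parameter as π̃U = π̄U + 0.5·π̄A.  In bulk, π̃U = π̄U.

## Sampler

One sweep updates, in order: δ | π, π | X, δ, ρ | X, and X | Z, π.

* **δ | π** is the only non-conjugate block.  Each feature runs an
  independent Metropolis step on the unconstrained scale
  (log δ₊, alr(π̄)), with the change-of-variables Jacobian
  δ₊^K · Π_k π̄_k included in the target.  Proposals are Gaussian with
  Haario-style adaptive covariance, (2.38²/d) · (running empirical
  covariance) + 10⁻⁶·I, estimated by Welford updates during burn-in only
  and frozen afterwards; before 2d history points an isotropic 0.1²/d
  scale is used.  Non-finite proposal targets auto-reject.  Typical
  acceptance rates land in 0.2–0.35.
* **π | X, δ** and **ρ | X** are exact conjugate Beta/Dirichlet draws
  (Dirichlet via independent gamma variates).  π draws are clamped to
  [10⁻¹², 1−10⁻¹²] and renormalised, so allocation weights stay positive
  and the δ-likelihood stays finite on degenerate counts.
* **X | Z, π** is the expensive block and is under-sampled: it runs every
  `latent_update_every` = 10 iterations while all other blocks run every
  iteration against the last sampled X.  Single-member ECs are resolved
  once, deterministically; multi-member ECs are partitioned by a chain of
  conditional binomials, vectorised over ECs of equal member count.  Total
  reads per sample are conserved exactly at every update.

Defaults: 2000 iterations, 500 burn-in, every post-burn-in iteration
stored.  All randomness flows from one integer seed; a master seed fans
out to stage- and group-specific sub-seeds via a stable CRC-based hash, so
groups and clusters can be re-run in isolation and results do not depend
on the order clusters are processed in.

### Priors

The prior on δ is empirical Bayes: up to 1000 randomly selected features
get a per-feature Dirichlet-multinomial precision estimate computed on
naive equal-split counts (multi-mapping ECs divided evenly among members —
initialisation only), and log δ₊ receives a Normal prior with that
sample's location and scale; π̄ is uniform on the simplex, and ρ has a
symmetric Dirichlet(1) prior.  Each feature contributes a tiny fraction to
the prior, which keeps it mild (doubling one feature's counts moves the
location by ≪ 1/n_features).

Two numerical choices here departed from the obvious route, both forced by
parameter-recovery simulations:

* Per-feature precisions use a Kleinman-type weighted **moment** estimator
  (intra-class correlation from the count-weighted dispersion of sample
  proportions with an (N−1) degrees-of-freedom correction, category
  estimates combined weighted by p(1−p), bounded to [10⁻², 10⁶]) rather
  than fixed-mean maximum likelihood: with N = 6 samples, ML precision is
  biased upward by ≈ +0.4 on the log scale, while the moment estimator
  recovers a common true δ₊ = 20 to within ±0.25.
* The prior location/scale are the **median** and 1.4826·MAD of the log
  precisions (scale floored at 0.5 so the prior never collapses), because
  features whose few samples happen to show no overdispersion pile up at
  the upper precision bound and would otherwise drag the mean.

With fewer than 10 usable features the prior falls back to a weakly
informative default (location log 10, scale 2) with a warning.

Initialisation: X by equal split of EC counts, π at its posterior mean
under δ = 1, ρ proportional to initial totals, δ₊ at the prior mean with
π̄ at the pooled naive proportions.

### Convergence

A Heidelberger–Welch stationarity test runs on the post-burn-in trace of
the summed marginal log-posterior log p(δ | π): the Cramér–von Mises
statistic of the Brownian-bridge functional of the cumulative sums, with
the long-run variance S(0) estimated by an AIC-selected Yule-Walker AR fit
on the last half of the trace, retried while discarding 10%-prefixes up to
50% (this is the automatic burn-in escalation); if the test still fails,
one fresh chain with doubled length and burn-in is run, and a second
failure returns the chains flagged non-converged rather than silently
passing.  Zero-variance traces pass by definition.

Two implementation details differ from the common R implementation
(`coda::heidel.diag`) deliberately.  First, S(0) is estimated after
linear detrending: fitting the AR model to a strongly drifting trace
absorbs the drift as a near-unit root, inflating S(0) until the test
cannot reject exactly the non-stationarity it exists to detect (coda
passes a trace with slope 0.01/iteration and unit noise 95% of the time).
Detrending leaves stationary traces essentially untouched (simulated pass
rates: 100/100 iid, 100/100 for AR(1) with ρ = 0.9) while drifting traces
are rejected 100/100.  Second, the four-term Bessel series for the
Cramér–von Mises CDF loses accuracy deep in the upper tail, so the
(monotone) CDF is floored at its value at 1; this only affects p-values
already below 3·10⁻³.

## Group comparison

Groups are fitted independently (the empirical-Bayes prior is estimated
once on the pooled samples).  Per feature:

* p = Pr(π̃U_B > π̃U_A), the fraction of matched post-burn-in iteration
  pairs with π̃U_B above π̃U_A (chains truncated to the shorter length);
  ties count ½, making p(A,B) = 1 − p(B,A) exact and identical chains give
  exactly 0.5.  The two chains are independent posteriors, so any pairing
  is valid; matched pairing is deterministic and cheap, and an all-pairs
  estimator is available as an option.  Ranking: max(p, 1−p) descending,
  lexicographic tie-break.
* A Wald test on the free π̄ coordinates: T = Δm'(S_A+S_B)⁻¹Δm with
  posterior means and sample covariances (a posterior mode + Hessian would
  be ill-defined on an MCMC cloud), referred to a chi-square with as many
  degrees of freedom as free coordinates — (π̄S, π̄U) and 2 df for
  single-cell data (π̄A is determined by the other two), π̄U alone and
  1 df for bulk data (π̄S is determined by π̄U; the rank-deficient
  bivariate version referred to 2 df is measurably conservative under the
  null).  Singular pooled covariances get a 10⁻⁸·trace ridge with a
  warning.  Benjamini–Hochberg adjusted Wald p-values are attached as a
  convenience; the method ranks rather than thresholds.

Before fitting, features need at least 10 reads per group, where a
feature's abundance is the summed count of every EC containing any version
of it — available before estimation and deterministic; the filter is
idempotent.

## Synthetic benchmark generator

The generator produces count-level data with known truth, replacing
read-level simulation with a direct EC emulator:

* Baseline relative abundances log-normal(0, 1); per-feature negative-
  binomial totals with dispersion log-normal(−2, 0.5²) — a stand-in
  distribution for sample-to-sample variability estimated from external
  bulk datasets, which are out of scope; sequencing depth defaults to 200
  reads per feature.  Baseline unspliced fractions Beta(2, 6) (typical
  unspliced share ≈ 0.25); sample-level splice proportions drawn from the
  hierarchical model with precision δ₊ = 30.
* **DR**: s/u proportions inverted (πU ↦ 1−πU) in a randomly chosen group
  — 2000 transcripts in the default bulk configuration (10000 features,
  3+3 samples), 20% of genes per cell cluster (distinct genes per cluster)
  in single-cell mode.  `dr_pi_u` pins the baseline πU of DR features for
  fixed-effect-size experiments.
* **DGE** (nuisance): fold change 1 + Exponential(mean_fc − 1), giving the
  configured average (3, 6 or 9), applied to the affected group's mean for
  a feature fraction (default 10%) drawn independently of the DR labels —
  the selection rule is otherwise unidentified, and a disjoint draw would
  be infeasible when all features are DR.
* **DAS** (nuisance, bulk): transcripts are grouped into genes of size
  1–3; affected genes get a cyclic permutation of their transcripts'
  relative abundances in one group, preserving gene totals and every
  transcript's πU.
* **Batch**: two batches balanced across groups (alternating within
  group); batch 2 applies a multiplicative abundance shift and an additive
  logit shift of πU to a random feature subset orthogonal to DR labels.
* **EC emulation**: per (feature, version), a Binomial(count, p_multi)
  share of reads joins a multi-member EC with 1–3 random partners
  (same-feature s/u pairs allowed; defaults p_multi = 0.3, ≤ 4 members —
  enough to exercise allocation non-trivially), the rest stays unique;
  totals conserved exactly.  p_multi = 0 reduces the whole pipeline to the
  conjugate no-multi-mapping model, which is the oracle used in tests.
* **Single-cell**: 3 clusters, 2+2 samples, 100 cells per sample and
  cluster, a small ambiguous fraction Beta(2, 18); pseudo-bulk counts are
  spread over a per-gene subset of cells matching the requested zero
  fraction (default 90%) while keeping totals fixed — so, as asserted in
  tests, the zero pattern cannot affect the pseudo-bulk analysis.

What the generator does not emulate: positional/coverage biases,
length-dependent read sampling inside the EC emulator, correlated EC
structure from shared sequence (partners are random), empirically
calibrated dispersions, or cell-level expression heterogeneity beyond the
zero pattern.  Passing tests therefore demonstrate correctness of the
inference machinery and calibration under the model's own assumptions, not
performance on real libraries.

## Problem sizes and defaults in the shipped checks

The test suite and the acceptance script run at desk scale, chosen to keep
Monte-Carlo error well below the tolerances they assert: null calibration
at 300 features and 3+3 samples with default MCMC settings; conjugate-
oracle and allocation checks at a handful of features with 1500+ stored
draws; credible-interval coverage at 100 features; the power check at 200
features with 10% DR and πU 0.2 ↔ 0.8.  Known limitations: covariates
(including batch) are not modelled — the batch scenario exists to measure
robustness, not to adjust for it; single chains only (the stationarity
test is the convergence diagnostic); no transcript-level single-cell
inference.
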