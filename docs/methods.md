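# Methods

## Problem setting

In sample-barcoded droplet single-cell experiments (cell hashing,
MULTI-seq), cells from each sample are tagged with a sample-specific
hashtag oligonucleotide (HTO) before pooling. Sequencing yields, per
droplet (GEM), a vector of HTO UMI counts over the `M` samples. Droplets
containing cells from two or more samples — multi-sample multiplets
(MSMs) — are detectable from this vector and can be removed. Multiplets
whose cells all share one tag — same-sample multiplets (SSMs) — are
invisible in hashtag space; only their *rate* can be estimated, through a
generative model of droplet formation.

## MSM classifier

Counts are transformed column-wise with the centered log-ratio:
`x_i^l = log((c_i^l + 1) / geomean_j(c_j^l + 1))`. The +1 pseudocount is
required because raw UMI counts contain zeros; any positive constant only
shifts the column, and the default of 1 is the common choice for UMI
data. Each CLR column is bimodal: a low mode from background antibody
binding on droplets without that sample's cells, and a high mode from
genuinely tagged droplets. We fit a two-component univariate Gaussian
mixture per column by EM.

EM details (the literature around this method names EM but not its
configuration, so these are this package's choices):

- **Initialization**: split the column at its median, moment-match each
  half, priors 0.5/0.5. Deterministic, so classification is reproducible
  without seed bookkeeping.
- **Convergence**: relative log-likelihood change below 1e-6, at most
  1000 iterations.
- **Variance floor** 1e-6 on each component, so near-point-mass halves
  (e.g. an all-zero background) cannot collapse the likelihood.

Per GEM and sample, Bayes' rule gives `p_l = P(high | x_i^l)`, computed
in log space so values far outside both components stay defined. The
probability that a GEM contains exactly the sample subset `U` factorizes
as `P(U) = prod_{l in U} p_l * prod_{l not in U} (1 - p_l)`; these sum to
1 over all `2^M` subsets. Because the product factorizes per sample, the
argmax subset is simply `{l : p_l > 0.5}` and its probability is
`prod_l max(p_l, 1 - p_l)` — no subset enumeration is needed (an
enumeration routine is kept for inspection and testing). At a tie
(`p_l = 0.5` exactly) the sample is excluded, preferring the smaller
subset. GEMs whose best-subset probability falls below the confidence
cutoff `c` (default 0.8) are labelled *unclear*; the empty subset is the
*negative* class, giving at most `2^M + 1` labels. The cutoff is applied
to the raw maximum subset probability, without renormalizing away the
negative class.

## Droplet-formation model

`Y` cells (`y_l` per sample) are partitioned independently and uniformly
into `X` cell-assay droplets; each droplet is captured and sequenced with
probability `r_cap`. For one droplet,

```
P(non-empty) = 1 - (1 - 1/X)^Y
P(singlet)   = (Y/X) (1 - 1/X)^(Y-1)
P(SSD_l)     = (1 - (1 - 1/X)^{y_l}) (1 - 1/X)^{Y - y_l}
```

Conditional on non-empty, `P(MSM) = 1 - sum_l P(SSD_l)/P(non-empty)`,
and the SSM rate follows either as the complement
`1 - P(singlet) - P(MSM)` or per sample as
`P(SSM_l) = P(SSD_l) (1 - E[#singlets_l]/E[#SSD_l])`; the two routes are
algebraically identical and the test suite checks agreement to 1e-12.
The relative SSM rate (RSSM) — the irreducible multiplet fraction among
single-sample droplets after MSM removal — is
`P(SSM) / (P(singlet) + P(SSM))`.

`X` and `y_l` are treated as real-valued in all closed forms (maximum
likelihood estimates are continuous); the Monte-Carlo simulator, which
serves as an independent oracle, rounds them to integers. The special
case `X = 1` is handled explicitly (`0^0 = 1`), so degenerate
configurations remain exact. Analytic rates are verified against
exhaustive enumeration of all `X^Y` assignments for every configuration
with `X <= 4`, `Y <= 4` — exact to machine precision — and against
100,000-repetition simulations at larger sizes. When comparing simulated
to analytic rates we use the aggregate ratio (total tallies over all
repetitions), since the mean of per-repetition fractions is a ratio
estimator with O(1/droplets) bias that is detectable at these repetition
counts.

## Parameter estimation

The classifier observes `z_l`, the number of GEMs whose class contains
sample `l`. Modelling the count of `l`-cell-enclosing droplets as
Binomial(`X`, `1 - (1-1/X)^{y_l}`) thinned by `r_cap`, each `z_l / r_cap`
is scored with the continuous (Gamma-function) extension of the binomial
pmf; the binomial coefficient is evaluated as
`-log(X+1) - betaln(X-k+1, k+1)` because differencing `gammaln` values
loses all precision at large `X` (naively this manufactures spurious
likelihood maxima at absurd `X`). The user supplies the total loaded
cell count `Y` (hemocytometer), constraining `sum_l y_l = Y`.

The per-sample likelihood alone cannot identify all of `(X, r_cap, y)`:
there are `M` observations and `M + 1` free parameters, and for any `X`
over a wide range a choice of `(r_cap, y)` fits every `z_l` exactly, so
the profile likelihood is a near-flat ridge. The estimator therefore
anchors the fit with one more quantity the classifier already measures:
the total number of cell-enclosing GEMs, whose model expectation is
`r_cap * X * (1 - (1-1/X)^Y)` and which is scored with the same
continuous-binomial form. With the anchor the joint problem is exactly
identified; at realistic scales (X ≈ 70K, Y ≈ 30K, 4 samples) the
recovered rates sit within a fraction of a percent of truth and are
stable across optimizer seeds. Users who have profiled their equipment
can instead pin `X` (`fix_X`), in which case the anchor is unnecessary
and the plain per-sample likelihood is used; a profile-likelihood helper
exposes the ridge for inspection.

Optimization: `sum y_l = Y` via softmax weights, `X` via log, `r_cap`
via logit; Nelder-Mead from 12 seeded starts spanning `r_cap` in
[0.05, 1] and `X` between the largest observed count and `10 Y`, with a
final polish of the best optimum. The likelihood surface is smooth and
low-dimensional, so a derivative-free simplex search is reliable and
fast (a few seconds).

## Experiment planner

For a planned run the planner assumes an even split `y_l = Y / M`
(real-valued, no rounding) and evaluates the closed forms above,
reporting singlet/MSM/SSM/RSSM rates plus expected captured-GEM and SSD
yields (`X (1-(1-1/X)^Y) r_cap`, and that times `1 - P(MSM)`).
Parameters outside the typical interactive ranges (X 60–100K, Y 1–80K,
M 1–20) produce a warning rather than an error, since equipment varies.
A sweep utility evaluates grids over any parameter; the singlet rate is
invariant in `M`, while increasing `M` converts SSMs into removable
MSMs, driving the RSSM rate down.

## Cluster authentication

A putative cell-type cluster `G` is scored by its MSM fraction among
classified, non-negative, non-unclear member GEMs.

*Phony hypothesis*: every GEM in a cluster formed by cross-cell-type
multiplets holds at least two cells; with sample proportions `q`, a
`k`-cell multiplet carries one tag with probability `sum_l q_l^k`, so a
doublet-only phony cluster has expected MSM fraction `1 - sum_l q_l^2`
(`1 - 1/M` for even proportions, 75% at `M = 4`; slightly below that for
uneven loading). This doublet floor is the default expectation — it is
conservative, since triplets and higher orders only raise the fraction —
with an optional refinement averaging `k` over its truncated
Binomial(`Y`, `1/X`) distribution.

*Pure hypothesis*: a genuine type of population `y_t` only contributes
multiplets to its own cluster through self-collisions. `y_t` is inferred
by inverting `n_G = r_cap X (1 - (1-1/X)^{y_t})` from the cluster's GEM
count, and the expectation is the model MSM rate for a population `y_t`
split as `q`. It vanishes for rare types and grows with cluster size.
This reconstruction reproduces the qualitative structure reported for
real data (a single shared phony expectation per dataset; pure
expectations growing with cluster size; higher-order multiplet clusters
exceeding the doublet floor), but the absolute pure-type percentages it
produces are smaller than some published per-cluster values, whose exact
derivation is not recoverable from public material; verdicts depend on
the contrast between the two hypotheses, which is orders of magnitude
wide in practice.

Both hypotheses are tested with exact one-sided binomial tests
(upper-tail at the pure expectation, lower-tail at the phony
expectation), default `alpha = 0.05`, no cross-cluster multiplicity
correction (clusters are few and the decision is per cluster; a
correction flag can be layered on by the caller). Verdicts: *pure*
(phony rejected only), *phony* (pure rejected only), *mixture* (both
rejected), *indeterminate* (neither — typically tiny clusters; reported
explicitly rather than forced into a class).

## Synthetic data generator

The generator emulates the standard benchmark construction for hashtag
demultiplexing: real single-sample droplets re-assembled into droplets
with known composition.

- **SSD profiles**: per sample, the on-target column is drawn from a
  log-normal moment-matched to that sample's (mean, sd) and off-target
  columns from the sample's background statistics, rounded to integers.
  Log-normal is chosen because UMI counts are positive and
  right-skewed and their CLR transforms then show the two
  approximately-Gaussian modes the classifier assumes. Default
  statistics follow a published 4-sample PBMC benchmark (on-target
  means 717–2789 with sds of similar order; backgrounds 16–77),
  including its realistic per-sample imbalance.
- **Assembly**: exactly `ceil(f_msm * n)` droplets are cross-sample
  doublets (pairs of distinct samples drawn from the configured
  proportions), an optional `f_ssm * n` are same-sample doublets, and
  the rest hold one SSD. Multi-SSD droplet counts are
  `round(sum_i w_i x_i)` with independent weights `w_i ~ N(1, 0.04)`,
  emulating depth variation between the merged droplets.
- All randomness flows from one seed; ground truth records each
  droplet's member samples.

What the generator does *not* emulate: ambient-HTO "negative" droplets,
order-3+ multiplets by default, batch effects, or any RNA modality.
Passing tests on this data therefore demonstrate correctness of the
pipeline mechanics and of the statistical model under its own
assumptions, not robustness to every artifact of real libraries.

## Problem sizes used in tests

Enumeration oracles run at `X, Y <= 4`; Monte-Carlo oracles use 2e4–1e5
repetitions at `X ~ 100`; the end-to-end classification checks use
8,000–20,000 droplets; estimator recovery uses one simulated observation
at `X = 70,000`, `Y = 30,000`. These sizes give sampling errors well
inside the asserted tolerances while keeping the default suite around a
minute on one CPU.

## Known limitations

- The formation model ignores cell volume and size heterogeneity; it
  assumes independent uniform partitioning.
- Joint `(X, r_cap)` inference relies on the total-GEM-count anchor; if
  the classifier's negative/unclear filtering is badly miscalibrated the
  anchor inherits that bias. Pinning a profiled `X` sidesteps this.
- The mixture classifier assumes each CLR column is genuinely bimodal;
  with very few samples (M = 2) pooling dilutes background less and the
  modes can approach each other.
- Authentication requires an externally supplied clustering; poor
  clusterings yield mixture/indeterminate verdicts by design.
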