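# Methods

## Problem and model

A school district's weekly learning modality — fully remote (1), hybrid
(2), fully in-person (3) — is observed only through four trackers that
cover different districts in different weeks and sometimes disagree.
`modalhmm` models the true modality as a hidden first-order Markov
chain and each tracker as an independent noisy categorical channel:

- $\pi \in \Delta^2$: distribution of the week-1 modality;
- $T \in \mathbb{R}^{3\times 3}$, row-stochastic, time-invariant:
  weekly transition probabilities;
- $E^{(k)} \in \mathbb{R}^{3\times 3}$ for each source
  $k \in \{\text{BURBIO}, \text{MCH}, \text{R2LT}, \text{SD}\}$:
  $E^{(k)}_{ij}$ is the probability that source $k$ reports modality $j$
  when the truth is $i$.

Reports are conditionally independent across sources given the hidden
state, so the emission probability of a week's observation vector is
the product over present sources; a source that did not report
contributes a factor of 1 (exact marginalisation). A week in which no
source reports therefore has emission probability exactly 1 but still
participates in the transition structure — this is what lets the model
interpolate modalities through coverage gaps.

Assumptions worth keeping in mind: the Markov property (next week's
modality depends only on this week's — violated by, e.g., planned
temporary closures), time-invariant $T$ and $E^{(k)}$ across the school
year, conditional independence of sources given the truth (violated if
trackers scrape the same dashboards), and district sequences that are
independent draws from one pooled national model.

## Fitting

Parameters are estimated by Baum–Welch EM over all district sequences
pooled. The E-step runs scaled forward–backward per district
(per-week normalisation constants, so 100+-week sequences cannot
underflow; the log-likelihood is the sum of log scaling constants). The
M-step pools expected counts: $\pi$ from week-1 posteriors, $T$ from
pairwise transition posteriors, and each $E^{(k)}$ **only from
district-weeks where source $k$ is present**. Sequences of different
lengths are left-aligned and tail-padded with all-missing weeks; a
padded week has emission likelihood 1 and scaling constant 1, so it
perturbs neither the likelihood nor the posteriors, and padded steps are
excluded from all count accumulations.

Numerical choices:

- **Initialisation**: emissions 0.8 on-diagonal / 0.1 off-diagonal plus
  seeded uniform noise of magnitude 0.05, rows renormalised; transitions
  sticky (0.9 diagonal); $\pi$ near-uniform. Diagonal-dominant starts
  reflect the structure the model converges to on this kind of data and
  avoid label-degenerate saddle points, while restart noise still
  explores distinct local maxima.
- **Restarts**: 5 by default; restart seeds are spawned from the single
  run seed via `numpy.random.SeedSequence`, best final likelihood kept.
- **Convergence**: relative total-log-likelihood improvement < 1e-6, or
  500 EM updates. With `tol=inf` exactly one update is performed
  (useful for step-by-step debugging).
- **Flooring**: emission cells that receive zero expected counts are
  floored at 1e-10 and the row renormalised, so later decoding never
  evaluates log(0). A source with no observations at all falls back to
  uniform rows (it contributes nothing and biases nothing).
- **Tie-breaking**: posterior argmax and the Viterbi backtrace resolve
  ties to the lowest state index; output is deterministic.
- $\pi$ is estimated by EM like everything else: it is required for a
  well-defined likelihood, and the standard Baum–Welch update is the
  natural estimator; none of the recovery checks depend on its value.

## Label switching and confidence

The likelihood is invariant under relabelling hidden states, so a fit
returns arbitrary cluster indices. They are anchored to modalities by
majority vote: for each hidden state, count every reported modality
(all four sources pooled, unweighted) over the district-weeks whose
posterior-MAP state is that state, then assign greedily in descending
count order (ties: lowest modality code, then lowest state index) so the
result is a proper permutation. A hidden state with zero supporting
reports raises an error rather than guessing. Unweighted pooling is the
plain reading of "most common modality reported within each cluster";
weighting by source reliability would make the labeling depend on the
quantity being validated.

The headline per-week output is the **posterior MAP** modality (the
Viterbi path is also computed and exported); the high-confidence flag
marks district-weeks whose maximum posterior is ≥ 0.75, with an
inclusive comparison. The confidence refers to the MAP state's
posterior, which is what a ≥-threshold on a marginal probability
naturally means.

## Synthetic data: what it emulates and what it does not

The generator draws district paths from a transition matrix and
corrupts them through per-source emission matrices, with each
(district, week, source) cell present independently with a per-source,
per-week probability. The default spec (`default_paper_spec`) is the
published fitted model:

- $T$ and the four $E^{(k)}$ are the published point estimates (rows
  renormalised where three-decimal printing makes them sum to 0.999 or
  1.001);
- presence probabilities are the published per-source district-week
  counts divided by the full 14,688-district × 42-week inference grid:
  BURBIO ≈ 0.061, MCH ≈ 0.094, R2LT ≈ 0.557, SD ≈ 0.040;
- state dashboards are active only in the final ~40% of weeks, and MCH
  is inactive for a contiguous 8-week block starting ~52% through the
  year (the published activity gaps). The Table-level coverage ratios
  are treated as *marginal* rates, so within an active window the
  presence probability is scaled up by `n_weeks / n_active_weeks`;
  expected report counts then match the published totals exactly.
- $\pi$ defaults to (0.25, 0.35, 0.40), approximate early-autumn
  national shares; the published model states no initial distribution,
  so this is a convenience default, and recovery results are insensitive
  to it.

Not emulated: correlated presence across sources and weeks (real
coverage is strongly structured by state and tracker), source-specific
systematic bias shared across trackers, covariate-driven (e.g.
case-incidence-driven) modality changes, and district heterogeneity in
dynamics. A green recovery test therefore establishes that the
estimator is correct and well-conditioned *under the model*, not that
the model is correct for the real feeds — with proprietary, undeposited
sources, that is the strongest claim desk-scale validation can make.

## Statistical reporting

- **Pairwise agreement**: for each pair of trackers (four sources plus
  the fused output), the share of district-weeks covered by both where
  the reported modalities match; empty overlap is reported as missing,
  not zero.
- **Paired t-test**: whether the fused output agrees with a given
  tracker more than each single source does. The sampling unit is the
  week: weekly agreement proportions are paired across the weeks both
  series cover, and a one-sided paired t-test (alternative: fused
  agreement greater) is run per comparator. Weekly pairing avoids
  treating strongly correlated district-weeks as independent
  observations. A comparator that never co-reports with the tracker is
  omitted; exactly one paired week is an error. An all-zero difference
  series (comparator identical to the fused output) is reported as
  statistic 0, one-sided p = 0.5 — the limiting value — rather than the
  0/0 NaN a t-test would produce.
- **Trends**: weekly modality shares over districts with an inferred
  modality that week (the only computable denominator), optionally
  restricted to high-confidence district-weeks, stratified by state or
  by the six-class NCHS urban-rural scheme with a catch-all
  `unclassified` stratum for districts missing from the crosswalk.

## Known limitations

- One pooled national model: per-state dynamics are not fitted.
- Transition and emission matrices are time-invariant.
- The elementwise ±0.02 recovery band is met for every parameter the
  stated coverage world can identify at 3,000 districts × 43 weeks
  — all of $T$ and all emission rows except the state-dashboard
  remote row, which receives only ~450 simulated reports (SD covers 4%
  of district-weeks and only late in the year, when few districts remain
  remote), so its binomial sampling error (~0.022) exceeds the band
  before any estimation error enters. Its recovered values remain within
  ~0.02–0.03.
- Panels are assumed pre-aggregated to one report per
  (district, week, source); within-week modality changes must be
  resolved upstream, and contradictory duplicates are rejected loudly.
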