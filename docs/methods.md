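# Methods

## The model

For endpoint *e* and trial *i* with arms ordered as randomized (first arm =
baseline *b_i*), the observed data are the log-scale contrasts
`y_i = (y_i1, …, y_im)` of each non-baseline arm versus the baseline —
log hazard ratios for PFS and OS, log odds ratios for ORR and CR, log risk
ratios for the most frequent grade 3–4 adverse event — with within-trial
covariance `S_i`.  The random-effects consistency model is

    y_i | δ_i ~ N(δ_i, S_i)
    δ_i | d, τ ~ N(X_i d, Σ_τ)

where `d` holds the basic parameters (log effect of each treatment versus
the reference, `d_ref = 0`), `X_i` encodes consistency
(`d_bk = d_k − d_b`), and `Σ_τ` has diagonal `τ²` and off-diagonal `τ²/2`.
That half-correlation is the unique exchangeable structure under which every
pairwise contrast keeps heterogeneity variance `τ²`, so two-arm and
multi-arm trials are treated coherently.

Assumptions worth keeping in mind:

* **Normal likelihood on contrasts.**  Binary endpoints are converted to log
  OR / log RR with large-sample variances rather than modelled with an exact
  binomial arm-level likelihood.  The survival endpoints only exist as
  summary HRs, which forces the contrast level there; the binary endpoints
  follow for uniformity.  This is an approximation that degrades for very
  small trials or rare events.
* **Common τ per endpoint** across all comparisons.
* **Consistency** (transitivity) of the network, which the inconsistency
  module tests loop by loop rather than assumes silently.

### Within-trial covariance

For count endpoints, the off-diagonal of `S_i` is the baseline arm's
variance contribution: `1/e_b + 1/(n_b − e_b)` on the OR scale,
`1/e_b − 1/n_b` on the RR scale.  If any cell of the trial's 2×k table is
zero, 0.5 is added to every event count (and 1 to every total) of the whole
trial before any contrast is formed — correcting per pair instead would
break positive-definiteness of `S_i` in multi-arm trials.  For survival
endpoints the baseline share is not recoverable from reported HRs; it
defaults to 0 and is exposed as `baseline_var_share`.

### Hazard-ratio reconstruction

When a trial reports no HR, `loghr_from_logrank` rebuilds it from a
two-sided log-rank p-value and the total event count via
`V = events·R/(1+R)²` (allocation ratio R, default 1), `O−E = ±z·√V`,
`logHR = (O−E)/V`, `var = 1/V`.  The sign cannot come from the p-value and
must be supplied.  `loghr_from_ci` back-calculates the variance from a
reported CI, `se = (ln hi − ln lo)/(2 z)`.  The actuarial survival-curve
variant of the reconstruction is out of scope: the package's inputs are
summary statistics, not digitized curves.

## Sampling

Metropolis-within-Gibbs, all updates seeded:

* `δ_i | y, d, τ` and `d | δ, τ` are conjugate normal draws.  Trials are
  batched by contrast dimension so the δ-updates use vectorized (batched)
  Cholesky solves; `Σ_τ⁻¹ = (2/τ²)(I − J/(m+1))` is used in closed form.
* `τ | δ, d` uses shrinkage slice sampling on its bounded support — no
  step-size tuning, deterministic given the seed.
* Priors: `d_k ~ N(0, 10²)` on the log scale, `τ ~ U(0, 5)` — vague
  defaults on scales where observed log effects are O(1); both are exposed
  in `NMAConfig`.
* Defaults: 4 chains × 30,000 iterations, first 10,000 discarded, no
  thinning.  Chains are initialized from seeded jitter; convergence is
  monitored with split-R̂ (threshold 1.05) computed in-package; failure
  attaches a warning rather than discarding the fit.

Reference treatment defaults to MP (the historical melphalan–prednisone
standard) when present; `relative_effects` re-references exactly per draw,
so the choice is cosmetic.

## Ranking

Per retained draw, treatments are ranked on `d` (the reference enters at 0)
after applying the endpoint direction: lower is better for PFS/OS hazard
ratios and for the safety risk ratio, higher is better for response odds
ratios.  Because rank 1 = best, the safety SUCRA automatically lands on the
"higher = safer" orientation.  Ties (measure zero) break by stable input
order.  SUCRA_i is the mean cumulative rank probability over ranks 1..a−1;
the rank matrix is doubly stochastic, hence ΣSUCRA = a/2 — asserted to
1e-6 in the tests as a standing identity.  The chart's overall criterion is
the unweighted mean over the five endpoints; weighting is deliberately left
to the caller.

## Loop inconsistency and heterogeneity

For each triangle with direct pooled estimates d_AB, d_AC, d_BC on one
measure, `RoR = |d_AB − (d_AC − d_BC)|`, `se² = v_AB + v_AC + v_BC`, with a
normal 95% CI truncated at zero on the absolute scale.  Direct estimates
are inverse-variance pooled with weights `1/(v_i + τ²_loop)`; `τ²_loop` is
REML-estimated on the union of the loop's per-trial estimates under a
common-τ², one-mean-per-comparison restricted likelihood (a comparison with
a single trial contributes nothing, which is the correct degenerate
behaviour).  REML is solved by bounded scalar optimization on [0, τ²_max]
with an explicit boundary check at 0; a dense grid search is the test
oracle.  Only triangles are assessed; quadrilateral loops are out of scope.

## Profiling

The treatments × 5 SUCRA matrix is reduced by PCA — eigendecomposition of
the correlation matrix by default (center = scale = on, as in R's
`prcomp(scale.=TRUE)`): SUCRAs share the [0,1] scale but their dispersions
differ by endpoint, and correlation PCA keeps one endpoint from dominating.
Component signs are fixed by making each component's largest-magnitude
loading positive.  Clustering runs on the smallest leading set of components
explaining ≥ 80% of variance (configurable), by PAM: greedy BUILD, then
SWAP over all (medoid, non-medoid) exchanges to a local optimum.  Because
single-start SWAP can terminate in a single-exchange local optimum that is
not the global k-medoids minimum even for n = 8, SWAP restarts from 10
seeded random medoid sets and keeps the best objective (ties broken
lexicographically); the result is deterministic given input order and seed.
k defaults to the mean-silhouette maximizer over 2..6 (silhouette of a
singleton cluster counts 0); `k=3` reproduces a fixed three-group reading.

## Synthetic data

`simulate_trialset` draws trials under exactly the model above: a spanning
tree over the treatments guarantees a connected network, trial random
effects use the τ²/2 covariance, binary endpoints produce binomial counts
around a per-trial baseline risk (logit-normal spread 0.3 between trials;
control-arm defaults ORR 50%, CR 15%, grade 3–4 AE 30%), and survival
endpoints produce observed log HRs with variance `4/events` (the
equal-allocation log-rank approximation, `events = 0.6 ×` patients at
risk).  `simulate_profiled_network` plants regimen groups whose
endpoint-effect vectors share a benefit axis (correlation 0.8 across
endpoints, jitter 0.05, consecutive groups 1.0 apart on the log scale).

What the generator does *not* emulate: censoring and follow-up time,
correlated outcomes within patients, non-proportional hazards, arm-size
imbalance, selective reporting, and era effects.  Passing tests therefore
show that the chain is correct under its own statistical assumptions — not
that published myeloma trials satisfy those assumptions.

The structural fixture reproduces the published 27-trial network (study
ids, years, arm labels, per-trial enrolment, most frequent grade 3–4 AE
label).  Per-arm sizes split the printed per-trial total equally with the
remainder to the first arm; endpoint summaries are drawn, seeded, from a
plausible truth in which later-era regimens tend to do better.  Analyses of
the fixture exercise the published network structure; its effect estimates
are synthetic by construction.

## Problem sizes used in the tests and acceptance script

Chosen as the smallest sizes at which each check is informative: pairwise
reduction on 10 trials; identities on a 6-treatment, 25-trial network;
bias over 10 replicates of the 6-treatment / 40-trial / ~400-patient
design; interval coverage over 200 replicates (50 in the script) of a
20-trial version; loop calibration over 2,000 simulated loops (10,000 in
the script); planted-group recovery over 20 seeds (5 in the script) of a
9-treatment, 26-trial, 5-endpoint network with short chains
(2 × 3,000 iterations).  Test fits use 2 chains and a few thousand
iterations; the analysis drivers use the full 4 × 30,000 default.

## Known limitations

* Contrast-level normal likelihood (no exact binomial arm model); no
  meta-regression, node-splitting, or design-by-treatment interaction
  model.
* Loop τ² plumbing (common τ² across a loop's comparisons, plugged into the
  pooling weights) is one reasonable reading of the inconsistency-plot
  methodology; alternatives exist.
* The funnel export centers on the fixed-effect pooled value per pairwise
  comparison; comparison-adjusted whole-network funnels are not
  implemented.
* P-scores, median ranks, and MRD endpoints are out of scope.
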