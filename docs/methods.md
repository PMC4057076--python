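# Methods

This note documents the statistical model, the algorithmic choices and the
synthetic-data design behind `ruletrait`, including where the design was
genuinely open and why the defaults are what they are.

## Rule model

A *rule* is a conjunction of interval conditions on named baseline
markers; a subject *endorses* a rule when every condition holds. Rules are
canonicalized by intersecting same-marker conditions and sorting by marker
name; an empty intersection is an error. A condition evaluated on a
missing value is false, so a subject missing any marker a rule mentions
does not endorse it. This convention is deterministic and conservative;
surrogate-split imputation during evaluation is deliberately out of scope.
The *support* of a rule is the endorsing fraction of the cohort and always
equals the mean of its endorsement column.

## Rule discovery

**Generation.** `generate_candidate_rules` fits `n_trees` (default 250)
CART classifiers on bootstrap subsamples (`subsample_fraction` 0.8 of the
cohort, drawn with replacement). Tree size is randomized: the terminal-node
budget is `2 + Geometric(p)` with `p` set so the mean equals
`avg_terminal_nodes` (default 4.5), and depth is capped at 3 — the deepest
rules have three conditions, matching the complexity a clinician can still
read. Every root-to-node path of depth ≥ 1 is a candidate rule. Two
controls keep the candidate pool clean:

- `min_impurity_decrease` (default 5e-3): a split must buy a minimum Gini
  improvement. Without it, trees refine genuinely predictive subgroups
  with sampling-noise splits, and those refined paths later compete with —
  and sometimes displace — the simpler true rule during selection.
- Near-duplicate consolidation (`consolidate_jaccard`, default 0.85):
  candidates whose endorsement sets overlap at Jaccard ≥ 0.85 are merged;
  when the merged rules share the same condition structure the
  representative takes the *median* of each cutoff, which denoises the
  split-point jitter between trees. Set the threshold to 1 to disable.

Categorical markers are expanded to 0/1 indicators (`marker=level`) before
tree fitting, so rules on them read as threshold conditions on the
indicator.

**Pruning.** `prune_rules` drops constant endorsement columns, collapses
perfectly collinear columns keeping the shorter rule, and fits an
L1-penalized logistic regression of the outcome on the remaining columns
over a penalty grid (default 10 points, log-spaced over [1e-4, 1e-1] on
the per-observation scale; the liblinear `C` is `1/(nλ)`). The penalty is
chosen by stratified 5-fold cross-validated deviance using the **1-SE
rule**: the sparsest grid point within one standard error of the minimum
mean deviance. The plain minimizer (`lambda_rule="min"`) is available, but
it systematically selects dense models in which several near-substitute
tree paths share the weight of one underlying rule; the 1-SE rule is the
standard remedy and directly serves the goal of a *minimum* predictive
set. Selected rules carry their coefficient sign as a direction:
positive = risk-increasing.

**Stability.** `rule_stability` reruns generation+pruning on stratified
80% subsamples, matches rules across repeats by marker set, and reports
reappearance frequencies and per-cutoff standard deviations. With
`n_repeats=2` the SDs come from two values; that is allowed but noisy.

## Latent-trait model

Endorsements are 2PL item responses on a latent severity θ:
`P(x_ij=1|θ_i) = σ(a_j(θ_i − b_j))`, onset is `P(y_i=1|θ_i) =
σ(β0 + β1θ_i + γᵀz_i)`. Identification:

- θ_i ~ N(0, 1) fixes location and scale of the severity axis.
- The posterior is invariant under the reflection
  (θ, a, b, β1) → (−θ, −a, −b, −β1). Every retained draw is flipped, if
  needed, so β1 ≥ 0: higher severity means higher risk by convention. In
  the items-only mode (two-stage fitting) the flip instead enforces a
  nonnegative mean discrimination.
- Discriminations may be negative — risk-decreasing rules are modeled
  directly rather than reverse-coded.

Priors are mean-zero normals: a_j, b_j ~ N(0, 2²) (wide enough for any
realistic item, proper enough to regularize items with extreme supports),
β, γ ~ N(0, 10²). These are package defaults, recorded in every fit's
settings.

**Sampler.** Adaptive random-walk Metropolis-within-Gibbs, fully seeded.
Per sweep: all θ_i update simultaneously with element-wise accept/reject
(they are conditionally independent); each item's (a_j, b_j) pair updates
jointly with a per-item step size; the link block (β0, β1, γ) updates as
one proposal. Step sizes adapt every 50 sweeps during burn-in toward ~0.3
acceptance and freeze afterwards. Two extra devices matter in practice:

- Initialization: θ starts at the standardized endorsement count (oriented
  to correlate positively with the outcome), item signs come from the
  point-biserial correlation with that score, and b_j matches the observed
  support at θ = 0. Neutral starts leave low-support items stranded on a
  constant-probability likelihood ridge (a → 0, |b| → ∞).
- A per-item sign-flip involution proposal (a_j, b_j) → (−a_j, −b_j) each
  sweep, accepted by the ordinary Metropolis ratio, which lets an item
  stuck on the wrong-sign ridge jump to the mirrored ridge that connects
  to its true mode.

Defaults are 25,000 draws with 5,000 burn-in; parameter-recovery tests use
a scaled-down 5,000-draw chain, which already recovers (a, b) of a
2,000-subject, 10-item cohort to mean absolute error ≈ 0.1. Point
estimates are posterior means over retained draws. Split-window acceptance
rates are recorded; convergence is checked by comparing seeded reruns, not
by automatic restarts.

**Prediction.** For a new subject, the θ posterior given the endorsement
profile alone (items fixed at point estimates, N(0,1) prior) is computed
by deterministic quadrature on a 201-point grid over [−6, 6]; risk is the
quadrature average of the link probability (a plug-in mode exists for
comparison). With all-zero discriminations the prior (mean 0, sd 1) is
returned exactly. Joint fitting of items and link is the default; the
two-stage mode (items first, logistic link on θ̂ second) is provided for
ablation.

## Survival validation

Each rule splits the cohort into endorsing / non-endorsing groups.
`km_estimate` computes the product-limit curve at distinct event times
with 95% bands from the Greenwood variance on the log-survival scale,
clipped to (0, 1]; ties are handled by the simultaneous-death convention.
`logrank_test` is the standard two-group test, `(Σ(O−E))²/ΣV` against
χ²(1). Rules with support 0 or 1 are reported untestable rather than
raising. The AUC uses the Mann–Whitney formulation with ties counting one
half.

`cv_80_20` repeats (default 100×) a stratified 80/20 split: rules are
induced and pruned on the training split only, the latent-trait model is
fitted on the training endorsements, held-out subjects are scored by
`predict_risk`, and the AUC is recorded. If pruning selects no usable rule
the repeat scores a constant (AUC 0.5 by the tie convention). Unstratified
splitting is available; repeats that lose an outcome class are redrawn and
logged. Comparator classifiers on the raw (median-imputed) markers can be
attached to the same splits.

The binary outcome used for model fitting is event-within-horizon: y = 1
iff the event occurred at or before the administrative horizon. The
synthetic generator makes this mapping explicit; for external cohorts the
time/event columns are optional and the outcome column is taken as given.

## Synthetic cohorts

`sample_latent_cohort` draws directly from the generative model:
θ ~ N(0,1), x from the ICCs, y from the link. Its empirical endorsement
rates converge to the quadrature integral of each ICC against the normal
severity density (tested at n = 50,000).

`sample_marker_cohort` emulates a prevention-trial baseline table:
independent normal or lognormal markers, planted conjunctive rules each
adding a configured effect to a raw severity score, N(0, 0.5²) severity
noise, standardization of severity, exponential onset times with rate
`hazard_scale · exp(hazard_gamma · θ)` and administrative censoring, and
completely-at-random missingness applied after the ground truth is
computed. One global seed is split into per-stage substreams (markers,
severity, times, missingness), so cohorts are bit-identical under a fixed
seed.

`hazard_gamma` (log-hazard ratio per severity SD, default 1) exists
because severity is standardized: with a unit coefficient the onset
probability transition spans roughly four severity SDs regardless of
`hazard_scale` or the censoring horizon, which caps the true-θ AUC near
0.8. Scenarios that require strong separability (e.g. the hold-out
harness sanity check) use a steeper gradient (γ = 3–4, true-θ AUC ≈
0.95–0.99).

What the generator does *not* emulate: physiologic correlation between
markers, informative missingness, longitudinal marker trajectories, and
calibration drift between cohorts. Passing tests therefore demonstrate
that the machinery recovers planted structure under clean conditions, not
that it is robust to the full messiness of trial data.

## Problem sizes used in the test suite

Parameter recovery runs at n = 2,000 subjects × 10 items with 5,000
draws; oracle-closeness fits at n = 1,000 and evaluates both scorers on a
fresh 20,000-subject draw so the AUC comparison reflects population
values rather than test-set noise; planted-rule recovery uses 20 seeded
2,000-subject cohorts with 12 markers; the hold-out harness runs 10
(planted) and 20 (permuted-label) repeats on a 500-subject cohort with
reduced tree and chain sizes. These sizes were chosen to make the whole
suite comfortably reproducible on a single CPU while keeping every check
statistically meaningful.

## Known limitations

- The MCMC sampler is single-chain; multi-chain diagnostics are manual
  (rerun with different seeds and compare).
- Item responses are conditionally independent given θ; heavily
  overlapping rules violate this and inflate |a| for near-duplicate items
  (mitigated, not eliminated, by candidate consolidation).
- Only the 2PL response family is implemented; no guessing parameter and
  no nonparametric item response functions.
- Linear terms of the classic rule-ensemble formulation are not generated;
  the model is rules-only.
- Covariate selection for z is out of scope; covariates are passed through
  the link untouched.
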