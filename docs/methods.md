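# Methods

## The task and its synthetic stand-in

The package models a deadlined two-bundle value choice: each trial shows a
left and a right bundle of two "fractals" with learned values on a
€0.10–€0.80 grid (step €0.10), the participant must answer within 750 ms or
forfeit the trial, and 22 subjects complete 160 trials whose bundles are
balanced on total value and on the left–right value difference.

No participant data ship with the package, so `ssmlab.task` builds the
design from scratch. Balance is implemented factorially: total set value S
(sum of all four fractals) and equal-weight bundle difference D take
`n_sum_levels x n_diff_levels` (default 4 x 4) lattice values chosen inside
the region where every (S, D) combination is representable on the grid;
each of the 16 cells receives exactly `n_trials / 16` trials; fractal
quadruples are drawn uniformly from each cell's pool, and the higher-valued
bundle goes to a random side. With the default grid this yields
S ∈ {1.0, 1.4, 1.8, 2.2} and equal-weight |VD| ∈ {0, 0.1, 0.2, 0.3}, and
makes overall value and equal-weight value difference exactly orthogonal
(measured |r| < 1e-15). Whether the original balancing was exact or
approximate is not documented; the factorial reading was chosen because it
reproduces the stated orthogonality by construction. Under 5:1 re-weighting
of each bundle's better fractal the same design yields |r| ≈ 0.26–0.35
between weighted value difference and weighted overall value — the
confound at the centre of the analysis.

Ties (equal bundle sums) are possible on the hardest trials; the left
option is then coded as the nominally correct one. Side assignment is
randomised, so this convention carries no marginal bias.

## Value regressors

For bundle values (high, low) per side:

- `maxVD = left_high − right_high`, `minVD = left_low − right_low`
- `maxOV = left_high + right_high`, `minOV = left_low + right_low`,
  `OV = maxOV + minOV`
- `signVD = w_high·maxVD + w_low·minVD` (equal weights give
  `(maxVD + minVD)/2`), `absVD = |signVD|`

Regressors are exact decimals (rounded at 1e-10) so that genuinely tied
bundles get exactly zero difference regressors.

## The DDM zoo

Every model maps regressors to trial-level DDM parameters through linear
formulas; e.g. the revised original specification is
`v ~ -1 + signVD`, `a ~ 1 + absVD` with free start point z and lapse rate
`p_outlier` (response coding: upper bound = left). The collapsing-bound
("angle") variants add `theta` formulas; "init"/"rate" variants restrict
the value modulation to the initial bound or the collapse rate. Free
parameters are counted as all formula coefficients plus the scalar extras
(z, p_outlier), excluding non-decision time — the convention that gives 5
for the revised original model and 14 for the full collapsing model. The
condition-split original specification (accuracy-coded, hard/easy median
split on absVD) is also registered, with 6 parameters by the same
convention.

Simulation is Euler–Maruyama with unit diffusion, dt = 0.005 s during
fitting and 0.001 s when sampling from fitted models, symmetric absorbing
bounds ±B(t), B(t) = max(0, a − θt), start x₀ = a(2z − 1). Naive Euler
absorption under-detects within-step crossings (bias ~ O(√dt) ≈ 0.005 at
dt = 1e-3), so each step applies the Brownian-bridge crossing probability
exp(−2(B−x)(B−x')/dt) to both barriers; with this correction simulated
absorption probabilities agree with the classical two-barrier closed form
P(upper) = (1 − e^(−2vx₀'))/(1 − e^(−2vA)) within Monte-Carlo error even
at dt = 0.005. The closed form and the eigenfunction series for the
first-passage density (truncated adaptively so the smallest retained decay
factor is below double-precision noise) serve as the static-bound oracle;
they are verification tools, never part of fitting. Positivity of
regression-driven a and θ is enforced by a softplus link. Lapses replace
the outcome with a uniform response and an RT uniform on (0, deadline).
If the bound reaches zero before a crossing, the sign of the current
evidence decides (exact zero: fair seeded coin). Omissions are their own
outcome, never censored. Across-trial drift variability (sv) exists as a
per-trial normal perturbation of v and is off by default.

## The rectified LCA

Two accumulators start at zero and race to a shared collapsing bound
B(t) = max(0, a0 − ct):

    y ← ReLU(y + dt·(I − k·y − w·y_other) + s√dt),  s ~ N(0, σ)

with drive I = b·(m·V_max + (1−m)·V_min) computed from each option's own
fractal pair. Noise is added before rectification, as the update is
written. The printed form of the second accumulator's update applies w to
its own activation, which is redundant with leak; mutual (cross)
inhibition is the default here and the printed variant stays available
behind `printed_inhibition=True` for auditability. The model is
accuracy-coded internally (accumulator 1 = objectively better bundle) and
emitted as a response-coded trial table. If the bound floor is reached
first, the larger activation wins at the floor-crossing time (tie: seeded
coin). The collapse is placed on the bound, not the gain; the source
wording ("boundary collapse rate") does not fully disambiguate this, and
the bound reading is the one implemented.

Default generating parameters (t0 = 0.15 s, b = 6 /s·€, m = 5/6, k = 2 /s,
w = 2 /s, a0 = 1.1, c = 1.0 /s, σ = 0.5) were chosen once so that simulated
behaviour sits in the documented regime of the task: accuracy ≈ 0.74,
omission rate ≈ 2–3 %, right-skewed RTs (skew ≈ 0.6), strong
overall-value speeding (≈ −77 ms across the OV median split) and
difficulty slowing (≈ +26 ms). m = 5/6 encodes the reported 5:1
over-weighting of each bundle's better fractal.

An important identifiability note: scaling (b, a0, c, σ) jointly leaves
LCA behaviour unchanged, so only σ-normalised ratios (b/σ, a0/σ, c/σ),
plus t0, k, w, m, are identified. Parameter-recovery reports include these
derived ratios; the recovery criterion is applied to b/σ, the identified
value-drive quantity.

## Likelihood-free fitting

RTs are first between-subject normalised (subtract the subject mean, add
back the pooled grand mean); the operation is idempotent and preserves the
grand mean. Observed and simulated trials are reduced to categories:
overall-value median split × correct/error, 10 empirical RT-quantile bins
per stratum (right-closed edges; an RT equal to an edge falls in the lower
bin; tied quantile edges on the discrete RT lattice are separated by one
ulp), plus one omission category per split level — 42 categories. The same
empirical edges always categorise simulated data.

Inverse binomial sampling estimates each trial's log-probability: simulate
until the observed category is first matched at draw K and score
−Σ_{j=1}^{K−1} 1/j, unbiased for ln p. Draws are capped at `k_max`
(default 10⁴ for the standalone estimator; a few hundred inside the
optimizer) with the contribution floored at −Σ_{j<k_max} 1/j — the cap is
needed because a category with (near-)zero model probability would never
terminate; how such categories were originally handled is not documented.
The floor can only raise the estimate, which matters when comparing runs
at different caps; reported log-likelihoods are re-estimated at the large
cap with fresh seeds.

The optimizer is bounded differential evolution (Latin-hypercube
initial population including one moment-based heuristic point; fresh-seed
restarts compared head-to-head on matched repeats), followed by a short
Nelder–Mead refinement at higher IBS repeats. Two implementation details
carry most of the speed: per-trial IBS contributions are non-positive, so
an evaluation aborts as soon as its running sum is provably worse than the
incumbent by a margin; and specs with more than ten parameters fit in two
stages (threshold/collapse slopes frozen at zero, then released from a
population centred on the stage-1 solution). Box bounds are documented in
`ssmlab.fitting.default_bounds`; DDM coefficients are fitted on
standardised regressors (signed regressors scaled but not centred, so
zero still means a balanced trial) with the scaling stored on the result
for mapping back to the euro scale. The original study's optimizer (BADS)
and its hierarchical Bayesian stack are intentionally not reproduced;
fitting here is group-level maximum likelihood, which is what the
quantile-BIC comparisons require.

## Model comparison

Quantile BIC: `−2 Σᵢ N pᵢ ln πᵢ + M ln N` over all categories jointly
(deciles for correct/error × easy/hard equal-weight value difference,
omission categories included), with simulated probabilities floored at
1/(2·n_simulated) because finite simulations leave empty cells. Whether
the original sum runs per stratum or jointly is implicit in the source;
the joint reading is used. `compare_models` simulates `n_sim` datasets
per fitted model (default 100), reports per-model BIC distributions,
pairwise mean differences with percentile-bootstrap CIs (10⁴ resamples)
over simulations, win fractions, and the conservative best-single-
simulation comparison. ΔBIC > 2 / 6 / 10 are labelled meaningful / strong
/ very strong.

## Validation experiments and their scales

Fits cost one to three minutes each on a single core (every IBS
evaluation simulates every trial), so the shipped experiments run at
documented reduced scales; all are seed-reproducible and the scales are
recorded in each report.

- **Parameter recovery** (`run_parameter_recovery`): each dataset draws
  one group-level parameter set (log-normal for positive parameters,
  logit-normal for unit-interval ones, normal for coefficients), simulates
  the design, refits, and correlates generated with estimated values on
  the natural scale. Test suite: 4 datasets × 640 trials for the
  6-parameter DDM and the LCA. Probes at this scale recover drift and
  threshold-intercept with r ≈ 0.9 and the LCA drive ratio with r ≈ 0.95;
  with 4 points these correlations are necessarily coarse.
- **Model recovery** (`run_model_recovery`): generators × candidates BIC
  table. Test suite: static-VD and collapsing-VD generators, one dataset
  each, 960 trials; the acceptance script adds the revised-original
  generator row. The collapsing generator is self-selected; the static
  row reproduces the known bias toward collapsing-bound models and the
  report quantifies it rather than asserting it away.
- **Mimicry** (`run_mimicry`): control-free LCA datasets fitted with the
  static revised-original DDM and the full collapsing DDM; threshold
  coefficients aggregated over replicate simulate-and-fit runs with
  percentile-bootstrap CIs. Test suite: three replicates of 1,920 trials
  for the static fit, two replicates of 640 trials each for the
  14-parameter collapsing fit and for the constant-drive control. Verdicts: the static fit's absVD→threshold
  coefficient CI above zero ("thresholds lower for harder choices"), the
  collapsing fit's maxOV→threshold CI below zero (threshold decreasing
  with the max-pair overall value — under 5:1 weighting the min pair
  carries ~1/6 of the drive, so its coefficient is reported but not part
  of the verdict), and a constant-drive control in which the CIs must
  cover zero.

## What the synthetic data do and do not show

The generator reproduces the task's design constants, deadline censoring,
value-driven speeding and subject-level heterogeneity, but not learning of
fractal values, sequential effects, motor biases beyond the starting
point, or the original subjects' true parameter values (which are not
public). Passing recovery and mimicry tests therefore demonstrates
properties of the method — identifiability at the stated scale, and the
artifact mechanism — not numerical agreement with the original dataset;
the original study's DIC/credible-interval values are out of reach without
the participant data and are not reproduced anywhere in this package.

## Numerical conventions

Seeds propagate explicitly to every stochastic step (designs, parameter
draws, simulators, IBS, optimizers, bootstraps); identical seeds give
byte-identical tables. Time steps: 0.005 s fitting, 0.001 s sampling.
RT-bin edge ties broken toward the lower bin. BIC floors at
1/(2·n_simulated). Bootstrap CIs are percentile, 10⁴ resamples unless a
test reduces them. CSV trial tables use UTF-8, "." decimals, seconds for
RT, and an empty RT field for omissions.
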