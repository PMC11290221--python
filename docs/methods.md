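# Methods

This note records the statistical model, the concrete numerical choices,
and what the test suite does and does not demonstrate.

## Design and data-generating model

We consider a two-arm superiority trial (1:1 target allocation) with a
single time-to-event endpoint and three binary prognostic factors
z₁, z₂ ~ Bernoulli(2/3), z₃ ~ Bernoulli(1/3), i.i.d. across patients.
Treatment is assigned sequentially by Pocock–Simon minimisation: for each
arriving patient the candidate imbalance of each arm is the sum over
factors of |n_exp − n_con| among previously assigned patients sharing the
patient's factor level, evaluated *after* hypothetically adding the
patient; the arm with smaller total is assigned with probability 0.7, and
exact ties (including the first patient) are a fair coin.  Only the three
factors enter the imbalance — total sample size is not a separate term —
and factors are equally weighted.  These are the canonical Pocock–Simon
choices; the procedure description we follow names minimisation and the
0.7 preference probability but not the metric variant, so the canonical
"range" metric is adopted.

Event times follow a piecewise-exponential hazard

    λ_i(t) = λ₀ · exp{ (β₁·I(t<ε) + β₂·I(t≥ε))·Z_i0 + γ(z₁+z₂+z₃) },

with Z_i0 = 1 for the experimental arm, so hazard ratios below one favour
the experimental arm.  Sampling is by inversion: with pre/post-ε rates
r₁, r₂ and E ~ Exp(1), Y = E/r₁ if E < r₁ε, else ε + (E − r₁ε)/r₂.
Censoring is purely administrative: uniform accrual over 20 months with
20 further months of follow-up gives C ~ U[20, 40] months, independent of
Y.  There is no dropout process.  The seven catalogued scenarios (null,
strong nulls A and B, PH, delayed, crossing, diminishing) live in
`data/scenarios.yaml`; users can add rows.

An exact audit of the implied censoring fractions (mixing the closed-form
piecewise-exponential survivor function over the covariate distribution
and the censoring window) reproduces the catalogued per-arm censoring
percentages to printed-integer rounding in 10 of 12 arm×scenario cells;
the remaining two (delayed/experimental, exact 25.4 vs printed 26;
strong-null-B/control, exact 37.2 vs printed 38) differ by under one
percentage point, and the generator follows the stated model.

## Test statistics

All tests are one-sided and **oriented**: large positive Z supports
experimental-arm superiority, and p is the upper tail.  This fixes a
single convention for asymptotic and re-randomisation modes alike.

**Weighted log-rank.**  Over pooled distinct event times t_j with at-risk
counts n_j (n_1j experimental) and event counts d_j (d_1j experimental),

    U = Σ_j w_j (d_1j − n_1j d_j/n_j),
    V = Σ_j w_j² n_1j n_0j d_j (n_j − d_j) / (n_j²(n_j − 1)),

dropping j-terms with n_j = 1, and Z = −U/√V.  Fleming–Harrington weights
w_j = Ŝ(t_j−)^ρ(1−Ŝ(t_j−))^γ use the *left-continuous* pooled (over arms)
Kaplan–Meier curve.  Stratified versions sum U and V over the z₁×z₂×z₃
cells, each cell using its own risk table and its own within-stratum
pooled KM for weights; event-free cells contribute nothing.  Whether the
stratified variant should instead draw weights from the overall pooled
curve is not documented for the study we follow; within-stratum weights
are the default and the alternative would be a small localised change in
`_StratumTerms`.

**MaxCombo.**  z_max over the (0,0), (1,0), (1,1), (0,1) components, with
asymptotic p = 1 − Φ_R(z_max,…,z_max) where R is the estimated component
correlation, Cov(U_k,U_l) = Σ_j w_kj w_lj V_j.  The 4-dimensional normal
probability is computed by the Genz sequential-conditioning transform
integrated with scrambled-Sobol points (cached at import, so results are
deterministic); the point count escalates from 2^13 to 2^15 per scrambling
until the spread of 4 independent scramblings is below 2·10⁻⁵.  At the top
rung the verified absolute error against a slow reference integration is
~3·10⁻⁷; 2·10⁻⁵ is two orders of magnitude below the Monte-Carlo noise of
any simulated rejection rate reported here, and was chosen over a tighter
tolerance purely to keep 10⁴-replicate grids fast.  Numerically singular
correlation matrices (duplicated weights) receive a 10⁻⁸ ridge.

**dRMST.**  Per arm, μ(τ) = area under the KM step curve on [0, τ], with
the curve held constant beyond the last observed time when that time is
below τ (the horizontal-extension repair for the case where the longest
time in an arm is censored before τ).  The variance is
Σ_{t_j≤τ} A_j² d_j/(n_j(n_j−d_j)) with A_j = ∫_{t_j}^τ Ŝ; terms with
n_j = d_j are dropped.  Z = (μ̂₁−μ̂₂)/√(v̂₁+v̂₂).  The pair is
non-computable exactly when no events occur in either arm by τ (the pooled
variance vanishes, so no standard error exists); an event-free *single*
arm contributes μ = τ, v = 0 and the test proceeds.  Default τ = 30
months; 20 and 25 are supported.

**IPCW-adjusted dRMST.**  A weighted least-squares regression of
X_i = min(T_i, τ) on (1, arm, z₁, z₂, z₃) with weights δ_i(τ)/Ĝ_arm(X_i−),
where δ_i(τ) indicates the restricted time is fully observed (event by τ,
or followed beyond τ) and Ĝ_arm is the per-arm reverse Kaplan–Meier
censoring-survivor curve; the treatment coefficient is tested with an
HC0 sandwich variance.  The published appendix defining this statistic was
not available to us; the construction above is the standard IPCW
regression used for covariate-adjusted RMST analysis and should be read as
a faithful reconstruction.  Arm-specific (rather than pooled) Ĝ and the
sandwich (rather than model-based) variance are deliberate, documented
switches: both match the common reference implementation of RMST ANCOVA.

**Cox.**  Breslow-tie partial likelihood maximised by Newton–Raphson
(gradient tolerance 10⁻⁸, ≤50 iterations, step-halving on likelihood
decrease).  Breslow keeps the score test at β = 0 *identical* to the
unweighted log-rank statistic on tie-free data — an identity the test
suite asserts to 10⁻¹⁰.  Runaway coefficients (|β| > 15) are flagged as
monotone-likelihood/separation and reported non-computable; this threshold
is reached before the vanishing gradient can masquerade as convergence.
The reported statistic is the Wald Z = −β̂₀/SE.

## Re-randomisation inference

The reference distribution of any oriented statistic S is generated by
re-running the minimisation procedure M times over the fixed covariate
table in fixed entry order (outcomes never change), recomputing S each
time, and reporting p = Σ_m I(S_m ≥ S_obs)/D over the D computable
replicates.  There is deliberately no +1 continuity correction — p = 0 is
attainable — and duplicate assignment sequences are retained.  Default
M = 1000.  Non-computable replicates (possible for the dRMST family in
tiny strata) are dropped from the denominator and counted; how such
replicates were handled in the original study is not stated, and dropping
them is our documented convention.

Every assignment consumes exactly one uniform deviate (the tie folds into
the assignment probability), which makes the scalar path and the
M-vectorised batch path bit-compatible and lets a single master seed fix
the entire reference set.

For fixed outcomes the weighted log-rank score is *linear* in the
assignment vector — d_1j and n_1j are inner products of per-time indicator
rows with it — so all M statistics of the log-rank/WLRT/MaxCombo family
(stratified included) are computed as a handful of matrix products against
the n×M assignment matrix.  A full stratified-MaxCombo re-randomisation
test at n = 50, M = 500 costs ~10 ms.  Cox- and RMST-based statistics are
refitted per replicate.

## Simulation harness

`run_grid` evaluates every requested method on the *same* simulated trials
per cell (paired comparison; this sharpens between-method contrasts and
does not bias marginal rates), counts p ≤ α rejections at one-sided
α = 0.025, and reports rates with binomial Monte-Carlo SEs,
100·√(p̂(1−p̂)/N).  dRMST-family exclusions (no events in either arm) are
counted per cell.  Per-replicate p-values and a seeded manifest are
persisted so every table is re-derivable without re-simulation.  Cell RNG
streams are derived from (seed, scenario, n), so results do not depend on
which other cells or methods run.

Replication profiles: `smoke` (200 reps, M = 200), `desk` (2000/1000
reps, M = 500), `paper` (10,000 null / 5,000 alternative reps, M = 1000).
The shipped acceptance checks run between `smoke` and `desk` scale —
e.g. 10,000 replicates for the null log-rank rate but 1,000–2,000 for the
strong-null MaxCombo cells and re-randomisation grids — sizes chosen so
the full battery completes in minutes on one core while keeping every
comparison inside three combined Monte-Carlo standard errors of the
published full-replication values.

## What the synthetic generator does and does not emulate

It reproduces the study conditions exactly as stated: minimisation with
preference 0.7 on three binary factors, the piecewise-exponential hazard,
independent uniform administrative censoring, and the seven parameter
rows.  It does not model staggered calendar-time analysis beyond the
censoring window, dropout or competing risks, non-binary or correlated
covariates, tied event times (continuous model; ties only arise in user
data, where events are taken to precede censorings), or allocation ratios
other than 1:1.  Passing tests therefore demonstrate correctness of the
statistics and the randomisation-inference machinery under these
idealised conditions, not robustness to informative censoring or
real-world data irregularities.

## Known limitations

- Two-sided testing, unequal allocation, weighted or additional
  minimisation factors, and stratified permuted blocks are out of scope.
- The asymptotic stratified MaxCombo uses within-stratum weights (see
  above); with n = 50 and up to 8 cells, some cells carry very few events,
  which is precisely the regime where the stratified re-randomisation
  test's deep conservatism under the strong null appears.
- `rerand_cox*` and `rerand_drmst*` refit per replicate (~seconds per
  trial at M = 1000); they are exercised at small M in the tests.
- The IPCW statistic is a reconstruction (see above); small numerical
  differences from the original appendix definition cannot be excluded.
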