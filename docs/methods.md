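# Methods

## Coordinate frame and per-trial metrics

All quantities live on the 2D goal plane: X lateral (positive to the
kicker's right), Y vertical (positive up), meters. Every serial metric
relates consecutive retained trials (n−1, n) of the same block. The
previous displacement Δₙ₋₁ = B_after(n−1) − B_before(n−1) defines the
prior-informed landing L̂ₙ = B_before(n) + Δₙ₋₁; prediction deviation is
|Lₙ − L̂ₙ| and the directional updating index is the signed scalar
projection αₙ = ((Lₙ − B_before(n))·Δₙ₋₁)/|Δₙ₋₁|². α is *undefined* — never
zero — when Δₙ₋₁ is the zero vector, and undefined pairs are excluded from
all α averages. All distance metrics are translation invariant, so the
goal-plane origin is immaterial; real-data ingestion should still document
its origin for auditability.

A pair's *condition* is the previous trial's distortion level: `neutral`
(zero force), `max` (largest configured magnitude, either sign — left/right
are collapsed), `mid` otherwise. Serial metrics concern carryover from
trial n−1, so conditioning on the previous trial is the only labeling under
which the flexibility mechanism (down-weighting after a large perturbation)
is visible.

### Eligibility of zero-displacement pairs

When Δₙ₋₁ = 0 exactly, L̂ₙ = B_before(n) and PredictionDeviation ≡
ResponseError: the row contributes a tautological y = x observation that
mechanically inflates β_pred. We therefore restrict the prediction-model
fits (full and simple variants) to pairs with |Δₙ₋₁| > 0, the same
eligibility that guards α. In real recordings the projectile's natural
continuation makes Δ nonzero even on neutral trials, so this guard is
inert there; in the simulator, neutral trials have Δ = 0 by construction,
so the simulated "neutral" cell of β_pred (and of α) is empty, and
distortion contrasts on simulated cohorts compare the mid (±475 cN) and max
cells. The signed history regressions keep all pairs: a zero previous
lateral displacement is a legitimate predictor value, not a degeneracy.

## Exclusion cascade

Per participant, in fixed order: (1) invalid flights (ball on the floor or
outside the goal) and their immediate within-block successor; (2) trials
whose response error is more than 2.5 SD from the participant's mean
(mean/SD pooled over blocks on the post-validity remainder), plus immediate
successors — the successor rule is one step and non-recursive, because only
trial n+1 uses trial n as history; (3) the literal first trial of every
block (no preceding trial). Gaps left by exclusions break pairing: pairs
are formed only from originally consecutive retained trials. A trial
removable for several reasons is tallied once by the earliest pass. With
fewer than 3 trials after pass 1 the outlier SD is undefined and the
participant is unusable. Re-applying the cascade to its own output is a
fixed point on well-behaved data, though trimming can in principle expose
new 2.5 SD outliers on pathological error distributions.

## Per-participant fits

The prediction model is OLS of response error on an intercept, stimulus
proximity, response proximity, and prediction deviation. The headline
β_pred is the multivariate coefficient; a simple-regression variant
(response error on prediction deviation alone) is computed and reported
separately, as condition-specific figures are sometimes drawn from the
simple fit. Slopes are only trusted with at least `min_pairs = 10` rows
(default; participants below it are excluded from group statistics).
Signed history slopes come from simple regressions of the current signed
lateral error on the previous lateral displacement (β_Stim) or previous
signed error (β_Resp). Partial residuals are ε̂ₙ + β̂ₓXₙ; regressing them on
X returns β̂ₓ exactly. The OLS engine is a compact normal-theory
implementation (solve of X'X, classical SEs, t-based p-values) because the
shuffle and calibration loops refit it thousands of times; it agrees with
statsmodels to numerical precision and is tested against brute-force normal
equations.

The shuffle control permutes a participant's retained trials uniformly
(block boundaries ignored — the simplest exchangeable null), recomputes all
history-dependent predictors from the permuted order, and refits the
prediction model. On calibrated data the mean shuffled β_pred is ≈ 0 and
its p-values are ≈ uniform (mean ≈ 0.5). Default 100 shuffles per
participant; a single shuffle is the degenerate case.

## Group inference

Pearson correlations use the t transform (n−2 df) and Fisher-z 95% CIs,
tanh(atanh r ± z/√(n−3)). The default correlation Bayes factor is the JZS
form — a Cauchy prior on the standardized regression effect, evaluated by
adaptive quadrature over the g-prior integral — which is what mainstream
Bayesian toolboxes report for correlations and what reproduces the
reference values this package is checked against (e.g. BF₁₀ ≈ 26.2 at
r = 0.49, n = 42). The Jeffreys stretched-beta prior (width κ, default 1)
is available as an option and is cross-checked against an independent
trapezoid-grid quadrature and against pingouin. Note the two priors differ
materially (stretched-beta κ=1 gives ≈ 36.3 for the same r, n). t-tests
(one-sample, paired, independent pooled-variance) report the JZS Bayes
factor with Cauchy scale √2/2 via quadrature over the non-central t
likelihood, plus Cohen's d (mean/SD, mean change/SD of changes, or
pooled-SD standardized difference). BF thresholds 3 and 1/3 are the
conventional moderate-evidence markers.

Trait grouping: quartile extreme groups (scores ≤ 25th / ≥ 75th percentile,
linear-interpolation quantiles — chosen because reference quartile values
like 12.75 imply an interpolating estimator) for pairwise contrasts; a
median split is used for the 2 × 2 ANOVAs, where quartile groups would be
too small. The two-factor ANOVA is mixed-design by default (group between,
condition within, pingouin's implementation, validated against an explicit
sums-of-squares decomposition); a fully-between variant is available by
flag since published df conventions for such designs are not always
recoverable. ANCOVA fits group indicators plus covariates by OLS and
reports the omnibus group F and adjusted pairwise contrasts. Jarque–Bera
uses the moment formula JB = n/6·(S² + K²/4) with χ²(2) p. Holm adjustment
is statsmodels' step-down implementation.

## Synthetic cohorts

The simulator emulates the statistical structure the analysis assumes — not
the physics. Per trial, a distortion force is drawn from the configured
levels under the constraint that no level repeats more than twice
consecutively (each draw uniform over admissible levels); the last-seen
position is drawn near the goal center (X ~ N(0, 2.5 m), Y ~
N(goal_height/2 − 1.35, 1.0 m), clipped to the 20 × 5.7 m goal rectangle);
the reappearance shift is purely lateral, Δx = k·F with k = 0.004 m/cN
(maximal force → 3.8 m). Responses follow, per block (trial 1 has no
history term):

    Err_x[n] = a_eff[n]·Δx[n−1] + r·Err_x[n−1] + ε_x
    Err_y[n] =                    r·Err_y[n−1] + ε_y
    a_eff[n] = a·(1 − f·1[|F[n−1]| = max]),   ε ~ N(0, σ²)

with carry gain a (ground truth for α), flexibility f (fractional
down-weighting after maximal distortion), inertia r (ground truth for
β_Resp), and motor noise σ (default 0.3 m). Trait linkage is linear in
z-scored AQ with clipping: a = clip(a₀ + γ_carry·z, 0, 1.5),
f = clip(f₀ − γ_flex·z, 0, 1); defaults a₀ = 0.6, f₀ = 0.3, r₀ = 0.2,
γ_carry = −0.1/SD, γ_flex = 0.15/SD, AQ ~ N(17, 6) rounded and clipped to
[0, 50]. Zero gradients give a null cohort. Invalid flights are independent
Bernoulli flags (default 5%), not physics. Participant i's stream is
`SeedSequence([master_seed, i])` (profiles use a reserved counter), so
cohorts are byte-identical under a fixed master seed.

### Why k = 0.004 m/cN

The shuffle-control null is only calibrated when displacement magnitudes
dominate the response-offset scale, as they do in the task being emulated
(perturbations are salient, several times the ~0.3 m motor noise). With
k = 0.002 the carryover component of the response offset (up to a·1.9 m)
overlaps the mid-level displacement (0.95 m) and the shared dependence of
|Lₙ − B_before| and |Lₙ − L̂ₙ| on the same offset vector produces a
mechanical positive shuffled slope (≈ +0.03, mean p ≈ 0.39–0.44). At
k = 0.004 the same code yields mean shuffled slope ≈ +0.003 and mean
p ≈ 0.49. The choice is a property of what the generator emulates; the
estimators themselves are k-free.

### What the simulator does and does not emulate

It reproduces: the distortion randomization constraint, trait-linked
individual differences in carryover/flexibility, response inertia, additive
motor noise, invalid-trial attrition, and the block structure (5 × 25
trials). It does not reproduce: projectile flight between disappearance and
reappearance (so neutral trials have exactly zero displacement — see the
eligibility note), vertical distortion components, learning or fatigue
across blocks, response-time structure, or any dependence of invalidity on
kick kinematics. Passing recovery tests therefore show the estimators are
consistent under the assumed generative structure, not that real data meet
those assumptions.

## Numerical choices and problem sizes

Quadratures use scipy's adaptive `quad` with convergence guards; the
correlation BF depends on |r| only and is evaluated at |r| to keep the
two-sided symmetry exact. OLS rank is checked via SVD rank; rank-deficient
designs are rejected rather than pseudo-inverted. Calibration and recovery
checks run at the study's natural sizes — 42 participants × 125 trials with
100 shuffles for the permutation null, 200 replicate participants for α
recovery, 50 for inertia recovery, 500 null cohorts for the 5%-level
rejection-rate check (central 99% binomial band) — sizes chosen to make
Monte-Carlo error small relative to the tested tolerances.

## Known limitations

* The mixed-design ANOVA assumes complete cells; participants missing a
  condition cell are dropped listwise from that ANOVA.
* The conventional "neutral" condition cells for α and β_pred cannot be
  produced from simulated data (zero displacement ⇒ undefined/ineligible);
  mid-level cells stand in for the low-uncertainty condition there.
* The shuffle-control calibration degrades for extreme carry gains
  (a·max-shift ≫ displacement levels), an intrinsic property of distance-
  based serial metrics, not of the implementation.
* Expertise effects are modeled only through the `expert` flag and group
  contrasts; no expert-specific generative parameters are provided beyond
  what the profile fields expose.
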