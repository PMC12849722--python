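# goalplane

Trial-history analysis for dynamic sensorimotor prediction tasks, built for
the setting where an observer repeatedly launches a projectile toward a goal
plane, the projectile vanishes mid-flight, the observer marks the expected
arrival point, and the projectile then reappears, shifted laterally by a
force drawn from a small set of levels (e.g. −950, −475, 0, +475, +950 cN).
The question is how the *previous* trial's perturbation shapes the *current*
response — and how that trial-to-trial updating varies with individual
traits such as the autism-spectrum quotient (AQ).

The package provides, per participant and trial pair (n−1, n), all in
goal-plane coordinates (X lateral, Y vertical, meters):

* **Response error** — |Lₙ − B_before(n)|, the distance from the response to
  the last-seen position.
* **Prior-informed landing** — L̂ₙ = B_before(n) + ΔDistortionₙ₋₁, the
  landing expected if the previous perturbation repeated, with
  ΔDistortionₙ₋₁ = B_after(n−1) − B_before(n−1).
* **Prediction deviation** — |Lₙ − L̂ₙ|; small values mean the response
  stays close to the prior-based expectation.
* **Prediction-reliance slope β_pred** — from the per-participant OLS model
  `ResponseErrorₙ = β₀ + β_StimHist·StimulusProximity + β_RespHist·ResponseProximity + β_Pred·PredictionDeviationₙ + ε`;
  β_pred > 0 means responses are more accurate near the prior.
* **Directional updating index α** —
  `αₙ = ((Lₙ − B_before(n)) · ΔDistortionₙ₋₁) / |ΔDistortionₙ₋₁|²`
  (defined only for nonzero previous displacement): 1 = full reuse of the
  previous displacement, 0 = none, negative = repulsion.
* **Signed history slopes β_Stim, β_Resp** — simple regressions of the
  current signed lateral error on the previous lateral displacement /
  previous signed error (attraction > 0, repulsion < 0).

Around these sit the standard participant-level exclusion cascade (invalid
flights, 2.5 SD response-error outliers, their immediate successors, block
starts), a trial-shuffling control that destroys serial structure and refits
the model, and group-level inference: Pearson and partial correlations with
Fisher-z CIs and JZS correlation Bayes factors, quartile/median trait
grouping, t-tests with JZS Bayes factors (Cauchy scale √2/2), mixed-design
and between-subject ANOVAs, ANCOVA, Kruskal–Wallis, Jarque–Bera, and Holm
adjustment. A synthetic-cohort simulator with known per-participant ground
truth (carry gain, flexibility, response inertia, motor noise, trait
linkage) exercises the full pipeline and supports recovery tests.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
cohort and write their tables to `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_exclusions_and_metrics.py
python analysis/03_participant_fits.py
python analysis/04_group_inference.py
python analysis/05_shuffle_control.py
```

Output of the run shipped here (master seed 1):

```
cohort: 42 participants, 5250 trials
AQ range 2-34, carry gain 0.32-0.85
mean retained fraction: 0.859
42/42 participants usable
mean alpha 0.487; corr(alpha, true carry gain) = 0.89
mean beta_resp 0.128 (true inertia 0.20)
AQ vs prediction_deviation: r = +0.62 CI [+0.39, +0.78], p = 1.29e-05, BF10 = 1498.84
AQ vs alpha: r = -0.89 CI [-0.94, -0.81], p = 2.16e-15, BF10 = 3814602237492.79
alpha group x distortion interaction: F(1,40) = 84.68, p = 2.01e-11
mean shuffled slope +0.0031, mean p 0.488 (calibrated null: slope ~ 0, p ~ 0.5)
```

Read: the cohort was built with a negative trait gradient on carryover, and
the pipeline recovers it — per-participant mean α tracks the true carry gain
(r = 0.89), α falls with AQ, flexible (low-AQ-designed) participants
down-weight α after maximal distortions (the interaction), and once trial
order is shuffled the prediction-reliance slope vanishes and its p-values
are uniform, confirming the serial effects are not exclusion artifacts.

The same machinery is scriptable from a shell:

```bash
goalplane simulate --seed 1 --out data/
goalplane analyze data/trials.csv --out report/ --shuffles 100
goalplane shuffle-check --seed 1
```

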