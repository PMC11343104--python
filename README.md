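# hilopt

Simulation benchmark of **dynamic Bayesian optimization (DBO)** against
classical **Bayesian optimization (BO)** for human-in-the-loop (HIL) tuning
of stimulus parameters when the human response changes through motor
learning.

HIL optimization tunes the control parameters of human-interacting devices
(exoskeleton assistance, stimulation intensity, perturbation schedules) by
treating the measured human response as the objective of a closed-loop
optimizer. Classical BO assumes the input–response relationship is fixed;
people adapt, so it is not. DBO augments the Gaussian-process surrogate with
an iteration-time kernel,

    k((u,t),(u',t')) = σ² · exp(−Σ_p (u_p−u'_p)² / (2 l_p²)) · (1−α)^|t−t'|,

so that observations lose weight geometrically (forgetting factor
α ∈ [0,1); α = 0 recovers static BO exactly). Proposals come from Expected
Improvement with an overexploitation safeguard: a proposal whose posterior
uncertainty has collapsed below a fraction *e* (the exploration–exploitation
ratio) of the prior uncertainty triggers a hyperparameter adjustment under
tightened length-scale bounds.

Because closed-loop experiments on people are expensive, the package
benchmarks the optimizers against *virtual subjects*:

* an explicitly time-dependent system whose optimal input and output drift
  along decaying oscillating exponentials, and
* a family of modified use-dependent-learning (UDL) state-space models —
  second-order linear learners with reference-movement drift covering
  slow/fast positive and negative learning, a stationary no-learning
  control, and pure adaptation (presets `model1`..`model6`).

Per iteration the pipeline records implementation outcomes (applied input /
measured output vs. the currently optimal feasible ones) and estimation
outcomes (the optimizer's estimated optimum vs. the true one), then an
iteration-wise 2×2 factorial ANOVA (optimizer type × e-ratio) with post-hoc
t tests locates when DBO becomes statistically superior.

See `docs/methods.md` for the model equations, design decisions and their
rationale.

## Worked example

Run six repetitions of the closed loop against the fast negative-learning
subject (`model4`, 200 iterations, four optimizer variants) and ask when the
dynamic optimizer's estimate of the optimal stimulus becomes significantly
better:

```python
from hilopt import ExperimentConfig, run_experiment
from hilopt.analysis import iteration_anova, superiority_series, proportion_superior

config = ExperimentConfig(subject="model4", n_repetitions=6, master_seed=42)
results = run_experiment(config)

late = results[results.iteration > 180]
print(late.groupby("variant")["input_estim_error"].median().round(3))

table = iteration_anova(results, "input_estim_error")
series = superiority_series(table)
print(f"DBO significantly superior in {100 * proportion_superior(series, 44):.0f}% "
      f"of iterations past 44")
```

which prints (a few minutes on one CPU):

```
variant
BO-0.2     4.175
BO-0.4     4.600
DBO-0.2    0.000
DBO-0.4    0.000
Name: input_estim_error, dtype: float64
DBO significantly superior in 96% of iterations past 44
```

The numbers say: in the last 20 iterations both DBO variants estimate the
optimal stimulus essentially exactly (their estimate sits on the saturation
limit, which *is* the feasible optimum for this diverging learner), while
static BO — whose model still trusts observations from an earlier state of
the learner — is off by ≈ 4–5 input units; the iteration-wise ANOVA finds
DBO significantly better in 96% of iterations past iteration 44.

## Command line

```
hilopt simulate --config configs/model3.yaml --out runs/m3 --reps 25
hilopt analyze  --results runs/m3 --out runs/m3/analysis
hilopt protocol --model model3 --out m3_trajectory.csv
```

`simulate` writes a tidy per-iteration results table plus median/20th/80th
percentile summaries; `analyze` writes per-iteration ANOVA tables and a
crossover summary (first iteration of continuous DBO superiority, 80%
threshold crossover, overall significant fraction) per outcome; `protocol`
regenerates the open-loop null/stimulus/null training trajectory of a
learner preset. Example configuration files for all standard experiments
are in `configs/`.

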