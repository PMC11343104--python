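# Methods

`hilopt` simulates human-in-the-loop (HIL) optimization: an optimizer chooses
a stimulus each trial, a virtual human subject responds, and the optimizer
updates its model of the input–response relationship. The package compares
classical Bayesian optimization (BO) against dynamic Bayesian optimization
(DBO), which discounts observations by their separation in iteration time, on
subjects whose input–output relationship changes as they learn.

## Surrogate model

Both optimizer variants use a Gaussian-process surrogate over pairs
`(u, t)` of input and iteration index, with the separable covariance

    k((u,t),(u',t')) = σ² · exp(−Σ_p (u_p−u'_p)²/(2 l_p²)) · (1−α)^|t−t'|

plus additive observation noise σ_n² on the diagonal. The model variance at
a query is the posterior function variance plus σ_n², exactly. The prior
mean is the sample mean of the outputs (outputs are centered before
fitting). With α = 0 the kernel is time-agnostic and the dynamic variant
reduces bitwise to static BO; this degeneracy is asserted by a test.

**Hyperparameter fitting.** Length scale, signal variance and noise variance
are chosen by maximizing the log marginal likelihood with bounded L-BFGS-B in
log space, with analytic gradients. A full 3-start search runs when the
optimizer is initialized, every 50th iteration, and whenever the
overexploitation safeguard triggers a re-fit; in between, a single
warm-started search with a small iteration cap (5 iterations, 10 function
evaluations) keeps the fit current at a fraction of the cost. Numerically,
Cholesky factorizations receive an escalating diagonal jitter
(`1e-10 σ²` up to `1e-6 σ²`) on failure; the covariance inverse needed by
the gradient is formed from the Cholesky factor (LAPACK `dpotri`).

**The forgetting factor α is a model constant, not a fitted quantity.**
This is a deliberate design decision. Under closed-loop (adaptively sampled)
data the marginal likelihood contains a degenerate ridge — α → 0 with the
signal variance inflated by orders of magnitude and a length scale spanning
the domain — that explains slow temporal drift as quasi-static structure and
always dominates genuinely dynamic fits. Fitting α therefore collapses DBO
onto BO in every run. Treating the forgetting rate as a known constant is
standard in the time-varying bandit literature from which the `(1−α)^|Δt|`
kernel derives. The default is α = 0.05: a correlation half-life of ≈ 13.5
iterations, matched to the slowest time constant (15 iterations) of the
time-dependent test system. Likelihood-based fitting of α remains available
(`fit_alpha: true`) for studying the degeneracy itself.

## Acquisition and the exploration–exploitation ratio

Inputs are proposed by maximizing closed-form Expected Improvement (for
minimization) on a dense uniform grid (default 301 points per dimension),
with the query time set to the next iteration index; ties are broken by the
lower posterior mean, then the lower input value. The incumbent is the
minimum posterior mean over previously observed inputs evaluated at the
current iteration time, which is robust to noise and meaningful under drift.
Proposals and optimum estimates are clipped to the subject's saturation
limits; the optimum estimate is the grid argmin of the posterior mean at the
current iteration index.

A proposal is flagged as *overexploitation* when the posterior function
standard deviation there falls below `e · σ`, where `e ∈ (0,1]` is the
exploration–exploitation ratio and `σ` is, by default, the **prior**
standard deviation (the square root of the kernel signal variance). Under
this reading the flag means "the model is already more than `(1−e)`-certain
at the proposed point relative to its prior uncertainty". Two alternative
references — the fitted noise sd and the model sd at the proposal — are
available as configuration switches, but both are inert in practice: the
fitted noise variance collapses to its lower bound for the dynamic variant
(the temporal kernel absorbs noise), so the threshold is never reached and
the two e-ratios produce indistinguishable trajectories.

A flagged proposal triggers the adjustment loop: the length-scale upper
bound is tightened to half the currently fitted length scale, the
hyperparameters are re-fit, the model is rebuilt, and a new proposal is made
(one retry by default). If the flag persists, the proposal is applied anyway
— the safeguard nudges the acquisition rather than overriding it, which
lets a static optimizer fixate on a stale optimum, as static BO is expected
to. An alternative terminal action that overrides the proposal with the
most uncertain grid point is available (`overexploitation_fallback:
"max_variance"`), but it converts any converged optimizer into a pure
max-uncertainty sampler, because the posterior sd at a repeatedly sampled
point tends to zero under a static kernel.

For the dynamic variant, α = 0.05 places the floor of the relative posterior
sd at a re-sampled point, `√(2α−α²) ≈ 0.31`, between the two study e-ratios
0.2 and 0.4 — so the safeguard engages differentially for the two settings,
which is what makes them behaviorally distinct.

## Virtual subjects

**Explicitly time-dependent system.** A zero-order system whose optimal
input and optimal output drift along decaying oscillating exponentials
(time constant 15 iterations, oscillation period 10); the response is the
optimal output plus a quadratic penalty on the distance from the optimal
input, plus N(0, 0.1²) measurement noise. Saturation limits are |u| < 15.
The optimizer minimizes the raw response. The sine coefficient of the
optimal-output drift (`osc_coefficient`) defaults to 13 and is exposed in
configuration; with the alternative value 1/3 the optimal output drifts
gently instead of oscillating strongly, and the package reproduces the same
qualitative optimizer ordering under both settings.

**Modified use-dependent-learning (UDL) model.** A second-order linear
learner with reference movement `x0`, planned movement `x`, stimulus
sensitivity `d` and target response `y_obj = 1`:

    x0(n+1) = a·x0(n) + (1−a)·y(n)
    x(n+1)  = b·x(n) + c·y(n) + (1−b−c)·x0(n)
    y(n+1)  = x(n+1) + d·u(n+1)

Its state matrix `A' = [[a, 1−a], [1−b−c, b+c]]` has row sums 1, so every
parameterization carries an eigenvalue-1 mode — the learner never fully
forgets. Six presets span slow/fast positive and negative learning, a
stationary no-learning control and pure adaptation; saturation limits are
|u| < 3 (models 1, 2, 5) or |u| < 10 (models 3, 4, 6). The optimizer
minimizes the squared target miss `(y−1)²` of the *measured* (noisy)
response. Measurement noise is added to the output seen by the optimizer
only; the learner's own recursion uses the noise-free output (a switch
feeds the noisy output back instead). Initial state is quiescent
(`x0 = x = y(0) = 0`).

**Ground truth.** Each trial records the input that would have achieved the
target from the subject's actual state (inverting the output map), *clipped
to the saturation limits*, together with the attainable noise-free output at
that feasible input. The clipping matters only for the fast negative
learner: under faithful tracking its unconstrained target-achieving input
crosses the |u| = 10 limit near iteration 30 and grows without bound
afterwards, so an infeasible benchmark would assign every optimizer an
unboundedly growing error — and the better tracker, which accelerates the
learner's drift, the largest one. Benchmark errors are the four absolute
deviations: applied input and measured output against the feasible optimum
(implementation outcomes), and the estimated optimal input and its
noise-free counterfactual response against the same (estimation outcomes).

## Experiment protocol and seeds

A repetition draws three initial inputs uniformly from the saturation range
and evaluates them on the subject; every optimizer variant in that
repetition starts from the identical three (input, response) pairs,
including identical measurement-noise draws. The initial design occupies
iteration indices −2, −1, 0; optimization iterations are 1..N (100 for the
time-dependent system, 200 for the learners). After each observation the
optimizer re-fits, updates its optimum estimate, and proposes the next
input through the safeguard.

The master seed spawns one stream per repetition for the shared initial
design and independent per-repetition, per-variant streams for subsequent
measurement noise and for the multi-start randomness — so results are fully
deterministic given the master seed, and variants within a repetition share
exactly the initial information. By default each repetition draws fresh
initial inputs (shared across variants); a switch fixes one triple across
all repetitions instead. Per-repetition variation is the default because it
gives the iteration-wise ANOVA a non-degenerate error term.

## Statistical analysis

At every iteration the four variants form a balanced 2×2 design (optimizer
type × e-ratio) with one replicate per repetition. A classical
sums-of-squares two-way fixed-effects ANOVA is computed per iteration
(verified against a general-linear-model oracle and by the partition
identity); significant effects are followed by two-sample t tests with
direction. Significance is uncorrected α = 0.05 per iteration, with no
across-iteration multiplicity correction; outcomes enter untransformed.
Zero within-cell variance is flagged as degenerate (p set to 0 or 1 by
whether the effect sum of squares is positive).

Per-iteration significance series are condensed into: the first iteration
of the terminal run of "significant with DBO lower" extending to the final
iteration (a configurable number of gap iterations may be tolerated,
default 0); the fraction of iterations past a cutoff that are significant
with DBO lower; and the smallest cutoff whose post-cutoff fraction reaches
80%.

## What the simulations do and do not show

The virtual subjects are noiseless low-order linear learners plus additive
Gaussian measurement noise. They emulate trial-by-trial drift of the
input–response relationship — the feature that separates DBO from BO — but
not input-variance-dependent behavior (e.g. co-contraction under
unpredictable stimuli), fatigue, or inter-individual parameter variability.
Passing benchmarks therefore demonstrate correct closed-loop machinery and
the qualitative BO/DBO contrast under drift, not performance on real human
data.

Two quantitative caveats follow from the design decisions above and are
visible in the shipped benchmark statistics. First, because the forgetting
factor is a constant, the dynamic variant keeps probing even when the
subject happens to be stationary; its implemented inputs then differ
measurably from static BO's on the no-learning control, where an optimizer
with an adaptively vanishing α would not. Second, the onset of statistically
detectable DBO superiority on the time-dependent system occurs within the
first few iterations here; reconstructions with different (unreported)
hyperparameter-adjustment details can delay that onset by ten or more
iterations without changing the steady-state ordering.

## Problem sizes

The shipped acceptance computation uses 60 repetitions of the
time-dependent experiment and 25/12/12 repetitions of the fast-positive /
fast-negative / no-learning learner experiments (full iteration counts
everywhere). These sizes keep the complete recomputation near a quarter
hour on one CPU while leaving the median/proportion summaries stable; the
configuration files accept any repetition count.
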