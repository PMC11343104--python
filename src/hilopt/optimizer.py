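"""Bayesian-optimization decision loop with an overexploitation safeguard.

The optimizer maintains a spatiotemporal GP surrogate over (input, iteration)
pairs and proposes the next input by maximizing Expected Improvement on a
dense candidate grid.  A proposal is flagged as *overexploitation* when the
posterior function standard deviation at the proposed point falls below
``e_ratio`` times the observation-noise standard deviation; flagged proposals
trigger a hyperparameter re-fit under progressively tightened length-scale
bounds, falling back to the maximum-uncertainty grid point.

Two variants share this loop: static BO (temporal forgetting factor pinned to
zero, so observation times are ignored) and dynamic BO (the forgetting factor
is fitted, letting the surrogate discount stale observations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import ndtr

from .gp import (
    GaussianProcess,
    HyperparamBounds,
    KernelHyperparams,
    ObservationSet,
    fit,
    optimize_hyperparams,
)

__all__ = [
    "OptimizerConfig",
    "BayesOptimizer",
    "expected_improvement",
    "check_overexploitation",
]

_SQRT2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class OptimizerConfig:
    """Configuration of one optimizer variant.

    Parameters
    ----------
    dynamic
        Use the time-discounting kernel (dynamic BO) instead of pinning the
        forgetting factor to zero (static BO).
    alpha
        Forgetting factor of the dynamic variant, treated as a model constant
        (the rate at which past observations are discounted is not reliably
        identifiable from closed-loop data, so it is specified a priori as in
        the time-varying bandit literature).  Ignored by the static variant.
    fit_alpha
        Fit the forgetting factor by marginal likelihood within the
        ``hyperparam_bounds.alpha`` interval instead of pinning it to
        ``alpha``.  Off by default: the marginal likelihood admits a
        degenerate near-static ridge (tiny alpha, inflated signal variance)
        under adaptively sampled data, which collapses DBO onto BO.
    e_ratio
        Exploration-exploitation ratio in (0, 1]: threshold multiplier on the
        noise standard deviation below which a proposal is flagged as
        overexploitation.
    input_bounds
        Closed saturation interval per input dimension, ``(lo, hi)`` or a
        sequence of such pairs.
    grid_size
        Candidate-grid resolution per input dimension.
    n_initial
        Number of random initial inputs expected before optimization starts.
    hyperparam_bounds
        Box constraints for marginal-likelihood fitting.  The alpha interval
        only applies to the dynamic variant.
    max_overexploitation_retries
        Bound on the refit-and-repropose loop.
    full_refit_every
        Period (in iterations) of full multi-start hyperparameter searches;
        in between, a single warm-started search keeps the fit current at a
        fraction of the cost.
    refit_on_flag_only
        If set, hyperparameters are refit only when overexploitation is
        flagged (the GP itself is still rebuilt each iteration).
    overexploitation_sigma
        Which scale the overexploitation flag compares the posterior function
        sd against: ``"signal"`` (the prior sd, i.e. the square root of the
        kernel signal variance; default — the flag then reads "posterior
        uncertainty at the proposal has collapsed below fraction e of prior
        uncertainty"), ``"noise"`` (the fitted observation-noise sd) or
        ``"model"`` (the square root of the model variance at the proposal).
    overexploitation_fallback
        What to do when the proposal is still flagged after all retries:
        ``"accept"`` (default) applies it anyway — repeated flagging then
        nudges rather than overrides the acquisition, so a static optimizer
        can still fixate on a stale optimum; ``"max_variance"`` overrides the
        proposal with the most uncertain grid point (forced exploration).
    """

    dynamic: bool = False
    alpha: float = 0.05
    fit_alpha: bool = False
    e_ratio: float = 0.2
    input_bounds: tuple = (-15.0, 15.0)
    grid_size: int = 301
    n_initial: int = 3
    hyperparam_bounds: HyperparamBounds = field(default_factory=HyperparamBounds)
    max_overexploitation_retries: int = 1
    seed: int = 0
    n_starts: int = 3
    full_refit_every: int = 50
    warm_maxiter: int = 5
    full_maxiter: int = 30
    refit_on_flag_only: bool = False
    overexploitation_sigma: str = "signal"
    overexploitation_fallback: str = "accept"

    def __post_init__(self) -> None:
        if not (0.0 < self.e_ratio <= 1.0):
            raise ValueError("e_ratio must lie in (0, 1]")
        b = np.atleast_2d(np.asarray(self.input_bounds, dtype=float))
        if b.shape[1] != 2 or np.any(b[:, 0] >= b[:, 1]):
            raise ValueError("input_bounds must be (lo, hi) pairs with lo < hi")
        object.__setattr__(self, "input_bounds", tuple(map(tuple, b)))
        if self.overexploitation_sigma not in ("signal", "noise", "model"):
            raise ValueError("overexploitation_sigma must be 'signal', 'noise' or 'model'")
        if self.overexploitation_fallback not in ("accept", "max_variance"):
            raise ValueError("overexploitation_fallback must be 'accept' or 'max_variance'")

    @property
    def bounds_array(self) -> np.ndarray:
        return np.asarray(self.input_bounds, dtype=float)


def expected_improvement(model: GaussianProcess, u, t_query, incumbent: float) -> float:
    """Closed-form Expected Improvement (minimization) at one query point."""
    p = model.predict(u, t_query)
    return float(_ei(np.array([p.mean]), np.array([np.sqrt(p.function_variance)]), incumbent)[0])


def _ei(mu: np.ndarray, sigma: np.ndarray, incumbent: float) -> np.ndarray:
    imp = incumbent - mu
    out = np.maximum(imp, 0.0)
    pos = sigma > 0.0
    if np.any(pos):
        z = imp[pos] / sigma[pos]
        out[pos] = imp[pos] * ndtr(z) + sigma[pos] * np.exp(-0.5 * z * z) / _SQRT2PI
    return np.clip(out, 0.0, None)


def check_overexploitation(
    model: GaussianProcess, u_next, t_next, e_ratio: float, sigma: str = "signal"
) -> bool:
    """Flag a proposal whose posterior function sd is below ``e_ratio * sigma``."""
    p = model.predict(u_next, t_next)
    sg = np.sqrt(p.function_variance)
    if sigma == "signal":
        ref = np.sqrt(model.hyperparams.signal_variance)
    elif sigma == "model":
        ref = np.sqrt(p.model_variance)
    else:
        ref = np.sqrt(model.hyperparams.noise_variance)
    return bool(sg < e_ratio * ref)


def _candidate_grid(bounds: np.ndarray, grid_size: int) -> np.ndarray:
    axes = [np.linspace(lo, hi, grid_size) for lo, hi in bounds]
    if len(axes) == 1:
        return axes[0][:, None]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


class BayesOptimizer:
    """Stateful BO/DBO loop over a bounded input space.

    Typical use::

        opt = BayesOptimizer(config)
        opt.initialize(initial_inputs, initial_outputs)
        for i in range(n_iterations):
            u = opt.propose()
            y = subject(u)
            opt.tell(u, y)
            estimate = opt.estimated_input

    Iteration bookkeeping follows the convention that the ``n_initial``
    seeding observations occupy times ``-(n_initial-1) .. 0`` and optimization
    iterations are ``1 .. N``.
    """

    def __init__(self, config: OptimizerConfig, rng: Optional[np.random.Generator] = None):
        self.config = config
        self.rng = np.random.default_rng(config.seed) if rng is None else rng
        self.grid = _candidate_grid(config.bounds_array, config.grid_size)
        self.observations: Optional[ObservationSet] = None
        self.hyperparams: Optional[KernelHyperparams] = None
        self.model: Optional[GaussianProcess] = None
        self.iteration = 0
        self.estimated_input: Optional[np.ndarray] = None
        self.estimated_value: Optional[float] = None
        self._last_proposal: Optional[np.ndarray] = None

    # -- fitting -----------------------------------------------------------

    def _fit_bounds(self, shrink: float = 1.0) -> HyperparamBounds:
        b = self.config.hyperparam_bounds
        if shrink < 1.0:
            # tighten relative to the current fitted length scale so the
            # adjustment always binds, sharpening the model locally
            cur = max(self.hyperparams.length_scales)
            lo, hi = b.length_scale
            b = replace(b, length_scale=(lo, max(lo, min(hi, cur * shrink))))
        return b

    def _refit_hyperparams(self, full: bool, shrink: float = 1.0) -> None:
        if not self.config.dynamic:
            fixed = {"alpha": 0.0}
        elif self.config.fit_alpha:
            fixed = {}
        else:
            fixed = {"alpha": self.config.alpha}
        self.hyperparams = optimize_hyperparams(
            self.observations,
            self._fit_bounds(shrink),
            fixed=fixed,
            initial=self.hyperparams,
            n_starts=self.config.n_starts if full else 1,
            rng=self.rng,
            maxiter=self.config.full_maxiter if full else self.config.warm_maxiter,
        )

    def _rebuild(self) -> None:
        self.model = fit(self.observations, self.hyperparams)

    # -- public protocol ---------------------------------------------------

    def initialize(self, inputs, outputs, times=None) -> None:
        """Ingest the random seeding design and fit the first surrogate."""
        inputs = np.atleast_2d(np.asarray(inputs, dtype=float).T).T
        if inputs.ndim == 1:
            inputs = inputs[:, None]
        n = len(inputs)
        if times is None:
            times = np.arange(-(n - 1), 1)
        self.observations = ObservationSet(inputs, times, outputs)
        self.iteration = 0
        self._refit_hyperparams(full=True)
        self._rebuild()
        self._update_estimate()

    def _incumbent(self, t: float) -> float:
        mu = self.model.predict_mean(self.observations.inputs, t)
        return float(mu.min())

    def _propose_on_grid(self, t_next: float) -> tuple[np.ndarray, np.ndarray]:
        mu, fvar = self.model.predict_batch(self.grid, t_next)
        incumbent = self._incumbent(float(self.iteration))
        ei = _ei(mu, np.sqrt(fvar), incumbent)
        best = ei == ei.max()
        if best.sum() > 1:  # ties: lowest posterior mean, then lowest input
            idx = np.flatnonzero(best)
            idx = idx[mu[idx] == mu[idx].min()]
            i = int(idx[0])
        else:
            i = int(np.argmax(best))
        return self.grid[i].copy(), fvar

    def propose(self) -> np.ndarray:
        """Next input to test, passed through the overexploitation safeguard."""
        t_next = float(self.iteration + 1)
        u, fvar = self._propose_on_grid(t_next)
        cfg = self.config
        flagged = check_overexploitation(self.model, u, t_next, cfg.e_ratio, cfg.overexploitation_sigma)
        shrink = 1.0
        for _ in range(cfg.max_overexploitation_retries):
            if not flagged:
                break
            shrink *= 0.5
            self._refit_hyperparams(full=False, shrink=shrink)
            self._rebuild()
            u, fvar = self._propose_on_grid(t_next)
            flagged = check_overexploitation(self.model, u, t_next, cfg.e_ratio, cfg.overexploitation_sigma)
        if flagged and cfg.overexploitation_fallback == "max_variance":
            _, fvar = self.model.predict_batch(self.grid, t_next)
            u = self.grid[int(np.argmax(fvar))].copy()
        b = cfg.bounds_array
        u = np.clip(u, b[:, 0], b[:, 1])
        self._last_proposal = u
        return u

    def tell(self, u, y: float) -> None:
        """Record the observed output for input ``u`` at the next iteration."""
        self.iteration += 1
        self.observations = self.observations.append(u, self.iteration, y)
        cfg = self.config
        if not cfg.refit_on_flag_only:
            full = cfg.full_refit_every > 0 and self.iteration % cfg.full_refit_every == 0
            self._refit_hyperparams(full=full)
        self._rebuild()
        self._update_estimate()

    def step(self, observed_output: float) -> np.ndarray:
        """Record the output of the last proposal and return the next input."""
        if self._last_proposal is None:
            raise RuntimeError("step() requires a preceding propose()")
        self.tell(self._last_proposal, observed_output)
        return self.propose()

    def _update_estimate(self) -> None:
        mu = self.model.predict_mean(self.grid, float(self.iteration))
        i = int(np.argmin(mu))  # ties resolve to the lowest input (grid order)
        b = self.config.bounds_array
        self.estimated_input = np.clip(self.grid[i], b[:, 0], b[:, 1])
        self.estimated_value = float(mu[i])

    def estimate_optimum(self) -> tuple[np.ndarray, float]:
        """Current argmin of the posterior mean over the candidate grid."""
        return self.estimated_input.copy(), self.estimated_value
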