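"""Gaussian-process regression with a separable input x iteration-time kernel.

The surrogate used by both optimizer variants is a zero-mean (after centering)
Gaussian process whose covariance is the product of a squared-exponential term
over the input space and a geometric decay term over the iteration index,

    k((u, t), (u', t')) = sigma2 * exp(-sum_p (u_p - u'_p)^2 / (2 l_p^2))
                          * (1 - alpha)^|t - t'|,

with ``alpha = 0`` recovering an ordinary time-agnostic kernel.  Observation
noise enters as an additive diagonal term, kept distinct from the signal
variance prefactor.  The *model variance* at a query point is the posterior
function variance plus the observation-noise variance.

Hyperparameters are selected by maximizing the log marginal likelihood with a
bounded multi-start quasi-Newton search in log space (alpha is optimized on
its natural scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.linalg.lapack import dpotrf, dpotri

__all__ = [
    "KernelHyperparams",
    "HyperparamBounds",
    "ObservationSet",
    "GPPrediction",
    "GaussianProcess",
    "static_kernel",
    "temporal_kernel",
    "composite_kernel",
    "fit",
    "optimize_hyperparams",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class KernelHyperparams:
    """Hyperparameters of the separable spatiotemporal kernel.

    Parameters
    ----------
    length_scales
        One positive length scale per input dimension.
    signal_variance
        Prefactor of the squared-exponential term (> 0).
    alpha
        Temporal forgetting factor in [0, 1); 0 disables time discounting.
    noise_variance
        Variance of the additive observation noise (>= 0).
    """

    length_scales: tuple[float, ...]
    signal_variance: float
    alpha: float = 0.0
    noise_variance: float = 0.0

    def __post_init__(self) -> None:
        ls = tuple(float(v) for v in np.atleast_1d(self.length_scales))
        if any(v <= 0 for v in ls):
            raise ValueError("length scales must be positive")
        object.__setattr__(self, "length_scales", ls)
        object.__setattr__(self, "signal_variance", float(self.signal_variance))
        object.__setattr__(self, "alpha", float(self.alpha))
        object.__setattr__(self, "noise_variance", float(self.noise_variance))
        if self.signal_variance <= 0:
            raise ValueError("signal_variance must be positive")
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must lie in [0, 1)")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be non-negative")

    @property
    def ndim(self) -> int:
        return len(self.length_scales)


@dataclass(frozen=True)
class HyperparamBounds:
    """Box bounds for marginal-likelihood hyperparameter fitting.

    ``length_scale``, ``signal_variance`` and ``noise_variance`` are searched
    in log space; ``alpha`` on its natural scale within ``[alpha[0], alpha[1]]``.
    A degenerate interval (lo == hi) pins the corresponding hyperparameter.
    """

    length_scale: tuple[float, float] = (1e-2, 1e2)
    signal_variance: tuple[float, float] = (1e-6, 1e6)
    noise_variance: tuple[float, float] = (1e-6, 1.0)
    alpha: tuple[float, float] = (0.0, 0.95)

    def __post_init__(self) -> None:
        for name in ("length_scale", "signal_variance", "noise_variance", "alpha"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} bounds inverted: {lo} > {hi}")
        if self.length_scale[0] <= 0 or self.signal_variance[0] <= 0:
            raise ValueError("log-space bounds require positive lower limits")
        if self.noise_variance[0] < 0:
            raise ValueError("noise_variance lower bound must be >= 0")
        if not (0.0 <= self.alpha[0] and self.alpha[1] < 1.0):
            raise ValueError("alpha bounds must lie in [0, 1)")

    def shrink_length_scale_upper(self, factor: float) -> "HyperparamBounds":
        lo, hi = self.length_scale
        return replace(self, length_scale=(lo, max(lo, hi * factor)))


class ObservationSet:
    """History of (input, iteration-time, output) triples seen by an optimizer.

    Inputs are stored as an (n, r) array, times as integers (the iteration
    index at which each observation was collected; the initial design occupies
    non-positive indices by convention) and outputs as a flat array.  Times
    must be non-decreasing.
    """

    __slots__ = ("inputs", "times", "outputs")

    def __init__(self, inputs, times, outputs) -> None:
        X = np.asarray(inputs, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        t = np.asarray(times)
        y = np.asarray(outputs, dtype=float)
        if not (len(X) == len(t) == len(y)):
            raise ValueError(
                f"inputs ({len(X)}), times ({len(t)}) and outputs ({len(y)}) "
                "must have equal length"
            )
        if t.ndim != 1 or y.ndim != 1:
            raise ValueError("times and outputs must be one-dimensional")
        if len(t) and np.any(np.diff(t) < 0):
            raise ValueError("times must be non-decreasing")
        self.inputs = X
        self.times = t.astype(float)
        self.outputs = y

    def __len__(self) -> int:
        return len(self.outputs)

    @property
    def ndim(self) -> int:
        return self.inputs.shape[1]

    def append(self, u, t, y) -> "ObservationSet":
        """Return a new set with one more observation."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        return ObservationSet(
            np.vstack([self.inputs, u[None, :]]),
            np.append(self.times, float(t)),
            np.append(self.outputs, float(y)),
        )


@dataclass(frozen=True)
class GPPrediction:
    """Posterior prediction: mean, function variance and model variance.

    ``model_variance`` is exactly ``function_variance + noise_variance``.
    """

    mean: float
    function_variance: float
    model_variance: float


def static_kernel(u1, u2, hp: KernelHyperparams) -> float:
    """Squared-exponential covariance between two input vectors."""
    u1 = np.atleast_1d(np.asarray(u1, dtype=float))
    u2 = np.atleast_1d(np.asarray(u2, dtype=float))
    if u1.shape != u2.shape or u1.shape[0] != hp.ndim:
        raise ValueError(
            f"input dimension mismatch: got {u1.shape[0]} and {u2.shape[0]}, "
            f"kernel has {hp.ndim} length scale(s)"
        )
    d = (u1 - u2) / np.asarray(hp.length_scales)
    return float(hp.signal_variance * np.exp(-0.5 * np.dot(d, d)))


def temporal_kernel(t1, t2, alpha: float) -> float:
    """Geometric time-decay covariance ``(1 - alpha)^|t1 - t2|``."""
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must lie in [0, 1)")
    return float((1.0 - alpha) ** abs(float(t1) - float(t2)))


def composite_kernel(u1, t1, u2, t2, hp: KernelHyperparams) -> float:
    """Product of the static and temporal kernel components."""
    return static_kernel(u1, u2, hp) * temporal_kernel(t1, t2, hp.alpha)


def _cross_cov(X1, t1, X2, t2, hp: KernelHyperparams) -> np.ndarray:
    """Dense covariance block between two sets of (input, time) pairs."""
    ls = np.asarray(hp.length_scales)
    d = (X1[:, None, :] - X2[None, :, :]) / ls
    Q = -0.5 * np.einsum("ijk,ijk->ij", d, d)
    if hp.alpha > 0.0:
        Q += np.log(1.0 - hp.alpha) * np.abs(t1[:, None] - t2[None, :])
    return hp.signal_variance * np.exp(Q)


class GaussianProcess:
    """A fitted GP over (input, iteration-time) pairs.

    The prior mean is the sample mean of the outputs (outputs are centered
    before fitting; predictions add the mean back).  On Cholesky failure a
    jitter of ``1e-10 * signal_variance`` is added to the diagonal, escalating
    tenfold up to ``1e-6 * signal_variance`` before giving up.
    """

    def __init__(self, obs: ObservationSet, hp: KernelHyperparams, center: bool = True):
        if len(obs) == 0:
            raise ValueError("cannot fit a GP to an empty observation set")
        self.obs = obs
        self.hyperparams = hp
        self.y_mean = float(obs.outputs.mean()) if center else 0.0
        self._yc = obs.outputs - self.y_mean
        K = _cross_cov(obs.inputs, obs.times, obs.inputs, obs.times, hp)
        K[np.diag_indices_from(K)] += hp.noise_variance
        self._chol, self.jitter = _chol_with_jitter(K, hp.signal_variance)
        self._alpha_vec = cho_solve(self._chol, self._yc)
        self._lml: Optional[float] = None

    def _kstar(self, U: np.ndarray, t: float) -> np.ndarray:
        U = np.asarray(U, dtype=float)
        if U.ndim == 1:
            U = U[:, None]
        tq = np.full(len(U), float(t))
        return _cross_cov(U, tq, self.obs.inputs, self.obs.times, self.hyperparams)

    def predict_mean(self, U, t) -> np.ndarray:
        """Posterior mean only (cheaper than ``predict_batch``)."""
        return self.y_mean + self._kstar(U, t) @ self._alpha_vec

    def predict_batch(self, U, t) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and function variance at many inputs, one query time."""
        Ks = self._kstar(U, t)
        mean = self.y_mean + Ks @ self._alpha_vec
        v = cho_solve(self._chol, Ks.T)
        fvar = self.hyperparams.signal_variance - np.einsum("ij,ji->i", Ks, v)
        np.clip(fvar, 0.0, None, out=fvar)
        return mean, fvar

    def predict(self, u, t) -> GPPrediction:
        """Posterior prediction at a single (input, time) query."""
        mean, fvar = self.predict_batch(np.atleast_1d(u)[None, :] if np.ndim(u) else np.array([[u]]), t)
        fv = float(fvar[0])
        return GPPrediction(
            mean=float(mean[0]),
            function_variance=fv,
            model_variance=fv + self.hyperparams.noise_variance,
        )

    def log_marginal_likelihood(self) -> float:
        """Gaussian log marginal likelihood of the (centered) outputs."""
        if self._lml is None:
            L = self._chol[0]
            n = len(self.obs)
            self._lml = float(
                -0.5 * self._yc @ self._alpha_vec
                - np.log(np.diag(L)).sum()
                - 0.5 * n * _LOG2PI
            )
        return self._lml


def fit(obs: ObservationSet, hp: KernelHyperparams, center: bool = True) -> GaussianProcess:
    """Factorize the kernel matrix and return a prediction-ready model handle."""
    return GaussianProcess(obs, hp, center=center)


def _chol_with_jitter(K: np.ndarray, signal_variance: float):
    jitter = 0.0
    try:
        return cho_factor(K, lower=True), jitter
    except LinAlgError:
        pass
    jitter = 1e-10 * signal_variance
    while jitter <= 1e-6 * signal_variance:
        try:
            Kj = K.copy()
            Kj[np.diag_indices_from(Kj)] += jitter
            return cho_factor(Kj, lower=True), jitter
        except LinAlgError:
            jitter *= 10.0
    raise LinAlgError("covariance matrix numerically singular even with jitter")


def _nll_grad_kernel(diffsq, absdt, yc, inv_ls2, sv, nv, alpha, free_alpha, jitter):
    """Negative log marginal likelihood and gradient (dense inner loop).

    Gradient order: log length scales (r entries), log signal variance,
    log noise variance, then alpha when ``free_alpha``.  The covariance
    inverse is formed from the Cholesky factor (LAPACK dpotri), which is the
    dominant cost at O(n^3/3).
    """
    r, n, _ = diffsq.shape
    Q = (-0.5 * inv_ls2[0]) * diffsq[0]
    for p in range(1, r):
        Q += (-0.5 * inv_ls2[p]) * diffsq[p]
    if alpha > 0.0:
        Q += np.log(1.0 - alpha) * absdt
    S = sv * np.exp(Q)
    K = S.copy()
    K.flat[:: n + 1] += nv + jitter
    c, info = dpotrf(K, lower=1, overwrite_a=1)
    if info != 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    logdet = np.log(np.diag(c)).sum()
    Ki, info = dpotri(c, lower=1, overwrite_c=1)
    if info != 0:
        raise np.linalg.LinAlgError("covariance inversion failed")
    Kinv = np.tril(Ki) + np.tril(Ki, -1).T
    a = Kinv @ yc
    nll = 0.5 * yc @ a + logdet + 0.5 * n * _LOG2PI
    M = np.outer(a, a)
    M -= Kinv
    MS = M * S
    grad = np.empty(r + 2 + (1 if free_alpha else 0))
    for p in range(r):
        grad[p] = -0.5 * np.sum(MS * diffsq[p]) * inv_ls2[p]
    grad[r] = -0.5 * MS.sum()
    grad[r + 1] = -0.5 * nv * np.trace(M)
    if free_alpha:
        grad[r + 2] = 0.5 * np.sum(MS * absdt) / (1.0 - alpha)
    return nll, grad


class _MarginalLikelihoodProblem:
    """Negative log marginal likelihood and its gradient, with cached geometry.

    The squared input differences and absolute time differences do not depend
    on the hyperparameters, so they are computed once per observation set and
    reused across all optimizer evaluations.  Free parameters are, in order:
    log length scales (one per input dimension), log signal variance, log
    noise variance, and (when free) alpha on its natural scale.
    """

    def __init__(self, obs: ObservationSet, center: bool = True):
        X, t = obs.inputs, obs.times
        self.n, self.r = X.shape
        d = X[:, None, :] - X[None, :, :]
        self.diffsq = np.ascontiguousarray(np.moveaxis(d * d, -1, 0))  # (r, n, n)
        self.absdt = np.ascontiguousarray(np.abs(t[:, None] - t[None, :]), dtype=float)
        y = obs.outputs
        self.yc = np.ascontiguousarray(y - y.mean() if center else y, dtype=float)

    def value_and_grad(self, log_ls, log_sv, log_nv, alpha, free_alpha):
        inv_ls2 = np.exp(-2.0 * np.atleast_1d(np.asarray(log_ls, dtype=float)))
        sv = float(np.exp(log_sv))
        nv = float(np.exp(log_nv))
        jitter = 0.0
        while True:
            try:
                nll, grad = _nll_grad_kernel(
                    self.diffsq, self.absdt, self.yc, inv_ls2, sv, nv,
                    float(alpha), bool(free_alpha), jitter,
                )
                return float(nll), grad
            except np.linalg.LinAlgError:
                jitter = 1e-10 * sv if jitter == 0.0 else jitter * 10.0
                if jitter > 1e-6 * sv:
                    raise LinAlgError("covariance singular during hyperparameter fit")


def optimize_hyperparams(
    obs: ObservationSet,
    bounds: HyperparamBounds = HyperparamBounds(),
    fixed: Optional[dict] = None,
    initial: Optional[KernelHyperparams] = None,
    n_starts: int = 3,
    rng: Optional[np.random.Generator] = None,
    maxiter: int = 40,
    center: bool = True,
) -> KernelHyperparams:
    """Maximize the log marginal likelihood over the kernel hyperparameters.

    Parameters
    ----------
    obs
        Observation set to fit.
    bounds
        Box constraints; degenerate intervals pin a hyperparameter.
    fixed
        Mapping from hyperparameter name (``length_scales``, ``signal_variance``,
        ``noise_variance``, ``alpha``) to a pinned value.
    initial
        Warm-start point used as the first of ``n_starts`` starts.
    n_starts
        Number of local searches; starts beyond the first (and beyond the
        warm start) are drawn uniformly in log space from ``rng``.
    rng
        Source of randomness for the extra starts (seeded for determinism).

    Returns
    -------
    KernelHyperparams maximizing the marginal likelihood among all starts.
    If every local search fails, the best candidate evaluated so far is
    returned with a warning.
    """
    fixed = dict(fixed or {})
    rng = np.random.default_rng(0) if rng is None else rng
    r = obs.ndim

    def interval(name):
        lo, hi = getattr(bounds, name)
        return float(lo), float(hi)

    ls_lo, ls_hi = interval("length_scale")
    sv_lo, sv_hi = interval("signal_variance")
    nv_lo, nv_hi = interval("noise_variance")
    al_lo, al_hi = interval("alpha")

    fixed_ls = None
    if "length_scales" in fixed:
        fixed_ls = tuple(float(v) for v in np.atleast_1d(fixed["length_scales"]))
    free_ls = fixed_ls is None and ls_lo < ls_hi
    free_sv = "signal_variance" not in fixed and sv_lo < sv_hi
    free_nv = "noise_variance" not in fixed and nv_lo < nv_hi
    free_al = "alpha" not in fixed and al_lo < al_hi

    pin_ls = fixed_ls if fixed_ls is not None else (np.sqrt(ls_lo * ls_hi),) * r
    pin_sv = float(fixed.get("signal_variance", np.sqrt(sv_lo * sv_hi)))
    pin_nv = float(fixed.get("noise_variance", np.sqrt(max(nv_lo, 1e-12) * nv_hi)))
    pin_al = float(fixed.get("alpha", al_lo))

    if not (free_ls or free_sv or free_nv or free_al):
        return KernelHyperparams(pin_ls, pin_sv, pin_al, pin_nv)

    problem = _MarginalLikelihoodProblem(obs, center=center)

    def unpack(theta):
        i = 0
        if free_ls:
            log_ls = theta[i : i + r]
            i += r
        else:
            log_ls = np.log(pin_ls)
        log_sv = theta[i] if free_sv else np.log(pin_sv)
        i += free_sv
        log_nv = theta[i] if free_nv else np.log(max(pin_nv, 1e-300))
        i += free_nv
        alpha = theta[i] if free_al else pin_al
        return np.atleast_1d(log_ls), float(log_sv), float(log_nv), float(alpha)

    def objective(theta):
        log_ls, log_sv, log_nv, alpha = unpack(theta)
        try:
            nll, g = problem.value_and_grad(log_ls, log_sv, log_nv, alpha, free_alpha=free_al)
        except LinAlgError:
            return 1e25, np.zeros_like(theta)
        # project full gradient onto the free coordinates
        grad = []
        if free_ls:
            grad.extend(g[:r])
        if free_sv:
            grad.append(g[r])
        if free_nv:
            grad.append(g[r + 1])
        if free_al:
            grad.append(g[r + 2])
        return nll, np.asarray(grad)

    box = []
    if free_ls:
        box += [(np.log(ls_lo), np.log(ls_hi))] * r
    if free_sv:
        box.append((np.log(sv_lo), np.log(sv_hi)))
    if free_nv:
        box.append((np.log(max(nv_lo, 1e-12)), np.log(nv_hi)))
    if free_al:
        box.append((al_lo, al_hi))
    box = np.asarray(box)

    starts = []
    if initial is not None:
        th = []
        if free_ls:
            th.extend(np.log(np.clip(initial.length_scales, ls_lo, ls_hi)))
        if free_sv:
            th.append(np.log(np.clip(initial.signal_variance, sv_lo, sv_hi)))
        if free_nv:
            th.append(np.log(np.clip(max(initial.noise_variance, nv_lo), max(nv_lo, 1e-12), nv_hi)))
        if free_al:
            th.append(np.clip(initial.alpha, al_lo, al_hi))
        starts.append(np.asarray(th))
    else:
        starts.append(box.mean(axis=1))
    while len(starts) < n_starts:
        starts.append(rng.uniform(box[:, 0], box[:, 1]))

    best_theta, best_val, any_success = None, np.inf, False
    for th0 in starts:
        v0, _ = objective(th0)
        if v0 < best_val:
            best_theta, best_val = th0, v0
        try:
            res = optimize.minimize(
                objective, th0, jac=True, method="L-BFGS-B", bounds=box,
                options={"maxiter": maxiter, "maxfun": 2 * maxiter},
            )
        except (LinAlgError, FloatingPointError):
            continue
        if np.isfinite(res.fun) and res.fun < best_val:
            best_theta, best_val = res.x, float(res.fun)
        any_success = any_success or np.isfinite(res.fun)
    if not any_success:
        warnings.warn(
            "all marginal-likelihood searches failed; returning best evaluated "
            "candidate", RuntimeWarning,
        )

    log_ls, log_sv, log_nv, alpha = unpack(best_theta)
    return KernelHyperparams(
        tuple(np.exp(log_ls)), float(np.exp(log_sv)), float(alpha), float(np.exp(log_nv))
    )
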