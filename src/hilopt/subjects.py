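"""Virtual human response generators for closed-loop optimizer benchmarking.

Two families are provided:

* An explicitly time-dependent zero-order system whose optimal input and
  optimal output drift along a decaying oscillating exponential; the response
  deviates quadratically from the optimum and carries additive Gaussian
  measurement noise.
* A modified use-dependent-learning (UDL) model: a second-order linear
  state-space learner with a drifting reference movement ``x0``, a planned
  movement ``x`` biased toward previously produced outputs, and a direct
  input sensitivity ``d``.  Six named presets span slow/fast positive and
  negative learning, a stationary no-learning control, and pure adaptation.

Both generators expose the ground truth (the input that would currently be
optimal and the associated optimal output) so a simulation pipeline can score
an optimizer without the optimizer itself having access to it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "ExplicitTimeSystemParams",
    "explicit_optimal",
    "explicit_respond",
    "LinearStateSpace",
    "ModifiedUDLParams",
    "UDLState",
    "udl_step",
    "udl_matrices",
    "udl_optimal_input",
    "udl_counterfactual_response",
    "simulate_protocol",
    "training_protocol_schedule",
    "MODEL_PRESETS",
    "get_preset",
]


# ---------------------------------------------------------------------------
# Explicitly time-dependent system
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExplicitTimeSystemParams:
    """Parameters of the explicitly time-dependent response.

    ``osc_coefficient`` multiplies the sine term of the optimal-output drift.
    ``bounds`` are the bilateral input saturation limits.
    """

    noise_sd: float = 0.1
    osc_coefficient: float = 13.0
    bounds: tuple[float, float] = (-15.0, 15.0)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def explicit_optimal(i, params: ExplicitTimeSystemParams = ExplicitTimeSystemParams()):
    """Optimal input and output of the time-dependent system at iteration ``i``.

    The three seeding trials occupy iterations -2, -1, 0 and the optimization
    iterations 1..N, so the physical trial number is ``i + 3 >= 1``.
    """
    i = np.asarray(i, dtype=float)
    if np.any(i + 3 < 0):
        raise ValueError("iteration index must satisfy i >= -3")
    decay = np.exp(-(i + 3.0) / 15.0)
    osc = np.sin(np.pi * (i + 3.0) / 5.0)
    u_opt = 5.0 + 10.0 * decay + 0.2 * osc
    y_opt = 5.0 + 5.0 * decay - params.osc_coefficient * osc
    if np.ndim(u_opt) == 0:
        return float(u_opt), float(y_opt)
    return u_opt, y_opt


def explicit_respond(
    i,
    u,
    params: ExplicitTimeSystemParams = ExplicitTimeSystemParams(),
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Noisy measured response at iteration ``i`` to input ``u``.

    The response equals the optimal output plus a quadratic penalty on the
    distance from the optimal input, plus N(0, noise_sd^2) measurement noise.
    """
    u_opt, y_opt = explicit_optimal(i, params)
    y = y_opt + (u_opt - float(u)) ** 2
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        y += rng.normal(0.0, params.noise_sd)
    return float(y)


# ---------------------------------------------------------------------------
# Generic linear learner
# ---------------------------------------------------------------------------

class LinearStateSpace:
    """Generic linear learner ``X(n+1) = A X(n) + B u(n)``, ``y(n+1) = C X(n+1) + D u(n+1)``.

    Note the index offset: the state update uses the *previous* input while
    the output map uses the *current* one, matching trial-by-trial learning
    models where the planned movement is set before the current stimulus is
    applied.
    """

    def __init__(self, A, B, C, D, x0=None):
        self.A = np.atleast_2d(np.asarray(A, dtype=float))
        self.B = np.atleast_2d(np.asarray(B, dtype=float))
        self.C = np.atleast_2d(np.asarray(C, dtype=float))
        self.D = np.atleast_2d(np.asarray(D, dtype=float))
        p = self.A.shape[0]
        if self.A.shape != (p, p):
            raise ValueError("A must be square")
        if self.B.shape[0] != p or self.C.shape[1] != p:
            raise ValueError("B/C dimensions inconsistent with A")
        if self.D.shape != (self.C.shape[0], self.B.shape[1]):
            raise ValueError("D dimensions inconsistent with B and C")
        self.X = np.zeros(p) if x0 is None else np.asarray(x0, dtype=float).copy()

    def simulate(self, inputs) -> np.ndarray:
        """Outputs y(1..N) for the input schedule u(1..N), with u(0) = 0."""
        U = np.atleast_2d(np.asarray(inputs, dtype=float).T).T
        if U.ndim == 1:
            U = U[:, None]
        ys = np.empty((len(U), self.C.shape[0]))
        u_prev = np.zeros(self.B.shape[1])
        for n, u in enumerate(U):
            self.X = self.A @ self.X + self.B @ u_prev
            ys[n] = self.C @ self.X + self.D @ u
            u_prev = u
        return ys.squeeze(-1) if ys.shape[1] == 1 else ys


# ---------------------------------------------------------------------------
# Modified use-dependent-learning model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModifiedUDLParams:
    """Parameters of the modified UDL learner.

    a : retention of the reference movement, in [0, 1].
    b : retention of the previous planned movement.
    c : use-dependent learning gain on the previous output.
    d : sensitivity of the response to the applied stimulus (nonzero).
    y_obj : target response the optimizer is asked to induce.
    bounds : bilateral input saturation limits for closed-loop runs.
    """

    a: float
    b: float
    c: float
    d: float
    y_obj: float = 1.0
    bounds: tuple[float, float] = (-3.0, 3.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0):
            raise ValueError("a must lie in [0, 1]")
        if self.d == 0:
            raise ValueError("d must be nonzero")


@dataclass
class UDLState:
    """Hidden state: reference movement, planned movement, last output, counter."""

    x0: float = 0.0
    x: float = 0.0
    y_last: float = 0.0
    n: int = 0


#: Table of named model presets: slow negative (1), slow positive (2), fast
#: positive (3), fast negative (4), no learning/no adaptation (5), and pure
#: adaptation (6).  Saturation limits are |u| < 3 for models 1, 2, 5 and
#: |u| < 10 for models 3, 4, 6.
MODEL_PRESETS: dict[str, ModifiedUDLParams] = {
    "model1": ModifiedUDLParams(0.9202, 1.001, -0.02, 1.0, 1.0, (-3.0, 3.0)),
    "model2": ModifiedUDLParams(0.7, 0.9977, -0.02, 1.0, 1.0, (-3.0, 3.0)),
    "model3": ModifiedUDLParams(0.6, 0.99, -0.02, 1.0, 1.0, (-10.0, 10.0)),
    "model4": ModifiedUDLParams(0.6, 1.089, -0.02, 1.0, 1.0, (-10.0, 10.0)),
    "model5": ModifiedUDLParams(0.0, 1.0, 0.0, 1.0, 1.0, (-3.0, 3.0)),
    "model6": ModifiedUDLParams(1.0, 1.0, -0.02, 1.0, 1.0, (-10.0, 10.0)),
}


def get_preset(name: str) -> ModifiedUDLParams:
    try:
        return MODEL_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown model preset {name!r}; choose from {sorted(MODEL_PRESETS)}"
        ) from None


def udl_step(state: UDLState, u: float, params: ModifiedUDLParams) -> tuple[UDLState, float]:
    """Advance the learner one trial under stimulus ``u``; return (state, y).

    The reference movement drifts toward the previous output, the planned
    movement mixes retention, use-dependence and the reference, and the output
    adds the direct input term.
    """
    a, b, c, d = params.a, params.b, params.c, params.d
    x0_new = a * state.x0 + (1.0 - a) * state.y_last
    x_new = b * state.x + c * state.y_last + (1.0 - b - c) * state.x0
    y = x_new + d * float(u)
    return UDLState(x0=x0_new, x=x_new, y_last=y, n=state.n + 1), y


def udl_matrices(params: ModifiedUDLParams):
    """State-space matrices (A, B, C, D) of the modified UDL recursion."""
    a, b, c, d = params.a, params.b, params.c, params.d
    A = np.array([[a, 1.0 - a], [1.0 - b - c, b + c]])
    B = d * np.array([[1.0 - a], [c]])
    C = np.array([[0.0, 1.0]])
    D = np.array([[d]])
    return A, B, C, D


def udl_optimal_input(state: UDLState, params: ModifiedUDLParams) -> float:
    """Input that would drive the *next* output exactly to the target.

    Inverts the output map given the current (pre-update) state: the planned
    movement the learner is about to form is fully determined by the state,
    so the stimulus achieving ``y = y_obj`` is unique whenever ``d != 0``.
    """
    a, b, c, d = params.a, params.b, params.c, params.d
    return (
        params.y_obj / d
        - (b / d) * state.x
        - (c / d) * state.y_last
        - ((1.0 - b - c) / d) * state.x0
    )


def udl_counterfactual_response(state: UDLState, u: float, params: ModifiedUDLParams) -> float:
    """Noise-free output the learner would produce at input ``u`` right now.

    ``state`` must be the post-update state of the current trial (its planned
    movement already formed); the state itself is not advanced.
    """
    return state.x + params.d * float(u)


def training_protocol_schedule(
    n_pre: int = 100, n_stim: int = 200, n_post: int = 100, amplitude: float = 1.0
) -> np.ndarray:
    """Null / constant-stimulus / null washout input schedule."""
    return np.concatenate(
        [np.zeros(n_pre), np.full(n_stim, amplitude), np.zeros(n_post)]
    )


def simulate_protocol(params: ModifiedUDLParams, input_schedule) -> dict[str, np.ndarray]:
    """Noise-free open-loop simulation of an input schedule from rest.

    Returns arrays ``u``, ``x0``, ``x`` and ``y``, one entry per trial, for
    regenerating training/washout trajectories of the learner family.
    """
    schedule = np.asarray(input_schedule, dtype=float).ravel()
    state = UDLState()
    x0s = np.empty(len(schedule))
    xs = np.empty(len(schedule))
    ys = np.empty(len(schedule))
    for n, u in enumerate(schedule):
        state, y = udl_step(state, u, params)
        x0s[n], xs[n], ys[n] = state.x0, state.x, y
    return {"u": schedule, "x0": x0s, "x": xs, "y": ys}
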