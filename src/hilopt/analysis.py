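"""Iteration-wise factorial analysis of closed-loop benchmarking results.

At every iteration the four optimizer variants form a balanced 2 x 2 design
(optimizer type x exploration-exploitation ratio) with one replicate per
repetition.  A classical fixed-effects two-way ANOVA is fitted per iteration;
significant effects are followed by two-sample t tests, and the per-iteration
significance series is condensed into crossover summaries: the first
iteration after which one optimizer is continuously (or in a given proportion
of iterations) statistically superior.

All p values are reported at an uncorrected per-iteration level (default
alpha 0.05); no across-iteration multiplicity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoWayAnova",
    "anova2",
    "posthoc_ttest",
    "iteration_anova",
    "superiority_series",
    "first_continuous_crossover",
    "proportion_superior",
    "threshold_crossover",
    "eratio_posthoc",
    "CrossoverSummary",
    "crossover_summary",
    "OUTCOMES",
]

OUTCOMES = ["input_error", "output_error", "input_estim_error", "output_estim_error"]


@dataclass(frozen=True)
class TwoWayAnova:
    """F and p values of a balanced two-way fixed-effects ANOVA."""

    f_a: float
    p_a: float
    f_b: float
    p_b: float
    f_ab: float
    p_ab: float
    ss: dict = field(default_factory=dict)
    cell_means: Optional[np.ndarray] = None
    degenerate: bool = False


def anova2(cells) -> TwoWayAnova:
    """Classical sums-of-squares two-way ANOVA on a balanced 2 x 2 design.

    Parameters
    ----------
    cells
        Nested structure ``cells[i][j]`` with the replicate list of factor-A
        level ``i`` and factor-B level ``j``; all cells must hold the same
        number (>= 2) of replicates.

    Returns
    -------
    TwoWayAnova with main-effect and interaction F ratios tested against the
    within-cell error.  If the within-cell variance is zero the result is
    flagged ``degenerate`` and p values are set to 0 (effect present) or 1
    (no effect) by convention.
    """
    data = np.asarray([[np.asarray(cells[i][j], dtype=float) for j in range(2)] for i in range(2)])
    if data.shape[:2] != (2, 2):
        raise ValueError("anova2 expects a 2 x 2 design")
    n = data.shape[2]
    if n < 2:
        raise ValueError("at least 2 replicates per cell are required")
    grand = data.mean()
    cell_means = data.mean(axis=2)
    a_means = cell_means.mean(axis=1)
    b_means = cell_means.mean(axis=0)
    ss_a = 2 * n * float(((a_means - grand) ** 2).sum())
    ss_b = 2 * n * float(((b_means - grand) ** 2).sum())
    ss_cells = n * float(((cell_means - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_e = float(((data - cell_means[:, :, None]) ** 2).sum())
    df_e = 4 * (n - 1)
    ms_e = ss_e / df_e
    ss = {"A": ss_a, "B": ss_b, "AB": ss_ab, "E": ss_e,
          "total": float(((data - grand) ** 2).sum())}

    if ms_e <= 0.0:
        def degenerate_p(ss_effect):
            return 0.0 if ss_effect > 0 else 1.0
        return TwoWayAnova(
            np.inf if ss_a > 0 else 0.0, degenerate_p(ss_a),
            np.inf if ss_b > 0 else 0.0, degenerate_p(ss_b),
            np.inf if ss_ab > 0 else 0.0, degenerate_p(ss_ab),
            ss=ss, cell_means=cell_means, degenerate=True,
        )

    def f_p(ss_effect):
        f = (ss_effect / 1.0) / ms_e
        return float(f), float(stats.f.sf(f, 1, df_e))

    f_a, p_a = f_p(ss_a)
    f_b, p_b = f_p(ss_b)
    f_ab, p_ab = f_p(ss_ab)
    return TwoWayAnova(f_a, p_a, f_b, p_b, f_ab, p_ab, ss=ss, cell_means=cell_means)


def posthoc_ttest(x, y) -> tuple[float, float, Optional[str]]:
    """Two-sample t test with the direction of the lower-mean group.

    Returns ``(t, p, direction)`` where direction is ``"first"``/``"second"``
    for whichever sample has the lower mean, or ``None`` when the samples are
    indistinguishable (degenerate zero-variance equality gives p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0, None
        return (np.inf if x.mean() > y.mean() else -np.inf), 0.0, (
            "second" if x.mean() > y.mean() else "first"
        )
    t, p = stats.ttest_ind(x, y)
    direction = None
    if x.mean() < y.mean():
        direction = "first"
    elif y.mean() < x.mean():
        direction = "second"
    return float(t), float(p), direction


def iteration_anova(
    results: pd.DataFrame, outcome: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-way ANOVA (optimizer x e-ratio) at every iteration of a results table.

    The returned frame is indexed by iteration and carries F/p for the
    optimizer main effect, the e-ratio main effect and their interaction,
    the DBO and BO marginal means, and the significant-with-DBO-lower flag.
    """
    if outcome not in results.columns:
        raise ValueError(f"unknown outcome {outcome!r}")
    opts = sorted(results["optimizer"].unique())
    ers = sorted(results["e_ratio"].unique())
    if len(opts) != 2 or len(ers) != 2:
        raise ValueError("iteration_anova requires exactly 2 optimizers x 2 e-ratios")
    rows = []
    for it, sub in results.groupby("iteration"):
        cells = [
            [sub.loc[(sub.optimizer == o) & (sub.e_ratio == e), outcome].to_numpy() for e in ers]
            for o in opts
        ]
        sizes = {len(c) for row in cells for c in row}
        if len(sizes) != 1:
            raise ValueError(f"unbalanced design at iteration {it}: cell sizes {sizes}")
        res = anova2(cells)
        # factor A levels follow `opts` (alphabetical: BO before DBO)
        bo_mean, dbo_mean = res.cell_means.mean(axis=1)
        if opts[0] == "DBO":
            bo_mean, dbo_mean = dbo_mean, bo_mean
        rows.append(
            {
                "iteration": it,
                "f_optimizer": res.f_a, "p_optimizer": res.p_a,
                "f_eratio": res.f_b, "p_eratio": res.p_b,
                "f_interaction": res.f_ab, "p_interaction": res.p_ab,
                "mean_bo": bo_mean, "mean_dbo": dbo_mean,
                "degenerate": res.degenerate,
                "dbo_superior": bool(res.p_a < alpha and dbo_mean < bo_mean),
            }
        )
    return pd.DataFrame(rows).set_index("iteration").sort_index()


def superiority_series(anova_table: pd.DataFrame) -> pd.Series:
    """Boolean per-iteration series: optimizer effect significant with DBO lower."""
    return anova_table["dbo_superior"]


def first_continuous_crossover(series: pd.Series, tolerate: int = 0) -> Optional[int]:
    """First iteration of the terminal run of superiority extending to the end.

    Scans backwards from the final iteration, tolerating up to ``tolerate``
    non-significant iterations inside the run; returns ``None`` when the final
    iteration itself is outside any such run.
    """
    s = series.sort_index()
    idx = s.index.to_numpy()
    vals = s.to_numpy(dtype=bool)
    if len(vals) == 0 or not vals[-1] and tolerate == 0:
        return None
    gaps = 0
    start = None
    for i in range(len(vals) - 1, -1, -1):
        if vals[i]:
            start = i
        else:
            gaps += 1
            if gaps > tolerate:
                break
    return int(idx[start]) if start is not None else None


def proportion_superior(series: pd.Series, after: int) -> float:
    """Fraction of iterations strictly past ``after`` flagged superior."""
    s = series.sort_index()
    tail = s[s.index > after]
    if len(tail) == 0:
        raise ValueError(f"no iterations past {after}")
    return float(tail.mean())


def threshold_crossover(series: pd.Series, frac: float = 0.8) -> Optional[int]:
    """Smallest cutoff whose post-cutoff superiority proportion reaches ``frac``."""
    s = series.sort_index()
    last = int(s.index.max())
    for cut in [int(s.index.min()) - 1] + [int(i) for i in s.index if i < last]:
        if proportion_superior(s, cut) >= frac:
            return cut
    return None


def eratio_posthoc(
    results: pd.DataFrame,
    outcome: str,
    optimizer: str = "DBO",
    iterations: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Per-iteration t test between the two e-ratio levels within one optimizer.

    Returns a frame indexed by iteration with ``t``, ``p`` and the lower
    e-ratio level (``direction_lower``), restricted to ``iterations`` when
    given.
    """
    sub = results[results["optimizer"] == optimizer]
    ers = sorted(sub["e_ratio"].unique())
    if len(ers) != 2:
        raise ValueError("eratio_posthoc requires exactly two e-ratio levels")
    if iterations is not None:
        sub = sub[sub["iteration"].isin(list(iterations))]
    rows = []
    for it, g in sub.groupby("iteration"):
        x = g.loc[g.e_ratio == ers[0], outcome].to_numpy()
        y = g.loc[g.e_ratio == ers[1], outcome].to_numpy()
        t, p, direction = posthoc_ttest(x, y)
        lower = {"first": ers[0], "second": ers[1], None: None}[direction]
        rows.append({"iteration": it, "t": t, "p": p, "direction_lower": lower})
    return pd.DataFrame(rows).set_index("iteration").sort_index()


@dataclass(frozen=True)
class CrossoverSummary:
    """Condensed per-outcome summary of when DBO becomes superior to BO."""

    outcome: str
    first_continuous_crossover: Optional[int]
    threshold_crossover_80: Optional[int]
    proportion_superior_after: dict
    significant_fraction_overall: float


def crossover_summary(
    results: pd.DataFrame,
    outcome: str,
    after: Sequence[int] = (),
    alpha: float = 0.05,
    tolerate: int = 0,
) -> CrossoverSummary:
    """Run the per-iteration ANOVA on one outcome and condense it."""
    table = iteration_anova(results, outcome, alpha=alpha)
    series = superiority_series(table)
    props = {int(a): proportion_superior(series, int(a)) for a in after}
    return CrossoverSummary(
        outcome=outcome,
        first_continuous_crossover=first_continuous_crossover(series, tolerate=tolerate),
        threshold_crossover_80=threshold_crossover(series, 0.8),
        proportion_superior_after=props,
        significant_fraction_overall=float((table["p_optimizer"] < alpha).mean()),
    )
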