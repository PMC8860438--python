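"""Scoring and parameterization of gross-motor (juggling) learning.

Performance in each 3-min block is the number of three-ball cascades
(three consecutive catches = one cascade; a run of k consecutive catches
contributes floor(k/3)).  Within each performance test the block scores
y_i at block index x_i = 1..n are summarized by the closed-form
least-squares line

    m = sum((x_i - mean(x)) * (y_i - mean(y))) / sum((x_i - mean(x))^2)
    c = mean(y) - m * mean(x)

where the slope m is the learning curve and y1 = m + c (the fit evaluated
at the first block) is the task proficiency.  Overnight changes are
post-minus-pre differences of y1 and m across a retention interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LearningCurveFit",
    "cascades_from_catch_runs",
    "fit_learning_curve",
    "fit_table",
    "overnight_change",
    "proficiency_vs_first_block",
]


@dataclass
class LearningCurveFit:
    """Least-squares line through one performance test's block scores."""

    m: float           # learning curve (cascades/block)
    c: float           # intercept (cascades)
    y1: float          # task proficiency = m + c (cascades)
    n_blocks: int
    residual_ss: float

    def __post_init__(self):
        # identity is exact by construction; guard against drift
        assert abs(self.y1 - (self.m + self.c)) < 1e-9


def cascades_from_catch_runs(runs) -> int:
    """Number of three-ball cascades in a block from consecutive-catch runs.

    Each uninterrupted run of k catches contributes floor(k/3) cascades
    (a run of fewer than three catches is not a cascade).
    """
    total = 0
    for r in runs:
        if r < 0 or int(r) != r:
            raise ValueError(f"catch runs must be nonnegative integers, got {r!r}")
        total += int(r) // 3
    return total


def fit_learning_curve(block_scores) -> LearningCurveFit:
    """Exact closed-form least-squares fit with block index x = 1..n."""
    y = np.asarray(block_scores, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("need at least 2 block scores")
    if not np.all(np.isfinite(y)):
        raise ValueError("block scores must be finite")
    x = np.arange(1, y.size + 1, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    m = float((dx * dy).sum() / (dx * dx).sum())
    c = float(y.mean() - m * x.mean())
    resid = y - (m * x + c)
    return LearningCurveFit(m, c, m + c, y.size, float((resid**2).sum()))


def fit_table(behavior: pd.DataFrame) -> pd.DataFrame:
    """Fit every (subject, test) of a behavior table.

    Expects columns subject, test, block, cascades (block ordering is
    taken from the block index, not row order).
    """
    rows = []
    for (subj, test), grp in behavior.groupby(["subject", "test"]):
        scores = grp.sort_values("block")["cascades"].to_numpy()
        fit = fit_learning_curve(scores)
        rows.append({"subject": subj, "test": int(test), "m": fit.m,
                     "c": fit.c, "y1": fit.y1, "n_blocks": fit.n_blocks})
    return pd.DataFrame(rows)


def overnight_change(fits: pd.DataFrame, pre_test: int = 1,
                     post_test: int = 2) -> pd.DataFrame:
    """Post-minus-pre change in task proficiency and learning curve.

    Subjects missing either test are omitted (left to the caller's log).
    Returns columns subject, d_y1, d_m.
    """
    pre = fits[fits.test == pre_test].set_index("subject")
    post = fits[fits.test == post_test].set_index("subject")
    common = pre.index.intersection(post.index)
    return pd.DataFrame({
        "subject": common,
        "d_y1": (post.loc[common, "y1"] - pre.loc[common, "y1"]).to_numpy(),
        "d_m": (post.loc[common, "m"] - pre.loc[common, "m"]).to_numpy(),
    })


def proficiency_vs_first_block(fits: pd.DataFrame, behavior: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho between fitted y1 and observed block-1 cascades, per test.

    A consistency check of the parameterization: with little block noise
    the model-predicted first-block performance should track the observed
    one.  Needs at least 5 subjects per test; constant inputs make the
    rank correlation undefined and raise.
    """
    first = behavior[behavior.block == 1].set_index(["subject", "test"])["cascades"]
    rows = []
    for test, grp in fits.groupby("test"):
        merged = grp.set_index("subject")
        obs = np.array([first.get((s, test), np.nan) for s in merged.index])
        ok = ~np.isnan(obs)
        if ok.sum() < 5:
            raise ValueError(f"need >= 5 subjects with test {test}")
        y1 = merged["y1"].to_numpy()[ok]
        if np.all(y1 == y1[0]) or np.all(obs[ok] == obs[ok][0]):
            raise ValueError("constant values: rank correlation undefined")
        rho, p = stats.spearmanr(y1, obs[ok])
        rows.append({"test": int(test), "rho": float(rho), "p": float(p),
                     "n": int(ok.sum())})
    return pd.DataFrame(rows)
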