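"""Trend classification and posterior predictive trajectories.

A stratum trend is "significant" exactly when the equal-tailed credible
interval for its slope beta_j excludes zero — increasing if the lower
bound is above zero, decreasing if the upper bound is below zero, and
no_change otherwise.  No multiple-comparison adjustment is applied
across strata (a deliberate, documented caveat: the classification is a
per-stratum statement, not a family-wise one).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import PosteriorResult
from .observation import zinb_logpmf  # noqa: F401  (re-export convenience)

__all__ = ["classify_trends", "posterior_predict_stratum",
           "write_trend_table", "write_predictive"]

CLASSES = ("increasing", "decreasing", "no_change")


def _classify_by_interval(draws: np.ndarray, level: float):
    """Interval rule on equal-tailed quantiles (inverted-CDF quantiles,
    so the rule is exactly the order statistics of the draws)."""
    a = (1.0 - level) / 2.0
    lo = np.quantile(draws, a, axis=0, method="inverted_cdf")
    hi = np.quantile(draws, 1.0 - a, axis=0, method="inverted_cdf")
    cls = np.where(lo > 0, "increasing",
                   np.where(hi < 0, "decreasing", "no_change"))
    return cls, lo, hi


def _classify_by_tail_probability(draws: np.ndarray, level: float):
    """Sign-test route: increasing iff P(beta <= 0) < (1-level)/2,
    decreasing iff P(beta < 0) >= 1 - (1-level)/2.  For equal-tailed
    inverted-CDF intervals this coincides exactly with the interval
    rule; both paths are computed and asserted identical."""
    a = (1.0 - level) / 2.0
    n = draws.shape[0]
    p_le = (draws <= 0).sum(axis=0) / n
    p_lt = (draws < 0).sum(axis=0) / n
    return np.where(p_le < a, "increasing",
                    np.where(p_lt >= 1.0 - a, "decreasing", "no_change"))


def classify_trends(result: PosteriorResult, level: float = 0.95
                    ) -> pd.DataFrame:
    """Per-stratum trend table at a given credibility level.

    Columns: stratum, beta_mean, beta_sd, q2.5, q97.5 (at the requested
    level), class, pairs_change (posterior-mean trend-only change in
    mean counted pairs from the first to the last occasion).  The
    summary row fractions per class are attached as ``DataFrame.attrs``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if "beta" not in result.draws:
        raise ValueError("no beta draws in result")
    beta = result.stacked("beta")          # (ndraw, m)
    alpha = result.stacked("alpha")
    cls, lo, hi = _classify_by_interval(beta, level)
    cls2 = _classify_by_tail_probability(beta, level)
    assert (cls == cls2).all(), \
        "interval rule and tail-probability rule disagree"

    x_last = float(result.x[-1])
    change = (np.exp(alpha + beta * x_last) - np.exp(alpha)).mean(axis=0)
    table = pd.DataFrame({
        "stratum": list(result.stratum_ids),
        "beta_mean": beta.mean(axis=0),
        "beta_sd": beta.std(axis=0, ddof=1),
        "q2.5": lo,
        "q97.5": hi,
        "class": cls,
        "pairs_change": change,
    })
    m = len(table)
    table.attrs["class_fractions"] = {
        c: float((cls == c).sum()) / m for c in CLASSES}
    table.attrs["level"] = level
    return table


def posterior_predict_stratum(result: PosteriorResult, stratum,
                              level: float = 0.95,
                              seed: int = 0) -> pd.DataFrame:
    """Posterior predictive distribution of a new segment count per year.

    For each posterior draw the stratum-year mean mu_jt is pushed
    through the fitted data model (one simulated count per draw and
    year); the returned mean is the analytic predictive mean
    (1 - p_zero) * mu averaged over draws, and the interval the
    equal-tailed quantiles of the simulated counts.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    stratum = str(stratum)
    if stratum not in result.stratum_ids:
        raise ValueError(f"unknown stratum {stratum!r}")
    j = result.stratum_ids.index(stratum)
    spec = result.spec
    alpha = result.stacked("alpha")[:, j]
    beta = result.stacked("beta")[:, j]
    x = result.x
    lp = alpha[:, None] + beta[:, None] * x[None, :]
    if spec is None or spec.spatial_on:
        if "eta" in result.draws:
            lp = lp + result.stacked("eta")[:, j, :]
    if spec is None or spec.temporal_on:
        if "gamma" in result.draws:
            lp = lp + result.stacked("gamma")[:, j, :]
    mu = np.exp(lp)                                   # (ndraw, T)
    theta = result.stacked("theta")
    n = np.exp(theta)[:, None]
    if "p_zero" in result.draws:
        p = result.stacked("p_zero")[:, None]
    else:
        p = np.zeros((mu.shape[0], 1))

    rng = np.random.default_rng(seed)
    y = rng.negative_binomial(n, n / (n + mu))
    y = np.where(rng.random(mu.shape) < p, 0, y)
    a = (1.0 - level) / 2.0
    return pd.DataFrame({
        "year": result.base_year + np.arange(len(x)),
        "mean": ((1.0 - p) * mu).mean(axis=0),
        "q2.5": np.quantile(y, a, axis=0),
        "q97.5": np.quantile(y, 1.0 - a, axis=0),
    })


def write_trend_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_predictive(path, pred: pd.DataFrame) -> None:
    pred.to_csv(path, index=False)
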