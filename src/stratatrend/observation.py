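"""Negative binomial and zero-inflated negative binomial data models.

Segment-level counts y_ijt are modelled as

    NB:    y ~ NegBinom(mu, n)            (mean mu, size n)
    ZINB:  y ~ p_zero * delta_0 + (1 - p_zero) * NegBinom(mu, n)

in the (mu, size) parameterisation, P(y) = Gamma(y+n)/(Gamma(n) y!) *
(n/(n+mu))^n * (mu/(n+mu))^y, with variance mu + mu^2/n.  The size
parameter is carried on the log scale, theta = log(n), by the sampler.

Excess zeros in a survey mix "false" zeros (birds present but missed, or
temporarily absent) with "true" zeros (habitat unused); the mixture
weight p_zero absorbs both without distinguishing them per record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ObsParams", "nb_logpmf", "zinb_logpmf", "deviance",
           "load_counts", "write_counts"]

DATA_MODELS = ("nb", "zinb")


@dataclass(frozen=True)
class ObsParams:
    """Observation-model parameters: NB mean ``mu`` > 0, log-size
    ``theta`` (so size_n = exp(theta) exactly), zero-inflation weight
    ``p_zero`` in [0, 1]."""

    mu: float
    theta: float
    p_zero: float = 0.0

    @property
    def size_n(self) -> float:
        return float(np.exp(self.theta))

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if not np.isfinite(self.theta):
            raise ValueError("theta must be finite")
        if not 0.0 <= self.p_zero <= 1.0:
            raise ValueError("p_zero must lie in [0, 1]")


def _check_counts(y) -> np.ndarray:
    arr = np.asarray(y)
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("counts must be numeric")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("counts must be non-negative integers")
    return arr.astype(float)


def nb_logpmf(y, mu, size_n):
    """Log pmf of NegBinom(mean mu, size n); vectorised.

    scipy's nbinom uses (n, p) with p = n/(n+mu); the variance is
    mu + mu^2/n, approaching Poisson(mu) as n -> infinity.
    """
    yv = _check_counts(y)
    mu = np.asarray(mu, dtype=float)
    size_n = np.asarray(size_n, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be > 0")
    if np.any(size_n <= 0):
        raise ValueError("size_n must be > 0")
    p = size_n / (size_n + mu)
    return stats.nbinom.logpmf(yv, size_n, p)


def zinb_logpmf(y, params: ObsParams = None, *, mu=None, size_n=None,
                p_zero=None):
    """Log pmf of the zero-inflated NB mixture; vectorised.

    P(0) = p_zero + (1-p_zero)*NB(0); P(y>0) = (1-p_zero)*NB(y), with the
    zero atom combined in log space (log-sum-exp).  Accepts either an
    ObsParams or explicit (mu, size_n, p_zero) arrays.
    """
    if params is not None:
        mu, size_n, p_zero = params.mu, params.size_n, params.p_zero
    p_zero = np.asarray(p_zero, dtype=float)
    if np.any(p_zero < 0) or np.any(p_zero > 1):
        raise ValueError("p_zero must lie in [0, 1]")
    yv = _check_counts(y)
    base = nb_logpmf(yv, mu, size_n)
    with np.errstate(divide="ignore"):
        log_p = np.log(p_zero)
        log_q = np.log1p(-p_zero)
    nonzero = np.where(yv > 0, log_q + base, -np.inf)
    at_zero = np.logaddexp(log_p, log_q + base)
    return np.where(yv == 0, at_zero, nonzero)


def deviance(y, mu, size_n, p_zero=0.0, model: str = "nb") -> float:
    """-2 * total log-likelihood of the counts under the chosen model.

    ``mu`` must supply one mean per record (scalar broadcast allowed for
    convenience only when it matches).
    """
    if model not in DATA_MODELS:
        raise ValueError(f"model must be one of {DATA_MODELS}")
    yv = np.asarray(y)
    muv = np.asarray(mu, dtype=float)
    if muv.ndim > 0 and muv.shape != yv.shape:
        raise ValueError("mu must have one entry per record")
    if model == "nb":
        ll = nb_logpmf(yv, muv, size_n)
    else:
        ll = zinb_logpmf(yv, mu=muv, size_n=size_n, p_zero=p_zero)
    return float(-2.0 * ll.sum())


def load_counts(path, base_year: int = 1957) -> pd.DataFrame:
    """Read a count file (CSV, header ``segment,stratum,year,count``).

    Adds ``year_index`` = year - base_year (0-based); validates
    non-negative integer counts and joint uniqueness of
    (segment, stratum, year).
    """
    df = pd.read_csv(path, dtype={"segment": str, "stratum": str})
    missing = {"segment", "stratum", "year", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"count file missing columns: {sorted(missing)}")
    _check_counts(df["count"].to_numpy())
    if df.duplicated(["segment", "stratum", "year"]).any():
        raise ValueError("duplicate (segment, stratum, year) records")
    if (df["year"] < base_year).any():
        raise ValueError(f"years before base year {base_year}")
    df = df.copy()
    df["year_index"] = df["year"].astype(int) - int(base_year)
    return df


def write_counts(path, df: pd.DataFrame) -> None:
    df[["segment", "stratum", "year", "count"]].to_csv(path, index=False)
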