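"""Log-linear process model and model/prior configuration.

The stratum-year log mean is

    log mu_jt = alpha_j + beta_j * x_t + eta_jt + gamma_jt,

with x_t = t (years since the first survey occasion, so alpha_j is the
first-year log mean and beta_j a per-year log-scale trend), eta the CAR
spatial field (independent slices over time) and gamma the AR(1)
temporal field (independent series over strata).  All segments within a
(stratum, year) cell are replicate observations of the same mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

__all__ = ["PriorConfig", "ModelSpec", "LatentState", "linear_predictor",
           "log_mean_matrix", "cumulative_change", "preset", "PRESETS"]


@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative default priors; everything overridable.

    Gaussian priors on the regression parameters, conjugate gamma priors
    on the field precisions, a Gaussian prior on theta = log(NB size),
    Gaussian priors on the transformed autocorrelation parameters
    (z = log((1+rho)/(1-rho)), logit(lam)), and Beta on p_zero.  The
    precision-0.15 transformed-scale priors are the defaults of the
    latent-Gaussian framework this model family is usually fit with.
    ``gamma_center_prec`` is the soft sum-to-zero constraint: each
    stratum's gamma series mean gets a Normal(0, 1/prec) prior to keep
    the temporal residuals identifiable against the intercepts.  The
    default (precision 25, sd 0.2) is deliberately no tighter than the
    stationary spread of an AR(1) series mean at moderate rho, so the
    constraint pins down the flat direction without distorting the
    residual series (an over-tight constraint narrows the trend
    intervals below their honest width).
    """

    alpha_mean: float = 0.0
    alpha_prec: float = 0.001
    beta_mean: float = 0.0
    beta_prec: float = 0.001
    tau_shape: float = 1.0
    tau_rate: float = 5e-5
    theta_mean: float = 0.0
    theta_prec: float = 0.01
    rho_trans_mean: float = 0.0
    rho_trans_prec: float = 0.15
    lam_trans_mean: float = 0.0
    lam_trans_prec: float = 0.15
    p_zero_a: float = 1.0
    p_zero_b: float = 1.0
    gamma_center_prec: float = 25.0

    def __post_init__(self):
        for name, v in asdict(self).items():
            if not np.isfinite(v):
                raise ValueError(f"prior hyperparameter {name} must be finite")
        for name in ("alpha_prec", "beta_prec", "tau_shape", "tau_rate",
                     "theta_prec", "rho_trans_prec", "lam_trans_prec",
                     "p_zero_a", "p_zero_b", "gamma_center_prec"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ModelSpec:
    """Data-model choice x random-effect configuration.

    data_model: "nb" or "zinb".  spatial_on / temporal_on give the four
    compared random-effect configurations (none / spatial / temporal /
    both).  lam_mode: "estimated" or a fixed float in [0, 1).
    """

    data_model: str = "zinb"
    spatial_on: bool = True
    temporal_on: bool = True
    lam_mode: object = "estimated"
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self):
        if self.data_model not in ("nb", "zinb"):
            raise ValueError("data_model must be 'nb' or 'zinb'")
        if self.lam_mode != "estimated":
            lam = float(self.lam_mode)
            if not (0.0 <= lam < 1.0):
                raise ValueError("fixed lam must lie in [0, 1)")

    @property
    def effects(self) -> str:
        return {(False, False): "none", (True, False): "spatial",
                (False, True): "temporal", (True, True): "both"}[
            (self.spatial_on, self.temporal_on)]

    @property
    def label(self) -> str:
        return f"{self.effects}-{self.data_model}"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["priors"] = asdict(self.priors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if "priors" in d and isinstance(d["priors"], dict):
            d["priors"] = PriorConfig(**d["priors"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


_EFFECTS = {"none": (False, False), "spatial": (True, False),
            "temporal": (False, True), "both": (True, True)}
PRESETS = tuple(f"{e}-{d}" for d in ("nb", "zinb") for e in _EFFECTS)


def preset(name: str, priors: PriorConfig = None,
           lam_mode="estimated") -> ModelSpec:
    """Named model presets: '<effects>-<data model>' for effects in
    none/spatial/temporal/both and data model in nb/zinb."""
    try:
        eff, dm = name.rsplit("-", 1)
        spatial, temporal = _EFFECTS[eff]
    except (ValueError, KeyError):
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    if dm not in ("nb", "zinb"):
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    kw = {} if priors is None else {"priors": priors}
    return ModelSpec(data_model=dm, spatial_on=spatial, temporal_on=temporal,
                     lam_mode=lam_mode, **kw)


@dataclass
class LatentState:
    """One full configuration of the latent process.

    alpha, beta: length-m fixed effects; eta, gamma: (m, T) fields
    (zero when the corresponding effect is off); hyperparameters
    tau_eta, tau_gamma > 0, |rho| < 1, lam in [0,1), p_zero in [0,1],
    theta = log NB size.
    """

    alpha: np.ndarray
    beta: np.ndarray
    eta: np.ndarray
    gamma: np.ndarray
    tau_eta: float = 1.0
    tau_gamma: float = 1.0
    rho: float = 0.0
    lam: float = 0.0
    p_zero: float = 0.0
    theta: float = 0.0

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        m = self.alpha.shape[0]
        if self.beta.shape != (m,):
            raise ValueError("alpha and beta must both have length m")
        if self.eta.shape != self.gamma.shape or self.eta.ndim != 2 \
                or self.eta.shape[0] != m:
            raise ValueError("eta and gamma must both be (m, T)")
        for arr in (self.alpha, self.beta, self.eta, self.gamma):
            if not np.all(np.isfinite(arr)):
                raise ValueError("latent state must be finite")
        if not (self.tau_eta > 0 and self.tau_gamma > 0):
            raise ValueError("precisions must be > 0")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if not (0.0 <= self.lam < 1.0):
            raise ValueError("lam must lie in [0, 1)")
        if not (0.0 <= self.p_zero <= 1.0):
            raise ValueError("p_zero must lie in [0, 1]")

    @property
    def m(self) -> int:
        return self.alpha.shape[0]

    @property
    def T(self) -> int:
        return self.eta.shape[1]

    @property
    def size_n(self) -> float:
        return float(np.exp(self.theta))

    def copy(self) -> "LatentState":
        return replace(self, alpha=self.alpha.copy(), beta=self.beta.copy(),
                       eta=self.eta.copy(), gamma=self.gamma.copy())

    def to_dict(self) -> dict:
        return {"alpha": self.alpha.tolist(), "beta": self.beta.tolist(),
                "eta": self.eta.tolist(), "gamma": self.gamma.tolist(),
                "tau_eta": self.tau_eta, "tau_gamma": self.tau_gamma,
                "rho": self.rho, "lam": self.lam, "p_zero": self.p_zero,
                "theta": self.theta}

    @classmethod
    def from_dict(cls, d: dict) -> "LatentState":
        return cls(**d)


def linear_predictor(state: LatentState, j: int, t: int, x_t: float = None,
                     spatial_on: bool = True, temporal_on: bool = True) -> float:
    """log mu_jt = alpha_j + beta_j * x_t [+ eta_jt] [+ gamma_jt].

    x_t defaults to t itself (years since the first occasion).  The mean
    is identical for every segment within the (j, t) cell.
    """
    m, T = state.m, state.T
    if not (0 <= j < m) or not (0 <= t < T):
        raise IndexError(f"(j, t) = ({j}, {t}) out of range for ({m}, {T})")
    if x_t is None:
        x_t = float(t)
    lp = state.alpha[j] + state.beta[j] * x_t
    if spatial_on:
        lp += state.eta[j, t]
    if temporal_on:
        lp += state.gamma[j, t]
    return float(lp)


def log_mean_matrix(state: LatentState, x: np.ndarray = None,
                    spatial_on: bool = True,
                    temporal_on: bool = True) -> np.ndarray:
    """The full (m, T) matrix of log means (vectorised predictor)."""
    T = state.T
    if x is None:
        x = np.arange(T, dtype=float)
    lp = state.alpha[:, None] + state.beta[:, None] * x[None, :]
    if spatial_on:
        lp = lp + state.eta
    if temporal_on:
        lp = lp + state.gamma
    return lp


def cumulative_change(state: LatentState, j: int, span_years: int) -> float:
    """Trend-only change in mean counted pairs from the first to the last
    occasion of a span: exp(alpha_j + beta_j*x_last) - exp(alpha_j),
    with x_first = 0 and x_last = span_years - 1.  Positive values are
    pairs gained, negative pairs lost; the random fields are excluded.
    """
    if span_years < 1:
        raise ValueError("span_years must be >= 1")
    if not (0 <= j < state.m):
        raise IndexError(f"stratum index {j} out of range")
    x_last = float(span_years - 1)
    a, b = state.alpha[j], state.beta[j]
    return float(np.exp(a + b * x_last) - np.exp(a))
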