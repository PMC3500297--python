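"""Posterior sampling and DIC model comparison.

The joint model — NB/ZINB observations over a log-linear process with
stratum intercepts and trends, a proper-CAR spatial field and stationary
AR(1) temporal residuals, under the prior layer in
:class:`~stratatrend.process.PriorConfig` — is sampled with an adaptive
Metropolis-within-Gibbs scheme:

* zero-inflation: latent structural-zero counts per cell are drawn by
  conjugate binomial augmentation, after which ``p_zero`` is a Beta draw;
* field precisions ``tau_eta``/``tau_gamma`` have conjugate gamma full
  conditionals;
* ``(alpha_j, beta_j)`` blocks use per-stratum adaptive random-walk
  proposals with a learned 2x2 covariance (the two are strongly
  correlated because the time covariate is uncentered);
* the CAR field is updated by vectorised single-site Metropolis over
  graph-colour classes (same-colour strata are non-adjacent, so their
  full conditionals are independent); the AR(1) field by single-site
  Metropolis sweeping time points sequentially (strata vectorised);
* ``rho``, ``lam`` and ``theta`` use adaptive scalar random walks on
  their transformed scales.

Only sparse structure is ever used (tridiagonal AR(1) conditionals, CAR
neighbour sums, a precomputed normalized-adjacency spectrum for the CAR
log-determinant); no dense (mT x mT) matrix is formed.

DIC follows Spiegelhalter: pD = Dbar - Dhat with Dhat the deviance at
the posterior means of every quantity entering the likelihood (per-record
mu, p_zero, theta); DIC = Dbar + pD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, expit, logit

from . import observation
from .process import LatentState, ModelSpec
from .spatial import StrataGraph, greedy_coloring
from .temporal import ar1_quadform

__all__ = ["SamplerSettings", "PosteriorResult", "fit_model", "compute_dic",
           "compare_models", "load_result"]


class InferenceError(RuntimeError):
    """Sampling failed (non-finite likelihood, degenerate design, ...)."""


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC run configuration (all overridable)."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 20121116
    thin: int = 1

    def __post_init__(self):
        if self.chains < 1 or self.warmup < 0 or self.draws < 1 or self.thin < 1:
            raise ValueError("invalid sampler settings")


@dataclass
class PosteriorResult:
    """Draws, summaries and DIC components from one model fit.

    ``draws`` maps parameter names to arrays of shape (chains, draws,
    *param_shape).  ``deviance`` is the per-draw deviance trace and
    ``deviance_at_mean`` the deviance at the posterior means of the
    likelihood inputs (Dhat).  ``flags`` collects non-fatal warnings
    (low acceptance, negative pD, single-chain diagnostics).
    """

    draws: dict
    deviance: np.ndarray
    deviance_at_mean: float
    stratum_ids: tuple = ()
    x: np.ndarray = None
    base_year: int = 1957
    spec: ModelSpec = None
    settings: SamplerSettings = None
    mu_mean: np.ndarray = None
    summary: pd.DataFrame = None
    dic: dict = None
    accept_rates: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    example_draw: LatentState = None

    @property
    def n_chains(self) -> int:
        return self.deviance.shape[0]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for ``name`` with chain and draw axes flattened."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def save(self, outdir, full_draws: bool = False) -> None:
        """Serialize to a directory: summary.csv, dic.json, settings.json
        and (optionally) draws.csv, a flat columnar text archive."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "summary.csv", index=False)
        with open(out / "dic.json", "w") as fh:
            json.dump({k: float(v) for k, v in self.dic.items()}, fh, indent=1)
        meta = {
            "settings": asdict(self.settings) if self.settings else None,
            "spec": self.spec.to_dict() if self.spec else None,
            "stratum_ids": list(self.stratum_ids),
            "base_year": int(self.base_year),
            "x": None if self.x is None else self.x.tolist(),
            "deviance_at_mean": float(self.deviance_at_mean),
            "accept_rates": {k: float(v) for k, v in self.accept_rates.items()},
            "flags": list(self.flags),
        }
        with open(out / "settings.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        if full_draws:
            cols = {}
            for name in self.draws:
                arr = self.draws[name]
                flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
                labels = _element_labels(name, arr.shape[2:], self.stratum_ids)
                for i, lab in enumerate(labels):
                    cols[lab] = flat[:, i]
            cols["deviance"] = self.deviance.reshape(-1)
            nchain, ndraw = self.deviance.shape
            idx = pd.MultiIndex.from_product(
                [range(nchain), range(ndraw)], names=["chain", "draw"])
            pd.DataFrame(cols, index=idx).to_csv(out / "draws.csv")


def _element_labels(name, shape, stratum_ids):
    if shape == ():
        return [name]
    if len(shape) == 1:
        return [f"{name}[{stratum_ids[j]}]" for j in range(shape[0])]
    return [f"{name}[{stratum_ids[j]},{t}]"
            for j in range(shape[0]) for t in range(shape[1])]


def load_result(outdir) -> PosteriorResult:
    """Load a saved fit (requires the full-draw archive)."""
    out = Path(outdir)
    with open(out / "settings.json") as fh:
        meta = json.load(fh)
    df = pd.read_csv(out / "draws.csv", index_col=[0, 1])
    nchain = df.index.get_level_values(0).nunique()
    ndraw = df.index.get_level_values(1).nunique()
    sids = tuple(meta["stratum_ids"])
    m = len(sids)
    x = np.asarray(meta["x"], dtype=float)
    T = len(x)
    spec = ModelSpec.from_dict(meta["spec"]) if meta["spec"] else None
    draws = {}
    names = {c.split("[", 1)[0] for c in df.columns} - {"deviance"}
    for name in names:
        sub = [c for c in df.columns if c == name or c.startswith(name + "[")]
        arr = df[sub].to_numpy().reshape(nchain, ndraw, -1)
        if len(sub) == 1 and sub[0] == name:
            arr = arr[:, :, 0]
        elif len(sub) == m:
            pass
        else:
            arr = arr.reshape(nchain, ndraw, m, T)
        draws[name] = arr
    dev = df["deviance"].to_numpy().reshape(nchain, ndraw)
    with open(out / "dic.json") as fh:
        dic = json.load(fh)
    res = PosteriorResult(
        draws=draws, deviance=dev,
        deviance_at_mean=float(meta["deviance_at_mean"]),
        stratum_ids=sids, x=x, base_year=int(meta["base_year"]), spec=spec,
        settings=SamplerSettings(**meta["settings"]),
        dic=dic, accept_rates=meta.get("accept_rates", {}),
        flags=meta.get("flags", []),
        summary=pd.read_csv(out / "summary.csv"))
    return res


# --------------------------------------------------------------------------
# data preparation

class _FitData:
    """Preprocessed view of the count records for one graph."""

    def __init__(self, counts: pd.DataFrame, graph: StrataGraph):
        df = counts
        if "year" in df.columns:
            base = int(df["year"].min())
            df = df.assign(year_index=df["year"].astype(int) - base)
            self.base_year = base
        elif "year_index" in df.columns:
            self.base_year = 1957
        else:
            raise ValueError("counts need a 'year' or 'year_index' column")
        sid_index = {s: i for i, s in enumerate(graph.stratum_ids)}
        strata = df["stratum"].astype(str)
        unknown = sorted(set(strata) - set(sid_index))
        if unknown:
            raise ValueError(f"records reference strata absent from the "
                             f"graph: {unknown[:5]}")
        self.y = observation._check_counts(df["count"].to_numpy())
        self.j = strata.map(sid_index).to_numpy()
        self.t = df["year_index"].to_numpy(dtype=int)
        if self.t.min() < 0:
            raise ValueError("negative year_index")
        self.m = graph.m
        self.T = int(self.t.max()) + 1
        if self.T < 2:
            raise ValueError("need at least 2 survey occasions to estimate "
                             "stratum trends (T >= 2)")
        self.N = self.y.size
        self.x = np.arange(self.T, dtype=float)
        self.cell = self.j * self.T + self.t
        nc = self.m * self.T
        pos = self.y > 0
        self.k_all = np.bincount(self.cell, minlength=nc).astype(float)
        self.k0 = np.bincount(self.cell[~pos], minlength=nc).astype(float)
        self.k_pos = self.k_all - self.k0
        self.S = np.bincount(self.cell[pos], weights=self.y[pos], minlength=nc)
        self.n_pos = int(pos.sum())
        uy, cnt = np.unique(self.y[pos], return_counts=True)
        self.uy, self.uy_cnt = uy, cnt.astype(float)
        self.cells_nonempty = self.k_all > 0


# --------------------------------------------------------------------------
# adaptive proposal helpers

_TARGET_SCALAR = 0.44
_TARGET_BLOCK = 0.30


class _RMScale:
    """Robbins-Monro adaptation of elementwise log proposal scales."""

    def __init__(self, shape, init=0.3, target=_TARGET_SCALAR):
        self.log_s = np.full(shape, np.log(init))
        self.target = target
        self.i = 0

    @property
    def s(self):
        return np.exp(self.log_s)

    def update(self, accepted):
        self.i += 1
        step = self.i ** -0.6
        self.log_s += step * (np.asarray(accepted, dtype=float) - self.target)
        np.clip(self.log_s, -10.0, 4.0, out=self.log_s)


class _AdaptiveBlocks:
    """Per-stratum adaptive 2x2 Gaussian proposals for (alpha, beta)."""

    def __init__(self, m, init_scales=(0.2, 0.02)):
        self.m = m
        self.count = 0
        self.mean = np.zeros((m, 2))
        self.M2 = np.zeros((m, 2, 2))
        self.chol = np.zeros((m, 2, 2))
        self.chol[:, 0, 0] = init_scales[0]
        self.chol[:, 1, 1] = init_scales[1]
        self.scale = _RMScale(m, init=1.0, target=_TARGET_BLOCK)

    def observe(self, ab):
        self.count += 1
        delta = ab - self.mean
        self.mean += delta / self.count
        self.M2 += delta[:, :, None] * (ab - self.mean)[:, None, :]
        if self.count > 40 and self.count % 20 == 0:
            cov = self.M2 / (self.count - 1)
            cov = (2.38**2 / 2.0) * cov
            cov[:, 0, 0] += 1e-8
            cov[:, 1, 1] += 1e-10
            try:
                self.chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass

    def propose(self, ab, rng):
        z = rng.standard_normal((self.m, 2))
        step = np.einsum("mij,mj->mi", self.chol, z)
        return ab + self.scale.s[:, None] * step


# --------------------------------------------------------------------------
# the sampler

def one_rho2_diag(rho, T):
    """Diagonal of the unit-innovation stationary AR(1) precision."""
    d = np.full(T, 1.0 + rho**2)
    d[0] = d[-1] = 1.0
    return d


def _cell_loglik(lp, S, k_act, n):
    """NB log-likelihood per (stratum, year) cell up to mu-independent
    terms, as a function of the log mean lp (mu = exp(lp))."""
    return S * lp - (S + k_act * n) * np.log(n + np.exp(lp))


def _run_chain(data: _FitData, graph: StrataGraph, spec: ModelSpec,
               settings: SamplerSettings, rng: np.random.Generator,
               store: dict, dev_out: np.ndarray, accum: dict,
               accept_tally: dict):
    m, T, x = data.m, data.T, data.x
    pri = spec.priors
    zinb = spec.data_model == "zinb"
    estimate_lam = spec.spatial_on and spec.lam_mode == "estimated"
    nwarm, nkeep, thin = settings.warmup, settings.draws, settings.thin

    d_row = np.diag(graph.D)
    if spec.spatial_on:
        graph.require_connected()
        colors = greedy_coloring(graph.W)
        classes = [np.nonzero(colors == c)[0] for c in range(colors.max() + 1)]
        s = 1.0 / np.sqrt(d_row)
        adj_eigs = np.linalg.eigvalsh(graph.W * s[:, None] * s[None, :])
        logdetD = float(np.log(d_row).sum())

    # --- initial state -----------------------------------------------------
    cell_mean = np.divide(data.S.reshape(m, T),
                          np.maximum(data.k_all.reshape(m, T), 1.0))
    strat_mean = cell_mean.mean(axis=1)
    alpha = np.log(strat_mean + 0.1)
    beta = np.zeros(m)
    # fields start at prior scale (tau = 10) rather than exactly zero:
    # a zero field would make the first conjugate precision draw huge and
    # pin the field there (the usual funnel trap).
    eta = 0.2 * rng.standard_normal((m, T)) if spec.spatial_on \
        else np.zeros((m, T))
    gamma = 0.2 * rng.standard_normal((m, T)) if spec.temporal_on \
        else np.zeros((m, T))
    tau_eta = 10.0
    tau_gamma = 10.0
    rho = 0.0
    lam = 0.5 if estimate_lam else (
        float(spec.lam_mode) if spec.spatial_on and spec.lam_mode != "estimated"
        else 0.0)
    p_zero = 0.02 if zinb else 0.0
    theta = 0.0

    S2 = data.S.reshape(m, T)
    k0 = data.k0.reshape(m, T)
    k_pos = data.k_pos.reshape(m, T)
    k_act = k_pos + k0          # NB: every record active

    ab_blocks = _AdaptiveBlocks(m)
    eta_scale = _RMScale((m, T), init=0.5)
    gamma_scale = _RMScale((m, T), init=0.5)
    theta_scale = _RMScale((), init=0.3)
    rho_scale = _RMScale((), init=0.5)
    lam_scale = _RMScale((), init=0.8)
    eta_rescale = _RMScale((), init=0.3)
    gamma_rescale = _RMScale((), init=0.3)
    marg_scales = {k: _RMScale((), init=0.5)
                   for k in ("tau_eta", "lam", "tau_gamma", "rho")}
    shift_scale = _RMScale(m, init=0.1)
    tilt_scale = _RMScale(m, init=0.01)

    kappa = pri.gamma_center_prec
    gamma_bar = gamma.mean(axis=1)

    def fixed_lp():
        return alpha[:, None] + beta[:, None] * x[None, :]

    def theta_loglik(th, lp):
        n = np.exp(th)
        ll = (self_uy_cnt * gammaln(self_uy + n)).sum() \
            - data.n_pos * gammaln(n)
        ll += (k_act * n).sum() * th \
            - ((S2 + k_act * n) * np.log(n + np.exp(lp))).sum()
        return ll

    self_uy, self_uy_cnt = data.uy, data.uy_cnt

    lp = fixed_lp() + eta + gamma
    if not np.all(np.isfinite(_cell_loglik(lp, S2, k_act, np.exp(theta)))):
        raise InferenceError("non-finite likelihood at initialization")

    total = nwarm + nkeep * thin
    kept = 0
    for it in range(total):
        warm = it < nwarm
        n_size = np.exp(theta)

        # ---- zero augmentation and p_zero (ZINB) -------------------------
        if zinb:
            lp = fixed_lp() + eta + gamma
            mu = np.exp(lp)
            nb0 = np.exp(n_size * (np.log(n_size) - np.log(n_size + mu)))
            pi = np.where(k0 > 0,
                          p_zero / (p_zero + (1 - p_zero) * nb0), 0.0)
            k_struct = rng.binomial(k0.astype(int), pi)
            k_act = k_pos + (k0 - k_struct)
            K = k_struct.sum()
            p_zero = rng.beta(pri.p_zero_a + K, pri.p_zero_b + data.N - K)

        # ---- (alpha_j, beta_j) blocks ------------------------------------
        ab = np.column_stack([alpha, beta])
        prop = ab_blocks.propose(ab, rng)
        lp_cur = fixed_lp() + eta + gamma
        lp_new = prop[:, 0][:, None] + prop[:, 1][:, None] * x[None, :] \
            + eta + gamma
        ll_cur = _cell_loglik(lp_cur, S2, k_act, n_size).sum(axis=1)
        ll_new = _cell_loglik(lp_new, S2, k_act, n_size).sum(axis=1)
        dprior = (-0.5 * pri.alpha_prec
                  * ((prop[:, 0] - pri.alpha_mean) ** 2
                     - (ab[:, 0] - pri.alpha_mean) ** 2)
                  - 0.5 * pri.beta_prec
                  * ((prop[:, 1] - pri.beta_mean) ** 2
                     - (ab[:, 1] - pri.beta_mean) ** 2))
        delta = ll_new - ll_cur + dprior
        acc = np.log(rng.random(m)) < delta
        alpha = np.where(acc, prop[:, 0], alpha)
        beta = np.where(acc, prop[:, 1], beta)
        accept_tally["alpha_beta"] += acc.mean()
        if warm:
            ab_blocks.scale.update(acc)
            ab_blocks.observe(np.column_stack([alpha, beta]))

        # ---- spatial CAR field ------------------------------------------
        if spec.spatial_on:
            F = fixed_lp()
            for cls in classes:
                lp_c = F[cls] + eta[cls] + gamma[cls]
                step = eta_scale.s[cls] * rng.standard_normal((cls.size, T))
                e_new = eta[cls] + step
                ll_c = _cell_loglik(lp_c, S2[cls], k_act[cls], n_size)
                ll_n = _cell_loglik(lp_c + step, S2[cls], k_act[cls], n_size)
                nbr_mean = lam * (graph.W[cls] @ eta) / d_row[cls, None]
                dpr = -0.5 * tau_eta * d_row[cls, None] * (
                    (e_new - nbr_mean) ** 2 - (eta[cls] - nbr_mean) ** 2)
                acc = np.log(rng.random((cls.size, T))) < ll_n - ll_c + dpr
                eta[cls] = np.where(acc, e_new, eta[cls])
                accept_tally["eta"] += acc.mean() / len(classes)
                if warm:
                    eta_scale.log_s[cls] += (eta_scale.i + 1) ** -0.6 * (
                        acc.astype(float) - eta_scale.target)
            if warm:
                eta_scale.i += 1
                np.clip(eta_scale.log_s, -10, 4, out=eta_scale.log_s)

            quad_D = float((d_row[:, None] * eta**2).sum())
            quad_W = float((eta * (graph.W @ eta)).sum())
            tau_eta = rng.gamma(pri.tau_shape + 0.5 * m * T,
                                1.0 / (pri.tau_rate
                                       + 0.5 * (quad_D - lam * quad_W)))

            # joint rescale move (field, tau_eta) -> (field/sqrt(c), tau*c):
            # leaves the Gaussian field prior invariant up to the gamma
            # prior on tau, so the chain can traverse the variance funnel.
            c = float(np.exp(eta_rescale.s * rng.standard_normal()))
            F = fixed_lp()
            ll_cur = _cell_loglik(F + eta + gamma, S2, k_act, n_size).sum()
            ll_new = _cell_loglik(F + eta / np.sqrt(c) + gamma, S2, k_act,
                                  n_size).sum()
            d_acc = (ll_new - ll_cur + pri.tau_shape * np.log(c)
                     - pri.tau_rate * tau_eta * (c - 1.0))
            if np.log(rng.random()) < d_acc:
                tau_eta *= c
                eta /= np.sqrt(c)
            if warm:
                eta_rescale.update(float(np.exp(min(d_acc, 0.0))))

            if estimate_lam:
                z = logit(lam)
                z_new = z + lam_scale.s * rng.standard_normal()
                lam_new = float(expit(z_new))

                def lam_logpost(l, zval):
                    return (0.5 * T * np.log1p(-l * adj_eigs).sum()
                            + 0.5 * tau_eta * l * quad_W
                            - 0.5 * pri.lam_trans_prec
                            * (zval - pri.lam_trans_mean) ** 2)

                dl = lam_logpost(lam_new, z_new) - lam_logpost(lam, z)
                if np.log(rng.random()) < dl:
                    lam = lam_new
                    accept_tally["lam"] += 1.0
                if warm:
                    lam_scale.update(float(np.exp(min(dl, 0.0))))

        # ---- temporal AR(1) field ---------------------------------------
        if spec.temporal_on:
            F = fixed_lp()
            one_rho2 = 1.0 + rho**2
            for t in range(T):
                if T == 1:
                    prec_t, mean_t = tau_gamma, np.zeros(m)
                elif t == 0:
                    prec_t, mean_t = tau_gamma, rho * gamma[:, 1]
                elif t == T - 1:
                    prec_t, mean_t = tau_gamma, rho * gamma[:, T - 2]
                else:
                    prec_t = tau_gamma * one_rho2
                    mean_t = rho * (gamma[:, t - 1] + gamma[:, t + 1]) / one_rho2
                g = gamma[:, t]
                step = gamma_scale.s[:, t] * rng.standard_normal(m)
                g_new = g + step
                lp_t = F[:, t] + eta[:, t] + g
                ll_c = _cell_loglik(lp_t, S2[:, t], k_act[:, t], n_size)
                ll_n = _cell_loglik(lp_t + step, S2[:, t], k_act[:, t], n_size)
                dpr = -0.5 * prec_t * ((g_new - mean_t) ** 2
                                       - (g - mean_t) ** 2)
                dbar = gamma_bar + step / T
                dpr += -0.5 * kappa * (dbar**2 - gamma_bar**2)
                acc = np.log(rng.random(m)) < ll_n - ll_c + dpr
                gamma[:, t] = np.where(acc, g_new, g)
                gamma_bar = np.where(acc, dbar, gamma_bar)
                accept_tally["gamma"] += acc.mean() / T
                if warm:
                    gamma_scale.log_s[:, t] += (gamma_scale.i + 1) ** -0.6 * (
                        acc.astype(float) - gamma_scale.target)
            if warm:
                gamma_scale.i += 1
                np.clip(gamma_scale.log_s, -10, 4, out=gamma_scale.log_s)

            # exchange moves along the two likelihood-flat directions:
            # (alpha_j + d, gamma_j - d) and (beta_j + d, gamma_j - d*x)
            # leave every record's mean untouched, so acceptance is a
            # pure prior ratio; without them the confounded intercept/
            # trend components of the AR(1) residuals mix very slowly.
            delta = shift_scale.s * rng.standard_normal(m)
            g_new = gamma - delta[:, None]
            dpr = -0.5 * tau_gamma * (ar1_quadform(g_new, rho)
                                      - ar1_quadform(gamma, rho))
            gb_new = gamma_bar - delta
            dpr += -0.5 * kappa * (gb_new**2 - gamma_bar**2)
            a_new = alpha + delta
            dpr += -0.5 * pri.alpha_prec * ((a_new - pri.alpha_mean) ** 2
                                            - (alpha - pri.alpha_mean) ** 2)
            acc = np.log(rng.random(m)) < dpr
            alpha = np.where(acc, a_new, alpha)
            gamma = np.where(acc[:, None], g_new, gamma)
            gamma_bar = np.where(acc, gb_new, gamma_bar)
            if warm:
                shift_scale.update(acc)

            delta = tilt_scale.s * rng.standard_normal(m)
            g_new = gamma - delta[:, None] * x[None, :]
            dpr = -0.5 * tau_gamma * (ar1_quadform(g_new, rho)
                                      - ar1_quadform(gamma, rho))
            gb_new = gamma_bar - delta * x.mean()
            dpr += -0.5 * kappa * (gb_new**2 - gamma_bar**2)
            b_new = beta + delta
            dpr += -0.5 * pri.beta_prec * ((b_new - pri.beta_mean) ** 2
                                           - (beta - pri.beta_mean) ** 2)
            acc = np.log(rng.random(m)) < dpr
            beta = np.where(acc, b_new, beta)
            gamma = np.where(acc[:, None], g_new, gamma)
            gamma_bar = np.where(acc, gb_new, gamma_bar)
            if warm:
                tilt_scale.update(acc)

            qf = float(ar1_quadform(gamma, rho).sum())
            tau_gamma = rng.gamma(pri.tau_shape + 0.5 * m * T,
                                  1.0 / (pri.tau_rate + 0.5 * qf))

            # joint rescale move, as for the spatial field; the AR(1)
            # quadratic form scales exactly by 1/c, and the soft
            # centering prior on the series means is included.
            c = float(np.exp(gamma_rescale.s * rng.standard_normal()))
            rt_c = np.sqrt(c)
            F = fixed_lp()
            ll_cur = _cell_loglik(F + eta + gamma, S2, k_act, n_size).sum()
            ll_new = _cell_loglik(F + eta + gamma / rt_c, S2, k_act,
                                  n_size).sum()
            d_acc = (ll_new - ll_cur + pri.tau_shape * np.log(c)
                     - pri.tau_rate * tau_gamma * (c - 1.0)
                     - 0.5 * kappa * ((gamma_bar**2).sum() / c
                                      - (gamma_bar**2).sum()))
            if np.log(rng.random()) < d_acc:
                tau_gamma *= c
                gamma /= rt_c
                gamma_bar /= rt_c
            if warm:
                gamma_rescale.update(float(np.exp(min(d_acc, 0.0))))

            z = np.log((1 + rho) / (1 - rho))
            z_new = z + rho_scale.s * rng.standard_normal()
            rho_new = float(np.tanh(z_new / 2.0))

            def rho_logpost(r, zval):
                return (0.5 * m * np.log1p(-r**2)
                        - 0.5 * tau_gamma * ar1_quadform(gamma, r).sum()
                        - 0.5 * pri.rho_trans_prec
                        * (zval - pri.rho_trans_mean) ** 2)

            dr = rho_logpost(rho_new, z_new) - rho_logpost(rho, z)
            if np.log(rng.random()) < dr:
                rho = rho_new
                accept_tally["rho"] += 1.0
            if warm:
                rho_scale.update(float(np.exp(min(dr, 0.0))))

        # ---- collapsed hyper updates + exact field re-decomposition ------
        # The likelihood sees only zeta = eta + gamma, so (i) the
        # hyperparameters can be updated against the *marginal* density
        # of zeta (the split integrated out: zeta is Gaussian with
        # covariance Qe^{-1} (+) Qg^{-1}, a Kronecker sum diagonal in the
        # product of the CAR and AR(1) eigenbases), and (ii) the split
        # itself is then resampled exactly from its Gaussian conditional
        # given zeta.  Without this partially-collapsed step one field
        # permanently absorbs the other's share — a mode trap that
        # single-site moves cannot escape.
        if spec.spatial_on and spec.temporal_on:
            zeta = eta + gamma
            center_pen = (kappa / T**2) * np.ones((T, T))

            def _marg(te, l, tg, r):
                le, Ue = np.linalg.eigh(te * (graph.D - l * graph.W))
                Qg = np.diag(tg * one_rho2_diag(r, T)) + center_pen
                off = -tg * r * np.ones(T - 1)
                Qg += np.diag(off, 1) + np.diag(off, -1)
                lt, Ut = np.linalg.eigh(Qg)
                v = 1.0 / le[:, None] + 1.0 / lt[None, :]
                Zc = Ue.T @ zeta @ Ut
                ll = -0.5 * float((np.log(v) + Zc**2 / v).sum())
                return ll, (le, Ue, lt, Ut)

            cur_ll, eig = _marg(tau_eta, lam, tau_gamma, rho)
            a0, b0 = pri.tau_shape, pri.tau_rate

            for _sweep in range(3):
                # log tau_eta
                u = np.log(tau_eta)
                u_new = u + marg_scales["tau_eta"].s * rng.standard_normal()
                new_ll, new_eig = _marg(np.exp(u_new), lam, tau_gamma, rho)
                d = (new_ll - cur_ll + a0 * (u_new - u)
                     - b0 * (np.exp(u_new) - np.exp(u)))
                if np.log(rng.random()) < d:
                    tau_eta, cur_ll, eig = float(np.exp(u_new)), new_ll, \
                        new_eig
                if warm:
                    marg_scales["tau_eta"].update(float(np.exp(min(d, 0.0))))

                # logit lam
                if estimate_lam:
                    z = logit(lam)
                    z_new = z + marg_scales["lam"].s * rng.standard_normal()
                    lam_new = float(expit(z_new))
                    new_ll, new_eig = _marg(tau_eta, lam_new, tau_gamma, rho)
                    d = (new_ll - cur_ll - 0.5 * pri.lam_trans_prec
                         * ((z_new - pri.lam_trans_mean) ** 2
                            - (z - pri.lam_trans_mean) ** 2))
                    if np.log(rng.random()) < d:
                        lam, cur_ll, eig = lam_new, new_ll, new_eig
                    if warm:
                        marg_scales["lam"].update(float(np.exp(min(d, 0.0))))

                # log tau_gamma
                u = np.log(tau_gamma)
                u_new = u + marg_scales["tau_gamma"].s * rng.standard_normal()
                new_ll, new_eig = _marg(tau_eta, lam, np.exp(u_new), rho)
                d = (new_ll - cur_ll + a0 * (u_new - u)
                     - b0 * (np.exp(u_new) - np.exp(u)))
                if np.log(rng.random()) < d:
                    tau_gamma, cur_ll, eig = float(np.exp(u_new)), new_ll, \
                        new_eig
                if warm:
                    marg_scales["tau_gamma"].update(
                        float(np.exp(min(d, 0.0))))

                # transformed rho
                z = np.log((1 + rho) / (1 - rho))
                z_new = z + marg_scales["rho"].s * rng.standard_normal()
                rho_new = float(np.tanh(z_new / 2.0))
                new_ll, new_eig = _marg(tau_eta, lam, tau_gamma, rho_new)
                d = (new_ll - cur_ll - 0.5 * pri.rho_trans_prec
                     * ((z_new - pri.rho_trans_mean) ** 2
                        - (z - pri.rho_trans_mean) ** 2))
                if np.log(rng.random()) < d:
                    rho, cur_ll, eig = rho_new, new_ll, new_eig
                if warm:
                    marg_scales["rho"].update(float(np.exp(min(d, 0.0))))

            # exact re-split of zeta into (eta, gamma)
            le, Ue, lt, Ut = eig
            Z = Ue.T @ zeta @ Ut
            denom = le[:, None] + lt[None, :]
            mean = (lt[None, :] * Z) / denom
            X = mean + rng.standard_normal((m, T)) / np.sqrt(denom)
            eta = Ue @ X @ Ut.T
            gamma = zeta - eta
            gamma_bar = gamma.mean(axis=1)

        # ---- theta (log NB size) ----------------------------------------
        lp = fixed_lp() + eta + gamma
        th_new = theta + theta_scale.s * rng.standard_normal()
        dth = (theta_loglik(th_new, lp) - theta_loglik(theta, lp)
               - 0.5 * pri.theta_prec * ((th_new - pri.theta_mean) ** 2
                                         - (theta - pri.theta_mean) ** 2))
        if np.log(rng.random()) < dth:
            theta = float(th_new)
            accept_tally["theta"] += 1.0
        if warm:
            theta_scale.update(float(np.exp(min(dth, 0.0))))

        # ---- bookkeeping -------------------------------------------------
        if not warm and (it - nwarm) % thin == 0:
            lp = fixed_lp() + eta + gamma
            mu = np.exp(lp)
            mu_rec = mu.reshape(-1)[data.cell]
            dev = observation.deviance(data.y, mu_rec, np.exp(theta),
                                       p_zero, model=spec.data_model)
            dev_out[kept] = dev
            store["alpha"][kept] = alpha
            store["beta"][kept] = beta
            if spec.spatial_on:
                store["eta"][kept] = eta
                store["tau_eta"][kept] = tau_eta
                if estimate_lam:
                    store["lam"][kept] = lam
            if spec.temporal_on:
                store["gamma"][kept] = gamma
                store["tau_gamma"][kept] = tau_gamma
                store["rho"][kept] = rho
            if zinb:
                store["p_zero"][kept] = p_zero
            store["theta"][kept] = theta
            accum["mu"] += mu
            accum["p_zero"] += p_zero
            accum["theta"] += theta
            accum["count"] += 1
            kept += 1

    return LatentState(alpha=alpha.copy(), beta=beta.copy(), eta=eta.copy(),
                       gamma=gamma.copy(), tau_eta=tau_eta,
                       tau_gamma=tau_gamma, rho=rho, lam=lam, p_zero=p_zero,
                       theta=theta)


def fit_model(counts: pd.DataFrame, graph: StrataGraph, spec: ModelSpec,
              settings: SamplerSettings = None) -> PosteriorResult:
    """Sample the joint posterior for one model specification.

    Parameters
    ----------
    counts : DataFrame
        Long-format records with columns ``stratum``, ``count`` and
        ``year`` (or ``year_index``); segments are rows.
    graph : StrataGraph
        Neighbourhood structure; every record's stratum must be present.
    spec : ModelSpec
        Data model x random-effect configuration and priors.
    settings : SamplerSettings
        Chains, warmup, kept draws, seed.

    Returns
    -------
    PosteriorResult
        With per-parameter summaries, ESS/split-Rhat diagnostics, the
        deviance trace and DIC.  Reproducible given seed and settings.
    """
    if settings is None:
        settings = SamplerSettings()
    data = _FitData(counts, graph)
    zinb = spec.data_model == "zinb"
    estimate_lam = spec.spatial_on and spec.lam_mode == "estimated"

    m, T = data.m, data.T
    C, K = settings.chains, settings.draws

    def empty(shape=()):
        return np.empty((C, K) + shape)

    draws = {"alpha": empty((m,)), "beta": empty((m,)), "theta": empty()}
    if spec.spatial_on:
        draws["eta"] = empty((m, T))
        draws["tau_eta"] = empty()
        if estimate_lam:
            draws["lam"] = empty()
    if spec.temporal_on:
        draws["gamma"] = empty((m, T))
        draws["tau_gamma"] = empty()
        draws["rho"] = empty()
    if zinb:
        draws["p_zero"] = empty()
    deviance = np.empty((C, K))
    accum = {"mu": np.zeros((m, T)), "p_zero": 0.0, "theta": 0.0, "count": 0}
    accept_tally = {k: 0.0 for k in
                    ("alpha_beta", "eta", "gamma", "rho", "lam", "theta")}

    seeds = np.random.SeedSequence(settings.seed).spawn(C)
    example = None
    for c in range(C):
        rng = np.random.default_rng(seeds[c])
        chain_store = {k: draws[k][c] for k in draws}
        example = _run_chain(data, graph, spec, settings, rng, chain_store,
                             deviance[c], accum, accept_tally)

    total_iters = C * (settings.warmup + settings.draws * settings.thin)
    accept_rates = {k: v / total_iters for k, v in accept_tally.items()
                    if v > 0 or k in ("alpha_beta",)}

    mu_mean = accum["mu"] / accum["count"]
    p_mean = accum["p_zero"] / accum["count"]
    th_mean = accum["theta"] / accum["count"]
    mu_rec = mu_mean.reshape(-1)[data.cell]
    dhat = observation.deviance(data.y, mu_rec, float(np.exp(th_mean)),
                                float(p_mean), model=spec.data_model)

    flags = []
    for k, v in accept_rates.items():
        if v < 0.05:
            flags.append(f"low acceptance rate for {k}: {v:.3f}")
    if C < 2:
        flags.append("single chain: split-Rhat unreliable")

    result = PosteriorResult(
        draws=draws, deviance=deviance, deviance_at_mean=float(dhat),
        stratum_ids=graph.stratum_ids, x=data.x, base_year=data.base_year,
        spec=spec, settings=settings, mu_mean=mu_mean,
        accept_rates=accept_rates, flags=flags, example_draw=example)
    dbar, pd_, dic = compute_dic(result)
    result.dic = {"Dbar": dbar, "pD": pd_, "DIC": dic}
    if pd_ < 0:
        result.flags.append(f"negative pD ({pd_:.2f}); DIC unreliable")
    result.summary = _summarize(result)
    return result


def _summarize(result: PosteriorResult) -> pd.DataFrame:
    """Posterior mean/sd/quantiles plus ESS and split-Rhat per element."""
    import arviz as az

    ds = az.convert_to_dataset({k: v for k, v in result.draws.items()})
    with np.errstate(invalid="ignore"):
        if result.n_chains >= 2:
            rhat = az.rhat(ds)
            ess = az.ess(ds)
        else:
            rhat = ess = None
    rows = []
    for name, arr in result.draws.items():
        flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
        labels = _element_labels(name, arr.shape[2:], result.stratum_ids)
        q = np.quantile(flat, [0.025, 0.5, 0.975], axis=0)
        r = (np.asarray(rhat[name]).reshape(-1) if rhat is not None
             else np.full(flat.shape[1], np.nan))
        e = (np.asarray(ess[name]).reshape(-1) if ess is not None
             else np.full(flat.shape[1], np.nan))
        for i, lab in enumerate(labels):
            rows.append((lab, flat[:, i].mean(), flat[:, i].std(ddof=1),
                         q[0, i], q[1, i], q[2, i], e[i], r[i]))
    return pd.DataFrame(rows, columns=["parameter", "mean", "sd", "q2.5",
                                       "q50", "q97.5", "ess", "rhat"])


def compute_dic(result: PosteriorResult):
    """Spiegelhalter DIC from the stored deviance trace.

    Dbar is the posterior-mean deviance; Dhat the deviance at the
    posterior means of the likelihood inputs; pD = Dbar - Dhat and
    DIC = Dbar + pD.  Negative pD is returned as-is (flagged upstream,
    never clipped).
    """
    if result.deviance is None or result.deviance.size == 0:
        raise ValueError("no deviance trace available")
    dbar = float(result.deviance.mean())
    pd_ = dbar - float(result.deviance_at_mean)
    return dbar, pd_, dbar + pd_


def compare_models(counts: pd.DataFrame, graph: StrataGraph, specs,
                   settings: SamplerSettings = None,
                   labels=None) -> pd.DataFrame:
    """Fit several model specifications and rank them by DIC.

    Returns a DataFrame (label, Dbar, pD, DIC, dDIC, error) sorted
    ascending by DIC; individual fit failures are recorded per-row and
    the comparison proceeds with the survivors.
    """
    specs = list(specs)
    if len(specs) < 2:
        raise ValueError("need at least 2 model specifications to compare")
    if labels is None:
        labels = [s.label for s in specs]
    rows = []
    for lab, spec in zip(labels, specs):
        try:
            res = fit_model(counts, graph, spec, settings)
            rows.append({"label": lab, "Dbar": res.dic["Dbar"],
                         "pD": res.dic["pD"], "DIC": res.dic["DIC"],
                         "error": ""})
        except Exception as err:  # recorded, comparison continues
            rows.append({"label": lab, "Dbar": np.nan, "pD": np.nan,
                         "DIC": np.nan, "error": str(err)})
    df = pd.DataFrame(rows).sort_values(
        "DIC", na_position="last").reset_index(drop=True)
    df["dDIC"] = df["DIC"] - df["DIC"].min()
    return df[["label", "Dbar", "pD", "DIC", "dDIC", "error"]]
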