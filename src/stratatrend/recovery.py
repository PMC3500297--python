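"""Replicate simulation-and-refit harnesses.

These drive the end-to-end checks the package is validated with:
simulate from known parameters, refit, and score interval coverage,
posterior-mean bias, DIC model ranking and trend-sign recovery across
replicates.  They are ordinary library code (the acceptance script and
the test suite both call them) rather than test fixtures.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .inference import SamplerSettings, compare_models, fit_model
from .process import ModelSpec
from .reporting import classify_trends
from .synthetic import SimConfig, simulate_dataset

__all__ = ["recovery_study", "dic_preference_study", "trend_sign_study"]


def _interval(summary: pd.DataFrame, name: str):
    row = summary.set_index("parameter").loc[name]
    return float(row["mean"]), float(row["q2.5"]), float(row["q97.5"])


def recovery_study(base_config: SimConfig, spec: ModelSpec,
                   settings: SamplerSettings, n_reps: int,
                   seed: int) -> pd.DataFrame:
    """Simulate/refit ``n_reps`` datasets; score beta coverage and
    hyperparameter recovery.

    Each replicate draws fresh fixed effects and fields from
    ``base_config`` (only the seed changes) and is refit with ``spec``.
    Returns one row per replicate: the fraction of beta_j 95% intervals
    covering their truths, and posterior mean / truth pairs for rho,
    p_zero and theta.
    """
    rows = []
    rep_seeds = np.random.SeedSequence(seed).generate_state(2 * n_reps) \
        % (2**31 - 1)
    for r in range(n_reps):
        cfg = replace(base_config, seed=int(rep_seeds[2 * r]))
        sim = simulate_dataset(cfg)
        fit_settings = replace(settings, seed=int(rep_seeds[2 * r + 1]))
        res = fit_model(sim.counts, sim.graph, spec, fit_settings)
        summ = res.summary
        covered = 0
        for i, sid in enumerate(res.stratum_ids):
            _, lo, hi = _interval(summ, f"beta[{sid}]")
            covered += lo <= sim.truth.beta[i] <= hi
        row = {"rep": r, "beta_coverage": covered / len(res.stratum_ids)}
        for name, true_val in (("rho", sim.truth.rho),
                               ("p_zero", sim.truth.p_zero),
                               ("theta", sim.truth.theta)):
            if name in res.draws:
                mean, lo, hi = _interval(summ, name)
                row[f"{name}_mean"] = mean
                row[f"{name}_true"] = true_val
                row[f"{name}_covered"] = lo <= true_val <= hi
        rows.append(row)
    return pd.DataFrame(rows)


def dic_preference_study(base_config: SimConfig, spec_a: ModelSpec,
                         spec_b: ModelSpec, settings: SamplerSettings,
                         n_reps: int, seed: int) -> pd.DataFrame:
    """Across replicates, does DIC prefer ``spec_a`` over ``spec_b``?

    Returns one row per replicate with both DIC values and the
    preference indicator (True when spec_a has the lower DIC).
    """
    rows = []
    rep_seeds = np.random.SeedSequence(seed).generate_state(2 * n_reps) \
        % (2**31 - 1)
    for r in range(n_reps):
        cfg = replace(base_config, seed=int(rep_seeds[2 * r]))
        sim = simulate_dataset(cfg)
        fit_settings = replace(settings, seed=int(rep_seeds[2 * r + 1]))
        table = compare_models(sim.counts, sim.graph, [spec_a, spec_b],
                               fit_settings,
                               labels=["a", "b"]).set_index("label")
        dic_a, dic_b = table.loc["a", "DIC"], table.loc["b", "DIC"]
        rows.append({"rep": r, "dic_a": dic_a, "dic_b": dic_b,
                     "a_preferred": bool(dic_a < dic_b)})
    return pd.DataFrame(rows)


def trend_sign_study(base_config: SimConfig, spec: ModelSpec,
                     settings: SamplerSettings, n_reps: int,
                     seed: int, strong_cut: float = 0.05) -> pd.DataFrame:
    """Trend-classification recovery for strata with strong true slopes.

    Strata whose true |beta| exceeds ``strong_cut`` are "strong"; a
    replicate recovers the sign pattern when every strong stratum is
    classified on the correct side of zero.  Returns one row per
    replicate with the per-stratum hit count and the all-correct flag.
    """
    rows = []
    rep_seeds = np.random.SeedSequence(seed).generate_state(2 * n_reps) \
        % (2**31 - 1)
    for r in range(n_reps):
        cfg = replace(base_config, seed=int(rep_seeds[2 * r]))
        sim = simulate_dataset(cfg)
        fit_settings = replace(settings, seed=int(rep_seeds[2 * r + 1]))
        res = fit_model(sim.counts, sim.graph, spec, fit_settings)
        table = classify_trends(res).set_index("stratum")
        hits, n_strong = 0, 0
        for i, sid in enumerate(res.stratum_ids):
            b = sim.truth.beta[i]
            if abs(b) <= strong_cut:
                continue
            n_strong += 1
            want = "increasing" if b > 0 else "decreasing"
            hits += table.loc[sid, "class"] == want
        rows.append({"rep": r, "n_strong": n_strong, "hits": hits,
                     "all_correct": hits == n_strong})
    return pd.DataFrame(rows)
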