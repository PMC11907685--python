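"""Posterior summaries and the desk-scale simulation study driver."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata

from . import glm, protocol_sim
from .gibbs import PosteriorSamples, SamplerConfig, run_chain
from .group_data import AssayAccuracy

__all__ = [
    "variable_inclusion", "predict_prob", "auc", "coverage",
    "accuracy_summary", "StudyConfig", "run_simulation_study",
    "dorfman_accuracy_study", "glm_recovery_study",
]


def variable_inclusion(split_counts: np.ndarray,
                       totals: Optional[np.ndarray] = None) -> np.ndarray:
    """Variable inclusion proportions v_q averaged over posterior draws.

    ``split_counts[s, q]`` is the number of decision rules splitting on
    covariate q in draw s.  Draws with no rules at all contribute a uniform
    1/Q to every covariate so that v stays a proper distribution.
    """
    counts = np.atleast_2d(np.asarray(split_counts, dtype=float))
    S, Q = counts.shape
    tot = counts.sum(axis=1) if totals is None else np.asarray(totals, float)
    frac = np.full((S, Q), 1.0 / Q)
    nz = tot > 0
    frac[nz] = counts[nz] / tot[nz, None]
    return frac.mean(axis=0)


def predict_prob(eta_draws: np.ndarray, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean and equal-tail quantiles of Phi(eta) per query row."""
    p = ndtr(np.atleast_2d(np.asarray(eta_draws, dtype=float)))
    a = (1.0 - level) / 2.0
    return pd.DataFrame({
        "mean": p.mean(axis=0),
        "lower": np.quantile(p, a, axis=0),
        "upper": np.quantile(p, 1.0 - a, axis=0),
    })


def auc(scores, truth) -> float:
    """Rank-statistic AUC: P(random positive outscores random negative),
    ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both a positive and a negative example")
    ranks = rankdata(scores)
    r_pos = ranks[truth == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def coverage(intervals: Sequence, truths) -> float:
    """Fraction of truths inside their closed interval [lo, hi]."""
    truths = np.asarray(truths, dtype=float)
    intervals = list(intervals)
    if len(intervals) != truths.shape[0]:
        raise ValueError("intervals and truths differ in length")
    lo = np.array([iv[0] for iv in intervals], dtype=float)
    hi = np.array([iv[1] for iv in intervals], dtype=float)
    if np.any(lo > hi):
        raise ValueError("interval with lo > hi")
    return float(np.mean((truths >= lo) & (truths <= hi)))


def effective_sample_size(draws: np.ndarray) -> float:
    """Bulk effective sample size of a single chain of draws (reported as a
    convergence diagnostic, never auto-enforced)."""
    import arviz as az
    return float(az.ess(np.asarray(draws, dtype=float)[None, :]))


def accuracy_summary(samples: PosteriorSamples, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean, equal-tail interval and ESS of (Se, Sp) per stratum."""
    a = (1.0 - level) / 2.0
    rows = []
    for name, draws in (("Se", samples.se), ("Sp", samples.sp)):
        for l in range(draws.shape[1]):
            d = draws[:, l]
            rows.append({"parameter": name, "stratum": l + 1,
                         "mean": d.mean(),
                         "lower": float(np.quantile(d, a)),
                         "upper": float(np.quantile(d, 1.0 - a)),
                         "ess": (effective_sample_size(d)
                                 if np.ptp(d) > 0 else float(len(d)))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation study driver
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Replicated simulate-fit-evaluate experiment.

    ``se_truth``/``sp_truth`` give the generating accuracies per stratum
    (stratum 1 = master pools / IT, stratum 2 = DT retests).  When
    ``estimate_accuracy`` is true all strata get flat beta priors and are
    estimated; otherwise they are treated as known.
    """

    models: Sequence[str] = ("M3",)
    protocols: Sequence[str] = ("DT",)
    methods: Sequence[str] = ("bart",)   # "bart" and/or "glm"
    reps: int = 10
    n: int = 1000
    n_out: int = 1000
    pool_size: int = 4
    K: int = 20
    n_burn: int = 1000
    n_keep: int = 1000
    se_truth: Sequence[float] = (0.95, 0.98)
    sp_truth: Sequence[float] = (0.98, 0.99)
    estimate_accuracy: bool = False
    seed: int = 0
    level: float = 0.95


def _make_accuracy(cfg: StudyConfig) -> AssayAccuracy:
    if cfg.estimate_accuracy:
        return AssayAccuracy.uniform_prior(cfg.se_truth, cfg.sp_truth)
    return AssayAccuracy.fixed(cfg.se_truth, cfg.sp_truth)


def _fit_rows(cfg: StudyConfig, method, data, truth, out_truth, seed):
    scfg = SamplerConfig(K=cfg.K, n_burn=cfg.n_burn, n_keep=cfg.n_keep,
                         seed=seed)
    acc = _make_accuracy(cfg)
    if method == "bart":
        post = run_chain(data, acc, scfg, X_query=out_truth.X)
    elif method == "glm":
        post = glm.run_glm_chain(data, acc, scfg, X_query=out_truth.X)
    else:
        raise ValueError(f"unknown method {method!r}")

    rows = {}
    p_in = ndtr(post.eta).mean(axis=0)
    p_out = ndtr(post.eta_query).mean(axis=0)
    for name, scores, y in (("auc_in", p_in, truth.y_true),
                            ("auc_out", p_out, out_truth.y_true)):
        try:
            rows[name] = auc(scores, y)
        except ValueError:   # degenerate single-class sample
            pass
    a = (1.0 - cfg.level) / 2.0
    for l in range(post.se.shape[1]):
        for name, draws in (("se", post.se[:, l]), ("sp", post.sp[:, l])):
            rows[f"{name}{l + 1}_mean"] = float(draws.mean())
            rows[f"{name}{l + 1}_lower"] = float(np.quantile(draws, a))
            rows[f"{name}{l + 1}_upper"] = float(np.quantile(draws, 1.0 - a))
    if post.split_counts is not None:
        v = variable_inclusion(post.split_counts)
        for q in range(len(v)):
            rows[f"v{q + 1}"] = float(v[q])
    if post.beta is not None:
        for p in range(post.beta.shape[1]):
            rows[f"beta{p}_mean"] = float(post.beta[:, p].mean())
            rows[f"beta{p}_lower"] = float(np.quantile(post.beta[:, p], a))
            rows[f"beta{p}_upper"] = float(np.quantile(post.beta[:, p], 1.0 - a))
    return rows


def run_simulation_study(cfg: StudyConfig) -> pd.DataFrame:
    """Run the replicated study; one tidy row per
    (replicate, model, protocol, method, metric)."""
    records = []
    for r in range(cfg.reps):
        for mi, model in enumerate(cfg.models):
            for pi, protocol in enumerate(cfg.protocols):
                sim_seed = _derived_seed(cfg.seed, r, mi, pi, 0)
                design = protocol_sim.SimulationDesign(
                    model=model, N=cfg.n, protocol=protocol,
                    accuracy_truth=AssayAccuracy.fixed(cfg.se_truth,
                                                       cfg.sp_truth),
                    seed=sim_seed, pool_size=cfg.pool_size)
                truth, data = protocol_sim.simulate_dataset(design)
                out_design = protocol_sim.SimulationDesign(
                    model=model, N=cfg.n_out, protocol="IT",
                    accuracy_truth=AssayAccuracy.fixed(cfg.se_truth[:1],
                                                       cfg.sp_truth[:1]),
                    seed=_derived_seed(cfg.seed, r, mi, pi, 1),
                    pool_size=1)
                out_truth = protocol_sim.simulate_statuses(out_design)
                for me, method in enumerate(cfg.methods):
                    fit_seed = _derived_seed(cfg.seed, r, mi, pi, 2 + me)
                    metrics = _fit_rows(cfg, method, data, truth,
                                        out_truth, fit_seed)
                    for metric, value in metrics.items():
                        records.append({
                            "replicate": r, "model": model,
                            "protocol": protocol, "method": method,
                            "metric": metric, "value": value,
                        })
    return pd.DataFrame.from_records(records)


def _derived_seed(base: int, *path: int) -> int:
    return int(np.random.SeedSequence((base,) + path).generate_state(1)[0])


# canonical desk-scale experiment presets -----------------------------------

def dorfman_accuracy_study(seed: int, reps: int = 10, n: int = 1000,
                           n_burn: int = 1000, n_keep: int = 1000) -> StudyConfig:
    """Two-stage Dorfman design with all four accuracies unknown (flat beta
    priors): generating truths Se=(0.95, 0.98), Sp=(0.98, 0.99), model M3,
    pools of 4, BART with K=20."""
    return StudyConfig(models=["M3"], protocols=["DT"], methods=["bart"],
                       reps=reps, n=n, n_out=250, pool_size=4, K=20,
                       n_burn=n_burn, n_keep=n_keep,
                       se_truth=(0.95, 0.98), sp_truth=(0.98, 0.99),
                       estimate_accuracy=True, seed=seed)


def glm_recovery_study(seed: int, reps: int = 50, n: int = 2000,
                       n_burn: int = 1000, n_keep: int = 1000) -> StudyConfig:
    """Probit-GLM coefficient recovery under the linear model M2 with known
    accuracies Se=0.95, Sp=0.98 applied to both Dorfman strata."""
    return StudyConfig(models=["M2"], protocols=["DT"], methods=["glm"],
                       reps=reps, n=n, n_out=250, pool_size=4,
                       n_burn=n_burn, n_keep=n_keep,
                       se_truth=(0.95, 0.95), sp_truth=(0.98, 0.98),
                       estimate_accuracy=False, seed=seed)
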