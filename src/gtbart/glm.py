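"""Bayesian probit GLM comparator for group testing data.

Shares the latent-status / omega / accuracy updates with the tree sampler;
the surface model is ``eta_i = w_i' beta`` with a conjugate multivariate
normal coefficient draw given omega.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError

from .gibbs import (LatentState, PosteriorSamples, SamplerConfig,
                    sample_all_statuses, sample_omega, update_accuracy)
from .group_data import AssayAccuracy, GroupTestingData, validate

__all__ = ["GlmSpec", "design_matrix", "sample_beta", "run_glm_chain"]


@dataclass
class GlmSpec:
    """Probit GLM specification: linear covariate effects plus intercept,
    with a proper but diffuse N(mean, cov) coefficient prior."""

    intercept: bool = True
    prior_mean: Optional[np.ndarray] = None
    prior_cov: Optional[np.ndarray] = None
    prior_scale: float = 100.0    # default prior is N(0, prior_scale * I)

    def resolve(self, P: int):
        mean = (np.zeros(P) if self.prior_mean is None
                else np.asarray(self.prior_mean, dtype=float))
        cov = (self.prior_scale * np.eye(P) if self.prior_cov is None
               else np.asarray(self.prior_cov, dtype=float))
        if mean.shape != (P,) or cov.shape != (P, P):
            raise ValueError(f"prior dimensions do not match P={P}")
        return mean, cov


def design_matrix(X: np.ndarray, spec: GlmSpec) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if spec.intercept:
        return np.column_stack([np.ones(X.shape[0]), X])
    return X.copy()


def sample_beta(omega: np.ndarray, W: np.ndarray, spec: GlmSpec,
                rng: np.random.Generator) -> np.ndarray:
    """One conjugate draw of beta given the Gaussian latents.

    Posterior is ``N(V (W'omega + C0^-1 m0), V)`` with
    ``V = (W'W + C0^-1)^-1``.
    """
    W = np.atleast_2d(W)
    P = W.shape[1]
    m0, C0 = spec.resolve(P)
    C0_inv = np.linalg.inv(C0)
    prec = W.T @ W + C0_inv
    try:
        cf = cho_factor(prec)
    except LinAlgError as err:
        raise ValueError("singular posterior precision for beta") from err
    mean = cho_solve(cf, W.T @ np.asarray(omega, dtype=float) + C0_inv @ m0)
    # draw via upper-Cholesky of the precision: mean + U^-1 z
    U = cholesky(prec, lower=False)
    z = rng.standard_normal(P)
    return mean + np.linalg.solve(U, z)


def run_glm_chain(data: GroupTestingData, accuracy: AssayAccuracy,
                  config: SamplerConfig, spec: Optional[GlmSpec] = None,
                  X_query: Optional[np.ndarray] = None) -> PosteriorSamples:
    """Gibbs chain identical to the tree sampler's scan, with the ensemble
    update replaced by the conjugate coefficient draw."""
    problems = validate(data)
    if problems:
        raise ValueError("invalid group testing data: " + "; ".join(problems))
    spec = spec or GlmSpec()
    rng = np.random.default_rng(config.seed)
    acc = accuracy.copy()

    W = design_matrix(data.X, spec)
    P = W.shape[1]
    beta = np.zeros(P)
    state = LatentState.initial(data, W @ beta)
    # same data-informed accuracy start as the tree sampler (see gibbs.py)
    update_accuracy(state, data, acc, rng)
    W_query = None if X_query is None else design_matrix(X_query, spec)

    S, L = config.n_keep, acc.L
    out = PosteriorSamples(
        eta=np.empty((S, data.N)),
        se=np.empty((S, L)), sp=np.empty((S, L)),
        beta=np.empty((S, P)),
        eta_query=None if X_query is None else np.empty((S, len(X_query))),
        meta={"sampler": "glm", "n_burn": config.n_burn,
              "n_keep": config.n_keep, "thin": config.thin,
              "seed": config.seed, "intercept": spec.intercept},
    )

    total = config.n_burn + config.n_keep * config.thin
    kept = 0
    y_acc = np.zeros(data.N)
    for it in range(total):
        sample_all_statuses(state, data, acc, rng)
        sample_omega(state, rng)
        beta = sample_beta(state.omega, W, spec, rng)
        state.eta = W @ beta
        update_accuracy(state, data, acc, rng)
        if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
            y_acc += state.Y
            out.eta[kept] = state.eta
            out.se[kept] = acc.se
            out.sp[kept] = acc.sp
            out.beta[kept] = beta
            if X_query is not None:
                out.eta_query[kept] = W_query @ beta
            kept += 1
    out.y_mean = y_acc / S
    return out
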