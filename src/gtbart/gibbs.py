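"""Posterior sampler for probit regression from misclassified pooled tests.

One sweep updates, in a fixed order,

1. the latent true statuses ``Y~`` (sequential Gibbs scan, each individual
   conditional on all others through its pools' other-positive counts),
2. the truncated-normal latents ``omega`` (Albert-Chib augmentation),
3. the surface model given ``omega`` (tree-ensemble backfitting here; the
   probit GLM in :mod:`gtbart.glm` swaps in a conjugate coefficient draw),
4. the per-stratum assay accuracies via conjugate beta updates (strata
   flagged ``known`` are left untouched).

The status scan is the hot loop and is compiled with numba; randomness is
pre-drawn with a numpy Generator so runs are bit-reproducible under a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy.special import log_ndtr, ndtr, ndtri

from .group_data import AssayAccuracy, GroupTestingData, validate
from .tree_model import (Tree, TreePrior, make_cutpoints, propose_tree,
                         tree_integrated_loglik, tree_log_prior)

__all__ = [
    "SamplerConfig", "LatentState", "PosteriorSamples", "prepare",
    "latent_status_probability", "sample_all_statuses", "sample_omega",
    "update_accuracy", "TreeEnsembleSampler", "run_chain",
]


@dataclass
class SamplerConfig:
    K: int = 200
    n_burn: int = 2500
    n_keep: int = 2500
    thin: int = 1
    seed: int = 0
    alpha: float = 0.95
    beta: float = 2.0
    H: float = 2.0
    sigma_mu: Optional[float] = None
    printed_scale: bool = True

    def __post_init__(self) -> None:
        if self.n_burn < 1 or self.n_keep < 1 or self.thin < 1:
            raise ValueError("n_burn, n_keep, thin must be >= 1")

    def tree_prior(self) -> TreePrior:
        return TreePrior(K=self.K, alpha=self.alpha, beta=self.beta,
                         H=self.H, sigma_mu=self.sigma_mu,
                         printed_scale=self.printed_scale)


class _Prepared:
    """CSR views of the pool structure for the compiled status scan."""

    def __init__(self, data: GroupTestingData):
        N, J = data.N, data.J
        counts = np.zeros(N, dtype=np.int64)
        for p in data.pools:
            counts[p] += 1
        self.ind_ptr = np.zeros(N + 1, dtype=np.int64)
        np.cumsum(counts, out=self.ind_ptr[1:])
        self.ind_tests = np.empty(self.ind_ptr[-1], dtype=np.int64)
        fill = self.ind_ptr[:-1].copy()
        for j, p in enumerate(data.pools):
            for i in p:
                self.ind_tests[fill[i]] = j
                fill[i] += 1
        self.Z = np.ascontiguousarray(data.Z, dtype=np.int8)
        self.stratum = np.ascontiguousarray(data.stratum, dtype=np.int64)


def prepare(data: GroupTestingData) -> _Prepared:
    prep = getattr(data, "_prepared", None)
    if prep is None:
        prep = _Prepared(data)
        data._prepared = prep
    return prep


@dataclass
class LatentState:
    Y: np.ndarray           # (N,) int8 current statuses
    omega: np.ndarray       # (N,) latent normals, sign-coupled to Y
    pool_pos: np.ndarray    # (J,) count of current positives per pool
    eta: np.ndarray         # (N,) cached surface values

    @classmethod
    def initial(cls, data: GroupTestingData, eta: np.ndarray) -> "LatentState":
        # data-plausible start: positive iff tested at least once and every
        # test containing the individual is positive (so Dorfman retest
        # outcomes, the most specific evidence, dominate the master pool)
        Y = np.zeros(data.N, dtype=np.int8)
        tested = np.zeros(data.N, dtype=bool)
        all_pos = np.ones(data.N, dtype=bool)
        for j, p in enumerate(data.pools):
            tested[p] = True
            if data.Z[j] == 0:
                all_pos[p] = False
        Y[tested & all_pos] = 1
        pool_pos = np.array([int(Y[p].sum()) for p in data.pools],
                            dtype=np.int64)
        omega = np.where(Y == 1, 0.5, -0.5) + eta * 0.0
        return cls(Y=Y, omega=omega, pool_pos=pool_pos, eta=eta.copy())

    def recount(self, data: GroupTestingData) -> np.ndarray:
        return np.array([int(self.Y[p].sum()) for p in data.pools],
                        dtype=np.int64)


@dataclass
class PosteriorSamples:
    eta: np.ndarray                        # (S, N)
    se: np.ndarray                         # (S, L)
    sp: np.ndarray                         # (S, L)
    split_counts: Optional[np.ndarray] = None   # (S, Q) BART only
    beta: Optional[np.ndarray] = None           # (S, P) GLM only
    y_mean: Optional[np.ndarray] = None         # (N,) retained-draw mean of Y~
    eta_query: Optional[np.ndarray] = None      # (S, N_query)
    trees: Optional[list] = None                # S lists of serialized trees
    accept_rate: Optional[float] = None
    meta: dict = field(default_factory=dict)

    @property
    def S(self) -> int:
        return self.eta.shape[0]


# ---------------------------------------------------------------------------
# latent status scan
# ---------------------------------------------------------------------------

@njit(cache=True)
def _status_sweep(Y, pool_pos, ind_ptr, ind_tests, Z, stratum,
                  lse, l1mse, lsp, l1msp, lphi, l1mphi, u):  # pragma: no cover
    N = Y.shape[0]
    for i in range(N):
        lp1 = lphi[i]
        lp0 = l1mphi[i]
        yi = Y[i]
        for t in range(ind_ptr[i], ind_ptr[i + 1]):
            j = ind_tests[t]
            l = stratum[j]
            z = Z[j]
            if z == 1:
                lp1 += lse[l]
            else:
                lp1 += l1mse[l]
            if pool_pos[j] - yi > 0:
                if z == 1:
                    lp0 += lse[l]
                else:
                    lp0 += l1mse[l]
            else:
                if z == 1:
                    lp0 += l1msp[l]
                else:
                    lp0 += lsp[l]
        m = lp1 if lp1 > lp0 else lp0
        p1 = math.exp(lp1 - m)
        p0 = math.exp(lp0 - m)
        ynew = 1 if u[i] * (p0 + p1) < p1 else 0
        if ynew != yi:
            Y[i] = ynew
            d = ynew - yi
            for t in range(ind_ptr[i], ind_ptr[i + 1]):
                pool_pos[ind_tests[t]] += d


def _log_accuracy(accuracy: AssayAccuracy):
    se, sp = accuracy.se, accuracy.sp
    return (np.log(se), np.log1p(-se), np.log(sp), np.log1p(-sp))


def latent_status_probability(i: int, state: LatentState,
                              data: GroupTestingData,
                              accuracy: AssayAccuracy) -> float:
    """Full-conditional P(Y~_i = 1 | everything else), computed in log space.

    Reference implementation mirrored by the compiled sweep; used directly
    by the enumeration oracles.
    """
    prep = prepare(data)
    lse, l1mse, lsp, l1msp = _log_accuracy(accuracy)
    lp1 = float(log_ndtr(state.eta[i]))
    lp0 = float(log_ndtr(-state.eta[i]))
    yi = int(state.Y[i])
    for t in range(prep.ind_ptr[i], prep.ind_ptr[i + 1]):
        j = prep.ind_tests[t]
        l = prep.stratum[j]
        z = prep.Z[j]
        lp1 += lse[l] if z else l1mse[l]
        s_ij = state.pool_pos[j] - yi
        if s_ij > 0:
            lp0 += lse[l] if z else l1mse[l]
        else:
            lp0 += l1msp[l] if z else lsp[l]
    m = max(lp0, lp1)
    p1 = math.exp(lp1 - m)
    p0 = math.exp(lp0 - m)
    return p1 / (p0 + p1)


def sample_all_statuses(state: LatentState, data: GroupTestingData,
                        accuracy: AssayAccuracy,
                        rng: np.random.Generator) -> None:
    """One sequential Gibbs scan over all individual statuses, in place."""
    prep = prepare(data)
    lse, l1mse, lsp, l1msp = _log_accuracy(accuracy)
    _status_sweep(state.Y, state.pool_pos, prep.ind_ptr, prep.ind_tests,
                  prep.Z, prep.stratum, lse, l1mse, lsp, l1msp,
                  log_ndtr(state.eta), log_ndtr(-state.eta),
                  rng.random(data.N))


# ---------------------------------------------------------------------------
# truncated-normal latents
# ---------------------------------------------------------------------------

def sample_omega(state: LatentState, rng: np.random.Generator) -> None:
    """Draw omega_i ~ N(eta_i, 1) truncated to (0, inf) when Y_i = 1 and to
    (-inf, 0] when Y_i = 0, in place.

    Uses the tail-stable inversion ``eta - ndtri(u * ndtr(eta))`` (and its
    mirror image), accurate for |eta| well past 10.
    """
    eta = state.eta
    u = np.clip(rng.random(eta.shape[0]), 1e-300, 1.0 - 1e-16)
    pos = state.Y == 1
    omega = np.empty_like(eta)
    omega[pos] = eta[pos] - ndtri(u[pos] * ndtr(eta[pos]))
    omega[~pos] = eta[~pos] + ndtri(u[~pos] * ndtr(-eta[~pos]))
    omega[pos] = np.maximum(omega[pos], 1e-12)
    omega[~pos] = np.minimum(omega[~pos], 0.0)
    state.omega = omega


# ---------------------------------------------------------------------------
# accuracy updates
# ---------------------------------------------------------------------------

def update_accuracy(state: LatentState, data: GroupTestingData,
                    accuracy: AssayAccuracy, rng: np.random.Generator) -> None:
    """Conjugate beta draws of (Se, Sp) per unknown stratum, in place."""
    z_tilde = (state.pool_pos > 0).astype(np.int64)
    Z = np.asarray(data.Z, dtype=np.int64)
    strat = data.stratum
    L = accuracy.L
    tp = np.bincount(strat, weights=Z * z_tilde, minlength=L)
    fn = np.bincount(strat, weights=(1 - Z) * z_tilde, minlength=L)
    tn = np.bincount(strat, weights=(1 - Z) * (1 - z_tilde), minlength=L)
    fp = np.bincount(strat, weights=Z * (1 - z_tilde), minlength=L)
    for l in range(L):
        if accuracy.known[l]:
            continue
        a_e, b_e, a_p, b_p = accuracy.hyper[l]
        accuracy.se[l] = rng.beta(a_e + tp[l], b_e + fn[l])
        accuracy.sp[l] = rng.beta(a_p + tn[l], b_p + fp[l])


# ---------------------------------------------------------------------------
# tree-ensemble backfitting
# ---------------------------------------------------------------------------

class TreeEnsembleSampler:
    """Backfitting sampler state for the sum-of-trees surface.

    Keeps, per tree, the training-row leaf assignment and fitted
    contribution so that eta updates are incremental.
    """

    def __init__(self, X: np.ndarray, prior: TreePrior,
                 offset: float = 0.0):
        self.X = np.ascontiguousarray(X, dtype=float)
        self.prior = prior
        self.cutpoints = make_cutpoints(self.X)
        # fixed probit offset: the leaf prior shrinks tree contributions to
        # zero, so the surface is centered at `offset` rather than at eta=0
        # (which would drag weakly-identified individuals toward p=0.5)
        self.offset = float(offset)
        N = self.X.shape[0]
        self.trees = [Tree() for _ in range(prior.K)]
        self.assign = [np.zeros(N, dtype=np.int64) for _ in range(prior.K)]
        self.g = [np.zeros(N) for _ in range(prior.K)]
        self.eta = np.full(N, self.offset)
        self.n_proposed = 0
        self.n_accepted = 0

    def _integrated(self, n, s, ssq):
        v = self.prior.sigma_mu ** 2
        return float(np.sum(-0.5 * n * math.log(2.0 * math.pi)
                            - 0.5 * np.log1p(n * v)
                            - 0.5 * ssq
                            + 0.5 * v * s * s / (1.0 + n * v)))

    def _leaf_stats(self, idx, b, r):
        n = np.bincount(idx, minlength=b).astype(float)
        s = np.bincount(idx, weights=r, minlength=b)
        ssq = np.bincount(idx, weights=r * r, minlength=b)
        return n, s, ssq

    def sweep(self, omega: np.ndarray, rng: np.random.Generator) -> None:
        for k in range(self.prior.K):
            tree = self.trees[k]
            r = omega - (self.eta - self.g[k])
            idx = self.assign[k]
            n, s, ssq = self._leaf_stats(idx, tree.n_leaves, r)

            proposal, log_ratio, _ = propose_tree(tree, self.cutpoints, rng)
            self.n_proposed += 1
            new_idx = proposal.leaf_index(self.X)
            nn, sn, ssqn = self._leaf_stats(new_idx, proposal.n_leaves, r)
            if np.all(nn > 0):
                log_acc = (self._integrated(nn, sn, ssqn)
                           - self._integrated(n, s, ssq)
                           + tree_log_prior(proposal, self.prior, self.cutpoints)
                           - tree_log_prior(tree, self.prior, self.cutpoints)
                           + log_ratio)
                if math.log(rng.random()) < log_acc:
                    self.n_accepted += 1
                    tree = self.trees[k] = proposal
                    idx, n, s = new_idx, nn, sn
                    self.assign[k] = idx

            # conjugate leaf redraw
            var = 1.0 / (n + self.prior.sigma_mu ** -2)
            mu = s * var + np.sqrt(var) * rng.standard_normal(n.shape[0])
            tree.set_leaf_values(mu)
            g_new = mu[idx]
            self.eta += g_new - self.g[k]
            self.g[k] = g_new

    def evaluate(self, X_query: np.ndarray) -> np.ndarray:
        total = np.full(X_query.shape[0], self.offset)
        for t in self.trees:
            total += t.evaluate(X_query)
        return total

    def split_counts(self) -> np.ndarray:
        Q = self.X.shape[1]
        counts = np.zeros(Q, dtype=np.int64)
        for t in self.trees:
            counts += t.split_counts(Q)
        return counts

    @property
    def accept_rate(self) -> float:
        return self.n_accepted / max(self.n_proposed, 1)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def _probit_offset(data: GroupTestingData, Y0: np.ndarray) -> float:
    """Fixed surface offset Phi^-1(ybar) from the data-plausible Y init."""
    ybar = float(np.clip(Y0.mean(), 1.0 / (data.N + 1), 1 - 1.0 / (data.N + 1)))
    return float(ndtri(ybar))


def run_chain(data: GroupTestingData, accuracy: AssayAccuracy,
              config: SamplerConfig,
              X_query: Optional[np.ndarray] = None,
              store_trees: bool = False) -> PosteriorSamples:
    """Run the full sampler and return retained posterior draws.

    ``accuracy`` supplies initial values, known flags and beta
    hyperparameters; it is not modified.  ``X_query`` rows, when given, get
    the surface evaluated and stored at every retained draw (for
    out-of-sample prediction).
    """
    problems = validate(data)
    if problems:
        raise ValueError("invalid group testing data: " + "; ".join(problems))
    rng = np.random.default_rng(config.seed)
    acc = accuracy.copy()

    prior = config.tree_prior()
    Y0 = LatentState.initial(data, np.zeros(data.N)).Y
    model = TreeEnsembleSampler(data.X, prior, _probit_offset(data, Y0))
    state = LatentState.initial(data, model.eta)
    # start unknown (Se, Sp) from one conjugate draw given the initial Y;
    # prior-mean starts (0.5 under flat priors) make the first status scan
    # treat all tests as noise and can trap the chain in the mirrored mode
    update_accuracy(state, data, acc, rng)

    S, L, Q = config.n_keep, acc.L, data.Q
    out = PosteriorSamples(
        eta=np.empty((S, data.N)),
        se=np.empty((S, L)), sp=np.empty((S, L)),
        split_counts=np.empty((S, Q), dtype=np.int64),
        eta_query=None if X_query is None else np.empty((S, len(X_query))),
        trees=[] if store_trees else None,
        meta={"sampler": "bart", "K": config.K, "n_burn": config.n_burn,
              "n_keep": config.n_keep, "thin": config.thin,
              "seed": config.seed, "sigma_mu": prior.sigma_mu},
    )

    total = config.n_burn + config.n_keep * config.thin
    kept = 0
    y_acc = np.zeros(data.N)
    for it in range(total):
        sample_all_statuses(state, data, acc, rng)
        sample_omega(state, rng)
        model.sweep(state.omega, rng)
        state.eta = model.eta
        update_accuracy(state, data, acc, rng)
        if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
            y_acc += state.Y
            out.eta[kept] = model.eta
            out.se[kept] = acc.se
            out.sp[kept] = acc.sp
            out.split_counts[kept] = model.split_counts()
            if X_query is not None:
                out.eta_query[kept] = model.evaluate(X_query)
            if store_trees:
                out.trees.append([t.to_dict() for t in model.trees])
            kept += 1
    out.accept_rate = model.accept_rate
    out.y_mean = y_acc / S
    return out
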