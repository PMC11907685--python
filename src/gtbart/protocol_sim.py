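"""Synthetic group testing data: covariates, statuses, and test protocols.

Three probit generating models over Q = 3 covariates (x1, x2 uniform on
(0, 10); x3 Bernoulli(0.5)) are built in:

* ``M1``: ``f(x) = sin(pi * x1) - 1.25`` (highly non-linear in x1 only)
* ``M2``: ``f(x) = -0.85 + 0.55 x1 - 1.25 x2 - 0.35 x3`` (linear)
* ``M3``: ``f(x) = -sin(x1 / 3) - x1 * x3 + x3`` (non-linear interaction)

Supported protocols:

* ``IT``  — individual testing, one singleton pool per person;
* ``MPT`` — master pool testing, each person assayed once inside one pool;
* ``DT``  — Dorfman testing: master pools (stratum 1) followed by individual
  retests (stratum 2) of every member of each observed-positive master pool.

Misclassification follows the standard model: a test on a pool with true
status ``z`` reads positive with probability ``Se`` if ``z = 1`` and
``1 - Sp`` if ``z = 0``, using the (Se, Sp) of the test's stratum.

One master seed drives four independent sub-streams (covariates, statuses,
pool assignment, test noise) so that protocols can be compared on identical
underlying populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.special import ndtr

from .group_data import AssayAccuracy, GroupTestingData, pool_true_status

__all__ = [
    "M2_BETA", "SimulationDesign", "SimulatedTruth", "true_f",
    "simulate_statuses", "assign_pools", "test_response", "run_protocol",
    "simulate_dataset",
]

#: coefficients (b0, b1, b2, b3) of the linear generating model M2
M2_BETA = np.array([-0.85, 0.55, -1.25, -0.35])

_PROTOCOLS = ("IT", "MPT", "DT")


def true_f(model: str, x, custom: Optional[Callable] = None) -> np.ndarray:
    """Deterministic probit-scale surface of a generating model.

    ``x`` may be a single covariate vector of length 3 or an (N, 3) matrix;
    the return matches (scalar or length-N vector).  ``model="custom"``
    dispatches to ``custom``, which receives the (N, Q) matrix.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if model == "M1":
        out = np.sin(np.pi * X[:, 0]) - 1.25
    elif model == "M2":
        out = M2_BETA[0] + X[:, :3] @ M2_BETA[1:]
    elif model == "M3":
        out = -np.sin(X[:, 0] / 3.0) - X[:, 0] * X[:, 2] + X[:, 2]
    elif model == "custom":
        if custom is None:
            raise ValueError("model='custom' requires a callable")
        out = np.asarray(custom(X), dtype=float)
    else:
        raise ValueError(f"unknown generating model {model!r}")
    return float(out[0]) if single else out


@dataclass
class SimulationDesign:
    """Everything needed to generate one synthetic dataset."""

    model: str
    N: int
    protocol: str
    accuracy_truth: AssayAccuracy
    seed: int
    pool_size: int = 4
    custom_f: Optional[Callable] = None

    def __post_init__(self) -> None:
        if self.protocol not in _PROTOCOLS:
            raise ValueError(f"protocol must be one of {_PROTOCOLS}")
        if self.pool_size < 1 or self.N < self.pool_size:
            raise ValueError("need pool_size >= 1 and N >= pool_size")
        if self.protocol == "DT" and self.accuracy_truth.L < 2:
            raise ValueError("DT needs two accuracy strata "
                             "(1 = master pools, 2 = individual retests)")

    def streams(self):
        """Independent child generators: covariates, statuses, pools, noise."""
        kids = np.random.SeedSequence(self.seed).spawn(4)
        return tuple(np.random.default_rng(k) for k in kids)


@dataclass
class SimulatedTruth:
    X: np.ndarray
    y_true: np.ndarray
    p_true: np.ndarray


def simulate_statuses(design: SimulationDesign) -> SimulatedTruth:
    """Draw covariates and true statuses ``y_i ~ Bernoulli(Phi(f(x_i)))``."""
    rng_x, rng_y, _, _ = design.streams()
    N = design.N
    X = np.column_stack([
        rng_x.uniform(0.0, 10.0, size=N),
        rng_x.uniform(0.0, 10.0, size=N),
        rng_x.integers(0, 2, size=N).astype(float),
    ])
    p = ndtr(true_f(design.model, X, design.custom_f))
    y = (rng_y.random(N) < p).astype(np.int8)
    return SimulatedTruth(X=X, y_true=y, p_true=p)


def assign_pools(N: int, pool_size: int, rng: np.random.Generator) -> list:
    """Random partition of ``{0..N-1}`` into pools of ``pool_size``.

    When ``pool_size`` does not divide ``N``, the final pool is smaller and
    kept in the same stratum.
    """
    perm = rng.permutation(N)
    return [perm[k:k + pool_size] for k in range(0, N, pool_size)]


def test_response(z_true: int, se: float, sp: float,
                  rng: np.random.Generator) -> int:
    """Observed assay outcome for a pool with true status ``z_true``."""
    p_pos = se if z_true else 1.0 - sp
    return int(rng.random() < p_pos)


def run_protocol(truth: SimulatedTruth, design: SimulationDesign) -> GroupTestingData:
    """Apply the design's testing protocol to a simulated population."""
    _, _, rng_pool, rng_noise = design.streams()
    acc = design.accuracy_truth
    y = truth.y_true
    pools, Z, stratum = [], [], []

    def _observe(pool, lab):
        z_true = pool_true_status(y, pool)
        z = test_response(z_true, acc.se[lab], acc.sp[lab], rng_noise)
        pools.append(np.asarray(pool, dtype=np.int64))
        Z.append(z)
        stratum.append(lab)
        return z

    if design.protocol == "IT":
        for i in range(design.N):
            _observe(np.array([i]), 0)
    else:
        masters = assign_pools(design.N, design.pool_size, rng_pool)
        observed = [_observe(p, 0) for p in masters]
        if design.protocol == "DT":
            for p, z in zip(masters, observed):
                if z == 1:
                    for i in p:
                        _observe(np.array([i]), 1)

    return GroupTestingData(X=truth.X, Z=np.array(Z, dtype=np.int8),
                            pools=pools, stratum=np.array(stratum))


def simulate_dataset(design: SimulationDesign):
    """Convenience wrapper: returns ``(truth, data)`` for one design."""
    truth = simulate_statuses(design)
    return truth, run_protocol(truth, design)
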