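"""Core data model for group testing observations.

A study consists of ``N`` individuals with covariates ``X`` and ``J`` binary
test outcomes ``Z``.  Each test ``j`` assays a pool of individuals (an index
set), and carries a stratum label so that tests sharing assay characteristics
share one (sensitivity, specificity) pair.  Pools may overlap: an individual
can be retested in several pools.

Internally everything is 0-based; the on-disk CSV formats (see
:mod:`gtbart.io`) use explicit 1-based individual/test identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GroupTestingData", "AssayAccuracy", "validate", "pool_true_status"]


@dataclass
class GroupTestingData:
    """Observed group testing data.

    Parameters
    ----------
    X : ndarray of shape (N, Q)
        Individual-level covariate matrix.
    Z : ndarray of shape (J,)
        Binary test outcomes (1 = positive).
    pools : list of ndarray
        ``pools[j]`` holds the 0-based indices of individuals contributing
        to test ``j``.
    stratum : ndarray of shape (J,)
        0-based stratum label of each test, in ``{0, ..., L-1}``.
    """

    X: np.ndarray
    Z: np.ndarray
    pools: list
    stratum: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.Z = np.asarray(self.Z)
        self.stratum = np.asarray(self.stratum, dtype=np.int64)
        self.pools = [np.asarray(p, dtype=np.int64) for p in self.pools]

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def Q(self) -> int:
        return self.X.shape[1]

    @property
    def J(self) -> int:
        return len(self.pools)

    @property
    def L(self) -> int:
        return int(self.stratum.max()) + 1 if self.J else 0

    def tests_of(self, i: int) -> list:
        """Indices of tests whose pool contains individual ``i``."""
        return [j for j, p in enumerate(self.pools) if i in p]


@dataclass
class AssayAccuracy:
    """Per-stratum assay accuracy with beta prior hyperparameters.

    ``known[l]`` marks strata whose (Se, Sp) are fixed and never updated by
    the sampler.  ``hyper`` holds one ``(a_e, b_e, a_p, b_p)`` row per
    stratum; the default is the flat beta(1, 1) prior for all four.
    """

    se: np.ndarray
    sp: np.ndarray
    known: np.ndarray
    hyper: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.se = np.atleast_1d(np.asarray(self.se, dtype=float)).copy()
        self.sp = np.atleast_1d(np.asarray(self.sp, dtype=float)).copy()
        self.known = np.atleast_1d(np.asarray(self.known, dtype=bool)).copy()
        if self.hyper is None:
            self.hyper = np.ones((self.L, 4))
        self.hyper = np.asarray(self.hyper, dtype=float).reshape(self.L, 4).copy()
        if not (self.se.shape == self.sp.shape == self.known.shape):
            raise ValueError("se, sp, known must have identical length")
        if np.any((self.se <= 0) | (self.se >= 1)) or np.any((self.sp <= 0) | (self.sp >= 1)):
            raise ValueError("Se and Sp must lie strictly inside (0, 1)")
        if np.any(self.hyper <= 0):
            raise ValueError("beta hyperparameters must be strictly positive")

    @property
    def L(self) -> int:
        return self.se.shape[0]

    @classmethod
    def fixed(cls, se, sp) -> "AssayAccuracy":
        """All strata known; no estimation."""
        se = np.atleast_1d(np.asarray(se, dtype=float))
        return cls(se=se, sp=sp, known=np.ones(se.shape[0], dtype=bool))

    @classmethod
    def uniform_prior(cls, se, sp) -> "AssayAccuracy":
        """All strata unknown with flat beta(1,1) priors; ``se``/``sp`` are
        only used as generating truths or chain initial values."""
        se = np.atleast_1d(np.asarray(se, dtype=float))
        return cls(se=se, sp=sp, known=np.zeros(se.shape[0], dtype=bool))

    def copy(self) -> "AssayAccuracy":
        return AssayAccuracy(self.se.copy(), self.sp.copy(), self.known.copy(),
                             self.hyper.copy())


def validate(data: GroupTestingData) -> list:
    """Check structural invariants; return a list of violation messages.

    An empty list means the dataset is well formed.  Messages name the
    offending test or individual (1-based, matching the on-disk format).
    """
    problems = []
    N = data.N
    if len(data.stratum) != data.J:
        problems.append(
            f"stratum vector has length {len(data.stratum)}, expected J={data.J}")
    if len(data.Z) != data.J:
        problems.append(f"Z has length {len(data.Z)}, expected J={data.J}")
    for j, pool in enumerate(data.pools):
        if pool.size == 0:
            problems.append(f"test {j + 1}: empty pool")
            continue
        bad = pool[(pool < 0) | (pool >= N)]
        for i in bad:
            problems.append(
                f"test {j + 1}: pool references individual {int(i) + 1} "
                f"outside 1..{N}")
        if np.unique(pool).size != pool.size:
            problems.append(f"test {j + 1}: duplicated individual in pool")
    for j, z in enumerate(np.asarray(data.Z).ravel()[: data.J]):
        if z not in (0, 1):
            problems.append(f"test {j + 1}: outcome {z!r} is not binary")
    for j, s in enumerate(data.stratum[: data.J]):
        if s < 0:
            problems.append(f"test {j + 1}: negative stratum label")
    if not np.all(np.isfinite(data.X)):
        problems.append("covariate matrix contains non-finite values")
    return problems


def pool_true_status(y_tilde: np.ndarray, pool: np.ndarray) -> int:
    """True status of a pool: 1 iff any member is truly positive."""
    pool = np.asarray(pool, dtype=np.int64)
    if pool.size == 0:
        raise ValueError("empty pool: malformed group testing data")
    return int(np.any(np.asarray(y_tilde)[pool] > 0))
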