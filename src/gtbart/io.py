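"""On-disk formats: dataset CSV pair, truth CSV, posterior store, manifests.

Dataset format (version 1), given a path prefix ``P``:

* ``P.covariates.csv`` — columns ``individual_id, x1..xQ`` (ids 1..N);
* ``P.tests.csv`` — columns ``test_id, stratum, outcome, members`` where
  ``members`` is a colon-separated list of individual ids;
* ``P.truth.csv`` (simulations only) — ``individual_id, p_true, y_true``.

A posterior store is a directory of CSV files plus ``meta.json``; every CLI
run also writes a ``manifest.json`` echoing its configuration and seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .gibbs import PosteriorSamples
from .group_data import GroupTestingData
from .protocol_sim import SimulatedTruth

__all__ = [
    "write_dataset", "read_dataset", "write_truth", "read_truth",
    "write_posterior", "read_posterior", "write_manifest",
]

FORMAT_VERSION = 1


def write_dataset(prefix, data: GroupTestingData,
                  truth: Optional[SimulatedTruth] = None) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    cov = pd.DataFrame(data.X, columns=[f"x{q + 1}" for q in range(data.Q)])
    cov.insert(0, "individual_id", np.arange(1, data.N + 1))
    cov.to_csv(f"{prefix}.covariates.csv", index=False)
    tests = pd.DataFrame({
        "test_id": np.arange(1, data.J + 1),
        "stratum": data.stratum + 1,
        "outcome": np.asarray(data.Z, dtype=int),
        "members": [":".join(str(i + 1) for i in p) for p in data.pools],
    })
    tests.to_csv(f"{prefix}.tests.csv", index=False)
    if truth is not None:
        write_truth(prefix, truth)


def read_dataset(prefix) -> GroupTestingData:
    prefix = Path(prefix)
    cov = pd.read_csv(f"{prefix}.covariates.csv")
    if cov["individual_id"].duplicated().any():
        raise ValueError("duplicated individual_id in covariate table")
    cov = cov.sort_values("individual_id")
    ids = cov["individual_id"].to_numpy()
    if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
        raise ValueError("individual_id must be exactly 1..N")
    X = cov.drop(columns="individual_id").to_numpy(dtype=float)

    tests = pd.read_csv(f"{prefix}.tests.csv")
    if tests["test_id"].duplicated().any():
        raise ValueError("duplicated test_id in test table")
    tests = tests.sort_values("test_id")
    pools = []
    for tid, members in zip(tests["test_id"], tests["members"]):
        parts = [p for p in str(members).split(":") if p != ""]
        if not parts or str(members).lower() == "nan":
            raise ValueError(f"test {tid}: empty member list")
        pools.append(np.array([int(p) - 1 for p in parts], dtype=np.int64))
    stratum = tests["stratum"].to_numpy(dtype=np.int64)
    if np.any(stratum < 1):
        raise ValueError("stratum labels must be >= 1")
    return GroupTestingData(X=X, Z=tests["outcome"].to_numpy(dtype=np.int8),
                            pools=pools, stratum=stratum - 1)


def write_truth(prefix, truth: SimulatedTruth) -> None:
    pd.DataFrame({
        "individual_id": np.arange(1, len(truth.y_true) + 1),
        "p_true": truth.p_true,
        "y_true": truth.y_true,
    }).to_csv(f"{Path(prefix)}.truth.csv", index=False)


def read_truth(prefix) -> pd.DataFrame:
    return pd.read_csv(f"{Path(prefix)}.truth.csv")


def write_posterior(outdir, samples: PosteriorSamples) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = dict(samples.meta)
    meta.update({"format_version": FORMAT_VERSION, "S": samples.S,
                 "accept_rate": samples.accept_rate})
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
    np.savetxt(outdir / "eta.csv", samples.eta, delimiter=",")
    np.savetxt(outdir / "se.csv", samples.se, delimiter=",")
    np.savetxt(outdir / "sp.csv", samples.sp, delimiter=",")
    if samples.split_counts is not None:
        np.savetxt(outdir / "split_counts.csv", samples.split_counts,
                   delimiter=",", fmt="%d")
    if samples.beta is not None:
        np.savetxt(outdir / "beta.csv", samples.beta, delimiter=",")
    if samples.eta_query is not None:
        np.savetxt(outdir / "eta_query.csv", samples.eta_query, delimiter=",")
    if samples.trees is not None:
        with open(outdir / "trees.jsonl", "w") as fh:
            for draw in samples.trees:
                fh.write(json.dumps(draw) + "\n")


def _load_csv(path) -> Optional[np.ndarray]:
    path = Path(path)
    if not path.exists():
        return None
    arr = np.loadtxt(path, delimiter=",")
    return np.atleast_2d(arr)


def read_posterior(outdir) -> PosteriorSamples:
    outdir = Path(outdir)
    meta = json.loads((outdir / "meta.json").read_text())
    trees = None
    tree_path = outdir / "trees.jsonl"
    if tree_path.exists():
        trees = [json.loads(line) for line in tree_path.read_text().splitlines()
                 if line.strip()]
    split = _load_csv(outdir / "split_counts.csv")
    return PosteriorSamples(
        eta=_load_csv(outdir / "eta.csv"),
        se=_load_csv(outdir / "se.csv"),
        sp=_load_csv(outdir / "sp.csv"),
        split_counts=None if split is None else split.astype(np.int64),
        beta=_load_csv(outdir / "beta.csv"),
        eta_query=_load_csv(outdir / "eta_query.csv"),
        trees=trees,
        accept_rate=meta.get("accept_rate"),
        meta=meta,
    )


def write_manifest(path, config: dict) -> None:
    from . import __version__
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"gtbart_version": __version__, "config": config}
    path.write_text(json.dumps(payload, indent=2, default=str))
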