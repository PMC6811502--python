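"""Persistence of networks, ensembles, responses and results.

Connectivity matrices travel as Matrix Market coordinate files (real,
general); vectors and matrices of averages as headered CSV; run metadata as
JSON sidecars.  All formats are plain text.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .model import Network, NetworkParams
from .synth import InputEnsemble

__all__ = [
    "save_network",
    "load_network",
    "save_ensemble",
    "load_ensemble",
    "save_response_matrices",
    "save_matrix_mtx",
    "load_matrix_mtx",
]

SPARSIFY_TOL = 1e-12  # entries below this magnitude are dropped on write


def save_matrix_mtx(path, M, tol: float = SPARSIFY_TOL) -> None:
    """Write a (dense or sparse) matrix as Matrix Market, dropping tiny entries."""
    M = sp.csc_matrix(M)
    if tol > 0:
        M.data[np.abs(M.data) < tol] = 0.0
        M.eliminate_zeros()
    mmwrite(str(path), M)


def load_matrix_mtx(path) -> sp.csc_matrix:
    return sp.csc_matrix(mmread(str(path)))


def save_network(outdir, network: Network, stem: str = "network") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_matrix_mtx(outdir / f"{stem}_R.mtx", network.R)
    pd.DataFrame(
        {"neuron_id": np.arange(network.N), "value": network.theta}
    ).to_csv(outdir / f"{stem}_theta.csv", index=False)
    (outdir / f"{stem}_params.json").write_text(
        json.dumps(dataclasses.asdict(network.params), indent=2)
    )


def load_network(outdir, stem: str = "network") -> Network:
    outdir = Path(outdir)
    params = NetworkParams(**json.loads((outdir / f"{stem}_params.json").read_text()))
    R = load_matrix_mtx(outdir / f"{stem}_R.mtx")
    theta = pd.read_csv(outdir / f"{stem}_theta.csv")["value"].to_numpy()
    return Network(params=params, R=R, theta=theta)


def save_ensemble(path, ensemble: InputEnsemble) -> None:
    """Long-format CSV: (neuron_id, trial_id, value)."""
    N, r = ensemble.P.shape
    df = pd.DataFrame(
        {
            "neuron_id": np.repeat(np.arange(N), r),
            "trial_id": np.tile(np.arange(r), N),
            "value": ensemble.P.ravel(),
        }
    )
    df.attrs["m0"] = ensemble.m0
    df.to_csv(path, index=False)


def load_ensemble(path, m0: float = 1.0, seed: int = -1) -> InputEnsemble:
    df = pd.read_csv(path)
    N = df["neuron_id"].max() + 1
    r = df["trial_id"].max() + 1
    P = df["value"].to_numpy().reshape(N, r)
    return InputEnsemble(P=P, m0=m0, seed=seed)


def save_response_matrices(outdir, response, meta: dict | None = None) -> None:
    """X.csv / U.csv with neuron rows and trial columns, plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [f"trial_{t}" for t in range(response.r)]
    for name, M in (("X", response.X), ("U", response.U)):
        df = pd.DataFrame(M, columns=cols)
        df.insert(0, "neuron_id", np.arange(M.shape[0]))
        df.to_csv(outdir / f"{name}.csv", index=False)
    sidecar = {"t_obs_ms": response.t_obs, "t_burn_ms": response.t_burn, "r": response.r}
    if meta:
        sidecar.update(meta)
    (outdir / "response_meta.json").write_text(json.dumps(sidecar, indent=2))
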