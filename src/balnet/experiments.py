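"""Config-driven experiment families: single reconstructions and parameter sweeps.

Each sweep regenerates the network for the cell's parameters, simulates the
response to a fresh random input ensemble, reconstructs R row-wise by L1
minimization, and records regime diagnostics plus the relative Frobenius
error.  Every result row carries the full parameter set and master seed, so
any cell can be re-run in isolation and reproduced bit-for-bit.  Sweeps with
an output directory are restartable: completed cells (one JSON each) are
skipped on re-invocation.

Conventions: the quotient ``R_EI/R_II`` is swept by varying R_EI at fixed
R_II; ``f_E/f_I`` by varying f_E at fixed f_I.  The alpha sweep holds K and
the sparsity pattern fixed so only strengths change.  Times at this layer
are seconds (converted to the model's milliseconds internally).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as bio
from .diagnostics import regime_stats, relative_error
from .model import NetworkParams, check_balance_condition
from .reconstruct import SolverConfig, reconstruct
from .simulate import ResponseData, run_ensemble, simulate_trial, simulate_trial_prefixes
from .synth import generate_connectivity, generate_input_ensemble, trial_seed

__all__ = [
    "ExperimentConfig",
    "run_single_reconstruction",
    "run_balance_plane",
    "run_quotient_slice",
    "run_alpha_sweep",
    "run_input_count_sweep",
    "run_observation_time_sweep",
]

MS_PER_S = 1000.0


@dataclass
class ExperimentConfig:
    """Everything needed to run one experiment family."""

    params: NetworkParams = field(default_factory=NetworkParams)
    kind: str = "single_reconstruction"
    grid: dict = field(default_factory=dict)  # axis name -> list of values
    r: int = 900
    t_obs: float = 2.5  # seconds
    t_burn: float = 0.5  # seconds
    n_seeds: int = 1
    seed: int = 0
    solver: SolverConfig = field(default_factory=SolverConfig)
    outdir: Optional[str] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = dataclasses.asdict(self.params)
        d["solver"] = dataclasses.asdict(self.solver)
        return d


def _pipeline(params, r, t_obs_s, t_burn_s, seed, solver):
    """generate -> simulate -> reconstruct; returns (network, response, result, eps)."""
    network = generate_connectivity(params, seed)
    ensemble = generate_input_ensemble(params, r, seed)
    response = run_ensemble(
        network, ensemble, t_obs_s * MS_PER_S, t_burn_s * MS_PER_S, seed=seed
    )
    result = reconstruct(response, ensemble, network.f, solver)
    eps = relative_error(network.R, result.R_recon)
    return network, ensemble, response, result, eps


def _regime_snapshot(params, seed, t_obs_s, t_burn_s):
    """Regime stats from one E/I-tracked trial under the first ensemble input."""
    network = generate_connectivity(params, seed)
    ensemble = generate_input_ensemble(params, 1, seed)
    s = simulate_trial(
        network,
        ensemble.P[:, 0],
        t_obs_s * MS_PER_S,
        t_burn_s * MS_PER_S,
        seed=trial_seed(seed, 0),
        track_ei=True,
    )
    return regime_stats(s)


def run_single_reconstruction(config: ExperimentConfig) -> dict:
    """End-to-end run; persists all artifacts when an output directory is set."""
    t0 = time.time()
    params, solver = config.params, config.solver
    network, ensemble, response, result, eps = _pipeline(
        params, config.r, config.t_obs, config.t_burn, config.seed, solver
    )
    stats = _regime_snapshot(params, config.seed, config.t_obs, config.t_burn)
    summary = {
        "relative_error": eps,
        "mean_ei_ratio": stats.mean_ratio,
        "ei_ratio_sd": stats.ratio_sd,
        "dev_from_balance": stats.dev_from_balance,
        "frac_quiescent": stats.frac_quiescent,
        "frac_saturated": stats.frac_saturated,
        "balance_condition": dataclasses.asdict(check_balance_condition(params)),
        "r": config.r,
        "t_obs_s": config.t_obs,
        "t_burn_s": config.t_burn,
        "seed": config.seed,
        "solver": solver.solver,
        "n_row_failures": len(result.failures),
        "runtime_s": round(time.time() - t0, 2),
        "params": dataclasses.asdict(params),
    }
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        bio.save_network(out, network)
        bio.save_ensemble(out / "P.csv", ensemble)
        bio.save_response_matrices(out, response, meta={"seed": config.seed})
        bio.save_matrix_mtx(out / "R_recon.mtx", result.R_recon)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return summary


def _cell_cache(outdir, tag):
    if outdir is None:
        return None
    p = Path(outdir) / "cells"
    p.mkdir(parents=True, exist_ok=True)
    return p / f"{tag}.json"


def _run_cell(cache, fn):
    if cache is not None and cache.exists():
        return json.loads(cache.read_text())
    rec = fn()
    if cache is not None:
        cache.write_text(json.dumps(rec))
    return rec


def run_balance_plane(config: ExperimentConfig) -> pd.DataFrame:
    """Sweep the quotients R_EI/R_II and f_E/f_I on a grid.

    Grid axes: ``mid`` (R_EI/R_II values) and ``lhs`` (f_E/f_I values).
    Returns one row per cell per seed with regime stats and relative error.
    """
    mids = config.grid.get("mid", [10.0 / 9.0])
    lhss = config.grid.get("lhs", [1.2])
    rows = []
    for mid in mids:
        for lhs in lhss:
            params = config.params.replace(
                R_EI=mid * config.params.R_II, f_E=lhs * config.params.f_I
            )
            for s in range(config.n_seeds):
                seed = config.seed + s
                cache = _cell_cache(config.outdir, f"plane_{mid:.4f}_{lhs:.4f}_{seed}")

                def cell(params=params, seed=seed, mid=mid, lhs=lhs):
                    try:
                        stats = _regime_snapshot(params, seed, config.t_obs, config.t_burn)
                        *_, eps = _pipeline(
                            params, config.r, config.t_obs, config.t_burn, seed,
                            config.solver,
                        )
                        return {
                            "mid": mid, "lhs": lhs, "seed": seed,
                            "dev_from_balance": stats.dev_from_balance,
                            "ratio_sd": stats.ratio_sd,
                            "frac_quiescent": stats.frac_quiescent,
                            "frac_saturated": stats.frac_saturated,
                            "relative_error": eps, "error": None,
                        }
                    except Exception as err:  # record, keep sweeping
                        return {"mid": mid, "lhs": lhs, "seed": seed, "error": str(err)}

                rows.append(_run_cell(cache, cell))
    df = pd.DataFrame(rows)
    _maybe_save(config, df, "balance_plane.csv")
    return df


def run_quotient_slice(config: ExperimentConfig) -> pd.DataFrame:
    """One-dimensional slice: vary R_EI/R_II at fixed f_E/f_I."""
    cfg = dataclasses.replace(
        config, grid={"mid": config.grid.get("mid", [1.0, 10 / 9, 1.2]),
                      "lhs": [config.grid.get("lhs_fixed", 1.2)]}
    )
    return run_balance_plane(cfg)


def run_alpha_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Relative error across the synaptic-scaling exponent alpha.

    K and the sparsity pattern are held fixed per seed (the pattern depends
    only on the seed, not on alpha), so only the strengths R_kl/K^alpha vary.
    """
    alphas = config.grid.get("alpha", [0.1, 0.3, 0.5, 0.7, 0.9, 1.0])
    rows = []
    for a in alphas:
        params = config.params.replace(alpha=a)
        for s in range(config.n_seeds):
            seed = config.seed + s
            cache = _cell_cache(config.outdir, f"alpha_{a:.3f}_{seed}")

            def cell(params=params, seed=seed, a=a):
                try:
                    stats = _regime_snapshot(params, seed, config.t_obs, config.t_burn)
                    *_, eps = _pipeline(
                        params, config.r, config.t_obs, config.t_burn, seed, config.solver
                    )
                    return {
                        "alpha": a, "seed": seed,
                        "dev_from_balance": stats.dev_from_balance,
                        "relative_error": eps, "error": None,
                    }
                except Exception as err:
                    return {"alpha": a, "seed": seed, "error": str(err)}

            rows.append(_run_cell(cache, cell))
    df = pd.DataFrame(rows)
    _maybe_save(config, df, "alpha_sweep.csv")
    return df


def run_input_count_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Relative error vs ensemble size r, with nested trial subsets per seed.

    One ensemble of max(r) trials is simulated per seed; smaller r reuse its
    leading columns (paired design, lower variance across the r axis).
    """
    r_values = sorted(config.grid.get("r", [100, 300, 500, 700, 900]))
    r_max = r_values[-1]
    rows = []
    for s in range(config.n_seeds):
        seed = config.seed + s
        params = config.params
        network = generate_connectivity(params, seed)
        ensemble = generate_input_ensemble(params, r_max, seed)
        response = run_ensemble(
            network, ensemble, config.t_obs * MS_PER_S, config.t_burn * MS_PER_S, seed=seed
        )
        for r in r_values:
            cache = _cell_cache(config.outdir, f"rsweep_{r}_{seed}")

            def cell(r=r, seed=seed):
                sub_resp = ResponseData(
                    X=response.X[:, :r], U=response.U[:, :r], E_bar=None, I_bar=None,
                    ensemble=ensemble, t_obs=response.t_obs, t_burn=response.t_burn,
                )
                from .synth import InputEnsemble

                sub_ens = InputEnsemble(P=ensemble.P[:, :r], m0=ensemble.m0, seed=seed)
                result = reconstruct(sub_resp, sub_ens, network.f, config.solver)
                eps = relative_error(network.R, result.R_recon)
                return {"r": r, "seed": seed, "relative_error": eps, "error": None}

            rows.append(_run_cell(cache, cell))
    df = pd.DataFrame(rows)
    _maybe_save(config, df, "input_count_sweep.csv")
    return df


def run_observation_time_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Relative error vs observation time, via prefix windows of one trajectory.

    Each trial is simulated once for the longest duration; averages over the
    shorter windows are exact prefixes of the same trajectory.
    """
    t_values = sorted(config.grid.get("t_obs", [0.25, 0.5, 1.0, 2.0, 2.5]))
    cps = [t * MS_PER_S for t in t_values]
    rows = []
    for s in range(config.n_seeds):
        seed = config.seed + s
        params = config.params
        network = generate_connectivity(params, seed)
        ensemble = generate_input_ensemble(params, config.r, seed)
        N, r = ensemble.P.shape
        Xs = np.empty((len(cps), N, r))
        Us = np.empty((len(cps), N, r))
        for t in range(r):
            x, mu = simulate_trial_prefixes(
                network, ensemble.P[:, t], cps, config.t_burn * MS_PER_S,
                seed=trial_seed(seed, t),
            )
            Xs[:, :, t] = x
            Us[:, :, t] = mu
        for k, t_obs in enumerate(t_values):
            cache = _cell_cache(config.outdir, f"tsweep_{t_obs:.3f}_{seed}")

            def cell(k=k, t_obs=t_obs, seed=seed):
                resp = ResponseData(
                    X=Xs[k], U=Us[k], E_bar=None, I_bar=None, ensemble=ensemble,
                    t_obs=t_obs * MS_PER_S, t_burn=config.t_burn * MS_PER_S,
                )
                result = reconstruct(resp, ensemble, network.f, config.solver)
                eps = relative_error(network.R, result.R_recon)
                return {"t_obs": t_obs, "seed": seed, "relative_error": eps, "error": None}

            rows.append(_run_cell(cache, cell))
    df = pd.DataFrame(rows)
    _maybe_save(config, df, "observation_time_sweep.csv")
    return df


def _maybe_save(config, df, name):
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / name, index=False)
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
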