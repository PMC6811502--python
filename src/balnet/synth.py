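"""Synthetic ground-truth networks, thresholds, and random input ensembles.

Connectivity follows a block Erdős–Rényi rule: each off-diagonal entry
``(i, j)`` is independently nonzero with probability ``K / N_l`` (``l`` the
population of the presynaptic neuron ``j``) and, when present, equals
``R_kl / K**alpha`` (``k`` the population of the postsynaptic neuron ``i``).
Each neuron therefore receives on average ``K`` excitatory and ``K``
inhibitory projections.  External drives are i.i.d. uniform on
``[0, m0 * sqrt(K))``, entrywise independent across neurons and trials, so
that the applied input ``f_k * p_i`` is of the same sqrt(K) order as the
per-population recurrent drive.

All generators are pure functions of ``(params, seed)``.  A single master
seed is split into independent named streams (connectivity, thresholds,
inputs, per-trial dynamics) via :class:`numpy.random.SeedSequence`, so each
component can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .model import Network, NetworkParams

__all__ = [
    "InputEnsemble",
    "generate_connectivity",
    "generate_thresholds",
    "generate_input_ensemble",
    "generate_network",
    "split_seed",
]

# spawn-key indices of the named substreams of a master seed
_STREAMS = {"connectivity": 0, "thresholds": 1, "inputs": 2, "trials": 3}


def split_seed(master_seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """Deterministic independent RNG for a named substream of a master seed.

    ``index`` distinguishes parallel uses within a stream (e.g. trial number).
    """
    key = _STREAMS[stream]
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(key, index))
    return np.random.default_rng(ss)


def trial_seed(master_seed: int, trial: int) -> int:
    """31-bit integer seed for the dynamics of one trial."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(_STREAMS["trials"], trial))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class InputEnsemble:
    """An ensemble of r static external-input vectors, stored columnwise.

    ``P[i, t]`` is the raw drive into neuron ``i`` on trial ``t``; the applied
    external input of the model is ``f_{k(i)} * P[i, t]``.
    """

    P: np.ndarray
    m0: float
    seed: int

    @property
    def r(self) -> int:
        return self.P.shape[1]

    @property
    def N(self) -> int:
        return self.P.shape[0]


def generate_connectivity(params: NetworkParams, seed: int) -> Network:
    """Draw a ground-truth network (sparse R plus thresholds) from a master seed.

    Entry ``(i, j)`` of R is nonzero with probability ``K/N_l`` where ``l`` is
    the population of presynaptic neuron ``j``; autapses (the diagonal) are
    excluded.  Nonzero values depend only on the population pair.
    """
    rng = split_seed(seed, "connectivity")
    N_E, N_I, N = params.N_E, params.N_I, params.N

    p_col = np.concatenate(
        [np.full(N_E, params.K / N_E), np.full(N_I, params.K / N_I)]
    )
    mask = rng.random((N, N)) < p_col[None, :]
    np.fill_diagonal(mask, False)

    ka = params.K**params.alpha
    vals = np.empty((N, N))
    # four population blocks share a single strength each
    vals[:N_E, :N_E] = params.R_EE / ka
    vals[N_E:, :N_E] = params.R_IE / ka
    vals[:N_E, N_E:] = params.R_EI / ka
    vals[N_E:, N_E:] = params.R_II / ka

    R = sp.csc_matrix(np.where(mask, vals, 0.0))
    theta = generate_thresholds(params, seed)
    return Network(params=params, R=R, theta=theta)


def generate_thresholds(params: NetworkParams, seed: int) -> np.ndarray:
    """Per-neuron thresholds theta_k + delta_i with delta_i ~ U[0, d).

    ``d = 0`` reproduces the homogeneous-threshold model exactly.
    """
    base = np.concatenate(
        [np.full(params.N_E, params.theta_E), np.full(params.N_I, params.theta_I)]
    )
    if params.d == 0:
        return base
    rng = split_seed(seed, "thresholds")
    return base + rng.uniform(0.0, params.d, size=params.N)


def generate_input_ensemble(params: NetworkParams, r: int, seed: int) -> InputEnsemble:
    """r i.i.d. uniform external-input vectors on [0, m0*sqrt(K))."""
    if r < 1:
        raise ValueError("ensemble size r must be >= 1")
    rng = split_seed(seed, "inputs")
    high = params.m0 * np.sqrt(params.K)
    P = rng.uniform(0.0, high, size=(params.N, r))
    return InputEnsemble(P=P, m0=params.m0, seed=seed)


def generate_network(params: NetworkParams, seed: int) -> Network:
    """Alias of :func:`generate_connectivity` (thresholds included)."""
    return generate_connectivity(params, seed)
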