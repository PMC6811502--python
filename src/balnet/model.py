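"""Core model types and pointwise dynamical rules for balanced E/I binary networks.

The model is a network of ``N = N_E + N_I`` binary threshold units.  Neuron
``i`` carries a state ``sigma_i(t)`` in {0, 1}; at asynchronous update times
the state is set by thresholding the instantaneous total synaptic drive

    mu_i(t) = sum_j R_ij * sigma_j(t) + (F p)_i ,

where ``R`` is the sparse recurrent connectivity matrix (rows postsynaptic,
columns presynaptic), ``F`` is diagonal with the per-population external
scaling factors ``f_E``, ``f_I``, and ``p`` is a static external input vector.
Excitatory columns of ``R`` are nonnegative, inhibitory columns nonpositive,
with strengths ``R_kl / K**alpha`` where ``K`` is the expected in-degree per
population.  For ``alpha = 1/2`` and external drive of order ``sqrt(K)`` the
network admits a balanced regime in which large excitatory and inhibitory
inputs dynamically cancel; the classical mean-field condition for balance is

    f_E / f_I > R_EI / R_II > 1 .
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "NetworkParams",
    "Network",
    "BalanceReport",
    "check_balance_condition",
    "neuron_state",
    "synaptic_drive",
]


@dataclass(frozen=True)
class NetworkParams:
    """Scalar parameters of the balanced binary-state network model.

    Defaults follow the standard balanced configuration used throughout:
    a 4:1 E:I network of 1000 neurons with expected in-degree K = 0.03*N_E
    per population (0.05 total connection density) and strengths scaled by
    ``K**(-alpha)``.

    Parameters
    ----------
    N_E, N_I : int
        Number of excitatory / inhibitory neurons.
    K : int
        Expected number of presynaptic partners per population.
    R_EE, R_IE : float
        Base excitatory strengths (> 0); first index is the postsynaptic
        population, second presynaptic.
    R_EI, R_II : float
        Base inhibitory strengths (< 0).
    f_E, f_I : float
        External-input scaling factors (> 0), the diagonal of ``F``.
    theta_E, theta_I : float
        Firing thresholds (> 0).
    tau_E, tau_I : float
        Mean time between state updates, in milliseconds.
    alpha : float
        Synaptic scaling exponent in (0, 1]; strengths are ``R_kl / K**alpha``.
        Balance holds in the large-K limit only for alpha = 1/2.
    m0 : float
        Magnitude scale of the uniform external drive; entries of ``p`` are
        uniform on ``[0, m0 * sqrt(K))``.
    d : float
        Width of the uniform per-neuron threshold inhomogeneity (>= 0).
    """

    N_E: int = 800
    N_I: int = 200
    K: int = 24
    R_EE: float = 1.0
    R_IE: float = 1.0
    R_EI: float = -2.0
    R_II: float = -1.8
    f_E: float = 1.2
    f_I: float = 1.0
    theta_E: float = 1.0
    theta_I: float = 0.7
    tau_E: float = 10.0
    tau_I: float = 9.0
    alpha: float = 0.5
    m0: float = 1.0
    d: float = 0.0

    def __post_init__(self) -> None:
        if self.N_E < 1 or self.N_I < 1:
            raise ValueError("population sizes must be >= 1")
        if not (1 <= self.K <= min(self.N_E, self.N_I)):
            raise ValueError(
                f"K={self.K} must satisfy 1 <= K <= min(N_E, N_I)="
                f"{min(self.N_E, self.N_I)} (connection probability K/N_l <= 1)"
            )
        if self.R_EE <= 0 or self.R_IE <= 0:
            raise ValueError("excitatory strengths R_EE, R_IE must be > 0")
        if self.R_EI >= 0 or self.R_II >= 0:
            raise ValueError("inhibitory strengths R_EI, R_II must be < 0")
        if self.f_E <= 0 or self.f_I <= 0:
            raise ValueError("external scalings f_E, f_I must be > 0")
        if self.theta_E <= 0 or self.theta_I <= 0:
            raise ValueError("thresholds must be > 0")
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("update time constants must be > 0")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if self.m0 <= 0:
            raise ValueError("m0 must be > 0")
        if self.d < 0:
            raise ValueError("threshold inhomogeneity width d must be >= 0")

    @property
    def N(self) -> int:
        """Total network size."""
        return self.N_E + self.N_I

    def replace(self, **kwargs) -> "NetworkParams":
        """Return a copy with the given fields replaced (re-validated)."""
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)

    def strength(self, post: str, pre: str) -> float:
        """Effective connection strength R_kl / K**alpha for a population pair."""
        base = {
            ("E", "E"): self.R_EE,
            ("I", "E"): self.R_IE,
            ("E", "I"): self.R_EI,
            ("I", "I"): self.R_II,
        }[(post, pre)]
        return base / self.K**self.alpha

    @property
    def f_vector(self) -> np.ndarray:
        """Diagonal of F as a length-N vector (f_E first, then f_I)."""
        return np.concatenate(
            [np.full(self.N_E, self.f_E), np.full(self.N_I, self.f_I)]
        )


@dataclass
class Network:
    """A realized network: sparse recurrent matrix, external scalings, thresholds.

    ``R`` is stored in CSC format so a presynaptic neuron's postsynaptic
    targets (one column) can be traversed in O(out-degree), which the
    event-driven simulator relies on.  Neurons are indexed 0..N-1 with the
    excitatory population first.
    """

    params: NetworkParams
    R: sp.csc_matrix
    theta: np.ndarray
    f: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        N = self.params.N
        if self.R.shape != (N, N):
            raise ValueError(f"R must be {N}x{N}, got {self.R.shape}")
        if self.theta.shape != (N,):
            raise ValueError("theta must be a length-N vector")
        if self.f is None:
            self.f = self.params.f_vector
        self.R = sp.csc_matrix(self.R)

    @property
    def N(self) -> int:
        return self.params.N

    @property
    def F(self) -> sp.dia_matrix:
        """The diagonal feed-forward scaling matrix."""
        return sp.diags(self.f)

    def population(self, i: int) -> str:
        """Population label ('E' or 'I') of neuron i."""
        return "E" if i < self.params.N_E else "I"


@dataclass(frozen=True)
class BalanceReport:
    """Verdict of the mean-field balance condition f_E/f_I > R_EI/R_II > 1."""

    lhs: float
    mid: float
    satisfied: bool


def check_balance_condition(params: NetworkParams) -> BalanceReport:
    """Evaluate the balance condition on the connection-strength quotients.

    Balance in the large-K limit requires the chain of strict inequalities
    ``f_E/f_I > R_EI/R_II > 1``.  Both quotients are dimensionless and
    invariant under positive rescaling of the pair they are formed from.
    """
    lhs = params.f_E / params.f_I
    mid = params.R_EI / params.R_II
    return BalanceReport(lhs=lhs, mid=mid, satisfied=(lhs > mid > 1.0))


def neuron_state(mu, theta):
    """Heaviside update rule: state is 1 iff the drive reaches threshold.

    The fires-at-threshold convention H(0) = 1 is fixed so that tests are
    deterministic; under continuous random drive the event mu == theta has
    probability zero.  Accepts scalars or arrays (broadcast).
    """
    mu = np.asarray(mu)
    theta = np.asarray(theta)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(theta))):
        raise ValueError("non-finite drive or threshold")
    out = (mu >= theta).astype(np.int8)
    return out if out.ndim else int(out)


def synaptic_drive(network: Network, sigma: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Instantaneous total drive mu = R sigma + F p into every neuron."""
    sigma = np.asarray(sigma, dtype=float)
    p = np.asarray(p, dtype=float)
    N = network.N
    if sigma.shape != (N,) or p.shape != (N,):
        raise ValueError(f"sigma and p must be length-{N} vectors")
    return network.R @ sigma + network.f * p
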