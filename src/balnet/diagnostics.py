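"""Reconstruction-quality and dynamical-regime diagnostics.

The headline quality metric is the relative Frobenius error
``||R - R_recon||_F / ||R||_F``.  The regime diagnostic is the per-neuron
ratio of time-averaged excitatory input (recurrent excitatory plus external
drive) to time-averaged inhibitory input: in the balanced state this ratio
is narrowly distributed near -1 across the network, and reconstruction
quality degrades as its mean departs from -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import scipy.sparse as sp

from .simulate import ResponseData, TrialSummary

__all__ = ["RegimeStats", "relative_error", "regime_stats", "support_metrics"]

Q_LOW = 0.01  # time-averaged state below which a neuron counts as quiescent
Q_HIGH = 0.99  # and above which as saturated
INHIBITION_FLOOR_REL = 1e-6  # x median |i_bar|: exclusion floor for ratios


@dataclass
class RegimeStats:
    """Summary of the E/I input-ratio distribution and occupancy extremes."""

    mean_ratio: float
    ratio_sd: float
    dev_from_balance: float
    frac_quiescent: float
    frac_saturated: float
    n_excluded: int


def _as_dense(M) -> np.ndarray:
    return M.toarray() if sp.issparse(M) else np.asarray(M, dtype=float)


def relative_error(R_true, R_recon) -> float:
    """Relative Frobenius error ||R_true - R_recon||_F / ||R_true||_F."""
    Rt = _as_dense(R_true)
    Rr = _as_dense(R_recon)
    if Rt.shape != Rr.shape:
        raise ValueError("dimension mismatch")
    denom = np.linalg.norm(Rt)
    if denom == 0:
        raise ValueError("true matrix is zero; relative error undefined")
    return float(np.linalg.norm(Rt - Rr) / denom)


def regime_stats(
    summary: Union[TrialSummary, ResponseData],
    q_low: float = Q_LOW,
    q_high: float = Q_HIGH,
) -> RegimeStats:
    """E/I-ratio statistics of a trial (or trial-averaged ensemble).

    Per neuron the ratio is ``e_bar_i / i_bar_i`` (negative under balance).
    Neurons whose inhibitory input magnitude falls below a floor relative to
    the network median are excluded from the ratio statistics (they would
    blow up the quotient in near-quiescent regimes) and counted.
    """
    if isinstance(summary, ResponseData):
        if summary.E_bar is None:
            raise ValueError("ResponseData lacks E/I components (track_ei=False)")
        e = summary.E_bar.mean(axis=1)
        ih = summary.I_bar.mean(axis=1)
        x = summary.X.mean(axis=1)
    else:
        if summary.e_bar is None:
            raise ValueError("TrialSummary lacks E/I components (track_ei=False)")
        e, ih, x = summary.e_bar, summary.i_bar, summary.x_bar

    floor = INHIBITION_FLOOR_REL * np.median(np.abs(ih))
    keep = np.abs(ih) > max(floor, 0.0)
    if not np.any(keep):
        raise ValueError("no neuron receives inhibitory input; E/I ratio undefined")
    ratios = e[keep] / ih[keep]
    mean_ratio = float(ratios.mean())
    return RegimeStats(
        mean_ratio=mean_ratio,
        ratio_sd=float(ratios.std()),
        dev_from_balance=abs(mean_ratio - (-1.0)),
        frac_quiescent=float(np.mean(x < q_low)),
        frac_saturated=float(np.mean(x > q_high)),
        n_excluded=int(np.sum(~keep)),
    )


def support_metrics(R_true, R_recon, tol: float):
    """Support and sign recovery: (precision, recall, sign_accuracy).

    An entry is detected when ``|R_recon| >= tol``.  Precision is over
    detected entries (reported as 1.0 when nothing is detected), recall over
    true nonzeros, and sign accuracy over detected true entries.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    Rt = _as_dense(R_true)
    Rr = _as_dense(R_recon)
    true_supp = Rt != 0
    det = np.abs(Rr) >= tol
    n_det = int(det.sum())
    tp = det & true_supp
    precision = float(tp.sum() / n_det) if n_det else 1.0
    n_true = int(true_supp.sum())
    recall = float(tp.sum() / n_true) if n_true else 1.0
    if tp.any():
        sign_accuracy = float(np.mean(np.sign(Rr[tp]) == np.sign(Rt[tp])))
    else:
        sign_accuracy = 1.0
    return precision, recall, sign_accuracy
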