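"""Row-wise L1-minimization recovery of the recurrent connectivity matrix.

Time-averaging the binary dynamics under a static drive gives the linear
mapping ``mu_bar = R x_bar + F p`` per trial.  Stacking r trials columnwise,
row i of R solves the underdetermined system

    A v = b,   A = X^T (r x N, rows = trials),   b_t = U[i, t] - f_i P[i, t].

With R sparse and the average states approximately uncorrelated in the
balanced regime, the compressive-sensing estimate of the row is the solution
of minimal L1 norm.  No sign constraints are imposed: connection signs are
recovered, not assumed.  The N row problems share the sensing matrix and are
independent, so the Gram matrix ``A^T A`` is formed once and rows are solved
in any order with identical results.

Solvers
-------
``lasso`` (default)
    Coordinate descent on ``1/(2r) ||A v - b||^2 + alpha ||v||_1`` with the
    penalty set per row as ``lambda_rel * ||A^T b||_inf / r``.  A small
    relative penalty approximates basis pursuit while absorbing finite-time
    averaging noise; this is the practical workhorse at full scale.
``basis_pursuit``
    Exact ``min ||v||_1 s.t. A v = b`` as a split-variable linear program
    (HiGHS).  Preferred for small/exact-data problems and used as the
    reference formulation in cross-checks.
``bpdn``
    ``min ||v||_1 s.t. ||A v - b||_2 <= delta`` via bisection on the lasso
    penalty until the residual constraint is active.
``omp``
    Orthogonal matching pursuit (scikit-learn), greedy baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linprog

from .simulate import ResponseData
from .synth import InputEnsemble

__all__ = [
    "SolverConfig",
    "RowSystem",
    "ReconstructionResult",
    "build_row_system",
    "l1_solve_row",
    "reconstruct",
]


@dataclass(frozen=True)
class SolverConfig:
    """Settings of the row solver.

    lambda_rel : lasso penalty relative to the per-row ``alpha_max``
        (the smallest penalty with an all-zero solution).
    delta : BPDN residual bound; if None it is set to zero-noise default.
    tol, max_iter : coordinate-descent convergence controls.
    n_nonzero : OMP sparsity budget (defaults to 2K when reconstructing).
    """

    solver: str = "lasso"
    lambda_rel: float = 1e-3
    delta: Optional[float] = None
    tol: float = 1e-6
    max_iter: int = 5000
    n_nonzero: Optional[int] = None

    def __post_init__(self):
        if self.solver not in {"lasso", "basis_pursuit", "bpdn", "omp"}:
            raise ValueError(f"unknown solver {self.solver!r}")


@dataclass
class RowSystem:
    """The r x N sensing system for one row of R."""

    A: np.ndarray
    b: np.ndarray
    row_index: int

    def __post_init__(self):
        if self.A.shape[0] != self.b.shape[0]:
            raise ValueError("A and b have mismatched trial counts")
        if not np.all(np.isfinite(self.b)):
            raise ValueError("non-finite right-hand side")


@dataclass
class ReconstructionResult:
    """Estimated connectivity matrix with per-row solver metadata."""

    R_recon: np.ndarray
    solver_name: str
    per_row_residuals: np.ndarray
    config: SolverConfig
    failures: list = field(default_factory=list)


def build_row_system(
    response: ResponseData, ensemble: InputEnsemble, f: np.ndarray, i: int
) -> RowSystem:
    """Assemble ``A = X^T`` and ``b_t = U[i,t] - f_i P[i,t]`` for row i."""
    N = response.X.shape[0]
    if not (0 <= i < N):
        raise IndexError(f"row index {i} out of range for N={N}")
    if ensemble.r != response.r:
        raise ValueError("response and ensemble trial counts differ")
    A = response.X.T
    b = response.U[i, :] - f[i] * ensemble.P[i, :]
    return RowSystem(A=A, b=b, row_index=i)


def _lasso_gram(A, b, alpha, cfg, gram=None, Xy=None):
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import lasso_path

    r = A.shape[0]
    if Xy is None:
        Xy = A.T @ b
    if alpha <= 0:  # degenerate: plain min-norm least squares would differ; use BP
        return _basis_pursuit(A, b)
    with warnings.catch_warnings():
        # deliberately small penalties trip the duality-gap heuristic; the
        # iteration cap is the effective stopping rule (see docs/methods.md)
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = lasso_path(
            A,
            b,
            alphas=[alpha],
            precompute=gram if gram is not None else "auto",
            Xy=Xy,
            copy_X=False,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
        )
    return coefs[:, 0]


def _basis_pursuit(A, b):
    """min ||v||_1 s.t. Av = b, as a split-variable LP (v = u - w, u,w >= 0)."""
    r, N = A.shape
    res = linprog(
        c=np.ones(2 * N),
        A_eq=np.hstack([A, -A]),
        b_eq=b,
        bounds=(0, None),
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"basis pursuit LP failed: {res.message}")
    return res.x[:N] - res.x[N:]


def _bpdn(A, b, delta, cfg, gram=None, Xy=None):
    """Residual-constrained L1 via bisection on the lasso penalty."""
    r = A.shape[0]
    if Xy is None:
        Xy = A.T @ b
    bnorm = float(np.linalg.norm(b))
    if bnorm <= delta:
        return np.zeros(A.shape[1])
    if delta <= 1e-8 * bnorm:  # effectively an equality constraint
        return _basis_pursuit(A, b)
    alpha_hi = float(np.max(np.abs(Xy))) / r  # residual = ||b|| > delta here
    alpha_lo = 0.0
    v = np.zeros(A.shape[1])
    for _ in range(40):
        alpha = 0.5 * (alpha_lo + alpha_hi) if alpha_lo > 0 else alpha_hi / 2
        v = _lasso_gram(A, b, alpha, cfg, gram=gram, Xy=Xy)
        resid = float(np.linalg.norm(A @ v - b))
        if abs(resid - delta) <= 0.01 * delta:
            break
        if resid > delta:
            alpha_hi = alpha
        else:
            alpha_lo = alpha
    return v


def _omp(A, b, cfg):
    from sklearn.linear_model import OrthogonalMatchingPursuit

    k = cfg.n_nonzero or max(1, A.shape[0] // 4)
    est = OrthogonalMatchingPursuit(n_nonzero_coefs=min(k, A.shape[0]), fit_intercept=False)
    est.fit(A, b)
    return est.coef_


def l1_solve_row(
    system: RowSystem,
    config: SolverConfig = SolverConfig(),
    gram: Optional[np.ndarray] = None,
    Xy: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Solve one row system by the configured L1 method.

    ``gram`` (= A^T A) and ``Xy`` (= A^T b) may be supplied to amortize work
    across rows sharing the sensing matrix.  Non-convergence raises with the
    row index; rows are never silently zeroed.
    """
    A, b = system.A, system.b
    try:
        if config.solver == "basis_pursuit":
            return _basis_pursuit(A, b)
        if gram is None and config.solver in {"lasso", "bpdn"}:
            gram = A.T @ A  # coordinate descent is unreliable without it
        if config.solver == "lasso":
            if Xy is None:
                Xy = A.T @ b
            alpha = config.lambda_rel * float(np.max(np.abs(Xy))) / A.shape[0]
            if alpha == 0.0:  # b orthogonal to all columns (e.g. b = 0)
                return np.zeros(A.shape[1])
            return _lasso_gram(A, b, alpha, config, gram=gram, Xy=Xy)
        if config.solver == "bpdn":
            delta = config.delta if config.delta is not None else 1e-9 * max(
                1.0, float(np.linalg.norm(b))
            )
            return _bpdn(A, b, delta, config, gram=gram, Xy=Xy)
        return _omp(A, b, config)
    except Exception as err:  # annotate with row identity, re-raise
        raise RuntimeError(f"row {system.row_index}: solver failed: {err}") from err


def reconstruct(
    response: ResponseData,
    ensemble: InputEnsemble,
    f: np.ndarray,
    config: SolverConfig = SolverConfig(),
) -> ReconstructionResult:
    """Estimate every row of R by L1 minimization; rows are independent.

    The feed-forward scalings ``f`` and the injected inputs ``P`` are known
    to the reconstructor; R is the only unknown.
    """
    N, r = response.X.shape
    A = np.ascontiguousarray(response.X.T)
    B = response.U - f[:, None] * ensemble.P  # row i = b_i
    gram = A.T @ A
    XY = response.X @ B.T  # column i = A^T b_i
    R_recon = np.empty((N, N))
    residuals = np.empty(N)
    failures = []
    for i in range(N):
        system = RowSystem(A=A, b=B[i, :], row_index=i)
        try:
            v = l1_solve_row(system, config, gram=gram, Xy=XY[:, i].copy())
        except RuntimeError as err:
            failures.append((i, str(err)))
            v = np.full(N, np.nan)
        R_recon[i, :] = v
        residuals[i] = np.linalg.norm(A @ np.nan_to_num(v) - B[i, :])
    return ReconstructionResult(
        R_recon=R_recon,
        solver_name=config.solver,
        per_row_residuals=residuals,
        config=config,
        failures=failures,
    )
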