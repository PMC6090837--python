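"""Linear stimulus-response model estimators.

All schemes minimize the residual sum of squares ``(Y - XW)^T (Y - XW)`` plus
a scheme-specific penalty, and (except the elastic net) admit closed forms in
terms of the sufficient statistics ``Cxx = X^T X`` and ``Cxy = X^T Y``:

====================  =======================================================
ols                   ``W = Cxx^{-1} Cxy``
ridge                 ``W = (Cxx + lam I)^{-1} Cxy``            (L2 penalty)
lra                   spectral truncation of Cxx at the smallest rank whose
                      eigenvalue mass covers a fraction ``lam`` of the trace
shrinkage             ``W = ((1-lam) Cxx + lam nu I)^{-1} Cxy`` with ``nu``
                      the average eigenvalue (trace / dim); flattens the
                      eigenvalue spectrum toward its mean
tikhonov              ``W = (Cxx + lam M)^{-1} Cxy`` with ``M = D^T D`` the
                      second-difference matrix; penalizes the first
                      derivative of the kernel across adjacent columns
                      (temporal smoothness)
elasticnet            coordinate descent on
                      ``1/(2N) ||Y - XW||^2 + lam[(1-alpha)||W||^2/2
                      + alpha ||W||_1]``
====================  =======================================================

Ridge and shrinkage flatten the eigenvalue spectrum smoothly (ridge shifts it
up, shrinkage pulls it toward the average), LRA hard-thresholds it, Tikhonov
penalizes roughness, the elastic net adds sparsity.  The lambda values of the
different schemes are *not* comparable; each scheme is tuned on its own path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .datamodel import DesignMatrix, TimeSeries
from .exceptions import (
    DegenerateInputError,
    InvalidParameterError,
    ShapeError,
    SingularMatrixError,
)

__all__ = [
    "CovariancePair",
    "RegularizationPath",
    "SpectralDecomposition",
    "ElasticNetResult",
    "assemble_covariances",
    "solve_ols",
    "solve_ridge",
    "solve_lra",
    "solve_shrinkage",
    "build_second_difference_matrix",
    "solve_tikhonov",
    "solve_elastic_net",
    "solve_by_name",
    "default_path",
    "sweep_geometric_lambdas",
    "sweep_logsigmoid_lambdas",
    "ESTIMATOR_NAMES",
]

ESTIMATOR_NAMES = ("ols", "ridge", "lra", "shrinkage", "tikhonov", "elasticnet")

#: eigenvalues below this fraction of the largest are treated as exact zeros
#: (numerical PSD noise) before LRA inversion
LRA_EIG_CLIP = 1e-12

#: default upper bound on the condition number accepted by solve_ols
OLS_COND_MAX = 1e12


# ---------------------------------------------------------------------------
# Sufficient statistics
# ---------------------------------------------------------------------------

@dataclass
class CovariancePair:
    """``Cxx = X^T X`` (autocovariance) and ``Cxy = X^T Y`` (cross-covariance)."""

    cxx: np.ndarray
    cxy: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.cxx = np.asarray(self.cxx, dtype=float)
        self.cxy = np.asarray(self.cxy, dtype=float)
        if self.cxy.ndim == 1:
            self.cxy = self.cxy[:, None]
        if self.cxx.ndim != 2 or self.cxx.shape[0] != self.cxx.shape[1]:
            raise ShapeError("cxx must be square")
        if self.cxy.shape[0] != self.cxx.shape[0]:
            raise ShapeError("cxy row count must equal the cxx dimension")

    @property
    def dim(self) -> int:
        return self.cxx.shape[0]


def assemble_covariances(design: DesignMatrix, target: TimeSeries) -> CovariancePair:
    """Accumulate ``X^T X`` and ``X^T Y`` from a design matrix and target."""
    x = design.values
    y = target.samples
    if x.shape[0] != y.shape[0]:
        raise ShapeError(
            f"design has {x.shape[0]} rows but target has {y.shape[0]}"
        )
    return CovariancePair(x.T @ x, x.T @ y, x.shape[0])


@dataclass
class SpectralDecomposition:
    """Eigendecomposition ``Cxx = U diag(s) U^T`` of a PSD covariance.

    Eigenvalues are sorted descending and clipped at zero; for a PSD input the
    left and right singular vectors coincide, so ``U`` plays both roles.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @classmethod
    def from_covariance(cls, cxx: np.ndarray) -> "SpectralDecomposition":
        s, u = sla.eigh(cxx)
        order = np.argsort(s)[::-1]
        return cls(np.maximum(s[order], 0.0), u[:, order])


# ---------------------------------------------------------------------------
# Closed-form solvers
# ---------------------------------------------------------------------------

def _cho_solve_sym(a: np.ndarray, b: np.ndarray, context: str) -> np.ndarray:
    """Solve the symmetric positive-definite system ``a w = b`` via Cholesky."""
    try:
        c, low = sla.cho_factor(a, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise SingularMatrixError(f"{context}: matrix is not positive definite") from exc
    except sla.LinAlgError as exc:
        raise SingularMatrixError(f"{context}: matrix is not positive definite") from exc
    return sla.cho_solve((c, low), b, check_finite=False)


def solve_ols(cov: CovariancePair, cond_max: float = OLS_COND_MAX) -> np.ndarray:
    """Ordinary least squares ``W = Cxx^{-1} Cxy`` via symmetric factorization.

    Refuses ill-conditioned systems: the reciprocal condition number is
    estimated from the Cholesky factor (LAPACK ``pocon``) and compared
    against ``1 / cond_max``.
    """
    a = cov.cxx
    try:
        c, low = sla.cho_factor(a, lower=True, check_finite=False)
    except sla.LinAlgError as exc:
        raise SingularMatrixError("OLS: covariance is singular (not PD)") from exc
    pocon = sla.get_lapack_funcs("pocon", (a,))
    anorm = np.abs(a).sum(axis=0).max()  # 1-norm
    rcond, info = pocon(c, anorm, uplo="L")
    if info != 0 or not np.isfinite(rcond) or rcond < 1.0 / cond_max:
        est = np.inf if rcond == 0 else 1.0 / max(rcond, np.finfo(float).tiny)
        raise SingularMatrixError(
            f"OLS: covariance condition estimate {est:.3g} exceeds bound {cond_max:.3g}"
        )
    return sla.cho_solve((c, low), cov.cxy, check_finite=False)


def solve_ridge(cov: CovariancePair, lam: float) -> np.ndarray:
    """Ridge solution ``W = (Cxx + lam I)^{-1} Cxy`` (L2-shrunk weights)."""
    if lam < 0:
        raise InvalidParameterError(f"ridge lambda must be >= 0, got {lam}")
    a = cov.cxx + lam * np.eye(cov.dim)
    return _cho_solve_sym(a, cov.cxy, "ridge")


def solve_lra(cov: CovariancePair, lam: float) -> np.ndarray:
    """Low-rank-approximation (normalized reverse correlation) solution.

    Keeps the smallest leading rank ``K`` whose eigenvalue sum covers a
    fraction ``lam`` of the total eigenvalue mass, inverts only that
    subspace, and zeroes the rest: ``W = U diag(1/s_1..1/s_K, 0,..) U^T Cxy``.
    """
    if not 0 < lam <= 1:
        raise InvalidParameterError(f"LRA lambda must be in (0, 1], got {lam}")
    dec = SpectralDecomposition.from_covariance(cov.cxx)
    s = dec.eigenvalues.copy()
    if s[0] <= 0:
        raise DegenerateInputError("LRA: covariance matrix is all zero")
    s[s < LRA_EIG_CLIP * s[0]] = 0.0
    total = s.sum()
    csum = np.cumsum(s)
    k = int(np.searchsorted(csum, lam * total - 1e-15 * total) + 1)
    k = min(k, int(np.count_nonzero(s)))
    inv = np.zeros_like(s)
    inv[:k] = 1.0 / s[:k]
    u = dec.eigenvectors
    return u @ (inv[:, None] * (u.T @ cov.cxy))


def solve_shrinkage(cov: CovariancePair, lam: float) -> np.ndarray:
    """Shrinkage solution ``W = ((1-lam) Cxx + lam nu I)^{-1} Cxy``.

    ``nu = trace(Cxx)/d`` is the average eigenvalue; ``lam = 0`` reduces to
    OLS and ``lam = 1`` to a plain cross-correlation ``Cxy / nu``.
    """
    if not 0 <= lam <= 1:
        raise InvalidParameterError(f"shrinkage lambda must be in [0, 1], got {lam}")
    nu = np.trace(cov.cxx) / cov.dim
    if lam == 1.0:
        if nu == 0:
            raise DegenerateInputError("shrinkage: zero covariance trace")
        return cov.cxy / nu
    a = (1.0 - lam) * cov.cxx + lam * nu * np.eye(cov.dim)
    return _cho_solve_sym(a, cov.cxy, "shrinkage")


def build_second_difference_matrix(d: int) -> np.ndarray:
    """Tridiagonal penalty matrix ``M = D^T D`` of the first-difference operator.

    ``w^T M w`` equals the roughness penalty ``sum_i (w_i - w_{i+1})^2``; its
    null space is the constant vector, so perfectly smooth (flat) kernels are
    unpenalized.
    """
    if d < 2:
        raise InvalidParameterError(f"second-difference matrix needs d >= 2, got {d}")
    m = 2.0 * np.eye(d)
    m[0, 0] = m[-1, -1] = 1.0
    idx = np.arange(d - 1)
    m[idx, idx + 1] = -1.0
    m[idx + 1, idx] = -1.0
    return m


def tikhonov_penalty_matrix(dim: int, n_channels: int = 1,
                            per_channel: bool = False) -> np.ndarray:
    """Penalty matrix for Tikhonov smoothing over the combined channel-lag axis.

    By default a single global second-difference matrix spans the full
    combined dimension, so with a multichannel regressor the kernel endpoints
    of adjacent channels leak into each other — the convention used when the
    backward direction is reported "for completeness".  ``per_channel=True``
    instead builds a block-diagonal matrix with one smoother per channel
    (no cross-channel leakage).
    """
    if not per_channel or n_channels <= 1:
        return build_second_difference_matrix(dim)
    if dim % n_channels:
        raise InvalidParameterError(
            f"dimension {dim} not divisible by {n_channels} channels"
        )
    block = build_second_difference_matrix(dim // n_channels)
    return sla.block_diag(*([block] * n_channels))


def solve_tikhonov(cov: CovariancePair, lam: float, n_channels: int = 1,
                   per_channel: bool = False) -> np.ndarray:
    """First-derivative Tikhonov solution ``W = (Cxx + lam M)^{-1} Cxy``."""
    if lam < 0:
        raise InvalidParameterError(f"tikhonov lambda must be >= 0, got {lam}")
    m = tikhonov_penalty_matrix(cov.dim, n_channels, per_channel)
    return _cho_solve_sym(cov.cxx + lam * m, cov.cxy, "tikhonov")


# ---------------------------------------------------------------------------
# Elastic net (cyclic coordinate descent)
# ---------------------------------------------------------------------------

@dataclass
class ElasticNetResult:
    """Coordinate-descent solution with its convergence flag."""

    weights: np.ndarray
    converged: bool
    n_iter: int


def _soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def solve_elastic_net(design: DesignMatrix, target: TimeSeries, lam: float,
                      alpha: float, tol: float = 1e-6, max_iter: int = 10_000,
                      w0: np.ndarray | None = None) -> ElasticNetResult:
    """Elastic net via naive cyclic coordinate descent with soft thresholding.

    Minimizes ``1/(2N) ||Y - XW||^2 + lam [(1-alpha) ||W||^2 / 2 +
    alpha ||W||_1]``.  Columns are assumed approximately standardized; the
    solver rescales each column to unit root-mean-square internally and maps
    the coefficients back, so only the interpretation of ``lam`` (not the
    optimum of the stated objective on standardized data) depends on scaling.
    ``w0`` warm-starts the iteration (used along a lambda path); warm starts
    change only the iteration count, not the converged solution beyond ``tol``.
    """
    if not 0 < alpha <= 1:
        raise InvalidParameterError(f"alpha must be in (0, 1], got {alpha}")
    if lam < 0:
        raise InvalidParameterError(f"lambda must be >= 0, got {lam}")
    x = design.values
    y = target.samples
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] != y.shape[0]:
        raise ShapeError("design and target row counts differ")
    n, d = x.shape
    n_out = y.shape[1]

    scale = np.sqrt((x * x).sum(axis=0) / n)
    scale[scale == 0] = 1.0
    xs = x / scale
    col_sq = np.full(d, float(n))  # xs_j^T xs_j for unit-RMS columns

    w = np.zeros((d, n_out)) if w0 is None else (np.asarray(w0, float).reshape(d, n_out) * scale[:, None])
    converged = True
    total_iter = 0
    for j_out in range(n_out):
        wj = w[:, j_out].copy()
        r = y[:, j_out] - xs @ wj
        ok = False
        it = 0
        for it in range(1, max_iter + 1):
            max_delta = 0.0
            for j in range(d):
                old = wj[j]
                rho = (xs[:, j] @ r) / n + old  # uses xs_j^T xs_j / n == 1
                new = _soft_threshold(np.array(rho), lam * alpha) / (1.0 + lam * (1.0 - alpha))
                new = float(new)
                if new != old:
                    r += xs[:, j] * (old - new)
                    wj[j] = new
                    max_delta = max(max_delta, abs(new - old))
            if max_delta < tol:
                ok = True
                break
        total_iter = max(total_iter, it)
        if not ok:
            converged = False
        w[:, j_out] = wj
    if not converged:
        warnings.warn(
            f"elastic net did not converge in {max_iter} iterations "
            f"(lam={lam:g}, alpha={alpha:g})",
            RuntimeWarning,
        )
    return ElasticNetResult(w / scale[:, None], converged, total_iter)


# ---------------------------------------------------------------------------
# Estimator selection
# ---------------------------------------------------------------------------

def solve_by_name(name: str, cov: CovariancePair, lam: float,
                  design: DesignMatrix | None = None,
                  target: TimeSeries | None = None,
                  **kwargs) -> np.ndarray:
    """Dispatch a solver by name: ols | ridge | lra | shrinkage | tikhonov | elasticnet.

    All closed-form schemes consume the :class:`CovariancePair` sufficient
    statistics; the elastic net is the deliberate exception — coordinate
    descent needs the raw design and target.
    """
    name = name.lower()
    if name == "ols":
        return solve_ols(cov, **kwargs)
    if name == "ridge":
        return solve_ridge(cov, lam)
    if name == "lra":
        return solve_lra(cov, lam)
    if name == "shrinkage":
        return solve_shrinkage(cov, lam)
    if name == "tikhonov":
        return solve_tikhonov(cov, lam, **kwargs)
    if name == "elasticnet":
        if design is None or target is None:
            raise InvalidParameterError(
                "elasticnet requires the raw design matrix and target"
            )
        alpha = kwargs.pop("alpha", 0.5)
        return solve_elastic_net(design, target, lam, alpha, **kwargs).weights
    raise InvalidParameterError(
        f"unknown estimator {name!r}; choose from {ESTIMATOR_NAMES}"
    )


# ---------------------------------------------------------------------------
# Regularization paths
# ---------------------------------------------------------------------------

@dataclass
class RegularizationPath:
    """Strictly increasing sweep of candidate regularization strengths."""

    lambdas: np.ndarray
    family: str  # "geometric" | "logsigmoid"

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.lambdas.ndim != 1 or self.lambdas.size < 1:
            raise InvalidParameterError("path must hold at least one lambda")
        if np.any(self.lambdas <= 0):
            raise InvalidParameterError("all lambdas must be positive")
        if self.lambdas.size > 1 and np.any(np.diff(self.lambdas) <= 0):
            raise InvalidParameterError("lambdas must be strictly increasing")
        if self.family == "geometric" and self.lambdas.size > 2:
            ratios = self.lambdas[1:] / self.lambdas[:-1]
            if np.ptp(ratios) > 1e-12 * ratios[0]:
                raise InvalidParameterError("geometric path has non-constant ratio")

    def __len__(self) -> int:
        return self.lambdas.size

    def __iter__(self):
        return iter(self.lambdas)


def sweep_geometric_lambdas(lam0: float = 1e-6, ratio: float = 1.848,
                            n_steps: int = 54) -> RegularizationPath:
    """Geometric sweep ``lam_n = lam0 * ratio**n`` for ``n = 0..n_steps-1``.

    The defaults cover 1e-6 to roughly 1.4e8 in 54 logarithmically spaced
    steps, the conventional range for penalties that live on (0, inf)
    (ridge, Tikhonov, overall elastic-net strength).
    """
    if n_steps < 1:
        raise InvalidParameterError(f"need n_steps >= 1, got {n_steps}")
    if ratio <= 0:
        raise InvalidParameterError(f"ratio must be positive, got {ratio}")
    if lam0 <= 0:
        raise InvalidParameterError(f"lam0 must be positive, got {lam0}")
    lams = lam0 * ratio ** np.arange(n_steps)
    return RegularizationPath(lams, "geometric")


def sweep_logsigmoid_lambdas(lam0: float = 1e-6, step: float = 0.475,
                             n_steps: int = 41) -> RegularizationPath:
    """Log-sigmoid sweep for penalties that live on (0, 1) (LRA, shrinkage).

    Iterates ``logit(lam) <- logit(lam) + step`` and maps back through the
    logistic function, compressing an unbounded geometric-like progression
    into (0, 1).  ``n_steps`` counts the emitted values including ``lam0``.
    """
    if not 0 < lam0 < 1:
        raise InvalidParameterError(f"lam0 must be in (0, 1), got {lam0}")
    if n_steps < 1:
        raise InvalidParameterError(f"need n_steps >= 1, got {n_steps}")
    logits = np.log(lam0 / (1 - lam0)) + step * np.arange(n_steps)
    lams = 1.0 / (1.0 + np.exp(-logits))
    return RegularizationPath(lams, "logsigmoid")


def default_path(estimator: str) -> RegularizationPath:
    """The conventional sweep for each scheme's natural parameter range."""
    estimator = estimator.lower()
    if estimator in ("ridge", "tikhonov", "elasticnet"):
        return sweep_geometric_lambdas()
    if estimator in ("lra", "shrinkage"):
        return sweep_logsigmoid_lambdas()
    if estimator == "ols":
        return RegularizationPath(np.array([1.0]), "geometric")  # unused dummy
    raise InvalidParameterError(f"unknown estimator {estimator!r}")
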