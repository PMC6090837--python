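"""Nested cross-validation and regression-accuracy scoring.

Outer loop: trials are split into ``n_folds`` folds (default 10); one fold is
held out for testing, the rest are training data.  Inner loop: the training
folds are re-split (default: leave-one-training-fold-out, 9 inner folds); for
every candidate regularization strength a model is fit on each inner-training
set and scored by the correlation between its prediction/reconstruction and
the validation fold.  The lambda maximizing the mean validation correlation
across inner folds is selected (smallest such lambda on ties — validation
curves are typically flat over a broad region), and the inner-fold models at
that lambda are averaged element-wise into the model that is applied to the
held-out test fold.  Models are always fit to attended-envelope/EEG pairs.

Implementation note: fitting at the full study scale (66 channels x 33 lags =
2,178 regressor dimensions) is done on *lagged sufficient statistics* — raw
per-trial lagged Gram matrices plus prefix-sum correction terms — so that
z-normalization with training-fold statistics can be applied to the
covariances exactly, without rebuilding design matrices for every fold, and
so ridge / shrinkage / LRA / OLS can share a single eigendecomposition per
inner fold.  Trial boundaries never leak: lagging and zero padding happen
within each trial before anything is summed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg as sla

from .datamodel import (
    LagSpec,
    LinearModel,
    TimeSeries,
    apply_model,
    build_lagged_design,
    pearson_r,
)
from .estimators import (
    CovariancePair,
    RegularizationPath,
    solve_elastic_net,
    solve_tikhonov,
)
from .exceptions import InvalidParameterError, TuningError

__all__ = [
    "Trial",
    "FoldAssignment",
    "CVReport",
    "TuningResult",
    "make_folds",
    "tune_lambda_nested",
    "cross_validate",
    "cross_validate_multi",
    "regression_accuracy_forward",
    "regression_accuracy_backward",
    "save_model",
    "load_model",
]

SPECTRAL_ESTIMATORS = ("ols", "ridge", "lra", "shrinkage")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Trial:
    """One experimental trial: EEG plus the two stream envelopes and the label."""

    eeg: TimeSeries
    attended_env: TimeSeries
    unattended_env: TimeSeries | None = None
    label: str | None = None


@dataclass
class FoldAssignment:
    """Per-trial fold index (trials, not samples, are the assignment unit)."""

    fold_of: np.ndarray
    n_folds: int

    def __post_init__(self) -> None:
        self.fold_of = np.asarray(self.fold_of, dtype=int)
        sizes = np.bincount(self.fold_of, minlength=self.n_folds)
        if np.any(sizes == 0):
            raise InvalidParameterError("every fold must contain at least one trial")

    def trials_in(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)


def make_folds(n_trials: int, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Seeded permutation of trials into folds of near-equal size (diff <= 1)."""
    if n_trials < n_folds:
        raise InvalidParameterError(
            f"cannot split {n_trials} trials into {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_trials)
    fold_of = np.empty(n_trials, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        fold_of[chunk] = f
    return FoldAssignment(fold_of, n_folds)


@dataclass
class TuningResult:
    """Outcome of one inner cross-validation loop."""

    selected_lambda: float | None
    model: np.ndarray                    # averaged (d, n_out) weight matrix
    validation_curve: np.ndarray         # mean validation r per lambda
    fold_models: list[np.ndarray]        # per-inner-fold models at lambda*
    fold_curves: np.ndarray              # (n_inner, n_lambda) validation r


@dataclass
class CVReport:
    """Nested-CV result for one estimator on one dataset."""

    estimator: str
    direction: str
    folds: FoldAssignment
    selected_lambdas: list[float | None]
    validation_curves: list[np.ndarray]
    models: list[LinearModel]
    r_attended: list[float]
    r_unattended: list[float | None]
    path: list[float] = field(default_factory=list)
    # per-outer-fold training normalization stats (mu_x, sd_x, mu_y, sd_y);
    # runtime-only, needed to normalize test data for decoding
    fold_norms: list[tuple] = field(default_factory=list)

    @property
    def mean_r_attended(self) -> float:
        return float(np.mean(self.r_attended))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "estimator": self.estimator,
            "direction": self.direction,
            "n_folds": self.folds.n_folds,
            "fold_of": self.folds.fold_of.tolist(),
            "lambda_path": list(self.path),
            "selected_lambdas": self.selected_lambdas,
            "validation_curves": [c.tolist() for c in self.validation_curves],
            "r_attended": self.r_attended,
            "r_unattended": self.r_unattended,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Lagged sufficient statistics
# ---------------------------------------------------------------------------

class _LaggedStats:
    """Raw (un-normalized) lagged cross-products of one trial or trial group.

    For regressor ``x`` (n x C), target ``y`` (n x K) and causal lags ``f``:

    - ``R[(c,f),(c',g)] = sum_t x[t-f,c] x[t-g,c']`` (zero-padded lagged Gram)
    - ``rxy[(c,f),k]    = sum_t x[t-f,c] y[t,k]``
    - ``A[c,f,g]        = sum_{t>=max(f,g)} x[t-f,c]``  (prefix-sum tails)
    - ``Ty[f,k]         = sum_{t>=f} y[t,k]``

    plus plain channel sums.  These are additive across trials and suffice to
    reconstruct the covariances of the *z-normalized* lagged design exactly,
    for any normalization stats, via :func:`_normalized_cov`.
    """

    __slots__ = ("n", "n_trials", "R", "rxy", "A", "Ty", "sx", "sxx", "sy", "syy")

    def __init__(self, n, n_trials, R, rxy, A, Ty, sx, sxx, sy, syy):
        self.n = n
        self.n_trials = n_trials
        self.R = R
        self.rxy = rxy
        self.A = A
        self.Ty = Ty
        self.sx = sx
        self.sxx = sxx
        self.sy = sy
        self.syy = syy

    @classmethod
    def compute(cls, x: np.ndarray, y: np.ndarray, lags: np.ndarray) -> "_LaggedStats":
        n, n_ch = x.shape
        n_lags = lags.size
        # channel-major columns (c * n_lags + k), zero-padded at trial edges;
        # column (c, f) at row t holds x[t - f, c] (f may be negative)
        design = np.zeros((n, n_ch * n_lags))
        for k, f in enumerate(lags):
            if f >= 0:
                design[f:, k::n_lags] = x[: n - f if f else n]
            else:
                design[: n + f, k::n_lags] = x[-f:]
        R = design.T @ design
        rxy = design.T @ y
        # prefix sums: column (c, f) is nonzero on rows [max(f,0), n+min(f,0));
        # a column pair (f, g) overlaps on [max(f,g,0), n+min(f,g,0))
        p = np.concatenate([np.zeros((1, n_ch)), np.cumsum(x, axis=0)])
        py = np.concatenate([np.zeros((1, y.shape[1])), np.cumsum(y, axis=0)])
        fgrid = lags[:, None]
        ggrid = lags[None, :]
        t_lo = np.maximum(np.maximum(fgrid, ggrid), 0)
        t_hi = n + np.minimum(np.minimum(fgrid, ggrid), 0)
        start = t_lo - fgrid
        end = np.broadcast_to(t_hi - fgrid, start.shape)
        A = (p[end.ravel(), :] - p[start.ravel(), :]).reshape(
            n_lags, n_lags, n_ch).transpose(2, 0, 1)
        Ty = py[n + np.minimum(lags, 0)] - py[np.maximum(lags, 0)]
        return cls(
            n=n, n_trials=1, R=R, rxy=rxy, A=np.ascontiguousarray(A), Ty=Ty,
            sx=x.sum(axis=0), sxx=(x * x).sum(axis=0),
            sy=y.sum(axis=0), syy=(y * y).sum(axis=0),
        )

    def __iadd__(self, other: "_LaggedStats") -> "_LaggedStats":
        self.n += other.n
        self.n_trials += other.n_trials
        self.R += other.R
        self.rxy += other.rxy
        self.A += other.A
        self.Ty += other.Ty
        self.sx += other.sx
        self.sxx += other.sxx
        self.sy += other.sy
        self.syy += other.syy
        return self

    def __add__(self, other: "_LaggedStats") -> "_LaggedStats":
        out = self.copy()
        out += other
        return out

    def __sub__(self, other: "_LaggedStats") -> "_LaggedStats":
        return _LaggedStats(
            self.n - other.n, self.n_trials - other.n_trials,
            self.R - other.R, self.rxy - other.rxy, self.A - other.A,
            self.Ty - other.Ty, self.sx - other.sx, self.sxx - other.sxx,
            self.sy - other.sy, self.syy - other.syy,
        )

    def copy(self) -> "_LaggedStats":
        return _LaggedStats(self.n, self.n_trials, self.R.copy(),
                            self.rxy.copy(), self.A.copy(), self.Ty.copy(),
                            self.sx.copy(), self.sxx.copy(),
                            self.sy.copy(), self.syy.copy())

    def norm_stats(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Population mean/sd of regressor channels and target channels."""
        mu_x = self.sx / self.n
        sd_x = np.sqrt(np.maximum(self.sxx / self.n - mu_x ** 2, 0.0))
        mu_y = self.sy / self.n
        sd_y = np.sqrt(np.maximum(self.syy / self.n - mu_y ** 2, 0.0))
        return mu_x, sd_x, mu_y, sd_y


def _normalized_cov(st: _LaggedStats, lags: np.ndarray, mu_x, sd_x, mu_y, sd_y):
    """Covariances of the z-normalized lagged design, from raw statistics.

    Returns ``(cxx, cxy, colsum, sy_n, syy_n, n)`` where ``colsum`` is the
    per-column sum of the normalized design (needed for exact Pearson
    correlations on validation folds).
    """
    n_ch, n_lags, _ = st.A.shape
    d = n_ch * n_lags
    fgrid, ggrid = lags[:, None], lags[None, :]
    overlap = (np.minimum(np.minimum(fgrid, ggrid), 0)
               - np.maximum(np.maximum(fgrid, ggrid), 0)).astype(float)
    n_eff = st.n + st.n_trials * overlap                    # (L, L) pair support

    r4 = st.R.reshape(n_ch, n_lags, n_ch, n_lags)
    b4 = st.A[:, :, None, :] * mu_x[None, None, :, None]    # mu_{c'} A[c,f,g]
    cxx4 = r4 - b4 - b4.transpose(2, 3, 0, 1)
    cxx4 += (mu_x[:, None, None, None] * mu_x[None, None, :, None]) * n_eff[None, :, None, :]
    sd_rep = np.repeat(sd_x, n_lags)
    cxx = cxx4.reshape(d, d) / np.outer(sd_rep, sd_rep)

    colsum_raw = np.einsum("cff->cf", st.A)                 # support sum of col (c,f)
    n_f = st.n - st.n_trials * np.abs(lags).astype(float)   # (L,) column support
    cxy = (st.rxy.reshape(n_ch, n_lags, -1)
           - mu_x[:, None, None] * st.Ty[None, :, :]
           - colsum_raw[:, :, None] * mu_y[None, None, :]
           + (mu_x[:, None, None] * mu_y[None, None, :]) * n_f[None, :, None])
    cxy = cxy.reshape(d, -1) / (sd_rep[:, None] * sd_y[None, :])

    colsum = ((colsum_raw - mu_x[:, None] * n_f[None, :]) / sd_x[:, None]).ravel()
    sy_n = (st.sy - st.n * mu_y) / sd_y
    syy_n = (st.syy - 2 * mu_y * st.sy + st.n * mu_y ** 2) / sd_y ** 2
    return cxx, cxy, colsum, sy_n, syy_n, st.n


def _val_correlations(w: np.ndarray, cxx_v, cxy_v, colsum_v, sy_v, syy_v, n_v):
    """Pearson r per output channel of ``X_val w`` vs the validation target,
    computed exactly from validation-fold sufficient statistics."""
    s_pred = w.T @ colsum_v                                  # (K,)
    s_pred2 = np.einsum("dk,dk->k", w, cxx_v @ w)
    s_cross = np.einsum("dk,dk->k", w, cxy_v)
    var_pred = s_pred2 - s_pred ** 2 / n_v
    var_y = syy_v - sy_v ** 2 / n_v
    cov = s_cross - s_pred * sy_v / n_v
    denom = np.sqrt(np.maximum(var_pred, 0.0) * np.maximum(var_y, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / np.maximum(denom, 1e-300), np.nan)
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Solvers on assembled covariances
# ---------------------------------------------------------------------------

def _spectral_weights(estimator: str, s: np.ndarray, u: np.ndarray,
                      uty: np.ndarray, lam: float | None) -> np.ndarray:
    """Weights for the eigen-spectrum family given ``Cxx = U diag(s) U^T``."""
    smax = s.max()
    if estimator == "ols" or (estimator == "ridge" and not lam):
        inv = 1.0 / np.maximum(s, 1e-12 * smax)
    elif estimator == "ridge":
        inv = 1.0 / (s + lam)
    elif estimator == "shrinkage":
        nu = s.mean()
        inv = 1.0 / ((1.0 - lam) * s + lam * nu)
    elif estimator == "lra":
        sc = np.where(s < 1e-12 * smax, 0.0, s)
        total = sc.sum()
        k = int(np.searchsorted(np.cumsum(sc), lam * total - 1e-15 * total) + 1)
        k = min(k, int(np.count_nonzero(sc)))
        inv = np.zeros_like(s)
        inv[:k] = 1.0 / sc[:k]
    else:  # pragma: no cover
        raise InvalidParameterError(f"{estimator} is not a spectral-family scheme")
    return u @ (inv[:, None] * uty)


def _fit_direct(estimator: str, cxx: np.ndarray, cxy: np.ndarray, lam: float,
                n_channels: int, design: np.ndarray | None,
                target: np.ndarray | None, fs: float, lag_spec: LagSpec,
                w0: np.ndarray | None) -> np.ndarray:
    """Tikhonov / elastic net, which cannot share the eigenbasis."""
    if estimator == "tikhonov":
        return solve_tikhonov(CovariancePair(cxx, cxy, 0), lam, n_channels)
    if estimator != "elasticnet":
        raise InvalidParameterError(f"unknown estimator {estimator!r}")
    from .datamodel import DesignMatrix

    dm = DesignMatrix(design, lag_spec, n_channels)
    ts = TimeSeries(target, fs)
    res = solve_elastic_net(dm, ts, lam, alpha=_fit_direct.alpha, w0=w0)
    return res.weights


_fit_direct.alpha = 0.25  # default elastic-net L1/L2 balance, overridden per run


# ---------------------------------------------------------------------------
# Nested tuning
# ---------------------------------------------------------------------------

def _tune_on_groups(estimator: str, path: RegularizationPath | None,
                    groups: list[_LaggedStats], lags: np.ndarray,
                    norm, n_channels: int, alpha: float = 0.25,
                    designs: list[tuple[np.ndarray, np.ndarray]] | None = None,
                    fs: float = 64.0, lag_spec: LagSpec | None = None,
                    ) -> TuningResult:
    """Inner CV over pre-summed fold groups; see :func:`tune_lambda_nested`."""
    mu_x, sd_x, mu_y, sd_y = norm
    lambdas = [None] if (estimator == "ols" or path is None) else list(path.lambdas)
    n_inner = len(groups)
    if n_inner < 2:
        raise InvalidParameterError("need at least 2 inner folds")
    total = groups[0].copy()
    for g in groups[1:]:
        total += g

    fold_curves = np.full((n_inner, len(lambdas)), np.nan)
    fold_weights: list[list[np.ndarray]] = []
    for i, val_group in enumerate(groups):
        train = total - val_group
        cxx, cxy, *_ = _normalized_cov(train, lags, mu_x, sd_x, mu_y, sd_y)
        val_stats = _normalized_cov(val_group, lags, mu_x, sd_x, mu_y, sd_y)
        cxx_v, cxy_v, colsum_v, sy_v, syy_v, n_v = val_stats
        ws: list[np.ndarray] = []
        if estimator in SPECTRAL_ESTIMATORS:
            s, u = sla.eigh(cxx)
            order = np.argsort(s)[::-1]
            s, u = np.maximum(s[order], 0.0), u[:, order]
            uty = u.T @ cxy
            for j, lam in enumerate(lambdas):
                w = _spectral_weights(estimator, s, u, uty, lam)
                ws.append(w)
                r = _val_correlations(w, cxx_v, cxy_v, colsum_v, sy_v, syy_v, n_v)
                fold_curves[i, j] = np.nan if np.all(np.isnan(r)) else np.nanmean(r)
        else:
            design = target = None
            if estimator == "elasticnet":
                if designs is None:
                    raise InvalidParameterError(
                        "elastic net tuning requires raw designs")
                # designs carries (design, target, group) triples
                design = np.vstack([d for d, _, g in designs if g != i])
                target = np.vstack([t for _, t, g in designs if g != i])
            _fit_direct.alpha = alpha
            w_prev = None
            for j, lam in enumerate(lambdas):
                w = _fit_direct(estimator, cxx, cxy, lam or 0.0, n_channels,
                                design, target, fs, lag_spec, w_prev)
                w_prev = w
                ws.append(w)
                r = _val_correlations(w, cxx_v, cxy_v, colsum_v, sy_v, syy_v, n_v)
                fold_curves[i, j] = np.nan if np.all(np.isnan(r)) else np.nanmean(r)
        fold_weights.append(ws)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN lambdas
        mean_curve = np.nanmean(fold_curves, axis=0)
    if np.all(np.isnan(mean_curve)):
        raise TuningError("all validation correlations undefined "
                          "(constant predictions at every lambda)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        best = int(np.nanargmax(mean_curve))   # first (smallest lambda) on ties
    chosen = [fw[best] for fw in fold_weights]
    avg = np.mean(chosen, axis=0)
    return TuningResult(lambdas[best], avg, mean_curve, chosen, fold_curves)


def tune_lambda_nested(training_folds: list[list[Trial]], estimator: str,
                       path: RegularizationPath | None,
                       lag_spec: LagSpec, direction: str = "backward",
                       alpha: float = 0.25) -> TuningResult:
    """Tune lambda by inner cross-validation over pre-split training folds.

    For each inner fold: fit on the remaining folds at every lambda in the
    path, score the Pearson correlation between prediction/reconstruction and
    the validation fold (channel-mean for forward models); select the lambda
    maximizing the mean validation correlation across inner folds; return the
    element-wise average of the inner-fold models at that lambda.
    Normalization statistics come from all training folds.
    """
    lags = lag_spec.lags
    groups = []
    designs = []
    fs = training_folds[0][0].eeg.fs
    for gi, fold in enumerate(training_folds):
        st = None
        for tr in fold:
            x, y = _xy_for(tr, direction)
            s = _LaggedStats.compute(x, y, lags)
            st = s if st is None else (st + s)
        groups.append(st)
    total = groups[0].copy()
    for g in groups[1:]:
        total += g
    norm = total.norm_stats()
    if estimator == "elasticnet":
        mu_x, sd_x, mu_y, sd_y = norm
        for gi, fold in enumerate(training_folds):
            for tr in fold:
                x, y = _xy_for(tr, direction)
                xn = (x - mu_x) / sd_x
                yn = (y - mu_y) / sd_y
                dm = build_lagged_design(TimeSeries(xn, fs), lag_spec)
                designs.append((dm.values, yn, gi))
    n_channels = _xy_for(training_folds[0][0], direction)[0].shape[1]
    return _tune_on_groups(estimator, path, groups, lags, norm, n_channels,
                           alpha=alpha, designs=designs or None, fs=fs,
                           lag_spec=lag_spec)


def _xy_for(trial: Trial, direction: str) -> tuple[np.ndarray, np.ndarray]:
    """Regressor/target arrays per model direction (attended stream only)."""
    if direction == "backward":
        return trial.eeg.samples, trial.attended_env.samples
    if direction == "forward":
        return trial.attended_env.samples, trial.eeg.samples
    raise InvalidParameterError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# Full nested cross-validation
# ---------------------------------------------------------------------------

def cross_validate_multi(trials: list[Trial], direction: str,
                         estimator_paths: dict[str, RegularizationPath | None],
                         lag_spec: LagSpec | None = None, n_folds: int = 10,
                         seed: int = 0, alpha: float = 0.25,
                         folds: FoldAssignment | None = None,
                         ) -> dict[str, CVReport]:
    """Nested CV for several estimators on shared folds (paired comparison).

    Sharing folds (and the expensive per-fold sufficient statistics and
    eigendecompositions) across estimators keeps comparisons paired, as a
    repeated-measures design requires.
    """
    fs = trials[0].eeg.fs
    if lag_spec is None:
        lag_spec = LagSpec.for_direction(0.5, fs, direction)
    lags = lag_spec.lags
    if folds is None:
        folds = make_folds(len(trials), n_folds, seed)
    n_folds = folds.n_folds

    # one pass over trials: per-outer-fold raw sufficient statistics
    group_stats: list[_LaggedStats | None] = [None] * n_folds
    for idx, tr in enumerate(trials):
        x, y = _xy_for(tr, direction)
        st = _LaggedStats.compute(x, y, lags)
        g = folds.fold_of[idx]
        group_stats[g] = st if group_stats[g] is None else (group_stats[g] + st)

    spectral = {n: p for n, p in estimator_paths.items() if n in SPECTRAL_ESTIMATORS}
    direct = {n: p for n, p in estimator_paths.items() if n not in SPECTRAL_ESTIMATORS}

    reports = {
        name: CVReport(name, direction, folds, [], [], [], [], [],
                       path=[] if p is None else list(p.lambdas))
        for name, p in estimator_paths.items()
    }

    n_channels = _xy_for(trials[0], direction)[0].shape[1]
    for o in range(n_folds):
        train_groups = [group_stats[g] for g in range(n_folds) if g != o]
        total = train_groups[0].copy()
        for g in train_groups[1:]:
            total += g
        norm = total.norm_stats()
        mu_x, sd_x, mu_y, sd_y = norm

        # ---- inner loop, spectral family shares one eigh per inner fold ----
        per_est = _inner_loop(spectral, direct, train_groups, lags, norm,
                              n_channels, alpha, trials, folds, o, direction,
                              lag_spec, fs)

        # ---- evaluate the averaged models on the held-out fold ----
        test_idx = folds.trials_in(o)
        for name, tuning in per_est.items():
            rep = reports[name]
            rep.selected_lambdas.append(tuning.selected_lambda)
            rep.validation_curves.append(tuning.validation_curve)
            model = LinearModel.from_matrix(
                tuning.model, direction, lag_spec, fs,
                n_inputs=n_channels if direction == "backward" else 1)
            rep.models.append(model)
            r_att, r_un = _test_fold_accuracy(
                model, [trials[i] for i in test_idx], direction,
                mu_x, sd_x, mu_y, sd_y, lag_spec)
            rep.r_attended.append(r_att)
            rep.r_unattended.append(r_un)
            rep.fold_norms.append((mu_x, sd_x, mu_y, sd_y))
    return reports


def _inner_loop(spectral, direct, train_groups, lags, norm, n_channels, alpha,
                trials, folds, outer, direction, lag_spec, fs):
    """Run the inner CV for all estimators, sharing eigendecompositions."""
    mu_x, sd_x, mu_y, sd_y = norm
    n_inner = len(train_groups)
    lambdas_of = {}
    curves = {}
    weights = {}
    for name, p in list(spectral.items()) + list(direct.items()):
        lambdas_of[name] = [None] if (name == "ols" or p is None) else list(p.lambdas)
        curves[name] = np.full((n_inner, len(lambdas_of[name])), np.nan)
        weights[name] = []

    total = train_groups[0].copy()
    for g in train_groups[1:]:
        total += g

    en_designs = None
    if "elasticnet" in direct:
        train_folds = [f for f in range(folds.n_folds) if f != outer]
        en_designs = []
        for gi, f in enumerate(train_folds):
            for t in folds.trials_in(f):
                x, y = _xy_for(trials[t], direction)
                xn = (x - mu_x) / sd_x
                yn = (y - mu_y) / sd_y
                dm = build_lagged_design(TimeSeries(xn, fs), lag_spec)
                en_designs.append((dm.values, yn, gi))

    for i in range(n_inner):
        train = total - train_groups[i]
        cxx, cxy, *_ = _normalized_cov(train, lags, mu_x, sd_x, mu_y, sd_y)
        cxx_v, cxy_v, colsum_v, sy_v, syy_v, n_v = _normalized_cov(
            train_groups[i], lags, mu_x, sd_x, mu_y, sd_y)

        if spectral:
            s, u = sla.eigh(cxx)
            order = np.argsort(s)[::-1]
            s, u = np.maximum(s[order], 0.0), u[:, order]
            uty = u.T @ cxy
            for name in spectral:
                ws = []
                for j, lam in enumerate(lambdas_of[name]):
                    w = _spectral_weights(name, s, u, uty, lam)
                    ws.append(w)
                    r = _val_correlations(w, cxx_v, cxy_v, colsum_v,
                                          sy_v, syy_v, n_v)
                    curves[name][i, j] = (np.nan if np.all(np.isnan(r))
                                          else np.nanmean(r))
                weights[name].append(ws)

        for name in direct:
            design = target = None
            if name == "elasticnet":
                design = np.vstack([d for d, _, g in en_designs if g != i])
                target = np.vstack([t for _, t, g in en_designs if g != i])
            _fit_direct.alpha = alpha
            ws = []
            w_prev = None
            for j, lam in enumerate(lambdas_of[name]):
                w = _fit_direct(name, cxx, cxy, lam or 0.0, n_channels,
                                design, target, fs, lag_spec, w_prev)
                w_prev = w
                ws.append(w)
                r = _val_correlations(w, cxx_v, cxy_v, colsum_v,
                                      sy_v, syy_v, n_v)
                curves[name][i, j] = (np.nan if np.all(np.isnan(r))
                                      else np.nanmean(r))
            weights[name].append(ws)

    out = {}
    for name in lambdas_of:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN lambdas
            mean_curve = np.nanmean(curves[name], axis=0)
        if np.all(np.isnan(mean_curve)):
            raise TuningError(
                f"{name}: all validation correlations undefined")
        best = int(np.nanargmax(mean_curve))
        chosen = [weights[name][i][best] for i in range(n_inner)]
        out[name] = TuningResult(lambdas_of[name][best], np.mean(chosen, axis=0),
                                 mean_curve, chosen, curves[name])
    return out


def cross_validate(trials: list[Trial], direction: str, estimator: str,
                   path: RegularizationPath | None = None,
                   lag_spec: LagSpec | None = None, n_folds: int = 10,
                   seed: int = 0, alpha: float = 0.25,
                   folds: FoldAssignment | None = None) -> CVReport:
    """Nested cross-validation of a single estimator (see module docstring)."""
    reports = cross_validate_multi(trials, direction, {estimator: path},
                                   lag_spec, n_folds, seed, alpha, folds)
    return reports[estimator]


def _test_fold_accuracy(model: LinearModel, test_trials: list[Trial],
                        direction: str, mu_x, sd_x, mu_y, sd_y,
                        lag_spec: LagSpec):
    """Pooled test-fold regression accuracy (attended, and unattended if known)."""
    preds, ys, uns = [], [], []
    for tr in test_trials:
        x, y = _xy_for(tr, direction)
        xn = (x - mu_x) / sd_x
        dm = build_lagged_design(TimeSeries(xn, model.fs), lag_spec)
        preds.append(dm.values @ model.as_matrix())
        ys.append((y - mu_y) / sd_y)
        if direction == "backward" and tr.unattended_env is not None:
            uns.append((tr.unattended_env.samples - mu_y) / sd_y)
    pred = np.vstack(preds)
    actual = np.vstack(ys)
    r_per_ch = _safe_channel_r(pred, actual)
    r_att = float(np.nanmean(r_per_ch))
    r_un = None
    if direction == "backward" and uns:
        r_un = float(np.nanmean(_safe_channel_r(pred, np.vstack(uns))))
    elif direction == "forward":
        un_preds = []
        have_un = all(tr.unattended_env is not None for tr in test_trials)
        if have_un:
            for tr in test_trials:
                xu = (tr.unattended_env.samples - mu_x) / sd_x
                dm = build_lagged_design(TimeSeries(xu, model.fs), lag_spec)
                un_preds.append(dm.values @ model.as_matrix())
            r_un = float(np.nanmean(_safe_channel_r(np.vstack(un_preds), actual)))
    return r_att, r_un


def _safe_channel_r(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Per-channel Pearson r; zero-variance channels become NaN with a warning."""
    out = np.empty(pred.shape[1])
    bad = 0
    for k in range(pred.shape[1]):
        try:
            out[k] = pearson_r(pred[:, k], actual[:, k])
        except Exception:
            out[k] = np.nan
            bad += 1
    if bad:
        warnings.warn(f"{bad} zero-variance channel(s) excluded from the "
                      "regression accuracy", RuntimeWarning)
    return out


# ---------------------------------------------------------------------------
# Regression accuracy (public scoring operations)
# ---------------------------------------------------------------------------

def regression_accuracy_forward(model: LinearModel, envelope: TimeSeries,
                                eeg: TimeSeries, mode: str = "mean"):
    """Correlate model-predicted EEG (from the envelope) with actual EEG.

    Inputs must be normalized the same way as the training data.  ``mode``
    reduces the per-channel correlations by mean (default) or max, or returns
    the full vector (``per_channel``).
    """
    design = build_lagged_design(envelope, model.lag_spec)
    pred = apply_model(model, design)
    r = _safe_channel_r(pred.samples, eeg.samples)
    if mode == "per_channel":
        return r
    if mode == "mean":
        return float(np.nanmean(r))
    if mode == "max":
        return float(np.nanmax(r))
    raise InvalidParameterError(f"unknown mode {mode!r}")


def regression_accuracy_backward(model: LinearModel, eeg: TimeSeries,
                                 attended_env: TimeSeries) -> float:
    """Correlate the EEG-based envelope reconstruction with the attended envelope."""
    design = build_lagged_design(eeg, model.lag_spec)
    pred = apply_model(model, design)
    return pearson_r(pred.samples[:, 0], attended_env.samples[:, 0])


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_model(model: LinearModel, path: str | Path, estimator: str = "",
               selected_lambda: float | None = None) -> None:
    """Save weights plus metadata (direction, lags, fs, estimator, lambda)."""
    np.savez(
        Path(path), weights=model.weights, direction=model.direction,
        min_lag=model.lag_spec.min_lag, max_lag=model.lag_spec.max_lag,
        fs=model.fs, estimator=estimator,
        selected_lambda=np.nan if selected_lambda is None else selected_lambda,
    )


def load_model(path: str | Path) -> LinearModel:
    with np.load(Path(path), allow_pickle=False) as z:
        return LinearModel(
            z["weights"], str(z["direction"]),
            LagSpec(int(z["min_lag"]), int(z["max_lag"])), float(z["fs"]),
        )
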