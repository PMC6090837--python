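"""Segment-wise attended-talker classification and its evaluation metrics.

Decisions are made on short windows of test data (the *decoding segment*,
whose stated duration includes the model kernel length, so the correlations
are computed over ``segment - kernel`` seconds).  For a backward model the
decision value is simply the difference of the correlations between the
EEG-reconstructed envelope and the two stream envelopes; for a forward model
each envelope predicts all EEG channels, giving one correlation per channel
per stream, and a linear soft-margin SVM trained on validation-fold features
supplies the decision value.

Evaluation: raw accuracy, the ROC curve over the signed decision values, the
Wolpaw information transfer rate (every segment classified), the Nykopp ITR
(low-confidence segments may be withheld; threshold chosen to maximize the
empirical mutual information), and a phase-randomization noise floor for
regression accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import LinearModel, TimeSeries, build_lagged_design, pearson_r
from .exceptions import (
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "DecisionRecord",
    "ROCCurve",
    "ITRResult",
    "segment_correlation_features",
    "classify_argmax",
    "train_forward_classifier",
    "apply_forward_classifier",
    "roc_from_decisions",
    "accuracy_from_records",
    "wolpaw_itr",
    "nykopp_itr",
    "noise_floor",
    "phase_randomize",
    "class_separability",
]


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class DecisionRecord:
    """One decoding segment: correlation features, decision value, labels."""

    segment_id: int
    true_label: str                   # "A" | "B"
    features_a: np.ndarray            # r(vs stream A): scalar (backward) or per channel
    features_b: np.ndarray
    decision_value: float | None = None
    predicted_label: str | None = None
    tie: bool = False

    @property
    def features(self) -> np.ndarray:
        """Concatenated (stream A, stream B) feature vector."""
        return np.concatenate([np.atleast_1d(self.features_a),
                               np.atleast_1d(self.features_b)])


def segment_correlation_features(model: LinearModel, eeg: TimeSeries,
                                 env_a: TimeSeries, env_b: TimeSeries,
                                 true_label: str, seg_len_s: float,
                                 step_s: float = 1.0,
                                 kernel_s: float | None = None,
                                 start_id: int = 0) -> list[DecisionRecord]:
    """Correlation features for every decoding window of one trial.

    Windows of ``seg_len_s`` step through the trial in ``step_s`` increments
    and never cross trial boundaries.  The window duration includes the
    kernel length: predictions/reconstructions are correlated only over the
    window minus its first ``kernel_s`` seconds, so every retained sample has
    a full lag history inside the window.
    """
    fs = eeg.fs
    if kernel_s is None:
        kernel_s = model.lag_spec.max_lag / fs
    if seg_len_s < kernel_s:
        raise InvalidParameterError(
            f"segment ({seg_len_s} s) shorter than the kernel ({kernel_s} s)"
        )
    n = eeg.n_times
    seg = int(round(seg_len_s * fs))
    step = max(1, int(round(step_s * fs)))
    if seg > n:
        raise InvalidParameterError("segment longer than the trial")

    if model.direction == "backward":
        design = build_lagged_design(eeg, model.lag_spec)
        recon = (design.values @ model.as_matrix())[:, 0]
        targets = {"A": env_a.samples[:, 0], "B": env_b.samples[:, 0]}
        preds = {"A": recon, "B": recon}
    else:
        w = model.as_matrix()
        pred_a = build_lagged_design(env_a, model.lag_spec).values @ w
        pred_b = build_lagged_design(env_b, model.lag_spec).values @ w
        preds = {"A": pred_a, "B": pred_b}
        targets = {"A": eeg.samples, "B": eeg.samples}

    # the stated window includes the kernel: correlations are computed only
    # over rows whose full lag history lies inside the window (trim the
    # leading max_lag rows for causal/forward windows, the trailing |min_lag|
    # rows for anti-causal/backward windows)
    trim_head = max(model.lag_spec.max_lag, 0)
    trim_tail = max(-model.lag_spec.min_lag, 0)
    if seg <= trim_head + trim_tail + 1:
        raise InvalidParameterError("segment too short for the model's lag window")
    records = []
    sid = start_id
    for t0 in range(0, n - seg + 1, step):
        lo, hi = t0 + trim_head, t0 + seg - trim_tail
        feats = {}
        for stream in ("A", "B"):
            p = np.atleast_2d(preds[stream][lo:hi].T).T
            y = np.atleast_2d(targets[stream][lo:hi].T).T
            r = np.empty(p.shape[1])
            for k in range(p.shape[1]):
                try:
                    r[k] = pearson_r(p[:, k], y[:, k])
                except DegenerateInputError:
                    r[k] = 0.0
            feats[stream] = r if r.size > 1 else r[0]
        records.append(DecisionRecord(sid, true_label,
                                      np.atleast_1d(feats["A"]),
                                      np.atleast_1d(feats["B"])))
        sid += 1
    return records


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def classify_argmax(record: DecisionRecord) -> str:
    """Backward-model decision: the stream with the larger correlation wins.

    The decision value is ``r_A - r_B``; an exact tie deterministically
    yields stream A with the tie flag set.
    """
    ra = float(np.asarray(record.features_a).ravel()[0])
    rb = float(np.asarray(record.features_b).ravel()[0])
    record.decision_value = ra - rb
    record.tie = ra == rb
    record.predicted_label = "A" if record.decision_value >= 0 else "B"
    return record.predicted_label


def train_forward_classifier(records: list[DecisionRecord]):
    """Linear soft-margin SVM (C = 1) on per-channel correlation features.

    Trained on validation-fold records; the decision value for a record is
    ``w . x + b`` with positive values mapping to stream A.
    """
    from sklearn.svm import SVC

    labels = {r.true_label for r in records}
    if labels != {"A", "B"}:
        raise InvalidInputError(
            f"need both classes to train the classifier, got {sorted(labels)}"
        )
    x = np.array([r.features for r in records])
    y = np.array([1 if r.true_label == "A" else -1 for r in records])
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(x, y)
    return clf


def apply_forward_classifier(clf, records: list[DecisionRecord]) -> None:
    """Fill decision values/predictions from a trained linear classifier."""
    x = np.array([r.features for r in records])
    d = clf.decision_function(x)
    for rec, dv in zip(records, d):
        rec.decision_value = float(dv)
        rec.tie = dv == 0
        rec.predicted_label = "A" if dv >= 0 else "B"


def accuracy_from_records(records: list[DecisionRecord]) -> float:
    """Fraction of segments whose decision sign matches the true label."""
    ok = [r.predicted_label == r.true_label for r in records]
    return float(np.mean(ok))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    """Signed-decision-value ROC with the retained-fraction bookkeeping."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    fraction_at_or_above: np.ndarray
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.auc = float(np.trapezoid(self.tpr, self.fpr))


def roc_from_decisions(records: list[DecisionRecord]) -> ROCCurve:
    """ROC over the signed decision values (positive class: stream A attended).

    Thresholds are taken at midpoints between sorted distinct decision values
    plus sentinels beyond both extremes, so the endpoints (0,0) and (1,1) are
    always present; a segment counts as predicted-A at threshold ``t`` when
    its decision value is >= t.
    """
    d = np.array([r.decision_value for r in records], dtype=float)
    y = np.array([r.true_label == "A" for r in records])
    if np.all(y) or not np.any(y):
        raise DegenerateInputError("ROC needs records from both classes")
    if np.any(np.isnan(d)):
        raise InvalidInputError("records carry undefined decision values")
    vals = np.unique(d)
    mids = (vals[:-1] + vals[1:]) / 2
    span = max(vals[-1] - vals[0], 1.0)
    thr = np.concatenate([[vals[-1] + span], vals[-1:], mids[::-1], [vals[0] - span]])
    thr = np.unique(thr)[::-1]
    n_pos = y.sum()
    n_neg = (~y).sum()
    tpr = np.array([(d[y] >= t).sum() / n_pos for t in thr])
    fpr = np.array([(d[~y] >= t).sum() / n_neg for t in thr])
    frac = np.array([(d >= t).mean() for t in thr])
    return ROCCurve(thr, tpr, fpr, frac)


# ---------------------------------------------------------------------------
# Information transfer rate
# ---------------------------------------------------------------------------

def _xlogx(p: np.ndarray | float) -> np.ndarray | float:
    """x * log2(x) with the 0 log 0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def wolpaw_itr(p: float, n_classes: int = 2, v: float = 1.0) -> float:
    """Wolpaw information transfer rate in bits per minute.

    ``v * [log2 N + P log2 P + (1-P) log2((1-P)/(N-1))]`` — the capacity of a
    symmetric channel at accuracy ``P`` with ``N`` classes and ``v`` decisions
    per minute.  Zero at chance (``P = 1/N``).
    """
    if not 0 <= p <= 1:
        raise InvalidParameterError(f"accuracy must be in [0, 1], got {p}")
    if n_classes < 2:
        raise InvalidParameterError("need at least 2 classes")
    bits = np.log2(n_classes) + _xlogx(p)
    if p < 1:
        bits += (1 - p) * np.log2((1 - p) / (n_classes - 1))
    return float(v * bits)


@dataclass
class ITRResult:
    """Wolpaw and Nykopp transfer rates for one decision set.

    Nykopp withholds low-confidence decisions: the threshold on the decision
    magnitude is chosen to maximize the empirical mutual information between
    true and predicted class over the retained segments (an upper bound on
    the achievable rate; in symmetric regimes it dominates the Wolpaw value).
    """

    segment_s: float
    v_per_min: float
    accuracy: float
    n_classes: int
    wolpaw_bits_per_min: float
    nykopp_bits_per_min: float
    nykopp_threshold: float
    nykopp_fraction_classified: float


def nykopp_itr(records: list[DecisionRecord], v: float, segment_s: float = 0.0,
               scale_v_by_fraction: bool = False) -> ITRResult:
    """Threshold-maximized mutual-information transfer rate.

    Sweeps thresholds on the decision-value magnitude; at each, builds the
    empirical confusion matrix over retained segments and evaluates
    ``I(true; predicted) = sum_ij p(w_i) p(w_j|w_i) log2 p(w_j|w_i)
    - sum_j p(w_j) log2 p(w_j)``.  Degenerate thresholds (one true class
    retained) are skipped.  ``v`` stays the attempted-segment rate unless
    ``scale_v_by_fraction``.
    """
    if len(records) < 2:
        raise InvalidInputError("need at least 2 segments")
    d = np.array([r.decision_value for r in records], dtype=float)
    true_a = np.array([r.true_label == "A" for r in records])
    pred_a = np.array([r.predicted_label == "A" for r in records])
    if np.all(true_a) or not np.any(true_a):
        raise InvalidInputError("need both true classes")

    mags = np.abs(d)
    cand = np.unique(np.concatenate([[0.0], np.unique(mags)[:-1]])) if mags.size else [0.0]
    best_mi, best_thr, best_frac = -np.inf, 0.0, 1.0
    for thr in cand:
        keep = mags >= thr if thr > 0 else np.ones_like(mags, bool)
        t, p = true_a[keep], pred_a[keep]
        if t.sum() == 0 or (~t).sum() == 0:
            continue
        mi = _empirical_mi(t, p)
        if mi > best_mi:
            best_mi, best_thr, best_frac = mi, float(thr), float(keep.mean())
    if not np.isfinite(best_mi):
        best_mi, best_thr, best_frac = 0.0, 0.0, 1.0

    acc = float((true_a == pred_a).mean())
    v_eff = v * best_frac if scale_v_by_fraction else v
    return ITRResult(
        segment_s=segment_s, v_per_min=v, accuracy=acc, n_classes=2,
        wolpaw_bits_per_min=wolpaw_itr(acc, 2, v),
        nykopp_bits_per_min=float(v_eff * best_mi),
        nykopp_threshold=best_thr,
        nykopp_fraction_classified=best_frac,
    )


def _empirical_mi(true_a: np.ndarray, pred_a: np.ndarray) -> float:
    """Mutual information (bits) of the empirical 2x2 confusion matrix."""
    mi = 0.0
    p_pred = np.array([pred_a.mean(), 1 - pred_a.mean()])
    for ti, tmask in ((0, true_a), (1, ~true_a)):
        p_t = tmask.mean()
        if p_t == 0:
            continue
        for pi, pmask in ((0, pred_a), (1, ~pred_a)):
            p_cond = (tmask & pmask).sum() / tmask.sum()
            mi += p_t * float(_xlogx(p_cond))
    mi -= float(np.sum(_xlogx(p_pred)))
    return mi


# ---------------------------------------------------------------------------
# Phase-randomization noise floor
# ---------------------------------------------------------------------------

def phase_randomize(x: np.ndarray, rng: np.random.Generator,
                    share_phases: bool = True) -> np.ndarray:
    """Randomize Fourier phases while preserving magnitudes exactly.

    Phases are drawn uniformly with conjugate symmetry so the output is real;
    DC and Nyquist bins keep their (real) values.  With ``share_phases`` the
    same phase perturbation is applied to every channel, preserving the
    cross-channel covariance structure along with each channel's spectrum.
    """
    x = np.atleast_2d(x.T).T
    n, n_ch = x.shape
    spec = np.fft.rfft(x, axis=0)
    n_bins = spec.shape[0]
    inner = slice(1, n_bins - 1 if n % 2 == 0 else n_bins)
    if share_phases:
        phases = rng.uniform(0, 2 * np.pi, size=(n_bins, 1))
    else:
        phases = rng.uniform(0, 2 * np.pi, size=(n_bins, n_ch))
    rot = np.exp(1j * phases)
    out_spec = spec.copy()
    out_spec[inner] = spec[inner] * rot[inner]
    return np.fft.irfft(out_spec, n, axis=0)


def noise_floor(score_fn, data: TimeSeries, n_randomizations: int = 100,
                seed: int = 0, ci: float = 0.95,
                share_phases: bool = True) -> tuple[float, float, np.ndarray]:
    """Empirical null interval for a regression accuracy.

    ``score_fn(surrogate: TimeSeries) -> float`` recomputes the accuracy with
    the trained model held fixed while ``data`` (audio for forward models,
    EEG for backward models) has its Fourier phases randomized.  Returns the
    central ``ci`` interval bounds and the null scores.
    """
    if n_randomizations < 20:
        warnings.warn("fewer than 20 randomizations: interval unreliable",
                      RuntimeWarning)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_randomizations)
    for i in range(n_randomizations):
        surr = data.copy_with(phase_randomize(data.samples, rng, share_phases))
        scores[i] = score_fn(surr)
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(scores, [alpha, 1 - alpha])
    return float(lo), float(hi), scores


# ---------------------------------------------------------------------------
# Class separability
# ---------------------------------------------------------------------------

def class_separability(records: list[DecisionRecord]) -> tuple[float, float]:
    """Mean attended-unattended correlation difference and within-class spread.

    Works on the paired correlation features of each segment: the attended
    feature is the one matching the true label.  The spread is the square
    root of the mean of the two class variances — both the numerator and the
    denominator of the discriminability that drives argmax accuracy.
    """
    att, unatt = [], []
    for r in records:
        ra = float(np.asarray(r.features_a).ravel()[0])
        rb = float(np.asarray(r.features_b).ravel()[0])
        if r.true_label == "A":
            att.append(ra)
            unatt.append(rb)
        else:
            att.append(rb)
            unatt.append(ra)
    if len(att) < 2:
        raise DegenerateInputError("need at least 2 segments per class")
    att_arr, un_arr = np.array(att), np.array(unatt)
    diff = float(att_arr.mean() - un_arr.mean())
    spread = float(np.sqrt(0.5 * (att_arr.var(ddof=1) + un_arr.var(ddof=1))))
    return diff, spread
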