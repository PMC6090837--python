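"""Core signal containers and lagged-regression primitives.

The linear stimulus-response model is ``Y_hat = X W`` where ``X`` is a
multichannel signal augmented with time-lagged copies of itself (lags indexed
by ``f``, channels by ``c``; the two are combined into one column dimension)
and ``W`` is the spatio-temporal kernel.  A *forward* model maps a stimulus
envelope to multichannel EEG (one kernel per EEG channel); a *backward* model
(decoder) maps lagged multichannel EEG back to the envelope.

Lag convention: a positive lag ``f`` means the regressor sample *precedes* the
target sample, i.e. column ``(c, f)`` at row ``t`` holds ``x[t - f, c]``.
Rows where ``t - f`` falls before the start of the series are zero padded so
that the design matrix keeps the same number of rows as the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateInputError,
    InvalidInputError,
    ShapeError,
)

__all__ = [
    "TimeSeries",
    "LagSpec",
    "DesignMatrix",
    "LinearModel",
    "build_lagged_design",
    "apply_model",
    "pearson_r",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TimeSeries:
    """A sampled multichannel signal.

    Parameters
    ----------
    samples : ndarray, shape (n_times, n_channels)
        Signal values. Finite.
    fs : float
        Sampling rate in Hz, > 0.
    channel_labels : list of str, optional
        One label per channel; defaults to ``ch0 .. chN-1``.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2:
            raise ShapeError("samples must be a 2-D (time x channels) array")
        if self.fs <= 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("samples contain non-finite values")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[1])]
        if len(self.channel_labels) != self.samples.shape[1]:
            raise ShapeError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[1]} channels"
            )

    @property
    def n_times(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds (sample count / fs)."""
        return self.n_times / self.fs

    def copy_with(self, samples: np.ndarray, fs: float | None = None) -> "TimeSeries":
        """New series with the same labels but different samples (and fs)."""
        return TimeSeries(samples, self.fs if fs is None else fs,
                          list(self.channel_labels))


@dataclass(frozen=True)
class LagSpec:
    """Range of integer sample lags applied to the regressor.

    Positive lag = regressor sample precedes the target sample
    (column ``(c, f)`` at row ``t`` is ``x[t - f, c]``).
    """

    min_lag: int
    max_lag: int

    def __post_init__(self) -> None:
        if self.min_lag > self.max_lag:
            raise InvalidInputError(
                f"min_lag ({self.min_lag}) exceeds max_lag ({self.max_lag})"
            )

    @property
    def n_lags(self) -> int:
        return self.max_lag - self.min_lag + 1

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.min_lag, self.max_lag + 1)

    @classmethod
    def from_duration(cls, kernel_s: float, fs: float, min_lag: int = 0) -> "LagSpec":
        """Causal lag window covering ``kernel_s`` seconds at rate ``fs``.

        A 0.5 s kernel at 64 Hz gives 33 lags (0..32), matching the
        conventional TRF kernel length for envelope tracking.
        """
        n = int(round(kernel_s * fs)) + 1
        return cls(min_lag, min_lag + n - 1)

    @classmethod
    def for_direction(cls, kernel_s: float, fs: float, direction: str) -> "LagSpec":
        """Kernel window oriented by model direction.

        Forward models regress EEG on *past* stimulus samples (lags 0..+K:
        the stimulus precedes the response), backward models reconstruct the
        envelope from *subsequent* EEG samples (lags -K..0: the response
        trails the stimulus).  Both windows span ``kernel_s`` seconds.
        """
        n = int(round(kernel_s * fs)) + 1
        if direction == "forward":
            return cls(0, n - 1)
        if direction == "backward":
            return cls(-(n - 1), 0)
        raise InvalidInputError(f"unknown direction {direction!r}")


@dataclass
class DesignMatrix:
    """Time-lag-augmented regressor matrix.

    ``values`` has one row per time sample and one column per
    (channel, lag) pair; ``column_map`` is the bijection
    ``(channel, lag) -> column index``.  Columns are channel-major:
    column ``c * n_lags + k`` holds channel ``c`` at the ``k``-th lag.
    """

    values: np.ndarray
    lag_spec: LagSpec
    n_channels: int
    column_map: dict[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_cols = self.n_channels * self.lag_spec.n_lags
        if self.values.shape[1] != n_cols:
            raise ShapeError(
                f"design has {self.values.shape[1]} columns, expected {n_cols}"
            )
        if not self.column_map:
            self.column_map = {
                (c, f): c * self.lag_spec.n_lags + k
                for c in range(self.n_channels)
                for k, f in enumerate(self.lag_spec.lags)
            }
        cols = sorted(self.column_map.values())
        if cols != list(range(n_cols)):
            raise ShapeError("column_map is not a bijection onto the column range")

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


@dataclass
class LinearModel:
    """Estimated stimulus-response kernel.

    ``weights`` is a (n_lags, n_input_channels, n_output_channels) tensor.
    A forward model has one input channel (the envelope) and one output
    per EEG channel; a backward model has one output channel (the envelope).
    """

    weights: np.ndarray
    direction: str  # "forward" | "backward"
    lag_spec: LagSpec
    fs: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3:
            raise ShapeError("weights must be (lags, inputs, outputs)")
        if self.weights.shape[0] != self.lag_spec.n_lags:
            raise ShapeError(
                f"{self.weights.shape[0]} lag rows for {self.lag_spec.n_lags} lags"
            )
        if self.direction not in ("forward", "backward"):
            raise InvalidInputError(f"unknown direction {self.direction!r}")
        if self.direction == "forward" and self.weights.shape[1] != 1:
            raise ShapeError("forward model must have a single input channel")
        if self.direction == "backward" and self.weights.shape[2] != 1:
            raise ShapeError("backward model must have a single output channel")
        if not np.all(np.isfinite(self.weights)):
            raise InvalidInputError("model weights contain non-finite values")

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[2]

    def as_matrix(self) -> np.ndarray:
        """Weights as the (channels*lags, n_outputs) matrix of ``Y_hat = X W``.

        Row ordering matches the channel-major column layout of
        :class:`DesignMatrix`.
        """
        n_lags, n_in, n_out = self.weights.shape
        return self.weights.transpose(1, 0, 2).reshape(n_in * n_lags, n_out)

    @classmethod
    def from_matrix(cls, w: np.ndarray, direction: str, lag_spec: LagSpec,
                    fs: float, n_inputs: int) -> "LinearModel":
        """Inverse of :meth:`as_matrix`."""
        w = np.asarray(w, dtype=float)
        if w.ndim == 1:
            w = w[:, None]
        n_out = w.shape[1]
        tensor = w.reshape(n_inputs, lag_spec.n_lags, n_out).transpose(1, 0, 2)
        return cls(tensor, direction, lag_spec, fs)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_lagged_design(ts: TimeSeries, lag_spec: LagSpec) -> DesignMatrix:
    """Augment a series with time-lagged copies of each channel.

    Column ``(c, f)`` at row ``t`` equals ``ts.samples[t - f, c]`` when
    ``0 <= t - f < n_times`` and 0 otherwise (zero padding at the edges keeps
    the row count equal to the input, so X and Y stay conformable).
    """
    x = ts.samples
    n, n_ch = x.shape
    if n == 0:
        raise InvalidInputError("cannot build a design matrix from an empty series")
    if lag_spec.n_lags > n:
        raise InvalidInputError(
            f"lag count ({lag_spec.n_lags}) exceeds series length ({n})"
        )
    n_lags = lag_spec.n_lags
    out = np.zeros((n, n_ch * n_lags))
    for k, f in enumerate(lag_spec.lags):
        if f >= 0:
            src = slice(0, n - f)
            dst = slice(f, n)
        else:
            src = slice(-f, n)
            dst = slice(0, n + f)
        for c in range(n_ch):
            out[dst, c * n_lags + k] = x[src, c]
    return DesignMatrix(out, lag_spec, n_ch)


def apply_model(model: LinearModel, design: DesignMatrix) -> TimeSeries:
    """Evaluate ``Y_hat = X W`` for a fitted model on a lagged design."""
    w = model.as_matrix()
    if design.n_columns != w.shape[0]:
        raise ShapeError(
            f"design has {design.n_columns} columns but model expects {w.shape[0]}"
        )
    if design.lag_spec != model.lag_spec:
        raise ShapeError("design and model lag specifications differ")
    pred = design.values @ w
    return TimeSeries(pred, model.fs,
                      [f"out{i}" for i in range(pred.shape[1])])


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation between two equal-length vectors.

    Raises :class:`DegenerateInputError` when either vector has zero
    variance (the correlation is undefined and must not silently become 0).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ShapeError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise InvalidInputError("need at least 2 samples for a correlation")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0.0 or nb == 0.0:
        raise DegenerateInputError("correlation undefined for zero-variance input")
    return float(np.clip(ac @ bc / (na * nb), -1.0, 1.0))
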