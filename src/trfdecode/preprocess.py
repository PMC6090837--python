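"""EEG and audio conditioning.

The EEG chain turns a raw multichannel recording into the 64 Hz, 1-9 Hz band,
z-normalized signal the stimulus-response models consume.  The fixed order is

    line-noise smoothing -> FFT resampling -> linear detrend -> 0.1 Hz
    high-pass (forward Butterworth) -> joint-decorrelation EOG removal ->
    1-9 Hz zero-phase FIR band-pass -> z-normalization (training stats only)

The audio chain passes clean speech through a 31-band gammatone filterbank
(80-8000 Hz, ERB-spaced), takes the magnitude of the analytic signal per band,
compresses with a 0.3 power law (approximating cochlear compression), sums
across bands, resamples to the EEG rate and low-passes at 9 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal as sps

from .datamodel import TimeSeries
from .exceptions import (
    DegenerateInputError,
    FilterDesignError,
    InvalidParameterError,
)

__all__ = [
    "NormalizationStats",
    "PreprocessConfig",
    "smooth_line_noise",
    "fft_resample",
    "detrend_linear",
    "highpass_butter",
    "remove_eog_components",
    "bandpass_fir_zerophase",
    "znormalize",
    "gammatone_envelope",
    "lowpass_envelope",
    "preprocess_eeg",
    "extract_envelope",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    """Defaults of the conditioning chain (units: Hz unless noted)."""

    line_freq: float = 50.0
    target_fs: float = 64.0
    hp_cutoff: float = 0.1
    hp_order: int = 4
    eog_z_thresh: float = 4.0
    eog_eig_frac: float = 0.8
    bp_band: tuple[float, float] = (1.0, 9.0)
    bp_order: int = 128
    gt_bands: int = 31
    gt_range: tuple[float, float] = (80.0, 8000.0)
    gt_exponent: float = 0.3
    env_lp_cutoff: float = 9.0


# ---------------------------------------------------------------------------
# EEG chain
# ---------------------------------------------------------------------------

def smooth_line_noise(ts: TimeSeries, line_freq: float = 50.0) -> TimeSeries:
    """Null line noise and harmonics by boxcar smoothing.

    A moving average of length ``fs / line_freq`` samples has spectral zeros
    at the line frequency and its harmonics.  The generally non-integer
    length is realized by linearly interpolating between the outputs of the
    two flanking integer-length boxcars.
    """
    if line_freq >= ts.fs / 2:
        raise InvalidParameterError(
            f"line frequency {line_freq} Hz is not below Nyquist ({ts.fs / 2} Hz)"
        )
    length = ts.fs / line_freq
    lo = int(np.floor(length))
    frac = length - lo
    x = ts.samples

    def boxcar(n: int) -> np.ndarray:
        if n <= 1:
            return x
        kern = np.ones(n) / n
        # centered moving average, edges padded by reflection to keep length
        pad_l = (n - 1) // 2
        pad_r = n - 1 - pad_l
        xp = np.pad(x, ((pad_l, pad_r), (0, 0)), mode="reflect")
        return np.apply_along_axis(lambda v: np.convolve(v, kern, "valid"), 0, xp)

    out = boxcar(lo) if frac == 0 else (1 - frac) * boxcar(lo) + frac * boxcar(lo + 1)
    return ts.copy_with(out)


def fft_resample(ts: TimeSeries, target_fs: float) -> TimeSeries:
    """Downsample by truncating high-frequency FFT components.

    Band-limited content below the target Nyquist is preserved exactly (up to
    edge effects of the implicit periodicity assumption).  Upsampling is
    refused.
    """
    if target_fs > ts.fs:
        raise InvalidParameterError(
            f"target rate {target_fs} Hz exceeds input rate {ts.fs} Hz (no upsampling)"
        )
    if target_fs == ts.fs:
        return ts.copy_with(ts.samples.copy())
    n_out = int(round(ts.n_times * target_fs / ts.fs))
    out = sps.resample(ts.samples, n_out, axis=0)
    return ts.copy_with(out, fs=target_fs)


def detrend_linear(ts: TimeSeries) -> TimeSeries:
    """Remove the per-channel least-squares line (minimizes filter start-up kicks)."""
    if ts.n_times < 2:
        raise InvalidParameterError("detrend needs at least 2 samples")
    return ts.copy_with(sps.detrend(ts.samples, axis=0, type="linear"))


def highpass_butter(ts: TimeSeries, cutoff: float = 0.1, order: int = 4) -> TimeSeries:
    """Causal (single forward pass) Butterworth high-pass.

    The forward-only pass keeps the filter causal.  With the default design
    at 64 Hz the group delay decays quickly with frequency: about 2.7 samples
    at 1 Hz, under 2 samples above ~1.2 Hz and under 0.7 samples above 2 Hz
    (see :func:`butter_group_delay`), so phase distortion in the 1-9 Hz
    modeling band is small.
    """
    if cutoff >= ts.fs / 2:
        raise InvalidParameterError(f"cutoff {cutoff} Hz must be below Nyquist")
    sos = sps.butter(order, cutoff, btype="highpass", fs=ts.fs, output="sos")
    if not np.all(np.abs(sps.sos2zpk(sos)[1]) < 1.0):
        raise FilterDesignError(
            f"unstable high-pass design (cutoff {cutoff} Hz at fs {ts.fs} Hz)"
        )
    return ts.copy_with(sps.sosfilt(sos, ts.samples, axis=0))


def butter_group_delay(fs: float, cutoff: float = 0.1, order: int = 4,
                       freqs: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Group delay (samples) of the high-pass design on a frequency grid."""
    b, a = sps.butter(order, cutoff, btype="highpass", fs=fs)
    if freqs is None:
        freqs = np.linspace(1.0, fs / 2 * 0.999, 512)
    w = 2 * np.pi * freqs / fs
    _, gd = sps.group_delay((b, a), w=w)
    return freqs, gd


def _bandpass_fir(x: np.ndarray, fs: float, low: float, high: float,
                  order: int) -> np.ndarray:
    """Zero-phase windowed-sinc band-pass of a (time x channels) array."""
    taps = sps.firwin(order + 1, [low, high], pass_zero=False, fs=fs)
    pad = order // 2
    xp = np.pad(x, ((pad, pad), (0, 0)), mode="reflect")
    y = sps.lfilter(taps, 1.0, xp, axis=0)
    # advance by the group delay of the linear-phase filter -> zero net delay
    return y[2 * pad:, :]


def bandpass_fir_zerophase(ts: TimeSeries, low: float = 1.0, high: float = 9.0,
                           order: int = 128) -> TimeSeries:
    """Linear-phase FIR band-pass, shifted by its group delay (zero net delay).

    The filter is a windowed-sinc type I design (even order, odd tap count,
    symmetric impulse response), so the group delay is exactly ``order / 2``
    samples and the compensation is exact at all frequencies.
    """
    if order % 2:
        raise InvalidParameterError(f"FIR order must be even (type I), got {order}")
    if high >= ts.fs / 2:
        raise InvalidParameterError(f"upper edge {high} Hz must be below Nyquist")
    return ts.copy_with(_bandpass_fir(ts.samples, ts.fs, low, high, order))


# ---------------------------------------------------------------------------
# EOG artifact removal (joint decorrelation)
# ---------------------------------------------------------------------------

@dataclass
class EOGReport:
    """What the joint-decorrelation cleanup did."""

    n_components_removed: int
    n_artifact_samples: int
    artifact_fraction: float
    spatial_patterns: np.ndarray  # (n_channels, n_removed)
    warning: str | None = None


def remove_eog_components(eeg: TimeSeries, veog: np.ndarray, heog: np.ndarray,
                          z_thresh: float = 4.0, eig_frac: float = 0.8,
                          ) -> tuple[TimeSeries, EOGReport]:
    """Remove ocular-artifact components via joint decorrelation.

    Blink/saccade samples are flagged where the z-scored 1-30 Hz band-passed
    EOG exceeds ``z_thresh``; the generalized eigenvalue problem
    ``R_A v = lam R v`` (artifact covariance vs whole-recording covariance,
    solved in the whitened space of ``R``) yields components ordered by how
    much more variance they carry during artifacts than overall.  Components
    with eigenvalue above ``eig_frac`` times the maximum are regressed out —
    with the conventional 80% threshold typically one or two components.
    """
    veog = np.asarray(veog, dtype=float).ravel()
    heog = np.asarray(heog, dtype=float).ravel()
    if veog.size != eeg.n_times or heog.size != eeg.n_times:
        raise InvalidParameterError("EOG channels must match the EEG length")

    # 1) artifact sample detection on 1-30 Hz band-passed, z-scored EOG
    high = min(30.0, 0.45 * eeg.fs)
    eog = np.column_stack([veog, heog])
    eog_bp = _bandpass_fir(eog, eeg.fs, 1.0, high, order=min(128, 2 * (eeg.n_times // 4)))
    sd = eog_bp.std(axis=0)
    sd[sd == 0] = 1.0
    z = (eog_bp - eog_bp.mean(axis=0)) / sd
    mask = np.any(np.abs(z) > z_thresh, axis=1)
    n_art = int(mask.sum())
    frac = n_art / eeg.n_times

    if n_art == 0:
        report = EOGReport(0, 0, 0.0, np.zeros((eeg.n_channels, 0)),
                           warning="no artifact samples found; data returned unchanged")
        return eeg.copy_with(eeg.samples.copy()), report
    warning = None
    if frac > 0.5:
        warning = (f"{frac:.0%} of samples flagged as artifact; "
                   "threshold may be too low for this recording")

    x = eeg.samples
    r_all = x.T @ x
    xa = x[mask]
    r_art = xa.T @ xa

    # 2) whiten R, solve the symmetric eigenproblem for R_A in whitened space
    s, q = np.linalg.eigh(r_all)
    keep = s > 1e-9 * s.max()
    wh = q[:, keep] / np.sqrt(s[keep])
    ra_w = wh.T @ r_art @ wh
    lam, u = np.linalg.eigh(ra_w)
    order = np.argsort(lam)[::-1]
    lam, u = lam[order], u[:, order]

    sel = lam > eig_frac * lam[0]
    comps = wh @ u[:, sel]            # spatial filters (channels x k)
    scores = x @ comps                # component time courses

    # 3) regress the selected component time courses out of every channel
    beta, *_ = np.linalg.lstsq(scores, x, rcond=None)
    cleaned = x - scores @ beta
    patterns = r_all @ comps          # forward patterns of the removed filters
    patterns /= np.linalg.norm(patterns, axis=0, keepdims=True)

    report = EOGReport(int(sel.sum()), n_art, frac, patterns, warning)
    return eeg.copy_with(cleaned), report


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationStats:
    """Per-channel mean/sd estimated on training data only (no test leakage)."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.sd = np.atleast_1d(np.asarray(self.sd, dtype=float))
        if np.any(self.sd <= 0):
            raise DegenerateInputError("normalization sd must be positive")

    @classmethod
    def from_training(cls, ts: TimeSeries | np.ndarray) -> "NormalizationStats":
        x = ts.samples if isinstance(ts, TimeSeries) else np.atleast_2d(ts)
        sd = x.std(axis=0)
        if np.any(sd == 0):
            raise DegenerateInputError("zero-variance channel in training data")
        return cls(x.mean(axis=0), sd)


def znormalize(ts: TimeSeries, stats: NormalizationStats) -> TimeSeries:
    """Center and scale each channel with training-derived statistics."""
    if stats.mean.size != ts.n_channels:
        raise InvalidParameterError(
            f"stats cover {stats.mean.size} channels, series has {ts.n_channels}"
        )
    return ts.copy_with((ts.samples - stats.mean) / stats.sd)


# ---------------------------------------------------------------------------
# Audio envelope
# ---------------------------------------------------------------------------

def _erb_space(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    """Center frequencies equally spaced on the ERB-rate scale."""
    erb = lambda f: 21.4 * np.log10(1.0 + 0.00437 * f)
    erb_inv = lambda e: (10.0 ** (e / 21.4) - 1.0) / 0.00437
    return erb_inv(np.linspace(erb(f_lo), erb(f_hi), n))


def gammatone_envelope(audio: TimeSeries, n_bands: int = 31, f_lo: float = 80.0,
                       f_hi: float = 8000.0, exponent: float = 0.3) -> TimeSeries:
    """Compressed broadband envelope from a gammatone filterbank.

    Each of ``n_bands`` 4th-order gammatone filters (ERB-spaced centers in
    [f_lo, f_hi]) is applied to the mono audio; the per-band envelope is the
    magnitude of the analytic (Hilbert) signal raised to ``exponent`` (a
    power-law compression mimicking cochlear compression), and the bands are
    summed into a single nonnegative envelope at the audio rate.
    """
    if audio.fs < 2 * f_hi:
        raise InvalidParameterError(
            f"audio rate {audio.fs} Hz cannot represent bands up to {f_hi} Hz"
        )
    x = audio.samples[:, 0] if audio.n_channels else audio.samples.ravel()
    env = np.zeros_like(x)
    # keep the top band strictly below Nyquist for the digital design
    centers = np.minimum(_erb_space(f_lo, f_hi, n_bands), 0.4999 * audio.fs)
    for fc in centers:
        b, a = sps.gammatone(fc, "iir", fs=audio.fs)
        band = sps.lfilter(b, a, x)
        mag = np.abs(sps.hilbert(band))
        env += mag ** exponent
    return TimeSeries(env[:, None], audio.fs, ["envelope"])


def lowpass_envelope(env: TimeSeries, cutoff: float = 9.0, order: int = 128) -> TimeSeries:
    """Zero-phase FIR low-pass of an envelope (default 9 Hz)."""
    if cutoff >= env.fs / 2:
        raise InvalidParameterError(f"cutoff {cutoff} Hz must be below Nyquist")
    order = min(order, 2 * (env.n_times // 4))
    order -= order % 2
    if order < 2:
        raise InvalidParameterError("envelope too short to low-pass")
    taps = sps.firwin(order + 1, cutoff, fs=env.fs)
    pad = order // 2
    xp = np.pad(env.samples, ((pad, pad), (0, 0)), mode="reflect")
    y = sps.lfilter(taps, 1.0, xp, axis=0)[2 * pad:, :]
    return env.copy_with(y)


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------

def preprocess_eeg(eeg: TimeSeries, veog: np.ndarray | None = None,
                   heog: np.ndarray | None = None,
                   config: PreprocessConfig | None = None,
                   ) -> tuple[TimeSeries, EOGReport | None]:
    """Run the fixed EEG conditioning chain (everything except z-normalization,
    which needs training-fold statistics and belongs to cross-validation).
    """
    cfg = config or PreprocessConfig()
    out = smooth_line_noise(eeg, cfg.line_freq)
    out = fft_resample(out, cfg.target_fs)
    out = detrend_linear(out)
    out = highpass_butter(out, cfg.hp_cutoff, cfg.hp_order)
    report = None
    if veog is not None and heog is not None:
        # EOG channels ride along through the same resampling
        eog_ts = TimeSeries(np.column_stack([veog, heog]), eeg.fs, ["VEOG", "HEOG"])
        eog_ts = fft_resample(smooth_line_noise(eog_ts, cfg.line_freq), cfg.target_fs)
        out, report = remove_eog_components(
            out, eog_ts.samples[:, 0], eog_ts.samples[:, 1],
            cfg.eog_z_thresh, cfg.eog_eig_frac,
        )
        # reference to common average after the EOG channels are gone
        out = out.copy_with(out.samples - out.samples.mean(axis=1, keepdims=True))
    out = bandpass_fir_zerophase(out, *cfg.bp_band, cfg.bp_order)
    return out, report


def extract_envelope(audio: TimeSeries, config: PreprocessConfig | None = None,
                     ) -> TimeSeries:
    """Audio -> compressed gammatone envelope at the EEG rate, low-passed."""
    cfg = config or PreprocessConfig()
    env = gammatone_envelope(audio, cfg.gt_bands, *cfg.gt_range, cfg.gt_exponent)
    env = fft_resample(env, cfg.target_fs)
    return lowpass_envelope(env, cfg.env_lp_cutoff)
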