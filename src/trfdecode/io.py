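"""Readers and writers for :class:`~trfdecode.datamodel.TimeSeries`.

Delimited text is the interchange format (one row per sample, a header row of
channel labels, and a ``# fs=<Hz>`` comment line).  EEG recordings can be
imported from EDF/BDF via :mod:`mne`; mono audio from WAV via
:mod:`scipy.io.wavfile`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .datamodel import TimeSeries
from .exceptions import DataError

__all__ = [
    "read_timeseries_text",
    "write_timeseries_text",
    "read_eeg_edf",
    "read_audio_wav",
]


def write_timeseries_text(ts: TimeSeries, path: str | Path,
                          delimiter: str = "\t") -> None:
    path = Path(path)
    header = f"# fs={ts.fs!r}\n" + delimiter.join(ts.channel_labels)
    np.savetxt(path, ts.samples, delimiter=delimiter, header=header, comments="")


def read_timeseries_text(path: str | Path, delimiter: str = "\t",
                         fs: float | None = None) -> TimeSeries:
    """Read a delimited-text series written by :func:`write_timeseries_text`.

    ``fs`` overrides (or supplies, for plain files without the comment line)
    the sampling rate.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    labels: list[str] = []
    file_fs: float | None = None
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("# fs="):
            file_fs = float(first[5:])
            first = fh.readline().strip()
        labels = [tok for tok in first.split(delimiter) if tok]
        try:
            [float(tok) for tok in labels]
        except ValueError:
            pass  # proper header row
        else:
            raise DataError(f"{path}: missing channel-label header row")
        data = np.loadtxt(fh, delimiter=delimiter, ndmin=2)
    rate = fs if fs is not None else file_fs
    if rate is None:
        raise DataError(f"{path}: no sampling rate in file and none supplied")
    if data.shape[1] != len(labels):
        raise DataError(
            f"{path}: {data.shape[1]} data columns but {len(labels)} labels"
        )
    return TimeSeries(data, rate, labels)


def read_eeg_edf(path: str | Path, channels: list[str] | None = None) -> TimeSeries:
    """Import an EDF/BDF recording as a TimeSeries (volts, all or named channels)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix == ".bdf":
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    elif suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise DataError(f"unsupported EEG container: {suffix}")
    if channels is not None:
        raw.pick(channels)
    data = raw.get_data().T  # mne is channels x time
    return TimeSeries(data, float(raw.info["sfreq"]), list(raw.ch_names))


def read_audio_wav(path: str | Path) -> TimeSeries:
    """Import a WAV file as a float TimeSeries (integer PCM scaled to [-1, 1])."""
    from scipy.io import wavfile

    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    fs, raw = wavfile.read(path)
    data = np.atleast_2d(np.asarray(raw).T).T.astype(float)
    if np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype)
        data = data / max(abs(info.min), info.max)
    labels = [f"audio{i}" for i in range(data.shape[1])]
    return TimeSeries(data, float(fs), labels)
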