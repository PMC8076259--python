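"""Recording I/O, acquisition-chain filtering, downsampling and epoching.

Emulates the acquisition front end of a rodent polysomnography rig:
hardware band-pass (EEG 0.1-100 Hz, EMG 1-100 Hz), digitisation at 250 Hz,
offline downsampling to 125 Hz, and segmentation into non-overlapping 4 s
scoring epochs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .types import EpochedSignal, LightDarkSchedule, Recording

EEG_BAND = (0.1, 100.0)
EMG_BAND = (1.0, 100.0)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path) -> None:
    """Write a recording as CSV with columns ``time_s,eeg,emg``."""
    t = np.arange(recording.n_samples) / recording.fs
    pd.DataFrame({"time_s": t, "eeg": recording.eeg, "emg": recording.emg}).to_csv(
        path, index=False, float_format="%.6g"
    )


def read_recording(
    path,
    format: str = "csv",
    fs: float | None = None,
    start_zt: float = 0.0,
    schedule: LightDarkSchedule | None = None,
    channel_map: dict[str, str] | None = None,
) -> Recording:
    """Read a two-channel recording from CSV or EDF.

    CSV files use the ``time_s,eeg,emg`` dialect written by
    :func:`write_recording`; ``fs`` is taken from the time column unless
    given. EDF files are read through :mod:`mne` (optional dependency) and
    ``fs`` comes from the file header. ``channel_map`` maps the file's
    channel labels onto ``{"eeg": ..., "emg": ...}``.
    """
    schedule = schedule or LightDarkSchedule()
    if format == "csv":
        df = pd.read_csv(path)
        cmap = {"eeg": "eeg", "emg": "emg"}
        if channel_map:
            cmap.update({k.lower(): v for k, v in channel_map.items()})
        for role, col in cmap.items():
            if col not in df.columns:
                raise ValueError(f"missing channel column {col!r} (role {role!r}) in {path}")
        if fs is None:
            if "time_s" not in df.columns or len(df) < 2:
                raise ValueError("cannot infer fs: no time_s column; pass fs explicitly")
            dt = np.diff(df["time_s"].to_numpy())
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("non-uniform time_s column; pass fs explicitly")
            fs = 1.0 / dt[0]
        return Recording(
            eeg=df[cmap["eeg"]].to_numpy(float),
            emg=df[cmap["emg"]].to_numpy(float),
            fs=float(fs),
            start_zt=start_zt,
            schedule=schedule,
        )
    if format == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("EDF reading requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        labels = {name.lower(): name for name in raw.ch_names}
        cmap = {"eeg": "eeg", "emg": "emg"}
        if channel_map:
            cmap.update({k.lower(): v.lower() for k, v in channel_map.items()})
        chans = {}
        for role, want in cmap.items():
            if want.lower() not in labels:
                raise ValueError(
                    f"missing channel {want!r} in EDF (has {list(raw.ch_names)})"
                )
            chans[role] = labels[want.lower()]
        data = raw.get_data(picks=[chans["eeg"], chans["emg"]])
        return Recording(
            eeg=data[0],
            emg=data[1],
            fs=float(raw.info["sfreq"]),
            start_zt=start_zt,
            schedule=schedule,
        )
    raise ValueError(f"unknown format {format!r}; use 'csv' or 'edf'")


# ---------------------------------------------------------------------------
# filtering / resampling
# ---------------------------------------------------------------------------

def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def hardware_bandpass(recording: Recording) -> Recording:
    """Zero-phase emulation of the acquisition band-pass.

    EEG 0.1-100 Hz, EMG 1-100 Hz, 4th-order Butterworth applied
    forward-backward so epoch features downstream carry no filter lag.
    """
    if recording.fs <= 2 * EEG_BAND[1]:
        raise ValueError(f"fs={recording.fs} too low for a {EEG_BAND[1]} Hz band edge")
    return Recording(
        eeg=_bandpass(recording.eeg, recording.fs, *EEG_BAND),
        emg=_bandpass(recording.emg, recording.fs, *EMG_BAND),
        fs=recording.fs,
        start_zt=recording.start_zt,
        schedule=recording.schedule,
    )


def downsample(recording: Recording, target_fs: float) -> Recording:
    """Anti-aliased decimation to ``target_fs`` (must divide ``fs``).

    An 8th-order Butterworth low-pass at 0.8x the target Nyquist is applied
    zero-phase before taking every k-th sample.
    """
    factor = recording.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"fs={recording.fs} not an integer multiple of target_fs={target_fs}"
        )
    factor = int(round(factor))
    if factor == 1:
        return recording
    cutoff = 0.8 * (target_fs / 2.0)
    sos = signal.butter(8, cutoff, btype="lowpass", fs=recording.fs, output="sos")
    eeg = signal.sosfiltfilt(sos, recording.eeg)[::factor]
    emg = signal.sosfiltfilt(sos, recording.emg)[::factor]
    return Recording(
        eeg=eeg,
        emg=emg,
        fs=target_fs,
        start_zt=recording.start_zt,
        schedule=recording.schedule,
    )


def epoch_signal(x: np.ndarray | Recording, fs: float | None = None,
                 epoch_len: float = 4.0, channel: str = "eeg") -> EpochedSignal:
    """Cut a signal into non-overlapping ``epoch_len`` s epochs.

    Accepts a raw sample vector plus ``fs`` or a :class:`Recording` (with
    ``channel`` selecting eeg/emg). The trailing partial epoch is discarded;
    a recording shorter than one epoch is an error.
    """
    if isinstance(x, Recording):
        fs = x.fs
        x = getattr(x, channel)
    if fs is None:
        raise ValueError("fs required when passing a raw sample vector")
    if epoch_len <= 0:
        raise ValueError("epoch_len must be positive")
    spe = epoch_len * fs
    if abs(spe - round(spe)) > 1e-9:
        raise ValueError(f"epoch_len*fs = {spe} is not an integer sample count")
    spe = int(round(spe))
    x = np.asarray(x, dtype=float)
    n = x.size // spe
    if n == 0:
        raise ValueError(
            f"recording of {x.size} samples shorter than one {epoch_len} s epoch"
        )
    return EpochedSignal(epochs=x[: n * spe].reshape(n, spe), epoch_len=epoch_len, fs=fs)
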