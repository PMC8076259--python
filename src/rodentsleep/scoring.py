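"""Epoch-level vigilance-state scoring and bout-consolidation rescoring.

The scorer is a transparent two-feature threshold classifier: epochs with
high EMG tone are WAKE; among low-EMG epochs, a high EEG theta/delta ratio
marks REMS and the rest is NREMS. It stands in for interactive
semi-automated scoring software; everything downstream depends only on the
resulting hypnogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .types import (
    Hypnogram,
    EpochedSignal,
    LightDarkSchedule,
    VigilanceState,
    state_from_label,
)

DELTA_BAND = (1.0, 5.0)
THETA_BAND = (6.0, 9.0)


@dataclass
class EpochFeatures:
    """Per-epoch scoring features: EMG tone and EEG delta/theta power."""

    emg_rms: np.ndarray
    delta_power: np.ndarray
    theta_power: np.ndarray

    @property
    def theta_delta_ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.theta_power / self.delta_power
        return np.where(self.delta_power > 0, r, np.inf)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "emg_rms": self.emg_rms,
                "delta_power": self.delta_power,
                "theta_power": self.theta_power,
                "theta_delta_ratio": self.theta_delta_ratio,
            }
        )


def _band_power(epochs: EpochedSignal, band: tuple[float, float]) -> np.ndarray:
    """Mean periodogram power of each epoch inside ``band`` (edges inclusive)."""
    freqs, psd = signal.periodogram(epochs.epochs, fs=epochs.fs, axis=-1)
    sel = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    return psd[:, sel].sum(axis=1)


def compute_features(eeg_epochs: EpochedSignal, emg_epochs: EpochedSignal) -> EpochFeatures:
    if eeg_epochs.n_epochs != emg_epochs.n_epochs:
        raise ValueError("EEG and EMG epoch counts differ")
    if eeg_epochs.n_epochs == 0:
        raise ValueError("empty input")
    emg_rms = np.sqrt(np.mean(emg_epochs.epochs**2, axis=1))
    delta = _band_power(eeg_epochs, DELTA_BAND)
    theta = _band_power(eeg_epochs, THETA_BAND)
    feats = EpochFeatures(emg_rms=emg_rms, delta_power=delta, theta_power=theta)
    if not (
        np.isfinite(emg_rms).all() and np.isfinite(delta).all() and np.isfinite(theta).all()
    ):
        raise ValueError("non-finite epoch features")
    return feats


def _auto_emg_threshold(emg_rms: np.ndarray, min_separation: float = 2.0) -> float:
    """Two-cluster split of log EMG RMS (1-D k-means / Otsu-style).

    Separates the low-tone (sleep) and high-tone (WAKE) modes regardless of
    their mixing proportion, unlike a fixed percentile. If the two cluster
    means are closer than ``min_separation`` (ratio scale) the EMG is
    considered unimodal - no high-tone cluster - and the threshold is placed
    above the maximum so no epoch is called WAKE on EMG alone.
    """
    x = np.log(np.maximum(emg_rms, np.finfo(float).tiny))
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:  # constant EMG: nothing exceeds the cut
        return float(np.exp(hi) * 2.0)
    c0, c1 = lo, hi
    for _ in range(100):
        mid = 0.5 * (c0 + c1)
        left, right = x[x <= mid], x[x > mid]
        n0 = left.mean() if left.size else c0
        n1 = right.mean() if right.size else c1
        if abs(n0 - c0) < 1e-12 and abs(n1 - c1) < 1e-12:
            break
        c0, c1 = n0, n1
    if c1 - c0 < np.log(min_separation):
        return float(np.exp(hi) * 2.0)
    return float(np.exp(0.5 * (c0 + c1)))


def score_epochs(
    eeg_epochs: EpochedSignal,
    emg_epochs: EpochedSignal,
    emg_threshold: float | str = "auto",
    ratio_threshold: float = 1.0,
    start_zt: float = 0.0,
    schedule: LightDarkSchedule | None = None,
) -> Hypnogram:
    """Assign one vigilance state per epoch.

    Rule: WAKE if EMG RMS > ``emg_threshold``; else NREMS if the epoch's
    theta/delta power ratio <= ``ratio_threshold``; else REMS.

    ``emg_threshold`` may be a number, ``"auto"`` (two-cluster split of log
    EMG RMS, the default) or ``"p60"`` (60th percentile of EMG RMS).
    """
    feats = compute_features(eeg_epochs, emg_epochs)
    if emg_threshold == "auto":
        thr = _auto_emg_threshold(feats.emg_rms)
    elif emg_threshold == "p60":
        thr = float(np.percentile(feats.emg_rms, 60))
    else:
        thr = float(emg_threshold)
    states = np.full(feats.emg_rms.size, int(VigilanceState.REMS), dtype=np.int8)
    states[feats.theta_delta_ratio <= ratio_threshold] = int(VigilanceState.NREMS)
    states[feats.emg_rms > thr] = int(VigilanceState.WAKE)
    return Hypnogram(
        states=states,
        epoch_len=eeg_epochs.epoch_len,
        start_zt=start_zt,
        schedule=schedule or LightDarkSchedule(),
    )


def smooth_bouts(hypnogram: Hypnogram, min_bout_epochs: int = 3) -> Hypnogram:
    """Absorb sub-minimum runs so every bout lasts >= ``min_bout_epochs``.

    Left-to-right scan: a run shorter than the floor merges into the
    preceding run's state; a sub-minimum run at the start merges into the
    following run. Repeated to a fixpoint, so the operation is idempotent.
    """
    if min_bout_epochs < 1:
        raise ValueError("min_bout_epochs must be >= 1")
    if hypnogram.n_epochs < min_bout_epochs:
        raise ValueError("hypnogram shorter than the minimum bout length")
    states = hypnogram.states.copy()
    while True:
        changed = False
        # run-length encode
        edges = np.flatnonzero(np.diff(states)) + 1
        starts = np.concatenate(([0], edges))
        ends = np.concatenate((edges, [states.size]))
        for s, e in zip(starts, ends):
            if e - s >= min_bout_epochs:
                continue
            if s > 0:
                states[s:e] = states[s - 1]
            elif e < states.size:
                states[s:e] = states[e]
            else:
                break  # whole sequence is one short run; nothing to merge into
            changed = True
            break  # re-encode after each merge (runs coalesce)
        if not changed:
            break
    return Hypnogram(
        states=states,
        epoch_len=hypnogram.epoch_len,
        start_zt=hypnogram.start_zt,
        schedule=hypnogram.schedule,
    )


def write_hypnogram(hypnogram: Hypnogram, path) -> None:
    """Write a hypnogram as CSV with columns (epoch_index, zt_seconds, state)."""
    idx = np.arange(hypnogram.n_epochs)
    zt_s = hypnogram.start_zt * 3600.0 + idx * hypnogram.epoch_len
    labels = np.array([s.name for s in VigilanceState])[hypnogram.states]
    pd.DataFrame({"epoch_index": idx, "zt_seconds": zt_s, "state": labels}).to_csv(
        path, index=False
    )


def read_hypnogram(path, schedule: LightDarkSchedule | None = None) -> Hypnogram:
    df = pd.read_csv(path)
    for col in ("epoch_index", "zt_seconds", "state"):
        if col not in df.columns:
            raise ValueError(f"hypnogram CSV missing column {col!r}")
    idx = df["epoch_index"].to_numpy()
    if not np.array_equal(idx, np.arange(idx[0], idx[0] + idx.size)):
        raise ValueError("non-contiguous epoch indices in hypnogram CSV")
    states = np.array([int(state_from_label(t)) for t in df["state"]], dtype=np.int8)
    zt_s = df["zt_seconds"].to_numpy(float)
    if idx.size >= 2:
        epoch_len = float(zt_s[1] - zt_s[0])
    else:
        epoch_len = 4.0
    return Hypnogram(
        states=states,
        epoch_len=epoch_len,
        start_zt=float(zt_s[0]) / 3600.0,
        schedule=schedule or LightDarkSchedule(),
    )
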