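"""Sleep-spindle detection in NREMS via the cubed-RMS two-threshold method.

Pipeline: sigma band-pass (10-15 Hz Butterworth, >= 24 dB at the 3 / 22 Hz
stopband edges) -> centered 750 ms moving RMS -> elementwise cube (spreads
the envelope's dynamic range, making thresholds easier to place) -> events
as excursions above 1.0x the mean cubed RMS that reach 2.5x, restricted to
NREMS, merged across gaps <= 0.1 s and kept if 0.5-10 s long.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .types import Hypnogram, VigilanceState


@dataclass(frozen=True)
class SpindleParams:
    passband: tuple[float, float] = (10.0, 15.0)
    stopband: tuple[float, float] = (3.0, 22.0)
    stop_atten_db: float = 24.0
    rms_window_s: float = 0.75
    lower_thresh_mult: float = 1.0
    upper_thresh_mult: float = 2.5
    min_dur_s: float = 0.5
    max_dur_s: float = 10.0
    min_isi_s: float = 0.1
    baseline_scope: str = "nrems"  # or "all"
    containment: str = "start"  # event-in-NREMS rule: "start" or "full"

    def __post_init__(self) -> None:
        if not 0 < self.min_dur_s < self.max_dur_s:
            raise ValueError("need 0 < min_dur_s < max_dur_s")
        if self.lower_thresh_mult >= self.upper_thresh_mult:
            raise ValueError("lower threshold must be below upper threshold")
        if not (self.stopband[0] < self.passband[0] < self.passband[1] < self.stopband[1]):
            raise ValueError("passband must lie inside the stopband interval")


@dataclass(frozen=True)
class SpindleEvent:
    start_s: float
    end_s: float
    peak: float  # peak cubed-RMS value
    bout_index: int = -1  # containing NREMS bout (run index), -1 if unassigned

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def sigma_filter(eeg: np.ndarray, fs: float, params: SpindleParams = SpindleParams()) -> np.ndarray:
    """Zero-phase minimum-order Butterworth sigma band-pass.

    The order is the smallest meeting ``stop_atten_db`` at both stopband
    edges (single-pass design; forward-backward application only deepens
    stopband rejection).
    """
    if fs <= 2 * params.stopband[1]:
        raise ValueError(f"fs={fs} too low for a {params.stopband[1]} Hz stopband edge")
    order, wn = signal.buttord(
        wp=list(params.passband), ws=list(params.stopband),
        gpass=3.0, gstop=params.stop_atten_db, fs=fs,
    )
    sos = signal.butter(order, wn, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(eeg, dtype=float))


def cubed_rms_envelope(
    filtered: np.ndarray, fs: float, window_s: float = 0.75
) -> np.ndarray:
    """Centered moving RMS over ``window_s``, then cubed.

    The averaging window is truncated at the recording edges (each sample
    averages over however much of the window exists).
    """
    x = np.asarray(filtered, dtype=float)
    win = int(round(window_s * fs))
    if win <= 0 or win > x.size:
        raise ValueError(f"window of {win} samples invalid for signal of {x.size}")
    sq = x * x
    half_l = (win - 1) // 2
    half_r = win // 2
    csum = np.concatenate(([0.0], np.cumsum(sq)))
    idx = np.arange(x.size)
    lo = np.maximum(idx - half_l, 0)
    hi = np.minimum(idx + half_r + 1, x.size)
    means = (csum[hi] - csum[lo]) / (hi - lo)
    return np.sqrt(means) ** 3


def detect_spindles(
    envelope: np.ndarray,
    hypnogram: Hypnogram,
    fs: float,
    params: SpindleParams = SpindleParams(),
) -> list[SpindleEvent]:
    """Two-threshold spindle detection on a cubed-RMS envelope.

    Baseline = mean envelope over NREMS samples (``params.baseline_scope``).
    Candidates are maximal runs above lower_thresh that contain at least one
    sample above upper_thresh; candidates closer than ``min_isi_s`` merge;
    survivors must last ``min_dur_s``..``max_dur_s`` and start inside NREMS
    (or lie fully inside it when ``containment="full"``).
    """
    env = np.asarray(envelope, dtype=float)
    epoch_samples = int(round(hypnogram.epoch_len * fs))
    nrems_epochs = hypnogram.state_mask(VigilanceState.NREMS)
    sample_state = np.repeat(hypnogram.states, epoch_samples)[: env.size]
    nrems_samples = sample_state == int(VigilanceState.NREMS)
    if not nrems_epochs.any():
        import warnings

        warnings.warn("no NREMS in hypnogram; no spindles detectable", stacklevel=2)
        return []
    scope = nrems_samples if params.baseline_scope == "nrems" else np.ones_like(env, bool)
    baseline = env[scope].mean()
    lower = params.lower_thresh_mult * baseline
    upper = params.upper_thresh_mult * baseline

    above = env > lower
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [env.size]))
    # keep only excursions reaching the upper threshold
    cands = [(a, b) for a, b in zip(starts, ends) if env[a:b].max() > upper]
    # merge candidates separated by less than the inter-spindle interval
    merged: list[list[int]] = []
    min_gap = params.min_isi_s * fs
    for a, b in cands:
        if merged and a - merged[-1][1] < min_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    events: list[SpindleEvent] = []
    nrems_bout_index = _nrems_bout_indices(hypnogram)
    for a, b in merged:
        dur = (b - a) / fs
        if not (params.min_dur_s <= dur <= params.max_dur_s):
            continue
        if params.containment == "full":
            if not nrems_samples[a:b].all():
                continue
        elif not nrems_samples[a]:
            continue
        epoch = min(a // epoch_samples, hypnogram.n_epochs - 1)
        events.append(
            SpindleEvent(
                start_s=a / fs,
                end_s=b / fs,
                peak=float(env[a:b].max()),
                bout_index=int(nrems_bout_index[epoch]),
            )
        )
    return events


def _nrems_bout_indices(hypnogram: Hypnogram) -> np.ndarray:
    """Per-epoch index of the containing NREMS bout (-1 outside NREMS)."""
    s = hypnogram.states
    is_n = s == int(VigilanceState.NREMS)
    bout_start = is_n & np.concatenate(([True], s[1:] != s[:-1]))
    idx = np.cumsum(bout_start) - 1
    return np.where(is_n, idx, -1)


def detect_in_recording(
    eeg: np.ndarray,
    hypnogram: Hypnogram,
    fs: float,
    params: SpindleParams = SpindleParams(),
) -> list[SpindleEvent]:
    """Convenience: sigma filter + envelope + detection on raw EEG."""
    filtered = sigma_filter(eeg, fs, params)
    env = cubed_rms_envelope(filtered, fs, params.rms_window_s)
    return detect_spindles(env, hypnogram, fs, params)


@dataclass
class SpindleStats:
    phase: str
    amount: int
    nrems_minutes: float
    density_per_min: float | None  # None when no NREMS time in phase
    mean_duration_s: float | None  # None when no events
    binned_counts: dict[str, int] = field(default_factory=dict)


def spindle_stats(
    events: list[SpindleEvent] | list[tuple[float, float]],
    hypnogram: Hypnogram,
) -> dict[str, SpindleStats]:
    """Per-phase spindle amount, density per NREMS minute, mean duration and
    2 h-binned counts (event phase/bin from its start time)."""
    sched = hypnogram.schedule
    zt = hypnogram.epoch_zt_hours()
    el_min = hypnogram.epoch_len / 60.0
    pairs = [
        (e.start_s, e.end_s) if isinstance(e, SpindleEvent) else (float(e[0]), float(e[1]))
        for e in events
    ]
    start_h = np.array([hypnogram.start_zt + s / 3600.0 for s, _ in pairs])
    durations = np.array([b - a for a, b in pairs])
    edges = list(np.arange(0.0, sched.session_h, 2.0)) + [sched.session_h]
    out = {}
    for phase in ("light", "dark"):
        lo, hi = (0.0, sched.light_h) if phase == "light" else (sched.light_h, sched.session_h)
        in_phase = (start_h >= lo) & (start_h < hi) if pairs else np.array([], bool)
        amount = int(in_phase.sum())
        nrems_min = float(
            np.sum(hypnogram.state_mask(VigilanceState.NREMS) & hypnogram.phase_mask(phase))
            * el_min
        )
        binned = {}
        for a, b in zip(edges[:-1], edges[1:]):
            if not (a >= lo - 1e-9 and b <= hi + 1e-9):
                continue
            sel = in_phase & (start_h >= a) & (start_h < b) if pairs else in_phase
            binned[f"ZT{a:g}-{b:g}"] = int(np.sum(sel)) if pairs else 0
        out[phase] = SpindleStats(
            phase=phase,
            amount=amount,
            nrems_minutes=nrems_min,
            density_per_min=(amount / nrems_min) if nrems_min > 0 else None,
            mean_duration_s=float(durations[in_phase].mean()) if amount else None,
            binned_counts=binned,
        )
    return out


def events_table(events: list[SpindleEvent], hypnogram: Hypnogram) -> pd.DataFrame:
    sched = hypnogram.schedule
    rows = []
    for e in events:
        zt_h = hypnogram.start_zt + e.start_s / 3600.0
        rows.append(
            (
                e.start_s,
                e.end_s,
                e.duration_s,
                e.peak,
                "light" if zt_h < sched.light_h else "dark",
            )
        )
    return pd.DataFrame(rows, columns=["start_s", "end_s", "duration_s", "peak", "phase"])
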