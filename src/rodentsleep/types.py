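"""Core domain containers shared across the pipeline.

A recording session is aligned to Zeitgeber time (ZT): ZT0 = lights on.
The default schedule is 12 h light + 11 h dark = 23 h (the last hour of
the nominal 12 h dark phase is not recorded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class VigilanceState(IntEnum):
    """Vigilance state of a rodent: wakefulness, NREM sleep, REM sleep."""

    WAKE = 0
    NREMS = 1
    REMS = 2

    @property
    def label(self) -> str:
        return self.name


#: canonical state ordering used for vectors/matrices indexed by state
STATES: tuple[VigilanceState, ...] = (
    VigilanceState.WAKE,
    VigilanceState.NREMS,
    VigilanceState.REMS,
)

STATE_LABELS: tuple[str, str, str] = ("WAKE", "NREMS", "REMS")


def state_from_label(token: str) -> VigilanceState:
    """Parse a state token (case-insensitive; 'W'/'N'/'R' accepted)."""
    t = token.strip().upper()
    aliases = {"W": "WAKE", "N": "NREMS", "R": "REMS", "NREM": "NREMS", "REM": "REMS"}
    t = aliases.get(t, t)
    if t not in STATE_LABELS:
        raise ValueError(
            f"unknown vigilance state token {token!r}; allowed: "
            f"{', '.join(STATE_LABELS)} (or W/N/R)"
        )
    return VigilanceState[t]


@dataclass(frozen=True)
class LightDarkSchedule:
    """Light/dark structure of a session, in hours since lights-on (ZT0)."""

    light_h: float = 12.0
    dark_h: float = 11.0

    def __post_init__(self) -> None:
        if self.light_h <= 0 or self.dark_h <= 0:
            raise ValueError("light_h and dark_h must be positive")

    @property
    def session_h(self) -> float:
        return self.light_h + self.dark_h

    def phase_of(self, zt_hours):
        """Return 'light'/'dark' labels for ZT hour(s)."""
        zt = np.asarray(zt_hours, dtype=float)
        out = np.where(zt < self.light_h, "light", "dark")
        return out if out.ndim else str(out)


@dataclass
class Hypnogram:
    """Sequence of vigilance states, one per fixed-length scoring epoch."""

    states: np.ndarray  # int8 codes, see VigilanceState
    epoch_len: float = 4.0
    start_zt: float = 0.0
    schedule: LightDarkSchedule = field(default_factory=LightDarkSchedule)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1 or self.states.size == 0:
            raise ValueError("hypnogram must be a non-empty 1-D state sequence")
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        if not np.isin(self.states, [s.value for s in STATES]).all():
            raise ValueError("hypnogram contains invalid state codes")
        span_h = self.start_zt + self.states.size * self.epoch_len / 3600.0
        if span_h > self.schedule.session_h + 1e-9:
            raise ValueError(
                f"hypnogram spans {span_h:.3f} h from ZT{self.start_zt}, "
                f"exceeding the {self.schedule.session_h} h session"
            )

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    def epoch_zt_hours(self) -> np.ndarray:
        """ZT hour of each epoch's leading edge."""
        return self.start_zt + np.arange(self.n_epochs) * self.epoch_len / 3600.0

    def phase_mask(self, phase: str) -> np.ndarray:
        """Boolean mask of epochs whose leading edge lies in 'light' or 'dark'."""
        if phase not in ("light", "dark"):
            raise ValueError("phase must be 'light' or 'dark'")
        zt = self.epoch_zt_hours()
        light = zt < self.schedule.light_h
        return light if phase == "light" else ~light

    def state_mask(self, state: VigilanceState) -> np.ndarray:
        return self.states == int(state)

    def __len__(self) -> int:
        return self.n_epochs

    def __eq__(self, other) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            np.array_equal(self.states, other.states)
            and self.epoch_len == other.epoch_len
            and self.start_zt == other.start_zt
            and self.schedule == other.schedule
        )


@dataclass
class Recording:
    """Two-channel (EEG, EMG) signal with sampling rate and ZT alignment."""

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    start_zt: float = 0.0
    schedule: LightDarkSchedule = field(default_factory=LightDarkSchedule)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.ndim != 1 or self.emg.ndim != 1:
            raise ValueError("eeg and emg must be 1-D sample vectors")
        if self.eeg.size != self.emg.size:
            raise ValueError("eeg and emg must have equal length")
        if self.eeg.size == 0:
            raise ValueError("recording is empty")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.eeg.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochedSignal:
    """Non-overlapping, contiguous fixed-length segments of one channel."""

    epochs: np.ndarray  # (n_epochs, samples_per_epoch)
    epoch_len: float
    fs: float

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 2:
            raise ValueError("epochs must be a 2-D (n_epochs x samples) matrix")
        expected = self.epoch_len * self.fs
        if abs(expected - round(expected)) > 1e-9 or self.epochs.shape[1] != round(expected):
            raise ValueError(
                f"samples per epoch ({self.epochs.shape[1]}) must equal "
                f"epoch_len*fs ({expected})"
            )

    @property
    def n_epochs(self) -> int:
        return int(self.epochs.shape[0])

    @property
    def samples_per_epoch(self) -> int:
        return int(self.epochs.shape[1])
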