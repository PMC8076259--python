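"""Sleep-architecture metrics from a hypnogram.

Covers everything a circadian sleep study reads off the scored session:
state percentages in 2 h and light/dark bins, bout numbers and durations,
transition counts and percentage distributions, sleep latencies at light
onset (first-5-bout rule) and the dark-period REM latency, and the
light-to-dark diurnal change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Hypnogram, STATE_LABELS, VigilanceState

#: ordered transition keys as displayed in architecture reports
TRANSITION_KEYS = ("W/N", "N/W", "N/R", "R/N", "R/W", "W/R")
_PAIR_TO_KEY = {
    (0, 1): "W/N",
    (1, 0): "N/W",
    (1, 2): "N/R",
    (2, 1): "R/N",
    (2, 0): "R/W",
    (0, 2): "W/R",
}


@dataclass(frozen=True)
class Bout:
    """Maximal run of consecutive epochs in one state."""

    state: VigilanceState
    start_epoch: int
    n_epochs: int
    start_zt: float  # seconds from ZT0
    duration: float  # seconds


@dataclass
class TransitionSummary:
    total: int
    counts: dict[str, int]
    percentages: dict[str, float]


@dataclass
class BinnedPercentages:
    """State percentages per circadian bin; each bin's three values sum to 100."""

    bin_labels: list[str]
    bin_edges_h: list[tuple[float, float]]
    percent: np.ndarray  # (n_bins, 3) ordered WAKE, NREMS, REMS

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.percent, columns=list(STATE_LABELS))
        df.insert(0, "bin", self.bin_labels)
        return df

    def by_state(self, state: VigilanceState) -> np.ndarray:
        return self.percent[:, int(state)]


@dataclass
class LatencyResult:
    state: VigilanceState
    k: int
    onsets_min: list[float] = field(default_factory=list)
    latency_min: float | None = None

    @property
    def insufficient(self) -> bool:
        return self.latency_min is None


def extract_bouts(hypnogram: Hypnogram) -> list[Bout]:
    """Run-length encode the hypnogram; bouts tile it exactly."""
    s = hypnogram.states
    edges = np.flatnonzero(np.diff(s)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [s.size]))
    el = hypnogram.epoch_len
    t0 = hypnogram.start_zt * 3600.0
    return [
        Bout(
            state=VigilanceState(int(s[a])),
            start_epoch=int(a),
            n_epochs=int(b - a),
            start_zt=t0 + a * el,
            duration=(b - a) * el,
        )
        for a, b in zip(starts, ends)
    ]


def bout_phase(bout: Bout, hypnogram: Hypnogram) -> str:
    """Phase containing the bout's first epoch (straddlers go to their start phase)."""
    return "light" if bout.start_zt / 3600.0 < hypnogram.schedule.light_h else "dark"


def bouts_in_phase(hypnogram: Hypnogram, phase: str) -> list[Bout]:
    if phase not in ("light", "dark"):
        raise ValueError("phase must be 'light' or 'dark'")
    return [b for b in extract_bouts(hypnogram) if bout_phase(b, hypnogram) == phase]


def state_percentages(hypnogram: Hypnogram, bins: str = "2h") -> BinnedPercentages:
    """Percent of epochs per state in circadian bins.

    ``bins="2h"``: edges at ZT 0,2,...,22 and session end (the final dark bin
    spans 1 h for a 23 h session). ``bins="phase"``: one light and one dark bin.
    """
    zt = hypnogram.epoch_zt_hours()
    sched = hypnogram.schedule
    if bins == "2h":
        edges = list(np.arange(0.0, sched.session_h, 2.0)) + [sched.session_h]
        labels = [f"ZT{a:g}-{b:g}" for a, b in zip(edges[:-1], edges[1:])]
    elif bins == "phase":
        edges = [0.0, sched.light_h, sched.session_h]
        labels = ["light", "dark"]
    else:
        raise ValueError("bins must be '2h' or 'phase'")
    end_zt = hypnogram.start_zt + hypnogram.n_epochs * hypnogram.epoch_len / 3600.0
    rows = []
    pairs = []
    kept_labels = []
    for (a, b), label in zip(zip(edges[:-1], edges[1:]), labels):
        if a >= end_zt - 1e-12:
            continue  # bin entirely past the recording: dropped
        sel = (zt >= a - 1e-12) & (zt < b - 1e-12)
        n = sel.sum()
        if n == 0:
            raise ValueError(f"empty circadian bin ZT{a}-{b}")
        rows.append([100.0 * np.sum(hypnogram.states[sel] == st) / n for st in range(3)])
        pairs.append((a, b))
        kept_labels.append(label)
    return BinnedPercentages(
        bin_labels=kept_labels, bin_edges_h=pairs, percent=np.array(rows)
    )


def transition_summary(hypnogram: Hypnogram, phase: str) -> TransitionSummary:
    """Transitions between bouts whose *second* bout starts within ``phase``."""
    bouts = extract_bouts(hypnogram)
    counts = {k: 0 for k in TRANSITION_KEYS}
    total = 0
    for prev, nxt in zip(bouts[:-1], bouts[1:]):
        if bout_phase(nxt, hypnogram) != phase:
            continue
        key = _PAIR_TO_KEY[(int(prev.state), int(nxt.state))]
        counts[key] += 1
        total += 1
    if total == 0:
        return TransitionSummary(total=0, counts=counts, percentages={})
    pct = {k: 100.0 * v / total for k, v in counts.items()}
    return TransitionSummary(total=total, counts=counts, percentages=pct)


def sleep_latency(
    hypnogram: Hypnogram,
    state: VigilanceState,
    k: int = 5,
    from_zt: float = 0.0,
    min_bout_s: float = 12.0,
) -> LatencyResult:
    """Mean onset time of the first ``k`` qualifying bouts after ``from_zt``.

    A qualifying bout lasts at least ``min_bout_s`` (12 s = 3 epochs) of
    consecutive time in ``state``. Onsets are minutes from ``from_zt``. If
    fewer than ``k`` such bouts exist the result is flagged insufficient.
    """
    t0 = from_zt * 3600.0
    onsets = [
        (b.start_zt - t0) / 60.0
        for b in extract_bouts(hypnogram)
        if b.state == state and b.duration >= min_bout_s - 1e-9 and b.start_zt >= t0 - 1e-9
    ]
    if len(onsets) < k:
        return LatencyResult(state=state, k=k, onsets_min=onsets, latency_min=None)
    first = onsets[:k]
    return LatencyResult(
        state=state, k=k, onsets_min=first, latency_min=float(np.mean(first))
    )


def rems_latency_dark(hypnogram: Hypnogram, k: int = 1) -> LatencyResult:
    """Latency (min) from dark onset to the first ``k`` REMS bout(s)."""
    return sleep_latency(
        hypnogram,
        VigilanceState.REMS,
        k=k,
        from_zt=hypnogram.schedule.light_h,
    )


def diurnal_change(phase_pct: BinnedPercentages) -> dict[str, float]:
    """Dark-minus-light change per state; the three changes sum to 0."""
    if phase_pct.bin_labels != ["light", "dark"]:
        raise ValueError("diurnal_change expects phase-binned percentages")
    light, dark = phase_pct.percent
    return {lab: float(dark[i] - light[i]) for i, lab in enumerate(STATE_LABELS)}


def architecture_table(hypnogram: Hypnogram, animal_id: str = "animal") -> pd.DataFrame:
    """Long-format per-animal metric table (one row per phase x metric)."""
    rows = []
    phase_pct = state_percentages(hypnogram, bins="phase")
    for pi, phase in enumerate(phase_pct.bin_labels):
        for st, lab in enumerate(STATE_LABELS):
            rows.append((animal_id, phase, f"percent_{lab}", phase_pct.percent[pi, st]))
        bouts = bouts_in_phase(hypnogram, phase)
        for st, lab in enumerate(STATE_LABELS):
            sb = [b for b in bouts if int(b.state) == st]
            rows.append((animal_id, phase, f"bouts_{lab}", float(len(sb))))
            rows.append(
                (
                    animal_id,
                    phase,
                    f"bout_duration_min_{lab}",
                    float(np.mean([b.duration for b in sb]) / 60.0) if sb else np.nan,
                )
            )
        trans = transition_summary(hypnogram, phase)
        rows.append((animal_id, phase, "transitions_total", float(trans.total)))
        for key in TRANSITION_KEYS:
            rows.append(
                (
                    animal_id,
                    phase,
                    f"transition_pct_{key.replace('/', '_')}",
                    trans.percentages.get(key, np.nan),
                )
            )
    nrem_lat = sleep_latency(hypnogram, VigilanceState.NREMS)
    rem_lat = sleep_latency(hypnogram, VigilanceState.REMS)
    dark_rem = rems_latency_dark(hypnogram)
    rows.append(("", "light", "nrems_latency_min", np.nan if nrem_lat.insufficient else nrem_lat.latency_min))
    rows.append(("", "light", "rems_latency_min", np.nan if rem_lat.insufficient else rem_lat.latency_min))
    rows.append(("", "dark", "rems_latency_dark_min", np.nan if dark_rem.insufficient else dark_rem.latency_min))
    df = pd.DataFrame(rows, columns=["animal", "phase", "metric", "value"])
    df["animal"] = animal_id
    return df
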