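"""Ground-truthed synthetic hypnograms and EEG/EMG recordings.

The generator emulates the statistical structure the analysis assumes for
two inbred mouse strains: a semi-Markov vigilance-state process with
geometric dwell times at 4 s epoch resolution and phase-dependent
parameters (light vs dark), state-specific EEG spectral signatures (NREMS
delta dominance, a REMS ~8 Hz theta peak, WAKE broadband), state-ranked EMG
tone, and 11 Hz spindle bursts injected into NREMS at a per-profile rate.

The two presets encode the published strain contrast: the "S1-like" profile
sleeps more and is more fragmented in the dark period, falls asleep later
at light onset, has a flatter NREMS spectrum (less delta, more theta), a
damped REMS 8 Hz peak, and longer spindles; the "BL6-like" profile shows
the strong diurnal rhythm of a typical control strain. Dwell means and
occupancies are set to the published per-strain medians of bout durations
and state percentages per phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .types import Hypnogram, LightDarkSchedule, Recording, VigilanceState


@dataclass(frozen=True)
class PhaseDynamics:
    """State occupancy and mean bout duration for one light/dark phase."""

    occupancy: tuple[float, float, float]  # stationary P(WAKE, NREMS, REMS)
    mean_bout_s: tuple[float, float, float]  # mean dwell per state, seconds

    def validate(self, epoch_len: float) -> None:
        occ = np.asarray(self.occupancy, float)
        if (occ < 0).any() or abs(occ.sum() - 1.0) > 1e-6:
            raise ValueError("occupancies must be non-negative and sum to 1")
        if (np.asarray(self.mean_bout_s) <= epoch_len).any():
            raise ValueError(f"mean bout durations must exceed one epoch ({epoch_len} s)")


@dataclass(frozen=True)
class SpectralWeights:
    """Amplitude weights per band for one state's EEG noise shaping."""

    delta: float = 1.0
    theta: float = 1.0
    alpha: float = 1.0
    eta: float = 1.0
    pink: float = 1.0  # 1/f backbone amplitude
    peak8: float = 0.0  # narrowband ~8 Hz component (REMS theta peak)


@dataclass(frozen=True)
class StrainProfile:
    name: str
    light: PhaseDynamics
    dark: PhaseDynamics
    spectral: dict[str, SpectralWeights]  # keys WAKE/NREMS/REMS
    emg_amplitude: tuple[float, float, float] = (3.0, 1.0, 0.6)
    spindle_rate_per_min: float = 5.5
    spindle_mean_dur_s: float = 1.9
    spindle_amp_mult: float = 5.0  # burst RMS as multiple of NREMS sigma RMS
    sleep_latency_offset_min: float = 0.0

    def validate(self, epoch_len: float = 4.0) -> None:
        self.light.validate(epoch_len)
        self.dark.validate(epoch_len)
        if self.spindle_rate_per_min < 0:
            raise ValueError("spindle rate must be >= 0")
        if not (0.5 <= self.spindle_mean_dur_s <= 10.0):
            raise ValueError("mean spindle duration must lie in [0.5, 10] s")
        w, n, r = self.emg_amplitude
        if not (w > n >= r):
            raise ValueError("EMG amplitudes must rank WAKE > NREMS >= REMS")
        for phase in (self.light, self.dark):
            _embedded_chain(phase, epoch_len)  # raises if infeasible


@dataclass
class GroundTruth:
    hypnogram: Hypnogram
    spindle_events: list[tuple[float, float]]
    profile: StrainProfile
    seed: int


# ---------------------------------------------------------------------------
# presets (occupancies and dwell means = published per-strain medians)
# ---------------------------------------------------------------------------

S1_LIKE = StrainProfile(
    name="S1-like",
    light=PhaseDynamics(
        occupancy=(0.355, 0.590, 0.055),
        mean_bout_s=(207.8, 243.0, 37.2),
    ),
    dark=PhaseDynamics(
        occupancy=(0.531, 0.431, 0.038),
        mean_bout_s=(384.7, 206.4, 35.8),
    ),
    spectral={
        "WAKE": SpectralWeights(delta=1.0, theta=1.3, alpha=0.9, eta=0.7, pink=0.8),
        "NREMS": SpectralWeights(delta=2.2, theta=1.1, alpha=1.0, eta=0.45, pink=0.6),
        "REMS": SpectralWeights(delta=0.6, theta=1.0, alpha=0.6, eta=0.35, pink=0.5, peak8=2.6),
    },
    spindle_rate_per_min=5.3,
    spindle_mean_dur_s=2.0,
    sleep_latency_offset_min=12.0,
)

BL6_LIKE = StrainProfile(
    name="BL6-like",
    light=PhaseDynamics(
        occupancy=(0.3346, 0.6242, 0.0412),
        mean_bout_s=(246.8, 232.5, 29.6),
    ),
    dark=PhaseDynamics(
        occupancy=(0.8503, 0.1427, 0.0070),
        mean_bout_s=(1013.4, 161.7, 26.5),
    ),
    spectral={
        "WAKE": SpectralWeights(delta=1.1, theta=1.2, alpha=0.8, eta=0.6, pink=0.8),
        "NREMS": SpectralWeights(delta=3.0, theta=0.8, alpha=0.9, eta=0.3, pink=0.6),
        "REMS": SpectralWeights(delta=0.6, theta=1.0, alpha=0.5, eta=0.3, pink=0.5, peak8=3.6),
    },
    spindle_rate_per_min=5.6,
    spindle_mean_dur_s=1.8,
    sleep_latency_offset_min=0.0,
)

PRESETS = {"S1-like": S1_LIKE, "BL6-like": BL6_LIKE}


# ---------------------------------------------------------------------------
# semi-Markov hypnogram generation
# ---------------------------------------------------------------------------

def _embedded_chain(phase: PhaseDynamics, epoch_len: float):
    """Per-epoch exit probabilities and embedded transition matrix.

    The embedded (bout-to-bout) chain is solved so that the long-run state
    occupancy equals ``phase.occupancy`` given geometric dwells with the
    requested means. WAKE->REMS transitions are structurally excluded, which
    constrains the admissible parameter region; infeasible combinations
    raise with the violated condition.
    """
    occ = np.asarray(phase.occupancy, float)
    m = np.asarray(phase.mean_bout_s, float) / epoch_len  # dwell means in epochs
    active = occ > 0
    if active.sum() == 1:
        # degenerate chain: a single state that never leaves
        P = np.eye(3)
        return np.where(active, 1.0 / m, 1.0), P, occ
    if active.sum() == 2:
        # alternating two-state chain: bout frequencies are forced equal, so
        # the occupancy ratio must match the dwell ratio
        i, j = np.flatnonzero(active)
        if abs(occ[i] / occ[j] - m[i] / m[j]) > 0.05 * (m[i] / m[j]):
            raise ValueError(
                "infeasible two-state dynamics: occupancy ratio must equal "
                "the dwell-time ratio for an alternating chain"
            )
        P = np.eye(3)
        P[i, i], P[i, j] = 0.0, 1.0
        P[j, j], P[j, i] = 0.0, 1.0
        q = np.zeros(3)
        q[i] = q[j] = 0.5
        return 1.0 / m, P, q
    q = occ / m
    q = q / q.sum()  # embedded-chain stationary frequencies
    qW, qN, qR = q
    if qN > 0.5 + 1e-9:
        raise ValueError(
            "infeasible dynamics: NREMS bout frequency exceeds 1/2 (every "
            "NREMS bout must border WAKE or REMS)"
        )
    if qW > qN + 1e-9 or qR > qN + 1e-9:
        raise ValueError(
            "infeasible dynamics: WAKE and REMS bout frequencies cannot "
            "exceed the NREMS bout frequency when WAKE->REMS is excluded"
        )
    p_nr = qR / qN if qN > 0 else 0.0
    p_rw = (qW - qN + qR) / qR if qR > 0 else 0.0
    if not -1e-9 <= p_rw <= 1 + 1e-9:
        raise ValueError("infeasible dynamics: REMS->WAKE probability outside [0, 1]")
    P = np.array(
        [
            [0.0, 1.0, 0.0],  # WAKE -> NREMS always (no WAKE->REMS)
            [1.0 - p_nr, 0.0, p_nr],
            [np.clip(p_rw, 0, 1), 1.0 - np.clip(p_rw, 0, 1), 0.0],
        ]
    )
    exit_p = 1.0 / m  # geometric dwell hazard per epoch
    return exit_p, P, q


def generate_hypnogram(
    profile: StrainProfile,
    duration_s: float = 23 * 3600.0,
    epoch_len: float = 4.0,
    schedule: LightDarkSchedule | None = None,
    seed: int = 0,
) -> Hypnogram:
    """Simulate a semi-Markov hypnogram with phase-dependent dynamics.

    Dwell times are geometric at epoch resolution, so the process is
    memoryless and the light->dark parameter switch simply changes the
    per-epoch hazard mid-bout. The profile's sleep-latency offset forces
    WAKE for its duration at light onset before the chain starts.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n_epochs = duration_s / epoch_len
    if abs(n_epochs - round(n_epochs)) > 1e-9:
        raise ValueError(f"duration {duration_s} s not a multiple of epoch_len {epoch_len} s")
    n_epochs = int(round(n_epochs))
    schedule = schedule or LightDarkSchedule()
    profile.validate(epoch_len)
    rng = np.random.default_rng(seed)

    light_dyn = _embedded_chain(profile.light, epoch_len)
    dark_dyn = _embedded_chain(profile.dark, epoch_len)
    boundary = int(round(schedule.light_h * 3600.0 / epoch_len))  # first dark epoch

    states = np.empty(n_epochs, dtype=np.int8)
    offset_epochs = min(
        int(round(profile.sleep_latency_offset_min * 60.0 / epoch_len)), n_epochs
    )
    states[:offset_epochs] = int(VigilanceState.WAKE)
    i = offset_epochs
    if i >= n_epochs:
        return Hypnogram(states, epoch_len, 0.0, schedule)

    exit_p, P, q = light_dyn if i < boundary else dark_dyn
    if offset_epochs > 0:
        state = int(VigilanceState.WAKE)
    else:
        # stationary start in the entry phase
        start_dyn = profile.light if i < boundary else profile.dark
        state = int(rng.choice(3, p=np.asarray(start_dyn.occupancy, float)))
    while i < n_epochs:
        exit_p, P, q = light_dyn if i < boundary else dark_dyn
        # dwell in current phase; a geometric draw past the phase boundary is
        # truncated there and the dwell resumes under the new phase's hazard
        dwell = rng.geometric(exit_p[state])
        phase_end = boundary if i < boundary else n_epochs
        run = min(dwell, phase_end - i, n_epochs - i)
        states[i : i + run] = state
        i += run
        if run == dwell and i < n_epochs:
            # genuine bout end: draw the next state under the phase at entry
            _, P_next, _ = light_dyn if i < boundary else dark_dyn
            state = int(rng.choice(3, p=P_next[state]))
        # else: phase boundary truncation - same state continues, new hazard
    return Hypnogram(states, epoch_len, 0.0, schedule)


# ---------------------------------------------------------------------------
# ground-truth spindle events
# ---------------------------------------------------------------------------

def generate_spindle_events(
    hypnogram: Hypnogram,
    profile: StrainProfile,
    seed: int | np.random.Generator = 0,
    min_gap_s: float = 0.3,
) -> list[tuple[float, float]]:
    """Sample ground-truth spindle intervals inside NREMS bouts.

    Events form a renewal process with exponential gaps tuned so the
    expected count is ``spindle_rate_per_min`` per NREMS minute; durations
    are normal around the profile mean (sd = 15%), clipped to [0.5, 10] s
    and to the containing bout. Gaps never drop below ``min_gap_s`` so
    ground-truth events cannot merge under the detector's 0.1 s ISI rule.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = profile.spindle_rate_per_min
    if rate <= 0:
        return []
    mean_period = 60.0 / rate
    mean_gap = mean_period - profile.spindle_mean_dur_s
    if mean_gap <= min_gap_s:
        raise ValueError("spindle rate too high for the requested mean duration")
    events: list[tuple[float, float]] = []
    el = hypnogram.epoch_len
    s = hypnogram.states
    edges = np.flatnonzero(np.diff(s)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [s.size]))
    for a, b in zip(starts, ends):
        if s[a] != int(VigilanceState.NREMS):
            continue
        t = a * el + min_gap_s + rng.exponential(mean_gap - min_gap_s)
        bout_end = b * el
        while True:
            dur = float(
                np.clip(rng.normal(profile.spindle_mean_dur_s, 0.15 * profile.spindle_mean_dur_s),
                        0.5, 10.0)
            )
            if t + dur > bout_end:
                break
            events.append((float(t), float(t + dur)))
            t = t + dur + min_gap_s + rng.exponential(mean_gap - min_gap_s)
    return events


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

_BAND_NODES = {  # (Hz, attribute) control points for amplitude interpolation
    "delta": (1.0, 5.0),
    "theta": (6.0, 9.0),
    "alpha": (10.0, 15.0),
    "eta": (16.0, 22.75),
}


def _amplitude_weights(freqs: np.ndarray, w: SpectralWeights) -> np.ndarray:
    """Per-frequency amplitude shaping: 1/f backbone x band weights + 8 Hz peak."""
    xp = [0.0, 0.5]
    fp = [w.delta, w.delta]
    for name, (lo, hi) in _BAND_NODES.items():
        g = getattr(w, name)
        xp.extend([lo, hi])
        fp.extend([g, g])
    xp.extend([30.0, max(40.0, freqs[-1] + 1)])
    fp.extend([0.2, 0.1])
    band = np.interp(freqs, xp, fp)
    pink = w.pink / np.sqrt(np.maximum(freqs, 0.5))
    amp = band * pink
    if w.peak8:
        amp = amp + w.peak8 * np.exp(-0.5 * ((freqs - 8.0) / 0.5) ** 2) / np.sqrt(8.0)
    return amp


def _shaped_noise(length: int, fs: float, w: SpectralWeights,
                  rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(length)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(length, 1.0 / fs)
    spec *= _amplitude_weights(freqs, w)
    x = np.fft.irfft(spec, n=length)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_recording(
    truth_base: Hypnogram,
    profile: StrainProfile,
    fs: float = 250.0,
    seed: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Synthesize an EEG/EMG recording realizing ``truth_base``.

    EEG: per-bout spectrally shaped noise (unit RMS) per state, plus
    Hann-windowed 11 Hz bursts at the ground-truth spindle times with RMS
    ``spindle_amp_mult`` x the NREMS sigma-band (10-15 Hz) background RMS.
    EMG: white noise with state-ranked amplitude. Deterministic per seed.
    """
    if fs < 2 * 25.0:
        raise ValueError("fs must be at least twice the highest synthesized band (~25 Hz)")
    rng = np.random.default_rng(seed)
    el = truth_base.epoch_len
    spe = int(round(el * fs))
    n = truth_base.n_epochs * spe
    eeg = np.empty(n)
    emg = np.empty(n)
    s = truth_base.states
    edges = np.flatnonzero(np.diff(s)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [s.size]))
    for a, b in zip(starts, ends):
        st = VigilanceState(int(s[a])).name
        lo, hi = a * spe, b * spe
        eeg[lo:hi] = _shaped_noise(hi - lo, fs, profile.spectral[st], rng)
        emg[lo:hi] = profile.emg_amplitude[int(s[a])] * rng.standard_normal(hi - lo)

    events = generate_spindle_events(truth_base, profile, rng)
    if events:
        from .spindles import sigma_filter

        nrems_samples = np.repeat(s == int(VigilanceState.NREMS), spe)
        bg = sigma_filter(eeg, fs)
        bg_rms = float(np.sqrt(np.mean(bg[nrems_samples] ** 2)))
        from scipy.signal import windows

        for t0, t1 in events:
            i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
            # waxing/waning taper over ~0.375 s each side (half the detector's
            # RMS window, so a threshold crossing is centred on the true onset);
            # bursts shorter than twice the ramp degenerate to a Hann taper
            alpha = min(1.0, 2 * 0.375 / (t1 - t0))
            tt = np.arange(i0, i1) / fs
            burst = np.sin(2 * np.pi * 11.0 * tt) * windows.tukey(i1 - i0, alpha)
            burst_rms = np.sqrt(np.mean(burst**2))
            eeg[i0:i1] += burst * (profile.spindle_amp_mult * bg_rms / burst_rms)
    rec = Recording(eeg=eeg, emg=emg, fs=fs, start_zt=truth_base.start_zt,
                    schedule=truth_base.schedule)
    truth = GroundTruth(hypnogram=truth_base, spindle_events=events,
                        profile=profile, seed=seed if isinstance(seed, int) else -1)
    return rec, truth


# ---------------------------------------------------------------------------
# cohorts and profile serialization
# ---------------------------------------------------------------------------

def generate_cohort(
    profile: StrainProfile,
    n_animals: int,
    seed: int = 0,
    duration_s: float = 23 * 3600.0,
    epoch_len: float = 4.0,
    schedule: LightDarkSchedule | None = None,
    with_events: bool = True,
) -> list[GroundTruth]:
    """Independent animals from one profile (seeds derived from ``seed``)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_animals):
        sub = int(rng.integers(0, 2**31 - 1))
        hyp = generate_hypnogram(profile, duration_s, epoch_len, schedule, seed=sub)
        events = (
            generate_spindle_events(hyp, profile, seed=sub + 1) if with_events else []
        )
        out.append(GroundTruth(hypnogram=hyp, spindle_events=events,
                               profile=profile, seed=sub))
    return out


def profile_to_yaml(profile: StrainProfile, path) -> None:
    d = asdict(profile)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def profile_from_yaml(path) -> StrainProfile:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["light"] = PhaseDynamics(
        occupancy=tuple(d["light"]["occupancy"]),
        mean_bout_s=tuple(d["light"]["mean_bout_s"]),
    )
    d["dark"] = PhaseDynamics(
        occupancy=tuple(d["dark"]["occupancy"]),
        mean_bout_s=tuple(d["dark"]["mean_bout_s"]),
    )
    d["spectral"] = {k: SpectralWeights(**v) for k, v in d["spectral"].items()}
    d["emg_amplitude"] = tuple(d["emg_amplitude"])
    prof = StrainProfile(**d)
    prof.validate()
    return prof
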