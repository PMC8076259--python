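"""Per-epoch EEG spectral analysis on a 0.25 Hz grid.

Each 4 s scoring epoch (500 samples at 125 Hz) yields one Hamming-windowed
periodogram — at this epoch length the 0.25 Hz resolution requirement
forces Welch's method down to a single segment. Spectra are normalized
per epoch by total power, aggregated as median/IQR per state and phase,
and summed over the conventional rodent bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .types import EpochedSignal, Hypnogram, VigilanceState

#: rodent EEG frequency bands (Hz, edges inclusive, on the 0.25 Hz grid)
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 5.0),
    "theta": (6.0, 9.0),
    "alpha": (10.0, 15.0),
    "eta": (16.0, 22.75),
}

REPORT_RANGE = (1.0, 22.75)


@dataclass
class EpochSpectra:
    """Per-epoch power on the uniform 0.25 Hz frequency grid."""

    frequencies: np.ndarray  # bin centers, 0 .. fs/2
    power: np.ndarray  # (n_epochs, n_bins)
    normalized: bool = False
    valid: np.ndarray | None = None  # epochs with positive total power

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    @property
    def n_epochs(self) -> int:
        return int(self.power.shape[0])


def highpass_epochs(epochs: EpochedSignal, cutoff: float = 1.0, order: int = 4) -> EpochedSignal:
    """Zero-phase high-pass per epoch, suppressing movement artifacts < cutoff."""
    nyq = epochs.fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz not below Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff, btype="highpass", fs=epochs.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.epochs, axis=-1)
    return EpochedSignal(epochs=filtered, epoch_len=epochs.epoch_len, fs=epochs.fs)


def epoch_psd(epochs: EpochedSignal, window: str = "hamming") -> EpochSpectra:
    """One-sided PSD per epoch at 0.25 Hz resolution (single-segment Welch)."""
    n = epochs.samples_per_epoch
    df = epochs.fs / n
    if abs(df - 0.25) > 1e-9:
        raise ValueError(
            f"epoch of {n} samples at {epochs.fs} Hz gives {df} Hz resolution; "
            "0.25 Hz grid requires epoch_len*0.25 == 1 (e.g. 4 s at 125 Hz)"
        )
    freqs, psd = signal.welch(
        epochs.epochs,
        fs=epochs.fs,
        window=window,
        nperseg=n,
        noverlap=0,
        detrend=False,
        axis=-1,
    )
    return EpochSpectra(frequencies=freqs, power=psd, normalized=False)


def normalize_psd(spectra: EpochSpectra) -> EpochSpectra:
    """Divide each epoch's PSD by its total power so bins sum to 1.

    Epochs with zero total power are flagged invalid (``valid`` mask) and
    excluded from aggregation.
    """
    if spectra.normalized:
        return spectra
    totals = spectra.power.sum(axis=1)
    valid = totals > 0
    norm = np.zeros_like(spectra.power)
    norm[valid] = spectra.power[valid] / totals[valid, None]
    return EpochSpectra(
        frequencies=spectra.frequencies, power=norm, normalized=True, valid=valid
    )


@dataclass
class StatePSDSummary:
    state: VigilanceState
    phase: str
    frequencies: np.ndarray
    median: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    n_epochs: int

    @property
    def empty(self) -> bool:
        return self.n_epochs == 0


def state_psd_summary(
    spectra: EpochSpectra,
    hypnogram: Hypnogram,
    state: VigilanceState,
    phase: str,
    freq_range: tuple[float, float] = REPORT_RANGE,
) -> StatePSDSummary:
    """Median and IQR of relative power per bin over a state's epochs in a phase."""
    if spectra.n_epochs != hypnogram.n_epochs:
        raise ValueError("spectra and hypnogram are not epoch-aligned")
    sel = hypnogram.state_mask(state) & hypnogram.phase_mask(phase)
    if spectra.valid is not None:
        sel &= spectra.valid
    fsel = (spectra.frequencies >= freq_range[0] - 1e-9) & (
        spectra.frequencies <= freq_range[1] + 1e-9
    )
    freqs = spectra.frequencies[fsel]
    if not sel.any():
        nan = np.full(freqs.size, np.nan)
        return StatePSDSummary(state, phase, freqs, nan, nan.copy(), nan.copy(), 0)
    block = spectra.power[np.ix_(sel, fsel)]
    return StatePSDSummary(
        state=state,
        phase=phase,
        frequencies=freqs,
        median=np.median(block, axis=0),
        q25=np.percentile(block, 25, axis=0),
        q75=np.percentile(block, 75, axis=0),
        n_epochs=int(sel.sum()),
    )


def band_power(
    frequencies: np.ndarray, power: np.ndarray, band: tuple[float, float] | str
) -> np.ndarray | float:
    """Sum of power over grid bins inside ``band`` (both edges inclusive).

    ``power`` may be one curve or an (n_epochs, n_bins) matrix; ``band`` a
    (lo, hi) pair or a name from :data:`BANDS`.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    if lo < frequencies[0] - 1e-9 or hi > frequencies[-1] + 1e-9:
        raise ValueError(f"band {lo}-{hi} Hz outside the {frequencies[0]}-{frequencies[-1]} Hz grid")
    sel = (frequencies >= lo - 1e-9) & (frequencies <= hi + 1e-9)
    p = np.asarray(power)
    return p[..., sel].sum(axis=-1)


def eta_qc(
    animal_eta_power: dict[str, float], rel_threshold: float = 0.5
) -> dict[str, bool]:
    """Flag animals with attenuated high-frequency (eta) NREMS power.

    Input: per-animal median NREMS relative eta power. An animal is excluded
    from spectral aggregation when its value is below ``rel_threshold`` x the
    cohort median. Flags never affect architecture or spindle outputs.
    """
    if len(animal_eta_power) < 3:
        import warnings

        warnings.warn("eta QC skipped: fewer than 3 animals", stacklevel=2)
        return {a: True for a in animal_eta_power}
    cohort_median = float(np.median(list(animal_eta_power.values())))
    return {
        a: bool(v >= rel_threshold * cohort_median) for a, v in animal_eta_power.items()
    }


def spectral_table(
    spectra: EpochSpectra, hypnogram: Hypnogram, animal_id: str = "animal"
) -> pd.DataFrame:
    """Long-format per-animal relative-power table (state x phase x bin)."""
    rows = []
    for state in VigilanceState:
        for phase in ("light", "dark"):
            summ = state_psd_summary(spectra, hypnogram, state, phase)
            if summ.empty:
                continue
            for f, med, lo, hi in zip(summ.frequencies, summ.median, summ.q25, summ.q75):
                rows.append((animal_id, state.name, phase, f, med, lo, hi))
    return pd.DataFrame(
        rows,
        columns=["animal", "state", "phase", "freq_hz", "median", "q25", "q75"],
    )
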