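"""Synthetic multichannel EEG with condition-locked oscillatory amplitudes.

Each channel is 1/f ("pink") background noise plus a sum of band-limited
oscillators whose instantaneous amplitude follows the behavioral condition of
the current sample (baseline / LinkA / LinkB / NonlinkA / NonlinkB), derived
from the ground-truth linking masks of the simulated behavior. Optional
stereotyped blink transients can be injected on frontal channels to exercise
artifact removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tmteeg.eeg_prep import EEGRecording

__all__ = ["ACTICAP_32", "CONDITIONS", "Oscillator", "EEGSimParams", "simulate_eeg"]

# Standard 32-channel actiCAP montage (10-20 names), mastoids TP9/TP10 included.
ACTICAP_32 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
)

CONDITIONS = ("baseline", "LinkA", "LinkB", "NonlinkA", "NonlinkB")


@dataclass(frozen=True)
class Oscillator:
    """One band-limited component: RMS amplitude (µV) per condition.

    With ``bandwidth_hz`` = 0 the carrier is a pure sinusoid at
    ``center_hz``; otherwise it is band-limited Gaussian noise spanning
    center ± bandwidth/2, so that every wavelet overlapping the band sees the
    same condition-dependent amplitude ratio (a rhythm occupies a band, not a
    line). Conditions missing from ``amplitudes`` fall back to the 'baseline'
    entry; ``channels`` restricts the oscillator to a subset of electrodes
    (None = all channels).
    """

    center_hz: float
    amplitudes: dict[str, float]
    channels: tuple[str, ...] | None = None
    bandwidth_hz: float = 0.0

    def amplitude_vector(self) -> np.ndarray:
        base = self.amplitudes.get("baseline", 0.0)
        amps = np.array([self.amplitudes.get(c, base) for c in CONDITIONS])
        if (amps < 0).any():
            raise ValueError("oscillator amplitudes must be >= 0")
        return amps


@dataclass(frozen=True)
class EEGSimParams:
    channels: tuple[str, ...] = ACTICAP_32
    sample_rate_hz: float = 1000.0
    pink_noise_exponent: float = 1.0
    noise_rms_uv: float = 5.0
    band_oscillators: tuple[Oscillator, ...] = field(default_factory=tuple)
    blink_rate_per_min: float = 0.0
    blink_amplitude_uv: float = 120.0

    def __post_init__(self) -> None:
        if "TP9" not in self.channels or "TP10" not in self.channels:
            raise ValueError("channel set must include mastoids TP9 and TP10")
        for osc in self.band_oscillators:
            if not 0.0 < osc.center_hz < self.sample_rate_hz / 2.0:
                raise ValueError(
                    f"oscillator at {osc.center_hz} Hz outside (0, Nyquist)"
                )


def _pink_noise(
    rng: np.random.Generator, n: int, exponent: float, rms: float
) -> np.ndarray:
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, center: float, bandwidth: float
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to center ± bandwidth/2."""
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    keep = (freqs >= center - bandwidth / 2.0) & (freqs <= center + bandwidth / 2.0)
    x = np.fft.irfft(np.where(keep, spec, 0.0), n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _blink_kernel(fs: float) -> np.ndarray:
    # Stereotyped ~300 ms positive deflection (Gaussian bump).
    t = np.arange(-0.2, 0.2, 1.0 / fs)
    return np.exp(-0.5 * (t / 0.06) ** 2)


def simulate_eeg(
    condition_codes: np.ndarray,
    events: list[tuple[int, str]],
    params: EEGSimParams,
    rng: np.random.Generator,
) -> EEGRecording:
    """Render a recording from a per-sample condition index array.

    ``condition_codes`` holds indices into :data:`CONDITIONS` at the EEG
    sample rate; ``events`` are (sample_index, code) trigger annotations
    copied onto the recording.
    """
    n = condition_codes.size
    n_ch = len(params.channels)
    data = np.empty((n_ch, n), dtype=np.float32)
    for ci in range(n_ch):
        data[ci] = _pink_noise(rng, n, params.pink_noise_exponent, params.noise_rms_uv)
    t = np.arange(n) / params.sample_rate_hz
    for osc in params.band_oscillators:
        env = osc.amplitude_vector()[condition_codes]
        targets = (
            range(n_ch)
            if osc.channels is None
            else [params.channels.index(c) for c in osc.channels]
        )
        for ci in targets:
            if osc.bandwidth_hz > 0:
                carrier = _band_noise(
                    rng, n, params.sample_rate_hz, osc.center_hz, osc.bandwidth_hz
                )
            else:
                phase = rng.uniform(0, 2 * np.pi)
                carrier = np.sqrt(2.0) * np.sin(2 * np.pi * osc.center_hz * t + phase)
            data[ci] += (env * carrier).astype(np.float32)
    if params.blink_rate_per_min > 0:
        kernel = _blink_kernel(params.sample_rate_hz)
        n_blinks = rng.poisson(params.blink_rate_per_min * n / params.sample_rate_hz / 60.0)
        onsets = rng.integers(0, max(n - kernel.size, 1), size=n_blinks)
        gains = {"Fp1": 1.0, "Fp2": 1.0, "F7": 0.4, "F8": 0.4}
        for onset in onsets:
            burst = params.blink_amplitude_uv * kernel * rng.uniform(0.7, 1.3)
            for name, g in gains.items():
                if name in params.channels:
                    ci = params.channels.index(name)
                    data[ci, onset : onset + kernel.size] += (g * burst).astype(
                        np.float32
                    )
    return EEGRecording(
        data=data.astype(np.float64),
        sfreq=params.sample_rate_hz,
        ch_names=list(params.channels),
        events=list(events),
    )
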