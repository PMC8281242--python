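"""Morlet time-frequency decomposition and band-power feature extraction.

The wavelet bank holds 20 frequencies spaced geometrically from 0.1 to 50 Hz,
all with 6 cycles (Gaussian time SD sigma_t = 6 / (2 pi f)). Wavelets are
assigned to the five canonical EEG bands — delta 0.3-4, theta 4-8, alpha 8-13,
beta 13-30, gamma 30-50 Hz — and, for each interior band boundary (4, 8, 13,
30 Hz), the single nearest wavelet additionally joins the adjacent band, so
exactly four wavelets carry dual membership. Power is baseline-corrected in
decibels against the mean pre-stimulus fixation power (-8..-1 s), and band
features are means of the dB field over condition-period masks and band
wavelets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as spfft

logger = logging.getLogger(__name__)

__all__ = [
    "BANDS",
    "WaveletBank",
    "BandAssignment",
    "TFPower",
    "build_wavelet_bank",
    "assign_bands",
    "tf_decompose",
    "db_normalize",
    "band_period_features",
    "condition_masks_from_segmentation",
]

BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.3, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}
_INTERIOR_BOUNDARIES = (4.0, 8.0, 13.0, 30.0)


@dataclass(frozen=True)
class WaveletBank:
    frequencies: np.ndarray  # Hz, strictly increasing, geometric
    n_cycles: float = 6.0

    @property
    def sigma_t(self) -> np.ndarray:
        """Gaussian envelope SD in seconds per wavelet."""
        return self.n_cycles / (2.0 * np.pi * self.frequencies)


@dataclass(frozen=True)
class BandAssignment:
    """Wavelet index -> band memberships; ``dual`` lists the four
    boundary-straddling wavelets."""

    membership: tuple[tuple[str, ...], ...]
    dual: tuple[int, ...]

    def band_indices(self, band: str) -> list[int]:
        return [i for i, bands in enumerate(self.membership) if band in bands]


@dataclass
class TFPower:
    """dB-normalized power, channels x frequencies x time, with its time axis
    (seconds relative to stimulus onset, edge trims already applied)."""

    db: np.ndarray
    times: np.ndarray
    frequencies: np.ndarray


def build_wavelet_bank(
    n_freqs: int = 20, f_min: float = 0.1, f_max: float = 50.0, n_cycles: float = 6.0
) -> WaveletBank:
    """Geometric frequency grid anchored exactly at both range endpoints:
    f_i = f_min * (f_max / f_min)^(i / (n-1))."""
    freqs = f_min * (f_max / f_min) ** (np.arange(n_freqs) / (n_freqs - 1))
    return WaveletBank(freqs, n_cycles)


def assign_bands(bank: WaveletBank) -> BandAssignment:
    freqs = bank.frequencies
    membership: list[set[str]] = [set() for _ in freqs]
    for name, (lo, hi) in BANDS.items():
        for i, f in enumerate(freqs):
            if lo <= f < hi or (name == "gamma" and f == hi):
                membership[i].add(name)
    dual = []
    for boundary in _INTERIOR_BOUNDARIES:
        nearest = int(np.argmin(np.abs(freqs - boundary)))  # ties -> lower freq
        below = [n for n, (lo, hi) in BANDS.items() if hi == boundary]
        above = [n for n, (lo, hi) in BANDS.items() if lo == boundary]
        membership[nearest].update(below + above)
        dual.append(nearest)
    ordered = tuple(
        tuple(sorted(m, key=lambda n: BANDS[n][0])) for m in membership
    )
    return BandAssignment(ordered, tuple(dual))


def _morlet_spectrum(f0: float, sigma_t: float, freqs: np.ndarray) -> np.ndarray:
    """FFT of a unit-energy complex Morlet wavelet, evaluated analytically.

    Time-domain w(t) = (sigma_t * sqrt(pi))^{-1/2} exp(i 2 pi f0 t) *
    exp(-t^2 / (2 sigma_t^2)); its Fourier transform is a Gaussian centered at
    f0 with SD 1 / (2 pi sigma_t).
    """
    amp = (4.0 * np.pi * sigma_t**2) ** 0.25
    return amp * np.exp(-2.0 * (np.pi * sigma_t * (freqs - f0)) ** 2)


def tf_decompose(
    epoch: np.ndarray,
    sfreq: float,
    bank: WaveletBank,
    times: np.ndarray | None = None,
    edge_trim_s: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw wavelet power |conv|^2 per channel and frequency.

    Convolution is done by frequency-domain multiplication with analytically
    evaluated unit-energy Morlet spectra. ``edge_trim_s`` is cut from both
    ends of the time axis, absorbing convolution edge artifacts (epochs
    include matching 2 s pads around the analysis span). Returns
    (power[ch, freq, time], trimmed time axis). Wavelets whose temporal
    support exceeds the epoch are still computed; a warning notes their
    partial validity.
    """
    epoch = np.atleast_2d(epoch)
    n_ch, n_t = epoch.shape
    if times is None:
        times = np.arange(n_t) / sfreq
    too_long = bank.frequencies[6.0 * bank.sigma_t > n_t / sfreq]
    if too_long.size:
        logger.warning(
            "wavelet support exceeds epoch at %s Hz; power there is partially valid",
            np.round(too_long, 3).tolist(),
        )
    n_fft = spfft.next_fast_len(2 * n_t)
    fft_freqs = np.fft.fftfreq(n_fft, 1.0 / sfreq)
    epoch_fft = spfft.fft(epoch, n=n_fft, axis=1)
    trim = int(round(edge_trim_s * sfreq))
    keep = slice(trim, n_t - trim if trim else n_t)
    out = np.empty((n_ch, bank.frequencies.size, n_t - 2 * trim))
    for fi, (f0, st) in enumerate(zip(bank.frequencies, bank.sigma_t)):
        wspec = _morlet_spectrum(f0, st, fft_freqs)
        conv = spfft.ifft(epoch_fft * wspec[None, :], axis=1)[:, :n_t]
        out[:, fi, :] = np.abs(conv[:, keep]) ** 2
    return out, times[keep]


def db_normalize(
    power: np.ndarray,
    times: np.ndarray,
    frequencies: np.ndarray | None = None,
    baseline_window_s: tuple[float, float] = (-8.0, -1.0),
) -> TFPower:
    """dB(t, f) = 10 log10(power / mean baseline power) per channel & frequency."""
    lo, hi = baseline_window_s
    sel = (times >= lo) & (times < hi)
    if not sel.any():
        raise ValueError("baseline window outside epoch")
    base = power[:, :, sel].mean(axis=2, keepdims=True)
    if np.any(base <= 0):
        raise FloatingPointError("zero baseline power; cannot dB-normalize")
    db = 10.0 * np.log10(power / base)
    if frequencies is None:
        frequencies = np.full(power.shape[1], np.nan)
    return TFPower(db, times, frequencies)


def band_period_features(
    db: np.ndarray,
    times: np.ndarray,
    masks: dict[str, np.ndarray],
    assignment: BandAssignment,
    ch_names: list[str],
) -> pd.DataFrame:
    """Mean dB per (electrode, band) over each period mask for one trial.

    ``masks`` maps a period name (e.g. "Link") to a boolean mask on the
    trimmed epoch time axis; a wavelet with dual band membership contributes
    to both of its bands. Empty masks are skipped with a warning.
    """
    rows = []
    for period, mask in masks.items():
        if mask.shape != times.shape:
            raise ValueError("mask must match the trimmed epoch time axis")
        if not mask.any():
            logger.warning("empty %s mask; trial contributes no %s features", period, period)
            continue
        sub = db[:, :, mask]
        for band in BANDS:
            idx = assignment.band_indices(band)
            if not idx:
                continue
            vals = sub[:, idx, :].mean(axis=(1, 2))
            rows += [
                (period, ch, band, float(v)) for ch, v in zip(ch_names, vals)
            ]
    return pd.DataFrame(rows, columns=["period", "electrode", "band", "db"])


def condition_masks_from_segmentation(
    segmentation,
    times: np.ndarray,
) -> dict[str, np.ndarray]:
    """Link/Nonlink boolean masks on an epoch time axis (seconds, 0 = onset).

    Samples outside the performed duration (past completion) belong to
    neither period, implementing analysis over the available time only.
    """
    t_ms = times * 1000.0
    link = np.zeros(times.size, dtype=bool)
    nonlink = np.zeros(times.size, dtype=bool)
    for a, b in segmentation.linking_intervals:
        link |= (t_ms >= a) & (t_ms < b)
    for a, b in segmentation.nonlinking_intervals:
        nonlink |= (t_ms >= a) & (t_ms < b)
    return {"Link": link, "Nonlink": nonlink}
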