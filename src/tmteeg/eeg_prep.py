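"""EEG loading, filtering, artifact removal, re-referencing, epoching.

The preprocessing chain mirrors a conventional scalp-EEG workflow: read EDF or
BrainVision recordings, downsample to 1000 Hz, band-pass 0.1-100 Hz with a
zero-phase FIR, remove artifact components by ICA with a pluggable component
scorer, re-reference to the mean mastoids (TP9/TP10, which are then dropped
from the analysis set), and cut trial epochs spanning a 10 s pre-stimulus
baseline up to 2 s past the block end (-10..42 s for TMT-A, -10..62 s for
TMT-B; time 0 is the task-onset trigger).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import signal
from scipy.stats import kurtosis

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecording",
    "EpochedEEG",
    "RecordingFormatError",
    "ConfigurationError",
    "EpochBoundsError",
    "read_recording",
    "downsample",
    "bandpass_fir",
    "remove_artifact_components",
    "default_artifact_scorer",
    "rereference_mastoids",
    "epoch_trials",
]

PART_SPANS = {"A": (-10.0, 42.0), "B": (-10.0, 62.0)}
PART_TRIGGER = {"A": "tmta", "B": "tmtb"}


class RecordingFormatError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


class EpochBoundsError(ValueError):
    pass


@dataclass
class EEGRecording:
    """Channels x samples voltage matrix in µV with trigger events.

    ``events`` is a list of (sample_index, condition_code) pairs; channel
    labels are 10-20 names and must be unique.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("data rows must match channel labels")
        for sample, _ in self.events:
            if not 0 <= sample < self.data.shape[1]:
                raise ValueError(f"trigger sample {sample} outside record")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            self.data.copy(), self.sfreq, list(self.ch_names), list(self.events)
        )


@dataclass
class EpochedEEG:
    """Per-part stacks of trial epochs (trials x channels x time, µV).

    Epoch time axes are identical across trials of a part; at 1000 Hz the
    sample at index 10000 is time 0 (stimulus onset).
    """

    data: dict[str, np.ndarray]
    times: dict[str, np.ndarray]
    ch_names: list[str]
    sfreq: float
    trial_indices: dict[str, list[int]]
    completion_times_s: dict[str, list[float]] = field(default_factory=dict)


def read_recording(path: str | Path) -> EEGRecording:
    """Read an EDF or BrainVision (.vhdr) recording via MNE; data in µV."""
    import mne

    path = Path(path)
    try:
        if path.suffix.lower() == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        elif path.suffix.lower() == ".vhdr":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raise RecordingFormatError(f"unsupported recording format: {path.name}")
    except RecordingFormatError:
        raise
    except Exception as exc:
        raise RecordingFormatError(f"could not read {path}: {exc}") from exc
    data = raw.get_data() * 1e6
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        code = desc.split("/", 1)[1] if desc.startswith(("Stimulus/", "Comment/")) else desc
        events.append((int(round(onset * raw.info["sfreq"])), code.strip()))
    return EEGRecording(data, float(raw.info["sfreq"]), list(raw.ch_names), events)


def downsample(rec: EEGRecording, target_hz: float = 1000.0) -> EEGRecording:
    """Anti-alias filter and decimate; trigger indices rescale with rounding."""
    if target_hz == rec.sfreq:
        return rec.copy()
    frac = Fraction(target_hz / rec.sfreq).limit_denominator(1000)
    if frac.numerator == 1:
        data = signal.decimate(rec.data, frac.denominator, ftype="fir", zero_phase=True)
    else:
        data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    scale = target_hz / rec.sfreq
    events = [(int(round(s * scale)), c) for s, c in rec.events]
    events = [(min(s, data.shape[1] - 1), c) for s, c in events]
    return EEGRecording(data, target_hz, list(rec.ch_names), events)


def bandpass_fir(
    rec: EEGRecording,
    l_freq: float = 0.1,
    h_freq: float = 100.0,
    l_trans_bandwidth: float = 0.1,
    h_trans_bandwidth: float = 25.0,
) -> EEGRecording:
    """Zero-phase windowed-sinc band-pass; removes DC."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = mne.filter.filter_data(
            rec.data,
            rec.sfreq,
            l_freq,
            h_freq,
            l_trans_bandwidth=l_trans_bandwidth,
            h_trans_bandwidth=h_trans_bandwidth,
            phase="zero",
            fir_design="firwin",
            verbose="error",
        )
    return EEGRecording(data, rec.sfreq, list(rec.ch_names), list(rec.events))


def default_artifact_scorer(
    mixing: np.ndarray, sources: np.ndarray, ch_names: Sequence[str]
) -> np.ndarray:
    """Heuristic artifact probability from frontal topography and kurtosis.

    Blink components are stereotyped transients: strongly frontal scalp
    weights and heavy-tailed (high-kurtosis) source time-courses. The score is
    the product of two logistic terms so that only components that are both
    frontal and spiky exceed the 0.9 rejection threshold.
    """
    frontal = [i for i, c in enumerate(ch_names) if c in ("Fp1", "Fp2", "F7", "F8")]
    energy = mixing**2
    frac = energy[frontal].sum(axis=0) / np.maximum(energy.sum(axis=0), 1e-30)
    kurt = kurtosis(sources, axis=1, fisher=True)
    spiky = 1.0 / (1.0 + np.exp(-0.5 * (kurt - 10.0)))
    frontalness = 1.0 / (1.0 + np.exp(-8.0 * (frac - 0.4)))
    return spiky * frontalness


def remove_artifact_components(
    rec: EEGRecording,
    scorer: Callable[[np.ndarray, np.ndarray, Sequence[str]], np.ndarray] | None,
    threshold: float = 0.9,
    n_components: int | None = None,
    random_state: int = 0,
) -> EEGRecording:
    """ICA decomposition with pluggable component rejection.

    ``scorer(mixing, sources, ch_names)`` returns one artifact probability per
    component; components scoring above ``threshold`` are removed and the
    signal is reconstructed. With ``scorer=None`` the recording passes through
    unchanged (identity). ICA non-convergence falls back to identity with a
    warning.
    """
    if scorer is None:
        return rec.copy()
    import mne

    cov_rank = np.linalg.matrix_rank(np.cov(rec.data[:, :: max(rec.n_samples // 20000, 1)]))
    if cov_rank < len(rec.ch_names):
        raise np.linalg.LinAlgError(
            f"rank-deficient input (rank {cov_rank} < {len(rec.ch_names)} channels)"
        )
    info = mne.create_info(list(rec.ch_names), rec.sfreq, ch_types="eeg")
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    ica = mne.preprocessing.ICA(
        n_components=n_components,
        method="fastica",
        random_state=random_state,
        max_iter=1000,
        verbose="error",
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica.fit(raw, verbose="error")
    except Exception as exc:  # pragma: no cover - depends on solver behavior
        logger.warning("ICA failed (%s); returning recording unchanged", exc)
        return rec.copy()
    sources = ica.get_sources(raw).get_data()
    mixing = ica.get_components()  # channels x components
    probs = np.asarray(scorer(mixing, sources, rec.ch_names), dtype=float)
    exclude = list(np.flatnonzero(probs > threshold))
    ica.apply(raw, exclude=exclude, verbose="error")
    return EEGRecording(
        raw.get_data() * 1e6, rec.sfreq, list(rec.ch_names), list(rec.events)
    )


def rereference_mastoids(rec: EEGRecording) -> EEGRecording:
    """Subtract the TP9/TP10 mean from every channel, then drop the mastoids."""
    for m in ("TP9", "TP10"):
        if m not in rec.ch_names:
            raise ConfigurationError(f"mastoid channel {m} missing")
    i9, i10 = rec.ch_names.index("TP9"), rec.ch_names.index("TP10")
    ref = (rec.data[i9] + rec.data[i10]) / 2.0
    keep = [i for i in range(len(rec.ch_names)) if i not in (i9, i10)]
    data = rec.data[keep] - ref
    names = [rec.ch_names[i] for i in keep]
    return EEGRecording(data, rec.sfreq, names, list(rec.events))


def epoch_trials(
    rec: EEGRecording,
    exclusions: Sequence[int] = (0,),
    parts: Sequence[str] = ("A", "B"),
) -> EpochedEEG:
    """Cut per-trial epochs around the TMT onset triggers.

    Trials are numbered in time order per part across runs; trial indices in
    ``exclusions`` (default: the first trial) are omitted, retaining 7 of 8
    trials under the standard design.
    """
    out_data: dict[str, np.ndarray] = {}
    out_times: dict[str, np.ndarray] = {}
    kept: dict[str, list[int]] = {}
    for part in parts:
        tmin, tmax = PART_SPANS[part]
        onsets = [s for s, c in rec.events if c == PART_TRIGGER[part]]
        n_t = int(round((tmax - tmin) * rec.sfreq))
        epochs = []
        indices = []
        for idx, onset in enumerate(onsets):
            if idx in exclusions:
                continue
            start = onset + int(round(tmin * rec.sfreq))
            stop = start + n_t
            if start < 0 or stop > rec.n_samples:
                raise EpochBoundsError(
                    f"part {part} trial {idx}: epoch [{start}, {stop}) exceeds record"
                )
            epochs.append(rec.data[:, start:stop])
            indices.append(idx)
        out_data[part] = (
            np.stack(epochs) if epochs else np.empty((0, len(rec.ch_names), n_t))
        )
        out_times[part] = tmin + np.arange(n_t) / rec.sfreq
        kept[part] = indices
    return EpochedEEG(out_data, out_times, list(rec.ch_names), rec.sfreq, kept)
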