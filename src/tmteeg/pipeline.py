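"""End-to-end orchestration: traces -> metrics, recordings -> features.

Thin glue shared by the command-line interface, the validation studies and
the tests; all science lives in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tmteeg import eeg_prep, kinematics, timefreq

__all__ = [
    "TrialAnalysis",
    "analyze_trial",
    "behavior_tables",
    "extract_recording_features",
    "extract_session_features",
]


@dataclass
class TrialAnalysis:
    segmentation: kinematics.SegmentationResult
    links: list[kinematics.LinkEvent]
    metrics: kinematics.TrialKinematics


def analyze_trial(
    trace: kinematics.StylusTrace,
    layout,
    expected_links: int,
    block_duration_s: float,
) -> TrialAnalysis:
    """Full kinematic chain for one trial: speed, sigma filter, low-pass +
    resample to 1000 Hz, threshold segmentation, link scoring, metrics."""
    speed = kinematics.compute_speed(trace)
    speed = kinematics.sigma_filter(speed)
    speed = kinematics.lowpass_and_resample(speed)
    seg = kinematics.segment_by_threshold(speed, expected_links)
    links = kinematics.extract_links(seg, trace, layout)
    metrics = kinematics.compute_trial_metrics(seg, links, block_duration_s)
    return TrialAnalysis(seg, links, metrics)


def behavior_tables(
    sessions: list, exclusions: tuple[int, ...] = (0,)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial metric table and long-format period/link-speed table.

    Links are counted from the ground-truth sequence of each synthetic trial
    (standing in for the video-scored total link count); trials listed in
    ``exclusions`` are dropped.
    """
    metric_rows = []
    long_rows = []
    for session in sessions:
        pid = session.participant
        for part, records in session.trials.items():
            block = session.design.block_duration(part)
            for rec in records:
                if rec.trial_index in exclusions:
                    continue
                expected = len(rec.sequence)
                analysis = analyze_trial(rec.trace, rec.layout, expected, block)
                m = analysis.metrics
                metric_rows.append(
                    dict(
                        participant=pid,
                        part=part,
                        trial=rec.trial_index,
                        spl_s=m.spl_s,
                        completion_time_s=m.completion_time_s,
                        n_errors=m.n_errors,
                        n_total_links=m.n_total_links,
                        n_correct_links=m.n_correct_links,
                    )
                )
                for v in m.linking_period_ms:
                    long_rows.append((pid, part, rec.trial_index, "linking_period_ms", v))
                for v in m.nonlinking_period_ms:
                    long_rows.append((pid, part, rec.trial_index, "nonlinking_period_ms", v))
                for v in m.avg_link_speed_px_s:
                    long_rows.append((pid, part, rec.trial_index, "avg_link_speed_px_s", v))
    metrics = pd.DataFrame.from_records(metric_rows)
    longs = pd.DataFrame(
        long_rows, columns=["participant", "part", "trial", "metric", "value"]
    )
    return metrics, longs


def extract_recording_features(
    rec: eeg_prep.EEGRecording,
    segmentations: dict[str, dict[int, kinematics.SegmentationResult]],
    participant,
    exclusions: tuple[int, ...] = (0,),
    bandpass: bool = False,
    artifact_scorer=None,
    bank: timefreq.WaveletBank | None = None,
) -> pd.DataFrame:
    """Band-power features from a recording plus per-trial segmentations.

    Preprocesses (downsample to 1000 Hz, optional band-pass and ICA, mastoid
    re-reference), epochs per part, runs the wavelet decomposition with dB
    baseline normalization, and averages band power over linking /
    non-linking masks and trials. ``segmentations`` maps part -> trial index
    -> SegmentationResult (kinematic or ground truth).
    """
    bank = bank or timefreq.build_wavelet_bank()
    assignment = timefreq.assign_bands(bank)
    if rec.sfreq != 1000.0:
        rec = eeg_prep.downsample(rec, 1000.0)
    if bandpass:
        rec = eeg_prep.bandpass_fir(rec)
    if artifact_scorer is not None:
        rec = eeg_prep.remove_artifact_components(rec, artifact_scorer)
    rec = eeg_prep.rereference_mastoids(rec)
    epochs = eeg_prep.epoch_trials(rec, exclusions=exclusions)

    acc: dict[tuple[str, str, str], list[float]] = {}
    for part in ("A", "B"):
        if epochs.data[part].shape[0] == 0:
            continue
        for k, trial_idx in enumerate(epochs.trial_indices[part]):
            seg = segmentations[part][trial_idx]
            power, times = timefreq.tf_decompose(
                epochs.data[part][k], epochs.sfreq, bank, times=epochs.times[part]
            )
            tf = timefreq.db_normalize(power, times, bank.frequencies)
            masks = timefreq.condition_masks_from_segmentation(seg, times)
            feats = timefreq.band_period_features(
                tf.db, times, masks, assignment, epochs.ch_names
            )
            for _, row in feats.iterrows():
                key = (f"{row['period']}{part}", row["electrode"], row["band"])
                acc.setdefault(key, []).append(row["db"])
    rows = [
        (participant, cond, elec, band, float(np.mean(vals)))
        for (cond, elec, band), vals in acc.items()
    ]
    return pd.DataFrame(
        rows, columns=["participant", "condition", "electrode", "band", "db"]
    )


def extract_session_features(
    session,
    exclusions: tuple[int, ...] = (0,),
    use_ground_truth_masks: bool = True,
    segmentations: dict[str, dict[int, kinematics.SegmentationResult]] | None = None,
    bandpass: bool = False,
    artifact_scorer=None,
    bank: timefreq.WaveletBank | None = None,
) -> pd.DataFrame:
    """Features for a synthetic session, masked by ground truth (default) or
    by supplied kinematic segmentations."""
    if use_ground_truth_masks or segmentations is None:
        segmentations = {
            part: {rec.trial_index: rec.truth for rec in records}
            for part, records in session.trials.items()
        }
    return extract_recording_features(
        session.recording,
        segmentations,
        session.participant,
        exclusions=exclusions,
        bandpass=bandpass,
        artifact_scorer=artifact_scorer,
        bank=bank,
    )
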