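"""Block-design session assembly: behavior timeline, triggers, EEG.

One run is four repetitions of fixation (10 s) - control (19 s) - fixation -
TMT-A (40 s) - fixation - TMT-B (60 s), closed by a final fixation; a session
is two such runs, giving 8 trials per TMT part. Stimulus layouts vary across
trials by 180-degree rotation and label-set swaps of one base geometry per
participant, so inter-item distances are constant across trials and parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tmteeg.eeg_prep import EEGRecording
from tmteeg.kinematics import SegmentationResult, StylusTrace
from tmteeg.synth.behavior import BehaviorSimParams, simulate_trial_behavior
from tmteeg.synth.eeg import CONDITIONS, EEGSimParams, simulate_eeg
from tmteeg.synth.layout import StimulusLayout, generate_layout

__all__ = ["TaskDesign", "TrialRecord", "SyntheticSession", "simulate_session"]


@dataclass(frozen=True)
class TaskDesign:
    control_duration_s: float = 19.0
    tmta_duration_s: float = 40.0
    tmtb_duration_s: float = 60.0
    fixation_duration_s: float = 10.0
    trials_per_run: int = 4
    runs: int = 2

    def __post_init__(self) -> None:
        for d in (
            self.control_duration_s,
            self.tmta_duration_s,
            self.tmtb_duration_s,
            self.fixation_duration_s,
        ):
            if d <= 0:
                raise ValueError("all durations must be positive")

    @property
    def trials_per_part(self) -> int:
        return self.trials_per_run * self.runs

    def block_duration(self, part: str) -> float:
        return self.tmta_duration_s if part == "A" else self.tmtb_duration_s


@dataclass
class TrialRecord:
    part: str
    trial_index: int
    onset_s: float
    layout: StimulusLayout
    trace: StylusTrace
    truth: SegmentationResult
    sequence: list[tuple[str, str, bool]]


@dataclass
class SyntheticSession:
    participant: int
    design: TaskDesign
    trials: dict[str, list[TrialRecord]] = field(default_factory=dict)
    recording: EEGRecording | None = None
    seed: int | None = None


def _phase_plan(design: TaskDesign) -> list[tuple[str, float]]:
    plan: list[tuple[str, float]] = []
    for _ in range(design.runs):
        for _ in range(design.trials_per_run):
            plan += [
                ("fixation", design.fixation_duration_s),
                ("control", design.control_duration_s),
                ("fixation", design.fixation_duration_s),
                ("tmta", design.tmta_duration_s),
                ("fixation", design.fixation_duration_s),
                ("tmtb", design.tmtb_duration_s),
            ]
        plan.append(("fixation", design.fixation_duration_s))
    return plan


def simulate_session(
    participant: int,
    design: TaskDesign | None = None,
    behavior_params: BehaviorSimParams | None = None,
    eeg_params: EEGSimParams | None = None,
    seed: int = 0,
    with_eeg: bool = True,
) -> SyntheticSession:
    """Simulate a complete session for one participant.

    Deterministic for fixed (participant, seed). The base stimulus geometry is
    drawn once per participant; trial variants cycle through rotation/swap
    combinations as in the real task design.
    """
    design = design or TaskDesign()
    behavior_params = behavior_params or BehaviorSimParams()
    eeg_params = eeg_params or EEGSimParams()
    master = np.random.default_rng([seed % (2**31), participant])
    layout_seed = int(master.integers(2**31))
    rng = np.random.default_rng(master.integers(2**31))

    session = SyntheticSession(participant, design, {"A": [], "B": []}, seed=seed)
    fs = eeg_params.sample_rate_hz
    plan = _phase_plan(design)
    total_s = sum(d for _, d in plan)
    n_samples = int(round(total_s * fs))
    codes = np.zeros(n_samples, dtype=np.int8)  # baseline everywhere
    events: list[tuple[int, str]] = []

    trial_counter = {"A": 0, "B": 0}
    t = 0.0
    for phase, dur in plan:
        onset_sample = int(round(t * fs))
        events.append((onset_sample, phase))
        if phase in ("tmta", "tmtb"):
            part = "A" if phase == "tmta" else "B"
            idx = trial_counter[part]
            trial_counter[part] += 1
            layout = generate_layout(part, variant_id=idx % 2, seed=layout_seed)
            trace, truth, sequence = simulate_trial_behavior(
                layout, behavior_params, part, rng, design.block_duration(part)
            )
            session.trials[part].append(
                TrialRecord(part, idx, t, layout, trace, truth, sequence)
            )
            link_code = CONDITIONS.index(f"Link{part}")
            nonlink_code = CONDITIONS.index(f"Nonlink{part}")
            for a, b in truth.linking_intervals:
                codes[onset_sample + int(round(a * fs / 1000.0)) :
                      onset_sample + int(round(b * fs / 1000.0))] = link_code
            for a, b in truth.nonlinking_intervals:
                codes[onset_sample + int(round(a * fs / 1000.0)) :
                      onset_sample + int(round(b * fs / 1000.0))] = nonlink_code
        t += dur

    if with_eeg:
        session.recording = simulate_eeg(codes, events, eeg_params, rng)
    else:
        session.recording = None
    return session
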