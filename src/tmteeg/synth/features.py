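"""Feature-level cohort simulation for the task-PLS stage.

Generates the long-format band-power table (participant, condition,
electrode, band, dB) directly, bypassing the EEG pipeline, so the PLS
inference machinery can be validated at scale: independent Gaussian dB noise
per cell, optional participant offsets, and an optional injected condition
effect on a designated electrode/band subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tmteeg.synth.eeg import ACTICAP_32

__all__ = ["ANALYSIS_ELECTRODES", "BAND_NAMES", "FeatureEffect", "simulate_feature_cohort"]

# the 30 electrodes left after mean-mastoid re-referencing
ANALYSIS_ELECTRODES = tuple(c for c in ACTICAP_32 if c not in ("TP9", "TP10"))
BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")
PLS_CONDITIONS = ("LinkA", "LinkB", "NonlinkA", "NonlinkB")


@dataclass(frozen=True)
class FeatureEffect:
    """A condition-locked dB shift on a subset of electrodes and bands."""

    conditions: tuple[str, ...]
    electrodes: tuple[str, ...]
    bands: tuple[str, ...]
    delta_db: float


def simulate_feature_cohort(
    rng: np.random.Generator,
    n_participants: int = 16,
    electrodes: tuple[str, ...] = ANALYSIS_ELECTRODES,
    bands: tuple[str, ...] = BAND_NAMES,
    conditions: tuple[str, ...] = PLS_CONDITIONS,
    noise_sd_db: float = 0.5,
    participant_sd_db: float = 0.3,
    effects: tuple[FeatureEffect, ...] = (),
) -> pd.DataFrame:
    """Long-format feature table with optional injected effects.

    Each cell is ``participant_offset + N(0, noise_sd) + sum(effects)``; an
    effect contributes ``delta_db`` to every matching
    (condition, electrode, band) cell.
    """
    n_e, n_b, n_c = len(electrodes), len(bands), len(conditions)
    offsets = rng.normal(0.0, participant_sd_db, size=n_participants)
    values = rng.normal(0.0, noise_sd_db, size=(n_participants, n_c, n_e, n_b))
    values += offsets[:, None, None, None]
    for eff in effects:
        ci = [conditions.index(c) for c in eff.conditions]
        ei = [electrodes.index(e) for e in eff.electrodes]
        bi = [bands.index(b) for b in eff.bands]
        for c in ci:
            values[:, c][np.ix_(range(n_participants), ei, bi)] += eff.delta_db
    rows = []
    for p in range(n_participants):
        for c, cond in enumerate(conditions):
            for e, elec in enumerate(electrodes):
                for b, band in enumerate(bands):
                    rows.append((p, cond, elec, band, values[p, c, e, b]))
    return pd.DataFrame(
        rows, columns=["participant", "condition", "electrode", "band", "db"]
    )
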