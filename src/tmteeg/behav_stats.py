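"""Non-parametric behavioral statistics for tablet TMT metrics.

Distribution normality (one-sample Kolmogorov-Smirnov against a normal with
the sample's mean and SD), trial-effect screening (Kruskal-Wallis across
trials followed by Dunn's rank-based pairwise comparisons at a
Sidak-corrected alpha, flagging leading trials that are significantly slower
than several later trials — the habituation/learning pattern that motivates
excluding Trial 1), part comparisons (Wilcoxon signed rank on participant
means, two-sample KS on pooled distributions, signed rank on per-participant
skewness), and bootstrap confidence intervals for histogram-bin means with
the participant as the resampling unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatReport",
    "PartComparison",
    "TrialScreenResult",
    "ks_normality",
    "trial_effect_screen",
    "dunn_sidak",
    "compare_parts",
    "bootstrap_bin_ci",
    "metrics_to_frame",
]


@dataclass(frozen=True)
class StatReport:
    test: str
    statistic: float
    p_value: float
    groups: tuple
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class PartComparison:
    """The three per-metric part comparisons: participant means (signed
    rank), pooled distributions (two-sample KS), skewness (signed rank)."""

    means: StatReport
    distributions: StatReport
    skewness: StatReport | None


@dataclass
class TrialScreenResult:
    kruskal: StatReport
    pairwise: pd.DataFrame | None  # trial_a, trial_b, z, p, significant
    excluded_trials: list[int]
    post_exclusion_p: float | None


def metrics_to_frame(records: list[dict]) -> pd.DataFrame:
    """Tidy (participant, part, trial) metric table from per-trial dicts."""
    return pd.DataFrame.from_records(records)


def ks_normality(values: np.ndarray) -> StatReport:
    """One-sample KS against a normal with the sample mean and SD."""
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 observations")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample (SD = 0)")
    stat, p = stats.kstest(values, "norm", args=(values.mean(), sd))
    return StatReport("ks-normality", float(stat), float(p), ("sample",), values.size)


def dunn_sidak(groups: list[np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons with Sidak-corrected alpha.

    Uses the pooled ranks of all groups with tie correction; significance is
    judged against alpha' = 1 - (1 - alpha)^(1/m) for m pairs.
    """
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start : start + size].mean())
        start += size
    m = len(groups) * (len(groups) - 1) // 2
    alpha_sidak = 1.0 - (1.0 - alpha) ** (1.0 / m)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((i, j, z, p, p < alpha_sidak))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p", "significant"])


def trial_effect_screen(
    df: pd.DataFrame,
    metric: str = "spl_s",
    alpha: float = 0.05,
    min_later_trials: int = 4,
) -> TrialScreenResult:
    """Screen for systematic trial effects and decide exclusions for one part.

    Kruskal-Wallis across trial numbers (values pooled over participants); if
    significant, Dunn-Sidak pairwise comparisons flag any leading trial whose
    values are significantly slower (larger) than at least
    ``min_later_trials`` later trials. The screen is re-run on the remaining
    trials to confirm no residual effect.
    """
    trial_ids = sorted(df["trial"].unique())
    if len(trial_ids) < 2:
        raise ValueError("need at least 2 trials to screen for a trial effect")
    groups = [df.loc[df["trial"] == t, metric].to_numpy() for t in trial_ids]
    if np.ptp(np.concatenate(groups)) == 0:
        report = StatReport("kruskal-wallis", 0.0, 1.0, tuple(trial_ids), len(df))
        return TrialScreenResult(report, None, [], None)
    h, p = stats.kruskal(*groups)
    report = StatReport("kruskal-wallis", float(h), float(p), tuple(trial_ids), len(df))
    if p >= alpha:
        return TrialScreenResult(report, None, [], None)
    pw = dunn_sidak(groups, alpha=alpha)
    excluded = []
    for i, trial in enumerate(trial_ids):
        later = pw[(pw["group_a"] == i) & (pw["group_b"] > i) & pw["significant"]]
        slower = later[later["z"] > 0]  # larger mean rank = slower
        if len(slower) >= min_later_trials:
            excluded.append(trial)
        else:
            break  # only leading trials are candidates
    post_p = None
    if excluded:
        rest = [g for t, g in zip(trial_ids, groups) if t not in excluded]
        post_p = float(stats.kruskal(*rest)[1]) if len(rest) >= 2 else None
    return TrialScreenResult(report, pw, excluded, post_p)


def compare_parts(
    df: pd.DataFrame, metric: str, skew_min_n: int = 5
) -> PartComparison:
    """Three reports comparing TMT parts for one metric.

    ``df`` is long-format with columns participant, part and ``metric``; a
    participant may contribute many observations (e.g. one per link). The
    signed-rank tests pair participants; the KS test pools observations.
    """
    a = df[df["part"] == "A"]
    b = df[df["part"] == "B"]
    mean_a = a.groupby("participant")[metric].mean()
    mean_b = b.groupby("participant")[metric].mean()
    common = mean_a.index.intersection(mean_b.index)
    diffs = (mean_b[common] - mean_a[common]).to_numpy()
    if np.allclose(diffs, 0.0):
        means = StatReport("wilcoxon-means", 0.0, 1.0, ("A", "B"), common.size)
    else:
        w, p = stats.wilcoxon(diffs)
        means = StatReport("wilcoxon-means", float(w), float(p), ("A", "B"), common.size)
    ks, ks_p = stats.ks_2samp(a[metric], b[metric])
    distr = StatReport("ks-2samp", float(ks), float(ks_p), ("A", "B"), len(df))
    skew_a = a.groupby("participant")[metric].apply(
        lambda v: stats.skew(v) if len(v) >= skew_min_n else np.nan
    )
    skew_b = b.groupby("participant")[metric].apply(
        lambda v: stats.skew(v) if len(v) >= skew_min_n else np.nan
    )
    sk = (skew_b[common] - skew_a[common]).dropna().to_numpy()
    if sk.size < 5 or np.allclose(sk, 0.0):
        skewness = None
    else:
        w, p = stats.wilcoxon(sk)
        skewness = StatReport("wilcoxon-skewness", float(w), float(p), ("A", "B"), sk.size)
    return PartComparison(means, distr, skewness)


def bootstrap_bin_ci(
    values_by_participant: dict,
    bins: np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    ci: float = 95.0,
) -> pd.DataFrame:
    """Percentile bootstrap CI of the mean histogram height at each bin.

    The resampling unit is the participant (not the trial or observation),
    respecting within-participant dependence. Histogram heights are
    normalized per participant (fraction of observations per bin).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = rng or np.random.default_rng()
    parts = list(values_by_participant)
    hists = np.array(
        [
            np.histogram(values_by_participant[p], bins=bins)[0]
            / max(len(values_by_participant[p]), 1)
            for p in parts
        ]
    )
    n_p = len(parts)
    boot_means = np.empty((n_boot, bins.size - 1))
    for b in range(n_boot):
        draw = rng.integers(0, n_p, size=n_p)
        boot_means[b] = hists[draw].mean(axis=0)
    lo, hi = np.percentile(boot_means, [(100 - ci) / 2, 100 - (100 - ci) / 2], axis=0)
    return pd.DataFrame(
        {
            "bin_left": bins[:-1],
            "bin_right": bins[1:],
            "mean": hists.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
        }
    )
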