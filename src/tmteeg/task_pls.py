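"""Task partial least squares with permutation and bootstrap inference.

Band-power features of the four task conditions (LinkA, LinkB, NonlinkA,
NonlinkB) form the data matrix X (rows = participant-in-condition, columns =
electrode x band features, column-mean-centered); the condition indicator
matrix Y is one-hot. The effect space E = X^T Y is decomposed by SVD,
E = U S V^T, giving paired spatial saliences (U columns, one weight per
electrode x band feature) and task saliences (V columns, one weight per
condition) for each latent variable (LV), with variance explained s_i^2 /
sum s^2.

Inference is non-parametric: LV significance by permuting condition labels
within participant (respecting the repeated-measures design); salience
stability by bootstrap resampling of participants with replacement, each
resample sign-aligned to the observed saliences, summarized as bootstrap
ratios BSR = bootstrap mean / bootstrap SD. Electrode maps keep saliences
that survive Benjamini-Hochberg FDR (q = 0.05, normal approximation of the
BSR) and |BSR| > 2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PLS_CONDITIONS",
    "PLSDesign",
    "PLSResult",
    "AssemblyError",
    "assemble_matrices",
    "pls_svd",
    "permutation_test",
    "bootstrap_bsr",
    "contrast_saliences",
    "threshold_map",
    "run_task_pls",
    "run_subtest",
    "combine_link_nonlink",
]

PLS_CONDITIONS = ("LinkA", "LinkB", "NonlinkA", "NonlinkB")


class AssemblyError(ValueError):
    pass


@dataclass
class PLSDesign:
    """Centered X, one-hot Y, and the row/column bookkeeping.

    Rows are grouped by condition with participants nested identically in
    each condition block: row index r = c * n_participants + p.
    """

    X: np.ndarray
    Y: np.ndarray
    conditions: tuple[str, ...]
    participants: list
    feature_index: list[tuple[str, str]]  # (electrode, band), electrode-major

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)


@dataclass
class PLSResult:
    conditions: tuple[str, ...]
    feature_index: list[tuple[str, str]]
    singular_values: np.ndarray
    variance_explained: np.ndarray | None
    task_saliences: np.ndarray  # conditions x LVs
    spatial_saliences: np.ndarray  # features x LVs
    perm_p: np.ndarray | None = None
    spatial_boot_mean: np.ndarray | None = None
    spatial_boot_sd: np.ndarray | None = None
    spatial_bsr: np.ndarray | None = None
    task_boot_mean: np.ndarray | None = None
    task_boot_sd: np.ndarray | None = None
    task_bsr: np.ndarray | None = None
    task_boot_samples: np.ndarray | None = None  # n_boot x conditions x LVs
    contrasts: pd.DataFrame | None = None
    maps: dict[int, pd.DataFrame] = field(default_factory=dict)
    n_perm: int = 0
    n_boot: int = 0
    seed: int | None = None


def assemble_matrices(
    features: pd.DataFrame, conditions: tuple[str, ...] = PLS_CONDITIONS
) -> PLSDesign:
    """Stack the long-format feature table into centered X and one-hot Y.

    Column order is electrode-major then band; a missing
    (participant, condition, electrode, band) cell is an error listing the
    gaps.
    """
    df = features[features["condition"].isin(conditions)]
    participants = sorted(df["participant"].unique())
    electrodes = list(dict.fromkeys(df["electrode"]))
    bands = list(dict.fromkeys(df["band"]))
    wide = df.set_index(["participant", "condition", "electrode", "band"])["db"]
    if wide.index.duplicated().any():
        raise AssemblyError("duplicate feature cells")
    feature_index = [(e, b) for e in electrodes for b in bands]
    n_p, n_c, n_f = len(participants), len(conditions), len(feature_index)
    X = np.empty((n_c * n_p, n_f))
    gaps = []
    for ci, cond in enumerate(conditions):
        for pi, part in enumerate(participants):
            for fi, (e, b) in enumerate(feature_index):
                try:
                    X[ci * n_p + pi, fi] = wide[(part, cond, e, b)]
                except KeyError:
                    gaps.append((part, cond, e, b))
    if gaps:
        raise AssemblyError(f"missing feature cells: {gaps[:10]}" +
                            (f" (+{len(gaps) - 10} more)" if len(gaps) > 10 else ""))
    X -= X.mean(axis=0, keepdims=True)
    Y = np.zeros((n_c * n_p, n_c))
    for ci in range(n_c):
        Y[ci * n_p : (ci + 1) * n_p, ci] = 1.0
    return PLSDesign(X, Y, tuple(conditions), participants, feature_index)


def _svd(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    E = X.T @ Y
    U, S, Vt = np.linalg.svd(E, full_matrices=False)
    return U, S, Vt.T


def pls_svd(design: PLSDesign) -> PLSResult:
    U, S, V = _svd(design.X, design.Y)
    total = float(np.sum(S**2))
    varexp = S**2 / total if total > 0 else np.zeros_like(S)
    return PLSResult(
        conditions=design.conditions,
        feature_index=design.feature_index,
        singular_values=S,
        variance_explained=varexp,
        task_saliences=V,
        spatial_saliences=U,
    )


def _within_participant_permutation(
    design: PLSDesign, rng: np.random.Generator
) -> np.ndarray:
    """Row index permuting each participant's condition labels."""
    n_p, n_c = design.n_participants, design.n_conditions
    rows = np.arange(n_c * n_p).reshape(n_c, n_p)
    out = np.empty_like(rows)
    for p in range(n_p):
        out[:, p] = rows[rng.permutation(n_c), p]
    return out.ravel()


def permutation_test(
    design: PLSDesign,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Permutation p per LV: p_i = (1 + #{perm s_i >= obs s_i}) / (n_perm + 1).

    Condition labels are shuffled within participant. When the number of
    distinct permutations is smaller than ``n_perm`` they are enumerated
    exhaustively instead.
    """
    rng = rng or np.random.default_rng()
    _, s_obs, _ = _svd(design.X, design.Y)
    n_p, n_c = design.n_participants, design.n_conditions
    total = math.factorial(n_c) ** n_p

    def stat(row_index: np.ndarray) -> np.ndarray:
        return _svd(design.X[row_index], design.Y)[1]

    count = np.zeros_like(s_obs)
    if total <= n_perm:  # exhaustive enumeration for tiny designs
        perms = list(itertools.permutations(range(n_c)))
        rows = np.arange(n_c * n_p).reshape(n_c, n_p)
        n_done = 0
        for combo in itertools.product(perms, repeat=n_p):
            idx = np.empty_like(rows)
            for p, perm in enumerate(combo):
                idx[:, p] = rows[list(perm), p]
            count += stat(idx.ravel()) >= s_obs - 1e-12
            n_done += 1
        return count / n_done
    for _ in range(n_perm):
        count += stat(_within_participant_permutation(design, rng)) >= s_obs
    return (1.0 + count) / (n_perm + 1.0)


def bootstrap_bsr(
    design: PLSDesign,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Bootstrap resampling of participants (all condition rows together).

    Each resample's saliences are sign-aligned per LV to the observed
    solution before accumulation; BSR = bootstrap mean / bootstrap SD, with a
    signed-infinity sentinel where the SD is zero.
    """
    rng = rng or np.random.default_rng()
    U_obs, _, V_obs = _svd(design.X, design.Y)
    n_p, n_c = design.n_participants, design.n_conditions
    n_lv = V_obs.shape[1]
    sp_samples = np.empty((n_boot, U_obs.shape[0], n_lv))
    ta_samples = np.empty((n_boot, n_c, n_lv))
    base_rows = np.arange(n_c * n_p).reshape(n_c, n_p)
    for b in range(n_boot):
        draw = rng.integers(0, n_p, size=n_p)
        rows = base_rows[:, draw].ravel()
        Xb = design.X[rows]
        Xb = Xb - Xb.mean(axis=0, keepdims=True)
        Ub, _, Vb = _svd(Xb, design.Y)
        for lv in range(n_lv):
            align = U_obs[:, lv] @ Ub[:, lv] + V_obs[:, lv] @ Vb[:, lv]
            if align < 0:
                Ub[:, lv] *= -1.0
                Vb[:, lv] *= -1.0
        sp_samples[b] = Ub
        ta_samples[b] = Vb

    def summarize(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mean = samples.mean(axis=0)
        sd = samples.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            bsr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0),
                           np.sign(mean) * np.inf)
        return mean, sd, bsr

    sp_mean, sp_sd, sp_bsr = summarize(sp_samples)
    ta_mean, ta_sd, ta_bsr = summarize(ta_samples)
    return {
        "spatial_mean": sp_mean, "spatial_sd": sp_sd, "spatial_bsr": sp_bsr,
        "task_mean": ta_mean, "task_sd": ta_sd, "task_bsr": ta_bsr,
        "task_samples": ta_samples,
    }


def contrast_saliences(
    task_samples: np.ndarray, conditions: tuple[str, ...], lv: int = 0
) -> pd.DataFrame:
    """Paired condition contrasts of the bootstrap task-salience samples.

    For each ordered pair (a, b) the distribution of salience differences
    a - b across bootstrap resamples is summarized by mean, SD and BSR;
    contrast(a, b) = -contrast(b, a) by construction.
    """
    rows = []
    for i, j in itertools.combinations(range(len(conditions)), 2):
        d = task_samples[:, i, lv] - task_samples[:, j, lv]
        sd = float(d.std(ddof=1))
        mean = float(d.mean())
        if sd > 0:
            bsr = mean / sd
        else:
            bsr = 0.0 if mean == 0 else float(np.sign(mean) * np.inf)
        rows.append((conditions[i], conditions[j], mean, sd, bsr))
    return pd.DataFrame(rows, columns=["cond_a", "cond_b", "mean", "sd", "bsr"])


def threshold_map(
    result: PLSResult, lv: int = 0, q: float = 0.05, bsr_min: float = 2.0
) -> pd.DataFrame:
    """Band x electrode BSR map after FDR correction and stability threshold.

    Two-tailed p-values come from the standard-normal approximation of the
    BSR; Benjamini-Hochberg runs jointly across all electrode x band
    saliences of the LV. Entries failing either FDR or |BSR| > bsr_min are
    zeroed; non-finite BSRs (zero bootstrap SD) are excluded.
    """
    bsr = result.spatial_bsr[:, lv]
    finite = np.isfinite(bsr)
    pvals = np.ones_like(bsr)
    pvals[finite] = 2.0 * norm.sf(np.abs(bsr[finite]))
    reject = np.zeros_like(bsr, dtype=bool)
    if finite.any():
        reject[finite] = multipletests(pvals[finite], alpha=q, method="fdr_bh")[0]
    keep = reject & (np.abs(bsr) > bsr_min) & finite
    values = np.where(keep, bsr, 0.0)
    df = pd.DataFrame(
        {
            "electrode": [e for e, _ in result.feature_index],
            "band": [b for _, b in result.feature_index],
            "bsr": values,
        }
    )
    return df.pivot(index="band", columns="electrode", values="bsr")


def combine_link_nonlink(features: pd.DataFrame) -> pd.DataFrame:
    """Link(A+B) / Nonlink(A+B) features: dB power summed across parts."""
    df = features[features["condition"].isin(PLS_CONDITIONS)].copy()
    df["period"] = df["condition"].str.replace("A", "").str.replace("B", "")
    agg = (
        df.groupby(["participant", "period", "electrode", "band"], sort=False)["db"]
        .sum()
        .reset_index()
        .rename(columns={"period": "condition"})
    )
    return agg[["participant", "condition", "electrode", "band", "db"]]


def run_task_pls(
    features: pd.DataFrame,
    conditions: tuple[str, ...] = PLS_CONDITIONS,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    subtest: bool = False,
) -> PLSResult:
    """Full analysis: assembly, SVD, permutation test, bootstrap, contrasts,
    thresholded map for LV1.

    With ``subtest=True`` (two-condition analyses) the LV p-value and the
    variance explained are suppressed, as they are fixed by construction in a
    two-condition design.
    """
    design = assemble_matrices(features, conditions)
    result = pls_svd(design)
    rng = np.random.default_rng(seed)
    if subtest:
        result.variance_explained = None
    else:
        result.perm_p = permutation_test(design, n_perm, rng)
        result.n_perm = n_perm
    boot = bootstrap_bsr(design, n_boot, rng)
    result.spatial_boot_mean = boot["spatial_mean"]
    result.spatial_boot_sd = boot["spatial_sd"]
    result.spatial_bsr = boot["spatial_bsr"]
    result.task_boot_mean = boot["task_mean"]
    result.task_boot_sd = boot["task_sd"]
    result.task_bsr = boot["task_bsr"]
    result.task_boot_samples = boot["task_samples"]
    result.n_boot = n_boot
    result.seed = seed
    if not subtest:
        result.contrasts = contrast_saliences(boot["task_samples"], design.conditions)
    result.maps[0] = threshold_map(result, lv=0)
    return result


def run_subtest(
    features: pd.DataFrame,
    which: tuple[str, str] | str,
    n_boot: int = 1000,
    seed: int = 0,
) -> PLSResult:
    """Two-condition follow-up analysis.

    ``which`` is a pair of condition names, or the string
    ``"link_vs_nonlink_combined"`` for Link(A+B) vs Nonlink(A+B) with
    features summed across parts before assembly.
    """
    if which == "link_vs_nonlink_combined":
        feats = combine_link_nonlink(features)
        pair = ("Link", "Nonlink")
    else:
        pair = tuple(which)
        unknown = set(pair) - set(PLS_CONDITIONS)
        if len(pair) != 2 or unknown:
            raise ValueError(f"unknown subtest conditions: {sorted(unknown) or pair}")
        feats = features
    return run_task_pls(
        feats, conditions=pair, n_perm=0, n_boot=n_boot, seed=seed, subtest=True
    )
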