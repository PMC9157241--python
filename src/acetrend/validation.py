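"""Wet-lab verification statistics: qPCR folds, cross-platform correlation,
and densitometry fold changes.

qPCR quantification follows the 2^-ddCt model with a fixed amplification
efficiency of 2: per replicate, dCt = Ct_target - Ct_reference; ddCt
subtracts the control group's mean dCt; the group fold is the geometric
mean of replicate folds (folds are ratios), so the control group's fold is
1 by construction.  RNA-seq vs qPCR agreement is the Pearson correlation of
log2 folds over shared genes.  Pan-acetylation immunoblot lanes are
normalized to a per-lane total-protein loading value and compared to a
reference group with the equal-variance two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def read_qpcr_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"gene", "group", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    return df


@dataclass(frozen=True)
class GroupFold:
    fold: float  # geometric mean of replicate folds = 2^log2_fold
    log2_fold: float
    replicate_folds: tuple[float, ...]


def ddct_fold(
    table: pd.DataFrame, target: str, ref: str, control_group: str
) -> dict[str, GroupFold]:
    """2^-ddCt relative quantification of one target gene per group."""
    groups = sorted(table["group"].unique())
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not in table")

    def dcts(group: str) -> pd.Series:
        sub = table[table["group"] == group]
        t = sub[sub["gene"] == target].set_index("replicate")["ct"]
        r = sub[sub["gene"] == ref].set_index("replicate")["ct"]
        if r.empty:
            raise ValueError(f"reference gene {ref!r} missing in group {group!r}")
        if t.empty:
            raise ValueError(f"target gene {target!r} missing in group {group!r}")
        joined = pd.DataFrame({"t": t, "r": r}).dropna()
        if joined.empty:
            raise ValueError(
                f"no replicate pairs target/reference in group {group!r}"
            )
        return joined["t"] - joined["r"]

    control_mean_dct = dcts(control_group).mean()
    out: dict[str, GroupFold] = {}
    for group in groups:
        ddct = dcts(group) - control_mean_dct
        folds = np.power(2.0, -ddct.to_numpy())
        # geometric mean computed in log space: mean ddCt, then one power
        log2_fold = float(-ddct.mean())
        out[group] = GroupFold(
            float(2.0**log2_fold), log2_fold, tuple(float(f) for f in folds)
        )
    return out


def cross_platform_correlation(
    qpcr_log2fold: dict[str, float], rnaseq_log2fold: dict[str, float]
) -> tuple[float, float, float]:
    """(R^2, Pearson r, two-sided p) on log2 folds over shared genes."""
    shared = sorted(set(qpcr_log2fold) & set(rnaseq_log2fold))
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared genes for correlation, got {len(shared)}"
        )
    x = np.array([rnaseq_log2fold[g] for g in shared])
    y = np.array([qpcr_log2fold[g] for g in shared])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return math.nan, math.nan, math.nan
    # exact-agreement limit: avoid float cancellation reporting r = 1 - eps
    if np.array_equal(x, y):
        return 1.0, 1.0, float(stats.pearsonr(x, y).pvalue)
    if np.array_equal(x, -y):
        return 1.0, -1.0, float(stats.pearsonr(x, y).pvalue)
    r, p = stats.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    return r * r, r, float(p)


def read_densitometry_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"label", "group", "total_band_gray", "loading_gray"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"densitometry table missing columns: {sorted(missing)}")
    if (df["loading_gray"] <= 0).any():
        raise ValueError("loading_gray must be > 0")
    if (df["total_band_gray"] < 0).any():
        raise ValueError("total_band_gray must be >= 0")
    return df


@dataclass(frozen=True)
class GroupDensitometry:
    mean_fold: float
    sem: float
    p_value: float  # NaN when not computable (single lane)
    n_lanes: int


def pan_acetylation_fold(
    lanes: pd.DataFrame, reference_group: str
) -> dict[str, GroupDensitometry]:
    """Loading-normalized pan-acetylation folds vs a reference group.

    Per lane: normalized = total_band_gray / loading_gray; fold = normalized
    over the reference group's mean normalized signal.  p is the two-sided
    equal-variance Student's t-test of normalized signals vs the reference
    (NaN for single-lane groups; 1.0 when both groups are identical with
    zero variance).
    """
    if reference_group not in set(lanes["group"]):
        raise ValueError(f"reference group {reference_group!r} not in table")
    norm = lanes["total_band_gray"] / lanes["loading_gray"]
    lanes = lanes.assign(_norm=norm)
    ref_vals = lanes.loc[lanes["group"] == reference_group, "_norm"].to_numpy()
    ref_mean = ref_vals.mean()
    if ref_mean <= 0:
        raise ValueError("reference group has zero mean normalized signal")
    out: dict[str, GroupDensitometry] = {}
    for group, sub in lanes.groupby("group", sort=True):
        vals = sub["_norm"].to_numpy()
        folds = vals / ref_mean
        sem = float(stats.sem(folds, ddof=1)) if len(folds) > 1 else math.nan
        if group == reference_group:
            p = 1.0 if len(vals) > 1 else math.nan
        elif len(vals) < 2 or len(ref_vals) < 2:
            p = math.nan
        else:
            pooled_sd = math.sqrt(
                (vals.var(ddof=1) * (len(vals) - 1)
                 + ref_vals.var(ddof=1) * (len(ref_vals) - 1))
                / (len(vals) + len(ref_vals) - 2)
            )
            if pooled_sd == 0:
                p = 1.0 if vals.mean() == ref_vals.mean() else 0.0
            else:
                p = float(stats.ttest_ind(vals, ref_vals, equal_var=True).pvalue)
        out[str(group)] = GroupDensitometry(
            float(folds.mean()), sem, p, len(vals)
        )
    return out


def anova_oneway(lanes: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA across all lane groups on normalized signals."""
    norm = lanes["total_band_gray"] / lanes["loading_gray"]
    groups = [
        norm[lanes["group"] == g].to_numpy() for g in sorted(lanes["group"].unique())
    ]
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
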