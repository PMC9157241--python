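"""Normalization, expression summaries, and the NB exact differential test.

Counts are normalized with median-of-ratios size factors.  The two-group
test between a comparison window's endpoints is the conditioned
negative-binomial exact test: the pooled raw totals K_A and K_B of the two
groups are modelled as negative-binomial sums around a common per-gene mean
q (estimated from normalized counts), and the two-sided p-value sums, over
all splits (a, b) of K_A + K_B, the probabilities no larger than that of the
observed split, normalized by the total.  Dispersion follows the
Var = mu + alpha * mu^2 parameterization; alpha = 0 degenerates to Poisson.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import ComparisonWindow, StudyDesign
from .matrix import CountMatrix

log = logging.getLogger(__name__)

#: floor for the method-of-moments dispersion estimate
DISPERSION_FLOOR = 1e-8
#: pooled fallback when no group has >= 2 replicates
DEFAULT_DISPERSION = 0.1
#: pseudo-count keeping log2 fold changes finite at zero means
LOG2FC_PSEUDOCOUNT = 0.5


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style).

    The reference is the per-gene geometric mean across samples, computed
    over genes with strictly positive counts in every sample; each sample's
    factor is the median ratio of its counts to the reference.
    """
    mat = counts.counts.to_numpy(dtype=float)
    usable = (mat > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "size factors undefined: no gene has positive counts in every sample"
        )
    logs = np.log(mat[usable])
    ref = np.exp(logs.mean(axis=1))
    factors = np.median(mat[usable] / ref[:, None], axis=0)
    if not (factors > 0).all():
        raise ValueError("non-positive size factor encountered")
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalized_counts(counts: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    return counts.counts.div(factors.reindex(counts.sample_ids), axis=1)


def fpkm(counts: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    FPKM(g, s) = 1e9 * count(g, s) / (total_counts(s) * length_bp(g)).
    """
    totals = counts.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero column sum for sample(s): {zero}")
    return (
        counts.counts.div(totals, axis=1)
        .div(counts.lengths_bp, axis=0)
        .mul(1e9)
    )


def estimate_dispersion(
    counts: CountMatrix,
    factors: pd.Series,
    groups: Sequence[Sequence[str]],
) -> pd.Series:
    """Per-gene method-of-moments NB dispersion pooled across groups.

    alpha = max((pooled within-group variance - mean) / mean^2, floor) on
    normalized counts.  If no group has two or more replicates the estimate
    is undefined and a pooled default (0.1) is returned for every gene.
    """
    norm = normalized_counts(counts, factors)
    with_reps = [list(g) for g in groups if len(g) >= 2]
    if not with_reps:
        log.warning(
            "no group with >=2 replicates; falling back to pooled default "
            "dispersion %.3g for all genes", DEFAULT_DISPERSION,
        )
        return pd.Series(DEFAULT_DISPERSION, index=counts.gene_ids, name="dispersion")
    all_samples = [s for g in with_reps for s in g]
    num = np.zeros(counts.n_genes)
    df_total = 0
    for g in with_reps:
        sub = norm[list(g)].to_numpy()
        num += sub.var(axis=1, ddof=1) * (len(g) - 1)
        df_total += len(g) - 1
    pooled_var = num / df_total
    mean = norm[all_samples].to_numpy().mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / (mean * mean)
    alpha = np.where(mean > 0, alpha, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=counts.gene_ids, name="dispersion")


def _window_groups(
    counts: CountMatrix, window: ComparisonWindow, design: StudyDesign
) -> tuple[list[str], list[str]]:
    def resolve(tp: str, loc: str) -> list[str]:
        ids = [
            s
            for s in design.sample_ids(timepoint=tp, location=loc)
            if s in counts.counts.columns
        ]
        if not ids:
            raise ValueError(
                f"window {window.comparison_id!r}: no samples for "
                f"timepoint={tp!r}, location={loc!r} in the count matrix"
            )
        return ids

    return resolve(*window.group_a), resolve(*window.group_b)


def base_mean(
    counts: CountMatrix,
    factors: pd.Series,
    window: ComparisonWindow,
    design: StudyDesign,
) -> pd.Series:
    """Mean of normalized counts across all samples of both endpoint groups."""
    ga, gb = _window_groups(counts, window, design)
    norm = normalized_counts(counts, factors)
    return norm[ga + gb].mean(axis=1).rename("base_mean")


def _nb_logpmf(a: np.ndarray, mu: float, var: float) -> np.ndarray:
    """Log pmf of an NB with given mean/variance; Poisson when var <= mu."""
    if mu <= 0:
        out = np.full(a.shape, -np.inf)
        out[a == 0] = 0.0
        return out
    if var <= mu * (1 + 1e-12):
        return stats.poisson.logpmf(a, mu)
    size = mu * mu / (var - mu)
    p = size / (size + mu)
    return stats.nbinom.logpmf(a, size, p)


def nb_exact_pvalue(
    k_a: int,
    k_b: int,
    mu_a: float,
    mu_b: float,
    var_a: float,
    var_b: float,
) -> float:
    """Two-sided conditioned exact p-value for an observed (K_A, K_B) split."""
    k_s = k_a + k_b
    if k_s == 0:
        return 1.0
    a = np.arange(k_s + 1)
    logp = _nb_logpmf(a, mu_a, var_a) + _nb_logpmf(k_s - a, mu_b, var_b)
    # stabilize in log space before exponentiating
    m = logp.max()
    probs = np.exp(logp - m)
    total = probs.sum()
    if not np.isfinite(total) or total <= 0:
        return 1.0
    obs = probs[k_a]
    # tolerance absorbs float noise in pmf ties (cf. exact-test convention)
    return float(min(1.0, probs[probs <= obs * (1 + 1e-7)].sum() / total))


def nb_test(
    counts: CountMatrix,
    factors: pd.Series,
    window: ComparisonWindow,
    dispersion: pd.Series | Mapping[str, float] | float,
    design: StudyDesign,
) -> pd.DataFrame:
    """NB exact test between the window's endpoint groups.

    Returns a DataFrame with columns gene_id, comparison_id, base_mean,
    log2fc (group B over group A, with pseudo-count 0.5), p_value.
    """
    ga, gb = _window_groups(counts, window, design)
    if isinstance(dispersion, (int, float)):
        disp = pd.Series(float(dispersion), index=counts.gene_ids)
    else:
        disp = pd.Series(dispersion).reindex(counts.gene_ids)
        if disp.isna().any():
            raise ValueError("dispersion missing for some genes")
    if (disp < 0).any():
        raise ValueError("dispersion must be >= 0")

    norm = normalized_counts(counts, factors)
    mean_a = norm[ga].mean(axis=1).to_numpy()
    mean_b = norm[gb].mean(axis=1).to_numpy()
    bmean = norm[ga + gb].mean(axis=1).to_numpy()
    eps = LOG2FC_PSEUDOCOUNT
    log2fc = np.log2((mean_b + eps) / (mean_a + eps))

    raw = counts.counts
    k_a = raw[ga].sum(axis=1).to_numpy()
    k_b = raw[gb].sum(axis=1).to_numpy()
    sf_a = factors.reindex(ga).to_numpy()
    sf_b = factors.reindex(gb).to_numpy()
    s_a, s_b = sf_a.sum(), sf_b.sum()
    ssq_a, ssq_b = (sf_a**2).sum(), (sf_b**2).sum()

    disp_v = disp.to_numpy(dtype=float)
    pvals = np.empty(counts.n_genes)
    for i in range(counts.n_genes):
        q = bmean[i]
        mu_a, mu_b = q * s_a, q * s_b
        var_a = mu_a + disp_v[i] * q * q * ssq_a
        var_b = mu_b + disp_v[i] * q * q * ssq_b
        pvals[i] = nb_exact_pvalue(int(k_a[i]), int(k_b[i]), mu_a, mu_b, var_a, var_b)

    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "comparison_id": window.comparison_id,
            "base_mean": bmean,
            "log2fc": log2fc,
            "p_value": pvals,
        }
    )


def bh_adjust(p_values: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default in DE output)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values), method="fdr_bh")[1]
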