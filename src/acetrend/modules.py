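"""Per-phase trend calls and the three-way concordance module classifier.

The organizing rule is that a gene's expression change during development
matches its change during regeneration and opposes its change during injury.
Each phase contributes one trend call in {up, down, nc} (nc = no change,
i.e. not significant or directionless), and the triple (dev, inj, reg) is
classified into:

* module 1 — rule-conforming: either all three calls follow the rule, or two
  calls follow their pairwise constraint and the third is nc;
* module 2 — rule-violating: directional changes that break the rule;
* module 3 — unchanged: nc in at least two of the three phases.

"Opposite" is defined only between up and down; nc has no opposite.  The
classifier is a total function on the 27 possible triples.

Convention note: differential expression is called at p < alpha (default
0.05) with the sign taken from the log2 fold change; a log2 fold of exactly
0 cannot carry a direction and is called nc regardless of p.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

UP, DOWN, NC = "up", "down", "nc"
TREND_CALLS = (UP, DOWN, NC)

_OPPOSITE = {UP: DOWN, DOWN: UP}


def opposite(call: str) -> str | None:
    """The opposite directional call; nc has no opposite (returns None)."""
    return _OPPOSITE.get(call)


def call_trend(log2fc: float, p_value: float, alpha: float = 0.05) -> str:
    """Call up/down/nc from one differential-expression record."""
    if not (0.0 <= p_value <= 1.0):
        raise ValueError(f"p_value must be in [0, 1], got {p_value}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if p_value < alpha and log2fc > 0:
        return UP
    if p_value < alpha and log2fc < 0:
        return DOWN
    return NC


def call_trends(de: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Vectorized trend calls for a DE result table (gene_id-indexed)."""
    df = de.set_index("gene_id") if "gene_id" in de.columns else de
    sig = df["p_value"] < alpha
    calls = np.where(
        sig & (df["log2fc"] > 0), UP, np.where(sig & (df["log2fc"] < 0), DOWN, NC)
    )
    return pd.Series(calls, index=df.index, name="trend")


def classify_module(dev: str, inj: str, reg: str) -> int:
    """Classify one (dev, inj, reg) trend triple into module 1, 2, or 3."""
    for c in (dev, inj, reg):
        if c not in TREND_CALLS:
            raise ValueError(f"unknown trend call {c!r}")
    n_nc = (dev == NC) + (inj == NC) + (reg == NC)
    if n_nc >= 2:
        return 3
    if n_nc == 0:
        return 1 if (dev == reg and inj == opposite(dev)) else 2
    # exactly one nc: the remaining pair must satisfy its own constraint
    if inj == NC:
        ok = dev == reg
    elif reg == NC:
        ok = inj == opposite(dev)
    else:  # dev == NC
        ok = reg == opposite(inj)
    return 1 if ok else 2


def assign_modules(
    de_dev: pd.DataFrame,
    de_inj: pd.DataFrame,
    de_reg: pd.DataFrame,
    alpha: float = 0.05,
    location: str = "distal",
) -> pd.DataFrame:
    """Trend calls and module per gene over the shared gene universe.

    Genes missing from any of the three lists are reported with a warning
    rather than silently dropped.  Returns a DataFrame with columns
    gene_id, location, dev, inj, reg, module.
    """
    calls = {
        "dev": call_trends(de_dev, alpha),
        "inj": call_trends(de_inj, alpha),
        "reg": call_trends(de_reg, alpha),
    }
    shared = calls["dev"].index
    for s in (calls["inj"].index, calls["reg"].index):
        shared = shared.intersection(s)
    if len(shared) == 0:
        raise ValueError("empty shared gene universe across the three DE lists")
    union = calls["dev"].index.union(calls["inj"].index).union(calls["reg"].index)
    missing = union.difference(shared)
    if len(missing) > 0:
        warnings.warn(
            f"{len(missing)} gene(s) absent from at least one DE list were "
            f"excluded: {sorted(missing)[:10]}"
        )
    out = pd.DataFrame(
        {
            "gene_id": shared,
            "location": location,
            "dev": calls["dev"].loc[shared].to_numpy(),
            "inj": calls["inj"].loc[shared].to_numpy(),
            "reg": calls["reg"].loc[shared].to_numpy(),
        }
    )
    out["module"] = [
        classify_module(d, i, r) for d, i, r in zip(out["dev"], out["inj"], out["reg"])
    ]
    return out


@dataclass(frozen=True)
class ModuleProportions:
    counts: dict[int, int]
    share_m1_of_all: float
    share_m1_of_m1m2: float  # NaN when no module-1 or module-2 genes exist

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


def module_proportions(assignments: pd.DataFrame) -> ModuleProportions:
    """Module counts and the two headline shares of module 1."""
    if len(assignments) == 0:
        raise ValueError("no module assignments given")
    counts = {m: int((assignments["module"] == m).sum()) for m in (1, 2, 3)}
    total = sum(counts.values())
    m1m2 = counts[1] + counts[2]
    return ModuleProportions(
        counts=counts,
        share_m1_of_all=counts[1] / total,
        share_m1_of_m1m2=(counts[1] / m1m2) if m1m2 > 0 else math.nan,
    )


def de_proportions(calls_by_phase: dict[str, pd.Series]) -> dict[str, tuple[float, float, float]]:
    """Per-phase (up, down, nc) fractions; each triple sums to 1."""
    out: dict[str, tuple[float, float, float]] = {}
    for phase, calls in calls_by_phase.items():
        n = len(calls)
        if n == 0:
            raise ValueError(f"no trend calls for phase {phase!r}")
        vals = pd.Series(calls)
        out[phase] = (
            float((vals == UP).sum() / n),
            float((vals == DOWN).sum() / n),
            float((vals == NC).sum() / n),
        )
    return out


def trend_heatmap_matrix(
    fpkm: pd.DataFrame, reference: str | None = None, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, list[str]]:
    """Log2 fold matrix versus the reference timepoint, plus a clustered order.

    Each entry is log2((FPKM + eps) / (FPKM_ref + eps)) with eps = 1.  Gene
    order comes from average-linkage hierarchical clustering on the
    1 - Pearson correlation distance between log-fold rows; with fewer than
    two genes (or degenerate rows) the input order is kept.
    """
    if reference is None:
        reference = fpkm.columns[0]
    ref = fpkm[reference]
    logfold = np.log2(fpkm.add(pseudocount, axis=0).div(ref + pseudocount, axis=0))
    if logfold.shape[0] < 2:
        return logfold, list(logfold.index)

    x = logfold.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    # constant rows carry no trend: correlation 0 with everything else
    zero = norms == 0
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)

    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import squareform

    condensed = squareform(dist, checks=False)
    order_idx = leaves_list(average(condensed))
    order = [logfold.index[i] for i in order_idx]
    return logfold, order
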