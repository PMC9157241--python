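"""Interaction-edge tables, score filtering, hub overlap, and enrichment.

A desk-scale stand-in for the TRRUST/STRING/DAVID steps: TF-target and PPI
edge lists are read from TSV exports, filtered at a confidence-score cutoff
(strictly greater than 200 by default), intersected around two hub
regulators, and the resulting gene sets are tested for over-representation
with the upper-tail hypergeometric test and Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: default confidence-score cutoff (strictly greater-than)
DEFAULT_SCORE_CUTOFF = 200.0


@dataclass(frozen=True)
class InteractionEdge:
    source: str
    target: str
    score: float
    evidence: str  # 'tf_target' or 'ppi'


def read_edge_table(
    path, evidence: str, drop_self_loops: bool = True
) -> list[InteractionEdge]:
    """Parse a TSV with columns source, target[, score].

    score is required for evidence='ppi' and optional (default 1000, i.e.
    never filtered) for TF-target exports that carry no score.  Malformed
    rows are reported with their line numbers; duplicated (source, target)
    pairs are deduplicated keeping the maximum score.
    """
    if evidence not in ("tf_target", "ppi"):
        raise ValueError(f"unknown evidence type {evidence!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source", "target"}
    if evidence == "ppi":
        required.add("score")
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"edge table {path} missing columns: {sorted(missing)}")

    edges: dict[tuple[str, str], InteractionEdge] = {}
    bad: list[int] = []
    n_dup = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        src = getattr(row, "source", None)
        tgt = getattr(row, "target", None)
        raw_score = getattr(row, "score", None) if "score" in df.columns else None
        if pd.isna(src) or pd.isna(tgt):
            bad.append(i)
            continue
        if raw_score is None or (isinstance(raw_score, float) and np.isnan(raw_score)):
            score = 1000.0
            if evidence == "ppi":
                bad.append(i)
                continue
        else:
            try:
                score = float(raw_score)
            except (TypeError, ValueError):
                bad.append(i)
                continue
        if score <= 0:
            bad.append(i)
            continue
        if drop_self_loops and src == tgt:
            continue
        key = (str(src), str(tgt))
        prev = edges.get(key)
        if prev is not None:
            n_dup += 1
        if prev is None or score > prev.score:
            edges[key] = InteractionEdge(key[0], key[1], score, evidence)
    if bad:
        warnings.warn(f"{path}: rejected malformed row(s) at line(s) {bad}")
    if n_dup:
        warnings.warn(
            f"{path}: {n_dup} duplicated edge(s) deduplicated keeping max score"
        )
    return list(edges.values())


def filter_by_score(
    edges: list[InteractionEdge], min_score: float = DEFAULT_SCORE_CUTOFF
) -> list[InteractionEdge]:
    """Keep edges with score strictly greater than the cutoff; order kept."""
    return [e for e in edges if e.score > min_score]


def target_overlap(
    edges: list[InteractionEdge], hub_a: str, hub_b: str
) -> tuple[set[str], set[str], set[str]]:
    """(shared, a_only, b_only) neighbor sets of the two hubs.

    Edges are treated as undirected for neighborhood purposes; a hub absent
    from the edge list yields empty sets with a warning.
    """
    def neighbors(hub: str) -> set[str]:
        out = set()
        for e in edges:
            if e.source == hub:
                out.add(e.target)
            elif e.target == hub:
                out.add(e.source)
        return out

    na, nb = neighbors(hub_a), neighbors(hub_b)
    for hub, n in ((hub_a, na), (hub_b, nb)):
        if not n:
            warnings.warn(f"hub {hub!r} has no edges in the table")
    if not na or not nb:
        return set(), set(), set()
    return na & nb, na - nb, nb - na


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Standard GMT dialect: term <tab> description <tab> gene..."""
    terms: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {i}")
            terms[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return terms


def hypergeom_enrich(
    query: set[str],
    annotation: dict[str, tuple[str, list[str]]],
    universe: set[str],
) -> pd.DataFrame:
    """Over-representation of each annotation term in the query set.

    p = P(X >= k) for X ~ Hypergeom(N=|universe|, K=|term ∩ universe|,
    n=|query|); q by Benjamini-Hochberg over the tested terms.  Query genes
    outside the universe are dropped with a warning; terms are intersected
    with the universe.  Results sorted by p ascending, ties by term label.
    """
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) outside the universe were dropped"
        )
    q = query & universe
    n_universe, n_query = len(universe), len(q)
    rows = []
    for term, (_desc, genes) in annotation.items():
        term_genes = set(genes) & universe
        k = len(q & term_genes)
        big_k = len(term_genes)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_query))
        rows.append(
            {
                "term": term,
                "overlap_k": k,
                "term_size_K": big_k,
                "query_size_n": n_query,
                "universe_N": n_universe,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values(
            ["p_value", "term"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        out["q_value"] = []
    return out
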