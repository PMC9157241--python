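"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a two-arm nerve
transcriptome study: NB-distributed counts over a developmental time series
and an injury/regeneration series at two stump locations, with four planted
gene classes:

* ``concordant_up`` — rises across development, drops at injury, rises again
  across regeneration (the trend-concordance rule, upward flavour);
* ``concordant_down`` — the mirrored downward flavour;
* ``discordant`` — the injury-phase direction is flipped to match
  development, violating the rule while remaining fully differential;
* ``null`` — flat.

Gene means move between a baseline level and baseline x fold_magnitude with
geometric interpolation across intermediate timepoints, per-sample library
sizes carry multiplicative log-normal jitter, and counts are NB draws with
Var = mu + alpha * mu^2 (Poisson when alpha = 0).  All randomness flows from
explicit integer seeds; identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DEV_TIMEPOINTS, StudyDesign, canonical_design
from .matrix import CountMatrix
from .modules import NC, classify_module

GENE_CLASSES = ("concordant_up", "concordant_down", "discordant", "null")


@dataclass(frozen=True)
class SimulationConfig:
    n_concordant_up: int = 300
    n_concordant_down: int = 300
    n_discordant: int = 250
    n_null: int = 150
    baseline_mean: float = 100.0
    fold_magnitude: float = 4.0
    dispersion: float = 0.1
    n_replicates: int = 3
    library_size_jitter: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_concordant_up", "n_concordant_down", "n_discordant", "n_null"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.fold_magnitude < 1:
            raise ValueError("fold_magnitude must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.library_size_jitter < 0:
            raise ValueError("library_size_jitter must be >= 0")

    @property
    def n_genes(self) -> int:
        return (
            self.n_concordant_up
            + self.n_concordant_down
            + self.n_discordant
            + self.n_null
        )


@dataclass
class PlantedTruth:
    """Per-gene planted class, expected module, and per-phase log2 folds."""

    table: pd.DataFrame  # index gene_id; columns class, expected_module,
    # log2fc_dev, log2fc_inj, log2fc_reg

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "PlantedTruth":
        # keep_default_na: the class label 'null' is a string, not a missing value
        return cls(
            pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False)
            .astype(
                {
                    "expected_module": int,
                    "log2fc_dev": float,
                    "log2fc_inj": float,
                    "log2fc_reg": float,
                }
            )
        )

    @property
    def expected_module(self) -> pd.Series:
        return self.table["expected_module"]


def _sign_call(log2fc: float) -> str:
    if log2fc > 0:
        return "up"
    if log2fc < 0:
        return "down"
    return NC


def _planted_log2fc(gene_class: str, fold: float) -> tuple[float, float, float]:
    """(dev, inj, reg) planted log2 folds between each window's endpoints."""
    f = math.log2(fold)
    return {
        "concordant_up": (f, -f, f),
        "concordant_down": (-f, f, -f),
        "discordant": (f, f, f),
        "null": (0.0, 0.0, 0.0),
    }[gene_class]


def _geometric_path(start: float, stop: float, n: int) -> np.ndarray:
    return np.exp(np.linspace(math.log(start), math.log(stop), n))


def _dev_trajectory(cls_: str, base: float, fold: float) -> dict[str, float]:
    """Per-timepoint means along the developmental series.

    The planted change happens between the window endpoints S1d and S6m with
    geometric interpolation; before S1d and after S6m the mean stays at the
    nearest endpoint level.
    """
    lo, hi = base, base * fold
    start, stop = {
        "concordant_up": (lo, hi),
        "concordant_down": (hi, lo),
        "discordant": (lo, hi),
        "null": (lo, lo),
    }[cls_]
    tps = list(DEV_TIMEPOINTS)
    i0, i1 = tps.index("S1d"), tps.index("S6m")
    ramp = _geometric_path(start, stop, i1 - i0 + 1)
    means = {}
    for i, tp in enumerate(tps):
        if i < i0:
            means[tp] = start
        elif i > i1:
            means[tp] = stop
        else:
            means[tp] = float(ramp[i - i0])
    return means


def _injury_trajectory(cls_: str, base: float, fold: float) -> dict[str, float]:
    """Per-timepoint means along the injury series (N .. C21d).

    The injury window is N -> C1d and the regeneration window C7d -> C14d;
    between C1d and C7d the mean holds the post-injury level, and after C14d
    it holds the regenerated level.
    """
    lo, hi = base, base * fold
    levels = {
        # (N, C1d, C7d, C14d): injury drop then regeneration rise
        "concordant_up": (hi, lo, lo, hi),
        "concordant_down": (lo, hi, hi, lo),
        # injury sign flipped to match development; regeneration still up
        "discordant": (lo, hi, lo, hi),
        "null": (lo, lo, lo, lo),
    }[cls_]
    n_lvl, c1_lvl, c7_lvl, c14_lvl = levels
    return {
        "N": n_lvl,
        "C1d": c1_lvl,
        "C3d": float(_geometric_path(c1_lvl, c7_lvl, 3)[1]),
        "C7d": c7_lvl,
        "C14d": c14_lvl,
        "C21d": c14_lvl,
    }


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_study(
    config: SimulationConfig, design: StudyDesign | None = None
) -> tuple[CountMatrix, CountMatrix, CountMatrix, PlantedTruth]:
    """Simulate the full two-arm study.

    Returns (counts_dev, counts_injury_distal, counts_injury_proximal,
    truth).  The design must contain the endpoint timepoints of all three
    comparison windows (S1d, S6m, N, C1d, C7d, C14d).
    """
    if design is None:
        design = canonical_design(config.n_replicates)
    for tp, proc, loc in (
        ("S1d", "development", None),
        ("S6m", "development", None),
        ("N", "injury", None),
        ("C1d", "injury", None),
        ("C7d", "injury", None),
        ("C14d", "injury", None),
    ):
        if not design.samples_for(process=proc, timepoint=tp):
            raise ValueError(f"design lacks required endpoint timepoint {tp!r}")

    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    classes = np.repeat(
        GENE_CLASSES,
        [
            config.n_concordant_up,
            config.n_concordant_down,
            config.n_discordant,
            config.n_null,
        ],
    )
    width = max(4, len(str(max(n, 1))))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n + 1)]
    lengths = pd.Series(
        rng.integers(500, 5001, size=n), index=gene_ids, name="length_bp"
    )

    truth_rows = []
    for gid, cls_ in zip(gene_ids, classes):
        d, i, r = _planted_log2fc(cls_, config.fold_magnitude)
        truth_rows.append(
            {
                "gene_id": gid,
                "class": cls_,
                "expected_module": classify_module(
                    _sign_call(d), _sign_call(i), _sign_call(r)
                ),
                "log2fc_dev": d,
                "log2fc_inj": i,
                "log2fc_reg": r,
            }
        )
    truth = PlantedTruth(pd.DataFrame(truth_rows).set_index("gene_id"))

    dev_means = {
        cls_: _dev_trajectory(cls_, config.baseline_mean, config.fold_magnitude)
        for cls_ in GENE_CLASSES
    }
    inj_means = {
        cls_: _injury_trajectory(cls_, config.baseline_mean, config.fold_magnitude)
        for cls_ in GENE_CLASSES
    }

    def draw_matrix(samples, means_by_class) -> CountMatrix:
        cols = {}
        for s in samples:
            lib = (
                float(np.exp(rng.normal(0.0, config.library_size_jitter)))
                if config.library_size_jitter > 0
                else 1.0
            )
            mu = np.array(
                [means_by_class[cls_][s.timepoint] for cls_ in classes]
            ) * lib
            cols[s.sample_id] = _nb_draw(rng, mu, config.dispersion)
        df = pd.DataFrame(cols, index=gene_ids, dtype=np.int64)
        return CountMatrix(df, lengths.copy())

    counts_dev = draw_matrix(design.samples_for(process="development"), dev_means)
    counts_inj_d = draw_matrix(
        design.samples_for(process="injury", location="distal"), inj_means
    )
    counts_inj_p = draw_matrix(
        design.samples_for(process="injury", location="proximal"), inj_means
    )
    return counts_dev, counts_inj_d, counts_inj_p, truth


# ---------------------------------------------------------------------------
# qPCR panel


def simulate_qpcr_panel(
    true_log2fc: dict[str, float],
    ref_gene: str,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table whose expected 2^-ddCt fold equals 2^(true log2 fold).

    Returns a DataFrame with columns gene, group ('control'/'treated'),
    replicate, ct.  The reference gene must have true_log2fc = 0; Gaussian
    noise with sd noise_sd is added to every Ct measurement.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if ref_gene not in true_log2fc:
        raise ValueError(f"reference gene {ref_gene!r} missing from true_log2fc")
    if true_log2fc[ref_gene] != 0:
        raise ValueError("reference gene must have true_log2fc = 0")
    rng = np.random.default_rng(seed)
    ref_ct, target_base_ct = 20.0, 25.0
    rows = []
    for gene, lfc in true_log2fc.items():
        base = ref_ct if gene == ref_gene else target_base_ct
        for group, shift in (("control", 0.0), ("treated", -lfc)):
            for rep in range(1, n_replicates + 1):
                ct = base + shift if gene != ref_gene else base
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
                rows.append(
                    {"gene": gene, "group": group, "replicate": rep, "ct": ct}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# interaction networks


def simulate_networks(
    catalog,
    n_targets: int,
    shared_fraction: float,
    seed: int = 0,
    hub_a: str = "Hdac1",
    hub_b: str = "Kat2b",
):
    """TF-target and PPI edge tables around two hub regulators.

    round(shared_fraction * n_targets) targets attach to both hubs (in both
    tables); the remainder alternate between them.  Scores are uniform on
    (0, 1000].  Returns (tf_edges, ppi_edges) as InteractionEdge lists.
    """
    from .networks import InteractionEdge

    if not (0.0 <= shared_fraction <= 1.0):
        raise ValueError("shared_fraction must be in [0, 1]")
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    symbols = {e.symbol for e in catalog.entries}
    for hub in (hub_a, hub_b):
        if hub not in symbols:
            raise ValueError(f"hub {hub!r} not in catalog")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_targets)))
    targets = [f"T{i:0{width}d}" for i in range(1, n_targets + 1)]
    n_shared = round(shared_fraction * n_targets)

    def score() -> float:
        # uniform on (0, 1000]
        return float(1000.0 * (1.0 - rng.random()))

    tf_edges, ppi_edges = [], []
    for i, t in enumerate(targets):
        if i < n_shared:
            hubs = (hub_a, hub_b)
        else:
            hubs = (hub_a,) if (i - n_shared) % 2 == 0 else (hub_b,)
        for hub in hubs:
            tf_edges.append(InteractionEdge(hub, t, score(), "tf_target"))
            ppi_edges.append(InteractionEdge(hub, t, score(), "ppi"))
    return tf_edges, ppi_edges


def simulate_annotation(
    genes: list[str],
    enriched_term_genes: list[str] | None = None,
    n_terms: int = 10,
    term_size: int = 20,
    seed: int = 0,
) -> dict[str, tuple[str, list[str]]]:
    """GMT-style annotation: random terms plus one planted enriched term."""
    rng = np.random.default_rng(seed)
    terms: dict[str, tuple[str, list[str]]] = {}
    if enriched_term_genes:
        terms["planted_cell_cycle"] = (
            "planted enriched term",
            sorted(enriched_term_genes),
        )
    for i in range(1, n_terms + 1):
        size = min(term_size, len(genes))
        members = sorted(rng.choice(genes, size=size, replace=False).tolist())
        terms[f"random_term_{i:02d}"] = ("random background term", members)
    return terms


def write_gmt(terms: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in terms.items():
            fh.write("\t".join([term, desc, *genes]) + "\n")
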