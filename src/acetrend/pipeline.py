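"""End-to-end orchestration: simulate -> DE -> modules -> key regulators ->
networks -> machine-readable report.

Each stage draws its randomness from a seed derived as (run seed + stage
index), so stages are independently reproducible; re-running with an
identical config and seed reproduces the report byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import build_catalog, key_regulators, venn_regions
from .design import StudyDesign, canonical_design, canonical_windows
from .matrix import CountMatrix
from .modules import (
    assign_modules,
    call_trends,
    de_proportions,
    module_proportions,
    trend_heatmap_matrix,
)
from .networks import filter_by_score, hypergeom_enrich, target_overlap
from .quant import estimate_dispersion, fpkm, nb_test, size_factors
from .simulate import PlantedTruth, SimulationConfig, simulate_annotation, simulate_networks

log = logging.getLogger(__name__)

# stage indices for seed fan-out
_STAGE_SIMULATE = 0
_STAGE_NETWORKS = 2
_STAGE_ANNOTATION = 3


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    n_targets: int = 200
    shared_fraction: float = 0.5
    score_cutoff: float = 200.0

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "simulation": dataclasses.asdict(self.simulation),
            "alpha": self.alpha,
            "n_targets": self.n_targets,
            "shared_fraction": self.shared_fraction,
            "score_cutoff": self.score_cutoff,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    config: RunConfig
    design: StudyDesign
    counts_dev: CountMatrix
    counts_injury_distal: CountMatrix
    counts_injury_proximal: CountMatrix
    truth: PlantedTruth
    de_tables: dict[str, pd.DataFrame]
    assignments: dict[str, pd.DataFrame]  # location -> module table
    report: dict

    def report_json(self) -> str:
        return json.dumps(self.report, sort_keys=True, indent=2) + "\n"

    def write_report(self, path) -> None:
        Path(path).write_text(self.report_json())


def _confusion(truth: PlantedTruth, assignments: pd.DataFrame) -> dict:
    merged = assignments.set_index("gene_id").join(
        truth.table["expected_module"], how="inner"
    )
    out: dict[str, int] = {}
    for exp in (1, 2, 3):
        for rec in (1, 2, 3):
            out[f"planted_{exp}_recovered_{rec}"] = int(
                ((merged["expected_module"] == exp) & (merged["module"] == rec)).sum()
            )
    return out


def run_end_to_end(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic study and return the result bundle.

    When ``outdir`` is given, every stage output is written there as TSV /
    CSV / JSON; stages never mutate one another's inputs.
    """
    log.info("run config hash %s", config.config_hash())
    log.info(
        "trend-call convention: p < %.3g with the log2-fold sign defines "
        "up/down; otherwise nc", config.alpha,
    )
    sim = dataclasses.replace(
        config.simulation, seed=config.seed + _STAGE_SIMULATE
    )
    design = canonical_design(sim.n_replicates)
    from .simulate import simulate_study

    counts_dev, counts_inj_d, counts_inj_p, truth = simulate_study(sim, design)

    # --- differential expression per window -------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    matrices = {
        "development": counts_dev,
        "distal": counts_inj_d,
        "proximal": counts_inj_p,
    }
    factors = {k: size_factors(m) for k, m in matrices.items()}
    dispersions = {}
    for key, m in matrices.items():
        proc = "development" if key == "development" else "injury"
        loc = None if key == "development" else key
        groups = [
            design.sample_ids(process=proc, timepoint=tp, location=loc)
            for tp in design.timepoints(proc, loc)
        ]
        dispersions[key] = estimate_dispersion(m, factors[key], groups)

    dev_window = canonical_windows()["development"]
    de_tables["development"] = nb_test(
        counts_dev, factors["development"], dev_window,
        dispersions["development"], design,
    )
    for loc in ("distal", "proximal"):
        wins = canonical_windows(loc)
        m, f, d = matrices[loc], factors[loc], dispersions[loc]
        de_tables[f"injury-{loc}"] = nb_test(m, f, wins["injury"], d, design)
        de_tables[f"regeneration-{loc}"] = nb_test(
            m, f, wins["regeneration"], d, design
        )

    # --- module classification --------------------------------------------
    assignments: dict[str, pd.DataFrame] = {}
    proportions: dict[str, dict] = {}
    pies: dict[str, dict] = {}
    for loc in ("distal", "proximal"):
        assign = assign_modules(
            de_tables["development"],
            de_tables[f"injury-{loc}"],
            de_tables[f"regeneration-{loc}"],
            alpha=config.alpha,
            location=loc,
        )
        assignments[loc] = assign
        props = module_proportions(assign)
        proportions[loc] = {
            "counts": {str(k): v for k, v in props.counts.items()},
            "share_m1_of_all": props.share_m1_of_all,
            "share_m1_of_m1m2": props.share_m1_of_m1m2,
        }
        pies[loc] = {
            phase: list(fracs)
            for phase, fracs in de_proportions(
                {
                    "development": call_trends(de_tables["development"], config.alpha),
                    "injury": call_trends(de_tables[f"injury-{loc}"], config.alpha),
                    "regeneration": call_trends(
                        de_tables[f"regeneration-{loc}"], config.alpha
                    ),
                }
            ).items()
        }

    key_regs = sorted(key_regulators(assignments))

    # --- downstream networks ----------------------------------------------
    catalog = build_catalog()
    tf_edges, ppi_edges = simulate_networks(
        catalog,
        n_targets=config.n_targets,
        shared_fraction=config.shared_fraction,
        seed=config.seed + _STAGE_NETWORKS,
    )
    ppi_kept = filter_by_score(ppi_edges, config.score_cutoff)
    shared, a_only, b_only = target_overlap(ppi_kept, "Hdac1", "Kat2b")
    universe = {e.target for e in ppi_edges}
    annotation = simulate_annotation(
        sorted(universe),
        enriched_term_genes=sorted(shared)[: max(5, len(shared) // 4)] or None,
        seed=config.seed + _STAGE_ANNOTATION,
    )
    enrichment = (
        hypergeom_enrich(shared, annotation, universe)
        if shared
        else pd.DataFrame(
            columns=[
                "term", "overlap_k", "term_size_K", "query_size_n",
                "universe_N", "p_value", "q_value",
            ]
        )
    )
    venn = venn_regions({"Hdac1": shared | a_only, "Kat2b": shared | b_only})

    # --- report -------------------------------------------------------------
    planted_share_m1 = float(
        (truth.expected_module == 1).mean()
    )
    report = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_genes": sim.n_genes,
        "n_samples": {k: m.n_samples for k, m in matrices.items()},
        "de": {
            k: {
                "n_tested": int(len(t)),
                "n_significant": int((t["p_value"] < config.alpha).sum()),
            }
            for k, t in de_tables.items()
        },
        "module_proportions": proportions,
        "de_proportions": pies,
        "planted_module1_share": planted_share_m1,
        "confusion": {loc: _confusion(truth, a) for loc, a in assignments.items()},
        "key_regulators": key_regs,
        "networks": {
            "n_tf_edges": len(tf_edges),
            "n_ppi_edges": len(ppi_edges),
            "n_ppi_after_cutoff": len(ppi_kept),
            "overlap_shared": len(shared),
            "overlap_a_only": len(a_only),
            "overlap_b_only": len(b_only),
            "venn_region_sizes": {k: len(v) for k, v in venn.items()},
            "top_enriched_term": (
                str(enrichment.iloc[0]["term"]) if len(enrichment) else None
            ),
        },
    }

    result = PipelineResult(
        config=config,
        design=design,
        counts_dev=counts_dev,
        counts_injury_distal=counts_inj_d,
        counts_injury_proximal=counts_inj_p,
        truth=truth,
        de_tables=de_tables,
        assignments=assignments,
        report=report,
    )
    result._enrichment = enrichment  # type: ignore[attr-defined]
    result._venn = venn  # type: ignore[attr-defined]
    result._key_regs = key_regs  # type: ignore[attr-defined]

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        design.to_csv(outdir / "design.csv")
        counts_dev.to_tsv(outdir / "counts_development.tsv")
        counts_inj_d.to_tsv(outdir / "counts_injury_distal.tsv")
        counts_inj_p.to_tsv(outdir / "counts_injury_proximal.tsv")
        truth.to_tsv(outdir / "truth.tsv")
        for key, t in de_tables.items():
            t.to_csv(outdir / f"de_{key}.tsv", sep="\t", index=False)
        for loc, a in assignments.items():
            a.to_csv(outdir / f"modules_{loc}.tsv", sep="\t", index=False)
        enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        pd.DataFrame({"gene_id": key_regs}).to_csv(
            outdir / "key_regulators.tsv", sep="\t", index=False
        )
        result.write_report(outdir / "report.json")
    return result


def export_figure_tables(result: PipelineResult, outdir: str | Path) -> list[Path]:
    """Write heatmap-ready matrices and summary tables; no plotting.

    Emits one clustered log2-fold matrix per count matrix (development,
    injury-distal, injury-proximal; first column is the reference timepoint
    and is identically zero), the per-location module tables, pie-chart
    fractions, Venn region sizes, the enrichment table, and the
    key-regulator list.  Returns the written paths in a stable order.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    matrices = {
        "development": result.counts_dev,
        "injury_distal": result.counts_injury_distal,
        "injury_proximal": result.counts_injury_proximal,
    }
    for name, m in matrices.items():
        f = fpkm(m)
        # average replicate FPKM per timepoint, in design order
        proc = "development" if name == "development" else "injury"
        loc = None if name == "development" else name.split("_")[1]
        tps = result.design.timepoints(proc, loc)
        by_tp = pd.DataFrame(
            {
                tp: f[
                    [
                        s
                        for s in result.design.sample_ids(
                            process=proc, timepoint=tp, location=loc
                        )
                        if s in f.columns
                    ]
                ].mean(axis=1)
                for tp in tps
            }
        )
        logfold, order = trend_heatmap_matrix(by_tp)
        path = outdir / f"heatmap_{name}.tsv"
        logfold.loc[order].to_csv(path, sep="\t", index_label="gene_id")
        written.append(path)

    for loc, a in result.assignments.items():
        path = outdir / f"modules_{loc}.tsv"
        a.to_csv(path, sep="\t", index=False)
        written.append(path)

    pies_path = outdir / "pie_fractions.json"
    pies_path.write_text(
        json.dumps(result.report["de_proportions"], sort_keys=True, indent=2) + "\n"
    )
    written.append(pies_path)

    venn_path = outdir / "venn_regions.tsv"
    venn = getattr(result, "_venn", {})
    pd.DataFrame(
        {
            "region": list(venn),
            "size": [len(v) for v in venn.values()],
            "genes": [";".join(sorted(v)) for v in venn.values()],
        }
    ).to_csv(venn_path, sep="\t", index=False)
    written.append(venn_path)

    enrich_path = outdir / "enrichment.tsv"
    getattr(result, "_enrichment").to_csv(enrich_path, sep="\t", index=False)
    written.append(enrich_path)

    kr_path = outdir / "key_regulators.tsv"
    pd.DataFrame({"gene_id": getattr(result, "_key_regs", [])}).to_csv(
        kr_path, sep="\t", index=False
    )
    written.append(kr_path)
    return written
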