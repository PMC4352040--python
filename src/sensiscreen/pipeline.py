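"""End-to-end orchestration of the screen + phosphoproteome analysis.

:func:`run_full_analysis` wires the stages together:

    simulate (optional) -> score-screen -> call-hits -> error rates ->
    complex enrichment -> quant-phospho -> classify-sites

writing every intermediate table as TSV into one output directory and
returning a machine-readable summary (also written as ``summary.json``).
All seeds are derived from one pipeline seed; a rerun with the same
configuration reproduces every table and the summary exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment, hits, phospho, screen, sets, simulate
from .errors import DataError
from .io import write_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_analysis"]


@dataclass
class PipelineConfig:
    """Configuration of a full (synthetic-input) pipeline run."""

    outdir: Path = Path("sensiscreen_out")
    seed: int = 0
    thresholds: hits.ScreenThresholds = field(default_factory=hits.ScreenThresholds)
    classification_mode: str = "rules"  # "rules" | "cluster"
    fold_threshold: float = sets.FOLD_THRESHOLD
    common_mode: str = "reciprocal"  # "reciprocal" | "shared"
    fdr: float = 0.01
    n_random: int = 1000
    kmeans_k: int = 10
    n_complexes: int = 50
    complex_size_range: tuple[int, int] = (3, 6)
    planted_complex_fraction: float = 0.2
    n_nonexpressed: int = 100
    #: Optional simulator overrides; seeded from the pipeline seed when None.
    screen_sim: simulate.ScreenSimConfig | None = None
    phospho_sim: simulate.PhosphoSimConfig | None = None


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run the whole synthetic-data analysis and return the summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    screen_seed, complex_seed, enrich_seed, phospho_seed, kmeans_seed = _child_seeds(
        config.seed, 5
    )
    summary: dict = {
        "seed": config.seed,
        "parameters": {
            "thresholds": asdict(config.thresholds),
            "classification_mode": config.classification_mode,
            "fold_threshold": config.fold_threshold,
            "common_mode": config.common_mode,
            "fdr": config.fdr,
            "n_random": config.n_random,
            "kmeans_k": config.kmeans_k,
        },
    }
    logger.info("pipeline seed=%d outdir=%s", config.seed, out)

    # --- simulate screen ---------------------------------------------------
    scfg = config.screen_sim or simulate.ScreenSimConfig(seed=screen_seed)
    plates, gene_map, screen_truth = simulate.generate_screen_plates(scfg)
    write_table(plates, out / "plates.tsv")
    write_table(gene_map, out / "gene_map.tsv")
    write_table(screen_truth.amplicons, out / "screen_truth.tsv")

    # --- score screen ------------------------------------------------------
    if plates.empty:
        raise DataError("score-screen stage: empty plate/amplicon table")
    per_rep, merged = screen.score_screen(plates, gene_map=gene_map)
    write_table(merged, out / "amplicon_scores.tsv")

    # --- call hits ---------------------------------------------------------
    primary = hits.select_primary_hits(merged, config.thresholds)
    if config.classification_mode == "cluster":
        _, classified = hits.hierarchical_cluster(primary)
        classified = classified.rename(columns={"cluster_class": "hit_class"})
    else:
        classified = hits.classify_signatures(primary, config.thresholds)
    write_table(classified, out / "hits.tsv")
    gene_summaries = hits.compute_zdiff_final(merged)
    gene_summaries = hits.select_high_confidence(gene_summaries, config.thresholds)
    write_table(gene_summaries, out / "gene_summaries.tsv")
    summary["hit_class_counts"] = hits.class_counts(classified)
    hc = gene_summaries["confidence"].value_counts().to_dict()
    summary["high_confidence_counts"] = {
        "suppressors": int(hc.get(hits.HIGH_CONF_SUPPRESSOR, 0)),
        "enhancers": int(hc.get(hits.HIGH_CONF_ENHANCER, 0)),
    }

    # --- error rates (non-expressed stand-in list from planted nulls) ------
    truth_amp = screen_truth.amplicons
    null_genes = truth_amp.loc[truth_amp["true_class"] == simulate.NULL, "gene_id"]
    nonexpressed = set(null_genes.unique()[: config.n_nonexpressed])
    hit_genes = set(classified["gene_id"].dropna())
    hit_amplicons = set(classified["amplicon_id"])
    highconf_genes = set(
        gene_summaries.loc[gene_summaries["confidence"] != "None", "gene_id"]
    )
    library = truth_amp[["amplicon_id", "gene_id"]]
    fp, fn = hits.estimate_screen_error_rates(
        hit_genes, hit_amplicons, nonexpressed, highconf_genes, library
    )
    (out / "error_rates.txt").write_text(
        f"false_positive_rate\t{fp:.6f}\nfalse_negative_rate\t{fn:.6f}\n"
    )
    summary["error_rates"] = {"false_positive": fp, "false_negative": fn}

    # --- complex enrichment -------------------------------------------------
    scores = gene_summaries.set_index("gene_id")["zdiff_final"]
    complexes, complex_truth = simulate.generate_complex_library(
        config.n_complexes,
        config.complex_size_range,
        scores,
        planted_fraction=config.planted_complex_fraction,
        seed=complex_seed,
    )
    write_table(complexes, out / "complexes.tsv")
    write_table(complex_truth.complexes, out / "complex_truth.tsv")
    enriched = enrichment.enrich_complexes(
        complexes, gene_summaries, n_random=config.n_random, seed=enrich_seed
    )
    write_table(enriched, out / "enrichment.tsv")
    summary["enrichment"] = {
        "n_complexes_scored": int(len(enriched)),
        "n_significant_0.05": int((enriched["p_value"] <= 0.05).sum()),
    }

    # --- phospho quantification --------------------------------------------
    pcfg = config.phospho_sim or simulate.PhosphoSimConfig(seed=phospho_seed)
    experiments, phospho_truth, impurity = simulate.generate_phospho_study(pcfg)
    for name, (psms, _) in experiments.items():
        write_table(psms, out / f"psms_{name}.tsv")
    write_table(phospho_truth.phosphosites, out / "phospho_truth.tsv")
    # Replicated runs (one per background) carry the both-replicates rule;
    # cross-background ratios come from the all-six-condition run, where
    # they are within-run and hence free of between-run roster drift.
    replicated = {
        k: v for k, v in experiments.items() if v[1].has_replicates
    }
    site_rep = phospho.quantify_study(replicated, impurity, fdr=config.fdr)
    write_table(site_rep, out / "phosphosites_replicated.tsv")
    exp3_name = next(
        (k for k, v in experiments.items() if not v[1].has_replicates), None
    )
    if exp3_name is None:
        site_table = site_rep
    else:
        psms3, design3 = experiments[exp3_name]
        site_table = phospho.quantify_experiment(
            psms3, design3, impurity, fdr=config.fdr
        )
    write_table(site_table, out / "phosphosites.tsv")
    summary["n_phosphosites_quantified"] = int(len(site_table))
    summary["n_phosphosites_both_replicates"] = int(len(site_rep))

    # --- differential sets and profiles ------------------------------------
    _, set_summary = sets.analyze_study(
        site_rep,
        site_table if exp3_name is not None else None,
        threshold=config.fold_threshold,
        common_mode=config.common_mode,
    )
    summary["set_sizes"] = {
        k: v for k, v in set_summary.items() if k != "rescue_fraction"
    }
    summary["rescue_fraction"] = set_summary["rescue_fraction"]
    clusters = sets.kmeans_profiles(site_table, k=config.kmeans_k, seed=kmeans_seed)
    write_table(clusters, out / "clusters.tsv")
    summary["kmeans"] = {
        "k": config.kmeans_k,
        "n_profiled": int(len(clusters)),
    }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete; summary written to %s", out / "summary.json")
    return summary
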