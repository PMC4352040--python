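"""Hit selection, signature classification and screen error rates.

Primary hits are amplicons with |zdiff| at or beyond the primary cutoffs
(zdiff >= 2 or zdiff <= -2, inclusive). Hits fall into three signature
classes over the triple (z_pvr, z_gfp, zdiff):

* ``Suppressor`` — rescues cell number specifically in the sensitized
  background (zdiff >= 2, control background near baseline);
* ``Enhancer``   — worsens the sensitized phenotype (zdiff <= -2);
* ``Upstream``   — kills in the control background while having little
  additional effect once the receptor is already silenced (zdiff >= 2
  with a strong control-background deficit, z_gfp <= -2 by default).

The Suppressor/Upstream boundary was originally drawn by hierarchical
clustering of the score triples; both the explicit rule and the
clustering route (centered-correlation distance, complete linkage, three
flat clusters) are provided, and they agree on well-separated signatures.

Gene-level confidence uses ``zdiff_final``: the unweighted mean of zdiff
over all amplicons of a gene from the primary and verification screens.
High-confidence suppressors have zdiff_final >= 1.6, high-confidence
enhancers zdiff_final <= -1.2 (both inclusive).

Screen error rates follow the non-expressed-gene logic: the false
positive rate is the fraction of genes never expressed in the assayed
cell type that nevertheless score; the false negative rate is the
fraction of library amplicons targeting high-confidence genes that
failed to score in the primary screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import ConfigurationError, DataError, UndefinedRateError

__all__ = [
    "SUPPRESSOR",
    "ENHANCER",
    "UPSTREAM",
    "ScreenThresholds",
    "select_primary_hits",
    "classify_signatures",
    "hierarchical_cluster",
    "compute_zdiff_final",
    "select_high_confidence",
    "estimate_screen_error_rates",
    "class_counts",
]

SUPPRESSOR = "Suppressor"
ENHANCER = "Enhancer"
UPSTREAM = "Upstream"

HIGH_CONF_SUPPRESSOR = "HighConfSuppressor"
HIGH_CONF_ENHANCER = "HighConfEnhancer"


@dataclass(frozen=True)
class ScreenThresholds:
    """Score cutoffs for hit selection and gene-level confidence calls.

    All thresholds are inclusive. ``upstream_control_floor`` is the
    control-background Z at or below which an up-scoring hit is called
    Upstream rather than Suppressor.
    """

    primary_up: float = 2.0
    primary_down: float = -2.0
    final_sup: float = 1.6
    final_enh: float = -1.2
    upstream_control_floor: float = -2.0

    def __post_init__(self) -> None:
        if not (self.primary_up > 0 > self.primary_down):
            raise ConfigurationError("primary cutoffs must straddle zero")
        if not (self.final_sup > 0 > self.final_enh):
            raise ConfigurationError("final cutoffs must straddle zero")


def select_primary_hits(
    scores: pd.DataFrame, thresholds: ScreenThresholds = ScreenThresholds()
) -> pd.DataFrame:
    """Amplicons with zdiff at or beyond either primary cutoff (inclusive)."""
    if "complete" in scores.columns:
        scores = scores.loc[scores["complete"]]
    mask = (scores["zdiff"] >= thresholds.primary_up) | (
        scores["zdiff"] <= thresholds.primary_down
    )
    return scores.loc[mask].copy()


def classify_signatures(
    hits: pd.DataFrame, thresholds: ScreenThresholds = ScreenThresholds()
) -> pd.DataFrame:
    """Assign exactly one signature class to every primary hit."""
    out = hits.copy()
    is_enh = out["zdiff"] <= thresholds.primary_down
    is_up = (~is_enh) & (out["z_gfp"] <= thresholds.upstream_control_floor)
    out["hit_class"] = np.where(is_enh, ENHANCER, np.where(is_up, UPSTREAM, SUPPRESSOR))
    return out


def _centroid_class(centroid: pd.Series, thresholds: ScreenThresholds) -> str:
    # The signature rule applied to a cluster centroid. Hits are bimodal
    # in zdiff, so the sign separates enhancers from the rest even when a
    # centroid sits between the primary cutoffs.
    if centroid["zdiff"] < 0:
        return ENHANCER
    if centroid["z_gfp"] <= thresholds.upstream_control_floor:
        return UPSTREAM
    return SUPPRESSOR


def hierarchical_cluster(
    hits: pd.DataFrame,
    n_clusters: int = 3,
    n_subclusters: int = 12,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Cluster hit signatures by centered correlation, complete linkage.

    Rows are the (z_pvr, z_gfp, zdiff) triples; the distance between two
    amplicons is 1 minus the centered Pearson correlation of their
    triples. The tree is also cut into ``n_clusters`` flat clusters
    (``cluster`` column) for signature display.

    For class assignment the centered-correlation geometry is too
    coarse: the suppressor and upstream directions lie close together on
    the profile circle, so a 3-way cut often merges them while splitting
    another class on noise. The tree is therefore cut into
    ``n_subclusters`` micro-clusters and each micro-cluster centroid is
    mapped through the signature rule (``cluster_class`` column);
    several micro-clusters may share a class.

    Rows with zero variance (undefined correlation) are excluded and
    flagged with cluster 0 / class NA.

    Returns
    -------
    (linkage matrix, table with ``cluster`` and ``cluster_class`` columns)
    """
    X = hits[["z_pvr", "z_gfp", "zdiff"]].to_numpy(float)
    if len(X) < 2:
        raise DataError("need at least 2 hit amplicons to cluster")
    variable = X.std(axis=1) > 0
    Xv = X[variable]
    if len(Xv) < 2:
        raise DataError("fewer than 2 rows with per-row variance > 0")
    dist = pdist(Xv, metric="correlation")
    Z = linkage(dist, method="complete")
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    micro = fcluster(Z, t=min(n_subclusters, len(Xv)), criterion="maxclust")
    out = hits.copy()
    out["cluster"] = 0
    out.loc[out.index[variable], "cluster"] = flat
    out["_micro"] = 0
    out.loc[out.index[variable], "_micro"] = micro
    centroids = (
        out.loc[out["_micro"] > 0]
        .groupby("_micro")[["z_pvr", "z_gfp", "zdiff"]]
        .mean()
    )
    mapping = {
        cl: _centroid_class(row, thresholds) for cl, row in centroids.iterrows()
    }
    out["cluster_class"] = out["_micro"].map(mapping)
    out = out.drop(columns="_micro")
    return Z, out


def compute_zdiff_final(amplicon_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-gene ``zdiff_final``: unweighted mean over all amplicon zdiffs.

    Amplicons from the primary and verification screens are pooled and
    averaged equally. Input needs ``gene_id`` and ``zdiff`` columns.
    """
    if "gene_id" not in amplicon_scores.columns:
        raise DataError("amplicon scores lack a gene_id column")
    usable = amplicon_scores.dropna(subset=["zdiff"])
    if usable.empty:
        raise DataError("no amplicon zdiff values to average")
    summary = (
        usable.groupby("gene_id", sort=False)
        .agg(zdiff_final=("zdiff", "mean"), n_amplicons=("zdiff", "size"))
        .reset_index()
    )
    return summary


def select_high_confidence(
    gene_summaries: pd.DataFrame,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> pd.DataFrame:
    """Call high-confidence modifiers from gene-level ``zdiff_final``."""
    out = gene_summaries.copy()
    out["confidence"] = np.where(
        out["zdiff_final"] >= thresholds.final_sup,
        HIGH_CONF_SUPPRESSOR,
        np.where(out["zdiff_final"] <= thresholds.final_enh, HIGH_CONF_ENHANCER, "None"),
    )
    return out


def estimate_screen_error_rates(
    primary_hit_genes: set[str],
    primary_hit_amplicons: set[str],
    nonexpressed_genes: set[str],
    high_confidence_genes: set[str],
    library: pd.DataFrame,
) -> tuple[float, float]:
    """Estimate (false_positive_rate, false_negative_rate).

    Parameters
    ----------
    primary_hit_genes, primary_hit_amplicons
        Genes and amplicons that scored in the primary screen.
    nonexpressed_genes
        Genes with no detectable expression in the assayed cell type;
        any of these scoring is counted as a false positive.
    high_confidence_genes
        Genes confirmed by verification screening; all their library
        amplicons are expected to score, so those that did not are
        counted as false negatives.
    library
        Full amplicon library with ``amplicon_id`` and ``gene_id``.
    """
    if not nonexpressed_genes:
        raise UndefinedRateError("empty non-expressed gene list")
    if not high_confidence_genes:
        raise UndefinedRateError("empty high-confidence gene list")
    fp = len(nonexpressed_genes & primary_hit_genes) / len(nonexpressed_genes)
    relevant = library.loc[library["gene_id"].isin(high_confidence_genes), "amplicon_id"]
    if relevant.empty:
        raise UndefinedRateError("high-confidence genes have no library amplicons")
    n_total = relevant.nunique()
    n_scored = relevant.isin(primary_hit_amplicons).sum()
    fn = (n_total - n_scored) / n_total
    return fp, fn


def class_counts(classified_hits: pd.DataFrame, column: str = "hit_class") -> dict[str, int]:
    """Count amplicons per signature class (replay helper for score tables)."""
    counts = classified_hits[column].value_counts().to_dict()
    return {cls: int(counts.get(cls, 0)) for cls in (SUPPRESSOR, ENHANCER, UPSTREAM)}
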