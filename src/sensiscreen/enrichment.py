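"""Protein-complex over-representation among scored genes.

Each annotated complex receives an observed score: the mean absolute
gene-level phenotype score (|zdiff_final|) over its members that were
detected in the screen; members without a score are ignored. Its
significance is assessed by resampling: ``n_random`` gene sets of the
same size are drawn uniformly without replacement from the scored
universe, and

    p = (1 + #{random set score >= observed}) / (n_random + 1)

The plus-one correction keeps the p-value a valid permutation p-value,
bounded below by 1/(n_random+1) and never zero. Under exchangeable
scores p is approximately uniform on (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = ["EnrichmentResult", "complex_score", "enrichment_pvalue", "enrich_complexes"]


@dataclass(frozen=True)
class EnrichmentResult:
    complex_id: str
    n_members: int
    n_detected: int
    observed_score: float
    p_value: float
    n_random: int
    seed: int | None


def complex_score(members, gene_scores: pd.Series) -> float:
    """Mean |score| over complex members present in the scored universe."""
    present = [m for m in members if m in gene_scores.index]
    if not present:
        raise DataError("no complex member is present in the scored universe")
    return float(np.abs(gene_scores.loc[present]).mean())


def enrichment_pvalue(
    members,
    gene_scores: pd.Series,
    n_random: int = 1000,
    seed: int | None = None,
    complex_id: str = "",
) -> EnrichmentResult:
    """Permutation p-value for one complex against same-size random sets."""
    members = list(dict.fromkeys(members))
    present = [m for m in members if m in gene_scores.index]
    k = len(present)
    if k == 0:
        raise DataError(f"complex {complex_id!r} has no scored members")
    if k >= len(gene_scores):
        if k > len(gene_scores):
            raise ConfigurationError("complex larger than the scored universe")
    observed = float(np.abs(gene_scores.loc[present]).mean())
    abs_scores = np.abs(gene_scores.to_numpy(float))
    rng = np.random.default_rng(seed)
    n_universe = len(abs_scores)
    exceed = 0
    for _ in range(n_random):
        idx = rng.choice(n_universe, size=k, replace=False)
        if abs_scores[idx].mean() >= observed:
            exceed += 1
    p = (1 + exceed) / (n_random + 1)
    return EnrichmentResult(
        complex_id=complex_id,
        n_members=len(members),
        n_detected=k,
        observed_score=observed,
        p_value=p,
        n_random=n_random,
        seed=seed,
    )


def enrich_complexes(
    complexes: pd.DataFrame,
    gene_summaries: pd.DataFrame,
    n_random: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score every complex in a (complex_id, gene_id) membership table.

    Complexes with no member in the scored universe are not scorable and
    are silently excluded. Each complex draws its own random sets from a
    child seed so results do not depend on table order.
    """
    scores = gene_summaries.set_index("gene_id")["zdiff_final"]
    root = np.random.default_rng(seed)
    results = []
    for i, (cid, group) in enumerate(complexes.groupby("complex_id", sort=True)):
        members = list(group["gene_id"])
        if not any(m in scores.index for m in members):
            continue
        child_seed = int(root.integers(0, 2**31 - 1)) if seed is not None else None
        res = enrichment_pvalue(
            members, scores, n_random=n_random, seed=child_seed, complex_id=str(cid)
        )
        results.append(res)
    return pd.DataFrame(
        [
            {
                "complex_id": r.complex_id,
                "n_members": r.n_members,
                "n_detected": r.n_detected,
                "score": r.observed_score,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )
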