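"""Plate-level Z scoring for a sensitized differential RNAi screen.

An arrayed dsRNA library is screened twice per plate: once in a sensitized
background (receptor knockdown, here labelled ``Pvr``) and once in a
control background (``GFP`` knockdown), in duplicate. Each well's
luminescence reading ``x`` is standardized against the control wells of
its own plate/condition/replicate:

    z = (x - mu) / sigma

with ``mu`` and ``sigma`` the mean and sample standard deviation of the
control-well readings. The differential score of an amplicon is

    zdiff = z_sensitized - z_control

which is positive for reagents that rescue the sensitized phenotype and
negative for reagents that worsen it. Replicates are merged by averaging
Z per background and recomputing the difference, which equals the mean of
per-replicate ``zdiff`` values whenever both backgrounds carry the same
number of replicates.

Z scores are computed per plate x condition x replicate, so additive and
multiplicative plate effects cancel exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, DegeneratePlateError, MissingControlsError, PairingError

__all__ = [
    "PLATE_COLUMNS",
    "SENSITIZED",
    "CONTROL",
    "plate_zscores",
    "score_wells",
    "compute_zdiff",
    "amplicon_scores",
    "merge_replicates",
    "score_screen",
]

#: Canonical condition labels for the two screening backgrounds.
SENSITIZED = "Pvr"
CONTROL = "GFP"

#: Required columns of a plate-reading table (``plates.tsv``).
PLATE_COLUMNS = [
    "plate_id",
    "well",
    "condition",
    "replicate",
    "amplicon_id",
    "is_control",
    "reading",
]


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{what} is missing required columns: {missing}")


def plate_zscores(plate: pd.DataFrame) -> pd.DataFrame:
    """Standardize one plate/condition/replicate group against its controls.

    Parameters
    ----------
    plate
        Readings of a single plate under a single condition and replicate,
        with at least ``is_control`` and ``reading`` columns.

    Returns
    -------
    Copy of ``plate`` with a ``z`` column. Control wells standardize to
    mean exactly 0 and sample standard deviation exactly 1 because the
    same (n-1) estimator is used for sigma.
    """
    controls = plate.loc[plate["is_control"].astype(bool), "reading"]
    if len(controls) == 0:
        raise MissingControlsError("plate group has no control wells")
    if len(controls) < 2:
        raise MissingControlsError(
            "at least 2 control wells are needed to estimate sigma"
        )
    mu = controls.mean()
    sigma = controls.std(ddof=1)
    if not np.isfinite(sigma) or sigma <= 0:
        raise DegeneratePlateError(
            f"control wells have zero/undefined spread (sigma={sigma!r})"
        )
    out = plate.copy()
    out["z"] = (out["reading"] - mu) / sigma
    return out


def score_wells(plates: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`plate_zscores` to every plate x condition x replicate."""
    _require_columns(plates, PLATE_COLUMNS, "plate table")
    if plates.empty:
        raise DataError("plate table contains no readings")
    scored = [
        plate_zscores(group)
        for _, group in plates.groupby(
            ["plate_id", "condition", "replicate"], sort=False
        )
    ]
    return pd.concat(scored, ignore_index=True)


def compute_zdiff(z_sensitized, z_control):
    """Differential score: Z in the sensitized background minus control Z."""
    return z_sensitized - z_control


def amplicon_scores(
    plates: pd.DataFrame,
    gene_map: pd.DataFrame | None = None,
    sensitized: str = SENSITIZED,
    control: str = CONTROL,
) -> pd.DataFrame:
    """Per-replicate amplicon scores from raw plate readings.

    Candidate wells are Z scored per plate/condition/replicate and paired
    across the two backgrounds by (amplicon, replicate).

    Parameters
    ----------
    plates
        Long table with :data:`PLATE_COLUMNS`.
    gene_map
        Optional ``amplicon_id -> gene_id`` table; merged onto the output.

    Returns
    -------
    Table with columns ``amplicon_id, replicate, z_pvr, z_gfp, zdiff``
    (plus ``gene_id`` when a map is given). ``z_pvr`` holds the sensitized
    background, ``z_gfp`` the control background.
    """
    scored = score_wells(plates)
    candidates = scored.loc[~scored["is_control"].astype(bool)]
    dup = candidates.duplicated(["amplicon_id", "condition", "replicate"])
    if dup.any():
        raise PairingError(
            "amplicons must appear once per condition x replicate; duplicates: "
            f"{sorted(candidates.loc[dup, 'amplicon_id'].unique())[:5]}"
        )
    wide = (
        candidates.set_index(["amplicon_id", "replicate", "condition"])["z"]
        .unstack("condition")
        .reset_index()
    )
    for cond in (sensitized, control):
        if cond not in wide.columns:
            wide[cond] = np.nan
    wide = wide.rename(columns={sensitized: "z_pvr", control: "z_gfp"})
    wide["zdiff"] = compute_zdiff(wide["z_pvr"], wide["z_gfp"])
    if gene_map is not None:
        _require_columns(gene_map, ["amplicon_id", "gene_id"], "gene map")
        wide = wide.merge(gene_map, on="amplicon_id", how="left")
    cols = ["amplicon_id"] + (["gene_id"] if gene_map is not None else [])
    return wide[cols + ["replicate", "z_pvr", "z_gfp", "zdiff"]]


def merge_replicates(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Merge per-replicate scores into one record per amplicon.

    ``z_pvr`` and ``z_gfp`` are unweighted means over the replicates in
    which the amplicon was measured; ``zdiff`` is recomputed from the
    merged means. Amplicons entirely missing from one background are
    flagged ``complete=False`` and should be excluded from hit calling.
    """
    _require_columns(per_replicate, ["amplicon_id", "z_pvr", "z_gfp"], "score table")
    keys = ["amplicon_id"] + (
        ["gene_id"] if "gene_id" in per_replicate.columns else []
    )
    grouped = per_replicate.groupby(keys, sort=False, dropna=False)
    merged = grouped.agg(
        z_pvr=("z_pvr", "mean"),
        z_gfp=("z_gfp", "mean"),
        n_replicates=("z_pvr", "size"),
    ).reset_index()
    merged["zdiff"] = compute_zdiff(merged["z_pvr"], merged["z_gfp"])
    merged["complete"] = merged["z_pvr"].notna() & merged["z_gfp"].notna()
    return merged


def score_screen(
    plates: pd.DataFrame, gene_map: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full scoring stage: readings -> (per-replicate, merged) score tables."""
    per_rep = amplicon_scores(plates, gene_map=gene_map)
    return per_rep, merge_replicates(per_rep)
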