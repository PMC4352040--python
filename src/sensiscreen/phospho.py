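"""Six-plex TMT phosphopeptide quantification.

Takes PSM-level reporter-ion tables (channels 126-131) through the
standard quantification cascade:

1. site-localization and purity filters (AScore > 13, isolation
   specificity > 0.75; both strict),
2. target-decoy FDR thresholding of the search score at 1%,
3. isotopic impurity correction of the reporter intensities by solving
   the linear mixing system ``observed = M @ true``,
4. per-channel normalization to equalized channel totals,
5. replicate averaging with exclusion of peptides detected in only one
   replicate label set,
6. collapsing peptides to unique phosphosites (protein, residue,
   position), summing intensities per condition.

The experiment design maps each reporter channel to a biological
condition and replicate index; designs mirroring the three six-plex
layouts used for the receptor signaling study ship as
:data:`EXPERIMENT1` (high-Pvr background), :data:`EXPERIMENT2` (low-Pvr
background) and :data:`EXPERIMENT3` (all six conditions, single
replicate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DegenerateChannelError

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNELS",
    "INTENSITY_COLUMNS",
    "CONDITIONS",
    "TMTDesign",
    "EXPERIMENT1",
    "EXPERIMENT2",
    "EXPERIMENT3",
    "PSM_COLUMNS",
    "apply_psm_filters",
    "fdr_threshold",
    "correct_impurities",
    "normalize_channels",
    "aggregate_replicates",
    "collapse_to_phosphosites",
    "quantify_experiment",
    "quantify_study",
]

CHANNELS = (126, 127, 128, 129, 130, 131)
INTENSITY_COLUMNS = [f"i{c}" for c in CHANNELS]

# Condition labels: receptor state of the sensitizing RTK (Pvr), the
# insulin receptor (InR) and the ecdysone receptor (EcR).
HP_LI = "highPvr_lowInR"
HP_HI = "highPvr_highInR"
HP_LE = "highPvr_lowEcR"
LP_LI = "lowPvr_lowInR"
LP_HI = "lowPvr_highInR"
LP_LE = "lowPvr_lowEcR"
CONDITIONS = (HP_LI, HP_HI, HP_LE, LP_LI, LP_HI, LP_LE)

PSM_COLUMNS = [
    "peptide",
    "protein",
    "site_positions",
    "ascores",
    "isolation_specificity",
    "search_score",
    "is_decoy",
] + INTENSITY_COLUMNS


@dataclass(frozen=True)
class TMTDesign:
    """Channel layout of one six-plex experiment.

    ``channels`` maps each reporter channel to a (condition, replicate)
    pair. Replicates are biological replicates multiplexed as separate
    labels within the same run.
    """

    experiment: str
    channels: tuple[tuple[int, str, int], ...]

    def __post_init__(self) -> None:
        chans = [c for c, _, _ in self.channels]
        if sorted(chans) != list(CHANNELS):
            raise ConfigurationError(
                f"design must map all six channels 126-131, got {sorted(chans)}"
            )

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, cond, _ in self.channels:
            seen.setdefault(cond, None)
        return tuple(seen)

    @property
    def replicate_indices(self) -> tuple[int, ...]:
        return tuple(sorted({r for _, _, r in self.channels}))

    @property
    def has_replicates(self) -> bool:
        return len(self.replicate_indices) > 1

    def channels_of_replicate(self, replicate: int) -> list[int]:
        return [c for c, _, r in self.channels if r == replicate]

    def channels_of_condition(self, condition: str) -> list[tuple[int, int]]:
        return [(c, r) for c, cond, r in self.channels if cond == condition]


EXPERIMENT1 = TMTDesign(
    "exp1",
    (
        (126, HP_LI, 1),
        (127, HP_LI, 2),
        (128, HP_HI, 1),
        (129, HP_HI, 2),
        (130, HP_LE, 1),
        (131, HP_LE, 2),
    ),
)
EXPERIMENT2 = TMTDesign(
    "exp2",
    (
        (126, LP_LI, 1),
        (127, LP_LI, 2),
        (128, LP_HI, 1),
        (129, LP_HI, 2),
        (130, LP_LE, 1),
        (131, LP_LE, 2),
    ),
)
EXPERIMENT3 = TMTDesign(
    "exp3",
    (
        (126, LP_LI, 1),
        (127, LP_HI, 1),
        (128, LP_LE, 1),
        (129, HP_LI, 1),
        (130, HP_HI, 1),
        (131, HP_LE, 1),
    ),
)


def _split_sites(sites: str) -> list[str]:
    return [s for s in str(sites).split(";") if s]


def _split_ascores(ascores) -> list[float]:
    return [float(a) for a in str(ascores).split(";") if a]


def apply_psm_filters(
    psms: pd.DataFrame,
    ascore_min: float = 13.0,
    isolation_min: float = 0.75,
) -> pd.DataFrame:
    """Site-localization and co-isolation purity filters (both strict).

    A phosphosite is retained only if its AScore is strictly greater
    than ``ascore_min``; when a peptide carries several sites with
    different AScores the filter acts per site, and the peptide is
    dropped once no site survives. Peptides whose isolation specificity
    is not strictly above ``isolation_min`` are dropped entirely.
    Records with missing/malformed AScores are rejected with a logged
    warning count.
    """
    keep_rows: list[int] = []
    new_sites: list[str] = []
    new_ascores: list[str] = []
    n_rejected = 0
    for idx, row in psms.iterrows():
        iso = row["isolation_specificity"]
        if pd.isna(iso) or iso <= isolation_min:
            continue
        try:
            sites = _split_sites(row["site_positions"])
            ascores = _split_ascores(row["ascores"])
            if len(sites) != len(ascores) or not sites:
                raise ValueError
        except ValueError:
            n_rejected += 1
            continue
        kept = [(s, a) for s, a in zip(sites, ascores) if a > ascore_min]
        if not kept:
            continue
        keep_rows.append(idx)
        new_sites.append(";".join(s for s, _ in kept))
        new_ascores.append(";".join(repr(a) for _, a in kept))
    if n_rejected:
        logger.warning("rejected %d PSMs with missing/malformed AScores", n_rejected)
    out = psms.loc[keep_rows].copy()
    out["site_positions"] = new_sites
    out["ascores"] = new_ascores
    return out


def fdr_threshold(
    psms: pd.DataFrame, fdr: float = 0.01
) -> tuple[float, pd.DataFrame]:
    """Target-decoy FDR thresholding of the search score.

    Scanning records in decreasing score order, accept the largest
    prefix whose decoy/target ratio does not exceed ``fdr``; ties are
    broken with decoys first, which is the conservative direction.
    Returns the score cutoff and the accepted target records (decoys
    removed). When no prefix satisfies the bound the accept set is empty
    and a warning is logged.
    """
    if psms.empty or not (~psms["is_decoy"].astype(bool)).any():
        return np.inf, psms.iloc[0:0].copy()
    order = psms.sort_values(
        ["search_score", "is_decoy"], ascending=[False, False], kind="mergesort"
    )
    is_decoy = order["is_decoy"].astype(bool).to_numpy()
    cum_decoy = np.cumsum(is_decoy)
    cum_target = np.cumsum(~is_decoy)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (cum_target > 0) & (cum_decoy <= fdr * cum_target)
    if not ok.any():
        logger.warning("no score threshold achieves FDR <= %g", fdr)
        return np.inf, psms.iloc[0:0].copy()
    last = int(np.flatnonzero(ok)[-1])
    cutoff = float(order["search_score"].iloc[last])
    accepted = order.iloc[: last + 1]
    accepted = accepted.loc[~accepted["is_decoy"].astype(bool)]
    return cutoff, accepted.sort_index()


def correct_impurities(intensities, impurity_matrix) -> np.ndarray:
    """Invert isotopic cross-channel leakage.

    ``impurity_matrix[i, j]`` is the fraction of channel ``j``'s true
    signal observed in channel ``i`` (columns describe where each
    label's signal ends up). The observed vector obeys
    ``observed = M @ true``; this solves for ``true`` and clamps small
    negative solutions to zero.

    Accepts a single 6-vector or an (n, 6) matrix of rows.
    """
    M = np.asarray(impurity_matrix, float)
    if M.shape != (6, 6):
        raise ConfigurationError(f"impurity matrix must be 6x6, got {M.shape}")
    if np.linalg.matrix_rank(M) < 6:
        raise ConfigurationError("impurity matrix is singular")
    X = np.asarray(intensities, float)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    if X2.shape[1] != 6:
        raise DataError(f"expected 6 reporter channels, got {X2.shape[1]}")
    corrected = np.linalg.solve(M, X2.T).T
    corrected = np.clip(corrected, 0.0, None)
    return corrected[0] if single else corrected


def normalize_channels(table: pd.DataFrame) -> pd.DataFrame:
    """Equalize reporter-channel totals.

    Each intensity is divided by its channel's summed intensity and
    rescaled by the mean channel total, so that after normalization all
    channel totals are equal while magnitudes stay comparable to the
    input. Idempotent.
    """
    out = table.copy()
    X = out[INTENSITY_COLUMNS].to_numpy(float)
    totals = X.sum(axis=0)
    if np.any(totals <= 0):
        bad = [INTENSITY_COLUMNS[i] for i in np.flatnonzero(totals <= 0)]
        raise DegenerateChannelError(f"non-positive channel totals: {bad}")
    out[INTENSITY_COLUMNS] = X / totals * totals.mean()
    return out


def aggregate_replicates(table: pd.DataFrame, design: TMTDesign) -> pd.DataFrame:
    """Average channels into per-condition intensities, applying the
    single-replicate exclusion.

    A peptide counts as detected in replicate ``r`` when any of that
    replicate's channels is positive. In designs with replicates,
    peptides detected in only one replicate are excluded from further
    analysis; single-replicate designs pass through unchanged. The
    per-condition value is the mean over that condition's detectable
    channels (NA when none is detectable).
    """
    meta_cols = [c for c in table.columns if c not in INTENSITY_COLUMNS]
    X = table[INTENSITY_COLUMNS].to_numpy(float)
    col_of = {c: i for i, c in enumerate(CHANNELS)}

    detected = np.zeros((len(table), len(design.replicate_indices)), dtype=bool)
    for j, r in enumerate(design.replicate_indices):
        cols = [col_of[c] for c in design.channels_of_replicate(r)]
        detected[:, j] = (X[:, cols] > 0).any(axis=1)
    n_detected = detected.sum(axis=1)
    if design.has_replicates:
        keep = n_detected >= 2
    else:
        keep = n_detected >= 1

    out = table.loc[keep, meta_cols].copy()
    Xk = X[keep]
    for cond in design.conditions:
        cols = [col_of[c] for c, _ in design.channels_of_condition(cond)]
        block = Xk[:, cols]
        pos = block > 0
        with np.errstate(invalid="ignore"):
            vals = np.where(
                pos.any(axis=1), block.sum(axis=1) / np.maximum(pos.sum(axis=1), 1), np.nan
            )
        out[cond] = vals
        # Per-replicate values kept alongside the average, for the
        # average-of-per-replicate-ratios fold-change mode downstream.
        for c, r in design.channels_of_condition(cond):
            col = Xk[:, col_of[c]]
            out[f"{cond}__rep{r}"] = np.where(col > 0, col, np.nan)
    out["n_replicates_detected"] = n_detected[keep]
    return out


def collapse_to_phosphosites(peptide_table: pd.DataFrame, design: TMTDesign) -> pd.DataFrame:
    """Collapse peptide quantifications to unique phosphosites.

    The site key is (protein, residue, position), rendered as e.g.
    ``"FGF8:S45"``. Peptides covering the same site have their
    per-condition intensities summed before any ratio computation;
    multiply-phosphorylated peptides contribute to each constituent
    site. Sites with unparsable coordinates are dropped with a warning.
    """
    cond_cols = [
        c
        for c in peptide_table.columns
        if c in design.conditions
        or any(c.startswith(f"{cond}__rep") for cond in design.conditions)
    ]
    rows = []
    n_dropped = 0
    for _, row in peptide_table.iterrows():
        for site in _split_sites(row["site_positions"]):
            residue, pos_txt = site[0], site[1:]
            if residue not in "STY" or not pos_txt.isdigit():
                n_dropped += 1
                continue
            rec = {"site_id": f"{row['protein']}:{site}"}
            for c in cond_cols:
                rec[c] = row[c]
            rec["n_replicates_detected"] = row.get("n_replicates_detected", np.nan)
            rows.append(rec)
    if n_dropped:
        logger.warning("dropped %d site assignments with unmappable coordinates", n_dropped)
    if not rows:
        return pd.DataFrame(columns=["site_id", *cond_cols, "n_replicates_detected"])
    long = pd.DataFrame(rows)
    collapsed = (
        long.groupby("site_id", sort=True)
        .agg(
            **{c: (c, lambda s: s.sum(min_count=1)) for c in cond_cols},
            n_replicates_detected=("n_replicates_detected", "max"),
        )
        .reset_index()
    )
    return collapsed


def quantify_experiment(
    psms: pd.DataFrame,
    design: TMTDesign,
    impurity_matrix,
    fdr: float = 0.01,
    ascore_min: float = 13.0,
    isolation_min: float = 0.75,
) -> pd.DataFrame:
    """Full quantification cascade for one six-plex experiment.

    Order of operations: PSM filters -> FDR threshold -> impurity
    correction -> channel normalization -> replicate averaging -> site
    collapsing.
    """
    filtered = apply_psm_filters(psms, ascore_min=ascore_min, isolation_min=isolation_min)
    _, accepted = fdr_threshold(filtered, fdr=fdr)
    if accepted.empty:
        return pd.DataFrame(
            columns=["site_id", *design.conditions, "n_replicates_detected"]
        )
    accepted = accepted.copy()
    accepted[INTENSITY_COLUMNS] = correct_impurities(
        accepted[INTENSITY_COLUMNS].to_numpy(float), impurity_matrix
    )
    normalized = normalize_channels(accepted)
    averaged = aggregate_replicates(normalized, design)
    return collapse_to_phosphosites(averaged, design)


def quantify_study(
    experiments: dict[str, tuple[pd.DataFrame, TMTDesign]],
    impurity_matrix,
    **kwargs,
) -> pd.DataFrame:
    """Quantify several experiments and join them on the site key.

    Conditions quantified by more than one experiment keep the value of
    the first experiment that reports them (experiments are processed in
    dict order).
    """
    merged: pd.DataFrame | None = None
    for name, (psms, design) in experiments.items():
        sites = quantify_experiment(psms, design, impurity_matrix, **kwargs)
        sites = sites.rename(
            columns={"n_replicates_detected": f"n_replicates_detected_{name}"}
        )
        if merged is None:
            merged = sites
        else:
            overlap = [
                c
                for c in sites.columns
                if c != "site_id" and c in merged.columns
            ]
            merged = merged.merge(
                sites.drop(columns=overlap), on="site_id", how="outer"
            )
    return merged if merged is not None else pd.DataFrame(columns=["site_id"])
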