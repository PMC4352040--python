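"""Fold-change calling and differential phosphosite set logic.

Phosphosites quantified across six signaling states — every combination
of receptor state for Pvr (the sensitizing RTK), InR (insulin receptor)
and EcR (ecdysone receptor) — are classified by linear fold change with
a strict 1.5-fold rule: a comparison A vs B is "up" when the ratio of
replicate-averaged intensities exceeds 1.5 and "down" when it falls
below 1/1.5 (symmetric on the log scale). From these calls the module
derives the study's differential sets:

* the InR-specific set (insulin-responsive sites within one Pvr
  background),
* the Pvr-specific set (sites downregulated upon Pvr loss),
* the common Pvr/InR set (reciprocal regulation: lost upon Pvr
  knockdown and restored by insulin in the low-Pvr background, or the
  mirrored pairing), with a shared-directionality alternative,
* receptor-specific sets (higher under Pvr-only vs InR-only signaling,
  excluding common targets),
* EcR-responsive sets (EcR knockdown vs control, per background),

plus the rescue fraction (how much of the Pvr-dependent phosphorylation
insulin restores) and k-means profiling of median-normalized intensity
profiles across the six conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ConfigurationError, UndefinedRateError
from .phospho import CONDITIONS, HP_HI, HP_LE, HP_LI, LP_HI, LP_LE, LP_LI

__all__ = [
    "FOLD_THRESHOLD",
    "fold_change_call",
    "define_inr_set",
    "define_pvr_set",
    "define_common_set",
    "define_receptor_specific_sets",
    "define_ecr_sets",
    "rescue_fraction",
    "kmeans_profiles",
    "set_size_summary",
    "analyze_study",
]

FOLD_THRESHOLD = 1.5

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"
NOT_CALLABLE = "not_callable"


def _mean_replicate_ratio(
    sites: pd.DataFrame, condition_a: str, condition_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of per-replicate ratios over replicates where both sides are
    positive; returns (ratio-like numerator, denominator placeholder)."""
    rep_a = sorted(c for c in sites.columns if c.startswith(f"{condition_a}__rep"))
    rep_b = sorted(c for c in sites.columns if c.startswith(f"{condition_b}__rep"))
    if not rep_a or not rep_b:
        raise ConfigurationError(
            "average_of_ratios mode needs per-replicate columns "
            f"({condition_a}__rep*, {condition_b}__rep*)"
        )
    pairs = []
    for ca in rep_a:
        r = ca.rsplit("__rep", 1)[1]
        cb = f"{condition_b}__rep{r}"
        if cb in rep_b:
            pairs.append((ca, cb))
    if not pairs:
        raise ConfigurationError("no matching replicate indices between conditions")
    ratios = np.full((len(sites), len(pairs)), np.nan)
    for j, (ca, cb) in enumerate(pairs):
        a = sites[ca].to_numpy(float)
        b = sites[cb].to_numpy(float)
        ok = np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios[ok, j] = a[ok] / b[ok]
    with np.errstate(invalid="ignore"):
        mean_ratio = np.nanmean(ratios, axis=1)
    return mean_ratio, np.isfinite(mean_ratio)


def fold_change_call(
    sites: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    threshold: float = FOLD_THRESHOLD,
    mode: str = "ratio_of_averages",
) -> pd.DataFrame:
    """Call per-site fold changes for condition_a vs condition_b.

    In the default ``ratio_of_averages`` mode,
    ratio = averaged(A) / averaged(B); in ``average_of_ratios`` mode the
    ratio is the mean of per-replicate ratios (requires the
    ``<condition>__rep<i>`` columns emitted by replicate aggregation).
    Direction is ``up`` iff ratio > threshold (strict), ``down`` iff
    ratio < 1/threshold, otherwise ``unchanged``. Sites with a missing
    or non-positive value in either condition are ``not_callable`` and
    excluded from counts.
    """
    if threshold <= 1:
        raise ConfigurationError("fold threshold must exceed 1")
    if mode == "average_of_ratios":
        mean_ratio, callable_ = _mean_replicate_ratio(sites, condition_a, condition_b)
        direction = np.full(len(sites), NOT_CALLABLE, dtype=object)
        direction[callable_ & (mean_ratio > threshold)] = UP
        direction[callable_ & (mean_ratio < 1.0 / threshold)] = DOWN
        direction[
            callable_ & (mean_ratio <= threshold) & (mean_ratio >= 1.0 / threshold)
        ] = UNCHANGED
        return pd.DataFrame(
            {
                "site_id": sites["site_id"].to_numpy(),
                "comparison": f"{condition_a}_vs_{condition_b}",
                "ratio": mean_ratio,
                "direction": direction,
            }
        )
    if mode != "ratio_of_averages":
        raise ConfigurationError(f"unknown fold-change mode {mode!r}")
    a = sites[condition_a].to_numpy(float)
    b = sites[condition_b].to_numpy(float)
    callable_ = np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(callable_, a / b, np.nan)
    direction = np.full(len(sites), NOT_CALLABLE, dtype=object)
    direction[callable_ & (ratio > threshold)] = UP
    direction[callable_ & (ratio < 1.0 / threshold)] = DOWN
    direction[callable_ & (ratio <= threshold) & (ratio >= 1.0 / threshold)] = UNCHANGED
    return pd.DataFrame(
        {
            "site_id": sites["site_id"].to_numpy(),
            "comparison": f"{condition_a}_vs_{condition_b}",
            "ratio": ratio,
            "direction": direction,
        }
    )


def _direction_sets(calls: pd.DataFrame) -> dict[str, set[str]]:
    return {
        UP: set(calls.loc[calls["direction"] == UP, "site_id"]),
        DOWN: set(calls.loc[calls["direction"] == DOWN, "site_id"]),
    }


def define_inr_set(
    sites: pd.DataFrame, background: str = "highPvr", threshold: float = FOLD_THRESHOLD
) -> dict[str, set[str]]:
    """Insulin-responsive (InR-specific) up/down sets within a background.

    Compares (background, high InR) against (background, low InR).
    ``background`` is ``"highPvr"`` or ``"lowPvr"``.
    """
    if background not in ("highPvr", "lowPvr"):
        raise ConfigurationError(f"unknown background {background!r}")
    hi = f"{background}_highInR"
    lo = f"{background}_lowInR"
    return _direction_sets(fold_change_call(sites, hi, lo, threshold))


def define_pvr_set(sites: pd.DataFrame, threshold: float = FOLD_THRESHOLD) -> set[str]:
    """Pvr-dependent sites: downregulated in low-Pvr vs high-Pvr conditions."""
    calls = fold_change_call(sites, LP_LI, HP_LI, threshold)
    return _direction_sets(calls)[DOWN]


def define_common_set(
    sites: pd.DataFrame,
    mode: str = "reciprocal",
    threshold: float = FOLD_THRESHOLD,
) -> dict[str, set[str]]:
    """Common Pvr/InR targets.

    ``reciprocal`` (default): sites lost upon Pvr knockdown AND restored
    by insulin in the low-Pvr background (label ``up``), plus the
    mirrored pairing (gained upon Pvr knockdown AND reduced by insulin;
    label ``down``).

    ``shared``: sites with the same-direction insulin response in both
    Pvr backgrounds.
    """
    if mode == "reciprocal":
        pvr_calls = _direction_sets(fold_change_call(sites, LP_LI, HP_LI, threshold))
        ins_calls = define_inr_set(sites, "lowPvr", threshold)
        return {
            UP: pvr_calls[DOWN] & ins_calls[UP],
            DOWN: pvr_calls[UP] & ins_calls[DOWN],
        }
    if mode == "shared":
        hi = define_inr_set(sites, "highPvr", threshold)
        lo = define_inr_set(sites, "lowPvr", threshold)
        return {UP: hi[UP] & lo[UP], DOWN: hi[DOWN] & lo[DOWN]}
    raise ConfigurationError(f"unknown common-set mode {mode!r}")


def define_receptor_specific_sets(
    sites: pd.DataFrame,
    common: dict[str, set[str]] | None = None,
    threshold: float = FOLD_THRESHOLD,
) -> dict[str, set[str]]:
    """Pvr-only and InR-only targets.

    Compares the pure-Pvr state (high Pvr, low InR) against the pure-InR
    state (low Pvr, high InR); sites higher under Pvr-only signaling are
    Pvr-only, sites higher under InR-only signaling are InR-only, in
    both cases excluding common targets. The labels are mutually
    exclusive by construction.
    """
    if common is None:
        common = define_common_set(sites, threshold=threshold)
    common_ids = common[UP] | common[DOWN]
    calls = _direction_sets(fold_change_call(sites, HP_LI, LP_HI, threshold))
    return {
        "Pvr_only": calls[UP] - common_ids,
        "InR_only": calls[DOWN] - common_ids,
    }


def define_ecr_sets(
    sites: pd.DataFrame, background: str = "highPvr", threshold: float = FOLD_THRESHOLD
) -> dict[str, set[str]]:
    """EcR-responsive up/down sets: EcR knockdown vs control, per background."""
    if background not in ("highPvr", "lowPvr"):
        raise ConfigurationError(f"unknown background {background!r}")
    le = f"{background}_lowEcR"
    li = f"{background}_lowInR"
    return _direction_sets(fold_change_call(sites, le, li, threshold))


def rescue_fraction(
    pvr_set: set[str], sites: pd.DataFrame, threshold: float = FOLD_THRESHOLD
) -> float:
    """Fraction of Pvr-dependent sites restored by insulin in low-Pvr cells."""
    if not pvr_set:
        raise UndefinedRateError("the Pvr-dependent set is empty")
    restored = define_inr_set(sites, "lowPvr", threshold)[UP]
    return len(pvr_set & restored) / len(pvr_set)


def kmeans_profiles(
    sites: pd.DataFrame,
    k: int = 10,
    seed: int | None = None,
    n_init: int = 25,
    conditions: tuple[str, ...] = CONDITIONS,
) -> pd.DataFrame:
    """k-means clustering of median-normalized intensity profiles.

    Each site's profile across ``conditions`` is divided by its own
    median, then clustered with Euclidean k-means (``n_init`` restarts,
    lowest within-cluster sum of squares kept). Sites with missing or
    non-positive values in any condition are excluded beforehand.
    """
    cols = [c for c in conditions if c in sites.columns]
    X = sites[cols].to_numpy(float)
    usable = np.isfinite(X).all(axis=1) & (X > 0).all(axis=1)
    Xu = X[usable]
    if len(Xu) < k:
        raise ConfigurationError(
            f"k-means needs at least k={k} complete profiles, got {len(Xu)}"
        )
    profiles = Xu / np.median(Xu, axis=1, keepdims=True)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(profiles)
    return pd.DataFrame(
        {"site_id": sites.loc[usable, "site_id"].to_numpy(), "cluster": labels}
    )


def analyze_study(
    site_rep: pd.DataFrame,
    site_all: pd.DataFrame | None = None,
    threshold: float = FOLD_THRESHOLD,
    common_mode: str = "reciprocal",
) -> tuple[dict[str, set[str]], dict[str, int | float]]:
    """Differential-set analysis routed to the appropriate experiment.

    Ratios are only meaningful within one multiplexed run, so
    within-background comparisons (insulin and EcR responses) are taken
    from ``site_rep`` — the replicate-averaged tables of the two
    per-background runs — while cross-background comparisons (the
    Pvr-dependent and receptor-specific sets) are taken from
    ``site_all``, the single run spanning all six conditions. When
    ``site_all`` is omitted every comparison uses ``site_rep``.

    Returns ``(sets, sizes)``: the site-id sets per label and their
    sizes plus the rescue fraction.
    """
    if site_all is None:
        site_all = site_rep
    inr_hi = define_inr_set(site_rep, "highPvr", threshold)
    inr_lo = define_inr_set(site_rep, "lowPvr", threshold)
    ecr_hi = define_ecr_sets(site_rep, "highPvr", threshold)
    ecr_lo = define_ecr_sets(site_rep, "lowPvr", threshold)
    pvr_calls = _direction_sets(fold_change_call(site_all, LP_LI, HP_LI, threshold))
    pvr = pvr_calls[DOWN]
    if common_mode == "reciprocal":
        common = {UP: pvr & inr_lo[UP], DOWN: pvr_calls[UP] & inr_lo[DOWN]}
    elif common_mode == "shared":
        common = {UP: inr_hi[UP] & inr_lo[UP], DOWN: inr_hi[DOWN] & inr_lo[DOWN]}
    else:
        raise ConfigurationError(f"unknown common-set mode {common_mode!r}")
    receptor = define_receptor_specific_sets(site_all, common, threshold)
    site_sets: dict[str, set[str]] = {
        "inr_up_highPvr": inr_hi[UP],
        "inr_down_highPvr": inr_hi[DOWN],
        "inr_up_lowPvr": inr_lo[UP],
        "inr_down_lowPvr": inr_lo[DOWN],
        "pvr_set": pvr,
        "common_up": common[UP],
        "common_down": common[DOWN],
        "pvr_only": receptor["Pvr_only"],
        "inr_only": receptor["InR_only"],
        "ecr_up_highPvr": ecr_hi[UP],
        "ecr_down_highPvr": ecr_hi[DOWN],
        "ecr_up_lowPvr": ecr_lo[UP],
        "ecr_down_lowPvr": ecr_lo[DOWN],
    }
    sizes: dict[str, int | float] = {k: len(v) for k, v in site_sets.items()}
    sizes["rescue_fraction"] = (
        len(pvr & inr_lo[UP]) / len(pvr) if pvr else float("nan")
    )
    return site_sets, sizes


def set_size_summary(
    sites: pd.DataFrame,
    threshold: float = FOLD_THRESHOLD,
    common_mode: str = "reciprocal",
) -> dict[str, int | float]:
    """Sizes of every differential set plus the rescue fraction."""
    inr_hi = define_inr_set(sites, "highPvr", threshold)
    inr_lo = define_inr_set(sites, "lowPvr", threshold)
    pvr = define_pvr_set(sites, threshold)
    common = define_common_set(sites, mode=common_mode, threshold=threshold)
    receptor = define_receptor_specific_sets(sites, common, threshold)
    ecr_hi = define_ecr_sets(sites, "highPvr", threshold)
    ecr_lo = define_ecr_sets(sites, "lowPvr", threshold)
    summary: dict[str, int | float] = {
        "inr_up_highPvr": len(inr_hi[UP]),
        "inr_down_highPvr": len(inr_hi[DOWN]),
        "inr_up_lowPvr": len(inr_lo[UP]),
        "inr_down_lowPvr": len(inr_lo[DOWN]),
        "pvr_set": len(pvr),
        "common_up": len(common[UP]),
        "common_down": len(common[DOWN]),
        "pvr_only": len(receptor["Pvr_only"]),
        "inr_only": len(receptor["InR_only"]),
        "ecr_up_highPvr": len(ecr_hi[UP]),
        "ecr_down_highPvr": len(ecr_hi[DOWN]),
        "ecr_up_lowPvr": len(ecr_lo[UP]),
        "ecr_down_lowPvr": len(ecr_lo[DOWN]),
    }
    summary["rescue_fraction"] = (
        rescue_fraction(pvr, sites, threshold) if pvr else float("nan")
    )
    return summary
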