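"""Synthetic screen plates, PSM tables and complex libraries with planted truth.

Every downstream stage of the pipeline is testable without any external
download because this module fabricates its inputs with known ground
truth:

* :func:`generate_screen_plates` emulates an arrayed 384-well RNAi
  viability screen run under a sensitized (receptor knockdown) and a
  control background, in duplicate, with control wells in fixed plate
  positions and log-normal multiplicative reading noise. Amplicons carry
  planted modifier classes (suppressor / enhancer / upstream / null)
  realized as multiplicative effects on the reading in one or both
  backgrounds.
* :func:`generate_phospho_experiment` emulates a six-plex TMT
  phosphoproteomics run: planted insulin-responsive, Pvr-dependent,
  common and ecdysone-responsive phosphosites, forward-mixed through an
  isotopic impurity matrix, with log-normal intensity noise, per-replicate
  dropout and decoy PSMs drawn from a shifted search-score null.
* :func:`generate_complex_library` fabricates protein-complex
  definitions, with planted complexes sampled preferentially from
  high-|score| genes.

All randomness flows through one seeded :class:`numpy.random.Generator`
per call; identical configuration and seed give byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .phospho import (
    CHANNELS,
    CONDITIONS,
    EXPERIMENT1,
    EXPERIMENT2,
    EXPERIMENT3,
    INTENSITY_COLUMNS,
    HP_HI,
    HP_LE,
    HP_LI,
    LP_HI,
    LP_LE,
    LP_LI,
    TMTDesign,
)
from .screen import CONTROL, SENSITIZED

__all__ = [
    "GroundTruth",
    "ScreenSimConfig",
    "PhosphoSimConfig",
    "generate_screen_plates",
    "generate_phospho_experiment",
    "generate_phospho_study",
    "generate_complex_library",
    "generate_profile_groups",
    "default_impurity_matrix",
    "expected_set_sizes",
]

NULL = "null"
SUPPRESSOR = "suppressor"
ENHANCER = "enhancer"
UPSTREAM = "upstream"

PLATE_ROWS = "ABCDEFGHIJKLMNOP"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CONTROL_AMPLICON = "CTRL"


@dataclass
class GroundTruth:
    """Planted labels for whichever generators were run.

    ``amplicons``: amplicon_id, gene_id, true_class;
    ``phosphosites``: site_id, label;
    ``complexes``: complex_id, planted flag.
    """

    amplicons: pd.DataFrame | None = None
    phosphosites: pd.DataFrame | None = None
    complexes: pd.DataFrame | None = None


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with mean 1 and the given CV."""
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# RNAi screen plates
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimConfig:
    """Knobs of the synthetic viability screen.

    ``effect_sizes`` maps each planted class to a pair of multiplicative
    effects on the well reading, (fold in sensitized background, fold in
    control background). The defaults give roughly +/-5 control-SD
    signatures at a 10% baseline CV: suppressors rescue reading only
    under receptor knockdown, enhancers reduce it only there, upstream
    genes reduce it only in the control background. ``class_fractions``
    defaults emulate a verification-stage plate set strongly enriched
    for modifiers (a genome-wide run would be almost entirely null);
    control wells occupy two dedicated columns per 384-well plate.
    """

    n_plates: int = 4
    wells_per_plate: int = 384
    n_control_wells_per_plate: int = 32
    n_replicates: int = 2
    baseline_mean: float = 50_000.0
    baseline_cv: float = 0.10
    effect_sizes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            NULL: (1.0, 1.0),
            SUPPRESSOR: (1.6, 1.0),
            ENHANCER: (0.5, 1.0),
            UPSTREAM: (1.0, 0.5),
        }
    )
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            SUPPRESSOR: 0.25,
            ENHANCER: 0.25,
            UPSTREAM: 0.25,
            NULL: 0.25,
        }
    )
    amplicons_per_gene: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plates <= 0 or self.wells_per_plate <= 0 or self.n_replicates <= 0:
            raise ConfigurationError("counts must be positive")
        if self.n_control_wells_per_plate < 2:
            raise ConfigurationError("need at least 2 control wells per plate")
        if self.n_control_wells_per_plate >= self.wells_per_plate:
            raise ConfigurationError("control wells must leave room for candidates")
        if self.baseline_cv <= 0 or self.baseline_mean <= 0:
            raise ConfigurationError("baseline mean and CV must be positive")
        if self.amplicons_per_gene <= 0:
            raise ConfigurationError("amplicons_per_gene must be positive")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.class_fractions.values()):
            raise ConfigurationError("class_fractions must be a simplex")
        missing = set(self.class_fractions) - set(self.effect_sizes)
        if missing:
            raise ConfigurationError(f"no effect sizes for classes: {sorted(missing)}")
        for cls, (fs, fc) in self.effect_sizes.items():
            if fs <= 0 or fc <= 0:
                raise ConfigurationError(f"effect folds must be positive ({cls})")


def _well_names(n: int) -> list[str]:
    names = [f"{r}{c:02d}" for c in range(1, 25) for r in PLATE_ROWS]
    if n > len(names):
        names = [f"{r}{c:02d}" for c in range(1, n // 16 + 2) for r in PLATE_ROWS]
    return names[:n]


def generate_screen_plates(
    cfg: ScreenSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate plate readings for the differential screen.

    Returns ``(plates, gene_map, truth)``: a long reading table with one
    row per well x condition x replicate, the amplicon-to-gene map, and
    the planted amplicon classes. Control wells occupy the last
    ``n_control_wells_per_plate`` positions of each plate layout
    (mirroring arrayed-library practice of dedicated control columns)
    and are flagged ``is_control`` so scoring never guesses the layout.
    """
    rng = np.random.default_rng(cfg.seed)
    candidates_per_plate = cfg.wells_per_plate - cfg.n_control_wells_per_plate
    n_amplicons = cfg.n_plates * candidates_per_plate
    n_genes = math.ceil(n_amplicons / cfg.amplicons_per_gene)

    classes = sorted(cfg.class_fractions)
    probs = np.array([cfg.class_fractions[c] for c in classes])
    gene_classes = rng.choice(classes, size=n_genes, p=probs)

    amplicon_ids = [f"AMP{i:05d}" for i in range(n_amplicons)]
    gene_idx = np.arange(n_amplicons) // cfg.amplicons_per_gene
    gene_ids = [f"G{i:04d}" for i in gene_idx]
    amp_classes = gene_classes[gene_idx]

    truth_df = pd.DataFrame(
        {"amplicon_id": amplicon_ids, "gene_id": gene_ids, "true_class": amp_classes}
    )
    gene_map = truth_df[["amplicon_id", "gene_id"]].copy()

    wells = _well_names(cfg.wells_per_plate)
    candidate_wells = wells[:candidates_per_plate]
    control_wells = wells[candidates_per_plate:]

    records: list[dict] = []
    for plate in range(cfg.n_plates):
        lo = plate * candidates_per_plate
        plate_amps = amplicon_ids[lo : lo + candidates_per_plate]
        plate_cls = amp_classes[lo : lo + candidates_per_plate]
        for condition in (SENSITIZED, CONTROL):
            fold_index = 0 if condition == SENSITIZED else 1
            for replicate in range(1, cfg.n_replicates + 1):
                noise = _lognormal_noise(rng, cfg.baseline_cv, cfg.wells_per_plate)
                folds = np.array(
                    [cfg.effect_sizes[c][fold_index] for c in plate_cls]
                    + [1.0] * cfg.n_control_wells_per_plate
                )
                readings = cfg.baseline_mean * folds * noise
                for w, amp, is_ctrl, reading in zip(
                    candidate_wells + control_wells,
                    plate_amps + [CONTROL_AMPLICON] * cfg.n_control_wells_per_plate,
                    [False] * candidates_per_plate
                    + [True] * cfg.n_control_wells_per_plate,
                    readings,
                ):
                    records.append(
                        {
                            "plate_id": f"PL{plate:03d}",
                            "well": w,
                            "condition": condition,
                            "replicate": replicate,
                            "amplicon_id": amp,
                            "is_control": is_ctrl,
                            "reading": reading,
                        }
                    )
    plates = pd.DataFrame.from_records(records)
    return plates, gene_map, GroundTruth(amplicons=truth_df)


# ---------------------------------------------------------------------------
# TMT phosphoproteomics
# ---------------------------------------------------------------------------


def default_impurity_matrix(leak: float = 0.03) -> np.ndarray:
    """Nearest-neighbor isotopic leakage matrix.

    Column ``j`` describes where label ``j``'s signal lands: a fraction
    ``leak`` spills into each adjacent channel, the rest stays on the
    diagonal (edge channels keep more on-diagonal signal). Diagonally
    dominant, hence invertible.
    """
    if not 0 <= leak < 0.5:
        raise ConfigurationError("leak fraction must be in [0, 0.5)")
    M = np.zeros((6, 6))
    for j in range(6):
        neighbors = [i for i in (j - 1, j + 1) if 0 <= i < 6]
        for i in neighbors:
            M[i, j] = leak
        M[j, j] = 1.0 - leak * len(neighbors)
    return M


@dataclass
class PhosphoSimConfig:
    """Knobs of the synthetic six-plex phosphoproteomics experiment.

    Planted fractions follow the study-scale proportions: ~10% of sites
    insulin-responsive, ~10% Pvr-dependent, 5% common (reciprocally
    regulated by both receptors) and 1% ecdysone-responsive; the rest
    are unregulated. ``effect_fold`` is the true linear fold change of
    planted effects and must clear the 1.5-fold calling threshold.
    """

    n_phosphosites: int = 2000
    mean_extra_peptides_per_site: float = 3.0
    channel_design: TMTDesign = EXPERIMENT1
    impurity_matrix: np.ndarray = field(default_factory=default_impurity_matrix)
    planted_set_fractions: dict[str, float] = field(
        default_factory=lambda: {"inr": 0.10, "pvr": 0.10, "common": 0.05, "ecr": 0.01}
    )
    effect_fold: float = 2.0
    intensity_cv: float = 0.10
    dropout_rate: float = 0.05
    decoy_fraction: float = 0.10
    frac_low_ascore: float = 0.05
    frac_low_isolation: float = 0.05
    baseline_intensity: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phosphosites <= 0:
            raise ConfigurationError("n_phosphosites must be positive")
        if self.effect_fold <= 1:
            raise ConfigurationError("effect_fold must exceed 1")
        if not 0 <= self.dropout_rate < 1 or not 0 <= self.decoy_fraction < 1:
            raise ConfigurationError("rates must lie in [0, 1)")
        if self.intensity_cv < 0:
            raise ConfigurationError("intensity_cv must be non-negative")
        M = np.asarray(self.impurity_matrix, float)
        if M.shape != (6, 6):
            raise ConfigurationError(f"impurity matrix must be 6x6, got {M.shape}")
        if (M < 0).any():
            raise ConfigurationError("impurity matrix entries must be non-negative")
        if (M.sum(axis=0) > 1 + 1e-6).any() or (M.sum(axis=1) > 1 + 1e-6).any():
            raise ConfigurationError("impurity matrix rows/columns must sum to <= 1")
        if np.linalg.matrix_rank(M) < 6:
            raise ConfigurationError("impurity matrix is singular")
        total = sum(self.planted_set_fractions.values())
        if total > 1 or any(v < 0 for v in self.planted_set_fractions.values()):
            raise ConfigurationError("planted fractions must be non-negative, sum <= 1")
        unknown = set(self.planted_set_fractions) - {"inr", "pvr", "common", "ecr"}
        if unknown:
            raise ConfigurationError(f"unknown planted labels: {sorted(unknown)}")


def _condition_folds(label: str, direction: str, fold: float) -> dict[str, float]:
    """True per-condition intensity multiplier of a planted site class.

    Insulin- and ecdysone-responsive sites are planted in both
    directions (``direction`` is ``"up"`` or ``"down"``), mirroring real
    signaling responses and keeping total reporter intensity per channel
    balanced, so that summed-intensity normalization does not bias fold
    changes.
    """
    folds = {c: 1.0 for c in CONDITIONS}
    f = fold if direction != "down" else 1.0 / fold
    if label == "inr":
        # Insulin-responsive regardless of Pvr background.
        folds[HP_HI] = f
        folds[LP_HI] = f
    elif label == "pvr":
        # Requires Pvr activity; insulin does not restore it.
        for c in (LP_LI, LP_HI, LP_LE):
            folds[c] = 1.0 / fold
    elif label == "common":
        # Lost upon Pvr knockdown, restored by insulin (reciprocal).
        folds[LP_LI] = 1.0 / fold
        folds[LP_LE] = 1.0 / fold
    elif label == "ecr":
        # Responds to ecdysone-receptor knockdown in both backgrounds.
        folds[HP_LE] = f
        folds[LP_LE] = f
    return folds


def _site_truth(cfg: PhosphoSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_phosphosites
    labels = np.full(n, NULL, dtype=object)
    fractions = cfg.planted_set_fractions
    counts = {k: int(round(v * n)) for k, v in fractions.items()}
    directions = np.full(n, "", dtype=object)
    order = rng.permutation(n)
    pos = 0
    for k in sorted(counts):
        idx = order[pos : pos + counts[k]]
        labels[idx] = k
        if k in ("inr", "ecr"):
            # Half up, half down: balanced per-channel totals.
            directions[idx[: len(idx) // 2]] = "up"
            directions[idx[len(idx) // 2 :]] = "down"
        pos += counts[k]
    proteins = [f"P{i // 3:04d}" for i in range(n)]
    residues = rng.choice(list("STY"), size=n)
    positions = 53 + 61 * (np.arange(n) % 3)
    site_ids = [f"{p}:{r}{q}" for p, r, q in zip(proteins, residues, positions)]
    baselines = rng.lognormal(mean=math.log(cfg.baseline_intensity), sigma=1.0, size=n)
    return pd.DataFrame(
        {
            "site_id": site_ids,
            "protein": proteins,
            "site": [f"{r}{q}" for r, q in zip(residues, positions)],
            "label": labels,
            "direction": directions,
            "baseline": baselines,
        }
    )


def _index_to_peptide(i: int, j: int) -> str:
    code = i * 17 + j
    letters = []
    for _ in range(8):
        letters.append(AMINO_ACIDS[code % 20])
        code //= 20
    return "".join(letters) + "K"


def _generate_psms_for_design(
    cfg: PhosphoSimConfig,
    design: TMTDesign,
    site_truth: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    M = np.asarray(cfg.impurity_matrix, float)
    chan_cond = [cond for _, cond, _ in sorted(design.channels, key=lambda t: t[0])]
    chan_rep = [rep for _, _, rep in sorted(design.channels, key=lambda t: t[0])]
    records: list[dict] = []
    for i, site in site_truth.iterrows():
        folds = _condition_folds(site["label"], site["direction"], cfg.effect_fold)
        true_by_channel = np.array(
            [site["baseline"] * folds[c] for c in chan_cond]
        )
        n_pep = 1 + rng.poisson(cfg.mean_extra_peptides_per_site)
        for j in range(n_pep):
            abundance = rng.lognormal(mean=0.0, sigma=0.5)
            true = true_by_channel * abundance
            # Replicate channels carry independent biological noise.
            noisy_true = true * _lognormal_noise(rng, cfg.intensity_cv, 6)
            observed = M @ noisy_true
            observed *= _lognormal_noise(rng, cfg.intensity_cv / 2, 6)
            for r in design.replicate_indices:
                if rng.random() < cfg.dropout_rate:
                    mask = np.array([rep == r for rep in chan_rep])
                    observed = np.where(mask, 0.0, observed)
            low_ascore = rng.random() < cfg.frac_low_ascore
            ascore = (
                rng.uniform(2.0, 13.0) if low_ascore else rng.uniform(14.0, 40.0)
            )
            low_iso = rng.random() < cfg.frac_low_isolation
            isolation = (
                rng.uniform(0.30, 0.75) if low_iso else rng.uniform(0.76, 1.0)
            )
            rec = {
                "peptide": _index_to_peptide(i, j),
                "protein": site["protein"],
                "site_positions": site["site"],
                "ascores": f"{ascore:.3f}",
                "isolation_specificity": round(isolation, 4),
                "search_score": rng.normal(5.0, 1.0),
                "is_decoy": False,
            }
            rec.update({col: v for col, v in zip(INTENSITY_COLUMNS, observed)})
            records.append(rec)
    n_targets = len(records)
    n_decoys = int(round(cfg.decoy_fraction * n_targets))
    for d in range(n_decoys):
        observed = rng.lognormal(mean=math.log(cfg.baseline_intensity / 10), sigma=1.0, size=6)
        rec = {
            "peptide": _index_to_peptide(10**6 + d, 0),
            "protein": f"DECOY_{d:04d}",
            "site_positions": f"S{53 + d % 300}",
            "ascores": f"{rng.uniform(14.0, 40.0):.3f}",
            "isolation_specificity": round(rng.uniform(0.76, 1.0), 4),
            "search_score": rng.normal(0.0, 1.0),
            "is_decoy": True,
        }
        rec.update({col: v for col, v in zip(INTENSITY_COLUMNS, observed)})
        records.append(rec)
    return pd.DataFrame.from_records(records)


def generate_phospho_experiment(
    cfg: PhosphoSimConfig,
) -> tuple[pd.DataFrame, GroundTruth, np.ndarray]:
    """Simulate one six-plex experiment under ``cfg.channel_design``.

    Observed reporter intensities are the true per-condition intensities
    forward-mixed through the impurity matrix with multiplicative
    log-normal noise; per-replicate dropout zeroes the affected
    replicate's reporter channels; decoy PSMs carry search scores from a
    null distribution shifted well below the target distribution.
    """
    rng = np.random.default_rng(cfg.seed)
    site_truth = _site_truth(cfg, rng)
    psms = _generate_psms_for_design(cfg, cfg.channel_design, site_truth, rng)
    truth = GroundTruth(phosphosites=site_truth[["site_id", "label", "direction"]].copy())
    return psms, truth, np.asarray(cfg.impurity_matrix, float)


def generate_phospho_study(
    cfg: PhosphoSimConfig,
    designs: tuple[TMTDesign, ...] = (EXPERIMENT1, EXPERIMENT2, EXPERIMENT3),
) -> tuple[dict[str, tuple[pd.DataFrame, TMTDesign]], GroundTruth, np.ndarray]:
    """Simulate several experiments sharing one set of true phosphosites.

    The site roster and baselines are drawn once from ``cfg.seed``; each
    design then receives an independent peptide roster and measurement
    noise, mimicking run-to-run variation in which peptide species are
    identified. Cross-background ratios should therefore be computed
    within the all-six-condition run (the third layout) rather than
    across the two replicated runs.
    """
    rng = np.random.default_rng(cfg.seed)
    site_truth = _site_truth(cfg, rng)
    experiments: dict[str, tuple[pd.DataFrame, TMTDesign]] = {}
    for design in designs:
        psms = _generate_psms_for_design(cfg, design, site_truth, rng)
        experiments[design.experiment] = (psms, design)
    truth = GroundTruth(phosphosites=site_truth[["site_id", "label", "direction"]].copy())
    return experiments, truth, np.asarray(cfg.impurity_matrix, float)


def expected_set_sizes(truth: GroundTruth) -> dict[str, float]:
    """Planted differential-set sizes implied by the site labels.

    Pvr-dependent and common sites are both downregulated upon Pvr loss,
    so the planted Pvr-specific set is their union; likewise common
    sites respond to insulin in the low-Pvr background. The
    receptor-specific comparison (pure-Pvr vs pure-InR state) cannot
    distinguish a Pvr-promoted site from an insulin-suppressed one, so
    insulin-downregulated sites fall in the planted Pvr-only set.
    """
    t = truth.phosphosites
    counts = t["label"].value_counts()

    def _n(label: str, direction: str | None = None) -> int:
        if direction is None:
            return int(counts.get(label, 0))
        sel = (t["label"] == label) & (t["direction"] == direction)
        return int(sel.sum())

    pvr = _n("pvr")
    common = _n("common")
    inr_up, inr_down = _n("inr", "up"), _n("inr", "down")
    ecr_up, ecr_down = _n("ecr", "up"), _n("ecr", "down")
    return {
        "inr_up_highPvr": inr_up,
        "inr_down_highPvr": inr_down,
        "inr_up_lowPvr": inr_up + common,
        "inr_down_lowPvr": inr_down,
        "pvr_set": pvr + common,
        "common_up": common,
        "common_down": 0,
        "pvr_only": pvr + inr_down,
        "inr_only": inr_up,
        "ecr_up_highPvr": ecr_up,
        "ecr_down_highPvr": ecr_down,
        "ecr_up_lowPvr": ecr_up,
        "ecr_down_lowPvr": ecr_down,
        "rescue_fraction": common / (pvr + common) if (pvr + common) else float("nan"),
    }


def generate_profile_groups(
    n_groups: int = 10,
    n_per_group: int = 30,
    n_conditions: int = 6,
    noise_cv: float = 0.10,
    seed: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Planted intensity-profile groups for clustering benchmarks.

    Each group has a distinct condition-response pattern (random folds
    in [1/4, 4] on a log grid); members are the pattern scaled by a
    random per-site magnitude times log-normal noise. Returns a site
    table ready for :func:`sensiscreen.sets.kmeans_profiles` and the
    planted group labels.
    """
    rng = np.random.default_rng(seed)
    # Rejection-sample patterns until every pair is well separated in the
    # median-normalized space the clustering operates in, so the planted
    # groups are separable by construction.
    min_sep = 1.5
    patterns = np.empty((n_groups, n_conditions))
    accepted = 0
    while accepted < n_groups:
        cand = np.exp(rng.uniform(-np.log(4), np.log(4), size=n_conditions))
        cand_norm = cand / np.median(cand)
        prev = patterns[:accepted] / np.median(
            patterns[:accepted], axis=1, keepdims=True
        ) if accepted else np.empty((0, n_conditions))
        if accepted == 0 or np.linalg.norm(prev - cand_norm, axis=1).min() >= min_sep:
            patterns[accepted] = cand
            accepted += 1
    rows = []
    labels = []
    for g in range(n_groups):
        mags = rng.lognormal(mean=math.log(1e6), sigma=1.0, size=n_per_group)
        noise = _lognormal_noise(rng, noise_cv, (n_per_group, n_conditions))
        block = mags[:, None] * patterns[g][None, :] * noise
        rows.append(block)
        labels.extend([g] * n_per_group)
    X = np.vstack(rows)
    table = pd.DataFrame(X, columns=list(CONDITIONS)[:n_conditions])
    table.insert(0, "site_id", [f"PROF{i:05d}" for i in range(len(table))])
    return table, np.asarray(labels)


# ---------------------------------------------------------------------------
# Protein complex library
# ---------------------------------------------------------------------------


def generate_complex_library(
    n_complexes: int,
    size_range: tuple[int, int],
    universe_scores: pd.Series,
    planted_fraction: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Fabricate complex definitions over a scored gene universe.

    Planted (enriched) complexes sample their members with probability
    proportional to the squared gene score, concentrating them among
    strong modifiers; the remaining complexes sample uniformly.
    """
    genes = np.asarray(universe_scores.index)
    if len(genes) == 0:
        raise ConfigurationError("universe is empty")
    lo, hi = size_range
    if not (2 <= lo <= hi <= len(genes)):
        raise ConfigurationError(
            f"size_range {size_range} incompatible with universe of {len(genes)}"
        )
    if not 0 <= planted_fraction <= 1:
        raise ConfigurationError("planted_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    scores = np.abs(universe_scores.to_numpy(float))
    weights = scores**2
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    weights = weights / weights.sum()
    n_planted = int(round(planted_fraction * n_complexes))
    rows = []
    planted_flags = []
    for c in range(n_complexes):
        size = int(rng.integers(lo, hi + 1))
        planted = c < n_planted
        p = weights if planted else None
        members = rng.choice(genes, size=size, replace=False, p=p)
        cid = f"CPX{c:04d}"
        planted_flags.append({"complex_id": cid, "planted": planted})
        rows.extend({"complex_id": cid, "gene_id": g} for g in members)
    complexes = pd.DataFrame(rows)
    truth = GroundTruth(complexes=pd.DataFrame(planted_flags))
    return complexes, truth
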