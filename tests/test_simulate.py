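"""Synthetic-data generators: determinism, configs, forward models."""

import numpy as np
import pandas as pd
import pytest

import sensiscreen.phospho as phospho
import sensiscreen.screen as screen
import sensiscreen.simulate as sim
from sensiscreen.errors import ConfigurationError


class TestScreenGenerator:
    def test_identical_seed_identical_tables(self):
        cfg = dict(n_plates=1, wells_per_plate=96, n_control_wells_per_plate=8, seed=42)
        a, _, _ = sim.generate_screen_plates(sim.ScreenSimConfig(**cfg))
        b, _, _ = sim.generate_screen_plates(sim.ScreenSimConfig(**cfg))
        assert a.to_csv() == b.to_csv()

    def test_layout_contract(self):
        cfg = sim.ScreenSimConfig(n_plates=2, wells_per_plate=96, n_control_wells_per_plate=8, seed=0)
        plates, gene_map, truth = sim.generate_screen_plates(cfg)
        assert (plates["reading"] > 0).all()
        by_group = plates.groupby(["plate_id", "condition", "replicate"])
        assert (by_group["is_control"].sum() == 8).all()
        # every amplicon measured once per condition x replicate
        cand = plates[~plates.is_control]
        assert (cand.groupby(["amplicon_id", "condition", "replicate"]).size() == 1).all()
        assert set(gene_map["amplicon_id"]) == set(truth.amplicons["amplicon_id"])

    def test_null_only_run_has_centered_zdiff(self):
        cfg = sim.ScreenSimConfig(
            n_plates=2,
            class_fractions={sim.NULL: 1.0},
            seed=7,
        )
        plates, gm, truth = sim.generate_screen_plates(cfg)
        assert (truth.amplicons["true_class"] == sim.NULL).all()
        _, merged = screen.score_screen(plates, gene_map=gm)
        assert abs(merged["zdiff"].mean()) < 0.1
        # hit fraction approximately the two-sided tail mass of the null
        hit_frac = (merged["zdiff"].abs() >= 2).mean()
        assert hit_frac < 0.12

    @pytest.mark.parametrize(
        "bad",
        [
            {"class_fractions": {"null": 0.5, "suppressor": 0.4}},
            {"baseline_cv": 0.0},
            {"n_control_wells_per_plate": 1},
            {"n_plates": 0},
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            sim.ScreenSimConfig(**bad)


class TestPhosphoGenerator:
    def test_identical_seed_identical_tables(self):
        cfg = dict(n_phosphosites=40, seed=9)
        a, _, _ = sim.generate_phospho_experiment(sim.PhosphoSimConfig(**cfg))
        b, _, _ = sim.generate_phospho_experiment(sim.PhosphoSimConfig(**cfg))
        assert a.to_csv() == b.to_csv()

    def test_forward_model_unmixing_recovers_true_intensities(self):
        """Zero noise: observed = M @ true, so correction inverts exactly."""
        base = dict(
            n_phosphosites=30, intensity_cv=0.0, dropout_rate=0.0,
            decoy_fraction=0.0, frac_low_ascore=0.0, frac_low_isolation=0.0, seed=5,
        )
        mixed, _, M = sim.generate_phospho_experiment(
            sim.PhosphoSimConfig(**base)
        )
        pure, _, _ = sim.generate_phospho_experiment(
            sim.PhosphoSimConfig(**base, impurity_matrix=np.eye(6))
        )
        corrected = phospho.correct_impurities(
            mixed[phospho.INTENSITY_COLUMNS].to_numpy(), M
        )
        np.testing.assert_allclose(
            corrected, pure[phospho.INTENSITY_COLUMNS].to_numpy(), rtol=1e-6
        )

    def test_zero_dropout_excludes_no_peptide(self):
        cfg = sim.PhosphoSimConfig(
            n_phosphosites=30, dropout_rate=0.0, decoy_fraction=0.0, seed=5
        )
        psms, _, M = sim.generate_phospho_experiment(cfg)
        corrected = psms.copy()
        corrected[phospho.INTENSITY_COLUMNS] = phospho.correct_impurities(
            psms[phospho.INTENSITY_COLUMNS].to_numpy(), M
        )
        out = phospho.aggregate_replicates(corrected, cfg.channel_design)
        assert len(out) == len(psms)

    def test_decoy_scores_sit_below_targets(self):
        psms, _, _ = sim.generate_phospho_experiment(
            sim.PhosphoSimConfig(n_phosphosites=100, seed=2)
        )
        t = psms.loc[~psms.is_decoy, "search_score"]
        d = psms.loc[psms.is_decoy, "search_score"]
        assert d.mean() < t.mean() - 3

    def test_bad_impurity_matrix_rejected(self):
        with pytest.raises(ConfigurationError):
            sim.PhosphoSimConfig(impurity_matrix=np.ones((3, 3)))
        with pytest.raises(ConfigurationError):
            sim.PhosphoSimConfig(impurity_matrix=np.zeros((6, 6)))


class TestComplexGenerator:
    def test_determinism_and_size_bounds(self):
        scores = pd.Series(
            np.random.default_rng(0).normal(0, 2, 100),
            index=[f"g{i}" for i in range(100)],
        )
        a, ta = sim.generate_complex_library(20, (3, 6), scores, 0.3, seed=8)
        b, _ = sim.generate_complex_library(20, (3, 6), scores, 0.3, seed=8)
        assert a.to_csv() == b.to_csv()
        sizes = a.groupby("complex_id").size()
        assert sizes.between(3, 6).all()
        assert ta.complexes["planted"].sum() == 6

    def test_size_range_exceeding_universe_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ConfigurationError):
            sim.generate_complex_library(5, (3, 6), scores, 0.0, seed=1)
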