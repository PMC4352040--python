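"""TMT quantification: filters, FDR, impurity correction, normalization,
replicate handling and site collapsing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sensiscreen import phospho
from sensiscreen.errors import ConfigurationError, DegenerateChannelError
from sensiscreen.phospho import EXPERIMENT1, EXPERIMENT3, INTENSITY_COLUMNS


def psm_row(**kw):
    row = {
        "peptide": "PEPTIDEK",
        "protein": "P1",
        "site_positions": "S45",
        "ascores": "20.0",
        "isolation_specificity": 0.9,
        "search_score": 5.0,
        "is_decoy": False,
    }
    row.update({c: 100.0 for c in INTENSITY_COLUMNS})
    row.update(kw)
    return row


class TestFilters:
    @pytest.mark.parametrize(
        "ascore,iso,kept",
        [(13.0, 0.9, False), (0.75, 0.9, False), (14.0, 0.8, True), (20.0, 0.75, False)],
    )
    def test_strict_boundaries(self, ascore, iso, kept):
        df = pd.DataFrame([psm_row(ascores=str(ascore), isolation_specificity=iso)])
        out = phospho.apply_psm_filters(df)
        assert (len(out) == 1) is kept

    def test_per_site_filtering_on_multisite_peptides(self):
        df = pd.DataFrame(
            [psm_row(site_positions="S45;T52", ascores="20.0;10.0")]
        )
        out = phospho.apply_psm_filters(df)
        assert out["site_positions"].iloc[0] == "S45"

    def test_malformed_ascores_rejected(self):
        df = pd.DataFrame([psm_row(ascores="not-a-number"), psm_row()])
        out = phospho.apply_psm_filters(df)
        assert len(out) == 1


class TestFdrThreshold:
    def test_no_decoys_accepts_all_targets(self):
        df = pd.DataFrame([psm_row(search_score=s) for s in (1.0, 2.0, 3.0)])
        cutoff, accepted = phospho.fdr_threshold(df)
        assert len(accepted) == 3

    def test_all_decoys_accepts_nothing(self):
        df = pd.DataFrame([psm_row(is_decoy=True, search_score=s) for s in (1.0, 2.0)])
        _, accepted = phospho.fdr_threshold(df)
        assert accepted.empty

    def test_cutoff_matches_exhaustive_scan_oracle(self):
        """1000 synthetic PSMs: scan over every distinct score as oracle."""
        rng = np.random.default_rng(3)
        n_t, n_d = 900, 100
        scores = np.concatenate([rng.normal(3, 1, n_t), rng.normal(0, 1, n_d)])
        decoy = np.concatenate([np.zeros(n_t, bool), np.ones(n_d, bool)])
        df = pd.DataFrame(
            [psm_row(search_score=s, is_decoy=bool(d)) for s, d in zip(scores, decoy)]
        )
        fdr = 0.01
        cutoff, accepted = phospho.fdr_threshold(df, fdr=fdr)

        best_n, best_cut = -1, None
        for c in np.unique(scores):
            sel = scores >= c
            n_dec, n_tar = int(decoy[sel].sum()), int((~decoy[sel]).sum())
            if n_tar > 0 and n_dec <= fdr * n_tar and n_tar > best_n:
                best_n, best_cut = n_tar, c
        assert cutoff == pytest.approx(best_cut)
        assert len(accepted) == best_n


class TestImpurityCorrection:
    def test_identity_matrix_is_noop(self):
        v = np.array([10.0, 20, 30, 40, 50, 60])
        np.testing.assert_allclose(phospho.correct_impurities(v, np.eye(6)), v)

    def test_recovers_true_signal_after_known_leak(self):
        M = np.eye(6)
        M[0, 0], M[1, 0] = 0.95, 0.05  # 5% of channel 1 leaks into channel 2
        observed = np.array([95.0, 5.0, 0, 0, 0, 0])
        np.testing.assert_allclose(
            phospho.correct_impurities(observed, M), [100, 0, 0, 0, 0, 0], atol=1e-9
        )

    @given(
        true=arrays(np.float64, 6, elements=st.floats(0, 1e6)),
        leaks=arrays(np.float64, 5, elements=st.floats(0, 0.2)),
    )
    def test_forward_mix_round_trip(self, true, leaks):
        M = np.eye(6)
        for j, leak in enumerate(leaks):
            M[j, j] -= leak
            M[j + 1, j] = leak
        observed = M @ true
        recovered = phospho.correct_impurities(observed, M)
        np.testing.assert_allclose(recovered, true, rtol=1e-9, atol=1e-6)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ConfigurationError):
            phospho.correct_impurities(np.ones(6), np.zeros((6, 6)))


class TestNormalization:
    def table(self, X):
        df = pd.DataFrame(X, columns=INTENSITY_COLUMNS)
        df.insert(0, "peptide", [f"p{i}" for i in range(len(df))])
        return df

    def test_equal_totals_unchanged_and_idempotent(self):
        rng = np.random.default_rng(0)
        df = self.table(rng.uniform(1, 100, size=(20, 6)))
        once = phospho.normalize_channels(df)
        totals = once[INTENSITY_COLUMNS].sum()
        np.testing.assert_allclose(totals, totals.iloc[0], rtol=1e-12)
        twice = phospho.normalize_channels(once)
        np.testing.assert_allclose(
            once[INTENSITY_COLUMNS], twice[INTENSITY_COLUMNS], rtol=1e-12
        )

    def test_single_row_becomes_uniform(self):
        df = self.table([[1.0, 2, 3, 4, 5, 6]])
        out = phospho.normalize_channels(df)[INTENSITY_COLUMNS].to_numpy()[0]
        np.testing.assert_allclose(out, out[0])

    def test_zero_channel_total_raises(self):
        X = np.ones((3, 6))
        X[:, 2] = 0.0
        with pytest.raises(DegenerateChannelError):
            phospho.normalize_channels(self.table(X))


class TestReplicateAggregation:
    def test_single_replicate_detection_excluded(self):
        row = psm_row()
        for c in ("i127", "i129", "i131"):  # replicate 2 channels of EXPERIMENT1
            row[c] = 0.0
        df = pd.DataFrame([row, psm_row(peptide="OTHERK")])
        out = phospho.aggregate_replicates(df, EXPERIMENT1)
        assert out["peptide"].tolist() == ["OTHERK"]

    def test_replicates_averaged(self):
        row = psm_row(i126=2.0, i127=4.0)
        out = phospho.aggregate_replicates(pd.DataFrame([row]), EXPERIMENT1)
        assert out["highPvr_lowInR"].iloc[0] == pytest.approx(3.0)

    def test_single_run_design_passes_through(self):
        row = psm_row()
        for c in ("i127", "i129", "i131"):
            row[c] = 0.0
        out = phospho.aggregate_replicates(pd.DataFrame([row]), EXPERIMENT3)
        assert len(out) == 1


class TestSiteCollapsing:
    def test_peptides_covering_same_site_are_summed(self):
        df = pd.DataFrame(
            [
                {"peptide": "A", "protein": "P1", "site_positions": "S45",
                 "highPvr_lowInR": 10.0, "highPvr_highInR": 1.0, "highPvr_lowEcR": 1.0,
                 "n_replicates_detected": 2},
                {"peptide": "B", "protein": "P1", "site_positions": "S45",
                 "highPvr_lowInR": 5.0, "highPvr_highInR": 2.0, "highPvr_lowEcR": 1.0,
                 "n_replicates_detected": 2},
            ]
        )
        out = phospho.collapse_to_phosphosites(df, EXPERIMENT1)
        assert len(out) == 1
        assert out["highPvr_lowInR"].iloc[0] == pytest.approx(15.0)

    def test_multisite_peptide_contributes_to_each_site(self):
        df = pd.DataFrame(
            [
                {"peptide": "A", "protein": "P1", "site_positions": "S45;T52",
                 "highPvr_lowInR": 10.0, "highPvr_highInR": 1.0, "highPvr_lowEcR": 1.0,
                 "n_replicates_detected": 2},
            ]
        )
        out = phospho.collapse_to_phosphosites(df, EXPERIMENT1)
        assert sorted(out["site_id"]) == ["P1:S45", "P1:T52"]

    def test_unmappable_sites_dropped(self):
        df = pd.DataFrame(
            [
                {"peptide": "A", "protein": "P1", "site_positions": "X9",
                 "highPvr_lowInR": 1.0, "highPvr_highInR": 1.0, "highPvr_lowEcR": 1.0,
                 "n_replicates_detected": 2},
            ]
        )
        assert phospho.collapse_to_phosphosites(df, EXPERIMENT1).empty


class TestPipelineProperties:
    def test_row_order_independence(self, small_phospho):
        psms, design = small_phospho["experiments"]["exp1"]
        M = small_phospho["impurity"]
        a = phospho.quantify_experiment(psms, design, M)
        shuffled = psms.sample(frac=1.0, random_state=4).reset_index(drop=True)
        b = phospho.quantify_experiment(shuffled, design, M)
        a = a.sort_values("site_id").reset_index(drop=True)
        b = b.sort_values("site_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, rtol=1e-9)

    def test_both_replicates_rule_exact_on_synthetic_data(self, small_phospho):
        """Reported sites are exactly those with >=2 detected replicates."""
        psms, design = small_phospho["experiments"]["exp1"]
        M = small_phospho["impurity"]
        out = phospho.quantify_experiment(psms, design, M)
        assert (out["n_replicates_detected"] >= 2).all()
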