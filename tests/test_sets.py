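"""Fold-change calls, differential set logic and k-means profiling."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from sensiscreen import sets
from sensiscreen.errors import ConfigurationError, UndefinedRateError
from sensiscreen.phospho import CONDITIONS, HP_HI, HP_LI, LP_HI, LP_LI
from sensiscreen.simulate import generate_profile_groups


def site_table(values: dict[str, list[float]]) -> pd.DataFrame:
    n = len(next(iter(values.values())))
    df = pd.DataFrame({c: values.get(c, [1.0] * n) for c in CONDITIONS})
    df.insert(0, "site_id", [f"s{i}" for i in range(n)])
    return df


class TestFoldChangeCall:
    @pytest.mark.parametrize(
        "a,b,direction",
        [
            (3.2, 2.0, "up"),
            (3.0, 2.0, "unchanged"),  # exactly 1.5: strict threshold
            (2.0, 3.2, "down"),
            (2.0, 3.0, "unchanged"),  # exactly 1/1.5
            (np.nan, 2.0, "not_callable"),
            (2.0, 0.0, "not_callable"),
        ],
    )
    def test_boundaries_and_callability(self, a, b, direction):
        tbl = site_table({HP_HI: [a], HP_LI: [b]})
        call = sets.fold_change_call(tbl, HP_HI, HP_LI)
        assert call["direction"].iloc[0] == direction

    def test_direction_counts_partition_all_sites(self):
        rng = np.random.default_rng(1)
        tbl = site_table(
            {HP_HI: list(rng.lognormal(0, 1, 50)) + [np.nan], HP_LI: list(rng.lognormal(0, 1, 51))}
        )
        calls = sets.fold_change_call(tbl, HP_HI, HP_LI)
        assert calls["direction"].value_counts().sum() == len(tbl)

    def test_raising_threshold_never_adds_calls(self):
        rng = np.random.default_rng(2)
        tbl = site_table({HP_HI: rng.lognormal(0, 1, 200), HP_LI: rng.lognormal(0, 1, 200)})
        lo = sets.fold_change_call(tbl, HP_HI, HP_LI, threshold=1.5)
        hi = sets.fold_change_call(tbl, HP_HI, HP_LI, threshold=2.0)
        for d in ("up", "down"):
            assert (hi["direction"] == d).sum() <= (lo["direction"] == d).sum()


class TestSetLogic:
    def planted_table(self):
        # s0: common (down on Pvr loss, restored by insulin);
        # s1: Pvr-dependent only; s2: insulin only; s3: unregulated.
        return site_table(
            {
                HP_LI: [4.0, 4.0, 4.0, 4.0],
                HP_HI: [4.0, 4.0, 8.0, 4.0],
                LP_LI: [1.0, 2.0, 4.0, 4.0],
                LP_HI: [4.0, 2.0, 8.0, 4.0],
                "highPvr_lowEcR": [4.0, 4.0, 4.0, 4.0],
                "lowPvr_lowEcR": [1.0, 2.0, 4.0, 4.0],
            }
        )

    def test_reciprocal_common_set_and_algebra(self):
        tbl = self.planted_table()
        pvr = sets.define_pvr_set(tbl)
        common = sets.define_common_set(tbl)
        receptor = sets.define_receptor_specific_sets(tbl, common)
        assert pvr == {"s0", "s1"}
        assert common["up"] == {"s0"}
        assert common["up"] <= pvr
        assert receptor["Pvr_only"] == {"s1"}
        assert receptor["InR_only"] == {"s2"}
        assert not (receptor["Pvr_only"] & receptor["InR_only"])

    def test_insulin_only_site_excluded_from_common(self):
        common = sets.define_common_set(self.planted_table())
        assert "s2" not in common["up"] | common["down"]

    def test_rescue_fraction(self):
        tbl = self.planted_table()
        pvr = sets.define_pvr_set(tbl)
        assert sets.rescue_fraction(pvr, tbl) == pytest.approx(0.5)
        with pytest.raises(UndefinedRateError):
            sets.rescue_fraction(set(), tbl)


class TestRatioModes:
    def test_average_of_ratios_uses_replicate_columns(self):
        tbl = pd.DataFrame(
            {
                "site_id": ["s0"],
                HP_HI: [5.0],
                HP_LI: [2.0],
                f"{HP_HI}__rep1": [4.0],
                f"{HP_HI}__rep2": [6.0],
                f"{HP_LI}__rep1": [1.0],
                f"{HP_LI}__rep2": [3.0],
            }
        )
        avg = sets.fold_change_call(tbl, HP_HI, HP_LI)
        per = sets.fold_change_call(tbl, HP_HI, HP_LI, mode="average_of_ratios")
        assert avg["ratio"].iloc[0] == pytest.approx(2.5)
        assert per["ratio"].iloc[0] == pytest.approx((4 / 1 + 6 / 3) / 2)

    def test_modes_agree_when_replicates_identical(self):
        tbl = pd.DataFrame(
            {
                "site_id": ["s0"],
                HP_HI: [4.0],
                HP_LI: [2.0],
                f"{HP_HI}__rep1": [4.0],
                f"{HP_HI}__rep2": [4.0],
                f"{HP_LI}__rep1": [2.0],
                f"{HP_LI}__rep2": [2.0],
            }
        )
        avg = sets.fold_change_call(tbl, HP_HI, HP_LI)
        per = sets.fold_change_call(tbl, HP_HI, HP_LI, mode="average_of_ratios")
        assert avg["ratio"].iloc[0] == pytest.approx(per["ratio"].iloc[0])

    def test_missing_replicate_columns_rejected(self):
        tbl = site_table({HP_HI: [4.0], HP_LI: [2.0]})
        with pytest.raises(ConfigurationError):
            sets.fold_change_call(tbl, HP_HI, HP_LI, mode="average_of_ratios")


class TestKmeansProfiles:
    def test_k_one_single_cluster_and_duplicates_share_label(self):
        tbl, _ = generate_profile_groups(n_groups=2, n_per_group=5, seed=0)
        one = sets.kmeans_profiles(tbl, k=1, seed=0)
        assert one["cluster"].nunique() == 1
        dup = pd.concat([tbl, tbl.iloc[[0]].assign(site_id="copy")], ignore_index=True)
        labels = sets.kmeans_profiles(dup, k=2, seed=0).set_index("site_id")["cluster"]
        assert labels[tbl["site_id"].iloc[0]] == labels["copy"]

    def test_fewer_rows_than_k_rejected(self):
        tbl, _ = generate_profile_groups(n_groups=1, n_per_group=3, seed=0)
        with pytest.raises(ConfigurationError):
            sets.kmeans_profiles(tbl, k=10, seed=0)

    def test_recovers_planted_profile_groups(self):
        tbl, truth = generate_profile_groups(n_groups=10, n_per_group=25, seed=3)
        labels = sets.kmeans_profiles(tbl, k=10, seed=3)["cluster"]
        assert adjusted_rand_score(truth, labels) >= 0.9
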