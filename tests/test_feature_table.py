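"""Feature-table model, identifiers, normalization, QC filtering, pairing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantmet import feature_table as ft
from plantmet.synthetic import SimulationConfig, generate_study


class TestFeatureIds:
    @pytest.mark.parametrize("rt,mz,expected", [
        (2.41, 343.82, "2.41_343.82"),
        (0.4123, 532.8735, "0.4123_532.8735"),
        (1.0, 200.0, "1_200"),
    ])
    def test_make_feature_id(self, rt, mz, expected):
        assert ft.make_feature_id(rt, mz) == expected

    @given(rt=st.integers(1, 80_000), mz=st.integers(1_000_000, 10_000_000))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_on_four_decimal_grid(self, rt, mz):
        rt, mz = rt / 10_000, mz / 10_000
        assert ft.parse_feature_id(ft.make_feature_id(rt, mz)) == (rt, mz)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), 0.0, -1.0])
    def test_rejects_non_finite_or_non_positive(self, bad):
        with pytest.raises(ValueError):
            ft.make_feature_id(bad, 100.0)

    @pytest.mark.parametrize("fid", ["abc", "1.0", "a_b", "1.0_2.0_3.0"])
    def test_parse_rejects_malformed(self, fid):
        with pytest.raises(ValueError):
            ft.parse_feature_id(fid)


class TestTableValidation:
    def test_header_parses_into_rt_mz(self, tiny_table):
        assert tiny_table.features.loc["2.41_343.82", "rt"] == 2.41
        assert tiny_table.features.loc["2.41_343.82", "mz"] == 343.82

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="no features"):
            ft.FeatureTable(pd.DataFrame(index=["s1"]))

    def test_negative_intensity_errors(self):
        df = pd.DataFrame([[-5.0]], index=["s1"], columns=["1.0_100.0"])
        with pytest.raises(ValueError, match="negative"):
            ft.FeatureTable(df)

    def test_read_write_round_trip(self, tiny_table, tmp_path):
        path = tmp_path / "table.tsv"
        tiny_table.to_csv(path)
        back, _ = ft.read_feature_table(path)
        pd.testing.assert_frame_equal(back.intensities, tiny_table.intensities)

    def test_read_requires_metadata_for_all_samples(self, tiny_table, tmp_path):
        tiny_table.to_csv(tmp_path / "t.tsv")
        pd.DataFrame({"sample_id": ["s1", "s2"]}).to_csv(
            tmp_path / "m.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="without metadata"):
            ft.read_feature_table(tmp_path / "t.tsv", tmp_path / "m.tsv")


class TestNormalization:
    def test_proportional_scaling(self, tiny_table):
        out = ft.normalize_total_intensity(tiny_table, 10_000.0)
        assert out.intensities.loc["s1"].tolist() == [2000.0, 3000.0, 5000.0]

    def test_idempotent_on_normalized_rows(self, tiny_table):
        once = ft.normalize_total_intensity(tiny_table)
        twice = ft.normalize_total_intensity(once)
        np.testing.assert_allclose(once.values, twice.values, rtol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_row_sums_hit_target(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.gamma(1.0, 10.0, size=(6, 9))
        vals[vals < 2] = 0.0
        vals[:, 0] += 1.0  # no all-zero rows
        df = pd.DataFrame(vals, index=[f"s{i}" for i in range(6)],
                          columns=[f"{i}.1_{100+i}.5" for i in range(9)])
        out = ft.normalize_total_intensity(ft.FeatureTable(df), 10_000.0)
        np.testing.assert_allclose(out.values.sum(axis=1), 10_000.0, rtol=1e-9)
        assert ((out.values == 0) == (vals == 0)).all()

    def test_all_zero_sample_errors(self):
        df = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["a", "b"],
                          columns=["1.0_100.0", "2.0_200.0"])
        with pytest.raises(ValueError, match="all-zero"):
            ft.normalize_total_intensity(ft.FeatureTable(df))


class TestQCRSDFilter:
    def _table(self, qc_cols):
        df = pd.DataFrame(qc_cols, index=[f"qc{i}" for i in range(len(qc_cols))])
        df.columns = [f"{j + 1}.0_{200 + j}.0" for j in range(df.shape[1])]
        return ft.FeatureTable(df)

    def test_rsd_20pct_kept_at_threshold_30(self):
        # sd([10,12,8]) = 2, mean = 10 -> RSD 20%
        table = self._table([[10.0], [12.0], [8.0]])
        kept, removed = ft.qc_rsd_filter(table, table.sample_ids, 30.0)
        assert kept.feature_ids == table.feature_ids and removed.empty

    def test_constant_qc_values_have_zero_rsd(self):
        table = self._table([[7.0], [7.0], [7.0]])
        kept, removed = ft.qc_rsd_filter(table, table.sample_ids, 30.0)
        assert removed.empty

    def test_zero_mean_feature_removed(self):
        table = self._table([[0.0, 5.0], [0.0, 6.0], [0.0, 5.5]])
        kept, removed = ft.qc_rsd_filter(table, table.sample_ids, 30.0)
        assert removed["feature_id"].tolist() == ["1.0_200.0"]
        assert np.isnan(removed["rsd_pct"]).all()

    def test_requires_two_qc_samples(self):
        table = self._table([[1.0]])
        with pytest.raises(ValueError, match="at least 2"):
            ft.qc_rsd_filter(table, table.sample_ids)

    def test_planted_violators_removed_exactly(self, study):
        table, meta, truth = study
        norm = ft.normalize_total_intensity(table)
        qc_ids = meta.index[meta["role"] == ft.ROLE_QC]
        _, removed = ft.qc_rsd_filter(norm, qc_ids)
        assert set(removed["feature_id"]) == set(truth.rsd_violators)


class TestAveragingAndPairing:
    def test_replicate_means_match_groupby_oracle(self, study):
        table, meta, _ = study
        averaged, leaf_meta = ft.average_replicates(table, meta)
        bio = meta[meta["role"] == ft.ROLE_BIOLOGICAL]
        oracle = table.intensities.loc[bio.index].groupby(bio["leaf_id"]).mean()
        np.testing.assert_allclose(
            averaged.intensities.loc[oracle.index].to_numpy(),
            oracle.to_numpy(), rtol=1e-12)
        assert len(averaged.sample_ids) == bio["leaf_id"].nunique()
        assert not set(averaged.sample_ids) & set(
            meta.index[meta["role"] == ft.ROLE_QC])

    def test_paired_difference_is_undamaged_minus_damaged(self, study):
        table, meta, _ = study
        averaged, leaf_meta = ft.average_replicates(table, meta)
        paired = ft.paired_difference(averaged, leaf_meta)
        assert len(paired.plant_ids) == 45  # 90 leaves from 45 plants
        plant = paired.plant_ids[0]
        u = averaged.intensities.loc[f"{plant}_undamaged"]
        d = averaged.intensities.loc[f"{plant}_damaged"]
        np.testing.assert_allclose(paired.diff_intensities.loc[plant], u - d)
        meta_row = paired.plant_meta.loc[plant]
        lu = leaf_meta.loc[f"{plant}_undamaged"]
        ld = leaf_meta.loc[f"{plant}_damaged"]
        assert meta_row["diff_leaf_area_cm2"] == pytest.approx(
            lu["leaf_area_cm2"] - ld["leaf_area_cm2"])
        assert meta_row["damage_pct"] == pytest.approx(ld["damage_pct"])

    def test_missing_pair_member_errors(self, study):
        table, meta, _ = study
        averaged, leaf_meta = ft.average_replicates(table, meta)
        broken = leaf_meta.drop(index=leaf_meta.index[0])
        sub = averaged.subset_samples(broken.index)
        with pytest.raises(ValueError, match="exactly one"):
            ft.paired_difference(sub, broken)

    def test_preprocessing_preserves_non_negativity(self, preprocessed):
        averaged, _, _ = preprocessed
        assert (averaged.values >= 0).all()
        assert len(averaged.sample_ids) == 90
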