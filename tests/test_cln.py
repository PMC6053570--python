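"""Conditional log-normal model: eligibility, tests, FDR, post hoc."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from plantmet import feature_table as ft
from plantmet.cln import (
    CLNSpec,
    combined_lr_test,
    eligibility,
    fdr_bh,
    fit_cln,
    prepare_design,
    run_factor_analysis,
    significance_summary,
    tukey_posthoc,
)
from plantmet.synthetic import SimulationConfig, generate_study


@pytest.fixture(scope="module")
def region_spec():
    return CLNSpec(factor="region")


class TestEligibility:
    def test_all_positive_feature_is_eligible(self, design, region_spec):
        values = np.ones(len(design))
        ok, reason = eligibility(values, design, region_spec)
        assert ok and reason == "ok"

    def test_single_positive_is_ineligible(self, design, region_spec):
        values = np.zeros(len(design))
        values[0] = 5.0
        ok, reason = eligibility(values, design, region_spec)
        assert not ok and reason == "insufficient_positives"

    def test_all_zero_feature_is_ineligible(self, design, region_spec):
        ok, reason = eligibility(np.zeros(len(design)), design, region_spec)
        assert not ok and reason == "all_zero"

    def test_empty_factor_level_blocks_eligibility(self, design, region_spec):
        values = np.where(design["region"] == "western_jutland", 0.0, 1.0)
        ok, reason = eligibility(values, design, region_spec)
        assert not ok and reason.startswith("level_without_enough_positives")

    def test_default_study_eligible_counts_bracket(self):
        """Under default thresholds the study-shaped panel keeps most of the
        197 filtered features eligible for every factor."""
        table, meta, _ = generate_study(SimulationConfig(seed=8))
        norm = ft.normalize_total_intensity(table)
        qc = meta.index[meta["role"] == ft.ROLE_QC]
        filtered, _ = ft.qc_rsd_filter(norm, qc)
        averaged, leaf_meta = ft.average_replicates(filtered, meta)
        design = prepare_design(leaf_meta)
        assert len(filtered.feature_ids) == 197
        for factor in ("region", "habitat", "light"):
            spec = CLNSpec(factor=factor)
            n_ok = sum(
                eligibility(averaged.intensities[fid].to_numpy(), design, spec)[0]
                for fid in averaged.feature_ids)
            assert 170 <= n_ok <= 197


class TestCombinedLRTest:
    def test_partwise_deltas_add(self):
        lr, df, _ = combined_lr_test([1.0, 2.0], [0.0, 0.0], df=2)
        assert lr == pytest.approx(6.0)

    def test_df2_quantile(self):
        _, _, p = combined_lr_test([5.99 / 2], [0.0], df=2)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_identical_fits_give_p_one(self):
        lr, _, p = combined_lr_test([-3.0, -4.0], [-3.0, -4.0], df=1)
        assert lr == 0 and p == 1

    def test_rejects_zero_df(self):
        with pytest.raises(ValueError):
            combined_lr_test([1.0], [0.0], df=0)


class TestFdrBH:
    def test_hand_computed_step_up(self):
        q = fdr_bh([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        assert fdr_bh([0.123])[0] == pytest.approx(0.123)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(fdr_bh([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_q_at_least_p_and_rank_monotone(self, ps):
        q = fdr_bh(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_manual_step_up_oracle(self, rng):
        p = rng.uniform(size=37)
        m = len(p)
        order = np.argsort(p)
        manual = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            manual[i] = running
        np.testing.assert_allclose(fdr_bh(p), manual, atol=1e-12)


class TestFitCln:
    def test_all_positive_feature_skips_binary_part(self, design, region_spec):
        rng = np.random.default_rng(1)
        values = np.exp(rng.normal(5, 0.5, len(design)))
        fit = fit_cln(values, design.reset_index(drop=True), region_spec)
        assert fit.binary_degenerate and fit.df_bin == 0
        assert np.isnan(fit.p_bin) and fit.p == pytest.approx(fit.p_pos)

    def test_planted_region_effect_detected(self, preprocessed, design):
        averaged, _, truth = preprocessed
        spec = CLNSpec(factor="region")
        kept = [f for f in truth.affected("region") if f in averaged.feature_ids]
        d = design.reset_index(drop=True)
        ps = [fit_cln(averaged.intensities[f].to_numpy(), d, spec).p
              for f in kept]
        assert np.median(ps) < 0.001
        assert max(ps) < 0.05

    def test_null_lr_statistic_follows_chi2(self):
        """lr_chi2 combination on a leaf-level factor: LR ~ chi2(df) under
        the null (QQ agreement over 500 simulated features)."""
        rng = np.random.default_rng(12)
        pop = np.repeat([f"P{i}" for i in range(15)], 6)
        plant = np.repeat([f"p{i}" for i in range(45)], 2)
        design = pd.DataFrame({
            "population": pop, "plant_id": plant,
            "leaf_status": np.tile(["undamaged", "damaged"], 45),
            "log_area_c": rng.normal(0, 0.4, 90),
            "ph_c": np.repeat(rng.normal(0, 0.8, 15), 6),
        })
        design["ph_c2"] = design["ph_c"] ** 2
        spec = CLNSpec(factor="leaf_status", method="lr_chi2")
        lrs = []
        for _ in range(500):
            y = np.exp(rng.normal(5, 0.5, 90)
                       + np.repeat(rng.normal(0, 0.3, 45), 2))
            lrs.append(fit_cln(y, design, spec).statistic)
        lrs = np.asarray(lrs)
        qq = np.quantile(lrs, [0.5, 0.9, 0.95])
        expected = stats.chi2.ppf([0.5, 0.9, 0.95], df=1)
        np.testing.assert_allclose(qq, expected, rtol=0.25, atol=0.15)
        assert stats.kstest(stats.chi2.cdf(lrs, df=1), "uniform").pvalue > 1e-3

    def test_factor_missing_from_design_errors(self):
        with pytest.raises(ValueError, match="unknown factor"):
            CLNSpec(factor="altitude")


class TestRunFactorAnalysis:
    def test_summary_counts_are_consistent(self, preprocessed, design):
        averaged, _, _ = preprocessed
        res, _ = run_factor_analysis(averaged, design,
                                     CLNSpec(factor="leaf_area"))
        s = significance_summary(res)
        assert s["n_features"] == len(averaged.feature_ids)
        assert s["q_lt_0.05"] <= s["q_lt_0.10"] <= s["q_lt_0.20"]
        assert s["p_lt_0.001"] <= s["p_lt_0.01"] <= s["p_lt_0.05"]
        assert s["n_tested"] <= s["n_eligible"] <= s["n_features"]
        # q >= p featurewise
        both = res.dropna(subset=["p", "q"])
        assert (both["q"] >= both["p"] - 1e-12).all()


class TestTukeyPosthoc:
    def test_two_level_factor_equals_unadjusted_contrast(self, design):
        rng = np.random.default_rng(3)
        d = design.reset_index(drop=True)
        spec = CLNSpec(factor="leaf_status")
        values = np.exp(rng.normal(5, 0.5, len(d)))
        fit = fit_cln(values, d, spec)
        out = tukey_posthoc(fit, spec)
        assert len(out) == 1
        est, se = out.loc[0, "estimate"], out.loc[0, "se"]
        dof = fit.pos_fit_full.n - fit.pos_fit_full.rank
        p_t = 2 * stats.t.sf(abs(est) / se, dof)
        assert out.loc[0, "p_adj"] == pytest.approx(p_t, rel=1e-6)

    def test_planted_level_shift_flags_only_that_level(self, preprocessed, design):
        averaged, _, truth = preprocessed
        spec = CLNSpec(factor="habitat")
        kept = [f for f in truth.affected("habitat") if f in averaged.feature_ids]
        d = design.reset_index(drop=True)
        fit = fit_cln(averaged.intensities[kept[0]].to_numpy(), d, spec)
        out = tukey_posthoc(fit, spec)
        involving = out[(out["level_a"] == "forest") | (out["level_b"] == "forest")]
        others = out[(out["level_a"] != "forest") & (out["level_b"] != "forest")]
        assert (involving["p_adj"] < 0.05).all()
        assert (others["p_adj"] > 0.05).all()

    def test_equal_group_means_rarely_significant(self, design):
        rng = np.random.default_rng(4)
        d = design.reset_index(drop=True)
        spec = CLNSpec(factor="region")
        n_sig = 0
        for _ in range(40):
            values = np.exp(rng.normal(5, 0.5, len(d)))
            fit = fit_cln(values, d, spec)
            out = tukey_posthoc(fit, spec)
            n_sig += (out["p_adj"] < 0.05).sum()
        assert n_sig <= 0.05 * 40 * 3 + 4  # ~binomial slack

    def test_continuous_factor_rejected(self, design, region_spec):
        rng = np.random.default_rng(5)
        d = design.reset_index(drop=True)
        fit = fit_cln(np.exp(rng.normal(5, 0.5, len(d))), d, region_spec)
        with pytest.raises(ValueError):
            tukey_posthoc(fit, CLNSpec(factor="leaf_area"))
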