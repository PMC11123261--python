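"""Pretreatment chain: merging, drift correction, filters, imputation,
log/PQN/Pareto transforms and the fixed-order driver."""

import numpy as np
import pandas as pd
import pytest

from metabofinger import (
    GeneratorConfig,
    RunConfig,
    blank_filter,
    drift_correct,
    generate_run,
    impute_missing_rf,
    log_transform,
    merge_duplicates_and_isotopes,
    pareto_scale,
    pqn_normalize,
    presence_filter,
    rsd_filter,
    run_pretreatment,
)
from metabofinger.preprocess import (
    AllMissingFeatureError,
    NoBlankSamplesError,
    NonPositiveValueError,
)

from conftest import make_table, two_group_table
from oracles import brute_force_filters


class TestMergeDuplicatesAndIsotopes:
    def test_near_coeluting_duplicates_merge_to_strongest(self):
        table = make_table(
            [[100, 110, 120], [200, 210, 220]],
            ["biological"] * 3, ["control", "control", "exposed"],
            mz=[400.0, 400.0012], rt=[5.0, 5.02],
        )
        merged, log = merge_duplicates_and_isotopes(table)
        assert merged.n_features == 1
        assert merged.feature_ids == ["F1"]  # higher median intensity wins
        assert log.removed("dedupe") == ["F0"]

    def test_correlated_isotope_partner_removed(self):
        base = np.array([100.0, 200.0, 300.0, 400.0])
        table = make_table(
            [base, base / 2],
            ["biological"] * 4, ["control", "control", "exposed", "exposed"],
            mz=[400.0, 401.00335], rt=[5.0, 5.0],
        )
        merged, log = merge_duplicates_and_isotopes(table)
        assert merged.feature_ids == ["F0"]
        assert log.removed("deisotope") == ["F1"]

    def test_isolated_features_untouched(self):
        table = make_table(
            [[100, 110], [200, 210], [300, 310]],
            ["biological"] * 2, ["control", "exposed"],
            mz=[100.0, 200.0, 300.0], rt=[1.0, 2.0, 3.0],
        )
        merged, log = merge_duplicates_and_isotopes(table)
        assert merged.feature_ids == table.feature_ids
        assert not log.entries

    def test_uncorrelated_neighbor_kept(self):
        rng = np.random.default_rng(0)
        table = make_table(
            [np.array([100, 200, 300, 400.0]), rng.uniform(50, 500, 4)],
            ["biological"] * 4, ["control", "control", "exposed", "exposed"],
            mz=[400.0, 401.00335], rt=[5.0, 5.0],
        )
        merged, _ = merge_duplicates_and_isotopes(table, min_corr=0.95)
        assert merged.n_features == 2


def _drift_fixture(multiplier, n=20, qc_orders=(1, 5, 9, 13, 17, 20)):
    types = ["qc" if o in qc_orders else "biological" for o in range(1, n + 1)]
    groups = [None if t == "qc" else ("control" if o % 2 else "exposed")
              for o, t in zip(range(1, n + 1), types)]
    return make_table(
        np.atleast_2d(1000.0 * multiplier), types, groups,
        orders=np.arange(1, n + 1),
    )


class TestDriftCorrect:
    def test_linear_drift_flattened_on_noise_free_qcs(self):
        orders = np.arange(1, 21)
        mult = 1 + (orders - 1) / 19.0  # x1 -> x2 over the run
        table = _drift_fixture(mult)
        corrected, model = drift_correct(table)
        assert bool(model.per_feature["applied"].iloc[0])
        qc_cols = corrected.columns_of("qc")
        vals = corrected.intensities.loc["F0", qc_cols]
        assert (vals.max() - vals.min()) / vals.mean() < 0.01

    def test_constant_qcs_leave_table_untouched(self):
        table = _drift_fixture(np.ones(20))
        corrected, model = drift_correct(table)
        pd.testing.assert_frame_equal(corrected.intensities, table.intensities)
        assert not bool(model.per_feature["applied"].iloc[0])

    def test_pure_noise_mostly_left_uncorrected(self):
        cfg = GeneratorConfig(n_features=200, n_differential=10, n_contaminant=5,
                              drift_amplitude=0.0, seed=3,
                              platform_modes=("hilic_pos",))
        table, _ = generate_run(cfg, 1, "hilic_pos")
        _, model = drift_correct(table)
        assert model.per_feature["applied"].mean() <= 0.5

    def test_too_few_qcs_logged_not_corrected(self):
        table = _drift_fixture(np.linspace(1, 2, 20), qc_orders=(1, 10, 20))
        corrected, model = drift_correct(table)
        assert not bool(model.per_feature["applied"].iloc[0])
        assert "usable QCs" in model.per_feature["reason"].iloc[0]

    def test_applied_features_never_increase_qc_rsd(self):
        cfg = GeneratorConfig(n_features=150, n_differential=10, n_contaminant=5,
                              seed=5, platform_modes=("hilic_pos",))
        table, _ = generate_run(cfg, 1, "hilic_pos")
        _, model = drift_correct(table)
        pf = model.per_feature
        applied = pf[pf["applied"]]
        assert len(applied) > 0
        assert (applied["qc_rsd_after"] < applied["qc_rsd_before"]).all()


class TestBlankFilter:
    def _table(self, bio_max, blank_mean):
        return two_group_table(
            control=[[bio_max / 2, bio_max]], exposed=[[bio_max / 2, bio_max / 2]],
            blank=[[blank_mean, blank_mean]],
        )

    def test_below_tenfold_removed(self):
        filtered, log = blank_filter(self._table(900, 100))
        assert filtered.n_features == 0 and log.removed() == ["F0"]

    def test_boundary_kept_strict_inequality(self):
        filtered, _ = blank_filter(self._table(1000, 100))
        assert filtered.n_features == 1

    def test_all_blank_missing_counts_as_zero(self):
        table = two_group_table(
            control=[[100.0, 100.0]], exposed=[[100.0, 100.0]],
            blank=[[np.nan, np.nan]],
        )
        filtered, _ = blank_filter(table)
        assert filtered.n_features == 1

    def test_no_blank_samples_raises(self):
        table = two_group_table(control=[[1.0, 2.0]], exposed=[[1.0, 2.0]])
        with pytest.raises(NoBlankSamplesError):
            blank_filter(table)


class TestPresenceFilter:
    def _table(self, ctrl_present, expo_present, n=8, qc_present=0):
        ctrl = [100.0] * ctrl_present + [np.nan] * (n - ctrl_present)
        expo = [100.0] * expo_present + [np.nan] * (n - expo_present)
        qc = [100.0] * qc_present + [np.nan] * (6 - qc_present)
        return two_group_table(control=[ctrl], exposed=[expo], qc=[qc])

    def test_one_group_at_threshold_kept(self):
        filtered, _ = presence_filter(self._table(0, 6))
        assert filtered.n_features == 1  # 6/8 = 75%

    def test_both_groups_below_removed(self):
        filtered, log = presence_filter(self._table(5, 5))
        assert filtered.n_features == 0
        assert log.entries[0]["rule"].startswith("presence")

    def test_qc_only_presence_does_not_count(self):
        filtered, _ = presence_filter(self._table(0, 0, qc_present=6))
        assert filtered.n_features == 0


class TestRsdFilter:
    def test_constant_exposed_kept(self):
        table = two_group_table(control=[[1, 2, 3]], exposed=[[100, 100, 100]])
        filtered, _ = rsd_filter(table)
        assert filtered.n_features == 1

    def test_exactly_30_percent_removed(self):
        # mean 100, sd 30 -> RSD exactly 30%: strict < removes it
        table = two_group_table(control=[[1, 2, 3]], exposed=[[70.0, 100.0, 130.0]])
        filtered, log = rsd_filter(table)
        assert filtered.n_features == 0
        assert float(log.entries[0]["value"]) == pytest.approx(30.0)

    def test_single_present_exposed_removed_as_undefined(self):
        table = two_group_table(control=[[1, 2, 3]], exposed=[[50.0, np.nan, np.nan]])
        filtered, log = rsd_filter(table)
        assert filtered.n_features == 0
        assert log.entries[0]["rule"] == "undefined"


class TestFilterOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_filters_match_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(4, 1.5, size=(50, 20))
        vals[rng.random(vals.shape) < 0.15] = np.nan
        types = ["biological"] * 16 + ["qc"] * 2 + ["blank"] * 2
        groups = ["control"] * 8 + ["exposed"] * 8 + [None] * 4
        table = make_table(vals, types, groups)
        t, _ = blank_filter(table)
        t, _ = presence_filter(t)
        t, _ = rsd_filter(t)
        assert t.feature_ids == brute_force_filters(table)


class TestImputation:
    def test_no_missing_returns_identical_table(self, toy_table):
        complete = toy_table.copy()
        complete.intensities = complete.intensities.fillna(50.0)
        out = impute_missing_rf(complete, seed=0)
        pd.testing.assert_frame_equal(out.intensities, complete.intensities)

    def test_constant_feature_imputed_to_its_level(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(5, 0.5, size=(20, 10))
        vals[0] = 500.0
        vals[0, 3] = np.nan
        table = make_table(vals, ["biological"] * 10,
                           ["control"] * 5 + ["exposed"] * 5)
        out = impute_missing_rf(table, seed=0)
        assert out.intensities.iloc[0, 3] == pytest.approx(500.0, rel=0.01)

    def test_mcar_imputation_error_below_biological_cv(self):
        cfg = GeneratorConfig(n_features=80, n_differential=8, n_contaminant=4,
                              drift_amplitude=0.0, missing_lod_quantile=0.0,
                              missing_random_rate=0.0, seed=2,
                              platform_modes=("hilic_pos",))
        table, _ = generate_run(cfg, 1, "hilic_pos")
        rng = np.random.default_rng(0)
        truth_vals = table.intensities.to_numpy().copy()
        mask = rng.random(truth_vals.shape) < 0.10
        holey = table.copy()
        vals = truth_vals.copy()
        vals[mask] = np.nan
        holey.intensities = pd.DataFrame(vals, index=table.intensities.index,
                                         columns=table.intensities.columns)
        out = impute_missing_rf(holey, seed=0)
        rel_err = np.abs(out.intensities.to_numpy()[mask] - truth_vals[mask]) / truth_vals[mask]
        assert np.median(rel_err) < cfg.biological_cv

    def test_all_missing_feature_raises(self):
        table = make_table([[np.nan, np.nan], [1.0, 2.0]],
                           ["biological"] * 2, ["control", "exposed"])
        with pytest.raises(AllMissingFeatureError):
            impute_missing_rf(table, seed=0)


class TestTransforms:
    def test_log_transform_values(self):
        table = make_table([[1.0, np.e]], ["biological", "biological"],
                           ["control", "exposed"])
        out = log_transform(table)
        np.testing.assert_allclose(out.intensities.to_numpy(), [[0.0, 1.0]])

    def test_log_transform_rejects_zero(self):
        table = make_table([[0.0, 1.0]], ["biological", "biological"],
                           ["control", "exposed"])
        with pytest.raises(NonPositiveValueError):
            log_transform(table)

    def test_pqn_doubled_sample_gets_factor_two(self):
        ref = np.array([10.0, 20.0, 30.0])
        table = two_group_table(
            control=np.column_stack([ref, 2 * ref]),
            exposed=np.column_stack([ref, ref]),
            qc=np.column_stack([ref, ref]),
        )
        out, factors = pqn_normalize(table)
        assert factors["s1"] == pytest.approx(2.0)
        np.testing.assert_allclose(out.intensities["s1"], ref)

    def test_pqn_qc_equal_to_reference_has_factor_one(self):
        ref = np.array([10.0, 20.0, 30.0])
        table = two_group_table(control=[[15.0], [25.0], [35.0]],
                                exposed=[[5.0], [18.0], [33.0]],
                                qc=np.column_stack([ref]))
        _, factors = pqn_normalize(table)
        qc_col = table.columns_of("qc")[0]
        assert factors[qc_col] == pytest.approx(1.0)

    def test_pqn_median_quotient_by_hand(self):
        table = two_group_table(control=[[20.0], [30.0], [60.0]],
                                exposed=[[10.0], [10.0], [10.0]],
                                qc=[[10.0], [10.0], [10.0]])
        _, factors = pqn_normalize(table)
        assert factors["s0"] == pytest.approx(3.0)  # quotients {2, 3, 6}

    def test_pqn_log_scale_matches_raw_scale(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(3, 1, size=(30, 8))
        types = ["biological"] * 6 + ["qc"] * 2
        groups = ["control"] * 3 + ["exposed"] * 3 + [None, None]
        table = make_table(vals, types, groups)
        raw_out, raw_f = pqn_normalize(table, assume_log=False)
        logt = log_transform(table)
        log_out, log_f = pqn_normalize(logt, assume_log=True)
        np.testing.assert_allclose(raw_f, log_f, rtol=1e-10)
        np.testing.assert_allclose(
            np.log(raw_out.intensities), log_out.intensities, rtol=1e-10
        )

    def test_pqn_removes_scalar_dilution_exactly(self):
        rng = np.random.default_rng(4)
        profile = rng.lognormal(4, 1, size=40)
        dilutions = rng.uniform(0.5, 2.0, size=10)
        vals = profile[:, None] * dilutions[None, :]
        types = ["biological"] * 8 + ["qc"] * 2
        groups = ["control"] * 4 + ["exposed"] * 4 + [None, None]
        table = make_table(vals, types, groups)
        out, _ = pqn_normalize(table)
        cols = out.intensities.to_numpy()
        np.testing.assert_allclose(cols, cols[:, [0]] @ np.ones((1, 10)), rtol=1e-10)

    def test_pareto_centers_and_scales(self):
        table = make_table([[1.0, 2.0, 3.0]], ["biological"] * 3,
                           ["control", "control", "exposed"])
        out = pareto_scale(table)
        np.testing.assert_allclose(out.intensities.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_pareto_constant_feature_zeroed(self):
        table = make_table([[5.0, 5.0, 5.0]], ["biological"] * 3,
                           ["control", "control", "exposed"])
        out = pareto_scale(table)
        np.testing.assert_allclose(out.intensities.to_numpy(), 0.0)

    def test_pareto_variance_equals_original_sd(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(3, 1, size=(25, 12))
        table = make_table(vals, ["biological"] * 12,
                           ["control"] * 6 + ["exposed"] * 6)
        out = pareto_scale(table)
        sd_before = vals.std(axis=1, ddof=1)
        var_after = out.intensities.to_numpy().var(axis=1, ddof=1)
        np.testing.assert_allclose(var_after, sd_before, rtol=1e-8)
        assert np.abs(out.intensities.to_numpy().mean(axis=1)).max() < 1e-10


class TestRunPretreatment:
    def test_zero_feature_table_passes_through(self):
        table = make_table(np.empty((0, 4)),
                           ["biological", "biological", "qc", "blank"],
                           ["control", "exposed", None, None])
        result = run_pretreatment(table)
        assert result.table.n_features == 0
        assert not result.filter_log.entries

    def test_deterministic_under_fixed_seed(self, small_generator_config):
        table, _ = generate_run(small_generator_config, 1, "hilic_pos")
        r1 = run_pretreatment(table, RunConfig(seed=3))
        r2 = run_pretreatment(table, RunConfig(seed=3))
        pd.testing.assert_frame_equal(r1.table.intensities, r2.table.intensities)

    def test_stage_order_and_monotone_counts(self, small_generator_config):
        table, _ = generate_run(small_generator_config, 1, "hilic_pos")
        result = run_pretreatment(table, RunConfig(seed=3))
        stages = [s.stage for s in result.report.stages]
        assert stages == [
            "dedupe_deisotope", "drift_correction", "blank_filter",
            "presence_filter", "rsd_filter", "drop_blanks", "rf_imputation",
            "log_transform", "pqn_normalization", "pareto_scaling",
        ]
        counts = [s.n_features_out for s in result.report.stages]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        # snapshot is unimputed and un-normalized: raw scale, may hold NaN
        snap = result.univariate_snapshot
        assert (snap.intensities.min(axis=1) >= 0).all()
        assert set(snap.feature_ids) == set(result.table.feature_ids)

    def test_filter_stages_match_brute_force(self, small_generator_config):
        table, _ = generate_run(small_generator_config, 1, "hilic_pos")
        corrected, _ = drift_correct(merge_duplicates_and_isotopes(table)[0])
        expected = brute_force_filters(corrected)
        result = run_pretreatment(table, RunConfig(seed=3))
        assert result.table.feature_ids == expected
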