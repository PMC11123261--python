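"""Cross-batch matching, confirmation rules and review exports."""

import numpy as np
import pandas as pd
import pytest

from metabofinger import (
    GeneratorConfig,
    RunConfig,
    export_boxplots,
    export_fingerprint,
    generate_run,
    match_features,
    validate_selection,
)
from metabofinger.validate import PlatformMismatchError

from conftest import make_table


def simple_table(mz, rt, platform="hilic_pos", n_samples=4):
    vals = np.tile(np.linspace(100, 400, n_samples), (len(mz), 1))
    return make_table(vals, ["biological"] * n_samples,
                      ["control"] * (n_samples // 2) + ["exposed"] * (n_samples // 2),
                      mz=mz, rt=rt, platform_mode=platform)


def records(feature_ids, selected, fold_changes):
    fc = pd.Series(fold_changes, index=feature_ids, dtype=float)
    return pd.DataFrame(
        {
            "univariate_selected": selected,
            "multivariate_selected": False,
            "combined_selected": selected,
            "fold_change": fc,
            "direction": np.where(fc > 1, "up", "down"),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )


class TestMatchFeatures:
    def test_identical_lists_match_perfectly(self):
        t = simple_table([100.0, 200.0, 300.0], [1.0, 2.0, 3.0])
        matches = match_features(t, t)
        assert matches["feature_id_2"].tolist() == matches["feature_id_1"].tolist()
        assert matches["feature_id_2"].notna().all()

    def test_small_shift_within_tolerance_matches_all(self):
        t1 = simple_table([100.0, 200.0, 300.0], [1.0, 2.0, 3.0])
        t2 = simple_table([m * (1 + 3e-6) for m in (100.0, 200.0, 300.0)],
                          [1.02, 2.02, 3.02])
        matches = match_features(t1, t2)
        assert matches["feature_id_2"].notna().all()
        assert (matches["d_mz_ppm"] < 4).all()

    def test_nearest_mz_candidate_wins(self):
        t1 = simple_table([500.0], [5.0])
        t2 = simple_table([500.0 * (1 + 2e-6), 500.0 * (1 + 6e-6)], [5.0, 5.0])
        matches = match_features(t1, t2)
        assert matches.loc[0, "feature_id_2"] == "F0"
        assert matches.loc[0, "d_mz_ppm"] == pytest.approx(2.0, abs=0.01)

    def test_matching_is_one_to_one(self):
        t1 = simple_table([500.0, 500.0005, 900.0], [5.0, 5.0, 9.0])
        t2 = simple_table([500.0001, 700.0], [5.0, 7.0])
        matches = match_features(t1, t2)
        matched = matches["feature_id_2"].dropna()
        assert matched.is_unique

    def test_platform_mismatch_rejected(self):
        t1 = simple_table([100.0], [1.0], platform="hilic_pos")
        t2 = simple_table([100.0], [1.0], platform="rplc_pos")
        with pytest.raises(PlatformMismatchError):
            match_features(t1, t2)

    def test_generated_batches_match_near_completely(self):
        cfg = GeneratorConfig(n_features=150, n_differential=10, n_contaminant=5,
                              seed=4, platform_modes=("hilic_pos",))
        t1, _ = generate_run(cfg, 1, "hilic_pos")
        t2, _ = generate_run(cfg, 2, "hilic_pos")
        matches = match_features(t1, t2)
        assert matches["feature_id_2"].notna().mean() > 0.95


class TestValidateSelection:
    def _matches(self, ids):
        return pd.DataFrame({"feature_id_1": ids, "feature_id_2": ids,
                             "d_mz_ppm": 0.0, "d_rt": 0.0})

    def test_selected_in_one_batch_only_not_validated(self):
        r1 = records(["A"], [True], [8.0])
        r2 = records(["A"], [False], [7.0])
        out = validate_selection(r1, r2, self._matches(["A"]))
        assert not out.loc[0, "validated"]
        assert "both batches" in out.loc[0, "reason"]

    def test_consistent_direction_validated(self):
        r1 = records(["A"], [True], [8.1])
        r2 = records(["A"], [True], [6.9])
        out = validate_selection(r1, r2, self._matches(["A"]))
        assert out.loc[0, "validated"]
        assert out.loc[0, "direction_1"] == "up"

    def test_direction_conflict_rejected(self):
        r1 = records(["A"], [True], [8.0])
        r2 = records(["A"], [True], [0.1])
        out = validate_selection(r1, r2, self._matches(["A"]))
        assert not out.loc[0, "validated"]
        assert out.loc[0, "reason"] == "direction conflict"

    def test_direction_rule_can_be_disabled(self):
        r1 = records(["A"], [True], [8.0])
        r2 = records(["A"], [True], [0.1])
        cfg = RunConfig(require_direction_consistency=False)
        out = validate_selection(r1, r2, self._matches(["A"]), cfg)
        assert out.loc[0, "validated"]

    def test_symmetric_under_batch_swap(self):
        ids = ["A", "B", "C"]
        r1 = records(ids, [True, True, False], [8.0, 0.1, 9.0])
        r2 = records(ids, [True, True, True], [6.0, 0.15, 7.0])
        fwd = validate_selection(r1, r2, self._matches(ids))
        rev = validate_selection(r2, r1, self._matches(ids))
        assert fwd["validated"].tolist() == rev["validated"].tolist()


class TestExports:
    def _validated(self):
        r1 = records(["A", "B", "C"], [True, True, True], [8.0, 0.1, 6.0])
        r2 = records(["A", "B", "C"], [True, True, False], [7.0, 0.12, 5.5])
        matches = pd.DataFrame({"feature_id_1": ["A", "B", "C"],
                                "feature_id_2": ["A", "B", "C"],
                                "d_mz_ppm": 0.0, "d_rt": 0.0})
        return validate_selection(r1, r2, matches)

    def test_boxplots_one_file_per_validated_feature(self, tmp_path):
        tables = {
            1: simple_table([100.0, 200.0, 300.0], [1.0, 2.0, 3.0], n_samples=8),
            2: simple_table([100.0, 200.0, 300.0], [1.0, 2.0, 3.0], n_samples=8),
        }
        # rename features to match the validated records
        for t in tables.values():
            t.features.index = pd.Index(["A", "B", "C"])
            t.intensities.index = t.features.index
        validated = self._validated()
        paths = export_boxplots(tables, validated, tmp_path / "plots")
        assert len(paths) == 2  # A and B validated, C not
        assert (tmp_path / "plots" / "index.csv").exists()

    def test_boxplot_index_deterministic(self, tmp_path):
        validated = self._validated()
        tables = {1: simple_table([100.0], [1.0], n_samples=8)}
        tables[1].features.index = pd.Index(["A"])
        tables[1].intensities.index = tables[1].features.index
        export_boxplots(tables, validated, tmp_path / "p1")
        export_boxplots(tables, validated, tmp_path / "p2")
        assert (tmp_path / "p1" / "index.csv").read_bytes() == \
               (tmp_path / "p2" / "index.csv").read_bytes()

    def test_empty_validated_set_writes_empty_index(self, tmp_path):
        r1 = records(["A"], [False], [8.0])
        r2 = records(["A"], [False], [8.0])
        matches = pd.DataFrame({"feature_id_1": ["A"], "feature_id_2": ["A"],
                                "d_mz_ppm": 0.0, "d_rt": 0.0})
        validated = validate_selection(r1, r2, matches)
        paths = export_boxplots({}, validated, tmp_path / "plots")
        assert paths == []
        index = pd.read_csv(tmp_path / "plots" / "index.csv")
        assert index.empty

    def test_fingerprint_without_truth_has_no_metrics(self, tmp_path):
        table, metrics = export_fingerprint(self._validated(),
                                            out=tmp_path / "fp.csv")
        assert metrics is None
        assert len(table) == 2
        assert set(table["direction_1"]) == {"up", "down"}
        assert np.abs(table["normalized_log2_fc"]).max() == pytest.approx(1.0)

    def test_fingerprint_empty_validated_is_header_only(self, tmp_path):
        r1 = records(["A"], [False], [2.0])
        r2 = records(["A"], [False], [2.0])
        matches = pd.DataFrame({"feature_id_1": ["A"], "feature_id_2": ["A"],
                                "d_mz_ppm": 0.0, "d_rt": 0.0})
        validated = validate_selection(r1, r2, matches)
        table, _ = export_fingerprint(validated, out=tmp_path / "fp.csv")
        assert table.empty
        assert pd.read_csv(tmp_path / "fp.csv").empty
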