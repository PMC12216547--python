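import numpy as np
import pandas as pd
import pytest
from scipy import stats

from devodyn.omics_io import (
    DEFAULT_LOD, ExpressionMatrix, ImputationSpec, ParseError, SampleSheet,
    Scale, ShiftedBetaImputer, impute_shifted_beta, log_transform,
    read_matrix, replicate_correlation, timepoint_means, write_matrix,
)


def _write(tmp_path, text, name="m.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadWrite:
    def test_missing_cells_parsed_from_empty_and_na(self, tmp_path):
        p = _write(tmp_path, "id\ts1\ts2\ng1\t1.5\t\ng2\tNA\t2\ng3\t3\t4\n")
        m = read_matrix(p, Scale.lfq_log2)
        assert m.missing_mask.to_numpy().sum() == 2
        assert m.missing_mask.loc["g1", "s2"] and m.missing_mask.loc["g2", "s1"]
        assert m.values.loc["g3", "s2"] == 4.0

    def test_duplicate_feature_ids_rejected(self, tmp_path):
        p = _write(tmp_path, "id\ts1\ng1\t1\ng1\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_matrix(p, Scale.cpm)

    def test_non_numeric_cell_names_row_and_col(self, tmp_path):
        p = _write(tmp_path, "id\ts1\ts2\ng1\t1\tabc\n")
        with pytest.raises(ParseError, match="g1.*s2"):
            read_matrix(p, Scale.cpm)

    def test_round_trip_preserves_values_and_mask(self, tmp_path, tiny_matrix):
        tiny_matrix.values.iloc[0, 0] = np.nan
        m = ExpressionMatrix(tiny_matrix.values, Scale.lfq_log2)
        path = tmp_path / "rt.tsv"
        write_matrix(m, path)
        back = read_matrix(path, Scale.lfq_log2)
        pd.testing.assert_frame_equal(back.observed(), m.observed())
        pd.testing.assert_frame_equal(back.missing_mask, m.missing_mask)

    def test_round_trip_csv_dialect(self, tmp_path, tiny_matrix):
        path = tmp_path / "rt.csv"
        write_matrix(tiny_matrix, path)
        back = read_matrix(path, Scale.lfq_log2)
        pd.testing.assert_frame_equal(back.values, tiny_matrix.values)


class TestSampleSheet:
    def test_duplicate_timepoint_replicate_rejected(self, tiny_sheet):
        t = tiny_sheet.table.copy()
        t.loc[1, "replicate"] = 1  # collide with row 0
        with pytest.raises(ValueError, match="not unique"):
            SampleSheet(t)

    def test_timepoint_with_two_stages_rejected(self, tiny_sheet):
        t = tiny_sheet.table.copy()
        t.loc[t["timepoint"] == "E1", "stage"] = ["egg", "larva"]
        with pytest.raises(ValueError, match="more than one stage"):
            SampleSheet(t)

    def test_stage_timepoint_maps(self, tiny_sheet):
        assert tiny_sheet.stage_of()["L1"] == "larva"
        assert tiny_sheet.stage_timepoints()["egg"] == ["E1", "E2"]


class TestLogTransform:
    @pytest.mark.parametrize("cpm,expected", [(0.0, 0.0), (3.0, 2.0), (1.0, 1.0)])
    def test_cpm_log2_plus_one(self, cpm, expected):
        m = ExpressionMatrix(pd.DataFrame({"s1": [cpm]}, index=["g"]), Scale.cpm)
        assert log_transform(m).values.iloc[0, 0] == pytest.approx(expected)

    def test_lfq_linear_exact_power(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [2 ** 22.5]}, index=["g"]),
                             Scale.lfq_linear)
        out = log_transform(m)
        assert out.values.iloc[0, 0] == pytest.approx(22.5)
        assert out.scale is Scale.lfq_log2

    def test_nonpositive_lfq_rejected(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [0.0]}, index=["g"]), Scale.lfq_linear)
        with pytest.raises(ValueError, match="> 0"):
            log_transform(m)

    def test_monotone_on_observed_values(self, tiny_matrix):
        out = log_transform(ExpressionMatrix(
            np.exp(tiny_matrix.values / 10), Scale.lfq_linear))
        flat_in = tiny_matrix.values.to_numpy().ravel()
        flat_out = out.values.to_numpy().ravel()
        order = np.argsort(flat_in)
        assert (np.diff(flat_out[order]) >= 0).all()


class TestImputation:
    def test_no_missing_is_identity(self, tiny_matrix):
        out = impute_shifted_beta(tiny_matrix, ImputationSpec(seed=3))
        pd.testing.assert_frame_equal(out.values, tiny_matrix.values)
        assert not out.is_imputed

    def test_imputed_values_in_window_and_reproducible(self, tiny_matrix):
        vals = tiny_matrix.values.copy()
        vals.iloc[0, 0] = np.nan
        m = ExpressionMatrix(vals, Scale.lfq_log2)
        spec = ImputationSpec(loq=24.0, window_width=2.0, beta_alpha=2.0,
                              beta_beta=5.0, seed=42)
        out1 = impute_shifted_beta(m, spec)
        out2 = impute_shifted_beta(m, spec)
        v = out1.values.iloc[0, 0]
        assert 22.0 <= v <= 24.0
        assert v == out2.values.iloc[0, 0]
        # oracle: independent draw from the same seeded stream
        draw = np.random.default_rng(42).beta(2.0, 5.0, size=1)[0]
        assert v == pytest.approx(24.0 - 2.0 * (1.0 - draw))
        assert bool(out1.imputed_mask.iloc[0, 0])

    def test_observed_cells_never_altered_and_below_loq(self):
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(rng.normal(26, 2, (200, 20)),
                            index=[f"g{i}" for i in range(200)])
        holes = rng.random(vals.shape) < 0.2
        masked = vals.mask(holes)
        m = ExpressionMatrix(masked, Scale.lfq_log2)
        out = impute_shifted_beta(m, ImputationSpec(seed=1))
        obs = ~holes
        np.testing.assert_array_equal(out.values.to_numpy()[obs],
                                      vals.to_numpy()[obs])
        loq = np.percentile(vals.to_numpy()[obs], 1.0)
        assert (out.values.to_numpy()[holes] <= loq + 1e-12).all()

    def test_empirical_distribution_matches_direct_sampler(self):
        # 10^4 imputed cells vs a direct draw from the target shifted beta
        rng = np.random.default_rng(11)
        n_obs = 5000
        obs = rng.normal(26, 2, n_obs)
        vals = np.concatenate([obs, np.full(10000, np.nan)])
        m = ExpressionMatrix(pd.DataFrame(vals.reshape(-1, 1), columns=["s"],
                                          index=[f"g{i}" for i in range(vals.size)]),
                             Scale.lfq_log2)
        out = impute_shifted_beta(m, ImputationSpec(seed=5))
        imputed = out.values.to_numpy()[out.imputed_mask.to_numpy()]
        imp = ShiftedBetaImputer(random_state=99).fit(obs.reshape(-1, 1))
        direct = imp.loq_ - imp.window_width_ * (
            1.0 - np.random.default_rng(123).beta(imp.alpha_, imp.beta_, 10000))
        ks = stats.ks_2samp(imputed, direct).statistic
        assert ks < 0.02

    def test_all_missing_without_shapes_errors(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [np.nan, np.nan]},
                                          index=["a", "b"]), Scale.lfq_log2)
        with pytest.raises(ValueError, match="missing"):
            impute_shifted_beta(m, ImputationSpec())


class TestTimepointMeans:
    def test_mean_of_observed_replicates(self, tiny_sheet, tiny_matrix):
        vals = tiny_matrix.values.copy()
        vals.loc["g0", ["E1_r1", "E1_r2"]] = [4.0, 6.0]
        m = ExpressionMatrix(vals, Scale.lfq_log2)
        out = timepoint_means(m, tiny_sheet)
        assert out.values.loc["g0", "E1"] == pytest.approx(5.0)
        assert list(out.values.columns) == tiny_sheet.timepoints

    def test_unobserved_timepoint_filled_with_lod(self, tiny_sheet, tiny_matrix):
        vals = tiny_matrix.values.copy()
        vals.loc["g0", ["E1_r1", "E1_r2"]] = np.nan
        m = ExpressionMatrix(vals, Scale.lfq_log2)
        out = timepoint_means(m, tiny_sheet, lod_fill=DEFAULT_LOD)
        assert out.values.loc["g0", "E1"] == DEFAULT_LOD
        missing = timepoint_means(m, tiny_sheet)
        assert bool(missing.missing_mask.loc["g0", "E1"])

    def test_unknown_sample_id_rejected(self, tiny_sheet, tiny_matrix):
        bad = tiny_matrix.values.rename(columns={"E1_r1": "mystery"})
        m = ExpressionMatrix(bad, Scale.lfq_log2)
        with pytest.raises(ValueError, match="not in sample sheet"):
            timepoint_means(m, tiny_sheet)


class TestReplicateCorrelation:
    def test_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=50)
        vals = pd.DataFrame({"a": base, "b": base, "c": -base + base.mean() * 2},
                            index=[f"g{i}" for i in range(50)])
        corr = replicate_correlation(ExpressionMatrix(vals, Scale.lfq_log2))
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert (np.diag(corr) == 1.0).all()

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=100), rng.normal(size=100)
        vals = pd.DataFrame({"x": x, "y": y}, index=[f"g{i}" for i in range(100)])
        corr = replicate_correlation(ExpressionMatrix(vals, Scale.lfq_log2))
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert corr.loc["x", "y"] == pytest.approx(expected, abs=1e-12)

    def test_insufficient_overlap_gives_nan(self):
        vals = pd.DataFrame({"x": [1.0, 2, np.nan, np.nan, np.nan],
                             "y": [np.nan, 1.0, 2, 3, 4]},
                            index=list("abcde"))
        corr = replicate_correlation(ExpressionMatrix(vals, Scale.lfq_log2))
        assert np.isnan(corr.loc["x", "y"])
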