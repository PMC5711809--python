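import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mstbayes as mb
from mstbayes import (
    TABLE_CASES,
    TestCaseParams,
    TitrationDataset,
    generate_dataset,
    load_dataset,
    mass_action_response,
    save_dataset,
)


class TestGenerateDataset:
    def test_degenerate_generator_lies_on_true_curve(self, clean_dataset, clean_params):
        expected = mass_action_response(clean_dataset.concentrations, clean_params.binding_params)
        assert np.allclose(clean_dataset.responses, expected, rtol=0, atol=1e-12)
        assert not clean_dataset.data["is_outlier"].any()

    def test_outlier_count_is_floor_of_fraction(self):
        ds = generate_dataset(TABLE_CASES[0])  # 3 repeats x 16 points
        assert ds.n_points == 48
        assert int(ds.data["is_outlier"].sum()) == 9  # floor(0.2 * 48)

    @pytest.mark.parametrize("frac,n_expected", [(0.0, 0), (0.5, 24), (1.0, 48)])
    def test_outlier_fraction_extremes(self, frac, n_expected):
        params = TestCaseParams(kd_true=500, b_true=780, u_true=800, outlier_fraction=frac, rng_seed=1)
        ds = generate_dataset(params)
        assert int(ds.data["is_outlier"].sum()) == n_expected

    def test_outliers_span_the_ub_range_with_margin(self):
        params = TestCaseParams(kd_true=500, b_true=780, u_true=800, rng_seed=3, repeats=10)
        ds = generate_dataset(params)
        out = ds.data.loc[ds.data["is_outlier"], "response"]
        margin = 0.25 * 20.0
        assert out.between(780 - margin, 800 + margin).all()

    def test_seed_determinism(self):
        a = generate_dataset(TABLE_CASES[0])
        b = generate_dataset(TABLE_CASES[0])
        pd.testing.assert_frame_equal(a.data, b.data)
        from dataclasses import replace

        c = generate_dataset(replace(TABLE_CASES[0], rng_seed=999))
        assert not np.allclose(a.responses, c.responses)

    def test_fitting_x_is_targeted_not_true_concentration(self):
        ds = generate_dataset(TABLE_CASES[5])  # CoV 0.02: visible dilution error
        conc = ds.data["concentration_nM"]
        true_c = ds.data["true_concentration_nM"]
        per_rep = ds.data.groupby("replicate")["concentration_nM"]
        for _, x in per_rep:
            assert np.allclose(x.to_numpy(), mb.targeted_concentrations(TABLE_CASES[5].stock_concentration, 15))
        assert not np.allclose(conc, true_c)

    def test_non_outlier_residuals_are_normal(self):
        params = TestCaseParams(
            kd_true=500, b_true=780, u_true=800, noise_sd=1.0,
            pipette_cov=0.0, repeats=40, rng_seed=8,
        )
        ds = generate_dataset(params)
        keep = ~ds.data["is_outlier"]
        resid = ds.responses[keep] - mass_action_response(ds.concentrations[keep], params.binding_params)
        assert stats.normaltest(resid).pvalue > 1e-3

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            TestCaseParams(kd_true=500, b_true=780, u_true=800, repeats=0)
        with pytest.raises(ValueError):
            TestCaseParams(kd_true=500, b_true=780, u_true=800, outlier_fraction=1.5)
        with pytest.raises(ValueError):
            TestCaseParams(kd_true=-1, b_true=780, u_true=800)


class TestBenchmarkCases:
    def test_ten_cases_with_expected_structure(self):
        assert len(TABLE_CASES) == 10
        repeats = [c.repeats for c in TABLE_CASES]
        assert repeats[6] == 1 and repeats[7] == 10 and repeats[0] == 3
        assert TABLE_CASES[5].pipette_cov == pytest.approx(0.02)
        assert [c.noise_sd for c in TABLE_CASES[8:]] == [0.5, 2.0]
        assert TABLE_CASES[4].b_true == 795.0
        # each series brackets the true K_D
        for c in TABLE_CASES:
            assert c.stock_concentration / 2**c.n_steps < c.kd_true < c.stock_concentration


class TestDatasetIO:
    def test_round_trip_identity(self, tmp_path):
        ds = generate_dataset(TABLE_CASES[1])
        path = tmp_path / "ds.csv"
        save_dataset(ds, path)
        loaded = load_dataset(path)
        pd.testing.assert_frame_equal(ds.data, loaded.data, check_dtype=False)
        assert loaded.ground_truth == ds.ground_truth

    def test_unknown_columns_preserved(self, tmp_path):
        ds = generate_dataset(TABLE_CASES[0])
        df = ds.data.copy()
        df["operator"] = "A"
        path = tmp_path / "ds.csv"
        save_dataset(TitrationDataset(data=df, ground_truth=ds.ground_truth), path)
        assert "operator" in load_dataset(path).data.columns

    def test_hand_written_fixture_three_replicates(self, tmp_path):
        rows = ["replicate,concentration_nM,response"]
        for rep in (1, 2, 3):
            rows += [f"{rep},{1000/2**k},{800 - k}" for k in range(16)]
        path = tmp_path / "fixture.csv"
        path.write_text("\n".join(rows))
        ds = load_dataset(path)
        assert ds.n_points == 48
        assert ds.replicate_ids.tolist() == [1, 2, 3]

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="no data"):
            load_dataset(path)

    def test_nonpositive_concentration_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("replicate,concentration_nM,response\n1,100,800\n1,-5,790\n")
        with pytest.raises(ValueError, match="line 3"):
            load_dataset(path)

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("replicate,conc,resp\n1,100,800\n")
        with pytest.raises(ValueError, match="concentration_nM"):
            load_dataset(path)

    def test_noncontiguous_replicates_rejected(self):
        df = pd.DataFrame({"replicate": [1, 3], "concentration_nM": [100.0, 50.0], "response": [800.0, 790.0]})
        with pytest.raises(ValueError, match="contiguous"):
            TitrationDataset(data=df)
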