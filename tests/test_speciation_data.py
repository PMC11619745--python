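"""Speciation arithmetic, exceedance, split, screening, standardization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import alimix as am

finite = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


class TestComputeAlI:
    @pytest.mark.parametrize(
        "al_d, al_o, expected",
        [(364.0, 329.0, 35.0), (100.0, 100.0, 0.0)],
    )
    def test_difference(self, al_d, al_o, expected):
        assert am.compute_al_i(al_d, al_o) == pytest.approx(expected)

    def test_negative_flagged_but_returned(self):
        with pytest.warns(UserWarning, match="negative"):
            assert am.compute_al_i(50.0, 60.0) == pytest.approx(-10.0)

    def test_missing_propagates(self):
        assert math.isnan(am.compute_al_i(np.nan, 10.0))
        assert math.isnan(am.compute_al_i(10.0, np.nan))

    @given(a=finite, b=finite, c=finite)
    def test_shift_invariance(self, a, b, c):
        lhs = am.compute_al_i(a + c, b + c, warn_negative=False)
        rhs = am.compute_al_i(a, b, warn_negative=False)
        assert lhs == pytest.approx(rhs, abs=1e-6)


class TestSpeciationColumns:
    def test_censored_inputs_give_missing_al_i(self):
        frame = pd.DataFrame({
            "site": ["a", "a"],
            "date": ["2020-01-01", "2020-01-02"],
            "Al_d": [100.0, 100.0],
            "Al_d_censored": [True, False],
            "Al_o": [40.0, 40.0],
        })
        out = am.add_speciation(frame)
        assert math.isnan(out["Al_i"].iloc[0])
        assert out["Al_i"].iloc[1] == pytest.approx(60.0)
        assert math.isnan(out["pct_Al_i"].iloc[0])
        assert out["pct_Al_i"].iloc[1] == pytest.approx(0.6)

    def test_existing_field_al_i_kept(self):
        frame = pd.DataFrame({
            "site": ["a"], "date": ["2020-01-01"],
            "Al_d": [100.0], "Al_o": [40.0], "Al_i": [55.0],
        })
        out = am.add_speciation(frame, overwrite=False)
        assert out["Al_i"].iloc[0] == 55.0
        assert out["pct_Al_i"].iloc[0] == pytest.approx(0.55)

    def test_pct_undefined_for_nonpositive_al_d(self):
        frame = pd.DataFrame({
            "site": ["a"], "date": ["2020-01-01"], "Al_d": [0.0], "Al_o": [-5.0],
        })
        out = am.add_speciation(frame)
        assert math.isnan(out["pct_Al_i"].iloc[0])


def _frame_from_values(site_values: dict) -> pd.DataFrame:
    rows = []
    for site, vals in site_values.items():
        for i, v in enumerate(vals):
            rows.append({"site": site, "date": f"2020-01-{i + 1:02d}", "Al_i": v})
    return pd.DataFrame(rows)


class TestExceedance:
    def test_boundary_is_strict(self):
        table, overall = am.exceedance_summary(
            _frame_from_values({"a": [10.0, 20.0]}), threshold=15.0
        )
        row = table.iloc[0]
        assert row["ever_exceeded"]
        assert row["median_al_i"] == pytest.approx(15.0)
        assert not row["median_exceeded"]
        table, _ = am.exceedance_summary(
            _frame_from_values({"a": [14.9]}), threshold=15.0
        )
        assert not table.iloc[0]["ever_exceeded"]

    def test_site_counts(self):
        _, overall = am.exceedance_summary(
            _frame_from_values({"a": [20.0], "b": [10.0], "c": [16.0, 16.0]}),
            threshold=15.0,
        )
        assert overall["n_sites"] == 3
        assert overall["n_sites_ever_exceeded"] == 2

    def test_empty_site_excluded_and_reported(self):
        frame = _frame_from_values({"a": [20.0]})
        frame = pd.concat(
            [frame, pd.DataFrame({"site": ["b"], "date": ["2020-01-01"], "Al_i": [np.nan]})]
        )
        table, overall = am.exceedance_summary(frame)
        assert overall["n_sites"] == 1
        assert overall["sites_excluded"] == ["b"]

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame({
            "site": rng.choice(list("abcde"), size=200),
            "date": pd.Timestamp("2020-01-01") + pd.to_timedelta(rng.integers(0, 900, 200), "D"),
            "Al_i": np.where(rng.random(200) < 0.1, np.nan, rng.normal(15, 10, 200)),
        })
        table, overall = am.exceedance_summary(frame, threshold=15.0)
        for _, row in table.iterrows():
            vals = [
                v for v in frame.loc[frame["site"] == row["site"], "Al_i"]
                if np.isfinite(v)
            ]
            assert row["n"] == len(vals)
            assert row["n_exceed"] == sum(v > 15.0 for v in vals)
            assert row["ever_exceeded"] == any(v > 15.0 for v in vals)


class TestTemporalSplit:
    @pytest.mark.parametrize("n, expected_test", [(10, 2), (4, 0), (5, 1)])
    def test_per_site_counts(self, n, expected_test):
        frame = _frame_from_values({"a": list(range(n))})
        labels = am.temporal_split(frame)
        assert (labels == "test").sum() == expected_test

    def test_most_recent_labeled_test(self):
        frame = _frame_from_values({"a": list(range(10))})
        labels = am.temporal_split(frame)
        dates = pd.to_datetime(frame["date"])
        assert dates[labels == "train"].max() <= dates[labels == "test"].min()

    def test_ceil_rule_on_synthetic(self, small_frame):
        frame, _ = small_frame
        labels = am.temporal_split(frame, test_fraction=0.2, min_obs=5)
        for site, grp in frame.groupby("site"):
            n = len(grp)
            n_test = (labels.loc[grp.index] == "test").sum()
            assert n_test == (math.ceil(0.2 * n) if n >= 5 else 0)
            dates = pd.to_datetime(grp["date"])
            sub = labels.loc[grp.index]
            if n_test:
                assert dates[sub == "train"].max() <= dates[sub == "test"].min()

    def test_date_ties_broken_by_input_order(self):
        frame = pd.DataFrame({
            "site": ["a"] * 5,
            "date": ["2020-01-01"] * 5,
            "Al_i": range(5),
        })
        labels = am.temporal_split(frame)
        assert list(labels) == ["train"] * 4 + ["test"]


class TestSelectPredictors:
    def _train(self, **cols):
        n = len(next(iter(cols.values())))
        base = {"site": ["a"] * n, "date": ["2020-01-01"] * n}
        return pd.DataFrame({**base, **cols})

    def test_identical_to_response_selected(self):
        y = np.linspace(1, 10, 20)
        train = self._train(Al_i=y, Al_d=y.copy())
        kept, _ = am.select_predictors(train, candidates=["Al_d"])
        assert kept == ["Al_d"]

    def test_mostly_missing_excluded_even_if_supplementary(self):
        y = np.linspace(1, 10, 20)
        x = y.copy()
        x[:12] = np.nan  # 60% missing
        train = self._train(Al_i=y, Al_d=x)
        kept, report = am.select_predictors(
            train, candidates=["Al_d"], supplementary=["Al_d"]
        )
        assert kept == []
        assert "missing or censored" in report.iloc[0]["reason"]

    def test_weak_nonsupplementary_excluded(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=500)
        x = 0.05 * y + rng.normal(size=500)  # |r| ~ 0.05
        train = self._train(Al_i=y, Al_d=x)
        kept, report = am.select_predictors(train, candidates=["Al_d"])
        assert kept == []
        assert abs(report.iloc[0]["r"]) <= 0.1

    def test_constant_excluded_with_warning(self):
        y = np.linspace(1, 10, 20)
        train = self._train(Al_i=y, Al_d=np.ones(20))
        with pytest.warns(UserWarning, match="undefined"):
            kept, _ = am.select_predictors(train, candidates=["Al_d"])
        assert kept == []

    def test_censored_counts_toward_unobserved(self):
        y = np.linspace(1, 10, 20)
        train = self._train(Al_i=y, Al_d=y.copy())
        train["Al_d_censored"] = [True] * 11 + [False] * 9
        kept, _ = am.select_predictors(train, candidates=["Al_d"])
        assert kept == []


class TestStandardize:
    def _frame(self, values, censored=None, dl=None, response=None):
        n = len(values)
        frame = pd.DataFrame({
            "site": ["a"] * n,
            "date": pd.date_range("2020-01-01", periods=n),
            "Al_i": response if response is not None else np.linspace(0, 1, n),
            "Al_d": values,
        })
        if censored is not None:
            frame["Al_d_censored"] = censored
            frame["Al_d_dl"] = dl
        return frame

    def test_unit_triplet(self):
        data, scaling = am.standardize(self._frame([1.0, 2.0, 3.0]), ["Al_d"])
        assert np.allclose(data.X[:, 0], [-1.0, 0.0, 1.0])

    def test_censored_bound_transformed(self):
        frame = self._frame(
            [2.0, 1.0, 3.0], censored=[True, False, False], dl=[2.0, np.nan, np.nan]
        )
        data, scaling = am.standardize(frame, ["Al_d"])
        # location/scale from the observed entries {1, 3}: mean 2, sd sqrt(2)
        assert scaling.location["Al_d"] == pytest.approx(2.0)
        assert data.censor_bounds[0, 0] == pytest.approx(0.0)
        assert data.censored_mask[0, 0]

    def test_test_row_at_train_mean_maps_to_zero(self):
        frame = self._frame([1.0, 2.0, 3.0, 2.0])
        split = pd.Series(["train", "train", "train", "test"], index=frame.index)
        data, _ = am.standardize(frame, ["Al_d"], split)
        assert data.X[3, 0] == pytest.approx(0.0)

    def test_round_trip(self, small_frame):
        frame, _ = small_frame
        data, scaling = am.standardize(frame, am.PREDICTORS)
        for j, name in enumerate(am.PREDICTORS):
            observed = ~(data.missing_mask[:, j] | data.censored_mask[:, j])
            back = scaling.inverse(name, data.X[observed, j])
            orig = frame.loc[frame["Al_i"].notna(), name].to_numpy()[observed]
            assert np.allclose(back, orig, atol=1e-12 * max(1, np.abs(orig).max()))

    def test_scaling_invariant_on_fitting_subset(self, small_frame):
        frame, _ = small_frame
        data, scaling = am.standardize(frame, am.PREDICTORS)
        j = am.PREDICTORS.index("DOC")
        obs = ~(data.missing_mask[:, j] | data.censored_mask[:, j])
        obs &= data.split_label == "train"
        assert abs(np.mean(data.X[obs, j])) < 1e-10
        assert abs(np.std(data.X[obs, j], ddof=1) - 1.0) < 1e-10

    def test_zero_scale_names_variable(self):
        frame = self._frame([2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="Al_d"):
            am.standardize(frame, ["Al_d"])


class TestCsvDialect:
    def test_round_trip_with_censoring(self, tmp_path, small_frame):
        frame, _ = small_frame
        path = tmp_path / "samples.csv"
        am.write_samples_csv(frame, path, header_comment="test artifact")
        back = am.read_samples_csv(path)
        assert len(back) == len(frame)
        for name in ["Al_d", "DOC", "Fe_d"]:
            a = frame[name].to_numpy(dtype=float)
            b = back[name].to_numpy(dtype=float)
            assert np.allclose(a, b, equal_nan=True, rtol=1e-5)
            assert (
                frame[f"{name}_censored"].to_numpy(dtype=bool)
                == back[f"{name}_censored"].to_numpy(dtype=bool)
            ).all()

    def test_flag_column_convention(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text(
            "site,date,Al_d,Al_d_censored,Al_d_dl\n"
            "a,2020-01-01,5.0,true,5.0\n"
            "a,2020-01-02,9.0,false,\n"
            "a,2020-01-03,,false,\n"
        )
        frame = am.read_samples_csv(path)
        assert frame["Al_d_censored"].tolist() == [True, False, False]
        assert frame["Al_d"].iloc[0] == 5.0
        assert np.isnan(frame["Al_d"].iloc[2])

    def test_less_than_convention(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text("site,date,Al_d\na,2020-01-01,<4.5\na,2020-01-02,12\n")
        frame = am.read_samples_csv(path)
        assert frame["Al_d_censored"].tolist() == [True, False]
        assert frame["Al_d"].iloc[0] == 4.5
        assert frame["Al_d_dl"].iloc[0] == 4.5

    def test_requires_site_and_date(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text("foo,bar\n1,2\n")
        with pytest.raises(ValueError, match="site"):
            am.read_samples_csv(path)


class TestDomainTypes:
    def test_censored_requires_limit_and_equality(self):
        with pytest.raises(ValueError):
            am.AnalyteValue(value=5.0, censored=True)
        with pytest.raises(ValueError):
            am.AnalyteValue(value=4.0, censored=True, detection_limit=5.0)
        av = am.AnalyteValue(value=5.0, censored=True, detection_limit=5.0)
        assert av.censored

    def test_missing_is_exclusive(self):
        with pytest.raises(ValueError):
            am.AnalyteValue(value=5.0, censored=True, detection_limit=5.0, missing=True)
        av = am.AnalyteValue(value=None, missing=True)
        assert av.missing

    def test_water_sample_ordinal_day(self):
        import datetime

        ws = am.WaterSample(site_id="a", date=datetime.date(2020, 3, 1))
        assert ws.ordinal_day == 61  # 2020 is a leap year
        ws = am.WaterSample(site_id="a", date=datetime.date(2021, 3, 1))
        assert ws.ordinal_day == 60
        with pytest.raises(ValueError):
            am.WaterSample(site_id="", date=datetime.date(2020, 1, 1))

    def test_samples_to_frame(self):
        import datetime

        ws = am.WaterSample(
            site_id="a",
            date=datetime.date(2020, 1, 2),
            analytes={
                "Al_d": am.AnalyteValue(value=5.0, censored=True, detection_limit=5.0)
            },
            ph_sonde=4.5,
        )
        frame = am.samples_to_frame([ws])
        assert frame["Al_d_censored"].iloc[0]
        assert frame["pH_sonde"].iloc[0] == 4.5
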