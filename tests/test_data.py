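"""Data validation, follow-up windows, risk-set expansion and stacking."""

import numpy as np
import pandas as pd
import pytest

import fpcrisk as fp
from fpcrisk.data import censoring_survival_km, from_arrays


def _toy_csv(tmp_path, rows):
    path = tmp_path / "toy.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


class TestLoadValidate:
    def test_counts_by_cause(self, tmp_path):
        path = _toy_csv(
            tmp_path,
            {
                "id": [1, 2, 3, 4, 5],
                "time": [1.0, 2.0, 3.0, 4.0, 5.0],
                "cause": [1, 2, 0, 1, 3],
                "age": [50, 60, 70, 55, 65],
            },
        )
        ds = fp.load_and_validate(path, {"covariates": ["age"]}, n_causes=3)
        assert ds.event_counts() == {0: 1, 1: 2, 2: 1, 3: 1}
        assert ds.report()["covariates"]["age"]["mean"] == pytest.approx(60.0)

    def test_zero_time_names_subject(self, tmp_path):
        path = _toy_csv(tmp_path, {"id": [7], "time": [0.0], "cause": [1]})
        with pytest.raises(fp.ValidationError, match="subject 7"):
            fp.load_and_validate(path, n_causes=1)

    def test_cause_out_of_range(self, tmp_path):
        path = _toy_csv(tmp_path, {"id": [1, 2], "time": [1.0, 2.0], "cause": [1, 4]})
        with pytest.raises(fp.ValidationError, match="cause code"):
            fp.load_and_validate(path, n_causes=3)

    def test_missing_covariate_itemised(self, tmp_path):
        path = _toy_csv(
            tmp_path,
            {"id": [1, 2], "time": [1.0, 2.0], "cause": [1, 0], "age": [50, None]},
        )
        with pytest.raises(fp.ValidationError, match="covariate 'age'"):
            fp.load_and_validate(path, {"covariates": ["age"]}, n_causes=1)

    def test_schema_renames_columns(self, tmp_path):
        path = _toy_csv(
            tmp_path, {"patid": [1], "exit": [2.5], "cod": [1], "sex": [0]}
        )
        ds = fp.load_and_validate(
            path, {"id": "patid", "time": "exit", "cause": "cod", "covariates": ["sex"]}
        )
        assert ds.frame.loc[0, "time"] == 2.5


class TestFollowupWindow:
    def test_event_beyond_window_censored(self):
        ds = from_arrays([12.0], [1], n_causes=1)
        out = fp.apply_followup_window(ds, 10.0)
        assert out.frame.loc[0, "time"] == 10.0
        assert out.frame.loc[0, "cause"] == 0

    def test_event_at_boundary_retained(self):
        ds = from_arrays([10.0], [1], n_causes=1)
        out = fp.apply_followup_window(ds, 10.0)
        assert out.frame.loc[0, "cause"] == 1

    def test_window_beyond_all_times_is_identity(self):
        ds = from_arrays([1.0, 2.0, 3.0], [1, 0, 1], n_causes=1)
        out = fp.apply_followup_window(ds, 99.0)
        pd.testing.assert_frame_equal(out.frame, ds.frame)


class TestExpansion:
    def test_no_censoring_all_weights_one(self):
        ds = from_arrays([1, 2, 3, 4, 5], [1, 2, 1, 2, 1], n_causes=2)
        ex = fp.expand_subdistribution(ds, cause=1)
        assert np.all(ex.frame["weight"] == 1.0)
        # competing subjects (times 2 and 4) stay at risk to the last cause-1
        # event time (5)
        last = ex.frame.groupby("id")["tstop"].max()
        assert last.loc[2] == 5.0 and last.loc[4] == 5.0

    def test_single_cause_expansion_is_identity(self):
        ds = from_arrays([1.0, 2.0, 3.0], [1, 0, 1], n_causes=1)
        ex = fp.expand_subdistribution(ds, cause=1)
        assert len(ex.frame) == 3
        assert np.all(ex.frame["tstart"] == 0.0)
        assert np.all(ex.frame["weight"] == 1.0)

    def test_six_subject_hand_km_weights(self):
        # times 1..6, causes (1,2,0,1,2,1); the only censoring is at t=3 with
        # 4 subjects at risk, so G(t-) = 1 for t<=3 and 3/4 beyond.
        ds = from_arrays([1, 2, 3, 4, 5, 6], [1, 2, 0, 1, 2, 1], n_causes=2)
        ex = fp.expand_subdistribution(ds, cause=1)
        rows2 = ex.frame[(ex.frame["id"] == 2) & (ex.frame["tstart"] > 0)]
        # subject 2 dies of cause 2 at t=2; weights G(t-)/G(2-) = 0.75 after t=3
        assert rows2["weight"].to_numpy() == pytest.approx([0.75])
        assert rows2["tstop"].max() == 6.0
        rows5 = ex.frame[(ex.frame["id"] == 5) & (ex.frame["tstart"] > 0)]
        # subject 5 dies at t=5 > 3: G(t-)/G(5-) = 1 for the remaining window
        assert rows5["weight"].to_numpy() == pytest.approx([1.0])

    def test_left_continuous_censoring_km(self):
        ds = from_arrays([1, 2, 3, 4, 5, 6], [1, 2, 0, 1, 2, 1], n_causes=2)
        G = censoring_survival_km(ds)
        assert G.left([3.0])[0] == 1.0
        assert G.left([3.0001])[0] == pytest.approx(0.75)

    def test_weighted_risk_set_matches_fine_gray_brute_force(self, rng):
        # at each cause-1 event time the weighted size of the expanded risk
        # set equals #alive + sum of weights of prior competing failures
        n = 50
        t = rng.exponential(2.0, n).round(3) + 0.001
        cause = rng.integers(0, 3, n)
        ds = from_arrays(t, cause, n_causes=2)
        if not np.any(cause == 1):
            pytest.skip("no cause-1 events drawn")
        ex = fp.expand_subdistribution(ds, cause=1)
        G = censoring_survival_km(ds)
        f = ex.frame
        for tau in np.unique(t[cause == 1]):
            in_risk = (f["tstart"] < tau) & (tau <= f["tstop"])
            expanded = f.loc[in_risk, "weight"].sum()
            alive = np.sum(t >= tau)
            prior_competing = (t < tau) & (cause == 2)
            brute = alive + np.sum(G.left([tau])[0] / G.left(t[prior_competing]))
            assert expanded == pytest.approx(brute, rel=1e-10)

    def test_weights_nonincreasing_within_subject(self, rng):
        t = rng.exponential(2.0, 200).round(2) + 0.01
        cause = rng.integers(0, 3, 200)
        ds = from_arrays(t, cause, n_causes=2)
        ex = fp.expand_subdistribution(ds, cause=1)
        for _, grp in ex.frame.groupby("id"):
            w = grp.sort_values("tstart")["weight"].to_numpy()
            assert np.all(np.diff(w) <= 1e-12)

    def test_requires_events_of_cause(self):
        ds = from_arrays([1.0, 2.0], [2, 0], n_causes=2)
        with pytest.raises(ValueError, match="no events of cause 1"):
            fp.expand_subdistribution(ds, cause=1)

    def test_fpm_censoring_route_close_to_km(self, rng):
        # parametric censoring weights track the KM weights on smooth data
        n = 800
        t = rng.exponential(3.0, n)
        c = rng.exponential(5.0, n)
        cause = np.where(c < t, 0, rng.integers(1, 3, n))
        ds = from_arrays(np.minimum(t, c), cause, n_causes=2)
        ex_km = fp.expand_subdistribution(ds, cause=1, censoring_model="km")
        ex_fpm = fp.expand_subdistribution(ds, cause=1, censoring_model="fpm")
        merged = ex_km.frame.merge(
            ex_fpm.frame, on=["id", "tstart", "tstop"], suffixes=("_km", "_fpm")
        )
        late = merged[merged["tstart"] > 0]
        assert len(late) > 0
        assert np.quantile(np.abs(late["weight_km"] - late["weight_fpm"]), 0.9) < 0.05


class TestStacking:
    def _ds(self):
        return from_arrays(
            [2.0, 5.0], [1, 3], {"sex": [1.0, 0.0]}, n_causes=3
        )

    def test_shape_and_event_flags(self):
        st = fp.stack_causes(self._ds())
        assert len(st.frame) == 6
        assert st.frame["event"].sum() == 2
        assert set(st.cause_dummies) == {"_cause1", "_cause2", "_cause3"}

    def test_interaction_columns(self):
        st = fp.stack_causes(self._ds())
        f = st.frame
        row = f[(f["id"] == 1) & (f["at_risk_cause"] == 1)].iloc[0]
        assert row["sex_cause1"] == 1.0 and row["sex_cause2"] == 0.0
        row = f[(f["id"] == 2) & (f["at_risk_cause"] == 2)].iloc[0]
        assert row["sex_cause2"] == 0.0  # sex is 0 for subject 2

    def test_round_trip(self):
        ds = self._ds()
        back = fp.collapse_stack(fp.stack_causes(ds))
        pd.testing.assert_frame_equal(
            back.frame.reset_index(drop=True)[ds.frame.columns], ds.frame
        )

    def test_requires_k_at_least_two(self):
        ds = from_arrays([1.0], [1], n_causes=1)
        with pytest.raises(ValueError, match="K >= 2"):
            fp.stack_causes(ds)
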