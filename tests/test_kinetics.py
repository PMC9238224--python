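"""Signal -> AUC preprocessing rules, checked against closed forms and
independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinomescreen as ks
from kinomescreen.kinetics import (
    AUC_WINDOW,
    InputError,
    PipelineError,
    VmaxMatrix,
)
from kinomescreen.simulate import INTERNAL_CONTROL_ID

from conftest import make_signal_table

TIMES = np.arange(40, 1841, 60, dtype=float)


def write_tsv(df, path):
    df.to_csv(path, sep="\t", index=False)
    return path


class TestReadSignalTable:
    def test_roundtrip(self, tmp_path):
        df = make_signal_table({("s1", "p1", 1): lambda t: 2 * t}, TIMES)
        out = ks.read_signal_table(write_tsv(df, tmp_path / "s.tsv"))
        assert len(out) == len(df)
        assert list(out.columns) == list(df.columns)

    def test_missing_column_named(self, tmp_path):
        df = make_signal_table({("s1", "p1", 1): lambda t: t}, TIMES).drop(columns=["time_s"])
        with pytest.raises(InputError, match="time_s"):
            ks.read_signal_table(write_tsv(df, tmp_path / "s.tsv"))

    def test_duplicate_key_cited(self, tmp_path):
        df = make_signal_table({("s1", "p1", 1): lambda t: t}, TIMES)
        df = pd.concat([df, df.iloc[[0]]])
        with pytest.raises(InputError, match="duplicate"):
            ks.read_signal_table(write_tsv(df, tmp_path / "s.tsv"))

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(InputError, match="empty"):
            ks.read_signal_table(p)

    def test_non_numeric_signal_row_numbered(self, tmp_path):
        df = make_signal_table({("s1", "p1", 1): lambda t: t}, TIMES)
        df["signal_lux"] = df["signal_lux"].astype(object)
        df.loc[3, "signal_lux"] = "oops"
        with pytest.raises(InputError, match="row"):
            ks.read_signal_table(write_tsv(df, tmp_path / "s.tsv"))


class TestExcludeInternalControl:
    def test_control_removed(self):
        curves = {(f"s1", f"p{i}", 1): lambda t: t for i in range(143)}
        curves[("s1", INTERNAL_CONTROL_ID, 1)] = lambda t: t
        table = make_signal_table(curves, TIMES[:4])
        assert table["peptide_id"].nunique() == 144
        out = ks.exclude_internal_control(table)
        assert out["peptide_id"].nunique() == 143
        assert INTERNAL_CONTROL_ID not in set(out["peptide_id"])

    def test_absent_control_warns_unchanged(self):
        table = make_signal_table({("s1", "p1", 1): lambda t: t}, TIMES[:4])
        with pytest.warns(UserWarning, match="not present"):
            out = ks.exclude_internal_control(table)
        assert len(out) == len(table)

    def test_only_control_gives_empty_table(self):
        table = make_signal_table({("s1", INTERNAL_CONTROL_ID, 1): lambda t: t}, TIMES[:4])
        out = ks.exclude_internal_control(table)
        assert out.empty


class TestEstimateVmax:
    def test_exact_linear_slope(self):
        table = make_signal_table({("s1", "p1", 1): lambda t: 2 * t}, TIMES)
        vm = ks.estimate_vmax(table)
        assert vm.mean.loc["s1", "p1"] == pytest.approx(2.0, abs=1e-12)

    def test_constant_signal_zero_slope(self):
        table = make_signal_table({("s1", "p1", 1): lambda t: np.full_like(t, 7.0)}, TIMES)
        assert ks.estimate_vmax(table).mean.loc["s1", "p1"] == pytest.approx(0.0, abs=1e-12)

    def test_saturating_curve_matches_normal_equations_oracle(self):
        f = lambda t: 100 * (1 - np.exp(-t / 500.0))
        table = make_signal_table({("s1", "p1", 1): f}, TIMES)
        vm = ks.estimate_vmax(table, initial_phase_end=640.0)
        t = TIMES[TIMES <= 640.0]
        y = f(t)
        # independent oracle: solve the normal equations explicitly
        a = np.vstack([t, np.ones_like(t)]).T
        slope = np.linalg.solve(a.T @ a, a.T @ y)[0]
        assert vm.mean.loc["s1", "p1"] == pytest.approx(slope, abs=1e-9)

    def test_replicates_averaged(self):
        table = make_signal_table(
            {("s1", "p1", 1): lambda t: 2 * t, ("s1", "p1", 2): lambda t: 4 * t}, TIMES
        )
        vm = ks.estimate_vmax(table)
        assert vm.per_replicate.loc[("s1", 1), "p1"] == pytest.approx(2.0)
        assert vm.per_replicate.loc[("s1", 2), "p1"] == pytest.approx(4.0)
        assert vm.mean.loc["s1", "p1"] == pytest.approx(3.0)


class TestClampAndFilter:
    def make_vmax(self, values: dict) -> VmaxMatrix:
        per_rep = pd.DataFrame(
            values, index=pd.MultiIndex.from_tuples([("s1", 1), ("s1", 2), ("s1", 3)])
        )
        return VmaxMatrix(per_replicate=per_rep, mean=per_rep.groupby(level=0).mean())

    def test_negative_clamped_and_kept_when_average_positive(self):
        vm = self.make_vmax({"p1": [-2.0, 3.0, 5.0]})
        out, dropped = ks.clamp_and_filter_vmax(vm)
        assert dropped == []
        assert list(out.per_replicate["p1"]) == [0.0, 3.0, 5.0]
        assert out.mean.loc["s1", "p1"] == pytest.approx(8.0 / 3.0)

    def test_all_nonpositive_peptide_dropped(self):
        vm = self.make_vmax({"p1": [-1.0, 0.0, -3.0], "p2": [0.0, 0.0, 1.0]})
        out, dropped = ks.clamp_and_filter_vmax(vm)
        assert dropped == ["p1"]
        assert list(out.per_replicate.columns) == ["p2"]

    def test_positive_in_one_cell_only_is_kept(self):
        vm = self.make_vmax({"p1": [0.0, 0.0, 0.5]})
        _, dropped = ks.clamp_and_filter_vmax(vm)
        assert dropped == []

    def test_idempotent(self):
        vm = self.make_vmax({"p1": [-2.0, 3.0, 5.0], "p2": [-1.0, -1.0, -1.0]})
        once, d1 = ks.clamp_and_filter_vmax(vm)
        twice, d2 = ks.clamp_and_filter_vmax(once)
        assert d2 == []
        pd.testing.assert_frame_equal(once.per_replicate, twice.per_replicate)

    def test_everything_dropped_is_pipeline_error(self):
        vm = self.make_vmax({"p1": [-1.0, -2.0, 0.0]})
        with pytest.raises(PipelineError, match="no peptides"):
            ks.clamp_and_filter_vmax(vm)


class TestComputeAuc:
    def test_constant_signal_rectangle(self):
        table = make_signal_table({("s1", "p1", 1): lambda t: np.ones_like(t)}, TIMES)
        auc = ks.compute_auc(table)
        assert auc.loc["s1", "p1"] == pytest.approx(1200.0, abs=1e-9)

    def test_linear_signal_closed_form(self):
        table = make_signal_table({("s1", "p1", 1): lambda t: t}, TIMES)
        auc = ks.compute_auc(table)
        assert auc.loc["s1", "p1"] == pytest.approx((1840.0**2 - 640.0**2) / 2, rel=1e-12)

    def test_saturating_curve_within_half_percent_of_exact_integral(self):
        f = lambda t: 100.0 * (1.0 - np.exp(-t / 500.0))
        table = make_signal_table({("s1", "p1", 1): f}, TIMES)
        auc = ks.compute_auc(table).loc["s1", "p1"]
        t0, t1 = AUC_WINDOW
        exact = 100.0 * ((t1 - t0) + 500.0 * (np.exp(-t1 / 500.0) - np.exp(-t0 / 500.0)))
        assert auc == pytest.approx(exact, rel=0.005)

    def test_edge_interpolation_off_grid(self):
        # grid misses 640 and 1840; for a linear signal the interpolated
        # trapezoid is still exact
        times = np.arange(25, 1976, 150, dtype=float)
        table = make_signal_table({("s1", "p1", 1): lambda t: 3 * t + 5}, times)
        auc = ks.compute_auc(table).loc["s1", "p1"]
        exact = 1.5 * (1840.0**2 - 640.0**2) + 5 * 1200.0
        assert auc == pytest.approx(exact, rel=1e-12)

    def test_replicate_mean_first_equals_auc_mean_on_shared_grid(self):
        rng = np.random.default_rng(0)
        y1, y2 = rng.normal(size=len(TIMES)), rng.normal(size=len(TIMES))
        both = make_signal_table({("s1", "p1", 1): y1, ("s1", "p1", 2): y2}, TIMES)
        only1 = make_signal_table({("s1", "p1", 1): y1}, TIMES)
        only2 = make_signal_table({("s1", "p1", 1): y2}, TIMES)
        mean_first = ks.compute_auc(both).loc["s1", "p1"]
        auc_first = (ks.compute_auc(only1).loc["s1", "p1"] + ks.compute_auc(only2).loc["s1", "p1"]) / 2
        assert mean_first == pytest.approx(auc_first, rel=1e-12)

    def test_window_not_covered_is_error(self):
        table = make_signal_table({("s1", "p1", 1): lambda t: t}, np.array([0.0, 300.0, 600.0]))
        with pytest.raises(InputError, match="cover"):
            ks.compute_auc(table)

    @settings(max_examples=25, deadline=None)
    @given(
        a=st.floats(-5, 5),
        b=st.floats(-5, 5),
        seed=st.integers(0, 1000),
    )
    def test_auc_is_linear_in_the_signal(self, a, b, seed):
        rng = np.random.default_rng(seed)
        y1, y2 = rng.normal(size=len(TIMES)), rng.normal(size=len(TIMES))
        t_s = make_signal_table(
            {("s1", "pS", 1): a * y1 + b * y2, ("s1", "p1", 1): y1, ("s1", "p2", 1): y2}, TIMES
        )
        auc = ks.compute_auc(t_s)
        lhs = auc.loc["s1", "pS"]
        rhs = a * auc.loc["s1", "p1"] + b * auc.loc["s1", "p2"]
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_peptide_order_invariance(self, tiny_dataset):
        signals, _, _ = tiny_dataset
        auc = ks.compute_auc(signals)
        shuffled = signals.sort_values("peptide_id", ascending=False, kind="stable")
        auc2 = ks.compute_auc(shuffled)
        pd.testing.assert_frame_equal(auc, auc2[auc.columns])


class TestReplaceZeroAuc:
    def test_zero_replaced_by_sample_minimum_positive(self):
        m = pd.DataFrame({"p1": [0.0], "p2": [5.0], "p3": [10.0]}, index=["s1"])
        out, flags = ks.replace_zero_auc(m)
        assert list(out.loc["s1"]) == [5.0, 5.0, 10.0]
        assert list(flags.loc["s1"]) == [True, False, False]

    def test_negative_treated_as_zero(self):
        m = pd.DataFrame({"p1": [-0.5], "p2": [2.0]}, index=["s1"])
        out, _ = ks.replace_zero_auc(m)
        assert out.loc["s1", "p1"] == 2.0

    def test_no_zeros_unchanged_unflagged(self):
        m = pd.DataFrame({"p1": [1.0], "p2": [2.0]}, index=["s1"])
        out, flags = ks.replace_zero_auc(m)
        pd.testing.assert_frame_equal(out, m)
        assert not flags.to_numpy().any()

    def test_idempotent(self):
        m = pd.DataFrame({"p1": [0.0, 3.0], "p2": [5.0, 0.0], "p3": [10.0, 7.0]},
                         index=["s1", "s2"])
        once, _ = ks.replace_zero_auc(m)
        twice, flags = ks.replace_zero_auc(once)
        pd.testing.assert_frame_equal(once, twice)
        assert not flags.to_numpy().any()

    def test_all_zero_sample_is_error(self):
        m = pd.DataFrame({"p1": [0.0], "p2": [0.0], "p3": [0.0]}, index=["s1"])
        with pytest.raises(PipelineError, match="s1"):
            ks.replace_zero_auc(m)


class TestNormalizeByControl:
    def test_ratio_and_control_column_dropped(self):
        m = pd.DataFrame({"CTRL": [200.0], "X": [400.0]}, index=["s1"])
        out = ks.normalize_by_control(m, "CTRL")
        assert out.loc["s1", "X"] == pytest.approx(2.0)
        assert "CTRL" not in out.columns

    def test_control_column_identically_one_when_kept(self):
        m = pd.DataFrame({"CTRL": [200.0, 50.0], "X": [400.0, 25.0]}, index=["s1", "s2"])
        out = ks.normalize_by_control(m, "CTRL", drop_control=False)
        assert np.allclose(out["CTRL"], 1.0)

    def test_nonpositive_control_names_sample(self):
        m = pd.DataFrame({"CTRL": [200.0, 0.0], "X": [400.0, 25.0]}, index=["s1", "s2"])
        with pytest.raises(PipelineError, match="s2"):
            ks.normalize_by_control(m, "CTRL")

    def test_missing_control_is_error(self):
        m = pd.DataFrame({"X": [400.0]}, index=["s1"])
        with pytest.raises(PipelineError, match="CTRL"):
            ks.normalize_by_control(m, "CTRL")


class TestPreprocessChain:
    def test_activity_strictly_positive_and_controls_excluded(self, tiny_dataset, tiny_config):
        signals, _, _ = tiny_dataset
        res = ks.preprocess(signals)
        assert (res.activity.to_numpy() > 0).all()
        assert tiny_config.internal_control_id not in res.activity.columns
        assert tiny_config.control_peptide_id not in res.activity.columns
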