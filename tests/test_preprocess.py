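"""Preprocessing chain: control filter, geometric-mean normalization,
Box-Cox + Pareto scaling, detection matrix and the 0-5 dose mapping."""

import numpy as np
import pandas as pd
import pytest

from hostscent import preprocess as pp
from hostscent.synthetic import (CompoundMeta, GeneratorConfig,
                                 VolatilomeDataset, generate_volatilome)


def _tiny_dataset(fruit: dict, control: dict) -> VolatilomeDataset:
    fruit_df = pd.DataFrame(fruit)
    n = len(fruit_df)
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "species_id": [f"sp{i % 2}" for i in range(n)],
        "condition": "intact", "replicate": range(n)})
    fruit_df.index = samples["sample_id"]
    ctrl_df = pd.DataFrame(control, columns=fruit_df.columns).fillna(0.0)
    ctrl_df.index = [f"c{i}" for i in range(len(ctrl_df))]
    compounds = [CompoundMeta(c, "ester", 1.0, 1.0)
                 for c in fruit_df.columns]
    return VolatilomeDataset(samples, fruit_df, ctrl_df, compounds)


class TestControlFilter:
    def test_control_dominated_compound_excluded(self):
        ds = _tiny_dataset({"a": [0.0] * 20}, {"a": [10.0, 10.0, 10.0]})
        excluded, report = pp.control_filter(ds)
        assert excluded == {"a"}
        assert report.set_index("compound_id").loc["a", "p_value"] < 0.05

    def test_absent_from_controls_retained(self):
        ds = _tiny_dataset({"a": [3.0, 4.0, 5.0, 6.0]}, {"a": [0.0, 0.0]})
        excluded, _ = pp.control_filter(ds)
        assert excluded == set()

    def test_small_overlapping_groups_retained(self):
        # control {5,6} vs fruit {4,5,6,7}: the rank-sum evidence cannot
        # reach p < 0.05 with these group sizes
        ds = _tiny_dataset({"a": [4.0, 5.0, 6.0, 7.0]}, {"a": [5.0, 6.0]})
        excluded, report = pp.control_filter(ds, alpha=0.05)
        assert excluded == set()

    def test_absent_everywhere_flagged_untestable(self):
        ds = _tiny_dataset({"a": [0.0, 0.0, 0.0]}, {"a": [0.0, 0.0]})
        excluded, report = pp.control_filter(ds)
        assert excluded == set()
        assert report.loc[0, "reason"] == "untestable"

    def test_exclusions_monotone_in_alpha(self, dataset):
        sizes = []
        for alpha in (0.0, 0.01, 0.05, 0.2, 0.5):
            excl, _ = pp.control_filter(dataset, alpha=alpha)
            sizes.append(excl)
        assert sizes[0] == set()  # alpha = 0 excludes nothing
        for smaller, larger in zip(sizes, sizes[1:]):
            assert smaller <= larger

    def test_requires_controls(self):
        ds = _tiny_dataset({"a": [1.0, 2.0]}, {"a": []})
        ds.control = ds.control.iloc[:0]
        with pytest.raises(ValueError):
            pp.control_filter(ds)


class TestGeometricMean:
    def test_two_entry_sample(self):
        m = pd.DataFrame([[1.0, 100.0]], index=["s"], columns=["a", "b"])
        out = pp.geometric_mean_normalize(m)
        np.testing.assert_allclose(out.to_numpy(), [[0.1, 10.0]])

    def test_constant_sample_maps_to_ones(self):
        m = pd.DataFrame([[7.0, 7.0, 7.0]], index=["s"],
                         columns=list("abc"))
        np.testing.assert_allclose(
            pp.geometric_mean_normalize(m).to_numpy(), [[1.0, 1.0, 1.0]])

    def test_zeros_ignored_in_mean_and_preserved(self):
        # geometric mean over positives {2, 8} = 4
        m = pd.DataFrame([[2.0, 0.0, 8.0]], index=["s"],
                         columns=list("abc"))
        np.testing.assert_allclose(
            pp.geometric_mean_normalize(m).to_numpy(), [[0.5, 0.0, 2.0]])

    def test_all_zero_sample_is_an_error(self):
        m = pd.DataFrame([[0.0, 0.0]], index=["empty"], columns=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            pp.geometric_mean_normalize(m)


class TestBoxcoxPareto:
    def test_unit_value_maps_to_zero_before_scaling(self):
        m = pd.DataFrame({"a": [1.0, np.e, np.e ** 2]})
        out, _ = pp.boxcox_pareto(m, lmbda=0.0)
        # ln values {0,1,2}; centred {-1,0,1}; sd(ddof=1)=1 so sqrt(sd)=1
        np.testing.assert_allclose(out["a"].to_numpy(), [-1.0, 0.0, 1.0],
                                   atol=1e-12)

    def test_small_lambda_approaches_log(self):
        x = np.array([0.5, 1.0, 3.0, 10.0])
        m = pd.DataFrame({"a": x})
        out, _ = pp.boxcox_pareto(m, lmbda=1e-8)
        raw = (x ** 1e-8 - 1) / 1e-8
        np.testing.assert_allclose(raw, np.log(x), rtol=1e-6)
        # and the pipeline value matches the scaled log transform
        scaled = (np.log(x) - np.log(x).mean()) / np.sqrt(np.log(x).std(ddof=1))
        np.testing.assert_allclose(out["a"].to_numpy(), scaled, rtol=1e-6)

    def test_zeros_become_absent_and_constant_column_flagged(self):
        m = pd.DataFrame({"a": [0.0, 2.0, 4.0], "b": [3.0, 3.0, 3.0]})
        out, flagged = pp.boxcox_pareto(m)
        assert np.isnan(out.loc[0, "a"])
        assert flagged == ["b"]
        np.testing.assert_allclose(out["b"].to_numpy(), [0.0, 0.0, 0.0])


def test_detection_matrix_is_positivity_indicator():
    m = pd.DataFrame({"a": [0.0, 3.0, 0.0], "b": [1.0, 2.0, 3.0]})
    det = pp.detection_matrix(m)
    assert det["a"].tolist() == [0, 1, 0]
    assert det["b"].tolist() == [1, 1, 1]


class TestDoseScale:
    def test_affine_anchors_and_midpoint(self):
        t = pd.DataFrame({"a": [0.0, 1.0], "b": [2.0, np.nan]})
        det = pd.DataFrame({"a": [1, 1], "b": [1, 0]})
        dose, flags = pp.to_dose_scale(t, det)
        assert dose.loc[0, "a"] == 0.0
        assert dose.loc[0, "b"] == 5.0
        assert dose.loc[1, "a"] == 2.5  # midway between global min and max
        assert np.isnan(dose.loc[1, "b"])  # absent, never dose 0
        assert flags["minmax"] == (0.0, 2.0)

    def test_degenerate_all_equal_maps_to_midpoint(self):
        t = pd.DataFrame({"a": [1.0, 1.0]})
        det = pd.DataFrame({"a": [1, 1]})
        dose, flags = pp.to_dose_scale(t, det)
        assert flags["degenerate"]
        assert (dose["a"] == 2.5).all()

    def test_shared_minmax_across_paired_runs(self):
        t = pd.DataFrame({"a": [0.5, 1.5]})
        det = pd.DataFrame({"a": [1, 1]})
        dose, _ = pp.to_dose_scale(t, det, minmax=(0.0, 2.0))
        np.testing.assert_allclose(dose["a"].to_numpy(), [1.25, 3.75])


class TestPipeline:
    def test_rerun_is_bit_identical(self, dataset, processed):
        again = pp.preprocess(dataset)
        pd.testing.assert_frame_equal(again.dose, processed.dose)
        pd.testing.assert_frame_equal(again.transformed,
                                      processed.transformed)

    def test_doses_in_range_and_monotone(self, processed):
        d = processed.dose.to_numpy()
        det = ~np.isnan(d)
        assert d[det].min() >= 0.0 and d[det].max() <= 5.0
        # monotone: dose ordering matches transformed-value ordering
        t = processed.transformed.to_numpy()[det]
        order = np.argsort(t)
        assert (np.diff(d[det][order]) >= -1e-12).all()

    def test_contaminants_are_excluded(self, dataset, processed):
        excluded = set(processed.exclusions["compound_id"])
        assert set(dataset.meta["contaminants"]) <= excluded
        assert not excluded & set(processed.dose.columns)
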