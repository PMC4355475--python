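"""Differential expression: probe collapsing, d statistic, permutation p-values."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from pathminer.diffexpr import (
    ExpressionDataset,
    collapse_probes,
    intersect_platforms,
    permutation_test,
    read_expression,
    sam_d_statistic,
    write_expression,
)


def dataset(matrix, n_control, n_case, features=None, probe_map=None, platform="P"):
    matrix = np.asarray(matrix, dtype=float)
    samples = [f"s{i}" for i in range(matrix.shape[1])]
    features = features or [f"f{i}" for i in range(matrix.shape[0])]
    values = pd.DataFrame(matrix, index=features, columns=samples)
    groups = pd.Series(["control"] * n_control + ["case"] * n_case, index=samples)
    pm = None
    if probe_map is not None:
        pm = pd.Series(probe_map).reindex(features)
    return ExpressionDataset(values=values, groups=groups, platform=platform, probe_map=pm)


class TestExpressionDataset:
    def test_rejects_single_group(self):
        with pytest.raises(ValueError, match="group label set"):
            dataset([[1, 2, 3]], 3, 0)

    def test_exclude_samples(self):
        ds = dataset([[1, 2, 3, 4]], 2, 2)
        kept = ds.exclude_samples({"s0", "nonexistent"})
        assert kept.sample_ids == ["s1", "s2", "s3"]
        assert kept.n_control == 1 and kept.n_case == 2

    def test_tsv_roundtrip(self, tmp_path):
        ds = dataset([[1.5, 2.5], [3.0, 4.0]], 1, 1, probe_map={"f0": "G1", "f1": "G1"})
        write_expression(ds, tmp_path / "e.tsv", tmp_path / "l.tsv", tmp_path / "m.tsv")
        back = read_expression(
            tmp_path / "e.tsv", tmp_path / "l.tsv", tmp_path / "m.tsv"
        )
        pd.testing.assert_frame_equal(back.values, ds.values)
        assert list(back.groups) == list(ds.groups)
        pd.testing.assert_series_equal(
            back.probe_map, ds.probe_map, check_names=False
        )


class TestCollapseProbes:
    def test_mean_of_two_probes(self):
        ds = dataset([[2, 4], [4, 6]], 1, 1, probe_map={"f0": "G", "f1": "G"})
        out = collapse_probes(ds)
        assert out.values.loc["G"].tolist() == [3.0, 5.0]

    def test_single_probe_passthrough(self):
        ds = dataset([[1.0, 2.0, 3.0, 4.0]], 2, 2, probe_map={"f0": "G"})
        out = collapse_probes(ds)
        assert out.values.loc["G"].tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_three_probe_mean_matches_cellwise_average(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(3, 4))
        ds = dataset(mat, 2, 2, probe_map={"f0": "G", "f1": "G", "f2": "G"})
        out = collapse_probes(ds)
        # oracle: independent per-cell average
        expected = [sum(mat[i][j] for i in range(3)) / 3 for j in range(4)]
        assert np.allclose(out.values.loc["G"].to_numpy(), expected)

    def test_unmapped_probes_dropped_and_reported(self):
        ds = dataset([[1, 1], [2, 2]], 1, 1, probe_map={"f0": "G"})
        out, report = collapse_probes(ds, return_report=True)
        assert list(out.values.index) == ["G"]
        assert report["n_probes_unmapped"] == 1

    def test_empty_map_is_error(self):
        ds = dataset([[1, 1]], 1, 1)
        with pytest.raises(ValueError, match="probe map"):
            collapse_probes(ds)

    def test_weighted_totals_preserved(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(size=(5, 4))
        pm = {"f0": "A", "f1": "A", "f2": "B", "f3": "B", "f4": "B"}
        ds = dataset(mat, 2, 2, probe_map=pm)
        out = collapse_probes(ds)
        counts = pd.Series(pm).value_counts()
        weighted = (out.values.T * counts.reindex(out.values.index)).T.sum(axis=0)
        assert np.allclose(weighted.to_numpy(), mat.sum(axis=0))


class TestDStatistic:
    def test_zero_numerator_gives_zero(self):
        ds = dataset([[1.0, 3.0, 1.0, 3.0]], 2, 2)
        assert sam_d_statistic(ds, s0=0.5).iloc[0] == 0.0

    def test_zero_spread_with_positive_s0(self):
        ds = dataset([[0.0, 0.0, 1.0, 1.0]], 2, 2)
        assert sam_d_statistic(ds, s0=1.0).iloc[0] == 1.0

    def test_zero_spread_with_zero_s0_raises(self):
        ds = dataset([[0.0, 0.0, 1.0, 1.0]], 2, 2)
        with pytest.raises(ZeroDivisionError):
            sam_d_statistic(ds, s0=0.0)

    def test_matches_direct_formula(self, small_dataset):
        s0 = 0.3
        d = sam_d_statistic(small_dataset, s0=s0)
        X = small_dataset.values.to_numpy()
        case = small_dataset.case_mask
        for i, feat in enumerate(small_dataset.feature_ids):
            ctrl, trt = X[i, ~case], X[i, case]
            pooled_var = (
                ((ctrl - ctrl.mean()) ** 2).sum() + ((trt - trt.mean()) ** 2).sum()
            ) / (len(ctrl) + len(trt) - 2)
            se = math.sqrt(pooled_var * (1 / len(ctrl) + 1 / len(trt)))
            expected = (trt.mean() - ctrl.mean()) / (se + s0)
            assert d.loc[feat] == pytest.approx(expected, rel=1e-12)

    def test_antisymmetric_under_label_swap(self, small_dataset):
        flipped = ExpressionDataset(
            values=small_dataset.values,
            groups=small_dataset.groups.map(
                {"control": "case", "case": "control"}
            ),
            platform=small_dataset.platform,
        )
        s0 = 0.2
        assert np.allclose(
            sam_d_statistic(small_dataset, s0=s0), -sam_d_statistic(flipped, s0=s0)
        )

    def test_too_few_samples_per_group(self):
        ds = dataset([[1.0, 2.0, 3.0]], 1, 2)
        with pytest.raises(ValueError, match="2 samples per group"):
            sam_d_statistic(ds, s0=0.1)


class TestPermutationTest:
    def test_same_seed_is_bit_identical(self, small_dataset):
        a = permutation_test(small_dataset, n_perm=50, seed=9)
        b = permutation_test(small_dataset, n_perm=50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_n_perm_below_one_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(small_dataset, n_perm=0)

    def test_single_feature_exhaustive_matches_enumeration(self):
        vals = [0.3, 1.9, 0.8, 2.6, 3.1, 2.2]
        ds = dataset([vals], 3, 3)
        res = permutation_test(ds, n_perm=1000, seed=0, s0=0.1)
        # oracle: enumerate all C(6,3)=20 case assignments directly
        x = np.array(vals)

        def d_for(case_idx):
            case = np.zeros(6, dtype=bool)
            case[list(case_idx)] = True
            ctrl, trt = x[~case], x[case]
            pooled_var = (
                ((ctrl - ctrl.mean()) ** 2).sum() + ((trt - trt.mean()) ** 2).sum()
            ) / 4
            se = math.sqrt(pooled_var * (2 / 3))
            return (trt.mean() - ctrl.mean()) / (se + 0.1)

        d_obs = abs(d_for((3, 4, 5)))
        null = [abs(d_for(idx)) for idx in combinations(range(6), 3)]
        expected_p = (1 + sum(v >= d_obs for v in null)) / (1 + len(null))
        assert res["p"].iloc[0] == pytest.approx(expected_p, rel=1e-12)

    def test_q_monotone_in_p(self, small_dataset):
        res = permutation_test(small_dataset, n_perm=60, seed=2)
        by_p = res.sort_values("p")
        assert by_p["q"].is_monotonic_increasing
        assert (res["q"] >= res["p"] - 1e-15).all()

    def test_p_threshold_rule(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(size=(20, 10))
        mat[0, 5:] += 5.0
        ds = dataset(mat, 5, 5)
        res = permutation_test(ds, n_perm=100, seed=1, q_threshold=None, p_threshold=0.05)
        assert (res["is_de"] == (res["p"] <= 0.05)).all()

    def test_null_p_values_approximately_uniform(self):
        from scipy.stats import kstest

        from pathminer.simulate import generate_dataset

        ds, _ = generate_dataset(
            n_features=500, n_control=10, n_case=10, effect_size=0.0, seed=42
        )
        res = permutation_test(ds, n_perm=200, seed=42)
        assert kstest(res["p"], "uniform").statistic < 0.1


class TestIntersectPlatforms:
    @staticmethod
    def result(de_map):
        return pd.DataFrame(
            {"d": 0.0, "p": 0.5, "q": 0.5, "is_de": pd.Series(de_map)}
        ).rename_axis("feature")

    def test_de_on_all_platforms_retained(self):
        res = [self.result({"g1": True, "g2": True}) for _ in range(6)]
        assert intersect_platforms(res) == {"g1", "g2"}

    def test_de_on_five_of_six_dropped(self):
        res = [self.result({"g1": True}) for _ in range(5)]
        res.append(self.result({"g1": False}))
        assert intersect_platforms(res) == set()

    def test_single_platform_identity(self):
        res = [self.result({"g1": True, "g2": False})]
        assert intersect_platforms(res) == {"g1"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            intersect_platforms([])
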