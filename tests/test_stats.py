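"""Pearson co-localization, ROC/AUC, balanced subsampling, group summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from msi3d.errors import InputError
from msi3d.peakpick import FeatureMatrix
from msi3d.stats import (
    balanced_subsample,
    group_intensity_summary,
    pearson_colocalization,
    roc_auc,
    roc_discriminative,
)


def feature_matrix(values, centers=None):
    values = np.asarray(values, float)
    n = values.shape[0]
    keys = pd.DataFrame(
        {
            "section": ["s0"] * n,
            "timepoint_days": [3] * n,
            "segment": ["L"] * n,
            "z_index": [0] * n,
            "x": np.arange(n),
            "y": np.zeros(n, dtype=int),
        }
    )
    centers = np.arange(values.shape[1], dtype=float) + 400 if centers is None else centers
    return FeatureMatrix(values, centers, np.full(len(centers), 0.1), keys,
                         {"s0": (slice(0, n), (1, n))})


def brute_force_auc(a, b):
    wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    return wins / (len(a) * len(b))


class TestPearson:
    def test_self_negation_and_known_value(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fm = feature_matrix(np.stack([x, 5.0 - x, np.ones(4)], axis=1))
        res = {round(r.center_mz): r for r in pearson_colocalization(fm, x)}
        assert res[400].r == pytest.approx(1.0, abs=1e-12)
        # 5 - x is a negated (affine) copy
        assert res[401].r == pytest.approx(-1.0, abs=1e-12)
        assert res[402].zero_variance and res[402].r == 0.0
        # ranked descending
        ranks = [r.rank for r in pearson_colocalization(fm, x)]
        assert ranks == [1, 2, 3]

        ref = np.array([1.0, 3.0, 2.0, 5.0])
        r = pearson_colocalization(feature_matrix(x[:, None]), ref)[0].r
        # direct covariance-formula oracle
        oracle = float(np.sum((x - x.mean()) * (ref - ref.mean()))
                       / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((ref - ref.mean()) ** 2)))
        assert r == pytest.approx(oracle, abs=1e-12)
        # hand derivation: cov = 5.5/n, sds from sums of squares 5 and 8.75
        assert r == pytest.approx(5.5 / np.sqrt(5 * 8.75), abs=1e-12)

    def test_constant_reference_rejected(self):
        fm = feature_matrix(np.random.default_rng(0).random((5, 2)))
        with pytest.raises(InputError):
            pearson_colocalization(fm, np.ones(5))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(st.floats(0, 50), min_size=4, max_size=12),
        st.floats(0.1, 10),
        st.floats(0, 5),
    )
    def test_affine_invariance(self, xs, scale, shift):
        x = np.asarray(xs)
        ref = np.arange(len(x), dtype=float)
        if np.std(x) == 0:
            return
        fm1 = feature_matrix(x[:, None])
        fm2 = feature_matrix((scale * x + shift)[:, None])
        r1 = pearson_colocalization(fm1, ref)[0].r
        r2 = pearson_colocalization(fm2, ref)[0].r
        assert r2 == pytest.approx(r1, abs=1e-9)


class TestROC:
    def test_complete_separation_ties_and_known_overlap(self):
        assert roc_auc([1, 2, 3], [4, 5, 6]) == 0.0
        assert roc_auc([4, 5, 6], [1, 2, 3]) == 1.0
        assert roc_auc([1, 2, 3], [1, 2, 3]) == 0.5
        assert roc_auc([1, 2, 3], [2, 3, 4]) == pytest.approx(2 / 9)
        assert roc_auc([2, 3, 4], [1, 2, 3]) == pytest.approx(7 / 9)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=20),
        st.lists(st.integers(0, 8), min_size=1, max_size=20),
    )
    def test_matches_pair_counting_oracle(self, a, b):
        assert roc_auc(a, b) == pytest.approx(brute_force_auc(a, b), abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=15),
           st.lists(st.floats(0.01, 100), min_size=2, max_size=15))
    def test_invariant_under_monotone_transform(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        assert roc_auc(np.log(a), np.log(b)) == pytest.approx(roc_auc(a, b), abs=1e-12)
        assert roc_auc(a**2, b**2) == pytest.approx(roc_auc(a, b), abs=1e-12)

    def test_discriminative_orientation_and_errors(self):
        rng = np.random.default_rng(1)
        vals = np.stack([np.r_[rng.normal(5, 0.1, 10), rng.normal(1, 0.1, 10)],
                         np.r_[rng.normal(1, 0.1, 10), rng.normal(5, 0.1, 10)]], axis=1)
        fm = feature_matrix(vals)
        res = roc_discriminative(fm, np.arange(10), np.arange(10, 20))
        assert all(r.auc >= 0.5 for r in res)
        directions = {round(r.center_mz): r.direction for r in res}
        assert directions[400] == "A" and directions[401] == "B"
        with pytest.raises(InputError):
            roc_discriminative(fm, np.arange(10), np.arange(5, 15))
        with pytest.raises(InputError):
            roc_discriminative(fm, np.array([]), np.arange(10))


class TestBalancedSubsample:
    def test_even_split_and_determinism(self):
        r1 = np.arange(0, 50)
        c1 = np.arange(100, 150)
        sub = balanced_subsample(r1, c1, 40, seed=4)
        assert len(sub) == 40
        assert (sub < 50).sum() == 20 and (sub >= 100).sum() == 20
        np.testing.assert_array_equal(sub, balanced_subsample(r1, c1, 40, seed=4))
        assert not np.array_equal(sub, balanced_subsample(r1, c1, 40, seed=5))

    def test_overdraw_rejected(self):
        with pytest.raises(InputError):
            balanced_subsample(np.arange(3), np.arange(100), 10)


class TestGroupSummary:
    def test_constant_group_and_planted_outlier(self):
        vals = np.full((20, 1), 2.0)
        fm = feature_matrix(vals)
        (summary,) = group_intensity_summary(fm, "segment")
        assert summary.sd == 0.0
        assert summary.ci_lower == summary.ci_upper == summary.mean == 2.0
        assert summary.outlier_rows == ()

        rng = np.random.default_rng(3)
        vals = rng.normal(10, 1, (200, 1))
        vals[17] = 10 + 5 * vals.std()
        fm = feature_matrix(vals)
        (summary,) = group_intensity_summary(fm, "segment", ci_level=0.95)
        assert 17 in summary.outlier_rows
        assert summary.ci_lower <= summary.mean <= summary.ci_upper

    def test_margin_ion_peaks_in_lesion_segment_and_acute_timepoint(self, multi_tp):
        fm = multi_tp.features
        j = fm.interval_index(400.3)
        by_seg = {
            s.group: s.mean
            for s in group_intensity_summary(fm, "segment")
            if s.center_mz == pytest.approx(fm.centers[j])
        }
        assert max(by_seg, key=by_seg.get) == "L"
        by_tp = {
            s.group: s.mean
            for s in group_intensity_summary(fm, "timepoint_days")
            if s.center_mz == pytest.approx(fm.centers[j])
        }
        assert max(by_tp, key=by_tp.get) == 3
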