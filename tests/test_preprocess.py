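import math

import numpy as np
import pandas as pd
import pytest

from mirmodulenet.io_expression import ExpressionDataset
from mirmodulenet import preprocess
from mirmodulenet.preprocess import (
    apply_zscore,
    differential_filter,
    drop_missing_features,
    fit_zscore,
    normalize_counts,
)


def _ds(matrix, kind="mRNA", features=None, samples=None):
    matrix = np.asarray(matrix, dtype=float)
    features = features or [f"f{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"s{i}" for i in range(matrix.shape[1])]
    return ExpressionDataset(pd.DataFrame(matrix, index=features, columns=samples), kind)


class TestDropMissing:
    def test_removes_features_with_any_nan(self):
        m = np.ones((5, 3))
        m[2, 1] = np.nan
        out = drop_missing_features(_ds(m))
        assert out.n_features == 4 and "f2" not in out.feature_ids

    def test_identity_without_missing(self):
        ds = _ds(np.arange(12.0).reshape(3, 4))
        out = drop_missing_features(ds)
        pd.testing.assert_frame_equal(out.values, ds.values)

    def test_all_missing_rejected(self):
        m = np.full((2, 3), np.nan)
        with pytest.raises(ValueError, match="all features"):
            drop_missing_features(_ds(m))


class TestNormalizeCounts:
    def test_rpm_arithmetic(self):
        # sample column sums 5 -> counts (2,3) map to (4e5, 6e5)
        ds = _ds([[2.0], [3.0]])
        out = normalize_counts(ds, "RPM")
        np.testing.assert_allclose(out.values.values[:, 0], [4e5, 6e5])

    def test_rpm_columns_sum_to_1e6(self):
        rng = np.random.default_rng(3)
        ds = _ds(rng.integers(0, 500, size=(30, 8)).astype(float) + 1)
        out = normalize_counts(ds, "RPM")
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_rpkm_arithmetic(self):
        # count 10 in a library of 1e6 for a 1000 bp gene -> 10
        ds = _ds([[10.0], [999990.0]])
        out = normalize_counts(ds, "RPKM", gene_lengths={"f0": 1000, "f1": 500})
        assert out.values.iloc[0, 0] == pytest.approx(10.0)

    def test_rpkm_without_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            normalize_counts(_ds([[1.0]]), "RPKM")

    def test_rpkm_missing_length_names_feature(self):
        with pytest.raises(ValueError, match="f1"):
            normalize_counts(_ds([[1.0], [2.0]]), "RPKM", gene_lengths={"f0": 100})

    def test_zero_library_names_sample(self):
        ds = _ds([[0.0, 1.0], [0.0, 2.0]])
        with pytest.raises(ValueError, match="s0"):
            normalize_counts(ds, "RPM")


class TestZScore:
    def test_closed_form(self):
        ds = _ds([[1.0, 2.0, 3.0]])
        out = apply_zscore(ds, fit_zscore(ds))
        np.testing.assert_allclose(
            out.values.values[0], [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )

    def test_constant_feature_maps_to_zero(self):
        ds = _ds([[5.0, 5.0, 5.0]])
        out = apply_zscore(ds, fit_zscore(ds))
        np.testing.assert_array_equal(out.values.values, 0.0)

    def test_train_mean_zero_unit_sd(self):
        rng = np.random.default_rng(0)
        ds = _ds(rng.normal(5, 3, size=(4, 50)))
        out = apply_zscore(ds, fit_zscore(ds))
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_train_params_applied_to_new_samples(self):
        train = _ds([[0.0, 2.0]], samples=["a", "b"])
        test = _ds([[4.0]], samples=["c"])
        out = apply_zscore(test, fit_zscore(train))
        assert out.values.iloc[0, 0] == pytest.approx(3.0)  # (4-1)/1

    def test_unparameterized_feature_rejected(self):
        params = fit_zscore(_ds([[1.0, 2.0]], features=["f0"]))
        with pytest.raises(KeyError):
            apply_zscore(_ds([[1.0, 2.0]], features=["other"]), params)


def _labelled(matrix, labels):
    ds = _ds(matrix)
    y = pd.Series(np.asarray(labels, dtype=np.int8), index=ds.sample_ids)
    return ds, y


class TestDifferentialFilter:
    def test_identical_distributions_not_kept(self):
        # case and control see the exact same set of values
        base = np.linspace(5, 15, 10)
        ds, y = _labelled([np.concatenate([base, base])], [1] * 10 + [0] * 10)
        res = differential_filter(ds, y, alpha=0.05, min_abs_log2fc=0.0)
        assert res.kept == []
        assert res.stats["p_value"].iloc[0] > 0.9

    def test_tenfold_separation_kept(self):
        # case values exactly 10x control; complete separation of 10 vs 10.
        # Enumeration oracle: only 1 of C(20,10) label assignments puts every
        # case above every control, so the exact two-sided p is
        # 2/C(20,10) = 1.0824e-5 <= 0.05; |log2 FC| = log2(10) > 1.
        control = np.linspace(1, 2, 10)
        case = 10 * control
        exact_p = 2 / math.comb(20, 10)
        assert exact_p < 0.05
        ds, y = _labelled([np.concatenate([case, control])], [1] * 10 + [0] * 10)
        res = differential_filter(ds, y, alpha=0.05, min_abs_log2fc=1.0)
        assert res.kept == ["f0"]
        assert res.stats["log2_fc"].iloc[0] == pytest.approx(math.log2(10), abs=1e-6)

    def test_vacuous_thresholds_keep_all(self):
        rng = np.random.default_rng(2)
        ds, y = _labelled(rng.normal(size=(5, 12)), [1] * 6 + [0] * 6)
        res = differential_filter(ds, y, alpha=1.0, min_abs_log2fc=0.0)
        assert set(res.kept) == set(ds.feature_ids)

    def test_single_class_rejected(self):
        ds, y = _labelled(np.ones((2, 6)), [1] * 6)
        with pytest.raises(ValueError, match="both classes"):
            differential_filter(ds, y)

    def test_null_calibration(self):
        # 200 pure-noise features, permuted labels: kept fraction stays
        # within [0, 3*alpha].
        rng = np.random.default_rng(4)
        alpha = 0.05
        ds, y = _labelled(rng.normal(size=(200, 30)), rng.permutation([1] * 15 + [0] * 15))
        res = differential_filter(ds, y, alpha=alpha, min_abs_log2fc=0.0)
        assert len(res.kept) / 200 <= 3 * alpha

    def test_kept_set_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(5)
        X = np.abs(rng.normal(5, 2, size=(30, 24)))
        X[:5, :12] *= 4.0  # class-dependent shift in first 5 features
        y = [1] * 12 + [0] * 12
        ds, yv = _labelled(X, y)
        res = differential_filter(ds, yv, alpha=0.05, min_abs_log2fc=1.0)
        scale = rng.uniform(0.5, 10, size=(30, 1))
        ds2, _ = _labelled(X * scale, y)
        res2 = differential_filter(ds2, yv, alpha=0.05, min_abs_log2fc=1.0)
        assert res.kept == res2.kept

    def test_top_features_by_p_orders_by_significance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 24))
        X[3, :12] += 5.0
        ds, y = _labelled(X, [1] * 12 + [0] * 12)
        res = differential_filter(ds, y, alpha=1e-12, min_abs_log2fc=10.0)
        assert res.kept == []  # thresholds deliberately unattainable
        assert preprocess.top_features_by_p(res, 1) == ["f3"]
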