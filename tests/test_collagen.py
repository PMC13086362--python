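"""Tests for collagen QC and the site-level statistics toolbox."""

import numpy as np
import pytest

from paleoherd import synth
from paleoherd.collagen import (
    CollagenSample,
    QCRules,
    apply_qc,
    cn_atomic,
    confidence_ellipse,
    correlate,
    iqr_outliers,
    oneway_anova,
    read_collagen,
    summarize,
)


class TestCNAtomic:
    @pytest.mark.parametrize(
        "pctC,pctN,expected",
        [
            (45.0, 16.0, 3.280),   # (45/12.011)/(16/14.007)
            (43.0, 15.7, 3.194),
            (10.0, 10.0, 1.166),   # equal % gives the mass-ratio constant
        ],
    )
    def test_hand_computed_values(self, pctC, pctN, expected):
        assert cn_atomic(pctC, pctN) == pytest.approx(expected, abs=5e-4)

    def test_scale_invariance(self):
        assert cn_atomic(42.0, 15.0) == pytest.approx(cn_atomic(4.2, 1.5), rel=1e-12)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            cn_atomic(0.0, 15.0)

    def test_qc_verdict(self):
        good = apply_qc(CollagenSample("g", -18.0, 7.0, 43.0, 15.5, 5.0))
        assert good.qc_pass
        bad_yield = apply_qc(CollagenSample("y", -18.0, 7.0, 43.0, 15.5, 0.5))
        assert not bad_yield.qc_pass
        bad_cn = apply_qc(CollagenSample("c", -18.0, 7.0, 45.0, 10.0, 5.0))
        assert not bad_cn.qc_pass


class TestSummarize:
    def test_basic(self):
        s = summarize([1.0, 2.0, 3.0])
        assert (s.n, s.mean, s.sd, s.min, s.max) == (3, 2.0, 1.0, 1.0, 3.0)

    def test_single_value_sd_undefined(self):
        s = summarize([5.0])
        assert s.mean == 5.0 and s.sd is None

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_generator_round_trip(self):
        df = synth.gen_collagen_dataset(2000, seed=5)
        s = summarize(df["d13C"])
        assert s.mean == pytest.approx(-17.7, abs=0.1)
        assert s.sd == pytest.approx(0.8, abs=0.1)


class TestCorrelate:
    def test_perfect_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = correlate(x, x)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)
        res_neg = correlate(x, [-v for v in x])
        assert res_neg.pearson_r == pytest.approx(-1.0)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        a = correlate(x, y)
        b = correlate(y, x)
        assert a.pearson_r == pytest.approx(b.pearson_r, rel=1e-12)
        c = correlate(3.0 * x + 7.0, y)
        assert c.pearson_r == pytest.approx(a.pearson_r, rel=1e-12)
        d = correlate(-2.0 * x, y)
        assert d.pearson_r == pytest.approx(-a.pearson_r, rel=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_permutation_p_tracks_parametric(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=15)
        y = x + rng.normal(scale=0.3, size=15)
        res = correlate(x, y, n_permutations=400, seed=1)
        assert res.pearson_p_perm < 0.02
        assert res.pearson_p < 0.01

    def test_independent_generator_correlation_near_zero(self):
        df = synth.gen_collagen_dataset(10_000, correlation=0.0, seed=9)
        res = correlate(df["d13C"], df["d15N"])
        assert abs(res.pearson_r) < 0.03


class TestIQROutliers:
    def test_textbook_example(self):
        # Q1=2, Q3=4, fences (−1, 7)
        kept, flagged = iqr_outliers([1.0, 2.0, 3.0, 4.0, 100.0])
        assert list(flagged) == [100.0]
        assert list(kept) == [1.0, 2.0, 3.0, 4.0]

    def test_constant_vector_no_outliers(self):
        kept, flagged = iqr_outliers([5.0] * 6)
        assert flagged.size == 0 and kept.size == 6

    def test_clean_data_kept(self):
        vals = np.linspace(0, 1, 12)
        kept, flagged = iqr_outliers(vals)
        assert flagged.size == 0

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError):
            iqr_outliers([1.0, 2.0, 3.0])


class TestConfidenceEllipse:
    def _points_with_cov(self, cov, n=400, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.multivariate_normal([0, 0], np.eye(2), size=n)
        # whiten exactly, then colour to the requested covariance
        pts -= pts.mean(axis=0)
        c = np.cov(pts.T)
        w = np.linalg.cholesky(np.linalg.inv(c))
        l = np.linalg.cholesky(cov)
        return pts @ w.T @ l.T

    def test_identity_covariance_circle(self):
        e = confidence_ellipse(self._points_with_cov(np.eye(2)))
        assert e.semi_major == pytest.approx(np.sqrt(5.991), abs=1e-2)
        assert e.semi_minor == pytest.approx(np.sqrt(5.991), abs=1e-2)

    def test_diagonal_covariance_axes(self):
        e = confidence_ellipse(self._points_with_cov(np.diag([4.0, 1.0])))
        assert e.semi_major == pytest.approx(2 * np.sqrt(5.991), rel=1e-2)
        assert e.semi_minor == pytest.approx(np.sqrt(5.991), rel=1e-2)
        assert abs(e.rotation_rad) < 0.05

    def test_rotation_equivariance(self):
        pts = self._points_with_cov(np.diag([4.0, 1.0]))
        theta = np.deg2rad(30)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        e0 = confidence_ellipse(pts)
        e1 = confidence_ellipse(pts @ rot.T)
        assert e1.semi_major == pytest.approx(e0.semi_major, rel=1e-9)
        assert (e1.rotation_rad - e0.rotation_rad) % np.pi == pytest.approx(theta, abs=1e-9)

    def test_singular_covariance_errors(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="singular"):
            confidence_ellipse(pts)


class TestOnewayAnova:
    def test_identical_groups(self):
        f, p = oneway_anova([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        assert (f, p) == (0.0, 1.0)

    def test_perfect_separation(self):
        f, p = oneway_anova([[0.0, 0.0, 0.0], [10.0, 10.0, 10.0]])
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_groups(self):
        # groups {1,2,3}, {4,5,6}: SSB = 13.5, SSW = 4, F = 13.5/(4/4) = 13.5
        f, p = oneway_anova([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert f == pytest.approx(13.5, rel=1e-12)
        assert 0.01 < p < 0.03

    def test_too_few_groups_errors(self):
        with pytest.raises(ValueError):
            oneway_anova([[1.0, 2.0]])


def test_read_collagen_applies_qc(tmp_path):
    import pandas as pd

    df = synth.gen_collagen_dataset(8, seed=3).drop(columns="true_cn")
    path = tmp_path / "collagen.csv"
    df.to_csv(path, index=False)
    samples = read_collagen(path)
    assert len(samples) == 8
    assert all(np.isfinite(s.cn_atomic) for s in samples)
    assert all(s.qc_pass for s in samples)  # generator targets the QC window
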