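"""Preprocessing stages: detection filter, normalization, QC, batch adjustment."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pharmtx.containers import ExpressionMatrix, ValidationError
from pharmtx.preprocess import (
    batch_anova_check,
    combat_adjust,
    detection_filter,
    euclidean_outlier_filter,
    log2_transform,
    mahalanobis_distances,
    mahalanobis_qc,
    quantile_normalize,
)

from conftest import make_expression


class TestDetectionFilter:
    def test_boundary_inclusive(self, rng):
        # probe 0: detected in exactly 5 of 100 samples -> kept; probe 1: 4 -> removed
        det = np.ones((2, 100))
        det[0, :5] = 0.01
        det[1, :4] = 0.01
        expr = make_expression(rng.random((2, 100)) + 1, scale="raw", detection=det)
        mask = detection_filter(expr, alpha=0.05, min_fraction=0.05)
        assert mask.keep.tolist() == [True, False]

    def test_unexpressed_probes_removed(self, rng):
        n, p = 500, 400
        expressed = np.arange(p) < 200
        det = np.where(
            expressed[:, None],
            rng.beta(0.5, 20, (p, n)),
            rng.uniform(0.1, 1.0, (p, n)),  # never below the 0.05 detection alpha
        )
        expr = make_expression(rng.random((p, n)) + 1, scale="raw", detection=det)
        mask = detection_filter(expr)
        assert (~mask.keep[~expressed]).all()

    def test_missing_detection_errors(self, rng):
        expr = make_expression(rng.random((5, 10)) + 1, scale="raw")
        with pytest.raises(ValidationError, match="detection"):
            detection_filter(expr)


class TestQuantileNormalize:
    def test_mean_of_order_statistics(self):
        expr = make_expression(np.array([[1.0, 2.0], [3.0, 4.0]]), scale="raw")
        out = quantile_normalize(expr)
        np.testing.assert_allclose(out.values.to_numpy(), [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_fixed_point(self, rng):
        col = rng.random(30)
        expr = make_expression(np.tile(col[:, None], (1, 5)), scale="raw")
        out = quantile_normalize(expr)
        np.testing.assert_allclose(out.values.to_numpy(), expr.values.to_numpy())

    def test_columns_share_order_statistics_exactly(self, rng):
        expr = make_expression(rng.random((50, 10)), scale="raw")
        out = quantile_normalize(expr).values.to_numpy()
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, 10):
            np.testing.assert_array_equal(sorted_cols[:, 0], sorted_cols[:, j])

    def test_total_sum_preserved(self, rng):
        x = rng.random((40, 8))
        expr = make_expression(x, scale="raw")
        out = quantile_normalize(expr).values.to_numpy()
        reference_sum = np.sort(x, axis=0).mean(axis=1).sum()
        assert out.sum() == pytest.approx(8 * reference_sum)

    def test_ties_get_average_reference(self):
        x = np.array([[1.0, 5.0], [1.0, 2.0], [4.0, 1.0]])
        out = quantile_normalize(make_expression(x, scale="raw")).values.to_numpy()
        # tied entries in column 0 receive identical values
        assert out[0, 0] == out[1, 0]

    def test_single_sample_rejected(self, rng):
        with pytest.raises(ValidationError):
            quantile_normalize(make_expression(rng.random((5, 1)), scale="raw"))


class TestLog2:
    def test_known_values(self):
        expr = make_expression(np.array([[8.0, 1.0]]), scale="raw")
        out = log2_transform(expr)
        np.testing.assert_allclose(out.values.to_numpy(), [[3.0, 0.0]])
        assert out.scale == "log2"

    def test_roundtrip(self, rng):
        x = rng.normal(7, 1, size=(20, 10))
        out = log2_transform(make_expression(2.0**x, scale="raw"))
        np.testing.assert_allclose(out.values.to_numpy(), x, atol=1e-12)

    def test_nonpositive_entries_reported(self):
        expr = make_expression(np.array([[1.0, -2.0]]), scale="raw")
        with pytest.raises(ValidationError, match="non-positive"):
            log2_transform(expr)


class TestMahalanobis:
    def test_matches_direct_quadratic_form(self, rng):
        x = rng.normal(size=(100, 4))
        qc = pd.DataFrame(x)
        d = mahalanobis_distances(qc)
        center = x.mean(axis=0)
        s_inv = np.linalg.inv(np.cov(x, rowvar=False))
        expected = np.sqrt(np.einsum("ij,jk,ik->i", x - center, s_inv, x - center))
        np.testing.assert_allclose(d, expected, atol=1e-8)

    def test_single_feature_reduces_to_z_score(self, rng):
        x = rng.normal(5, 2, size=200)
        qc = pd.DataFrame({"f": x})
        d = mahalanobis_distances(qc)
        np.testing.assert_allclose(d, np.abs(x - x.mean()) / x.std(ddof=1), atol=1e-10)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(150, 5))
        a = rng.normal(size=(5, 5)) + 2 * np.eye(5)
        b = rng.normal(size=5)
        d1 = mahalanobis_distances(pd.DataFrame(x))
        d2 = mahalanobis_distances(pd.DataFrame(x @ a + b))
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_squared_distances_chi2_under_null(self, rng):
        x = rng.normal(size=(2000, 5))
        d2 = mahalanobis_distances(pd.DataFrame(x)) ** 2
        ks = stats.kstest(d2, "chi2", args=(5,))
        assert ks.pvalue > 0.01

    def test_upper_fence_rule(self, rng):
        x = rng.normal(size=(300, 3))
        x[0] += 50.0
        mask = mahalanobis_qc(pd.DataFrame(x))
        assert not mask.keep[0]
        assert mask.score is not None and mask.score[0] == mask.score.max()

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValidationError):
            mahalanobis_qc(pd.DataFrame(rng.normal(size=(4, 4))))


class TestCombat:
    def _cohort(self, rng, shift=0.0, scale=1.0, p=150, n_per=100):
        x = rng.normal(7, 1, size=(p, 2 * n_per))
        x[:, n_per:] = x[:, n_per:] * scale + shift
        batch = pd.Series(
            ["b0"] * n_per + ["b1"] * n_per,
            index=[f"S{j:04d}" for j in range(2 * n_per)],
        )
        return make_expression(x, scale="log2"), batch

    def test_single_batch_is_noop(self, rng):
        expr = make_expression(rng.normal(7, 1, (50, 30)), scale="log2")
        batch = pd.Series(["b0"] * 30, index=expr.sample_ids)
        out, model = combat_adjust(expr, batch)
        np.testing.assert_allclose(out.values.to_numpy(), expr.values.to_numpy(), atol=1e-10)
        assert model is None

    def test_location_shift_removed(self, rng):
        # Empirical-Bayes shrinkage leaves small per-probe residuals; the
        # planted 1.0 shift must drop by an order of magnitude on average.
        expr, batch = self._cohort(rng, shift=1.0, n_per=200)
        out, _ = combat_adjust(expr, batch)
        x = out.values.to_numpy()
        diff = x[:, 200:].mean(axis=1) - x[:, :200].mean(axis=1)
        assert np.abs(diff).mean() < 0.1
        assert np.abs(diff).max() < 0.4
        assert np.abs(diff.mean()) < 0.02  # no systematic residual shift

    def test_scale_factor_removed(self, rng):
        # Planted variance ratio is 4; after adjustment it must centre on 1.
        expr, batch = self._cohort(rng, scale=2.0, n_per=200)
        out, _ = combat_adjust(expr, batch)
        x = out.values.to_numpy()
        ratio = x[:, 200:].var(axis=1) / x[:, :200].var(axis=1)
        assert 0.9 < ratio.mean() < 1.1
        assert (ratio > 0.5).all() and (ratio < 2.0).all()

    def test_near_idempotent(self, rng):
        # Re-running re-fits the priors, so the fixed point is approximate:
        # the second pass must move the data far less than the first.
        expr, batch = self._cohort(rng, shift=0.5, scale=1.3)
        once, _ = combat_adjust(expr, batch)
        twice, _ = combat_adjust(once, batch)
        delta1 = np.abs(once.values.to_numpy() - expr.values.to_numpy()).mean()
        delta2 = np.abs(twice.values.to_numpy() - once.values.to_numpy()).mean()
        assert delta2 < 0.05 * delta1

    def test_singleton_batch_rejected(self, rng):
        expr = make_expression(rng.normal(7, 1, (20, 5)), scale="log2")
        batch = pd.Series(["b0", "b0", "b0", "b0", "b1"], index=expr.sample_ids)
        with pytest.raises(ValidationError, match="single sample"):
            combat_adjust(expr, batch)

    def test_matches_bioconductor_reference(self, rng, tmp_path):
        """Independent oracle: sva::ComBat on the same matrix."""
        expr, batch = self._cohort(rng, shift=0.8, scale=1.5, p=60, n_per=25)
        out, _ = combat_adjust(expr, batch)
        expr.values.to_csv(tmp_path / "in.tsv", sep="\t")
        batch.to_frame("batch").to_csv(tmp_path / "batch.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(sva))
            x <- as.matrix(read.delim("in.tsv", row.names=1))
            b <- read.delim("batch.tsv", row.names=1)$batch
            out <- ComBat(dat=x, batch=b, par.prior=TRUE)
            write.table(out, "out.tsv", sep="\t", quote=FALSE)
            """
        )
        (tmp_path / "run.R").write_text(script)
        subprocess.run(
            ["Rscript", "run.R"], cwd=tmp_path, check=True,
            capture_output=True, timeout=300,
        )
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(
            out.values.to_numpy(), ref.to_numpy(), atol=1e-4
        )


class TestBatchAnova:
    def test_null_fraction_near_alpha(self, rng):
        expr = make_expression(rng.normal(7, 1, (2000, 120)), scale="log2")
        batch = pd.Series(np.repeat(["b0", "b1", "b2"], 40), index=expr.sample_ids)
        _, summary = batch_anova_check(expr, batch)
        assert 0.02 < summary["fraction_significant_at_0.05"] < 0.09

    def test_adjustment_removes_batch_signal(self, rng):
        x = rng.normal(7, 1, size=(300, 200))
        x[:, 100:] += rng.normal(0, 0.8, size=300)[:, None]
        expr = make_expression(x, scale="log2")
        batch = pd.Series(["b0"] * 100 + ["b1"] * 100, index=expr.sample_ids)
        _, before = batch_anova_check(expr, batch)
        adjusted, _ = combat_adjust(expr, batch)
        _, after = batch_anova_check(adjusted, batch)
        assert before["fraction_significant_at_0.05"] > 0.5
        assert after["fraction_significant_at_0.05"] < 0.07

    def test_minimum_two_samples_per_batch_runs(self, rng):
        expr = make_expression(rng.normal(7, 1, (30, 4)), scale="log2")
        batch = pd.Series(["b0", "b0", "b1", "b1"], index=expr.sample_ids)
        pvals, summary = batch_anova_check(expr, batch)
        assert len(pvals) == 30

    def test_single_batch_rejected(self, rng):
        expr = make_expression(rng.normal(size=(5, 6)), scale="log2")
        with pytest.raises(ValidationError):
            batch_anova_check(expr, pd.Series(["b"] * 6, index=expr.sample_ids))


class TestEuclideanFilter:
    def test_identical_samples_all_kept(self):
        x = np.tile(np.arange(20, dtype=float)[:, None], (1, 15))
        mask = euclidean_outlier_filter(make_expression(x, scale="log2"))
        assert mask.keep.all()
        np.testing.assert_allclose(mask.score, 0.0)

    def test_extreme_sample_removed(self, rng):
        x = rng.normal(7, 1, size=(100, 500))
        x[:, 3] += 50.0
        mask = euclidean_outlier_filter(make_expression(x, scale="log2"))
        assert not mask.keep[3]
        assert mask.keep.sum() >= 495

    def test_zero_trim_equals_untrimmed_mean(self, rng):
        x = rng.normal(7, 1, size=(50, 40))
        expr = make_expression(x, scale="log2")
        mask = euclidean_outlier_filter(expr, trim=0.0)
        mean = x.mean(axis=1)
        d = np.sqrt(((x - mean[:, None]) ** 2).sum(axis=0))
        np.testing.assert_allclose(mask.score, d, atol=1e-10)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValidationError):
            euclidean_outlier_filter(make_expression(rng.random((5, 8)), scale="log2"))
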