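"""Probe and sample quality control, normalization, and batch adjustment.

Stage order for a full run: detection filter -> quantile normalization ->
log2 transform -> Mahalanobis sample QC on chip control features ->
empirical-Bayes batch adjustment (location/scale, parametric priors) ->
per-probe ANOVA check of adjustment success -> Euclidean whole-transcriptome
outlier filter. Each filtering stage returns a mask recording, per id, the
keep decision, the triggering score and a reason code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .containers import ExpressionMatrix, ProbeMask, SampleMask, ValidationError

__all__ = [
    "detection_filter",
    "quantile_normalize",
    "log2_transform",
    "mahalanobis_qc",
    "combat_adjust",
    "batch_anova_check",
    "euclidean_outlier_filter",
    "BatchModel",
]


def detection_filter(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    min_fraction: float = 0.05,
) -> ProbeMask:
    """Keep probes detected (detection p <= alpha) in >= min_fraction of samples.

    The boundary is inclusive: a probe detected in exactly
    ``min_fraction * n_samples`` samples is kept.
    """
    if expr.detection_p is None:
        raise ValidationError(
            "expression matrix has no detection p-values; skip the detection "
            "filter explicitly if they are unavailable"
        )
    detected = (expr.detection_p.to_numpy() <= alpha).mean(axis=1)
    keep = detected >= min_fraction
    reasons = [
        "" if k else f"detected in {d:.4f} < {min_fraction} of samples"
        for k, d in zip(keep, detected)
    ]
    return ProbeMask(ids=expr.probe_ids, keep=keep, reason=reasons, score=detected)


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the mean empirical distribution.

    Each sample's values are replaced by the mean of the order statistics
    across samples, assigned by within-sample rank; ties receive the average
    of the reference values they span.
    """
    if expr.n_samples < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    x = expr.values.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    reference = sorted_x.mean(axis=1)

    out = np.empty_like(x)
    rows = np.arange(x.shape[0])
    for j in range(x.shape[1]):
        out[order[:, j], j] = reference
        col = x[:, j]
        # average reference values over tied entries
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if len(uniq) < len(col):
            sums = np.bincount(inv, weights=out[rows, j])
            out[:, j] = (sums / counts)[inv]

    values = pd.DataFrame(out, index=expr.probe_ids, columns=expr.sample_ids)
    return ExpressionMatrix(values=values, detection_p=expr.detection_p, scale=expr.scale)


def log2_transform(expr: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Elementwise log2 of (values + offset); sets the scale tag to log2."""
    x = expr.values.to_numpy(dtype=float) + offset
    if np.any(x <= 0):
        bad = np.argwhere(x <= 0)
        entries = ", ".join(
            f"({expr.probe_ids[i]}, {expr.sample_ids[j]})" for i, j in bad[:5]
        )
        raise ValidationError(
            f"{len(bad)} non-positive values after offset {offset}; first: {entries}"
        )
    values = pd.DataFrame(np.log2(x), index=expr.probe_ids, columns=expr.sample_ids)
    return ExpressionMatrix(values=values, detection_p=expr.detection_p, scale="log2")


def mahalanobis_distances(qc: pd.DataFrame, ridge: float = 0.0) -> np.ndarray:
    """Mahalanobis distance of each sample to the feature-mean 'average individual'."""
    x = qc.to_numpy(dtype=float)
    center = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if ridge > 0:
        cov = cov + ridge * np.eye(cov.shape[0])
    try:
        cho = scipy.linalg.cho_factor(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValidationError(
            "singular QC feature covariance; prune collinear features or enable "
            "the ridge fallback"
        ) from exc
    diff = x - center
    sol = scipy.linalg.cho_solve(cho, diff.T)
    d2 = np.einsum("ij,ji->i", diff, sol)
    return np.sqrt(np.maximum(d2, 0.0))


def mahalanobis_qc(
    qc: pd.DataFrame,
    k_iqr: float = 4.0,
    ridge: float = 0.0,
) -> SampleMask:
    """Flag samples whose QC-feature Mahalanobis distance exceeds the upper fence.

    A sample is kept iff its distance to the average individual is
    <= median(distances) + k_iqr * IQR(distances) (one-sided upper fence;
    distances are non-negative and only large values indicate failure).
    Missing feature values are mean-imputed before covariance estimation.
    """
    if qc.shape[0] <= qc.shape[1] + 1:
        raise ValidationError(
            f"need n_samples > n_features + 1 ({qc.shape[0]} samples, "
            f"{qc.shape[1]} features)"
        )
    if qc.isna().any().any():
        qc = qc.fillna(qc.mean())
    d = mahalanobis_distances(qc, ridge=ridge)
    med = np.median(d)
    iqr = np.subtract(*np.percentile(d, [75, 25]))
    fence = med + k_iqr * iqr
    keep = d <= fence
    reasons = [
        "" if k else f"Mahalanobis distance {di:.3f} > fence {fence:.3f}"
        for k, di in zip(keep, d)
    ]
    return SampleMask(ids=qc.index, keep=keep, reason=reasons, score=d)


@dataclass
class BatchModel:
    """Fitted empirical-Bayes batch model: shrunken location/scale per batch x probe."""

    batches: list[str]
    gamma_star: np.ndarray  # n_batches x n_probes location shifts (log2 units)
    delta2_star: np.ndarray  # n_batches x n_probes variance factors (> 0)
    gamma_bar: np.ndarray  # prior means of gamma per batch
    tau2: np.ndarray  # prior variances of gamma per batch
    a_prior: np.ndarray  # inverse-gamma shape per batch
    b_prior: np.ndarray  # inverse-gamma scale per batch
    n_iter: int = 0


def _ig_moments(delta2_hat: np.ndarray) -> tuple[float, float]:
    """Method-of-moments inverse-gamma hyperparameters from batch variances."""
    m = delta2_hat.mean()
    s2 = delta2_hat.var(ddof=1)
    a = (2.0 * s2 + m * m) / s2
    b = (m * s2 + m**3) / s2
    return float(a), float(b)


def combat_adjust(
    expr: ExpressionMatrix,
    batch: pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[ExpressionMatrix, BatchModel | None]:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per probe the data are standardized by the pooled model fit; per-batch
    location (gamma) and scale (delta^2) estimates are shrunk toward normal /
    inverse-gamma priors whose hyperparameters are method-of-moments
    estimates across probes, via the standard fixed-point posterior-mean
    update iterated to convergence. With a single batch the matrix is
    returned unchanged (nothing to adjust).
    """
    if expr.scale != "log2":
        raise ValidationError("batch adjustment expects log2-scale values")
    batch = pd.Series(batch).reindex(expr.sample_ids)
    if batch.isna().any():
        raise ValidationError("batch labels missing for some samples")
    levels = batch.unique().tolist()
    if len(levels) == 1:
        return expr, None
    counts = batch.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(
            "batches with a single sample: "
            f"{list(small.index)}; drop these samples before adjustment"
        )

    x = expr.values.to_numpy(dtype=float)
    p, n = x.shape
    codes = pd.Categorical(batch, categories=levels).codes
    nb = len(levels)
    b_onehot = np.eye(nb)[codes]  # n x nb

    design = b_onehot
    q = 0
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        q = cov.shape[1]
        design = np.hstack([b_onehot, cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("batch design rank-deficient (covariate confounded with batch)")

    # pooled OLS fit per probe (shared design)
    beta_hat, *_ = np.linalg.lstsq(design, x.T, rcond=None)  # (nb+q) x p
    n_per_batch = np.bincount(codes, minlength=nb).astype(float)
    alpha = (n_per_batch / n) @ beta_hat[:nb]  # grand mean per probe
    fitted = design @ beta_hat
    var_pooled = ((x.T - fitted) ** 2).mean(axis=0)  # per probe, ddof 0
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = np.tile(alpha[None, :], (n, 1))
    if q:
        stand_mean = stand_mean + design[:, nb:] @ beta_hat[nb:]
    z = (x.T - stand_mean) / np.sqrt(var_pooled)  # n x p

    gamma_hat = np.vstack([z[codes == b].mean(axis=0) for b in range(nb)])
    delta2_hat = np.vstack([z[codes == b].var(axis=0, ddof=1) for b in range(nb)])

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    ab = [_ig_moments(delta2_hat[b]) for b in range(nb)]
    a_prior = np.array([v[0] for v in ab])
    b_prior = np.array([v[1] for v in ab])

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    n_iter = 0
    for b in range(nb):
        nb_samples = n_per_batch[b]
        zb = z[codes == b]  # nb_samples x p
        g_old = gamma_hat[b].copy()
        d_old = delta2_hat[b].copy()
        for it in range(max_iter):
            g_new = (nb_samples * tau2[b] * gamma_hat[b] + d_old * gamma_bar[b]) / (
                nb_samples * tau2[b] + d_old
            )
            sse = ((zb - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (0.5 * sse + b_prior[b]) / (nb_samples / 2.0 + a_prior[b] - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-12)),
                np.max(np.abs(d_new - d_old) / (np.abs(d_old) + 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        n_iter = max(n_iter, it + 1)
        gamma_star[b] = g_old
        delta2_star[b] = d_old

    z_adj = (z - gamma_star[codes]) / np.sqrt(delta2_star[codes])
    out = z_adj * np.sqrt(var_pooled) + stand_mean  # n x p

    values = pd.DataFrame(out.T, index=expr.probe_ids, columns=expr.sample_ids)
    model = BatchModel(
        batches=[str(b) for b in levels],
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar,
        tau2=tau2,
        a_prior=a_prior,
        b_prior=b_prior,
        n_iter=n_iter,
    )
    adjusted = ExpressionMatrix(values=values, detection_p=expr.detection_p, scale="log2")
    return adjusted, model


def batch_anova_check(
    expr: ExpressionMatrix,
    batch: pd.Series,
) -> tuple[pd.Series, dict]:
    """One-way ANOVA of expression on batch per probe.

    Returns per-probe p-values and a summary with the fraction of probes
    significant at 0.05 — expected to sit near 0.05 after successful batch
    adjustment.
    """
    batch = pd.Series(batch).reindex(expr.sample_ids)
    levels = batch.unique()
    if len(levels) < 2:
        raise ValidationError("ANOVA check needs >= 2 batches")
    x = expr.values.to_numpy(dtype=float)
    groups = [x[:, (batch == lv).to_numpy()] for lv in levels]
    stat = scipy.stats.f_oneway(*groups, axis=1)
    pvals = pd.Series(stat.pvalue, index=expr.probe_ids, name="anova_p")
    frac = float((stat.pvalue < 0.05).mean())
    summary = {
        "n_probes": expr.n_probes,
        "n_batches": len(levels),
        "fraction_significant_at_0.05": frac,
    }
    return pvals, summary


def euclidean_outlier_filter(
    expr: ExpressionMatrix,
    trim: float = 0.10,
    k_iqr: float = 4.0,
) -> SampleMask:
    """Remove samples far from the trimmed average transcriptome.

    A provisional mean sample is computed; the ``trim`` fraction of samples
    farthest from it (Euclidean) is set aside; the mean is recomputed from
    the rest; every sample's distance to this trimmed mean is compared with
    the upper fence median + k_iqr * IQR (median/IQR over all samples).
    """
    if expr.n_samples < 10:
        raise ValidationError("Euclidean outlier filter needs >= 10 samples")
    x = expr.values.to_numpy(dtype=float)
    mean0 = x.mean(axis=1)
    d0 = np.sqrt(((x - mean0[:, None]) ** 2).sum(axis=0))
    n_trim = int(np.floor(trim * expr.n_samples))
    if n_trim > 0:
        keep_for_mean = np.argsort(d0, kind="stable")[: expr.n_samples - n_trim]
        mean1 = x[:, keep_for_mean].mean(axis=1)
    else:
        mean1 = mean0
    d = np.sqrt(((x - mean1[:, None]) ** 2).sum(axis=0))
    fence = np.median(d) + k_iqr * np.subtract(*np.percentile(d, [75, 25]))
    keep = d <= fence
    reasons = [
        "" if k else f"Euclidean distance {di:.3f} > fence {fence:.3f}"
        for k, di in zip(keep, d)
    ]
    return SampleMask(ids=expr.sample_ids, keep=keep, reason=reasons, score=d)
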