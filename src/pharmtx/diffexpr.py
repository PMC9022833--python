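"""Per-substance differential expression with empirical-Bayes moderated t-statistics.

Per probe an ordinary least-squares fit of log2 expression on the design
(intercept + base covariates + screened adjustment drugs + tested substance)
yields coefficients and residual variances; the residual variances are then
shrunk toward a pooled prior estimated across probes by moment matching on
log variances (the classic moderated-t construction), gaining d0 prior
degrees of freedom. P-values for the tested coefficient are two-sided from a
t-distribution with d0 + d residual df, and adjusted per substance with the
Benjamini-Hochberg step-up. Probe-level calls are summarized to genes: a gene
is significant if at least one of its probes is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix, ValidationError
from .covariates import AdjustmentModel, base_design, pairwise_or_screen

__all__ = [
    "LinearFit",
    "ModeratedFit",
    "DEResult",
    "fit_linear_models",
    "moderate_variances",
    "bh_adjust",
    "test_substance",
    "gene_level_summary",
]


@dataclass
class LinearFit:
    """Per-probe OLS results against a shared design matrix."""

    coef: pd.DataFrame  # probes x design columns, log2 units
    sigma2: pd.Series  # residual variance per probe
    df_resid: int  # n_samples - rank(design)
    unscaled_var: pd.Series  # diag of (X'X)^-1 per design column

    @property
    def n_probes(self) -> int:
        return self.coef.shape[0]


@dataclass
class ModeratedFit:
    """Moderated statistics for one design coefficient."""

    coef_name: str
    d0: float  # prior df (may be inf)
    s0_2: float  # prior variance
    s2_post: np.ndarray  # posterior (shrunk) variances per probe
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_total: float
    probe_ids: pd.Index


@dataclass
class DEResult:
    """Differential-expression result for one substance."""

    substance: str
    table: pd.DataFrame  # probe-indexed: gene, beta, se, t, p, q, direction
    n_users: int
    adjustment_substances: list[str]
    or_report: pd.DataFrame | None = None

    @property
    def n_significant(self) -> int:
        return int((self.table["q"] <= 0.05).sum())

    def counts(self, q_cut: float = 0.05) -> dict:
        sig = self.table[self.table["q"] <= q_cut]
        return {
            "substance": self.substance,
            "n_users": self.n_users,
            "n_significant": len(sig),
            "n_up": int((sig["direction"] > 0).sum()),
            "n_down": int((sig["direction"] < 0).sum()),
            "min_q": float(self.table["q"].min()) if len(self.table) else np.nan,
        }


def fit_linear_models(
    expr: ExpressionMatrix,
    design: pd.DataFrame | np.ndarray,
) -> LinearFit:
    """OLS of every probe on a shared design matrix.

    Vectorized over probes: one QR factorization of the design serves all
    probes. Residual df = n_samples - n_columns (the design must be full
    column rank).
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        x = design.to_numpy(dtype=float)
    else:
        x = np.asarray(design, dtype=float)
        names = [f"x{j}" for j in range(x.shape[1])]
    n, k = x.shape
    if n != expr.n_samples:
        raise ValidationError(
            f"design rows ({n}) != number of samples ({expr.n_samples})"
        )
    if n <= k:
        raise ValidationError(f"need n_samples > design columns ({n} <= {k})")
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        # name the dependent columns via QR pivoting on correlations
        r = np.linalg.qr(x, mode="r")
        dep = [names[j] for j in range(k) if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
        raise ValidationError(
            f"design rank-deficient (rank {rank} < {k}); dependent columns: {dep or names}"
        )

    y = expr.values.to_numpy(dtype=float).T  # n x p
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = xtx_inv @ (x.T @ y)  # k x p
    resid = y - x @ coef
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df

    return LinearFit(
        coef=pd.DataFrame(coef.T, index=expr.probe_ids, columns=names),
        sigma2=pd.Series(sigma2, index=expr.probe_ids, name="sigma2"),
        df_resid=df,
        unscaled_var=pd.Series(np.diag(xtx_inv), index=names, name="unscaled_var"),
    )


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of the (d0, s0^2) variance prior.

    Works on e_g = log s2_g - digamma(d/2) + log(d/2), whose mean and excess
    variance over the theoretical trigamma(d/2) identify the scaled inverse
    chi-square prior. Zero excess variance gives d0 = inf (all variances
    shrunk fully to s0^2).
    """
    s2 = np.asarray(sigma2, dtype=float)
    positive = s2 > 0
    if not positive.any():
        raise ValidationError("all residual variances are zero; cannot moderate")
    z = np.log(s2[positive])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return float(d0), s0_2


def moderate_variances(
    fit: LinearFit,
    coef: int | str = -1,
    moderate: bool = True,
) -> ModeratedFit:
    """Empirical-Bayes moderated t for one design coefficient.

    With ``moderate=False`` the ordinary t-statistic (no shrinkage, d resid
    df) is returned, the degenerate d0 = 0 limit.
    """
    if fit.n_probes < 10 and moderate:
        raise ValidationError("variance moderation needs >= 10 probes")
    names = list(fit.coef.columns)
    if isinstance(coef, str):
        coef_name = coef
    else:
        coef_name = names[coef]
    j = names.index(coef_name)

    beta = fit.coef.iloc[:, j].to_numpy(dtype=float)
    s2 = fit.sigma2.to_numpy(dtype=float)
    d = float(fit.df_resid)
    v = float(fit.unscaled_var.iloc[j])

    if not moderate:
        d0, s0_2 = 0.0, np.nan
        s2_post = s2.copy()
        df_total = d
    else:
        d0, s0_2 = estimate_prior(s2, d)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
            df_total = d0 + d
    se = np.sqrt(s2_post * v)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return ModeratedFit(
        coef_name=coef_name,
        d0=d0,
        s0_2=s0_2,
        s2_post=s2_post,
        beta=beta,
        se=se,
        t=t,
        p=p,
        df_total=df_total,
        probe_ids=fit.coef.index,
    )


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("p must be one-dimensional")
    if not np.all(np.isfinite(arr)) or arr.min() < 0 or arr.max() > 1:
        raise ValidationError("p-values must be finite and in [0, 1]")
    m = len(arr)
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def build_design(
    annot: pd.DataFrame,
    med: pd.DataFrame,
    substance: str,
    adjustment: list[str],
    sample_ids: pd.Index,
) -> pd.DataFrame:
    """Intercept + base covariates + adjustment drugs + tested substance."""
    design = base_design(annot.loc[sample_ids])
    design.insert(0, "intercept", 1.0)
    for drug in adjustment:
        design[drug] = med.loc[sample_ids, drug].astype(float)
    design[substance] = med.loc[sample_ids, substance].astype(float)
    return design


def test_substance(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    med: pd.DataFrame,
    substance: str,
    model: AdjustmentModel,
    probe_annot: pd.DataFrame | None = None,
    min_users: int = 20,
    or_lo: float = 0.125,
    or_hi: float = 8.0,
) -> DEResult | None:
    """Moderated-t association of every probe with one substance.

    The adjustment set is first pruned by the extreme pairwise odds-ratio
    rule against the tested substance; the substance is skipped (returns
    ``None``) if fewer than ``min_users`` samples take it.
    """
    intake = med.loc[expr.sample_ids, substance]
    n_users = int(intake.sum())
    if n_users < min_users:
        return None

    screened, or_report = pairwise_or_screen(
        med.loc[expr.sample_ids], substance, model.substances, lo=or_lo, hi=or_hi
    )
    design = build_design(annot, med, substance, screened, expr.sample_ids)
    fit = fit_linear_models(expr, design)
    mod = moderate_variances(fit, coef=substance)
    q = bh_adjust(mod.p)

    table = pd.DataFrame(
        {
            "beta": mod.beta,
            "se": mod.se,
            "t": mod.t,
            "p": mod.p,
            "q": q,
            "direction": np.sign(mod.beta).astype(int),
        },
        index=expr.probe_ids,
    )
    if probe_annot is not None:
        table.insert(0, "gene", probe_annot["gene"].reindex(expr.probe_ids))
    return DEResult(
        substance=substance,
        table=table,
        n_users=n_users,
        adjustment_substances=screened,
        or_report=or_report,
    )


def gene_level_summary(
    de: DEResult,
    probe_annot: pd.DataFrame,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Gene-level calls: a gene is significant iff >= 1 mapped probe has q <= q_cut.

    The best probe per gene is the one with minimal q; ties break by larger
    |t|, then lexicographic probe id. Probes mapped to several genes count
    for each of them; unmapped probes are reported under gene id ``""``.
    """
    tab = de.table.copy()
    genes = probe_annot["gene"].reindex(tab.index).fillna("")
    tab = tab.assign(gene=genes, probe=tab.index)
    rows = []
    for gene, grp in tab.groupby("gene", sort=True):
        grp = grp.sort_values(
            by=["q", "t", "probe"],
            key=lambda s: -s.abs() if s.name == "t" else s,
            kind="stable",
        )
        best = grp.iloc[0]
        rows.append(
            {
                "gene": gene,
                "significant": bool(best["q"] <= q_cut),
                "best_probe": best["probe"],
                "min_q": float(best["q"]),
                "direction": int(best["direction"]),
                "n_probes": len(grp),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
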