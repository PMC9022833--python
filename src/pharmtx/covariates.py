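"""Polymedication adjustment model.

Builds the covariate set for per-substance association testing: the base
covariates (sex, age, lymphocyte %, monocyte %, smoking status, log BMI), a
prevalence screen for candidate co-medications, per-substance FDR-based
selection of adjustment drugs, variance-inflation-factor collinearity checks,
and the per-test extreme-odds-ratio pruning rule that drops an adjustment
drug strongly co-prescribed with the substance under test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError

__all__ = [
    "BASE_COVARIATES",
    "AdjustmentModel",
    "base_design",
    "candidate_substances",
    "select_adjustment_substances",
    "vif",
    "pairwise_or_screen",
]

#: base covariates, in model order; log_bmi is derived from the bmi column
BASE_COVARIATES = ["sex", "age", "lymphocytes", "monocytes", "smoking", "log_bmi"]


@dataclass
class AdjustmentModel:
    """Selected adjustment substances plus their selection audit trail."""

    base_covariates: list[str] = field(default_factory=lambda: list(BASE_COVARIATES))
    substances: list[str] = field(default_factory=list)
    selection: pd.DataFrame | None = None  # per candidate: n significant, min q
    vif: pd.Series | None = None

    def to_dict(self) -> dict:
        d = {
            "base_covariates": list(self.base_covariates),
            "substances": list(self.substances),
        }
        if self.selection is not None:
            d["selection"] = self.selection.reset_index().to_dict(orient="records")
        if self.vif is not None:
            d["vif"] = {k: float(v) for k, v in self.vif.items()}
        return d


def base_design(annot: pd.DataFrame, covariates: list[str] | None = None) -> pd.DataFrame:
    """Base covariate design (no intercept column) from the sample annotation.

    BMI enters as its natural log; all other covariates are used as-is.
    """
    covariates = covariates or BASE_COVARIATES
    cols = {}
    for cov in covariates:
        if cov == "log_bmi":
            if "log_bmi" in annot:
                cols[cov] = annot["log_bmi"].astype(float)
            elif "bmi" in annot:
                cols[cov] = np.log(annot["bmi"].astype(float))
            else:
                raise ValidationError("annotation has neither 'log_bmi' nor 'bmi'")
        else:
            if cov not in annot:
                raise ValidationError(f"annotation missing covariate {cov!r}")
            cols[cov] = annot[cov].astype(float)
    return pd.DataFrame(cols, index=annot.index)


def candidate_substances(med: pd.DataFrame, min_prevalence: float = 0.05) -> list[str]:
    """Substances taken by strictly more than ``min_prevalence`` of samples.

    Sorted by descending prevalence (ties by label).
    """
    if med.shape[1] == 0 or med.shape[0] == 0:
        return []
    prev = med.mean(axis=0)
    kept = prev[prev > min_prevalence]
    kept = kept.sort_values(ascending=False, kind="stable")
    # stable tie-break on label
    order = sorted(kept.index, key=lambda lab: (-kept[lab], lab))
    return list(order)


def select_adjustment_substances(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    med: pd.DataFrame,
    candidates: list[str],
    fdr: float = 0.05,
) -> AdjustmentModel:
    """Select adjustment drugs: candidates with >= 1 probe at q <= fdr.

    Each candidate is tested alone (base covariates + that candidate) with
    moderated t-statistics and per-candidate BH adjustment across probes.
    """
    from .diffexpr import bh_adjust, fit_linear_models, moderate_variances

    base = base_design(annot.loc[expr.sample_ids])
    records = []
    selected = []
    for cand in candidates:
        intake = med.loc[expr.sample_ids, cand].astype(float)
        if intake.nunique() < 2:
            warnings.warn(f"candidate {cand!r} constant in analysis samples; skipped")
            continue
        design = pd.concat([base, intake.rename(cand)], axis=1)
        design.insert(0, "intercept", 1.0)
        fit = fit_linear_models(expr, design)
        mod = moderate_variances(fit, coef=design.columns.get_loc(cand))
        q = bh_adjust(mod.p)
        n_sig = int((q <= fdr).sum())
        records.append(
            {
                "substance": cand,
                "prevalence": float(intake.mean()),
                "n_significant_probes": n_sig,
                "min_q": float(q.min()),
            }
        )
        if n_sig >= 1:
            selected.append(cand)

    selection = pd.DataFrame(
        records, columns=["substance", "prevalence", "n_significant_probes", "min_q"]
    ).set_index("substance") if records else None

    model = AdjustmentModel(substances=selected, selection=selection)
    if selected:
        full = pd.concat(
            [base, med.loc[expr.sample_ids, selected].astype(float)], axis=1
        )
        model.vif = vif(full)
        high = model.vif[np.isfinite(model.vif) & (model.vif > 5)]
        if len(high) or not np.isfinite(model.vif).all():
            warnings.warn(
                "high collinearity in adjustment design (VIF > 5): "
                f"{list(model.vif[~np.isfinite(model.vif) | (model.vif > 5)].index)}"
            )
    return model


def vif(design: pd.DataFrame | np.ndarray) -> pd.Series:
    """Variance inflation factor per design column.

    VIF_j = 1 / (1 - R^2_j), with R^2_j from regressing column j on all other
    columns plus an intercept. Perfectly collinear columns are reported as
    ``inf`` rather than raising.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        x = design.to_numpy(dtype=float)
    else:
        x = np.asarray(design, dtype=float)
        names = [f"x{j}" for j in range(x.shape[1])]
    n, k = x.shape
    if n <= k:
        raise ValidationError(f"need n > number of columns ({n} <= {k})")
    out = np.empty(k)
    ones = np.ones((n, 1))
    for j in range(k):
        y = x[:, j]
        others = np.hstack([ones, np.delete(x, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0.0:
            out[j] = np.inf  # constant column
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, index=names, name="vif")


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """2x2 odds ratio (ad)/(bc) with Haldane-Anscombe +0.5 on all cells if any is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def pairwise_or_screen(
    med: pd.DataFrame,
    tested: str,
    adjustment: list[str],
    lo: float = 0.125,
    hi: float = 8.0,
) -> tuple[list[str], pd.DataFrame]:
    """Drop adjustment drugs with an extreme intake odds ratio vs the tested substance.

    For each adjustment drug the 2x2 joint-intake table against the tested
    substance is cross-tabulated; the drug is dropped iff OR < lo or OR > hi.
    The tested substance itself is removed from the adjustment set first (a
    variable cannot adjust for itself). Returns the pruned list and a report
    of every OR and decision.
    """
    if tested not in med.columns:
        raise ValidationError(f"tested substance {tested!r} absent from medication table")
    t = med[tested].to_numpy(dtype=int)
    pruned = []
    rows = []
    for drug in adjustment:
        if drug == tested:
            rows.append(
                {"drug": drug, "a": 0, "b": 0, "c": 0, "d": 0, "odds_ratio": np.nan,
                 "kept": False, "reason": "tested substance itself"}
            )
            continue
        u = med[drug].to_numpy(dtype=int)
        a = int(((t == 1) & (u == 1)).sum())
        b = int(((t == 1) & (u == 0)).sum())
        c = int(((t == 0) & (u == 1)).sum())
        d = int(((t == 0) & (u == 0)).sum())
        orr = odds_ratio_2x2(a, b, c, d)
        keep = lo <= orr <= hi
        rows.append(
            {
                "drug": drug, "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": orr, "kept": keep,
                "reason": "" if keep else f"extreme OR {orr:.3f} outside [{lo}, {hi}]",
            }
        )
        if keep:
            pruned.append(drug)
    report = pd.DataFrame(
        rows, columns=["drug", "a", "b", "c", "d", "odds_ratio", "kept", "reason"]
    )
    return pruned, report
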