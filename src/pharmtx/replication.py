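"""Hierarchical replication of discovery hits in an independent cohort.

Discovery-significant probes are grouped into one family per substance and
retested in the replication cohort with the same adjustment model. Within
each family, p-values are BH-adjusted; the family's minimum q is carried to a
second, across-family BH step (the Benjamini-Bogomolov construction for
selective inference over families). Probes in selected families are declared
significant at the selection-adjusted within-family level q * S / M (S of M
families selected), and count as replicated only if their effect direction
matches discovery. Nominal-significance and sign-test criteria are provided
as sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ValidationError
from .covariates import AdjustmentModel
from .diffexpr import DEResult, bh_adjust, test_substance

__all__ = [
    "Family",
    "ReplicationInput",
    "ReplicationResult",
    "build_replication_input",
    "hierarchical_replication",
    "nominal_replication",
    "sign_test",
    "sensitivity_analysis",
]


@dataclass
class Family:
    """One substance's discovery-significant probes with their directions."""

    substance: str
    probes: list[str]
    discovery_direction: pd.Series  # probe -> +1/-1
    discovery_beta: pd.Series | None = None


@dataclass
class ReplicationInput:
    families: list[Family]
    excluded: dict[str, str] = field(default_factory=dict)  # substance -> reason


@dataclass
class ReplicationResult:
    """Family-level selection plus per-probe and per-gene replication flags."""

    family_table: pd.DataFrame  # per substance: min q, selected, counts
    probe_table: pd.DataFrame  # per (substance, probe): stats and flags
    gene_table: pd.DataFrame | None
    n_families: int
    n_selected: int
    excluded: dict[str, str]


def build_replication_input(
    discovery: dict[str, DEResult],
    replication_probes: pd.Index,
    replication_substances: list[str] | pd.Index,
    q_cut: float = 0.05,
) -> ReplicationInput:
    """Families of discovery hits available on the replication platform.

    Probes absent from the replication platform are dropped; substances not
    recorded in the replication medication table, or with no available
    probes, are excluded with a reason.
    """
    families = []
    excluded: dict[str, str] = {}
    for substance in sorted(discovery):
        de = discovery[substance]
        sig = de.table[de.table["q"] <= q_cut]
        if sig.empty:
            continue
        if substance not in list(replication_substances):
            excluded[substance] = "not recorded in replication cohort"
            continue
        avail = [p for p in sig.index if p in replication_probes]
        if not avail:
            excluded[substance] = "no significant probes on replication platform"
            continue
        families.append(
            Family(
                substance=substance,
                probes=avail,
                discovery_direction=sig.loc[avail, "direction"].astype(int),
                discovery_beta=sig.loc[avail, "beta"],
            )
        )
    return ReplicationInput(families=families, excluded=excluded)


def hierarchical_replication(
    rep_input: ReplicationInput,
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    med: pd.DataFrame,
    model: AdjustmentModel,
    probe_annot: pd.DataFrame | None = None,
    q_level: float = 0.05,
    min_users: int = 20,
    method: str = "selective",
) -> ReplicationResult:
    """Two-level FDR over families of hypotheses.

    ``method="selective"`` (default) re-thresholds probes within selected
    families at the selection-adjusted level q_level * S / M;
    ``method="minq_adjust"`` treats the across-family BH adjustment as the
    only extra correction and keeps the plain within-family level q_level.
    """
    if method not in ("selective", "minq_adjust"):
        raise ValidationError(f"unknown method {method!r}")
    if not rep_input.families:
        raise ValidationError("no families to replicate")

    excluded = dict(rep_input.excluded)
    fits: list[tuple[Family, pd.DataFrame]] = []
    for fam in rep_input.families:
        de = test_substance(
            expr, annot, med, fam.substance, model,
            probe_annot=probe_annot, min_users=min_users,
        )
        if de is None:
            excluded[fam.substance] = f"fewer than {min_users} users in replication cohort"
            continue
        avail = [p for p in fam.probes if p in de.table.index]
        if not avail:
            excluded[fam.substance] = "no family probes measured in replication cohort"
            continue
        sub = de.table.loc[avail, ["beta", "se", "t", "p", "direction"]].copy()
        sub["q"] = bh_adjust(sub["p"].to_numpy())
        sub["direction_discovery"] = fam.discovery_direction.reindex(avail).astype(int)
        fits.append((fam, sub))

    if not fits:
        raise ValidationError("no family could be tested in the replication cohort")

    m_families = len(fits)
    min_q = np.array([sub["q"].min() for _, sub in fits])
    bb_adjusted = bh_adjust(min_q)
    selected = bb_adjusted <= q_level
    n_selected = int(selected.sum())
    probe_level = (
        q_level * n_selected / m_families if method == "selective" else q_level
    )

    fam_rows = []
    probe_frames = []
    for i, (fam, sub) in enumerate(fits):
        sig = selected[i] & (sub["q"] <= probe_level)
        same_dir = sub["direction"].astype(int) == sub["direction_discovery"]
        replicated = sig & same_dir
        sub = sub.assign(
            substance=fam.substance,
            significant=sig,
            replicated=replicated,
        )
        sub.index.name = "probe"
        probe_frames.append(sub.reset_index())
        called = sub[replicated]
        fam_rows.append(
            {
                "substance": fam.substance,
                "n_probes_available": len(sub),
                "min_q": float(sub["q"].min()),
                "bb_adjusted": float(bb_adjusted[i]),
                "selected": bool(selected[i]),
                "n_replicated": int(replicated.sum()),
                "n_up": int((called["direction"] > 0).sum()),
                "n_down": int((called["direction"] < 0).sum()),
            }
        )

    family_table = pd.DataFrame(fam_rows).set_index("substance")
    probe_table = pd.concat(probe_frames, ignore_index=True)

    gene_table = None
    if probe_annot is not None:
        pt = probe_table.assign(
            gene=probe_annot["gene"].reindex(probe_table["probe"]).to_numpy()
        )
        gene_rows = []
        for (substance, gene), grp in pt.groupby(["substance", "gene"], sort=True):
            gene_rows.append(
                {
                    "substance": substance,
                    "gene": gene,
                    "replicated": bool(grp["replicated"].any()),
                    "n_probes": len(grp),
                }
            )
        gene_table = pd.DataFrame(gene_rows)

    return ReplicationResult(
        family_table=family_table,
        probe_table=probe_table,
        gene_table=gene_table,
        n_families=m_families,
        n_selected=n_selected,
        excluded=excluded,
    )


def nominal_replication(probe_table: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Nominal criterion: replication p <= alpha and same effect direction."""
    required = {"p", "direction", "direction_discovery"}
    missing = required - set(probe_table.columns)
    if missing:
        raise ValidationError(f"probe table missing columns: {sorted(missing)}")
    flags = (probe_table["p"] <= alpha) & (
        probe_table["direction"].astype(int)
        == probe_table["direction_discovery"].astype(int)
    )
    return flags.rename("nominal_replicated")


def sign_test(
    signs_discovery: np.ndarray | list,
    signs_replication: np.ndarray | list,
) -> float:
    """Exact two-sided binomial test of direction concordance against chance.

    With k of n concordant sign pairs, returns the two-sided p-value of k
    under Binomial(n, 1/2).
    """
    a = np.asarray(signs_discovery)
    b = np.asarray(signs_replication)
    if a.shape != b.shape:
        raise ValidationError("sign vectors differ in length")
    if a.size < 1:
        raise ValidationError("need >= 1 sign pair")
    if not (np.all(np.abs(a) == 1) and np.all(np.abs(b) == 1)):
        raise ValidationError("signs must be +1 or -1")
    k = int((a == b).sum())
    return float(stats.binomtest(k, a.size, 0.5, alternative="two-sided").pvalue)


def sensitivity_analysis(probe_table: pd.DataFrame) -> pd.DataFrame:
    """Per substance: nominal same-direction count and sign-test concordance p."""
    nominal = nominal_replication(probe_table)
    rows = []
    for substance, grp in probe_table.groupby("substance", sort=True):
        p_sign = sign_test(
            grp["direction_discovery"].to_numpy(),
            np.where(grp["direction"].to_numpy() == 0, 1, grp["direction"].to_numpy()),
        )
        rows.append(
            {
                "substance": substance,
                "n_probes": len(grp),
                "n_nominal_same_direction": int(nominal[grp.index].sum()),
                "n_concordant": int(
                    (grp["direction"].astype(int) == grp["direction_discovery"]).sum()
                ),
                "sign_test_p": p_sign,
            }
        )
    return pd.DataFrame(rows).set_index("substance")
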