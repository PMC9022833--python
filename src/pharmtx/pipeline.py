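"""End-to-end orchestration: discovery and replication pipelines.

``discovery_pipeline`` runs, in fixed order, detection filtering, quantile
normalization, log2 transform, Mahalanobis sample QC, empirical-Bayes batch
adjustment with an ANOVA check, the Euclidean whole-transcriptome filter,
polymedication adjustment-model selection, and per-substance moderated-t
testing with gene-level summaries. ``replication_pipeline`` preprocesses the
replication cohort the same way, reuses the discovery adjustment model
(re-running the odds-ratio screen on replication-cohort intake frequencies),
and applies the hierarchical family-level multiple-testing correction plus
the nominal and sign-test sensitivity criteria, with optional pathway
over-representation of replicated genes.

Every stage that changes the data dimensions appends a record to the run
manifest, so the probe/sample chain is auditable end to end.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .containers import ExpressionMatrix, ValidationError
from .covariates import (
    AdjustmentModel,
    candidate_substances,
    select_adjustment_substances,
)
from .diffexpr import DEResult, gene_level_summary, test_substance
from .enrichment import GeneSetCollection, deduplicate_pathways, enrich_substance
from .preprocess import (
    batch_anova_check,
    combat_adjust,
    detection_filter,
    euclidean_outlier_filter,
    log2_transform,
    mahalanobis_qc,
    quantile_normalize,
)
from .replication import (
    ReplicationResult,
    build_replication_input,
    hierarchical_replication,
    nominal_replication,
    sensitivity_analysis,
)
from .simulate import _QC_FEATURES

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "DiscoveryOutput",
    "ReplicationOutput",
    "discovery_pipeline",
    "replication_pipeline",
]


@dataclass
class PipelineConfig:
    """Stage toggles and thresholds; defaults match the published analysis."""

    detection_alpha: float = 0.05
    detection_min_fraction: float = 0.05
    k_iqr: float = 4.0
    euclid_trim: float = 0.10
    min_prevalence: float = 0.05
    min_users: int = 20
    fdr: float = 0.05
    or_lo: float = 0.125
    or_hi: float = 8.0
    replication_method: str = "selective"
    run_detection_filter: bool = True
    run_quantile_normalize: bool = True
    run_log2: bool = True
    run_mahalanobis_qc: bool = True
    run_combat: bool = True
    run_euclidean_filter: bool = True
    qc_features: list[str] = field(default_factory=lambda: list(_QC_FEATURES))
    seed: int = 0

    def validate(self) -> None:
        for name in ("detection_alpha", "detection_min_fraction", "min_prevalence", "fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if not 0 <= self.euclid_trim < 0.5:
            raise ValidationError(f"euclid_trim must be in [0, 0.5), got {self.euclid_trim}")
        if self.k_iqr <= 0:
            raise ValidationError(f"k_iqr must be > 0, got {self.k_iqr}")
        if self.min_users < 1:
            raise ValidationError(f"min_users must be >= 1, got {self.min_users}")
        if not 0 < self.or_lo < 1 < self.or_hi:
            raise ValidationError("need 0 < or_lo < 1 < or_hi")


@dataclass
class RunManifest:
    """Audit trail: config snapshot, stage dimension chain, timestamps."""

    config: dict = field(default_factory=dict)
    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    input_checksums: dict = field(default_factory=dict)
    started: float = field(default_factory=time.time)
    finished: float | None = None
    notes: list[str] = field(default_factory=list)

    def record(self, stage: str, shape_in: tuple, shape_out: tuple, **extra) -> None:
        self.stages.append(
            {
                "stage": stage,
                "probes_in": shape_in[0],
                "samples_in": shape_in[1],
                "probes_out": shape_out[0],
                "samples_out": shape_out[1],
                **extra,
            }
        )

    def note(self, text: str) -> None:
        self.notes.append(text)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def checksum_frame(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes())
    return h.hexdigest()[:16]


@dataclass
class DiscoveryOutput:
    expr: ExpressionMatrix  # preprocessed matrix actually analysed
    annot: pd.DataFrame
    med: pd.DataFrame
    probe_annot: pd.DataFrame
    adjustment_model: AdjustmentModel
    de_results: dict[str, DEResult]
    gene_results: dict[str, pd.DataFrame]
    summary: pd.DataFrame  # per substance: n significant, up/down, min q
    anova_summary: dict | None
    manifest: RunManifest
    skipped_substances: dict[str, str] = field(default_factory=dict)

    @property
    def analysed_genes(self) -> set[str]:
        genes = self.probe_annot["gene"].reindex(self.expr.probe_ids).dropna()
        return set(genes)


def preprocess_cohort(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    config: PipelineConfig,
    manifest: RunManifest,
) -> ExpressionMatrix:
    """QC/normalization/batch-adjustment stages shared by both cohorts."""
    shape = (expr.n_probes, expr.n_samples)

    if config.run_detection_filter and expr.detection_p is not None:
        pmask = detection_filter(expr, config.detection_alpha, config.detection_min_fraction)
        expr = expr.subset(probes=pmask.kept_ids)
        manifest.record("detection_filter", shape, (expr.n_probes, expr.n_samples),
                        removed=pmask.n_removed)
        shape = (expr.n_probes, expr.n_samples)
    elif config.run_detection_filter:
        manifest.note("detection filter skipped: no detection p-values")

    if config.run_quantile_normalize:
        if expr.scale != "raw":
            raise ValidationError("quantile normalization expects raw-scale values")
        expr = quantile_normalize(expr)
        manifest.record("quantile_normalize", shape, shape)

    if config.run_log2:
        expr = log2_transform(expr)
        manifest.record("log2_transform", shape, shape)

    if config.run_mahalanobis_qc:
        feats = [f for f in config.qc_features if f in annot.columns]
        if len(feats) >= 2:
            qmask = mahalanobis_qc(annot.loc[expr.sample_ids, feats], config.k_iqr)
            expr = expr.subset(samples=qmask.kept_ids)
            manifest.record("mahalanobis_qc", shape, (expr.n_probes, expr.n_samples),
                            removed=qmask.n_removed)
            shape = (expr.n_probes, expr.n_samples)
        else:
            manifest.note("Mahalanobis QC skipped: QC features not in annotation")

    if config.run_combat:
        batch = annot.loc[expr.sample_ids, "batch"]
        counts = batch.value_counts()
        singles = counts[counts < 2].index
        if len(singles):
            keep = expr.sample_ids[~batch.isin(singles)]
            expr = expr.subset(samples=keep)
            batch = annot.loc[expr.sample_ids, "batch"]
            manifest.record("drop_singleton_batches", shape,
                            (expr.n_probes, expr.n_samples), removed=len(singles))
            shape = (expr.n_probes, expr.n_samples)
        if batch.nunique() < 2:
            manifest.note("batch adjustment skipped: single batch")
        else:
            expr, _model = combat_adjust(expr, batch)
            manifest.record("combat_adjust", shape, shape)
            _, anova = batch_anova_check(expr, batch)
            manifest.note(
                "post-adjustment ANOVA fraction significant at 0.05: "
                f"{anova['fraction_significant_at_0.05']:.4f}"
            )

    if config.run_euclidean_filter:
        emask = euclidean_outlier_filter(expr, config.euclid_trim, config.k_iqr)
        expr = expr.subset(samples=emask.kept_ids)
        manifest.record("euclidean_outlier_filter", shape,
                        (expr.n_probes, expr.n_samples), removed=emask.n_removed)

    return expr


def discovery_pipeline(
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    med: pd.DataFrame,
    probe_annot: pd.DataFrame,
    config: PipelineConfig | None = None,
    adjustment_model: AdjustmentModel | None = None,
) -> DiscoveryOutput:
    """Full discovery analysis on one cohort.

    If ``adjustment_model`` is provided (replication use-case) the
    polymedication selection step is skipped and the given model reused.
    Zero significant findings is a valid outcome, not an error.
    """
    config = config or PipelineConfig()
    config.validate()
    manifest = RunManifest(config=asdict(config))
    manifest.input_checksums = {
        "expression": checksum_frame(expr.values),
        "medication": checksum_frame(med) if med.shape[1] else "",
    }

    expr = preprocess_cohort(expr, annot, config, manifest)

    # restrict tables to the analysis samples
    med = med.loc[expr.sample_ids]
    if adjustment_model is None:
        candidates = candidate_substances(med, config.min_prevalence)
        adjustment_model = select_adjustment_substances(
            expr, annot, med, candidates, fdr=config.fdr
        )
        manifest.note(
            f"adjustment model: {len(adjustment_model.substances)} of "
            f"{len(candidates)} candidates selected"
        )

    de_results: dict[str, DEResult] = {}
    gene_results: dict[str, pd.DataFrame] = {}
    skipped: dict[str, str] = {}
    for substance in med.columns:
        de = test_substance(
            expr, annot, med, substance, adjustment_model,
            probe_annot=probe_annot, min_users=config.min_users,
            or_lo=config.or_lo, or_hi=config.or_hi,
        )
        if de is None:
            skipped[substance] = f"fewer than {config.min_users} users"
            continue
        de_results[substance] = de
        gene_results[substance] = gene_level_summary(de, probe_annot, q_cut=config.fdr)

    summary = pd.DataFrame(
        [de.counts(config.fdr) for de in de_results.values()]
    )
    if not summary.empty:
        summary = summary.set_index("substance")

    anova_summary = None
    manifest.finished = time.time()
    return DiscoveryOutput(
        expr=expr,
        annot=annot.loc[expr.sample_ids],
        med=med,
        probe_annot=probe_annot,
        adjustment_model=adjustment_model,
        de_results=de_results,
        gene_results=gene_results,
        summary=summary,
        anova_summary=anova_summary,
        manifest=manifest,
        skipped_substances=skipped,
    )


@dataclass
class ReplicationOutput:
    replication: ReplicationResult
    sensitivity: pd.DataFrame
    nominal: pd.Series
    enrichment: pd.DataFrame | None
    manifest: RunManifest


def replication_pipeline(
    discovery: DiscoveryOutput,
    expr: ExpressionMatrix,
    annot: pd.DataFrame,
    med: pd.DataFrame,
    probe_annot: pd.DataFrame,
    config: PipelineConfig | None = None,
    gene_sets: GeneSetCollection | None = None,
) -> ReplicationOutput:
    """Replicate discovery hits in an independent cohort.

    Uses the discovery adjustment model (OR screen re-run per substance on
    the replication medication table inside ``test_substance``).
    """
    config = config or PipelineConfig()
    config.validate()
    manifest = RunManifest(config=asdict(config))
    expr = preprocess_cohort(expr, annot, config, manifest)
    med = med.loc[expr.sample_ids]

    rep_input = build_replication_input(
        discovery.de_results,
        replication_probes=expr.probe_ids,
        replication_substances=list(med.columns),
        q_cut=config.fdr,
    )
    if not rep_input.families:
        raise ValidationError(
            "no discovery-significant substance has probes available in the "
            "replication cohort"
        )
    result = hierarchical_replication(
        rep_input, expr, annot, med, discovery.adjustment_model,
        probe_annot=probe_annot, q_level=config.fdr,
        min_users=config.min_users, method=config.replication_method,
    )
    sensitivity = sensitivity_analysis(result.probe_table)
    nominal = nominal_replication(result.probe_table)

    enr = None
    if gene_sets is not None and result.gene_table is not None:
        genes = probe_annot["gene"].reindex(expr.probe_ids).dropna()
        background = set(genes)
        frames = []
        for substance, grp in result.gene_table.groupby("substance"):
            hits = set(grp.loc[grp["replicated"], "gene"]) & background
            frames.append(
                enrich_substance(hits, gene_sets, background,
                                 substance=substance, fdr=config.fdr)
            )
        enr = pd.concat([f for f in frames if not f.empty], ignore_index=True) if frames else None
        if enr is not None and not enr.empty:
            enr = deduplicate_pathways(enr)

    manifest.finished = time.time()
    return ReplicationOutput(
        replication=result,
        sensitivity=sensitivity,
        nominal=nominal,
        enrichment=enr,
        manifest=manifest,
    )
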