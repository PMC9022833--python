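"""Synthetic cohort generator.

Emulates the data structure of a population-based bead-array expression study:
a probe x sample intensity matrix with detection p-values, a sample annotation
table (sex, age, differential blood count, smoking, BMI, chip/batch id), a
binary sample x substance medication table with correlated co-medication, a
probe -> gene annotation, and a per-sample QC feature table with planted
failing samples. Ground truth (planted drug effects, QC outliers, expressed
probes) is returned alongside so recovery and calibration of every downstream
stage can be tested without any external data.

The generative model on the log2 scale is

    x_gi = baseline_g + sum_c beta_c z_ci + sum_d beta_true(d, g) m_di
           + gamma_{b(i), g} + sqrt(delta2_{b(i), g}) * eps_gi

with eps ~ N(0, noise_sd^2), per-batch location shifts gamma ~ N(0,
batch_location_sd^2) and per-batch scale factors delta2 drawn inverse-gamma
(mean 1) — the location/scale family assumed by empirical-Bayes batch
adjustment. Raw intensities are 2**x.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, ValidationError

__all__ = [
    "SubstanceSpec",
    "SimConfig",
    "TrueEffects",
    "generate_cohort",
    "assign_medication",
    "generate_qc_features",
]

#: per-unit log2 effects of the base covariates on affected probes
DEFAULT_COVARIATE_EFFECTS = {
    "sex": 0.10,
    "age": 0.005,
    "lymphocytes": 0.010,
    "monocytes": 0.020,
    "smoking": 0.10,
    "log_bmi": 0.20,
}


@dataclass
class SubstanceSpec:
    """One active substance: prevalence, planted expression effects, co-medication.

    ``effect_distribution`` is a (low, high) interval of log2-scale effect
    sizes; each affected probe gets a uniform draw from it. A
    ``comedication_partner`` declares a pairwise association (log odds ratio
    of joint intake) with another substance in the same cohort.
    """

    label: str
    prevalence: float
    n_affected_probes: int = 0
    effect_distribution: tuple[float, float] = (0.0, 0.0)
    #: explicit effect sizes cycled over the affected probes; overrides
    #: effect_distribution when given (e.g. [-0.45, 0.45] for balanced
    #: up/down regulation of fixed magnitude)
    effect_values: list[float] | None = None
    comedication_partner: str | None = None
    comedication_log_or: float = 0.0

    def validate(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValidationError(
                f"substance {self.label!r}: prevalence must be in (0, 1), "
                f"got {self.prevalence}"
            )
        lo, hi = self.effect_distribution
        if lo > hi:
            raise ValidationError(
                f"substance {self.label!r}: effect_distribution low > high"
            )
        if self.n_affected_probes < 0:
            raise ValidationError(
                f"substance {self.label!r}: n_affected_probes must be >= 0"
            )


@dataclass
class SimConfig:
    """Full description of a synthetic cohort; reproducible from ``seed``."""

    n_samples: int = 1000
    n_probes: int = 2000
    n_genes: int = 1600
    n_batches: int = 10
    substances: list[SubstanceSpec] = field(default_factory=list)
    covariate_effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    covariate_affected_fraction: float = 0.3
    noise_sd: float = 1.0
    batch_location_sd: float = 0.3
    batch_scale_shape: float = 25.0
    qc_outlier_fraction: float = 0.0
    control_fraction: float = 0.19
    expressed_fraction: float = 0.8
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    unexpressed_mean: float = 4.5
    seed: int = 0
    #: sample-level seed; None reuses ``seed``. Two configs with equal ``seed``
    #: but different ``sample_seed`` share probe structure and planted effects
    #: (the same biology) while drawing independent participants — the
    #: discovery/replication two-cohort design.
    sample_seed: int | None = None

    def validate(self) -> None:
        for name in ("n_samples", "n_probes", "n_genes", "n_batches"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_genes > self.n_probes:
            raise ValidationError(
                f"n_genes ({self.n_genes}) must be <= n_probes ({self.n_probes})"
            )
        if self.noise_sd <= 0:
            raise ValidationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.batch_scale_shape <= 0:
            raise ValidationError(
                f"batch_scale_shape must be > 0, got {self.batch_scale_shape}"
            )
        if not 0.0 <= self.qc_outlier_fraction < 1.0:
            raise ValidationError(
                "qc_outlier_fraction must be in [0, 1), "
                f"got {self.qc_outlier_fraction}"
            )
        if not 0.0 <= self.control_fraction < 1.0:
            raise ValidationError(
                f"control_fraction must be in [0, 1), got {self.control_fraction}"
            )
        if self.n_samples < 2 * self.n_batches:
            raise ValidationError(
                f"n_samples ({self.n_samples}) must allow >= 2 samples per batch "
                f"(n_batches = {self.n_batches})"
            )
        labels = [s.label for s in self.substances]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate substance labels")
        for s in self.substances:
            s.validate()
            if s.comedication_partner is not None:
                if s.comedication_partner not in labels:
                    raise ValidationError(
                        f"comedication partner {s.comedication_partner!r} of "
                        f"{s.label!r} is not a declared substance"
                    )
                if s.comedication_partner == s.label:
                    raise ValidationError(
                        f"substance {s.label!r} cannot be its own partner"
                    )

    def to_yaml(self) -> str:
        d = asdict(self)
        d["substances"] = [asdict(s) for s in self.substances]
        for s in d["substances"]:
            s["effect_distribution"] = list(s["effect_distribution"])
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        d = yaml.safe_load(text)
        subs = [
            SubstanceSpec(
                label=s["label"],
                prevalence=s["prevalence"],
                n_affected_probes=s.get("n_affected_probes", 0),
                effect_distribution=tuple(s.get("effect_distribution", (0.0, 0.0))),
                effect_values=s.get("effect_values"),
                comedication_partner=s.get("comedication_partner"),
                comedication_log_or=s.get("comedication_log_or", 0.0),
            )
            for s in d.pop("substances", [])
        ]
        return cls(substances=subs, **d)


@dataclass
class TrueEffects:
    """Ground truth emitted by the simulator for recovery/calibration tests."""

    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    qc_outlier: dict[str, bool] = field(default_factory=dict)
    expressed: dict[str, bool] = field(default_factory=dict)

    def effect_frame(self) -> pd.DataFrame:
        rows = [
            {"substance": sub, "probe": probe, "beta_true": beta}
            for (sub, probe), beta in self.effects.items()
        ]
        return pd.DataFrame(rows, columns=["substance", "probe", "beta_true"])


def _plackett_joint(a: float, b: float, log_or: float) -> float:
    """P(A=1, B=1) for given marginals and log odds ratio (Plackett 2x2 root)."""
    psi = float(np.exp(log_or))
    if abs(psi - 1.0) < 1e-12:
        return a * b
    s = 1.0 + (a + b) * (psi - 1.0)
    disc = s * s - 4.0 * psi * (psi - 1.0) * a * b
    p11 = (s - np.sqrt(disc)) / (2.0 * (psi - 1.0))
    lo, hi = max(0.0, a + b - 1.0), min(a, b)
    if not (lo - 1e-9 <= p11 <= hi + 1e-9):
        raise ValidationError(
            f"no joint distribution exists for marginals ({a:.3f}, {b:.3f}) "
            f"and log-OR {log_or:.3f}"
        )
    return float(np.clip(p11, lo, hi))


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Baseline covariates with plausible population moments."""
    sex = rng.integers(0, 2, size=n)
    age = np.clip(rng.normal(60.0, 12.0, size=n), 18.0, 90.0)
    lymphocytes = np.clip(rng.normal(30.0, 8.0, size=n), 2.0, 70.0)
    monocytes = np.clip(rng.normal(8.2, 2.1, size=n), 1.0, 20.0)
    smoking = (rng.random(n) < 0.2).astype(int)
    bmi = np.clip(rng.normal(27.5, 4.6, size=n), 15.0, 55.0)
    return pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "lymphocytes": lymphocytes,
            "monocytes": monocytes,
            "smoking": smoking,
            "bmi": bmi,
        },
        index=[f"S{i:05d}" for i in range(n)],
    )


def assign_medication(
    covariates: pd.DataFrame,
    specs: list[SubstanceSpec],
    seed: int,
    control_fraction: float = 0.19,
) -> pd.DataFrame:
    """Draw a binary sample x substance intake table.

    A ``control_fraction`` of samples is forced to zero intake (the
    no-medication control group); intake among the rest is rescaled so each
    substance's marginal frequency matches its spec prevalence. Declared
    co-medication pairs are drawn jointly from the 2x2 distribution with the
    requested marginals and odds ratio.
    """
    if not specs:
        raise ValidationError("specs must be non-empty")
    for s in specs:
        s.validate()
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate substance labels")

    rng = np.random.default_rng(seed)
    n = len(covariates)
    n_control = int(round(control_fraction * n))
    perm = rng.permutation(n)
    control_idx = perm[:n_control]
    user_idx = perm[n_control:]
    scale = 1.0 / (1.0 - control_fraction) if control_fraction > 0 else 1.0

    by_label = {s.label: s for s in specs}
    # each substance may appear in at most one declared pair
    pairs: list[tuple[SubstanceSpec, SubstanceSpec]] = []
    paired: set[str] = set()
    for s in specs:
        if s.comedication_partner is None:
            continue
        partner = by_label.get(s.comedication_partner)
        if partner is None:
            raise ValidationError(
                f"comedication partner {s.comedication_partner!r} not in specs"
            )
        if s.label in paired or partner.label in paired:
            raise ValidationError(
                f"substance {s.label!r} or {partner.label!r} declared in more "
                "than one comedication pair"
            )
        pairs.append((s, partner))
        paired.update((s.label, partner.label))

    med = pd.DataFrame(
        0, index=covariates.index, columns=labels, dtype=np.int8
    )
    m = len(user_idx)

    def adjusted(prev: float, label: str) -> float:
        p = prev * scale
        if p >= 1.0:
            raise ValidationError(
                f"substance {label!r}: prevalence {prev} is not achievable with "
                f"control fraction {control_fraction} (adjusted {p:.3f} >= 1)"
            )
        return p

    for s, partner in pairs:
        a = adjusted(s.prevalence, s.label)
        b = adjusted(partner.prevalence, partner.label)
        p11 = _plackett_joint(a, b, s.comedication_log_or)
        probs = [p11, a - p11, b - p11, 1.0 - a - b + p11]
        cells = rng.choice(4, size=m, p=probs)
        med.iloc[user_idx, med.columns.get_loc(s.label)] = np.isin(
            cells, [0, 1]
        ).astype(np.int8)
        med.iloc[user_idx, med.columns.get_loc(partner.label)] = np.isin(
            cells, [0, 2]
        ).astype(np.int8)
    for s in specs:
        if s.label in paired:
            continue
        p = adjusted(s.prevalence, s.label)
        med.iloc[user_idx, med.columns.get_loc(s.label)] = (
            rng.random(m) < p
        ).astype(np.int8)
    return med


#: QC feature means emulating bead-array control metrics (perfect-match /
#: mismatch controls, concentration controls, negative-control mean,
#: housekeeping mean, expressed-gene count, biotin signal, mean distance)
_QC_FEATURES = {
    "pm_mm_ratio": (12.0, 1.0),
    "concentration_control": (8.0, 0.8),
    "negative_control_mean": (4.0, 0.3),
    "housekeeping_mean": (11.0, 0.7),
    "n_expressed_genes": (15000.0, 800.0),
    "biotin_signal": (9.5, 0.6),
    "mean_euclidean_distance": (40.0, 4.0),
}


def generate_qc_features(
    n_samples: int,
    outlier_fraction: float,
    seed: int,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample QC feature table with planted multivariate outliers.

    Inliers are drawn from one multivariate normal (equicorrelated, rho=0.3);
    each planted outlier is shifted by 6-10 marginal SDs on one to three
    randomly chosen features. Returns the table and a boolean outlier flag
    per sample.
    """
    if not 0.0 <= outlier_fraction < 0.25:
        raise ValidationError(
            f"outlier_fraction must be in [0, 0.25), got {outlier_fraction}"
        )
    rng = np.random.default_rng(seed)
    names = list(_QC_FEATURES)
    means = np.array([_QC_FEATURES[f][0] for f in names])
    sds = np.array([_QC_FEATURES[f][1] for f in names])
    k = len(names)
    corr = np.full((k, k), 0.3)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sds, sds)
    x = rng.multivariate_normal(means, cov, size=n_samples, method="cholesky")

    n_out = int(round(outlier_fraction * n_samples))
    flags = np.zeros(n_samples, dtype=bool)
    if n_out:
        out_idx = rng.choice(n_samples, size=n_out, replace=False)
        flags[out_idx] = True
        for i in out_idx:
            n_feat = rng.integers(1, 4)
            feats = rng.choice(k, size=n_feat, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_feat)
            x[i, feats] += signs * rng.uniform(6.0, 10.0, size=n_feat) * sds[feats]

    table = pd.DataFrame(x, columns=names, index=[f"S{i:05d}" for i in range(n_samples)])
    return table, flags


def generate_cohort(
    config: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame, TrueEffects]:
    """Generate one synthetic cohort.

    Returns ``(expression, sample_annotation, medication, probe_annotation,
    truth)``. Expression is raw-scale (2**log2-signal) with detection
    p-values: Beta(0.5, 20) for expressed probes, Uniform(0, 1) for
    unexpressed ones. Batches are assigned by random permutation into
    near-equal groups, so every batch receives at least two samples.
    """
    config.validate()
    struct_root = np.random.SeedSequence(config.seed)
    (ss_probe,) = struct_root.spawn(1)
    sample_seed = config.seed if config.sample_seed is None else config.sample_seed
    sample_root = np.random.SeedSequence((sample_seed, 1))
    ss_cov, ss_med, ss_qc, ss_batch, ss_expr = sample_root.spawn(5)

    n, p = config.n_samples, config.n_probes
    rng_probe = np.random.default_rng(ss_probe)
    rng_batch = np.random.default_rng(ss_batch)
    rng_expr = np.random.default_rng(ss_expr)

    annot = _draw_covariates(n, np.random.default_rng(ss_cov))
    sample_ids = annot.index

    # batches: random permutation into near-equal groups
    batch = np.repeat(np.arange(config.n_batches), int(np.ceil(n / config.n_batches)))[:n]
    batch = batch[rng_batch.permutation(n)]
    annot["batch"] = [f"chip{b:03d}" for b in batch]

    med = (
        assign_medication(
            annot,
            config.substances,
            seed=int(ss_med.generate_state(1)[0] % (2**31)),
            control_fraction=config.control_fraction,
        )
        if config.substances
        else pd.DataFrame(index=sample_ids)
    )

    qc_seed = int(ss_qc.generate_state(1)[0] % (2**31))
    qc_table, qc_flags = generate_qc_features(n, config.qc_outlier_fraction, qc_seed)
    qc_table.index = sample_ids

    # probe -> gene annotation: genes get 1+ probes round-robin
    probe_ids = pd.Index([f"ILMN_{i:06d}" for i in range(p)])
    gene_ids = [f"GENE{i % config.n_genes:05d}" for i in range(p)]
    mapping_ok = rng_probe.random(p) < 0.95
    probe_annot = pd.DataFrame(
        {"gene": gene_ids, "mapping_ok": mapping_ok}, index=probe_ids
    )

    expressed = rng_probe.random(p) < config.expressed_fraction
    baseline = np.where(
        expressed,
        rng_probe.normal(config.baseline_mean, config.baseline_sd, size=p),
        rng_probe.normal(config.unexpressed_mean, 0.5, size=p),
    )

    truth = TrueEffects(
        qc_outlier=dict(zip(sample_ids, map(bool, qc_flags))),
        expressed=dict(zip(probe_ids, map(bool, expressed))),
    )

    signal = np.tile(baseline[:, None], (1, n))

    # covariate effects on random probe subsets
    design_cov = annot[["sex", "age", "lymphocytes", "monocytes", "smoking"]].copy()
    design_cov["log_bmi"] = np.log(annot["bmi"])
    for cov_name, eff in config.covariate_effect_sizes.items():
        if eff == 0.0 or cov_name not in design_cov:
            continue
        affected = rng_probe.random(p) < config.covariate_affected_fraction
        z = design_cov[cov_name].to_numpy(dtype=float)
        signal[affected] += eff * (z - z.mean())[None, :]

    # planted drug effects on expressed probes
    expressed_idx = np.flatnonzero(expressed)
    for spec in config.substances:
        if spec.n_affected_probes == 0:
            continue
        if spec.n_affected_probes > len(expressed_idx):
            raise ValidationError(
                f"substance {spec.label!r}: n_affected_probes exceeds number of "
                "expressed probes"
            )
        chosen = rng_probe.choice(
            expressed_idx, size=spec.n_affected_probes, replace=False
        )
        if spec.effect_values:
            reps = int(np.ceil(spec.n_affected_probes / len(spec.effect_values)))
            betas = np.tile(np.asarray(spec.effect_values, dtype=float), reps)[
                : spec.n_affected_probes
            ]
        else:
            lo, hi = spec.effect_distribution
            betas = (
                rng_probe.uniform(lo, hi, size=spec.n_affected_probes)
                if hi > lo
                else np.full(spec.n_affected_probes, lo)
            )
        intake = med[spec.label].to_numpy(dtype=float)
        for j, beta in zip(chosen, betas):
            if beta == 0.0:
                continue
            signal[j] += beta * intake
            truth.effects[(spec.label, probe_ids[j])] = float(beta)

    # batch location/scale effects (per batch, per probe)
    gamma = rng_batch.normal(0.0, config.batch_location_sd, size=(config.n_batches, p))
    shape = config.batch_scale_shape
    # inverse-gamma with mean 1: scale = shape - 1 (requires shape > 1)
    if shape > 1.0:
        delta2 = (shape - 1.0) / rng_batch.gamma(shape, 1.0, size=(config.n_batches, p))
    else:
        delta2 = 1.0 / rng_batch.gamma(shape, 1.0 / shape, size=(config.n_batches, p))
    if config.n_batches > 1:
        signal += gamma[batch].T
        noise_scale = np.sqrt(delta2[batch]).T
    else:
        noise_scale = np.ones((p, n))

    eps = rng_expr.normal(0.0, config.noise_sd, size=(p, n))
    log2_values = signal + noise_scale * eps

    detp = np.where(
        expressed[:, None],
        rng_expr.beta(0.5, 20.0, size=(p, n)),
        rng_expr.random((p, n)),
    )

    values = pd.DataFrame(2.0 ** log2_values, index=probe_ids, columns=sample_ids)
    detection = pd.DataFrame(detp, index=probe_ids, columns=sample_ids)
    expr = ExpressionMatrix(values=values, detection_p=detection, scale="raw")

    annot = annot.join(qc_table)
    return expr, annot, med, probe_annot, truth
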