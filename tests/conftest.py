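import numpy as np
import pandas as pd
import pytest

from pharmtx.simulate import SimConfig, SubstanceSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Modest cohort with two effect-carrying substances and one null substance."""
    subs = [
        SubstanceSpec("C07AG02", 0.15, 10, effect_values=[0.45]),
        SubstanceSpec("H02AB06", 0.10, 8, effect_values=[-0.75]),
        SubstanceSpec("B01AC06", 0.20, 0),
    ]
    cfg = SimConfig(
        n_samples=800, n_probes=600, n_genes=450, n_batches=5,
        substances=subs, seed=7,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_pair():
    """Two cohorts sharing planted effects (same structural seed, fresh samples)."""
    import dataclasses

    subs = [
        SubstanceSpec("C07AG02", 0.15, 12, effect_values=[0.45, -0.45]),
        SubstanceSpec("H02AB06", 0.10, 8, effect_values=[-0.75]),
        SubstanceSpec("B01AC06", 0.20, 0),
    ]
    cfg = SimConfig(
        n_samples=1500, n_probes=800, n_genes=600, n_batches=5,
        substances=subs, seed=7,
    )
    cfg2 = dataclasses.replace(cfg, sample_seed=99)
    return cfg, generate_cohort(cfg), generate_cohort(cfg2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_expression(values: np.ndarray, scale: str = "log2", detection=None):
    """Wrap a plain array as an ExpressionMatrix with generated ids."""
    from pharmtx.containers import ExpressionMatrix

    p, n = values.shape
    df = pd.DataFrame(
        values,
        index=[f"P{i:04d}" for i in range(p)],
        columns=[f"S{j:04d}" for j in range(n)],
    )
    det = None
    if detection is not None:
        det = pd.DataFrame(detection, index=df.index, columns=df.columns)
    return ExpressionMatrix(values=df, detection_p=det, scale=scale)
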