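import warnings

import numpy as np
import pandas as pd
import pytest

from irlpair.datagen import SimConfig, generate_cohort
from irlpair.io_formats import ExpressionMatrix, SurvivalTable
from irlpair.pipeline import PipelineConfig, run_on_cohort
from irlpair.studies import recovery_study


@pytest.fixture(scope="session")
def strong_cohort():
    """Default strong-effect cohort: 400 tumor / 50 normal, three planted
    pairs at log-HR 1.0."""
    return generate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def strong_result(strong_cohort):
    """Full pipeline output on the strong cohort, at scaled-down cycles."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_on_cohort(strong_cohort, PipelineConfig(n_cycles=100, min_freq=10, seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 120 tumor / 30 normal cohort for cheap end-to-end checks."""
    return generate_cohort(SimConfig(n_tumor=120, n_normal=30, seed=7))


@pytest.fixture(scope="session")
def recovery_frame():
    """Shared 20-seed recovery study (full pipeline per seed)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return recovery_study(n_seeds=20, base_seed=0, n_cycles=200)


def random_expression(n_genes, n_samples, seed, n_normal=0, prefix="G"):
    """Helper: random positive expression matrix with group labels."""
    rng = np.random.default_rng(seed)
    genes = [f"{prefix}{i:03d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    values = pd.DataFrame(rng.lognormal(1.0, 1.0, size=(n_genes, n_samples)), index=genes, columns=samples)
    groups = pd.Series(["normal"] * n_normal + ["tumor"] * (n_samples - n_normal), index=samples)
    return ExpressionMatrix(values, groups)


def random_survival(n, seed, censor_scale=2500.0):
    """Helper: exponential survival with independent censoring."""
    rng = np.random.default_rng(seed)
    patients = [f"P{i:04d}" for i in range(n)]
    t_event = rng.exponential(1000.0, size=n)
    t_cens = rng.exponential(censor_scale, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return SurvivalTable(pd.DataFrame({"time": time, "event": event}, index=pd.Index(patients, name="patient_id")))
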