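import numpy as np
import pandas as pd
import pytest

from vascsig import (
    CountMatrix,
    SyntheticConfig,
    assign_vascular_groups,
    build_cohort,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A light cohort: 60 samples, 12 with MRI, 300 genes, 10 signature genes."""
    return SyntheticConfig(
        n_samples=60,
        n_mri=12,
        n_genes=300,
        n_signature_genes=10,
        signature_logfc_range=(2.0, 3.0),
        frac_hv=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_cohort(small_config)


@pytest.fixture
def small_cohort(small_sim):
    counts, annotation, clinical, _ = small_sim
    cohort = build_cohort(counts, clinical, annotation)
    return assign_vascular_groups(cohort)


def toy_counts(values, gene_ids=None, sample_ids=None) -> CountMatrix:
    values = np.asarray(values)
    g, s = values.shape
    return CountMatrix(
        gene_ids=gene_ids or [f"g{i}" for i in range(g)],
        sample_ids=sample_ids or [f"s{i}" for i in range(s)],
        counts=values,
    )


def clinical_frame(sample_ids, os_days=None, event=None, age=None, rcbv=None):
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "patient_id": sample_ids,
            "os_days": os_days if os_days is not None else [100.0] * n,
            "event": event if event is not None else [1] * n,
            "age": age if age is not None else [60.0] * n,
            "rcbv_hat_median": rcbv if rcbv is not None else [np.nan] * n,
        }
    )
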