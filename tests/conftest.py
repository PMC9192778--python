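"""Shared fixtures: small synthetic cohorts generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dcistraj import preprocess, synthgen

SMALL_SIZES = {"basal": 80, "emt": 60, "proliferation": 60, "marker": 8}


def small_config(**overrides) -> synthgen.CohortConfig:
    base = dict(
        n_patients=40,
        lesions_range=(1, 15),
        lesions_mean=6.0,
        n_genes=800,
        program_sizes=dict(SMALL_SIZES),
        seed=11,
    )
    base.update(overrides)
    return synthgen.CohortConfig(**base).validate()


@pytest.fixture(scope="session")
def small_cohort():
    """A clean reduced-scale cohort (~450 samples x 800 genes)."""
    return synthgen.simulate_cohort(small_config())


@pytest.fixture(scope="session")
def small_cohort_bad():
    """Same cohort scale with 10% corrupted samples."""
    return synthgen.simulate_cohort(small_config(frac_low_quality=0.10))


@pytest.fixture(scope="session")
def small_expr(small_cohort):
    """Filtered log2-CPM matrix for the clean small cohort."""
    counts, meta, truth = small_cohort
    filtered = preprocess.filter_genes(counts)
    factors = preprocess.tmm_factors(filtered)
    return preprocess.log_cpm(filtered, factors)


@pytest.fixture()
def toy_counts() -> pd.DataFrame:
    rng = np.random.default_rng(5)
    x = rng.negative_binomial(5, 0.02, size=(50, 4)).astype(np.int64)
    return pd.DataFrame(
        x, index=[f"g{i:02d}" for i in range(50)], columns=["s1", "s2", "s3", "s4"]
    )
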