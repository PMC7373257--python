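import numpy as np
import pandas as pd
import pytest

from cafescore.config import GpsConfig, QcThresholds, SimulationConfig
from cafescore.simulate import simulate_dataset, simulate_genotypes

ZERO_EFFECTS = {k: 0.0 for k in (
    "healthy_purchasing_score", "total_items", "breakfast_time", "lunch_time",
    "skips_breakfast", "skips_lunch", "skips_dinner",
    "prepares_breakfast_home", "prepares_lunch_home", "prepares_dinner_home")}


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_participants=120, n_variants=200, n_blocks=40,
                            frac_causal=0.1, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_genotypes(small_dataset):
    return small_dataset.genotypes


@pytest.fixture(scope="session")
def qc_thresholds():
    return QcThresholds()


@pytest.fixture(scope="session")
def gps_config():
    return GpsConfig()


def toy_genotypes(dosage, chrom=None, pos=None, ids=None, freq=None, impq=None):
    """Build a GenotypeMatrix from a raw dosage array for hand-constructed tests."""
    from cafescore.genotypes import GenotypeMatrix

    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        f = np.nanmean(dosage, axis=0) / 2.0
    f = np.where(np.isnan(f), 0.5, f)
    variants = pd.DataFrame({
        "id": ids if ids is not None else [f"v{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else [1] * m,
        "pos": pos if pos is not None else (1 + 1000 * np.arange(m)),
        "a1": ["A"] * m, "a0": ["G"] * m,
        "freq": freq if freq is not None else f,
        "impq": impq if impq is not None else [1.0] * m,
    })
    return GenotypeMatrix(samples=[f"S{i:03d}" for i in range(n)],
                          variants=variants, dosage=dosage)
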