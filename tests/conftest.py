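import numpy as np
import pandas as pd
import pytest

import featsig as fs
from featsig import presets


@pytest.fixture(scope="session")
def catalog():
    return presets.reference_catalog()


@pytest.fixture(scope="session")
def apobec_cohort():
    """A small APOBEC-driven cohort shared across tests (seed-fixed)."""
    cfg = presets.scenario_config("apobec", n_samples=120,
                                  mutations_per_sample=1000, seed=7)
    return fs.simulate_cohort(cfg)


@pytest.fixture
def disjoint_profiles():
    """Two exact profiles with disjoint support, integer-friendly."""
    a = np.zeros(96)
    a[[0, 1, 2, 3]] = 0.25
    b = np.zeros(96)
    b[[10, 11, 12, 13]] = 0.25
    return a, b


def spectrum_from_counts(counts, sample_id="s"):
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    return fs.Spectrum96(sample_id, counts, n, n, eligible=n >= 50)


@pytest.fixture
def make_spectrum():
    return spectrum_from_counts


def set_from_counts(count_rows: dict[str, np.ndarray]) -> fs.SpectrumSet:
    counts = pd.DataFrame({sid: np.asarray(v, dtype=np.int64)
                           for sid, v in count_rows.items()}).T
    counts.columns = fs.CHANNELS
    counts.index.name = "sample_id"
    n = counts.sum(axis=1)
    meta = pd.DataFrame({"n_snv": n, "tmb": n, "eligible": n >= 50})
    return fs.SpectrumSet(counts=counts, meta=meta)


@pytest.fixture
def make_spectrum_set():
    return set_from_counts
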