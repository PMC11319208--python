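import numpy as np
import pytest

from hictopo.contacts import ContactMatrix, ice_normalize
from hictopo.genome import GenomeBins
from hictopo.synthetic import TruthSpec, simulate_cohort, simulate_contact_map


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def symmetric_random(n: int, rng, low: float = 0.5, high: float = 3.0) -> np.ndarray:
    a = rng.uniform(low, high, size=(n, n))
    return (a + a.T) / 2.0


def matrix_from_dense(dense: np.ndarray, chrom: str = "chr1",
                      bin_width: int = 10_000, **kw) -> ContactMatrix:
    n = dense.shape[0]
    bins = GenomeBins({chrom: n * bin_width}, bin_width)
    return ContactMatrix(bins, {chrom: np.asarray(dense, dtype=float)}, **kw)


@pytest.fixture(scope="session")
def small_spec():
    """Single 8-Mb chromosome, the workhorse problem size for planted tests."""
    return TruthSpec(chrom_lengths={"chr1": 8_000_000})


@pytest.fixture(scope="session")
def balanced_sample(small_spec):
    """One simulated sample (raw + balanced) with its planted truth."""
    raw, tads_truth, comp_truth = simulate_contact_map(small_spec, seed=11)
    return {
        "raw": raw,
        "balanced": ice_normalize(raw),
        "tads": tads_truth,
        "compartments": comp_truth,
    }


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """Six-sample cohort with matrices and omics (shared planted layouts)."""
    return simulate_cohort(6, small_spec, seed=4)
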