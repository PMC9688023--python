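import numpy as np
import pytest

from gptk.genotype_io import GenotypeMatrix, Marker
from gptk.simulate import SimConfig, simulate_dataset


def make_panel(dosage_rows, ids=None):
    """Build a GenotypeMatrix from a list of per-individual dosage rows."""
    d = np.array(dosage_rows, dtype=float)
    n, m = d.shape
    ids = ids or [f"s{i}" for i in range(n)]
    markers = [Marker(f"m{j}", "1", j + 1, "A", "B") for j in range(m)]
    return GenotypeMatrix(d, ids, markers)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated panel with a moderately heritable trait."""
    cfg = SimConfig(
        n_individuals=200,
        n_markers=300,
        n_chromosomes=5,
        n_qtl=40,
        heritability=0.5,
        n_reference=150,
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
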