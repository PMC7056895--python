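import numpy as np
import pytest

from dsplmf import synthetic
from dsplmf.datasets import CellLineDataset


@pytest.fixture(scope="session")
def micro() -> CellLineDataset:
    """The documented 6-cell-line x 4-drug hand-checkable cohort."""
    return synthetic.worked_micro_example()


@pytest.fixture(scope="session")
def planted():
    """Default planted cohort (60 x 10, rank 4, seed 0) with ground truth."""
    return synthetic.generate(synthetic.FixtureSpec())


def make_dataset(
    n=4, m=3, g_e=5, g_c=4, g_m=4, seed=0, ic50=None, mutation=None, cnv=None
) -> CellLineDataset:
    """Small hand-constructible dataset for unit tests."""
    rng = np.random.default_rng(seed)
    ds = CellLineDataset(
        cell_ids=[f"c{i}" for i in range(n)],
        drug_ids=[f"d{j}" for j in range(m)],
        expression=rng.normal(size=(n, g_e)),
        cnv=cnv if cnv is not None else rng.normal(size=(n, g_c)),
        mutation=mutation if mutation is not None else (rng.random((n, g_m)) < 0.3).astype(float),
        ic50=ic50 if ic50 is not None else rng.normal(size=(n, m)),
        fingerprints=(rng.random((m, 881)) < 0.1).astype(float),
    )
    ds.validate()
    return ds
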