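import numpy as np
import pandas as pd
import pytest

from pcenet.io import ExpressionMatrix, TraitTable
from pcenet.simulate import SyntheticConfig, generate_dataset


@pytest.fixture
def tiny_counts(tmp_path):
    """3-protein x 2-sample spectral-count TSV."""
    path = tmp_path / "counts.tsv"
    path.write_text(
        "protein\tS1\tS2\nP1\t4\t0\nP2\t2\t2\nP3\t0\t8\n", encoding="utf-8"
    )
    return path


@pytest.fixture
def cohort_traits():
    """7 + 8 two-class design with complementary subtype indicators."""
    samples = [f"S{i}" for i in range(15)]
    x = np.array([1] * 7 + [0] * 8)
    return TraitTable(pd.DataFrame({"SqCC": x, "PPA": 1 - x}, index=samples))


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted dataset shared by recovery-style tests."""
    cfg = SyntheticConfig(
        n_proteins=600,
        n_modules=10,
        module_size_range=(15, 100),
        n_trait_modules=2,
        background_fraction=0.1,
        seed=11,
    )
    return cfg, *generate_dataset(cfg)


def random_expression(rng, n_proteins=12, n_samples=15, prefix="P"):
    data = rng.integers(0, 50, size=(n_proteins, n_samples)).astype(float)
    data += rng.random(data.shape)  # break ties / zero variance
    return ExpressionMatrix(
        pd.DataFrame(
            data,
            index=[f"{prefix}{i}" for i in range(n_proteins)],
            columns=[f"S{j}" for j in range(n_samples)],
        )
    )
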