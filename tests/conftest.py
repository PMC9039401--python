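import numpy as np
import pandas as pd
import pytest

from mirmodulenet.io_expression import ExpressionDataset, PairedOmicsDataset
from mirmodulenet.synthetic import SyntheticConfig, generate


@pytest.fixture
def tiny_expression() -> ExpressionDataset:
    """3 features x 4 samples, hand-written values."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0], [2.0, 2.0, 2.0, 2.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionDataset(df, "mRNA")


@pytest.fixture
def small_paired() -> PairedOmicsDataset:
    """Deterministic 20-sample paired dataset with one planted driver."""
    rng = np.random.default_rng(7)
    n = 20
    labels = pd.Series(
        np.array([1] * 12 + [0] * 8, dtype=np.int8),
        index=[f"s{i:02d}" for i in range(n)],
        name="label",
    )
    driver = rng.normal(size=n) + 2.0 * labels.to_numpy()
    mirna = pd.DataFrame(
        {
            "miR-driver": driver,
            "miR-noise1": rng.normal(size=n),
            "miR-noise2": rng.normal(size=n),
        }
    ).T
    mirna.columns = labels.index
    targets = {
        f"gene-t{j}": -0.8 * driver + 0.3 * rng.normal(size=n) for j in range(3)
    }
    targets.update({f"gene-n{j}": rng.normal(size=n) for j in range(4)})
    mrna = pd.DataFrame(targets).T
    mrna.columns = labels.index
    return PairedOmicsDataset(
        ExpressionDataset(mirna, "miRNA"), ExpressionDataset(mrna, "mRNA"), labels
    )


@pytest.fixture(scope="session")
def default_synthetic():
    """One dataset at the generator's default study conditions."""
    return generate(SyntheticConfig(seed=11))
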