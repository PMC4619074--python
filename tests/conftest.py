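import numpy as np
import pandas as pd
import pytest

from micnet import CohortSpec, OmicsBlock, generate_cohort, reduced_spec
from micnet.pipeline import fuse_cohort


@pytest.fixture(scope="session")
def reduced_cohort():
    return generate_cohort(reduced_spec(seed=3))


@pytest.fixture(scope="session")
def fused_reduced(reduced_cohort):
    fused, qc = fuse_cohort(reduced_cohort)
    return fused


@pytest.fixture(scope="session")
def full_cohort():
    """Study-scale cohort (1505 CpG / 800 miRNA / 84 genes, 46 samples)."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture()
def count_block():
    """Tiny miRNA-style block: 2 target rows, 2 positive and 4 negative controls."""
    samples = ["s1", "s2"]
    values = pd.DataFrame(
        [[10.0, 40.0], [2.0, 20.0],
         [100.0, 400.0], [100.0, 400.0],
         [1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]],
        index=["t1", "t2", "p1", "p2", "n1", "n2", "n3", "n4"], columns=samples)
    meta = pd.DataFrame(
        {"control_role": ["none", "none", "positive", "positive",
                          "negative", "negative", "negative", "negative"]},
        index=values.index)
    return OmicsBlock("mirna", values, meta)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
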