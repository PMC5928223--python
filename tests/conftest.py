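import numpy as np
import pandas as pd
import pytest

from lipotaste import (
    BlockSet,
    CohortSpec,
    build_concentration_series,
    generate_cohort,
)


@pytest.fixture(scope="session")
def series():
    return build_concentration_series(0.00028, 0.25, 18)


@pytest.fixture(scope="session")
def cohort():
    """Default-sized cohort (21 NW + 17 O) with the default planted effects."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def fitted(cohort):
    from lipotaste import MBPLS

    return MBPLS(cohort.blocks, cohort.group_taste.to_numpy(), n_components=2).fit()


def random_blockset(rng, n=None, n_blocks=None, max_vars=8):
    """A random BlockSet for property checks."""
    n = int(rng.integers(8, 30)) if n is None else n
    n_blocks = int(rng.integers(2, 5)) if n_blocks is None else n_blocks
    mats = {}
    for b in range(n_blocks):
        p = int(rng.integers(1, max_vars))
        mats[f"B{b}"] = pd.DataFrame(
            rng.normal(size=(n, p)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"B{b}v{j}" for j in range(p)],
        )
    return BlockSet(mats)


def random_two_class_labels(rng, n):
    y = rng.integers(0, 2, n)
    while len(np.unique(y)) < 2:
        y = rng.integers(0, 2, n)
    return y
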