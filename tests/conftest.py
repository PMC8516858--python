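import logging

import numpy as np
import pytest

from ballmoss.landscape import LandscapeGrid, Tree

logging.getLogger("ballmoss").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def one_tree_grid():
    """A 20 x 20 m landscape with a single central tree (crown 2 m)."""
    return LandscapeGrid((20.0, 20.0), [Tree(0, 10.0, 10.0, 20.0, 6.0, 2.0)])


def make_sample(genotypes, subpop, coords=None, mlg=None, mll=None):
    from ballmoss.sumstats import SampleMatrix

    return SampleMatrix(
        np.asarray(genotypes, dtype=np.int16),
        np.asarray(subpop),
        coords=None if coords is None else np.asarray(coords, float),
        mlg=None if mlg is None else np.asarray(mlg),
        mll=None if mll is None else np.asarray(mll),
    )
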