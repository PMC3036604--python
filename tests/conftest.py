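import numpy as np
import pytest

from phorescreen.pharmacophore import FeatureKind
from phorescreen import synthdata

PLANTED_KINDS = [FeatureKind.HBD] + [FeatureKind.HBIC] * 4
PLANTED_MULTISET = ("HBD", "HBic", "HBic", "HBic", "HBic")


@pytest.fixture()
def truth5():
    """The planted five-feature model: one donor plus four hydrophobes."""
    return synthdata.make_pharmacophore(5, kinds=PLANTED_KINDS, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
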