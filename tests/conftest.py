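import numpy as np
import pytest
from hypothesis import settings

from tetramap import Locus, MarkerMap, SporeRecord, Tetrad

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture
def chr3_map() -> MarkerMap:
    """Two adjacent 0.2-Morgan intervals on one chromosome."""
    return MarkerMap(
        [Locus("A", "III", 0.0), Locus("B", "III", 0.2), Locus("C", "III", 0.4)]
    )


@pytest.fixture
def two_locus_map() -> MarkerMap:
    return MarkerMap([Locus("A", "III", 0.0), Locus("B", "III", 0.2)])


def make_tetrad(calls_per_spore, tetrad_id="t1", viable=None):
    """Build a tetrad from per-spore call strings, e.g. ("PP", "PM", "MP", "MM")."""
    if viable is None:
        viable = [True] * 4
    spores = tuple(
        SporeRecord(spore_id=f"{tetrad_id}.{i + 1}", viable=v, calls=tuple(c))
        for i, (c, v) in enumerate(zip(calls_per_spore, viable))
    )
    return Tetrad(tetrad_id=tetrad_id, spores=spores)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
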