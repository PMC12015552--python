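import numpy as np
import pytest
from hypothesis import settings

from cytopoly.band_model import ARMS, BandOrder
from cytopoly.population_io import (
    GenotypeCombination,
    LarvaKaryotype,
    PopulationSample,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_larva(larva_id, genotypes=None, b=0):
    """Larva from a compact {arm: "i.j"} spec; unspecified arms are 1.1."""
    genotypes = genotypes or {}
    combos = {
        arm: GenotypeCombination.parse(arm, genotypes.get(arm, "1.1")) for arm in ARMS
    }
    return LarvaKaryotype(larva_id=larva_id, combinations=combos, b_chromosome_count=b)


def make_sample(locality, rows, region=None, dates=None):
    """Population from a list of {arm: "i.j"} specs."""
    larvae = [make_larva(f"{locality}-{k}", row) for k, row in enumerate(rows)]
    return PopulationSample(
        locality=locality, larvae=larvae, region=region, dates=dates or []
    )


def perm_of(order: BandOrder, reference: BandOrder):
    """Signed-integer reading of ``order`` relative to ``reference`` (for oracles)."""
    index = {s.label: (k + 1, s.orientation) for k, s in enumerate(reference.segments)}
    return tuple(
        index[s.label][0] * (1 if s.orientation == index[s.label][1] else -1)
        for s in order.segments
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
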