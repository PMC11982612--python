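import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import xover as xo

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def make_tiny_map():
    """Two chromosomes, 4 + 3 markers, with centromeres."""
    table = pd.DataFrame({
        "marker": ["c1m1", "c1m2", "c1m3", "c1m4", "c2m1", "c2m2", "c2m3"],
        "chrom": ["chr1"] * 4 + ["chr2"] * 3,
        "pos_bp": [0, 1_000_000, 3_000_000, 6_000_000,
                   0, 2_000_000, 5_000_000],
    })
    return xo.MarkerMap(table,
                        chrom_lengths={"chr1": 6_000_000, "chr2": 5_000_000},
                        centromeres={"chr1": (2_500_000, 3_500_000),
                                     "chr2": (2_200_000, 2_800_000)})


@pytest.fixture
def tiny_map():
    return make_tiny_map()


@pytest.fixture
def tiny_genotypes(tiny_map):
    calls = pd.DataFrame(
        [[0, 0, 1, 1, 0, 0, 0],   # 1 crossover on chr1
         [0, 1, 1, 0, 1, 1, 1],   # 2 crossovers on chr1
         [0, 1, 0, 1, 0, 1, 0]],  # 3 on chr1, 2 on chr2
        index=["i1", "i2", "i3"], columns=tiny_map.marker_ids,
        dtype=np.int8)
    return xo.GenotypeMatrix(calls)


def simulate_called(n_individuals, preset="flat", nu=1.0, n_intervals=40,
                    seed=0, n_chromosomes=10, genetic_length=1.0):
    """Simulate, call, and return (marker_map, genotypes, events)."""
    chroms = xo.default_chromosomes(n_chromosomes, genetic_length, 25e6,
                                    preset)
    mm = xo.uniform_marker_map(chroms, n_intervals=n_intervals)
    cfg = xo.SimulationConfig(chroms, n_individuals,
                              interference_shape=nu, seed=seed)
    gm, truths = xo.simulate_population(cfg, mm)
    return mm, gm, xo.call_crossovers(gm, mm), truths


@pytest.fixture(scope="session")
def flat_population():
    """A moderately sized no-interference population shared across tests."""
    chroms = xo.default_chromosomes(10, 1.0, 25e6, "flat")
    mm = xo.uniform_marker_map(chroms, n_intervals=40)
    cfg = xo.SimulationConfig(chroms, 300, seed=1234)
    gm, truths = xo.simulate_population(cfg, mm)
    events = xo.call_crossovers(gm, mm)
    return mm, gm, events, truths
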