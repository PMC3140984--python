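import itertools

import numpy as np
import pandas as pd
import pytest

import ailepi as ai

GENOS = ("LL", "HL", "HH")


@pytest.fixture(scope="session")
def small_spec():
    return ai.PedigreeSpec(hws_males=3, lws_females=4, lws_males=3, hws_females=4,
                           generation_sizes=(20, 30, 40))


@pytest.fixture(scope="session")
def small_map():
    return ai.default_marker_map(markers_per_segment=3,
                                 segments=ai.synthetic_ail.DEFAULT_SEGMENTS[:3])


@pytest.fixture(scope="session")
def small_sim(small_spec, small_map):
    """Small simulated dataset: pedigree, map, contrasts, phenotypes, arch."""
    return ai.simulate_dataset(preset="additive3", spec=small_spec,
                               marker_map=small_map, noise_sd=50.0, seed=11)


def enumerated_calls(loci, reps=1, index_prefix="i"):
    """Genotype matrix enumerating all 3^L combinations, `reps` copies each."""
    combos = list(itertools.product(GENOS, repeat=len(loci))) * reps
    idx = [f"{index_prefix}{k}" for k in range(len(combos))]
    return pd.DataFrame(combos, columns=list(loci), index=idx)


@pytest.fixture
def enumerated_pair():
    return enumerated_calls(["L1", "L2"], reps=3)


@pytest.fixture
def enumerated_triplet():
    return enumerated_calls(["L1", "L2", "L3"], reps=3)
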