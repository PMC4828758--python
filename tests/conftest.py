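"""Shared fixtures: small deterministic simulations reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from smallrna import annotate, preprocess
from smallrna.simdata import SimConfig, simulate_library


def reads_from_sim(sim):
    return [
        preprocess.SmallRNARead(i, s, tuple(ord(c) - 33 for c in q))
        for i, s, q in sim.reads
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def small_clean_sim():
    """Noise-free 8k-read library: every insert is exactly its truth insert."""
    cfg = SimConfig(rng_seed=1, n_reads=8000, error_rate=0.0)
    return simulate_library(cfg)


@pytest.fixture(scope="session")
def small_clean_preprocessed(small_clean_sim):
    res = preprocess.run(reads_from_sim(small_clean_sim), small_clean_sim.config.adapter3)
    return small_clean_sim, res


@pytest.fixture(scope="session")
def small_clean_classified(small_clean_preprocessed):
    sim, res = small_clean_preprocessed
    ref_sets = dict(sim.ncrna_refs)
    ref_sets["mature"] = sim.mature_refs(known_only=False)
    result = annotate.classify(res.tags, sim.genome, ref_sets)
    return sim, res, result
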