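"""Shared fixtures: randomized de Bruijn graph instances.

The random suite draws genome lengths log-uniformly (so small, dense
graphs and large, sparse ones are both represented), k uniformly over
the supported range above 2, and alternates strand models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from simplitig import (
    KmerSet,
    Representation,
    StrandModel,
    build_kmer_set,
    compute_simplitigs,
    compute_unitigs,
    random_genome,
)


@dataclass
class Instance:
    genome: str
    kmer_set: KmerSet
    simplitigs: Representation
    unitigs: Representation


def make_instances(
    seed: int,
    n_instances: int,
    log10_g_range: tuple[float, float] = (2.0, 5.0),
    k_range: tuple[int, int] = (3, 32),
) -> list[Instance]:
    rng = np.random.default_rng(seed)
    out: list[Instance] = []
    while len(out) < n_instances:
        g_len = int(round(10 ** rng.uniform(*log10_g_range)))
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        model = StrandModel.UNI if len(out) % 2 == 0 else StrandModel.BI
        genome = random_genome(g_len, int(rng.integers(0, 2**31)))
        kmer_set = build_kmer_set([genome], k, model)
        if not len(kmer_set):
            continue
        out.append(
            Instance(
                genome=genome,
                kmer_set=kmer_set,
                simplitigs=compute_simplitigs(kmer_set),
                unitigs=compute_unitigs(kmer_set),
            )
        )
    return out


@pytest.fixture(scope="session")
def small_random_suite() -> list[Instance]:
    """A quick 40-instance suite for module-level property tests."""
    return make_instances(seed=11, n_instances=40, log10_g_range=(2.0, 3.8))
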