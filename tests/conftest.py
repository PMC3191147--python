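from __future__ import annotations

import numpy as np
import pytest

from mmsdk import (
    SimulationConfig,
    build_count_matrix,
    map_tags,
    simulate_dataset,
)
from mmsdk.tag_processing import TagRead


@pytest.fixture(scope="session")
def dataset():
    """Default-design synthetic dataset: 2 tissues x (2 clones + 2 controls)."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def mapped(dataset):
    """Reads of the session dataset mapped back to its virtual library."""
    reads = [
        TagRead(f"{lib}.{i}", s, lib)
        for lib, seqs in sorted(dataset.reads.items())
        for i, s in enumerate(seqs)
    ]
    assignments = map_tags(reads, dataset.library, seed=5)
    lib_ids = sorted(dataset.reads)
    high = build_count_matrix(assignments, "high",
                              site_ids=dataset.truth.site_ids,
                              library_ids=lib_ids)
    low = build_count_matrix(assignments, "low",
                             site_ids=dataset.truth.site_ids,
                             library_ids=lib_ids)
    return {"reads": reads, "assignments": assignments,
            "high": high, "low": low}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
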