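from __future__ import annotations

import numpy as np
import pytest

from orthokmeans import ProteinRecord, ProteinRegistry


def make_registry(rows) -> ProteinRegistry:
    """Build a registry from ``(id, species[, group])`` tuples."""
    records = []
    for row in rows:
        pid, species, *rest = row
        group = rest[0] if rest else None
        records.append(ProteinRecord(id=pid, species=species, group=group))
    return ProteinRegistry(records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_registry():
    """Two species, one shared group and one species-private group."""
    return make_registry(
        [
            ("a1", "spaa", "G1"),
            ("a2", "spaa", "G1"),
            ("b1", "spab", "G1"),
            ("a3", "spaa", "G2"),
            ("a4", "spaa", "G2"),
        ]
    )


def random_partition_pair(rng, n_items, max_groups=5, max_clusters=5):
    """Two random partitions over the same ids, as id->label dicts."""
    ids = [f"p{i}" for i in range(n_items)]
    ref = {pid: f"G{rng.integers(max_groups)}" for pid in ids}
    pred = {pid: int(rng.integers(max_clusters)) for pid in ids}
    return ref, pred
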