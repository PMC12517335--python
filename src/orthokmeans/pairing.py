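"""Extract ortholog predictions from clusters.

Two pair-extraction modes operate on each *eligible* cluster — one with at
least two members spanning at least two species (single-species clusters
would only yield paralogs, and singletons yield nothing):

* naive pairing (``all``): every cross-species pair of members is predicted
  as an ortholog pair;
* distance-based pairing (``top``): only the member closest to the cluster
  centroid, paired with the closest member of a different species.

Candidate 1:1 orthologous groups are clusters whose size equals the number
of studied species S; by default they must additionally contain exactly one
protein per species (a size-S single-species cluster cannot be a 1:1 group),
with ``strict=False`` restoring the literal size-only filter.

All ties on centroid distance break toward the lexicographically smaller
protein id, and pairs are canonicalized smaller-id-first, so outputs are
deterministic across platforms.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .cluster import ClusterModel
from .core_io import ProteinRecord, ProteinRegistry
from .errors import ParameterError

MODE_TOP = "top"
MODE_ALL = "all"


class PairSet:
    """Set of unordered cross-species protein-id pairs with provenance.

    Each pair maps to ``(label, mode)`` — the cluster (or reference group)
    it came from and the extraction mode. Pairs are stored canonicalized
    (lexicographically smaller id first); re-adding an existing pair keeps
    the first provenance.
    """

    def __init__(self) -> None:
        self._pairs: dict[tuple[str, str], tuple[object, str]] = {}

    @staticmethod
    def canonical(id_a: str, id_b: str) -> tuple[str, str]:
        if id_a == id_b:
            raise ParameterError(f"self-pair not allowed: {id_a!r}")
        return (id_a, id_b) if id_a < id_b else (id_b, id_a)

    def add(self, id_a: str, id_b: str, label: object, mode: str) -> None:
        key = self.canonical(id_a, id_b)
        self._pairs.setdefault(key, (label, mode))

    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._pairs)

    def items(self):
        return self._pairs.items()

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self._pairs or (pair[1], pair[0]) in self._pairs

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._pairs)

    def __le__(self, other: "PairSet") -> bool:
        return self.pairs <= other.pairs


def eligible_clusters(model: ClusterModel, registry: ProteinRegistry) -> list[int]:
    """Clusters with >= 2 members spanning >= 2 species, in label order."""
    if len(registry) != model.labels.shape[0]:
        raise ParameterError(
            f"registry has {len(registry)} proteins but model labels "
            f"{model.labels.shape[0]}"
        )
    species = [rec.species for rec in registry]
    seen: dict[int, set[str]] = {}
    counts: dict[int, int] = {}
    for lab, sp in zip(model.labels, species):
        lab = int(lab)
        seen.setdefault(lab, set()).add(sp)
        counts[lab] = counts.get(lab, 0) + 1
    return sorted(
        lab for lab in counts if counts[lab] >= 2 and len(seen[lab]) >= 2
    )


def naive_pairs(members: Sequence[ProteinRecord]) -> set[tuple[str, str]]:
    """All cross-species unordered pairs among the given cluster members."""
    out: set[tuple[str, str]] = set()
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            if a.species != b.species:
                out.add(PairSet.canonical(a.id, b.id))
    return out


def top_pair(
    members: Sequence[ProteinRecord], distances: Sequence[float]
) -> tuple[str, str] | None:
    """Distance-based pair: centroid-closest member + closest other-species.

    Returns ``None`` when no cross-species partner exists (never the case
    for an eligible cluster). Distance ties break on lexicographic id.
    """
    if len(members) != len(distances):
        raise ParameterError("members and distances must align")
    order = sorted(range(len(members)), key=lambda i: (distances[i], members[i].id))
    first = members[order[0]]
    for i in order[1:]:
        if members[i].species != first.species:
            return PairSet.canonical(first.id, members[i].id)
    return None


def extract_pairs(
    model: ClusterModel, registry: ProteinRegistry, mode: str = MODE_TOP
) -> PairSet:
    """Predicted ortholog pairs over all eligible clusters of a model."""
    if mode not in (MODE_TOP, MODE_ALL):
        raise ParameterError(f"mode must be '{MODE_TOP}' or '{MODE_ALL}', got {mode!r}")
    ps = PairSet()
    for lab in eligible_clusters(model, registry):
        idx = model.members(lab)
        members = [registry[int(i)] for i in idx]
        if mode == MODE_ALL:
            for a, b in sorted(naive_pairs(members)):
                ps.add(a, b, lab, MODE_ALL)
        else:
            pair = top_pair(members, [float(model.distances[i]) for i in idx])
            if pair is not None:
                ps.add(pair[0], pair[1], lab, MODE_TOP)
    return ps


def extract_one_to_one(
    model: ClusterModel,
    registry: ProteinRegistry,
    n_species: int | None = None,
    strict: bool = True,
) -> list[frozenset[str]]:
    """Candidate 1:1 orthologous groups: clusters of size S.

    With ``strict`` (default) a candidate must contain exactly one protein
    from each of the S studied species; with ``strict=False`` only the size
    filter applies.
    """
    S = registry.n_species if n_species is None else n_species
    if S < 2:
        raise ParameterError(f"need at least 2 species, got {S}")
    out: list[frozenset[str]] = []
    for lab in range(model.k):
        idx = model.members(lab)
        if len(idx) != S:
            continue
        members = [registry[int(i)] for i in idx]
        if strict:
            if len({m.species for m in members}) != S:
                continue
        out.append(frozenset(m.id for m in members))
    return out
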