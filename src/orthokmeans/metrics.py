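"""Evaluation of predicted pairs and groups against reference groups.

Pair-level metrics (for n:m ortholog retrieval, in percent):

* precision  = 100 * correct / retrieved,
* sensitivity = 100 * correct / reference-pair count,
* F1 = 2 / (precision^-1 + sensitivity^-1),

where a correct pair is one that also appears in the reference pair set
(all cross-species pairs inside each reference orthologous group; groups
that are 1:1 — exactly one protein per studied species — are excluded from
the reference by default, since n:m and 1:1 orthology are disjoint notions
here). Undefined quantities (e.g. precision with zero predictions) are
reported as ``None``.

Group-level metrics compare the predicted clustering with the reference
partition:

* family completeness: sum over reference groups of the largest number of
  members sharing one cluster, divided by the total protein count T;
* adjusted mutual information (AMI, arithmetic normalization) — the
  chance-corrected agreement between the two partitions;
* exact-match percentage: share of predicted clusters whose member set
  equals some reference group exactly.

All percent values are kept at full precision internally and rounded
half-even to 3 significant figures only when serialized into a report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Hashable, Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_mutual_info_score

from .core_io import ProteinRegistry
from .errors import CoverageError, EmptyInputError, UnknownIdError
from .pairing import PairSet, naive_pairs

Partition = Mapping[str, Hashable]


def round_sig(x: float | None, sig: int = 3) -> float | None:
    """Round half-even to ``sig`` significant figures (None passes through)."""
    if x is None:
        return None
    x = float(x)
    if x == 0 or not math.isfinite(x):
        return x
    shift = sig - 1 - math.floor(math.log10(abs(x)))
    quantum = Decimal(1).scaleb(-shift)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_EVEN))


def f1_from_rates(precision: float | None, sensitivity: float | None) -> float | None:
    """Harmonic mean of precision and sensitivity; None when undefined.

    Undefined when either input is None or zero (the harmonic mean has no
    finite value there), mirroring the empty-prediction sentinel.
    """
    if precision is None or sensitivity is None:
        return None
    if precision == 0 or sensitivity == 0:
        return None
    return 2.0 / (1.0 / precision + 1.0 / sensitivity)


# ---------------------------------------------------------------------------
# pair-level evaluation
# ---------------------------------------------------------------------------


@dataclass
class PairEvalReport:
    """Precision/sensitivity/F1 of a predicted pair (or 1:1 group) set."""

    n_predicted: int
    n_reference: int
    n_correct: int
    precision: float | None
    sensitivity: float | None
    f1: float | None

    @classmethod
    def from_counts(
        cls, n_predicted: int, n_reference: int, n_correct: int
    ) -> "PairEvalReport":
        precision = 100.0 * n_correct / n_predicted if n_predicted > 0 else None
        sensitivity = 100.0 * n_correct / n_reference if n_reference > 0 else None
        return cls(
            n_predicted=n_predicted,
            n_reference=n_reference,
            n_correct=n_correct,
            precision=precision,
            sensitivity=sensitivity,
            f1=f1_from_rates(precision, sensitivity),
        )

    def to_dict(self, sig: int = 3) -> dict:
        return {
            "n_predicted": self.n_predicted,
            "n_reference": self.n_reference,
            "n_correct": self.n_correct,
            "precision": round_sig(self.precision, sig),
            "sensitivity": round_sig(self.sensitivity, sig),
            "f1": round_sig(self.f1, sig),
        }


def is_one_to_one_group(members, species_set: frozenset[str]) -> bool:
    """True iff the group has exactly one protein from every studied species."""
    species = [m.species for m in members]
    return len(species) == len(species_set) and set(species) == set(species_set)


def reference_nm_pairs(
    registry: ProteinRegistry, exclude_one_to_one: bool = True
) -> PairSet:
    """Reference n:m ortholog pairs: cross-species pairs within each group.

    Every protein must carry a reference group (assign singleton groups
    first). Groups that are 1:1 over the registry's species set are skipped
    unless ``exclude_one_to_one=False``.
    """
    try:
        registry.partition()
    except UnknownIdError as exc:
        raise UnknownIdError(
            f"{exc} — ungrouped proteins must be given private singleton groups "
            "before building the reference pair set"
        ) from exc
    species_set = registry.species_set
    by_group: dict[str, list] = {}
    for rec in registry:
        by_group.setdefault(rec.group, []).append(rec)
    ps = PairSet()
    for label, members in by_group.items():
        if exclude_one_to_one and is_one_to_one_group(members, species_set):
            continue
        for a, b in sorted(naive_pairs(members)):
            ps.add(a, b, label, "reference")
    return ps


def pair_scores(predicted: PairSet, reference: PairSet) -> PairEvalReport:
    """Score a predicted pair set against the reference pair set."""
    n_correct = len(predicted.pairs & reference.pairs)
    return PairEvalReport.from_counts(len(predicted), len(reference), n_correct)


def reference_one_to_one_groups(registry: ProteinRegistry) -> set[frozenset[str]]:
    """Reference 1:1 groups: exactly one protein from each studied species."""
    registry.partition()
    species_set = registry.species_set
    by_group: dict[str, list] = {}
    for rec in registry:
        by_group.setdefault(rec.group, []).append(rec)
    return {
        frozenset(m.id for m in members)
        for members in by_group.values()
        if is_one_to_one_group(members, species_set)
    }


def one_to_one_scores(
    predicted_groups: Sequence[frozenset[str]], registry: ProteinRegistry
) -> PairEvalReport:
    """Group-level 1:1 evaluation: a prediction is correct iff its member
    set equals a reference 1:1 group exactly."""
    reference = reference_one_to_one_groups(registry)
    predicted = {frozenset(g) for g in predicted_groups}
    n_correct = len(predicted & reference)
    return PairEvalReport.from_counts(len(predicted), len(reference), n_correct)


# ---------------------------------------------------------------------------
# group-level evaluation
# ---------------------------------------------------------------------------


@dataclass
class ContingencyTable:
    """Group-by-cluster count matrix underpinning the group metrics."""

    y: np.ndarray
    group_labels: list
    cluster_labels: list

    @property
    def n_groups(self) -> int:
        return self.y.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.y.shape[1]

    @property
    def total(self) -> int:
        return int(self.y.sum())


def _check_coverage(reference: Partition, predicted: Partition) -> list[str]:
    ref_ids, pred_ids = set(reference), set(predicted)
    if ref_ids != pred_ids:
        diff = sorted(ref_ids ^ pred_ids)
        raise CoverageError(
            f"partitions cover different proteins; symmetric difference "
            f"({len(diff)} ids): {diff[:10]}{'...' if len(diff) > 10 else ''}"
        )
    if not ref_ids:
        raise EmptyInputError("partitions are empty")
    return sorted(ref_ids)


def contingency(reference: Partition, predicted: Partition) -> ContingencyTable:
    """Count matrix ``y[i, j]`` = members of reference group i in cluster j."""
    ids = _check_coverage(reference, predicted)
    group_labels = sorted({reference[i] for i in ids}, key=str)
    cluster_labels = sorted({predicted[i] for i in ids}, key=str)
    gpos = {g: i for i, g in enumerate(group_labels)}
    cpos = {c: j for j, c in enumerate(cluster_labels)}
    y = np.zeros((len(group_labels), len(cluster_labels)), dtype=int)
    for pid in ids:
        y[gpos[reference[pid]], cpos[predicted[pid]]] += 1
    return ContingencyTable(y=y, group_labels=group_labels, cluster_labels=cluster_labels)


def family_completeness(table: ContingencyTable) -> float:
    """Sum over groups of the largest same-cluster member count, over T."""
    T = table.total
    if T == 0:
        raise EmptyInputError("empty contingency table")
    return float(table.y.max(axis=1).sum()) / T


def adjusted_mutual_information(reference: Partition, predicted: Partition) -> float:
    """AMI between the two partitions (arithmetic mean normalization).

    1.0 for identical partitions; near 0 for chance-level agreement. When
    one partition is a single zero-entropy block and the other differs, the
    value is 0 by convention (both identical single blocks give 1).
    """
    ids = _check_coverage(reference, predicted)
    ref_labels = [str(reference[i]) for i in ids]
    pred_labels = [str(predicted[i]) for i in ids]
    return float(
        adjusted_mutual_info_score(ref_labels, pred_labels, average_method="arithmetic")
    )


def exact_match_percentage(
    reference: Partition, predicted: Partition, denominator: str = "clusters"
) -> float:
    """Percent of predicted clusters identical to some reference group.

    ``denominator`` is ``"clusters"`` (the default: share of predicted
    clusters that are exact) or ``"groups"`` (share of reference groups
    recovered exactly).
    """
    if denominator not in ("clusters", "groups"):
        raise EmptyInputError(f"unknown denominator {denominator!r}")
    ids = _check_coverage(reference, predicted)
    groups: dict = {}
    clusters: dict = {}
    for pid in ids:
        groups.setdefault(reference[pid], set()).add(pid)
        clusters.setdefault(predicted[pid], set()).add(pid)
    group_sets = {frozenset(v) for v in groups.values()}
    n_exact = sum(1 for v in clusters.values() if frozenset(v) in group_sets)
    denom = len(clusters) if denominator == "clusters" else len(group_sets)
    return 100.0 * n_exact / denom


@dataclass
class GroupEvalReport:
    """The three group-creation metrics plus partition bookkeeping."""

    family_completeness: float
    ami: float
    exact_match_pct: float
    n_groups: int
    n_clusters: int
    n_proteins: int

    def to_dict(self, sig: int = 3) -> dict:
        return {
            "family_completeness": round_sig(self.family_completeness, sig),
            "ami": round_sig(self.ami, sig),
            "exact_match_pct": round_sig(self.exact_match_pct, sig),
            "n_groups": self.n_groups,
            "n_clusters": self.n_clusters,
            "n_proteins": self.n_proteins,
        }


def group_scores(reference: Partition, predicted: Partition) -> GroupEvalReport:
    """Compute all three group metrics on a pair of partitions."""
    table = contingency(reference, predicted)
    return GroupEvalReport(
        family_completeness=family_completeness(table),
        ami=adjusted_mutual_information(reference, predicted),
        exact_match_pct=exact_match_percentage(reference, predicted),
        n_groups=table.n_groups,
        n_clusters=table.n_clusters,
        n_proteins=table.total,
    )
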