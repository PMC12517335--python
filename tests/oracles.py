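"""Independent brute-force reference implementations used only by tests.

Each function recomputes a quantity from first principles (enumeration,
naive loops, direct summation) without touching the package's own code
paths, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
from scipy.special import gammaln


def column_means_loop(X):
    """Per-column arithmetic mean via an explicit accumulation loop."""
    X = np.asarray(X, dtype=float)
    L, p = X.shape
    out = []
    for j in range(p):
        s = 0.0
        for i in range(L):
            s += X[i, j]
        out.append(s / L)
    return np.asarray(out)


def covariance_eigen_pca(X):
    """Explained variances from an eigendecomposition of the covariance."""
    X = np.asarray(X, dtype=float)
    C = np.cov(X, rowvar=False, ddof=1)
    evals = np.linalg.eigvalsh(C)[::-1]
    return np.clip(evals, 0.0, None)


def best_two_partition_wcss(X):
    """Exhaustive search over all 2-partitions minimizing the WCSS."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    best = None
    best_wcss = np.inf
    for assignment in itertools.product([0, 1], repeat=n - 1):
        labels = np.array((0,) + assignment)  # fix point 0 to side 0 (symmetry)
        if labels.sum() in (0, n):
            continue
        wcss = 0.0
        for j in (0, 1):
            members = X[labels == j]
            wcss += ((members - members.mean(axis=0)) ** 2).sum()
        if wcss < best_wcss:
            best_wcss = wcss
            best = labels
    return best, best_wcss


def census_loop(labels, k):
    """Tally cluster sizes (including empty clusters) one label at a time."""
    sizes = {j: 0 for j in range(k)}
    for lab in labels:
        sizes[int(lab)] += 1
    return dict(Counter(sizes.values()))


def cross_species_pair_count(species_counts):
    """Number of cross-species pairs given per-species member counts."""
    counts = list(species_counts)
    total = 0
    for i in range(len(counts)):
        for j in range(i + 1, len(counts)):
            total += counts[i] * counts[j]
    return total


def enumerate_cross_species_pairs(members):
    """All unordered cross-species id pairs by double loop.

    ``members`` is a sequence of ``(protein_id, species)`` tuples.
    """
    out = set()
    for (ida, spa), (idb, spb) in itertools.combinations(members, 2):
        if spa != spb:
            out.add((min(ida, idb), max(ida, idb)))
    return out


def family_completeness_loop(groups, clusters):
    """Family completeness via an explicit per-group scan.

    ``groups`` / ``clusters`` map each protein id to its label.
    """
    T = len(groups)
    by_group = {}
    for pid, g in groups.items():
        by_group.setdefault(g, []).append(pid)
    total = 0
    for members in by_group.values():
        tally = Counter(clusters[pid] for pid in members)
        total += max(tally.values())
    return total / T


def ami_direct(ref_labels, pred_labels):
    """Adjusted mutual information by direct summation.

    Mutual information and entropies from the contingency table; the
    expected MI under the permutation (hypergeometric) model from the exact
    sum over all feasible cell counts; arithmetic-mean normalization.
    """
    ref_labels = list(ref_labels)
    pred_labels = list(pred_labels)
    N = len(ref_labels)
    a = Counter(ref_labels)
    b = Counter(pred_labels)
    nij = Counter(zip(ref_labels, pred_labels))

    mi = 0.0
    for (gi, cj), n in nij.items():
        mi += (n / N) * math.log(N * n / (a[gi] * b[cj]))
    h_ref = -sum((ai / N) * math.log(ai / N) for ai in a.values())
    h_pred = -sum((bj / N) * math.log(bj / N) for bj in b.values())

    emi = 0.0
    lg = gammaln  # log-factorials via log-gamma
    for ai in a.values():
        for bj in b.values():
            lo = max(1, ai + bj - N)
            hi = min(ai, bj)
            for n in range(lo, hi + 1):
                log_term = (
                    lg(ai + 1) + lg(bj + 1) + lg(N - ai + 1) + lg(N - bj + 1)
                    - lg(N + 1) - lg(n + 1) - lg(ai - n + 1) - lg(bj - n + 1)
                    - lg(N - ai - bj + n + 1)
                )
                emi += (n / N) * math.log(N * n / (ai * bj)) * math.exp(log_term)

    denom = 0.5 * (h_ref + h_pred) - emi
    if denom == 0.0:
        return 1.0 if nij.keys() and len(a) == len(b) == len(nij) else 0.0
    return (mi - emi) / denom
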