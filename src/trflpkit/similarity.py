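"""Association coefficients between T-RF profiles.

Two complementary coefficients: the Jaccard similarity weights every T-RF
equally (presence/absence — shared fragments over total distinct
fragments), while the Bray-Curtis similarity weights by relative abundance,
1 - (1/2) * sum |p_i - q_i|, which for unit-sum vectors equals
sum min(p_i, q_i).  Both are reported as fractions in [0, 1]; distance
matrices (1 - similarity) are written for external ordination tools.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np

from .core import (
    AbundanceMatrix,
    Alignment,
    DataError,
    Profile,
    SignalBasis,
    SimilarityMatrix,
    profiles_by_id,
)

__all__ = [
    "jaccard_similarity",
    "bray_curtis_similarity",
    "similarity_matrix",
    "abundance_matrix",
]


def jaccard_similarity(a_bins: Iterable, b_bins: Iterable) -> float:
    """|A n B| / |A u B| over presence sets; two empty profiles count as
    identical (similarity 1, with a warning)."""
    a, b = set(a_bins), set(b_bins)
    union = a | b
    if not union:
        warnings.warn("both profiles empty; Jaccard similarity defined as 1", stacklevel=2)
        return 1.0
    return len(a & b) / len(union)


def bray_curtis_similarity(p: np.ndarray, q: np.ndarray) -> float:
    """1 - (1/2) * sum |p_i - q_i| for unit-sum abundance vectors on shared bins."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise DataError("abundance vectors must share the same bins")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise DataError(f"abundance vector {name} must sum to 1, got {v.sum():.8f}")
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def abundance_matrix(
    alignment: Alignment,
    profiles: Sequence[Profile],
    basis: SignalBasis = "height",
) -> AbundanceMatrix:
    """Bins x profiles relative abundances over the alignment's bins.

    Abundances are renormalized over the retained bins, so columns sum to 1
    even after ambiguous bins have been dropped.
    """
    by_id = profiles_by_id(profiles)
    pids = alignment.profile_ids
    values = np.zeros((len(alignment.bins), len(pids)))
    for i, bin_ in enumerate(alignment.bins):
        for pid, idx in bin_.members.items():
            values[i, pids.index(pid)] = by_id[pid].peaks[idx].signal(basis)
    sums = values.sum(axis=0)
    empty = sums == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} profile(s) have no signal in any retained bin",
            stacklevel=2,
        )
    values = np.divide(values, np.where(empty, 1.0, sums), out=values)
    return AbundanceMatrix(
        bin_sizes=tuple(b.mean_size for b in alignment.bins),
        profile_ids=pids,
        values=values,
        basis=basis,
    )


def similarity_matrix(
    matrix: AbundanceMatrix, metric: str = "bray_curtis"
) -> SimilarityMatrix:
    """All pairwise similarities between the matrix's profiles.

    Presence for Jaccard is abundance > 0.  Profiles with an all-zero
    column (emptied by filtering) are treated as empty presence sets.
    """
    v = matrix.values
    n = len(matrix.profile_ids)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "jaccard":
                s = jaccard_similarity(
                    np.flatnonzero(v[:, i] > 0), np.flatnonzero(v[:, j] > 0)
                )
            elif metric == "bray_curtis":
                if v[:, i].sum() == 0 or v[:, j].sum() == 0:
                    if v[:, i].sum() == 0 and v[:, j].sum() == 0:
                        warnings.warn(
                            "both profiles empty; Bray-Curtis defined as 1", stacklevel=2
                        )
                        s = 1.0
                    else:
                        s = 0.0
                else:
                    s = bray_curtis_similarity(v[:, i], v[:, j])
            else:
                raise DataError(f"unknown metric {metric!r}")
            out[i, j] = out[j, i] = s
    return SimilarityMatrix(profile_ids=matrix.profile_ids, values=out, metric=metric)
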