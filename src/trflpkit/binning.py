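"""Alignment of T-RFs across profiles by moving-average binning.

Binning decides which peaks in different profiles represent the same
terminal restriction fragment.  The moving-average procedure works from the
shortest fragment upward: the globally shortest unbinned T-RF seeds a bin,
every unbinned T-RF at most Y bases longer joins (one per profile), and the
bin is then extended with T-RFs at most Z bases above the running bin mean,
the mean being recomputed after every addition.  Bins whose members lie
within the alignment range of a member of another bin are classified
ambiguous; for two-profile alignments ambiguity is resolved by re-pairing
the most size-similar peaks, and bins that remain ambiguous can be dropped
so that analyses proceed only on unambiguously aligned fragments.

An integer rounding binner is provided as the simple alternative: it places
every T-RF in the bin of its nearest integer size, which splits fragments
such as 134.4 and 134.6 into different bins and is included only for
comparison with the moving-average procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Literal, Sequence

import numpy as np

from .core import (
    Alignment,
    AlignmentBin,
    BinningParams,
    DataError,
    Profile,
    profiles_by_id,
)

__all__ = [
    "moving_average_bin",
    "classify_bins",
    "resolve_duplicate_ambiguity",
    "integer_bin",
    "drop_ambiguous_bins",
]

SizeBasis = Literal["original", "corrected"]


def _peak_sizes(profiles: Sequence[Profile], size_basis: SizeBasis) -> list[tuple[float, int, str, int]]:
    """Flatten to (size, profile_order, profile_id, peak_index), ascending.

    The profile input order breaks exact size ties deterministically.
    """
    corrected = size_basis == "corrected"
    flat = []
    for order, prof in enumerate(profiles):
        sizes = prof.sizes(corrected=corrected)
        for idx, s in enumerate(sizes):
            flat.append((float(s), order, prof.profile_id, idx))
    flat.sort(key=lambda t: (t[0], t[1], t[3]))
    return flat


def moving_average_bin(
    profiles: Sequence[Profile],
    params: BinningParams | None = None,
    size_basis: SizeBasis = "original",
) -> Alignment:
    """Partition all peaks of ``profiles`` into alignment bins.

    Each bin seeds from the globally shortest unbinned T-RF, fills from the
    Y window above the seed (one T-RF per profile, shorter candidates
    first), then repeatedly extends with the unbinned T-RF closest to the
    bin mean among those at most Z bases above it, from profiles not yet
    represented, recomputing the mean after every addition.
    """
    if params is None:
        params = BinningParams()
    if not profiles or all(len(p) == 0 for p in profiles):
        raise DataError("moving_average_bin requires at least one profile with peaks")

    flat = _peak_sizes(profiles, size_basis)
    unbinned = list(flat)
    bins: list[AlignmentBin] = []

    while unbinned:
        seed_size, _, seed_pid, seed_idx = unbinned.pop(0)
        members: dict[str, int] = {seed_pid: seed_idx}
        member_sizes = [seed_size]

        # Y phase: one pass over the seed window, shorter candidates first;
        # the first candidate seen for a profile wins (it is nearest the seed).
        remaining = []
        for item in unbinned:
            size, _, pid, idx = item
            if size <= seed_size + params.y_seed_window and pid not in members:
                members[pid] = idx
                member_sizes.append(size)
            else:
                remaining.append(item)
        unbinned = remaining

        # Z phase: extend from the running mean until no candidate fits.
        while True:
            mean = float(np.mean(member_sizes))
            best = None
            best_key = None
            for pos, (size, order, pid, idx) in enumerate(unbinned):
                if pid in members:
                    continue
                if size > mean + params.z_extend_window:
                    break  # sorted ascending: nothing further fits
                key = (abs(size - mean), size, order)
                if best_key is None or key < best_key:
                    best, best_key = pos, key
            if best is None:
                break
            size, _, pid, idx = unbinned.pop(best)
            members[pid] = idx
            member_sizes.append(size)

        bins.append(
            AlignmentBin(
                bin_id=len(bins),
                members=members,
                mean_size=float(np.mean(member_sizes)),
            )
        )

    bins.sort(key=lambda b: b.mean_size)
    bins = [replace(b, bin_id=i) for i, b in enumerate(bins)]
    return Alignment(
        bins=tuple(bins),
        profile_ids=tuple(p.profile_id for p in profiles),
        params=params,
        size_basis=size_basis,
    )


def _bin_sizes(alignment: Alignment, profiles: dict[str, Profile]) -> list[np.ndarray]:
    corrected = alignment.size_basis == "corrected"
    return [b.member_sizes(profiles, corrected=corrected) for b in alignment.bins]


def classify_bins(
    alignment: Alignment,
    profiles: Sequence[Profile],
    ambiguity_range: float | None = None,
) -> Alignment:
    """Set each bin's status to ambiguous or correct.

    A bin is ambiguous if any of its member T-RFs lies strictly within
    ``ambiguity_range`` of a member of another bin; the relation is
    symmetric by construction.
    """
    if ambiguity_range is None:
        ambiguity_range = alignment.params.ambiguity_range
    by_id = profiles_by_id(profiles)
    sizes = _bin_sizes(alignment, by_id)
    n = len(alignment.bins)
    ambiguous = [False] * n
    for i in range(n):
        for j in range(i + 1, n):
            if sizes[i].size == 0 or sizes[j].size == 0:
                continue
            # bins are mean-sorted; prune once the gap cannot close
            if sizes[j].min() - sizes[i].max() >= ambiguity_range:
                break
            d = np.abs(sizes[i][:, None] - sizes[j][None, :]).min()
            if d < ambiguity_range:
                ambiguous[i] = ambiguous[j] = True
    new_bins = tuple(
        replace(b, status="ambiguous" if amb else "correct")
        for b, amb in zip(alignment.bins, ambiguous)
    )
    return replace(alignment, bins=new_bins)


def _min_cost_order_preserving_pairs(
    a: np.ndarray, b: np.ndarray, max_diff: float
) -> list[tuple[int, int]]:
    """Order-preserving matching of two ascending size lists.

    Maximizes the number of matched pairs with |a_i - b_j| <= max_diff,
    then minimizes the total absolute size difference.  Dynamic program on
    the two sequences; O(len(a) * len(b)).
    """
    na, nb = len(a), len(b)
    NEG = (-1, 0.0)
    # dp[i][j] = (pairs, -cost) best over a[:i], b[:j]; store cost positive.
    pairs = [[0] * (nb + 1) for _ in range(na + 1)]
    cost = [[0.0] * (nb + 1) for _ in range(na + 1)]
    choice = [[0] * (nb + 1) for _ in range(na + 1)]  # 0 skip-a, 1 skip-b, 2 match
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            best = (pairs[i - 1][j], -cost[i - 1][j], 0)
            cand = (pairs[i][j - 1], -cost[i][j - 1], 1)
            if cand[:2] > best[:2]:
                best = cand
            d = abs(a[i - 1] - b[j - 1])
            if d <= max_diff:
                cand = (pairs[i - 1][j - 1] + 1, -(cost[i - 1][j - 1] + d), 2)
                if cand[:2] > best[:2]:
                    best = cand
            pairs[i][j], cost[i][j], choice[i][j] = best[0], -best[1], best[2]
    out = []
    i, j = na, nb
    while i > 0 and j > 0:
        c = choice[i][j]
        if c == 2:
            out.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif c == 1:
            j -= 1
        else:
            i -= 1
    out.reverse()
    return out


def resolve_duplicate_ambiguity(
    alignment: Alignment, profiles: Sequence[Profile]
) -> Alignment:
    """Re-pair ambiguous bins of a two-profile alignment by size similarity.

    The forward-moving binner always pairs the shortest T-RFs first, which
    can mis-pair when one replicate has a peak between two close peaks of
    the other.  Within each connected cluster of mutually ambiguous bins the
    two profiles' peaks are re-matched to minimize the total absolute size
    difference (after maximizing the number of matched pairs), keeping size
    order; unmatched peaks become singleton bins.  Statuses are recomputed.
    """
    if len(alignment.profile_ids) != 2:
        raise DataError(
            "resolve_duplicate_ambiguity applies to exactly two profiles; for "
            "multi-profile alignments use the systematic-shift correction"
        )
    if all(b.status != "ambiguous" for b in alignment.bins):
        return alignment

    by_id = profiles_by_id(profiles)
    pid_a, pid_b = alignment.profile_ids
    rng = alignment.params.ambiguity_range
    corrected = alignment.size_basis == "corrected"

    # Connected clusters of ambiguous bins: consecutive ambiguous bins whose
    # member sizes are within the ambiguity range of each other.
    sizes = _bin_sizes(alignment, by_id)
    clusters: list[list[int]] = []
    for i, b in enumerate(alignment.bins):
        if b.status != "ambiguous":
            continue
        if clusters and any(
            np.abs(sizes[j][:, None] - sizes[i][None, :]).min() < rng
            for j in clusters[-1]
        ):
            clusters[-1].append(i)
        else:
            clusters.append([i])

    new_bins: list[AlignmentBin] = [
        b for b in alignment.bins if b.status != "ambiguous"
    ]
    for cluster in clusters:
        entries_a: list[int] = []
        entries_b: list[int] = []
        for i in cluster:
            m = alignment.bins[i].members
            if pid_a in m:
                entries_a.append(m[pid_a])
            if pid_b in m:
                entries_b.append(m[pid_b])
        entries_a.sort(key=lambda idx: by_id[pid_a].peaks[idx].size)
        entries_b.sort(key=lambda idx: by_id[pid_b].peaks[idx].size)
        off_a = by_id[pid_a].size_offset if corrected else 0.0
        off_b = by_id[pid_b].size_offset if corrected else 0.0
        sz_a = np.array([by_id[pid_a].peaks[i].size + off_a for i in entries_a])
        sz_b = np.array([by_id[pid_b].peaks[i].size + off_b for i in entries_b])
        matched = _min_cost_order_preserving_pairs(sz_a, sz_b, rng)
        used_a = {ia for ia, _ in matched}
        used_b = {ib for _, ib in matched}
        for ia, ib in matched:
            new_bins.append(
                AlignmentBin(
                    bin_id=0,
                    members={pid_a: entries_a[ia], pid_b: entries_b[ib]},
                    mean_size=float((sz_a[ia] + sz_b[ib]) / 2),
                )
            )
        for ia in range(len(entries_a)):
            if ia not in used_a:
                new_bins.append(
                    AlignmentBin(0, {pid_a: entries_a[ia]}, float(sz_a[ia]))
                )
        for ib in range(len(entries_b)):
            if ib not in used_b:
                new_bins.append(
                    AlignmentBin(0, {pid_b: entries_b[ib]}, float(sz_b[ib]))
                )

    new_bins.sort(key=lambda b: b.mean_size)
    new_bins = [replace(b, bin_id=i, status="unclassified") for i, b in enumerate(new_bins)]
    realigned = replace(alignment, bins=tuple(new_bins))
    return classify_bins(realigned, profiles)


def integer_bin(profiles: Sequence[Profile], size_basis: SizeBasis = "original") -> Alignment:
    """Round-up/down binning: each T-RF joins the bin of its nearest integer
    size (ties, x.5, round away from zero).

    Included as the simple comparison method: fragments whose size estimates
    straddle a half-integer boundary (134.4 vs 134.6) land in different bins.
    If two peaks of the same profile round to the same integer, the taller
    peak is kept in the bin and a warning is emitted.
    """
    if not profiles or all(len(p) == 0 for p in profiles):
        raise DataError("integer_bin requires at least one profile with peaks")
    corrected = size_basis == "corrected"
    groups: dict[int, dict[str, int]] = {}
    for prof in profiles:
        sizes = prof.sizes(corrected=corrected)
        for idx, s in enumerate(sizes):
            label = int(np.floor(s + 0.5))  # half away from zero for positive sizes
            members = groups.setdefault(label, {})
            if prof.profile_id in members:
                prev = members[prof.profile_id]
                if prof.peaks[idx].height > prof.peaks[prev].height:
                    members[prof.profile_id] = idx
                warnings.warn(
                    f"profile {prof.profile_id!r}: two peaks round to {label}; "
                    "keeping the taller",
                    stacklevel=2,
                )
            else:
                members[prof.profile_id] = idx
    bins = tuple(
        AlignmentBin(bin_id=i, members=groups[label], mean_size=float(label))
        for i, label in enumerate(sorted(groups))
    )
    return Alignment(
        bins=bins,
        profile_ids=tuple(p.profile_id for p in profiles),
        params=BinningParams(),
        size_basis=size_basis,
    )


def drop_ambiguous_bins(alignment: Alignment) -> Alignment:
    """Remove bins still classified ambiguous, keeping only unambiguously
    aligned T-RFs for downstream analysis."""
    if any(b.status == "unclassified" for b in alignment.bins):
        raise DataError("classify_bins must be applied before drop_ambiguous_bins")
    kept = [b for b in alignment.bins if b.status == "correct"]
    n_dropped = len(alignment.bins) - len(kept)
    if kept or not alignment.bins:
        if n_dropped:
            warnings.warn(
                f"dropped {n_dropped} ambiguous of {len(alignment.bins)} bins",
                stacklevel=2,
            )
    else:
        warnings.warn(
            f"all {len(alignment.bins)} bins ambiguous; alignment is empty",
            stacklevel=2,
        )
    kept = [replace(b, bin_id=i) for i, b in enumerate(kept)]
    return replace(alignment, bins=tuple(kept))
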