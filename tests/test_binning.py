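"""Moving-average binning, ambiguity classification, duplicate resolution,
integer binning.

The oracle for the moving-average procedure is an independent, literal
re-execution of the published description on small instances: seed with the
globally shortest unbinned fragment, fill the Y window (one fragment per
profile, nearest the seed first), then repeatedly add the fragment nearest
the running mean among those at most Z above it, recomputing the mean after
every addition.
"""

import numpy as np
import pytest

from trflpkit import (
    BinningParams,
    DataError,
    classify_bins,
    drop_ambiguous_bins,
    integer_bin,
    moving_average_bin,
    resolve_duplicate_ambiguity,
)

from conftest import make_profile


def oracle_moving_average(profile_sizes, y=1.0, z=0.5):
    """Literal step-by-step re-execution; profile_sizes is a list of size
    lists, one per profile.  Returns bins as sorted tuples of
    (profile_index, size)."""
    items = [
        (s, pi) for pi, sizes in enumerate(profile_sizes) for s in sizes
    ]
    bins = []
    while items:
        seed = min(items, key=lambda t: (t[0], t[1]))
        items.remove(seed)
        members = {seed[1]: seed[0]}
        # Y window: candidates at most Y longer than the seed, shortest first
        for cand in sorted(items):
            if cand[0] <= seed[0] + y and cand[1] not in members:
                members[cand[1]] = cand[0]
                items.remove(cand)
        # Z extension from the running mean
        while True:
            mean = sum(members.values()) / len(members)
            cands = [
                t for t in items if t[1] not in members and t[0] <= mean + z
            ]
            if not cands:
                break
            pick = min(cands, key=lambda t: (abs(t[0] - mean), t[0], t[1]))
            items.remove(pick)
            members[pick[1]] = pick[0]
        bins.append(tuple(sorted((pi, s) for pi, s in members.items())))
    return sorted(bins, key=lambda b: sum(s for _, s in b) / len(b))


def as_tuples(alignment, profiles):
    by_id = {p.profile_id: i for i, p in enumerate(profiles)}
    out = []
    for b in alignment.bins:
        out.append(
            tuple(
                sorted(
                    (by_id[pid], profiles[by_id[pid]].peaks[idx].size)
                    for pid, idx in b.members.items()
                )
            )
        )
    return out


def test_published_hand_trace():
    p1 = make_profile("P1", [100.0, 101.2])
    p2 = make_profile("P2", [100.4])
    aln = moving_average_bin([p1, p2])
    got = as_tuples(aln, [p1, p2])
    assert got == [((0, 100.0), (1, 100.4)), ((0, 101.2),)]
    assert aln.bins[0].mean_size == pytest.approx(100.2)


def test_exact_matches_bin_together():
    p1 = make_profile("P1", [100.0, 200.0])
    p2 = make_profile("P2", [100.0, 200.0])
    aln = moving_average_bin([p1, p2])
    assert [len(b) for b in aln.bins] == [2, 2]


def test_single_profile_gets_one_bin_per_peak():
    p = make_profile("P", [100.0, 100.3, 100.6])
    aln = moving_average_bin([p])
    assert [len(b) for b in aln.bins] == [1, 1, 1]


def test_oracle_equivalence_on_random_small_instances(rng):
    """The implementation matches the literal re-execution on 1000 random
    instances of up to 6 peaks over up to 3 profiles."""
    for _ in range(1000):
        n_prof = int(rng.integers(1, 4))
        sizes = []
        total = 0
        for _ in range(n_prof):
            k = int(rng.integers(0, 7 - total)) if total < 6 else 0
            total += k
            s = np.round(100 + rng.uniform(0, 4, k), 2)
            sizes.append(sorted(set(s.tolist())))
        if not any(sizes):
            continue
        profiles = [make_profile(f"P{i}", s) for i, s in enumerate(sizes) if s]
        dense = [s for s in sizes if s]
        aln = moving_average_bin(profiles)
        assert as_tuples(aln, profiles) == oracle_moving_average(dense)


def test_partition_property(rng):
    profiles = [
        make_profile(f"P{i}", sorted(set(np.round(rng.uniform(50, 120, 15), 2))))
        for i in range(4)
    ]
    aln = moving_average_bin(profiles)
    aln.check_partition({p.profile_id: p for p in profiles})
    classified = classify_bins(aln, profiles)
    assert classified.total_members() == aln.total_members()


def test_permutation_invariance_with_distinct_sizes(rng):
    profiles = [
        make_profile(f"P{i}", sorted(100 + rng.uniform(0, 30, 8) + i * 1e-4))
        for i in range(3)
    ]
    ref = {
        frozenset((pid, profiles_idx) for pid, profiles_idx in b.members.items())
        for b in moving_average_bin(profiles).bins
    }
    for perm in ([2, 0, 1], [1, 2, 0], [2, 1, 0]):
        permuted = [profiles[i] for i in perm]
        got = {
            frozenset(b.members.items()) for b in moving_average_bin(permuted).bins
        }
        assert got == ref


def test_classification_symmetry_and_examples():
    p1 = make_profile("P1", [100.0, 101.2])
    p2 = make_profile("P2", [100.4])
    aln = classify_bins(moving_average_bin([p1, p2]), [p1, p2])
    assert [b.status for b in aln.bins] == ["ambiguous", "ambiguous"]

    far1, far2 = make_profile("A", [100.0, 200.0]), make_profile("B", [100.1, 200.1])
    aln = classify_bins(moving_average_bin([far1, far2]), [far1, far2])
    assert all(b.status == "correct" for b in aln.bins)

    single = make_profile("S", [100.0])
    aln = classify_bins(moving_average_bin([single]), [single])
    assert aln.bins[0].status == "correct"


def test_duplicate_resolution_repairs_nearest_pair():
    d1 = make_profile("D1", [100.0, 100.9])
    d2 = make_profile("D2", [100.8])
    aln = classify_bins(moving_average_bin([d1, d2]), [d1, d2])
    resolved = resolve_duplicate_ambiguity(aln, [d1, d2])
    pairs = [
        sorted(b.members) for b in resolved.bins if len(b.members) == 2
    ]
    assert pairs == [["D1", "D2"]]
    paired = next(b for b in resolved.bins if len(b) == 2)
    sizes = sorted(
        {"D1": d1, "D2": d2}[pid].peaks[idx].size for pid, idx in paired.members.items()
    )
    assert sizes == [100.8, 100.9]
    resolved.check_partition({"D1": d1, "D2": d2})


def test_duplicate_resolution_identity_when_unambiguous():
    d1 = make_profile("D1", [100.0, 200.0])
    d2 = make_profile("D2", [100.0, 200.0])
    aln = classify_bins(moving_average_bin([d1, d2]), [d1, d2])
    assert resolve_duplicate_ambiguity(aln, [d1, d2]) is aln


def test_duplicate_resolution_rejects_more_than_two_profiles():
    ps = [make_profile(f"P{i}", [100.0 + i * 0.1]) for i in range(3)]
    aln = classify_bins(moving_average_bin(ps), ps)
    with pytest.raises(DataError, match="two profiles"):
        resolve_duplicate_ambiguity(aln, ps)


def test_integer_binning_splits_half_neighbours():
    # 134.4 and 134.6 land in different integer bins
    p1 = make_profile("P1", [134.4])
    p2 = make_profile("P2", [134.6])
    aln = integer_bin([p1, p2])
    assert [b.mean_size for b in aln.bins] == [134.0, 135.0]
    assert all(len(b) == 1 for b in aln.bins)


@pytest.mark.parametrize("size, label", [(100.0, 100), (99.5, 100), (100.49, 100)])
def test_integer_binning_rounds_half_up(size, label):
    aln = integer_bin([make_profile("P", [size])])
    assert aln.bins[0].mean_size == label


def test_drop_ambiguous_bins_counts_and_idempotence():
    p1 = make_profile("P1", [100.0, 101.2, 200.0])
    p2 = make_profile("P2", [100.4, 200.1])
    aln = classify_bins(moving_average_bin([p1, p2]), [p1, p2])
    n_amb = sum(1 for b in aln.bins if b.status == "ambiguous")
    assert n_amb == 2
    with pytest.warns(UserWarning, match="dropped"):
        kept = drop_ambiguous_bins(aln)
    assert len(kept.bins) == len(aln.bins) - n_amb
    assert all(b.status == "correct" for b in kept.bins)
    assert drop_ambiguous_bins(kept).bins == kept.bins


def test_drop_all_ambiguous_warns_and_empties():
    p1 = make_profile("P1", [100.0, 100.9])
    p2 = make_profile("P2", [100.45])
    aln = classify_bins(moving_average_bin([p1, p2]), [p1, p2])
    assert all(b.status == "ambiguous" for b in aln.bins)
    with pytest.warns(UserWarning, match="ambiguous"):
        out = drop_ambiguous_bins(aln)
    assert len(out.bins) == 0
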