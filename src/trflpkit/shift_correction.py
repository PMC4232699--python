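"""Detection and correction of systematic shifts in fragment-size estimates.

Capillary runs estimate the same fragment at slightly different sizes, and
the error is often systematic: every T-RF of one profile reads a little
longer than the corresponding T-RF of another.  Such shifts inflate
alignment ambiguity.  They are corrected with a constant additive offset
per profile, chosen through a reference fragment: a T-RF present in every
profile, in a bin classified correct, has its size set to a common value in
all profiles, and all other sizes in each profile move by that profile's
resulting offset.  Every eligible reference is scored by the sum of
standard deviations of the corrected member sizes over the unambiguously
binned T-RFs, the reference with the lowest sum wins, and the profiles are
re-aligned on the corrected sizes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .binning import classify_bins, moving_average_bin
from .core import Alignment, BinningParams, DataError, Profile, profiles_by_id

__all__ = [
    "ShiftReport",
    "ShiftCorrection",
    "detect_pairwise_shift",
    "count_shifted_pairs",
    "correct_systematic_shift",
]


@dataclass(frozen=True)
class ShiftReport:
    """Pairwise evidence for a systematic size shift.

    ``differences`` are the signed size differences (second minus first
    profile) over the bins shared by the pair.  The pair is flagged shifted
    when at least one difference is nonzero and all nonzero differences
    share one sign — identical estimates carry no evidence either way.
    """

    pair: tuple[str, str]
    shared_bins: int
    differences: tuple[float, ...]
    shifted: bool
    direction: str  # profile_id running longer, or "" when not shifted
    mean_offset: float


@dataclass(frozen=True)
class ShiftCorrection:
    """Chosen reference bin and the per-profile additive offsets it implies.

    ``score`` is the sum over correct bins of the standard deviation of the
    corrected member sizes; the chosen reference minimizes it over all
    candidates.
    """

    reference_bin: int
    per_profile_offset: dict[str, float]
    score: float


def detect_pairwise_shift(a: Profile, b: Profile, alignment: Alignment) -> ShiftReport:
    """Compare sizes of T-RFs shared by two profiles within an alignment."""
    if a.profile_id not in alignment.profile_ids or b.profile_id not in alignment.profile_ids:
        raise DataError("both profiles must be part of the alignment")
    corrected = alignment.size_basis == "corrected"
    off_a = a.size_offset if corrected else 0.0
    off_b = b.size_offset if corrected else 0.0
    diffs: list[float] = []
    for bin_ in alignment.bins:
        if a.profile_id in bin_.members and b.profile_id in bin_.members:
            sa = a.peaks[bin_.members[a.profile_id]].size + off_a
            sb = b.peaks[bin_.members[b.profile_id]].size + off_b
            diffs.append(sb - sa)
    if not diffs:
        warnings.warn(
            f"profiles {a.profile_id!r} and {b.profile_id!r} share no bins",
            stacklevel=2,
        )
        return ShiftReport((a.profile_id, b.profile_id), 0, (), False, "", 0.0)
    arr = np.array(diffs)
    nonzero = arr[arr != 0]
    shifted = nonzero.size > 0 and (np.all(nonzero > 0) or np.all(nonzero < 0))
    direction = ""
    if shifted:
        direction = b.profile_id if nonzero[0] > 0 else a.profile_id
    return ShiftReport(
        pair=(a.profile_id, b.profile_id),
        shared_bins=len(diffs),
        differences=tuple(float(d) for d in diffs),
        shifted=bool(shifted),
        direction=direction,
        mean_offset=float(arr.mean()),
    )


def count_shifted_pairs(
    profiles: Sequence[Profile], alignment: Alignment
) -> tuple[int, int]:
    """Count (total unordered pairs, pairs showing a systematic shift)."""
    if len(profiles) < 2:
        raise DataError("count_shifted_pairs requires at least two profiles")
    total = 0
    shifted = 0
    for a, b in itertools.combinations(profiles, 2):
        total += 1
        if detect_pairwise_shift(a, b, alignment).shifted:
            shifted += 1
    return total, shifted


def _score_candidate(
    alignment: Alignment,
    profiles: dict[str, Profile],
    offsets: dict[str, float],
) -> float:
    """Sum of standard deviations of offset-corrected member sizes over
    correct bins (population sd; singleton bins contribute 0)."""
    score = 0.0
    for bin_ in alignment.bins:
        if bin_.status != "correct":
            continue
        sizes = np.array(
            [
                profiles[pid].peaks[idx].size + offsets[pid]
                for pid, idx in bin_.members.items()
            ]
        )
        score += float(sizes.std())
    return score


def correct_systematic_shift(
    profiles: Sequence[Profile],
    alignment: Alignment,
    params: BinningParams | None = None,
    allow_ambiguous_reference: bool = False,
) -> tuple[list[Profile], ShiftCorrection, Alignment]:
    """Estimate per-profile offsets from the best reference T-RF and re-align.

    Candidate references are bins classified correct with a member in every
    profile (``allow_ambiguous_reference`` relaxes the status requirement).
    For each candidate the common value is the mean of the reference sizes
    and each profile's offset is (common value - its reference size); the
    candidate minimizing the sum of member-size standard deviations over the
    correct bins of the *pre-correction* alignment wins, ties going to the
    smaller mean size.  Offsets are applied as profile ``size_offset`` (the
    observed sizes are preserved) and the profiles are re-binned and
    re-classified on the corrected sizes.
    """
    if params is None:
        params = alignment.params
    if any(b.status == "unclassified" for b in alignment.bins):
        raise DataError("alignment must be classified before shift correction")
    by_id = profiles_by_id(profiles)
    n = len(alignment.profile_ids)
    candidates = [
        b
        for b in alignment.bins
        if len(b.members) == n and (allow_ambiguous_reference or b.status == "correct")
    ]
    if not candidates:
        raise DataError(
            "no correct bin has a member in every profile; no usable reference "
            "T-RF (relax with allow_ambiguous_reference=True or add profiles)"
        )

    best: tuple[float, float, AlignmentBin, dict[str, float]] | None = None
    for cand in candidates:
        ref_sizes = {
            pid: by_id[pid].peaks[idx].size for pid, idx in cand.members.items()
        }
        common = float(np.mean(list(ref_sizes.values())))
        offsets = {pid: common - s for pid, s in ref_sizes.items()}
        score = _score_candidate(alignment, by_id, offsets)
        key = (score, cand.mean_size)
        if best is None or key < (best[0], best[1]):
            best = (score, cand.mean_size, cand, offsets)

    score, _, ref_bin, offsets = best
    corrected = [
        by_id[pid].with_offset(
            offsets[pid], f"shift-correct offset={offsets[pid]:+.4f} ref_bin={ref_bin.bin_id}"
        )
        for pid in alignment.profile_ids
    ]
    correction = ShiftCorrection(
        reference_bin=ref_bin.bin_id,
        per_profile_offset={pid: float(v) for pid, v in offsets.items()},
        score=score,
    )
    new_alignment = moving_average_bin(corrected, params, size_basis="corrected")
    new_alignment = classify_bins(new_alignment, corrected)
    return corrected, correction, new_alignment
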