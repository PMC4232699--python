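"""Consensus profiles from replicate fingerprints.

Single profiles are unreliable: low-abundance T-RFs flicker in and out
between loadings and false peaks occur.  A consensus profile keeps only the
fragments observed in all (or at least ``min_presence``) replicates, with
size, height and area averaged over the replicates in which the fragment
was present.
"""

from __future__ import annotations

import math
import warnings
from typing import Literal, Sequence

import numpy as np

from .core import Alignment, DataError, Peak, Profile, profiles_by_id

__all__ = ["build_consensus"]


def build_consensus(
    replicates: Sequence[Profile],
    alignment: Alignment,
    min_presence: int | Literal["all"] = "all",
    profile_id: str | None = None,
) -> Profile:
    """Average the replicate peaks of every bin present in enough replicates.

    Means are unweighted and taken over the members actually present in a
    bin.  The consensus inherits the sample_id of the replicates (which must
    agree) and records the replicate ids in its provenance.
    """
    by_id = profiles_by_id(replicates)
    if set(alignment.profile_ids) != set(by_id):
        raise DataError("alignment must cover exactly the given replicates")
    n = len(replicates)
    need = n if min_presence == "all" else int(min_presence)
    if not (1 <= need <= n):
        raise DataError(f"min_presence {min_presence!r} out of range for {n} replicates")

    peaks = []
    for bin_ in alignment.bins:
        if len(bin_.members) < need:
            continue
        members = [by_id[pid].peaks[idx] for pid, idx in bin_.members.items()]
        sizes = [p.size for p in members]
        heights = [p.height for p in members]
        areas = [p.area for p in members]
        area = float(np.mean(areas)) if all(not math.isnan(a) for a in areas) else math.nan
        peaks.append(
            Peak(size=float(np.mean(sizes)), height=float(np.mean(heights)), area=area)
        )
    if not peaks:
        warnings.warn(
            f"no bin present in >= {need} of {n} replicates; consensus is empty",
            stacklevel=2,
        )

    sample_ids = {p.sample_id for p in replicates}
    sample_id = sample_ids.pop() if len(sample_ids) == 1 else "+".join(sorted(sample_ids))
    return Profile(
        profile_id=profile_id or f"{sample_id}~consensus",
        sample_id=sample_id,
        replicate_label="consensus",
        peaks=tuple(sorted(peaks, key=lambda p: p.size)),
        provenance=(
            f"consensus of {sorted(by_id)} min_presence={min_presence}",
        ),
    )
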