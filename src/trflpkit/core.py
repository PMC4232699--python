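"""Domain types for T-RFLP fingerprint processing.

A terminal restriction fragment (T-RF) profile is the community fingerprint
produced by capillary electrophoresis of fluorescently end-labelled,
restriction-digested amplicons: a set of called peaks, each with an estimated
fragment size (bases), a peak height and a peak area (fluorescence units).
All downstream operations — detection thresholding, normalization, binning,
shift correction, consensus building, similarity analysis — transform these
types.

Sizes, heights and areas are carried at full floating-point precision;
rounding for display (two decimals for sizes) happens only at output time,
because the systematic-shift correction discriminates sub-0.1-base
differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "Peak",
    "Profile",
    "DetectionConfig",
    "BinningParams",
    "AlignmentBin",
    "Alignment",
    "AbundanceMatrix",
    "SimilarityMatrix",
    "InvariantError",
    "DataError",
]


class InvariantError(ValueError):
    """A domain type was constructed with an invariant violated."""


class DataError(ValueError):
    """Input data is structurally valid but semantically unusable."""


SignalBasis = Literal["height", "area"]
BinStatus = Literal["correct", "ambiguous", "unclassified"]


@dataclass(frozen=True)
class Peak:
    """One called T-RF: estimated size in bases, height and area in
    fluorescence units.

    ``area`` may be NaN to flag a height-only export; area-based operations
    must reject such peaks explicitly.
    """

    size: float
    height: float
    area: float = math.nan

    def __post_init__(self) -> None:
        if not (self.size > 0):
            raise InvariantError(f"Peak size must be > 0, got {self.size}")
        if not (self.height > 0):
            raise InvariantError(f"Peak height must be > 0, got {self.height}")
        if not math.isnan(self.area) and not (self.area > 0):
            raise InvariantError(f"Peak area must be > 0 (or NaN for missing), got {self.area}")

    @property
    def has_area(self) -> bool:
        return not math.isnan(self.area)

    def signal(self, basis: SignalBasis) -> float:
        if basis == "height":
            return self.height
        if basis == "area":
            if not self.has_area:
                raise DataError("peak area missing; cannot use area basis")
            return self.area
        raise ValueError(f"unknown signal basis {basis!r}")


@dataclass(frozen=True)
class Profile:
    """An ordered set of T-RFs from one loading of one sample.

    Peaks are kept sorted by ascending size; duplicate sizes within a profile
    are rejected as a read error.  ``size_offset`` holds the additive
    systematic-shift correction for this profile; the observed (original)
    sizes in ``peaks`` are never overwritten, because corrections are
    relative to the profile set they were estimated in.
    ``provenance`` is an append-only log of the transformations applied.
    """

    profile_id: str
    sample_id: str
    replicate_label: str = ""
    peaks: tuple[Peak, ...] = ()
    provenance: tuple[str, ...] = ()
    size_offset: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        object.__setattr__(self, "provenance", tuple(self.provenance))
        sizes = [p.size for p in self.peaks]
        for a, b in zip(sizes, sizes[1:]):
            if not (a < b):
                raise InvariantError(
                    f"profile {self.profile_id!r}: peak sizes must be strictly "
                    f"increasing, found {a} then {b}"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    def sizes(self, corrected: bool = False) -> np.ndarray:
        """Observed sizes, or shift-corrected sizes (observed + offset)."""
        s = np.array([p.size for p in self.peaks], dtype=float)
        return s + self.size_offset if corrected else s

    def signals(self, basis: SignalBasis) -> np.ndarray:
        return np.array([p.signal(basis) for p in self.peaks], dtype=float)

    def with_peaks(self, peaks: Iterable[Peak], note: str) -> "Profile":
        return replace(
            self,
            peaks=tuple(sorted(peaks, key=lambda p: p.size)),
            provenance=self.provenance + (note,),
        )

    def with_offset(self, offset: float, note: str) -> "Profile":
        return replace(self, size_offset=offset, provenance=self.provenance + (note,))


@dataclass(frozen=True)
class DetectionConfig:
    """Peak detection threshold (PDT) and analysis range.

    The PDT is the lowest acceptable peak height, so the comparison is
    inclusive; defaults are a PDT of 50 fluorescence units and an analysis
    range of 50-1020 bases, the range over which fragment sizes can be
    estimated reliably against the size standard.
    """

    pdt: float = 50.0
    range_min: float = 50.0
    range_max: float = 1020.0

    def __post_init__(self) -> None:
        if self.pdt < 0:
            raise InvariantError(f"pdt must be >= 0, got {self.pdt}")
        if not (0 < self.range_min < self.range_max):
            raise InvariantError(
                f"analysis range requires 0 < range_min < range_max, "
                f"got ({self.range_min}, {self.range_max})"
            )


@dataclass(frozen=True)
class BinningParams:
    """Parameters of the moving-average binning procedure.

    ``y_seed_window`` (Y) is the window, in bases above the seed T-RF, used
    for the initial fill of an alignment bin; ``z_extend_window`` (Z) is the
    window above the running bin mean used for extension; ``ambiguity_range``
    is the inter-bin proximity below which bins are classified ambiguous.
    Defaults Y=1, Z=0.5, ambiguity range 1 base.
    """

    y_seed_window: float = 1.0
    z_extend_window: float = 0.5
    ambiguity_range: float = 1.0

    def __post_init__(self) -> None:
        for name in ("y_seed_window", "z_extend_window", "ambiguity_range"):
            if not (getattr(self, name) > 0):
                raise InvariantError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.z_extend_window > self.y_seed_window:
            raise InvariantError(
                f"z_extend_window ({self.z_extend_window}) must not exceed "
                f"y_seed_window ({self.y_seed_window})"
            )


@dataclass(frozen=True)
class AlignmentBin:
    """A group of T-RFs, at most one per profile, judged to be the same
    fragment.  ``members`` maps profile_id to the index of the member peak in
    that profile; ``mean_size`` is the arithmetic mean of member sizes on the
    alignment's size basis."""

    bin_id: int
    members: Mapping[str, int]
    mean_size: float
    status: BinStatus = "unclassified"

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", dict(self.members))

    def member_sizes(self, profiles: Mapping[str, Profile], corrected: bool = False) -> np.ndarray:
        out = []
        for pid, idx in self.members.items():
            p = profiles[pid].peaks[idx]
            out.append(p.size + (profiles[pid].size_offset if corrected else 0.0))
        return np.array(out, dtype=float)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Alignment:
    """An ordered partition of all in-scope peaks into alignment bins."""

    bins: tuple[AlignmentBin, ...]
    profile_ids: tuple[str, ...]
    params: BinningParams
    size_basis: Literal["original", "corrected"] = "original"

    def __post_init__(self) -> None:
        object.__setattr__(self, "bins", tuple(self.bins))
        object.__setattr__(self, "profile_ids", tuple(self.profile_ids))
        means = [b.mean_size for b in self.bins]
        for a, b in zip(means, means[1:]):
            if a > b:
                raise InvariantError("alignment bins must be sorted ascending by mean_size")
        seen: set[tuple[str, int]] = set()
        for b in self.bins:
            for pid, idx in b.members.items():
                if pid not in self.profile_ids:
                    raise InvariantError(f"bin member profile {pid!r} not in alignment")
                if (pid, idx) in seen:
                    raise InvariantError(
                        f"peak {idx} of profile {pid!r} appears in more than one bin"
                    )
                seen.add((pid, idx))

    def __len__(self) -> int:
        return len(self.bins)

    def total_members(self) -> int:
        return sum(len(b) for b in self.bins)

    def check_partition(self, profiles: Mapping[str, Profile]) -> None:
        """Verify every peak of every aligned profile sits in exactly one bin."""
        expected = {(pid, i) for pid in self.profile_ids for i in range(len(profiles[pid]))}
        got = {(pid, i) for b in self.bins for pid, i in b.members.items()}
        if expected != got:
            missing = expected - got
            extra = got - expected
            raise InvariantError(
                f"alignment is not a partition: {len(missing)} peaks unbinned, "
                f"{len(extra)} phantom members"
            )


@dataclass(frozen=True)
class AbundanceMatrix:
    """Relative abundances: bins (rows, labelled by mean size) x profiles
    (columns).  Each column sums to 1 over the bins retained at build time."""

    bin_sizes: tuple[float, ...]
    profile_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_bins, n_profiles)
    basis: SignalBasis = "height"

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_sizes", tuple(self.bin_sizes))
        object.__setattr__(self, "profile_ids", tuple(self.profile_ids))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.bin_sizes), len(self.profile_ids)):
            raise InvariantError(
                f"abundance matrix shape {v.shape} does not match "
                f"{len(self.bin_sizes)} bins x {len(self.profile_ids)} profiles"
            )
        if v.size:
            if (v < -1e-12).any() or (v > 1 + 1e-12).any():
                raise InvariantError("abundances must lie in [0, 1]")
            sums = v.sum(axis=0)
            nonempty = sums > 0
            if not np.allclose(sums[nonempty], 1.0, atol=1e-9):
                raise InvariantError("each profile's abundances must sum to 1")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise profile similarities in [0, 1]; symmetric with unit diagonal."""

    profile_ids: tuple[str, ...]
    values: np.ndarray
    metric: Literal["jaccard", "bray_curtis"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "profile_ids", tuple(self.profile_ids))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.profile_ids)
        if v.shape != (n, n):
            raise InvariantError(f"similarity matrix must be {n}x{n}, got {v.shape}")
        if n:
            if not np.allclose(v, v.T, atol=1e-12):
                raise InvariantError("similarity matrix must be symmetric")
            if not np.allclose(np.diag(v), 1.0, atol=1e-12):
                raise InvariantError("similarity matrix diagonal must be 1")
            if (v < -1e-12).any() or (v > 1 + 1e-12).any():
                raise InvariantError("similarities must lie in [0, 1]")


def profiles_by_id(profiles: Sequence[Profile]) -> dict[str, Profile]:
    out: dict[str, Profile] = {}
    for p in profiles:
        if p.profile_id in out:
            raise DataError(f"duplicate profile_id {p.profile_id!r}")
        out[p.profile_id] = p
    return out
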