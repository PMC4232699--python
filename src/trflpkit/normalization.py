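"""Normalization of T-RF profiles for differences in loaded DNA.

Profiles loaded with more DNA show a higher total fluorescence (TF) and,
with it, more detectable low-abundance T-RFs; unnormalized comparisons then
mistake loading differences for community differences.  Two families of
procedures are provided:

Total fluorescence normalization (TFN) rescales every profile to the lowest
TF in the group.  Signals are multiplied by TFmin/TF, peaks whose scaled
signal falls below a threshold are removed, TF is recomputed and the cycle
repeats until TF equals TFmin.  When a peak near the threshold flips in and
out — TF alternating above and below TFmin — the profile is finalized as
the peak-wise average of the two alternating states.  Variants: TFN-heights
(TF = sum of heights, threshold = the peak detection threshold), TFN-areas
(TF = sum of areas, threshold = the minimum observed area in the whole
dataset) and TFN-areas-LT (threshold = the minimum observed area among the
replicates being normalized).

Fixed percentage threshold (FPT) removes, in a single pass, every T-RF
whose relative abundance is below a fixed fraction (default 1%); signals
are not rescaled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core import DataError, DetectionConfig, Peak, Profile, SignalBasis
from .preprocess import total_fluorescence

__all__ = ["NormalizationConfig", "tfn_normalize", "fpt_normalize", "METHOD_CONFIGS"]

ThresholdRule = Literal["pdt", "global_min_area", "local_min_area"]


@dataclass(frozen=True)
class NormalizationConfig:
    """Which procedure, on which signal, with which threshold rule.

    ``tolerance`` is the relative convergence tolerance for TF = TFmin;
    ``max_iterations`` caps the TFN loop.  ``destructive`` switches the TFN
    iteration to remove peaks permanently instead of re-evaluating the full
    original peak set each round (the re-evaluating mode is the default —
    it is what makes the above/below-TFmin oscillation possible).
    """

    method: Literal["TFN", "FPT"] = "TFN"
    basis: SignalBasis = "height"
    threshold_rule: ThresholdRule = "pdt"
    fpt_fraction: float = 0.01
    tolerance: float = 1e-9
    max_iterations: int = 1000
    destructive: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.fpt_fraction < 1):
            raise DataError(f"fpt_fraction must be in (0,1), got {self.fpt_fraction}")
        if not (self.tolerance > 0):
            raise DataError("tolerance must be > 0")
        if self.method == "TFN":
            if self.basis == "height" and self.threshold_rule != "pdt":
                raise DataError("TFN on heights uses the PDT as threshold")
            if self.basis == "area" and self.threshold_rule == "pdt":
                raise DataError("TFN on areas requires an area threshold rule")


#: The five evaluated procedures by their conventional names.
METHOD_CONFIGS: dict[str, NormalizationConfig] = {
    "TFN-heights": NormalizationConfig("TFN", "height", "pdt"),
    "TFN-areas": NormalizationConfig("TFN", "area", "global_min_area"),
    "TFN-areas-LT": NormalizationConfig("TFN", "area", "local_min_area"),
    "FPT-heights": NormalizationConfig("FPT", "height", fpt_fraction=0.01),
    "FPT-areas": NormalizationConfig("FPT", "area", fpt_fraction=0.01),
}


def _scaled_profile(profile: Profile, factor: float, retained: Sequence[int], note: str) -> Profile:
    peaks = []
    for i in retained:
        p = profile.peaks[i]
        area = p.area * factor if p.has_area else math.nan
        peaks.append(Peak(size=p.size, height=p.height * factor, area=area))
    return profile.with_peaks(peaks, note)


def _averaged_profile(
    profile: Profile,
    c1: float,
    retained1: frozenset[int],
    c2: float,
    retained2: frozenset[int],
    note: str,
) -> Profile:
    """Peak-wise average of the two alternating TFN states.

    A peak absent from one state contributes zero to its average; averaged
    peaks below the threshold are retained (averaging is the terminal step).
    """
    peaks = []
    for i, p in enumerate(profile.peaks):
        w = ((c1 if i in retained1 else 0.0) + (c2 if i in retained2 else 0.0)) / 2.0
        if w > 0:
            area = p.area * w if p.has_area else math.nan
            peaks.append(Peak(size=p.size, height=p.height * w, area=area))
    return profile.with_peaks(peaks, note)


def _resolve_threshold(
    config: NormalizationConfig,
    detection: DetectionConfig,
    profiles: Sequence[Profile],
    dataset_min_area: float | None,
) -> float:
    if config.threshold_rule == "pdt":
        return detection.pdt
    areas = [p.area for prof in profiles for p in prof.peaks]
    if any(math.isnan(a) for a in areas):
        raise DataError("area threshold rule requires areas on every peak")
    local_min = min(areas) if areas else 0.0
    if config.threshold_rule == "local_min_area":
        return local_min
    if dataset_min_area is None:
        # Called with the whole dataset in one go: the group minimum is the
        # dataset minimum.
        return local_min
    return dataset_min_area


def tfn_normalize(
    profiles: Sequence[Profile],
    config: NormalizationConfig | None = None,
    detection: DetectionConfig | None = None,
    dataset_min_area: float | None = None,
) -> list[Profile]:
    """Iteratively rescale every profile in the group to the group's minimum
    total fluorescence, removing sub-threshold peaks.

    ``dataset_min_area`` supplies the whole-dataset minimum peak area for
    the ``global_min_area`` rule when the group passed here (e.g. one
    duplicate pair) is a subset of the dataset.  The minimum-TF profile is
    returned unchanged.
    """
    if config is None:
        config = NormalizationConfig()
    if detection is None:
        detection = DetectionConfig()
    if config.method != "TFN":
        raise DataError("tfn_normalize requires a TFN config")
    if len(profiles) < 2:
        raise DataError("TFN normalizes a group of at least two profiles")

    tfs = [total_fluorescence(p, config.basis) for p in profiles]
    tf_min = min(tfs)
    if tf_min <= 0:
        raise DataError("TFmin is 0; an empty profile cannot anchor normalization")
    threshold = _resolve_threshold(config, detection, profiles, dataset_min_area)

    out: list[Profile] = []
    min_taken = False
    for profile, tf0 in zip(profiles, tfs):
        if tf0 == tf_min and not min_taken:
            # exactly the minimum-TF profile: unchanged by definition
            min_taken = True
            out.append(profile)
            continue
        out.append(_tfn_one(profile, tf0, tf_min, threshold, config))
    return out


def _tfn_one(
    profile: Profile,
    tf0: float,
    tf_min: float,
    threshold: float,
    config: NormalizationConfig,
) -> Profile:
    signals = profile.signals(config.basis)
    note = f"tfn basis={config.basis} tfmin={tf_min:.6g} threshold={threshold:.6g}"
    c = 1.0
    tf = tf0
    pool = np.arange(len(signals))  # candidate peaks (shrinks only in destructive mode)
    history: list[tuple[frozenset[int], float]] = []
    for _ in range(config.max_iterations):
        c *= tf_min / tf
        scaled = signals[pool] * c
        keep_mask = scaled >= threshold
        retained = frozenset(int(i) for i in pool[keep_mask])
        if not retained:
            warnings.warn(
                f"profile {profile.profile_id!r}: TFN removed all peaks", stacklevel=3
            )
            return profile.with_peaks([], note + " -> empty")
        tf = float(signals[list(retained)].sum() * c)
        if abs(tf - tf_min) / tf_min <= config.tolerance:
            return _scaled_profile(profile, c, sorted(retained), note)
        if config.destructive:
            pool = np.array(sorted(retained))
        elif len(history) >= 2 and history[-2][0] == retained != history[-1][0]:
            # period-2 cycle: a threshold-straddling peak flips in and out;
            # finalize as the average of the two states
            (set1, c1) = history[-1]
            return _averaged_profile(
                profile, c1, set1, c, retained, note + " cycle-averaged"
            )
        history.append((retained, c))
    raise DataError(
        f"profile {profile.profile_id!r}: TFN did not converge in "
        f"{config.max_iterations} iterations and no two-state cycle was found"
    )


def fpt_normalize(profile: Profile, config: NormalizationConfig | None = None) -> Profile:
    """Remove T-RFs with relative abundance below the fixed fraction.

    Single pass: abundances are computed once on the input profile and the
    survivors' signals are not rescaled, so every retained peak's abundance,
    recomputed on the original profile, is >= the threshold.
    """
    if config is None:
        config = NormalizationConfig(method="FPT")
    if len(profile) == 0:
        raise DataError(f"profile {profile.profile_id!r} is empty")
    signals = profile.signals(config.basis)
    abundance = signals / signals.sum()
    kept = [p for p, a in zip(profile.peaks, abundance) if a >= config.fpt_fraction]
    if not kept:
        warnings.warn(
            f"profile {profile.profile_id!r}: FPT {config.fpt_fraction:.2%} removed "
            "all peaks",
            stacklevel=2,
        )
    return profile.with_peaks(
        kept, f"fpt fraction={config.fpt_fraction} basis={config.basis}"
    )
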