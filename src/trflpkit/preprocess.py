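"""Detection thresholding, total fluorescence and relative abundance.

The peak detection threshold (PDT) separates accepted T-RFs from baseline
noise and low artifact peaks; it can be applied post hoc to an already
exported peak table, so the same raw data can be analysed under several
thresholds.  Total fluorescence (TF) — the sum of peak heights or areas —
is the proxy for the amount of DNA loaded on the gel and drives the
normalization procedures.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import DataError, DetectionConfig, Profile, SignalBasis

__all__ = ["apply_detection_threshold", "total_fluorescence", "relative_abundance"]


def apply_detection_threshold(profile: Profile, config: DetectionConfig) -> Profile:
    """Retain peaks with height >= PDT and size inside the analysis range.

    Both comparisons are inclusive: the PDT is the lowest *acceptable*
    height.  Idempotent; peak order is preserved.
    """
    kept = [
        p
        for p in profile.peaks
        if p.height >= config.pdt and config.range_min <= p.size <= config.range_max
    ]
    if not kept:
        warnings.warn(
            f"profile {profile.profile_id!r}: no peaks survive PDT {config.pdt} "
            f"in range {config.range_min}-{config.range_max}",
            stacklevel=2,
        )
    return profile.with_peaks(
        kept, f"pdt={config.pdt} range={config.range_min}:{config.range_max}"
    )


def total_fluorescence(profile: Profile, basis: SignalBasis = "height") -> float:
    """Sum of peak heights (or areas) of the profile; 0 for an empty profile."""
    if len(profile) == 0:
        return 0.0
    return float(profile.signals(basis).sum())


def relative_abundance(profile: Profile, basis: SignalBasis = "height") -> np.ndarray:
    """Per-peak signal divided by total fluorescence, aligned with peak order."""
    if len(profile) == 0:
        raise DataError(f"profile {profile.profile_id!r} is empty; relative abundance undefined")
    s = profile.signals(basis)
    return s / s.sum()
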