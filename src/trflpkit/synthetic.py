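"""Synthetic T-RF profile datasets with a characterized noise structure.

The generator emulates the reproducibility-limiting phenomena observed in
repeated capillary runs of the same digest, so that detection, alignment,
shift correction and normalization can be exercised against known truth:

* per-peak size-estimation jitter — repeated loadings of the same digest
  re-estimate a fragment's size with a mean absolute difference of about
  0.21 bases and differences never reaching a full base; modelled as
  truncated Gaussian noise per peak (for the difference of two independent
  jitters, E|d| = 2*sigma/sqrt(pi));
* per-profile systematic shifts — a constant additive offset per run,
  uniform on ``shift_range``, matching the constant-offset correction
  model;
* loading-dependent total fluorescence — a per-loading multiplier with a
  bounded U-shaped (arcsine) spread around 1, sized so duplicate TF
  differences average roughly 17% of the higher TF and are hard-bounded
  near the observed 33% maximum;
* artifact peaks — spurious low peaks (baseline noise, spectral pull-up)
  with uniform sizes over the analysis range and heights spanning the
  20-30-unit baseline up to just under a high detection threshold.

Peak heights are abundance * base_signal * concentration * loading
multiplier; areas grow with fragment size (peaks broaden as they migrate),
area = height * (1 + width_slope * size).  All randomness flows from the
single seed in the spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import Alignment, DataError, Peak, Profile, profiles_by_id
from .shift_correction import ShiftCorrection

__all__ = [
    "SyntheticSpec",
    "DatasetDesign",
    "GroundTruth",
    "simulate_dataset",
    "evaluate_recovery",
    "random_community",
]

#: sigma for which E|jitter_a - jitter_b| = 0.21 bases (E|d| = 2 sigma / sqrt(pi))
DEFAULT_JITTER_SD = 0.21 * math.sqrt(math.pi) / 2.0


def random_community(
    n_fragments: int,
    rng: np.random.Generator,
    size_range: tuple[float, float] = (60.0, 1000.0),
    dominance_sd: float = 1.2,
    min_spacing: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw fragment sizes and a dominance-skewed abundance distribution.

    Log-normal abundance weights give the few-dominant/many-rare shape
    typical of community fingerprints; sizes are spaced at least
    ``min_spacing`` bases so distinct fragments are resolvable in truth.
    """
    lo, hi = size_range
    span = hi - lo
    if n_fragments * min_spacing > span:
        raise DataError(f"{n_fragments} fragments do not fit in {span} bases")
    gaps = rng.dirichlet(np.ones(n_fragments + 1)) * (span - n_fragments * min_spacing)
    sizes = lo + np.cumsum(gaps[:-1] + min_spacing) - min_spacing / 2.0
    weights = rng.lognormal(mean=0.0, sigma=dominance_sd, size=n_fragments)
    return sizes, weights / weights.sum()


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters; defaults encode the characterized noise levels."""

    true_sizes: tuple[float, ...]
    true_abundances: tuple[float, ...]
    base_signal: float = 30000.0
    jitter_sd: float = DEFAULT_JITTER_SD
    jitter_cap: float = 0.48
    shift_range: tuple[float, float] = (-0.4, 0.4)
    loading_cv: float = 0.163
    noise_peak_rate: float = 3.0
    noise_height_range: tuple[float, float] = (20.0, 100.0)
    width_slope: float = 0.002
    size_range: tuple[float, float] = (50.0, 1020.0)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_sizes", tuple(float(s) for s in self.true_sizes))
        object.__setattr__(
            self, "true_abundances", tuple(float(a) for a in self.true_abundances)
        )
        if len(self.true_sizes) != len(self.true_abundances):
            raise DataError("true_sizes and true_abundances must have equal length")
        if abs(sum(self.true_abundances) - 1.0) > 1e-9:
            raise DataError("true_abundances must sum to 1")
        if not (0 <= self.jitter_cap < 1):
            raise DataError("jitter_cap must lie in [0, 1) bases")
        lo, hi = self.size_range
        if any(not (lo <= s <= hi) for s in self.true_sizes):
            raise DataError(f"true sizes must lie within the analysis range {lo}-{hi}")

    @property
    def n_fragments(self) -> int:
        return len(self.true_sizes)

    @classmethod
    def random(cls, n_fragments: int, seed: int, **overrides) -> "SyntheticSpec":
        rng = np.random.default_rng(seed)
        sizes, abund = random_community(n_fragments, rng)
        return cls(
            true_sizes=tuple(sizes), true_abundances=tuple(abund), seed=seed, **overrides
        )


@dataclass(frozen=True)
class DatasetDesign:
    """Shape of the simulated experiment."""

    samples: int = 1
    replicates_per_sample: int = 1
    loadings_per_replicate: int = 2
    concentrations: tuple[float, ...] | None = None  # per sample; default all 1.0

    def concentration(self, sample: int) -> float:
        if self.concentrations is None:
            return 1.0
        return self.concentrations[sample]


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator actually generated, keyed for later scoring.

    ``peak_origin`` maps profile_id -> {observed size -> true fragment
    index}, with -1 marking artifact peaks; lookups key on the observed
    (uncorrected) size, which downstream operations never overwrite.
    """

    spec: SyntheticSpec
    shifts: Mapping[str, float]
    loading_multipliers: Mapping[str, float]
    concentrations: Mapping[str, float]
    peak_origin: Mapping[str, Mapping[float, int]]

    def origin(self, profile_id: str, size: float) -> int:
        return self.peak_origin[profile_id][size]


def simulate_dataset(
    spec: SyntheticSpec, design: DatasetDesign | None = None
) -> tuple[list[Profile], GroundTruth]:
    """Generate profiles for every sample x replicate x loading, plus truth.

    Identical spec (including seed) and design give byte-identical output.
    """
    if design is None:
        design = DatasetDesign()
    if design.concentrations is not None and len(design.concentrations) != design.samples:
        raise DataError("one concentration per sample required")
    rng = np.random.default_rng(spec.seed)
    sizes0 = np.array(spec.true_sizes)
    abund = np.array(spec.true_abundances)
    lo, hi = spec.size_range
    # arcsine multiplier on [1-c, 1+c]; sd of the arcsine is c/sqrt(2)
    mult_half_width = math.sqrt(2.0) * spec.loading_cv

    profiles: list[Profile] = []
    shifts: dict[str, float] = {}
    mults: dict[str, float] = {}
    concs: dict[str, float] = {}
    origins: dict[str, dict[float, int]] = {}

    for s in range(design.samples):
        conc = design.concentration(s)
        for r in range(design.replicates_per_sample):
            for l in range(design.loadings_per_replicate):
                pid = f"S{s}_R{r}_L{l}"
                shift = float(rng.uniform(*spec.shift_range))
                mult = float(1.0 + mult_half_width * (2.0 * rng.beta(0.5, 0.5) - 1.0))
                jitter = _truncated_normal(
                    rng, spec.jitter_sd, spec.jitter_cap, sizes0.size
                )
                obs_sizes = sizes0 + shift + jitter
                heights = abund * spec.base_signal * conc * mult
                origin = list(range(sizes0.size))

                n_art = int(rng.poisson(spec.noise_peak_rate))
                art_sizes = rng.uniform(lo, hi, n_art)
                art_heights = rng.uniform(*spec.noise_height_range, n_art)
                all_sizes = np.concatenate([obs_sizes, art_sizes])
                all_heights = np.concatenate([heights, art_heights])
                origin += [-1] * n_art

                order = np.argsort(all_sizes)
                all_sizes, all_heights = all_sizes[order], all_heights[order]
                origin = [origin[i] for i in order]
                # nudge exact collisions apart (a profile's sizes must be unique)
                for k in range(1, all_sizes.size):
                    if all_sizes[k] <= all_sizes[k - 1]:
                        all_sizes[k] = np.nextafter(all_sizes[k - 1], np.inf)

                peaks = tuple(
                    Peak(
                        size=float(sz),
                        height=float(h),
                        area=float(h * (1.0 + spec.width_slope * sz)),
                    )
                    for sz, h in zip(all_sizes, all_heights)
                )
                profiles.append(
                    Profile(
                        profile_id=pid,
                        sample_id=f"S{s}",
                        replicate_label=f"R{r}_L{l}",
                        peaks=peaks,
                        provenance=(f"simulated seed={spec.seed}",),
                    )
                )
                shifts[pid] = shift
                mults[pid] = mult
                concs[pid] = conc
                origins[pid] = {
                    float(sz): o for sz, o in zip(all_sizes, origin)
                }

    truth = GroundTruth(
        spec=spec,
        shifts=shifts,
        loading_multipliers=mults,
        concentrations=concs,
        peak_origin=origins,
    )
    return profiles, truth


def _truncated_normal(
    rng: np.random.Generator, sd: float, cap: float, n: int
) -> np.ndarray:
    """N(0, sd) truncated to |x| <= cap by redrawing."""
    if sd == 0:
        return np.zeros(n)
    out = rng.normal(0.0, sd, n)
    bad = np.abs(out) > cap
    while bad.any():
        out[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(out) > cap
    return out


@dataclass(frozen=True)
class RecoveryMetrics:
    """Scores of a pipeline result against simulation truth."""

    assignment_accuracy: float
    abundance_rmse: float | None
    shift_errors: dict[str, float]
    max_shift_error: float | None
    artifact_leaks: int


def evaluate_recovery(
    truth: GroundTruth,
    alignment: Alignment,
    profiles: Sequence[Profile],
    abundance_values: np.ndarray | None = None,
    correction: ShiftCorrection | None = None,
) -> RecoveryMetrics:
    """Score an alignment (and optionally abundances and shift estimates)
    against the generative truth.

    Assignment accuracy: each true fragment is credited with the peaks that
    landed in its plurality bin; the score is credited peaks over all
    observed true-fragment peaks.  Shift errors compare estimated offsets
    with the negated true shifts after removing the common additive
    constant (only relative offsets are identifiable).  Artifact leaks
    count artifact-origin peaks surviving into the alignment.
    """
    by_id = profiles_by_id(profiles)
    for pid in alignment.profile_ids:
        if pid not in truth.peak_origin:
            raise DataError(f"profile {pid!r} unknown to the ground truth record")

    frag_bins: dict[int, dict[int, int]] = {}
    artifact_leaks = 0
    total_true = 0
    bin_fragment: dict[int, int] = {}
    for b in alignment.bins:
        counts: dict[int, int] = {}
        for pid, idx in b.members.items():
            o = truth.origin(pid, by_id[pid].peaks[idx].size)
            if o < 0:
                artifact_leaks += 1
                continue
            total_true += 1
            counts[o] = counts.get(o, 0) + 1
            frag_bins.setdefault(o, {})[b.bin_id] = (
                frag_bins.setdefault(o, {}).get(b.bin_id, 0) + 1
            )
        if counts:
            bin_fragment[b.bin_id] = max(counts, key=lambda f: (counts[f], -f))
    credited = sum(max(bins.values()) for bins in frag_bins.values())
    accuracy = credited / total_true if total_true else 0.0

    rmse = None
    if abundance_values is not None:
        true_ab = np.array(truth.spec.true_abundances)
        errs: list[float] = []
        pids = alignment.profile_ids
        matched = [
            (i, bin_fragment[b.bin_id])
            for i, b in enumerate(alignment.bins)
            if b.bin_id in bin_fragment
        ]
        for j, pid in enumerate(pids):
            rows = [i for i, _ in matched]
            frags = [f for _, f in matched]
            est = abundance_values[rows, j]
            tru = true_ab[frags]
            present = est > 0
            if present.any():
                tru = np.where(present, tru, 0.0)
                tru = tru / tru.sum()
                est = est / est.sum()
                errs.extend((est - tru) ** 2)
        rmse = float(np.sqrt(np.mean(errs))) if errs else 0.0

    shift_errors: dict[str, float] = {}
    max_err = None
    if correction is not None:
        pids = list(correction.per_profile_offset)
        est = np.array([correction.per_profile_offset[p] for p in pids])
        tru = np.array([-truth.shifts[p] for p in pids])
        delta = (est - est.mean()) - (tru - tru.mean())
        shift_errors = {p: float(d) for p, d in zip(pids, delta)}
        max_err = float(np.abs(delta).max())

    return RecoveryMetrics(
        assignment_accuracy=float(accuracy),
        abundance_rmse=rmse,
        shift_errors=shift_errors,
        max_shift_error=max_err,
        artifact_leaks=artifact_leaks,
    )
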