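"""Composable treatment pipelines for T-RF profile datasets.

A treatment is a named combination of detection threshold, normalization,
alignment and correction choices.  Stages always run in the same order:

    PDT filter -> replicate normalization -> replicate alignment (with
    duplicate-pair resolution) -> consensus -> consensus normalization ->
    dataset alignment (+ systematic shift correction) -> classification ->
    drop ambiguous bins -> abundance matrix -> Jaccard and Bray-Curtis
    similarity matrices

and a stage report records the mean T-RF count and mean total fluorescence
of the working profile set after every stage, which makes the attrition of
data through a conservative treatment explicit.

The shipped presets cover the commonly compared strategies: PDT 50 or 100;
no normalization vs TFN on heights or areas of consensus profiles, with or
without additional replicate normalization; alignment with or without
systematic shift correction; and an integer round-up/down alignment as the
simple comparison.  The ``TRex-A`` and ``TRex-H`` presets assume their
input was already noise-filtered by an external statistical filter and
refuse to run otherwise; the filter itself is out of scope here.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import __version__
from .binning import (
    classify_bins,
    drop_ambiguous_bins,
    integer_bin,
    moving_average_bin,
    resolve_duplicate_ambiguity,
)
from .consensus import build_consensus
from .core import (
    AbundanceMatrix,
    BinningParams,
    DataError,
    DetectionConfig,
    Profile,
    SignalBasis,
    SimilarityMatrix,
)
from .normalization import METHOD_CONFIGS, fpt_normalize, tfn_normalize
from .preprocess import apply_detection_threshold, total_fluorescence
from .similarity import abundance_matrix, similarity_matrix

__all__ = ["TreatmentConfig", "StageRecord", "StageReport", "PRESETS", "run_treatment"]


@dataclass(frozen=True)
class TreatmentConfig:
    """One named data-treatment strategy."""

    name: str
    pdt: float = 50.0
    normalize_replicates: str | None = None  # key into METHOD_CONFIGS
    consensus: bool = True
    min_presence: int | Literal["all"] = "all"
    normalize_consensus: str | None = None
    alignment: Literal["moving_average", "integer"] = "moving_average"
    shift_correction: bool = True
    drop_ambiguous: bool = True
    basis: SignalBasis = "height"
    requires_prefiltered: bool = False
    binning: BinningParams = field(default_factory=BinningParams)

    def __post_init__(self) -> None:
        if self.alignment == "integer" and self.shift_correction:
            raise DataError("integer alignment does not support shift correction")
        for key in (self.normalize_replicates, self.normalize_consensus):
            if key is not None and key not in METHOD_CONFIGS:
                raise DataError(
                    f"unknown normalization {key!r}; choose from {sorted(METHOD_CONFIGS)}"
                )

    def digest(self) -> str:
        payload = asdict(self)
        payload["binning"] = asdict(self.binning)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


PRESETS: dict[str, TreatmentConfig] = {
    cfg.name: cfg
    for cfg in [
        TreatmentConfig(
            "PDT50 TFN-A", pdt=50, normalize_consensus="TFN-areas", basis="area"
        ),
        TreatmentConfig("PDT50 TFN-H", pdt=50, normalize_consensus="TFN-heights"),
        TreatmentConfig("PDT50 NoNorm", pdt=50),
        TreatmentConfig("PDT50 NoNorm NoAlCorr", pdt=50, shift_correction=False),
        TreatmentConfig("PDT100 TFN-H", pdt=100, normalize_consensus="TFN-heights"),
        TreatmentConfig(
            "PDT100 TFN-H RepNorm",
            pdt=100,
            normalize_replicates="TFN-heights",
            normalize_consensus="TFN-heights",
        ),
        TreatmentConfig(
            "TRex-A",
            basis="area",
            shift_correction=False,
            drop_ambiguous=False,
            requires_prefiltered=True,
        ),
        TreatmentConfig(
            "TRex-H",
            shift_correction=False,
            drop_ambiguous=False,
            requires_prefiltered=True,
        ),
        TreatmentConfig(
            "TRex-H Round-up",
            alignment="integer",
            shift_correction=False,
            drop_ambiguous=False,
            requires_prefiltered=True,
        ),
    ]
}


@dataclass(frozen=True)
class StageRecord:
    stage: str
    n_profiles: int
    mean_trf_count: float
    mean_total_fluorescence: float


@dataclass
class StageReport:
    treatment: str
    config_digest: str
    input_digest: str
    version: str
    stages: list[StageRecord] = field(default_factory=list)

    def record(self, stage: str, profiles: Sequence[Profile], basis: SignalBasis) -> None:
        counts = [len(p) for p in profiles]
        tfs = [total_fluorescence(p, basis) for p in profiles]
        self.stages.append(
            StageRecord(
                stage=stage,
                n_profiles=len(profiles),
                mean_trf_count=float(np.mean(counts)) if counts else 0.0,
                mean_total_fluorescence=float(np.mean(tfs)) if tfs else 0.0,
            )
        )

    def counts(self) -> list[float]:
        return [s.mean_trf_count for s in self.stages]


def _input_digest(profiles: Sequence[Profile]) -> str:
    h = hashlib.sha256()
    for p in sorted(profiles, key=lambda x: x.profile_id):
        h.update(p.profile_id.encode())
        for pk in p.peaks:
            h.update(np.array([pk.size, pk.height, pk.area]).tobytes())
    return h.hexdigest()[:12]


def _group_by_sample(profiles: Sequence[Profile]) -> dict[str, list[Profile]]:
    groups: dict[str, list[Profile]] = {}
    for p in profiles:
        groups.setdefault(p.sample_id, []).append(p)
    return groups


def run_treatment(
    profiles: Sequence[Profile],
    config: TreatmentConfig,
    prefiltered: bool = False,
) -> tuple[AbundanceMatrix, tuple[SimilarityMatrix, SimilarityMatrix], StageReport]:
    """Run one treatment end to end.

    Returns the relative-abundance matrix, the (Jaccard, Bray-Curtis)
    similarity matrices and the stage report.  Any stage precondition
    failure aborts with the stage name and cause.
    """
    if config.requires_prefiltered and not prefiltered:
        raise DataError(
            f"treatment {config.name!r} requires an external noise filter; supply "
            "pre-filtered input and pass prefiltered=True"
        )
    report = StageReport(
        treatment=config.name,
        config_digest=config.digest(),
        input_digest=_input_digest(profiles),
        version=__version__,
    )
    basis = config.basis
    report.record("input", profiles, basis)
    detection = DetectionConfig(pdt=config.pdt)

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise DataError(f"treatment {config.name!r}, stage {name!r}: {exc}") from exc

    current: list[Profile] = list(profiles)
    if not prefiltered:
        current = stage(
            "pdt_filter",
            lambda: [apply_detection_threshold(p, detection) for p in current],
        )
        current = [p for p in current if len(p)]
        report.record(f"pdt_{config.pdt:g}", current, basis)

    if config.normalize_replicates is not None:
        ncfg = METHOD_CONFIGS[config.normalize_replicates]
        dataset_min_area = None
        if ncfg.method == "TFN" and ncfg.threshold_rule == "global_min_area":
            dataset_min_area = min(
                pk.area for p in current for pk in p.peaks
            )

        def _norm_reps():
            out = []
            for group in _group_by_sample(current).values():
                if ncfg.method == "TFN":
                    out.extend(
                        tfn_normalize(group, ncfg, detection, dataset_min_area)
                    )
                else:
                    out.extend(fpt_normalize(p, ncfg) for p in group)
            return out

        current = stage("replicate_normalization", _norm_reps)
        report.record(f"replicate_norm_{config.normalize_replicates}", current, basis)

    if config.consensus:
        def _consensus():
            out = []
            for sample, group in sorted(_group_by_sample(current).items()):
                aln = moving_average_bin(group, config.binning)
                if len(group) == 2:
                    aln = classify_bins(aln, group)
                    aln = resolve_duplicate_ambiguity(aln, group)
                out.append(
                    build_consensus(group, aln, config.min_presence, profile_id=sample)
                )
            return [p for p in out if len(p)]

        current = stage("consensus", _consensus)
        report.record("consensus", current, basis)

    if config.normalize_consensus is not None:
        ncfg = METHOD_CONFIGS[config.normalize_consensus]

        def _norm_cons():
            if ncfg.method == "TFN":
                return tfn_normalize(current, ncfg, detection)
            return [fpt_normalize(p, ncfg) for p in current]

        current = stage("consensus_normalization", _norm_cons)
        current = [p for p in current if len(p)]
        report.record(f"consensus_norm_{config.normalize_consensus}", current, basis)

    def _align():
        if config.alignment == "integer":
            return integer_bin(current)
        return classify_bins(moving_average_bin(current, config.binning), current)

    alignment = stage("alignment", _align)
    report.record("alignment", current, basis)

    if config.shift_correction:
        from .shift_correction import correct_systematic_shift

        def _correct():
            return correct_systematic_shift(current, alignment, config.binning)

        current, _, alignment = stage("shift_correction", _correct)
        report.record("shift_correction", current, basis)

    if config.drop_ambiguous:
        if config.alignment == "integer":
            raise DataError("integer alignment has no ambiguity classification")
        alignment = stage("drop_ambiguous", lambda: drop_ambiguous_bins(alignment))
        by_id = {p.profile_id: p for p in current}
        kept_counts = {pid: 0 for pid in alignment.profile_ids}
        for b in alignment.bins:
            for pid in b.members:
                kept_counts[pid] += 1
        kept_tf = {pid: 0.0 for pid in alignment.profile_ids}
        for b in alignment.bins:
            for pid, idx in b.members.items():
                kept_tf[pid] += by_id[pid].peaks[idx].signal(basis)
        report.stages.append(
            StageRecord(
                stage="drop_ambiguous",
                n_profiles=len(current),
                mean_trf_count=float(np.mean(list(kept_counts.values()))),
                mean_total_fluorescence=float(np.mean(list(kept_tf.values()))),
            )
        )

    ab = stage("abundance_matrix", lambda: abundance_matrix(alignment, current, basis))
    jac = stage("similarity_jaccard", lambda: similarity_matrix(ab, "jaccard"))
    bc = stage("similarity_bray_curtis", lambda: similarity_matrix(ab, "bray_curtis"))
    return ab, (jac, bc), report
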