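"""Reading peak tables and writing matrices and alignment reports.

Genotyping software exports per-peak fragment tables as delimited text with
a sample identifier, fragment size, peak height and peak area.  Column
layouts vary between exports, so the reader is driven by a
:class:`PeakTableDialect`; two are shipped: the package's canonical
tab-separated layout (``sample_id  replicate  size  height  area``) and a
GeneMapper-style layout (``Sample File / Size / Height / Area``).

Outputs are plain CSV: abundance matrices (bins as rows labelled by mean
size at two decimals, profiles as columns), square similarity or distance
matrices importable by ordination software, and a plain-text alignment
report listing bins, members and statuses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    AbundanceMatrix,
    Alignment,
    DataError,
    Peak,
    Profile,
    SimilarityMatrix,
    profiles_by_id,
)

__all__ = [
    "PeakTableDialect",
    "CANONICAL",
    "GENEMAPPER",
    "read_peak_table",
    "write_peak_table",
    "write_abundance_matrix",
    "read_abundance_matrix",
    "write_similarity_matrix",
    "read_similarity_matrix",
    "write_alignment_report",
]


@dataclass(frozen=True)
class PeakTableDialect:
    """How to interpret a peak-table export: delimiter, column names and the
    decimal convention.  ``replicate_column`` may be None for exports that
    encode the loading in the sample identifier."""

    delimiter: str = "\t"
    sample_column: str = "sample_id"
    replicate_column: str | None = "replicate"
    size_column: str = "size"
    height_column: str = "height"
    area_column: str = "area"
    decimal: str = "."


CANONICAL = PeakTableDialect()
GENEMAPPER = PeakTableDialect(
    sample_column="Sample File",
    replicate_column=None,
    size_column="Size",
    height_column="Height",
    area_column="Area",
)


def read_peak_table(
    path: str | Path, dialect: PeakTableDialect = CANONICAL
) -> list[Profile]:
    """Parse a delimited peak table into one Profile per sample/replicate.

    Rows are grouped by (sample, replicate); peaks are sorted by size, so
    shuffled input rows produce identical profiles.  Rows with non-numeric
    size or height are rejected with their row number; a blank area is
    accepted and flagged missing (area-based operations then error).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter, decimal=dialect.decimal, dtype=str)
    required = [dialect.sample_column, dialect.size_column, dialect.height_column]
    for col in required:
        if col not in df.columns:
            raise DataError(f"peak table {path.name}: missing required column {col!r}")
    has_area = dialect.area_column in df.columns
    has_rep = dialect.replicate_column is not None and dialect.replicate_column in df.columns

    groups: dict[tuple[str, str], list[Peak]] = {}
    seen: dict[tuple[str, str], set[float]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        sample = str(rec[dialect.sample_column]).strip()
        rep = str(rec[dialect.replicate_column]).strip() if has_rep else ""
        try:
            size = _parse_number(rec[dialect.size_column], dialect.decimal)
            height = _parse_number(rec[dialect.height_column], dialect.decimal)
        except ValueError as exc:
            raise DataError(f"peak table {path.name} row {row_no}: {exc}") from None
        area = math.nan
        if has_area:
            raw = rec[dialect.area_column]
            if raw is not None and str(raw).strip() not in ("", "nan"):
                try:
                    area = _parse_number(raw, dialect.decimal)
                except ValueError as exc:
                    raise DataError(f"peak table {path.name} row {row_no}: {exc}") from None
        key = (sample, rep)
        if size in seen.setdefault(key, set()):
            raise DataError(
                f"peak table {path.name} row {row_no}: duplicate size {size} "
                f"for sample {sample!r}"
            )
        seen[key].add(size)
        groups.setdefault(key, []).append(Peak(size=size, height=height, area=area))

    profiles = []
    for (sample, rep), peaks in groups.items():
        pid = f"{sample}|{rep}" if rep else sample
        profiles.append(
            Profile(
                profile_id=pid,
                sample_id=sample,
                replicate_label=rep,
                peaks=tuple(sorted(peaks, key=lambda p: p.size)),
                provenance=(f"read from {path.name}",),
            )
        )
    profiles.sort(key=lambda p: p.profile_id)
    return profiles


def _parse_number(raw, decimal: str) -> float:
    s = str(raw).strip()
    if decimal != ".":
        s = s.replace(decimal, ".")
    value = float(s)  # raises ValueError with the offending text
    if math.isnan(value):
        raise ValueError(f"non-numeric value {raw!r}")
    return value


def write_peak_table(profiles: Sequence[Profile], path: str | Path) -> None:
    """Write profiles in the canonical tab-separated layout."""
    rows = []
    for prof in profiles:
        for p in prof.peaks:
            rows.append(
                {
                    "sample_id": prof.sample_id,
                    "replicate": prof.replicate_label,
                    "size": repr(p.size),
                    "height": repr(p.height),
                    "area": "" if not p.has_area else repr(p.area),
                }
            )
    pd.DataFrame(rows, columns=["sample_id", "replicate", "size", "height", "area"]).to_csv(
        path, sep="\t", index=False
    )


def write_abundance_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    """CSV with bins as rows (labelled by mean size, two decimals) and
    profiles as columns; values survive a round trip to six decimals."""
    labels = [f"{s:.2f}" for s in matrix.bin_sizes]
    df = pd.DataFrame(matrix.values, index=labels, columns=list(matrix.profile_ids))
    df.index.name = "bin_size"
    df.to_csv(path, float_format="%.6f")


def read_abundance_matrix(path: str | Path, basis: str = "height") -> AbundanceMatrix:
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    if values.size:
        sums = values.sum(axis=0)
        nonzero = sums > 0
        values[:, nonzero] /= sums[nonzero]  # restore exact unit sums after rounding
    return AbundanceMatrix(
        bin_sizes=tuple(float(i) for i in df.index),
        profile_ids=tuple(df.columns),
        values=values,
        basis=basis,
    )


def write_similarity_matrix(
    matrix: SimilarityMatrix, path: str | Path, as_distance: bool = False
) -> None:
    """Square CSV of similarities, or of distances (1 - similarity)."""
    values = 1.0 - matrix.values if as_distance else matrix.values
    df = pd.DataFrame(
        values, index=list(matrix.profile_ids), columns=list(matrix.profile_ids)
    )
    df.index.name = "profile_id"
    df.to_csv(path, float_format="%.6f")


def read_similarity_matrix(
    path: str | Path, metric: str = "bray_curtis", as_distance: bool = False
) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    if as_distance:
        values = 1.0 - values
    values = (values + values.T) / 2.0  # re-symmetrize rounding noise
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        profile_ids=tuple(df.columns), values=values, metric=metric
    )


def write_alignment_report(
    alignment: Alignment, profiles: Sequence[Profile], path: str | Path
) -> None:
    """Plain-text report: one line per bin with mean size, status and the
    member T-RF of each profile."""
    by_id = profiles_by_id(profiles)
    corrected = alignment.size_basis == "corrected"
    with open(path, "w") as fh:
        fh.write(
            f"# alignment of {len(alignment.profile_ids)} profiles, "
            f"{len(alignment.bins)} bins, size basis: {alignment.size_basis}\n"
        )
        fh.write("bin\tmean_size\tstatus\tmembers\n")
        for b in alignment.bins:
            members = "; ".join(
                f"{pid}:{by_id[pid].peaks[idx].size + (by_id[pid].size_offset if corrected else 0):.2f}"
                for pid, idx in sorted(b.members.items())
            )
            fh.write(f"{b.bin_id}\t{b.mean_size:.2f}\t{b.status}\t{members}\n")
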