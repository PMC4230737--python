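"""Readers and writers for the plain-text formats the pipeline touches.

Everything is UTF-8 and tab-separated with a header row, except BED
(headerless, per convention). Round-trips preserve values to full float
precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import BetaMatrix, Group, PeakSet, ProbeAnnotation, RRBSProfile, SampleSheet

__all__ = [
    "compute_beta",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_bed_peaks",
    "write_bed_peaks",
    "read_rrbs_table",
    "write_rrbs_table",
    "write_results_table",
    "read_results_table",
]


def compute_beta(methylated_signal, unmethylated_signal):
    """Beta value from the two channel intensities: M / (M + U).

    Accepts scalars or arrays. Raises ``ValueError`` when a signal is
    negative or when M + U == 0 (a failed probe has no defined beta).
    """
    m = np.asarray(methylated_signal, dtype=float)
    u = np.asarray(unmethylated_signal, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("signal intensities must be non-negative")
    total = m + u
    if np.any(total == 0):
        raise ValueError("undefined beta: M + U == 0 (failed probe)")
    beta = m / total
    if beta.ndim == 0:
        return float(beta)
    return beta


# ---------------------------------------------------------------- beta matrix

def read_beta_matrix(path) -> BetaMatrix:
    """Read a probes x samples TSV (first column = probe id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df = df.astype(float)
    return BetaMatrix(df)  # validation in the container


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------- sample sheet

def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ("sample_id", "group"), path)
    return SampleSheet(pd.Series(df["group"].values, index=df["sample_id"].values))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    df = pd.DataFrame({"sample_id": sheet.groups.index, "group": sheet.groups.values})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- annotation

def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    _require(
        df,
        ("probe_id",) + ProbeAnnotation.REQUIRED,
        path,
    )
    df = df.set_index("probe_id")
    df["position"] = df["position"].astype(int)
    return ProbeAnnotation(df)


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    out = annotation.table.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------- BED peaks

def read_bed_peaks(path, factor_name: str) -> PeakSet:
    """Read a BED3+ file; intervals stay 0-based half-open."""
    chroms, starts, ends = [], [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(
                    f"{path}, line {lineno}: start >= end ({start} >= {end})"
                )
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
    intervals = pd.DataFrame({"chromosome": chroms, "start": starts, "end": ends})
    return PeakSet(factor_name=factor_name, intervals=intervals)


def write_bed_peaks(peaks: PeakSet, path) -> None:
    peaks.intervals[["chromosome", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------- RRBS

def read_rrbs_table(path) -> RRBSProfile:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    _require(df, ("chromosome", "position", "methylated_count", "total_count"), path)
    df["position"] = df["position"].astype(int)
    df["methylated_count"] = df["methylated_count"].astype(int)
    df["total_count"] = df["total_count"].astype(int)
    return RRBSProfile(df)


def write_rrbs_table(profile: RRBSProfile, path) -> None:
    profile.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- results

def write_results_table(results: pd.DataFrame, path) -> None:
    """Write any tabular result as TSV (no index column)."""
    results.to_csv(path, sep="\t", index=False)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
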