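"""Core data containers for methylation-array analysis.

All beta values are methylation fractions in [0, 1] (NaN = failed probe).
Array probe positions are 1-based genomic coordinates; binding-site peaks
keep the 0-based half-open BED convention. The two conventions are only
reconciled at the overlap test (see :mod:`reprometh.enrichment`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import StrEnum

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "State",
    "AberrationClass",
    "ISLAND_CONTEXTS",
    "BetaMatrix",
    "SampleSheet",
    "ProbeAnnotation",
    "PeakSet",
    "RRBSProfile",
]


class Group(StrEnum):
    """Sample strata of the study design."""

    FIB = "FIB"
    ESC = "ESC"
    Y_IPSC = "Y_IPSC"
    T_IPSC = "T_IPSC"
    TUMOR = "TUMOR"
    NORMAL = "NORMAL"


class State(StrEnum):
    """Discrete methylation state of a (group-mean) beta value."""

    HYPER = "HYPER"
    HYPO = "HYPO"
    INTERMEDIATE = "INTERMEDIATE"


class AberrationClass(StrEnum):
    """Taxonomy of methylation aberrations in reprogrammed cells.

    CLASS_I   de novo methylation     (FIB hypo,  ESC hypo,  iPSC hyper)
    CLASS_II  failed methylation      (FIB hypo,  ESC hyper, iPSC hypo)
    CLASS_III failed demethylation    (FIB hyper, ESC hypo,  iPSC hyper)
    CLASS_IV  de novo demethylation   (FIB hyper, ESC hyper, iPSC hypo)
    """

    CLASS_I = "CLASS_I"
    CLASS_II = "CLASS_II"
    CLASS_III = "CLASS_III"
    CLASS_IV = "CLASS_IV"
    UNCLASSIFIED = "UNCLASSIFIED"


NAMED_CLASSES = (
    AberrationClass.CLASS_I,
    AberrationClass.CLASS_II,
    AberrationClass.CLASS_III,
    AberrationClass.CLASS_IV,
)

ISLAND_CONTEXTS = ("island", "shore", "shelf", "open_sea")


@dataclass
class BetaMatrix:
    """Probes x samples matrix of beta values.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample.
        Entries are floats in [0, 1]; NaN marks a failed measurement.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate probe ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValueError(
                f"beta value out of [0, 1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}: "
                f"{vals[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.values[list(sample_ids)])

    def group_mean(self, sample_ids, max_missing: float = 0.5) -> pd.Series:
        """Per-probe mean beta over ``sample_ids``.

        Missing values are excluded pairwise; a probe missing in more
        than ``max_missing`` of the samples gets a NaN mean.
        """
        sub = self.values[list(sample_ids)]
        mean = sub.mean(axis=1, skipna=True)
        frac_missing = sub.isna().mean(axis=1)
        mean[frac_missing > max_missing] = np.nan
        return mean


@dataclass
class SampleSheet:
    """Assignment of each sample to a study group."""

    groups: pd.Series  # index: sample_id -> group label (str)

    def __post_init__(self) -> None:
        if self.groups.index.has_duplicates:
            raise ValueError("duplicate sample ids in sample sheet")
        valid = {g.value for g in Group}
        bad = set(self.groups.astype(str)) - valid
        if bad:
            raise ValueError(
                f"unknown group labels {sorted(bad)}; expected one of {sorted(valid)}"
            )
        self.groups = self.groups.astype(str)

    def samples(self, group: Group | str | tuple) -> list[str]:
        """Sample ids belonging to a group (or pooled over several groups)."""
        if isinstance(group, (tuple, list, set, frozenset)):
            wanted = {str(g) for g in group}
        else:
            wanted = {str(group)}
        out = [s for s, g in self.groups.items() if g in wanted]
        return out


@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation.

    ``table`` is indexed by probe id with columns: chromosome, position
    (1-based bp), island_context (island/shore/shelf/open_sea),
    nearest_gene (symbol or NaN), tss_distance (signed bp, negative =
    upstream of the TSS; NaN when nearest_gene is missing).
    """

    table: pd.DataFrame

    REQUIRED = ("chromosome", "position", "island_context", "nearest_gene", "tss_distance")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing required columns: {missing}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate probe ids in annotation")
        ctx = self.table["island_context"].astype(str).str.lower().str.replace(" ", "_")
        bad = set(ctx) - set(ISLAND_CONTEXTS)
        if bad:
            raise ValueError(f"unknown island_context values: {sorted(bad)}")
        self.table = self.table.assign(island_context=ctx)

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class PeakSet:
    """Binding intervals of one transcription factor (BED convention).

    Intervals are 0-based half-open; they may overlap each other.
    """

    factor_name: str
    intervals: pd.DataFrame  # columns: chromosome, start, end

    def __post_init__(self) -> None:
        if not self.factor_name:
            raise ValueError("factor_name must be non-empty")
        for col in ("chromosome", "start", "end"):
            if col not in self.intervals.columns:
                raise ValueError(f"peak intervals missing column {col!r}")
        bad = self.intervals["start"] >= self.intervals["end"]
        if bad.any():
            row = self.intervals[bad].iloc[0]
            raise ValueError(
                f"malformed interval for {self.factor_name}: "
                f"{row['chromosome']}:{row['start']}-{row['end']} (start >= end)"
            )

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class RRBSProfile:
    """Per-CpG bisulfite-sequencing counts.

    ``records`` columns: chromosome, position (1-based bp),
    methylated_count, total_count.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("chromosome", "position", "methylated_count", "total_count"):
            if col not in self.records.columns:
                raise ValueError(f"RRBS table missing column {col!r}")
        r = self.records
        if (r["total_count"] < 1).any():
            raise ValueError("RRBS total_count must be >= 1")
        if ((r["methylated_count"] < 0) | (r["methylated_count"] > r["total_count"])).any():
            raise ValueError("RRBS methylated_count must satisfy 0 <= m <= total")

    def levels(self, min_coverage: int = 1) -> pd.DataFrame:
        """Methylation levels m/t at sites with total_count >= min_coverage."""
        r = self.records[self.records["total_count"] >= min_coverage]
        out = r[["chromosome", "position"]].copy()
        out["level"] = r["methylated_count"] / r["total_count"]
        return out
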