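"""Permutation-based overlap enrichment of aberrant CpGs at binding regions.

The null distribution is built by redrawing, B times and without
replacement, a probe set of the observed size from the sampling universe
(by default every probe on the array) and recounting overlaps with the
binding intervals. Empirical p-values use the plus-one estimator
(k + 1) / (B + 1), which is never zero.

Coordinate convention: a probe at 1-based position p overlaps a 0-based
half-open interval [s, e) iff s <= p - 1 < e.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import AberrationClass, ISLAND_CONTEXTS, NAMED_CLASSES, PeakSet, ProbeAnnotation

__all__ = [
    "EnrichmentResult",
    "probe_overlap_flags",
    "overlap_count",
    "permutation_enrichment",
    "permutation_overlap",
    "gene_level_enrichment",
    "island_context_enrichment",
    "tss_distance_profile",
]


@dataclass
class EnrichmentResult:
    """Summary of one permutation overlap test."""

    factor_name: str
    observed_overlap: int
    n_query: int
    null_mean: float
    null_sd: float
    null_q2_5: float
    null_q97_5: float
    null_min: int
    null_max: int
    p_enrichment: float
    p_depletion: float
    n_permutations: int
    seed: int

    @property
    def outside_null_range(self) -> bool:
        """The "red diamond" call: observed outside the entire null range."""
        return (
            self.observed_overlap > self.null_max
            or self.observed_overlap < self.null_min
        )

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["outside_null_range"] = self.outside_null_range
        return d


def _build_trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.intervals.groupby("chromosome"):
        tree = IntervalTree()
        for s, e in zip(sub["start"], sub["end"]):
            tree.addi(int(s), int(e))
        trees[chrom] = tree
    return trees


def probe_overlap_flags(annotation: ProbeAnnotation, peaks: PeakSet) -> pd.Series:
    """Boolean per-probe flag: position covered by >= 1 binding interval.

    Probes without coordinates are flagged False with a warning.
    """
    trees = _build_trees(peaks)
    tbl = annotation.table
    missing = tbl["position"].isna() | tbl["chromosome"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} probes lack coordinates; excluded from overlap",
            stacklevel=2,
        )
    flags = np.zeros(len(tbl), dtype=bool)
    chroms = tbl["chromosome"].to_numpy()
    positions = tbl["position"].to_numpy()
    for i in np.flatnonzero(~missing.to_numpy()):
        tree = trees.get(chroms[i])
        if tree is not None:
            flags[i] = bool(tree[int(positions[i]) - 1])  # 1-based -> 0-based
    return pd.Series(flags, index=tbl.index)


def overlap_count(query_probes, annotation: ProbeAnnotation, peaks: PeakSet) -> int:
    """Number of query probes whose position falls inside >= 1 interval."""
    flags = probe_overlap_flags(annotation, peaks)
    return int(flags.reindex(pd.Index(query_probes), fill_value=False).sum())


def _null_subset_indices(n: int, q: int, B: int, rng, chunk: int = 512):
    """Yield blocks of B uniform q-subsets of range(n), without replacement."""
    done = 0
    while done < B:
        b = min(chunk, B - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, q - 1, axis=1)[:, :q] if q < n else (
            np.tile(np.arange(n), (b, 1))
        )
        yield idx
        done += b


def permutation_overlap(
    query_flags_count: int,
    covered: np.ndarray,
    n_query: int,
    B: int,
    seed: int,
    factor_name: str = "",
) -> EnrichmentResult:
    """Core permutation engine on a precomputed coverage indicator.

    ``covered`` is the boolean coverage vector over the universe;
    ``query_flags_count`` the observed overlap of the query set.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = covered.size
    if n_query > n:
        raise ValueError("query larger than universe")
    rng = np.random.default_rng(seed)
    null = np.empty(B, dtype=int)
    pos = 0
    for idx in _null_subset_indices(n, n_query, B, rng):
        null[pos : pos + idx.shape[0]] = covered[idx].sum(axis=1)
        pos += idx.shape[0]
    obs = int(query_flags_count)
    p_enr = (np.sum(null >= obs) + 1) / (B + 1)
    p_dep = (np.sum(null <= obs) + 1) / (B + 1)
    return EnrichmentResult(
        factor_name=factor_name,
        observed_overlap=obs,
        n_query=int(n_query),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if B > 1 else 0.0,
        null_q2_5=float(np.quantile(null, 0.025)),
        null_q97_5=float(np.quantile(null, 0.975)),
        null_min=int(null.min()),
        null_max=int(null.max()),
        p_enrichment=float(p_enr),
        p_depletion=float(p_dep),
        n_permutations=int(B),
        seed=int(seed),
    )


def permutation_enrichment(
    query_probes,
    universe_probes,
    annotation: ProbeAnnotation,
    peaks: PeakSet,
    B: int = 10000,
    seed: int = 0,
) -> EnrichmentResult:
    """CpG-level permutation enrichment of a probe set at binding intervals."""
    query = pd.Index(query_probes)
    universe = pd.Index(universe_probes)
    if not query.isin(universe).all():
        raise ValueError("query probes must be a subset of the universe")
    flags = probe_overlap_flags(annotation, peaks)
    covered = flags.reindex(universe, fill_value=False).to_numpy()
    observed = int(flags.reindex(query, fill_value=False).sum())
    return permutation_overlap(
        observed, covered, len(query), B=B, seed=seed, factor_name=peaks.factor_name
    )


def gene_level_enrichment(
    classified_probes: pd.DataFrame,
    annotation: ProbeAnnotation,
    peaks: PeakSet,
    universe_probes=None,
    window: int = 5000,
    B: int = 10000,
    seed: int = 0,
    diff: pd.DataFrame | None = None,
) -> tuple[EnrichmentResult, pd.DataFrame]:
    """Gene-level enrichment: the unit of counting is the target gene.

    A gene counts as hit when at least one aberrant probe lying within
    ``window`` bp of its TSS overlaps a binding interval; multiple probes
    in one promoter count once. The null redraws probe sets of the
    observed size from the universe and recounts genes.

    Returns the enrichment result plus a table of observed promoter hits
    (gene, probe, TSS offset, class, factor and, when ``diff`` is given,
    delta beta).
    """
    tbl = annotation.table
    universe = pd.Index(universe_probes) if universe_probes is not None else tbl.index
    named = classified_probes[
        classified_probes["aberration_class"] != AberrationClass.UNCLASSIFIED.value
    ].drop_duplicates(subset="probe_id")
    query = pd.Index(named["probe_id"])
    if not query.isin(universe).all():
        raise ValueError("query probes must be a subset of the universe")

    flags = probe_overlap_flags(annotation, peaks)
    sub = tbl.loc[universe]
    in_window = sub["tss_distance"].abs() <= window
    has_gene = sub["nearest_gene"].notna()
    eligible = (
        in_window.to_numpy()
        & has_gene.to_numpy()
        & flags.reindex(universe, fill_value=False).to_numpy()
    )
    gene_codes, _ = pd.factorize(sub["nearest_gene"])
    gene_codes = gene_codes.copy()
    gene_codes[~eligible] = -1

    pos_of = pd.Series(np.arange(len(universe)), index=universe)
    q_idx = pos_of.loc[query].to_numpy()
    observed_genes = np.unique(gene_codes[q_idx][gene_codes[q_idx] >= 0])
    observed = len(observed_genes)

    rng = np.random.default_rng(seed)
    if B < 1:
        raise ValueError("B must be >= 1")
    null = np.empty(B, dtype=int)
    pos = 0
    for idx in _null_subset_indices(len(universe), len(query), B, rng):
        for r in range(idx.shape[0]):
            g = gene_codes[idx[r]]
            null[pos + r] = np.unique(g[g >= 0]).size
        pos += idx.shape[0]

    p_enr = (np.sum(null >= observed) + 1) / (B + 1)
    p_dep = (np.sum(null <= observed) + 1) / (B + 1)
    result = EnrichmentResult(
        factor_name=peaks.factor_name,
        observed_overlap=observed,
        n_query=len(query),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if B > 1 else 0.0,
        null_q2_5=float(np.quantile(null, 0.025)),
        null_q97_5=float(np.quantile(null, 0.975)),
        null_min=int(null.min()),
        null_max=int(null.max()),
        p_enrichment=float(p_enr),
        p_depletion=float(p_dep),
        n_permutations=int(B),
        seed=int(seed),
    )

    hit_mask = np.zeros(len(universe), dtype=bool)
    hit_mask[q_idx] = True
    hit_mask &= eligible
    hits = sub[hit_mask][["nearest_gene", "tss_distance"]].copy()
    hits.insert(0, "probe_id", hits.index)
    hits = hits.rename(columns={"nearest_gene": "gene", "tss_distance": "tss_offset"})
    hits["factor_name"] = peaks.factor_name
    cls = named.set_index("probe_id")["aberration_class"]
    hits["aberration_class"] = cls.reindex(hits["probe_id"]).to_numpy()
    if diff is not None:
        db = diff.set_index("probe_id")["delta_beta"]
        hits["delta_beta"] = db.reindex(hits["probe_id"]).to_numpy()
    return result, hits.reset_index(drop=True)


def island_context_enrichment(
    classified_probes: pd.DataFrame,
    annotation: ProbeAnnotation,
    universe_probes=None,
    B: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed/expected CpG-island-context ratios per aberration class.

    Expected counts come from uniform redraws of equal-size probe sets
    from the universe. Classes with no probes are omitted.
    """
    tbl = annotation.table
    universe = pd.Index(universe_probes) if universe_probes is not None else tbl.index
    ctx = tbl.loc[universe, "island_context"].to_numpy()
    ctx_codes = np.searchsorted(np.array(sorted(ISLAND_CONTEXTS)), ctx)
    sorted_ctx = sorted(ISLAND_CONTEXTS)

    rng = np.random.default_rng(seed)
    rows = []
    for cls in NAMED_CLASSES:
        probes = pd.Index(
            classified_probes.loc[
                classified_probes["aberration_class"] == cls.value, "probe_id"
            ]
        ).unique()
        m = len(probes)
        if m == 0:
            continue
        obs_ctx = tbl.loc[probes, "island_context"]
        observed = obs_ctx.value_counts().reindex(sorted_ctx, fill_value=0)
        null = np.zeros((B, len(sorted_ctx)), dtype=int)
        n = len(universe)
        for d in range(B):
            idx = rng.choice(n, size=m, replace=False)
            null[d] = np.bincount(ctx_codes[idx], minlength=len(sorted_ctx))
        expected = null.mean(axis=0)
        for j, context in enumerate(sorted_ctx):
            obs = observed[context]
            exp = expected[j]
            if obs >= exp:
                p = (np.sum(null[:, j] >= obs) + 1) / (B + 1)
            else:
                p = (np.sum(null[:, j] <= obs) + 1) / (B + 1)
            rows.append(
                {
                    "aberration_class": cls.value,
                    "island_context": context,
                    "observed": int(obs),
                    "expected": float(exp),
                    "ratio": float(obs / exp) if exp > 0 else np.nan,
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "aberration_class",
            "island_context",
            "observed",
            "expected",
            "ratio",
            "p_value",
        ],
    )


def tss_distance_profile(
    classified_probes: pd.DataFrame,
    annotation: ProbeAnnotation,
    bins=None,
) -> pd.DataFrame:
    """Histogram of probe-to-TSS distances per scope.

    Counts cover every classified probe with a gene annotation. Default
    bins span -6 kb .. +6 kb in 1 kb steps.
    """
    if bins is None:
        bins = np.arange(-6000, 6001, 1000)
    bins = np.asarray(bins, dtype=float)
    rows = []
    for scope, sub in classified_probes.groupby("scope"):
        probes = pd.Index(sub["probe_id"]).unique()
        tss = annotation.table.loc[probes, "tss_distance"].dropna().to_numpy()
        counts, edges = np.histogram(tss, bins=bins)
        for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
            rows.append(
                {"scope": scope, "bin_left": lo, "bin_right": hi, "count": int(c)}
            )
    return pd.DataFrame(rows, columns=["scope", "bin_left", "bin_right", "count"])
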