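"""Sample-level structure, RRBS-array concordance and tumor/normal deltas.

Clustering of the sample correlation matrix is deliberately simple:
deterministic average-linkage hierarchical clustering on the distance
1 - r. Consensus (resampled) clustering adds stochastic machinery without
changing conclusions at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .types import AberrationClass, BetaMatrix, NAMED_CLASSES, ProbeAnnotation, RRBSProfile
from .enrichment import permutation_overlap

__all__ = [
    "ConcordanceReport",
    "CancerDeltaProfile",
    "pairwise_correlation_matrix",
    "cluster_samples",
    "pca_scores",
    "rrbs_array_concordance",
    "cancer_delta_profile",
]


@dataclass
class ConcordanceReport:
    """Agreement between sequencing-based and array methylation levels."""

    n_shared_cpgs: int
    pearson_r: float  # NaN when fewer than 2 shared CpGs
    min_coverage: int


@dataclass
class CancerDeltaProfile:
    """Tumor-minus-normal methylation deltas at iPSC-aberrant CpGs."""

    delta_beta: pd.Series  # per shared CpG, tumor mean - normal mean
    theta_diff: float
    enrichment: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: scope, aberration_class, n_probes, observed_overlap,
    #          null_mean, p_enrichment, p_depletion


def pairwise_correlation_matrix(matrix: BetaMatrix) -> pd.DataFrame:
    """Sample x sample Pearson correlations, pairwise-complete over probes."""
    return matrix.values.corr(method="pearson")


def cluster_samples(correlation: pd.DataFrame, k: int) -> pd.Series:
    """Average-linkage hierarchical clustering on distance 1 - r, cut at k."""
    dist = 1.0 - correlation.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=correlation.index, name="cluster")


def pca_scores(matrix: BetaMatrix, n_components: int = 2):
    """Principal-component scores of the samples.

    Probes with any missing value are dropped; data are probe-wise
    mean-centered. Returns (scores DataFrame samples x PCs, explained
    variance ratio array). Scores are deterministic up to sign.
    """
    complete = matrix.values.dropna(axis=0)
    X = complete.to_numpy(dtype=float).T  # samples x probes
    X = X - X.mean(axis=0, keepdims=True)
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=matrix.sample_ids, columns=cols),
        pca.explained_variance_ratio_,
    )


def rrbs_array_concordance(
    rrbs: RRBSProfile,
    array_betas: pd.Series,
    annotation: ProbeAnnotation,
    min_coverage: int = 5,
) -> ConcordanceReport:
    """Pearson correlation between RRBS levels and array betas.

    RRBS sites need ``total_count >= min_coverage``; they are joined to
    array probes on exact (chromosome, position). Both assays measure
    absolute methylation, so no normalisation is applied.
    """
    levels = rrbs.levels(min_coverage=min_coverage)
    coords = annotation.table.loc[
        annotation.table.index.isin(array_betas.index), ["chromosome", "position"]
    ].copy()
    coords["beta"] = array_betas.reindex(coords.index)
    merged = levels.merge(coords.reset_index(), on=["chromosome", "position"])
    merged = merged.dropna(subset=["beta"])
    n = len(merged)
    if n >= 2:
        r = float(np.corrcoef(merged["level"], merged["beta"])[0, 1])
    else:
        r = float("nan")
    return ConcordanceReport(n_shared_cpgs=n, pearson_r=r, min_coverage=min_coverage)


def cancer_delta_profile(
    tumor: BetaMatrix,
    normal: BetaMatrix,
    classified_probes: pd.DataFrame,
    theta_diff: float = 0.2,
    B: int = 10000,
    seed: int = 0,
) -> CancerDeltaProfile:
    """Tumor-vs-normal delta beta at iPSC-aberrant CpGs, with overlap tests.

    A CpG is called cancer-hypermethylated when its tumor-minus-normal
    group-mean delta exceeds ``theta_diff`` (cancer-hypomethylated below
    -theta_diff). For every (scope, class) stratum of ``classified_probes``
    the overlap of its CpGs with the cancer-directional set (hyper for
    Classes I/III, hypo for II/IV) is tested with the permutation engine
    against the universe of all CpGs shared by both matrices.
    """
    shared = tumor.probe_ids.intersection(normal.probe_ids)
    delta = (
        tumor.values.loc[shared].mean(axis=1, skipna=True)
        - normal.values.loc[shared].mean(axis=1, skipna=True)
    )
    delta.name = "delta_beta"

    hyper_flags = (delta > theta_diff).to_numpy()
    hypo_flags = (delta < -theta_diff).to_numpy()
    gain_classes = {AberrationClass.CLASS_I.value, AberrationClass.CLASS_III.value}

    rows = []
    named = classified_probes[
        classified_probes["aberration_class"].isin([c.value for c in NAMED_CLASSES])
    ]
    rng = np.random.default_rng(seed)
    for (scope, cls), sub in named.groupby(["scope", "aberration_class"]):
        probes = pd.Index(sub["probe_id"]).unique().intersection(shared)
        if len(probes) == 0:
            continue
        covered = hyper_flags if cls in gain_classes else hypo_flags
        pos_of = pd.Series(np.arange(len(shared)), index=shared)
        obs = int(covered[pos_of.loc[probes].to_numpy()].sum())
        res = permutation_overlap(
            obs,
            covered,
            len(probes),
            B=B,
            seed=int(rng.integers(2**31 - 1)),
            factor_name=f"{scope}:{cls}",
        )
        rows.append(
            {
                "scope": scope,
                "aberration_class": cls,
                "n_probes": len(probes),
                "observed_overlap": res.observed_overlap,
                "null_mean": res.null_mean,
                "p_enrichment": res.p_enrichment,
                "p_depletion": res.p_depletion,
            }
        )
    enr = pd.DataFrame(
        rows,
        columns=[
            "scope",
            "aberration_class",
            "n_probes",
            "observed_overlap",
            "null_mean",
            "p_enrichment",
            "p_depletion",
        ],
    )
    return CancerDeltaProfile(delta_beta=delta, theta_diff=theta_diff, enrichment=enr)
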