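import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

import reprometh as rm
from reprometh.concordance import (
    cancer_delta_profile,
    cluster_samples,
    pairwise_correlation_matrix,
    pca_scores,
    rrbs_array_concordance,
)
from reprometh.types import BetaMatrix, ProbeAnnotation, RRBSProfile


def test_correlation_trivial_cases():
    rng = np.random.default_rng(1)
    b = rng.uniform(0.05, 0.95, 30)
    df = pd.DataFrame({"a": b, "dup": b, "anti": 1 - b})
    corr = pairwise_correlation_matrix(BetaMatrix(df))
    assert corr.loc["a", "dup"] == pytest.approx(1.0)
    assert corr.loc["a", "anti"] == pytest.approx(-1.0)
    assert np.allclose(corr, corr.T, atol=1e-12)
    assert np.allclose(np.diag(corr), 1.0)


def test_correlation_matches_textbook_formula():
    df = pd.DataFrame(
        {"s1": [0.1, 0.4, 0.8, 0.3], "s2": [0.2, 0.5, 0.6, 0.1],
         "s3": [0.9, 0.2, 0.3, 0.7]}
    )
    corr = pairwise_correlation_matrix(BetaMatrix(df))
    for a in df.columns:
        for b in df.columns:
            x, y = df[a].to_numpy(), df[b].to_numpy()
            r = ((x - x.mean()) * (y - y.mean())).sum() / (
                np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            )
            assert corr.loc[a, b] == pytest.approx(r, abs=1e-12)


@pytest.fixture(scope="module")
def structured_dataset():
    # realistic structure: most fib-vs-ESC differences properly reprogrammed,
    # shared aberrations dominate over factor-specific ones
    fractions = {
        "NULL": 0.59,
        "REPROGRAMMED": 0.17,
        "SHARED_I": 0.04, "SHARED_II": 0.04, "SHARED_III": 0.04, "SHARED_IV": 0.04,
        "CLASS_I": 0.02, "CLASS_II": 0.02, "CLASS_III": 0.02, "CLASS_IV": 0.02,
    }
    config = rm.SimulationConfig(n_probes=1500, class_fractions=fractions, seed=33)
    return rm.generate_dataset(config)


def test_cluster_structure_fibroblasts_alone(structured_dataset):
    matrix, sheet, _, _ = structured_dataset
    corr = pairwise_correlation_matrix(matrix)
    clusters = cluster_samples(corr, k=3)
    groups = sheet.groups.reindex(clusters.index)
    fib_clusters = set(clusters[groups == "FIB"])
    assert len(fib_clusters) == 1
    fib_cluster = fib_clusters.pop()
    assert (clusters[groups != "FIB"] != fib_cluster).all()
    esc_clusters = set(clusters[groups == "ESC"])
    ipsc_clusters = set(clusters[groups.isin(["Y_IPSC", "T_IPSC"])])
    assert esc_clusters.isdisjoint(ipsc_clusters)


def test_cluster_edge_cases(structured_dataset):
    matrix, _, _, _ = structured_dataset
    corr = pairwise_correlation_matrix(matrix)
    singletons = cluster_samples(corr, k=len(corr))
    assert singletons.nunique() == len(corr)
    # permutation invariance up to labeling
    perm = corr.sample(frac=1, axis=0, random_state=4)
    perm = perm[perm.index]
    a = cluster_samples(corr, k=3)
    b = cluster_samples(perm, k=3).reindex(a.index)
    pairs_a = np.equal.outer(a.values, a.values)
    pairs_b = np.equal.outer(b.values, b.values)
    assert (pairs_a == pairs_b).all()


def test_pca_identical_samples_zero_variance():
    df = pd.DataFrame({"s1": [0.2, 0.8, 0.5], "s2": [0.2, 0.8, 0.5],
                       "s3": [0.2, 0.8, 0.5]})
    scores, _ = pca_scores(BetaMatrix(df), n_components=2)
    assert np.allclose(scores.to_numpy(), 0.0, atol=1e-12)


def test_pca_separates_planted_groups(structured_dataset):
    matrix, sheet, _, _ = structured_dataset
    pluri = sheet.samples(("ESC", "Y_IPSC", "T_IPSC"))
    scores, _ = pca_scores(matrix.subset_samples(pluri), n_components=2)
    labels = sheet.groups.reindex(scores.index)
    assert silhouette_score(scores.to_numpy(), labels) > 0


def test_pca_full_rank_preserves_distances(structured_dataset):
    matrix, _, _, _ = structured_dataset
    sub = matrix.subset_samples(matrix.sample_ids[:6])
    scores, evr = pca_scores(sub, n_components=6)
    assert evr.sum() == pytest.approx(1.0, abs=1e-9)
    X = sub.values.to_numpy().T
    X = X - X.mean(axis=0, keepdims=True)
    for i in range(6):
        for j in range(6):
            d_orig = np.linalg.norm(X[i] - X[j])
            d_pca = np.linalg.norm(scores.iloc[i] - scores.iloc[j])
            assert d_pca == pytest.approx(d_orig, abs=1e-8)


def _annotation_for(matrix):
    n = matrix.shape[0]
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "chromosome": ["chr1"] * n,
                "position": np.arange(1000, 1000 + 100 * n, 100),
                "island_context": ["open_sea"] * n,
                "nearest_gene": [f"G{i}" for i in range(n)],
                "tss_distance": [0] * n,
            },
            index=matrix.probe_ids,
        )
    )


def test_rrbs_exact_grid_gives_perfect_correlation():
    depth = 10
    betas = pd.Series(
        np.arange(1, 10) / depth, index=[f"cg{i}" for i in range(9)]
    )
    matrix = BetaMatrix(betas.to_frame("s1"))
    ann = _annotation_for(matrix)
    records = pd.DataFrame(
        {
            "chromosome": ann.table["chromosome"].values,
            "position": ann.table["position"].values,
            "methylated_count": (betas.values * depth).round().astype(int),
            "total_count": depth,
        }
    )
    rep = rrbs_array_concordance(RRBSProfile(records), betas, ann, min_coverage=5)
    assert rep.n_shared_cpgs == 9
    assert rep.pearson_r == pytest.approx(1.0, abs=1e-12)


def test_rrbs_low_coverage_sites_excluded():
    betas = pd.Series([0.5, 0.6], index=["cg0", "cg1"])
    matrix = BetaMatrix(betas.to_frame("s1"))
    ann = _annotation_for(matrix)
    records = pd.DataFrame(
        {
            "chromosome": ann.table["chromosome"].values,
            "position": ann.table["position"].values,
            "methylated_count": [1, 2],
            "total_count": [4, 3],
        }
    )
    rep = rrbs_array_concordance(RRBSProfile(records), betas, ann, min_coverage=5)
    assert rep.n_shared_cpgs == 0
    assert np.isnan(rep.pearson_r)


def test_cancer_profile_null_and_antisymmetry(default_dataset, default_analysis):
    _, matrix, _, _, _ = default_dataset
    factor = default_analysis["factor"]
    same = BetaMatrix(matrix.values.iloc[:, :6].copy())
    prof = cancer_delta_profile(same, same, factor, B=100, seed=1)
    assert np.allclose(prof.delta_beta, 0.0)
    assert (prof.enrichment["observed_overlap"] == 0).all()
    assert (prof.enrichment["p_enrichment"] == 1.0).all()

    other = BetaMatrix(matrix.values.iloc[:, 6:12].copy())
    ab = cancer_delta_profile(same, other, factor, B=100, seed=1)
    ba = cancer_delta_profile(other, same, factor, B=100, seed=1)
    assert np.allclose(ab.delta_beta, -ba.delta_beta)


def test_cancer_profile_planted_overlap_and_disjoint(default_dataset, default_analysis):
    _, matrix, _, _, truth = default_dataset
    factor = default_analysis["factor"]
    t1 = truth.aberrant_probes(["T_I"])
    B = 999
    # tumor hypermethylated exactly at the T-specific Class I probes
    tumor, normal, _ = rm.generate_tumor_normal(matrix.probe_ids, t1, seed=21)
    prof = cancer_delta_profile(tumor, normal, factor, B=B, seed=2)
    enr = prof.enrichment.set_index(["scope", "aberration_class"])
    assert enr.loc[("T_specific", "CLASS_I"), "p_enrichment"] == pytest.approx(
        1 / (B + 1)
    )
    # a disjoint hypermethylated set of equal size flags depletion
    null_probes = truth.labels.index[truth.labels == "NULL"][: len(t1)]
    tumor2, normal2, _ = rm.generate_tumor_normal(matrix.probe_ids, null_probes, seed=22)
    prof2 = cancer_delta_profile(tumor2, normal2, factor, B=B, seed=3)
    enr2 = prof2.enrichment.set_index(["scope", "aberration_class"])
    row = enr2.loc[("T_specific", "CLASS_I")]
    assert row["observed_overlap"] == 0
    assert row["p_depletion"] < 0.05
    assert row["p_enrichment"] > 0.95
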