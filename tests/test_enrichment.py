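import numpy as np
import pandas as pd
import pytest
from scipy import stats

import reprometh as rm
from reprometh.enrichment import (
    gene_level_enrichment,
    island_context_enrichment,
    overlap_count,
    permutation_enrichment,
    tss_distance_profile,
)
from reprometh.types import PeakSet, ProbeAnnotation


def _annotation(positions, chrom="chr1", genes=None, tss=None, contexts=None):
    n = len(positions)
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "chromosome": [chrom] * n,
                "position": positions,
                "island_context": contexts or ["open_sea"] * n,
                "nearest_gene": genes or [f"G{i}" for i in range(n)],
                "tss_distance": tss if tss is not None else [0] * n,
            },
            index=[f"cg{i}" for i in range(n)],
        )
    )


def _peaks(intervals, factor="NANOG"):
    return PeakSet(
        factor,
        pd.DataFrame(intervals, columns=["chromosome", "start", "end"]),
    )


def test_overlap_count_boundaries():
    ann = _annotation([150, 201, 101, 100])
    peaks = _peaks([("chr1", 100, 200)])
    # pos p overlaps [s, e) iff s <= p-1 < e
    assert overlap_count(["cg0"], ann, peaks) == 1  # 150 inside
    assert overlap_count(["cg1"], ann, peaks) == 0  # 201 just past half-open end
    assert overlap_count(["cg2"], ann, peaks) == 1  # 101 -> 0-based 100, first base
    assert overlap_count(["cg3"], ann, peaks) == 0  # 100 -> 0-based 99, before start
    assert overlap_count(["cg0", "cg1"], ann, _peaks([], "X")) == 0


def test_saturated_peaks_give_p_one():
    ann = _annotation(list(range(100, 600, 50)))
    peaks = _peaks([("chr1", 0, 10000)])
    res = permutation_enrichment(
        [f"cg{i}" for i in range(4)], ann.probe_ids, ann, peaks, B=200, seed=1
    )
    assert res.observed_overlap == 4
    assert res.p_enrichment == pytest.approx(1.0)
    assert res.p_depletion == pytest.approx(1.0)


def test_permutation_invariants():
    rng = np.random.default_rng(3)
    positions = np.arange(1000, 1000 + 500 * 40, 500)
    ann = _annotation(list(positions))
    covered_idx = rng.choice(40, 12, replace=False)
    peaks = _peaks([("chr1", positions[i] - 5, positions[i] + 5) for i in covered_idx])
    query = [f"cg{i}" for i in rng.choice(40, 10, replace=False)]
    res = permutation_enrichment(query, ann.probe_ids, ann, peaks, B=499, seed=11)
    assert res.p_enrichment >= 1 / 500 and res.p_depletion >= 1 / 500
    assert res.p_enrichment + res.p_depletion >= 1.0
    again = permutation_enrichment(query, ann.probe_ids, ann, peaks, B=499, seed=11)
    assert res.to_dict() == again.to_dict()


def test_permutation_matches_hypergeometric_small_instance():
    # universe 20 probes, 8 covered, query 5: closed-form tail oracle
    positions = np.arange(1000, 1000 + 500 * 20, 500)
    ann = _annotation(list(positions))
    peaks = _peaks([("chr1", positions[i] - 5, positions[i] + 5) for i in range(8)])
    query = [f"cg{i}" for i in (0, 1, 2, 10, 11)]  # 3 covered
    B = 4000
    res = permutation_enrichment(query, ann.probe_ids, ann, peaks, B=B, seed=5)
    p_true = stats.hypergeom.sf(res.observed_overlap - 1, 20, 8, 5)
    se = np.sqrt(p_true * (1 - p_true) / B)
    assert abs(res.p_enrichment - p_true) <= 3 * se + 1 / (B + 1)


def test_query_must_be_subset_of_universe():
    ann = _annotation([100, 200, 300])
    with pytest.raises(ValueError, match="subset"):
        permutation_enrichment(["cgX"], ann.probe_ids, ann, _peaks([]), B=10, seed=0)


def _classified(probe_ids, cls="CLASS_I", scope="shared"):
    return pd.DataFrame(
        {"probe_id": probe_ids, "aberration_class": cls, "scope": scope}
    )


def test_gene_level_counts_genes_not_probes():
    # two probes in one gene promoter, both in peaks -> one gene hit
    ann = _annotation(
        [1000, 2000, 50000, 60000],
        genes=["GENEA", "GENEA", "GENEB", "GENEC"],
        tss=[-100, 150, 0, 0],
    )
    peaks = _peaks([("chr1", 0, 3000)])
    res, hits = gene_level_enrichment(
        _classified(["cg0", "cg1"]), ann, peaks, B=50, seed=2
    )
    assert res.observed_overlap == 1
    assert set(hits["gene"]) == {"GENEA"}
    # idempotent under probe duplication
    res_dup, _ = gene_level_enrichment(
        _classified(["cg0", "cg1", "cg0"]), ann, peaks, B=50, seed=2
    )
    assert res_dup.observed_overlap == 1


def test_gene_level_window_boundary():
    ann = _annotation([1000, 2000], genes=["GENEA", "GENEB"], tss=[5001, -5000])
    peaks = _peaks([("chr1", 0, 3000)])
    res, hits = gene_level_enrichment(
        _classified(["cg0", "cg1"]), ann, peaks, window=5000, B=50, seed=4
    )
    assert res.observed_overlap == 1  # +5001 excluded, -5000 included
    assert set(hits["gene"]) == {"GENEB"}


def test_gene_level_power_with_planted_enrichment(default_dataset):
    _, matrix, _, annotation, truth = default_dataset
    targets = ["SHARED_I", "SHARED_II", "Y_I", "Y_II", "T_I", "T_II"]
    peaks = rm.generate_peaks(
        truth, annotation, "NANOG", enrichment_odds=20, seed=3, target_labels=targets
    )
    probes = truth.aberrant_probes(targets)
    classified = _classified(
        probes, cls=[str(rm.GroundTruth.label_class(l)) for l in truth.labels[probes]]
    )
    res, _ = gene_level_enrichment(classified, annotation, peaks, B=2000, seed=6)
    assert res.observed_overlap > res.null_max


def test_island_context_enrichment_all_island_set():
    rng = np.random.default_rng(8)
    n = 400
    contexts = list(np.repeat(["island", "shore", "shelf", "open_sea"], n // 4))
    ann = _annotation(
        list(np.arange(1000, 1000 + 500 * n, 500)), contexts=contexts
    )
    islands = [f"cg{i}" for i in range(n // 4)]
    res = island_context_enrichment(
        _classified(islands[:40], cls="CLASS_II"), ann, B=500, seed=9
    )
    row = res.set_index(["aberration_class", "island_context"]).loc[
        ("CLASS_II", "island")
    ]
    assert row["ratio"] == pytest.approx(4.0, rel=0.1)
    assert row["p_value"] <= 0.01
    # classes absent from the input are omitted
    assert set(res["aberration_class"]) == {"CLASS_II"}


def test_island_context_calibration_random_set():
    rng = np.random.default_rng(10)
    n = 400
    contexts = list(rng.choice(["island", "shore", "shelf", "open_sea"], n))
    ann = _annotation(list(np.arange(1000, 1000 + 500 * n, 500)), contexts=contexts)
    random_probes = [f"cg{i}" for i in rng.choice(n, 80, replace=False)]
    res = island_context_enrichment(
        _classified(random_probes, cls="CLASS_III"), ann, B=500, seed=12
    )
    # ratio sampling sd for an 80-probe draw is ~0.19 per context; allow 3 sd
    assert (res["ratio"] - 1.0).abs().max() < 0.57


def test_tss_profile_conservation_and_symmetry():
    tss = [0] * 10
    ann = _annotation(list(np.arange(1000, 1000 + 500 * 10, 500)), tss=tss)
    prof = tss_distance_profile(_classified([f"cg{i}" for i in range(10)]), ann)
    assert prof["count"].sum() == 10
    assert (prof.loc[prof["count"] > 0].shape[0]) == 1  # single central bin

    sym_tss = [-1500, -500, 500, 1500, -2500, 2500, -3500, 3500, -4500, 4500]
    ann2 = _annotation(list(np.arange(1000, 1000 + 500 * 10, 500)), tss=sym_tss)
    prof2 = tss_distance_profile(_classified([f"cg{i}" for i in range(10)]), ann2)
    counts = prof2["count"].to_numpy()
    assert (counts == counts[::-1]).all()
    assert counts.sum() == 10
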