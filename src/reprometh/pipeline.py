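"""End-to-end orchestration of the two analyses.

``run_full_pipeline`` wires the stages together: differential methylation
of pooled iPSCs vs ESCs (shared aberrations) and of Y- vs T-iPSCs
(factor-specific aberrations), Class I-IV classification, composition and
observed/expected summaries, binding-site and island-context enrichment,
TSS profiles, and sample-level structure. Every output is a TSV or JSON
file listed, with its SHA-256 checksum, in ``manifest.json``; thresholds,
seeds and input checksums are recorded in ``run.log``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .classify import (
    class_composition,
    factor_specific_aberrations,
    observed_expected_class_ratio,
    shared_aberrations,
)
from .concordance import (
    cluster_samples,
    pairwise_correlation_matrix,
    pca_scores,
    rrbs_array_concordance,
)
from .diffmeth import call_differential
from .enrichment import (
    gene_level_enrichment,
    island_context_enrichment,
    permutation_enrichment,
    tss_distance_profile,
)
from .types import Group

__all__ = ["PipelineConfig", "run_full_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and analysis parameters for one pipeline run."""

    beta_path: str
    samples_path: str
    annotation_path: str
    peak_paths: dict = field(default_factory=dict)  # factor name -> BED path
    rrbs_path: str | None = None
    rrbs_sample: str | None = None
    theta_diff: float = 0.2
    theta_hyper: float = 0.7
    theta_hypo: float = 0.3
    alpha: float = 0.05
    n_permutations: int = 10000
    tss_window: int = 5000
    n_clusters: int = 3
    seed: int = 1
    outdir: str = "reprometh_out"

    def __post_init__(self) -> None:
        for name in ("theta_diff", "theta_hyper", "theta_hypo", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if self.theta_hypo >= self.theta_hyper:
            raise ValueError("theta_hypo must be below theta_hyper")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run both analyses and write all result tables to ``config.outdir``.

    Returns the manifest dict. Deterministic under a fixed config seed.
    Any stage failure aborts with the stage name in the exception message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    inputs = {
        "beta": config.beta_path,
        "samples": config.samples_path,
        "annotation": config.annotation_path,
        **{f"peaks_{f}": p for f, p in config.peak_paths.items()},
    }
    if config.rrbs_path:
        inputs["rrbs"] = config.rrbs_path
    for name, path in inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"stage=read_inputs: missing input {name}: {path}")
        log(f"input {name} path={path} sha256={_sha256(Path(path))}")
    for name in (
        "theta_diff",
        "theta_hyper",
        "theta_hypo",
        "alpha",
        "n_permutations",
        "tss_window",
        "seed",
    ):
        log(f"param {name}={getattr(config, name)}")

    rng = np.random.default_rng(config.seed)

    def stage_seed() -> int:
        return int(rng.integers(2**31 - 1))

    outputs: dict[str, pd.DataFrame | dict] = {}

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"stage={name}: {exc}") from exc

    matrix = run_stage("read_beta", lambda: rio.read_beta_matrix(config.beta_path))
    sheet = run_stage("read_samples", lambda: rio.read_sample_sheet(config.samples_path))
    annotation = run_stage(
        "read_annotation", lambda: rio.read_probe_annotation(config.annotation_path)
    )
    peaks = {
        factor: run_stage("read_peaks", lambda p=path, f=factor: rio.read_bed_peaks(p, f))
        for factor, path in config.peak_paths.items()
    }

    # ---- differential methylation
    diff_shared = run_stage(
        "diffmeth_shared",
        lambda: call_differential(
            matrix, sheet, (Group.Y_IPSC, Group.T_IPSC), Group.ESC,
            theta_diff=config.theta_diff, alpha=config.alpha,
        ),
    )
    diff_factor = run_stage(
        "diffmeth_factor",
        lambda: call_differential(
            matrix, sheet, Group.Y_IPSC, Group.T_IPSC,
            theta_diff=config.theta_diff, alpha=config.alpha,
        ),
    )
    outputs["diffmeth_shared.tsv"] = diff_shared
    outputs["diffmeth_factor.tsv"] = diff_factor
    log(f"diffmeth shared: {int(diff_shared['significant'].sum())} significant probes")
    log(f"diffmeth factor: {int(diff_factor['significant'].sum())} significant probes")

    # ---- classification
    shared = run_stage(
        "classify_shared", lambda: shared_aberrations(matrix, sheet, diff_shared)
    )
    factor = run_stage(
        "classify_factor", lambda: factor_specific_aberrations(matrix, sheet, diff_factor)
    )
    outputs["classified_shared.tsv"] = shared
    outputs["classified_factor.tsv"] = factor
    outputs["composition_shared.tsv"] = class_composition(shared)
    outputs["composition_Y_specific.tsv"] = class_composition(
        factor[factor["scope"] == "Y_specific"]
    )
    outputs["composition_T_specific.tsv"] = class_composition(
        factor[factor["scope"] == "T_specific"]
    )
    for scope, sub in (("shared", shared), ("factor", factor)):
        if (sub["aberration_class"] != "UNCLASSIFIED").any():
            outputs[f"observed_expected_{scope}.tsv"] = run_stage(
                "observed_expected",
                lambda s=sub: observed_expected_class_ratio(
                    s, matrix, sheet, n_draws=config.n_permutations, seed=stage_seed()
                ),
            )

    # ---- enrichment at binding regions (per factor, per scope)
    enr_rows = []
    hits_frames = []
    for factor_name, peakset in peaks.items():
        for scope in ("shared", "Y_specific", "T_specific"):
            sub = shared if scope == "shared" else factor[factor["scope"] == scope]
            named = sub[sub["aberration_class"] != "UNCLASSIFIED"]
            if named.empty:
                continue
            query = pd.Index(named["probe_id"]).unique()
            cpg = run_stage(
                "enrichment_cpg",
                lambda q=query, ps=peakset: permutation_enrichment(
                    q, matrix.probe_ids, annotation, ps,
                    B=config.n_permutations, seed=stage_seed(),
                ),
            )
            gene_res, hits = run_stage(
                "enrichment_gene",
                lambda n=named, ps=peakset, d=(
                    diff_shared if scope == "shared" else diff_factor
                ): gene_level_enrichment(
                    n, annotation, ps, window=config.tss_window,
                    B=config.n_permutations, seed=stage_seed(), diff=d,
                ),
            )
            for level, res in (("cpg", cpg), ("gene", gene_res)):
                row = res.to_dict()
                row.update({"scope": scope, "level": level})
                enr_rows.append(row)
            hits["scope"] = scope
            hits_frames.append(hits)
    if enr_rows:
        outputs["enrichment.tsv"] = pd.DataFrame(enr_rows)
    if hits_frames:
        outputs["gene_promoter_hits.tsv"] = pd.concat(hits_frames, ignore_index=True)

    # ---- genomic context
    for scope, sub in (("shared", shared), ("factor", factor)):
        if not sub.empty:
            ctx = run_stage(
                "island_context",
                lambda s=sub: island_context_enrichment(
                    s, annotation, B=min(config.n_permutations, 2000), seed=stage_seed()
                ),
            )
            if not ctx.empty:
                outputs[f"island_context_{scope}.tsv"] = ctx
    profile = tss_distance_profile(pd.concat([shared, factor], ignore_index=True), annotation)
    if not profile.empty:
        outputs["tss_distance_profile.tsv"] = profile

    # ---- sample-level structure
    corr = pairwise_correlation_matrix(matrix)
    outputs["sample_correlation.tsv"] = corr.reset_index(names="sample_id")
    clusters = cluster_samples(corr, k=config.n_clusters)
    outputs["sample_clusters.tsv"] = (
        clusters.rename_axis("sample_id").reset_index()
    )
    scores, evr = pca_scores(matrix, n_components=2)
    outputs["pca_scores.tsv"] = scores.reset_index(names="sample_id")
    log(f"pca explained variance ratio: {[round(float(v), 4) for v in evr]}")

    # ---- optional RRBS concordance
    if config.rrbs_path and config.rrbs_sample:
        rrbs = run_stage("read_rrbs", lambda: rio.read_rrbs_table(config.rrbs_path))
        report = run_stage(
            "rrbs_concordance",
            lambda: rrbs_array_concordance(
                rrbs, matrix.values[config.rrbs_sample], annotation
            ),
        )
        outputs["rrbs_concordance.json"] = dataclasses.asdict(report)
        log(
            f"rrbs concordance: r={report.pearson_r:.4f} "
            f"n={report.n_shared_cpgs} min_coverage={report.min_coverage}"
        )

    # ---- write everything + manifest
    manifest: dict = {"outputs": {}, "config": dataclasses.asdict(config)}
    for name, obj in outputs.items():
        path = outdir / name
        if isinstance(obj, pd.DataFrame):
            rio.write_results_table(obj, path)
        else:
            path.write_text(json.dumps(obj, indent=2))
        manifest["outputs"][name] = _sha256(path)
    log_path.write_text("\n".join(log_lines) + "\n")
    manifest["outputs"]["run.log"] = _sha256(log_path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
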