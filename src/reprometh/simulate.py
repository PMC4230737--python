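"""Synthetic methylation-array data with planted aberrations.

The generator emulates the four-group reprogramming design: one parental
fibroblast culture (profiled as technical replicates), reference embryonic
stem cell (ESC) lines, and two cohorts of induced pluripotent stem cells
made with different factor cocktails (Y-iPSC and T-iPSC). Each probe is
planted with one ground-truth label:

* ``NULL`` — every group shares one methylation state;
* ``REPROGRAMMED`` — the fibroblast state differs but every pluripotent
  group matches the ESC state (a properly reset CpG, the dominant
  fibroblast-vs-pluripotent difference in real data; default fraction 0);
* ``SHARED_I`` .. ``SHARED_IV`` — both iPSC cohorts carry the aberration
  (Class I de novo methylation, II failed methylation, III failed
  demethylation, IV de novo demethylation) relative to ESC and fibroblast;
* ``Y_I`` .. ``Y_IV`` / ``T_I`` .. ``T_IV`` — only one cohort is aberrant,
  the other matches the ESC state.

Per-sample beta values are drawn from a beta distribution with the state's
mean and a concentration parameter kappa (variance = mu(1-mu)/(kappa+1)),
the standard model for bounded methylation fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    AberrationClass,
    BetaMatrix,
    Group,
    ISLAND_CONTEXTS,
    PeakSet,
    ProbeAnnotation,
    RRBSProfile,
    SampleSheet,
    State,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_peaks",
    "simulate_rrbs",
    "generate_tumor_normal",
    "recovery_report",
]

# fraction keys accepted in SimulationConfig.class_fractions; CLASS_k plants a
# factor-specific aberration whose affected cohort (Y or T) is drawn 50/50
_SHARED_KEYS = ("SHARED_I", "SHARED_II", "SHARED_III", "SHARED_IV")
_SPECIFIC_KEYS = ("CLASS_I", "CLASS_II", "CLASS_III", "CLASS_IV")

# planted state per label: (FIB, ESC, Y_IPSC, T_IPSC)
H, L = State.HYPER, State.HYPO
_LABEL_STATES: dict[str, tuple[State, State, State, State]] = {
    "SHARED_I": (L, L, H, H),
    "SHARED_II": (L, H, L, L),
    "SHARED_III": (H, L, H, H),
    "SHARED_IV": (H, H, L, L),
    "Y_I": (L, L, H, L),
    "Y_II": (L, H, L, H),
    "Y_III": (H, L, H, L),
    "Y_IV": (H, H, L, H),
    "T_I": (L, L, L, H),
    "T_II": (L, H, H, L),
    "T_III": (H, L, L, H),
    "T_IV": (H, H, H, L),
}

_LABEL_CLASS = {
    f"{scope}_{suffix}": AberrationClass[f"CLASS_{suffix}"]
    for scope in ("SHARED", "Y", "T")
    for suffix in ("I", "II", "III", "IV")
}


def _default_group_sizes() -> dict[str, int]:
    # 1 fibroblast pool (3 technical replicates so rank tests are defined),
    # 5 ESC lines, 9 Y-iPSC and 6 T-iPSC clones
    return {Group.FIB: 3, Group.ESC: 5, Group.Y_IPSC: 9, Group.T_IPSC: 6}


def _default_class_fractions() -> dict[str, float]:
    # 10% planted per named class (four shared + four factor-specific)
    d = {k: 0.1 for k in _SHARED_KEYS + _SPECIFIC_KEYS}
    d["NULL"] = 1.0 - sum(d.values())
    return d


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset; defaults are the study conditions."""

    n_probes: int = 2000
    group_sizes: dict = field(default_factory=_default_group_sizes)
    class_fractions: dict = field(default_factory=_default_class_fractions)
    noise_concentration: float = 100.0
    state_means: dict = field(default_factory=lambda: {"HYPER": 0.85, "HYPO": 0.15})
    island_context_freqs: tuple = (0.31, 0.23, 0.10, 0.36)
    gene_missing_rate: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1 (got {total})")
        unknown = set(self.class_fractions) - set(
            ("NULL", "REPROGRAMMED") + _SHARED_KEYS + _SPECIFIC_KEYS
        )
        if unknown:
            raise ValueError(f"unknown class_fraction keys: {sorted(unknown)}")
        if not self.state_means["HYPER"] > 0.7:
            raise ValueError("HYPER state mean must exceed 0.7")
        if not self.state_means["HYPO"] < 0.3:
            raise ValueError("HYPO state mean must be below 0.3")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if self.noise_concentration <= 0:
            raise ValueError("noise_concentration must be positive")


@dataclass
class GroundTruth:
    """Planted per-probe labels; the recovery target for the pipeline."""

    labels: pd.Series  # probe_id -> label string

    def aberrant_probes(self, labels=None) -> pd.Index:
        """Probes whose label is aberrant (optionally restricted to ``labels``)."""
        if labels is None:
            mask = ~self.labels.isin(("NULL", "REPROGRAMMED"))
        else:
            mask = self.labels.isin(set(labels))
        return self.labels.index[mask]

    @staticmethod
    def label_class(label: str) -> AberrationClass:
        return _LABEL_CLASS.get(label, AberrationClass.UNCLASSIFIED)

    @staticmethod
    def label_scope(label: str) -> str | None:
        """'shared', 'Y_specific', 'T_specific' or None for NULL."""
        if label.startswith("SHARED"):
            return "shared"
        if label.startswith("Y_"):
            return "Y_specific"
        if label.startswith("T_"):
            return "T_specific"
        return None


def generate_dataset(
    config: SimulationConfig,
) -> tuple[BetaMatrix, SampleSheet, ProbeAnnotation, GroundTruth]:
    """Simulate a full study: beta matrix, sample sheet, annotation, truth.

    Deterministic for a fixed ``config.seed`` (NumPy PCG64 generator).
    Probe positions are spaced >= 2 kb apart so fixed-width peaks from
    :func:`generate_peaks` never cover a neighbouring probe.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id")

    # ---- plant labels
    keys = [
        k
        for k in ("NULL", "REPROGRAMMED") + _SHARED_KEYS + _SPECIFIC_KEYS
        if k in config.class_fractions
    ]
    probs = np.array([config.class_fractions[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    drawn = rng.choice(len(keys), size=n, p=probs)
    subtype = rng.random(n) < 0.5  # True -> Y, for factor-specific plants
    labels = []
    for i, ki in enumerate(drawn):
        key = keys[ki]
        if key in _SPECIFIC_KEYS:
            labels.append(("Y_" if subtype[i] else "T_") + key.split("_", 1)[1])
        else:
            labels.append(key)
    truth = GroundTruth(pd.Series(labels, index=probe_ids, name="label"))

    # ---- per-probe per-group state means
    mu = {State.HYPER: config.state_means["HYPER"], State.HYPO: config.state_means["HYPO"]}
    null_state = np.where(rng.random(n) < 0.5, State.HYPER, State.HYPO)
    group_order = [Group.FIB, Group.ESC, Group.Y_IPSC, Group.T_IPSC]
    means = np.empty((n, 4), dtype=float)
    flip = {State.HYPER: State.HYPO, State.HYPO: State.HYPER}
    for i, label in enumerate(labels):
        if label == "NULL":
            states = (null_state[i],) * 4
        elif label == "REPROGRAMMED":
            esc = null_state[i]
            states = (flip[esc], esc, esc, esc)
        else:
            states = _LABEL_STATES[label]
        means[i] = [mu[s] for s in states]

    # ---- draw per-sample betas
    kappa = config.noise_concentration
    prefixes = {Group.FIB: "FIB", Group.ESC: "ESC", Group.Y_IPSC: "Y", Group.T_IPSC: "T"}
    columns: dict[str, np.ndarray] = {}
    group_of: dict[str, str] = {}
    for gi, group in enumerate(group_order):
        size = config.group_sizes.get(group, 0)
        m = means[:, gi]
        a, b = m * kappa, (1.0 - m) * kappa
        for j in range(size):
            sid = f"{prefixes[group]}_{j + 1}"
            columns[sid] = rng.beta(a, b)
            group_of[sid] = group.value
    matrix = BetaMatrix(pd.DataFrame(columns, index=probe_ids))
    sheet = SampleSheet(pd.Series(group_of))

    # ---- annotation: spaced positions, random context, paired gene symbols
    chroms = np.array([f"chr{1 + (i % 22)}" for i in range(n)])
    positions = np.empty(n, dtype=int)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        gaps = rng.integers(2000, 10001, size=len(idx))
        positions[idx] = 1000 + np.cumsum(gaps)
    context = rng.choice(ISLAND_CONTEXTS, size=n, p=config.island_context_freqs)
    genes = np.array([f"GENE{i // 2:05d}" for i in range(n)], dtype=object)
    tss = rng.integers(-6000, 6001, size=n).astype(float)
    no_gene = rng.random(n) < config.gene_missing_rate
    genes[no_gene] = np.nan
    tss[no_gene] = np.nan
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "chromosome": chroms,
                "position": positions,
                "island_context": context,
                "nearest_gene": genes,
                "tss_distance": tss,
            },
            index=probe_ids,
        )
    )
    return matrix, sheet, annotation, truth


def generate_peaks(
    truth: GroundTruth,
    annotation: ProbeAnnotation,
    factor_name: str,
    enrichment_odds: float = 1.0,
    seed: int = 0,
    base_rate: float = 0.1,
    peak_width: int = 200,
    target_labels=None,
) -> PeakSet:
    """Fixed-width binding peaks with controllable enrichment at aberrant probes.

    The odds that a probe position is covered by a peak are
    ``enrichment_odds``-fold higher for probes carrying a target label
    (default: any non-NULL label) than for NULL probes, whose coverage
    probability is ``base_rate``.
    """
    if not factor_name:
        raise ValueError("factor_name must be non-empty")
    if enrichment_odds <= 0:
        raise ValueError("enrichment_odds must be positive")
    rng = np.random.default_rng(seed)
    labels = truth.labels.reindex(annotation.probe_ids)
    if target_labels is None:
        target = (~labels.isin(("NULL", "REPROGRAMMED"))).to_numpy()
    else:
        target = labels.isin(set(target_labels)).to_numpy()
    odds0 = base_rate / (1.0 - base_rate)
    p1 = (odds0 * enrichment_odds) / (1.0 + odds0 * enrichment_odds)
    p = np.where(target, p1, base_rate)
    covered = rng.random(len(p)) < p

    pos0 = annotation.table["position"].to_numpy()[covered] - 1  # to 0-based
    start = np.maximum(pos0 - peak_width // 2, 0)
    end = start + peak_width
    intervals = pd.DataFrame(
        {
            "chromosome": annotation.table["chromosome"].to_numpy()[covered],
            "start": start,
            "end": end,
        }
    )
    return PeakSet(factor_name=factor_name, intervals=intervals)


def simulate_rrbs(
    matrix: BetaMatrix,
    sample_id: str,
    annotation: ProbeAnnotation,
    depth: int = 30,
    seed: int = 0,
) -> RRBSProfile:
    """Binomial read sampling from one sample's array betas.

    Every annotated probe with a non-missing beta yields one CpG record
    with ``total_count = depth`` and methylated reads Binomial(depth, beta).
    """
    rng = np.random.default_rng(seed)
    betas = matrix.values[sample_id].reindex(annotation.probe_ids)
    ok = betas.notna().to_numpy()
    beta_vals = betas.to_numpy()[ok]
    meth = rng.binomial(depth, beta_vals)
    records = pd.DataFrame(
        {
            "chromosome": annotation.table["chromosome"].to_numpy()[ok],
            "position": annotation.table["position"].to_numpy()[ok],
            "methylated_count": meth,
            "total_count": np.full(ok.sum(), depth, dtype=int),
        }
    )
    return RRBSProfile(records)


def generate_tumor_normal(
    probe_ids,
    hyper_probes,
    n_tumor: int = 8,
    n_normal: int = 8,
    noise_concentration: float = 100.0,
    state_means: tuple[float, float] = (0.85, 0.15),
    seed: int = 0,
) -> tuple[BetaMatrix, BetaMatrix, SampleSheet]:
    """Unmatched tumor/normal cohorts hypermethylated at ``hyper_probes``.

    Normal tissue is lowly methylated everywhere; tumors gain methylation
    (mean = hyper state) at the designated probes, mimicking group-level
    tumor-vs-normal array data.
    """
    rng = np.random.default_rng(seed)
    probe_ids = pd.Index(probe_ids)
    mu_h, mu_l = state_means
    hyper = probe_ids.isin(pd.Index(hyper_probes))
    kappa = noise_concentration

    def _draw(mean_vec, n_samples, prefix):
        a, b = mean_vec * kappa, (1.0 - mean_vec) * kappa
        cols = {f"{prefix}_{j + 1}": rng.beta(a, b) for j in range(n_samples)}
        return BetaMatrix(pd.DataFrame(cols, index=probe_ids))

    tumor_mean = np.where(hyper, mu_h, mu_l)
    normal_mean = np.full(len(probe_ids), mu_l)
    tumor = _draw(tumor_mean, n_tumor, "TUMOR")
    normal = _draw(normal_mean, n_normal, "NORMAL")
    groups = {f"TUMOR_{j + 1}": Group.TUMOR.value for j in range(n_tumor)}
    groups |= {f"NORMAL_{j + 1}": Group.NORMAL.value for j in range(n_normal)}
    sheet = SampleSheet(pd.Series(groups))
    return tumor, normal, sheet


def recovery_report(
    truth: GroundTruth,
    shared_classified: pd.DataFrame,
    factor_classified: pd.DataFrame,
) -> dict:
    """Score pipeline output against planted labels.

    Each planted probe is judged in its own analysis: shared plants in the
    pooled-iPSC-vs-ESC classification, factor-specific plants in the
    Y-vs-T classification. A probe "passes significance" when it appears
    in the corresponding classified table at all. Returns counts plus the
    recovery rate among significance-passing plants and the number of
    probes assigned a wrong named class anywhere (NULL probes included).
    """

    def _lookup(df: pd.DataFrame, scope: str) -> pd.Series:
        sub = df[df["scope"] == scope]
        return pd.Series(sub["aberration_class"].values, index=sub["probe_id"].values)

    by_scope = {
        "shared": _lookup(shared_classified, "shared"),
        "Y_specific": _lookup(factor_classified, "Y_specific"),
        "T_specific": _lookup(factor_classified, "T_specific"),
    }
    named = {c.value for c in AberrationClass} - {AberrationClass.UNCLASSIFIED.value}

    n_planted = n_significant = n_recovered = n_wrong = 0
    for probe, label in truth.labels.items():
        scope = GroundTruth.label_scope(label)
        if scope is None:  # NULL probe: any named call anywhere is wrong
            for calls in by_scope.values():
                got = calls.get(probe)
                if got is not None and got in named:
                    n_wrong += 1
            continue
        n_planted += 1
        expected = GroundTruth.label_class(label).value
        calls = by_scope[scope]
        got = calls.get(probe)
        if got is not None:
            n_significant += 1
            if got == expected:
                n_recovered += 1
            elif got in named:
                n_wrong += 1
        # a named call in the wrong scope (e.g. T_specific for a Y plant)
        for other_scope, other_calls in by_scope.items():
            if other_scope == scope:
                continue
            other = other_calls.get(probe)
            if other is not None and other in named:
                n_wrong += 1

    rate = n_recovered / n_significant if n_significant else float("nan")
    return {
        "n_planted": n_planted,
        "n_significant": n_significant,
        "n_recovered": n_recovered,
        "recovery_rate": rate,
        "n_wrong_named_class": n_wrong,
    }
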