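"""Discrete state calling and Class I-IV aberration taxonomy.

A group's methylation state is the state of its mean beta: HYPER above
0.7, HYPO below 0.3 (strict inequalities), INTERMEDIATE otherwise. A
significantly differential CpG is assigned one of four aberration classes
from the (fibroblast, ESC, iPSC) state triple:

==========  ==========  ==========  ===========================
fibroblast  ESC         iPSC        class
==========  ==========  ==========  ===========================
HYPO        HYPO        HYPER       I   (de novo methylation)
HYPO        HYPER       HYPO        II  (failed methylation)
HYPER       HYPO        HYPER       III (failed demethylation)
HYPER       HYPER       HYPO        IV  (de novo demethylation)
==========  ==========  ==========  ===========================

Any triple containing INTERMEDIATE, or with the iPSC state equal to the
ESC state (the cells are not aberrant there), is UNCLASSIFIED.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import AberrationClass, BetaMatrix, Group, NAMED_CLASSES, SampleSheet, State

__all__ = [
    "THETA_HYPER",
    "THETA_HYPO",
    "call_state",
    "call_states",
    "classify_aberration",
    "shared_aberrations",
    "factor_specific_aberrations",
    "class_composition",
    "observed_expected_class_ratio",
]

THETA_HYPER = 0.7
THETA_HYPO = 0.3

_CLASS_MAP = {
    (State.HYPO, State.HYPO, State.HYPER): AberrationClass.CLASS_I,
    (State.HYPO, State.HYPER, State.HYPO): AberrationClass.CLASS_II,
    (State.HYPER, State.HYPO, State.HYPER): AberrationClass.CLASS_III,
    (State.HYPER, State.HYPER, State.HYPO): AberrationClass.CLASS_IV,
}

# class implied by (FIB, ESC) when the iPSC state is flipped relative to ESC;
# used for the "expected by chance" null of observed_expected_class_ratio
_FLIPPED_CLASS = {
    (State.HYPO, State.HYPO): AberrationClass.CLASS_I,
    (State.HYPO, State.HYPER): AberrationClass.CLASS_II,
    (State.HYPER, State.HYPO): AberrationClass.CLASS_III,
    (State.HYPER, State.HYPER): AberrationClass.CLASS_IV,
}


def call_state(
    mean_beta: float, theta_hyper: float = THETA_HYPER, theta_hypo: float = THETA_HYPO
) -> State:
    """Discrete state of a group-mean beta (strict thresholds; NaN -> INTERMEDIATE)."""
    if np.isnan(mean_beta):
        return State.INTERMEDIATE
    if not 0.0 <= mean_beta <= 1.0:
        raise ValueError(f"beta out of range: {mean_beta}")
    if mean_beta > theta_hyper:
        return State.HYPER
    if mean_beta < theta_hypo:
        return State.HYPO
    return State.INTERMEDIATE


def call_states(
    mean_betas: pd.Series,
    theta_hyper: float = THETA_HYPER,
    theta_hypo: float = THETA_HYPO,
) -> pd.Series:
    """Vectorised :func:`call_state` over a Series of group means."""
    vals = mean_betas.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("beta out of range")
    out = np.full(vals.shape, State.INTERMEDIATE, dtype=object)
    out[vals > theta_hyper] = State.HYPER
    out[vals < theta_hypo] = State.HYPO
    return pd.Series(out, index=mean_betas.index)


def classify_aberration(fib: State, esc: State, ipsc: State) -> AberrationClass:
    """Aberration class of a (fibroblast, ESC, iPSC) state triple (total function)."""
    return _CLASS_MAP.get((fib, esc, ipsc), AberrationClass.UNCLASSIFIED)


def _classified_frame(
    probes, fib_states, esc_states, ipsc_states, scope: str
) -> pd.DataFrame:
    classes = [
        classify_aberration(f, e, i)
        for f, e, i in zip(fib_states, esc_states, ipsc_states)
    ]
    return pd.DataFrame(
        {
            "probe_id": list(probes),
            "fib_state": [str(s) for s in fib_states],
            "esc_state": [str(s) for s in esc_states],
            "ipsc_state": [str(s) for s in ipsc_states],
            "aberration_class": [str(c) for c in classes],
            "scope": scope,
        }
    )


def shared_aberrations(
    matrix: BetaMatrix, sheet: SampleSheet, diff: pd.DataFrame
) -> pd.DataFrame:
    """Classify CpGs aberrant in all iPSCs (pooled Y+T) relative to ESCs.

    ``diff`` must come from ``call_differential`` with group_a = both iPSC
    cohorts pooled and group_b = ESC. Only significant probes are
    classified; the iPSC state is the pooled-iPSC mean state.
    """
    sig = diff.loc[diff["significant"], "probe_id"]
    if sig.empty:
        return _classified_frame([], [], [], [], "shared")
    fib_mean = matrix.group_mean(sheet.samples(Group.FIB)).loc[sig]
    esc_mean = matrix.group_mean(sheet.samples(Group.ESC)).loc[sig]
    ipsc_mean = matrix.group_mean(
        sheet.samples((Group.Y_IPSC, Group.T_IPSC))
    ).loc[sig]
    return _classified_frame(
        sig,
        call_states(fib_mean),
        call_states(esc_mean),
        call_states(ipsc_mean),
        "shared",
    )


def factor_specific_aberrations(
    matrix: BetaMatrix, sheet: SampleSheet, diff: pd.DataFrame
) -> pd.DataFrame:
    """Classify CpGs differential between the Y and T cohorts.

    ``diff`` must come from ``call_differential`` with group_a = Y_IPSC and
    group_b = T_IPSC. Each significant probe is classified twice, once per
    cohort (scope Y_specific / T_specific) against the fibroblast and ESC
    states; the cohort whose state matches the ESC state is UNCLASSIFIED
    there (it is not aberrant).
    """
    sig = diff.loc[diff["significant"], "probe_id"]
    if sig.empty:
        return _classified_frame([], [], [], [], "Y_specific")

    fib = call_states(matrix.group_mean(sheet.samples(Group.FIB)).loc[sig])
    esc = call_states(matrix.group_mean(sheet.samples(Group.ESC)).loc[sig])
    frames = []
    for group, scope in ((Group.Y_IPSC, "Y_specific"), (Group.T_IPSC, "T_specific")):
        ipsc = call_states(matrix.group_mean(sheet.samples(group)).loc[sig])
        frames.append(_classified_frame(sig, fib, esc, ipsc, scope))
    return pd.concat(frames, ignore_index=True)


def class_composition(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per named class (fractions over classified probes).

    Returns a DataFrame with columns aberration_class, count, fraction;
    empty input yields an empty frame.
    """
    named = classified[
        classified["aberration_class"] != AberrationClass.UNCLASSIFIED.value
    ]
    if named.empty:
        return pd.DataFrame(columns=["aberration_class", "count", "fraction"])
    counts = named["aberration_class"].value_counts()
    counts = counts.reindex([c.value for c in NAMED_CLASSES], fill_value=0)
    total = counts.sum()
    return pd.DataFrame(
        {
            "aberration_class": counts.index,
            "count": counts.values,
            "fraction": counts.values / total,
        }
    ).reset_index(drop=True)


def observed_expected_class_ratio(
    classified: pd.DataFrame,
    matrix: BetaMatrix,
    sheet: SampleSheet,
    n_draws: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed/expected ratio per class against a uniform-resampling null.

    The eligible universe is every probe whose fibroblast and ESC mean
    states are both clear (non-INTERMEDIATE). Each null draw samples as
    many probes as were observed (named classes only), uniformly without
    replacement, and assigns each the class implied by its (FIB, ESC)
    states with the iPSC state flipped relative to ESC. The empirical p is
    the plus-one-corrected tail probability in the direction of the
    observed deviation.
    """
    fib = call_states(matrix.group_mean(sheet.samples(Group.FIB)))
    esc = call_states(matrix.group_mean(sheet.samples(Group.ESC)))
    eligible = (fib != State.INTERMEDIATE) & (esc != State.INTERMEDIATE)
    universe = matrix.probe_ids[eligible.to_numpy()]
    if len(universe) == 0:
        raise ValueError("no eligible probes (clear FIB and ESC states)")

    null_class = np.array(
        [
            _FLIPPED_CLASS[(f, e)].value
            for f, e in zip(fib[eligible.to_numpy()], esc[eligible.to_numpy()])
        ],
        dtype=object,
    )
    class_values = [c.value for c in NAMED_CLASSES]  # lexicographically sorted
    codes = np.searchsorted(np.array(class_values), null_class)

    named = classified[
        classified["aberration_class"] != AberrationClass.UNCLASSIFIED.value
    ]
    m = len(named)
    if m == 0:
        return pd.DataFrame(
            columns=["aberration_class", "observed", "expected", "ratio", "p_value"]
        )
    if m > len(universe):
        raise ValueError("observed set larger than eligible universe")

    observed = named["aberration_class"].value_counts().reindex(
        class_values, fill_value=0
    )

    rng = np.random.default_rng(seed)
    null_counts = np.empty((n_draws, 4), dtype=int)
    n_univ = len(universe)
    for d in range(n_draws):
        idx = rng.choice(n_univ, size=m, replace=False)
        null_counts[d] = np.bincount(codes[idx], minlength=4)

    expected = null_counts.mean(axis=0)
    rows = []
    for j, cls in enumerate(class_values):
        obs = observed[cls]
        exp = expected[j]
        if obs >= exp:
            p = (np.sum(null_counts[:, j] >= obs) + 1) / (n_draws + 1)
        else:
            p = (np.sum(null_counts[:, j] <= obs) + 1) / (n_draws + 1)
        rows.append(
            {
                "aberration_class": cls,
                "observed": int(obs),
                "expected": float(exp),
                "ratio": float(obs / exp) if exp > 0 else np.nan,
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)
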