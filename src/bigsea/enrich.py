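"""Bi-directional gene-set enrichment by sample-label permutation.

For each gene set the observed statistic is the size-normalized sum of
per-gene two-group t statistics — signed (directional enrichment) or of
their absolute values (bi-directional enrichment, which detects sets where
some members go up and others down so the signed sum cancels).  The null
distribution permutes the group labels of ALL genes simultaneously, which
preserves the inter-gene correlation within sets (a self-contained test).
p-values are plug-in permutation tail proportions with ties counted, and
are BH-adjusted across sets within each of the three test families.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, SampleGroups
from .diffexpr import adjust_bh, fit_gene_linear_models, two_group_t

logger = logging.getLogger("bigsea")

__all__ = [
    "PermutationNull",
    "set_statistic",
    "build_permutation_null",
    "permutation_p",
    "gsea_test",
    "summarize_direction_classes",
]


@dataclass
class PermutationNull:
    """Permutation null distribution of set statistics (B x sets)."""

    statistics: np.ndarray
    set_names: list[str]
    B: int
    seed: int | None
    scheme: str  # "full-shuffle" | "exhaustive"
    mode: str  # "signed" | "absolute"


def set_statistic(t_stats, mode: str = "signed", scaling: str = "size") -> float:
    """Size-normalized sum of (absolute) t statistics for one gene set.

    ``signed`` mode sums the t statistics as-is and divides by set size k
    (so opposing changes cancel); ``absolute`` sums |t| (so they add up).
    ``scaling="sqrt"`` divides by sqrt(k) instead, which upweights large
    sets; the permutation test is invariant to this within-set rescaling.
    """
    t = np.asarray(t_stats, dtype=float)
    if t.size == 0:
        raise ValueError("set_statistic requires a non-empty list of t statistics")
    if mode == "absolute":
        t = np.abs(t)
    elif mode != "signed":
        raise ValueError(f"unknown mode {mode!r}")
    if scaling == "size":
        return float(t.sum() / t.size)
    if scaling == "sqrt":
        return float(t.sum() / math.sqrt(t.size))
    raise ValueError(f"unknown scaling {scaling!r}")


def _membership_matrix(
    sets: GeneSetCollection, gene_ids: list[str], scaling: str
) -> tuple[np.ndarray, list[str]]:
    """Row-normalized set-membership indicator (sets x genes)."""
    index = {g: i for i, g in enumerate(gene_ids)}
    rows = []
    names = []
    for name, members in sets.sets.items():
        cols = [index[g] for g in members if g in index]
        if not cols:
            continue
        row = np.zeros(len(gene_ids))
        k = len(cols)
        row[cols] = 1.0 / (k if scaling == "size" else math.sqrt(k))
        rows.append(row)
        names.append(name)
    if not rows:
        raise ValueError("no gene set has members in the expression matrix")
    return np.vstack(rows), names


def _permutation_masks(
    n: int, n_b: int, B: int, rng: np.random.Generator | None
) -> tuple[np.ndarray, str]:
    """B boolean masks (rows) selecting the non-reference group.

    Switches to exhaustive enumeration of all C(n, n_b) distinct two-group
    assignments when that count does not exceed B.
    """
    n_distinct = math.comb(n, n_b)
    if n_distinct <= B:
        masks = np.zeros((n_distinct, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n_b)):
            masks[i, list(idx)] = True
        return masks, "exhaustive"
    if rng is None:
        raise ValueError("a seeded generator is required for random permutations")
    masks = np.zeros((B, n), dtype=bool)
    for i in range(B):
        masks[i, rng.choice(n, size=n_b, replace=False)] = True
    return masks, "full-shuffle"


def _null_t_matrix(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Per-gene t statistics for every permutation row: (B x genes)."""
    out = np.empty((masks.shape[0], values.shape[0]))
    for i, mask in enumerate(masks):
        _, t, _, _ = two_group_t(values, mask)
        out[i] = t
    return out


def _set_stat_rows(membership: np.ndarray, t_rows: np.ndarray) -> np.ndarray:
    """Set statistics for each t row: (B x sets).

    Computed row-by-row with the same matrix-vector product used for the
    observed statistics, so an identity permutation reproduces the observed
    values bit-for-bit (exact tie counting under the exhaustive scheme).
    """
    return np.vstack([membership @ t for t in t_rows])


def build_permutation_null(
    x: ExpressionMatrix,
    groups: SampleGroups,
    sets: GeneSetCollection,
    mode: str = "signed",
    B: int = 1000,
    seed: int | None = None,
    scaling: str = "size",
) -> PermutationNull:
    """Null distribution of set statistics under group-label permutation.

    Each row applies ONE label reassignment (group sizes preserved) to all
    genes, refits the per-gene t, and recomputes every set's statistic, so
    between-set dependence is preserved.  Deterministic given ``seed``.
    """
    groups.validate_for_testing(x.sample_ids, min_per_group=2)
    labels = groups.labels
    mask_obs = groups.mask(x.sample_ids, labels[1])
    rng = np.random.default_rng(seed) if seed is not None else None
    masks, scheme = _permutation_masks(x.n_samples, int(mask_obs.sum()), B, rng)
    null_t = _null_t_matrix(x.values, masks)
    if mode == "absolute":
        null_t = np.abs(null_t)
    membership, names = _membership_matrix(sets, x.gene_ids, scaling)
    statistics = _set_stat_rows(membership, null_t)
    return PermutationNull(
        statistics=statistics,
        set_names=names,
        B=masks.shape[0],
        seed=seed,
        scheme=scheme,
        mode=mode,
    )


def permutation_p(observed: float, null_values, tail: str = "upper") -> float:
    """Plug-in permutation p-value: tail proportion with ties included.

    upper: #{b : null_b >= observed} / B;  lower: #{b : null_b <= observed} / B.
    An observed statistic greater than exactly 95% of 1000 null values (the
    remaining 50 tying or exceeding it) therefore yields p = 0.05.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("permutation_p requires a non-empty null distribution")
    if tail == "upper":
        return float(np.sum(null >= observed) / null.size)
    if tail == "lower":
        return float(np.sum(null <= observed) / null.size)
    raise ValueError(f"unknown tail {tail!r}")


def gsea_test(
    x: ExpressionMatrix,
    groups: SampleGroups,
    sets: GeneSetCollection,
    B: int = 1000,
    seed: int | None = 0,
    alpha: float = 0.05,
    min_set_size: int = 5,
    scaling: str = "size",
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Directional and bi-directional permutation enrichment for every set.

    Returns a DataFrame indexed by set name with columns:

    - ``size_used`` — members present in the (filtered) expression matrix;
    - ``stat_signed`` / ``stat_abs`` — observed set statistics;
    - ``p_up`` / ``p_down`` — upper / lower tail of the signed statistic
      against the signed permutation null;
    - ``p_bidir`` — upper tail of the absolute statistic against its own
      absolute-statistic null (not |signed null|);
    - ``q_up`` / ``q_down`` / ``q_bidir`` — BH across sets per family;
    - ``pct_up`` / ``pct_down`` — percent of set members with unpermuted
      raw p < ``alpha`` moving up / down.

    Sets with fewer than ``min_set_size`` members in the matrix are skipped
    (logged).  The same permutations serve all sets and both statistics.
    """
    usable = sets.restrict(x.gene_ids, min_size=1)
    n_small = sum(
        1
        for members in usable.sets.values()
        if len(members) < min_set_size
    )
    if n_small:
        logger.info(
            "gsea_test: skipping %d sets with fewer than %d members present",
            n_small,
            min_set_size,
        )
    usable = GeneSetCollection(
        {n: m for n, m in usable.sets.items() if len(m) >= min_set_size}
    )
    if len(usable) == 0:
        raise ValueError("no gene set passes the minimum-size filter")

    de = fit_gene_linear_models(x, groups, reference_group=reference_group)
    t_obs = de.t_stat
    membership, names = _membership_matrix(usable, x.gene_ids, scaling)
    stat_signed = membership @ t_obs
    stat_abs = membership @ np.abs(t_obs)

    groups.validate_for_testing(x.sample_ids, min_per_group=3)
    labels = groups.labels
    other = (
        [g for g in labels if g != reference_group][0]
        if reference_group is not None
        else labels[1]
    )
    mask_obs = groups.mask(x.sample_ids, other)
    rng = np.random.default_rng(seed) if seed is not None else None
    masks, scheme = _permutation_masks(x.n_samples, int(mask_obs.sum()), B, rng)
    null_t = _null_t_matrix(x.values, masks)
    null_signed = _set_stat_rows(membership, null_t)
    null_abs = _set_stat_rows(membership, np.abs(null_t))
    B_used = masks.shape[0]
    logger.info("gsea_test: %s scheme with %d permutations", scheme, B_used)

    p_up = (null_signed >= stat_signed).sum(axis=0) / B_used
    p_down = (null_signed <= stat_signed).sum(axis=0) / B_used
    p_bidir = (null_abs >= stat_abs).sum(axis=0) / B_used

    sig = de.p_raw < alpha
    up = sig & (de.log_fc > 0)
    down = sig & (de.log_fc < 0)
    sizes = np.array([len(usable.sets[n]) for n in names], dtype=float)
    indicator = (membership > 0).astype(float)
    pct_up = 100.0 * (indicator @ up.astype(float)) / sizes
    pct_down = 100.0 * (indicator @ down.astype(float)) / sizes

    return pd.DataFrame(
        {
            "size_used": sizes.astype(int),
            "stat_signed": stat_signed,
            "stat_abs": stat_abs,
            "p_up": p_up,
            "p_down": p_down,
            "p_bidir": p_bidir,
            "q_up": adjust_bh(p_up),
            "q_down": adjust_bh(p_down),
            "q_bidir": adjust_bh(p_bidir),
            "pct_up": pct_up,
            "pct_down": pct_down,
        },
        index=pd.Index(names, name="set"),
    )


def summarize_direction_classes(
    result: pd.DataFrame, alpha: float = 0.05
) -> dict[str, int]:
    """Count sets significant up, down, or only bi-directionally.

    A set counts "up" if q_up < alpha, "down" if q_down < alpha, and
    "bidirectional_only" if q_bidir < alpha while neither directional q is.
    """
    up = result["q_up"] < alpha
    down = result["q_down"] < alpha
    bidir_only = (result["q_bidir"] < alpha) & ~up & ~down
    return {
        "up": int(up.sum()),
        "down": int(down.sum()),
        "bidirectional_only": int(bidir_only.sum()),
    }
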