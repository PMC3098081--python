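"""Fisher's-exact overrepresentation of gene sets among selected genes.

Each set is tested against the 2x2 table (in-set/selected, in-set/not,
out-of-set/selected, out-of-set/not) over a stated gene universe — here the
set-annotated genes entering the CCA, not the whole array.  The one-sided
(enrichment) p-value is the hypergeometric upper tail P[X >= actual]; the
odds ratio is the conditional maximum-likelihood estimate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

from .containers import GeneSetCollection
from .diffexpr import adjust_bh

__all__ = [
    "expected_count",
    "overrep_pvalue",
    "fisher_overrepresentation",
]


def expected_count(pathway_size: int, k_selected: int, n_universe: int) -> float:
    """Expected in-set selections under proportional sampling: size * K / N."""
    if n_universe <= 0:
        raise ValueError("universe size must be positive")
    if not 0 <= k_selected <= n_universe:
        raise ValueError("selected count must lie in [0, universe size]")
    if not 0 <= pathway_size <= n_universe:
        raise ValueError("pathway size must lie in [0, universe size]")
    return pathway_size * k_selected / n_universe


def overrep_pvalue(actual, pathway_size, k_selected, n_universe, sided="greater"):
    """Hypergeometric p-value for in-set overlap of a selection.

    ``greater``: P[X >= actual] with X ~ Hypergeom(N, size, K) — the
    one-sided enrichment tail, identical to one-sided Fisher.  ``two-sided``
    sums the probabilities of all tables no more likely than the observed
    one (Fisher's method).  Vectorized over ``actual`` for ``greater``.
    """
    if sided == "greater":
        return stats.hypergeom.sf(
            np.asarray(actual) - 1, n_universe, pathway_size, k_selected
        )
    if sided == "two-sided":
        table = _table(int(actual), int(pathway_size), int(k_selected), int(n_universe))
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"unknown sidedness {sided!r}")


def _table(a: int, size: int, k: int, n: int) -> np.ndarray:
    return np.array([[a, size - a], [k - a, n - size - (k - a)]])


def fisher_overrepresentation(
    selected,
    universe,
    sets: GeneSetCollection,
    sided: str = "greater",
    with_bh: bool = False,
) -> pd.DataFrame:
    """Test every gene set for overrepresentation among ``selected`` genes.

    Returns a DataFrame (rows sorted by p ascending) with columns
    ``odds_ratio`` (conditional MLE), ``sample_odds_ratio``,
    ``expected_count``, ``actual_count``, ``pathway_size``, ``p_value``
    (+ ``q_value`` when ``with_bh``).  Set sizes are taken after
    intersection with the universe.
    """
    universe = list(universe)
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    sel = set(selected)
    stray = sorted(sel - uni)
    if stray:
        raise ValueError(f"selected gene not in universe: {stray[0]!r}")
    n = len(uni)
    k = len(sel)
    rows = []
    for name, members in sets.sets.items():
        in_uni = [g for g in members if g in uni]
        size = len(in_uni)
        if size == 0:
            continue
        a = sum(1 for g in in_uni if g in sel)
        table = _table(a, size, k, n)
        p = overrep_pvalue(a, size, k, n, sided=sided)
        with np.errstate(divide="ignore", invalid="ignore"):
            sample_or = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
        rows.append(
            {
                "set": name,
                "odds_ratio": float(_cmle_odds_ratio(table, kind="conditional").statistic),
                "sample_odds_ratio": float(sample_or),
                "expected_count": expected_count(size, k, n),
                "actual_count": a,
                "pathway_size": size,
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows).set_index("set").sort_values("p_value", kind="mergesort")
    if with_bh:
        out["q_value"] = adjust_bh(out["p_value"].to_numpy())
    return out
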