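"""Ridge-regularized canonical correlation analysis and relevance networks.

rCCA finds paired linear combinations (canonical variates) of a gene block
X (n samples x p genes) and a marker block Y (n x q markers) with maximal
correlation.  Ridge terms lambda_x, lambda_y added to the diagonal of the
within-block covariances make the problem well-posed when p or q exceeds n.
The gene-marker similarity score is the inner product, over the first d
dimensions, of each variable's correlations with the bisector variates
Z_l = (U_l + V_l)/2; thresholding |s| yields a bipartite relevance network.
"""

from __future__ import annotations

import logging
from itertools import product

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .containers import CcaModel, SampleGroups, SimilarityNetwork
from .diffexpr import DiffExpResult

logger = logging.getLogger("bigsea")

__all__ = [
    "zscore_within_group",
    "rcc",
    "estimate_regularization",
    "similarity_network",
    "select_marker_associated_genes",
]


def zscore_within_group(m: pd.DataFrame, groups: SampleGroups) -> pd.DataFrame:
    """Center and scale every variable to mean 0, variance 1 within each group.

    Operates on a samples x variables frame (index = sample ids).  Removing
    the group means strips the treatment effect, so downstream correlations
    reflect covariation irrespective of group — the intent behind running
    CCA on within-group z-scores.  Uses the n-1 variance denominator.
    """
    out = m.astype(float).copy()
    for label in groups.labels:
        mask = groups.mask(list(m.index), label)
        if mask.sum() < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        block = out.loc[mask]
        sd = block.std(ddof=1)
        flat = sd[sd <= 0]
        if len(flat):
            raise ValueError(
                f"variable {flat.index[0]!r} is constant within group {label!r}"
            )
        out.loc[mask] = (block - block.mean()) / sd
    return out


def _inv_sqrt_psd(c: np.ndarray, what: str) -> np.ndarray:
    w, v = linalg.eigh(c)
    # relative floor: whitening by smaller eigenvalues is numerically meaningless
    tol = 1e-10 * max(abs(w.max()), 1.0)
    if w.min() <= tol:
        raise np.linalg.LinAlgError(
            f"regularized {what} covariance is not positive definite; "
            "use a ridge penalty > 0 (columns are collinear)"
        )
    return (v / np.sqrt(w)) @ v.T


def _as_matrix(m) -> tuple[np.ndarray, list[str]]:
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float), [str(c) for c in m.columns]
    arr = np.asarray(m, dtype=float)
    return arr, [f"v{j}" for j in range(arr.shape[1])]


def rcc(x, y, lambda_x: float = 0.0, lambda_y: float = 0.0) -> CcaModel:
    """Fit regularized CCA between two centered blocks sharing the sample axis.

    With S_xx, S_yy, S_xy the sample covariance blocks (n-1 denominator),
    weights come from the SVD of C_xx^{-1/2} S_xy C_yy^{-1/2} where
    C = S + lambda I; singular values are the canonical correlations
    (clipped to [0, 1]).  Variates have unit variance under the regularized
    metric.  Sign convention: the largest-magnitude x-weight entry of each
    dimension is positive.
    """
    xv, x_names = _as_matrix(x)
    yv, y_names = _as_matrix(y)
    if xv.shape[0] != yv.shape[0]:
        raise ValueError("x and y must share the sample axis")
    if lambda_x < 0 or lambda_y < 0:
        raise ValueError("ridge penalties must be non-negative")
    n = xv.shape[0]
    if n < 3:
        raise ValueError(">= 3 samples required")
    col_means = np.abs(xv.mean(axis=0)).max(initial=0.0)
    col_means = max(col_means, np.abs(yv.mean(axis=0)).max(initial=0.0))
    if col_means > 1e-8 * max(1.0, np.abs(xv).max(), np.abs(yv).max()):
        raise ValueError("columns must be centered before calling rcc")

    sxx = xv.T @ xv / (n - 1)
    syy = yv.T @ yv / (n - 1)
    sxy = xv.T @ yv / (n - 1)
    cxx_is = _inv_sqrt_psd(sxx + lambda_x * np.eye(xv.shape[1]), "x")
    cyy_is = _inv_sqrt_psd(syy + lambda_y * np.eye(yv.shape[1]), "y")
    u, s, vt = linalg.svd(cxx_is @ sxy @ cyy_is, full_matrices=False)
    ndim = min(xv.shape[1], yv.shape[1], n - 1)
    a = cxx_is @ u[:, :ndim]
    b = cyy_is @ vt.T[:, :ndim]
    for l in range(ndim):
        j = int(np.argmax(np.abs(a[:, l])))
        if a[j, l] < 0:
            a[:, l] = -a[:, l]
            b[:, l] = -b[:, l]
    return CcaModel(
        lambda_x=float(lambda_x),
        lambda_y=float(lambda_y),
        can_cor=np.clip(s[:ndim], 0.0, 1.0),
        x_weights=a,
        y_weights=b,
        x_variates=xv @ a,
        y_variates=yv @ b,
        x_names=x_names,
        y_names=y_names,
    )


def _center_columns(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = arr.mean(axis=0)
    return arr - mu, mu


def loo_projection_score(
    xv: np.ndarray, yv: np.ndarray, lambda_x: float, lambda_y: float
) -> float:
    """Leave-one-out first-dimension projection correlation for one (lx, ly).

    For each sample i: fit rcc on the remaining n-1 rows (centered within
    the fold), project the held-out row (fold-mean centered) onto the first
    canonical weight pair; the score is the Pearson correlation of the n
    held-out (u_i, v_i) pairs.
    """
    n = xv.shape[0]
    u = np.empty(n)
    v = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        xt, x_mu = _center_columns(xv[keep])
        yt, y_mu = _center_columns(yv[keep])
        model = rcc(xt, yt, lambda_x, lambda_y)
        u[i] = (xv[i] - x_mu) @ model.x_weights[:, 0]
        v[i] = (yv[i] - y_mu) @ model.y_weights[:, 0]
    if np.std(u) == 0 or np.std(v) == 0:
        return np.nan
    return float(stats.pearsonr(u, v)[0])


def estimate_regularization(
    x, y, grid_x, grid_y
) -> tuple[float, float, pd.DataFrame]:
    """Choose ridge penalties by leave-one-out cross-validated correlation.

    Scores every (lambda_x, lambda_y) grid pair with
    :func:`loo_projection_score` and returns the maximizing pair plus the
    full score surface (rows = grid_x, columns = grid_y).  Ties resolve to
    the smallest lambda_x, then smallest lambda_y.
    """
    grid_x = [float(g) for g in grid_x]
    grid_y = [float(g) for g in grid_y]
    if not grid_x or not grid_y:
        raise ValueError("regularization grids must be non-empty")
    xv, _ = _as_matrix(x)
    yv, _ = _as_matrix(y)
    if xv.shape[0] < 4:
        raise ValueError(">= 4 samples required for leave-one-out selection")
    surface = pd.DataFrame(index=grid_x, columns=grid_y, dtype=float)
    best = None
    for lx, ly in product(grid_x, grid_y):
        score = loo_projection_score(xv, yv, lx, ly)
        surface.at[lx, ly] = score
        if np.isnan(score):
            continue
        key = (score, -lx, -ly)
        if best is None or key > best[0]:
            best = (key, lx, ly)
    if best is None:
        raise ValueError(
            "all cross-validation scores undefined (zero-variance projections)"
        )
    _, lx, ly = best
    logger.info("estimate_regularization: lambda_x=%g lambda_y=%g", lx, ly)
    return lx, ly, surface


def _corr_with(columns: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of ``columns`` with each column of z."""
    xc = columns - columns.mean(axis=0)
    zc = z - z.mean(axis=0)
    xn = np.sqrt((xc**2).sum(axis=0))
    zn = np.sqrt((zc**2).sum(axis=0))
    return (xc.T @ zc) / np.outer(xn, zn)


def similarity_network(
    model: CcaModel, x, y, d: int = 6, tau: float = 0.65
) -> SimilarityNetwork:
    """Bipartite gene-marker relevance network from a fitted CCA model.

    Coordinates are each variable's correlations with the bisector variates
    Z_l = (U_l + V_l)/2 for l = 1..d; the similarity is their inner product
    s_jk = sum_l corr(x_j, Z_l) * corr(y_k, Z_l).  Edges keep pairs with
    |s_jk| >= tau (default 0.65).
    """
    if not 1 <= d <= model.n_dims:
        raise ValueError(f"d must be in [1, {model.n_dims}], got {d}")
    xv, x_names = _as_matrix(x)
    yv, y_names = _as_matrix(y)
    z = (model.x_variates[:, :d] + model.y_variates[:, :d]) / 2.0
    p_x = _corr_with(xv, z)
    p_y = _corr_with(yv, z)
    sim = pd.DataFrame(p_x @ p_y.T, index=x_names, columns=y_names)
    return SimilarityNetwork.from_similarity(sim, dims_used=d, threshold=tau)


def select_marker_associated_genes(
    network: SimilarityNetwork,
    de: DiffExpResult,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> list[str]:
    """Genes with >= 1 retained network edge AND significant group effect.

    Significance gates on the BH-adjusted p by default (raw p with
    ``use_adjusted=False``).  Returns a lexicographically sorted id list.
    """
    universe = set(network.similarity.index) & set(de.gene_ids)
    if not universe:
        raise ValueError("network and differential-expression gene universes are disjoint")
    p = de.p_for_gene(adjusted=use_adjusted)
    connected = set(network.genes_with_edges())
    return sorted(g for g in connected if g in universe and p[g] < alpha)
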