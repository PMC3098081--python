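"""Per-gene two-group linear models with optional empirical-Bayes moderation.

The baseline statistic is the ordinary least-squares t for a two-level
factor (equivalently the pooled-variance two-sample t).  Variance
moderation shrinks per-gene residual variances toward a common prior fitted
by moment matching on log variances, and recomputes t and p on augmented
degrees of freedom.  Benjamini-Hochberg adjustment is shared by all stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, SampleGroups

logger = logging.getLogger("bigsea")

__all__ = [
    "DiffExpResult",
    "fit_gene_linear_models",
    "moderate_variances",
    "adjust_bh",
]


@dataclass
class DiffExpResult:
    """Per-gene differential-expression statistics.

    ``log_fc`` is the non-reference minus reference group mean on the log2
    scale; ``t_stat`` and ``p_raw`` follow the (possibly moderated) t
    distribution on ``df_residual`` degrees of freedom; ``p_adj`` is BH.
    """

    gene_ids: list[str]
    log_fc: np.ndarray
    t_stat: np.ndarray
    df_residual: np.ndarray
    residual_variance: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    moderated: bool
    reference_group: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "log_fc": self.log_fc,
                "t": self.t_stat,
                "df": self.df_residual,
                "residual_variance": self.residual_variance,
                "p_raw": self.p_raw,
                "p_adj": self.p_adj,
                "moderated": self.moderated,
            },
            index=pd.Index(self.gene_ids, name="gene_id"),
        )

    def p_for_gene(self, adjusted: bool = True) -> pd.Series:
        values = self.p_adj if adjusted else self.p_raw
        return pd.Series(values, index=self.gene_ids)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_group_t(
    values: np.ndarray, mask_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Vectorized pooled-variance two-sample t for every row of ``values``.

    ``mask_b`` selects the non-reference group.  Returns (diff, t, s2, df).
    Rows with zero pooled variance yield t = +/-inf (nonzero diff) or 0.
    """
    values = np.asarray(values, dtype=float)
    mask_b = np.asarray(mask_b, dtype=bool)
    n_b = int(mask_b.sum())
    n_a = int((~mask_b).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs >= 2 samples")
    xb = values[:, mask_b]
    xa = values[:, ~mask_b]
    mean_b = xb.mean(axis=1)
    mean_a = xa.mean(axis=1)
    diff = mean_b - mean_a
    ss = ((xb - mean_b[:, None]) ** 2).sum(axis=1) + (
        (xa - mean_a[:, None]) ** 2
    ).sum(axis=1)
    df = n_a + n_b - 2
    s2 = ss / df
    scale = np.sqrt(s2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / scale
    zero_var = s2 <= 0
    if np.any(zero_var):
        with np.errstate(invalid="ignore"):
            t = np.where(zero_var & (diff != 0), np.sign(diff) * np.inf, t)
        t = np.where(zero_var & (diff == 0), 0.0, t)
    return diff, t, s2, float(df)


def fit_gene_linear_models(
    x: ExpressionMatrix, groups: SampleGroups, reference_group: str | None = None
) -> DiffExpResult:
    """OLS fit of expression on a two-level group factor, gene by gene.

    ``log_fc`` is mean(non-reference) - mean(reference); the t statistic is
    the classical pooled-variance two-sample t on n1 + n2 - 2 df.  Genes
    with zero pooled variance and nonzero difference get t = +/-inf with
    p_raw = 0 (logged).
    """
    groups.validate_for_testing(x.sample_ids, min_per_group=2)
    labels = groups.labels
    if reference_group is None:
        reference_group = labels[0]
    if reference_group not in labels:
        raise ValueError(f"reference group {reference_group!r} not in {labels}")
    other = [g for g in labels if g != reference_group][0]
    mask_b = groups.mask(x.sample_ids, other)
    diff, t, s2, df = two_group_t(x.values, mask_b)
    n_degenerate = int(np.sum((s2 <= 0) & (diff != 0)))
    if n_degenerate:
        logger.warning(
            "fit_gene_linear_models: %d genes with zero pooled variance and "
            "nonzero fold change; t reported as +/-inf with p = 0",
            n_degenerate,
        )
    p_raw = 2.0 * stats.t.sf(np.abs(t), df)
    p_raw = np.where(np.isinf(t), 0.0, p_raw)
    return DiffExpResult(
        gene_ids=list(x.gene_ids),
        log_fc=diff,
        t_stat=t,
        df_residual=np.full(x.n_genes, df),
        residual_variance=s2,
        p_raw=p_raw,
        p_adj=adjust_bh(p_raw),
        moderated=False,
        reference_group=reference_group,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    # Standard initialization: trigamma(x) ~ 1/x for large x, ~ 1/x^2 near 0.
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit a scaled inverse-chi-square prior (d0, s0^2) to sample variances.

    Moment matching on log variances: under the hierarchical model,
    log(s2) has a shifted log-F distribution whose mean and variance give
    closed forms in digamma/trigamma of the prior df.  Returns
    (d0, s0_sq); d0 = inf when the observed log-variance spread does not
    exceed the sampling spread (no between-gene variance heterogeneity).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError(">= 2 genes with finite positive variances required")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        # Observed spread is fully explained by chi-square sampling noise.
        s0_sq = float(np.exp(e_mean))
        return np.inf, s0_sq
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderate_variances(result: DiffExpResult) -> DiffExpResult:
    """Empirical-Bayes shrinkage of per-gene variances toward a fitted prior.

    Each variance is replaced by the posterior mean
    (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g) and t is recomputed on
    d0 + d_g degrees of freedom.  With d0 = inf (homogeneous variances)
    every gene gets s0^2 exactly.
    """
    if result.moderated:
        return result
    df = result.df_residual
    d0, s0_sq = fit_variance_prior(result.residual_variance, float(df[0]))
    if np.isinf(d0):
        logger.info(
            "moderate_variances: no excess variance heterogeneity; "
            "all variances set to the common value %.4g",
            s0_sq,
        )
        post_var = np.full_like(result.residual_variance, s0_sq)
        post_df = np.full_like(df, np.inf)
    else:
        post_var = (d0 * s0_sq + df * result.residual_variance) / (d0 + df)
        post_df = d0 + df
    # Back out the standard-error multiplier from the unmoderated fit so the
    # moderated t only swaps the variance estimate.
    with np.errstate(divide="ignore", invalid="ignore"):
        se_unit = np.where(
            result.residual_variance > 0,
            result.log_fc / (result.t_stat * np.sqrt(result.residual_variance)),
            np.nan,
        )
    # se_unit = sqrt(1/n1 + 1/n2); constant across genes, recover robustly.
    unit = float(np.nanmedian(np.abs(se_unit)))
    if not np.isfinite(unit) or unit <= 0:
        raise ValueError("cannot recover design scale from degenerate input")
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = result.log_fc / (unit * np.sqrt(post_var))
    t_mod = np.where(post_var <= 0, np.where(result.log_fc != 0, np.sign(result.log_fc) * np.inf, 0.0), t_mod)
    finite_df = np.where(np.isinf(post_df), 1e12, post_df)
    p_raw = 2.0 * stats.t.sf(np.abs(t_mod), finite_df)
    p_raw = np.where(np.isinf(t_mod), 0.0, p_raw)
    return replace(
        result,
        t_stat=t_mod,
        df_residual=post_df,
        residual_variance=post_var,
        p_raw=p_raw,
        p_adj=adjust_bh(p_raw),
        moderated=True,
    )
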