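"""Synthetic two-group expression, gene sets and markers with planted truth.

Emulates the study design every stage of the pipeline expects: two
treatment groups (default 7 + 7 samples), log2-scale expression with
additive homoscedastic Gaussian noise, gene sets planted as up-, down-,
bi-directionally or not regulated, and clinical-marker columns correlated
with chosen gene subsets *independently of group* (links are built on
within-group-centered gene signals, so they survive within-group
z-scoring).  The planted structure is returned as a `SimTruth` so recovery
by the enrichment, network and selection stages can be scored.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    MarkerMatrix,
    SampleGroups,
    SimilarityNetwork,
)

__all__ = [
    "SetSpec",
    "MarkerSpec",
    "SimConfig",
    "SimTruth",
    "simulate_expression",
    "simulate_markers",
    "simulate_study",
    "evaluate_recovery",
]

REGIMES = ("up", "down", "bidirectional", "null")


@dataclass
class SetSpec:
    """One planted gene set: size, regulation regime, effect size in SD units."""

    name: str
    size: int
    regime: str = "null"
    effect_size: float = 0.0
    members: list[str] | None = None  # explicit ids; default: next free block

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected {REGIMES}")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if self.size < 1:
            raise ValueError("set size must be >= 1")


@dataclass
class MarkerSpec:
    """One marker linked to a gene subset with correlation ``link_strength``."""

    name: str
    linked_gene_ids: list[str] = field(default_factory=list)
    link_strength: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.link_strength <= 1.0:
            raise ValueError("link strength must lie in [0, 1]")


@dataclass
class SimConfig:
    n_genes: int
    n_per_group: int = 7
    set_specs: list[SetSpec] = field(default_factory=list)
    marker_specs: list[MarkerSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline: float = 8.0
    group_labels: tuple[str, str] = ("control", "treated")
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be positive")
        if self.n_per_group < 2:
            raise ValueError(">= 2 samples per group required")


@dataclass
class SimTruth:
    """Planted structure: per-set regimes, per-gene direction, marker links."""

    set_regimes: dict[str, str]
    gene_direction: dict[str, int]  # +1 up, -1 down, 0 unaffected
    marker_links: list[tuple[str, str, float]]  # (marker, gene, strength)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            set_regimes=d["set_regimes"],
            gene_direction={k: int(v) for k, v in d["gene_direction"].items()},
            marker_links=[tuple(t) for t in d["marker_links"]],
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def _sample_ids(config: SimConfig) -> tuple[list[str], SampleGroups]:
    a, b = config.group_labels
    ids = [f"{a}_{i + 1:02d}" for i in range(config.n_per_group)] + [
        f"{b}_{i + 1:02d}" for i in range(config.n_per_group)
    ]
    assignment = {s: (a if s.startswith(f"{a}_") else b) for s in ids}
    return ids, SampleGroups(assignment)


def simulate_expression(
    config: SimConfig,
) -> tuple[ExpressionMatrix, SampleGroups, GeneSetCollection, SimTruth]:
    """Draw a two-group expression matrix with planted set regulation.

    Baseline values are i.i.d. Normal(baseline, noise_sd) on the log2-like
    scale.  For a set with effect size delta, the treated group's mean is
    shifted by +delta*sd (regime ``up``), -delta*sd (``down``), or +/- for
    the first/second half of the set (``bidirectional``; odd sizes put the
    extra gene in the up half).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    sample_ids, groups = _sample_ids(config)
    n = 2 * config.n_per_group
    values = rng.normal(config.baseline, config.noise_sd, size=(config.n_genes, n))
    treated = groups.mask(sample_ids, config.group_labels[1])

    gene_index = {g: i for i, g in enumerate(genes)}
    direction = {g: 0 for g in genes}
    sets: dict[str, list[str]] = {}
    regimes: dict[str, str] = {}
    cursor = 0
    for spec in config.set_specs:
        if spec.members is not None:
            members = list(spec.members)
            missing = [g for g in members if g not in gene_index]
            if missing:
                raise ValueError(f"set {spec.name!r} names unknown gene {missing[0]!r}")
        else:
            if cursor + spec.size > config.n_genes:
                raise ValueError(
                    f"set sizes exceed n_genes={config.n_genes} at set {spec.name!r}"
                )
            members = genes[cursor : cursor + spec.size]
            cursor += spec.size
        sets[spec.name] = members
        regimes[spec.name] = spec.regime
        if spec.regime == "null" or spec.effect_size == 0:
            continue
        shift = spec.effect_size * config.noise_sd
        half = (len(members) + 1) // 2
        for rank, g in enumerate(members):
            i = gene_index[g]
            if spec.regime == "up" or (spec.regime == "bidirectional" and rank < half):
                values[i, treated] += shift
                direction[g] = 1
            elif spec.regime == "down" or spec.regime == "bidirectional":
                values[i, treated] -= shift
                direction[g] = -1
    x = ExpressionMatrix(values, genes, sample_ids)
    truth = SimTruth(set_regimes=regimes, gene_direction=direction, marker_links=[])
    return x, groups, GeneSetCollection(sets), truth


def simulate_markers(
    x: ExpressionMatrix,
    groups: SampleGroups,
    config: SimConfig,
    truth: SimTruth | None = None,
) -> tuple[MarkerMatrix, SimTruth]:
    """Draw marker columns correlated with linked genes within groups.

    Each marker is rho * (standardized mean of its linked genes'
    within-group-centered values) + sqrt(1 - rho^2) * standard normal
    noise.  Group-mean shifts are deliberately NOT propagated, so links are
    orthogonal to the treatment contrast by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if not config.marker_specs:
        raise ValueError("no marker specs in config")
    gene_index = {g: i for i, g in enumerate(x.gene_ids)}
    n = x.n_samples
    centered = x.values.copy()
    for label in groups.labels:
        mask = groups.mask(x.sample_ids, label)
        centered[:, mask] -= centered[:, mask].mean(axis=1, keepdims=True)
    columns = []
    links: list[tuple[str, str, float]] = []
    for spec in config.marker_specs:
        noise = rng.standard_normal(n)
        rho = spec.link_strength
        if rho == 0 or not spec.linked_gene_ids:
            columns.append(noise)
            continue
        missing = [g for g in spec.linked_gene_ids if g not in gene_index]
        if missing:
            raise ValueError(f"marker {spec.name!r} links unknown gene {missing[0]!r}")
        rows = [gene_index[g] for g in spec.linked_gene_ids]
        signal = centered[rows].mean(axis=0)
        signal = signal / signal.std(ddof=1)
        columns.append(rho * signal + np.sqrt(1.0 - rho**2) * noise)
        links.extend((spec.name, g, rho) for g in spec.linked_gene_ids)
    markers = MarkerMatrix(
        np.column_stack(columns), x.sample_ids, [m.name for m in config.marker_specs]
    )
    if truth is None:
        truth = SimTruth(set_regimes={}, gene_direction={}, marker_links=[])
    truth.marker_links = links
    return markers, truth


def simulate_study(config: SimConfig):
    """Convenience wrapper: expression + groups + sets + markers + truth."""
    x, groups, sets, truth = simulate_expression(config)
    if config.marker_specs:
        markers, truth = simulate_markers(x, groups, config, truth)
    else:
        markers = None
    return x, groups, sets, markers, truth


def _precision_recall(predicted: set, planted: set) -> tuple[float, float]:
    tp = len(predicted & planted)
    precision = tp / len(predicted) if predicted else np.nan
    recall = tp / len(planted) if planted else np.nan
    return precision, recall


def evaluate_recovery(
    truth: SimTruth,
    enrichment=None,
    network: SimilarityNetwork | None = None,
    selected_genes=None,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Score pipeline outputs against the planted structure.

    Returns a flat metric dict; metrics whose denominator is empty (e.g.
    sensitivity with nothing planted) are NaN.  Enrichment sensitivities
    use the BH-adjusted q at ``alpha``; null-set false-positive rates use
    the raw permutation p (they should sit near ``alpha`` by calibration).
    """
    metrics: dict[str, float] = {}
    if enrichment is not None:
        unknown = [s for s in enrichment.index if s not in truth.set_regimes]
        if unknown:
            raise ValueError(f"enrichment result names unknown set {unknown[0]!r}")
        for regime, q_col in (("up", "q_up"), ("down", "q_down")):
            planted = [s for s in enrichment.index if truth.set_regimes[s] == regime]
            others = [s for s in enrichment.index if truth.set_regimes[s] != regime]
            metrics[f"enrich_sensitivity_{regime}"] = (
                float((enrichment.loc[planted, q_col] < alpha).mean())
                if planted
                else np.nan
            )
            metrics[f"enrich_specificity_{regime}"] = (
                float((enrichment.loc[others, q_col] >= alpha).mean())
                if others
                else np.nan
            )
        planted_bi = [
            s for s in enrichment.index if truth.set_regimes[s] == "bidirectional"
        ]
        if planted_bi:
            sub = enrichment.loc[planted_bi]
            detected = (
                (sub["q_bidir"] < alpha)
                & (sub["q_up"] >= alpha)
                & (sub["q_down"] >= alpha)
            )
            metrics["bidirectional_only_detection_rate"] = float(detected.mean())
        else:
            metrics["bidirectional_only_detection_rate"] = np.nan
        null_sets = [s for s in enrichment.index if truth.set_regimes[s] == "null"]
        for fam in ("p_up", "p_down", "p_bidir"):
            metrics[f"null_fpr_{fam}"] = (
                float((enrichment.loc[null_sets, fam] < alpha).mean())
                if null_sets
                else np.nan
            )
    if network is not None:
        predicted = {(g, m) for g, m, _s, _sign in network.edges}
        planted = {(g, m) for m, g, _rho in truth.marker_links}
        p, r = _precision_recall(predicted, planted)
        metrics["edge_precision"] = p
        metrics["edge_recall"] = r
    if selected_genes is not None:
        linked = {g for _m, g, _rho in truth.marker_links}
        affected = {g for g, d in truth.gene_direction.items() if d != 0}
        planted_genes = linked & affected
        p, r = _precision_recall(set(selected_genes), planted_genes)
        metrics["gene_selection_precision"] = p
        metrics["gene_selection_recall"] = r
    return metrics
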