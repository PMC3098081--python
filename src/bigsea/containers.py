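"""Core in-memory containers shared across the pipeline stages.

All containers are light dataclasses around numpy arrays with explicit
identifier lists, validated on construction.  Conversion to/from pandas
is provided where a tabular view is the natural interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleGroups",
    "GeneSetCollection",
    "MarkerMatrix",
    "CcaModel",
    "SimilarityNetwork",
]


def _check_unique(ids, axis_name):
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {axis_name} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, genes x samples."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(self.values[rows], list(gene_ids), self.sample_ids)


@dataclass
class SampleGroups:
    """Assignment of each sample to one of two group labels."""

    assignment: dict[str, str]

    def __post_init__(self):
        self.assignment = {str(k): str(v) for k, v in self.assignment.items()}
        if len(self.labels) != 2:
            raise ValueError(
                f"exactly 2 group labels required, got {sorted(self.labels)}"
            )

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def members(self, label: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == label]

    def mask(self, sample_ids, label: str) -> np.ndarray:
        """Boolean mask over ``sample_ids`` for membership in ``label``."""
        missing = [s for s in sample_ids if s not in self.assignment]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        return np.array([self.assignment[s] == label for s in sample_ids], dtype=bool)

    def validate_for_testing(self, sample_ids, min_per_group: int = 2) -> None:
        for label in self.labels:
            n = int(self.mask(sample_ids, label).sum())
            if n < min_per_group:
                raise ValueError(
                    f"group {label!r} has {n} samples; >= {min_per_group} required"
                )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways)."""

    sets: dict[str, list[str]]

    def __post_init__(self):
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            _check_unique(members, f"gene (in set {name!r})")

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe, min_size: int = 1) -> "GeneSetCollection":
        """Intersect members with ``universe`` (order preserved), drop small sets."""
        allowed = set(universe)
        kept = {}
        for name, members in self.sets.items():
            inter = [g for g in members if g in allowed]
            if len(inter) >= min_size:
                kept[name] = inter
        return GeneSetCollection(kept)


@dataclass
class MarkerMatrix:
    """Clinical/plasma marker measurements, samples x markers."""

    values: np.ndarray
    sample_ids: list[str]
    marker_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_names = [str(m) for m in self.marker_names]
        if self.values.shape != (len(self.sample_ids), len(self.marker_names)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_names)} markers"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("marker matrix contains non-finite values")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.marker_names, "marker")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.marker_names
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class CcaModel:
    """Fitted (regularized) canonical correlation analysis.

    ``x_weights`` / ``y_weights`` are scaled so each canonical variate has
    unit variance under the regularized covariance metric; ``can_cor`` holds
    the canonical correlations in non-increasing order.
    """

    lambda_x: float
    lambda_y: float
    can_cor: np.ndarray
    x_weights: np.ndarray  # (p, dims)
    y_weights: np.ndarray  # (q, dims)
    x_variates: np.ndarray  # (n, dims)
    y_variates: np.ndarray  # (n, dims)
    x_names: list[str] = field(default_factory=list)
    y_names: list[str] = field(default_factory=list)

    @property
    def n_dims(self) -> int:
        return len(self.can_cor)


@dataclass
class SimilarityNetwork:
    """Bipartite gene x marker similarity with a thresholded edge list.

    ``edges`` holds (gene, marker, similarity, sign) for exactly the pairs
    with |similarity| >= threshold, sorted by (gene, marker).
    """

    similarity: pd.DataFrame  # genes x markers
    dims_used: int
    threshold: float
    edges: list[tuple[str, str, float, str]]

    @classmethod
    def from_similarity(
        cls, similarity: pd.DataFrame, dims_used: int, threshold: float
    ) -> "SimilarityNetwork":
        edges = []
        for gene in sorted(similarity.index):
            for marker in sorted(similarity.columns):
                s = float(similarity.at[gene, marker])
                if abs(s) >= threshold:
                    edges.append(
                        (gene, marker, s, "positive" if s >= 0 else "negative")
                    )
        return cls(similarity, dims_used, threshold, edges)

    def genes_with_edges(self) -> list[str]:
        return sorted({e[0] for e in self.edges})
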