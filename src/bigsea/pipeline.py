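"""End-to-end orchestration: filter -> DE -> GSEA -> rCCA -> select -> overrep.

Every stage writes its outputs into a run directory once (write-once), and
a machine-readable manifest records versions, seeds and flags so a run is
reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cca import (
    estimate_regularization,
    rcc,
    select_marker_associated_genes,
    similarity_network,
    zscore_within_group,
)
from .diffexpr import fit_gene_linear_models, moderate_variances
from .enrich import gsea_test, summarize_direction_classes
from .io import (
    filter_low_expression,
    read_expression,
    read_gene_sets,
    read_markers,
    read_sample_groups,
    write_network,
)
from .overrep import fisher_overrepresentation

logger = logging.getLogger("bigsea")

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_LAMBDA_GRID = (0.001, 0.01, 0.1, 1.0)


@dataclass
class PipelineConfig:
    """Paths and tuning flags for a full pipeline run.

    Defaults pin the documented analysis settings: B = 1000 permutations,
    similarity threshold tau = 0.65 over d = 6 dimensions, alpha = 0.05,
    and the low-expression filter at intensity 3 on more than 50% of arrays.
    """

    expression_path: str
    groups_path: str
    gmt_path: str
    out_dir: str
    markers_path: str | None = None
    seed: int = 0
    B: int = 1000
    alpha: float = 0.05
    tau: float = 0.65
    d: int = 6
    intensity_floor: float = 3.0
    low_expr_fraction: float = 0.5
    min_set_size: int = 5
    stat_scaling: str = "size"  # or "sqrt"
    moderation_for_report: bool = True
    select_on_adjusted_p: bool = True
    overrep_sided: str = "greater"
    zscore_scope: str = "within-group"  # or "global"
    lambda_grid_x: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    lambda_grid_y: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    reference_group: str | None = None


def _write_once(df: pd.DataFrame, path: Path, **kwargs) -> None:
    if path.exists():
        raise FileExistsError(f"refusing to overwrite existing output {path}")
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full integrative analysis; returns the run directory.

    Stages: (1) low-expression filter, (2) per-gene differential
    expression, (3) permutation GSEA with direction-class summary,
    (4) rCCA + similarity network (when markers are provided),
    (5) marker-associated gene selection, (6) Fisher overrepresentation.
    Identical config + seed reproduce identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "bigsea_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "flags": {
            k: v
            for k, v in vars(config).items()
            if k not in ("expression_path", "groups_path", "gmt_path", "markers_path", "out_dir")
        },
        "stages": [],
    }
    stage = "load-inputs"
    try:
        x = read_expression(config.expression_path)
        groups = read_sample_groups(config.groups_path)
        sets = read_gene_sets(config.gmt_path)
        markers = read_markers(config.markers_path) if config.markers_path else None

        stage = "filter"
        x = filter_low_expression(x, config.intensity_floor, config.low_expr_fraction)
        manifest["stages"].append({"stage": stage, "genes_retained": x.n_genes})

        stage = "diffexpr"
        de = fit_gene_linear_models(x, groups, reference_group=config.reference_group)
        de_report = moderate_variances(de) if config.moderation_for_report else de
        _write_once(de_report.to_frame(), out / "diffexpr.tsv")
        manifest["stages"].append({"stage": stage, "moderated": de_report.moderated})

        stage = "gsea"
        enr = gsea_test(
            x,
            groups,
            sets,
            B=config.B,
            seed=config.seed,
            alpha=config.alpha,
            min_set_size=config.min_set_size,
            scaling=config.stat_scaling,
            reference_group=config.reference_group,
        )
        _write_once(enr, out / "enrichment.tsv")
        classes = summarize_direction_classes(enr, alpha=config.alpha)
        _write_once(
            pd.DataFrame([classes]), out / "direction_classes.tsv", index=False
        )
        manifest["stages"].append({"stage": stage, "n_sets": int(len(enr)), **classes})

        selected: list[str] = []
        if markers is not None:
            stage = "rcca"
            annotated = sorted({g for m in sets.sets.values() for g in m})
            x_cca = x.subset_genes([g for g in x.gene_ids if g in set(annotated)])
            x_frame = x_cca.to_frame().T  # samples x genes
            y_frame = markers.to_frame().loc[x_frame.index]
            if config.zscore_scope == "within-group":
                xz = zscore_within_group(x_frame, groups)
                yz = zscore_within_group(y_frame, groups)
            else:
                xz = (x_frame - x_frame.mean()) / x_frame.std(ddof=1)
                yz = (y_frame - y_frame.mean()) / y_frame.std(ddof=1)
            lx, ly, surface = estimate_regularization(
                xz, yz, config.lambda_grid_x, config.lambda_grid_y
            )
            _write_once(surface, out / "cv_score_surface.tsv", index_label="lambda_x")
            model = rcc(xz, yz, lx, ly)
            scree = pd.DataFrame(
                {"dimension": np.arange(1, model.n_dims + 1), "canonical_correlation": model.can_cor}
            )
            _write_once(scree, out / "canonical_correlations.tsv", index=False)
            d = min(config.d, model.n_dims)
            net = similarity_network(model, xz, yz, d=d, tau=config.tau)
            _write_once(net.similarity, out / "similarity.tsv", index_label="gene")
            write_network(net, out / "network")
            manifest["stages"].append(
                {
                    "stage": stage,
                    "lambda_x": lx,
                    "lambda_y": ly,
                    "dims_used": d,
                    "n_edges": len(net.edges),
                }
            )

            stage = "select"
            selected = select_marker_associated_genes(
                net, de_report, alpha=config.alpha, use_adjusted=config.select_on_adjusted_p
            )
            (out / "selected_genes.txt").write_text("\n".join(selected) + "\n")
            manifest["stages"].append({"stage": stage, "n_selected": len(selected)})

            stage = "overrep"
            universe = [g for g in x_cca.gene_ids]
            table = fisher_overrepresentation(
                selected, universe, sets.restrict(universe, min_size=1), sided=config.overrep_sided
            )
            _write_once(table, out / "overrepresentation.tsv")
            manifest["stages"].append({"stage": stage, "n_sets_tested": int(len(table))})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("run_pipeline: %d stages completed", len(manifest["stages"]))
    return out
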