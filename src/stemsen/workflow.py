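"""End-to-end orchestration: expression pipeline, slope fits, enrichment.

``run_all`` binds the modules into one reproducible run: it reads an FPKM
matrix, applies the preprocessing and trend-selection pipeline, fits a
per-culture linear model to every consensus candidate's log2 evolution,
runs overrepresentation analysis of the up- and down-regulated gene lists
when an annotation file is supplied, and writes everything to a run
directory together with a versioned manifest. Identical configuration and
seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .enrichment import enrich_table, rows_to_frame
from .fpkm import PipelineConfig, run_pipeline
from .stats import fit_linear

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger(__name__)

MANIFEST_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    matrix_path: str
    out_dir: str
    seed: int = 0
    housekeeping_id: str = "GAPDH"
    sum_threshold: float = 5.0
    initial_threshold: float = 1.0
    min_step: float = 0.0
    fold_limit: float = 3.0
    alpha: float = 0.05
    annotation_path: str | None = None
    background_path: str | None = None
    cultures: tuple[str, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "matrix_path": str(self.matrix_path),
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "housekeeping_id": self.housekeeping_id,
            "sum_threshold": self.sum_threshold,
            "initial_threshold": self.initial_threshold,
            "min_step": self.min_step,
            "fold_limit": self.fold_limit,
            "alpha": self.alpha,
            "annotation_path": None if self.annotation_path is None else str(self.annotation_path),
            "background_path": None if self.background_path is None else str(self.background_path),
            "cultures": None if self.cultures is None else list(self.cultures),
        }


def _slope_table(result, cultures) -> pd.DataFrame:
    rows = []
    candidates = result.trend_calls[result.trend_calls["consensus"] != "none"]
    for fid in candidates["feature_id"]:
        for cid in cultures:
            series = result.series.get((fid, cid))
            if series is None:
                continue
            log2 = np.asarray(series.log2_evolution)
            fit = fit_linear(np.arange(log2.size), log2)
            rows.append(
                {"feature_id": fid, "culture_id": cid, "slope": fit.slope,
                 "intercept": fit.intercept, "r2": fit.goodness_of_fit}
            )
    return pd.DataFrame(rows, columns=["feature_id", "culture_id", "slope", "intercept", "r2"])


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline and return the run directory.

    Stage failures abort with a stage-tagged error message; partial output
    is left in place and flagged incomplete in the manifest only when every
    stage before it completed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        matrix = sio.read_expression_tsv(config.matrix_path)
    except Exception as exc:
        raise RuntimeError(f"[read-matrix] {exc}") from exc

    pcfg = PipelineConfig(
        housekeeping_id=config.housekeeping_id,
        sum_threshold=config.sum_threshold,
        initial_threshold=config.initial_threshold,
        min_step=config.min_step,
        fold_limit=config.fold_limit,
        required_cultures=config.cultures,
    )
    try:
        result = run_pipeline(matrix, pcfg)
    except Exception as exc:
        raise RuntimeError(f"[fpkm-pipeline] {exc}") from exc

    rep = result.report
    logger.info("input features: %d", rep.n_input)
    logger.info("removed (status fail): %d", rep.n_removed_fail)
    logger.info("removed (low expression): %d", rep.n_removed_low)
    logger.info("kept for trend analysis: %d", rep.n_kept)

    result.trend_calls.to_csv(out / "trend_calls.tsv", sep="\t", index=False)
    result.cv_table.to_csv(out / "cv_table.tsv", sep="\t", index=False, float_format="%.10g")
    sio.write_json(rep.to_dict(), out / "filter_report.json")

    cultures = matrix.cultures
    try:
        slopes = _slope_table(result, cultures)
    except Exception as exc:
        raise RuntimeError(f"[trend-stats] {exc}") from exc
    slopes.to_csv(out / "trend_slopes.tsv", sep="\t", index=False, float_format="%.10g")

    up = sorted(result.trend_calls.loc[result.trend_calls["consensus"] == "up", "feature_id"])
    down = sorted(result.trend_calls.loc[result.trend_calls["consensus"] == "down", "feature_id"])
    sio.write_gene_list(up, out / "genes_up.txt")
    sio.write_gene_list(down, out / "genes_down.txt")

    enrichment_counts = {}
    if config.annotation_path is not None:
        try:
            path = Path(config.annotation_path)
            anns = sio.read_gmt(path) if path.suffix == ".gmt" else sio.read_annotation_tsv(path)
            if config.background_path:
                background = sio.read_gene_list(config.background_path)
            else:
                # reference list defaults to every feature that entered trend
                # analysis — the universe the query lists were drawn from
                background = sorted(result.trend_calls["feature_id"])
            for direction, genes in (("up", up), ("down", down)):
                if not genes:
                    enrichment_counts[direction] = 0
                    continue
                rows = enrich_table(genes, anns, background=background, alpha=config.alpha)
                rows_to_frame(rows).to_csv(
                    out / f"enrichment_{direction}.tsv", sep="\t", index=False,
                    float_format="%.10g",
                )
                enrichment_counts[direction] = sum(
                    1 for r in rows if r.q is not None and r.q < config.alpha
                )
        except Exception as exc:
            raise RuntimeError(f"[enrichment] {exc}") from exc

    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "config": config.to_dict(),
        "seed": config.seed,
        "counts": {
            "filter": rep.to_dict(),
            "consensus_up": len(up),
            "consensus_down": len(down),
            "excluded_in_normalization": len(result.excluded),
            "enriched_terms": enrichment_counts,
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    sio.write_json(manifest, out / "manifest.json")
    return out
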