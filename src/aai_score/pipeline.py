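"""End-to-end pipeline: quantify -> fit -> score -> cluster (+ AHR AUC).

The pipeline accepts either a raw C_T table (which is first run through the
comparative-C_T stage) or a ready-made fold-change response table, and
optionally an airway-resistance table.  It writes every intermediate as a
tidy CSV plus the score dendrogram in Newick, and a plain-text run log
recording the configuration and library versions, so a run is reproducible
from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .ahr import auc_by_group, auc_table
from .dose_response import ResponseRecord, fit_all
from .exceptions import InputValidationError
from .io import (
    fits_to_frame,
    fold_changes_to_frame,
    read_ahr_table,
    read_ct_table,
    read_response_table,
    scores_to_frame,
    write_newick,
)
from .qpcr import DEFAULT_REFERENCE_GENE, quantify_table
from .score import DEFAULT_ANALYTES, Dendrogram, ScoreResult, cluster_scores, score_groups

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    ct_table: str | None = None
    response_table: str | None = None
    ahr_table: str | None = None
    outdir: str = "results"
    reference_gene: str = DEFAULT_REFERENCE_GENE
    calibrator_dose: float = 0.0
    analytes: tuple[str, ...] = DEFAULT_ANALYTES
    include_ifng: bool = False
    alpha: float = 0.05
    include_dose_zero: bool = False
    linkage: str = "average"
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise InputValidationError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if self.ct_table is None and self.response_table is None and self.ahr_table is None:
            raise InputValidationError("at least one input table is required")
        if not self.analytes:
            raise InputValidationError("analytes must be non-empty")
        object.__setattr__(self, "analytes", tuple(self.analytes))


@dataclass
class PipelineReport:
    """In-memory results of a run, alongside the paths written."""

    config: PipelineConfig
    fold_changes: pd.DataFrame | None = None
    fits: pd.DataFrame | None = None
    scores: list[ScoreResult] = field(default_factory=list)
    dendrogram: Dendrogram | None = None
    ahr_per_mouse: pd.DataFrame | None = None
    ahr_summary: pd.DataFrame | None = None
    outputs: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every stage the configured inputs allow and write outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config=config)
    log_lines = [f"aai-score {__version__}", "config:"]
    for f in dataclasses.fields(config):
        log_lines.append(f"  {f.name}: {getattr(config, f.name)!r}")
    import numpy, scipy  # noqa: PLC0415 — versions for the run log

    log_lines.append(f"versions: numpy {numpy.__version__}, scipy {scipy.__version__}, pandas {pd.__version__}")

    responses: list[ResponseRecord] | None = None
    if config.ct_table is not None:
        ct_records = read_ct_table(config.ct_table)
        fold = quantify_table(
            ct_records, reference_gene=config.reference_gene, calibrator_dose=config.calibrator_dose
        )
        report.fold_changes = fold_changes_to_frame(fold)
        p = outdir / "fold_changes.csv"
        report.fold_changes.to_csv(p, index=False)
        report.outputs["fold_changes"] = p
        responses = [
            ResponseRecord(r.sample_id, r.group, r.dose, r.analyte, r.fold_change) for r in fold
        ]
        log_lines.append(f"quantified {len(ct_records)} C_T records -> {len(fold)} fold changes")
    if config.response_table is not None:
        if responses is not None:
            raise InputValidationError("provide either a C_T table or a response table, not both")
        responses = read_response_table(config.response_table)
        log_lines.append(f"read {len(responses)} response records")

    if responses is not None:
        # fit every analyte present (the fit table is a deliverable in itself);
        # the score then uses only the configured analyte set
        fits = fit_all(responses, include_dose_zero=config.include_dose_zero)
        report.fits = fits_to_frame(fits)
        p = outdir / "slope_fits.csv"
        report.fits.to_csv(p, index=False)
        report.outputs["fits"] = p

        report.scores = score_groups(
            fits, analytes=config.analytes, alpha=config.alpha, include_ifng=config.include_ifng
        )
        p = outdir / "scores.csv"
        scores_to_frame(report.scores).to_csv(p, index=False)
        report.outputs["scores"] = p
        log_lines.append(
            "scores: "
            + ", ".join(f"{s.group}={s.score:.4g} ({s.label})" for s in report.scores)
        )

        if len(report.scores) >= 2:
            report.dendrogram = cluster_scores(report.scores, linkage=config.linkage)
            p = outdir / "dendrogram.nwk"
            write_newick(report.dendrogram.to_newick(), p)
            report.outputs["dendrogram"] = p

    if config.ahr_table is not None:
        curves = read_ahr_table(config.ahr_table)
        report.ahr_per_mouse = auc_table(curves)
        report.ahr_summary = auc_by_group(curves)
        p1 = outdir / "ahr_auc_per_mouse.csv"
        p2 = outdir / "ahr_auc_summary.csv"
        report.ahr_per_mouse.to_csv(p1, index=False)
        report.ahr_summary.to_csv(p2, index=False)
        report.outputs["ahr_per_mouse"] = p1
        report.outputs["ahr_summary"] = p2
        log_lines.append(f"AHR: {len(curves)} curves summarized")

    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    report.outputs["log"] = log_path
    logger.info("pipeline finished; outputs in %s", outdir)
    return report
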