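"""End-to-end orchestration of the verification pipeline.

Stage order mirrors the verification workflow: optional blood-spike
filtering of the candidate list, spectral-contrast QC of every
(sample, replicate, peptide) measurement, removal of peptides below the
LOD in too many samples, light/heavy quantification with duplicate
averaging, and the tumor-vs-control biomarker statistics. One
structured log line per stage records the counts entering and leaving
each filter.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .blood import blood_filter_table
from .config import PipelineConfig
from .quantify import RatioMatrix, build_ratio_matrix, ratios_from_qc, sibling_correlation
from .simulate import ReferenceLibrary, TransitionDataset
from .spectral import (
    QCResult,
    QCStatus,
    estimate_background,
    evaluate_measurement,
    filter_peptides_by_lod,
    qc_results_to_frame,
    summarize_qc,
)
from .stats import compare_groups, select_significant

logger = logging.getLogger("prmverify")

__all__ = ["PipelineResult", "run_qc", "run_pipeline"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    qc_report: pd.DataFrame
    qc_summary: dict
    kept_peptides: list[str]
    removed_peptides: list[str]
    ratio_matrix: RatioMatrix
    sibling: pd.DataFrame
    results: pd.DataFrame
    significant: pd.DataFrame
    blood_table: pd.DataFrame | None = None
    blood_rejected: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_table(self.qc_report, outdir / "qc_report.tsv")
        pio.write_json(self.qc_summary, outdir / "qc_summary.json")
        matrix = self.ratio_matrix.ratios.copy()
        matrix.index.name = "peptide"
        pio.write_table(matrix, outdir / "ratio_matrix.tsv", index=True)
        cv = self.ratio_matrix.cv_percent.copy()
        cv.index.name = "peptide"
        pio.write_table(cv, outdir / "cv_report.tsv", index=True)
        pio.write_table(self.sibling, outdir / "sibling_correlation.tsv")
        pio.write_table(self.results, outdir / "results.tsv")
        if self.blood_table is not None:
            pio.write_table(self.blood_table, outdir / "blood_classification.tsv")


def run_qc(
    dataset: TransitionDataset,
    library: ReferenceLibrary,
    config: PipelineConfig,
) -> list[QCResult]:
    """Evaluate the spectral-matching cascade for every measurement."""
    records = dataset.records
    peptides = [p for p in sorted(records["peptide"].unique()) if p in library]
    missing = sorted(set(records["peptide"].unique()) - set(peptides))
    if missing:
        raise ValueError(f"peptides absent from the reference library: {missing}")

    backgrounds = {
        pep: estimate_background(records, pep, "light", lod_floor=config.lod_floor)
        for pep in peptides
    }

    pivot = records.pivot_table(
        index=["sample", "replicate", "peptide"],
        columns=["label", "ion"],
        values="area",
        aggfunc="first",
    ).sort_index()

    results = []
    for (sample, replicate, peptide), row in pivot.iterrows():
        ref = library[peptide]
        light = row["light"].loc[list(ref.ion_ids)].to_numpy(float)
        heavy = row["heavy"].loc[list(ref.ion_ids)].to_numpy(float)
        results.append(
            evaluate_measurement(
                light, heavy, ref,
                sample=sample, replicate=replicate,
                threshold=config.cos_threshold,
                share_factor=config.interference_share_factor,
                lod_criterion=config.lod_criterion,
                background=backgrounds[peptide],
            )
        )
    return results


def _rescue_fully_unresolved(
    qc_results: list[QCResult],
    backgrounds: dict[str, np.ndarray],
    library: ReferenceLibrary,
) -> list[QCResult]:
    """Treat (sample, peptide) cells where *every* replicate is
    unresolved as below-LOD with background substitution, so the ratio
    matrix keeps its no-missing-values guarantee. Logged; in the
    published data only single replicates were ever affected.
    """
    by_cell: dict[tuple[str, str], list[QCResult]] = {}
    for r in qc_results:
        by_cell.setdefault((r.sample, r.peptide), []).append(r)
    rescued = 0
    for cell in by_cell.values():
        if all(r.status == QCStatus.UNRESOLVED for r in cell):
            for r in cell:
                r.status = QCStatus.BELOW_LOD
                r.background_substituted = True
                r.light_substitute = backgrounds[r.peptide]
                r.ions_used = library[r.peptide].ion_ids
            rescued += len(cell)
    if rescued:
        logger.warning(
            "qc: %d measurements in fully-unresolved cells fell back to background",
            rescued,
        )
    return qc_results


def run_pipeline(
    dataset: TransitionDataset,
    library: ReferenceLibrary,
    config: PipelineConfig | None = None,
    blood_series: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run blood filter (optional) -> spectral QC -> quantification ->
    biomarker statistics and return the full result bundle."""
    config = config or PipelineConfig()
    dataset.validate()
    records = dataset.records

    blood_table = None
    blood_rejected: list[str] = []
    if blood_series is not None:
        blood_table = blood_filter_table(
            blood_series, tolerance=config.blood_slope_tolerance
        )
        blood_rejected = blood_table.loc[
            blood_table["decision"] == "reject", "peptide"
        ].tolist()
        n_before = records["peptide"].nunique()
        records = records[~records["peptide"].isin(blood_rejected)]
        logger.info(
            "blood_filter: %d candidates in, %d rejected, %d peptides remain",
            len(blood_table), len(blood_rejected), records["peptide"].nunique(),
        )
        if records.empty:
            raise ValueError("blood filter rejected every monitored peptide")
        dataset = TransitionDataset(records=records, provenance=dataset.provenance)
        logger.debug("blood_filter: %d -> %d peptides", n_before,
                     records["peptide"].nunique())

    qc_results = run_qc(dataset, library, config)
    backgrounds = {
        pep: estimate_background(records, pep, "light", lod_floor=config.lod_floor)
        for pep in records["peptide"].unique()
    }
    qc_results = _rescue_fully_unresolved(qc_results, backgrounds, library)

    kept, removed = filter_peptides_by_lod(qc_results)
    summary = summarize_qc(qc_results, removed_peptides=removed)
    logger.info(
        "spectral_qc: %d pairs, %.1f%% matched, %.1f%% below LOD, %.1f%% unresolved; "
        "%d peptides removed by the >50%% LOD rule",
        summary.total, 100 * summary.fraction_matched,
        100 * summary.fraction_below_lod, 100 * summary.fraction_unresolved,
        len(removed),
    )

    kept_qc = [r for r in qc_results if r.peptide not in set(removed)]
    ratio_records = ratios_from_qc(records, kept_qc)
    groups = records.drop_duplicates("sample").set_index("sample")["group"].to_dict()
    matrix = build_ratio_matrix(ratio_records, groups)
    logger.info(
        "quantification: %d peptides x %d samples; median duplicate CV %.2f%%",
        matrix.ratios.shape[0], matrix.ratios.shape[1],
        float(np.nanmedian(matrix.cv_percent.to_numpy())),
    )

    protein_map: dict[str, list[str]] = {}
    for protein, grp in records.drop_duplicates("peptide").groupby("protein"):
        protein_map[protein] = sorted(grp["peptide"])
    sibling = sibling_correlation(
        matrix, protein_map, log_scale=config.sibling_log_scale
    )

    peptide_proteins = (
        records.drop_duplicates("peptide").set_index("peptide")["protein"].to_dict()
    )
    results = compare_groups(
        matrix,
        peptide_proteins,
        alpha=config.alpha,
        fc_threshold=config.fc_threshold,
        fixed_specificity=config.fixed_specificity,
        fc_method=config.fc_definition,
    )
    significant = select_significant(
        results, alpha=config.alpha, fc_threshold=config.fc_threshold
    )
    logger.info(
        "biomarker_stats: %d peptides tested, %d significant (%d proteins) at "
        "adj p < %g and FC > %g",
        len(results), len(significant), significant["protein"].nunique(),
        config.alpha, config.fc_threshold,
    )

    qc_report = qc_results_to_frame(qc_results)
    summary_dict = {
        "total_pairs": summary.total,
        "fraction_accepted": summary.fraction_accepted,
        "fraction_substituted": summary.fraction_substituted,
        "fraction_matched": summary.fraction_matched,
        "fraction_below_lod": summary.fraction_below_lod,
        "fraction_unresolved": summary.fraction_unresolved,
        "removed_peptides": removed,
        "blood_rejected": blood_rejected,
        "seed": config.seed,
        "python": sys.version.split()[0],
    }
    return PipelineResult(
        config=config,
        qc_report=qc_report,
        qc_summary=summary_dict,
        kept_peptides=kept,
        removed_peptides=removed,
        ratio_matrix=matrix,
        sibling=sibling,
        results=results,
        significant=significant,
        blood_table=blood_table,
        blood_rejected=blood_rejected,
    )
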