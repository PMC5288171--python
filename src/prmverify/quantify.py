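"""Light/heavy ratio computation, duplicate averaging and consistency
metrics.

The quantitative readout per (sample, replicate, peptide) is the sum of
the light (endogenous) product-ion XIC areas divided by the sum of the
heavy (isotope-labeled internal standard) areas, restricted to the ions
the QC stage retained. Full-process duplicates are then averaged; the
per-cell CV% of duplicates is the reproducibility metric, and the
Pearson correlation between sibling peptides of one protein across
samples is the consistency metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spectral import QCResult, QCStatus

__all__ = [
    "RatioRecord",
    "RatioMatrix",
    "compute_ratio",
    "average_duplicates",
    "build_ratio_matrix",
    "sibling_correlation",
    "ratios_from_qc",
]


@dataclass(frozen=True)
class RatioRecord:
    sample: str
    replicate: int
    peptide: str
    ratio: float
    status: str


@dataclass
class RatioMatrix:
    """Duplicate-averaged light/heavy ratios, peptides x samples.

    Background substitution at the QC stage guarantees every kept
    peptide has a value for every sample. ``cv_percent`` holds the
    duplicate CV% (NaN where only one usable replicate existed).
    """

    ratios: pd.DataFrame
    cv_percent: pd.DataFrame
    groups: pd.Series  # sample -> 'tumor' | 'control'

    def group_values(self, peptide: str, group: str) -> np.ndarray:
        samples = self.groups.index[self.groups == group]
        return self.ratios.loc[peptide, samples].to_numpy(float)


def compute_ratio(
    qc_result: QCResult,
    light_areas: Sequence[float],
    heavy_areas: Sequence[float],
    ion_ids: Sequence[str] | None = None,
) -> RatioRecord:
    """Summed-light over summed-heavy ratio on the QC-retained ions.

    ``light_areas``/``heavy_areas`` are aligned to ``ion_ids`` (or
    already restricted to ``qc_result.ions_used`` when ion_ids is None).
    For a below-LOD result the background-substituted light vector from
    the QC stage replaces the measured one.
    """
    if qc_result.status == QCStatus.UNRESOLVED:
        raise ValueError(
            f"{qc_result.peptide}: cannot quantify an unresolved measurement"
        )
    light = np.asarray(light_areas, dtype=float)
    heavy = np.asarray(heavy_areas, dtype=float)
    if ion_ids is not None:
        keep = np.asarray([i in set(qc_result.ions_used) for i in ion_ids])
        light = light[keep]
        heavy = heavy[keep]
    if qc_result.status == QCStatus.BELOW_LOD and qc_result.light_substitute is not None:
        sub = np.asarray(qc_result.light_substitute, dtype=float)
        if ion_ids is not None and sub.size != light.size:
            sub = sub[keep]
        light = sub
    heavy_sum = heavy.sum()
    if heavy_sum <= 0:
        raise ValueError(
            f"{qc_result.peptide}: zero heavy area — corrupt internal standard"
        )
    return RatioRecord(
        sample=qc_result.sample,
        replicate=qc_result.replicate,
        peptide=qc_result.peptide,
        ratio=float(light.sum() / heavy_sum),
        status=qc_result.status,
    )


def average_duplicates(
    records: Iterable[RatioRecord],
) -> tuple[float, float]:
    """Mean ratio and CV% over the usable replicates of one
    (sample, peptide).

    Unresolved replicates are excluded (the accepted replicate's value
    is kept); CV% uses the n-1 standard deviation and is NaN for a
    single usable replicate.
    """
    usable = [r.ratio for r in records if r.status != QCStatus.UNRESOLVED]
    if not usable:
        raise ValueError("no usable replicate; below-LOD background required upstream")
    mean = float(np.mean(usable))
    if len(usable) < 2:
        return mean, float("nan")
    sd = float(np.std(usable, ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return mean, cv


def build_ratio_matrix(
    ratio_records: Iterable[RatioRecord], groups: Mapping[str, str]
) -> RatioMatrix:
    """Average duplicates and pivot into a peptides x samples grid."""
    recs = list(ratio_records)
    if not recs:
        raise ValueError("no ratio records")
    by_cell: dict[tuple[str, str], list[RatioRecord]] = {}
    for r in recs:
        by_cell.setdefault((r.peptide, r.sample), []).append(r)
    rows = []
    for (peptide, sample), cell in by_cell.items():
        mean, cv = average_duplicates(cell)
        rows.append(
            {"peptide": peptide, "sample": sample, "ratio": mean, "cv_percent": cv}
        )
    tidy = pd.DataFrame(rows)
    ratios = tidy.pivot(index="peptide", columns="sample", values="ratio")
    cv = tidy.pivot(index="peptide", columns="sample", values="cv_percent")
    if ratios.isna().any().any():
        missing = ratios.stack(dropna=False)
        gap = missing[missing.isna()].index[0]
        raise ValueError(f"missing ratio for peptide/sample {gap}")
    group_series = pd.Series({s: groups[s] for s in ratios.columns}, name="group")
    return RatioMatrix(ratios=ratios, cv_percent=cv, groups=group_series)


def sibling_correlation(
    matrix: RatioMatrix,
    protein_map: Mapping[str, Sequence[str]],
    log_scale: bool = False,
) -> pd.DataFrame:
    """Pearson R across samples between the two peptides of each
    protein monitored with exactly two kept peptides.

    Proteins with any other peptide count are skipped (reported with
    NaN). Computed on raw ratios by default, matching how the published
    workflow reported it; ``log_scale`` switches to log-ratios.
    """
    if matrix.ratios.shape[1] < 3:
        raise ValueError("sibling correlation needs at least 3 samples")
    rows = []
    for protein, peptides in protein_map.items():
        kept = [p for p in peptides if p in matrix.ratios.index]
        if len(kept) != 2:
            rows.append(
                {"protein": protein, "pearson_r": float("nan"),
                 "n_peptides": len(kept)}
            )
            continue
        a = matrix.ratios.loc[kept[0]].to_numpy(float)
        b = matrix.ratios.loc[kept[1]].to_numpy(float)
        if log_scale:
            a, b = np.log(a), np.log(b)
        r = float(sps.pearsonr(a, b).statistic)
        rows.append({"protein": protein, "pearson_r": r, "n_peptides": 2})
    return pd.DataFrame(rows)


def ratios_from_qc(
    records: pd.DataFrame, qc_results: Iterable[QCResult]
) -> list[RatioRecord]:
    """Compute a ratio for every non-unresolved QC result from the long
    transition table."""
    pivot = records.pivot_table(
        index=["sample", "replicate", "peptide", "ion"],
        columns="label",
        values="area",
        aggfunc="first",
    )
    out = []
    for qc in qc_results:
        if qc.status == QCStatus.UNRESOLVED:
            continue
        ions = list(qc.ions_used)
        cell = pivot.loc[(qc.sample, qc.replicate, qc.peptide)]
        cell = cell.loc[ions]
        out.append(
            compute_ratio(qc, cell["light"].to_numpy(), cell["heavy"].to_numpy())
        )
    return out
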