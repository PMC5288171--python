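"""Blood-contamination filtering of biomarker candidates.

Uterine aspirates carry a variable amount of residual blood, so a
candidate whose signal tracks the blood content of the sample reflects
the blood proteome rather than the endometrium. In the spike-in
experiment, aspirates from two patients are split into aliquots spiked
with increasing volume fractions of full blood; for each peptide the
ordinary-least-squares slope of its (replicate-averaged) area on the
blood fraction is computed per patient, and a peptide showing a
positive slope in both patients is rejected.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["linear_slope", "classify_blood_derived", "blood_filter_table"]


def linear_slope(fractions: Sequence[float], areas: Sequence[float]) -> float:
    """OLS slope of area on blood volume fraction (area units per unit
    fraction)."""
    x = np.asarray(fractions, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need equal-length 1-D vectors with >= 2 points")
    if np.unique(x).size < 2:
        raise ValueError("all blood fractions are equal; slope is undefined")
    if np.any(y < 0):
        raise ValueError("areas must be non-negative")
    return float(stats.linregress(x, y).slope)


def classify_blood_derived(
    slopes_by_patient: Mapping[str, float], tolerance: float = 0.0
) -> str:
    """'reject' iff the slope is positive in every patient, else 'keep'.

    ``tolerance`` sets the minimum slope counted as positive (default 0:
    any strictly positive slope counts), absorbing regression noise when
    desired.
    """
    if not slopes_by_patient:
        raise ValueError("no per-patient slopes provided")
    if any(s is None or np.isnan(s) for s in slopes_by_patient.values()):
        raise ValueError("missing slope for at least one patient")
    if all(s > tolerance for s in slopes_by_patient.values()):
        return "reject"
    return "keep"


def blood_filter_table(
    series: pd.DataFrame, tolerance: float = 0.0
) -> pd.DataFrame:
    """Run the spike-in filter over a long blood-series table.

    ``series`` columns: patient, peptide, fraction, replicate, area.
    Injection replicates are averaged per (patient, peptide, fraction)
    before the regression. Returns one row per peptide with the slope
    per patient and the keep/reject decision.
    """
    required = {"patient", "peptide", "fraction", "replicate", "area"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"blood series table missing columns: {sorted(missing)}")

    mean_areas = (
        series.groupby(["peptide", "patient", "fraction"], sort=True)["area"]
        .mean()
        .reset_index()
    )
    patients = sorted(series["patient"].unique())
    rows = []
    for peptide, grp in mean_areas.groupby("peptide", sort=True):
        slopes = {}
        for patient in patients:
            sub = grp[grp["patient"] == patient].sort_values("fraction")
            if sub.empty:
                raise ValueError(f"peptide {peptide!r} missing for patient {patient!r}")
            slopes[patient] = linear_slope(sub["fraction"], sub["area"])
        decision = classify_blood_derived(slopes, tolerance=tolerance)
        row = {"peptide": peptide, "decision": decision}
        row.update({f"slope_{p}": slopes[p] for p in patients})
        rows.append(row)
    return pd.DataFrame(rows)
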