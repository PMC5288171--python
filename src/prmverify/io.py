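"""Readers and writers for the pipeline's plain-text interchange formats.

Canonical formats (comma written, comma or tab auto-detected on read):

- transition table: sample, group, replicate, protein, peptide, label,
  ion, area [, censored] — one XIC peak area per row;
- reference library: peptide, ion, relative_area (TSV);
- blood series: patient, peptide, fraction, replicate, area;
- results / QC report / ratio matrix: tab-separated, 6 significant
  digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ReferenceLibrary, TransitionDataset

__all__ = [
    "read_transition_table",
    "write_transition_table",
    "read_reference_library",
    "write_reference_library",
    "read_blood_series",
    "write_blood_series",
    "write_table",
    "write_json",
]

TRANSITION_COLUMNS = [
    "sample", "group", "replicate", "protein", "peptide", "label", "ion", "area",
]
_LABELS = {"light", "heavy"}
FLOAT_FORMAT = "%.6g"


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table, sniffing the delimiter."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def read_transition_table(path: str | Path) -> TransitionDataset:
    """Load and validate a long-format transition table.

    Hard errors name the offending column or row: missing columns,
    unparseable or negative areas, duplicate (sample, replicate,
    peptide, label, ion) keys and unknown labels are all rejected.
    """
    frame = _read_delimited(path)
    missing = [c for c in TRANSITION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")

    areas = pd.to_numeric(frame["area"], errors="coerce")
    bad = areas.isna()
    if bad.any():
        raise ValueError(f"{path}: unparseable area at data row {int(bad.idxmax()) + 1}")
    frame["area"] = areas.astype(float)
    neg = frame["area"] < 0
    if neg.any():
        raise ValueError(f"{path}: negative area at data row {int(neg.idxmax()) + 1}")

    bad_label = ~frame["label"].isin(_LABELS)
    if bad_label.any():
        row = int(bad_label.idxmax()) + 1
        raise ValueError(f"{path}: unknown label at data row {row} (expect light/heavy)")

    key = ["sample", "replicate", "peptide", "label", "ion"]
    dup = frame.duplicated(subset=key)
    if dup.any():
        raise ValueError(f"{path}: duplicate transition key at data row {int(dup.idxmax()) + 1}")

    per_sample_groups = frame.groupby("sample")["group"].nunique()
    if (per_sample_groups > 1).any():
        bad_sample = per_sample_groups.index[per_sample_groups > 1][0]
        raise ValueError(f"{path}: sample {bad_sample!r} carries more than one group label")

    if "censored" not in frame.columns:
        frame["censored"] = False
    else:
        frame["censored"] = frame["censored"].astype(bool)
    frame["replicate"] = frame["replicate"].astype(int)
    return TransitionDataset(records=frame[list(TransitionDataset.RECORD_COLUMNS)])


def write_transition_table(dataset: TransitionDataset, path: str | Path) -> None:
    cols = [c for c in TransitionDataset.RECORD_COLUMNS if c in dataset.records.columns]
    dataset.records.to_csv(path, index=False, columns=cols, float_format="%.10g")


def read_reference_library(path: str | Path) -> ReferenceLibrary:
    frame = _read_delimited(path)
    missing = [c for c in ("peptide", "ion", "relative_area") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return ReferenceLibrary.from_frame(frame)


def write_reference_library(library: ReferenceLibrary, path: str | Path) -> None:
    library.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_blood_series(path: str | Path) -> pd.DataFrame:
    frame = _read_delimited(path)
    required = ["patient", "peptide", "fraction", "replicate", "area"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return frame


def write_blood_series(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a report table as TSV with 6 significant digits."""
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_json(data: dict, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
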