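"""Spectral-contrast quality control of PRM transition data.

Peptide identity in a PRM run is confirmed by comparing the fragment-ion
peak-area profile of a measurement against a matrix-free reference
acquisition of the synthetic peptide mix. The similarity score is the
cosine of the spectral contrast angle,

    cos(theta) = sum_i(A_exp_i * A_ref_i)
                 / sqrt(sum_i A_exp_i^2 * sum_i A_ref_i^2),

computed over the top product-ion XIC areas. A measurement is accepted
when both the endogenous (light) and the isotope-labeled (heavy) trace
score above the threshold (default 0.98, strict). Failures are resolved
by a cascade: a single interfered ion is dropped from both traces and
the score recomputed on the remaining ions (never fewer than four);
measurements below the limit of detection have their light areas
replaced by a background estimate; everything else is left unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceSpectrum",
    "QCResult",
    "QCSummary",
    "QCStatus",
    "spectral_contrast_cosine",
    "detect_interfered_ion",
    "evaluate_measurement",
    "estimate_background",
    "filter_peptides_by_lod",
    "summarize_qc",
    "ms1_tic_check",
    "qc_results_to_frame",
]


class QCStatus:
    """Mutually exclusive outcomes of the spectral-matching cascade."""

    ACCEPTED = "accepted"
    ACCEPTED_AFTER_SUBSTITUTION = "accepted_after_substitution"
    BELOW_LOD = "below_lod"
    UNRESOLVED = "unresolved"

    ALL = (ACCEPTED, ACCEPTED_AFTER_SUBSTITUTION, BELOW_LOD, UNRESOLVED)
    MATCHED = (ACCEPTED, ACCEPTED_AFTER_SUBSTITUTION)


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Relative product-ion intensities from the matrix-free reference run.

    ``relative_areas`` are strictly positive, sorted non-increasing
    (ion ids are ranks within the reference) and normalized to sum 1.
    At least four ions are required for the QC cascade to operate.
    """

    peptide: str
    ion_ids: tuple[str, ...]
    relative_areas: np.ndarray

    def __post_init__(self) -> None:
        areas = np.asarray(self.relative_areas, dtype=float)
        if len(self.ion_ids) != areas.size:
            raise ValueError(f"{self.peptide}: ion ids and areas differ in length")
        if areas.size < 4:
            raise ValueError(f"{self.peptide}: reference spectrum needs >= 4 ions")
        if np.any(areas <= 0):
            raise ValueError(f"{self.peptide}: reference areas must be positive")
        if np.any(np.diff(areas) > 1e-12):
            raise ValueError(f"{self.peptide}: reference areas must be non-increasing")
        if not np.isclose(areas.sum(), 1.0, rtol=1e-9):
            raise ValueError(f"{self.peptide}: reference areas must sum to 1")
        object.__setattr__(self, "relative_areas", areas)
        object.__setattr__(self, "ion_ids", tuple(self.ion_ids))

    @property
    def n_ions(self) -> int:
        return len(self.ion_ids)


@dataclass
class QCResult:
    """Spectral-matching outcome for one (sample, replicate, peptide)."""

    sample: str
    replicate: int
    peptide: str
    cos_light: float
    cos_heavy: float
    status: str
    ions_used: tuple[str, ...]
    background_substituted: bool = False
    light_substitute: np.ndarray | None = None
    n_ions_min: int = 4


@dataclass
class QCSummary:
    total: int
    fraction_accepted: float
    fraction_substituted: float
    fraction_below_lod: float
    fraction_unresolved: float
    removed_peptides: list[str] = field(default_factory=list)

    @property
    def fraction_matched(self) -> float:
        """Share of pairs with positive spectral matching (either accept path)."""
        return self.fraction_accepted + self.fraction_substituted


def spectral_contrast_cosine(
    areas_exp: Sequence[float], areas_ref: Sequence[float]
) -> float:
    """Cosine of the spectral contrast angle between a measured and a
    reference fragment-intensity vector.

    Scale-invariant in each argument; returns 0.0 for an all-zero
    experimental vector (the degenerate below-LOD convention).
    """
    exp = np.asarray(areas_exp, dtype=float)
    ref = np.asarray(areas_ref, dtype=float)
    if exp.shape != ref.shape or exp.ndim != 1 or exp.size < 1:
        raise ValueError("area vectors must be 1-D and of equal length >= 1")
    if np.any(exp < 0) or np.any(ref < 0):
        raise ValueError("XIC areas must be non-negative")
    ref_norm = np.linalg.norm(ref)
    if ref_norm == 0:
        raise ValueError("reference areas must not be all zero")
    exp_norm = np.linalg.norm(exp)
    if exp_norm == 0:
        return 0.0
    return float(np.dot(exp, ref) / (exp_norm * ref_norm))


def detect_interfered_ion(
    areas: Sequence[float],
    reference: ReferenceSpectrum,
    share_factor: float = 1.5,
) -> int | None:
    """Index of the single interfered ion, or None.

    An ion is an interference candidate when its observed relative
    contribution exceeds its reference share by more than
    ``share_factor``. Only a unique candidate is reported: the paper's
    manual curation dropped one obviously interfered trace, so an
    ambiguous pattern (zero or several candidates) is not "obvious".
    """
    areas = np.asarray(areas, dtype=float)
    total = areas.sum()
    if total <= 0:
        return None
    excess = (areas / total) / reference.relative_areas
    candidates = np.flatnonzero(excess > share_factor)
    if candidates.size != 1:
        return None
    return int(candidates[0])


def evaluate_measurement(
    light_areas: Sequence[float],
    heavy_areas: Sequence[float],
    reference: ReferenceSpectrum,
    *,
    sample: str = "",
    replicate: int = 1,
    threshold: float = 0.98,
    share_factor: float = 1.5,
    lod_criterion: float = 0.0,
    background: Sequence[float] | None = None,
) -> QCResult:
    """Run the full QC cascade for one light/heavy measurement pair.

    Cascade:

    1. cos(theta) on all reference ions for light and heavy; both
       strictly above ``threshold`` -> ``accepted``.
    2. Otherwise, if exactly one ion shows the interference pattern
       (observed share > ``share_factor`` x reference share, checked on
       the light then the heavy trace), drop it from BOTH labels and
       recompute on the remaining ions; both above threshold and at
       least 4 ions left -> ``accepted_after_substitution``.
    3. Otherwise, if the summed light area is below ``lod_criterion``,
       replace the light areas by the ``background`` estimate and mark
       ``below_lod``.
    4. Otherwise ``unresolved``.
    """
    light = np.asarray(light_areas, dtype=float)
    heavy = np.asarray(heavy_areas, dtype=float)
    n = reference.n_ions
    if light.size != n or heavy.size != n:
        raise ValueError(
            f"{reference.peptide}: light/heavy areas misaligned with the "
            f"{n}-ion reference spectrum"
        )

    ref_areas = reference.relative_areas
    cos_l = spectral_contrast_cosine(light, ref_areas)
    cos_h = spectral_contrast_cosine(heavy, ref_areas)
    keys = dict(sample=sample, replicate=replicate, peptide=reference.peptide)

    if cos_l > threshold and cos_h > threshold:
        return QCResult(
            **keys, cos_light=cos_l, cos_heavy=cos_h,
            status=QCStatus.ACCEPTED, ions_used=reference.ion_ids,
        )

    # Substitution: only possible when dropping an ion still leaves >= 4.
    if n > 4:
        drop = detect_interfered_ion(light, reference, share_factor)
        if drop is None:
            drop = detect_interfered_ion(heavy, reference, share_factor)
        if drop is not None:
            keep = np.arange(n) != drop
            sub_ref = ref_areas[keep]
            cos_l4 = spectral_contrast_cosine(light[keep], sub_ref)
            cos_h4 = spectral_contrast_cosine(heavy[keep], sub_ref)
            if cos_l4 > threshold and cos_h4 > threshold:
                ions = tuple(i for i, k in zip(reference.ion_ids, keep) if k)
                return QCResult(
                    **keys, cos_light=cos_l4, cos_heavy=cos_h4,
                    status=QCStatus.ACCEPTED_AFTER_SUBSTITUTION, ions_used=ions,
                )

    if light.sum() < lod_criterion:
        sub = None
        if background is not None:
            sub = np.asarray(background, dtype=float)
            if sub.size != n:
                raise ValueError("background vector misaligned with reference ions")
        return QCResult(
            **keys, cos_light=cos_l, cos_heavy=cos_h,
            status=QCStatus.BELOW_LOD, ions_used=reference.ion_ids,
            background_substituted=True, light_substitute=sub,
        )

    return QCResult(
        **keys, cos_light=cos_l, cos_heavy=cos_h,
        status=QCStatus.UNRESOLVED, ions_used=reference.ion_ids,
    )


def estimate_background(
    records: pd.DataFrame,
    peptide: str,
    label: str,
    *,
    lod_floor: float | None = None,
) -> np.ndarray:
    """Per-ion background estimate for one (peptide, label).

    Half of the smallest non-censored area observed for each ion across
    all samples; when every observation of an ion is censored the
    fallback is ``lod_floor / 2``. A ``censored`` boolean column is
    honoured when present, otherwise areas below ``lod_floor`` count as
    censored (nothing censored if no floor is known).
    """
    sub = records[(records["peptide"] == peptide) & (records["label"] == label)]
    if sub.empty:
        raise ValueError(f"peptide {peptide!r} ({label}) not present in dataset")
    if "censored" in sub.columns:
        censored = sub["censored"].astype(bool)
    elif lod_floor is not None:
        censored = sub["area"] < lod_floor
    else:
        censored = pd.Series(False, index=sub.index)

    ions = sorted(sub["ion"].unique())
    background = np.empty(len(ions))
    for j, ion in enumerate(ions):
        ok = (sub["ion"] == ion) & ~censored
        if ok.any():
            background[j] = sub.loc[ok, "area"].min() / 2.0
        else:
            if lod_floor is None:
                raise ValueError(
                    f"all observations of {peptide!r} ion {ion!r} are censored "
                    "and no lod_floor fallback was given"
                )
            background[j] = lod_floor / 2.0
    return background


def filter_peptides_by_lod(
    qc_results: Iterable[QCResult],
) -> tuple[list[str], list[str]]:
    """Partition peptides into (kept, removed) by the >50% below-LOD rule.

    A sample counts as below-LOD for a peptide only when *all* of its
    replicates are ``below_lod``; the peptide is removed iff the
    fraction of such samples strictly exceeds one half.
    """
    frame = qc_results_to_frame(qc_results)
    kept: list[str] = []
    removed: list[str] = []
    for peptide, grp in frame.groupby("peptide", sort=True):
        by_sample = grp.groupby("sample")["status"].apply(
            lambda s: (s == QCStatus.BELOW_LOD).all()
        )
        if by_sample.mean() > 0.5:
            removed.append(peptide)
        else:
            kept.append(peptide)
    return kept, removed


def summarize_qc(
    qc_results: Iterable[QCResult], removed_peptides: Sequence[str] = ()
) -> QCSummary:
    frame = qc_results_to_frame(qc_results)
    total = len(frame)
    if total == 0:
        raise ValueError("no QC results to summarize")
    counts = frame["status"].value_counts()
    frac = lambda s: float(counts.get(s, 0)) / total  # noqa: E731
    return QCSummary(
        total=total,
        fraction_accepted=frac(QCStatus.ACCEPTED),
        fraction_substituted=frac(QCStatus.ACCEPTED_AFTER_SUBSTITUTION),
        fraction_below_lod=frac(QCStatus.BELOW_LOD),
        fraction_unresolved=frac(QCStatus.UNRESOLVED),
        removed_peptides=list(removed_peptides),
    )


def ms1_tic_check(
    tics: Sequence[float], k: float = 5.0, sample_ids: Sequence[str] | None = None
) -> pd.Series:
    """Advisory flag for samples whose MS1 total ion chromatogram is an
    outlier: |TIC - median| > k median-absolute-deviations.

    A constant injected protein amount should give near-constant TICs;
    flagged samples are reported, never dropped. Scale-invariant.
    """
    tics = np.asarray(tics, dtype=float)
    if tics.size < 3:
        raise ValueError("TIC check needs at least 3 samples")
    if np.any(tics <= 0):
        raise ValueError("TIC values must be positive")
    med = np.median(tics)
    mad = np.median(np.abs(tics - med))
    flags = np.abs(tics - med) > k * mad
    index = list(sample_ids) if sample_ids is not None else list(range(tics.size))
    return pd.Series(flags, index=index, name="tic_outlier")


def qc_results_to_frame(qc_results: Iterable[QCResult]) -> pd.DataFrame:
    """Tabulate QC results, one row per (sample, replicate, peptide)."""
    if isinstance(qc_results, pd.DataFrame):
        return qc_results
    rows = [
        {
            "sample": r.sample,
            "replicate": r.replicate,
            "peptide": r.peptide,
            "cos_light": r.cos_light,
            "cos_heavy": r.cos_heavy,
            "status": r.status,
            "ions_used": ";".join(r.ions_used),
            "background_substituted": r.background_substituted,
        }
        for r in qc_results
    ]
    return pd.DataFrame(rows)
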