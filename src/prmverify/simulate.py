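"""Synthetic PRM cohort and blood-spike data generation.

The generator emulates the verification cohort the pipeline was built
for: 20 tumor and 18 control uterine aspirates, digested in full-process
duplicate, with ~100 light/heavy peptide pairs monitored through the
five most intense product-ion XICs per precursor. Group abundance
(light/heavy ratio) distributions are log-normal, fitted to published
per-group interquartile ranges; sample preparation adds multiplicative
log-normal noise (default CV 3.6%), sporadic single-ion interference
inflates one light trace, and areas under a detection floor are flagged
censored (the QC stage, not the generator, performs background
substitution).

Everything is seeded: one top-level seed, deterministic sub-streams per
operation, and the drawn truths (true ratios, interference coordinates,
blood flags) are retained in provenance for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import ReferenceSpectrum

__all__ = [
    "Z75",
    "LogNormalParams",
    "PeptideSpec",
    "GeneratorConfig",
    "ReferenceLibrary",
    "TransitionDataset",
    "BloodSeriesConfig",
    "BloodSpikeData",
    "fit_lognormal_from_quartiles",
    "generate_reference_library",
    "simulate_cohort",
    "inject_interference",
    "simulate_blood_series",
]

# 75th percentile of the standard normal; maps quartiles to (mu, sigma).
Z75 = float(stats.norm.ppf(0.75))


@dataclass(frozen=True)
class LogNormalParams:
    """Log-normal location/scale on the natural-log scale."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    def quartiles(self) -> tuple[float, float]:
        return (
            math.exp(self.mu - Z75 * self.sigma),
            math.exp(self.mu + Z75 * self.sigma),
        )

    def draw(self, rng: np.random.Generator, size=None):
        return np.exp(rng.normal(self.mu, self.sigma, size=size))


def fit_lognormal_from_quartiles(q1: float, q3: float) -> LogNormalParams:
    """Invert a printed interquartile range into log-normal parameters.

    mu = (ln q1 + ln q3) / 2,  sigma = (ln q3 - ln q1) / (2 * z_0.75);
    the returned distribution has q1 and q3 as its exact 25th/75th
    percentiles.
    """
    if not (0 < q1 <= q3):
        raise ValueError(f"quartiles must satisfy 0 < q1 <= q3, got ({q1}, {q3})")
    lq1, lq3 = math.log(q1), math.log(q3)
    return LogNormalParams(mu=(lq1 + lq3) / 2.0, sigma=(lq3 - lq1) / (2.0 * Z75))


@dataclass(frozen=True)
class PeptideSpec:
    """Generative description of one monitored light/heavy peptide pair."""

    protein: str
    peptide: str
    tumor_q1: float
    tumor_q3: float
    control_q1: float
    control_q3: float
    detectable: bool = True

    def __post_init__(self) -> None:
        for lo, hi, grp in (
            (self.tumor_q1, self.tumor_q3, "tumor"),
            (self.control_q1, self.control_q3, "control"),
        ):
            if not (0 < lo <= hi):
                raise ValueError(
                    f"{self.peptide}: {grp} quartiles must satisfy 0 < q1 <= q3"
                )

    def group_params(self, group: str) -> LogNormalParams:
        if group == "tumor":
            return fit_lognormal_from_quartiles(self.tumor_q1, self.tumor_q3)
        if group == "control":
            return fit_lognormal_from_quartiles(self.control_q1, self.control_q3)
        raise ValueError(f"unknown group {group!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated world of the simulated verification cohort."""

    peptide_specs: tuple[PeptideSpec, ...]
    n_tumor: int = 20
    n_control: int = 18
    n_replicates: int = 2
    n_ions: int = 5
    heavy_total_area: float = 1e6
    prep_cv: float = 0.036
    ion_cv: float = 0.0
    interference_rate: float = 0.0
    interference_factor: float = 20.0
    interfere_heavy: bool = False
    lod_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptide_specs", tuple(self.peptide_specs))
        if not self.peptide_specs:
            raise ValueError("peptide_specs must not be empty")
        if min(self.n_tumor, self.n_control, self.n_replicates, self.n_ions) < 1:
            raise ValueError("counts must all be >= 1")
        if self.prep_cv < 0 or self.ion_cv < 0:
            raise ValueError("noise CVs must be non-negative")
        if not 0 <= self.interference_rate <= 1:
            raise ValueError("interference_rate must be in [0, 1]")
        if self.interference_rate > 0 and self.interference_factor <= 1:
            raise ValueError("interference_factor must exceed 1")
        if self.lod_floor < 0:
            raise ValueError("lod_floor must be non-negative")


@dataclass(frozen=True)
class ReferenceLibrary:
    """Per-peptide reference spectra from the matrix-free acquisition."""

    spectra: Mapping[str, ReferenceSpectrum]

    def __getitem__(self, peptide: str) -> ReferenceSpectrum:
        return self.spectra[peptide]

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.spectra

    def __len__(self) -> int:
        return len(self.spectra)

    def peptides(self) -> list[str]:
        return list(self.spectra)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"peptide": s.peptide, "ion": ion, "relative_area": a}
            for s in self.spectra.values()
            for ion, a in zip(s.ion_ids, s.relative_areas)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReferenceLibrary":
        spectra = {}
        for peptide, grp in frame.groupby("peptide", sort=False):
            spectra[peptide] = ReferenceSpectrum(
                peptide=peptide,
                ion_ids=tuple(grp["ion"]),
                relative_areas=grp["relative_area"].to_numpy(float),
            )
        return cls(spectra=spectra)


@dataclass
class TransitionDataset:
    """Long-format transition areas plus (for simulated data) provenance.

    ``records`` columns: sample, group, replicate, protein, peptide,
    label, ion, area, censored. Provenance carries the generating
    config, the per-sample true ratios and any interference coordinates.
    """

    records: pd.DataFrame
    provenance: dict | None = None

    RECORD_COLUMNS = (
        "sample", "group", "replicate", "protein", "peptide",
        "label", "ion", "area", "censored",
    )

    def validate(self) -> "TransitionDataset":
        missing = set(self.RECORD_COLUMNS[:-1]) - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        if (self.records["area"] < 0).any():
            bad = self.records.index[self.records["area"] < 0][0]
            raise ValueError(f"negative area at row {bad}")
        key = ["sample", "replicate", "peptide", "label", "ion"]
        dup = self.records.duplicated(subset=key)
        if dup.any():
            raise ValueError(f"duplicate transition key at row {dup.idxmax()}")
        return self

    @property
    def true_ratios(self) -> pd.DataFrame | None:
        if self.provenance is None:
            return None
        return self.provenance.get("true_ratios")


def _mult_lognormal(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    s2 = math.log1p(cv * cv)
    return np.exp(rng.normal(-s2 / 2.0, math.sqrt(s2), size=size))


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def generate_reference_library(
    peptides: Sequence[PeptideSpec | str], seed: int, n_ions: int = 5
) -> ReferenceLibrary:
    """Draw a reference spectrum per peptide: strictly positive relative
    intensities, sorted non-increasing, normalized to sum 1.

    Intensities are gamma-distributed (shape 3) before sorting, giving
    fragment patterns with a realistic dominance of the top ion without
    vanishing minor ions. Deterministic for a fixed seed.
    """
    if not peptides:
        raise ValueError("peptide list must not be empty")
    if n_ions < 4:
        raise ValueError("reference spectra need at least 4 ions")
    names = [p.peptide if isinstance(p, PeptideSpec) else str(p) for p in peptides]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ion_ids = tuple(f"ion{i + 1}" for i in range(n_ions))
    spectra = {}
    for name in names:
        rel = np.sort(rng.gamma(3.0, 1.0, size=n_ions))[::-1]
        rel = rel / rel.sum()
        spectra[name] = ReferenceSpectrum(
            peptide=name, ion_ids=ion_ids, relative_areas=rel
        )
    return ReferenceLibrary(spectra=spectra)


def simulate_cohort(
    config: GeneratorConfig, library: ReferenceLibrary
) -> TransitionDataset:
    """Generate one full verification cohort.

    Per (sample, protein) a latent standard-normal draw is shared by
    sibling peptides, so peptides of one protein report the same
    underlying abundance (this is what makes the sibling-peptide Pearson
    check meaningful). The sample's true ratio for a peptide is the
    group log-normal evaluated at that latent draw; both prep replicates
    share it and differ only by preparation noise:

        heavy_i = H * p_i * eps,   light_i = r * H * p_i * eps'

    with eps, eps' one multiplicative log-normal scalar per measurement
    and label (CV = prep_cv), preserving the within-measurement ion
    profile. Interference and LOD flagging are applied afterwards.
    """
    for spec in config.peptide_specs:
        if spec.peptide not in library:
            raise ValueError(f"peptide {spec.peptide!r} missing from reference library")

    rng_truth, rng_noise, rng_interf, rng_lod = _substreams(config.seed, 4)

    samples = [(f"T{i + 1:02d}", "tumor") for i in range(config.n_tumor)] + [
        (f"C{i + 1:02d}", "control") for i in range(config.n_control)
    ]
    proteins = sorted({s.protein for s in config.peptide_specs})
    z = {
        (sample, protein): rng_truth.normal()
        for sample, _ in samples
        for protein in proteins
    }

    truth_rows = []
    rec: dict[str, list] = {c: [] for c in TransitionDataset.RECORD_COLUMNS}
    H = config.heavy_total_area

    for sample, group in samples:
        for spec in config.peptide_specs:
            ref = library[spec.peptide]
            p = ref.relative_areas
            n = ref.n_ions
            if spec.detectable:
                params = spec.group_params(group)
                r = math.exp(params.mu + params.sigma * z[(sample, spec.protein)])
            else:
                r = 0.0
            truth_rows.append(
                {"sample": sample, "group": group, "peptide": spec.peptide,
                 "protein": spec.protein, "true_ratio": r}
            )
            for rep in range(1, config.n_replicates + 1):
                eps_h = _mult_lognormal(rng_noise, config.prep_cv)
                eps_l = _mult_lognormal(rng_noise, config.prep_cv)
                ion_h = _mult_lognormal(rng_noise, config.ion_cv, size=n)
                ion_l = _mult_lognormal(rng_noise, config.ion_cv, size=n)
                heavy = H * p * eps_h * ion_h
                if spec.detectable:
                    light = r * H * p * eps_l * ion_l
                else:
                    # undetectable peptide: light trace is pure background
                    floor = max(config.lod_floor, 1.0)
                    light = rng_lod.uniform(0.05, 0.5, size=n) * floor / n
                for label, areas in (("light", light), ("heavy", heavy)):
                    rec["sample"].extend([sample] * n)
                    rec["group"].extend([group] * n)
                    rec["replicate"].extend([rep] * n)
                    rec["protein"].extend([spec.protein] * n)
                    rec["peptide"].extend([spec.peptide] * n)
                    rec["label"].extend([label] * n)
                    rec["ion"].extend(ref.ion_ids)
                    rec["area"].extend(areas.tolist())
                    rec["censored"].extend([False] * n)

    records = pd.DataFrame(rec)
    records["censored"] = records["area"] < config.lod_floor
    dataset = TransitionDataset(
        records=records,
        provenance={
            "config": config,
            "true_ratios": pd.DataFrame(truth_rows),
            "interference": pd.DataFrame(
                columns=["sample", "replicate", "peptide", "label", "ion", "factor"]
            ),
        },
    )
    if config.interference_rate > 0:
        dataset = inject_interference(
            dataset,
            rate=config.interference_rate,
            factor=config.interference_factor,
            rng=rng_interf,
            interfere_heavy=config.interfere_heavy,
        )
    return dataset.validate()


def inject_interference(
    dataset: TransitionDataset,
    rate: float,
    factor: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    interfere_heavy: bool = False,
) -> TransitionDataset:
    """Inflate exactly one ion of a Bernoulli(rate) subset of light
    measurements by ``factor``, emulating a co-eluting contaminant on a
    single PRM trace. Coordinates are recorded in provenance.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    if rate > 0 and factor <= 1:
        raise ValueError("factor must exceed 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(0 if seed is None else seed))

    records = dataset.records.reset_index(drop=True).copy()
    labels = ("light", "heavy") if interfere_heavy else ("light",)
    hits = []
    if rate > 0:
        eligible = records[records["label"].isin(labels)]
        # .groups maps each key to the original row labels, which after the
        # reset_index above are integer positions into `records`
        groups = eligible.groupby(
            ["sample", "replicate", "peptide", "label"], sort=True
        ).groups
        areas = records["area"].to_numpy(copy=True)
        ions = records["ion"].to_numpy()
        for key in groups:
            if rng.random() >= rate:
                continue
            pos = np.asarray(groups[key])
            hit = pos[rng.integers(len(pos))]
            areas[hit] *= factor
            sample, rep, peptide, label = key
            hits.append(
                {"sample": sample, "replicate": rep, "peptide": peptide,
                 "label": label, "ion": ions[hit], "factor": factor}
            )
        records["area"] = areas

    provenance = dict(dataset.provenance or {})
    hit_frame = pd.DataFrame(
        hits, columns=["sample", "replicate", "peptide", "label", "ion", "factor"]
    )
    prior = provenance.get("interference")
    if prior is not None and len(prior):
        hit_frame = pd.concat([prior, hit_frame], ignore_index=True)
    provenance["interference"] = hit_frame
    return TransitionDataset(records=records, provenance=provenance)


@dataclass(frozen=True)
class BloodSeriesConfig:
    """Stated world of the blood spike-in experiment: aspirates from
    two patients split into aliquots spiked with 0/10/20/40% (v/v) full
    blood, analyzed in duplicate; blood-derived peptides rise with the
    blood fraction, endometrial peptides are diluted or unaffected.
    """

    blood_flags: Mapping[str, bool]
    blood_fractions: tuple[float, ...] = (0.0, 0.10, 0.20, 0.40)
    n_patients: int = 2
    n_replicates: int = 2
    noise_cv: float = 0.05
    nonblood_profile: str = "mixed"  # 'dilution', 'flat' or alternate 'mixed'
    seed: int = 0

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.blood_fractions)
        object.__setattr__(self, "blood_fractions", fr)
        object.__setattr__(self, "blood_flags", dict(self.blood_flags))
        if len(fr) < 2 or any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("blood fractions must be strictly increasing")
        if not all(0 <= f < 1 for f in fr):
            raise ValueError("blood fractions must lie in [0, 1)")
        if self.n_patients < 1 or self.n_replicates < 1:
            raise ValueError("patient and replicate counts must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.nonblood_profile not in ("dilution", "flat", "mixed"):
            raise ValueError("nonblood_profile must be dilution, flat or mixed")
        if not self.blood_flags:
            raise ValueError("blood_flags must not be empty")


@dataclass
class BloodSpikeData:
    """Simulated spike-in series plus its ground truth."""

    frame: pd.DataFrame  # patient, peptide, fraction, replicate, area
    truth: pd.DataFrame  # peptide, blood_derived, profile
    config: BloodSeriesConfig


def simulate_blood_series(
    config: BloodSeriesConfig, seed: int | None = None
) -> BloodSpikeData:
    """Generate per-peptide MS1 area profiles across the blood dilution
    series. Blood-derived peptides follow a + b*f with b > 0; endometrial
    peptides follow a*(1-f) (dilution) or stay flat, the two readings of
    the observed non-increasing profiles.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed)
    )
    peptides = sorted(config.blood_flags)
    truth_rows = []
    rows = []
    for i, peptide in enumerate(peptides):
        is_blood = bool(config.blood_flags[peptide])
        if is_blood:
            profile = "blood"
        elif config.nonblood_profile == "mixed":
            profile = "dilution" if i % 2 == 0 else "flat"
        else:
            profile = config.nonblood_profile
        truth_rows.append(
            {"peptide": peptide, "blood_derived": is_blood, "profile": profile}
        )
        for patient in range(1, config.n_patients + 1):
            base = rng.uniform(1e4, 1e6)
            gain = rng.uniform(3.0, 8.0)
            for f in config.blood_fractions:
                if profile == "blood":
                    level = base * (1.0 + gain * f)
                elif profile == "dilution":
                    level = base * (1.0 - f)
                else:
                    level = base
                for rep in range(1, config.n_replicates + 1):
                    rows.append(
                        {
                            "patient": f"P{patient}",
                            "peptide": peptide,
                            "fraction": f,
                            "replicate": rep,
                            "area": level * _mult_lognormal(rng, config.noise_cv),
                        }
                    )
    return BloodSpikeData(
        frame=pd.DataFrame(rows), truth=pd.DataFrame(truth_rows), config=config
    )
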