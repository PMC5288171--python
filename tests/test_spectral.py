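"""Spectral-contrast QC: the cosine score, the substitution cascade and
the LOD rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from prmverify import (
    GeneratorConfig,
    QCResult,
    QCStatus,
    ReferenceSpectrum,
    estimate_background,
    evaluate_measurement,
    filter_peptides_by_lod,
    generate_reference_library,
    inject_interference,
    ms1_tic_check,
    simulate_cohort,
    spectral_contrast_cosine,
    summarize_qc,
)
from prmverify.simulate import PeptideSpec

REF = ReferenceSpectrum(
    peptide="TESTPEP",
    ion_ids=("ion1", "ion2", "ion3", "ion4", "ion5"),
    relative_areas=np.array([90, 85, 55, 45, 25]) / 300.0,
)

pos_vectors = hnp.arrays(
    float, 5, elements=st.floats(1e-3, 1e6, allow_nan=False, allow_infinity=False)
)


class TestCosine:
    def test_identical_profiles_give_one(self):
        v = [90, 85, 55, 45, 25]
        assert spectral_contrast_cosine(v, v) == pytest.approx(1.0)

    def test_orthogonal_profiles_give_zero(self):
        assert spectral_contrast_cosine([1, 0, 0, 0, 0], [0, 1, 0, 0, 0]) == 0.0

    def test_hand_computed_value(self):
        # dot = 21400, |exp|^2 = 22000, |ref|^2 = 21000
        got = spectral_contrast_cosine([100, 80, 60, 40, 20], [90, 85, 55, 45, 25])
        assert got == pytest.approx(21400 / np.sqrt(22000 * 21000), rel=1e-12)
        assert got == pytest.approx(0.995618, abs=1e-6)

    def test_all_zero_experimental_returns_zero(self):
        assert spectral_contrast_cosine([0, 0, 0, 0, 0], [1, 2, 3, 4, 5]) == 0.0

    @pytest.mark.parametrize(
        "exp,ref",
        [([1, 2], [1, 2, 3]), ([-1, 2, 3], [1, 2, 3]), ([1, 2, 3], [0, 0, 0])],
    )
    def test_rejects_invalid_inputs(self, exp, ref):
        with pytest.raises(ValueError):
            spectral_contrast_cosine(exp, ref)

    @given(exp=pos_vectors, ref=pos_vectors, c=st.floats(1e-3, 1e3))
    @settings(max_examples=200, derandomize=True)
    def test_bounds_and_scale_invariance(self, exp, ref, c):
        """cos(theta) lies in [0,1], is invariant under positive
        rescaling of either argument, and proportional vectors score 1."""
        score = spectral_contrast_cosine(exp, ref)
        assert 0.0 <= score <= 1.0 + 1e-12
        assert spectral_contrast_cosine(c * exp, ref) == pytest.approx(score, rel=1e-9)
        assert spectral_contrast_cosine(exp, c * ref) == pytest.approx(score, rel=1e-9)
        assert spectral_contrast_cosine(c * ref, ref) == pytest.approx(1.0, rel=1e-9)


class TestEvaluateMeasurement:
    def test_clean_measurement_accepted_on_five_ions(self):
        light = 1000.0 * REF.relative_areas
        heavy = 5000.0 * REF.relative_areas
        res = evaluate_measurement(light, heavy, REF)
        assert res.status == QCStatus.ACCEPTED
        assert res.ions_used == REF.ion_ids
        assert res.cos_light == pytest.approx(1.0)

    def test_single_ion_interference_resolved_by_substitution(self):
        """The inflated fifth ion drives cos below 0.98; dropping it
        from both labels restores the match on 4 ions. Both cosines are
        checked against an inline dot/norm recomputation."""
        light = np.array([100.0, 80.0, 60.0, 40.0, 2000.0])
        heavy = 5000.0 * REF.relative_areas
        ref5 = REF.relative_areas

        def cos(a, b):
            return np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b))

        assert cos(light, ref5) < 0.98
        assert cos(light[:4], ref5[:4]) > 0.98

        res = evaluate_measurement(light, heavy, REF)
        assert res.status == QCStatus.ACCEPTED_AFTER_SUBSTITUTION
        assert res.ions_used == ("ion1", "ion2", "ion3", "ion4")
        assert res.cos_light == pytest.approx(cos(light[:4], ref5[:4]), rel=1e-12)
        assert res.cos_heavy == pytest.approx(1.0)

    def test_below_lod_substitutes_background(self):
        light = np.full(5, 0.1)
        heavy = 5000.0 * REF.relative_areas
        background = np.full(5, 0.05)
        res = evaluate_measurement(
            light, heavy, REF, lod_criterion=10.0, background=background
        )
        assert res.status == QCStatus.BELOW_LOD
        assert res.background_substituted
        np.testing.assert_array_equal(res.light_substitute, background)

    def test_distorted_above_lod_is_unresolved(self):
        # two inflated ions: no unique interference candidate
        light = np.array([100.0, 80.0, 2000.0, 40.0, 2000.0])
        heavy = 5000.0 * REF.relative_areas
        res = evaluate_measurement(light, heavy, REF, lod_criterion=10.0)
        assert res.status == QCStatus.UNRESOLVED

    def test_rejects_misaligned_ions(self):
        with pytest.raises(ValueError, match="misaligned"):
            evaluate_measurement([1, 2, 3], [1, 2, 3], REF)

    def test_four_ion_reference_never_substitutes(self):
        ref4 = ReferenceSpectrum(
            "FOURION", ("ion1", "ion2", "ion3", "ion4"),
            np.array([0.4, 0.3, 0.2, 0.1]),
        )
        light = np.array([0.4, 0.3, 0.2, 10.0])
        heavy = np.array([0.4, 0.3, 0.2, 0.1]) * 100
        res = evaluate_measurement(light, heavy, ref4, lod_criterion=0.0)
        assert res.status == QCStatus.UNRESOLVED  # never fewer than 4 ions


def brute_force_cascade(light, heavy, ref, threshold=0.98, share_factor=1.5,
                        lod_criterion=0.0):
    """Independent oracle: enumerate every 4-ion subset, identify the
    interfered ion as the one whose observed share most exceeds its
    reference share, and apply the stated acceptance rule."""

    def cos(a, b):
        na = np.sqrt(np.dot(a, a))
        if na == 0:
            return 0.0
        return np.dot(a, b) / (na * np.sqrt(np.dot(b, b)))

    p = ref.relative_areas
    n = len(p)
    if cos(light, p) > threshold and cos(heavy, p) > threshold:
        return QCStatus.ACCEPTED

    if n > 4:
        for vec in (light, heavy):
            total = vec.sum()
            if total <= 0:
                continue
            excess = (vec / total) / p
            over = np.flatnonzero(excess > share_factor)
            if over.size != 1:
                continue
            drop = over[0]
            for subset in [np.delete(np.arange(n), i) for i in range(n)]:
                if drop in subset:
                    continue
                if (
                    cos(light[subset], p[subset]) > threshold
                    and cos(heavy[subset], p[subset]) > threshold
                ):
                    return QCStatus.ACCEPTED_AFTER_SUBSTITUTION
            break

    if light.sum() < lod_criterion:
        return QCStatus.BELOW_LOD
    return QCStatus.UNRESOLVED


class TestCascadeOracle:
    def test_agrees_with_brute_force_on_random_measurements(self, rng):
        """Cascade decisions match the subset-enumerating oracle on
        1,000 random measurements spanning clean, interfered, noisy and
        below-LOD regimes."""
        mismatches = 0
        for _ in range(1000):
            scale = 10 ** rng.uniform(0, 4)
            light = scale * REF.relative_areas * np.exp(rng.normal(0, 0.15, 5))
            heavy = 1e4 * REF.relative_areas * np.exp(rng.normal(0, 0.05, 5))
            if rng.random() < 0.4:
                light[rng.integers(5)] *= 10 ** rng.uniform(0.5, 2)
            if rng.random() < 0.1:
                light *= 1e-4
            got = evaluate_measurement(
                light, heavy, REF, lod_criterion=5.0, background=np.full(5, 1.0)
            ).status
            want = brute_force_cascade(light, heavy, REF, lod_criterion=5.0)
            mismatches += got != want
        assert mismatches == 0

    def test_substitution_soundness_on_generated_interference(self, small_specs,
                                                              small_library):
        """Single-ion interference at factor >= 10 with prep CV <= 5%:
        at least 99% of interfered measurements end
        accepted_after_substitution and their recomputed ratios sit
        within 2% of the interference-free value."""
        from prmverify import PipelineConfig, ratios_from_qc
        from prmverify.pipeline import run_qc

        config = GeneratorConfig(
            peptide_specs=small_specs, prep_cv=0.05, seed=31,
        )
        clean = simulate_cohort(config, small_library)
        dirty = inject_interference(clean, rate=0.3, factor=15.0, seed=77)

        pcfg = PipelineConfig()
        qc = run_qc(dirty, small_library, pcfg)
        hits = dirty.provenance["interference"]
        hit_keys = set(zip(hits["sample"], hits["replicate"], hits["peptide"]))
        interfered = [r for r in qc if (r.sample, r.replicate, r.peptide) in hit_keys]
        assert len(interfered) == len(hit_keys) > 50
        ok = sum(
            r.status == QCStatus.ACCEPTED_AFTER_SUBSTITUTION for r in interfered
        )
        assert ok / len(interfered) >= 0.99

        # recomputed 4-ion ratios vs the interference-free measurement
        clean_sums = clean.records.groupby(
            ["sample", "replicate", "peptide", "label"]
        )["area"].sum().unstack("label")
        clean_ratio = clean_sums["light"] / clean_sums["heavy"]
        recs = {
            (r.sample, r.replicate, r.peptide): r.ratio
            for r in ratios_from_qc(dirty.records, interfered)
        }
        for key, ratio in recs.items():
            assert ratio == pytest.approx(clean_ratio.loc[key], rel=0.02)


def _qc(sample, peptide, status, replicate=1):
    return QCResult(
        sample=sample, replicate=replicate, peptide=peptide,
        cos_light=1.0, cos_heavy=1.0, status=status,
        ions_used=("ion1", "ion2", "ion3", "ion4", "ion5"),
    )


class TestLodRemoval:
    def _results(self, peptide, n_below, n_samples=38):
        out = []
        for i in range(n_samples):
            status = QCStatus.BELOW_LOD if i < n_below else QCStatus.ACCEPTED
            for rep in (1, 2):
                out.append(_qc(f"S{i:02d}", peptide, status, replicate=rep))
        return out

    def test_boundary_more_than_half(self):
        """20 of 38 samples below LOD removes the peptide; 19 of 38
        (exactly half is not 'more than') keeps it."""
        kept, removed = filter_peptides_by_lod(
            self._results("PEPA", 20) + self._results("PEPB", 19)
        )
        assert removed == ["PEPA"]
        assert kept == ["PEPB"]

    def test_sample_counts_only_when_all_replicates_below(self):
        results = []
        for i in range(4):
            results.append(_qc(f"S{i}", "PEP", QCStatus.BELOW_LOD, replicate=1))
            results.append(_qc(f"S{i}", "PEP", QCStatus.ACCEPTED, replicate=2))
        kept, removed = filter_peptides_by_lod(results)
        assert kept == ["PEP"] and removed == []

    def test_published_removal_scenario(self):
        """Fixture reconstruction of the reported outcome: exactly the
        two peptides below the LOD in more than half the samples are
        removed, by name."""
        results = []
        for pep, n_below in [
            ("VHITSLLPTPEDNLEIVLHR", 25), ("VTILELFR", 30), ("IANVFTNAFR", 2),
            ("SFVYGGCLGNK", 0),
        ]:
            results += self._results(pep, n_below)
        kept, removed = filter_peptides_by_lod(results)
        assert sorted(removed) == ["VHITSLLPTPEDNLEIVLHR", "VTILELFR"]
        assert "IANVFTNAFR" in kept and "SFVYGGCLGNK" in kept

    def test_statuses_partition_the_pairs(self):
        results = (
            self._results("PEPA", 5, 10)
            + [_qc("S00", "PEPB", QCStatus.UNRESOLVED),
               _qc("S01", "PEPB", QCStatus.ACCEPTED_AFTER_SUBSTITUTION)]
        )
        summary = summarize_qc(results)
        total = (
            summary.fraction_accepted + summary.fraction_substituted
            + summary.fraction_below_lod + summary.fraction_unresolved
        )
        assert total == pytest.approx(1.0)
        assert summary.total == len(results)


class TestBackgroundEstimate:
    def _records(self, areas, censored):
        return pd.DataFrame(
            {
                "sample": [f"S{i}" for i in range(len(areas))],
                "replicate": 1,
                "peptide": "PEP",
                "label": "light",
                "ion": "ion1",
                "area": areas,
                "censored": censored,
            }
        )

    def test_half_of_minimum_accepted(self):
        bg = estimate_background(
            self._records([10.0, 20.0, 50.0], [False] * 3), "PEP", "light"
        )
        assert bg == pytest.approx([5.0])

    def test_all_censored_falls_back_to_half_floor(self):
        bg = estimate_background(
            self._records([1.0, 2.0], [True, True]), "PEP", "light", lod_floor=8.0
        )
        assert bg == pytest.approx([4.0])

    def test_censored_values_ignored(self):
        """A censored value below every accepted one must not set the
        background: brute-force minimum over the accepted set only."""
        areas = [0.5, 10.0, 20.0, 50.0]
        censored = [True, False, False, False]
        accepted_min = min(a for a, c in zip(areas, censored) if not c)
        bg = estimate_background(self._records(areas, censored), "PEP", "light")
        assert bg == pytest.approx([accepted_min / 2.0])

    def test_unknown_peptide_rejected(self):
        with pytest.raises(ValueError):
            estimate_background(self._records([1.0], [False]), "OTHER", "light")


class TestTicCheck:
    def test_equal_tics_not_flagged(self):
        assert not ms1_tic_check([5.0] * 10).any()

    def test_tenfold_outlier_flagged(self):
        tics = [1.0] * 9 + [10.0]
        flags = ms1_tic_check(tics, k=5.0)
        assert flags.iloc[-1] and flags.sum() == 1

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            ms1_tic_check([1.0, 2.0])

    @given(
        tics=hnp.arrays(float, 12, elements=st.floats(0.1, 1e5)),
        c=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, tics, c):
        base = ms1_tic_check(tics)
        scaled = ms1_tic_check(c * np.asarray(tics))
        assert (base == scaled).all()
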