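# Methods

## The verification problem

A biomarker verification study sits between discovery (long candidate
lists, few samples) and validation (few candidates, many samples). The
workflow implemented here verifies candidate proteins in uterine
aspirates by LC-PRM: each target peptide is measured through the XIC
areas of its five most intense product ions, with a stable-isotope-
labeled (heavy) synthetic copy spiked as internal standard. The
quantity carried through the analysis is the light/heavy ratio
L/H = Σ light areas / Σ heavy areas, which cancels injection and
ionization variability.

## Spectral-contrast QC

Identity and interference are judged by the cosine of the spectral
contrast angle between the measured fragment-area vector and a
reference acquisition of the synthetic peptide mix without biological
matrix. Decisions cascade per (sample, replicate, peptide):

1. **accepted** — cos θ > `cos_threshold` (default 0.98, strict) for
   both light and heavy on all reference ions.
2. **accepted_after_substitution** — exactly one ion's observed share
   of the trace exceeds its reference share by more than
   `interference_share_factor` (default 1.5); that ion is dropped from
   *both* labels (keeping the ratio commensurable) and both cosines are
   recomputed on the remaining ≥ 4 ions. The factor 1.5 was chosen so
   that a genuine co-eluting interference of 10× or more is detected
   even on the top-ranked ion (inflating an ion of reference share p by
   F gives share excess F/(1+(F−1)p), ≈ 1.8 at p = 0.5, F = 10), while a
   clean profile sits at excess ≈ 1. Ambiguous patterns (zero or
   several candidate ions) are not treated as interference.
3. **below_lod** — summed light area < `lod_criterion`; light areas are
   replaced by the background estimate. The study never defines its
   LOD numerically, so the criterion is configuration.
4. **unresolved** — everything else; such replicates are excluded and
   the accepted replicate's value kept. If *every* replicate of a cell
   is unresolved the pipeline falls back to background substitution
   (logged) so the ratio matrix never has missing values.

Background per (peptide, label, ion) is half the smallest non-censored
area across samples, falling back to `lod_floor`/2 when everything is
censored — the study says only "an estimation of the background value".
An all-zero measured vector scores cos θ = 0 (avoids 0/0 and lands in
the below-LOD branch). A peptide is removed when the fraction of
samples below the LOD (a sample counts only when **all** its replicates
are) strictly exceeds `lod_removal_fraction` = 0.5; the unit is the
sample, not the replicate, which the source text leaves ambiguous.

The MS1 TIC check (`ms1_tic_check`) is advisory only: samples whose
summed MS1 signal deviates from the cohort median by more than k = 5
median absolute deviations are flagged, never dropped.

## Blood-contamination filter

Per peptide and patient, the OLS slope of replicate-averaged MS1 area
on blood volume fraction (0, 0.10, 0.20, 0.40) is fitted; the peptide
is rejected iff the slope is strictly positive in **both** patients.
This is deliberately not a significance test — it mirrors the published
rule — so under multiplicative noise a truly flat profile is rejected
with probability ≈ (1/2)^(n patients). The default analysis accepts
that (the 5%-noise demo rejects ~10 flat candidates beyond the 32 true
blood peptides); `blood_slope_tolerance` can absorb noise when a
minimum slope is preferred, default 0. Replicate injections are
averaged before the regression (the aggregation is unstated in the
source).

## Quantification

Ratios use only the QC-retained ion subset. Duplicates are averaged
arithmetically; CV% = 100·sd/mean with the n−1 standard deviation
(unstated in the source; NaN for singleton cells). Sibling-peptide
consistency is the Pearson R across samples between the two kept
peptides of a protein, computed on raw ratios (a `sibling_log_scale`
switch exists); proteins with any other kept-peptide count are skipped.

## Biomarker statistics

- **Mann-Whitney U**, two-sided, U counting tumor-over-control pairs
  with ties ½ (scipy; exact for small untied samples, otherwise normal
  approximation with tie and continuity corrections).
- **BH adjustment** across all tested peptides jointly (statsmodels
  step-up). Note the step-up is *not* idempotent: re-adjusting an
  adjusted vector rescales by m/i again; the tests assert the true
  invariants (elementwise ≥ raw, ≤ 1, monotone in the sort order) and
  equivalence with a brute-force oracle.
- **Fold change** = tumor median / control median. The source never
  defines FC and the printed quartiles are compatible with several
  definitions, so FC reproduction is not asserted anywhere;
  `fc_definition: mean_ratio` is available.
- **AUC** = U/(n₁n₂) — the empirical probability a random tumor ratio
  exceeds a random control ratio, ties ½.
- **Operating points**: thresholds are swept midway between adjacent
  pooled values; the reported pair maximizes Youden's J with ties
  resolved toward higher specificity (whether the published pairs are
  Youden-optimal is unstated; this is the package's reading), and
  sensitivity at fixed 95% specificity is the maximum sensitivity among
  thresholds with specificity ≥ 0.95.
- **Gate**: adjusted p < 0.05 and FC > 3, both strict.

## The synthetic cohort generator

The generator is a stated world, not a tuning knob:

- Cohort: 20 tumor / 18 control samples, 2 full-process duplicates,
  5 product ions per precursor, `heavy_total_area` = 10⁶ (arbitrary
  area units; only ratios matter).
- Group ratio distributions are **log-normal** — ratios are positive
  and right-skewed and only quartiles are published — fitted in closed
  form: μ = (ln Q1 + ln Q3)/2, σ = (ln Q3 − ln Q1)/(2·z₀.₇₅) with
  z₀.₇₅ = 0.67449. Published quartiles printed as "0.00" are censored
  at two decimals and are lifted to 0.005 (half the last printed digit)
  before fitting.
- One latent standard-normal draw per (sample, protein) is shared by
  sibling peptides, so peptides of one protein report the same
  underlying abundance — this is what the sibling Pearson check
  measures. One true ratio per sample is shared by both duplicates.
- Prep noise is **one multiplicative log-normal scalar per measurement
  and label** (default CV 0.036, the reported average duplicate CV).
  A scalar preserves the within-measurement ion profile, so a 4-ion
  ratio after substitution equals the interference-free ratio exactly;
  a per-ion `ion_cv` knob exists (default 0) for profile-level noise.
  With per-label scalars the duplicate ratio CV is ≈ √2 × 0.036 ≈ 5%,
  which keeps >99% of duplicate CVs under the reported 15% bound.
- Interference multiplies exactly one light ion by
  `interference_factor` (default 20) for a Bernoulli(rate) subset of
  measurements; heavy interference is supported behind a flag, off by
  default. Coordinates are kept in provenance.
- Censoring only *flags* areas below `lod_floor`; the QC stage, not the
  generator, performs background substitution. Undetectable peptides
  (never-synthesized standards) emit a flat uniform background light
  trace below the floor.
- Blood series: blood-derived peptides follow a(1 + g·f) with gain
  g ~ U(3, 8); endometrial peptides follow a(1 − f) (dilution) or stay
  flat — both readings of the published non-increasing profiles are
  implemented, alternating by default. Default measurement noise CV
  0.05 (the source gives no noise model for this experiment; 5% is a
  typical label-free MS1 area CV), zero in the truth-recovery fixtures.
- RNG: one top-level seed; deterministic sub-streams per operation via
  `numpy.random.SeedSequence.spawn`. Identical seeds give byte-identical
  output files.

What the generator does **not** emulate: raw spectra, chromatographic
peak shapes, retention-time drift, missingness from scheduling windows,
between-peptide response differences (areas are generated directly from
ratios), or correlated interference. A green test therefore establishes
that the *rules* of the pipeline are implemented correctly and that the
published summary statistics are internally consistent — not that the
pipeline would reproduce the study's raw-data numbers, which live on an
instrument-data server and are out of scope.

## Numerical choices and degenerate inputs

- Strict comparisons everywhere the published rules are strict
  (cos θ > 0.98, FC > 3, adj p < 0.05, "more than 50%").
- `fit_lognormal_from_quartiles` rejects q1 ≤ 0 or q1 > q3; q1 = q3
  gives σ = 0 (a point mass).
- `spectral_contrast_cosine` rejects negative areas and an all-zero
  reference; an all-zero experimental vector returns 0.
- Zero summed heavy area raises (corrupt internal standard) rather than
  returning infinity.
- Ties in the rank statistics use midranks; ROC thresholds use
  midpoints between distinct pooled values plus sentinels beyond the
  extremes.
- Tables are written with 6 significant digits; the staged CLI
  (`qc`/`quantify`/`stats`) therefore reproduces `run-all` up to that
  print precision.

## Known limitations

- The substitution cascade automates what was a manual curation step;
  the "next most intense available XIC" phrasing also admits replacing
  the interfered trace with a sixth candidate ion, which this package
  does not model (no candidate list beyond the top five exists in the
  inputs).
- The blood filter's strict-positive rule has a high false-rejection
  rate for flat profiles under noise, by design (see above).
- CV statistics are computed on ratios, not areas (unstated in the
  source).
- No multi-marker panel modelling, pathway analysis, absolute
  quantification or raw-file parsing.
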