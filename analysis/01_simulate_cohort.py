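#!/usr/bin/env python
"""Generate the synthetic verification inputs.

Emulates the study design: 20 tumor and 18 control uterine aspirates in
full-process duplicate, 52 proteins / 100 light+heavy peptide pairs
(two of them undetectable, as in the study) with group ratio
distributions fitted to the published per-group quartiles, prep noise
at the reported 3.6% CV, sporadic single-ion interference and a
detection floor; plus the blood spike-in series (129 candidate
peptides, 32 of them blood-derived, at 0/10/20/40% v/v blood).

Writes the transition table, reference library, blood series and the
generator truth sidecars under results/data/.
"""

from pathlib import Path

from prmverify import (
    BloodSeriesConfig,
    GeneratorConfig,
    generate_reference_library,
    simulate_blood_series,
    simulate_cohort,
)
from prmverify import io as pio
from prmverify.panel import default_panel

SEED = 2016
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    specs = default_panel()
    library = generate_reference_library(specs, seed=SEED)
    config = GeneratorConfig(
        peptide_specs=tuple(specs),
        prep_cv=0.036,
        interference_rate=0.02,
        interference_factor=20.0,
        lod_floor=400.0,
        seed=SEED,
    )
    dataset = simulate_cohort(config, library)
    pio.write_transition_table(dataset, OUT / "transitions.csv")
    pio.write_reference_library(library, OUT / "reference_library.tsv")
    pio.write_table(dataset.provenance["true_ratios"], OUT / "truth_ratios.tsv")
    pio.write_table(dataset.provenance["interference"], OUT / "truth_interference.tsv")

    n_meas = len(dataset.records) // (2 * config.n_ions)
    print(f"cohort: {config.n_tumor} tumor + {config.n_control} control samples, "
          f"{len(specs)} peptides, {n_meas} light/heavy measurement pairs "
          f"({len(dataset.records)} transition records)")
    print(f"interfered measurements: {len(dataset.provenance['interference'])}")

    flags = {f"CAND{i:03d}": i < 32 for i in range(129)}
    blood = simulate_blood_series(
        BloodSeriesConfig(blood_flags=flags, noise_cv=0.05, seed=SEED)
    )
    pio.write_blood_series(blood.frame, OUT / "blood_series.csv")
    pio.write_table(blood.truth, OUT / "truth_blood.tsv")
    print(f"blood series: {len(flags)} candidates, "
          f"{sum(flags.values())} blood-derived, "
          f"{len(blood.frame)} MS1 area records -> {OUT}")


if __name__ == "__main__":
    main()
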