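#!/usr/bin/env python
"""Generate the synthetic cohort and every downstream input class.

Writes a full synthetic data set (cohort table, annotated variants, the
13-tissue-pair allele-signal stand-in, a probe track with a planted
deletion, a fully penetrant pedigree) plus truth sidecars under
``results/synthetic/``.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from poromech import io
from poromech.fixtures import study_signal_sets
from poromech.simulate import (
    SimulationConfig,
    gen_cohort,
    gen_pedigree,
    gen_probe_track,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED)

    cohort, variants, truth = gen_cohort(config)
    io.write_cohort_table(cohort, OUT / "cohort.tsv")
    io.write_variant_table(variants, OUT / "variants.tsv")
    io._write_tsv(truth, OUT / "variants.truth.tsv")
    carriers = sum(1 for r in cohort if r.is_carrier)
    print(f"cohort: {len(cohort)} index patients, {carriers} carriers, "
          f"{len(variants)} variant observations")

    sets, truths = study_signal_sets(config, seed=SEED)
    io.write_allele_signals(sets, OUT / "allele_signals.tsv")
    io._write_tsv(pd.DataFrame(truths), OUT / "allele_signals.truth.tsv")
    print(f"allele signals: {len(sets)} tissue pairs "
          f"({sum(len(s.measurements) for s in sets)} measurements)")

    track, track_truth = gen_probe_track(
        deletion_spec=("E02", "E05"), config=config
    )
    io.write_probe_track(track, OUT / "probe_track.tsv")
    print(f"probe track: {len(track.probes)} probes, planted deletion "
          f"{track_truth['deleted_probes']}")

    ped, _ = gen_pedigree(3, "c.746T>C", penetrance=1.0, rng=SEED)
    io.write_pedigree(ped, OUT / "pedigree.ped")
    print(f"pedigree: {len(ped.members)} members")

    io.write_manifest(OUT, command="01_simulate_cohort", seed=SEED,
                      config=dataclasses.asdict(config))


if __name__ == "__main__":
    main()
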