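#!/usr/bin/env python
"""Run the rare-variant filter cascade and summarise the mutation spectrum.

Screens the synthetic variant table from step 01 against the benign-
polymorphism, deleteriousness and control rules, checks the result against
the generator truth, and classifies the 51-mutation study list into the
published spectrum categories.  Writes ``results/screen/``.
"""

from pathlib import Path

import pandas as pd

from poromech import io
from poromech.datamodel import VariantRecord
from poromech.fixtures import spectrum_mutations
from poromech.variant_screen import (
    FilterConfig,
    classify_mutation_type,
    screen_cascade,
    summarize_mutation_spectrum,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "screen"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    variants = io.read_variant_table(ROOT / "results/synthetic/variants.tsv")
    truth = io._read_tsv(ROOT / "results/synthetic/variants.truth.tsv")

    candidates, log = screen_cascade(variants, controls={}, cfg=FilterConfig())
    io.write_variant_table(candidates, OUT / "candidates.tsv")
    io._write_tsv(pd.DataFrame(log), OUT / "exclusions.tsv")

    truth_keys = {
        (r["patient_id"], r["gene"], r["cdna_hgvs"])
        for _, r in truth.iterrows() if r["pathogenic"] == "True"
    }
    got_keys = {(v.sample_id, v.gene, v.cdna_hgvs) for v in candidates}
    print(f"cascade: {len(variants)} in -> {len(candidates)} candidates "
          f"({len(log)} excluded)")
    print(f"truth agreement: {len(got_keys & truth_keys)}/{len(truth_keys)} "
          f"planted pathogenic recovered, "
          f"{len(got_keys - truth_keys)} false candidates")

    records = [
        VariantRecord(sample_id="SD", gene=g, cdna_hgvs=c, protein_hgvs=p,
                      vtype=classify_mutation_type(c, p, large_deletion=ld))
        for g, c, p, ld in spectrum_mutations()
    ]
    spectrum = summarize_mutation_spectrum(records)
    io._write_tsv(spectrum, OUT / "mutation_spectrum.tsv")
    print("study spectrum (count, %):")
    for _, row in spectrum[spectrum["count"] > 0].iterrows():
        print(f"  {row['vtype']:18s} {row['count']:3d}  {row['percent']}%")


if __name__ == "__main__":
    main()
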