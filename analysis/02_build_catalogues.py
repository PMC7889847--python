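#!/usr/bin/env python
"""Sense-check the simulated cohort and build its SBS96 catalogues.

Reads scratch/synthetic_inputs/ (from 01_simulate_cohort.py), validates
every SNV against the reference, builds subtype- and sample-level 96-channel
catalogues, tabulates per-sample burden, and lists recurrent driver
variants.  Tables land in results/.
"""

import sys
from pathlib import Path

import pyfaidx

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "synthetic_inputs"
RESULTS = ROOT / "results"

from lymphosig import catalogue as cat
from lymphosig.io_formats import read_mutation_table


def main() -> None:
    records, report = read_mutation_table(SCRATCH / "mutations.tsv")
    reference = pyfaidx.Fasta(str(SCRATCH / "genome.fa"), sequence_always_upper=True)
    records, sense = cat.sense_check(records, reference)
    print(f"read {len(records)} SNVs ({len(report.errors)} malformed, "
          f"{sense.n_mismatches} reference mismatches)")

    by_subtype, _ = cat.build_catalogue(records, reference, "subtype")
    by_subtype.to_csv(RESULTS / "catalogue_subtype.tsv", sep="\t")
    by_sample, n_boundary = cat.build_catalogue(records, reference, "sample")
    by_sample.to_csv(RESULTS / "catalogue_sample.tsv", sep="\t")
    print(f"catalogues: {by_subtype.shape[0]} subtypes, {by_sample.shape[0]} "
          f"samples, {n_boundary} contig-edge exclusions")

    counts = cat.per_sample_counts(records)
    counts.to_csv(RESULTS / "per_sample_counts.tsv", sep="\t", index=False)
    print("\nper-subtype burden (coding SNVs per sample):")
    print(counts.attrs["subtype_summary"].to_string(index=False))

    recurrent = cat.find_recurrent_variants(records, min_carriers=3)
    recurrent.assign(
        carriers=[";".join(c) for c in recurrent["carriers"]],
        substitution_breakdown=[str(b) for b in recurrent["substitution_breakdown"]],
        carriers_by_subtype=[str(b) for b in recurrent["carriers_by_subtype"]],
    ).to_csv(RESULTS / "recurrent_variants.tsv", sep="\t", index=False)
    print(f"\nrecurrent variants in >=3 patients: {len(recurrent)}")
    if len(recurrent):
        print(recurrent[["gene", "protein_change", "n_carriers"]].to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
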