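#!/usr/bin/env python
"""Simulate the study inputs: reference, signatures, cohort, driver, UV sample.

Writes the bulky raw inputs (FASTA, BED, mutation TSVs, truth table) under
scratch/synthetic_inputs/ — they are regenerated deterministically from the
seed — and a small cohort summary under results/.

The cohort emulates the structure of the real meta-analysis: an MF-like
subtype dominated by the UV signature, an SS-like subtype with a more even
aging/UV mix, and an ATLL-like subtype carrying the signature-17-like
process with an injected IRF4 K59R driver whose carriers are the samples
most exposed to that signature.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "synthetic_inputs"
RESULTS = ROOT / "results"
SEED = 7

from lymphosig.channels import channel_from_label
from lymphosig.cli_pipeline import summarize_cohort
from lymphosig.io_formats import (
    write_gene_annotation_bed,
    write_mutation_table,
    write_signature_matrix,
    write_trinucleotide_frequencies,
)
from lymphosig.synthetic_data import (
    SubtypeSpec,
    SyntheticCohortSpec,
    demo_signatures,
    generate_reference,
    generate_strand_cohort,
    inject_recurrent_variant,
    synthesize_cohort,
    trinucleotide_frequencies,
)


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    genome = generate_reference(100_000, seed=SEED)
    sigs = demo_signatures()
    spec = SyntheticCohortSpec(
        subtypes=[
            SubtypeSpec("MF", 20, {"Signature 1": 0.35, "Signature 7": 0.65}),
            SubtypeSpec("SS", 30, {"Signature 1": 0.55, "Signature 7": 0.45}),
            SubtypeSpec("ATLL", 10,
                        {"Signature 1": 0.25, "Signature 5": 0.15,
                         "Signature 17": 0.60},
                        sample_prefix="ATLLhi"),
            SubtypeSpec("ATLL", 35,
                        {"Signature 1": 0.50, "Signature 5": 0.35,
                         "Signature 17": 0.15},
                        sample_prefix="ATLLlo"),
        ],
        seed=SEED,
    )
    cohort = synthesize_cohort(spec, genome, sigs)
    carriers = inject_recurrent_variant(
        cohort, genome, "IRF4", "K59R", channel_from_label("C[T>G]T"),
        k=10, mode="top_by_share", signature_id="Signature 17", seed=SEED + 1,
    )
    uv = generate_strand_cohort(genome, n_ct=400, untranscribed_fraction=2 / 3,
                                n_cc_tt_pairs=20, sample_id="wgs_ctcl",
                                subtype="MF", seed=SEED + 2)
    nodal = generate_strand_cohort(genome, n_ct=400, untranscribed_fraction=0.5,
                                   n_cc_tt_pairs=0, sample_id="wgs_nodal",
                                   subtype="PTCL", seed=SEED + 3)

    genome.write_fasta(SCRATCH / "genome.fa")
    write_gene_annotation_bed(genome.genes, SCRATCH / "genes.bed")
    write_signature_matrix(sigs, SCRATCH / "signatures.tsv")
    write_mutation_table(cohort.records, SCRATCH / "mutations.tsv")
    write_mutation_table(uv + nodal, SCRATCH / "wgs_samples.tsv")
    cohort.truth.to_csv(SCRATCH / "truth.tsv", sep="\t")
    for territory in ("genome", "exome"):
        write_trinucleotide_frequencies(
            trinucleotide_frequencies(genome, territory),
            SCRATCH / f"trinucleotide_{territory}.tsv",
        )

    summary = summarize_cohort(cohort.records)
    summary.to_csv(RESULTS / "cohort_summary.tsv", sep="\t")
    print(f"genome: 1 contig of 100 kb, {len(genome.genes.intervals)} genes")
    print(f"cohort: {len(cohort.truth)} samples, {len(cohort.records)} SNVs")
    print(f"injected IRF4 K59R into {len(carriers)} signature-17-high carriers")
    print(f"UV / nodal whole-genome-style samples: {len(uv)} / {len(nodal)} SNVs")
    print(summary.to_string())
    print(f"\ninputs under {SCRATCH}")


if __name__ == "__main__":
    sys.exit(main())
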