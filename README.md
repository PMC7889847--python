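# lymphosig

Mutational-signature analysis for T-cell non-Hodgkin lymphoma exome
cohorts: SBS96 catalogue construction from somatic SNV lists, non-negative
least-squares refitting of reference signatures (COSMIC-v2-layout input)
with exome trinucleotide adjustment, cosine-budget sparsification and
per-sample gating, causal-peak attribution for testing recurrent driver
variants against signature exposure, and genome-level UV diagnostics
(transcriptional strand bias, CC>TT doublets, rainfall distances, burden
per Mb). A seeded synthetic-cohort generator makes every stage verifiable
end to end without downloads.

It is written for cancer-genomics analysts who have per-sample somatic SNV
tables (or single-sample VCFs), a reference FASTA, a signature probability
matrix, and — for strand analyses — stranded gene intervals.

## The method in brief

A sample or cohort is a 96-channel catalogue **v** (six pyrimidine-strand
substitution classes × 16 trinucleotide contexts). Exposures to reference
signatures **P** (rows summing to 1) are estimated by

    e* = argmin_{e ≥ 0} ‖ v − Pᵀ e ‖₂            (Lawson–Hanson NNLS)

with fit quality measured as the cosine similarity between **v** and its
reconstruction. Cohort fits are sparsified by greedy backward elimination
under a 0.05 cosine budget; per-sample fits are restricted to the cohort's
retained signatures and gated (>20 SNVs; ≥20 mutations per signature, with
refitting; cosine ≥ 0.6). Channels where one retained signature holds ≥75%
of the probability mass are its *causal peaks*; summing a patient's
mutations over a signature's peaks gives a percentage contribution, and
carriers versus non-carriers of each recurrent driver variant are compared
by a two-sided Wilcoxon rank-sum test at a Bonferroni threshold of
0.00029. UV exposure is corroborated at genome level by a C>T excess on
the untranscribed strand (exact binomial test), CC>TT doublets, and
near-zero rainfall distances. `docs/methods.md` has the details and
conventions.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables to `results/` (raw simulated inputs go to
`scratch/synthetic_inputs/`):

```
python analysis/01_simulate_cohort.py
python analysis/02_build_catalogues.py
python analysis/03_fit_signatures.py
python analysis/04_causal_associations.py
python analysis/05_uv_genome_diagnostics.py
```

`01` simulates a 95-sample, three-subtype cohort (27,826 SNVs on a 100 kb
reference) with an IRF4 K59R driver injected into the ten samples most
exposed to the signature-17-like process. `03` then prints the
subtype-level fits:

```
subtype-level exposures after sparsification:
  MF: Signature 1 34%, Signature 7 66% (cosine 0.998)
  SS: Signature 1 54%, Signature 7 46% (cosine 0.999)
  ATLL: Signature 1 66%, Signature 17 34% (cosine 0.983)
```

The MF-like and SS-like subtypes recover their generating UV share (65%
and 45%); in the ATLL-like subtype the deliberately flat signature
(generated at a low share) is pruned by the cosine budget and its mass
absorbed by the aging-like signature — the expected behaviour of
sparsification on featureless profiles. `04` recovers the injected
association:

```
significant: IRF4 K59R x Signature 17 (p = 2.63e-07)
```

(carrier median contribution 44% versus 4% in wild type). The same run
also flags the UV and aging signatures for this variant — carriers all sit
in one subtype, a visible reminder that pooled wild-type groups confound
subtype-private signatures. `05` contrasts the UV-mode and null
whole-genome-style samples:

```
wgs_ctcl:  C>T 171 transcribed vs 269 untranscribed, p = 3.44e-06, direction = untranscribed
  dinucleotide variants: 24, CC>TT: 21
wgs_nodal: C>T 191 transcribed vs 209 untranscribed, p = 3.95e-01, direction = none
  dinucleotide variants: 2, CC>TT: 0
```

Each stage is also available as a CLI subcommand over the TSV interchange
formats (`lymphosig simulate | catalogue | fit | fit-samples | peaks |
associate | strand | run-all`), e.g.:

```
lymphosig simulate --out-dir sim --seed 3
lymphosig run-all --config pipeline.yaml
```

`data/driver_genes_example.txt` is an illustrative driver-gene list for the
recurrence filter; supply your own curated list for real analyses.

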