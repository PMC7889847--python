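# Methods

## The model

A tumour's somatic single-base substitutions are summarised as an SBS96
catalogue: counts of the six pyrimidine-strand substitution classes (C>A,
C>G, C>T, T>A, T>C, T>G) split by the 5' and 3' flanking base. Purine-
reference mutations are reverse-complemented into this representation, so
the catalogue is strand symmetric by construction. The canonical channel
order is substitution-major, then 5' flank A/C/G/T, then 3' flank.

A catalogue `v ∈ ℝ⁹⁶` is modelled as a non-negative combination of fixed
reference signature profiles `P` (rows are signatures, each summing to 1):

    e* = argmin_{e ≥ 0} ‖ v − Pᵀ e ‖₂

solved by the Lawson–Hanson active-set method (scipy). Exposures `e` are in
mutation-count units; percentages are derived at reporting time as
`100 · e_s / Σv`, because the per-sample gate below is count-based. Fit
quality is the cosine similarity between `v` and its reconstruction
`r = Pᵀe*`. NNLS stationarity gives `r·(v−r) = 0`, hence
`cos(v, r) = |r|/|v| = √(1 − ‖v−r‖²/|v|²)`: cosine is exactly monotone in
the residual, so removing signatures can never raise it. This identity is
what makes the greedy trace provably monotone.

### Exome adjustment

Reference signatures estimated from whole genomes are refit to exome
catalogues after multiplying each channel probability by
`f_exome(context)/f_genome(context)` for its pyrimidine-centred
trinucleotide context and renormalising each signature to sum to 1.
Catalogues are left untouched; only the signatures move between territories.
Applying genome→exome then exome→genome recovers the input exactly.

### Sparsification (cohort level)

Exome catalogues are noisy enough that a full 30-signature NNLS fit keeps
spurious low-weight signatures. Starting from the full fit with cosine
`c_full`, zero-exposure signatures are removed first (no cosine change);
then, repeatedly, each retained signature is refit out in turn and the
removal with the smallest cosine decrease is accepted — as long as the
refitted cosine stays within `max_cosine_drop` (default **0.05**) of
`c_full`. The budget is measured against the full-model cosine
(cumulative), the stricter reading of a "maximum allowed reduction"; a
per-step variant is available behind `FitConfig(per_step_budget=True)`.
Ties are broken by smaller exposure, then lexicographic id, so runs are
deterministic. The last signature is never removed.

### Per-sample gates

Per-sample fitting is restricted to the signatures retained at the
sample's subtype level, then three gates apply:

1. samples with **more than 20** SNVs are fit; at or below 20 the sample is
   rejected (`rejected_too_few_snvs`). The strict `>` follows the stated
   eligibility wording; the same strict rule gates causal-peak
   contributions.
2. signatures assigned **fewer than 20 mutations** are dropped and the fit
   re-run on the survivors, iterated to a fixed point — refitting is
   required because the dropped mass must be reassigned to reconstruct the
   catalogue.
3. if the final reconstruction cosine is **below 0.6**, no signatures are
   assigned (`rejected_low_cosine`). When step 2 empties the retained set,
   the reconstruction is the zero vector, its cosine is taken as 0, and
   this gate closes — the gate enum stays three-valued.

## Causal peaks and driver association

Per-mutation attribution is only trustworthy where one signature dominates.
Channel `c` is a *causal peak* of retained signature `s` when
`p_s(c) / Σ_retained p_r(c) ≥ dominance_fraction` (default **0.75**) and
`p_s(c) > 0`. The dominance rule is the package's own concrete choice for
"contexts strongly associated with a particular signature"; the sanity
anchor is that with an aging-like and a UV-like signature retained, the
T[C>T]C channel must fall to the UV signature. With one retained signature
every channel it touches is a peak; two identical signatures produce none
(dominance 0.5 < 0.75). A sample's contribution of `s` is
`100 ×` (SNVs in peaks of `s`) / (total SNVs), computed for samples with
more than 20 SNVs; unassigned channels contribute to nothing, so
contributions are sub-additive and scale invariant.

For each recurrent driver variant — keyed by (gene, protein change), since
distinct nucleotide events producing one amino-acid change are one variant,
with the nucleotide breakdown retained — carried by at least
`min_carriers = 5` eligible samples, and each retained signature, carrier
and wild-type contribution distributions are compared by a two-sided
Wilcoxon rank-sum test (exact null when the pooled size is ≤ 12 and
tie-free, otherwise the continuity- and tie-corrected normal
approximation). Significance uses the fixed Bonferroni threshold
`0.00029` by default, reproducing the published decision rule rather than
recomputing `0.05/#tests` (a recompute flag would change the rule whenever
the test count changes; the fixed constant keeps decisions comparable).
Wild-type eligibility pools all subtypes by default; the caveat is visible
in the demo analysis, where a driver confined to one subtype also shifts
the contributions of signatures private to *other* subtypes. The 2×2
subtype-versus-signature comparisons use Fisher's exact test (two-sided,
hypergeometric-sum definition; sample odds ratio with a flagged Haldane
0.5 correction when a cell is zero).

## Strand diagnostics

UV photoproducts form at dipyrimidines and are cleared from the template
strand by transcription-coupled repair, so UV-exposed genomes carry a C>T
excess on the **untranscribed** (coding) strand. Convention: take the
mutation in its pyrimidine representation; inside genes of a single strand,
the label is `untranscribed` when the pyrimidine lies on the coding strand,
`transcribed` when it lies on the template strand; overlapping genes of
opposite strands, and intergenic positions, are `ambiguous`. Worked
example for a + strand gene (template = − strand):

    coding (+):   5'-… C …-3'    C>T here → pyrimidine on coding strand
    template (−): 3'-… G …-5'      → untranscribed
    coding (+):   5'-… G …-3'    G>A here → the pyrimidine C is on the
    template (−): 3'-… C …-5'      template strand → transcribed

Each substitution class is tested with a two-sided **exact binomial** test
of the transcribed count against p₀ = 0.5 — counts are small to moderate
and exactness keeps the oracle trivial; the full gene body is used, not
exons. Rainfall tracks report log10 distance to the previous SNV per
chromosome (adjacent positions, the CC>TT doublets, sit at 0); duplicates
are dropped with a warning. Dinucleotide variants are derived from pairs of
adjacent same-sample SNVs; runs of ≥ 3 adjacent mutated positions are
longer MNVs and are excluded from DNV calls. Constituent SNVs stay in the
SBS96 catalogue by default (the classic 30-signature analysis predates a
separate doublet decomposition), with exclusion available via the
constituent list the detector returns. Burden is coding SNVs divided by a
user-supplied capture territory in Mb.

## The synthetic data generator

The generator exists so that every stage is verifiable without downloads;
its defaults are the study conditions of the verification experiments.

* **Reference**: i.i.d. uniform ACGT contigs (default 100 kb), genes of
  1 kb tiled with 1 kb gaps and alternating strands (~50% genic). An index
  maps each of the 32 pyrimidine-centred trinucleotides to the interior
  positions matching it on either strand; generation redraws (bounded at
  100 attempts) until all 32 are populated, which is essentially certain
  above a few kb.
* **Signatures** (`demo_signatures`): a hand-built synthetic five-signature
  set — not the COSMIC matrices — caricaturing aging (C>T at NpCpG),
  APOBEC (C>T/C>G at TpCpN), a flat featureless process, UV (C>T at
  dipyrimidines, T[C>T]C dominant, 22% of its mass there), and a
  signature-17-like process (T>G at NpTpT). Peak weights sit on a uniform
  background of 0.3–0.6 so profiles overlap realistically.
* **Cohorts**: per sample, burden ~ round(10^N(log10 median, σ)) with
  default median 200 and σ_log10 0.4 (right-skewed, spanning the observed
  order-of-magnitude heterogeneity); the catalogue is one multinomial draw
  from the subtype's signature mixture; every counted mutation is placed
  uniformly at a position whose reference context matches its channel, with
  the strand resolved so the written ref allele matches the reference.
  Records therefore sense-check cleanly and rebuild the drawn catalogues
  exactly, and the returned truth table (shares, burdens, carrier flags)
  supports parameter-recovery assertions at any grouping.
* **Driver injection**: one annotated SNV per carrier at a single shared
  locus matching a chosen channel; `top_by_share` carriers create a true
  signature association, `random` carriers a null.
* **Strand fixtures**: C>T mutations inside genes with a configurable
  untranscribed fraction (2/3 in UV mode, 1/2 in the null mode) plus
  adjacent CC>TT doublets at genic CC sites.

What the generator does **not** emulate: human genome composition and
covariates (GC/replication timing), selection, subclonality, sequencing
error, study-to-study calling heterogeneity. Passing tests therefore
demonstrate correctness of the computation under the stated statistical
model, not robustness to real-data artefacts.

## Verification experiments and problem sizes

`lymphosig.experiments` (used by the test suite and `scripts/acceptance.py`)
runs: NNLS versus an exhaustive share-simplex grid search (step 0.005 with
the closed-form optimal scale per direction; 50 random 3-signature
instances at n = 2000, agreement required within 1% of total);
sparsification admissibility on 200 instances; 60/40 cohort share recovery
on a 50-sample subtype at 200 SNVs each; the three gate fixtures;
association power and calibration over 100 replicates of a 10-carrier /
40-wild-type cohort with a ~35-point contribution shift; exact-test
enumeration values; strand diagnostics at 400 C>T per sample; and the
generator round trip. These sizes keep each experiment in the seconds-to-
a-minute range while leaving the multinomial noise clearly smaller than the
tolerances being asserted.

## Numerical and design notes

* Sparsification's 0.05 budget deliberately trades sensitivity for
  specificity: a signature holding ~15% of a sample's mutations whose
  removal costs under 0.05 cosine (flat profiles especially) can be pruned.
  Accordingly, share-recovery accuracy is a property of the NNLS fit
  (observed mean absolute share error ≈ 0.013 at n = 2000), while the
  sparsifier's property is admissibility plus not retaining inactive
  signatures.
* The exact and normal-approximation Wilcoxon paths differ by at most
  ≈ 0.0155 over all tie-free 6+6 splits (worst near p = 0.5); the
  asymptotic path is only used beyond pooled size 12 or under ties.
* The null-calibration check accepts an observed flag rate up to 0.10 over
  100 replicates: the nominal rate is ≤ 0.05 and 0.10 is the ~99% binomial
  upper band around it.
* Degenerate inputs: zero catalogues are hard errors for fitting and
  cosine; empty record lists give empty tables with warnings; contig-edge
  SNVs are excluded from catalogues with a count; all-carrier variants
  (empty wild-type group) are skipped with a reason.

## Limitations

Only refitting to a fixed signature set is supported — no de novo
extraction, no doublet/indel signature decomposition, no bootstrap
intervals on exposures. Liftover and multi-assembly harmonisation are out
of scope: inputs are assumed on one assembly, and `sense_check` is the
guard that catches violations. The dominance rule for causal peaks is one
reasonable formalisation among several; its threshold is exposed as
configuration.
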