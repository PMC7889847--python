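"""Synthetic genomes, signatures and cohorts for end-to-end verification.

Every pipeline stage is testable without downloads: a random reference with
tiled, stranded genes; a hand-built signature set with the qualitative
features the analysis leans on (aging-like NCG C>T peaks, a UV-like
signature peaking at C>T in TCC/CCC dipyrimidine contexts, a signature-17-
like NTT T>G pattern, an APOBEC-like TCN pattern and one deliberately flat
"featureless" signature); cohorts whose per-sample catalogues are drawn
multinomially from known signature mixtures with log-normal burden
heterogeneity; injected recurrent driver variants whose carriers are
enriched for one signature; and a UV strand-bias mode that places C>T
mutations in genes with a controlled transcribed:untranscribed ratio plus
adjacent CC>TT doublets.

Generated records always pass ``sense_check`` against the generating
genome, and the returned truth table holds the exact generating shares and
burdens, so parameter-recovery tests can compare against ground truth at
any grouping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import (
    BASES,
    CHANNEL_LABELS,
    CHANNELS,
    COMPLEMENT,
    Channel96,
    PYR_TRINUCLEOTIDES,
    PYRIMIDINES,
)
from .io_formats import (
    GeneAnnotation,
    GeneInterval,
    MutationRecord,
    SignatureMatrix,
    TrinucleotideFrequencyTable,
)

logger = logging.getLogger(__name__)

_LABEL_TO_INDEX = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------


def _profile(
    background: float,
    peaks: dict[str, float] | None = None,
    class_spread: dict[str, float] | None = None,
) -> np.ndarray:
    p = np.full(96, background / 96.0)
    for label, w in (peaks or {}).items():
        p[_LABEL_TO_INDEX[label]] += w
    for cls, w in (class_spread or {}).items():
        idx = [i for i, ch in enumerate(CHANNELS) if ch.substitution == cls]
        p[idx] += w / len(idx)
    return p / p.sum()


def demo_signatures() -> SignatureMatrix:
    """A synthetic five-signature reference set (not the COSMIC matrices).

    The ids echo the COSMIC v2 processes they caricature:

    * Signature 1 — aging: C>T peaks at NpCpG (deamination of 5mC).
    * Signature 2 — APOBEC-like: C>T / C>G at TpCpN.
    * Signature 5 — flat and featureless with a mild T>C tilt.
    * Signature 7 — UV-like: C>T at dipyrimidines, T[C>T]C dominant.
    * Signature 17 — T>G at NpTpT, C[T>G]T dominant.
    """
    profiles = {
        "Signature 1": _profile(
            0.40,
            {"A[C>T]G": 0.17, "C[C>T]G": 0.13, "G[C>T]G": 0.12, "T[C>T]G": 0.18},
        ),
        "Signature 2": _profile(
            0.40,
            {"T[C>T]A": 0.17, "T[C>T]T": 0.18, "T[C>G]A": 0.12, "T[C>G]T": 0.13},
        ),
        "Signature 5": _profile(0.60, None, {"T>C": 0.25, "C>T": 0.15}),
        "Signature 7": _profile(
            0.30,
            {
                "T[C>T]C": 0.22, "C[C>T]C": 0.13, "T[C>T]T": 0.10, "C[C>T]T": 0.08,
                "T[C>T]A": 0.05, "A[C>T]C": 0.05, "G[C>T]C": 0.04, "C[C>T]A": 0.03,
            },
        ),
        "Signature 17": _profile(
            0.30,
            {
                "C[T>G]T": 0.24, "A[T>G]T": 0.12, "G[T>G]T": 0.08, "T[T>G]T": 0.08,
                "C[T>C]T": 0.10, "A[T>C]T": 0.08,
            },
        ),
    }
    return SignatureMatrix(list(profiles), np.vstack(list(profiles.values())))


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGenome:
    """Random reference with stranded gene tiling and a trinucleotide index.

    ``triplet_index`` maps each of the 32 pyrimidine-centred trinucleotides
    to the interior positions whose reference triplet matches it on either
    strand, as (chrom, 1-based pos, strand carrying the pyrimidine).
    """

    contigs: dict[str, str]
    genes: GeneAnnotation
    triplet_index: dict[str, list[tuple[str, int, str]]]

    def __getitem__(self, chrom: str) -> str:
        return self.contigs[chrom]

    def keys(self):
        return self.contigs.keys()

    def write_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _build_triplet_index(contigs: dict[str, str]) -> dict[str, list]:
    index: dict[str, list] = {tri: [] for tri in PYR_TRINUCLEOTIDES}
    for chrom, seq in contigs.items():
        for p in range(2, len(seq)):  # 1-based positions 2 .. len-1
            tri = seq[p - 2 : p + 1]
            centre = tri[1]
            if centre in PYRIMIDINES:
                index[tri].append((chrom, p, "+"))
            else:
                rc = COMPLEMENT[tri[2]] + COMPLEMENT[tri[1]] + COMPLEMENT[tri[0]]
                index[rc].append((chrom, p, "-"))
    return index


def generate_reference(
    length: int = 100_000,
    n_contigs: int = 1,
    seed: int | np.random.Generator = 0,
    gene_length: int = 1_000,
    gene_gap: int = 1_000,
) -> SyntheticGenome:
    """I.i.d.-uniform ACGT contigs with alternating-strand gene tiling.

    Genes of ``gene_length`` bp alternate with gaps of ``gene_gap`` bp
    (covering ~50% of the genome) and alternate between + and − strands.
    The trinucleotide index is rebuilt until all 32 contexts have at least
    one matching position (virtually certain above a few kb; bounded at 100
    redraws).
    """
    if length < 10_000:
        raise ValueError("contigs must be at least 10 kb")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _attempt in range(100):
        contigs = {
            f"chr{i + 1}": "".join(rng.choice(list(BASES), size=length))
            for i in range(n_contigs)
        }
        index = _build_triplet_index(contigs)
        if all(index[tri] for tri in PYR_TRINUCLEOTIDES):
            break
    else:
        raise RuntimeError("could not cover all 32 trinucleotides in 100 redraws")
    intervals: list[GeneInterval] = []
    g = 0
    for chrom in contigs:
        start = 1
        while start + gene_length - 1 <= length:
            strand = "+" if g % 2 == 0 else "-"
            intervals.append(
                GeneInterval(chrom, start, start + gene_length - 1, strand, f"gene{g + 1}")
            )
            g += 1
            start += gene_length + gene_gap
    return SyntheticGenome(contigs, GeneAnnotation(intervals), index)


def trinucleotide_frequencies(
    genome: SyntheticGenome, territory: str = "genome"
) -> TrinucleotideFrequencyTable:
    """Folded trinucleotide frequencies of the whole genome or its genes.

    ``territory="exome"`` counts only positions inside gene intervals,
    giving a genuinely different table to exercise the exome adjustment.
    """
    counts = {tri: 0 for tri in PYR_TRINUCLEOTIDES}
    if territory == "genome":
        for tri, entries in genome.triplet_index.items():
            counts[tri] = len(entries)
    elif territory == "exome":
        genic: dict[str, list[tuple[int, int]]] = {}
        for iv in genome.genes.intervals:
            genic.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for tri, entries in genome.triplet_index.items():
            counts[tri] = sum(
                1
                for chrom, pos, _ in entries
                if any(s <= pos <= e for s, e in genic.get(chrom, ()))
            )
    else:
        raise ValueError("territory must be 'genome' or 'exome'")
    counts = {k: max(v, 1) for k, v in counts.items()}  # guard empty exome cells
    return TrinucleotideFrequencyTable(
        {k: float(v) for k, v in counts.items()}, territory
    )


# ---------------------------------------------------------------------------
# Catalogue and cohort sampling
# ---------------------------------------------------------------------------


def sample_catalogue(
    exposure_shares: dict[str, float],
    n_mutations: int,
    signatures: SignatureMatrix,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Multinomial 96-channel draw from a mixture of signature profiles."""
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    total = sum(exposure_shares.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"exposure shares sum to {total}, not 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.zeros(96)
    for sid, share in exposure_shares.items():
        p += share * signatures.profile(sid)
    return rng.multinomial(n_mutations, p / p.sum())


@dataclass
class SubtypeSpec:
    """One block of samples sharing a subtype label and exposure mixture.

    Two blocks may carry the same ``name`` with different mixtures (to build
    within-subtype heterogeneity); give them distinct ``sample_prefix``
    values so sample ids stay unique.
    """

    name: str
    n_samples: int
    exposure_shares: dict[str, float]
    burden_median: float = 200.0
    burden_sigma_log10: float = 0.4
    sample_prefix: str | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        total = sum(self.exposure_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"shares for {self.name} sum to {total}, not 1")
        if self.sample_prefix is None:
            self.sample_prefix = self.name


@dataclass
class SyntheticCohortSpec:
    subtypes: list[SubtypeSpec]
    seed: int = 0
    study_id: str = "synthetic"


@dataclass
class SyntheticCohort:
    records: list[MutationRecord]
    truth: pd.DataFrame  # sample_id, subtype, study, burden, share_<sig>...
    catalogues: dict[str, np.ndarray]  # the drawn per-sample 96-vectors


def _materialize(
    channel: Channel96,
    entry: tuple[str, int, str],
    sample_id: str,
    study_id: str,
    subtype: str,
    **kwargs,
) -> MutationRecord:
    chrom, pos, pyr_strand = entry
    if pyr_strand == "+":
        ref, alt = channel.ref, channel.alt
    else:
        ref, alt = COMPLEMENT[channel.ref], COMPLEMENT[channel.alt]
    return MutationRecord(
        sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
        study_id=study_id, subtype=subtype, **kwargs,
    )


def synthesize_cohort(
    spec: SyntheticCohortSpec,
    genome: SyntheticGenome,
    signatures: SignatureMatrix,
) -> SyntheticCohort:
    """Draw a cohort of per-sample catalogues and place them on the genome.

    Per sample the burden is log-normal (``10**N(log10 median, sigma)``,
    floored at 1), the catalogue is a multinomial draw from the subtype's
    signature mixture, and each counted mutation is materialised at a
    position drawn uniformly from the genome's matching-trinucleotide index
    (strand resolved so the written ref allele matches the reference).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[MutationRecord] = []
    catalogues: dict[str, np.ndarray] = {}
    truth_rows = []
    sig_ids = signatures.signature_ids
    for sub in spec.subtypes:
        for i in range(sub.n_samples):
            sample_id = f"{sub.sample_prefix}_{i + 1:03d}"
            burden = max(
                1,
                int(round(10 ** rng.normal(np.log10(sub.burden_median),
                                           sub.burden_sigma_log10))),
            )
            vec = sample_catalogue(sub.exposure_shares, burden, signatures, rng)
            catalogues[sample_id] = vec
            for ci in np.nonzero(vec)[0]:
                channel = CHANNELS[ci]
                entries = genome.triplet_index[channel.context]
                if not entries:
                    raise RuntimeError(
                        f"generator contract violated: no position for {channel.context}"
                    )
                picks = rng.integers(0, len(entries), size=int(vec[ci]))
                for j in picks:
                    records.append(
                        _materialize(channel, entries[j], sample_id,
                                     spec.study_id, sub.name)
                    )
            truth_rows.append(
                {
                    "sample_id": sample_id, "subtype": sub.name,
                    "study": spec.study_id, "burden": burden,
                    **{f"share_{s}": sub.exposure_shares.get(s, 0.0) for s in sig_ids},
                }
            )
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    return SyntheticCohort(records, truth, catalogues)


def inject_recurrent_variant(
    cohort: SyntheticCohort,
    genome: SyntheticGenome,
    gene: str,
    protein_change: str,
    channel: Channel96,
    k: int,
    mode: str = "top_by_share",
    signature_id: str | None = None,
    seed: int = 0,
) -> list[str]:
    """Add one annotated driver SNV per carrier at a fixed genome position.

    ``top_by_share`` selects the k samples with the highest generating share
    of ``signature_id`` (a true association); ``random`` selects k samples
    uniformly (a null).  All carriers share one position — it is the same
    variant.  An existing record of a carrier at that position is replaced
    with a warning.  Returns the carrier sample ids; the cohort is modified
    in place (records appended, truth gains a carrier column).
    """
    rng = np.random.default_rng(seed)
    samples = list(cohort.truth.index)
    if k > len(samples):
        raise ValueError(f"k={k} exceeds cohort size {len(samples)}")
    if mode == "top_by_share":
        if signature_id is None:
            raise ValueError("top_by_share mode needs signature_id")
        shares = cohort.truth[f"share_{signature_id}"]
        carriers = list(
            shares.sort_values(ascending=False, kind="stable").index[:k]
        )
    elif mode == "random":
        carriers = list(rng.choice(samples, size=k, replace=False))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    entries = genome.triplet_index[channel.context]
    entry = entries[int(rng.integers(0, len(entries)))]
    chrom, pos, _ = entry
    kept = []
    n_replaced = 0
    for r in cohort.records:
        if r.sample_id in carriers and r.chrom == chrom and r.pos == pos:
            n_replaced += 1
            continue
        kept.append(r)
    if n_replaced:
        logger.warning(
            "inject_recurrent_variant: replaced %d existing records at %s:%d",
            n_replaced, chrom, pos,
        )
    cohort.records[:] = kept
    for sid in carriers:
        row = cohort.truth.loc[sid]
        cohort.records.append(
            _materialize(
                channel, entry, sid, str(row["study"]), str(row["subtype"]),
                gene=gene, protein_change=protein_change,
            )
        )
    cohort.truth[f"carrier_{gene}_{protein_change}"] = [
        s in set(carriers) for s in cohort.truth.index
    ]
    return carriers


# ---------------------------------------------------------------------------
# UV strand-bias fixtures
# ---------------------------------------------------------------------------


def _genic_c_positions(genome: SyntheticGenome) -> dict[str, list]:
    """Genic positions with a C on the pyrimidine strand, split by strand tag.

    The tag matches ``annotate_strand``: the pyrimidine on the gene's coding
    strand means the damage sits on the untranscribed strand.
    """
    genes_by_chrom: dict[str, list[GeneInterval]] = {}
    for iv in genome.genes.intervals:
        genes_by_chrom.setdefault(iv.chrom, []).append(iv)
    out = {"untranscribed": [], "transcribed": []}
    for context in PYR_TRINUCLEOTIDES:
        if context[1] != "C":
            continue
        for chrom, pos, pyr_strand in genome.triplet_index[context]:
            hits = [
                iv for iv in genes_by_chrom.get(chrom, ()) if iv.start <= pos <= iv.end
            ]
            if len({iv.strand for iv in hits}) != 1:
                continue
            tag = "untranscribed" if hits[0].strand == pyr_strand else "transcribed"
            out[tag].append((chrom, pos, pyr_strand))
    return out


def generate_strand_cohort(
    genome: SyntheticGenome,
    n_ct: int = 400,
    untranscribed_fraction: float = 2 / 3,
    n_cc_tt_pairs: int = 20,
    sample_id: str = "uv_sample",
    subtype: str = "MF",
    seed: int = 0,
) -> list[MutationRecord]:
    """C>T mutations inside genes with a controlled strand split, plus CC>TT.

    ``untranscribed_fraction`` is the probability that each C>T lands with
    its pyrimidine on the coding strand (the UV expectation is > 0.5 because
    transcription-coupled repair clears the template strand);  0.5 gives the
    null mode.  CC>TT doublets are placed at genic CC dinucleotides on the
    pyrimidine strand.
    """
    if not 0 < untranscribed_fraction < 1:
        raise ValueError("untranscribed_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pools = _genic_c_positions(genome)
    records: list[MutationRecord] = []
    used: set[tuple[str, int]] = set()

    def place(entry):
        chrom, pos, pyr_strand = entry
        if (chrom, pos) in used:
            return False
        used.add((chrom, pos))
        ref, alt = ("C", "T") if pyr_strand == "+" else ("G", "A")
        records.append(
            MutationRecord(sample_id=sample_id, chrom=chrom, pos=pos, ref=ref,
                           alt=alt, study_id="synthetic", subtype=subtype)
        )
        return True

    for _ in range(n_ct):
        tag = "untranscribed" if rng.random() < untranscribed_fraction else "transcribed"
        pool = pools[tag]
        for _try in range(50):
            if place(pool[int(rng.integers(0, len(pool)))]):
                break

    # adjacent CC (pyrimidine strand) inside genes -> CC>TT doublets
    cc_sites = []
    for chrom, pos, pyr_strand in pools["untranscribed"] + pools["transcribed"]:
        seq = genome.contigs[chrom]
        if pyr_strand == "+" and pos < len(seq) - 1 and seq[pos] == "C":
            cc_sites.append((chrom, pos, "+"))
        elif pyr_strand == "-" and pos >= 2 and seq[pos - 2] == "G":
            # + strand shows GG at pos-1..pos; record 5' base position
            cc_sites.append((chrom, pos - 1, "-"))
    placed = 0
    order = rng.permutation(len(cc_sites))
    for idx in order:
        if placed >= n_cc_tt_pairs:
            break
        chrom, pos, strand = cc_sites[idx]
        if (chrom, pos) in used or (chrom, pos + 1) in used:
            continue
        used.update({(chrom, pos), (chrom, pos + 1)})
        ref, alt = ("C", "T") if strand == "+" else ("G", "A")
        for p in (pos, pos + 1):
            records.append(
                MutationRecord(sample_id=sample_id, chrom=chrom, pos=p, ref=ref,
                               alt=alt, study_id="synthetic", subtype=subtype)
            )
        placed += 1
    if placed < n_cc_tt_pairs:
        logger.warning(
            "generate_strand_cohort: placed only %d/%d CC>TT pairs", placed, n_cc_tt_pairs
        )
    return records
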