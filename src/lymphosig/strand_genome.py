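"""Genome-level UV diagnostics: strand bias, rainfall distances, burden.

UV photoproducts form at dipyrimidines and are repaired preferentially on
the template (transcribed) strand by transcription-coupled nucleotide
excision repair, so UV-exposed tumours show an excess of C>T mutations
whose pyrimidine lies on the untranscribed (coding) strand of genes.  This
module tags SNVs by strand relative to gene annotation, tests each
substitution class for bias with an exact binomial test, computes rainfall
(log inter-mutation distance) tracks, and converts coding SNV counts to
mutations per megabase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from intervaltree import IntervalTree

from .channels import PYRIMIDINES, SUBSTITUTIONS, substitution_class
from .io_formats import GeneAnnotation, MutationRecord

logger = logging.getLogger(__name__)

TRANSCRIBED = "transcribed"
UNTRANSCRIBED = "untranscribed"
AMBIGUOUS = "ambiguous"


def annotate_strand(
    records: Sequence[MutationRecord], annotation: GeneAnnotation
) -> list[str]:
    """Tag each SNV transcribed / untranscribed / ambiguous.

    The mutation is taken in its pyrimidine representation.  For an SNV
    inside genes of a single strand: if the pyrimidine of the mutated pair
    lies on the template (transcribed) strand the tag is ``transcribed``,
    otherwise ``untranscribed``.  A reference pyrimidine (C or T) sits on
    the + strand, so for a + strand gene (template = − strand) it is on the
    coding strand: ``untranscribed``.  SNVs outside genes, or covered by
    genes of both strands, are ``ambiguous``.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in annotation.intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, iv.strand)
    labels = []
    for r in records:
        tree = trees.get(r.chrom)
        strands = {hit.data for hit in tree[r.pos]} if tree is not None else set()
        if len(strands) != 1:
            labels.append(AMBIGUOUS)
            continue
        gene_strand = strands.pop()
        pyr_strand = "+" if r.ref in PYRIMIDINES else "-"
        template_strand = "-" if gene_strand == "+" else "+"
        labels.append(TRANSCRIBED if pyr_strand == template_strand else UNTRANSCRIBED)
    return labels


def strand_counts(
    records: Sequence[MutationRecord], labels: Sequence[str]
) -> pd.DataFrame:
    """Per substitution class: transcribed / untranscribed / ambiguous counts."""
    counts = {sub: {TRANSCRIBED: 0, UNTRANSCRIBED: 0, AMBIGUOUS: 0}
              for sub in SUBSTITUTIONS}
    for r, lab in zip(records, labels):
        counts[substitution_class(r.ref, r.alt)][lab] += 1
    return pd.DataFrame(
        [
            {"class": sub, "n_transcribed": c[TRANSCRIBED],
             "n_untranscribed": c[UNTRANSCRIBED], "n_ambiguous": c[AMBIGUOUS]}
            for sub, c in counts.items()
        ]
    ).set_index("class")


@dataclass
class StrandBiasResult:
    substitution_class: str
    n_transcribed: int
    n_untranscribed: int
    two_sided_p: float
    direction: str  # transcribed | untranscribed | none


def strand_bias_test(
    n_transcribed: int,
    n_untranscribed: int,
    substitution: str = "C>T",
    alpha: float = 0.05,
) -> StrandBiasResult:
    """Two-sided exact binomial test of strand counts against p0 = 0.5.

    Symmetric in its two counts; direction is the majority strand when the
    p-value falls below ``alpha``, otherwise ``none``.
    """
    n = n_transcribed + n_untranscribed
    if n < 1:
        raise ValueError("no strand-resolvable SNVs for this class")
    p = scipy.stats.binomtest(n_transcribed, n, 0.5, alternative="two-sided").pvalue
    if p < alpha and n_transcribed != n_untranscribed:
        direction = TRANSCRIBED if n_transcribed > n_untranscribed else UNTRANSCRIBED
    else:
        direction = "none"
    return StrandBiasResult(substitution, n_transcribed, n_untranscribed, float(p), direction)


def strand_bias_table(counts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Run :func:`strand_bias_test` for every class with resolvable SNVs."""
    rows = []
    for sub, row in counts.iterrows():
        n_t, n_u = int(row["n_transcribed"]), int(row["n_untranscribed"])
        if n_t + n_u == 0:
            logger.info("strand_bias_table: %s has no resolvable SNVs; skipped", sub)
            continue
        res = strand_bias_test(n_t, n_u, str(sub), alpha)
        rows.append(
            {"class": res.substitution_class, "n_transcribed": res.n_transcribed,
             "n_untranscribed": res.n_untranscribed, "p_value": res.two_sided_p,
             "direction": res.direction}
        )
    return pd.DataFrame(
        rows, columns=["class", "n_transcribed", "n_untranscribed", "p_value", "direction"]
    )


def rainfall_distances(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """Log10 distance from each SNV to the previous one on its chromosome.

    One sample's records are sorted per chromosome; the first SNV of each
    chromosome has no distance (NaN).  Duplicate (sample, chrom, pos)
    entries are dropped with a warning.  Adjacent positions give distance
    log10(1) = 0 — the UV doublet signature shows up as a dense band at 0.
    The output carries the pyrimidine substitution class per point, ready
    for plotting.
    """
    seen = set()
    dedup = []
    n_dup = 0
    for r in records:
        key = (r.sample_id, r.chrom, r.pos)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        dedup.append(r)
    if n_dup:
        logger.warning("rainfall_distances: dropped %d duplicate positions", n_dup)
    rows = []
    by_chrom: dict[str, list[MutationRecord]] = {}
    for r in dedup:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: r.pos)
        prev = None
        for r in recs:
            dist = np.log10(r.pos - prev) if prev is not None else np.nan
            rows.append(
                {"chrom": chrom, "pos": r.pos,
                 "class": substitution_class(r.ref, r.alt), "log10_dist": dist}
            )
            prev = r.pos
    return pd.DataFrame(rows, columns=["chrom", "pos", "class", "log10_dist"])


@dataclass
class BurdenEstimate:
    sample_id: str
    n_coding_snvs: int
    territory_mb: float
    per_mb: float


def burden_per_mb(
    per_sample: pd.DataFrame, territory_mb: float
) -> list[BurdenEstimate]:
    """Somatic coding SNVs per megabase of captured territory, per sample.

    ``per_sample`` is the table from
    :func:`lymphosig.catalogue.per_sample_counts`; ``territory_mb`` the
    coding territory in Mb (user-supplied, e.g. ~30 for a standard exome).
    """
    if territory_mb <= 0:
        raise ValueError("territory_mb must be positive")
    return [
        BurdenEstimate(
            sample_id=row["sample_id"],
            n_coding_snvs=int(row["n_snvs"]),
            territory_mb=territory_mb,
            per_mb=row["n_snvs"] / territory_mb,
        )
        for _, row in per_sample.iterrows()
    ]


def burden_table(estimates: list[BurdenEstimate]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"sample_id": e.sample_id, "n_coding_snvs": e.n_coding_snvs,
             "territory_mb": e.territory_mb, "per_mb": e.per_mb}
            for e in estimates
        ],
        columns=["sample_id", "n_coding_snvs", "territory_mb", "per_mb"],
    )
    if not df.empty:
        df.attrs["range"] = (float(df["per_mb"].min()), float(df["per_mb"].max()))
    return df
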