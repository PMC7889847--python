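"""SBS96 catalogue construction and per-sample mutation summaries.

Validated SNVs are turned into pyrimidine-centred 96-channel count matrices
(per sample, subtype or study), per-sample burden tables, recurrent-driver
tables keyed by (gene, protein change), and dinucleotide-variant calls
derived from adjacent same-sample SNVs (the CC>TT doublets characteristic of
UV damage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .channels import CHANNEL_LABELS, pyrimidine_channel, substitution_class
from .io_formats import MutationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "context_from_reference",
    "sense_check",
    "build_catalogue",
    "per_sample_counts",
    "find_recurrent_variants",
    "detect_dinucleotides",
    "BoundaryError",
    "DinucleotideVariant",
]


class BoundaryError(ValueError):
    """Position too close to a contig edge to have both flanking bases."""


def _contig(reference, chrom: str) -> str:
    """Fetch a contig as an uppercase string from a dict or pyfaidx.Fasta."""
    try:
        seq = reference[chrom]
    except KeyError as exc:
        raise KeyError(f"unknown contig {chrom!r}") from exc
    return str(seq[:]) if not isinstance(seq, str) else seq


class ReferenceView:
    """Caches contigs of a dict-like or FASTA reference as uppercase strings."""

    def __init__(self, reference):
        self._reference = reference
        self._cache: dict[str, str] = {}

    def contig(self, chrom: str) -> str:
        if chrom not in self._cache:
            self._cache[chrom] = _contig(self._reference, chrom).upper()
        return self._cache[chrom]


def context_from_reference(reference, chrom: str, pos: int) -> tuple[str, str, str]:
    """Uppercase bases at pos-1, pos, pos+1 (1-based) on the given contig.

    Raises :class:`BoundaryError` when the position lacks a flank and
    ``KeyError`` for an unknown contig.
    """
    view = reference if isinstance(reference, ReferenceView) else ReferenceView(reference)
    seq = view.contig(chrom)
    if pos < 2 or pos > len(seq) - 1:
        raise BoundaryError(
            f"{chrom}:{pos} is at a contig edge (length {len(seq)}); no trinucleotide context"
        )
    return seq[pos - 2], seq[pos - 1], seq[pos]


@dataclass
class SenseCheckReport:
    mismatches: list[tuple[str, str, int, str, str]] = field(default_factory=list)

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


def sense_check(
    records: Sequence[MutationRecord], reference
) -> tuple[list[MutationRecord], SenseCheckReport]:
    """Keep records whose stated reference base matches the reference sequence.

    Mismatches are excluded and reported as (sample, chrom, pos, stated,
    actual).  Positions outside the contig are treated as mismatches with
    actual base 'N'.
    """
    view = ReferenceView(reference)
    valid: list[MutationRecord] = []
    report = SenseCheckReport()
    for r in records:
        seq = view.contig(r.chrom)
        actual = seq[r.pos - 1] if 1 <= r.pos <= len(seq) else "N"
        if actual == r.ref:
            valid.append(r)
        else:
            report.mismatches.append((r.sample_id, r.chrom, r.pos, r.ref, actual))
    return valid, report


def _row_key(record: MutationRecord, grouping: str) -> str:
    if grouping == "sample":
        return record.sample_id
    if grouping == "subtype":
        return record.subtype
    if grouping == "study":
        return record.study_id
    raise ValueError(f"grouping must be sample/subtype/study, got {grouping!r}")


def build_catalogue(
    records: Sequence[MutationRecord],
    reference,
    grouping: str = "sample",
) -> tuple[pd.DataFrame, int]:
    """Count each SNV into one of the 96 channels of one row.

    Returns a (rows x 96) integer DataFrame whose columns are the canonical
    channel labels (``df.attrs["grouping"]`` records the row meaning) and the
    number of SNVs excluded because they sit at a contig edge.  Row sums
    equal the number of contributing SNVs.
    """
    view = ReferenceView(reference)
    counts: dict[str, np.ndarray] = {}
    n_boundary = 0
    for r in records:
        try:
            f5, ref_at, f3 = context_from_reference(view, r.chrom, r.pos)
        except BoundaryError:
            n_boundary += 1
            continue
        if ref_at != r.ref:
            raise ValueError(
                f"reference mismatch at {r.chrom}:{r.pos} ({r.ref} vs {ref_at}); "
                "run sense_check first"
            )
        ch = pyrimidine_channel(r.ref, r.alt, f5, f3)
        key = _row_key(r, grouping)
        if key not in counts:
            counts[key] = np.zeros(96, dtype=np.int64)
        counts[key][ch.index] += 1
    if not counts:
        logger.warning("build_catalogue: no usable records; returning empty matrix")
    df = pd.DataFrame(
        {k: v for k, v in counts.items()}, index=list(CHANNEL_LABELS)
    ).T.astype(np.int64)
    if df.empty:
        df = pd.DataFrame(columns=list(CHANNEL_LABELS), dtype=np.int64)
    if n_boundary:
        logger.info("build_catalogue: %d SNVs excluded at contig edges", n_boundary)
    df.attrs["grouping"] = grouping
    return df, n_boundary


def per_sample_counts(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """One row per sample: (sample_id, subtype, study, n_snvs).

    ``df.attrs["subtype_summary"]`` carries the per-subtype median and range.
    """
    rows: dict[str, dict] = {}
    for r in records:
        d = rows.setdefault(
            r.sample_id, {"sample_id": r.sample_id, "subtype": r.subtype,
                          "study": r.study_id, "n_snvs": 0}
        )
        d["n_snvs"] += 1
    df = pd.DataFrame(list(rows.values()),
                      columns=["sample_id", "subtype", "study", "n_snvs"])
    if not df.empty:
        summary = (
            df.groupby("subtype")["n_snvs"]
            .agg(n_samples="size", median="median", min="min", max="max")
            .reset_index()
        )
    else:
        summary = pd.DataFrame(columns=["subtype", "n_samples", "median", "min", "max"])
    df.attrs["subtype_summary"] = summary
    return df


def find_recurrent_variants(
    records: Sequence[MutationRecord],
    driver_genes: set[str] | None = None,
    min_carriers: int = 3,
) -> pd.DataFrame:
    """Recurrent variants keyed by (gene, protein_change).

    A carrier is a distinct sample; the same variant recorded twice in one
    sample counts once.  The substitution breakdown records the distinct
    underlying nucleotide changes (pyrimidine classes) behind one amino-acid
    change — e.g. JAK3 M511I arising from both C>A and C>G events.  Records
    without gene annotation, or outside ``driver_genes`` when given, are
    ignored.
    """
    if min_carriers < 2:
        raise ValueError("min_carriers must be >= 2")
    variants: dict[tuple[str, str], dict] = {}
    n_unannotated = 0
    for r in records:
        if not r.gene or not r.protein_change:
            n_unannotated += 1
            continue
        if driver_genes is not None and r.gene not in driver_genes:
            continue
        key = (r.gene, r.protein_change)
        v = variants.setdefault(
            key, {"carriers": {}, "breakdown": {}, "by_subtype": {}}
        )
        if r.sample_id not in v["carriers"]:
            v["carriers"][r.sample_id] = r.subtype
            cls = substitution_class(r.ref, r.alt)
            v["breakdown"][cls] = v["breakdown"].get(cls, 0) + 1
            v["by_subtype"][r.subtype] = v["by_subtype"].get(r.subtype, 0) + 1
    if n_unannotated:
        logger.info(
            "find_recurrent_variants: %d records lacked gene/protein annotation",
            n_unannotated,
        )
    rows = []
    for (gene, pc), v in variants.items():
        if len(v["carriers"]) < min_carriers:
            continue
        rows.append(
            {
                "gene": gene,
                "protein_change": pc,
                "n_carriers": len(v["carriers"]),
                "carriers": sorted(v["carriers"]),
                "substitution_breakdown": dict(sorted(v["breakdown"].items())),
                "carriers_by_subtype": dict(sorted(v["by_subtype"].items())),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene", "protein_change", "n_carriers", "carriers",
                 "substitution_breakdown", "carriers_by_subtype"],
    )
    return df.sort_values(
        ["n_carriers", "gene", "protein_change"], ascending=[False, True, True]
    ).reset_index(drop=True)


@dataclass(frozen=True, slots=True)
class DinucleotideVariant:
    """Two adjacent same-sample SNVs treated as one double substitution."""

    sample_id: str
    chrom: str
    pos: int  # position of the 5' base
    ref_dinucleotide: str
    alt_dinucleotide: str
    is_cc_to_tt: bool


def detect_dinucleotides(
    records: Sequence[MutationRecord], reference=None
) -> tuple[list[DinucleotideVariant], list[MutationRecord]]:
    """Pair adjacent same-sample SNVs into dinucleotide variants.

    ``is_cc_to_tt`` is true when the change is CC>TT on either strand
    (GG>AA on the opposite one).  Runs of >= 3 consecutive mutated positions
    are longer MNVs, reported via a warning and excluded from DNV calls.
    Returns the DNV list and the constituent SNV records (so catalogues can
    optionally exclude them; they are kept by default).
    """
    by_sample_chrom: dict[tuple[str, str], list[MutationRecord]] = {}
    for r in records:
        by_sample_chrom.setdefault((r.sample_id, r.chrom), []).append(r)
    dnvs: list[DinucleotideVariant] = []
    constituents: list[MutationRecord] = []
    n_mnv_runs = 0
    for (sample, chrom), recs in by_sample_chrom.items():
        recs = sorted(recs, key=lambda r: r.pos)
        # split into runs of consecutive positions
        runs: list[list[MutationRecord]] = []
        for r in recs:
            if runs and r.pos == runs[-1][-1].pos + 1:
                runs[-1].append(r)
            else:
                runs.append([r])
        for run in runs:
            if len(run) == 2:
                a, b = run
                ref_d, alt_d = a.ref + b.ref, a.alt + b.alt
                cc_tt = (ref_d, alt_d) in (("CC", "TT"), ("GG", "AA"))
                dnvs.append(
                    DinucleotideVariant(sample, chrom, a.pos, ref_d, alt_d, cc_tt)
                )
                constituents.extend(run)
            elif len(run) >= 3:
                n_mnv_runs += 1
    if n_mnv_runs:
        logger.warning(
            "detect_dinucleotides: %d runs of >=3 adjacent SNVs excluded as MNVs",
            n_mnv_runs,
        )
    return dnvs, constituents


def load_driver_genes(path) -> set[str]:
    """Read a plain-text driver gene list (one symbol per line, # comments)."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes
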