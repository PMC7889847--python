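"""Readers and writers for the interchange formats the pipeline touches.

Everything entering the pipeline is validated into typed containers here:
mutation tables (TSV or single-sample VCF) into :class:`MutationRecord`
lists, COSMIC-v2-layout signature files into :class:`SignatureMatrix`,
trinucleotide frequency tables, and BED6/GFF3 gene annotation.  Internal
genomic coordinates are 1-based inclusive (VCF convention); BED is converted
at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .channels import (
    BASES,
    CHANNEL_LABELS,
    PYR_TRINUCLEOTIDES,
    fold_trinucleotide,
)

logger = logging.getLogger(__name__)

#: Subtypes appearing in the study cohort; user-defined labels are accepted too.
KNOWN_SUBTYPES = ("AITL", "ATLL", "EATL", "HSTL", "MF", "NKTCL", "PTCL", "SS")


@dataclass(frozen=True, slots=True)
class MutationRecord:
    """One somatic SNV with sample/study/subtype provenance."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    study_id: str = ""
    subtype: str = ""
    gene: str | None = None
    protein_change: str | None = None
    treatment_naive: bool | None = None

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-ACGT allele in {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.chrom:
            raise ValueError("empty chromosome name")


@dataclass
class ReadReport:
    """Record-level problems collected while reading a mutation table."""

    errors: list[str] = field(default_factory=list)
    n_skipped_non_snv: int = 0

    def __bool__(self) -> bool:
        return bool(self.errors) or self.n_skipped_non_snv > 0


class SignatureMatrix:
    """Reference signatures as per-channel probability distributions.

    Rows are signatures, columns the 96 canonical channels; every row sums
    to 1.
    """

    def __init__(self, signature_ids: Sequence[str], probabilities: np.ndarray):
        probabilities = np.asarray(probabilities, dtype=float)
        if probabilities.shape != (len(signature_ids), 96):
            raise ValueError(
                f"expected ({len(signature_ids)}, 96) matrix, got {probabilities.shape}"
            )
        if (probabilities < 0).any():
            raise ValueError("negative signature probability")
        sums = probabilities.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValueError(
                f"signature {signature_ids[bad[0]]!r} sums to {sums[bad[0]]:.8f}, not 1"
            )
        self.signature_ids = list(signature_ids)
        self.probabilities = probabilities
        self._row = {s: i for i, s in enumerate(self.signature_ids)}

    def __len__(self) -> int:
        return len(self.signature_ids)

    def profile(self, signature_id: str) -> np.ndarray:
        return self.probabilities[self._row[signature_id]]

    def restrict(self, ids: Iterable[str]) -> "SignatureMatrix":
        ids = list(ids)
        missing = [s for s in ids if s not in self._row]
        if missing:
            raise KeyError(f"unknown signature ids: {missing}")
        rows = [self._row[s] for s in ids]
        return SignatureMatrix(ids, self.probabilities[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probabilities, index=self.signature_ids, columns=list(CHANNEL_LABELS)
        )


@dataclass
class TrinucleotideFrequencyTable:
    """Frequencies of the 32 pyrimidine-centred trinucleotides in a territory."""

    frequencies: dict[str, float]
    territory_label: str = "genome"

    def __post_init__(self) -> None:
        keys = set(self.frequencies)
        expected = set(PYR_TRINUCLEOTIDES)
        if keys != expected:
            missing = sorted(expected - keys)
            extra = sorted(keys - expected)
            raise ValueError(
                f"frequency table must have exactly the 32 pyrimidine-centred "
                f"trinucleotides (missing {missing}, unexpected {extra})"
            )
        if any(v <= 0 for v in self.frequencies.values()):
            raise ValueError("all trinucleotide frequencies must be positive")
        total = sum(self.frequencies.values())
        self.frequencies = {k: v / total for k, v in self.frequencies.items()}

    def __getitem__(self, tri: str) -> float:
        return self.frequencies[tri]


@dataclass(frozen=True, slots=True)
class GeneInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end for {self.gene_id} ({self.start}>{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class GeneAnnotation:
    """Gene intervals with strand, 1-based inclusive coordinates."""

    intervals: list[GeneInterval]

    def by_chrom(self) -> dict[str, list[GeneInterval]]:
        out: dict[str, list[GeneInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


# ---------------------------------------------------------------------------
# Mutation tables
# ---------------------------------------------------------------------------

DEFAULT_COLUMN_MAP = {
    "sample": "sample",
    "study": "study",
    "subtype": "subtype",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "gene": "gene",
    "protein_change": "protein_change",
    "treatment_naive": "treatment_naive",
}


def load_column_map(path: str | Path) -> dict[str, str]:
    """Load a field -> column-name mapping from YAML (for heterogeneous TSVs)."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_COLUMN_MAP)
    if unknown:
        raise ValueError(f"unknown fields in column map: {sorted(unknown)}")
    return {**DEFAULT_COLUMN_MAP, **user}


def _parse_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().lower()
    if s in ("", "na", "nan", "none"):
        return None
    return s in ("1", "true", "yes", "y")


def read_mutation_table(
    path: str | Path,
    dialect: str = "tsv",
    defaults: Mapping[str, str] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[MutationRecord], ReadReport]:
    """Read SNVs from a TSV or a single-sample VCF.

    Non-SNV rows (indels, MNVs) are skipped and counted; malformed rows are
    collected into the report without aborting the read.  ``defaults``
    supplies sample/study/subtype for files that lack those columns (always
    needed for VCF).
    """
    if dialect == "tsv":
        return _read_mutation_tsv(path, defaults or {}, column_map)
    if dialect == "vcf":
        return _read_mutation_vcf(path, defaults or {})
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'vcf')")


def _read_mutation_tsv(
    path, defaults: Mapping[str, str], column_map: Mapping[str, str] | None
) -> tuple[list[MutationRecord], ReadReport]:
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    report = ReadReport()
    records: list[MutationRecord] = []
    if df.empty:
        logger.warning("mutation table %s is empty", path)
        return records, report
    required = ["sample", "chrom", "pos", "ref", "alt"]
    missing = [f for f in required if cmap[f] not in df.columns and f not in defaults]
    if missing:
        raise ValueError(f"mutation table {path} lacks required columns: {missing}")

    def get(row, f, default=""):
        col = cmap[f]
        if col in df.columns:
            v = row[col].strip()
            if v:
                return v
        return defaults.get(f, default)

    for i, row in df.iterrows():
        ref, alt = get(row, "ref"), get(row, "alt")
        if len(ref) != 1 or len(alt) != 1:
            report.n_skipped_non_snv += 1
            continue
        try:
            records.append(
                MutationRecord(
                    sample_id=get(row, "sample"),
                    study_id=get(row, "study"),
                    subtype=get(row, "subtype"),
                    chrom=get(row, "chrom"),
                    pos=int(get(row, "pos")),
                    ref=ref.upper(),
                    alt=alt.upper(),
                    gene=get(row, "gene") or None,
                    protein_change=get(row, "protein_change") or None,
                    treatment_naive=_parse_bool(get(row, "treatment_naive", None)),
                )
            )
        except (ValueError, TypeError) as exc:
            report.errors.append(f"row {i + 2}: {exc}")
    if report.n_skipped_non_snv:
        logger.info(
            "skipped %d non-SNV rows in %s", report.n_skipped_non_snv, path
        )
    return records, report


def _read_mutation_vcf(path, defaults) -> tuple[list[MutationRecord], ReadReport]:
    from cyvcf2 import VCF

    report = ReadReport()
    records: list[MutationRecord] = []
    sample = defaults.get("sample")
    vcf = VCF(str(path))
    if sample is None:
        if len(vcf.samples) == 1:
            sample = vcf.samples[0]
        else:
            raise ValueError(
                f"VCF {path} is not single-sample; pass defaults={{'sample': ...}}"
            )
    for v in vcf:
        if v.FILTER is not None:  # None means PASS / '.'
            continue
        for alt in v.ALT:  # multi-allelic rows split into one record per ALT
            if len(v.REF) != 1 or len(alt) != 1 or alt not in BASES:
                report.n_skipped_non_snv += 1
                continue
            try:
                records.append(
                    MutationRecord(
                        sample_id=sample,
                        study_id=defaults.get("study", ""),
                        subtype=defaults.get("subtype", ""),
                        chrom=v.CHROM,
                        pos=v.POS,
                        ref=v.REF.upper(),
                        alt=alt.upper(),
                    )
                )
            except ValueError as exc:
                report.errors.append(f"{v.CHROM}:{v.POS}: {exc}")
    vcf.close()
    return records, report


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records to the TSV dialect read back by :func:`read_mutation_table`."""
    rows = [
        {
            "sample": r.sample_id,
            "study": r.study_id,
            "subtype": r.subtype,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "gene": r.gene or "",
            "protein_change": r.protein_change or "",
            "treatment_naive": "" if r.treatment_naive is None else str(r.treatment_naive),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(DEFAULT_COLUMN_MAP)).rename(
        columns=DEFAULT_COLUMN_MAP
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Signature matrices (COSMIC v2 layout)
# ---------------------------------------------------------------------------


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Read a COSMIC v2 layout signature TSV.

    Expected columns: ``Substitution Type`` (e.g. ``C>A``), ``Trinucleotide``
    (e.g. ``ACA``), then one column per signature.  Rows may be in any order;
    they are reindexed into the canonical channel order.  A ``Somatic
    Mutation Type`` column (``A[C>A]A``), if present, is ignored in favour of
    the two key columns.
    """
    df = pd.read_csv(path, sep="\t")
    key_cols = ["Substitution Type", "Trinucleotide"]
    for c in key_cols:
        if c not in df.columns:
            raise ValueError(f"signature file {path} lacks column {c!r}")
    labels = [
        f"{tri[0]}[{sub}]{tri[2]}"
        for sub, tri in zip(df["Substitution Type"], df["Trinucleotide"])
    ]
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate channel {lab!r} in {path}")
        seen.add(lab)
    missing = [lab for lab in CHANNEL_LABELS if lab not in seen]
    if missing:
        raise ValueError(
            f"incomplete channel set ({96 - len(missing)}/96); first missing: "
            f"{missing[0]!r}"
        )
    df = df.set_index(pd.Index(labels))
    sig_cols = [
        c for c in df.columns if c not in key_cols and c != "Somatic Mutation Type"
    ]
    mat = df.loc[list(CHANNEL_LABELS), sig_cols].to_numpy(dtype=float).T
    sums = mat.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > 1e-3)[0]
    if bad.size:
        raise ValueError(
            f"signature column {sig_cols[bad[0]]!r} sums to {sums[bad[0]]:.4f}, not 1"
        )
    # renormalise away printed-precision round-off before the strict 1e-6 check
    mat = mat / sums[:, None]
    return SignatureMatrix(sig_cols, mat)


def write_signature_matrix(signatures: SignatureMatrix, path: str | Path) -> None:
    """Write a signature matrix in the COSMIC v2 TSV layout."""
    from .channels import CHANNELS

    df = pd.DataFrame(
        {
            "Substitution Type": [ch.substitution for ch in CHANNELS],
            "Trinucleotide": [ch.context for ch in CHANNELS],
            "Somatic Mutation Type": list(CHANNEL_LABELS),
        }
    )
    for sid in signatures.signature_ids:
        df[sid] = signatures.profile(sid)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trinucleotide frequencies
# ---------------------------------------------------------------------------


def read_trinucleotide_frequencies(
    path: str | Path, territory_label: str = "genome"
) -> TrinucleotideFrequencyTable:
    """Read a trinucleotide -> count/frequency TSV.

    Purine-centred trinucleotides are folded onto their pyrimidine-centred
    reverse complements (values summed); the result is normalised to sum to 1
    over the 32 keys.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["trinucleotide", "value"])
    if df["trinucleotide"].iloc[0].lower() in ("trinucleotide", "context"):
        df = df.iloc[1:]
    folded: dict[str, float] = {}
    for tri, value in zip(df["trinucleotide"], df["value"]):
        v = float(value)
        if v <= 0:
            raise ValueError(f"non-positive value for {tri!r}: {v}")
        key = fold_trinucleotide(str(tri).upper())
        folded[key] = folded.get(key, 0.0) + v
    return TrinucleotideFrequencyTable(folded, territory_label)


def write_trinucleotide_frequencies(
    table: TrinucleotideFrequencyTable, path: str | Path
) -> None:
    pd.DataFrame(
        {"trinucleotide": list(table.frequencies), "value": list(table.frequencies.values())}
    ).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


def read_gene_annotation(path: str | Path, dialect: str = "bed") -> GeneAnnotation:
    """Read gene intervals from BED6 (0-based half-open) or GFF3 (1-based).

    Both are converted to the internal 1-based inclusive convention; a
    missing strand is a hard error.
    """
    intervals: list[GeneInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if dialect == "bed":
                if len(f) < 6:
                    raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
                chrom, start0, end0, name, _score, strand = f[:6]
                start, end = int(start0) + 1, int(end0)
            elif dialect == "gff":
                if len(f) < 9:
                    raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns")
                chrom, _src, _type, s, e, _score, strand, _phase, attrs = f[:9]
                start, end = int(s), int(e)
                name = _gff_id(attrs) or f"{chrom}:{start}-{end}"
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            if strand not in "+-":
                raise ValueError(
                    f"{path}:{lineno}: missing/invalid strand {strand!r}: {line!r}"
                )
            intervals.append(GeneInterval(chrom, start, end, strand, name))
    return GeneAnnotation(intervals)


def _gff_id(attrs: str) -> str | None:
    for part in attrs.split(";"):
        k, _, v = part.strip().partition("=")
        if k in ("ID", "gene_id", "Name"):
            return v
    return None


def write_gene_annotation_bed(annotation: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in annotation.intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.gene_id}\t0\t{iv.strand}\n"
            )
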