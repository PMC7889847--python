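"""Canonical SBS96 channel definitions.

Somatic single-base substitutions are reported on the pyrimidine strand:
the six substitution classes are C>A, C>G, C>T, T>A, T>C, T>G, and each is
split by its 5' and 3' flanking base, giving 96 trinucleotide channels.
The canonical ordering is substitution-major (classes in the order above),
then 5' flank A,C,G,T, then 3' flank A,C,G,T, so ``A[C>A]A`` is channel 0
and ``T[T>G]T`` is channel 95.
"""

from __future__ import annotations

from dataclasses import dataclass

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_SUB_INDEX = {s: i for i, s in enumerate(SUBSTITUTIONS)}
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string (uppercase in, uppercase out)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class Channel96:
    """One pyrimidine-centred trinucleotide mutation channel."""

    substitution: str
    five_prime: str
    three_prime: str

    @property
    def ref(self) -> str:
        return self.substitution[0]

    @property
    def alt(self) -> str:
        return self.substitution[2]

    @property
    def context(self) -> str:
        """Reference trinucleotide on the pyrimidine strand, e.g. ``TCC``."""
        return self.five_prime + self.ref + self.three_prime

    @property
    def index(self) -> int:
        return (
            _SUB_INDEX[self.substitution] * 16
            + _BASE_INDEX[self.five_prime] * 4
            + _BASE_INDEX[self.three_prime]
        )

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.substitution}]{self.three_prime}"


CHANNELS: tuple[Channel96, ...] = tuple(
    Channel96(sub, f5, f3) for sub in SUBSTITUTIONS for f5 in BASES for f3 in BASES
)
CHANNEL_LABELS: tuple[str, ...] = tuple(ch.label for ch in CHANNELS)
_LABEL_INDEX = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}

#: The 32 pyrimidine-centred reference trinucleotides (NCN then NTN).
PYR_TRINUCLEOTIDES: tuple[str, ...] = tuple(
    f5 + c + f3 for c in "CT" for f5 in BASES for f3 in BASES
)


def channel_from_label(label: str) -> Channel96:
    """Parse a label such as ``"A[C>A]A"`` into its channel."""
    if label not in _LABEL_INDEX:
        raise ValueError(f"not a canonical SBS96 channel label: {label!r}")
    return CHANNELS[_LABEL_INDEX[label]]


def _check_base(b: str) -> None:
    if b not in _BASE_INDEX:
        raise ValueError(f"invalid base {b!r}; expected one of A, C, G, T")


def pyrimidine_channel(
    ref: str, alt: str, five_prime: str, three_prime: str
) -> Channel96:
    """Map a substitution with its flanks to the pyrimidine-strand channel.

    Purine-reference mutations are reverse-complemented: flanks are swapped
    and complemented and both alleles complemented, so the returned channel's
    central base is always C or T.  The mapping is strand symmetric —
    applying it to the full reverse complement of the input yields the same
    channel.
    """
    for b in (ref, alt, five_prime, three_prime):
        _check_base(b)
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref})")
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five_prime, three_prime = COMPLEMENT[three_prime], COMPLEMENT[five_prime]
    return Channel96(f"{ref}>{alt}", five_prime, three_prime)


def substitution_class(ref: str, alt: str) -> str:
    """Pyrimidine-strand substitution class (one of the six) for a ref/alt pair."""
    _check_base(ref)
    _check_base(alt)
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref})")
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


def fold_trinucleotide(tri: str) -> str:
    """Fold a trinucleotide onto its pyrimidine-centred representative.

    ``TGT`` (centre G) folds to ``ACA``; pyrimidine-centred inputs are
    returned unchanged.
    """
    if len(tri) != 3:
        raise ValueError(f"expected a trinucleotide, got {tri!r}")
    for b in tri:
        _check_base(b)
    return tri if tri[1] in PYRIMIDINES else revcomp(tri)
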