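"""Shared domain types and small sequence utilities.

The pipeline moves variants between three coordinate conventions: VCF
positions are 1-based, BED intervals are 0-based half-open, and window
offsets are 0-based. The single conversion point is :func:`pos_to_zero_based`;
everything downstream works in the convention of the file format it touches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

DNA_BASES = "ACGT"
DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# integer encoding used by the motif scanner: A=0 C=1 G=2 T=3, N=4
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' so hg19-style and plain names compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def pos_to_zero_based(pos: int) -> int:
    """1-based variant position -> 0-based sequence/interval coordinate."""
    return pos - 1


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, stored uppercase."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"sequence {self.name!r} is empty")
        for i, base in enumerate(self.sequence):
            if base not in DNA_ALPHABET:
                raise FormatError(
                    f"illegal residue {base!r} at position {i + 1} of record {self.name!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Variant:
    """A biallelic SNP, optionally annotated with its index-SNP LD assignment."""

    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str
    index_id: str = ""
    r2_to_index: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        for label, allele in (("ref", self.ref), ("alt", self.alt)):
            if len(allele) != 1 or allele not in DNA_BASES:
                raise ValueError(
                    f"variant {self.id}: {label} allele {allele!r} is not a single base"
                )
        if self.ref == self.alt:
            raise ValueError(f"variant {self.id}: ref == alt ({self.ref})")
        if self.r2_to_index is not None and not 0.0 <= self.r2_to_index <= 1.0:
            raise ValueError(f"variant {self.id}: r2 {self.r2_to_index} outside [0,1]")

    @property
    def pos0(self) -> int:
        return pos_to_zero_based(self.pos)


@dataclass(frozen=True)
class Peak:
    """A ChIP-Seq peak interval, 0-based half-open, tagged with its TF."""

    chrom: str
    start: int
    end: int
    tf_name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: requires 0 <= start < end"
            )

    def contains(self, chrom: str, pos0: int) -> bool:
        return (
            normalize_chrom(chrom) == normalize_chrom(self.chrom)
            and self.start <= pos0 < self.end
        )
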