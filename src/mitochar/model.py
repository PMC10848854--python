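"""Domain types for annotated circular mitochondrial genomes.

Coordinates follow the GenBank / annotation-table convention everywhere a
user sees them: 1-based, inclusive on both ends.  Helpers that touch the
sequence convert to Python slices internally so off-by-one arithmetic is
confined to this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Optional, Sequence

GeneClass = Literal["PCG", "tRNA", "rRNA", "other"]
Strand = Literal["H", "L"]

GENE_CLASSES: tuple[str, ...] = ("PCG", "tRNA", "rRNA", "other")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MitocharError(Exception):
    """Base class for all errors raised by this package."""


class AnnotationError(MitocharError):
    """An annotation violates a structural invariant."""


class ParseError(MitocharError):
    """An input file could not be parsed."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a mitochondrial genome.

    Parameters
    ----------
    name
        Canonical gene label, e.g. ``Cox1``, ``trnM2``, ``rrnL1``.
    gene_class
        ``"PCG"``, ``"tRNA"``, ``"rRNA"`` or ``"other"``.
    start, end
        1-based inclusive coordinates with ``start <= end``.  Features that
        span the origin of the circle are not representable and are rejected
        so they cannot silently corrupt downstream arithmetic.
    strand
        ``"H"`` (heavy / plus) or ``"L"`` (light / minus; extraction
        reverse-complements).
    start_codon, stop_codon
        Present for protein-coding genes only.  ``stop_codon`` may be a
        truncated 1- or 2-base codon (``"T"``, ``"TA"``) completed to UAA by
        post-transcriptional polyadenylation.
    declared_size, declared_gap
        Values copied verbatim from an annotation table, if the feature was
        read from one; used by the validator, never by the arithmetic.
    """

    name: str
    gene_class: str
    start: int
    end: int
    strand: str = "H"
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    declared_size: Optional[int] = None
    declared_gap: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise AnnotationError(
                f"{self.name}: unknown gene class {self.gene_class!r}")
        if self.strand not in ("H", "L"):
            raise AnnotationError(
                f"{self.name}: strand must be 'H' or 'L', got {self.strand!r}")
        if self.start < 1:
            raise AnnotationError(
                f"{self.name}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise AnnotationError(
                f"{self.name}: end {self.end} < start {self.start} "
                "(origin-spanning features are not supported)")
        if (self.gene_class == "PCG") != (self.start_codon is not None):
            raise AnnotationError(
                f"{self.name}: start codon must be present exactly for "
                "protein-coding genes")
        if self.stop_codon is not None and not 1 <= len(self.stop_codon) <= 3:
            raise AnnotationError(
                f"{self.name}: stop codon {self.stop_codon!r} must have "
                "1-3 bases")

    @property
    def length(self) -> int:
        """Feature length in bp (inclusive-coordinate arithmetic)."""
        return self.end - self.start + 1

    def extract(self, sequence: str) -> str:
        """Coding-strand sequence of this feature.

        L-strand features are reverse-complemented so the result always reads
        5'->3' in the gene's own sense.
        """
        if self.end > len(sequence):
            raise AnnotationError(
                f"{self.name}: end {self.end} beyond sequence length "
                f"{len(sequence)}")
        sub = sequence[self.start - 1:self.end]
        return reverse_complement(sub) if self.strand == "L" else sub

    def with_(self, **changes) -> "GeneFeature":
        return replace(self, **changes)


@dataclass(frozen=True)
class MitoAnnotation:
    """A circular (by default) mitogenome annotation.

    ``features`` are kept sorted by start coordinate.  Overlap between
    features is legal at this level — the validator reports it — but no
    feature may extend past ``genome_length``.
    """

    genome_length: int
    features: tuple[GeneFeature, ...]
    circular: bool = True

    def __post_init__(self) -> None:
        feats = tuple(sorted(self.features, key=lambda f: (f.start, f.end)))
        object.__setattr__(self, "features", feats)
        if self.genome_length < 1:
            raise AnnotationError(
                f"genome length must be positive, got {self.genome_length}")
        for f in feats:
            if f.end > self.genome_length:
                raise AnnotationError(
                    f"{f.name}: end {f.end} exceeds genome length "
                    f"{self.genome_length}")

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_class(self, gene_class: str) -> tuple[GeneFeature, ...]:
        return tuple(f for f in self.features if f.gene_class == gene_class)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)
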