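"""Core genomic data model.

All coordinates are 0-based half-open on the forward genome strand,
regardless of the transcript's strand. Transcribed (5'->3') orientation is
derived from the strand at the point of sequence extraction, never stored.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """One protein-coding transcript: exon chain plus optional 3'-UTR.

    ``exons`` are kept sorted by genomic start and must be pairwise
    non-overlapping on a single chromosome/strand. ``utr3`` holds zero or
    more intervals, each contained in the exon union (Ensembl annotations
    carry one or zero 3'-UTR features per protein-coding transcript; a
    multi-interval utr3 means the UTR spans an exon junction).
    """

    transcript_id: str
    gene_id: str
    biotype: str
    exons: list[GenomicInterval]
    utr3: list[GenomicInterval] = field(default_factory=list)
    cds_end_genomic: int | None = None

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def single_exon_utr3(self) -> bool:
        return len(self.utr3) == 1

    @property
    def is_protein_coding(self) -> bool:
        return self.biotype == "protein_coding"

    @property
    def utr3_length(self) -> int:
        return sum(iv.length for iv in self.utr3)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) of the whole transcript."""
        return self.exons[0].start, self.exons[-1].end

    def utr3_distal_end(self) -> int:
        """Genomic coordinate of the 3'-most UTR edge on the transcribed strand.

        On '+' this is the largest ``end``; on '-' the smallest ``start``.
        Requires a non-empty utr3.
        """
        if not self.utr3:
            raise ValueError(f"{self.transcript_id} has no 3'-UTR annotation")
        if self.strand == "+":
            return self.utr3[-1].end
        return self.utr3[0].start

    def utr3_five_prime_edge(self) -> int:
        """Genomic coordinate of the UTR start (5' edge, transcribed sense)."""
        if not self.utr3:
            raise ValueError(f"{self.transcript_id} has no 3'-UTR annotation")
        if self.strand == "+":
            return self.utr3[0].start
        return self.utr3[-1].end

    def validate(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        chrom, strand = self.exons[0].chrom, self.exons[0].strand
        for iv in self.exons + self.utr3:
            if iv.chrom != chrom or iv.strand != strand:
                raise ValueError(
                    f"{self.transcript_id}: mixed chrom/strand in features"
                )
        for a, b in zip(self.exons, self.exons[1:]):
            if a.start > b.start:
                raise ValueError(f"{self.transcript_id}: exons not sorted")
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for a, b in zip(self.utr3, self.utr3[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"{self.transcript_id}: overlapping 3'-UTR intervals"
                )
        for u in self.utr3:
            if not any(e.contains(u) for e in self.exons):
                raise ValueError(
                    f"{self.transcript_id}: 3'-UTR interval "
                    f"[{u.start},{u.end}) not contained in any exon"
                )

    def copy(self) -> "TranscriptModel":
        return replace(self, exons=list(self.exons), utr3=list(self.utr3))


@dataclass
class ReferenceBundle:
    """Genome sequences plus transcript models."""

    genome: dict[str, str]
    models: list[TranscriptModel]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def validate(self) -> None:
        lengths = self.chrom_lengths
        for m in self.models:
            m.validate()
            if m.chrom not in lengths:
                raise ValueError(
                    f"{m.transcript_id}: chromosome {m.chrom} absent from genome"
                )
            if m.exons[-1].end > lengths[m.chrom]:
                raise ValueError(
                    f"{m.transcript_id}: features extend beyond {m.chrom} "
                    f"length {lengths[m.chrom]}"
                )


def interval_positions(intervals: list[GenomicInterval], strand: str) -> np.ndarray:
    """Genomic coordinate of each transcribed base, 5'->3'.

    Plus strand walks the intervals in genomic order left to right; minus
    strand walks them right to left, each interval in decreasing coordinate.
    Returns an int array whose length is the summed interval length.
    """
    if not intervals:
        return np.empty(0, dtype=np.int64)
    parts = []
    if strand == "+":
        for iv in intervals:
            parts.append(np.arange(iv.start, iv.end, dtype=np.int64))
    else:
        for iv in reversed(intervals):
            parts.append(np.arange(iv.end - 1, iv.start - 1, -1, dtype=np.int64))
    return np.concatenate(parts)
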