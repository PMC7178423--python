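"""Readers and writers for GTF, BED12 and FASTA, plus 3'-UTR sequence extraction.

GTF input is the Ensembl dialect: 1-based closed intervals, attributes as
``key "value";`` pairs. Everything is converted to 0-based half-open at this
boundary; BED12 is native 0-based half-open.
"""
from __future__ import annotations

import re
import logging
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GenomicInterval, ReferenceBundle, TranscriptModel, revcomp

logger = logging.getLogger(__name__)

_GTF_FEATURES = {"exon", "three_prime_utr", "transcript"}
_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"\s*;?')


class GtfParseError(ValueError):
    """Raised for structurally malformed GTF input, naming the line."""


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse transcript models from an Ensembl-dialect GTF file.

    Only ``exon``, ``three_prime_utr`` and ``transcript`` features are
    consumed. Transcripts lacking any ``three_prime_utr`` feature get an
    empty ``utr3``. Non-protein-coding transcripts are parsed but flagged
    inert via their biotype.
    """
    by_tid: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature not in _GTF_FEATURES:
                continue
            try:
                start = int(start_s) - 1  # 1-based closed -> 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise GtfParseError(
                    f"{path}: line {lineno}: empty/negative interval after "
                    f"coordinate conversion (start={start_s}, end={end_s})"
                )
            attrs = _parse_attributes(attrs_s)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise GtfParseError(
                    f"{path}: line {lineno}: missing transcript_id attribute"
                )
            rec = by_tid.setdefault(
                tid,
                {"gene_id": attrs.get("gene_id", ""), "biotype": None,
                 "exons": [], "utr3": []},
            )
            biotype = attrs.get("transcript_biotype") or attrs.get("gene_biotype")
            if biotype and rec["biotype"] is None:
                rec["biotype"] = biotype
            iv = GenomicInterval(chrom, start, end, strand)
            if feature == "exon":
                rec["exons"].append(iv)
            elif feature == "three_prime_utr":
                rec["utr3"].append(iv)

    models = []
    for tid, rec in by_tid.items():
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            biotype=rec["biotype"] or "unknown",
            exons=sorted(rec["exons"], key=lambda iv: iv.start),
            utr3=sorted(rec["utr3"], key=lambda iv: iv.start),
        )
        model.validate()
        models.append(model)
    return models


def write_gtf(models: list[TranscriptModel], path: str | Path) -> None:
    """Write models back to Ensembl-dialect GTF (transcript/exon/three_prime_utr)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'transcript_biotype "{m.biotype}";'
            )
            span_start, span_end = m.span

            def line(feature: str, iv_start: int, iv_end: int) -> str:
                return "\t".join(
                    [m.chrom, "utrtar", feature, str(iv_start + 1), str(iv_end),
                     ".", m.strand, ".", attrs]
                )

            fh.write(line("transcript", span_start, span_end) + "\n")
            for e in m.exons:
                fh.write(line("exon", e.start, e.end) + "\n")
            for u in m.utr3:
                fh.write(line("three_prime_utr", u.start, u.end) + "\n")


def to_bed12(model: TranscriptModel) -> str:
    """Render one transcript as a BED12 line (blocks = exons)."""
    if not model.exons:
        raise ValueError(f"{model.transcript_id}: cannot convert 0 exons to BED12")
    chrom_start, chrom_end = model.span
    sizes = ",".join(str(e.length) for e in model.exons)
    starts = ",".join(str(e.start - chrom_start) for e in model.exons)
    return "\t".join(
        [model.chrom, str(chrom_start), str(chrom_end), model.transcript_id,
         "0", model.strand, str(chrom_start), str(chrom_end), "0",
         str(len(model.exons)), sizes, starts]
    )


def read_bed12_line(line: str, gene_id: str = "", biotype: str = "unknown") -> TranscriptModel:
    """Parse one BED12 line into a transcript model (no UTR information)."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ValueError(f"BED12 line has {len(fields)} columns, expected 12")
    chrom, chrom_start, _chrom_end, name, _score, strand = fields[:6]
    block_count = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    if not (len(sizes) == len(starts) == block_count):
        raise ValueError(f"BED12 block fields inconsistent for {name}")
    base = int(chrom_start)
    exons = [
        GenomicInterval(chrom, base + s, base + s + sz, strand)
        for s, sz in zip(starts, sizes)
    ]
    model = TranscriptModel(
        transcript_id=name, gene_id=gene_id, biotype=biotype, exons=exons
    )
    model.validate()
    return model


def write_bed12(models: list[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(to_bed12(m) + "\n")


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                models.append(read_bed12_line(line))
    return models


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into chrom -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 60 columns."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def extract_utr_sequence(
    bundle: ReferenceBundle,
    model: TranscriptModel,
    utr_override: list[GenomicInterval] | None = None,
) -> str:
    """Contiguous 3'-UTR sequence, 5'->3' in transcribed sense (DNA alphabet).

    Individual UTR exon chunks are merged into one string: plus strand by
    concatenating the genomic substrings in genomic order, minus strand by
    reverse-complementing each chunk and concatenating in transcription
    order (genomically right to left). Empty utr3 yields "".
    """
    intervals = model.utr3 if utr_override is None else utr_override
    if not intervals:
        return ""
    chrom_seq = bundle.genome.get(model.chrom)
    if chrom_seq is None:
        raise KeyError(f"chromosome {model.chrom} absent from genome")
    for iv in intervals:
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"{model.transcript_id}: interval [{iv.start},{iv.end}) beyond "
                f"end of {model.chrom} (length {len(chrom_seq)})"
            )
    if model.strand == "+":
        return "".join(chrom_seq[iv.start:iv.end] for iv in intervals)
    return "".join(revcomp(chrom_seq[iv.start:iv.end]) for iv in reversed(intervals))
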