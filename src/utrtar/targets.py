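"""Canonical miRNA seed-site prediction on 3'-UTR sequences.

Site taxonomy follows the canonical seed-match hierarchy: with S6 the
reverse complement of miRNA positions 2-7 and S7 the reverse complement of
positions 2-8 (one extra base on the mRNA 5' side), each S6 occurrence in a
UTR is classified as 8mer (S7 extension and a 3' A), 7mer-m8 (S7 extension
only), 7mer-A1 (3' A only) or 6mer, with precedence 8mer > 7mer-m8 >
7mer-A1 > 6mer. The A in A1 sites is an adenosine opposite miRNA position
1 regardless of the miRNA's first base.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .models import ReferenceBundle, TranscriptModel, interval_positions, revcomp

logger = logging.getLogger(__name__)

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_SITE_LEN = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3', stored in DNA alphabet (U converted to T)."""

    mirna_id: str
    mature_seq: str

    def __post_init__(self) -> None:
        seq = self.mature_seq.upper().replace("U", "T")
        object.__setattr__(self, "mature_seq", seq)
        if len(seq) < 8:
            raise ValueError(
                f"{self.mirna_id}: mature sequence must be >= 8 nt, got {len(seq)}"
            )
        if set(seq) - set("ACGT"):
            raise ValueError(f"{self.mirna_id}: invalid characters in {seq}")

    @property
    def seed6_match(self) -> str:
        """Reverse complement of miRNA positions 2-7 (the mRNA 6mer site)."""
        return revcomp(self.mature_seq[1:7])

    @property
    def seed7_match(self) -> str:
        """Reverse complement of positions 2-8 (6mer site plus one 5' base)."""
        return revcomp(self.mature_seq[1:8])


@dataclass(frozen=True)
class SeedSite:
    transcript_id: str
    mirna_id: str
    site_type: str
    utr_offset: int  # 0-based start of the maximal matched span, 5'->3' in UTR
    match_len: int
    chrom: str | None = None
    genomic_start: int | None = None
    genomic_end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.match_len != _SITE_LEN[self.site_type]:
            raise ValueError(
                f"{self.site_type} must have match_len {_SITE_LEN[self.site_type]}"
            )

    @property
    def genomic_5p(self) -> int | None:
        """Genomic coordinate of the site's 5'-most base (transcribed sense)."""
        if self.genomic_start is None:
            return None
        return self.genomic_start if self.strand != "-" else self.genomic_end - 1


def scan_seed_sites(utr_seq: str, mirna: MiRNA) -> list[SeedSite]:
    """All canonical seed sites of one miRNA in one 5'->3' UTR sequence.

    Each S6 occurrence yields exactly one site of the strongest type whose
    flanking requirements hold; matches truncated by the UTR boundary fall
    back to the strongest fully contained type. N never matches anything
    (including the 3' A position).
    """
    utr_seq = utr_seq.upper()
    s6 = mirna.seed6_match
    m8_base = mirna.seed7_match[0]  # complement of miRNA position 8
    sites = []
    pos = utr_seq.find(s6)
    while pos != -1:
        has_m8 = pos > 0 and utr_seq[pos - 1] == m8_base
        has_a1 = pos + 6 < len(utr_seq) and utr_seq[pos + 6] == "A"
        if has_m8 and has_a1:
            site_type, offset, length = "8mer", pos - 1, 8
        elif has_m8:
            site_type, offset, length = "7mer-m8", pos - 1, 7
        elif has_a1:
            site_type, offset, length = "7mer-A1", pos, 7
        else:
            site_type, offset, length = "6mer", pos, 6
        sites.append(
            SeedSite(
                transcript_id="",
                mirna_id=mirna.mirna_id,
                site_type=site_type,
                utr_offset=offset,
                match_len=length,
            )
        )
        pos = utr_seq.find(s6, pos + 1)
    return sites


@dataclass
class PredictionSet:
    """All predicted seed sites under one annotation version."""

    annotation_label: str
    sites: list[SeedSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        unique = []
        for s in self.sites:
            key = (s.transcript_id, s.mirna_id, s.utr_offset, s.site_type)
            if key in seen:
                continue
            seen.add(key)
            unique.append(s)
        self.sites = unique

    def __len__(self) -> int:
        return len(self.sites)

    def site_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sites:
            counts[s.transcript_id] = counts.get(s.transcript_id, 0) + 1
        return counts

    def transcripts(self) -> set[str]:
        return {s.transcript_id for s in self.sites}

    def genomic_keys(self) -> set[tuple]:
        """Site identities keyed by genomic position (stable under reannotation)."""
        return {
            (s.transcript_id, s.mirna_id, s.site_type, s.chrom, s.genomic_5p)
            for s in self.sites
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript_id": s.transcript_id,
                    "mirna_id": s.mirna_id,
                    "site_type": s.site_type,
                    "utr_offset": s.utr_offset,
                    "chrom": s.chrom,
                    "genomic_start": s.genomic_start,
                    "genomic_end": s.genomic_end,
                    "strand": s.strand,
                }
                for s in self.sites
            ],
            columns=[
                "transcript_id", "mirna_id", "site_type", "utr_offset",
                "chrom", "genomic_start", "genomic_end", "strand",
            ],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, annotation_label: str = "") -> "PredictionSet":
        df = pd.read_csv(path, sep="\t")
        sites = [
            SeedSite(
                transcript_id=str(r.transcript_id),
                mirna_id=str(r.mirna_id),
                site_type=str(r.site_type),
                utr_offset=int(r.utr_offset),
                match_len=_SITE_LEN[str(r.site_type)],
                chrom=None if pd.isna(r.chrom) else str(r.chrom),
                genomic_start=None if pd.isna(r.genomic_start) else int(r.genomic_start),
                genomic_end=None if pd.isna(r.genomic_end) else int(r.genomic_end),
                strand=None if pd.isna(r.strand) else str(r.strand),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(annotation_label=annotation_label or str(path), sites=sites)


def read_mirna_fasta(path: str | Path) -> list[MiRNA]:
    """Load mature miRNA sequences (U or T alphabet); duplicates deduped by id."""
    mirnas: list[MiRNA] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            logger.warning("duplicate miRNA id %s: keeping first occurrence", rec.id)
            continue
        seen.add(rec.id)
        mirnas.append(MiRNA(mirna_id=rec.id, mature_seq=str(rec.seq)))
    return mirnas


def predict(
    bundle: ReferenceBundle,
    models: list[TranscriptModel],
    mirnas: list[MiRNA],
    annotation_label: str = "annotation",
) -> PredictionSet:
    """Scan every protein-coding transcript's 3'-UTR for every miRNA.

    Site offsets are mapped back to genomic coordinates via the per-base
    UTR coordinate map, so a site keeps its identity when the UTR around it
    is extended or truncated.
    """
    from .annotation_io import extract_utr_sequence

    uniq: dict[str, MiRNA] = {}
    for m in mirnas:
        if m.mirna_id in uniq:
            logger.warning("duplicate miRNA id %s ignored", m.mirna_id)
            continue
        uniq[m.mirna_id] = m

    sites: list[SeedSite] = []
    for model in models:
        if not model.is_protein_coding or not model.utr3:
            continue
        seq = extract_utr_sequence(bundle, model)
        if len(seq) < 6:
            continue
        positions = interval_positions(model.utr3, model.strand)
        for mirna in uniq.values():
            for s in scan_seed_sites(seq, mirna):
                span = positions[s.utr_offset:s.utr_offset + s.match_len]
                sites.append(
                    SeedSite(
                        transcript_id=model.transcript_id,
                        mirna_id=s.mirna_id,
                        site_type=s.site_type,
                        utr_offset=s.utr_offset,
                        match_len=s.match_len,
                        chrom=model.chrom,
                        genomic_start=int(span.min()),
                        genomic_end=int(span.max()) + 1,
                        strand=model.strand,
                    )
                )
    return PredictionSet(annotation_label=annotation_label, sites=sites)


def filter_by_expression(
    preds: PredictionSet,
    tpm: dict[str, float],
    threshold: float = 0.1,
) -> tuple[PredictionSet, set[str]]:
    """Keep only sites on transcripts expressed at TPM >= threshold.

    Returns the filtered set and the set of transcripts whose sites were
    removed. Transcripts absent from the TPM table count as 0 (and so are
    always removed for positive thresholds).
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    kept, removed = [], set()
    for s in preds.sites:
        if tpm.get(s.transcript_id, 0.0) >= threshold:
            kept.append(s)
        else:
            removed.add(s.transcript_id)
    return (
        PredictionSet(
            annotation_label=f"{preds.annotation_label}|tpm>={threshold:g}",
            sites=kept,
        ),
        removed,
    )


@dataclass
class ComparisonStats:
    """Gain/loss bookkeeping between two annotation versions' predictions."""

    sites_gained: int
    sites_lost: int
    pct_gained: float | None
    pct_lost: float | None
    bases_added: int
    bases_removed: int
    pct_utr_bases_lost: float | None
    fraction_utrs_affected: float | None
    gained: set[tuple] = field(default_factory=set, repr=False)
    lost: set[tuple] = field(default_factory=set, repr=False)

    def as_dict(self) -> dict:
        return {
            "sites_gained": self.sites_gained,
            "sites_lost": self.sites_lost,
            "pct_gained": self.pct_gained,
            "pct_lost": self.pct_lost,
            "bases_added": self.bases_added,
            "bases_removed": self.bases_removed,
            "pct_utr_bases_lost": self.pct_utr_bases_lost,
            "fraction_utrs_affected": self.fraction_utrs_affected,
        }


def compare_annotation_sets(
    baseline: PredictionSet,
    revised: PredictionSet,
    baseline_models: list[TranscriptModel],
    revised_models: list[TranscriptModel],
) -> ComparisonStats:
    """Gained/lost sites and UTR base deltas, revised vs baseline.

    Site identity uses genomic coordinates so an unchanged site is never
    relabelled merely because the UTR around it moved. Percentages are
    relative to the baseline site total and reported as None when that
    total is zero.
    """
    base_keys = baseline.genomic_keys()
    rev_keys = revised.genomic_keys()
    gained = rev_keys - base_keys
    lost = base_keys - rev_keys

    base_len = {m.transcript_id: m.utr3_length for m in baseline_models}
    rev_len = {m.transcript_id: m.utr3_length for m in revised_models}
    bases_added = bases_removed = 0
    changed_tids = set()
    for tid, blen in base_len.items():
        rlen = rev_len.get(tid, blen)
        if rlen > blen:
            bases_added += rlen - blen
        elif rlen < blen:
            bases_removed += blen - rlen
        if rlen != blen:
            changed_tids.add(tid)
    for key in gained | lost:
        changed_tids.add(key[0])

    n_base_sites = len(base_keys)
    total_base_utr = sum(blen for blen in base_len.values() if blen > 0)
    baseline_utr_tids = {tid for tid, blen in base_len.items() if blen > 0}
    return ComparisonStats(
        sites_gained=len(gained),
        sites_lost=len(lost),
        pct_gained=100.0 * len(gained) / n_base_sites if n_base_sites else None,
        pct_lost=100.0 * len(lost) / n_base_sites if n_base_sites else None,
        bases_added=bases_added,
        bases_removed=bases_removed,
        pct_utr_bases_lost=(
            100.0 * bases_removed / total_base_utr if total_base_utr else None
        ),
        fraction_utrs_affected=(
            len(changed_tids & baseline_utr_tids) / len(baseline_utr_tids)
            if baseline_utr_tids else None
        ),
        gained=gained,
        lost=lost,
    )
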