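"""Seeded generator of complete toy datasets for the whole pipeline.

One call produces a random genome with plus/minus-strand protein-coding
genes, an annotation with single-exon, multi-exon and absent 3'-UTRs,
replicate coverage tracks with planted distal-end shifts (alternative
polyadenylation breakpoints), a TPM abundance table, miRNAs with planted
seed sites, and a transfection-style log2 fold-change table with planted
repression of true targets. A truth table records, per transcript, the
true distal end, the planted shift, planted/actual seed sites and target
flags, so recovery can be scored exactly.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import extract_utr_sequence, write_fasta, write_gtf
from .models import GenomicInterval, ReferenceBundle, TranscriptModel, revcomp
from .quantify import AbundanceTable, compute_tpm
from .reannotation import CoverageTrack
from .targets import MiRNA, scan_seed_sites

# An arbitrary but fixed mature miRNA sequence used by default; its 6mer
# seed match on the mRNA is CAGGGT and the full 8mer site is ACAGGGTA.
DEFAULT_MIRNA = MiRNA("syn-miR-1", "UACCCUGUAGAUCCGAAUUUGUG")


@dataclass
class SimulationParams:
    """Study conditions for the synthetic datasets.

    Defaults mirror the benchmark design the package is tested under:
    100 transcripts, planted distal-end shifts of 200-600 nt, 20x mean
    coverage with Poisson noise over two replicates, and a repression
    shift of -0.5 log2 units (sigma 0.5) for true targets.
    """

    n_transcripts: int = 100
    utr_len_range: tuple[int, int] = (600, 1200)
    cds_exon_len: int = 300
    terminal_cds_len: int = 50
    intron_len: int = 100
    intergenic_gap: int = 6000
    frac_minus_strand: float = 0.5
    frac_multi_exon_utr: float = 0.1
    frac_no_utr: float = 0.1
    frac_extended: float = 0.2
    frac_truncated: float = 0.2
    delta_range: tuple[int, int] = (200, 600)
    coverage_depth: float = 20.0
    poisson_noise: bool = True
    n_replicates: int = 2
    tpm_mode: str = "lognormal"  # or "uniform"
    tpm_low_frac: float = 0.2
    mirnas: list[MiRNA] = field(default_factory=lambda: [DEFAULT_MIRNA])
    p_core_site: float = 0.6
    repression_delta: float = 0.5
    repression_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_minus_strand", "frac_multi_exon_utr", "frac_no_utr",
                     "frac_extended", "frac_truncated", "tpm_low_frac",
                     "p_core_site"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_multi_exon_utr + self.frac_no_utr > 1:
            raise ValueError("frac_multi_exon_utr + frac_no_utr > 1")
        if self.frac_extended + self.frac_truncated > 1:
            raise ValueError("frac_extended + frac_truncated > 1")
        lo, hi = self.delta_range
        if lo > hi or lo < 0:
            raise ValueError(f"bad delta_range {self.delta_range}")
        if self.utr_len_range[0] < lo + 250:
            raise ValueError(
                "utr_len_range minimum must exceed delta_range minimum by "
                ">= 250 nt so truncated UTRs keep a measurable proximal part"
            )
        if self.intergenic_gap < hi + 200:
            raise ValueError("intergenic_gap too small for planted extensions")
        if self.repression_sigma <= 0:
            raise ValueError("repression_sigma must be > 0")
        if self.tpm_mode not in ("lognormal", "uniform"):
            raise ValueError(f"unknown tpm_mode {self.tpm_mode!r}")


@dataclass
class TranscriptTruth:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    utr_class: str  # single / multi / none
    annotated_distal_end: int
    true_distal_end: int
    planted_delta: int  # signed, 0 when no breakpoint planted
    tpm: float
    planted_sites: list[dict] = field(default_factory=list)
    is_target: dict[str, bool] = field(default_factory=dict)
    removed_target: dict[str, bool] = field(default_factory=dict)
    gained_target: dict[str, bool] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    params: SimulationParams
    bundle: ReferenceBundle
    truth: list[TranscriptTruth]
    tracks: list[CoverageTrack]
    abundance: AbundanceTable
    mirnas: list[MiRNA]
    fold_changes: dict[str, float]

    @property
    def models(self) -> list[TranscriptModel]:
        return self.bundle.models

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript_id": t.transcript_id,
                    "strand": t.strand,
                    "utr_class": t.utr_class,
                    "annotated_distal_end": t.annotated_distal_end,
                    "true_distal_end": t.true_distal_end,
                    "planted_delta": t.planted_delta,
                    "tpm": t.tpm,
                    "n_planted_sites": len(t.planted_sites),
                    "is_target": any(t.is_target.values()),
                    "removed_target": any(t.removed_target.values()),
                    "gained_target": any(t.gained_target.values()),
                }
                for t in self.truth
            ]
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.bundle.genome, outdir / "genome.fa")
        write_gtf(self.models, outdir / "annotation.gtf")
        for i, track in enumerate(self.tracks, start=1):
            track.write_bedgraph(outdir / f"coverage_rep{i}.bedgraph")
        self.abundance.write(outdir / "abundance.tsv")
        write_fasta(
            {m.mirna_id: m.mature_seq.replace("T", "U") for m in self.mirnas},
            outdir / "mirnas.fa",
        )
        pd.DataFrame(
            {"transcript_id": list(self.fold_changes),
             "log2fc": list(self.fold_changes.values())}
        ).to_csv(outdir / "log2fc.tsv", sep="\t", index=False)
        self.truth_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump([asdict(t) for t in self.truth], fh, indent=1)


def _write_site(
    genome: np.ndarray,
    model: TranscriptModel,
    offset: int,
    site_seq: str,
) -> None:
    """Plant ``site_seq`` (UTR 5'->3') at a UTR-space offset into the genome.

    Offsets within the annotated UTR follow its exon geometry (so a site may
    straddle a junction); offsets beyond the annotated distal end continue
    linearly into the downstream genome, which is where planted extensions
    live.
    """
    from .models import interval_positions

    positions = interval_positions(model.utr3, model.strand)
    utr_len = positions.size
    step = 1 if model.strand == "+" else -1
    for k, base in enumerate(site_seq):
        o = offset + k
        if o < utr_len:
            gpos = int(positions[o])
        else:
            gpos = int(positions[-1]) + step * (o - utr_len + 1)
        genome[gpos] = (base if model.strand == "+" else revcomp(base)).encode()


def _site8(mirna: MiRNA) -> str:
    """The strongest canonical site string: seed(2-8) complement plus a 3' A."""
    return mirna.seed7_match + "A"


def simulate_reference(
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[ReferenceBundle, list[TranscriptTruth]]:
    """Lay out genes on one chromosome and plant breakpoints and seed sites."""
    rng = rng or np.random.default_rng(params.seed)
    chrom = "chr1"
    gap, intron = params.intergenic_gap, params.intron_len
    cds_len, term_cds = params.cds_exon_len, params.terminal_cds_len

    models: list[TranscriptModel] = []
    truths: list[TranscriptTruth] = []
    cursor = gap
    for i in range(params.n_transcripts):
        tid, gid = f"SYNT{i:05d}", f"SYNG{i:05d}"
        strand = "-" if rng.random() < params.frac_minus_strand else "+"
        u = rng.random()
        if u < params.frac_no_utr:
            utr_class = "none"
        elif u < params.frac_no_utr + params.frac_multi_exon_utr:
            utr_class = "multi"
        else:
            utr_class = "single"
        utr_len = int(rng.integers(*params.utr_len_range, endpoint=True))

        delta = 0
        if utr_class == "single":
            v = rng.random()
            mag = int(rng.integers(*params.delta_range, endpoint=True))
            if v < params.frac_extended:
                delta = mag
            elif v < params.frac_extended + params.frac_truncated:
                delta = -min(mag, utr_len - 250)

        exons: list[GenomicInterval] = []
        utr3: list[GenomicInterval] = []
        g = cursor
        if strand == "+":
            exons.append(GenomicInterval(chrom, g, g + cds_len, strand))
            s2 = g + cds_len + intron
            if utr_class == "none":
                exons.append(GenomicInterval(chrom, s2, s2 + term_cds, strand))
            elif utr_class == "single":
                exons.append(GenomicInterval(chrom, s2, s2 + term_cds + utr_len, strand))
                utr3.append(GenomicInterval(chrom, s2 + term_cds, s2 + term_cds + utr_len, strand))
            else:  # multi-exon UTR: split roughly in half over two exons
                half = utr_len // 2
                exons.append(GenomicInterval(chrom, s2, s2 + term_cds + half, strand))
                utr3.append(GenomicInterval(chrom, s2 + term_cds, s2 + term_cds + half, strand))
                s3 = s2 + term_cds + half + intron
                exons.append(GenomicInterval(chrom, s3, s3 + (utr_len - half), strand))
                utr3.append(GenomicInterval(chrom, s3, s3 + (utr_len - half), strand))
        else:
            # terminal (3') region genomically leftmost on the minus strand
            if utr_class == "none":
                exons.append(GenomicInterval(chrom, g, g + term_cds, strand))
                nxt = g + term_cds + intron
            elif utr_class == "single":
                exons.append(GenomicInterval(chrom, g, g + utr_len + term_cds, strand))
                utr3.append(GenomicInterval(chrom, g, g + utr_len, strand))
                nxt = g + utr_len + term_cds + intron
            else:
                half = utr_len // 2
                exons.append(GenomicInterval(chrom, g, g + (utr_len - half), strand))
                utr3.append(GenomicInterval(chrom, g, g + (utr_len - half), strand))
                s2 = g + (utr_len - half) + intron
                exons.append(GenomicInterval(chrom, s2, s2 + half + term_cds, strand))
                utr3.append(GenomicInterval(chrom, s2, s2 + half, strand))
                nxt = s2 + half + term_cds + intron
            exons.append(GenomicInterval(chrom, nxt, nxt + cds_len, strand))

        model = TranscriptModel(
            transcript_id=tid, gene_id=gid, biotype="protein_coding",
            exons=exons, utr3=utr3,
        )
        model.validate()
        models.append(model)

        if utr3:
            ann_end = model.utr3_distal_end()
            true_end = ann_end + delta if strand == "+" else ann_end - delta
        else:
            # 3' edge of the terminal exon stands in for the transcript end
            ann_end = exons[-1].end if strand == "+" else exons[0].start
            true_end = ann_end
        truths.append(
            TranscriptTruth(
                transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
                utr_class=utr_class, annotated_distal_end=ann_end,
                true_distal_end=true_end, planted_delta=delta, tpm=0.0,
            )
        )
        span = model.span
        cursor = max(cursor, span[1]) + gap

    chrom_len = cursor + gap
    genome = rng.choice(
        np.frombuffer(b"ACGT", dtype="S1"), size=chrom_len
    ).copy()

    # plant seed sites (after background so plants are not overwritten)
    for model, truth in zip(models, truths):
        if not model.utr3:
            continue
        utr_len = model.utr3_length
        true_len = utr_len + truth.planted_delta
        for mirna in params.mirnas:
            site = _site8(mirna)
            if rng.random() < params.p_core_site and truth.planted_delta >= 0:
                # core site: inside both the annotated and the true UTR
                off = int(rng.integers(10, min(utr_len, true_len) - len(site) - 10))
                _write_site(genome, model, off, site)
                truth.planted_sites.append(
                    {"mirna_id": mirna.mirna_id, "utr_offset": off, "where": "core"}
                )
            if truth.planted_delta < 0:
                # lost-tail site: annotated UTR only, beyond the true end
                off = int(rng.integers(true_len + 20, utr_len - len(site) - 5))
                _write_site(genome, model, off, site)
                truth.planted_sites.append(
                    {"mirna_id": mirna.mirna_id, "utr_offset": off, "where": "lost_tail"}
                )
            elif truth.planted_delta > 0:
                # extension site: true UTR only, beyond the annotated end
                off = int(rng.integers(utr_len + 20, true_len - len(site) - 5))
                _write_site(genome, model, off, site)
                truth.planted_sites.append(
                    {"mirna_id": mirna.mirna_id, "utr_offset": off, "where": "extension"}
                )

    bundle = ReferenceBundle(
        genome={chrom: genome.tobytes().decode()}, models=models
    )
    bundle.validate()

    # TPM assignment
    n = params.n_transcripts
    if params.tpm_mode == "uniform":
        tpms = np.full(n, 50.0)
    else:
        tpms = rng.lognormal(mean=math.log(20.0), sigma=1.0, size=n)
        low = rng.random(n) < params.tpm_low_frac
        tpms[low] = rng.uniform(0.001, 0.09, size=int(low.sum()))
    for truth, tpm in zip(truths, tpms):
        truth.tpm = float(tpm)

    # truth flags from re-scanning the emitted sequences (background matches
    # and planted sites are both captured this way)
    for model, truth in zip(models, truths):
        if not model.utr3:
            for mirna in params.mirnas:
                truth.is_target[mirna.mirna_id] = False
                truth.removed_target[mirna.mirna_id] = False
                truth.gained_target[mirna.mirna_id] = False
            continue
        ann_seq = extract_utr_sequence(bundle, model)
        true_seq = _true_utr_sequence(bundle, model, truth)
        for mirna in params.mirnas:
            ann_offsets = {_site_key(s) for s in scan_seed_sites(ann_seq, mirna)}
            true_offsets = {_site_key(s) for s in scan_seed_sites(true_seq, mirna)}
            truth.is_target[mirna.mirna_id] = bool(true_offsets)
            truth.removed_target[mirna.mirna_id] = bool(ann_offsets - true_offsets)
            truth.gained_target[mirna.mirna_id] = bool(true_offsets - ann_offsets)
    return bundle, truths


def _site_key(site) -> tuple:
    return (site.utr_offset, site.site_type)


def _true_utr_sequence(bundle, model, truth) -> str:
    """UTR sequence extended/truncated to the true distal end."""
    utr3 = [GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand) for iv in model.utr3]
    if model.strand == "+":
        new_end = truth.true_distal_end
        last = utr3[-1]
        if new_end <= last.start:
            raise ValueError("true distal end collapses the UTR")
        utr3[-1] = GenomicInterval(last.chrom, last.start, new_end, last.strand)
    else:
        new_end = truth.true_distal_end
        first = utr3[0]
        if new_end >= first.end:
            raise ValueError("true distal end collapses the UTR")
        utr3[0] = GenomicInterval(first.chrom, new_end, first.end, first.strand)
    return extract_utr_sequence(bundle, model, utr_override=utr3)


def simulate_coverage(
    bundle: ReferenceBundle,
    truths: list[TranscriptTruth],
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> list[CoverageTrack]:
    """Piecewise-constant coverage to each true distal end, one track per
    replicate, scaled by relative expression, with optional Poisson noise."""
    rng = rng or np.random.default_rng(params.seed + 1)
    by_tid = {m.transcript_id: m for m in bundle.models}
    tpms = np.array([t.tpm for t in truths])
    med = float(np.median(tpms[tpms > 0])) if np.any(tpms > 0) else 1.0

    chrom_arrays: dict[str, np.ndarray] = {
        c: np.zeros(ln) for c, ln in bundle.chrom_lengths.items()
    }
    for truth in truths:
        model = by_tid[truth.transcript_id]
        value = params.coverage_depth * (truth.tpm / med)
        span = model.span
        if truth.strand == "+":
            lo, hi = span[0], truth.true_distal_end
        else:
            lo, hi = truth.true_distal_end, span[1]
        if hi > lo:
            chrom_arrays[truth.chrom][lo:hi] += value

    tracks = []
    for _rep in range(params.n_replicates):
        intervals: dict[str, list] = {}
        for chrom, arr in chrom_arrays.items():
            if params.poisson_noise:
                noisy = np.zeros_like(arr)
                nz = arr > 0
                noisy[nz] = rng.poisson(arr[nz]).astype(float)
            else:
                noisy = arr
            track = CoverageTrack.from_array(chrom, noisy)
            intervals.update(track.intervals)
        tracks.append(CoverageTrack(intervals))
    return tracks


def simulate_abundance(truths: list[TranscriptTruth], models: list[TranscriptModel]) -> AbundanceTable:
    """Abundance table whose TPM values reproduce the truth TPMs.

    Counts are back-computed from the truth TPM and the transcript length so
    that the in-house TPM formula returns the planted values (up to the
    1e6 normalisation).
    """
    by_tid = {m.transcript_id: m for m in models}
    triples = []
    for t in truths:
        m = by_tid[t.transcript_id]
        eff_len = float(sum(e.length for e in m.exons))
        count = t.tpm * eff_len / 1e3
        triples.append((t.transcript_id, count, eff_len))
    records = compute_tpm(triples)
    # rescale back to the planted absolute TPMs (compute_tpm normalises to 1e6)
    planted_total = sum(t.tpm for t in truths)
    for rec, t in zip(records, truths):
        rec.tpm = rec.tpm * planted_total / 1e6
    return AbundanceTable(records)


def simulate_transfection(
    truths: list[TranscriptTruth],
    params: SimulationParams,
    mirna_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Transfection-style log2 fold changes with planted repression.

    True targets of the transfected miRNA (a seed site within the *true*
    UTR extent) are shifted by -repression_delta; everything else —
    including transcripts whose only site lies beyond a planted truncation
    — behaves as a non-target.
    """
    rng = rng or np.random.default_rng(params.seed + 2)
    mirna_id = mirna_id or params.mirnas[0].mirna_id
    fc = {}
    for t in truths:
        shift = -params.repression_delta if t.is_target.get(mirna_id) else 0.0
        fc[t.transcript_id] = float(rng.normal(shift, params.repression_sigma))
    return fc


def simulate_dataset(params: SimulationParams | None = None) -> SyntheticDataset:
    """End-to-end dataset generation from a single seed."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    bundle, truths = simulate_reference(params, rng)
    tracks = simulate_coverage(bundle, truths, params, rng)
    abundance = simulate_abundance(truths, bundle.models)
    fc = simulate_transfection(truths, params, rng=rng)
    return SyntheticDataset(
        params=params, bundle=bundle, truth=truths, tracks=tracks,
        abundance=abundance, mirnas=list(params.mirnas), fold_changes=fc,
    )


def simulate_benchmark_table(
    n_targets: int = 500,
    n_non_targets: int = 500,
    n_removed: int = 0,
    delta: float = 0.5,
    sigma: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, set[str]]]:
    """Fold-change table with planted repression, for KS calibration runs.

    Targets are shifted by -delta; removed targets (sites lost to a
    truncation) and non-targets draw from the null distribution. Returns
    the table and a group assignment (group name -> transcript ids).
    """
    rng = np.random.default_rng(seed)
    fc: dict[str, float] = {}
    groups: dict[str, set[str]] = {
        "seed_target": set(), "non_target": set(), "removed_target": set(),
    }
    for i in range(n_targets):
        tid = f"TGT{i:05d}"
        fc[tid] = float(rng.normal(-delta, sigma))
        groups["seed_target"].add(tid)
    for i in range(n_non_targets):
        tid = f"NON{i:05d}"
        fc[tid] = float(rng.normal(0.0, sigma))
        groups["non_target"].add(tid)
    for i in range(n_removed):
        tid = f"REM{i:05d}"
        fc[tid] = float(rng.normal(0.0, sigma))
        groups["removed_target"].add(tid)
    if not n_removed:
        del groups["removed_target"]
    return fc, groups
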