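"""Coverage-driven 3'-UTR reannotation.

Three stages: merge replicate bedgraph coverage tracks into a per-base mean
track; detect a coverage-supported distal 3'-UTR end per transcript with a
windowed threshold detector; integrate proposed ends into transcript models
under explicit eligibility rules (single-exon UTRs only, novel UTRs
discarded, 5' UTR edge fixed, truncation gated on expression).
"""
from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .models import GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

OUTCOMES = ("extended", "truncated", "unchanged", "skipped")
SKIP_REASONS = (
    "multi_exon_utr",
    "no_utr_annotation",
    "low_expression_truncation",
    "no_coverage",
    "none",
)


class CoverageTrack:
    """Strand-agnostic per-base coverage as sorted value intervals per chromosome.

    Intervals are 0-based half-open, non-overlapping and sorted; any base not
    covered by an interval has value 0. Zero-valued intervals are dropped on
    normalisation so the representation is canonical.
    """

    def __init__(self, intervals: dict[str, list[tuple[int, int, float]]] | None = None):
        self.intervals: dict[str, list[tuple[int, int, float]]] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                self.intervals[chrom] = self._normalise(chrom, ivs)

    @staticmethod
    def _normalise(chrom: str, ivs) -> list[tuple[int, int, float]]:
        ivs = sorted((int(s), int(e), float(v)) for s, e, v in ivs)
        out: list[tuple[int, int, float]] = []
        prev_end = -1
        for s, e, v in ivs:
            if e <= s:
                raise ValueError(f"{chrom}: empty interval [{s},{e})")
            if v < 0:
                raise ValueError(f"{chrom}: negative coverage {v} at [{s},{e})")
            if s < prev_end:
                raise ValueError(f"{chrom}: overlapping coverage intervals at {s}")
            prev_end = e
            if v == 0.0:
                continue
            if out and out[-1][1] == s and out[-1][2] == v:
                out[-1] = (out[-1][0], e, v)  # coalesce equal-value neighbours
            else:
                out.append((s, e, v))
        return out

    @property
    def chroms(self) -> list[str]:
        return sorted(self.intervals)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base coverage over [start, end) as a float array (absent = 0)."""
        if end < start:
            raise ValueError("end < start")
        out = np.zeros(end - start, dtype=float)
        ivs = self.intervals.get(chrom)
        if not ivs:
            return out
        starts = [iv[0] for iv in ivs]
        i = max(0, bisect.bisect_right(starts, start) - 1)
        for s, e, v in ivs[i:]:
            if s >= end:
                break
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                out[lo - start:hi - start] = v
        return out

    def scale(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: [(s, e, v * factor) for s, e, v in ivs]
             for c, ivs in self.intervals.items()}
        )

    @classmethod
    def from_array(cls, chrom: str, arr: np.ndarray, offset: int = 0) -> "CoverageTrack":
        """Run-length encode a dense per-base array into a track."""
        arr = np.asarray(arr, dtype=float)
        if arr.size == 0:
            return cls({chrom: []})
        change = np.flatnonzero(np.diff(arr) != 0) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [arr.size]))
        ivs = [
            (int(s) + offset, int(e) + offset, float(arr[s]))
            for s, e in zip(starts, ends)
            if arr[s] != 0
        ]
        return cls({chrom: ivs})

    @classmethod
    def read_bedgraph(cls, path: str | Path) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise ValueError(
                        f"{path}: line {lineno}: bedgraph needs 4 columns, "
                        f"got {len(fields)}"
                    )
                chrom, s, e, v = fields
                by_chrom.setdefault(chrom, []).append((int(s), int(e), float(v)))
        return cls(by_chrom)

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                for s, e, v in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def merge_replicates(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Mean per-base coverage over replicate tracks.

    The output value at every base is the arithmetic mean of the inputs at
    that base, with bases absent from a track counting as 0 (bedgraph
    semantics of genome-coverage emitters). Output intervals are the atomic
    segments of the union of breakpoints, equal-value neighbours coalesced.
    """
    if not tracks:
        raise ValueError("merge_replicates requires at least one track")
    n = len(tracks)
    chroms = sorted({c for t in tracks for c in t.intervals})
    merged: dict[str, list[tuple[int, int, float]]] = {}
    for chrom in chroms:
        per_track = [t.intervals.get(chrom, []) for t in tracks]
        bps = np.unique(
            np.array(
                [p for ivs in per_track for s, e, _v in ivs for p in (s, e)],
                dtype=np.int64,
            )
        )
        if bps.size < 2:
            merged[chrom] = []
            continue
        seg_starts = bps[:-1]
        total = np.zeros(seg_starts.size)
        for ivs in per_track:
            if not ivs:
                continue
            starts = np.array([iv[0] for iv in ivs], dtype=np.int64)
            ends = np.array([iv[1] for iv in ivs], dtype=np.int64)
            vals = np.array([iv[2] for iv in ivs])
            idx = np.searchsorted(starts, seg_starts, side="right") - 1
            valid = (idx >= 0) & (ends[np.clip(idx, 0, None)] > seg_starts)
            total[valid] += vals[idx[valid]]
        means = total / n
        merged[chrom] = [
            (int(bps[j]), int(bps[j + 1]), float(means[j]))
            for j in range(seg_starts.size)
        ]
    return CoverageTrack(merged)


@dataclass
class ReannotationParams:
    """Detector and integration knobs.

    window_w / step drive the coverage-window scan (bases); min_cov is the
    absolute floor on accepted window mean coverage (reads/base); cov_fraction
    is the floor relative to the proximal reference coverage; extension_limit
    bounds how far past the annotated end the search runs; min_delta is the
    smallest end shift worth reporting; tpm_truncation_gate blocks truncation
    of poorly expressed transcripts (TPM >= 5 required by default).
    """

    window_w: int = 100
    step: int = 50
    min_cov: float = 1.0
    cov_fraction: float = 0.2
    extension_limit: int = 5000
    min_delta: int = 50
    tpm_truncation_gate: float = 5.0

    def __post_init__(self) -> None:
        if not (self.window_w >= self.step >= 1):
            raise ValueError("need window_w >= step >= 1")
        if not (0 < self.cov_fraction <= 1):
            raise ValueError("cov_fraction must be in (0, 1]")
        if self.extension_limit < 0 or self.min_delta < 0:
            raise ValueError("extension_limit and min_delta must be >= 0")


@dataclass
class ReannotationResult:
    transcript_id: str
    old_distal_end: int
    new_distal_end: int
    outcome: str
    skip_reason: str = "none"
    bases_delta: int = 0

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.skip_reason not in SKIP_REASONS:
            raise ValueError(f"unknown skip_reason {self.skip_reason!r}")


def _skip(model: TranscriptModel, reason: str) -> ReannotationResult:
    old = model.utr3_distal_end() if model.utr3 else -1
    return ReannotationResult(
        transcript_id=model.transcript_id,
        old_distal_end=old,
        new_distal_end=old,
        outcome="skipped",
        skip_reason=reason,
    )


def propose_distal_end(
    model: TranscriptModel,
    track: CoverageTrack,
    params: ReannotationParams,
    chrom_length: int | None = None,
    clip_at: int | None = None,
) -> ReannotationResult:
    """Detect the coverage-supported distal 3'-UTR end for one transcript.

    A coverage vector is oriented 5'->3' over the annotated UTR plus an
    extension margin (``extension_limit`` bases past the annotated end,
    clipped at the chromosome end and at ``clip_at`` — e.g. the nearest
    downstream gene boundary). The proximal reference r is the mean coverage
    of the first window of the annotated UTR; windows of ``window_w`` bases
    at stride ``step`` are accepted while their mean is >= max(min_cov,
    cov_fraction * r), and the scan stops at the first failing window. The
    proposed end is refined to the last base with coverage >= threshold
    inside the final accepted window plus one stride of lookahead, so
    noise-free step edges are recovered exactly.
    """
    if not model.utr3:
        return _skip(model, "no_utr_annotation")
    if len(model.utr3) > 1:
        return _skip(model, "multi_exon_utr")
    utr = model.utr3[0]
    W, step, E = params.window_w, params.step, params.extension_limit
    utr_len = utr.length

    if model.strand == "+":
        anchor = utr.start  # 5' edge
        old_end = utr.end
        region_end = old_end + E
        if chrom_length is not None:
            region_end = min(region_end, chrom_length)
        if clip_at is not None:
            region_end = min(region_end, max(clip_at, old_end))
        vec = track.values(model.chrom, anchor, region_end)
    else:
        anchor = utr.end  # 5' edge (genomically right)
        old_end = utr.start
        region_start = max(0, old_end - E)
        if clip_at is not None:
            region_start = max(region_start, min(clip_at, old_end))
        vec = track.values(model.chrom, region_start, anchor)[::-1]

    ref_span = min(W, utr_len)
    r = float(vec[:ref_span].mean()) if ref_span > 0 else 0.0
    if r <= 0:
        return _skip(model, "no_coverage")
    threshold = max(params.min_cov, params.cov_fraction * r)

    last_pass_start = None
    for start in range(0, len(vec), step):
        window = vec[start:start + W]
        if window.size == 0:
            break
        if float(window.mean()) >= threshold:
            last_pass_start = start
        else:
            break
    if last_pass_start is None:
        # proximal reference itself below the absolute floor: no usable signal
        return _skip(model, "no_coverage")

    # base-level refinement inside the last accepted window (+ one stride)
    hi = min(last_pass_start + W + step, len(vec))
    tail = vec[last_pass_start:hi]
    passing = np.flatnonzero(tail >= threshold)
    if passing.size:
        new_offset = last_pass_start + int(passing[-1]) + 1
    else:
        new_offset = min(last_pass_start + W, len(vec))
    delta = new_offset - utr_len

    if delta > params.min_delta:
        outcome = "extended"
    elif delta < -params.min_delta:
        outcome = "truncated"
    else:
        return ReannotationResult(
            transcript_id=model.transcript_id,
            old_distal_end=old_end,
            new_distal_end=old_end,
            outcome="unchanged",
        )
    new_end = anchor + new_offset if model.strand == "+" else anchor - new_offset
    return ReannotationResult(
        transcript_id=model.transcript_id,
        old_distal_end=old_end,
        new_distal_end=new_end,
        outcome=outcome,
        bases_delta=delta,
    )


def _apply_end(model: TranscriptModel, new_end: int) -> TranscriptModel:
    """Move the distal UTR edge (and terminal exon edge in lockstep)."""
    out = model.copy()
    utr = out.utr3[0]
    if model.strand == "+":
        out.utr3[0] = GenomicInterval(utr.chrom, utr.start, new_end, utr.strand)
        term = out.exons[-1]
        if term.end == utr.end or new_end > term.end:
            out.exons[-1] = GenomicInterval(term.chrom, term.start, new_end, term.strand)
    else:
        out.utr3[0] = GenomicInterval(utr.chrom, new_end, utr.end, utr.strand)
        term = out.exons[0]
        if term.start == utr.start or new_end < term.start:
            out.exons[0] = GenomicInterval(term.chrom, new_end, term.end, term.strand)
    out.validate()
    return out


def apply_reannotations(
    models: list[TranscriptModel],
    results: list[ReannotationResult],
    tpm: dict[str, float],
    params: ReannotationParams,
) -> tuple[list[TranscriptModel], list[ReannotationResult]]:
    """Integrate proposed distal ends under the eligibility rules.

    Multi-exon UTRs and transcripts without a UTR annotation are never
    altered (novel predictions are discarded); the 5' UTR edge is never
    moved; truncations require TPM >= ``tpm_truncation_gate`` (missing
    transcripts count as TPM 0) while extensions are un-gated. Returns the
    updated models plus the final per-transcript results with outcomes
    adjusted for any rule that fired.
    """
    by_tid = {m.transcript_id: m for m in models}
    for res in results:
        if res.transcript_id not in by_tid:
            raise ValueError(f"result references unknown transcript {res.transcript_id}")
    res_by_tid = {r.transcript_id: r for r in results}

    out_models: list[TranscriptModel] = []
    out_results: list[ReannotationResult] = []
    for model in models:
        res = res_by_tid.get(model.transcript_id)
        if res is None:
            out_models.append(model)
            continue
        if not model.utr3:
            final = _skip(model, "no_utr_annotation")
        elif len(model.utr3) > 1:
            final = _skip(model, "multi_exon_utr")
        elif res.outcome in ("skipped", "unchanged"):
            final = res
        elif res.outcome == "truncated" and tpm.get(model.transcript_id, 0.0) < params.tpm_truncation_gate:
            final = _skip(model, "low_expression_truncation")
        else:
            final = res
        if final.outcome in ("extended", "truncated"):
            out_models.append(_apply_end(model, final.new_distal_end))
        else:
            out_models.append(model)
        out_results.append(final)
    return out_models, out_results


def downstream_clip_bounds(models: list[TranscriptModel]) -> dict[str, int]:
    """Per-transcript genomic bound where extension search must stop.

    The bound is the nearest boundary of another gene on the same
    chromosome and strand, downstream of the transcript in transcribed
    sense; extensions never run through a neighbouring gene.
    """
    genes: dict[tuple[str, str, str], tuple[int, int]] = {}
    for m in models:
        key = (m.chrom, m.strand, m.gene_id)
        s, e = m.span
        if key in genes:
            gs, ge = genes[key]
            genes[key] = (min(gs, s), max(ge, e))
        else:
            genes[key] = (s, e)
    bounds: dict[str, int] = {}
    for m in models:
        others = [
            span for (c, st, g), span in genes.items()
            if c == m.chrom and st == m.strand and g != m.gene_id
        ]
        s, e = m.span
        if m.strand == "+":
            cands = [gs for gs, _ge in others if gs >= e]
            if cands:
                bounds[m.transcript_id] = min(cands)
        else:
            cands = [ge for _gs, ge in others if ge <= s]
            if cands:
                bounds[m.transcript_id] = max(cands)
    return bounds


def reannotate(
    models: list[TranscriptModel],
    tracks: list[CoverageTrack],
    tpm: dict[str, float],
    params: ReannotationParams | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[list[TranscriptModel], list[ReannotationResult]]:
    """Full reannotation pass: merge replicates, detect ends, apply rules.

    Non-protein-coding transcripts pass through untouched.
    """
    params = params or ReannotationParams()
    track = merge_replicates(tracks)
    clips = downstream_clip_bounds(models)
    results = []
    for m in models:
        if not m.is_protein_coding:
            continue
        chrom_len = chrom_lengths.get(m.chrom) if chrom_lengths else None
        results.append(
            propose_distal_end(
                m, track, params,
                chrom_length=chrom_len,
                clip_at=clips.get(m.transcript_id),
            )
        )
    return apply_reannotations(models, results, tpm, params)


def report_frame(results: list[ReannotationResult]) -> pd.DataFrame:
    """Tabular reannotation report (one row per transcript)."""
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "outcome": r.outcome,
                "skip_reason": r.skip_reason,
                "old_end": r.old_distal_end,
                "new_end": r.new_distal_end,
                "bases_delta": r.bases_delta,
            }
            for r in results
        ]
    )
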