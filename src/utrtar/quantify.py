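"""Transcript abundance: TPM computation and abundance-table lookups.

TPM (transcripts per million) is the standard length-normalised relative
abundance: rate_i = count_i / eff_length_i, tpm_i = 1e6 * rate_i / sum_j
rate_j. Values over a sample sum to 1e6 and are invariant to uniform
scaling of the counts.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class AbundanceRecord:
    transcript_id: str
    tpm: float
    est_count: float | None = None
    eff_length: float | None = None


def compute_tpm(
    records: list[tuple[str, float, float]],
) -> list[AbundanceRecord]:
    """TPM from (transcript_id, est_count, eff_length) triples.

    Raises if any effective length is non-positive or if every count is
    zero (TPM is then undefined).
    """
    rates = []
    for tid, count, length in records:
        if length <= 0:
            raise ValueError(f"{tid}: non-positive effective length {length}")
        if count < 0:
            raise ValueError(f"{tid}: negative count {count}")
        rates.append(count / length)
    total = math.fsum(rates)
    if total == 0:
        raise ValueError("all counts are zero: TPM undefined")
    return [
        AbundanceRecord(tid, tpm=1e6 * rate / total, est_count=count, eff_length=length)
        for (tid, count, length), rate in zip(records, rates)
    ]


class AbundanceTable:
    """TPM lookups with a conservative default of 0 for unknown transcripts."""

    def __init__(self, records: list[AbundanceRecord]):
        self._by_tid = {r.transcript_id: r for r in records}
        self.missing_lookups = 0

    def __len__(self) -> int:
        return len(self._by_tid)

    def __contains__(self, tid: str) -> bool:
        return tid in self._by_tid

    def record(self, tid: str) -> AbundanceRecord | None:
        return self._by_tid.get(tid)

    def tpm(self, tid: str) -> float:
        rec = self._by_tid.get(tid)
        if rec is None:
            self.missing_lookups += 1
            if self.missing_lookups == 1:
                logger.warning(
                    "TPM lookup for unknown transcript %s: defaulting to 0 "
                    "(further misses counted silently)", tid
                )
            return 0.0
        return rec.tpm

    def as_dict(self) -> dict[str, float]:
        return {tid: r.tpm for tid, r in self._by_tid.items()}

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "transcript_id": r.transcript_id,
                    "est_count": r.est_count,
                    "eff_length": r.eff_length,
                    "tpm": r.tpm,
                }
                for r in self._by_tid.values()
            ]
        ).to_csv(path, sep="\t", index=False)


def read_abundance(path: str | Path) -> AbundanceTable:
    """Load a headered TSV with transcript_id and tpm (counts/lengths optional)."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "tpm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AbundanceRecord(
                transcript_id=str(row.transcript_id),
                tpm=float(row.tpm),
                est_count=float(row.est_count) if "est_count" in df.columns else None,
                eff_length=float(row.eff_length) if "eff_length" in df.columns else None,
            )
        )
    return AbundanceTable(records)


def tpm_from_counts_file(path: str | Path) -> list[AbundanceRecord]:
    """Compute TPM from a TSV with transcript_id, est_count, eff_length."""
    df = pd.read_csv(path, sep="\t")
    missing = {"transcript_id", "est_count", "eff_length"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    triples = [
        (str(r.transcript_id), float(r.est_count), float(r.eff_length))
        for r in df.itertuples(index=False)
    ]
    return compute_tpm(triples)
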