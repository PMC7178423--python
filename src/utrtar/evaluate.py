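"""Benchmarking predictions against miRNA-transfection log2 fold changes.

Groups of transcripts (non-targets, seed targets, expression-filtered
targets, gained/removed targets) are compared through their cumulative
log2 fold-change distributions with one-sided two-sample Kolmogorov-
Smirnov tests. The first sample of a comparison is hypothesised to be
more repressed (stochastically smaller, its CDF above the reference), so
the statistic is d+ = sup_x [F1(x) - F2(x)] and the approximate p-value
is the one-sided asymptotic tail exp(-2 d^2 n1 n2 / (n1 + n2)), capped
at 1.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_NAMES = (
    "non_target",
    "seed_target",
    "filtered_target",
    "gained_target",
    "removed_target",
)


class ECDF:
    """Right-continuous empirical CDF: F(x) = #{v <= x} / n."""

    def __init__(self, values):
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError("ECDF needs at least one value")
        if not np.all(np.isfinite(arr)):
            raise ValueError("ECDF values must be finite")
        self.support = np.sort(arr)
        self.n = arr.size

    def __call__(self, x):
        return np.searchsorted(self.support, x, side="right") / self.n

    def table(self) -> pd.DataFrame:
        """Sorted support with cumulative fractions (for plotting)."""
        xs, counts = np.unique(self.support, return_counts=True)
        return pd.DataFrame({"x": xs, "cdf": np.cumsum(counts) / self.n})


@dataclass(frozen=True)
class KSResult:
    d: float
    p_approx: float
    n1: int
    n2: int
    direction: str = "first_more_repressed"

    def __post_init__(self) -> None:
        if not (0 <= self.d <= 1):
            raise ValueError(f"d out of range: {self.d}")
        if not (0 < self.p_approx <= 1):
            raise ValueError(f"p out of range: {self.p_approx}")


def _one_sided_p(d: float, n1: int, n2: int) -> float:
    return min(1.0, math.exp(-2.0 * d * d * n1 * n2 / (n1 + n2)))


def ks_one_sided(more_repressed, reference) -> KSResult:
    """One-sided two-sample KS test.

    d = sup over the pooled support of F1(x) - F2(x), where F1 is the ECDF
    of the sample hypothesised to be more repressed. d is clipped below at
    0 (the signed supremum is never negative at the pooled maximum, where
    both CDFs reach 1, so the clip only guards floating-point noise).
    """
    f1, f2 = ECDF(more_repressed), ECDF(reference)
    pooled = np.concatenate([f1.support, f2.support])
    d = float(np.max(f1(pooled) - f2(pooled)))
    d = min(1.0, max(0.0, d))
    return KSResult(d=d, p_approx=_one_sided_p(d, f1.n, f2.n), n1=f1.n, n2=f2.n)


def ks_permutation_p(
    more_repressed,
    reference,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for the same one-sided statistic (cross-check).

    Uses the add-one estimator (b + 1) / (n + 1), which is valid and never
    returns 0.
    """
    rng = rng or np.random.default_rng()
    a = np.asarray(more_repressed, dtype=float)
    b = np.asarray(reference, dtype=float)
    observed = ks_one_sided(a, b).d
    pooled = np.concatenate([a, b])
    n1 = a.size
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        d = ks_one_sided(perm[:n1], perm[n1:]).d
        if d >= observed:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def read_fold_changes(path: str | Path) -> dict[str, float]:
    """Load a transcript_id -> log2 fold-change TSV (finite values, unique ids)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"transcript_id", "log2fc"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    if df["transcript_id"].duplicated().any():
        dups = df.loc[df["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise ValueError(f"{path}: duplicate transcript_id (e.g. {dups})")
    if not np.all(np.isfinite(df["log2fc"].to_numpy(dtype=float))):
        raise ValueError(f"{path}: non-finite log2 fold-change values")
    return dict(zip(df["transcript_id"].astype(str), df["log2fc"].astype(float)))


def write_fold_changes(fc: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"transcript_id": list(fc), "log2fc": list(fc.values())}
    ).to_csv(path, sep="\t", index=False)


@dataclass
class BenchmarkRow:
    pair: tuple[str, str]
    ks: KSResult
    group_sizes: dict[str, int]
    cdfs: dict[str, pd.DataFrame]


def benchmark(
    fc: dict[str, float],
    groups: dict[str, set[str]],
    comparisons: list[tuple[str, str]],
) -> list[BenchmarkRow]:
    """KS comparisons between named transcript groups.

    ``groups`` maps a group name to its transcript ids (groups may overlap:
    a transcript can be both a seed target and a filtered target).
    Transcripts missing from the fold-change table are dropped with a
    logged count; a group empty after the join is an error naming it.
    """
    joined: dict[str, np.ndarray] = {}
    for name, tids in groups.items():
        vals = [fc[t] for t in tids if t in fc]
        dropped = len(tids) - len(vals)
        if dropped:
            logger.info("group %s: dropped %d transcripts absent from fold-change table",
                        name, dropped)
        joined[name] = np.asarray(vals, dtype=float)

    rows = []
    for first, second in comparisons:
        for name in (first, second):
            if name not in joined:
                raise ValueError(f"comparison group {name!r} not in assignments")
            if joined[name].size == 0:
                raise ValueError(f"group {name!r} is empty after joining to fold changes")
        ks = ks_one_sided(joined[first], joined[second])
        rows.append(
            BenchmarkRow(
                pair=(first, second),
                ks=ks,
                group_sizes={first: int(joined[first].size),
                             second: int(joined[second].size)},
                cdfs={name: ECDF(joined[name]).table() for name in (first, second)},
            )
        )
    return rows


def benchmark_report(rows: list[BenchmarkRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_more_repressed": r.pair[0],
                "group_reference": r.pair[1],
                "n1": r.ks.n1,
                "n2": r.ks.n2,
                "d": r.ks.d,
                "p_approx": r.ks.p_approx,
            }
            for r in rows
        ]
    )


def plot_cdfs(
    fc: dict[str, float],
    groups: dict[str, set[str]],
    path: str | Path,
    title: str = "Cumulative log2 fold-change distributions",
) -> None:
    """Cumulative distribution plot per group, one curve each."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4))
    palette = {"non_target": "black", "seed_target": "tab:orange",
               "filtered_target": "tab:green", "gained_target": "tab:blue",
               "removed_target": "tab:red"}
    for name, tids in groups.items():
        vals = np.asarray([fc[t] for t in tids if t in fc])
        if vals.size == 0:
            continue
        table = ECDF(vals).table()
        ax.step(table["x"], table["cdf"], where="post",
                label=f"{name} ({vals.size})", color=palette.get(name))
    ax.set_xlabel("log2 fold change (mimic vs control)")
    ax.set_ylabel("cumulative fraction")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
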