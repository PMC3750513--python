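"""Assembly statistics, length histograms and the Ortholog Hit Ratio.

The N-statistic here is the classic assembly definition: sort contigs by
decreasing length and walk down until the cumulative length first reaches the
requested fraction of the total; the contig length at that point is N50 (or
N80, N90...).  The Ortholog Hit Ratio (OHR) measures transcript completeness
as the fraction of a known ortholog's full length covered by a contig's best
hit; because raw OHR is depressed by inter-species divergence, the summary is
restricted to highly conserved hits (identity above a configurable floor,
default 90%, regardless of hit length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bases: int
    mean_length: float
    median_length: float
    n50: int
    n80: int
    n90: int
    longest: int
    n_over_5kb: int
    n_over_10kb: int

    def to_dict(self) -> dict:
        return {
            "number_of_contigs": self.n_contigs,
            "number_of_bases": self.total_bases,
            "average_length_bp": self.mean_length,
            "median_length_bp": self.median_length,
            "N50": self.n50,
            "N80": self.n80,
            "N90": self.n90,
            "longest_contig_bp": self.longest,
            "contigs_over_5kb": self.n_over_5kb,
            "contigs_over_10kb": self.n_over_10kb,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssemblyStats":
        return cls(
            n_contigs=d["number_of_contigs"],
            total_bases=d["number_of_bases"],
            mean_length=d["average_length_bp"],
            median_length=d["median_length_bp"],
            n50=d["N50"],
            n80=d["N80"],
            n90=d["N90"],
            longest=d["longest_contig_bp"],
            n_over_5kb=d["contigs_over_5kb"],
            n_over_10kb=d["contigs_over_10kb"],
        )


@dataclass
class OrthologHit:
    """Best hit of a contig against a known ortholog."""

    contig_id: str
    ortholog_id: str
    identity: float  # percent
    span: int  # aligned residues on the ortholog
    full_length: int  # ortholog full length, residues

    @property
    def ohr(self) -> float:
        # span is capped at the ortholog length so UTR-bearing contigs cannot
        # push the ratio above 1
        return min(self.span, self.full_length) / self.full_length


def n_stat(lengths: Iterable[int], fraction: float) -> int:
    """Length of the contig at which the cumulative (descending-sorted)
    length first reaches ``fraction`` of the total."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("empty length list")
    if arr.min() <= 0:
        raise ValueError("lengths must be positive")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    target = fraction * arr.sum()
    cum = np.cumsum(arr)
    idx = int(np.searchsorted(cum, target, side="left"))
    return int(arr[idx])


def assembly_stats(lengths: Iterable[int]) -> AssemblyStats:
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty assembly")
    return AssemblyStats(
        n_contigs=int(arr.size),
        total_bases=int(arr.sum()),
        mean_length=round(float(arr.mean()), 2),
        median_length=float(np.median(arr)),
        n50=n_stat(arr, 0.5),
        n80=n_stat(arr, 0.8),
        n90=n_stat(arr, 0.9),
        longest=int(arr.max()),
        n_over_5kb=int((arr > 5000).sum()),
        n_over_10kb=int((arr > 10000).sum()),
    )


def length_histogram(lengths: Iterable[int], bin_width: int = 100, start: int = 250) -> pd.Series:
    """Percent of contigs per length bin ([250, 350), [350, 450), ...).

    Bins extend below ``start`` if shorter contigs are present; percentages
    sum to 100.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty length list")
    lo = start
    while lo > arr.min():
        lo -= bin_width
    edges = np.arange(lo, arr.max() + bin_width + 1, bin_width)
    counts, _ = np.histogram(arr, bins=edges)
    pct = 100.0 * counts / arr.size
    index = pd.IntervalIndex.from_breaks(edges, closed="left")
    return pd.Series(pct, index=index, name="pct_contigs")


@dataclass
class OhrSummary:
    mean: float
    median: float
    fraction_below_half: float
    fraction_full_length: float
    n_used: int
    n_filtered_out: int


def ohr_summary(
    hits: Sequence[OrthologHit],
    min_identity: float = 90.0,
    full_length_threshold: float = 0.9,
) -> OhrSummary:
    """Summarize per-contig OHR over hits with identity > ``min_identity``.

    ``hits`` must hold one best hit per contig.  Raises when nothing survives
    the identity filter.
    """
    used = [h for h in hits if h.identity > min_identity]
    if not used:
        raise ValueError(
            f"no hits above {min_identity}% identity ({len(list(hits))} supplied)"
        )
    ratios = np.array([h.ohr for h in used])
    return OhrSummary(
        mean=float(ratios.mean()),
        median=float(np.median(ratios)),
        fraction_below_half=float((ratios < 0.5).mean()),
        fraction_full_length=float((ratios >= full_length_threshold).mean()),
        n_used=len(used),
        n_filtered_out=len(list(hits)) - len(used),
    )


def hits_from_frame(df: pd.DataFrame) -> list[OrthologHit]:
    """Convert a tabular hit file (see :func:`txqc.io.read_hits_tsv`) keeping
    one best hit per query, ranked by identity x span."""
    df = df.copy()
    df["span"] = (df["send"] - df["sstart"]).abs() + 1
    df["score"] = df["identity"] * df["span"]
    best = df.sort_values(["query", "score"], ascending=[True, False]).groupby("query").head(1)
    return [
        OrthologHit(
            contig_id=r["query"],
            ortholog_id=r["subject"],
            identity=float(r["identity"]),
            span=int(r["span"]),
            full_length=int(r["slen"]),
        )
        for _, r in best.iterrows()
    ]
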