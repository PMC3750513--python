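"""Read processing: quality/adapter trimming, length filter, rRNA depletion.

Trimming follows the modified-Mott convention: each base contributes a score
``limit - p`` where ``p = 10^(-Q/10)`` is its error probability, and the
retained region is the contiguous window with the maximum total score.  With
the default limit of 0.05 a base needs Q > 13 to argue for its own retention.
Pairs are kept intact through every filter: when either mate fails, the whole
pair is discarded — the accounting of the final report assumes this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadPair:
    """A sequenced cDNA fragment: two mates with per-base PHRED qualities."""

    id: str
    seq1: str
    qual1: np.ndarray
    seq2: str
    qual2: np.ndarray

    def __post_init__(self):
        self.qual1 = np.asarray(self.qual1, dtype=np.int64)
        self.qual2 = np.asarray(self.qual2, dtype=np.int64)
        for seq, qual, mate in ((self.seq1, self.qual1, 1), (self.seq2, self.qual2, 2)):
            if len(seq) != len(qual):
                raise ValueError(
                    f"{self.id}/{mate}: sequence length {len(seq)} != quality length {len(qual)}"
                )
            if qual.size and qual.min() < 0:
                raise ValueError(f"{self.id}/{mate}: negative PHRED score")


@dataclass
class TrimReport:
    """Per-tissue read accounting mirroring a standard trimming report.

    ``high_quality_reads`` is what survives both trimming and rRNA removal;
    ``pct_rrna`` is expressed relative to the pre-trimming read count.
    """

    reads_before: int
    reads_kept: int
    rrna_reads: int
    mean_length_before: float = 0.0
    median_length_before: float = 0.0
    mean_length_after: float = 0.0
    median_length_after: float = 0.0
    pct_discarded: float = field(init=False)
    pct_rrna: float = field(init=False)
    high_quality_reads: int = field(init=False)

    def __post_init__(self):
        if min(self.reads_before, self.reads_kept, self.rrna_reads) < 0:
            raise ValueError("read counts must be non-negative")
        if self.reads_kept > self.reads_before:
            raise ValueError("reads_kept exceeds reads_before")
        if self.rrna_reads > self.reads_kept:
            raise ValueError("rrna_reads exceeds reads_kept")
        self.high_quality_reads = self.reads_kept - self.rrna_reads
        if self.reads_before:
            self.pct_discarded = round(
                100.0 * (self.reads_before - self.reads_kept) / self.reads_before, 2
            )
            self.pct_rrna = round(100.0 * self.rrna_reads / self.reads_before, 2)
        else:
            self.pct_discarded = 0.0
            self.pct_rrna = 0.0

    def to_dict(self) -> dict:
        return {
            "reads_before": self.reads_before,
            "reads_kept": self.reads_kept,
            "pct_discarded": self.pct_discarded,
            "mean_length_before": self.mean_length_before,
            "median_length_before": self.median_length_before,
            "mean_length_after": self.mean_length_after,
            "median_length_after": self.median_length_after,
            "rrna_reads": self.rrna_reads,
            "pct_rrna": self.pct_rrna,
            "high_quality_reads": self.high_quality_reads,
        }


def trimming_report(reads_before: int, reads_kept: int, rrna_reads: int, **lengths) -> TrimReport:
    """Build a validated :class:`TrimReport` from raw counts."""
    return TrimReport(reads_before=reads_before, reads_kept=reads_kept, rrna_reads=rrna_reads, **lengths)


def remove_adapter(
    seq: str,
    qual: np.ndarray,
    adapters: Sequence[str],
    min_overlap: int = 8,
    max_mismatch_frac: float = 0.10,
) -> tuple[str, np.ndarray]:
    """Clip a 3' adapter by suffix-overlap matching.

    The leftmost position where the adapter 5' end overlaps the read 3' end
    with an exact ``min_overlap``-bp seed and at most ``max_mismatch_frac``
    mismatches over the whole overlap wins; everything from that position on
    is removed.
    """
    best_cut = len(seq)
    for adapter in adapters:
        seed = adapter[:min_overlap]
        start = seq.find(seed)
        while 0 <= start < best_cut:
            ov = min(len(seq) - start, len(adapter))
            if ov >= min_overlap:
                mismatches = sum(a != b for a, b in zip(seq[start : start + ov], adapter[:ov]))
                if mismatches <= int(max_mismatch_frac * ov):
                    best_cut = start
                    break
            start = seq.find(seed, start + 1)
    return seq[:best_cut], qual[:best_cut]


def mott_window(qual: np.ndarray, quality_limit: float = 0.05) -> tuple[int, int]:
    """Best-scoring retention window ``[i, j)`` under the modified-Mott score.

    Ties are broken toward the leftmost start, then the longest window.
    Returns ``(0, 0)`` when no window has a positive score.
    """
    qual = np.asarray(qual, dtype=np.float64)
    if qual.size == 0:
        return (0, 0)
    p = np.power(10.0, -qual / 10.0)
    s = quality_limit - p
    cum = np.concatenate(([0.0], np.cumsum(s)))
    minpre = np.minimum.accumulate(cum[:-1])
    end_scores = cum[1:] - minpre
    m = end_scores.max()
    if m <= 0:
        return (0, 0)
    s_list = s.tolist()
    best = None  # (score, -i, j)
    for j in (np.nonzero(end_scores >= m - 1e-9)[0] + 1):
        pre = cum[:j]
        mn = pre.min()
        for i in np.nonzero(pre <= mn + 1e-9)[0]:
            score = sum(s_list[i:j])  # exact left-to-right recompute for tie stability
            key = (score, -i, j)
            if best is None or key > best:
                best = key
    _, neg_i, j = best
    return (-neg_i, int(j))


def trim_read(
    seq: str,
    qual: np.ndarray,
    quality_limit: float = 0.05,
    adapters: Sequence[str] = (),
) -> tuple[str, np.ndarray]:
    """Adapter-clip then quality-trim one read; may return an empty read."""
    qual = np.asarray(qual, dtype=np.int64)
    if len(seq) != len(qual):
        raise ValueError("sequence and quality lengths differ")
    if qual.size and qual.min() < 0:
        raise ValueError("negative PHRED score in quality string")
    if adapters:
        seq, qual = remove_adapter(seq, qual, adapters)
    i, j = mott_window(qual, quality_limit)
    return seq[i:j], qual[i:j]


def trim_pairs(
    pairs: Iterable[ReadPair],
    quality_limit: float = 0.05,
    adapters: Sequence[str] = (),
) -> list[ReadPair]:
    out = []
    for p in pairs:
        s1, q1 = trim_read(p.seq1, p.qual1, quality_limit, adapters)
        s2, q2 = trim_read(p.seq2, p.qual2, quality_limit, adapters)
        out.append(ReadPair(id=p.id, seq1=s1, qual1=q1, seq2=s2, qual2=q2))
    return out


def filter_pairs(pairs: Iterable[ReadPair], min_length: int = 75) -> tuple[list[ReadPair], int]:
    """Keep pairs where *both* mates are at least ``min_length`` bp."""
    kept, discarded = [], 0
    for p in pairs:
        if len(p.seq1) >= min_length and len(p.seq2) >= min_length:
            kept.append(p)
        else:
            discarded += 1
    return kept, discarded


def _reference_kmers(reference: Iterable[str], k: int) -> set[str]:
    kmers: set[str] = set()
    for seq in reference:
        seq = seq.upper()
        rc = _revcomp(seq)
        for s in (seq, rc):
            for i in range(len(s) - k + 1):
                kmers.add(s[i : i + k])
    return kmers


def filter_reference_reads(
    pairs: Iterable[ReadPair],
    reference: Iterable[str] | dict[str, str],
    k: int = 21,
    min_shared_fraction: float = 0.5,
) -> tuple[list[ReadPair], int]:
    """Remove pairs matching a reference set by k-mer containment.

    A pair is removed when either mate shares at least ``min_shared_fraction``
    of its k-mers with the reference (both strands indexed).  Used for rRNA
    depletion; the same machinery estimates e.g. the mitochondrial fraction.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if isinstance(reference, dict):
        reference = reference.values()
    ref_kmers = _reference_kmers(reference, k)
    if not ref_kmers:
        raise ValueError("empty reference")
    kept, removed = [], 0
    for p in pairs:
        hit = False
        for seq in (p.seq1, p.seq2):
            n = len(seq) - k + 1
            if n <= 0:
                continue
            shared = sum(1 for i in range(n) if seq[i : i + k] in ref_kmers)
            if shared >= min_shared_fraction * n:
                hit = True
                break
        if hit:
            removed += 1
        else:
            kept.append(p)
    return kept, removed


def process_reads(
    pairs: Sequence[ReadPair],
    rrna_reference: Iterable[str] | dict[str, str],
    quality_limit: float = 0.05,
    min_length: int = 75,
    adapters: Sequence[str] = (),
    k: int = 21,
    min_shared_fraction: float = 0.5,
) -> tuple[list[ReadPair], TrimReport]:
    """Full preprocessing: trim -> length filter -> rRNA depletion -> report."""
    lens_before = [len(p.seq1) for p in pairs] + [len(p.seq2) for p in pairs]
    trimmed = trim_pairs(pairs, quality_limit, adapters)
    long_enough, _ = filter_pairs(trimmed, min_length)
    kept, removed = filter_reference_reads(long_enough, rrna_reference, k, min_shared_fraction)
    lens_after = [len(p.seq1) for p in kept] + [len(p.seq2) for p in kept]
    report = TrimReport(
        reads_before=2 * len(pairs),
        # mirror the original accounting: rRNA reads are part of the kept set
        reads_kept=2 * len(long_enough),
        rrna_reads=2 * removed,
        mean_length_before=round(float(np.mean(lens_before)), 2) if lens_before else 0.0,
        median_length_before=float(np.median(lens_before)) if lens_before else 0.0,
        mean_length_after=round(float(np.mean(lens_after)), 2) if lens_after else 0.0,
        median_length_after=float(np.median(lens_after)) if lens_after else 0.0,
    )
    if not kept:
        warnings.warn("no read pairs survived preprocessing")
    return kept, report
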