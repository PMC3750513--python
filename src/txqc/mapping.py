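"""Paired-end read mapping with counted / non-specific / broken / unmapped accounting.

The mapper reproduces the threshold contract of the original RNA-seq mapping:
a mate alignment *qualifies* when its aligned length is at least
``length_fraction`` of the read and its identity over the aligned region is at
least ``similarity``; a fragment (read pair) is *counted* when both mates
qualify on the same contig as a proper pair — opposite strands, outer distance
within ``insert_range``.  Fragments with more than one equal-best target are
counted as non-specific and assigned to one target uniformly at random under
the run seed; fragments where only one mate qualifies (or the geometry is
improper) are broken pairs.

Search is k-mer seeding followed by banded glocal (infix) alignment with
edlib; when the full read fails, its ``length_fraction``-long prefix and
suffix are tried, which implements the aligned-length floor for reads with a
bad end.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from txqc.reads import ReadPair

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MateAlignment:
    contig: str
    strand: int  # +1: read aligns forward; -1: reverse complement aligns
    start: int  # 0-based half-open interval on the contig
    end: int
    similarity: float
    aligned_len: int  # query bases aligned


@dataclass
class FragmentMapping:
    """Outcome for one read pair."""

    fragment_id: str
    status: str  # counted_unique | counted_nonspecific | broken_pair | unmapped
    contig: str | None = None
    mate1: MateAlignment | None = None
    mate2: MateAlignment | None = None
    similarity: float = 0.0
    equal_best: int = 0


@dataclass
class MappingSummary:
    """Fragment and read accounting plus per-contig tallies.

    Invariants (checked by :meth:`validate`): counted + uncounted equals the
    fragment total; reads_in_pairs = 2 x counted; reads_in_pairs +
    reads_broken + reads_unmapped equals the read total.
    """

    total_fragments: int = 0
    counted_total: int = 0
    counted_unique: int = 0
    counted_nonspecific: int = 0
    reads_broken: int = 0
    reads_unmapped: int = 0
    contig_lengths: dict[str, int] = field(default_factory=dict)
    fragment_counts: Counter = field(default_factory=Counter)
    aligned_bases: Counter = field(default_factory=Counter)

    @property
    def uncounted(self) -> int:
        return self.total_fragments - self.counted_total

    @property
    def reads_in_pairs(self) -> int:
        return 2 * self.counted_total

    @property
    def total_reads(self) -> int:
        return 2 * self.total_fragments

    def pct(self, value: int, denom: int) -> float:
        return round(100.0 * value / denom, 2) if denom else 0.0

    def validate(self) -> None:
        assert self.counted_unique + self.counted_nonspecific == self.counted_total
        assert self.counted_total + self.uncounted == self.total_fragments
        assert self.reads_in_pairs + self.reads_broken + self.reads_unmapped == self.total_reads

    def to_dict(self) -> dict:
        return {
            "counted_fragments": self.counted_total,
            "pct_counted_fragments": self.pct(self.counted_total, self.total_fragments),
            "counted_uniquely": self.counted_unique,
            "counted_nonspecifically": self.counted_nonspecific,
            "uncounted_fragments": self.uncounted,
            "reads_mapped_in_pairs": self.reads_in_pairs,
            "reads_mapped_in_broken_pairs": self.reads_broken,
            "pct_mapped_reads": self.pct(self.reads_in_pairs + self.reads_broken, self.total_reads),
            "reads_not_mapped": self.reads_unmapped,
        }


class ContigIndex:
    """Sampled k-mer index over a contig set for seed-and-extend mapping."""

    def __init__(
        self,
        contigs: Mapping[str, str],
        k: int = 15,
        step: int = 5,
        max_candidates: int = 20,
    ):
        if not contigs:
            raise ValueError("empty contig set")
        self.seqs = {cid: seq.upper() for cid, seq in contigs.items()}
        self.k = k
        self.step = step
        self.max_candidates = max_candidates
        self._index: dict[str, set[str]] = {}
        for cid, seq in self.seqs.items():
            for i in range(0, max(len(seq) - k, 0) + 1, step):
                self._index.setdefault(seq[i : i + k], set()).add(cid)

    def _candidates(self, query: str) -> list[str]:
        votes: Counter = Counter()
        k = self.k
        qstep = max(1, (k + 1) // 2)  # ensure sampled contig k-mers are hit
        for i in range(0, max(len(query) - k, 0) + 1, qstep):
            for cid in self._index.get(query[i : i + k], ()):
                votes[cid] += 1
        if not votes:
            return []
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        return [cid for cid, _ in ranked[: self.max_candidates]]

    def align_mate(
        self,
        read: str,
        length_fraction: float = 0.75,
        similarity: float = 0.95,
    ) -> list[MateAlignment]:
        """All qualifying alignments of one mate, both strands."""
        read = read.upper()
        if len(read) < self.k:
            return []
        out: list[MateAlignment] = []
        rc = _revcomp(read)
        for strand, q in ((1, read), (-1, rc)):
            for cid in self._candidates(q):
                out.extend(self._align_query(q, cid, strand, length_fraction, similarity))
        return out

    def _align_query(self, q, cid, strand, length_fraction, similarity):
        target = self.seqs[cid]
        pieces = [q]
        min_len = int(np.ceil(length_fraction * len(q)))
        if min_len < len(q):
            pieces.append(q[:min_len])
            pieces.append(q[len(q) - min_len :])
        found: list[MateAlignment] = []
        for piece in pieces:
            max_edits = int(len(piece) * (1.0 - similarity))
            res = edlib.align(piece, target, mode="HW", task="locations", k=max_edits)
            if res["editDistance"] < 0:
                continue
            ident = 1.0 - res["editDistance"] / len(piece)
            if ident < similarity:
                continue
            for loc in res["locations"][:8]:
                start, end = loc[0], loc[1] + 1
                found.append(
                    MateAlignment(
                        contig=cid,
                        strand=strand,
                        start=start,
                        end=end,
                        similarity=round(ident, 4),
                        aligned_len=len(piece),
                    )
                )
            if found:
                break  # full-read alignment preferred over clipped pieces
        return found


def _best_mate(aligns: Sequence[MateAlignment]) -> MateAlignment:
    return max(aligns, key=lambda a: (a.similarity, a.aligned_len, a.contig, -a.start))


def map_pairs(
    pairs: Sequence[ReadPair],
    contigs: Mapping[str, str] | Sequence,
    length_fraction: float = 0.75,
    similarity: float = 0.95,
    insert_range: tuple[int, int] = (100, 350),
    seed: int = 0,
    index: ContigIndex | None = None,
) -> tuple[list[FragmentMapping], MappingSummary]:
    """Map read pairs against a contig set.

    ``contigs`` may be a mapping id -> sequence or a sequence of objects with
    ``id`` and ``sequence`` attributes (duplicate ids are rejected).
    """
    contigs = _as_contig_dict(contigs)
    if index is None:
        index = ContigIndex(contigs)
    rng = np.random.default_rng(seed)
    lo, hi = insert_range
    mappings: list[FragmentMapping] = []
    summary = MappingSummary(contig_lengths={cid: len(s) for cid, s in contigs.items()})

    for pair in pairs:
        a1 = index.align_mate(pair.seq1, length_fraction, similarity)
        a2 = index.align_mate(pair.seq2, length_fraction, similarity)
        combos = _proper_combos(a1, a2, lo, hi)
        summary.total_fragments += 1
        if combos:
            best_key = max((round(m1.similarity + m2.similarity, 4), m1.aligned_len + m2.aligned_len)
                           for m1, m2 in combos)
            best = [(m1, m2) for m1, m2 in combos
                    if (round(m1.similarity + m2.similarity, 4), m1.aligned_len + m2.aligned_len) == best_key]
            best_contigs = sorted({m1.contig for m1, _ in best})
            if len(best_contigs) == 1:
                status, chosen_contig = "counted_unique", best_contigs[0]
                summary.counted_unique += 1
            else:
                status = "counted_nonspecific"
                chosen_contig = best_contigs[int(rng.integers(len(best_contigs)))]
                summary.counted_nonspecific += 1
            summary.counted_total += 1
            m1, m2 = next((c1, c2) for c1, c2 in best if c1.contig == chosen_contig)
            summary.fragment_counts[chosen_contig] += 1
            summary.aligned_bases[chosen_contig] += m1.aligned_len + m2.aligned_len
            mappings.append(
                FragmentMapping(
                    fragment_id=pair.id,
                    status=status,
                    contig=chosen_contig,
                    mate1=m1,
                    mate2=m2,
                    similarity=round((m1.similarity + m2.similarity) / 2, 4),
                    equal_best=len(best_contigs),
                )
            )
        elif a1 or a2:
            m1 = _best_mate(a1) if a1 else None
            m2 = _best_mate(a2) if a2 else None
            for m in (m1, m2):
                if m is not None:
                    summary.reads_broken += 1
                    summary.aligned_bases[m.contig] += m.aligned_len
                else:
                    summary.reads_unmapped += 1
            mappings.append(
                FragmentMapping(
                    fragment_id=pair.id,
                    status="broken_pair",
                    contig=(m1 or m2).contig,
                    mate1=m1,
                    mate2=m2,
                    similarity=(m1 or m2).similarity,
                    equal_best=0,
                )
            )
        else:
            summary.reads_unmapped += 2
            mappings.append(FragmentMapping(fragment_id=pair.id, status="unmapped"))

    summary.validate()
    return mappings, summary


def _proper_combos(a1, a2, lo, hi):
    by_contig: dict[str, tuple[list, list]] = {}
    for m in a1:
        by_contig.setdefault(m.contig, ([], []))[0].append(m)
    for m in a2:
        by_contig.setdefault(m.contig, ([], []))[1].append(m)
    combos = []
    for cid, (m1s, m2s) in by_contig.items():
        for m1 in m1s:
            for m2 in m2s:
                if m1.strand == m2.strand:
                    continue
                fwd, rev = (m1, m2) if m1.strand == 1 else (m2, m1)
                if fwd.start > rev.start:
                    continue
                insert = rev.end - fwd.start  # outer distance, inclusive bounds
                if lo <= insert <= hi:
                    combos.append((m1, m2))
    return combos


def _as_contig_dict(contigs) -> dict[str, str]:
    if isinstance(contigs, Mapping):
        d = dict(contigs)
    else:
        d = {}
        for c in contigs:
            if c.id in d:
                raise ValueError(f"duplicate contig id: {c.id}")
            d[c.id] = c.sequence
    if not d:
        raise ValueError("empty contig set")
    return d


def redundancy_pct(summary: MappingSummary) -> float:
    """Percent of counted fragments mapping non-specifically.

    Broken pairs are excluded from both numerator and denominator.
    """
    if summary.counted_total == 0:
        raise ValueError("redundancy undefined: no counted fragments")
    return 100.0 * summary.counted_nonspecific / summary.counted_total


def average_coverage(summary: MappingSummary, contig: str) -> float:
    """Total aligned bases on a contig divided by its length (fold coverage)."""
    if contig not in summary.contig_lengths:
        raise KeyError(f"unknown contig: {contig}")
    length = summary.contig_lengths[contig]
    if length <= 0:
        raise ValueError(f"contig {contig} has non-positive length")
    return summary.aligned_bases.get(contig, 0) / length


def reference_fraction(
    pairs: Sequence[ReadPair],
    reference: Mapping[str, str],
    length_fraction: float = 0.75,
    similarity: float = 0.95,
) -> float:
    """Percent of individual reads with a qualifying alignment on a reference set."""
    index = ContigIndex(dict(reference))
    total = 0
    hits = 0
    for pair in pairs:
        for seq in (pair.seq1, pair.seq2):
            total += 1
            if index.align_mate(seq, length_fraction, similarity):
                hits += 1
    return 100.0 * hits / total if total else 0.0
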