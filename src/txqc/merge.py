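"""Dual-assembly integration and filtering.

Implements the combined assembly strategy: keep the longest isoform per gene
from the primary (graph-based) assembly, collapse residual redundancy,
select protein-coding candidates from the secondary assembly by open reading
frame length, replace primary contigs with matching-but-significantly-longer
candidates, and finally drop contigs with low read coverage or short length.
Each stage records its counts in a :class:`MergeAudit` so that
kept + discarded = input everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_STOPS = {"TAA", "TAG", "TGA"}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Contig:
    id: str
    sequence: str
    source: str = "primary_assembly"
    gene_id: str | None = None
    average_coverage: float | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MergeAudit:
    stage_counts: dict[str, int] = field(default_factory=dict)
    replaced: dict[str, str] = field(default_factory=dict)  # primary id -> candidate id
    discarded_candidates: list[str] = field(default_factory=list)

    def record(self, stage: str, count: int) -> None:
        self.stage_counts[stage] = count

    def to_dict(self) -> dict:
        return {
            "stage_counts": dict(self.stage_counts),
            "replaced": dict(self.replaced),
            "discarded_candidates": list(self.discarded_candidates),
        }


def longest_isoform_per_gene(contigs: Sequence[Contig]) -> list[Contig]:
    """One contig per gene id: the longest (ties -> lexicographically smallest id).

    Contigs without a gene id pass through untouched.
    """
    by_gene: dict[str, Contig] = {}
    passthrough: list[Contig] = []
    for c in contigs:
        if c.gene_id is None:
            passthrough.append(c)
            continue
        cur = by_gene.get(c.gene_id)
        if cur is None or (len(c), _NegStr(c.id)) > (len(cur), _NegStr(cur.id)):
            by_gene[c.gene_id] = c
    kept = list(by_gene.values()) + passthrough
    kept.sort(key=lambda c: c.id)
    return kept


class _NegStr(str):
    """String with reversed ordering, for 'longest then smallest id' keys."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def _identity_within(query: str, target: str, min_identity: float, min_fraction: float) -> float:
    """Best identity of ``query`` (or a ``min_fraction`` end piece) inside ``target``.

    Returns identity weighted by the aligned fraction of the query, or 0.0
    when nothing qualifies.  Both strands are tried.
    """
    n = len(query)
    pieces = [(query, 1.0)]
    if min_fraction < 1.0:
        m = max(1, int(n * min_fraction))
        pieces += [(query[:m], min_fraction), (query[n - m :], min_fraction)]
    best = 0.0
    for q, frac in pieces:
        max_edits = int(len(q) * (1.0 - min_identity)) + 1
        for qq in (q, _revcomp(q)):
            res = edlib.align(qq, target, mode="HW", task="distance", k=max_edits)
            if res["editDistance"] < 0:
                continue
            ident = 1.0 - res["editDistance"] / len(q)
            if ident >= min_identity:
                best = max(best, ident * frac)
        if best:
            break  # full-length match beats any piece
    return best


def _shared_kmer_prefilter(seqs: dict[str, str], k: int = 21, step: int = 10):
    """Map sampled k-mers (both strands) -> contig ids, for all-vs-all pruning."""
    index: dict[str, set[str]] = {}
    for cid, seq in seqs.items():
        for s in (seq, _revcomp(seq)):
            for i in range(0, max(len(s) - k, 0) + 1, step):
                index.setdefault(s[i : i + k], set()).add(cid)
    return index


def collapse_redundant(
    contigs: Sequence[Contig],
    min_identity: float = 0.95,
    min_containment: float = 0.90,
) -> list[Contig]:
    """Remove contigs contained in a longer survivor at high identity.

    Processing is longest-first, so the output is a non-redundant set: a
    contig is dropped iff it aligns to an already-accepted (longer, or
    equal-length with smaller id) contig with identity >= ``min_identity``
    over >= ``min_containment`` of its own length.
    """
    ordered = sorted(contigs, key=lambda c: (-len(c), c.id))
    survivors: list[Contig] = []
    surv_index: dict[str, set[str]] = {}
    surv_seqs: dict[str, str] = {}
    k, step = 21, 10
    for c in ordered:
        votes: dict[str, int] = {}
        for i in range(0, max(len(c.sequence) - k, 0) + 1, step):
            for sid in surv_index.get(c.sequence[i : i + k], ()):
                votes[sid] = votes.get(sid, 0) + 1
        redundant = False
        for sid in sorted(votes, key=lambda s: -votes[s]):
            if _identity_within(c.sequence, surv_seqs[sid], min_identity, min_containment) > 0:
                redundant = True
                break
        if not redundant:
            survivors.append(c)
            surv_seqs[c.id] = c.sequence
            for s in (c.sequence, _revcomp(c.sequence)):
                for i in range(0, max(len(s) - k, 0) + 1, step):
                    surv_index.setdefault(s[i : i + k], set()).add(c.id)
    survivors.sort(key=lambda c: c.id)
    return survivors


def longest_orf_codons(seq: str) -> int:
    """Longest stop-free codon run over all six reading frames (stop-to-stop;
    an internal start codon is not required)."""
    best = 0
    for s in (seq.upper(), _revcomp(seq.upper())):
        for frame in range(3):
            run = 0
            for i in range(frame, len(s) - 2, 3):
                if s[i : i + 3] in _STOPS:
                    best = max(best, run)
                    run = 0
                else:
                    run += 1
            best = max(best, run)
    return best


def select_coding_candidates(contigs: Sequence[Contig], min_orf_codons: int = 100) -> list[Contig]:
    """Keep contigs with a >= ``min_orf_codons`` open reading frame."""
    return [c for c in contigs if longest_orf_codons(c.sequence) >= min_orf_codons]


def integrate_assemblies(
    primary: Sequence[Contig],
    candidates: Sequence[Contig],
    min_identity: float = 0.95,
    min_overlap_fraction: float = 0.5,
    longer_margin: float = 1.10,
) -> tuple[list[Contig], MergeAudit]:
    """Replace primary contigs with matching, significantly longer candidates.

    A candidate C replaces a primary P iff P aligns within C at identity >=
    ``min_identity`` over >= ``min_overlap_fraction`` of P, and
    len(C) >= ``longer_margin`` * len(P).  Each candidate is assigned to its
    single best-scoring primary; each primary takes its single best candidate
    (highest alignment score, then longest).  Remaining candidates are
    discarded.  The replacement is stored in the orientation of P.
    """
    audit = MergeAudit()
    audit.record("primary_input", len(primary))
    audit.record("candidate_input", len(candidates))

    prim_by_id = {p.id: p for p in primary}
    prim_index = _shared_kmer_prefilter({p.id: p.sequence for p in primary})

    # candidate -> best qualifying primary
    cand_best: dict[str, tuple[float, str]] = {}
    for c in candidates:
        votes: dict[str, int] = {}
        for s in (c.sequence, _revcomp(c.sequence)):
            for i in range(0, max(len(s) - 21, 0) + 1, 10):
                for pid in prim_index.get(s[i : i + 21], ()):
                    votes[pid] = votes.get(pid, 0) + 1
        best: tuple[float, str] | None = None
        for pid in sorted(votes, key=lambda p: -votes[p]):
            p = prim_by_id[pid]
            if len(c) < longer_margin * len(p):
                continue
            score = _identity_within(p.sequence, c.sequence, min_identity, min_overlap_fraction)
            if score > 0:
                key = (score * len(p), pid)
                if best is None or key[0] > best[0]:
                    best = key
        if best is not None:
            cand_best[c.id] = best

    # primary -> best candidate among those that chose it
    prim_best: dict[str, tuple[float, int, str]] = {}
    for cid, (score, pid) in cand_best.items():
        clen = len(next(c for c in candidates if c.id == cid))
        key = (score, clen, cid)
        if pid not in prim_best or key > prim_best[pid]:
            prim_best[pid] = key

    cand_by_id = {c.id: c for c in candidates}
    merged: list[Contig] = []
    for p in primary:
        if p.id in prim_best:
            cid = prim_best[p.id][2]
            cand = cand_by_id[cid]
            seq = cand.sequence
            if _orientation_mismatch(p.sequence, seq, min_identity):
                seq = _revcomp(seq)
            merged.append(
                Contig(id=cand.id, sequence=seq, source="secondary_assembly", gene_id=p.gene_id)
            )
            audit.replaced[p.id] = cand.id
        else:
            merged.append(p)
    used = set(audit.replaced.values())
    audit.discarded_candidates = sorted(c.id for c in candidates if c.id not in used)
    audit.record("merged", len(merged))
    audit.record("candidates_used", len(used))
    audit.record("candidates_discarded", len(audit.discarded_candidates))
    return merged, audit


def _orientation_mismatch(primary_seq: str, cand_seq: str, min_identity: float) -> bool:
    """True when the primary matches the candidate only on the reverse strand."""
    max_edits = int(len(primary_seq) * (1.0 - min_identity)) + 1
    fwd = edlib.align(primary_seq, cand_seq, mode="HW", task="distance", k=max_edits)["editDistance"]
    rev = edlib.align(_revcomp(primary_seq), cand_seq, mode="HW", task="distance", k=max_edits)[
        "editDistance"
    ]
    if fwd < 0 and rev >= 0:
        return True
    if fwd >= 0 and rev >= 0:
        return rev < fwd
    return False


def coverage_length_filter(
    contigs: Sequence[Contig],
    coverage: dict[str, float] | None = None,
    min_avg_coverage: float = 5.0,
    min_length_bp: int = 250,
) -> list[Contig]:
    """Keep contigs with average coverage >= 5x and length >= 250 bp (inclusive).

    Coverage comes from ``coverage`` or from ``contig.average_coverage``;
    a contig with neither raises.
    """
    kept = []
    for c in contigs:
        cov = coverage.get(c.id) if coverage is not None else c.average_coverage
        if cov is None:
            raise ValueError(f"no coverage available for contig {c.id}")
        if cov >= min_avg_coverage and len(c) >= min_length_bp:
            kept.append(c)
    return kept
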