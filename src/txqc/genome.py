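"""Fragment classification against gene models: exon / intron / junctions.

Counted fragments are placed into exactly one category with the precedence
exon-exon junction > exon > exon-intron junction > intron > intergenic:
a mate whose alignment blocks span two exons of one gene is a junction
fragment (counted within exons); a mate with a block straddling an
exon-intron boundary counts within introns.  A fragment takes the highest-
precedence category of its two mates.  Classification is positional
(strand-agnostic): a minus-strand gene classifies fragments by genome
coordinates all the same.

Gene-model coordinates are 1-based inclusive as read from GFF3; alignment
blocks are 0-based half-open internally.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from txqc.mapping import ContigIndex, MappingSummary, map_pairs
from txqc.reads import ReadPair

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

CATEGORY_PRECEDENCE = {
    "exon_exon_junction": 4,
    "exon": 3,
    "exon_intron_junction": 2,
    "intron": 1,
    "intergenic": 0,
}


@dataclass
class GeneModel:
    gene_id: str
    scaffold: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted, non-overlapping
    transcript_id: str | None = None

    def __post_init__(self):
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model without exons")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]


def spliced_transcript(genome: Mapping[str, str], model: GeneModel) -> str:
    """Extract the mature transcript: concatenated exons, reverse-complemented
    for minus-strand models."""
    scaffold = genome[model.scaffold]
    seq = "".join(scaffold[s - 1 : e] for s, e in model.exons)
    if model.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def project_to_genome(model: GeneModel, start: int, end: int) -> list[tuple[int, int]]:
    """Project a transcript-coordinate interval (0-based half-open) onto genome
    blocks (0-based half-open), honouring strand."""
    exon_lens = [e - s + 1 for s, e in model.exons]
    tlen = sum(exon_lens)
    if not (0 <= start < end <= tlen):
        raise ValueError(f"interval ({start},{end}) outside transcript of length {tlen}")
    if model.strand == "-":
        start, end = tlen - end, tlen - start
    blocks = []
    offset = 0
    for (gs, ge), elen in zip(model.exons, exon_lens):
        lo = max(start, offset)
        hi = min(end, offset + elen)
        if lo < hi:
            blocks.append((gs - 1 + (lo - offset), gs - 1 + (hi - offset)))
        offset += elen
    return blocks


class GenomeAnnotation:
    """Interval lookup over gene models, per scaffold."""

    def __init__(self, models: Sequence[GeneModel]):
        self.models = list(models)
        self._by_scaffold: dict[str, list[GeneModel]] = {}
        for m in self.models:
            self._by_scaffold.setdefault(m.scaffold, []).append(m)
        self._starts: dict[str, list[int]] = {}
        for sc, ms in self._by_scaffold.items():
            ms.sort(key=lambda m: m.span)
            self._starts[sc] = [m.span[0] for m in ms]

    def overlapping(self, scaffold: str, start: int, end: int) -> list[GeneModel]:
        """Gene models overlapping a 0-based half-open genome interval."""
        ms = self._by_scaffold.get(scaffold, [])
        if not ms:
            return []
        lo1, hi1 = start + 1, end  # to 1-based inclusive
        i = bisect_right(self._starts[scaffold], hi1)
        out = []
        for m in ms[:i]:
            gs, ge = m.span
            if ge >= lo1 and gs <= hi1:
                out.append(m)
        return out


def _classify_mate(blocks: Sequence[tuple[int, int]], genes: Sequence[GeneModel]) -> str:
    best = "intergenic"

    def consider(cat):
        nonlocal best
        if CATEGORY_PRECEDENCE[cat] > CATEGORY_PRECEDENCE[best]:
            best = cat

    for gene in genes:
        touched_exons: set[int] = set()
        straddles = False
        all_in_exons = True
        all_in_introns = True
        any_overlap = False
        for b0, b1 in blocks:
            lo, hi = b0 + 1, b1  # 1-based inclusive
            in_exon = False
            for idx, (es, ee) in enumerate(gene.exons):
                if lo >= es and hi <= ee:
                    in_exon = True
                    touched_exons.add(idx)
                    break
                if hi >= es and lo <= ee:  # partial overlap with this exon
                    any_overlap = True
                    straddles = True
            in_intron = any(lo >= s and hi <= e for s, e in gene.introns)
            if in_exon:
                any_overlap = True
                all_in_introns = False
            elif in_intron:
                any_overlap = True
                all_in_exons = False
            else:
                all_in_exons = False
                if not straddles:
                    all_in_introns = False
        if not any_overlap:
            continue
        if len(touched_exons) >= 2:
            consider("exon_exon_junction")
        elif all_in_exons and touched_exons:
            consider("exon")
        elif straddles:
            consider("exon_intron_junction")
        elif all_in_introns:
            consider("intron")
    return best


def classify_fragment(
    mate_blocks: Sequence[Sequence[tuple[int, int]]],
    annotation: GenomeAnnotation | Sequence[GeneModel],
    scaffold: str,
) -> str:
    """Category of a fragment from its mates' genome alignment blocks.

    ``mate_blocks`` holds one block list per aligned mate (one or two),
    each block 0-based half-open on a single scaffold.  The fragment takes
    the highest-precedence category over its mates.
    """
    if not isinstance(annotation, GenomeAnnotation):
        annotation = GenomeAnnotation(list(annotation))
    best = "intergenic"
    for blocks in mate_blocks:
        if not blocks:
            continue
        lo = min(b[0] for b in blocks)
        hi = max(b[1] for b in blocks)
        genes = annotation.overlapping(scaffold, lo, hi)
        cat = _classify_mate(blocks, genes)
        if CATEGORY_PRECEDENCE[cat] > CATEGORY_PRECEDENCE[best]:
            best = cat
    return best


@dataclass
class GenomeMappingReport:
    """Mapping-on-genome accounting in the shape of the study's genome table."""

    counted_fragments: int
    uncounted_fragments: int
    reads_in_pairs: int
    reads_broken: int
    reads_unmapped_genes: int
    frag_exon_exon_junction: int
    frag_exon_intron_junction: int
    frag_exon_total: int
    frag_intron_total: int
    genes_expressed: int
    genes_annotated: int
    reads_on_scaffolds: int
    reads_outside_genes: int
    reads_unmapped_genome: int

    def __post_init__(self):
        if self.frag_exon_total + self.frag_intron_total != self.counted_fragments:
            raise ValueError("exon + intron fragment totals must equal counted fragments")
        if self.frag_exon_exon_junction > self.frag_exon_total:
            raise ValueError("junction count exceeds exon total")
        if self.frag_exon_intron_junction > self.frag_intron_total:
            raise ValueError("exon-intron junction count exceeds intron total")

    def to_dict(self) -> dict:
        total_frag = self.counted_fragments + self.uncounted_fragments
        total_reads = 2 * total_frag

        def pct(x, d):
            return round(100.0 * x / d, 2) if d else 0.0

        return {
            "counted_fragments": self.counted_fragments,
            "pct_counted_fragments": pct(self.counted_fragments, total_frag),
            "uncounted_fragments": self.uncounted_fragments,
            "reads_mapped_in_pairs": self.reads_in_pairs,
            "reads_mapped_in_broken_pairs": self.reads_broken,
            "pct_reads_broken": pct(self.reads_broken, total_reads),
            "unmapped_reads_genes": self.reads_unmapped_genes,
            "fragments_exon_exon_junctions": self.frag_exon_exon_junction,
            "pct_exon_exon_junctions": pct(self.frag_exon_exon_junction, self.counted_fragments),
            "fragments_exon_intron_junctions": self.frag_exon_intron_junction,
            "pct_exon_intron_junctions": pct(self.frag_exon_intron_junction, self.counted_fragments),
            "fragments_exons_total": self.frag_exon_total,
            "pct_exons_total": pct(self.frag_exon_total, self.counted_fragments),
            "fragments_introns_total": self.frag_intron_total,
            "pct_introns_total": pct(self.frag_intron_total, self.counted_fragments),
            "genes_expressed": self.genes_expressed,
            "pct_genes_expressed": pct(self.genes_expressed, self.genes_annotated),
            "reads_on_scaffolds": self.reads_on_scaffolds,
            "pct_reads_on_scaffolds": pct(self.reads_on_scaffolds, total_reads),
            "reads_outside_annotated_genes": self.reads_outside_genes,
            "pct_reads_outside_annotated_genes": pct(self.reads_outside_genes, total_reads),
            "unmapped_reads_genome": self.reads_unmapped_genome,
            "pct_unmapped_reads_genome": pct(self.reads_unmapped_genome, total_reads),
        }


def genome_mapping_report(
    category_counts: Mapping[str, int],
    total_fragments: int,
    reads_broken: int,
    genes_expressed: int,
    genes_annotated: int,
    reads_on_scaffolds: int = 0,
    reads_outside_genes: int = 0,
    reads_unmapped_genome: int = 0,
) -> GenomeMappingReport:
    """Aggregate per-fragment categories into the genome-mapping table."""
    counts = Counter(category_counts)
    exon_total = counts["exon"] + counts["exon_exon_junction"]
    intron_total = counts["intron"] + counts["exon_intron_junction"]
    counted = exon_total + intron_total
    if counted > total_fragments:
        raise ValueError("category counts exceed total fragments")
    reads_unmapped_genes = 2 * total_fragments - 2 * counted - reads_broken
    return GenomeMappingReport(
        counted_fragments=counted,
        uncounted_fragments=total_fragments - counted,
        reads_in_pairs=2 * counted,
        reads_broken=reads_broken,
        reads_unmapped_genes=reads_unmapped_genes,
        frag_exon_exon_junction=counts["exon_exon_junction"],
        frag_exon_intron_junction=counts["exon_intron_junction"],
        frag_exon_total=exon_total,
        frag_intron_total=intron_total,
        genes_expressed=genes_expressed,
        genes_annotated=genes_annotated,
        reads_on_scaffolds=reads_on_scaffolds,
        reads_outside_genes=reads_outside_genes,
        reads_unmapped_genome=reads_unmapped_genome,
    )


def map_to_genome(
    pairs: Sequence[ReadPair],
    genome: Mapping[str, str],
    models: Sequence[GeneModel],
    length_fraction: float = 0.75,
    similarity: float = 0.95,
    insert_range: tuple[int, int] = (100, 350),
    seed: int = 0,
) -> tuple[GenomeMappingReport, MappingSummary]:
    """Map read pairs onto an annotated genome and classify counted fragments.

    Alignment is transcript-space: reads are mapped against the spliced
    transcripts of the gene models (block-split alignments are therefore
    permitted exactly at annotated exon boundaries) and mate intervals are
    projected back to genome blocks for classification.  Reads of fragments
    not counted on any transcript are then aligned directly against the
    scaffolds: qualifying alignments outside annotated gene spans count as
    expression of non-annotated regions.
    """
    transcripts = {}
    model_by_tid = {}
    for m in models:
        tid = m.transcript_id or f"{m.gene_id}.t1"
        transcripts[tid] = spliced_transcript(genome, m)
        model_by_tid[tid] = m
    mappings, summary = map_pairs(
        pairs, transcripts, length_fraction, similarity, insert_range, seed
    )
    annotation = GenomeAnnotation(models)
    categories: Counter = Counter()
    genes_hit: set[str] = set()
    leftover: list[ReadPair] = []
    pair_by_id = {p.id: p for p in pairs}
    reads_broken = 0
    for fm in mappings:
        if fm.status in ("counted_unique", "counted_nonspecific"):
            model = model_by_tid[fm.contig]
            genes_hit.add(model.gene_id)
            mate_blocks = [
                project_to_genome(model, m.start, m.end) for m in (fm.mate1, fm.mate2)
            ]
            categories[classify_fragment(mate_blocks, annotation, model.scaffold)] += 1
        else:
            if fm.status == "broken_pair":
                reads_broken += sum(1 for m in (fm.mate1, fm.mate2) if m is not None)
            leftover.append(pair_by_id[fm.fragment_id])

    # genome-space rescue of reads from uncounted fragments
    reads_on_scaffolds = 2 * summary.counted_total
    reads_outside = 0
    reads_unmapped_genome = 0
    if leftover:
        gidx = ContigIndex(dict(genome))
        for p in leftover:
            for seq in (p.seq1, p.seq2):
                aligns = gidx.align_mate(seq, length_fraction, similarity)
                if not aligns:
                    reads_unmapped_genome += 1
                    continue
                reads_on_scaffolds += 1
                a = max(aligns, key=lambda x: (x.similarity, x.aligned_len))
                if not annotation.overlapping(a.contig, a.start, a.end):
                    reads_outside += 1

    report = genome_mapping_report(
        categories,
        total_fragments=summary.total_fragments,
        reads_broken=reads_broken,
        genes_expressed=len(genes_hit),
        genes_annotated=len({m.gene_id for m in models}),
        reads_on_scaffolds=reads_on_scaffolds,
        reads_outside_genes=reads_outside,
        reads_unmapped_genome=reads_unmapped_genome,
    )
    return report, summary
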