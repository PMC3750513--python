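# txqc

Post-assembly processing, quality control and quantification for *de novo*
transcriptomes built from short paired-end RNA-seq reads — the computational
backbone of a two-tissue (e.g. liver/testis) transcriptome project on a
non-model organism, implemented as a tested, reusable Python library with a
seeded synthetic-data generator so that every stage can be exercised and
validated without any sequencing download.

## Who this is for

Groups assembling a transcriptome from bulk RNA-seq when no (or only a
related species') genome is available: after the assembler runs, one still
has to trim and deplete the reads, reconcile the outputs of two assemblers,
measure how redundant and how fragmented the contig set is, quantify
expression per tissue, and — when a congener's genome exists — classify the
reads against its gene models and date the divergence between the species.

## What it computes

* **Read processing** (`txqc.reads`) — modified-Mott quality trimming: each
  base scores `limit − p_i` with `p_i = 10^(−Q_i/10)` (default limit 0.05)
  and the retained region is the contiguous window maximising the summed
  score; adapter clipping by suffix overlap; pairs discarded when either
  mate falls under 75 bp; rRNA depletion by k-mer containment (k = 21); a
  full accounting report (`high_quality = kept − rRNA`).
* **Paired-end mapper** (`txqc.mapping`) — a mate qualifies when its aligned
  length is ≥ 0.75 of the read and identity ≥ 0.95; a fragment is *counted*
  when both mates qualify on one contig as a proper pair with outer distance
  in [100, 350] bp; fragments with several equal-best targets are
  *non-specific* (assembly redundancy = non-specific / counted); single
  qualifying mates are *broken pairs*. Average coverage = aligned bases /
  contig length.
* **Assembly integration** (`txqc.merge`) — longest isoform per gene,
  redundancy collapse (≥ 95% identity over ≥ 90% containment), coding
  candidates by a ≥ 100-codon six-frame ORF, replacement of contigs by
  matching candidates ≥ 10% longer, and the final ≥ 5× coverage / ≥ 250 bp
  filter, with conservation audits at every stage.
* **Assembly QC** (`txqc.qc`) — N50/N80/N90 (cumulative length of the
  descending-sorted contigs first reaching the fraction of the total),
  length histograms, and the Ortholog Hit Ratio
  `OHR = hit span / ortholog full length`, summarised over hits with
  identity > 90% to suppress the divergence bias of the raw ratio.
* **Expression** (`txqc.expression`) —
  `FPKM = count / ((length/10³)·(counted/10⁶))`, cumulative richness curves
  (how many transcripts carry 50% of all expression), top-N overlap between
  tissues, and the specificity rule "top-N in one tissue, FPKM < 1 in the
  others".
* **Genome classification** (`txqc.genome`) — counted fragments placed into
  exon / exon–exon junction / intron / exon–intron junction categories
  against GFF3 gene models, with annotated-vs-unannotated read accounting.
* **Divergence dating** (`txqc.divergence`) — substitution rate as p-distance
  per 100 bp over ungapped columns; a calibration interval scaled by the
  focal/calibrator rate ratio gives the divergence time.
* **Synthetic data** (`txqc.simulate`) — seeded generator of genome, gene
  models, spliced transcripts, two-tissue paired FASTQ reads (log-normal
  expression, housekeeping and tissue-specific genes, rRNA contamination,
  adapter read-through, error model encoded in the qualities), corrupted
  assembler outputs and diverged ortholog pairs — with full ground truth.

## Worked example

```bash
python examples/06_molecular_clock.py
```

```
published rates 0.49 vs 8.25 per 100 bp -> divergence 1.9-3.3 Mya
recovered focal rate:      0.525 per 100 bp over 40,000 sites
recovered calibrator rate: 8.195 per 100 bp
rate ratio: 15.6x slower
scaled divergence interval: 2.1-3.6 Mya
```

The first line reproduces the classic two-pair dating: a focal species pair
accumulating 0.49 substitutions per 100 bp against a calibrator pair at 8.25
per 100 bp whose divergence is dated 32.25–56 Mya by fossils; scaling the
interval by the rate ratio places the focal divergence at 1.9–3.3 Mya. The
remaining lines plant the same rates in ~40 kb of synthetic coding sequence
and recover them by counting mismatched ungapped columns — the recovered
interval wobbles around the exact one with the binomial noise of ~200
substitutions.

The other scripts in `examples/` walk the remaining capabilities (simulation,
trimming, assembly integration, mapping/quantification, genome
classification), each printing the numbers it computes and what they mean.

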