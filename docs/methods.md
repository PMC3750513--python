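# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic-data tests do and do not demonstrate.

## Read model and trimming

Reads are 100-cycle paired-end with mates on opposite strands of a cDNA
fragment whose insert length is uniform on [100, 350] bp and whose start is
uniform along the transcript. Sequencing errors are independent per-base
substitutions; the quality string encodes the injected model (Q37 at clean
bases, Q5 at error sites, Q2 on optional randomized 3' tails). This is
deliberately simpler than a machine-specific error profile: position- and
context-dependent error rates, indels and PCR duplicates are not emulated,
so trimming and mapping results on real data will be somewhat worse than on
the synthetic reads.

Quality trimming is the modified-Mott algorithm: with error probability
`p_i = 10^(−Q_i/10)` and limit 0.05 (a base must be better than Q≈13 to
argue for retention), the kept region is the contiguous window maximising
`Σ (limit − p_i)`. Ties are resolved to the leftmost start, then the longest
window; candidate windows within 1e−9 of the optimum are re-scored by direct
left-to-right summation so the choice is stable against floating-point
association. Adapter clipping runs before quality trimming and requires an
exact 8-bp seed plus ≤ 10% mismatches over the suffix overlap. Pairs stay
paired: a pair is dropped when either mate fails the 75-bp floor, and the
report's `high_quality = kept − rRNA` identity assumes exactly this
semantics.

rRNA depletion is k-mer containment (k = 21, both reference strands indexed,
removal when either mate shares ≥ 50% of its k-mers) rather than alignment —
cheaper, and exact on verbatim contamination; heavily diverged rRNA would
need the alignment route (the same machinery doubles as the
mitochondrial-fraction estimator).

## Mapper

The original analysis used a commercial mapper; only its threshold contract
is reproduced: a mate alignment qualifies at aligned length ≥ 0.75 of the
read and identity ≥ 0.95; a fragment is counted when both mates qualify on
the same contig, in forward/reverse orientation, with outer distance within
[100, 350] inclusive. Search is sampled k-mer seeding (k = 15 every 5 bp on
the contig) followed by edlib infix alignment of the whole read; when the
full read fails, its 0.75-length prefix and suffix are tried, implementing
the aligned-length floor for reads with one bad end. Identity is
`1 − edits/aligned query length`. Equal-best targets are those matching the
best (similarity rounded to 1e−4, aligned length); non-specific fragments
are assigned to one equal-best contig uniformly at random under the run
seed — a `fractional` counting mode was considered and rejected to keep
counts integral; the seeded assignment is what the expression tables
consume. Internal coordinates are 0-based half-open; emitted ones 1-based
inclusive. Qualifying mates of broken pairs contribute their aligned bases
to coverage but never to fragment counts.

The test oracle for status assignment is an exhaustive scan: every mate
against every contig and strand with no seeding. The qualifying thresholds
are shared by definition (they are the contract); the independence is in the
search, which is where a seeded mapper can silently miss targets.

## Assembly integration

The merge pipeline mirrors a combined two-assembler strategy: keep the
longest isoform per labelled gene (ties to the smallest id); collapse a
contig into a longer survivor at ≥ 95% identity over ≥ 90% of its length
(longest-first, so the output is non-redundant and the operation
idempotent); select coding candidates from the unlabelled secondary assembly
by a ≥ 100-codon stop-to-stop ORF in any of six frames (an internal ATG is
not required); replace a primary contig with a candidate that matches at
≥ 95% identity over ≥ 50% of the primary and is at least 10% longer
(`longer_margin = 1.10` — "significantly longer" is not defined in the
source analysis, so the margin is exposed as a knob); finally keep contigs
with average coverage ≥ 5× and length ≥ 250 bp (both inclusive). Alignment
everywhere is the same edlib engine, both strands; a replacement matched on
the reverse strand is stored in the orientation of the contig it replaces.
Whether the end-to-end containment of the primary should be required for
replacement is left configurable (`min_overlap_fraction`); the default 0.5
accepts candidates that extend a partially diverged contig.

## QC metrics

N-statistics use the standard definition (first descending-cumulative length
reaching the fraction of the total). The OHR numerator is the alignment span
on the ortholog, capped at the ortholog length, so UTR-bearing contigs
cannot exceed 1; the summary is computed only over hits with identity
strictly above 90%, which corrects the downward bias that inter-species
divergence imposes on the raw ratio. "Assembled to full length" is OHR
≥ 0.9 (configurable). Hits are consumed from a generic six-column table so
any aligner can feed them; the tests generate hits from ground truth rather
than running a protein search.

## Expression

FPKM normalises by contig kilobases and by million *counted* fragments, so
broken pairs never inflate totals. Detection is ≥ 1 counted fragment
(numerically equivalent to FPKM > 0). Top-N ranking breaks ties by (FPKM
desc, count desc, id asc) for determinism. The specificity rule is literal:
in the top-N of one tissue and FPKM < 1.0 in every other tissue supplied.

## Genome classification

Classification is positional and strand-agnostic. Reads are aligned in
transcript space (spliced transcripts built from the gene models), so
block-split alignments occur exactly at annotated exon boundaries, and mate
intervals are projected back to genome blocks; full spliced-alignment
discovery is out of scope. Precedence per mate: exon–exon junction > exon >
exon–intron junction > intron > intergenic; a fragment takes the
highest-precedence category of its mates (mate aggregation is not defined in
the source analysis; precedence keeps the partition exact:
exon + intron totals = counted fragments). Reads of fragments not counted on
any transcript are rescued by direct scaffold alignment and split into
annotated / non-annotated / unmapped.

## Divergence dating

The substitution rate is a raw p-distance per 100 bp over ungapped,
unambiguous columns — no multiple-hit correction by default, because at the
sub-percent divergences targeted the Jukes–Cantor correction
(`−3/4·ln(1−4p/3)`) is far below counting noise; it is available behind a
flag. Dating scales the calibration interval by the focal/calibrator rate
ratio elementwise and rounds to one decimal; the unrounded interval is also
emitted, and a ratio of exactly 1 returns the calibration verbatim.

## Synthetic study conditions

Generator defaults describe the emulated regime: 300 genes (~1.4 isoforms
each, extra isoforms as 5'-exon-prefix truncations), transcript lengths
log-normal around 1.1 kb (clipped 0.3–6 kb) with a planted ORF spanning
~70% so coding selection has signal; ~4 exons per transcript, introns
log-normal around 300 bp; per-gene per-tissue log-normal abundance
(σ = 1.5), 30% housekeeping (shared level), 30% tissue-specific (zero
elsewhere); rRNA contamination 20% of pairs, adapter read-through 3%,
low-quality tails on 10% of first mates, base error 0.5%. Assembly
corruption: 50% of genes duplicated as 2%-mutated copies under fake gene
labels (what an isoform-happy graph assembler emits), 30% fragmented into
exact substrings, 20% truncated to 60% in the primary with a full-length
secondary copy (the replace-with-longer substrate; planted only on genes
long enough that the full copy passes the 100-codon screen, so the
ground-truth audit is exact). Divergence: independent uniform substitutions,
no transition bias, no indels — the estimator counts raw mismatches, so a
biased process with the same rate would give the same answer.

Determinism: every operation draws from a child stream of the config seed
(`default_rng([seed, stream])`); identical (seed, config) gives
byte-identical FASTA/FASTQ/GFF3 output.

## Problem sizes and tolerances

The full desk run — 300 genes, 2 tissues, 50,000 read pairs through
trimming, depletion, integration, two mapping passes, filtering and
quantification — is the size the acceptance script executes (≈ 40 s on one
CPU); the test suite runs the same pipeline once at that size plus smaller
per-module instances. Stochastic recoveries are asserted within 3 binomial
standard errors of the planted parameter at n ≥ 10,000 (rRNA fraction,
error rate, substitution count); FPKM–truth agreement is Spearman ≥ 0.9 at
100k fragments; the OHR mean must come back within 0.01 on
truncation-planted hits. Directional properties (integration strictly
reduces mapper redundancy; N50 never decreases at integration) are asserted
as inequalities, not numeric targets.

## Known limitations

No spliced-alignment discovery, no indel realism in the read simulator, no
isoform-aware quantification (counts are per contig), no protein-space
search for OHR inputs, and the mapper's banded glocal alignment does not
model large structural differences between read and contig. Passing the
synthetic suite shows the bookkeeping, thresholds and estimators are
implemented exactly; it does not certify performance on real libraries with
structured error and bias.
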