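"""Seeded generator of every input the pipeline consumes, with ground truth.

The generator emulates the data regime of a deep two-tissue bulk RNA-seq
study on a non-model vertebrate: 100-cycle paired-end reads from poly-A
selected libraries with ~20% residual rRNA contamination, adapter
read-through on a small fraction of short inserts, low-quality 3' tails,
substitution sequencing errors; two corrupted assembler outputs (a redundant
isoform-rich one and a fragmented but sometimes longer-contig one); and
aligned ortholog pairs diverged at a configurable substitution rate for the
molecular-clock analysis.

Expression follows a per-gene log-normal across tissues: a housekeeping
subset shares its abundance between tissues, a tissue-specific subset is
silent outside its tissue, and the remainder varies independently.  Fragment
start positions are uniform along the transcript and insert sizes uniform in
``insert_range``, matching the mapper's proper-pair contract.

Determinism: a fixed (seed, config) yields byte-identical outputs; every
operation draws from its own child stream of the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from txqc.genome import GeneModel
from txqc.merge import Contig
from txqc.reads import ReadPair

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic two-tissue transcriptome."""

    seed: int = 0
    n_genes: int = 300
    tissues: tuple[str, ...] = ("liver", "testis")
    mean_isoforms_per_gene: float = 1.4
    mean_exons_per_transcript: float = 4.0
    transcript_len_mean: float = 1100.0
    transcript_len_sigma: float = 0.45
    transcript_len_min: int = 300
    transcript_len_max: int = 6000
    intron_len_mean: float = 300.0
    intron_len_sigma: float = 0.6
    intron_len_min: int = 60
    read_length: int = 100
    insert_range: tuple[int, int] = (100, 350)
    base_error_rate: float = 0.005
    rrna_fraction: float = 0.20
    adapter_fraction: float = 0.03
    lowq_tail_fraction: float = 0.10
    lowq_tail_len: int = 12
    tissue_specific_fraction: float = 0.30
    housekeeping_fraction: float = 0.30
    expression_dispersion: float = 1.5  # log-normal sigma
    redundancy_rate: float = 0.50
    fragmentation_rate: float = 0.30
    extension_rate: float = 0.20
    divergence_rate: float = 0.49  # substitutions per 100 bp
    adapter: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

    def validate(self) -> None:
        probs = {
            "base_error_rate": self.base_error_rate,
            "rrna_fraction": self.rrna_fraction,
            "adapter_fraction": self.adapter_fraction,
            "lowq_tail_fraction": self.lowq_tail_fraction,
            "tissue_specific_fraction": self.tissue_specific_fraction,
            "housekeeping_fraction": self.housekeeping_fraction,
            "redundancy_rate": self.redundancy_rate,
            "fragmentation_rate": self.fragmentation_rate,
            "extension_rate": self.extension_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.tissue_specific_fraction + self.housekeeping_fraction > 1.0:
            raise ConfigError("tissue-specific and housekeeping fractions exceed 1")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.mean_isoforms_per_gene < 1:
            raise ConfigError("mean_isoforms_per_gene must be >= 1")
        if self.mean_exons_per_transcript < 1:
            raise ConfigError("mean_exons_per_transcript must be >= 1")
        if self.insert_range[0] >= self.insert_range[1]:
            raise ConfigError("insert_range min must be < max")
        if self.read_length > self.insert_range[0]:
            raise ConfigError("read_length must be <= insert minimum")
        if self.divergence_rate < 0:
            raise ConfigError("divergence_rate must be >= 0")
        if len(self.tissues) < 2:
            raise ConfigError("need at least two tissues")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    abundance: dict[str, dict[str, float]]  # tissue -> transcript -> rel. molar abundance
    transcript_to_gene: dict[str, str]
    gene_class: dict[str, str]  # housekeeping | specific:<tissue> | background
    redundant_ids: list[str] = field(default_factory=list)
    fragmented_ids: dict[str, list[str]] = field(default_factory=dict)  # source -> fragments
    extended_ids: dict[str, str] = field(default_factory=dict)  # truncated primary -> full secondary
    divergence_rates: dict[str, float] = field(default_factory=dict)
    read_origin: dict[str, tuple[str, int, int]] = field(default_factory=dict)  # frag -> (src, start, insert)

    def validate(self) -> None:
        for tissue, ab in self.abundance.items():
            total = sum(ab.values())
            assert abs(total - 1.0) < 1e-9, f"{tissue} abundances sum to {total}"
        for t in {t for ab in self.abundance.values() for t in ab}:
            assert t in self.transcript_to_gene


@dataclass
class SimulatedTranscriptome:
    genome: dict[str, str]
    gene_models: list[GeneModel]  # one per isoform (mRNA)
    transcripts: dict[str, str]
    rrna: dict[str, str]
    truth: GroundTruth


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _coding_transcript(rng: np.random.Generator, length: int) -> str:
    """UTR + long ORF + UTR, so coding-candidate selection has signal."""
    utr5 = max(10, int(0.10 * length))
    orf_codons = max(34, int(0.70 * length) // 3)
    codons = rng.integers(0, len(_NONSTOP_CODONS), orf_codons - 2)
    orf = "ATG" + "".join(_NONSTOP_CODONS[i] for i in codons) + "TAA"
    utr3 = max(10, length - utr5 - len(orf))
    return _random_seq(rng, utr5) + orf + _random_seq(rng, utr3)


def simulate_transcriptome(config: SimConfig) -> SimulatedTranscriptome:
    """Genome, gene models (GFF3-ready), spliced transcripts and ground truth."""
    config.validate()
    rng = config.rng(1)
    scaffold_parts: list[str] = []
    scaffold_name = "scaffold_1"
    cursor = 0
    models: list[GeneModel] = []
    transcripts: dict[str, str] = {}
    transcript_to_gene: dict[str, str] = {}

    for g in range(config.n_genes):
        gene_id = f"G{g:04d}"
        tlen = int(
            np.clip(
                rng.lognormal(np.log(config.transcript_len_mean), config.transcript_len_sigma),
                config.transcript_len_min,
                config.transcript_len_max,
            )
        )
        tseq = _coding_transcript(rng, tlen)
        tlen = len(tseq)
        n_exons = 1 + int(rng.poisson(config.mean_exons_per_transcript - 1))
        n_exons = min(n_exons, max(1, tlen // 60))
        weights = rng.dirichlet(np.ones(n_exons))
        min_exon = 30
        exon_lens = (weights * (tlen - min_exon * n_exons)).astype(int) + min_exon
        exon_lens[-1] += tlen - int(exon_lens.sum())
        intron_lens = [
            max(
                config.intron_len_min,
                int(rng.lognormal(np.log(config.intron_len_mean), config.intron_len_sigma)),
            )
            for _ in range(n_exons - 1)
        ]
        strand = "+" if rng.random() < 0.5 else "-"

        # sense-strand gene body: exons interleaved with introns
        pieces = []
        sense_exon_offsets = []
        off = 0
        pos = 0
        for i, elen in enumerate(exon_lens):
            pieces.append(tseq[pos : pos + int(elen)])
            sense_exon_offsets.append((off, off + int(elen)))
            off += int(elen)
            pos += int(elen)
            if i < n_exons - 1:
                intr = _random_seq(rng, intron_lens[i])
                pieces.append(intr)
                off += len(intr)
        body = "".join(pieces)
        if strand == "-":
            body_genomic = _revcomp(body)
            exon_intervals = [
                (len(body) - e, len(body) - s) for s, e in sense_exon_offsets
            ][::-1]
        else:
            body_genomic = body
            exon_intervals = sense_exon_offsets

        spacer = _random_seq(rng, int(rng.integers(200, 1000)))
        scaffold_parts.append(spacer)
        cursor += len(spacer)
        gene_start = cursor
        scaffold_parts.append(body_genomic)
        cursor += len(body_genomic)

        exons_1based = [(gene_start + s + 1, gene_start + e) for s, e in exon_intervals]

        n_iso = min(3, 1 + int(rng.poisson(config.mean_isoforms_per_gene - 1)))
        iso_exon_counts = [n_exons]
        for _ in range(n_iso - 1):
            if n_exons < 2:
                break
            iso_exon_counts.append(int(rng.integers(1, n_exons)))
        for i, k in enumerate(iso_exon_counts, 1):
            tid = f"{gene_id}.{i}"
            # truncation keeps the 5'-most k exons in transcript order
            if strand == "+":
                iso_exons = exons_1based[:k]
            else:
                iso_exons = exons_1based[len(exons_1based) - k :]
            model = GeneModel(
                gene_id=gene_id,
                transcript_id=tid,
                scaffold=scaffold_name,
                strand=strand,
                exons=list(iso_exons),
            )
            models.append(model)
            transcripts[tid] = tseq[: sum(e - s + 1 for s, e in iso_exons)]
            transcript_to_gene[tid] = gene_id

    scaffold_parts.append(_random_seq(rng, int(rng.integers(200, 1000))))
    genome = {scaffold_name: "".join(scaffold_parts)}

    rrna = {
        "rRNA_18S": _random_seq(rng, 1900),
        "rRNA_28S": _random_seq(rng, 4700),
        "rRNA_5.8S": _random_seq(rng, 160),
    }

    truth = _assign_expression(config, transcripts, transcript_to_gene)
    truth.validate()
    return SimulatedTranscriptome(
        genome=genome, gene_models=models, transcripts=transcripts, rrna=rrna, truth=truth
    )


def _assign_expression(config, transcripts, transcript_to_gene) -> GroundTruth:
    rng = config.rng(2)
    genes = sorted({g for g in transcript_to_gene.values()})
    n = len(genes)
    perm = rng.permutation(n)
    n_hk = int(round(config.housekeeping_fraction * n))
    n_ts = int(round(config.tissue_specific_fraction * n))
    gene_class: dict[str, str] = {}
    for rank, gi in enumerate(perm):
        g = genes[gi]
        if rank < n_hk:
            gene_class[g] = "housekeeping"
        elif rank < n_hk + n_ts:
            tissue = config.tissues[rank % len(config.tissues)]
            gene_class[g] = f"specific:{tissue}"
        else:
            gene_class[g] = "background"

    by_gene: dict[str, list[str]] = {}
    for tid, g in transcript_to_gene.items():
        by_gene.setdefault(g, []).append(tid)

    sigma = config.expression_dispersion
    abundance: dict[str, dict[str, float]] = {t: {} for t in config.tissues}
    for g in genes:
        shared = float(rng.lognormal(0.0, sigma))
        per_tissue = {t: float(rng.lognormal(0.0, sigma)) for t in config.tissues}
        tids = sorted(by_gene[g])
        iso_w = rng.dirichlet(np.ones(len(tids)))
        for tissue in config.tissues:
            cls = gene_class[g]
            if cls == "housekeeping":
                level = shared
            elif cls.startswith("specific:"):
                level = per_tissue[tissue] if cls == f"specific:{tissue}" else 0.0
            else:
                level = per_tissue[tissue]
            for w, tid in zip(iso_w, tids):
                abundance[tissue][tid] = level * float(w)
    for tissue in config.tissues:
        total = sum(abundance[tissue].values())
        abundance[tissue] = {tid: v / total for tid, v in abundance[tissue].items()}
    return GroundTruth(
        abundance=abundance, transcript_to_gene=dict(transcript_to_gene), gene_class=gene_class
    )


def _apply_errors(rng, seq: str, qualities: np.ndarray, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hit = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
        qualities[i] = 5  # quality string encodes the injected error model
    return "".join(arr)


def simulate_reads(
    transcripts: Mapping[str, str],
    truth: GroundTruth,
    config: SimConfig,
    n_pairs: int,
    rrna: Mapping[str, str] | None = None,
    tissue: str | None = None,
) -> dict[str, list[ReadPair]]:
    """Paired reads per tissue; origins are recorded in ``truth.read_origin``.

    ``n_pairs`` is per tissue.  An ``rrna_fraction`` share of pairs is drawn
    from ``rrna`` when given.  Transcripts shorter than the insert minimum
    are skipped with a warning.
    """
    config.validate()
    tissues = (tissue,) if tissue else config.tissues
    rl = config.read_length
    lo, hi = config.insert_range
    rrna_seqs = rrna
    out: dict[str, list[ReadPair]] = {}
    for ti, tis in enumerate(config.tissues):
        if tis not in tissues:
            continue
        rng = config.rng(10 + ti)
        ab = truth.abundance[tis]
        tids = sorted(t for t in ab if ab[t] > 0)
        usable, weights = [], []
        skipped = 0
        for t in tids:
            if len(transcripts[t]) < lo:
                skipped += 1
                continue
            usable.append(t)
            # molar abundance times length: longer transcripts shed more fragments
            weights.append(ab[t] * len(transcripts[t]))
        if skipped:
            warnings.warn(f"{tis}: skipped {skipped} transcripts shorter than insert minimum")
        if not usable:
            raise ConfigError(f"{tis}: no transcript long enough for insert range")
        weights = np.asarray(weights)
        weights = weights / weights.sum()

        rrna = rrna_seqs or {}
        rrna_ids = sorted(rrna)
        pairs: list[ReadPair] = []
        src_idx = rng.choice(len(usable), size=n_pairs, p=weights)
        is_rrna = rng.random(n_pairs) < config.rrna_fraction
        is_adapter = rng.random(n_pairs) < config.adapter_fraction
        for i in range(n_pairs):
            frag_id = f"frag_{tis}_{i:07d}"
            if is_rrna[i] and rrna_ids:
                src = rrna_ids[int(rng.integers(len(rrna_ids)))]
                source = rrna[src]
                src_name = f"rRNA:{src}"
            else:
                src = usable[src_idx[i]]
                source = transcripts[src]
                src_name = src
            if is_adapter[i]:
                insert = int(rng.integers(60, rl))
            else:
                insert = int(rng.integers(lo, min(hi, len(source)) + 1))
            start = int(rng.integers(0, len(source) - insert + 1))
            frag = source[start : start + insert]
            if insert >= rl:
                s1 = frag[:rl]
                s2 = _revcomp(frag[-rl:])
            else:  # read-through into the 3' adapter
                pad = config.adapter[: rl - insert]
                s1 = (frag + pad)[:rl]
                s2 = (_revcomp(frag) + pad)[:rl]
                s1 += "A" * (rl - len(s1))
                s2 += "A" * (rl - len(s2))
            q1 = np.full(len(s1), 37, dtype=np.int64)
            q2 = np.full(len(s2), 37, dtype=np.int64)
            s1 = _apply_errors(rng, s1, q1, config.base_error_rate)
            s2 = _apply_errors(rng, s2, q2, config.base_error_rate)
            if config.lowq_tail_fraction and rng.random() < config.lowq_tail_fraction:
                tail = min(config.lowq_tail_len, len(s1))
                s1 = s1[:-tail] + _random_seq(rng, tail)
                q1[-tail:] = 2
            pairs.append(ReadPair(id=frag_id, seq1=s1, qual1=q1, seq2=s2, qual2=q2))
            truth.read_origin[frag_id] = (src_name, start, insert)
        out[tis] = pairs
    return out


def corrupt_assembly(
    transcripts: Mapping[str, str],
    truth: GroundTruth,
    config: SimConfig,
) -> tuple[list[Contig], list[Contig]]:
    """Two corrupted assembler outputs from the truth transcript set.

    Assembly A (primary): every isoform with its gene label, near-duplicate
    copies for a ``redundancy_rate`` share of genes (under fake gene labels,
    as a graph assembler would emit), and a truncated-to-60% version of an
    ``extension_rate`` share of genes.  Assembly B (secondary): one contig
    per gene, unlabelled; a ``fragmentation_rate`` share split into >= 2
    exact substrings, the extension share kept full length (longer than its
    A counterpart), the rest truncated.  All corruption is recorded in
    ``truth``.
    """
    config.validate()
    rng = config.rng(3)
    by_gene: dict[str, list[str]] = {}
    for tid, g in truth.transcript_to_gene.items():
        by_gene.setdefault(g, []).append(tid)
    genes = sorted(by_gene)
    n = len(genes)
    perm = [genes[i] for i in rng.permutation(n)]
    n_ext = int(round(config.extension_rate * n))
    # extensions are only planted on genes long enough that the full-length
    # secondary copy passes a 100-codon ORF screen (the generated ORF spans
    # ~70% of the transcript), so the replacement bookkeeping stays exact
    maxlen = {g: max(len(transcripts[t]) for t in by_gene[g]) for g in genes}
    ext_eligible = [g for g in perm if maxlen[g] >= 470]
    extended_genes = set(ext_eligible[:n_ext])
    rest = [g for g in perm if g not in extended_genes]
    n_frag = int(round(config.fragmentation_rate * n))
    fragmented_genes = set(rest[:n_frag])
    # duplicated genes drawn outside the extension set so the planted
    # replace-with-longer bookkeeping stays exact
    n_dup = min(int(round(config.redundancy_rate * n)), len(rest))
    duplicated_genes = set(rest[::-1][:n_dup])

    assembly_a: list[Contig] = []
    for g in genes:
        for tid in sorted(by_gene[g]):
            seq = transcripts[tid]
            if g in extended_genes:
                # truncate every isoform so the surviving longest contig of
                # this gene is strictly shorter than the secondary full copy
                cut = max(150, int(0.6 * len(seq)))
                if tid == sorted(by_gene[g])[0]:
                    truth.extended_ids[tid] = f"{g}_full"
                seq = seq[:cut]
            assembly_a.append(Contig(id=tid, sequence=seq, source="primary_assembly", gene_id=g))
        if g in duplicated_genes:
            tid = sorted(by_gene[g])[0]
            seq = _mutate(rng, transcripts[tid], 0.02)
            dup_id = f"{tid}_dup"
            truth.redundant_ids.append(dup_id)
            assembly_a.append(
                Contig(id=dup_id, sequence=seq, source="primary_assembly", gene_id=f"{g}_dup")
            )

    assembly_b: list[Contig] = []
    for g in genes:
        tid = max(sorted(by_gene[g]), key=lambda t: len(transcripts[t]))
        seq = transcripts[tid]
        if g in fragmented_genes and len(seq) >= 2 * config.transcript_len_min:
            k = 2 if len(seq) < 3 * config.transcript_len_min else int(rng.integers(2, 4))
            cuts = sorted(
                rng.choice(
                    np.arange(config.transcript_len_min, len(seq) - config.transcript_len_min + 1),
                    size=k - 1,
                    replace=False,
                ).tolist()
            )
            bounds = [0] + cuts + [len(seq)]
            frag_ids = []
            for j in range(len(bounds) - 1):
                fid = f"{g}_frag{j}"
                frag_ids.append(fid)
                assembly_b.append(
                    Contig(id=fid, sequence=seq[bounds[j] : bounds[j + 1]], source="secondary_assembly")
                )
            truth.fragmented_ids[tid] = frag_ids
        elif g in extended_genes:
            assembly_b.append(Contig(id=f"{g}_full", sequence=seq, source="secondary_assembly"))
        elif config.fragmentation_rate > 0 or config.extension_rate > 0:
            cut = max(config.transcript_len_min, int(0.7 * len(seq)))
            assembly_b.append(Contig(id=f"{g}_part", sequence=seq[:cut], source="secondary_assembly"))
        else:  # no corruption requested: emit the transcript as-is
            assembly_b.append(Contig(id=tid, sequence=seq, source="secondary_assembly"))
    return assembly_a, assembly_b


def _mutate(rng, seq: str, rate: float) -> str:
    arr = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def diverge_sequences(
    cds_set: Mapping[str, str],
    rate_per_100bp: float,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Aligned pairs differing by independent substitutions at the given rate.

    Returns ``(id, original, diverged)`` triples; no indels are introduced,
    so the sequences come back aligned column-for-column.
    """
    if rate_per_100bp < 0:
        raise ConfigError("divergence rate must be >= 0")
    if rate_per_100bp > 100:
        raise ConfigError("divergence rate above 100 per 100 bp is meaningless")
    rng = np.random.default_rng([seed, 4])
    p = rate_per_100bp / 100.0
    out = []
    for name in sorted(cds_set):
        seq = cds_set[name].upper()
        out.append((name, seq, _mutate(rng, seq, p)))
    return out
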