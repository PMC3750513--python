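"""Generate a small synthetic two-tissue transcriptome study and write its files.

Outputs (FASTA / paired FASTQ / GFF3) land in ./example_data; the ground
truth stays in memory for the downstream examples.
"""

from pathlib import Path

from txqc import io
from txqc.simulate import SimConfig, simulate_reads, simulate_transcriptome

out = Path("example_data")
out.mkdir(exist_ok=True)

config = SimConfig(seed=42, n_genes=50)
sim = simulate_transcriptome(config)
reads = simulate_reads(sim.transcripts, sim.truth, config, n_pairs=2000, rrna=sim.rrna)

io.write_fasta(sim.genome, out / "genome.fa")
io.write_fasta(sim.transcripts, out / "transcripts.fa")
io.write_fasta(sim.rrna, out / "rrna.fa")
io.write_gff3(sim.gene_models, out / "genes.gff3")
for tissue, pairs in reads.items():
    io.write_fastq_pairs(pairs, out / f"{tissue}_1.fq", out / f"{tissue}_2.fq")

print(f"genome: {sum(len(s) for s in sim.genome.values()):,} bp on {len(sim.genome)} scaffold(s)")
print(f"gene models: {len(sim.gene_models)} isoforms over {config.n_genes} genes")
print(f"read pairs per tissue: 2,000 ({config.read_length}-cycle paired-end)")
print(f"planted rRNA contamination: {config.rrna_fraction:.0%} of pairs")
# The ground truth records, per tissue, each transcript's relative molar
# abundance; these are what FPKM estimates should recover downstream.
liver = sim.truth.abundance["liver"]
top = max(liver, key=liver.get)
print(f"most abundant liver transcript: {top} ({liver[top]:.1%} of molecules)")
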