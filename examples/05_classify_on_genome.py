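"""Classify mapped fragments against gene models: exon / intron / junctions.

Reads simulated from spliced transcripts are mapped, projected onto the
genome through the exon coordinates, and placed into the annotation
categories; the report mirrors the genome-mapping accounting table.
"""

import warnings

from txqc.genome import map_to_genome
from txqc.simulate import SimConfig, simulate_reads, simulate_transcriptome

config = SimConfig(seed=42, n_genes=50, rrna_fraction=0.0, adapter_fraction=0.0)
sim = simulate_transcriptome(config)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    reads = simulate_reads(sim.transcripts, sim.truth, config, n_pairs=2000, rrna=None)

report, _ = map_to_genome(reads["liver"], sim.genome, sim.gene_models, seed=1)
d = report.to_dict()
for key in (
    "counted_fragments",
    "pct_exons_total",
    "pct_exon_exon_junctions",
    "pct_introns_total",
    "genes_expressed",
    "pct_genes_expressed",
    "reads_on_scaffolds",
    "unmapped_reads_genome",
):
    print(f"{key}: {d[key]:,}" if isinstance(d[key], int) else f"{key}: {d[key]}")
# Mature-mRNA reads should be almost entirely exonic, with roughly half of
# the counted fragments having a mate that spans an exon-exon junction.
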