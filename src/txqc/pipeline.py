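"""End-to-end desk run: simulate -> trim -> deplete rRNA -> merge assemblies
-> map -> quantify -> QC.

This is the orchestration the acceptance run and the examples use; every
stage is the public function of its module, so the pipeline doubles as a
usage reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from txqc import expression, mapping, merge, qc, reads, simulate


@dataclass
class PipelineResult:
    config: simulate.SimConfig
    truth: simulate.GroundTruth
    trim_reports: dict[str, reads.TrimReport] = field(default_factory=dict)
    audit: merge.MergeAudit | None = None
    final_contigs: list[merge.Contig] = field(default_factory=list)
    mapping_summaries: dict[str, mapping.MappingSummary] = field(default_factory=dict)
    redundancy_primary_raw: float = 0.0
    redundancy_merged: float = 0.0
    redundancy_final: float = 0.0
    stats_primary_raw: qc.AssemblyStats | None = None
    stats_after_integration: qc.AssemblyStats | None = None
    stats_final: qc.AssemblyStats | None = None
    expression_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    overlap: expression.OverlapResult | None = None


def run_pipeline(
    config: simulate.SimConfig,
    n_pairs_per_tissue: int = 25_000,
    top_n: int = 1000,
    min_avg_coverage: float = 5.0,
    min_length_bp: int = 250,
) -> PipelineResult:
    config.validate()
    sim = simulate.simulate_transcriptome(config)
    result = PipelineResult(config=config, truth=sim.truth)

    raw = simulate.simulate_reads(
        sim.transcripts, sim.truth, config, n_pairs_per_tissue, rrna=sim.rrna
    )
    clean: dict[str, list[reads.ReadPair]] = {}
    for tissue, pairs in raw.items():
        kept, report = reads.process_reads(pairs, sim.rrna, adapters=(config.adapter,))
        clean[tissue] = kept
        result.trim_reports[tissue] = report

    assembly_a, assembly_b = simulate.corrupt_assembly(sim.transcripts, sim.truth, config)
    result.stats_primary_raw = qc.assembly_stats([len(c) for c in assembly_a])

    # integration strategy: longest isoform -> collapse -> ORF candidates ->
    # replace-with-longer -> coverage/length filter
    primary = merge.longest_isoform_per_gene(assembly_a)
    primary = merge.collapse_redundant(primary)
    candidates = merge.select_coding_candidates(assembly_b)
    integrated, audit = merge.integrate_assemblies(primary, candidates)
    result.audit = audit
    result.stats_after_integration = qc.assembly_stats([len(c) for c in integrated])

    all_pairs = [p for tissue in sorted(clean) for p in clean[tissue]]
    raw_index_pairs = all_pairs
    _, summary_raw = mapping.map_pairs(raw_index_pairs, assembly_a, seed=config.seed)
    result.redundancy_primary_raw = mapping.redundancy_pct(summary_raw)

    integrated_seqs = {c.id: c.sequence for c in integrated}
    _, summary_int = mapping.map_pairs(all_pairs, integrated_seqs, seed=config.seed)
    result.redundancy_merged = mapping.redundancy_pct(summary_int)
    coverage = {
        cid: mapping.average_coverage(summary_int, cid) for cid in integrated_seqs
    }
    final = merge.coverage_length_filter(
        integrated, coverage, min_avg_coverage=min_avg_coverage, min_length_bp=min_length_bp
    )
    result.final_contigs = final
    result.stats_final = qc.assembly_stats([len(c) for c in final])
    audit.record("after_coverage_length_filter", len(final))

    final_seqs = {c.id: c.sequence for c in final}
    for tissue in sorted(clean):
        _, summary = mapping.map_pairs(clean[tissue], final_seqs, seed=config.seed)
        result.mapping_summaries[tissue] = summary
        result.expression_tables[tissue] = expression.expression_table(summary, tissue)
    result.redundancy_final = _pooled_redundancy(result.mapping_summaries)

    result.detection = expression.detection_summary(result.expression_tables)
    n = min(top_n, len(final_seqs))
    result.overlap = expression.top_overlap(result.expression_tables, top_n=n)
    return result


def _pooled_redundancy(summaries: Mapping[str, mapping.MappingSummary]) -> float:
    nonspec = sum(s.counted_nonspecific for s in summaries.values())
    counted = sum(s.counted_total for s in summaries.values())
    if counted == 0:
        raise ValueError("no counted fragments in any tissue")
    return 100.0 * nonspec / counted
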