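"""Dual-assembly integration: isoform selection, collapse, ORF filter,
replace-with-longer, coverage/length filter."""

import numpy as np
import pytest

from txqc.merge import (
    Contig,
    collapse_redundant,
    coverage_length_filter,
    integrate_assemblies,
    longest_isoform_per_gene,
    longest_orf_codons,
    select_coding_candidates,
)
from txqc.simulate import corrupt_assembly

from conftest import random_seq

RC = str.maketrans("ACGT", "TGCA")


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


class TestLongestIsoform:
    def test_longest_isoform_wins(self, rng):
        contigs = [
            Contig("t1", random_seq(rng, 1200), gene_id="g1"),
            Contig("t2", random_seq(rng, 800), gene_id="g1"),
        ]
        kept = longest_isoform_per_gene(contigs)
        assert [c.id for c in kept] == ["t1"]

    def test_equal_length_tie_keeps_smallest_id(self, rng):
        seq = random_seq(rng, 500)
        contigs = [Contig("b", seq, gene_id="g"), Contig("a", seq, gene_id="g")]
        assert [c.id for c in longest_isoform_per_gene(contigs)] == ["a"]

    def test_two_genes_five_isoforms(self, rng):
        contigs = [Contig(f"g1.{i}", random_seq(rng, 400 + 100 * i), gene_id="g1") for i in range(3)]
        contigs += [Contig(f"g2.{i}", random_seq(rng, 300 + 50 * i), gene_id="g2") for i in range(2)]
        kept = longest_isoform_per_gene(contigs)
        assert sorted(c.id for c in kept) == ["g1.2", "g2.1"]

    def test_unlabelled_contigs_pass_through(self, rng):
        contigs = [Contig("x", random_seq(rng, 300)), Contig("y", random_seq(rng, 200))]
        assert len(longest_isoform_per_gene(contigs)) == 2


class TestCollapseRedundant:
    def test_exact_duplicate_collapsed_to_one(self, rng):
        seq = random_seq(rng, 800)
        kept = collapse_redundant([Contig("a", seq), Contig("b", seq)])
        assert [c.id for c in kept] == ["a"]

    def test_verbatim_substring_removed(self, rng):
        seq = random_seq(rng, 1000)
        kept = collapse_redundant([Contig("big", seq), Contig("small", seq[200:800])])
        assert [c.id for c in kept] == ["big"]

    def test_planted_near_duplicates_at_96pct(self, rng):
        base = [Contig(f"c{i}", random_seq(rng, 900)) for i in range(7)]
        dups = [
            Contig(f"d{i}", _mutate(rng, base[i].sequence, 0.04)) for i in range(3)
        ]
        kept = collapse_redundant(base + dups)
        assert len(kept) == 7
        assert all(c.id.startswith("c") for c in kept)

    def test_reverse_complement_duplicate_removed(self, rng):
        seq = random_seq(rng, 700)
        kept = collapse_redundant([Contig("a", seq), Contig("b", seq.translate(RC)[::-1])])
        assert len(kept) == 1

    def test_idempotent_and_pairwise_nonredundant(self, rng):
        import edlib

        contigs = [Contig(f"c{i}", random_seq(rng, 600)) for i in range(6)]
        contigs += [Contig("dup0", contigs[0].sequence), Contig("dup1", contigs[1].sequence[:400])]
        once = collapse_redundant(contigs)
        twice = collapse_redundant(once)
        assert [c.id for c in once] == [c.id for c in twice]
        # no surviving pair satisfies the redundancy predicate
        for a in once:
            for b in once:
                if a.id == b.id or len(a) > len(b):
                    continue
                res = edlib.align(a.sequence, b.sequence, mode="HW", task="distance",
                                  k=int(0.05 * len(a)) + 1)
                assert res["editDistance"] < 0 or res["editDistance"] > 0.05 * len(a)


def orf_6frame_oracle(seq):
    """Brute-force scan: longest stop-free codon run over all six frames."""
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    rc = seq.translate(RC)[::-1]
    for s in (seq, rc):
        for f in range(3):
            codons = [s[i : i + 3] for i in range(f, len(s) - 2, 3)]
            run = 0
            for c in codons:
                run = 0 if c in stops else run + 1
                best = max(best, run)
    return best


class TestCodingCandidates:
    def test_planted_long_orf_kept(self, rng):
        nonstop = "GCT"  # alanine codons, no stops in this frame
        seq = random_seq(rng, 50) + "ATG" + nonstop * 150 + "TAA" + random_seq(rng, 50)
        assert select_coding_candidates([Contig("c", seq)]) != []

    def test_short_random_sequence_discarded(self, rng):
        # below 300 bp a 100-codon stop-free run cannot exist in any frame
        contigs = [Contig(f"c{i}", random_seq(rng, 290)) for i in range(20)]
        survivors = select_coding_candidates(contigs)
        assert survivors == []

    def test_planted_subset_recovered_exactly(self, rng):
        nonstop = "GAA"
        coding = [
            Contig(f"orf{i}", random_seq(rng, 30) + nonstop * 120 + random_seq(rng, 30))
            for i in range(8)
        ]
        junk = [Contig(f"j{i}", random_seq(rng, 290)) for i in range(12)]
        kept = select_coding_candidates(coding + junk)
        assert sorted(c.id for c in kept) == sorted(c.id for c in coding)

    def test_orf_scan_matches_oracle(self, rng):
        for _ in range(20):
            seq = random_seq(rng, int(rng.integers(60, 400)))
            assert longest_orf_codons(seq) == orf_6frame_oracle(seq)


class TestIntegration:
    def test_longer_candidate_replaces_primary(self, rng):
        core = random_seq(rng, 600)
        primary = [Contig("p", core, gene_id="g")]
        cand = [Contig("c", core + random_seq(rng, 300), source="secondary_assembly")]
        merged, audit = integrate_assemblies(primary, cand)
        assert audit.replaced == {"p": "c"}
        assert merged[0].id == "c" and merged[0].gene_id == "g"
        assert len(merged[0]) >= 1.10 * len(core)

    def test_candidate_below_margin_discarded(self, rng):
        core = random_seq(rng, 600)
        primary = [Contig("p", core)]
        cand = [Contig("c", core + random_seq(rng, 30))]  # 1.05x, below 1.10
        merged, audit = integrate_assemblies(primary, cand)
        assert audit.replaced == {}
        assert merged[0].id == "p"
        assert audit.discarded_candidates == ["c"]

    def test_reverse_complement_candidate_stored_in_primary_orientation(self, rng):
        core = random_seq(rng, 600)
        ext = core + random_seq(rng, 200)
        primary = [Contig("p", core)]
        cand = [Contig("c", ext.translate(RC)[::-1])]
        merged, audit = integrate_assemblies(primary, cand)
        assert audit.replaced == {"p": "c"}
        assert core in merged[0].sequence

    def test_ground_truth_extensions_all_replaced(self, small_config, small_sim):
        a, b = corrupt_assembly(small_sim.transcripts, small_sim.truth, small_config)
        primary = collapse_redundant(longest_isoform_per_gene(a))
        candidates = select_coding_candidates(b)
        merged, audit = integrate_assemblies(primary, candidates)
        expected = small_sim.truth.extended_ids
        assert expected  # the corruption planted something to recover
        for old, new in expected.items():
            assert audit.replaced.get(old) == new
        # replacement never shortens below the margin
        lengths = {c.id: len(c) for c in primary}
        merged_len = {c.id: len(c) for c in merged}
        for old, new in audit.replaced.items():
            assert merged_len[new] >= 1.10 * lengths[old]

    def test_stage_conservation(self, small_config, small_sim):
        a, b = corrupt_assembly(small_sim.transcripts, small_sim.truth, small_config)
        primary = collapse_redundant(longest_isoform_per_gene(a))
        candidates = select_coding_candidates(b)
        merged, audit = integrate_assemblies(primary, candidates)
        assert len(merged) == len(primary)  # replacement preserves count
        assert audit.stage_counts["candidates_used"] + audit.stage_counts[
            "candidates_discarded"
        ] == len(candidates)
        assert sorted(audit.replaced) == sorted(set(audit.replaced))


class TestCoverageLengthFilter:
    def test_inclusive_boundaries_kept(self, rng):
        c = Contig("c", random_seq(rng, 250), average_coverage=5.0)
        assert coverage_length_filter([c]) == [c]

    def test_low_coverage_discarded(self, rng):
        c = Contig("c", random_seq(rng, 1000), average_coverage=4.99)
        assert coverage_length_filter([c]) == []

    def test_hand_counted_mixture(self, rng):
        highs = [Contig(f"h{i}", random_seq(rng, 500), average_coverage=8.0) for i in range(7)]
        lows = [Contig(f"l{i}", random_seq(rng, 500), average_coverage=1.0) for i in range(5)]
        kept = coverage_length_filter(highs + lows)
        assert len(kept) == 7
        assert len(kept) + 5 == 12

    def test_missing_coverage_raises(self, rng):
        with pytest.raises(ValueError):
            coverage_length_filter([Contig("c", random_seq(rng, 500))])
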