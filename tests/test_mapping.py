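"""Mapper status contract, accounting identities, redundancy and coverage."""

import warnings

import edlib
import numpy as np
import pytest

from txqc.mapping import (
    MappingSummary,
    average_coverage,
    map_pairs,
    redundancy_pct,
    reference_fraction,
)
from txqc.reads import ReadPair

from conftest import random_seq

RC = str.maketrans("ACGT", "TGCA")


def make_pair(pid, source, start, insert, rl=100):
    frag = source[start : start + insert]
    return ReadPair(
        pid,
        frag[:rl],
        np.full(rl, 37),
        frag[-rl:].translate(RC)[::-1],
        np.full(rl, 37),
    )


def exhaustive_status(pair, contigs, length_fraction=0.75, similarity=0.95, insert_range=(100, 350)):
    """Oracle: align every mate against every contig (both strands, no
    seeding) with edlib and apply the counted/broken/unmapped rules."""

    def qualifying(read):
        out = []
        for cid, target in contigs.items():
            for strand, q in ((1, read), (-1, read.translate(RC)[::-1])):
                res = edlib.align(q, target, mode="HW", task="locations",
                                  k=int(len(q) * (1 - similarity)))
                if res["editDistance"] < 0:
                    continue
                ident = 1.0 - res["editDistance"] / len(q)
                if ident < similarity:
                    continue
                for s, e in res["locations"]:
                    out.append((cid, strand, s, e + 1, round(ident, 4)))
        return out

    a1, a2 = qualifying(pair.seq1), qualifying(pair.seq2)
    best = None
    contigs_at_best = set()
    for c1, s1, b1, e1, i1 in a1:
        for c2, s2, b2, e2, i2 in a2:
            if c1 != c2 or s1 == s2:
                continue
            (fb, fe), (rb, re_) = ((b1, e1), (b2, e2)) if s1 == 1 else ((b2, e2), (b1, e1))
            if fb > rb:
                continue
            insert = re_ - fb
            if not insert_range[0] <= insert <= insert_range[1]:
                continue
            key = round(i1 + i2, 4)
            if best is None or key > best:
                best = key
                contigs_at_best = {c1}
            elif key == best:
                contigs_at_best.add(c1)
    if best is not None:
        return "counted_unique" if len(contigs_at_best) == 1 else "counted_nonspecific"
    if a1 or a2:
        return "broken_pair"
    return "unmapped"


class TestStatusAssignment:
    def test_error_free_pair_counted_unique(self, rng):
        contig = random_seq(rng, 1000)
        pair = make_pair("p", contig, 300, 200)
        mappings, summary = map_pairs([pair], {"c1": contig})
        assert mappings[0].status == "counted_unique"
        assert mappings[0].contig == "c1"
        assert summary.counted_unique == 1

    def test_duplicate_contig_makes_pair_nonspecific(self, rng):
        contig = random_seq(rng, 1000)
        pair = make_pair("p", contig, 300, 200)
        mappings, _ = map_pairs([pair], {"c1": contig, "c2": contig})
        assert mappings[0].status == "counted_nonspecific"
        assert mappings[0].equal_best == 2

    def test_one_random_mate_gives_broken_pair(self, rng):
        contig = random_seq(rng, 1000)
        good = make_pair("p", contig, 300, 200)
        pair = ReadPair("p", good.seq1, good.qual1, random_seq(rng, 100), np.full(100, 37))
        mappings, summary = map_pairs([pair], {"c1": contig})
        assert mappings[0].status == "broken_pair"
        assert exhaustive_status(pair, {"c1": contig}) == "broken_pair"
        assert summary.reads_broken == 1 and summary.reads_unmapped == 1

    def test_improper_insert_not_counted(self, rng):
        contig = random_seq(rng, 2000)
        pair = make_pair("p", contig, 100, 600)  # outer distance beyond 350
        mappings, _ = map_pairs([pair], {"c1": contig})
        assert mappings[0].status == "broken_pair"

    def test_empty_and_duplicate_contig_sets_rejected(self, rng):
        pair = make_pair("p", random_seq(rng, 500), 100, 200)
        with pytest.raises(ValueError):
            map_pairs([pair], {})
        from txqc.merge import Contig

        c = Contig(id="x", sequence=random_seq(rng, 400))
        with pytest.raises(ValueError):
            map_pairs([pair], [c, c])


class TestOracleEquivalence:
    def test_status_matches_exhaustive_aligner(self, clean_config, clean_sim, clean_reads, rng):
        """Seeded search agrees with the all-contig DP scan on a mixed set:
        simulated pairs, a duplicated contig, and random-mate corruptions."""
        tx = dict(list(clean_sim.transcripts.items())[:18])
        contigs = dict(tx)
        first = next(iter(tx))
        contigs["dup_of_first"] = tx[first]
        pairs = [p for p in clean_reads["liver"][:200]]
        # corrupt a few mates so broken/unmapped branches are exercised
        for i in range(0, 40, 7):
            p = pairs[i]
            pairs[i] = ReadPair(p.id, p.seq1, p.qual1, random_seq(rng, 100), np.full(100, 37))
        for i in range(1, 30, 9):
            p = pairs[i]
            pairs[i] = ReadPair(
                p.id, random_seq(rng, 100), np.full(100, 37), random_seq(rng, 100), np.full(100, 37)
            )
        mappings, _ = map_pairs(pairs, contigs, seed=5)
        mismatches = [
            (m.fragment_id, m.status, exhaustive_status(p, contigs))
            for p, m in zip(pairs, mappings)
            if m.status != exhaustive_status(p, contigs)
        ]
        assert mismatches == []


class TestAccountingInvariants:
    def test_summary_identities_on_simulated_run(self, clean_sim, clean_reads):
        _, summary = map_pairs(clean_reads["testis"], clean_sim.transcripts, seed=3)
        summary.validate()
        assert summary.counted_total + summary.uncounted == summary.total_fragments
        assert summary.reads_in_pairs == 2 * summary.counted_total
        assert (
            summary.reads_in_pairs + summary.reads_broken + summary.reads_unmapped
            == summary.total_reads
        )

    def test_error_free_unique_reads_nearly_all_counted(self, clean_sim, clean_reads):
        # duplicate-free contig set, error-free reads: >= 99.9% counted_unique
        singles = {
            tid: seq for tid, seq in clean_sim.transcripts.items()
        }
        mappings, summary = map_pairs(clean_reads["liver"], singles, seed=3)
        frac = summary.counted_unique / summary.total_fragments
        assert frac >= 0.999

    def test_duplicating_a_contig_never_decreases_redundancy(self, clean_sim, clean_reads):
        pairs = clean_reads["liver"][:300]
        base = dict(clean_sim.transcripts)
        _, s0 = map_pairs(pairs, base, seed=1)
        for tid in list(base)[:3]:
            dup = dict(base)
            dup[f"{tid}_copy"] = base[tid]
            _, s1 = map_pairs(pairs, dup, seed=1)
            assert redundancy_pct(s1) >= redundancy_pct(s0)


class TestRedundancyAndCoverage:
    def test_redundancy_all_unique_is_zero(self, rng):
        contig = random_seq(rng, 1500)
        pairs = [make_pair(f"p{i}", contig, 50 * i, 200) for i in range(10)]
        _, summary = map_pairs(pairs, {"c": contig})
        assert redundancy_pct(summary) == 0.0

    def test_redundancy_duplicate_library_is_hundred(self, rng):
        contig = random_seq(rng, 1500)
        pairs = [make_pair(f"p{i}", contig, 50 * i, 200) for i in range(10)]
        _, summary = map_pairs(pairs, {"c1": contig, "c2": contig})
        assert redundancy_pct(summary) == 100.0

    def test_redundancy_hand_count(self):
        s = MappingSummary(total_fragments=12, counted_total=12, counted_unique=9,
                           counted_nonspecific=3)
        assert redundancy_pct(s) == 25.0

    def test_redundancy_undefined_without_counted_fragments(self):
        with pytest.raises(ValueError):
            redundancy_pct(MappingSummary(total_fragments=5))

    def test_average_coverage_single_broken_mate(self, rng):
        contig = random_seq(rng, 1000)
        pair = ReadPair(
            "p", contig[200:300], np.full(100, 37), random_seq(rng, 100), np.full(100, 37)
        )
        _, summary = map_pairs([pair], {"c": contig})
        assert average_coverage(summary, "c") == pytest.approx(0.1)

    def test_average_coverage_counted_fragments(self, rng):
        contig = random_seq(rng, 2000)
        pairs = [make_pair(f"p{i}", contig, 30 * i, 250) for i in range(50)]
        _, summary = map_pairs(pairs, {"c": contig})
        assert average_coverage(summary, "c") == pytest.approx(5.0)

    def test_average_coverage_errors(self, rng):
        contig = random_seq(rng, 1000)
        _, summary = map_pairs([make_pair("p", contig, 100, 200)], {"c": contig})
        with pytest.raises(KeyError):
            average_coverage(summary, "nope")
        assert average_coverage(summary, "c") == pytest.approx(0.2)


class TestReferenceFraction:
    def test_no_matching_reads(self, rng):
        ref = {"mito": random_seq(rng, 2000)}
        other = random_seq(rng, 1000)
        pairs = [make_pair(f"p{i}", other, 20 * i, 200) for i in range(5)]
        assert reference_fraction(pairs, ref) == 0.0

    def test_all_reads_from_reference(self, rng):
        ref = {"mito": random_seq(rng, 2000)}
        pairs = [make_pair(f"p{i}", ref["mito"], 30 * i, 200) for i in range(5)]
        assert reference_fraction(pairs, ref) == 100.0

    def test_planted_fraction_recovered(self, rng):
        mito = random_seq(rng, 3000)
        nuc = random_seq(rng, 3000)
        n = 400
        n_mito = 20  # 5%
        pairs = [make_pair(f"m{i}", mito, 11 * i, 200) for i in range(n_mito)]
        pairs += [make_pair(f"n{i}", nuc, 6 * (i % 400), 200) for i in range(n - n_mito)]
        frac = reference_fraction(pairs, {"mito": mito}) / 100.0
        se = (0.05 * 0.95 / n) ** 0.5
        assert abs(frac - 0.05) <= 3 * se
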