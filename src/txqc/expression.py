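"""FPKM quantification, transcriptome richness and tissue overlap.

FPKM = fragments per kilobase of transcript per million counted fragments:
``count / ((length/1000) * (total/1e6))``.  Richness is summarized by the
cumulative normalized expression of top-ranked transcripts; specificity uses
the rule "among the top-N most expressed in one tissue, FPKM below a floor in
every other tissue".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from txqc.mapping import MappingSummary


def fpkm(count: float, contig_length_bp: int, total_counted_fragments: int) -> float:
    if contig_length_bp <= 0:
        raise ValueError("contig length must be positive")
    if total_counted_fragments <= 0:
        raise ValueError("total counted fragments must be positive")
    return count / ((contig_length_bp / 1000.0) * (total_counted_fragments / 1e6))


def expression_table(
    summary: MappingSummary,
    tissue: str,
    contig_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-contig counts and FPKM for one tissue from a mapping summary."""
    lengths = contig_lengths or summary.contig_lengths
    total = summary.counted_total
    rows = []
    for cid in sorted(lengths):
        count = summary.fragment_counts.get(cid, 0)
        rows.append(
            {
                "contig": cid,
                "length": lengths[cid],
                "tissue": tissue,
                "count": count,
                "fpkm": fpkm(count, lengths[cid], total) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def richness_curve(table: pd.DataFrame, top_n: int = 1000) -> np.ndarray:
    """Cumulative normalized FPKM of the ``top_n`` most expressed contigs.

    The curve is non-decreasing with values in (0, 1]."""
    fpkms = np.sort(table["fpkm"].to_numpy())[::-1]
    total = fpkms.sum()
    if total <= 0:
        raise ValueError("all-zero expression table")
    return np.cumsum(fpkms[:top_n]) / total


def genes_to_fraction(table: pd.DataFrame, fraction: float) -> int:
    """Smallest number of top-expressed contigs whose cumulative normalized
    expression reaches ``fraction``."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    curve = richness_curve(table, top_n=len(table))
    return int(np.searchsorted(curve, fraction, side="left")) + 1


@dataclass
class OverlapResult:
    top_sets: dict[str, set] = field(default_factory=dict)
    region_counts: dict[str, int] = field(default_factory=dict)  # exclusive Venn regions
    intersection_counts: dict[str, int] = field(default_factory=dict)  # plain intersections
    specific_counts: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        union = set().union(*self.top_sets.values())
        assert sum(self.region_counts.values()) == len(union)
        for t, n in self.specific_counts.items():
            assert n <= len(self.top_sets[t])


def _rank_key(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["fpkm", "count", "contig"], ascending=[False, False, True])


def top_overlap(
    tables: Mapping[str, pd.DataFrame],
    top_n: int = 1000,
    specificity_fpkm: float = 1.0,
) -> OverlapResult:
    """Top-N overlap between tissues and highly tissue-specific counts.

    A transcript is *specific* to a tissue when it is among that tissue's
    top-N most expressed but has FPKM below ``specificity_fpkm`` in every
    other tissue.  Ties at the top-N boundary rank by (fpkm desc, count desc,
    id asc).
    """
    tissues = sorted(tables)
    if len(tissues) < 2:
        raise ValueError("need at least two tissues")
    universe = set(tables[tissues[0]]["contig"])
    for t in tissues[1:]:
        if set(tables[t]["contig"]) != universe:
            raise ValueError("tables must share the contig universe")
    n = top_n
    if top_n > len(universe):
        import warnings

        warnings.warn("top_n exceeds universe size; using full universe")
        n = len(universe)

    result = OverlapResult()
    fpkm_by_tissue = {t: tables[t].set_index("contig")["fpkm"] for t in tissues}
    for t in tissues:
        result.top_sets[t] = set(_rank_key(tables[t]).head(n)["contig"])

    # exclusive Venn regions, keyed e.g. "liver" / "liver&testis"
    for r in range(1, len(tissues) + 1):
        for group in combinations(tissues, r):
            inside = set.intersection(*(result.top_sets[t] for t in group))
            result.intersection_counts["&".join(group)] = len(inside)
            outside = [result.top_sets[t] for t in tissues if t not in group]
            excl = inside - set().union(*outside) if outside else inside
            result.region_counts["&".join(group)] = len(excl)

    for t in tissues:
        others = [o for o in tissues if o != t]
        count = 0
        for contig in result.top_sets[t]:
            if all(fpkm_by_tissue[o][contig] < specificity_fpkm for o in others):
                count += 1
        result.specific_counts[t] = count
    result.validate()
    return result


def detection_summary(
    tables: Mapping[str, pd.DataFrame],
    min_fragments: int = 1,
) -> dict:
    """Per-tissue expressed-contig counts and the shared fraction.

    A contig is *expressed* when its fragment count is at least
    ``min_fragments``; percentages are relative to the contig universe and
    rounded to 2 decimals.
    """
    tissues = sorted(tables)
    universe = set(tables[tissues[0]]["contig"])
    expressed = {
        t: set(tables[t].loc[tables[t]["count"] >= min_fragments, "contig"]) for t in tissues
    }
    shared = set.intersection(*expressed.values())
    n_univ = len(universe)

    def pct(x):
        return round(100.0 * x / n_univ, 2) if n_univ else 0.0

    out = {"universe": n_univ}
    for t in tissues:
        out[f"expressed_{t}"] = len(expressed[t])
        out[f"pct_expressed_{t}"] = pct(len(expressed[t]))
    out["expressed_all"] = len(shared)
    out["pct_expressed_all"] = pct(len(shared))
    return out
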