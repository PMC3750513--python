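"""File-format helpers: FASTA/FASTQ via Biopython, GFF3, tabular hit files."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from txqc.genome import GeneModel
from txqc.reads import ReadPair

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq_pairs(pairs: Iterable[ReadPair], path1, path2) -> None:
    """Write mates to two PHRED+33 FASTQ files with /1 and /2 id suffixes."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = "".join(chr(q + 33) for q in p.qual1)
            q2 = "".join(chr(q + 33) for q in p.qual2)
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{q2}\n")


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    pairs = []
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for r1, r2 in zip(it1, it2):
        id1 = r1.id[:-2] if r1.id.endswith("/1") else r1.id
        id2 = r2.id[:-2] if r2.id.endswith("/2") else r2.id
        if id1 != id2:
            raise ValueError(f"mate id mismatch: {r1.id} vs {r2.id}")
        pairs.append(
            ReadPair(
                id=id1,
                seq1=str(r1.seq).upper(),
                qual1=np.asarray(r1.letter_annotations["phred_quality"], dtype=np.int64),
                seq2=str(r2.seq).upper(),
                qual2=np.asarray(r2.letter_annotations["phred_quality"], dtype=np.int64),
            )
        )
    return pairs


def write_gff3(models: Iterable[GeneModel], path) -> None:
    """Emit gene -> mRNA -> exon features, 1-based inclusive coordinates."""
    models = list(models)
    gene_span: dict[str, list] = {}
    for m in models:
        s, e = m.span
        cur = gene_span.setdefault(m.gene_id, [m.scaffold, m.strand, s, e])
        cur[2], cur[3] = min(cur[2], s), max(cur[3], e)
    written_genes: set[str] = set()
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gstart = min(s for s, _ in m.exons)
            gend = max(e for _, e in m.exons)
            if m.gene_id not in written_genes:
                written_genes.add(m.gene_id)
                sc, st, gs, ge = gene_span[m.gene_id]
                fh.write(f"{sc}\ttxqc\tgene\t{gs}\t{ge}\t.\t{st}\t.\tID={m.gene_id}\n")
            mrna = m.transcript_id or f"{m.gene_id}.t1"
            fh.write(
                f"{m.scaffold}\ttxqc\tmRNA\t{gstart}\t{gend}\t.\t{m.strand}\t.\t"
                f"ID={mrna};Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.scaffold}\ttxqc\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )


def read_gff3(path) -> list[GeneModel]:
    """Read back the gene/mRNA/exon subset written by :func:`write_gff3`."""
    exons: dict[str, list[tuple[str, str, int, int]]] = {}
    mrna_to_gene: dict[str, str] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        scaffold, _, ftype, start, end, _, strand, _, attrs = cols
        fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if ftype == "mRNA":
            mrna_to_gene[fields["ID"]] = fields["Parent"]
            order.append(fields["ID"])
            exons.setdefault(fields["ID"], [])
        elif ftype == "exon":
            parent = fields["Parent"]
            exons.setdefault(parent, []).append((scaffold, strand, int(start), int(end)))
    models = []
    for mrna in order:
        ex = sorted(exons[mrna], key=lambda t: t[2])
        scaffold = ex[0][0]
        strand = ex[0][1]
        models.append(
            GeneModel(
                gene_id=mrna_to_gene[mrna],
                transcript_id=mrna,
                scaffold=scaffold,
                strand=strand,
                exons=[(s, e) for _, _, s, e in ex],
            )
        )
    return models


def read_hits_tsv(path) -> pd.DataFrame:
    """Read a generic tabular ortholog-hit file.

    Columns: query, subject, identity (percent), sstart, send, slen
    (subject coordinates 1-based inclusive, subject length in residues).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"query", "subject", "identity", "sstart", "send", "slen"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
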