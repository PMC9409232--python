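"""Readers and writers for the formats the pipeline touches.

FASTA and GFF3 carry the genomes and gene models; counts, Ct values and
transcript alignment blocks travel as headered TSV.  Files keep their native
conventions (GFF3 1-based inclusive); everything in memory is 0-based
half-open (see :mod:`mitocms.genome`).

Origin-wrapping gene models cannot be expressed natively in GFF3; they are
written as two features sharing an ID with ``part=1``/``part=2`` attributes
and rejoined on read.
"""

from __future__ import annotations

import os
import tempfile
from typing import Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .genome import CircularSequence, GeneModel, clean_sequence


# ---------------------------------------------------------------------------
# FASTA

def _is_circular_header(description: str) -> bool:
    d = description.lower()
    return "[circular]" in d or "circular=true" in d


def read_fasta(path) -> list[CircularSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        seq = clean_sequence(str(rec.seq), name=rec.id)
        out.append(CircularSequence(rec.id, seq, circular=_is_circular_header(rec.description)))
    return out


def write_fasta(path, genomes: Sequence[CircularSequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            tag = " [circular]" if g.circular else ""
            fh.write(f">{g.name}{tag}\n")
            for i in range(0, g.length, width):
                fh.write(g.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(path, models: Sequence[GeneModel], genomes: Sequence[CircularSequence] | None = None) -> None:
    """Write gene/exon features, splitting origin-wrapping models into parts."""
    lengths = {g.name: g.length for g in genomes} if genomes else {}
    lines = ["##gff-version 3"]
    for m in models:
        genomic = sorted(m.exons)
        gene_start, gene_end = genomic[0][0], genomic[-1][1]
        L = lengths.get(m.seq_name)
        if m.wrap and L is None:
            raise ValueError(f"writing wrapped gene {m.gene_id} requires the genome for its length")
        if m.wrap:
            # Two gene parts: [start, L) and [0, end-L); exons assigned to parts.
            parts = [(gene_start, L, 1), (0, gene_end - L, 2)]
            for ps, pe, pn in parts:
                attrs = f"ID={m.gene_id};biotype={m.biotype};part={pn}"
                lines.append(
                    "\t".join(
                        [m.seq_name, "mitocms", "gene", str(ps + 1), str(pe), ".", m.strand, ".", attrs]
                    )
                )
            for i, (s, e) in enumerate(genomic, 1):
                for seg_s, seg_e in _split_at(s, e, L):
                    lines.append(_exon_line(m, seg_s % L + 1, ((seg_e - 1) % L) + 1, i))
        else:
            attrs = f"ID={m.gene_id};biotype={m.biotype}"
            if m.pseudo:
                attrs += ";pseudo=true"
            lines.append(
                "\t".join(
                    [m.seq_name, "mitocms", "gene", str(gene_start + 1), str(gene_end), ".", m.strand, ".", attrs]
                )
            )
            for i, (s, e) in enumerate(genomic, 1):
                lines.append(_exon_line(m, s + 1, e, i))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _split_at(s: int, e: int, L: int):
    """Split a possibly origin-crossing exon [s, e) at the origin."""
    if e <= L:
        return [(s, e)]
    if s >= L:
        return [(s - L, e - L)]
    return [(s, L), (L, e)]


def _exon_line(m: GeneModel, start1: int, end1: int, idx: int) -> str:
    return "\t".join(
        [m.seq_name, "mitocms", "exon", str(start1), str(end1), ".", m.strand, ".",
         f"Parent={m.gene_id};exon_number={idx}"]
    )


def read_gff3(path, genomes: Sequence[CircularSequence]) -> list[GeneModel]:
    """Parse gene/exon features into GeneModels.

    Multi-part features sharing an ID with ``part=`` attributes are rejoined
    into a single origin-wrapping model.  Exon-less genes become single-exon
    models spanning the gene.
    """
    lengths = {g.name: g.length for g in genomes}
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: dict[str, dict] = {}
    for feat in db.features_of_type("gene"):
        if feat.seqid not in lengths:
            raise ValueError(f"unknown seqid {feat.seqid!r} in {path}")
        if feat.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be +/- (got {feat.strand!r})")
        gid = feat.attributes.get("ID", [feat.id])[0]
        entry = genes.setdefault(
            gid,
            {"seq_name": feat.seqid, "strand": feat.strand,
             "biotype": feat.attributes.get("biotype", ["protein_coding"])[0],
             "pseudo": feat.attributes.get("pseudo", ["false"])[0] == "true",
             "parts": [], "exons": []},
        )
        part = int(feat.attributes.get("part", ["0"])[0])
        entry["parts"].append((part, feat.start - 1, feat.end))
    for feat in db.features_of_type("exon"):
        parent = feat.attributes.get("Parent", [None])[0]
        if parent in genes:
            genes[parent]["exons"].append((feat.start - 1, feat.end))

    out = []
    for gid, entry in genes.items():
        L = lengths[entry["seq_name"]]
        wrap = len(entry["parts"]) > 1 and any(p for p, _, _ in entry["parts"])
        exons = sorted(entry["exons"]) or None
        if wrap:
            exons = _rejoin_wrapped(gid, entry["parts"], exons, L)
        else:
            if exons is None:
                _, s, e = entry["parts"][0]
                exons = [(s, e)]
            for s, e in exons:
                if e > L or s < 0:
                    raise ValueError(
                        f"exon {s + 1}..{e} of {gid} outside sequence bounds (length {L})"
                    )
        if entry["strand"] == "-":
            exons = exons[::-1]
        out.append(
            GeneModel(gid, entry["seq_name"], entry["strand"], exons,
                      biotype=entry["biotype"], pseudo=entry["pseudo"], wrap=wrap)
        )
    return out


def _rejoin_wrapped(gid, parts, exons, L):
    """Rejoin part=1 (tail of sequence) + part=2 (head) into wrapped coords."""
    by_part = sorted(parts)
    if len(by_part) != 2:
        raise ValueError(f"gene {gid}: expected exactly 2 parts, got {len(by_part)}")
    (_, s1, e1), (_, s2, e2) = by_part
    if e1 != L or s2 != 0:
        raise ValueError(f"gene {gid}: parts do not meet at the origin")
    if exons is None:
        return [(s1, L + e2)]
    joined = []
    for s, e in exons:
        if s >= s1:           # tail piece
            joined.append([s, e])
        else:                 # head piece, shifted past the origin
            joined.append([s + L, e + L])
    joined.sort()
    # merge the two pieces of the exon that crosses the origin
    merged = [joined[0]]
    for s, e in joined[1:]:
        if s == merged[-1][1]:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


# ---------------------------------------------------------------------------
# Tabular dialects

def read_counts_tsv(path) -> pd.DataFrame:
    """Gene-by-sample integer count table; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return df


def write_counts_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_ct_tsv(path) -> pd.DataFrame:
    """RT-qPCR Ct table: columns gene, condition, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "condition", "replicate", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def read_alignment_blocks(path) -> pd.DataFrame:
    """BED-like transcript alignment blocks: seq, start, end, transcript_id.

    Starts are 0-based half-open, the BED convention.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["seq", "start", "end", "transcript_id"], comment="#")
    return df


def write_alignment_blocks(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["seq", "start", "end", "transcript_id"])
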