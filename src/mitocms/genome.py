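"""Core sequence and annotation types for circular organelle genomes.

Plant mitochondrial genomes typically assemble into one or more circular
molecules, so every coordinate-bearing type here carries a wrap-aware
contract: a span may cross the origin of a circular sequence, in which case
its ``end`` exceeds the sequence length and slicing wraps around.

All coordinates are 0-based half-open internally.  File formats (GFF3, VCF)
keep their native 1-based conventions at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Seq import Seq

_ALLOWED = set("ACGTN")
# IUPAC one-letter ambiguity codes other than N; normalized to N on ingest.
_IUPAC_AMBIG = set("RYSWKMBDHV")


def clean_sequence(raw: str, name: str = "?") -> str:
    """Uppercase, convert U->T, and map IUPAC ambiguity codes to N.

    Raises ``ValueError`` on characters that are not nucleotides at all.
    """
    s = raw.upper().replace("U", "T")
    if set(s) <= _ALLOWED:
        return s
    cleaned = []
    n_ambig = 0
    for c in s:
        if c in _ALLOWED:
            cleaned.append(c)
        elif c in _IUPAC_AMBIG:
            cleaned.append("N")
            n_ambig += 1
        else:
            raise ValueError(f"non-nucleotide character {c!r} in sequence {name!r}")
    warnings.warn(
        f"{n_ambig} IUPAC ambiguity base(s) in {name!r} normalized to N",
        stacklevel=2,
    )
    return "".join(cleaned)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N stays N)."""
    if not set(seq) <= _ALLOWED:
        bad = sorted(set(seq) - _ALLOWED)
        raise ValueError(f"non-nucleotide character(s) {bad} in sequence")
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Span:
    """A located interval, 0-based half-open, optionally crossing the origin.

    ``wrap`` is true when the span crosses the circular origin, in which case
    ``end`` may run up to twice the sequence length.
    """

    seq_name: str
    start: int
    end: int
    strand: str = "+"
    wrap: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty span {self.start}..{self.end}")
        if self.start < 0:
            raise ValueError("negative span start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Span") -> bool:
        return self.seq_name == other.seq_name and self.start < other.end and other.start < self.end


@dataclass
class CircularSequence:
    """A named nucleotide sequence, optionally circular.

    ``fetch`` is the single point of coordinate truth: for a circular
    sequence a span with ``end > length`` wraps through the origin and
    returns the concatenation tail+head.
    """

    name: str
    seq: str
    circular: bool = False

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"empty sequence {self.name!r}")
        if not set(self.seq) <= _ALLOWED:
            raise ValueError(f"sequence {self.name!r} contains unnormalized characters")

    @property
    def length(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Wrap-aware slice.  0-based half-open; end may exceed length when circular."""
        L = self.length
        if not (0 <= start < L):
            raise IndexError(f"start {start} out of range for {self.name!r} (length {L})")
        if end <= start:
            raise IndexError(f"empty or inverted slice {start}..{end}")
        if end <= L:
            return self.seq[start:end]
        if not self.circular:
            raise IndexError(f"slice {start}..{end} beyond linear sequence of length {L}")
        if end - start > L:
            raise IndexError(f"slice {start}..{end} longer than the molecule ({L})")
        return self.seq[start:] + self.seq[: end - L]

    def fetch_span(self, span: Span) -> str:
        """Fetch a Span on its native strand (reverse-complemented for '-')."""
        s = self.fetch(span.start, span.end)
        return revcomp(s) if span.strand == "-" else s


@dataclass
class GeneModel:
    """An annotated gene: ordered exons, strand, and coding status.

    ``exons`` are (start, end) 0-based half-open genome-forward intervals,
    stored in 5'->3' order along the strand (descending genomic coordinates
    for '-' genes).  Exon spans may exceed the sequence length when the gene
    wraps the circular origin.
    """

    gene_id: str
    seq_name: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "protein_coding"
    pseudo: bool = False
    wrap: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for gene {self.gene_id}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")
        want = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != want:
            raise ValueError(f"exons of {self.gene_id} not ordered 5'->3' along strand")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, genome-forward, in transcript order.

        Intron i sits between exon i and exon i+1 (5'->3').
        """
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1, s2))
            else:
                out.append((e2, s1))
        return out

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def extract_spliced_cds(genome: CircularSequence, model: GeneModel) -> str:
    """Concatenate a gene's exons 5'->3', reverse-complementing '-' genes.

    Exon spans crossing the origin of a circular genome are resolved through
    ``fetch``.
    """
    if model.seq_name != genome.name:
        raise ValueError(f"gene {model.gene_id} is on {model.seq_name!r}, not {genome.name!r}")
    parts = []
    for s, e in model.exons:
        piece = genome.fetch(s, e)
        parts.append(revcomp(piece) if model.strand == "-" else piece)
    return "".join(parts)


def interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length covered by a set of (start, end) half-open intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total
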