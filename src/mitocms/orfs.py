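"""Six-frame ORF discovery on circular genomes.

ORFs are maximal ATG-initiated, stop-terminated open reading frames on both
strands; on a circular molecule frames crossing the origin are included.
Each stop codon contributes at most one ORF per frame — the longest one,
i.e. starting at the earliest in-frame ATG after the previous stop.  The
retained set is filtered to a minimum protein length (default 100 aa, the
convention for screening unidentified mitochondrial ORFs) and named
``orf<aa_length>`` with letter suffixes breaking ties in coordinate order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio.Seq import Seq
from Bio.Data import CodonTable

from .genome import CircularSequence, Span, revcomp

STOP_CODONS_TABLE1 = {"TAA", "TAG", "TGA"}


def translate(cds: str, table: int = 1) -> str:
    """Translate a CDS; internal stops appear as '*', N-containing codons as 'X'.

    Raises ``ValueError`` when the length is not a multiple of 3.
    """
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    codon_table = CodonTable.unambiguous_dna_by_id[table]
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            aas.append("X")
        elif codon in codon_table.stop_codons:
            aas.append("*")
        else:
            aas.append(codon_table.forward_table[codon])
    return "".join(aas)


def has_internal_stop(protein: str) -> bool:
    return "*" in protein


@dataclass
class OrfRecord:
    """One predicted ORF.  ``span`` includes the stop codon; ``protein`` omits it."""

    orf_id: str
    genome: str
    span: Span
    strand: str
    aa_length: int
    protein: str
    nt: str


def _scan_strand(seq: str, L: int, circular: bool, table: int, min_nt: int):
    """Yield (start, stop_end) of ORFs on one strand, coordinates on that strand.

    For circular sequences the doubled sequence is scanned so that frames
    crossing the origin are seen.  Each stop codon (mod L) keeps its longest
    candidate, which is the one scanned with complete upstream context; the
    caller receives starts normalized into [0, L).
    """
    s = seq + seq if circular else seq
    stops = CodonTable.unambiguous_dna_by_id[table].stop_codons
    n = len(s)
    best: dict[int, tuple[int, int]] = {}  # stop position mod L -> (start, end)
    for frame in range(3):
        pending_atg = None
        i = frame
        while i + 3 <= n:
            codon = s[i : i + 3]
            if pending_atg is None and codon == "ATG":
                pending_atg = i
            if codon in stops:
                if pending_atg is not None:
                    start, end = pending_atg, i + 3
                    if min_nt <= end - start <= L:
                        key = end % L if circular else end
                        cur = best.get(key)
                        if cur is None or (end - start) > (cur[1] - cur[0]):
                            best[key] = (start % L, start % L + (end - start))
                pending_atg = None
            i += 3
    yield from best.values()


def find_orfs(genome: CircularSequence, min_aa: int = 100, table: int = 1,
              inclusive: bool = True) -> list[OrfRecord]:
    """All maximal ATG-initiated ORFs >= the length cutoff, both strands.

    ``inclusive`` keeps ORFs of exactly ``min_aa`` residues (the default);
    set it False for a strict 'longer than' reading of the cutoff.
    """
    L = genome.length
    min_nt = 3 * (min_aa + 1) if inclusive else 3 * (min_aa + 2)
    out: list[OrfRecord] = []
    seen = set()
    for strand in ("+", "-"):
        seq = genome.seq if strand == "+" else revcomp(genome.seq)
        for s0, e0 in _scan_strand(seq, L, genome.circular, table, min_nt):
            if strand == "+":
                fs, fe = s0, e0
            else:
                # map strand-local coords back to forward coordinates
                fs, fe = L - e0, L - s0
                if fs < 0:  # ORF wraps the origin on the reverse strand
                    fs += L
                    fe += L
            key = (strand, fs % L, fe % L)
            if key in seen:
                continue
            seen.add(key)
            nt = seq[s0:e0] if e0 <= L else seq[s0:] + seq[: e0 - L]
            protein = translate(nt[:-3], table)
            wrap = fe > L
            out.append(
                OrfRecord(
                    orf_id="",
                    genome=genome.name,
                    span=Span(genome.name, fs, fe, strand, wrap=wrap),
                    strand=strand,
                    aa_length=len(protein),
                    protein=protein,
                    nt=nt,
                )
            )
    out.sort(key=lambda o: (o.strand, o.span.start, o.span.end))
    return name_orfs(out)


def name_orfs(orfs: list[OrfRecord]) -> list[OrfRecord]:
    """Assign ids ``orf<aa_length>`` with a/b/c suffixes for equal lengths.

    Suffixes are assigned in coordinate order; past 'z' a ``-k`` counter
    disambiguates further repeats (``orf119a-2`` style).
    """
    letters = "abcdefghijklmnopqrstuvwxyz"
    by_len: dict[int, list[OrfRecord]] = {}
    for o in sorted(orfs, key=lambda o: (o.span.start, o.span.end, o.strand)):
        by_len.setdefault(o.aa_length, []).append(o)
    named = {}
    for aa_len, group in by_len.items():
        for i, o in enumerate(group):
            suffix = letters[i % 26]
            rep = i // 26
            name = f"orf{aa_len}{suffix}" + (f"-{rep + 1}" if rep else "")
            named[id(o)] = name
    return [replace(o, orf_id=named[id(o)]) for o in orfs]
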