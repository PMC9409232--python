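"""Unique-ORF determination and chimeric decomposition.

CMS-associated ORFs are typically assembled by mitogenome recombination
from part of a known mitochondrial gene fused to sequence of unknown
origin.  This module (a) decides which ORFs exist in only one of the two
genomes, by best-reciprocal nucleotide matching, and (b) decomposes each
ORF against a known-CDS library with local alignments, tiling it into
known-gene and unknown segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
from Bio import Align

from .genome import revcomp
from .orfs import OrfRecord


@dataclass
class Segment:
    """One piece of an ORF: [start, end) on the ORF nucleotide sequence."""

    start: int
    end: int
    origin: str          # gene_id or "unknown"
    identity: float      # percent; 0 for unknown segments
    match_strand: str    # +/- strand of the library match; "." for unknown

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ChimeraDecomposition:
    orf_id: str
    segments: list[Segment]
    is_chimeric: bool
    known_bp: int
    unknown_bp: int


# ---------------------------------------------------------------------------
# Unique vs shared ORFs

def _kmer_set(seq: str, k: int = 15) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _match_stats_full(a: str, b: str) -> tuple[float, float, int]:
    """(identity %, coverage % of the shorter sequence, score) of the best local match."""
    if a == b:
        return 100.0, 100.0, len(a)
    if len(a) > len(b):
        a, b = b, a
    best = (0.0, 0.0, -1)
    for query in (a, revcomp(a)):
        h = _trimmed_local_hit(query, b)
        if h is None:
            continue
        if h["score"] > best[2]:
            best = (h["identity"], 100.0 * (h["end"] - h["start"]) / len(a), h["score"])
    return best


def _match_stats(a: str, b: str) -> tuple[float, float]:
    """(identity %, coverage % of the shorter sequence) of the best local match."""
    ident, cov, _ = _match_stats_full(a, b)
    return ident, cov


def match_orfs(orfsA: list[OrfRecord], orfsB: list[OrfRecord],
               min_identity: float = 95.0, min_coverage: float = 90.0) -> dict:
    """Partition two ORF sets into shared / uniqueA / uniqueB.

    An ORF is shared when a counterpart aligns at >= ``min_identity``
    percent over >= ``min_coverage`` percent of the shorter sequence, with
    the two lengths within the same coverage factor of each other.  The
    length condition stops a long chimeric ORF from being "matched" by a
    small ORF nested in its known segment; conversely an ORF duplicated
    within one genome is shared as long as any qualifying counterpart
    exists.  The best-scoring qualifying counterpart is reported.
    """
    # k-mer prescreen keeps the all-vs-all alignment count down
    kmA = [(_kmer_set(o.nt) | _kmer_set(revcomp(o.nt)), o) for o in orfsA]
    kmB = [(_kmer_set(o.nt) | _kmer_set(revcomp(o.nt)), o) for o in orfsB]

    def best_hit(o, pool_kmers):
        ks = _kmer_set(o.nt)
        best, best_score = None, -1
        for kset, other in pool_kmers:
            if ks and len(ks & kset) / max(1, min(len(ks), len(kset))) < 0.05:
                continue
            ratio = 100.0 * min(len(o.nt), len(other.nt)) / max(len(o.nt), len(other.nt))
            if ratio < min_coverage:
                continue
            ident, cov, score = _match_stats_full(o.nt, other.nt)
            if ident >= min_identity and cov >= min_coverage and score > best_score:
                best, best_score = other, score
        return best

    shared, uniqueA, uniqueB = [], [], []
    matchedB = set()
    for o in orfsA:
        hit = best_hit(o, kmB)
        if hit is not None:
            shared.append((o, hit))
            matchedB.add(hit.orf_id)
        else:
            uniqueA.append(o)
    for o in orfsB:
        if o.orf_id in matchedB:
            continue
        hit = best_hit(o, kmA)
        if hit is not None:
            shared.append((hit, o))
        else:
            uniqueB.append(o)
    return {"shared": shared, "uniqueA": uniqueA, "uniqueB": uniqueB}


# ---------------------------------------------------------------------------
# Decomposition against a known-CDS library

def _local_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -2
    return al


def _trimmed_local_hit(query: str, target: str):
    """Best Smith-Waterman hit of query in target with end trimming.

    Returns {"score", "identity", "start", "end"} with start/end on the
    query, or None.  See the inline note on why ends are re-trimmed.
    """
    al = _local_aligner()
    alns = al.align(query, target)
    if len(alns) == 0:
        return None
    aln = alns[0]
    # aln[0]/aln[1] hold the locally aligned region only; the query
    # coordinate of its first column is aln.aligned[0][0][0]
    ra, rb = str(aln[0]), str(aln[1])
    first = int(aln.aligned[0][0][0])
    matchmask = [(x == y and x != "-") for x, y in zip(ra, rb)]
    advance = [(1 if x != "-" else 0) for x in ra]

    # A Smith-Waterman path happily drags a low-identity tail along as long
    # as its net score stays positive, which drifts hit boundaries past the
    # true homology junction.  Re-score columns with a stricter penalty
    # (match +1, mismatch/gap -4) and keep the shortest maximal-scoring
    # sub-path, so the hit ends where sustained ~80%+ local identity ends.
    colscore = [1 if m else -4 for m in matchmask]
    prefix = [0]
    for s in colscore:
        prefix.append(prefix[-1] + s)
    hi = prefix.index(max(prefix))
    lo = max(j for j in range(hi + 1) if prefix[j] == min(prefix[: hi + 1]))
    if hi <= lo:
        return None
    matches = sum(matchmask[lo:hi])
    ncols = hi - lo
    return {
        "score": sum(1 if matchmask[i] else -1 for i in range(lo, hi)),
        "identity": 100.0 * matches / ncols,
        "start": first + sum(advance[:lo]),
        "end": first + sum(advance[:hi]),
    }


def _best_local_hit(orf_nt: str, cds: str):
    """Best trimmed local hit of a library CDS inside the ORF, both strands."""
    best = None
    for strand, target in (("+", cds), ("-", revcomp(cds))):
        h = _trimmed_local_hit(orf_nt, target)
        if h is None:
            continue
        h = {**h, "strand": strand}
        if best is None or h["score"] > best["score"]:
            best = h
    return best


def decompose(orf: OrfRecord, cds_library: list[tuple[str, str]],
              min_seg: int = 30, min_identity: float = 90.0,
              min_known_bp: int = 30, min_unknown_bp: int = 30) -> ChimeraDecomposition:
    """Tile an ORF into known-gene and unknown segments.

    Local alignments of the ORF against every library CDS are collected
    (both strands), filtered at ``min_seg`` bp and ``min_identity`` percent,
    and selected greedily by score with overlap trimming.  Uncovered
    stretches of at least ``min_seg`` bp become unknown segments; shorter
    gaps are absorbed into the flanking known segment.
    """
    if not cds_library:
        raise ValueError("empty CDS library")
    n = len(orf.nt)
    hits = []
    orf_kmers = _kmer_set(orf.nt) | _kmer_set(revcomp(orf.nt))
    for gene_id, cds in sorted(cds_library):
        # a >=min_seg bp match at >=90% identity implies shared exact 15-mers
        if not orf_kmers & _kmer_set(cds):
            continue
        h = _best_local_hit(orf.nt, cds)
        if h and h["end"] - h["start"] >= min_seg and h["identity"] >= min_identity:
            hits.append((h["score"], h["end"] - h["start"], gene_id, h))
    # greedy by score, ties by longer hit then lexicographic gene id
    hits.sort(key=lambda t: (-t[0], -t[1], t[2]))
    chosen: list[Segment] = []
    covered: list[tuple[int, int]] = []
    for _, _, gene_id, h in hits:
        s, e = h["start"], h["end"]
        for cs, ce in covered:
            if s < ce and cs < e:  # trim to the uncovered part
                if s >= cs and e <= ce:
                    s = e = 0
                    break
                if s < cs:
                    e = min(e, cs)
                else:
                    s = max(s, ce)
        if e - s >= min_seg:
            chosen.append(Segment(s, e, gene_id, h["identity"], h["strand"]))
            covered.append((s, e))
            covered.sort()
    chosen.sort(key=lambda seg: seg.start)

    # tile: fill gaps with unknown segments or absorb short ones
    segments: list[Segment] = []
    pos = 0
    for seg in chosen:
        gap = seg.start - pos
        if gap >= min_seg:
            segments.append(Segment(pos, seg.start, "unknown", 0.0, "."))
        elif gap > 0:
            if segments:
                segments[-1].end = seg.start
            else:
                seg.start = pos  # absorb leading sliver into the first known segment
        segments.append(seg)
        pos = seg.end
    if n - pos >= min_seg:
        segments.append(Segment(pos, n, "unknown", 0.0, "."))
    elif n - pos > 0:
        if segments:
            segments[-1].end = n
        else:
            segments.append(Segment(0, n, "unknown", 0.0, "."))
    if not segments:
        segments = [Segment(0, n, "unknown", 0.0, ".")]

    known_bp = sum(len(s) for s in segments if s.origin != "unknown")
    unknown_bp = n - known_bp
    is_chimeric = (
        any(s.origin != "unknown" and len(s) >= min_known_bp for s in segments)
        and any(s.origin == "unknown" and len(s) >= min_unknown_bp for s in segments)
    )
    return ChimeraDecomposition(orf.orf_id, segments, is_chimeric, known_bp, unknown_bp)


def decompositions_to_rows(decs: list[ChimeraDecomposition]) -> list[dict]:
    """Flat per-segment records for TSV/JSON reporting."""
    rows = []
    for d in decs:
        for seg in d.segments:
            rows.append(
                {
                    "orf_id": d.orf_id, "start": seg.start + 1, "end": seg.end,
                    "origin": seg.origin, "identity": round(seg.identity, 1),
                    "strand": seg.match_strand, "is_chimeric": d.is_chimeric,
                }
            )
    return rows
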