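"""Direct and inverted repeat annotation by native seed-and-extend.

Repeats are found by indexing k-mers of the genome against itself (direct,
DR) and against its reverse complement (inverted, IR).  Co-diagonal seed
runs become maximal exact matches; near-diagonal matches separated by small
gaps are chained and re-aligned with a gapped edit-distance alignment so a
long near-identical repeat interrupted by short indels is reported as one
pair with its percent identity and per-copy indel content — the way plant
mitogenome repeat tables present them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .genome import CircularSequence, Span, interval_union_length, revcomp


@dataclass
class RepeatPair:
    """Two copies of one repeat within a genome."""

    repeat_id: str
    copy1: Span
    copy2: Span
    rtype: str  # DR or IR
    size1: int
    size2: int
    identity: float  # percent, matches / alignment columns * 100
    copy1_indel_bp: int = 0
    copy2_indel_bp: int = 0

    @property
    def size(self) -> int:
        return max(self.size1, self.size2)


def _kmer_matches(s1: str, s2: str, k: int, self_compare: bool):
    """Seed positions (p1, p2) of shared k-mers; for self-comparison only p1 < p2."""
    index: dict[str, list[int]] = {}
    for i in range(len(s1) - k + 1):
        km = s1[i : i + k]
        if "N" in km:
            continue
        index.setdefault(km, []).append(i)
    pairs = []
    if self_compare:
        for positions in index.values():
            if len(positions) < 2:
                continue
            for a in range(len(positions)):
                for b in range(a + 1, len(positions)):
                    pairs.append((positions[a], positions[b]))
    else:
        for j in range(len(s2) - k + 1):
            km = s2[j : j + k]
            if "N" in km:
                continue
            for i in index.get(km, ()):
                pairs.append((i, j))
    return pairs


def _mems_from_seeds(pairs, s1, s2, k):
    """Merge co-diagonal seeds into maximal exact matches (p1, p2, length)."""
    by_diag: dict[int, list[int]] = {}
    for p1, p2 in pairs:
        by_diag.setdefault(p2 - p1, []).append(p1)
    mems = []
    for diag, starts in by_diag.items():
        starts.sort()
        runs = []
        run_s = prev = starts[0]
        for p in starts[1:]:
            if p <= prev + k:  # overlapping/adjacent seeds on the same diagonal
                prev = p
            else:
                runs.append((run_s, prev + k))
                run_s = prev = p
        runs.append((run_s, prev + k))
        for a, b in runs:
            # extend exactly at both ends
            p1, p2 = a, a + diag
            ln = b - a
            while p1 > 0 and p2 > 0 and s1[p1 - 1] == s2[p2 - 1] and s1[p1 - 1] != "N":
                p1 -= 1
                p2 -= 1
                ln += 1
            while p1 + ln < len(s1) and p2 + ln < len(s2) and s1[p1 + ln] == s2[p2 + ln] and s1[p1 + ln] != "N":
                ln += 1
            mems.append((p1, p2, ln))
    return sorted(set(mems))


def _chain_mems(mems, max_gap: int = 100, max_drift: int = 100):
    """Chain MEMs that continue one another (small gaps, bounded diagonal drift)."""
    mems = sorted(mems)
    used = [False] * len(mems)
    chains = []
    for i, (p1, p2, ln) in enumerate(mems):
        if used[i]:
            continue
        chain = [(p1, p2, ln)]
        used[i] = True
        e1, e2 = p1 + ln, p2 + ln
        diag = p2 - p1
        for j in range(i + 1, len(mems)):
            q1, q2, lm = mems[j]
            if used[j]:
                continue
            if q1 > e1 + max_gap:
                break
            g1, g2 = q1 - e1, q2 - e2
            if -max_drift <= g1 <= max_gap and -max_drift <= g2 <= max_gap and abs((q2 - q1) - diag) <= max_drift:
                chain.append((q1, q2, lm))
                used[j] = True
                e1, e2 = q1 + lm, q2 + lm
                diag = q2 - q1
        chains.append(chain)
    return chains


def _align_identity(a: str, b: str):
    """Global alignment identity (percent) and per-sequence gap bp via edlib."""
    if a == b:
        return 100.0, 0, 0
    res = edlib.align(a, b, task="path", mode="NW")
    cols = matches = gaps_a = gaps_b = 0
    for num, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        n = int(num)
        cols += n
        if op == "=":
            matches += n
        elif op == "I":   # present in query (a), gap in target (b)
            gaps_b += n
        elif op == "D":   # gap in query (a)
            gaps_a += n
    return 100.0 * matches / cols, gaps_a, gaps_b


def find_repeats(genome: CircularSequence, min_len: int = 50, min_identity: float = 99.0,
                 k: int = 21, max_gap: int = 100) -> list[RepeatPair]:
    """Annotate DR/IR pairs of at least ``min_len`` bp at ``min_identity`` percent.

    Output is sorted by size descending then coordinates, with contained
    pairs removed and the trivial self-diagonal excluded.
    """
    if min_len < k:
        raise ValueError(f"min_len ({min_len}) must be >= seed length k ({k})")
    s = genome.seq
    L = genome.length
    candidates: list[RepeatPair] = []

    def add_candidate(span1, span2, rtype):
        a = s[span1[0] : span1[1]]
        b = s[span2[0] : span2[1]]
        if rtype == "IR":
            b = revcomp(b)
        ident, gaps_a, gaps_b = _align_identity(a, b)
        size1, size2 = len(a), len(b)
        if min(size1, size2) < min_len or ident < min_identity:
            return
        if span1 == span2:
            return
        c1 = Span(genome.name, span1[0], span1[1])
        c2 = Span(genome.name, span2[0], span2[1])
        if c1.start > c2.start:
            c1, c2 = c2, c1
            size1, size2 = size2, size1
            gaps_a, gaps_b = gaps_b, gaps_a
        candidates.append(
            RepeatPair("", c1, c2, rtype, size1, size2, ident, gaps_a, gaps_b)
        )

    # Direct repeats: genome vs itself
    pairs = _kmer_matches(s, s, k, self_compare=True)
    mems = [(p1, p2, ln) for p1, p2, ln in _mems_from_seeds(pairs, s, s, k) if p1 != p2]
    for chain in _chain_mems(mems, max_gap=max_gap):
        p1s = min(c[0] for c in chain)
        p1e = max(c[0] + c[2] for c in chain)
        p2s = min(c[1] for c in chain)
        p2e = max(c[1] + c[2] for c in chain)
        if p1e > p2s:  # overlapping copies are allowed only if not identical span
            if (p1s, p1e) == (p2s, p2e):
                continue
        add_candidate((p1s, p1e), (p2s, p2e), "DR")

    # Inverted repeats: genome vs its reverse complement
    rc = revcomp(s)
    pairs = _kmer_matches(s, rc, k, self_compare=False)
    mems = _mems_from_seeds(pairs, s, rc, k)
    seen_ir = set()
    for chain in _chain_mems(mems, max_gap=max_gap):
        p1s = min(c[0] for c in chain)
        p1e = max(c[0] + c[2] for c in chain)
        q_s = min(c[1] for c in chain)
        q_e = max(c[1] + c[2] for c in chain)
        # map rc coordinates back to forward coordinates
        p2s, p2e = L - q_e, L - q_s
        key = tuple(sorted([(p1s, p1e), (p2s, p2e)]))
        if key in seen_ir:
            continue
        seen_ir.add(key)
        if (p1s, p1e) == (p2s, p2e):
            continue
        add_candidate((p1s, p1e), (p2s, p2e), "IR")

    # drop pairs contained within another pair of the same type
    candidates.sort(key=lambda r: (-r.size, r.copy1.start, r.copy2.start))
    kept: list[RepeatPair] = []
    for cand in candidates:
        contained = False
        for big in kept:
            if big.rtype == cand.rtype and _contains(big.copy1, cand.copy1) and _contains(big.copy2, cand.copy2):
                contained = True
                break
            if big.rtype == cand.rtype and _contains(big.copy1, cand.copy2) and _contains(big.copy2, cand.copy1):
                contained = True
                break
        if not contained:
            kept.append(cand)

    kept.sort(key=lambda r: (-r.size, r.copy1.start, r.copy2.start))
    for i, r in enumerate(kept, 1):
        r.repeat_id = f"R{i}"
    return kept


def _contains(outer: Span, inner: Span) -> bool:
    return outer.start <= inner.start and inner.end <= outer.end


def classify_repeat_sizes(repeats: list[RepeatPair]) -> dict:
    """Size-class tally: >10 kb, large (>1 kb) and small (<=1 kb), overall and by type."""
    def tally(rs):
        return {
            "count_gt_10kb": sum(1 for r in rs if r.size > 10_000),
            "count_gt_1kb": sum(1 for r in rs if r.size > 1_000),
            "count_le_1kb": sum(1 for r in rs if r.size <= 1_000),
        }

    out = tally(repeats)
    out["by_type"] = {t: tally([r for r in repeats if r.rtype == t]) for t in ("DR", "IR")}
    return out


def repeat_content(genome: CircularSequence, repeats: list[RepeatPair]) -> float:
    """Percent of the genome covered by the union of all repeat copies."""
    intervals = []
    for r in repeats:
        intervals.append((r.copy1.start, r.copy1.end))
        intervals.append((r.copy2.start, r.copy2.end))
    return 100.0 * interval_union_length(intervals) / genome.length


def repeats_to_tsv(repeats: list[RepeatPair], path) -> None:
    """BED-like TSV report (1-based inclusive coordinates, as repeat tables print)."""
    with open(path, "w") as fh:
        fh.write("repeat_id\tseq\tstart1\tend1\tstart2\tend2\ttype\tsize1\tsize2\tidentity\n")
        for r in repeats:
            fh.write(
                f"{r.repeat_id}\t{r.copy1.seq_name}\t{r.copy1.start + 1}\t{r.copy1.end}\t"
                f"{r.copy2.start + 1}\t{r.copy2.end}\t{r.rtype}\t{r.size1}\t{r.size2}\t"
                f"{round(r.identity)}\n"
            )
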