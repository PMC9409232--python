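"""Pairwise whole-genome comparison: synteny blocks, SNPs/InDels, coding effects.

The comparison is anchor-based: unique shared k-mers are chained into
synteny blocks (classified as collinear / translocation / inversion /
translocation+inversion), and the short stretches between consecutive
anchors are globally aligned to call base-level variants.  InDel gap
placement is left-normalized (the VCF convention) so coordinates are
deterministic regardless of how an aligner happened to place a gap.

Coding effects are annotated codon-aware on the spliced CDS: a substitution
is synonymous or non-synonymous by direct genetic-code comparison; an InDel
whose length is not a multiple of 3 is a frameshift, reported with the
number of downstream residues altered before the first stop in the new
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
from Bio import Align

from .genome import CircularSequence, GeneModel, Span, extract_spliced_cds, revcomp
from .orfs import translate

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


@dataclass
class SyntenyBlock:
    spanA: Span
    spanB: Span
    orientation: str  # forward | inverted
    sv_class: str = "collinear"
    anchors: list = field(default_factory=list, repr=False)
    anchor_k: int = 31


@dataclass
class Variant:
    vtype: str            # SNP | insertion | deletion
    posA: int             # 0-based internally; +1 in reports
    posB: int
    refA: str
    altB: str
    location_class: str = "intergenic"   # genic | intronic | intergenic
    gene_id: str | None = None
    snp_class: str | None = None          # transition | transversion
    coding_effect: str | None = None      # synonymous | non-synonymous | frameshift | noncoding | NA
    aa_change: tuple[str, str] | None = None
    frameshift_aa: int | None = None

    @property
    def length(self) -> int:
        if self.vtype == "SNP":
            return 1
        return len(self.altB) if self.vtype == "insertion" else len(self.refA)


# ---------------------------------------------------------------------------
# Anchoring and synteny blocks

def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        counts[km] = counts.get(km, 0) + 1
        pos[km] = i
    return {km: p for km, p in pos.items() if counts[km] == 1}


def align_genomes(genomeA: CircularSequence, genomeB: CircularSequence,
                  anchor_k: int = 31, max_gap: int = 5000) -> list[SyntenyBlock]:
    """Chain unique shared k-mers into oriented synteny blocks.

    Blocks are classified by comparing their order along both genomes:
    blocks on the longest increasing subsequence of B-coordinates are in
    place (collinear, or inversion when their orientation is flipped);
    blocks off it are translocations (plus inversion when flipped).
    """
    ka = _unique_kmers(genomeA.seq, anchor_k)
    kb = _unique_kmers(genomeB.seq, anchor_k)
    kb_rc = _unique_kmers(revcomp(genomeB.seq), anchor_k)
    LB = genomeB.length

    anchors = []  # (posA, posB, orientation); posB always on B forward strand start
    for km, pa in ka.items():
        if km in kb:
            anchors.append((pa, kb[km], "forward"))
        elif km in kb_rc:
            # anchor sits on B reverse strand; forward-strand start of the k-mer
            anchors.append((pa, LB - kb_rc[km] - anchor_k, "inverted"))
    if not anchors:
        raise ValueError("no shared unique anchors; genomes appear unrelated")
    anchors.sort()

    # greedy chaining along A
    blocks: list[SyntenyBlock] = []
    cur: list[tuple[int, int, str]] = []

    def flush():
        if not cur:
            return
        orient = cur[0][2]
        a_s, a_e = cur[0][0], cur[-1][0] + anchor_k
        bs = [p for _, p, _ in cur]
        b_s, b_e = min(bs), max(bs) + anchor_k
        blocks.append(
            SyntenyBlock(
                Span(genomeA.name, a_s, a_e),
                Span(genomeB.name, b_s, b_e),
                orient,
                anchors=list(cur),
                anchor_k=anchor_k,
            )
        )

    for a in anchors:
        if not cur:
            cur = [a]
            continue
        pa, pb, orient = a
        qa, qb, qorient = cur[-1]
        step_ok = (
            orient == qorient
            and pa - qa <= max_gap
            and ((orient == "forward" and 0 <= pb - qb <= max_gap)
                 or (orient == "inverted" and 0 <= qb - pb <= max_gap))
        )
        if step_ok:
            cur.append(a)
        else:
            flush()
            cur = [a]
    flush()

    # Classification.  The collinear backbone is a length-weighted longest
    # increasing subsequence (by B coordinate) over the forward blocks;
    # forward blocks off the backbone are translocations.  An inverted block
    # is an in-place inversion when its B span fits between its backbone
    # neighbours, otherwise it both moved and flipped.
    fwd_idx = [i for i, b in enumerate(blocks) if b.orientation == "forward"]
    backbone = set()
    if fwd_idx:
        starts = [blocks[i].spanB.start for i in fwd_idx]
        weights = [len(blocks[i].spanA) for i in fwd_idx]
        for j in _weighted_lis(starts, weights):
            backbone.add(fwd_idx[j])
    for i, b in enumerate(blocks):
        if b.orientation == "forward":
            b.sv_class = "collinear" if i in backbone else "translocation"
    for i, b in enumerate(blocks):
        if b.orientation != "inverted":
            continue
        prev_end = max(
            (blocks[j].spanB.end for j in backbone if j < i), default=0
        )
        next_start = min(
            (blocks[j].spanB.start for j in backbone if j > i),
            default=genomeB.length,
        )
        in_place = prev_end <= b.spanB.start and b.spanB.end <= next_start
        b.sv_class = "inversion" if in_place else "translocation+inversion"
    return blocks


def _weighted_lis(xs: list[int], weights: list[int]) -> list[int]:
    """Indices of the maximum-weight increasing subsequence of xs."""
    n = len(xs)
    if n == 0:
        return []
    best = list(weights)
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if xs[j] < xs[i] and best[j] + weights[i] > best[i]:
                best[i] = best[j] + weights[i]
                prev[i] = j
    end = max(range(n), key=lambda i: best[i])
    out = []
    while end != -1:
        out.append(end)
        end = prev[end]
    return out[::-1]


# ---------------------------------------------------------------------------
# Base-level calls

def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -4
    al.extend_gap_score = -1
    return al


def normalize_indel(ref: str, pos: int, seq: str, vtype: str) -> tuple[int, str]:
    """Left-normalize an indel against the reference context (VCF convention).

    ``pos`` is the 0-based position where ``seq`` is deleted from (deletion)
    or inserted before (insertion) the reference ``ref``.
    """
    seq = list(seq)
    if vtype == "deletion":
        ln = len(seq)
        while pos > 0 and ref[pos - 1] == ref[pos + ln - 1]:
            pos -= 1
        seq = list(ref[pos : pos + ln])
    elif vtype == "insertion":
        while pos > 0 and seq[-1] == ref[pos - 1]:
            seq.insert(0, ref[pos - 1])
            seq.pop()
            pos -= 1
    else:
        raise ValueError(vtype)
    return pos, "".join(seq)


def _columns_from_alignment(a: str, b: str):
    """Aligned column pairs for two short sequences (spec NW scoring for <=500 bp)."""
    if max(len(a), len(b)) <= 500:
        aln = _aligner().align(a, b)[0]
        ra, rb = str(aln[0]), str(aln[1])
    else:
        res = edlib.align(a, b, task="path", mode="NW")
        nice = edlib.getNiceAlignment(res, a, b)
        ra, rb = nice["query_aligned"], nice["target_aligned"]
    return ra, rb


def call_variants(blocks: list[SyntenyBlock], genomeA: CircularSequence,
                  genomeB: CircularSequence, min_block_identity: float = 70.0):
    """Base-level SNP/InDel calls within synteny blocks.

    Returns (variants, complex_regions); regions whose alignment identity
    falls below ``min_block_identity`` percent yield no base-level calls and
    are reported as complex-InDel regions instead.
    """
    variants: list[Variant] = []
    complex_regions: list[tuple[Span, Span]] = []
    for block in blocks:
        if block.orientation != "forward":
            continue  # calls are made in collinear orientation only
        anchors = sorted(block.anchors)
        segs = []
        k = block.anchor_k
        for (a1, b1, _), (a2, b2, _) in zip(anchors, anchors[1:]):
            sa, sb = a1 + k, b1 + k
            # adjacent anchor extents may overlap on one genome when a flank
            # base happens to match across an indel; trim the right anchor
            over = max(sa - a2, sb - b2, 0)
            if over >= k:
                continue
            a2, b2 = a2 + over, b2 + over
            if a2 > sa or b2 > sb:
                segs.append((sa, a2, sb, b2))
        for a_s, a_e, b_s, b_e in segs:
            segA = genomeA.seq[a_s:a_e]
            segB = genomeB.seq[b_s:b_e]
            if segA == segB:
                continue
            if not segA or not segB:
                # pure insertion/deletion between flush anchors
                if segB:
                    variants.append(_make_indel(genomeA.seq, a_s, segB, "insertion", a_s, b_s))
                else:
                    variants.append(_make_indel(genomeA.seq, a_s, segA, "deletion", a_s, b_s))
                continue
            ident = _quick_identity(segA, segB)
            if ident < min_block_identity and min(len(segA), len(segB)) > 50:
                complex_regions.append(
                    (Span(genomeA.name, a_s, a_e), Span(genomeB.name, b_s, b_e))
                )
                continue
            ra, rb = _columns_from_alignment(segA, segB)
            variants.extend(_parse_columns(ra, rb, genomeA.seq, a_s, b_s))
    variants.sort(key=lambda v: v.posA)
    return variants, complex_regions


def _quick_identity(a: str, b: str) -> float:
    d = edlib.align(a, b, task="distance", mode="NW")["editDistance"]
    return 100.0 * (1 - d / max(len(a), len(b)))


def _parse_columns(ra: str, rb: str, refseq: str, a_off: int, b_off: int) -> list[Variant]:
    out = []
    ia, ib = 0, 0
    i = 0
    n = len(ra)
    while i < n:
        ca, cb = ra[i], rb[i]
        if ca != "-" and cb != "-":
            if ca != cb:
                out.append(
                    Variant("SNP", a_off + ia, b_off + ib, ca, cb,
                            snp_class=classify_snp(ca, cb))
                )
            ia += 1
            ib += 1
            i += 1
        elif ca == "-":  # run of insertion (present in B only)
            j = i
            ins = []
            while j < n and ra[j] == "-":
                ins.append(rb[j])
                j += 1
            out.append(_make_indel(refseq, a_off + ia, "".join(ins), "insertion",
                                   a_off + ia, b_off + ib))
            ib += len(ins)
            i = j
        else:            # run of deletion (absent from B)
            j = i
            dele = []
            while j < n and rb[j] == "-":
                dele.append(ra[j])
                j += 1
            out.append(_make_indel(refseq, a_off + ia, "".join(dele), "deletion",
                                   a_off + ia, b_off + ib))
            ia += len(dele)
            i = j
    return out


def _make_indel(refseq: str, pos: int, seq: str, vtype: str, posA: int, posB: int) -> Variant:
    shift_src = pos
    npos, nseq = normalize_indel(refseq, pos, seq, vtype)
    shift = shift_src - npos
    if vtype == "insertion":
        return Variant("insertion", npos, posB - shift, "", nseq)
    return Variant("deletion", npos, posB - shift, nseq, "")


# ---------------------------------------------------------------------------
# Classification

def classify_snp(refA: str, altB: str) -> str:
    """Transition (A<->G, C<->T) vs transversion."""
    if refA == altB:
        raise ValueError("alleles are equal")
    if refA not in "ACGT" or altB not in "ACGT" or len(refA) != 1 or len(altB) != 1:
        raise ValueError(f"bad alleles {refA!r}/{altB!r}")
    both = {refA, altB}
    if both <= PURINES or both <= PYRIMIDINES:
        return "transition"
    return "transversion"


def locate_variant(v: Variant, models: list[GeneModel]) -> Variant:
    """Assign genic / intronic / intergenic by position on genome A.

    Genic means within an exon of a protein-coding model; positions inside
    an intron of such a model are labelled intronic (reported separately,
    folded into the intergenic tally in summaries).
    """
    pos = v.posA
    v.location_class = "intergenic"
    v.gene_id = None
    for m in models:
        if m.biotype != "protein_coding":
            continue
        for s, e in m.exons:
            if s <= pos < e:
                v.location_class = "genic"
                v.gene_id = m.gene_id
                return v
        for s, e in m.introns():
            if s <= pos < e:
                v.location_class = "intronic"
                v.gene_id = m.gene_id
    return v


def coding_effect(v: Variant, model: GeneModel, genomeA: CircularSequence,
                  genomeB: CircularSequence, table: int = 1) -> Variant:
    """Annotate the codon-level consequence of a genic variant.

    SNP: substitute the base in the spliced CDS and compare the affected
    residue.  Frameshifting InDel: count residues differing from the
    original translation before the first stop in the shifted frame.
    """
    cds = extract_spliced_cds(genomeA, model)
    if len(cds) % 3:
        v.coding_effect = "NA"
        return v
    cds_pos = _genome_to_cds(model, v.posA)
    if cds_pos is None:
        v.coding_effect = "noncoding"
        return v

    if v.vtype == "SNP":
        alt = v.altB if model.strand == "+" else revcomp(v.altB)
        mutated = cds[:cds_pos] + alt + cds[cds_pos + 1 :]
        ci = cds_pos // 3
        aaA = translate(cds[3 * ci : 3 * ci + 3], table)
        aaB = translate(mutated[3 * ci : 3 * ci + 3], table)
        v.aa_change = (aaA, aaB)
        v.coding_effect = "synonymous" if aaA == aaB else "non-synonymous"
        return v

    # InDel inside the CDS
    length = v.length
    if length % 3 == 0:
        v.coding_effect = "inframe-indel"
        return v
    if v.vtype == "insertion":
        ins = v.altB if model.strand == "+" else revcomp(v.altB)
        mutated = cds[:cds_pos] + ins + cds[cds_pos:]
    else:
        mutated = cds[:cds_pos] + cds[cds_pos + length :]
    orig_aa = translate(cds[: 3 * (len(cds) // 3)], table)
    mut_aa = translate(mutated[: 3 * (len(mutated) // 3)], table)
    affected = 0
    for i, aa in enumerate(mut_aa):
        if aa == "*":
            break
        if i >= len(orig_aa) or aa != orig_aa[i]:
            affected += 1
    v.coding_effect = "frameshift"
    v.frameshift_aa = affected
    return v


def _genome_to_cds(model: GeneModel, pos: int) -> int | None:
    """Map a genome-forward position to its 0-based index in the spliced CDS."""
    offset = 0
    for s, e in model.exons:
        if s <= pos < e:
            if model.strand == "+":
                return offset + (pos - s)
            return offset + (e - 1 - pos)
        offset += e - s
    return None


def annotate_variants(variants: list[Variant], models: list[GeneModel],
                      genomeA: CircularSequence, genomeB: CircularSequence,
                      table: int = 1) -> list[Variant]:
    """Locate every variant and annotate coding effects of genic ones."""
    by_gene = {m.gene_id: m for m in models}
    for v in variants:
        locate_variant(v, models)
        if v.location_class == "genic" and v.gene_id:
            coding_effect(v, by_gene[v.gene_id], genomeA, genomeB, table)
        elif v.location_class in ("intronic", "intergenic"):
            v.coding_effect = "noncoding"
    return variants


def summarize_variants(variants: list[Variant]) -> dict:
    """Count table mirroring a pairwise comparison report."""
    snps = [v for v in variants if v.vtype == "SNP"]
    ins = [v for v in variants if v.vtype == "insertion"]
    dels = [v for v in variants if v.vtype == "deletion"]
    hist: dict[int, int] = {}
    for v in ins + dels:
        hist[v.length] = hist.get(v.length, 0) + 1
    return {
        "n_snp": len(snps),
        "n_ins": len(ins),
        "n_del": len(dels),
        "n_genic": sum(1 for v in snps if v.location_class == "genic"),
        # the genic/intergenic dichotomy folds intronic into intergenic
        "n_intergenic": sum(1 for v in snps if v.location_class in ("intergenic", "intronic")),
        "n_syn": sum(1 for v in variants if v.coding_effect == "synonymous"),
        "n_nonsyn": sum(1 for v in variants if v.coding_effect == "non-synonymous"),
        "n_transition": sum(1 for v in snps if v.snp_class == "transition"),
        "n_transversion": sum(1 for v in snps if v.snp_class == "transversion"),
        "indel_length_histogram": dict(sorted(hist.items())),
    }


def variants_to_vcf(variants: list[Variant], genomeA: CircularSequence, path) -> None:
    """Minimal VCF export (CHROM = genome A, 1-based POS, VCF-style indel records)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genomeA.name},length={genomeA.length}>\n")
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="SNP/insertion/deletion">\n')
        fh.write('##INFO=<ID=LOC,Number=1,Type=String,Description="genic/intronic/intergenic">\n')
        fh.write('##INFO=<ID=EFFECT,Number=1,Type=String,Description="coding effect">\n')
        fh.write('##INFO=<ID=SNPCLASS,Number=1,Type=String,Description="transition/transversion">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            if v.vtype == "SNP":
                pos, ref, alt = v.posA + 1, v.refA, v.altB
            elif v.vtype == "insertion":
                anchor = genomeA.seq[v.posA - 1] if v.posA > 0 else genomeA.seq[0]
                pos, ref, alt = v.posA, anchor, anchor + v.altB
            else:
                anchor = genomeA.seq[v.posA - 1] if v.posA > 0 else genomeA.seq[0]
                pos, ref, alt = v.posA, anchor + v.refA, anchor
            info = f"TYPE={v.vtype};LOC={v.location_class}"
            if v.coding_effect:
                info += f";EFFECT={v.coding_effect}"
            if v.snp_class:
                info += f";SNPCLASS={v.snp_class}"
            fh.write(f"{genomeA.name}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")
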