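"""Synthetic CMS-like / restorer-like mitogenome pairs with planted ground truth.

The generator emulates the observable structure of a real sterile-line /
restorer-line mitochondrial genome comparison at desk scale: a conserved
protein-coding gene backbone on a circular ~100 kb molecule, direct and
inverted repeats, a scatter of SNPs (with known transition/transversion and
synonymous/non-synonymous status) and short 1-10 bp InDels, one
line-specific chimeric ORF (a known gene's 5' segment fused to unknown
sequence encoding a hydrophobic stretch), negative-binomial transcript
counts with planted fold-changes, and transcript alignment blocks with
planted intron-retention fractions.  Every planted feature is recorded in a
TruthSet so each downstream module can be scored exactly.

The "CMS-like" genome (B) is derived from the "restorer-like" genome (A) by
applying exactly the planted edits; truth coordinates are kept on both
genomes' final coordinate systems.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genome import CircularSequence, GeneModel, revcomp
from .orfs import translate
from .variants import normalize_indel

# A plausible plant mitochondrial gene complement (33 protein-coding genes).
MITO_GENE_NAMES = [
    "atp1", "atp4", "atp6", "atp8", "atp9", "ccmB", "ccmC", "ccmFc", "ccmFn",
    "cob", "cox1", "cox2", "cox3", "matR", "mttB", "nad1", "nad2", "nad3",
    "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9", "rpl2", "rpl5", "rpl10",
    "rpl16", "rps3", "rps4", "rps7", "rps10", "rps12", "sdh3", "sdh4",
]

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
HYDROPHOBIC_CODONS = ["CTT", "ATT", "GTT", "TTT", "GCT", "ATG"]  # L I V F A M
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class RepeatSpec:
    length: int
    rtype: str = "DR"          # DR | IR
    identity: float = 100.0    # percent; <100 plants substitutions in copy 2


@dataclass
class ChimeraSpec:
    donor_gene: str = "atp1"
    known_bp: int = 1336
    unknown_bp: int = 485
    tm_encoded: bool = True


@dataclass
class CountModel:
    mean: float = 500.0
    dispersion: float = 0.05
    log2_fold_changes: dict = field(default_factory=dict)  # gene -> planted log2FC (CMS over restorer)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic genome pair."""

    genome_length: int = 100_000
    n_genes: int = 33
    gene_length_range: tuple = (300, 1500)       # spliced CDS bp
    n_snps: int = 60
    n_genic_snps: int = 6
    n_indels: int = 12
    indel_length_range: tuple = (1, 10)
    repeats: list = field(default_factory=lambda: [
        RepeatSpec(1200, "DR"), RepeatSpec(400, "IR"), RepeatSpec(60, "DR"),
    ])
    chimera: ChimeraSpec | None = field(default_factory=ChimeraSpec)
    retention: dict = field(default_factory=lambda: {1: 0.95, 2: 0.0, 3: 0.5})
    count_model: CountModel = field(default_factory=CountModel)
    svs: list = field(default_factory=list)       # [("inversion", bp) | ("translocation", bp) | ("translocation+inversion", bp)]
    gc: float = 0.45
    intron_gene: str = "nad4"
    n_introns: int = 3
    seed: int = 0


@dataclass
class TruthSet:
    """Machine-readable record of everything planted into a genome pair."""

    snps: list = field(default_factory=list)
    indels: list = field(default_factory=list)
    repeats: list = field(default_factory=list)
    chimera: dict | None = None
    svs: list = field(default_factory=list)
    log2_fold_changes: dict = field(default_factory=dict)
    retention: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


class ConfigInfeasibleError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Sequence building blocks

def _background(rng, n, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _sense_cds(rng, n_codons):
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


# ---------------------------------------------------------------------------
# Generator

def generate_genome_pair(config: GeneratorConfig):
    """Build (genomeA, genomeB, annotations, truth).

    ``annotations`` maps genome name -> list of GeneModel (the chimeric ORF
    is annotated on genome B with biotype "orf").
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length

    # -- gene cassettes -----------------------------------------------------
    lo, hi = config.gene_length_range
    names = list(MITO_GENE_NAMES[: config.n_genes])
    if config.n_genes > len(MITO_GENE_NAMES):
        names += [f"gene{i}" for i in range(len(MITO_GENE_NAMES), config.n_genes)]
    if (config.n_introns > 0 and config.intron_gene in MITO_GENE_NAMES
            and config.intron_gene not in names):
        names[-1] = config.intron_gene
    donor = config.chimera.donor_gene if config.chimera else None
    cassettes = []  # (kind, name, seq, meta)
    gene_cds: dict[str, str] = {}
    for name in names:
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        if donor == name and config.chimera:
            # donor CDS long enough that the chimera's shared prefix stays
            # well below the reciprocal-match coverage threshold
            need = int(np.ceil(config.chimera.known_bp / 0.8 / 3)) + 8
            n_codons = max(n_codons, need)
        cds = _sense_cds(rng, n_codons)
        gene_cds[name] = cds
        strand = "+" if (donor == name or rng.random() < 0.5) else "-"
        if name == config.intron_gene and config.n_introns > 0:
            introns = [_background(rng, int(rng.integers(300, 800)), config.gc)
                       for _ in range(config.n_introns)]
            bounds = sorted(rng.choice(np.arange(60, len(cds) - 60, 3),
                                       size=config.n_introns, replace=False))
            pieces, prev = [], 0
            for b, intr in zip(bounds, introns):
                pieces.append(cds[prev:b])
                pieces.append(intr)
                prev = b
            pieces.append(cds[prev:])
            cassette = "".join(pieces)
            exon_lens = [len(cds[:bounds[0]])] + [
                bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)
            ] + [len(cds) - bounds[-1]]
            intron_lens = [len(i) for i in introns]
            meta = {"exon_lens": exon_lens, "intron_lens": intron_lens}
        else:
            cassette = cds
            meta = {"exon_lens": [len(cds)], "intron_lens": []}
        if strand == "-":
            cassette = revcomp(cassette)
        cassettes.append(("gene", name, cassette, {"strand": strand, **meta}))

    # -- repeat cassettes ---------------------------------------------------
    repeat_units = []
    for i, spec in enumerate(config.repeats):
        unit = _background(rng, spec.length, config.gc)
        copy2 = unit
        if spec.identity < 100.0:
            n_mut = max(1, round((100.0 - spec.identity) / 100.0 * spec.length))
            pos = rng.choice(spec.length, size=n_mut, replace=False)
            c2 = list(unit)
            for p in pos:
                c2[p] = rng.choice([b for b in "ACGT" if b != c2[p]])
            copy2 = "".join(c2)
        if spec.rtype == "IR":
            copy2 = revcomp(copy2)
        repeat_units.append((i, spec, unit, copy2))
        cassettes.append(("repeat", f"rep{i}.1", unit, {"ridx": i, "copy": 1}))
        cassettes.append(("repeat", f"rep{i}.2", copy2, {"ridx": i, "copy": 2}))

    # -- layout -------------------------------------------------------------
    order = rng.permutation(len(cassettes))
    cassettes = [cassettes[i] for i in order]
    total_feat = sum(len(c[2]) for c in cassettes)
    n_gaps = len(cassettes) + 1
    min_gap = 200
    free = L - total_feat - n_gaps * min_gap
    if free < 0:
        raise ConfigInfeasibleError(
            f"features ({total_feat} bp) exceed genome length {L}"
        )
    cuts = np.sort(rng.choice(free + 1, size=n_gaps - 1, replace=True)) if free else np.zeros(n_gaps - 1, int)
    gap_lens = np.diff(np.concatenate(([0], cuts, [free]))) + min_gap

    parts = []
    posA = 0
    placed = []  # (kind, name, start, end, meta)
    for i, (kind, name, seq, meta) in enumerate(cassettes):
        g = _background(rng, int(gap_lens[i]), config.gc)
        parts.append(g)
        posA += len(g)
        placed.append((kind, name, posA, posA + len(seq), meta))
        parts.append(seq)
        posA += len(seq)
    parts.append(_background(rng, int(gap_lens[-1]), config.gc))
    seqA = "".join(parts)
    assert len(seqA) == L
    genomeA = CircularSequence("restorer_mt", seqA, circular=True)

    # gene models on A
    modelsA = []
    gene_pos = {}
    for kind, name, s, e, meta in placed:
        if kind != "gene":
            continue
        gene_pos[name] = (s, e)
        exons = _cassette_exons(s, meta)
        modelsA.append(GeneModel(name, genomeA.name, meta["strand"], exons))

    truth = TruthSet()
    for ridx, spec, unit, copy2 in repeat_units:
        copies = sorted(
            (s, e) for kind, nm, s, e, meta in placed
            if kind == "repeat" and meta["ridx"] == ridx
        )
        truth.repeats.append(
            {"copy1": copies[0], "copy2": copies[1], "rtype": spec.rtype,
             "length": spec.length, "identity": spec.identity}
        )

    # -- choose edits on A --------------------------------------------------
    occupied = [(s - 50, e + 50) for _, _, s, e, _ in placed]
    occupied.append((0, 100))
    occupied.append((L - 100, L))

    def reserve(start, end):
        occupied.append((start, end))

    def free_position(width, margin=50):
        occ = sorted((max(0, s), min(L, e)) for s, e in occupied)
        merged = [list(occ[0])]
        for s, e in occ[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        windows = []
        gaps = []
        prev_end = 0
        for s, e in merged:
            if s > prev_end:
                gaps.append((prev_end, s))
            prev_end = max(prev_end, e)
        if prev_end < L:
            gaps.append((prev_end, L))
        for gs, ge in gaps:
            lo_w, hi_w = gs + margin, ge - margin - width
            if hi_w >= lo_w:
                windows.append((lo_w, hi_w))
        if not windows:
            raise ConfigInfeasibleError("could not place a feature; genome too crowded")
        weights = np.array([hi - lo + 1 for lo, hi in windows], dtype=float)
        wi = int(rng.choice(len(windows), p=weights / weights.sum()))
        lo_w, hi_w = windows[wi]
        return int(rng.integers(lo_w, hi_w + 1))

    edits = []  # dicts with kind snp|ins|del, posA ...

    # genic SNPs (inside CDS exons, away from start/stop codons)
    protein_genes = [m for m in modelsA if m.biotype == "protein_coding"]
    n_genic = min(config.n_genic_snps, config.n_snps)
    attempts = 0
    planted_genic = 0
    while planted_genic < n_genic and attempts < 10_000:
        attempts += 1
        m = protein_genes[int(rng.integers(len(protein_genes)))]
        cds = _spliced_from_truth(seqA, m)
        cds_idx = int(rng.integers(3, len(cds) - 3))
        if donor and m.gene_id == donor and cds_idx < config.chimera.known_bp + 50:
            # the chimera duplicates the donor 5' prefix; a SNP there would
            # overlap two planted features and make its context ambiguous
            continue
        pos = _cds_to_genome(m, cds_idx)
        if any(abs(pos - ed["posA"]) < 50 for ed in edits):
            continue
        ref_cds = cds[cds_idx]
        ci = cds_idx // 3
        codon = cds[3 * ci : 3 * ci + 3]
        options = []
        for alt_cds in "ACGT":
            if alt_cds == ref_cds:
                continue
            newc = codon[: cds_idx % 3] + alt_cds + codon[cds_idx % 3 + 1 :]
            aaA, aaB = translate(codon), translate(newc)
            if aaB == "*":
                continue
            options.append((alt_cds, "synonymous" if aaA == aaB else "non-synonymous",
                            (aaA, aaB)))
        if not options:
            continue
        alt_cds, effect, aa = options[int(rng.integers(len(options)))]
        refA = seqA[pos]
        altB = alt_cds if m.strand == "+" else revcomp(alt_cds)
        if not _edit_preserves_orfs(seqA, pos, 1, altB):
            continue
        snp_class = "transition" if TRANSITION[refA] == altB else "transversion"
        edits.append({"kind": "snp", "posA": pos, "ref": refA, "alt": altB,
                      "snp_class": snp_class, "location": "genic", "gene_id": m.gene_id,
                      "coding_effect": effect, "aa_change": aa})
        planted_genic += 1
    if planted_genic < n_genic:
        raise ConfigInfeasibleError("could not place the requested genic SNPs")

    # chimeric ORF insertion (CMS-like genome only)
    chim_nt = None
    if config.chimera:
        cs = config.chimera
        known = gene_cds[cs.donor_gene][: cs.known_bp]
        unk_len = cs.unknown_bp
        if (cs.known_bp + unk_len) % 3:
            raise ConfigInfeasibleError("chimera known+unknown must be a codon multiple")
        chim_nt = None
        for _ in range(25):  # spurious flank-initiated ORFs depend on the site
            pos = free_position(cs.known_bp + unk_len + 6)
            for _ in range(8):
                cand = _chimeric_orf(rng, known, unk_len, cs.tm_encoded,
                                     avoid_continuation=gene_cds[cs.donor_gene][cs.known_bp:cs.known_bp + 4])
                if _insert_is_clean(cand, seqA, pos):
                    chim_nt = cand
                    break
            if chim_nt is not None:
                break
        if chim_nt is None:
            raise ConfigInfeasibleError("could not draw a chimera without secondary ORFs")
        reserve(pos - 50, pos + len(chim_nt) + 53)
        # a same-frame stop immediately 5' pins the ORF start at the donor ATG
        edits.append({"kind": "ins", "posA": pos, "seq": "TAA" + chim_nt,
                      "chimera": True})

    # structural variants occupy gene-free windows
    sv_events = []
    for kind, ln in config.svs:
        pos = free_position(ln)
        reserve(pos - 50, pos + ln + 50)
        sv_events.append({"kind": kind, "a1": pos, "a2": pos + ln})

    # intergenic SNPs
    for _ in range(config.n_snps - n_genic):
        for _try in range(200):
            pos = free_position(1)
            refA = seqA[pos]
            if rng.random() < 0.5:
                altB = TRANSITION[refA]
                snp_class = "transition"
            else:
                altB = str(rng.choice([b for b in "ACGT" if b != refA and b != TRANSITION[refA]]))
                snp_class = "transversion"
            if _edit_preserves_orfs(seqA, pos, 1, altB):
                break
        else:
            raise ConfigInfeasibleError("could not place an intergenic SNP cleanly")
        reserve(pos - 50, pos + 51)
        edits.append({"kind": "snp", "posA": pos, "ref": refA, "alt": altB,
                      "snp_class": snp_class, "location": "intergenic", "gene_id": None,
                      "coding_effect": None, "aa_change": None})

    # intergenic InDels, 1-10 bp
    ilo, ihi = config.indel_length_range
    for _ in range(config.n_indels):
        for _try in range(200):
            ln = int(rng.integers(ilo, ihi + 1))
            pos = free_position(ln + 2)
            if rng.random() < 0.5:
                ed = {"kind": "ins", "posA": pos, "seq": _background(rng, ln, config.gc)}
                ok = _edit_preserves_orfs(seqA, pos, 0, ed["seq"])
            else:
                ed = {"kind": "del", "posA": pos, "seq": seqA[pos : pos + ln]}
                ok = _edit_preserves_orfs(seqA, pos, ln, "")
            if ok:
                break
        else:
            raise ConfigInfeasibleError("could not place an InDel cleanly")
        reserve(pos - 50, pos + ln + 50)
        edits.append(ed)

    # -- build genome B -----------------------------------------------------
    point_edits = sorted(edits, key=lambda d: d["posA"])
    seqB_parts = []
    offsets = []  # (a_pos_from, cumulative_shift): positions >= a_pos_from shift
    cursor = 0
    shift = 0
    for ed in point_edits:
        p = ed["posA"]
        seqB_parts.append(seqA[cursor:p])
        ed["shift_before"] = shift
        if ed["kind"] == "snp":
            seqB_parts.append(ed["alt"])
            cursor = p + 1
        elif ed["kind"] == "ins":
            seqB_parts.append(ed["seq"])
            cursor = p
            shift += len(ed["seq"])
            offsets.append((p, shift))
        else:
            cursor = p + len(ed["seq"])
            shift -= len(ed["seq"])
            offsets.append((cursor, shift))
    seqB_parts.append(seqA[cursor:])
    seqB0 = "".join(seqB_parts)

    def a_to_b0(p):
        sh = 0
        for a_pos, s in offsets:
            if p >= a_pos:
                sh = s
            else:
                break
        return p + sh

    # apply SVs on B0 coordinates
    seqB = seqB0
    sv_maps = []
    for ev in sv_events:
        b1, b2 = a_to_b0(ev["a1"]), a_to_b0(ev["a2"])
        kind = ev["kind"]
        if kind == "inversion":
            seqB = seqB[:b1] + revcomp(seqB[b1:b2]) + seqB[b2:]
            sv_maps.append(("inv", b1, b2))
            truth.svs.append({"kind": kind, "spanA": (ev["a1"], ev["a2"]), "spanB": (b1, b2)})
        else:
            ln = b2 - b1
            seg = seqB[b1:b2]
            if "inversion" in kind:
                seg = revcomp(seg)
            rest = seqB[:b1] + seqB[b2:]
            # move the segment roughly a third of the genome away
            dest = (b1 + len(rest) // 3) % (len(rest) - 1)
            seqB = rest[:dest] + seg + rest[dest:]
            sv_maps.append(("cut", b1, b2, dest))
            truth.svs.append({"kind": kind, "spanA": (ev["a1"], ev["a2"]),
                              "spanB": (dest, dest + ln)})

    def b0_to_b(p):
        for mp in sv_maps:
            if mp[0] == "inv":
                _, b1, b2 = mp
                if b1 <= p < b2:
                    p = b1 + (b2 - 1 - (p - b1))
            else:
                _, b1, b2, dest = mp
                ln = b2 - b1
                if b1 <= p < b2:
                    p = dest + (p - b1)
                    continue
                q = p - ln if p >= b2 else p
                p = q + ln if q >= dest else q
        return p

    def a_to_b(p):
        return b0_to_b(a_to_b0(p))

    genomeB = CircularSequence("cms_mt", seqB, circular=True)

    # -- truth records ------------------------------------------------------
    for ed in point_edits:
        if ed["kind"] == "snp":
            truth.snps.append(
                {"posA": ed["posA"], "posB": a_to_b(ed["posA"]), "ref": ed["ref"],
                 "alt": ed["alt"], "snp_class": ed["snp_class"],
                 "location": ed["location"], "gene_id": ed["gene_id"],
                 "coding_effect": ed["coding_effect"], "aa_change": ed["aa_change"]}
            )
        else:
            vtype = "insertion" if ed["kind"] == "ins" else "deletion"
            npos, nseq = normalize_indel(seqA, ed["posA"], ed["seq"], vtype)
            rec = {"vtype": vtype, "posA": npos,
                   "posB": b0_to_b(npos + ed["shift_before"]),
                   "seq": nseq, "length": len(nseq),
                   "chimera": bool(ed.get("chimera"))}
            truth.indels.append(rec)

    if config.chimera:
        cs = config.chimera
        ins = [e for e in point_edits if e.get("chimera")][0]
        orf_start_b = b0_to_b(ins["posA"] + ins["shift_before"] + 3)
        aa_len = (cs.known_bp + cs.unknown_bp) // 3 - 1
        truth.chimera = {
            "orf_name": f"orf{aa_len}a",
            "aa_length": aa_len,
            "nt": chim_nt,
            "spanB": (orf_start_b, orf_start_b + len(chim_nt)),
            "donor_gene": cs.donor_gene,
            "known_bp": cs.known_bp,
            "unknown_bp": cs.unknown_bp,
            "tm_encoded": cs.tm_encoded,
        }
    truth.log2_fold_changes = dict(config.count_model.log2_fold_changes)
    if not truth.log2_fold_changes:
        if config.chimera:
            truth.log2_fold_changes[truth.chimera["orf_name"]] = 3.0
        if config.intron_gene in gene_cds and config.n_introns:
            truth.log2_fold_changes[config.intron_gene] = -2.0
    truth.retention = {int(k): float(v) for k, v in config.retention.items()}

    # -- annotations on B ---------------------------------------------------
    modelsB = []
    for m in modelsA:
        exonsB = []
        ok = True
        for s, e in m.exons:
            bs, be = a_to_b(s), a_to_b(e - 1) + 1
            if be <= bs:
                ok = False
                break
            exonsB.append((bs, be))
        if ok:
            try:
                modelsB.append(GeneModel(m.gene_id, genomeB.name, m.strand, exonsB,
                                         biotype=m.biotype))
            except ValueError:
                pass  # gene disrupted by an SV; drop from B's annotation
    if truth.chimera:
        s, e = truth.chimera["spanB"]
        modelsB.append(GeneModel(truth.chimera["orf_name"], genomeB.name, "+",
                                 [(s, e)], biotype="orf"))

    annotations = {genomeA.name: modelsA, genomeB.name: modelsB}
    return genomeA, genomeB, annotations, truth


def _cassette_exons(start, meta):
    """Genome-forward exon coords from cassette-relative layout, 5'->3' ordered."""
    exon_lens, intron_lens, strand = meta["exon_lens"], meta["intron_lens"], meta["strand"]
    if strand == "+":
        exons, p = [], start
        for i, el in enumerate(exon_lens):
            exons.append((p, p + el))
            p += el + (intron_lens[i] if i < len(intron_lens) else 0)
        return exons
    # cassette was reverse-complemented before placement: walk from the end
    exons, p = [], start + sum(exon_lens) + sum(intron_lens)
    for i, el in enumerate(exon_lens):
        exons.append((p - el, p))
        p -= el + (intron_lens[i] if i < len(intron_lens) else 0)
    return exons


def _spliced_from_truth(seqA, model):
    parts = []
    for s, e in model.exons:
        piece = seqA[s:e]
        parts.append(revcomp(piece) if model.strand == "-" else piece)
    return "".join(parts)


def _cds_to_genome(model, cds_idx):
    offset = 0
    for s, e in model.exons:
        if cds_idx < offset + (e - s):
            k = cds_idx - offset
            return s + k if model.strand == "+" else e - 1 - k
        offset += e - s
    raise IndexError(cds_idx)


def _window_orf_extents(seq: str, min_aa: int):
    from .orfs import find_orfs  # local import: orfs does not depend on synthetic

    g = CircularSequence("w", seq, circular=False)
    return {(o.strand, o.span.start, o.span.end) for o in find_orfs(g, min_aa=min_aa)}


def _edit_preserves_orfs(seqA: str, pos: int, ref_len: int, alt: str,
                         min_aa: int = 100, ctx: int = 1500) -> bool:
    """True when replacing seqA[pos:pos+ref_len] by ``alt`` leaves every
    >=min_aa ORF extent around the site unchanged (up to the coordinate
    shift an indel introduces).

    An edit that creates or destroys a start/stop codon in any frame of a
    long ORF would surface downstream as a spurious line-specific ORF, so
    such positions are rejected and redrawn.
    """
    lo = max(0, pos - ctx)
    hi = min(len(seqA), pos + ref_len + ctx)
    winA = seqA[lo:hi]
    p = pos - lo
    winB = winA[:p] + alt + winA[p + ref_len:]
    delta = len(alt) - ref_len
    extA = _window_orf_extents(winA, min_aa)
    extB = _window_orf_extents(winB, min_aa)
    edit_end = p + len(alt)
    shifted = set()
    for strand, s, e in extB:
        s2 = s - delta if s >= edit_end else s
        e2 = e - delta if e >= edit_end else e
        shifted.add((strand, s2, e2))
    return shifted == extA


def _insert_is_clean(chim_nt: str, seqA: str, pos: int, min_aa: int = 100,
                     ctx: int = 350) -> bool:
    """True when inserting the chimera at ``pos`` spawns no extra unique ORFs.

    The probe is the insert plus flanking genome context; any ORF other
    than the planted chimera that overlaps the insert and whose sequence is
    absent from genome A would surface as a spurious line-specific ORF.
    """
    from .orfs import find_orfs  # local import: orfs does not depend on synthetic

    insert = "TAA" + chim_nt
    lo, hi = max(0, pos - ctx), min(len(seqA), pos + ctx)
    probe = seqA[lo:pos] + insert + seqA[pos:hi]
    ins_s, ins_e = pos - lo, pos - lo + len(insert)
    g = CircularSequence("probe", probe, circular=False)
    for o in find_orfs(g, min_aa=min_aa):
        s, e = o.span.start, o.span.end
        if e <= ins_s or s >= ins_e:
            continue  # fully in flank; exists in A as well
        if (s, e) == (ins_s + 3, ins_e) and o.strand == "+":
            continue  # the planted chimera itself
        if o.nt in seqA or revcomp(o.nt) in seqA:
            continue  # identical ORF exists in A; it will match as shared
        return False
    return True


def _chimeric_orf(rng, known_prefix, unknown_bp, tm_encoded, avoid_continuation=""):
    """known 5' prefix + unknown segment; in-frame, no internal stop, stop-terminated.

    The first bases of the unknown segment are constrained to differ from
    ``avoid_continuation`` (the donor's actual downstream sequence) so the
    planted known/unknown boundary is unambiguous.
    """
    for _ in range(200):
        orf = _chimeric_orf_once(rng, known_prefix, unknown_bp, tm_encoded)
        unk = orf[len(known_prefix):]
        cont = avoid_continuation[:4]
        if all(u != c for u, c in zip(unk, cont)):
            return orf
    raise ConfigInfeasibleError("could not draw an unambiguous chimera junction")


def _chimeric_orf_once(rng, known_prefix, unknown_bp, tm_encoded):
    total = len(known_prefix) + unknown_bp
    assert total % 3 == 0
    # fill the partial codon at the junction then whole codons, then the stop
    lead = (-len(known_prefix)) % 3
    n_body_codons = (unknown_bp - lead - 3) // 3
    body = []
    if tm_encoded:
        tm_start = int(rng.integers(0, max(1, n_body_codons - 25)))
        for i in range(n_body_codons):
            if tm_start <= i < tm_start + 25:
                body.append(HYDROPHOBIC_CODONS[int(rng.integers(len(HYDROPHOBIC_CODONS)))])
            else:
                body.append(SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))])
    else:
        polar = [c for c in SENSE_CODONS
                 if translate(c) in "RNDQEGHKPSTY"]
        body = [polar[int(rng.integers(len(polar)))] for _ in range(n_body_codons)]
    if lead:
        # complete the split codon without creating a stop
        while True:
            fill = "".join(rng.choice(list("ACGT"), size=lead))
            codon = known_prefix[len(known_prefix) - (3 - lead):] + fill
            if codon not in ("TAA", "TAG", "TGA"):
                break
        unknown = fill + "".join(body) + "TAA"
    else:
        unknown = "".join(body) + "TAA"
    orf = known_prefix + unknown
    assert len(orf) == total, (len(orf), total)
    prot = translate(orf[:-3])
    assert "*" not in prot
    return orf


# ---------------------------------------------------------------------------
# Expression simulators

def simulate_counts(truth: TruthSet, genes: list[str], config: GeneratorConfig,
                    n_replicates: int = 3, seed: int | None = None,
                    library_size_factors: dict | None = None) -> pd.DataFrame:
    """Two-condition negative-binomial count table with planted fold-changes.

    Columns are restorer_1..n then cms_1..n; the planted log2 fold-changes
    (CMS over restorer) come from the truth set.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cm = config.count_model
    r = 1.0 / cm.dispersion
    cols = [f"restorer_{i+1}" for i in range(n_replicates)] + \
           [f"cms_{i+1}" for i in range(n_replicates)]
    sf = {c: (library_size_factors or {}).get(c, 1.0) for c in cols}
    data = {}
    base = cm.mean * rng.lognormal(0.0, 0.5, size=len(genes))
    for gi, gene in enumerate(genes):
        lfc = truth.log2_fold_changes.get(gene, 0.0)
        row = []
        for c in cols:
            mu = base[gi] * (2.0 ** lfc if c.startswith("cms") else 1.0) * sf[c]
            row.append(rng.negative_binomial(r, r / (r + mu)))
        data[gene] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


def simulate_transcript_alignments(model: GeneModel, retention: dict,
                                   n_reads: int = 50, seed: int = 0) -> pd.DataFrame:
    """BED-like alignment blocks for transcripts of one gene.

    Each transcript covers every exon; for intron i (1-based, transcript
    order) it additionally retains a 5' prefix of the intron whose length is
    Binomial(intron_length, fraction), so the mean covered fraction equals
    the planted retention fraction.
    """
    rng = np.random.default_rng(seed)
    introns = model.introns()
    rows = []
    for t in range(n_reads):
        tx = f"{model.gene_id}.tx{t+1}"
        ivs = [list(x) for x in sorted(model.exons)]
        for i, (s, e) in enumerate(introns, start=1):
            frac = float(retention.get(i, 0.0))
            ilen = e - s
            k = int(rng.binomial(ilen, frac)) if 0.0 < frac < 1.0 else int(round(frac * ilen))
            if k <= 0:
                continue
            if model.strand == "+":
                ivs.append([s, s + k])
            else:
                ivs.append([e - k, e])
        ivs.sort()
        merged = [ivs[0]]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            rows.append({"seq": model.seq_name, "start": int(s), "end": int(e),
                         "transcript_id": tx})
    return pd.DataFrame(rows)
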