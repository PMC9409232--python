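"""End-to-end pipeline driver: simulate -> orfs -> repeats -> variants ->
chimeras -> tm -> expression -> screen, with all module outputs written to a
report directory and a single JSON summary.

The pipeline is configured by one mapping (typically loaded from YAML); a
fixed seed makes the whole run reproducible byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import io as mio
from .chimeras import decompose, decompositions_to_rows, match_orfs
from .expression import CountTable, differential_expression, intron_retention
from .genome import CircularSequence, GeneModel, extract_spliced_cds
from .hydropathy import predict_tm
from .orfs import find_orfs
from .repeats import classify_repeat_sizes, find_repeats, repeat_content, repeats_to_tsv
from .screen import screen
from .synthetic import (GeneratorConfig, generate_genome_pair, simulate_counts,
                        simulate_transcript_alignments)
from .variants import (align_genomes, annotate_variants, call_variants,
                       summarize_variants, variants_to_vcf)

log = logging.getLogger("mitocms")

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": True,
    "generator": {},          # GeneratorConfig overrides
    "min_aa": 100,
    "repeat_min_len": 50,
    "repeat_min_identity": 99.0,
    "anchor_k": 31,
    "inputs": {},             # genome_a, genome_b, gff_a, gff_b, counts, alignments
}


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            out = fn(*args, **kwargs)
            log.info("stage %-10s %6.2fs", name, time.time() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the full comparison and return the summary dict.

    Writes per-stage TSV/JSON/VCF reports plus ``summary.json`` to
    ``outdir``.  Missing inputs raise with the stage name in the message.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg["seed"]}

    # -- inputs -------------------------------------------------------------
    counts_df = ct_df = blocks_df = None
    if cfg["simulate"]:
        gen = GeneratorConfig(**{"seed": cfg["seed"], **cfg["generator"]})
        genomeA, genomeB, annotations, truth = _simulate(gen, out)
        genes = [m.gene_id for m in annotations[genomeA.name]]
        count_genes = genes + ([truth.chimera["orf_name"]] if truth.chimera else [])
        counts_df = simulate_counts(truth, count_genes, gen, seed=gen.seed + 1)
        intron_model = next(
            (m for m in annotations[genomeB.name] if m.gene_id == gen.intron_gene), None
        )
        if intron_model and intron_model.introns():
            blocks_df = simulate_transcript_alignments(
                intron_model, truth.retention, seed=gen.seed + 2
            )
            mio.write_alignment_blocks(out / "transcript_blocks.tsv", blocks_df)
        mio.write_counts_tsv(out / "counts.tsv", counts_df)
        summary["truth"] = "truth.json"
    else:
        inputs = cfg["inputs"]
        for key in ("genome_a", "genome_b", "gff_a", "gff_b"):
            if key not in inputs:
                raise ValueError(f"stage inputs: missing required input {key!r}")
        genomes = {g.name: g for g in mio.read_fasta(inputs["genome_a"])}
        genomes.update({g.name: g for g in mio.read_fasta(inputs["genome_b"])})
        ga = mio.read_fasta(inputs["genome_a"])[0]
        gb = mio.read_fasta(inputs["genome_b"])[0]
        genomeA, genomeB = ga, gb
        annotations = {
            genomeA.name: mio.read_gff3(inputs["gff_a"], [genomeA]),
            genomeB.name: mio.read_gff3(inputs["gff_b"], [genomeB]),
        }
        if inputs.get("counts"):
            counts_df = mio.read_counts_tsv(inputs["counts"])
        if inputs.get("alignments"):
            blocks_df = mio.read_alignment_blocks(inputs["alignments"])

    # -- orfs ---------------------------------------------------------------
    orfsA = _run_orfs(genomeA, cfg["min_aa"], out / "orfs_restorer.tsv")
    orfsB = _run_orfs(genomeB, cfg["min_aa"], out / "orfs_cms.tsv")
    summary["n_orfs"] = {genomeA.name: len(orfsA), genomeB.name: len(orfsB)}

    # -- repeats ------------------------------------------------------------
    summary["repeats"] = {}
    for g in (genomeA, genomeB):
        reps = _run_repeats(g, cfg, out / f"repeats_{g.name}.tsv")
        summary["repeats"][g.name] = {
            "n": len(reps),
            "content_pct": round(repeat_content(g, reps), 2),
            **classify_repeat_sizes(reps),
        }

    # -- variants -----------------------------------------------------------
    blocks, variants, vsummary = _run_variants(genomeA, genomeB,
                                               annotations[genomeA.name], cfg, out)
    summary["synteny"] = {
        "n_blocks": len(blocks),
        "sv_classes": sorted({b.sv_class for b in blocks}),
    }
    summary["variants"] = vsummary

    # -- chimeras (CMS-line unique ORFs vs the known-CDS library) -----------
    matches = match_orfs(orfsA, orfsB)
    unique_cms = matches["uniqueB"]
    library = [
        (m.gene_id, extract_spliced_cds(genomeA, m))
        for m in annotations[genomeA.name] if m.biotype == "protein_coding"
    ]
    decs = {o.orf_id: decompose(o, library) for o in unique_cms}
    pd.DataFrame(decompositions_to_rows(list(decs.values()))).to_csv(
        out / "chimera_segments.tsv", sep="\t", index=False
    )
    summary["n_unique_cms_orfs"] = len(unique_cms)
    summary["n_chimeric"] = sum(d.is_chimeric for d in decs.values())

    # -- tm -----------------------------------------------------------------
    tm_results = {o.orf_id: predict_tm(o.protein) for o in unique_cms}
    with open(out / "tm_segments.tsv", "w") as fh:
        fh.write("orf_id\tn_tm_segments\tsegments\n")
        for oid, segs in sorted(tm_results.items()):
            desc = ";".join(f"{s.start}-{s.end}" for s in segs)
            fh.write(f"{oid}\t{len(segs)}\t{desc}\n")

    # -- expression ---------------------------------------------------------
    de = None
    retention_notes = []
    if counts_df is not None:
        conditions = {c: ("cms" if c.startswith("cms") else "restorer")
                      for c in counts_df.columns}
        tbl = CountTable(counts_df, conditions)
        de = differential_expression(tbl, "restorer", "cms")
        de.to_csv(out / "differential_expression.tsv", sep="\t")
    if blocks_df is not None:
        for m in annotations[genomeB.name]:
            if m.biotype == "protein_coding" and m.introns():
                try:
                    ir = intron_retention(blocks_df, m)
                except ValueError:
                    continue
                low_expr = bool(de is not None and m.gene_id in de.index
                                and de.loc[m.gene_id, "significant"]
                                and de.loc[m.gene_id, "log2FC"] < 0)
                retained = [x for x in ir.per_intron if x["class"] in ("retained", "partial")]
                if retained:
                    retention_notes.append(
                        {"gene_id": m.gene_id, "low_expression": low_expr,
                         "introns": ir.per_intron}
                    )
    summary["splicing_defect_candidates"] = retention_notes

    # -- screen -------------------------------------------------------------
    report = screen(orfsB, orfsA, decs, tm_results, de_results=de,
                    retention_notes=retention_notes)
    report.to_frame().to_csv(out / "candidates.tsv", sep="\t", index=False)
    summary["venn"] = report.venn_counts
    summary["candidates"] = [
        {"orf_id": r.orf_id, "tier": r.tier, "upregulated": r.upregulated_in_cms}
        for r in report.rows if r.tier is not None
    ]
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary


@_stage("simulate")
def _simulate(gen: GeneratorConfig, out: Path):
    genomeA, genomeB, annotations, truth = generate_genome_pair(gen)
    mio.write_fasta(out / "genomes.fasta", [genomeA, genomeB])
    mio.write_gff3(out / f"{genomeA.name}.gff3", annotations[genomeA.name], [genomeA])
    mio.write_gff3(out / f"{genomeB.name}.gff3", annotations[genomeB.name], [genomeB])
    truth.to_json(out / "truth.json")
    return genomeA, genomeB, annotations, truth


@_stage("orfs")
def _run_orfs(genome: CircularSequence, min_aa: int, path: Path):
    orfs = find_orfs(genome, min_aa=min_aa)
    with open(path, "w") as fh:
        fh.write("orf_id\tgenome\tstart\tend\tstrand\taa_length\n")
        for o in orfs:
            fh.write(f"{o.orf_id}\t{o.genome}\t{o.span.start + 1}\t{o.span.end}\t"
                     f"{o.strand}\t{o.aa_length}\n")
    return orfs


@_stage("repeats")
def _run_repeats(genome: CircularSequence, cfg: dict, path: Path):
    reps = find_repeats(genome, min_len=cfg["repeat_min_len"],
                        min_identity=cfg["repeat_min_identity"])
    repeats_to_tsv(reps, path)
    return reps


@_stage("variants")
def _run_variants(genomeA, genomeB, modelsA, cfg, out: Path):
    blocks = align_genomes(genomeA, genomeB, anchor_k=cfg["anchor_k"])
    with open(out / "synteny_blocks.tsv", "w") as fh:
        fh.write("startA\tendA\tstartB\tendB\torientation\tsv_class\n")
        for b in blocks:
            fh.write(f"{b.spanA.start + 1}\t{b.spanA.end}\t{b.spanB.start + 1}\t"
                     f"{b.spanB.end}\t{b.orientation}\t{b.sv_class}\n")
    variants, complex_regions = call_variants(blocks, genomeA, genomeB)
    annotate_variants(variants, modelsA, genomeA, genomeB)
    variants_to_vcf(variants, genomeA, out / "variants.vcf")
    vsummary = summarize_variants(variants)
    vsummary["n_complex_regions"] = len(complex_regions)
    with open(out / "variant_summary.json", "w") as fh:
        json.dump(vsummary, fh, indent=1)
    return blocks, variants, vsummary
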