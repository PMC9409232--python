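"""Synteny blocks, base-level calls, SNP classes and codon-aware effects."""

import random
from itertools import product

import pytest

from mitocms.datasets import THREE_TO_ONE, classify_snp_table, cotton_cms_snp_table
from mitocms.genome import CircularSequence, GeneModel, revcomp
from mitocms.orfs import translate
from mitocms.synthetic import GeneratorConfig, generate_genome_pair
from mitocms.variants import (Variant, align_genomes, annotate_variants,
                              call_variants, classify_snp, coding_effect,
                              normalize_indel, summarize_variants)
from conftest import random_seq, sense_cds


@pytest.fixture(scope="module")
def backbone():
    return random_seq(30000, seed=11)


class TestAlignGenomes:
    def test_identical_genomes_single_collinear_block(self, backbone):
        A = CircularSequence("A", backbone)
        B = CircularSequence("B", backbone)
        blocks = align_genomes(A, B)
        assert len(blocks) == 1 and blocks[0].sv_class == "collinear"
        assert len(blocks[0].spanA) == len(backbone)

    def test_in_place_inversion(self, backbone):
        s = list(backbone)
        s[8000:14500] = revcomp(backbone[8000:14500])
        blocks = align_genomes(CircularSequence("A", backbone),
                               CircularSequence("B", "".join(s)))
        assert [b.sv_class for b in blocks].count("inversion") == 1

    def test_translocation_and_combined(self, backbone):
        s = backbone
        swapped = s[:5000] + s[11000:18000] + s[5000:11000] + s[18000:]
        classes = [b.sv_class for b in
                   align_genomes(CircularSequence("A", s), CircularSequence("B", swapped))]
        assert "translocation" in classes
        flipped = s[:5000] + s[11000:18000] + revcomp(s[5000:11000]) + s[18000:]
        classes = [b.sv_class for b in
                   align_genomes(CircularSequence("A", s), CircularSequence("B", flipped))]
        assert "translocation+inversion" in classes

    def test_unrelated_genomes_raise(self):
        A = CircularSequence("A", random_seq(2000, seed=1))
        B = CircularSequence("B", random_seq(2000, seed=2))
        with pytest.raises(ValueError):
            align_genomes(A, B)

    def test_generator_planted_sv_classified(self):
        cfg = GeneratorConfig(seed=3, genome_length=60000, n_genes=8,
                              n_snps=0, n_genic_snps=0, n_indels=0,
                              repeats=[], chimera=None,
                              svs=[("translocation+inversion", 7000)])
        A, B, _, truth = generate_genome_pair(cfg)
        blocks = align_genomes(A, B)
        assert any(b.sv_class == "translocation+inversion" for b in blocks)


class TestCallVariants:
    def test_identical_blocks_no_variants(self, backbone):
        A = CircularSequence("A", backbone)
        B = CircularSequence("B", backbone)
        variants, complex_regions = call_variants(align_genomes(A, B), A, B)
        assert variants == [] and complex_regions == []

    def test_planted_snps_and_insertion_called_exactly(self, backbone):
        s = list(backbone)
        truth = []
        for pos in (3000, 9000, 15000):
            alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[pos]]
            truth.append((pos, s[pos], alt))
            s[pos] = alt
        ins = "A" if s[11999] != "A" else "C"
        s.insert(12000, ins)
        A = CircularSequence("A", backbone)
        B = CircularSequence("B", "".join(s))
        variants, _ = call_variants(align_genomes(A, B), A, B)
        snps = [(v.posA, v.refA, v.altB) for v in variants if v.vtype == "SNP"]
        inss = [(v.posA, v.altB) for v in variants if v.vtype == "insertion"]
        assert snps == truth and inss == [(12000, ins)] and len(variants) == 4

    def test_symmetry_under_genome_swap(self, backbone):
        s = list(backbone)
        del s[7000:7004]
        s[20000] = "A" if s[20000] != "A" else "T"
        A = CircularSequence("A", backbone)
        B = CircularSequence("B", "".join(s))
        vAB, _ = call_variants(align_genomes(A, B), A, B)
        vBA, _ = call_variants(align_genomes(B, A), B, A)
        assert len(vAB) == len(vBA)
        swap = {"insertion": "deletion", "deletion": "insertion", "SNP": "SNP"}
        assert sorted(swap[v.vtype] for v in vAB) == sorted(v.vtype for v in vBA)

    def test_full_planted_recovery(self, default_pair):
        genomeA, genomeB, _, truth = default_pair
        variants, complex_regions = call_variants(
            align_genomes(genomeA, genomeB), genomeA, genomeB)
        got_snps = {(v.posA, v.refA, v.altB) for v in variants if v.vtype == "SNP"}
        exp_snps = {(s["posA"], s["ref"], s["alt"]) for s in truth.snps}
        got_ind = {(v.vtype, v.posA, v.refA + v.altB)
                   for v in variants if v.vtype != "SNP"}
        exp_ind = {(d["vtype"], d["posA"], d["seq"]) for d in truth.indels}
        assert got_snps == exp_snps       # precision and recall both exact
        assert got_ind == exp_ind
        assert not complex_regions


class TestNormalizeIndel:
    def test_left_shift_in_homopolymer(self):
        ref = "CCAAAATT"
        pos, seq = normalize_indel(ref, 5, "A", "deletion")
        assert pos == 2 and seq == "A"
        pos, seq = normalize_indel(ref, 6, "A", "insertion")
        assert pos == 2 and seq == "A"

    def test_repeat_motif_rotation(self):
        ref = "GGATATATCC"
        pos, seq = normalize_indel(ref, 6, "AT", "deletion")
        assert pos == 2 and seq == "AT"


class TestClassifySnp:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("C", "A", "transversion"),
        ("G", "A", "transition"),
        ("C", "T", "transition"),
        ("T", "G", "transversion"),
    ])
    def test_examples(self, ref, alt, expected):
        assert classify_snp(ref, alt) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            classify_snp("A", "A")
        with pytest.raises(ValueError):
            classify_snp("A", "N")


class TestCodingEffect:
    def test_leu_to_ile_nonsynonymous(self):
        cds = "ATG" + "CTT" + sense_cds(8, seed=2)[3:]
        g = CircularSequence("g", random_seq(50, seed=3) + cds + random_seq(50, seed=4))
        m = GeneModel("x", "g", "+", [(50, 50 + len(cds))])
        v = Variant("SNP", 53, 53, "C", "A")
        coding_effect(v, m, g, g)
        assert v.coding_effect == "non-synonymous" and v.aa_change == ("L", "I")

    def test_ile_synonymous_wobble(self):
        cds = "ATG" + "ATC" + "AAA" * 5 + "TAA"
        g = CircularSequence("g", "CCCCC" + cds + "GGGGG")
        m = GeneModel("x", "g", "+", [(5, 5 + len(cds))])
        v = Variant("SNP", 10, 10, "C", "A")
        coding_effect(v, m, g, g)
        assert v.coding_effect == "synonymous" and v.aa_change == ("I", "I")

    def test_minus_strand_substitution(self):
        cds = "ATG" + "CTT" + "AAA" * 5 + "TAA"
        g = CircularSequence("g", random_seq(40, seed=5) + revcomp(cds) + random_seq(40, seed=6))
        m = GeneModel("x", "g", "-", [(40, 40 + len(cds))])
        fwd = 40 + len(cds) - 1 - 3  # the 'C' of the Leu codon on the forward strand
        v = Variant("SNP", fwd, fwd, g.seq[fwd], revcomp("A"))
        coding_effect(v, m, g, g)
        assert v.coding_effect == "non-synonymous" and v.aa_change == ("L", "I")

    def test_engineered_frameshift_affects_44_residues(self):
        # 'T' inserted after the start codon shifts the frame onto a designed
        # track: 44 altered residues, then the first new-frame stop
        cds = "ATG" + "GCA" * 43 + "GCT" + "AAA" + "GCA" * 3 + "TAA"
        g = CircularSequence("g", random_seq(30, seed=7) + cds + random_seq(30, seed=8))
        m = GeneModel("x", "g", "+", [(30, 30 + len(cds))])
        v = Variant("insertion", 33, 33, "", "T")
        coding_effect(v, m, g, g)
        assert v.coding_effect == "frameshift" and v.frameshift_aa == 44

    def test_exhaustive_single_base_codon_oracle(self):
        mismatches = 0
        for codon_t in product("ACGT", repeat=3):
            codon = "".join(codon_t)
            if translate(codon) == "*":
                continue
            g = CircularSequence("g", "CC" + "ATG" + codon + "TAA" + "GG")
            m = GeneModel("x", "g", "+", [(2, 11)])
            for i, alt in product(range(3), "ACGT"):
                if alt == codon[i]:
                    continue
                new = codon[:i] + alt + codon[i + 1:]
                v = Variant("SNP", 5 + i, 5 + i, codon[i], alt)
                coding_effect(v, m, g, g)
                expect_syn = translate(new) != "*" and translate(new) == translate(codon)
                if (v.coding_effect == "synonymous") != expect_syn:
                    mismatches += 1
        assert mismatches == 0


class TestWorkedSnpTable:
    """The published 14-row genic SNP table as classifier input."""

    def test_effect_split_five_syn_nine_nonsyn(self):
        df = classify_snp_table()
        assert (df["computed_effect"] == "S").sum() == 5
        assert (df["computed_effect"] == "N").sum() == 9

    def test_per_row_labels_match_reported(self):
        df = classify_snp_table()
        assert (df["computed_effect"] == df["reported_effect"]).all()
        assert (df["computed_snp_class"] == df["reported_snp_class"]).all()

    def test_transversion_majority(self):
        df = classify_snp_table()
        assert (df["computed_snp_class"] == "transversion").sum() == 12
        assert (df["computed_snp_class"] == "transition").sum() == 2

    def test_amino_acids_are_known(self):
        df = cotton_cms_snp_table()
        for aa in list(df["aa_ref"]) + list(df["aa_alt"]):
            assert aa in THREE_TO_ONE


class TestSummaries:
    def test_annotation_and_summary_on_default_pair(self, default_pair):
        genomeA, genomeB, annotations, truth = default_pair
        variants, _ = call_variants(align_genomes(genomeA, genomeB), genomeA, genomeB)
        annotate_variants(variants, annotations[genomeA.name], genomeA, genomeB)
        summary = summarize_variants(variants)
        exp_genic = [s for s in truth.snps if s["location"] == "genic"]
        assert summary["n_snp"] == len(truth.snps)
        assert summary["n_genic"] == len(exp_genic)
        assert summary["n_syn"] == sum(1 for s in exp_genic
                                       if s["coding_effect"] == "synonymous")
        assert summary["n_nonsyn"] == sum(1 for s in exp_genic
                                          if s["coding_effect"] == "non-synonymous")
        assert summary["n_transition"] == sum(1 for s in truth.snps
                                              if s["snp_class"] == "transition")
        hist = summary["indel_length_histogram"]
        assert sum(hist.values()) == summary["n_ins"] + summary["n_del"]

    def test_empty(self):
        s = summarize_variants([])
        assert s["n_snp"] == 0 and s["indel_length_histogram"] == {}
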