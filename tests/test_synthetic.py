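"""Generator self-consistency: determinism, edit replay, truth coordinates."""

import numpy as np
import pytest

from mitocms.genome import extract_spliced_cds
from mitocms.orfs import find_orfs, translate
from mitocms.synthetic import (ChimeraSpec, ConfigInfeasibleError, CountModel,
                               GeneratorConfig, TruthSet, generate_genome_pair,
                               simulate_counts, simulate_transcript_alignments)


class TestGeneratePair:
    def test_deterministic_for_fixed_seed(self):
        a1 = generate_genome_pair(GeneratorConfig(seed=5))
        a2 = generate_genome_pair(GeneratorConfig(seed=5))
        assert a1[0].seq == a2[0].seq and a1[1].seq == a2[1].seq
        assert a1[3].snps == a2[3].snps and a1[3].indels == a2[3].indels

    def test_zero_edit_config_identity(self):
        cfg = GeneratorConfig(seed=2, n_snps=0, n_genic_snps=0, n_indels=0,
                              chimera=None, repeats=[])
        genomeA, genomeB, _, truth = generate_genome_pair(cfg)
        assert genomeA.seq == genomeB.seq
        assert not truth.snps and not truth.indels and truth.chimera is None

    def test_truth_alleles_match_both_genomes(self, default_pair):
        genomeA, genomeB, _, truth = default_pair
        for s in truth.snps:
            assert genomeA.seq[s["posA"]] == s["ref"]
            assert genomeB.seq[s["posB"]] == s["alt"]
        for d in truth.indels:
            if d["vtype"] == "insertion":
                assert genomeB.seq[d["posB"]:d["posB"] + d["length"]] == d["seq"]
            else:
                assert genomeA.seq[d["posA"]:d["posA"] + d["length"]] == d["seq"]

    def test_gene_models_yield_valid_cds_on_both_genomes(self, default_pair):
        genomeA, genomeB, annotations, _ = default_pair
        for genome, models in ((genomeA, annotations[genomeA.name]),
                               (genomeB, annotations[genomeB.name])):
            for m in models:
                if m.biotype != "protein_coding":
                    continue
                cds = extract_spliced_cds(genome, m)
                assert len(cds) % 3 == 0
                assert cds.startswith("ATG") and cds[-3:] in ("TAA", "TAG", "TGA")
                assert "*" not in translate(cds[:-3])

    def test_chimera_orf_planted_as_specified(self, default_pair):
        _, genomeB, _, truth = default_pair
        ch = truth.chimera
        s, e = ch["spanB"]
        assert genomeB.seq[s:e] == ch["nt"]
        assert ch["known_bp"] == 1336 and ch["unknown_bp"] == 485
        # the printed-name arithmetic: (1336 + 485)/3 - 1 = 606
        assert ch["aa_length"] == 606 and ch["orf_name"] == "orf606a"
        hits = [o for o in find_orfs(genomeB)
                if (o.span.start, o.span.end) == (s, e) and o.strand == "+"]
        assert hits and hits[0].orf_id == ch["orf_name"]

    def test_infeasible_config_rejected(self):
        with pytest.raises(ConfigInfeasibleError):
            generate_genome_pair(GeneratorConfig(seed=1, genome_length=20000))

    def test_indel_lengths_respect_bounds(self, default_pair):
        _, _, _, truth = default_pair
        for d in truth.indels:
            if d["chimera"]:
                continue
            assert 1 <= d["length"] <= 10


class TestSimulateCounts:
    def test_reproducible(self):
        cfg = GeneratorConfig(seed=1)
        t = TruthSet(log2_fold_changes={"a": 2.0})
        c1 = simulate_counts(t, ["a", "b"], cfg, seed=9)
        c2 = simulate_counts(t, ["a", "b"], cfg, seed=9)
        assert c1.equals(c2)

    def test_null_fold_changes_balanced(self):
        cfg = GeneratorConfig(seed=1, count_model=CountModel(mean=1000, dispersion=0.02))
        counts = simulate_counts(TruthSet(), [f"g{i}" for i in range(200)], cfg, seed=3)
        a = counts[[c for c in counts.columns if c.startswith("restorer")]].mean(axis=1)
        b = counts[[c for c in counts.columns if c.startswith("cms")]].mean(axis=1)
        ratio = np.log2((b.mean() + 0.5) / (a.mean() + 0.5))
        assert abs(ratio) < 0.1

    def test_planted_fold_change_shifts_means(self):
        cfg = GeneratorConfig(seed=1, count_model=CountModel(mean=500, dispersion=0.05))
        t = TruthSet(log2_fold_changes={"hot": 3.0})
        counts = simulate_counts(t, ["hot", "cold"], cfg, seed=4)
        row = counts.loc["hot"]
        up = row[[c for c in counts.columns if c.startswith("cms")]].mean()
        down = row[[c for c in counts.columns if c.startswith("restorer")]].mean()
        assert up / max(down, 1) > 4


class TestSimulateAlignments:
    def test_retention_extremes(self, default_pair):
        _, genomeB, annotations, _ = default_pair
        model = next(m for m in annotations[genomeB.name] if m.gene_id == "nad4")
        introns = model.introns()
        full = simulate_transcript_alignments(model, {1: 1.0, 2: 1.0, 3: 1.0},
                                              n_reads=10, seed=1)
        s, e = introns[0]
        for tx, df in full.groupby("transcript_id"):
            covered = sum(min(e, b) - max(s, a)
                          for a, b in df[["start", "end"]].to_numpy()
                          if a < e and b > s)
            assert covered == e - s
        none = simulate_transcript_alignments(model, {}, n_reads=10, seed=2)
        for s, e in introns:
            inside = none[(none["start"] < e) & (none["end"] > s)]
            for a, b in inside[["start", "end"]].to_numpy():
                assert min(e, b) - max(s, a) <= 0, "intronic coverage at retention 0"

    def test_mean_fraction_tracks_retention(self, default_pair):
        _, genomeB, annotations, _ = default_pair
        model = next(m for m in annotations[genomeB.name] if m.gene_id == "nad4")
        s, e = model.introns()[1]
        blocks = simulate_transcript_alignments(model, {2: 0.5}, n_reads=80, seed=3)
        fracs = []
        for tx, df in blocks.groupby("transcript_id"):
            covered = sum(min(e, b) - max(s, a)
                          for a, b in df[["start", "end"]].to_numpy()
                          if a < e and b > s)
            fracs.append(covered / (e - s))
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.05)
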