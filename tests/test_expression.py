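"""Normalization, differential expression, 2^-ddCt and intron retention."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitocms.expression import (CountTable, ddct, differential_expression,
                                intron_retention, normalize_counts, size_factors)
from mitocms.genome import GeneModel
from mitocms.synthetic import (CountModel, GeneratorConfig, TruthSet,
                               simulate_counts, simulate_transcript_alignments)


def make_table(data, n_rep=3):
    cols = [f"restorer_{i+1}" for i in range(n_rep)] + [f"cms_{i+1}" for i in range(n_rep)]
    df = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    conditions = {c: ("cms" if c.startswith("cms") else "restorer") for c in cols}
    return CountTable(df, conditions)


class TestNormalization:
    def test_identical_columns_unit_factors(self):
        df = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        assert np.allclose(size_factors(df), 1.0)

    def test_doubled_column_factor_two(self):
        df = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        f = size_factors(df)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)

    def test_recovers_planted_library_sizes_within_5pct(self):
        cfg = GeneratorConfig(seed=3, count_model=CountModel(mean=800, dispersion=0.05))
        genes = [f"g{i}" for i in range(300)]
        planted = {"restorer_2": 1.6, "cms_1": 0.7}
        counts = simulate_counts(TruthSet(), genes, cfg, seed=5,
                                 library_size_factors=planted)
        f = size_factors(counts)
        f = f / f["restorer_1"]
        assert f["restorer_2"] == pytest.approx(1.6, rel=0.05)
        assert f["cms_1"] == pytest.approx(0.7, rel=0.05)

    def test_all_zero_reference_rejected(self):
        df = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
        with pytest.raises(ValueError):
            size_factors(df)


class TestDifferentialExpression:
    def test_equal_means_zero_lfc(self):
        tbl = make_table({"g1": [100, 100, 100, 100, 100, 100]})
        out = differential_expression(tbl, "restorer", "cms")
        assert out.loc["g1", "log2FC"] == pytest.approx(0.0)

    def test_all_zero_gene_finite(self):
        tbl = make_table({"g0": [0] * 6, "g1": [50, 55, 45, 52, 48, 50]})
        out = differential_expression(tbl, "restorer", "cms")
        assert out.loc["g0", "log2FC"] == 0.0 and not out.loc["g0", "significant"]

    def test_single_replicate_gives_lfc_only(self):
        df = pd.DataFrame({"r1": [100, 10, 55, 210, 90], "c1": [400, 10, 57, 205, 88]},
                          index=["up", "flat1", "flat2", "flat3", "flat4"])
        tbl = CountTable(df, {"r1": "restorer", "c1": "cms"})
        out = differential_expression(tbl, "restorer", "cms")
        assert np.isnan(out["p_value"]).all()
        assert not out["significant"].any()
        assert out.loc["up", "log2FC"] > 1.5

    def test_power_planted_lfc3(self):
        """>=95% detection of a log2FC=3 gene at n=3 over 200 simulations."""
        cfg = GeneratorConfig(seed=0, count_model=CountModel(mean=500, dispersion=0.05))
        truth = TruthSet(log2_fold_changes={"hot": 3.0})
        genes = ["hot"] + [f"null{i}" for i in range(19)]
        hits = 0
        for rep in range(200):
            counts = simulate_counts(truth, genes, cfg, seed=1000 + rep)
            tbl = CountTable(counts, {c: ("cms" if c.startswith("cms") else "restorer")
                                      for c in counts.columns})
            out = differential_expression(tbl, "restorer", "cms")
            row = out.loc["hot"]
            if row["significant"] and row["log2FC"] > 0:
                hits += 1
        assert hits / 200 >= 0.95

    def test_type_i_error_bounded(self):
        """Null rejection rate at p<0.05 stays below 0.07 (n=3, 200 sims)."""
        cfg = GeneratorConfig(seed=0, count_model=CountModel(mean=500, dispersion=0.05))
        truth = TruthSet()
        genes = [f"g{i}" for i in range(50)]
        rejections = total = 0
        for rep in range(200):
            counts = simulate_counts(truth, genes, cfg, seed=2000 + rep)
            tbl = CountTable(counts, {c: ("cms" if c.startswith("cms") else "restorer")
                                      for c in counts.columns})
            out = differential_expression(tbl, "restorer", "cms")
            rejections += int((out["p_value"] < 0.05).sum())
            total += len(genes)
        assert rejections / total <= 0.07


class TestDdct:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])

    def test_closed_form_identities(self):
        rows = []
        for cond, tgt_ct in [("calib", 24.0), ("treat", 23.0)]:
            for rep in (1, 2, 3):
                rows.append(["target", cond, rep, tgt_ct])
                rows.append(["ref", cond, rep, 20.0])
        out = ddct(self._table(rows), "target", "ref", "calib")
        assert out["calib"] == pytest.approx(1.0)
        assert out["treat"] == pytest.approx(2.0)   # ddCt = -1

    def test_ddct_of_three_gives_eighth(self):
        rows = []
        for cond, tgt in [("calib", 22.0), ("treat", 25.0)]:
            for rep in (1, 2):
                rows.append(["t", cond, rep, tgt])
                rows.append(["ref", cond, rep, 20.0])
        out = ddct(self._table(rows), "t", "ref", "calib")
        assert out["treat"] == pytest.approx(0.125)

    @given(shift=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, shift):
        rows = []
        for cond, tgt in [("calib", 24.0), ("treat", 22.5)]:
            for rep in (1, 2, 3):
                rows.append(["t", cond, rep, tgt + 0.1 * rep])
                rows.append(["ref", cond, rep, 20.0 + 0.05 * rep])
        base = ddct(self._table(rows), "t", "ref", "calib")
        shifted_rows = [[g, c, r, ct + shift] for g, c, r, ct in rows]
        shifted = ddct(self._table(shifted_rows), "t", "ref", "calib")
        assert np.allclose(base.values, shifted.values)

    def test_missing_reference_rejected(self):
        rows = [["t", "calib", 1, 24.0]]
        with pytest.raises(ValueError):
            ddct(self._table(rows), "t", "ref", "calib")


class TestIntronRetention:
    @pytest.fixture
    def model(self):
        # 3 exons, 2 introns, plus strand
        return GeneModel("g", "chr", "+", [(100, 200), (300, 400), (500, 600)])

    def _blocks(self, rows):
        return pd.DataFrame(rows, columns=["seq", "start", "end", "transcript_id"])

    def test_full_retention_and_clean_splicing(self, model):
        rows = [("chr", 100, 400, "tx1"),          # retains intron 1 entirely
                ("chr", 500, 600, "tx1"),
                ("chr", 100, 200, "tx2"),          # splices both introns
                ("chr", 300, 400, "tx2"),
                ("chr", 500, 600, "tx2")]
        out = intron_retention(self._blocks(rows), model)
        fr1 = [x for x in out.per_intron if x["intron"] == 1][0]
        assert fr1["mean_fraction"] == pytest.approx(0.5)  # one full, one spliced
        fr2 = [x for x in out.per_intron if x["intron"] == 2][0]
        assert fr2["mean_fraction"] == 0.0 and fr2["class"] == "spliced"

    def test_transcript_must_span_flanking_exons(self, model):
        rows = [("chr", 205, 295, "stray")]  # intronic-only fragment, no exon overlap
        out = intron_retention(self._blocks(rows), model)
        assert all(x["class"] == "NA" for x in out.per_intron)

    def test_no_intron_model_rejected(self):
        single = GeneModel("s", "chr", "+", [(0, 300)])
        with pytest.raises(ValueError):
            intron_retention(self._blocks([("chr", 0, 300, "t")]), single)

    def test_simulated_retention_recovered(self, default_pair):
        genomeA, genomeB, annotations, truth = default_pair
        model = next(m for m in annotations[genomeB.name] if m.gene_id == "nad4")
        blocks = simulate_transcript_alignments(model, truth.retention, n_reads=50, seed=4)
        out = intron_retention(blocks, model)
        by_idx = {x["intron"]: x for x in out.per_intron}
        assert by_idx[1]["mean_fraction"] == pytest.approx(0.95, abs=0.1)
        assert by_idx[1]["class"] == "retained"
        assert by_idx[2]["mean_fraction"] == 0.0 and by_idx[2]["class"] == "spliced"
        assert by_idx[3]["mean_fraction"] == pytest.approx(0.5, abs=0.1)
        assert by_idx[3]["class"] == "partial"
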