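"""Two-class GSEA: ranking metric, enrichment score, permutation FDR."""

import numpy as np
import pandas as pd
import pytest

import immunosubtyper as ims
from _oracles import gsea_es_oracle


def _expr(values: np.ndarray) -> ims.ExpressionMatrix:
    genes = [f"g{i:03d}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ims.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def _ranked(genes, metric) -> ims.RankedGeneList:
    return ims.RankedGeneList(genes=tuple(genes), metric=np.asarray(metric, dtype=float))


class TestRankBySnr:
    def test_zero_variance_gene_capped_by_floor_and_ranked_first(self, rng):
        values = rng.normal(0, 1, (10, 8))
        values[0, :4] = 5.0   # class A, exactly constant
        values[0, 4:] = 0.0   # class B, exactly constant
        labels = pd.Series(list("AAAABBBB"), index=[f"s{j}" for j in range(8)])
        ranked = ims.rank_by_snr(_expr(values), labels)
        assert ranked.genes[0] == "g000"
        # sd floors: max(0.2*5, 0.2) + max(0, 0.2) = 1.2 -> metric 5/1.2
        assert ranked.metric[0] == pytest.approx(5 / 1.2)

    def test_swapping_classes_negates_and_reverses(self, rng):
        values = rng.normal(0, 1, (15, 10))
        labels = pd.Series(list("AAAAABBBBB"), index=[f"s{j}" for j in range(10)])
        fwd = ims.rank_by_snr(_expr(values), labels)
        swapped = labels.map({"A": "B", "B": "A"})
        # relabel so the alphabetically first class flips membership
        rev = ims.rank_by_snr(_expr(values), swapped)
        by_gene_fwd = dict(zip(fwd.genes, fwd.metric))
        by_gene_rev = dict(zip(rev.genes, rev.metric))
        for g in fwd.genes:
            assert by_gene_rev[g] == pytest.approx(-by_gene_fwd[g], abs=1e-12)

    def test_equal_means_metric_zero(self):
        values = np.tile(np.asarray([1.0, 2.0, 3.0, 1.0, 2.0, 3.0]), (3, 1))
        labels = pd.Series(list("AAABBB"), index=[f"s{j}" for j in range(6)])
        ranked = ims.rank_by_snr(_expr(values), labels)
        np.testing.assert_allclose(ranked.metric, 0.0, atol=1e-12)

    def test_small_class_is_error(self):
        values = np.zeros((4, 5))
        labels = pd.Series(list("AABBB"), index=[f"s{j}" for j in range(5)])
        with pytest.raises(ValueError, match=">= 3"):
            ims.rank_by_snr(_expr(values), labels)


class TestGseaEs:
    def test_top_two_of_six_oracle_value(self):
        genes = list("abcdef")
        metric = [3.0, 2.5, 1.0, 0.5, -1.0, -2.0]
        want = gsea_es_oracle(genes, metric, {"a", "b"}, 0)
        got = ims.gsea_es(_ranked(genes, metric), ims.GeneSet.from_genes("t", ["a", "b"]), 0)
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(1.0)  # frozen from the oracle

    def test_bottom_two_mirror_of_top_two(self):
        genes = list("abcdef")
        metric = [3.0, 2.5, 1.0, 0.5, -1.0, -2.0]
        top = ims.gsea_es(_ranked(genes, metric), ims.GeneSet.from_genes("t", ["a", "b"]), 0)
        bot = ims.gsea_es(_ranked(genes, metric), ims.GeneSet.from_genes("b", ["e", "f"]), 0)
        assert bot == pytest.approx(-top, abs=1e-12)

    def test_interleaved_set_smaller_deviation_than_clustered(self):
        genes = [f"g{i}" for i in range(8)]
        metric = np.linspace(3, -3, 8)
        clustered = ims.gsea_es(
            _ranked(genes, metric), ims.GeneSet.from_genes("c", genes[:4]), 0
        )
        interleaved = ims.gsea_es(
            _ranked(genes, metric), ims.GeneSet.from_genes("i", genes[::2]), 0
        )
        assert abs(interleaved) < abs(clustered)

    def test_matches_oracle_on_random_lists(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 11))
            genes = [f"g{i}" for i in range(n)]
            metric = np.sort(rng.normal(0, 2, n))[::-1]
            k = int(rng.integers(2, n))
            set_genes = set(rng.choice(genes, size=k, replace=False))
            p_weight = float(rng.choice([0.0, 1.0]))
            want = gsea_es_oracle(genes, metric, set_genes, p_weight)
            got = ims.gsea_es(
                _ranked(genes, metric), ims.GeneSet.from_genes("x", set_genes), p_weight
            )
            assert got == pytest.approx(want, abs=1e-9)

    def test_single_present_gene_is_skip_error(self):
        genes = list("abcdef")
        metric = np.linspace(2, -2, 6)
        with pytest.raises(ValueError, match="< 2"):
            ims.gsea_es(_ranked(genes, metric), ims.GeneSet.from_genes("x", ["a", "zz"]), 0)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(42)
    n_genes, n_per = 300, 15
    values = rng.normal(0, 1, (n_genes, 2 * n_per))
    values[:20, :n_per] += 1.5  # planted up-set in class A
    expr = _expr(values)
    labels = pd.Series(["A"] * n_per + ["B"] * n_per, index=expr.sample_ids)
    gene_ids = expr.gene_ids
    sets = ims.GeneSetCollection.from_sets(
        [ims.GeneSet.from_genes("planted", gene_ids[:20])]
        + [
            ims.GeneSet.from_genes(f"null{k}", gene_ids[20 + 20 * k : 40 + 20 * k])
            for k in range(8)
        ]
    )
    return expr, labels, sets


class TestGseaPermutation:
    def test_planted_set_significant_and_directed(self, planted):
        expr, labels, sets = planted
        table = ims.gsea_permutation(expr, labels, sets, n_perm=500, seed=3)
        assert table.loc["planted", "fdr_q"] < 0.05
        assert table.loc["planted", "direction"] == "up_in_A"

    def test_same_seed_identical_table(self, planted):
        expr, labels, sets = planted
        t1 = ims.gsea_permutation(expr, labels, sets, n_perm=200, seed=7)
        t2 = ims.gsea_permutation(expr, labels, sets, n_perm=200, seed=7)
        pd.testing.assert_frame_equal(t1, t2)

    def test_sign_coherence_es_nes_direction(self, planted):
        expr, labels, sets = planted
        table = ims.gsea_permutation(expr, labels, sets, n_perm=200, seed=3)
        for _, row in table.iterrows():
            assert np.sign(row["ES"]) == np.sign(row["NES"]) or row["ES"] == 0
            expected = "up_in_A" if row["ES"] >= 0 else "up_in_B"
            assert row["direction"] == expected

    def test_few_samples_fall_back_to_exhaustive(self, rng, caplog):
        values = rng.normal(0, 1, (50, 8))
        expr = _expr(values)
        labels = pd.Series(list("AAAABBBB"), index=expr.sample_ids)
        sets = ims.GeneSetCollection.from_sets(
            [ims.GeneSet.from_genes("s", expr.gene_ids[:10])]
        )
        with caplog.at_level("WARNING"):
            table = ims.gsea_permutation(expr, labels, sets, n_perm=100, seed=0)
        assert table.attrs["n_perm"] == 70  # C(8, 4) distinct assignments
        assert any("distinct" in rec.message for rec in caplog.records)

    def test_bh_mode_matches_bh_of_nominal(self, planted):
        expr, labels, sets = planted
        table = ims.gsea_permutation(expr, labels, sets, n_perm=200, seed=3, fdr_mode="bh")
        np.testing.assert_allclose(
            table["fdr_q"].to_numpy(), ims.bh_adjust(table["nominal_p"].to_numpy())
        )


class TestCommonPathways:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["pathway", "fdr_q", "direction"]
        ).set_index("pathway")

    def test_intersection_with_direction(self):
        t1 = self._table([("P1", 0.01, "up_in_A"), ("P2", 0.01, "up_in_A"), ("P3", 0.5, "up_in_A")])
        t2 = self._table([("P2", 0.02, "up_in_A"), ("P3", 0.01, "up_in_A")])
        assert ims.common_pathways([t1, t2]) == ["P2"]

    def test_opposite_direction_excluded(self):
        t1 = self._table([("P1", 0.01, "up_in_A")])
        t2 = self._table([("P1", 0.01, "up_in_B")])
        assert ims.common_pathways([t1, t2]) == []

    def test_single_table_is_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            ims.common_pathways([self._table([("P1", 0.01, "up_in_A")])])


class TestPathwayImmuneCorrelation:
    def _scores(self, rows: dict) -> ims.SignatureScoreMatrix:
        return ims.SignatureScoreMatrix(
            data=pd.DataFrame(rows).T, alpha=0.25
        )

    def test_identical_series_rho_one(self):
        imm = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        scores = self._scores({"p": imm})
        out = ims.pathway_immune_correlation(scores, imm)
        assert out.loc["p", "rho"] == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        imm = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        scores = self._scores({"p": -imm})
        out = ims.pathway_immune_correlation(scores, imm)
        assert out.loc["p", "rho"] == pytest.approx(-1.0)

    def test_constant_pathway_flagged(self):
        imm = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        scores = self._scores({"flat": pd.Series(2.0, index=imm.index), "ok": imm})
        out = ims.pathway_immune_correlation(scores, imm)
        assert out.loc["flat", "constant"]
        assert np.isnan(out.loc["flat", "rho"])
        assert not out.loc["ok", "constant"]

    def test_null_spearman_95th_percentile(self, rng):
        # |rho| under independence at n = 100 concentrates near 1.96/sqrt(99)
        rhos = []
        for _ in range(400):
            x, y = rng.normal(0, 1, 100), rng.normal(0, 1, 100)
            rhos.append(abs(ims.spearman(x, y).statistic))
        q95 = float(np.quantile(rhos, 0.95))
        assert q95 == pytest.approx(0.196, abs=0.03)

    def test_coupled_blocks_recovered_on_cohort(self, default_cohort, default_estimate):
        expr = default_cohort.expression
        both = ims.GeneSetCollection.from_sets(
            list(default_cohort.coupled_pathways)
            + list(default_cohort.anticoupled_pathways)
        )
        scores = ims.score_collection(expr, both)
        out = ims.pathway_immune_correlation(scores, default_estimate.immune_score)
        for name in default_cohort.coupled_pathways.names:
            assert out.loc[name, "rho"] > 0
            assert out.loc[name, "q"] < 0.05
        for name in default_cohort.anticoupled_pathways.names:
            assert out.loc[name, "rho"] < 0
            assert out.loc[name, "q"] < 0.05
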