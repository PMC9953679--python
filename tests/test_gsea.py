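import numpy as np
import pandas as pd
import pytest

from capmort import (
    CohortConfig,
    ExpressionConfig,
    enrichment_score,
    filter_significant,
    generate_cohort,
    generate_expression,
    generate_gene_sets,
    gsea_run,
    rank_genes,
    read_gmt,
)
from capmort.datasets import load_gsea_table
from capmort.gsea import GeneSetCollection

from conftest import naive_enrichment_walk


def make_ranked(metric_values, genes=None):
    genes = genes or [f"g{i}" for i in range(len(metric_values))]
    return pd.Series(list(metric_values), index=pd.Index(genes, name="gene"))


class TestReadGmt:
    def test_roundtrip(self, tmp_path):
        col = GeneSetCollection(
            {"SET_A": ["X", "Y"], "SET_B": ["Z"]}, {"SET_A": "desc", "SET_B": ""}
        )
        path = tmp_path / "toy.gmt"
        col.to_gmt(path)
        back = read_gmt(path)
        assert back.sets == col.sets
        assert back.descriptions["SET_A"] == "desc"

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("ONLY_NAME\tdesc\n")
        with pytest.raises(ValueError, match="line 1"):
            read_gmt(path)

    def test_restrict_drops_empty_sets(self):
        col = GeneSetCollection({"A": ["X", "Y"], "B": ["Q"]})
        kept = col.restrict(["X", "Y", "Z"])
        assert list(kept) == ["A"]


class TestRankGenes:
    @pytest.fixture(scope="class")
    @staticmethod
    def toy_matrix():
        # one gene with exact group means 2 vs 1, sd 0.5 in both groups
        cols = [f"d{i}" for i in range(4)] + [f"s{i}" for i in range(4)]
        died = np.array([2.5, 1.5, 2.5, 1.5])  # mean 2, sd ~0.577
        surv = np.array([1.5, 0.5, 1.5, 0.5])  # mean 1
        x = pd.DataFrame([np.concatenate([died, surv])], index=["gene1"], columns=cols)
        outcome = ["died"] * 4 + ["survived"] * 4
        return x, outcome

    def test_signal_to_noise_hand_value(self):
        # mu1=2, mu2=1, sd1=sd2=0.5 -> (2-1)/(0.5+0.5) = 1.0
        cols = [f"c{i}" for i in range(8)]
        g1 = [2.0 + 0.5, 2.0 - 0.5, 2.0 + 0.5, 2.0 - 0.5]
        g2 = [1.0 + 0.5, 1.0 - 0.5, 1.0 + 0.5, 1.0 - 0.5]
        sd = np.std(g1, ddof=1)
        x = pd.DataFrame([g1 + g2], index=["g"], columns=cols)
        ranked = rank_genes(x, ["died"] * 4 + ["survived"] * 4)
        assert ranked.iloc[0] == pytest.approx(1.0 / (2 * sd))

    def test_tie_break_lexicographic(self):
        cols = [f"c{i}" for i in range(8)]
        rng = np.random.default_rng(0)
        row = rng.normal(size=8)
        x = pd.DataFrame([row, row, row], index=["b", "a", "c"], columns=cols)
        ranked = rank_genes(x, ["died"] * 4 + ["survived"] * 4)
        assert list(ranked.index) == ["a", "b", "c"]

    def test_label_flip_negates_metric(self, small_expression, small_cohort):
        matrix, _ = small_expression
        sub = matrix.iloc[:40]
        fwd = rank_genes(sub, small_cohort["outcome"], positive_label="died")
        rev = rank_genes(sub, small_cohort["outcome"], positive_label="survived")
        np.testing.assert_allclose(
            fwd.sort_index().to_numpy(), -rev.sort_index().to_numpy(), atol=1e-12
        )

    def test_small_group_raises_for_s2n(self):
        x = pd.DataFrame(np.ones((2, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="t_stat"):
            rank_genes(x, ["died", "survived", "survived", "survived"])


class TestEnrichmentScore:
    def test_top_ranked_set_unweighted_es_one(self):
        ranked = make_ranked([5, 4, 3, 2, 1])
        es, _, peak = enrichment_score(ranked, {"g0", "g1"}, weight_p=0)
        assert es == pytest.approx(1.0)
        assert peak == 1

    def test_bottom_ranked_set_unweighted_es_minus_one(self):
        ranked = make_ranked([5, 4, 3, 2, 1])
        es, _, _ = enrichment_score(ranked, {"g3", "g4"}, weight_p=0)
        assert es == pytest.approx(-1.0)

    def test_weighted_hand_walk(self):
        # metrics [3,2,1,0.5,0.1], hits at ranks 1 and 3, p=1:
        # N_R = 3+1 = 4; walk +0.75, -1/3 net, +0.25 ... peak 0.75
        ranked = make_ranked([3, 2, 1, 0.5, 0.1])
        es, running, _ = enrichment_score(ranked, {"g0", "g2"}, weight_p=1)
        assert es == pytest.approx(0.75)
        np.testing.assert_allclose(
            running,
            [0.75, 0.75 - 1 / 3, 0.75 - 1 / 3 + 0.25,
             0.75 - 1 / 3 + 0.25 - 1 / 3, 0.75 - 1 / 3 + 0.25 - 2 / 3],
        )

    @pytest.mark.parametrize("weight_p", [0, 1])
    def test_matches_naive_walk_oracle_on_random_instances(self, weight_p):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 201))
            metric = np.sort(rng.normal(size=n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            k = int(rng.integers(1, max(2, n // 3)))
            gene_set = set(rng.choice(genes, size=k, replace=False))
            ranked = make_ranked(metric, genes)
            es, running, _ = enrichment_score(ranked, gene_set, weight_p)
            es_o, running_o = naive_enrichment_walk(genes, metric, gene_set, weight_p)
            assert es == pytest.approx(es_o, abs=1e-12)
            np.testing.assert_allclose(running, running_o, atol=1e-12)

    def test_unweighted_es_invariant_to_monotone_rescaling(self):
        metric = np.array([9.0, 4.0, 1.0, 0.5, 0.2, 0.1])
        ranked1 = make_ranked(metric)
        ranked2 = make_ranked(metric * 7 + 1)  # same order
        s = {"g1", "g4"}
        assert enrichment_score(ranked1, s, 0)[0] == pytest.approx(
            enrichment_score(ranked2, s, 0)[0]
        )

    def test_reversal_negates_unweighted_es(self):
        metric = np.array([5.0, 3.0, 2.0, 1.0, 0.5])
        genes = [f"g{i}" for i in range(5)]
        s = {"g0", "g3"}
        fwd = enrichment_score(make_ranked(metric, genes), s, 0)[0]
        rev = enrichment_score(make_ranked(metric[::-1], genes[::-1]), s, 0)[0]
        assert fwd == pytest.approx(-rev)

    def test_whole_universe_set_rejected(self):
        ranked = make_ranked([3, 2, 1])
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"g0", "g1", "g2"}, 1)


@pytest.fixture(scope="module")
def gsea_cohort():
    ann = generate_cohort(CohortConfig(n_samples=60, exact_deaths=15, seed=20))
    matrix, truth = generate_expression(
        ann,
        ExpressionConfig(n_genes=1500, n_de=30, effect_size=1.2, gene_sd=0.5,
                         prob_up=1.0, seed=21),
    )
    return ann, matrix, truth


class TestGseaRun:
    def test_planted_set_attains_top_positive_nes(self):
        # study-scale conditions: 198 samples / 13 deaths, 2000 genes
        ann = generate_cohort(CohortConfig(n_samples=198, exact_deaths=13, seed=20))
        matrix, truth = generate_expression(
            ann,
            ExpressionConfig(n_genes=2000, n_de=50, effect_size=1.0, gene_sd=0.5,
                             seed=21),
        )
        planted = list(truth.index[truth["direction"] == 1])[:30]
        collection = generate_gene_sets(matrix.index, n_sets=50, seed=22,
                                        planted=planted)
        res = gsea_run(matrix, ann["outcome"], collection, n_perm=200, seed=23)
        assert res["NES"].idxmax() == "HALLMARK_SYNTH_PLANTED"
        top = res.loc["HALLMARK_SYNTH_PLANTED"]
        assert top["nom_p"] <= 0.05 and top["sign"] == "positive"

    def test_null_calibration_of_nominal_p(self):
        fracs = []
        for seed in range(5):
            ann = generate_cohort(CohortConfig(n_samples=40, exact_deaths=14,
                                               seed=seed + 30))
            matrix, _ = generate_expression(
                ann, ExpressionConfig(n_genes=400, n_de=0, seed=seed + 40)
            )
            collection = generate_gene_sets(matrix.index, n_sets=50, seed=seed + 50)
            res = gsea_run(matrix, ann["outcome"], collection, n_perm=200,
                           seed=seed + 60)
            fracs.append((res["nom_p"] < 0.05).mean())
        assert 0.01 <= np.mean(fracs) <= 0.12

    def test_output_contract(self, gsea_cohort):
        ann, matrix, _ = gsea_cohort
        collection = generate_gene_sets(matrix.index, n_sets=20, seed=2)
        res = gsea_run(matrix, ann["outcome"], collection, n_perm=100, seed=3)
        assert (res["nom_p"] >= 1 / 101).all()
        assert res["fdr_q"].between(0, 1).all()
        assert (np.sign(res["NES"]) == np.sign(res["ES"])).all() or (
            ((res["NES"] == 0) | (np.sign(res["NES"]) == np.sign(res["ES"]))).all()
        )
        assert res["ES"].between(-1, 1).all()

    def test_fdr_monotone_within_sign_class(self, gsea_cohort):
        ann, matrix, _ = gsea_cohort
        collection = generate_gene_sets(matrix.index, n_sets=30, seed=4)
        res = gsea_run(matrix, ann["outcome"], collection, n_perm=100, seed=5)
        for sign in ("positive", "negative"):
            sub = res[res["sign"] == sign].sort_values(
                "NES", key=lambda s: -s.abs()
            )
            assert (np.diff(sub["fdr_q"]) >= -1e-12).all()

    def test_gene_set_permutation_mode(self, gsea_cohort):
        ann, matrix, _ = gsea_cohort
        collection = generate_gene_sets(matrix.index, n_sets=10, seed=6)
        res = gsea_run(matrix, ann["outcome"], collection, n_perm=50,
                       perm_type="gene_set", seed=7)
        assert len(res) == 10

    def test_small_group_warns_for_phenotype_permutation(self):
        ann = generate_cohort(CohortConfig(n_samples=30, exact_deaths=4, seed=8))
        matrix, _ = generate_expression(
            ann, ExpressionConfig(n_genes=100, n_de=0, seed=9)
        )
        collection = generate_gene_sets(matrix.index, n_sets=5, seed=10)
        with pytest.warns(UserWarning, match="fewer than"):
            gsea_run(matrix, ann["outcome"], collection, n_perm=20, seed=11)

    def test_too_few_permutations_rejected(self, gsea_cohort):
        ann, matrix, _ = gsea_cohort
        collection = generate_gene_sets(matrix.index, n_sets=5, seed=12)
        with pytest.raises(ValueError):
            gsea_run(matrix, ann["outcome"], collection, n_perm=5)


class TestFilterSignificant:
    def test_reported_collection_partitions_4_and_7(self):
        pos, neg = filter_significant(load_gsea_table())
        assert len(pos) == 4
        assert len(neg) == 7

    def test_or_rule_retains_high_p_low_q_row(self):
        table = load_gsea_table()
        row = table.loc[["HALLMARK_REACTIVE_OXYGEN_SPECIES_PATHWAY"]]
        pos, neg = filter_significant(row)
        assert len(neg) == 1  # p=0.139 fails, q=0.241 passes under OR

    def test_and_rule_drops_that_row(self):
        table = load_gsea_table()
        row = table.loc[["HALLMARK_REACTIVE_OXYGEN_SPECIES_PATHWAY"]]
        pos, neg = filter_significant(row, rule="and")
        assert len(pos) == 0 and len(neg) == 0

    def test_empty_input(self):
        empty = load_gsea_table().iloc[:0]
        pos, neg = filter_significant(empty)
        assert pos.empty and neg.empty

    def test_sorted_by_abs_nes_descending(self):
        pos, neg = filter_significant(load_gsea_table())
        assert (np.diff(neg["NES"].abs()) <= 1e-12).all()
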