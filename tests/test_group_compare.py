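"""Group assembly, Welch ANOVA, and post-hoc comparisons."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from phonobackbone import (
    all_node_metrics,
    assign_groups,
    build_network,
    describe_groups,
    extract_backbone,
    games_howell,
    posthoc,
    welch_anova,
)
from phonobackbone.backbone import BackboneResult
from phonobackbone.simulate import SyntheticLexiconConfig, generate_lexicon, generate_norms
from _oracles import welch_anova_textbook


class TestWelchAnova:
    def test_identical_means_give_f_zero(self):
        g = np.array([1.0, 2.0, 3.0])
        res = welch_anova([g, g, g])
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_two_group_case_equals_squared_welch_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 30), rng.normal(0.7, 2.5, 55)
        res = welch_anova([a, b])
        t = stats.ttest_ind(a, b, equal_var=False)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-12)
        assert res.p == pytest.approx(t.pvalue, rel=1e-10)
        assert res.df2 == pytest.approx(t.df, rel=1e-12)

    def test_balanced_homoscedastic_two_groups_match_classical(self):
        """With k = 2 the Welch correction factor vanishes, so on balanced
        equal-variance data Welch F coincides with the classical ANOVA F."""
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 40)
        a, b = base, base + 0.5  # identical sample variances by construction
        res = welch_anova([a, b])
        classical = stats.f_oneway(a, b)
        assert res.F == pytest.approx(classical.statistic, abs=1e-9)

    def test_textbook_oracle_agreement(self):
        """100 random heteroscedastic datasets: vectorized implementation vs
        an independently coded longhand oracle, to 1e-10."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            k = rng.integers(2, 6)
            groups = [
                rng.normal(rng.uniform(-2, 2), rng.uniform(0.3, 3.0), rng.integers(5, 60))
                for _ in range(k)
            ]
            res = welch_anova(groups)
            F, df2, p = welch_anova_textbook([list(g) for g in groups])
            assert res.F == pytest.approx(F, rel=1e-10)
            assert res.df2 == pytest.approx(df2, rel=1e-10)
            assert res.p == pytest.approx(p, rel=1e-8, abs=1e-12)

    def test_cross_check_against_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        groups = [rng.normal(m, s, n) for m, s, n in ((0, 1, 20), (0.5, 2, 35), (1, 0.5, 12))]
        res = welch_anova(groups)
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [len(g) for g in groups]),
            }
        )
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.df2 == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_invariance_shift_and_scale(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, s, n) for m, s, n in ((0, 1, 15), (1, 2, 25), (2, 3, 35))]
        base = welch_anova(groups)
        shifted = welch_anova([g + 100.0 for g in groups])
        scaled = welch_anova([g * 7.5 for g in groups])
        assert base.F == pytest.approx(shifted.F, rel=1e-9)
        assert base.F == pytest.approx(scaled.F, rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="at least 2"):
            welch_anova([np.array([1.0, 2.0])])
        with pytest.raises(ValueError, match="zero variance"):
            welch_anova([np.array([1.0, 1.0]), np.array([1.0, 2.0])])
        with pytest.raises(ValueError, match="fewer than 2"):
            welch_anova([np.array([1.0]), np.array([1.0, 2.0])])


class TestPosthoc:
    def test_identical_groups_adjusted_p_near_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        for res in games_howell([g, g + 1e-12, g], ("a", "b", "c")):
            assert res.p_adjusted >= 0.999

    def test_large_shift_detected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 50)
        b = rng.normal(10, 1, 50)
        res = games_howell([a, b], ("a", "b"))[0]
        assert res.p_adjusted < 1e-6

    @pytest.mark.parametrize("method", ["games_howell", "tukey_hsd"])
    def test_adjusted_ge_unadjusted(self, method):
        rng = np.random.default_rng(11)
        for _ in range(10):
            groups = [rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), 20) for _ in range(3)]
            for res in posthoc(groups, ("a", "b", "c"), method):
                assert res.p_adjusted >= res.p_unadjusted - 1e-12

    def test_games_howell_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(8)
        groups = [rng.normal(m, s, n) for m, s, n in ((0, 1, 25), (0.8, 2, 40), (0.2, 0.7, 15))]
        mine = games_howell(groups, ("a", "b", "c"))
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [len(g) for g in groups]),
            }
        )
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        for res in mine:
            row = ref[(ref["A"] == res.pair[0]) & (ref["B"] == res.pair[1])].iloc[0]
            assert abs(res.t) == pytest.approx(abs(float(row["T"])), rel=1e-9)
            assert res.df == pytest.approx(float(row["df"]), rel=1e-9)
            assert res.p_adjusted == pytest.approx(float(row["pval"]), rel=1e-6, abs=1e-9)


def _pipeline(n=800, seed=0, freq_model="degree_coupled"):
    cfg = SyntheticLexiconConfig(n_words=n, inventory_size=10, seed=seed, freq_model=freq_model)
    lex = generate_lexicon(cfg)
    G = build_network(lex)
    lex = generate_norms(lex, G, cfg)
    res = extract_backbone(G, s=0.0)
    return lex, G, res


class TestAssignGroups:
    def test_full_backbone_leaves_no_dropouts(self):
        _, G, _ = _pipeline(n=300)
        res = extract_backbone(G, s=1.0)
        a = assign_groups(G, res)
        assert a.members("GC_NOT_BACKBONE") == []
        assert set(a.members("BACKBONE_GC")) == set(a.members("ORIGINAL_GC"))

    def test_path_worked_example(self, path4):
        res = BackboneResult(
            retained_edges={("a", "b"), ("c", "d")},
            s=0.0,
            n_original_edges=3,
            n_nodes=4,
        )
        a = assign_groups(path4, res)
        assert set(a.members("ORIGINAL_GC")) == {"a", "b", "c", "d"}
        assert set(a.members("BACKBONE_GC")) == {"a", "b"}  # size tie broken by label
        assert set(a.members("GC_NOT_BACKBONE")) == {"c", "d"}

    def test_cardinality_identity(self):
        _, G, res = _pipeline(n=800, seed=4)
        a = assign_groups(G, res)
        n_orig = len(a.members("ORIGINAL_GC"))
        in_both = len(set(a.members("BACKBONE_GC")) & set(a.members("ORIGINAL_GC")))
        assert n_orig == in_both + len(a.members("GC_NOT_BACKBONE"))

    def test_mismatched_nodes_rejected(self, path4):
        other = nx.Graph([("x", "y")])
        with pytest.raises(ValueError):
            assign_groups(path4, other)


class TestDescribeGroups:
    def test_table_shape_and_consistency(self):
        lex, G, res = _pipeline(n=800, seed=4)
        table = describe_groups(assign_groups(G, res), lex, all_node_metrics(G))
        assert set(table.summary["variable"]) == {
            "familiarity", "log_frequency", "length", "degree", "clustering", "closeness"
        }
        assert (table.summary["F"] >= 0).all()
        sizes = table.group_sizes
        assert sizes["ORIGINAL_GC"] == sizes["BACKBONE_GC"] + sizes["GC_NOT_BACKBONE"]
        # three pairwise post hocs per variable
        assert len(table.posthocs) == 3 * len(table.summary)

    def test_network_variables_come_from_original_network(self):
        lex, G, res = _pipeline(n=800, seed=4)
        a = assign_groups(G, res)
        table = describe_groups(a, lex, all_node_metrics(G))
        row = table.summary.set_index("variable").loc["degree"]
        expect = np.mean([G.degree(w) for w in a.members("ORIGINAL_GC")])
        assert row["mean_ORIGINAL_GC"] == pytest.approx(expect)

    def test_null_familiarity_under_independent_norms(self):
        """Norms drawn independently of the network should not separate the
        groups: the familiarity omnibus p stays above .05 for most seeds."""
        hits = 0
        seeds = range(10)
        for seed in seeds:
            lex, G, res = _pipeline(n=800, seed=seed, freq_model="independent")
            table = describe_groups(assign_groups(G, res), lex, all_node_metrics(G))
            p = table.summary.set_index("variable").loc["familiarity", "p"]
            hits += p > 0.05
        assert hits >= 8

    def test_single_group_degenerate_error(self, path4):
        """An empty backbone collapses the groups: error, not NaN output."""
        res = BackboneResult(retained_edges=set(), s=0.0, n_original_edges=3, n_nodes=4)
        a = assign_groups(path4, res)
        with pytest.raises(ValueError, match="singleton group"):
            describe_groups(a, _pipeline(n=300)[0], all_node_metrics(path4))
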