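"""Association statistics: Spearman panels, sign strata, spread test, enrichment, binning."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import tfnetevo as t
from tfnetevo.core import AnnotationMap
from tfnetevo.networks import build_regulatory_network
from tfnetevo.stats import (
    binned_median_profile,
    coregulation_spread_test,
    fast_slow_target_sets,
    sign_stratified_correlations,
    spearman,
    target_set_enrichment,
    tf_target_correlation_panel,
)


def fisher_enumeration_p(a, b, c, d):
    """One-sided (enrichment) Fisher p by exact hypergeometric enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return (math.comb(c1, k) * math.comb(n - c1, r1 - k)) / math.comb(n, r1)

    return sum(pmf(k) for k in range(a, min(r1, c1) + 1))


def spearman_d2(x, y):
    """Brute-force untied Spearman: 1 - 6*sum(d^2)/(n(n^2-1))."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    return 1 - 6 * float(((rx - ry) ** 2).sum()) / (n * (n**2 - 1))


class TestSpearman:
    def test_monotone_extremes(self):
        x = list(range(1, 8))
        assert spearman(x, [v * 2 + 1 for v in x]).rho == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).rho == pytest.approx(-1.0)

    def test_five_point_example(self):
        # d = (-1, 1, -1, 1, 0), sum d^2 = 4 => rho = 1 - 24/120 = 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(1 - 6 * 4 / (5 * 24))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_d2_formula_on_untied_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        x = rng.permutation(n).astype(float)
        y = rng.permutation(n).astype(float)
        assert spearman(x, y).rho == pytest.approx(spearman_d2(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pearson_of_midranks_with_ties(self, seed):
        from scipy.stats import pearsonr, rankdata

        rng = np.random.default_rng(100 + seed)
        x = rng.integers(0, 5, size=20).astype(float)  # heavy ties
        y = rng.integers(0, 5, size=20).astype(float)
        expected = pearsonr(rankdata(x), rankdata(y))[0]
        assert spearman(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman([1, 2], [3, 4])

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestCorrelationPanel:
    def test_same_correlate_list_for_both_sets(self, small_bundle, small_genes, small_net):
        profiles = t.tf_target_profiles(small_net, small_genes, min_targets=3)
        ppi = t.PPINetwork.from_edges(
            zip(small_bundle.ppi_edges["gene_a"], small_bundle.ppi_edges["gene_b"],
                small_bundle.ppi_edges["n_reports"].astype(int))
        )
        panel = tf_target_correlation_panel(profiles, small_genes, ppi=ppi, net=small_net)
        tf_rows = panel[panel["set"] == "tf"][["x_label", "y_label"]]
        all_rows = panel[panel["set"] == "all"][["x_label", "y_label"]]
        assert tf_rows.values.tolist() == all_rows.values.tolist()

    def test_sparse_correlate_emitted_as_absent_not_zero(self, small_genes, small_net):
        profiles = t.tf_target_profiles(small_net, small_genes, min_targets=3)
        profiles = profiles.iloc[:2]  # < 3 TFs with aggregates
        panel = tf_target_correlation_panel(profiles, small_genes, net=small_net)
        row = panel[(panel["set"] == "tf") & (panel["y_label"] == "median_target_ka_ks")]
        assert row["rho"].isna().all()


class TestSignStratified:
    def test_tf_with_too_few_same_sign_targets_excluded(self, small_genes):
        rows = [("tf1", f"g{i}", "E1", "chip") for i in range(6)]
        rows += [("tf2", f"g{i}", "E1", "chip") for i in range(4)]
        net = build_regulatory_network(
            pd.DataFrame(rows, columns=["tf", "target", "experiment_id", "source"])
        )
        edges = net.edges.copy()
        edges["sign"] = "A"
        genes = t.GeneTable.from_frame(pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(6)] + ["tf1", "tf2"],
            "ka_ks": np.linspace(0.1, 0.8, 8),
            "is_tf": [False] * 6 + [True, True],
            "ortholog_par": 1,
        }))
        genes = t.assign_missing_ortholog_rate(genes)
        # with only two qualifying TFs at min 5 -> only tf1 enters, too few
        # pairs for a correlation, so the activated stratum reports absent rho
        out = sign_stratified_correlations(t.RegulatoryNetwork(edges), genes)
        act = out[out["sign"] == "activated"]
        assert (act["n_tfs"] == 1).all()
        assert act["rho"].isna().all()

    def test_all_unsigned_network_gives_empty_table(self, small_net, small_genes):
        out = sign_stratified_correlations(small_net, small_genes)
        assert out.empty

    def test_activator_coupled_generator_recovered(self):
        cfg = t.GeneratorConfig(out_degree_min=24, out_degree_max=80,
                                xscore_noise_sd=0.0, ko_background_sd=0.0)
        hits = 0
        for seed in range(5):
            b = t.generate_bundle(cfg, seed=500 + seed)
            genes = t.assign_missing_ortholog_rate(b.genes)
            net = t.assign_edge_signs(
                t.build_regulatory_network(b.edge_records).select_source("chip"),
                b.knockout,
            )
            tab = sign_stratified_correlations(net, genes)
            act = tab[(tab["sign"] == "activated")
                      & (tab["y_label"] == "median_target_ka_ks")]["rho"].iloc[0]
            rep = tab[(tab["sign"] == "repressed")
                      & (tab["y_label"] == "median_target_ka_ks")]["rho"].iloc[0]
            hits += (act > 0.1) and (abs(rep) < abs(act))
        assert hits >= 4


class TestSpreadTest:
    def test_three_target_pairwise_median(self):
        net = build_regulatory_network(pd.DataFrame(
            [("tf1", g, "E1", "chip") for g in "abc"]
            + [("tf2", g, "E1", "chip") for g in "abc"],
            columns=["tf", "target", "experiment_id", "source"],
        ))
        values = pd.Series({"a": 0.1, "b": 0.2, "c": 0.4})
        res = coregulation_spread_test(net, values, n_null=10, rng=0)
        assert res.per_tf["observed"].tolist() == pytest.approx([0.2, 0.2])

    def test_constant_values_give_null_result(self):
        net = build_regulatory_network(pd.DataFrame(
            [("tf1", g, "E1", "chip") for g in "abcd"]
            + [("tf2", g, "E1", "chip") for g in "abce"],
            columns=["tf", "target", "experiment_id", "source"],
        ))
        values = pd.Series(0.3, index=list("abcde"))
        res = coregulation_spread_test(net, values, n_null=20, rng=0)
        assert (res.per_tf["observed"] == 0).all()
        assert (res.per_tf["expected"] == 0).all()
        assert res.p == pytest.approx(1.0)

    def test_invariant_to_gene_relabeling(self, small_net, small_genes):
        values = small_genes.df.loc[small_genes.has_ortholog(), "ka_ks"]
        res1 = coregulation_spread_test(small_net, values, n_null=20, rng=3)
        mapping = {g: f"x_{g}" for g in small_genes.genes}
        edges = small_net.edges.copy()
        edges["tf"] = edges["tf"].map(mapping)
        edges["target"] = edges["target"].map(mapping)
        values2 = values.rename(index=mapping)
        res2 = coregulation_spread_test(
            t.RegulatoryNetwork(edges), values2, n_null=20, rng=3
        )
        np.testing.assert_allclose(res1.per_tf["observed"], res2.per_tf["observed"])
        assert res1.p == pytest.approx(res2.p)

    def test_degree_proportional_selection_frequencies(self):
        from scipy.stats import chisquare

        from tfnetevo.stats import degree_weighted_sample

        rows = [("tfA", "a", "E1", "chip")]
        rows += [(f"tf{i}", "b", f"E{i}", "chip") for i in range(2)]
        rows += [(f"tf{i}", "c", f"E{i}", "chip") for i in range(3)]
        net = build_regulatory_network(
            pd.DataFrame(rows, columns=["tf", "target", "experiment_id", "source"])
        )
        in_deg = net.in_degree
        assert in_deg.tolist() == [1, 2, 3]
        w = in_deg.to_numpy(dtype=float)
        w = w / w.sum()
        rng = np.random.default_rng(0)
        counts = np.zeros(3)
        for _ in range(10_000):  # singleton draws: inclusion probability == weight
            counts[degree_weighted_sample(3, 1, w, rng)[0]] += 1
        assert chisquare(counts, f_exp=w * 10_000).pvalue > 0.01


class TestEnrichment:
    def test_fold_and_exact_enumeration_oracle(self):
        fast = {f"f{i}" for i in range(20)}
        other = {f"o{i}" for i in range(80)}
        pairs = [(f"f{i}", "T") for i in range(8)] + [(f"o{i}", "T") for i in range(10)]
        # pad the term with extra genes outside both sets so it passes min size
        pairs += [(f"z{i}", "T") for i in range(60)]
        ann = AnnotationMap.from_pairs(pairs)
        out = target_set_enrichment(fast, other, ann, min_term_size=18)
        row = out[out["term_id"] == "T"].iloc[0]
        assert row["fold"] == pytest.approx((8 / 20) / (10 / 80))
        assert row["p"] == pytest.approx(fisher_enumeration_p(8, 12, 10, 70), rel=1e-9)

    def test_identical_fractions_fold_one(self):
        fast = {f"f{i}" for i in range(40)}
        other = {f"o{i}" for i in range(40)}
        pairs = [(f"f{i}", "T") for i in range(10)] + [(f"o{i}", "T") for i in range(10)]
        ann = AnnotationMap.from_pairs(pairs)
        out = target_set_enrichment(fast, other, ann, min_term_size=20)
        row = out.iloc[0]
        assert row["fold"] == pytest.approx(1.0)
        assert row["p"] >= 0.5

    def test_small_term_excluded(self):
        fast = {f"f{i}" for i in range(30)}
        other = {f"o{i}" for i in range(30)}
        pairs = [(f"f{i}", "small") for i in range(25)]
        pairs += [(f"o{i}", "small") for i in range(24)]
        ann = AnnotationMap.from_pairs(pairs)
        out = target_set_enrichment(fast, other, ann, min_term_size=50)
        assert out.empty

    def test_overlapping_sets_rejected(self):
        ann = AnnotationMap.from_pairs([("a", "T")])
        with pytest.raises(ValueError, match="disjoint"):
            target_set_enrichment({"a", "b"}, {"b", "c"}, ann)


class TestFastSlowSplit:
    def test_precedence_assigns_shared_targets_to_fast(self):
        rows = [("tfF", "shared", "E1", "chip"), ("tfF", "g1", "E1", "chip"),
                ("tfS1", "shared", "E1", "chip"), ("tfS1", "g2", "E1", "chip"),
                ("tfS2", "g3", "E1", "chip"), ("tfS3", "g4", "E1", "chip")]
        net = build_regulatory_network(
            pd.DataFrame(rows, columns=["tf", "target", "experiment_id", "source"])
        )
        rates = pd.Series({"tfF": 0.9, "tfS1": 0.2, "tfS2": 0.1, "tfS3": 0.05})
        fast, slow = fast_slow_target_sets(net, rates, fast_fraction=0.25)
        assert fast == {"shared", "g1"}
        assert slow == {"g2", "g3", "g4"}
        fast2, slow2 = fast_slow_target_sets(net, rates, fast_fraction=0.25,
                                             precedence="exclusive")
        assert "shared" not in fast2 and "shared" not in slow2

    def test_quartile_tie_broken_by_gene_id(self):
        rows = [(tf, f"g_{tf}", "E1", "chip") for tf in ("tfA", "tfB", "tfC", "tfD")]
        net = build_regulatory_network(
            pd.DataFrame(rows, columns=["tf", "target", "experiment_id", "source"])
        )
        rates = pd.Series({"tfA": 0.5, "tfB": 0.5, "tfC": 0.2, "tfD": 0.1})
        fast, _ = fast_slow_target_sets(net, rates, fast_fraction=0.25)
        assert fast == {"g_tfA"}


class TestBinnedProfile:
    def test_constant_y_zero_se(self):
        x = pd.Series(np.arange(40, dtype=float))
        y = pd.Series(np.ones(40))
        prof = binned_median_profile(x, y, n_bins=4, rng=0)
        assert (prof["median_y"] == 1.0).all()
        assert (prof["bootstrap_se"] == 0.0).all()

    def test_equal_count_bins(self):
        x = pd.Series(np.random.default_rng(0).random(100))
        y = pd.Series(np.random.default_rng(1).random(100))
        prof = binned_median_profile(x, y, n_bins=4, rng=0)
        assert prof["count"].tolist() == [25, 25, 25, 25]

    def test_fewer_points_than_bins_raises(self):
        with pytest.raises(ValueError, match="fewer points"):
            binned_median_profile(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]), n_bins=3)
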