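"""Generator determinism, marginal structure, configured-coupling recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import tfnetevo as t
from tfnetevo.synth import GeneratorConfig, generate_bundle, generate_genes


class TestDeterminism:
    def test_same_seed_gives_identical_tables(self, small_config):
        b1 = generate_bundle(small_config, seed=11)
        b2 = generate_bundle(small_config, seed=11)
        pd.testing.assert_frame_equal(b1.genes.df, b2.genes.df)
        pd.testing.assert_frame_equal(b1.edge_records, b2.edge_records)
        pd.testing.assert_frame_equal(b1.counts, b2.counts)
        pd.testing.assert_frame_equal(b1.knockout.x, b2.knockout.x)

    def test_written_files_byte_identical(self, small_config, tmp_path):
        p1 = generate_bundle(small_config, seed=12).write(tmp_path / "a")
        p2 = generate_bundle(small_config, seed=12).write(tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seeds_differ(self, small_config):
        b1 = generate_bundle(small_config, seed=1)
        b2 = generate_bundle(small_config, seed=2)
        assert not b1.genes.df["ka_ks"].equals(b2.genes.df["ka_ks"])


class TestGeneMarginals:
    def test_zero_slopes_give_near_independent_properties(self):
        cfg = GeneratorConfig(slope_ka_expression=0.0, slope_ka_ppi=0.0,
                              cai_expression_coupling=0.0,
                              tf_trend_multiplier_expression=0.0,
                              tf_trend_multiplier_ppi=0.0)
        genes, _ = generate_genes(cfg, np.random.default_rng(0))
        df = genes.df
        for a, b in (("ka_ks", "expression"), ("ka_ks", "cai"), ("cai", "expression")):
            rho = spearmanr(df[a], df[b])[0]
            assert abs(rho) < 0.1, (a, b, rho)

    @pytest.mark.parametrize("seed", range(4))
    def test_default_rank_slope_recovered(self, seed):
        cfg = GeneratorConfig()
        genes, _ = generate_genes(cfg, np.random.default_rng([seed, 1]))
        df = genes.df[~genes.df["is_tf"]]
        rho = spearmanr(df["ka_ks"], df["expression"])[0]
        assert rho == pytest.approx(cfg.slope_ka_expression, abs=0.1)

    def test_tfs_drawn_at_lower_expression(self):
        genes, _ = generate_genes(GeneratorConfig(), np.random.default_rng(0))
        df = genes.df
        assert (df.loc[df["is_tf"], "expression"].median()
                < df.loc[~df["is_tf"], "expression"].median())

    def test_infeasible_slopes_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            GeneratorConfig(slope_ka_expression=-0.95, slope_ka_ppi=-0.8)

    def test_cai_in_unit_interval(self, small_bundle):
        cai = small_bundle.genes.df["cai"]
        assert ((cai >= 0) & (cai <= 1)).all()


class TestNetworkGeneration:
    def test_sign_split_one_gives_no_repressive_edges(self):
        cfg = GeneratorConfig(n_genes=300, n_tfs=30, sign_split=1.0)
        b = generate_bundle(cfg, seed=0)
        assert (b.truth.edge_signs["sign"] == "A").all()

    def test_zero_redetection_makes_confirmed_network_empty(self):
        cfg = GeneratorConfig(n_genes=300, n_tfs=30, redetect_prob=0.0)
        b = generate_bundle(cfg, seed=0)
        net = t.build_regulatory_network(b.edge_records).select_source("chip")
        assert t.confirmed_edges(net).n_edges == 0

    def test_out_degree_within_configured_bounds(self, small_bundle, small_config):
        net = t.build_regulatory_network(small_bundle.edge_records)
        assert net.out_degree.min() >= small_config.out_degree_min
        assert net.out_degree.max() <= small_config.out_degree_max

    def test_excess_out_degree_demand_raises(self):
        with pytest.raises(ValueError, match="gene pool"):
            generate_bundle(GeneratorConfig(n_genes=50, n_tfs=10,
                                            out_degree_min=40, out_degree_max=60),
                            seed=0)

    def test_missing_fraction_near_base_rate(self, small_bundle, small_config):
        frac = 1.0 - small_bundle.genes.df["ortholog_par"].mean()
        assert frac == pytest.approx(small_config.missing_fraction_base, abs=0.06)

    def test_tfs_never_flagged_missing(self, small_bundle):
        df = small_bundle.genes.df
        assert df.loc[df["is_tf"], "ortholog_par"].all()


class TestKnockoutGeneration:
    def test_noise_free_scores_sit_at_plus_minus_mu(self):
        cfg = GeneratorConfig(n_genes=200, n_tfs=20, xscore_noise_sd=0.0,
                              ko_background_sd=0.0, ko_mu=2.0)
        b = generate_bundle(cfg, seed=0)
        for row in b.truth.edge_signs.itertuples(index=False):
            x = b.knockout.get(row.tf, row.target)
            assert x == (-2.0 if row.sign == "A" else 2.0)

    def test_partial_coverage_limits_columns(self):
        cfg = GeneratorConfig(n_genes=200, n_tfs=20, ko_coverage=0.5)
        b = generate_bundle(cfg, seed=0)
        assert len(b.knockout.tfs) == 10

    def test_noisy_scores_recover_most_signs(self):
        cfg = GeneratorConfig(n_genes=400, n_tfs=40, xscore_noise_sd=1.0, ko_mu=2.0)
        b = generate_bundle(cfg, seed=0)
        net = t.build_regulatory_network(b.edge_records).select_source("chip")
        signed = t.assign_edge_signs(net, b.knockout)
        truth = b.truth.edge_signs.set_index(["tf", "target"])["sign"]
        got = signed.edges.set_index(["tf", "target"])["sign"]
        signed_mask = got != "U"
        err = (got[signed_mask] != truth.reindex(got.index)[signed_mask]).mean()
        assert err < 0.10  # Gaussian tail beyond the opposite threshold is tiny

    def test_leakage_guard_truth_not_consumed_by_analysis(self, small_bundle, tmp_path):
        """Every analysis input is reconstructable from the written files alone."""
        paths = small_bundle.write(tmp_path)
        paths["truth"].unlink()  # remove ground truth
        from tfnetevo.pipeline import run_full_analysis

        report = run_full_analysis(
            {"inputs": {k: str(p) for k, p in paths.items() if k != "truth"},
             "analysis": {"n_samples": 50, "seed": 0}},
            tmp_path / "out", make_figures=False,
        )
        assert any(s.status == "ok" for s in report.stages)


class TestAnnotations:
    def test_unbiased_terms_are_null_calibrated(self):
        cfg = GeneratorConfig(niche_term_bias=1.0, term_size_min=60, term_size_max=120)
        sig = total = 0
        for seed in range(4):
            b = generate_bundle(cfg, seed=300 + seed)
            genes = t.assign_missing_ortholog_rate(b.genes)
            net = t.build_regulatory_network(b.edge_records).select_source("chip")
            rates = genes.df.loc[genes.df["is_tf"], "assigned_ka_ks"]
            fast, slow = t.fast_slow_target_sets(net, rates)
            out = t.target_set_enrichment(fast, slow, b.annotations, min_term_size=50)
            sig += int(out["significant"].sum())
            total += len(out)
        assert total > 20
        assert sig / total <= 0.12

    def test_biased_niche_terms_detected(self):
        cfg = GeneratorConfig(niche_term_bias=3.0, term_size_min=80, term_size_max=160)
        hits = 0
        for seed in range(3):
            b = generate_bundle(cfg, seed=400 + seed)
            genes = t.assign_missing_ortholog_rate(b.genes)
            net = t.build_regulatory_network(b.edge_records).select_source("chip")
            rates = genes.df.loc[genes.df["is_tf"], "assigned_ka_ks"]
            fast, slow = t.fast_slow_target_sets(net, rates)
            out = t.target_set_enrichment(fast, slow, b.annotations, min_term_size=50)
            niche = out[out["term_id"].isin(b.truth.niche_terms)]
            hits += bool(((niche["fold"] > 1.3) & (niche["p"] < 0.05)).any())
        assert hits >= 2

    def test_small_terms_never_reach_enrichment_output(self, small_bundle):
        genes = t.assign_missing_ortholog_rate(small_bundle.genes)
        net = t.build_regulatory_network(small_bundle.edge_records).select_source("chip")
        rates = genes.df.loc[genes.df["is_tf"], "assigned_ka_ks"]
        fast, slow = t.fast_slow_target_sets(net, rates)
        out = t.target_set_enrichment(fast, slow, small_bundle.annotations,
                                      min_term_size=10_000)
        assert out.empty
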