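import numpy as np
import pandas as pd
import pytest

from termscan import core_model as cm
from termscan import readthrough as rt
from termscan import synthetic_data as sd

from conftest import constant_coverage


def ramp_coverage(genes, body_depth, post_depth, post_len=50):
    """Constant body depth with a constant post-PAS shelf; zero elsewhere."""
    cov = constant_coverage(genes, 0.0)
    for g in genes:
        vec = cov.get(g.chrom, g.strand)
        vec[g.start : g.end] = body_depth
        lo, hi = cm.oriented_window(g.pas, g.strand, 0, post_len)
        vec[lo:hi] = post_depth
    return cov


class TestWindowCount:
    def test_zero_coverage(self, tiny_genes):
        cov = constant_coverage(tiny_genes, 0.0)
        assert rt.window_count(cov, tiny_genes[0], 0, 50) == 0.0

    def test_plus_strand_arithmetic(self, tiny_genes):
        cov = constant_coverage(tiny_genes, 0.0)
        g = tiny_genes.by_id("plusg")  # pas = 700
        cov.get("chr1", "+")[700:750] = 2.0
        assert rt.window_count(cov, g, 0, 50) == 100.0

    def test_minus_strand_mirrors_plus(self, tiny_genes):
        # minus gene [1200,1800): pas boundary 1200, first 50 post-PAS bases
        # are [1150, 1200) on the minus strand
        cov = constant_coverage(tiny_genes, 0.0)
        g = tiny_genes.by_id("minusg")
        cov.get("chr1", "-")[1150:1200] = 2.0
        assert rt.window_count(cov, g, 0, 50) == 100.0

    def test_off_chromosome_window_clipped_with_flag(self, tiny_genes):
        cov = constant_coverage(tiny_genes, 1.0)
        g = tiny_genes.by_id("minusg")
        total, clipped = rt.window_count(cov, g, 0, 5000, with_flag=True)
        assert clipped and total == 1200.0  # [0, 1200) remains after clipping


class TestReadthroughTable:
    def test_constant_tracks_closed_form(self, tiny_genes):
        theta, depth = 0.4, 10.0
        cov = ramp_coverage(tiny_genes, depth, theta * depth)
        table = rt.readthrough_table(cov, tiny_genes)
        for g in tiny_genes:
            assert table.loc[g.gene_id, "rt_index"] == pytest.approx(
                theta * 50 / g.length
            )

    def test_zero_post_pas_gives_zero_index(self, tiny_genes):
        cov = ramp_coverage(tiny_genes, 5.0, 0.0)
        table = rt.readthrough_table(cov, tiny_genes)
        assert (table["rt_index"] == 0).all()

    def test_low_body_flagged_excluded_not_dropped(self, tiny_genes):
        cov = constant_coverage(tiny_genes, 0.0)
        table = rt.readthrough_table(cov, tiny_genes, min_body=10)
        assert len(table) == len(tiny_genes)
        assert table["excluded"].all()
        assert np.isnan(table["rt_index"]).all()

    def test_generator_consistency_recovers_theta(self):
        # invert the generator's closed-form window mean to estimate theta:
        # E[post] = theta * e * sum_d exp(-d/lambda), E[body] = e * L
        cfg = sd.SimulationConfig(
            seed=3,
            readthrough={"wt": 0.4},
            antisense_background=0.0,
            expression_lognorm_sigma=0.0,
        )
        genes = sd.simulate_annotation(cfg)
        cov = sd.simulate_rnaseq(genes, cfg, "wt")
        table = rt.readthrough_table(cov, genes)
        decay_sum = np.exp(-np.arange(50) / cfg.decay_length).sum()
        est = table["rt_index"] * cfg.gene_length / decay_sum
        assert np.median(est) == pytest.approx(0.4, abs=0.05)


class TestCompareToWT:
    def test_self_comparison_is_zero(self, tiny_genes):
        cov = ramp_coverage(tiny_genes, 10.0, 2.0)
        table = rt.readthrough_table(cov, tiny_genes)
        comp = rt.compare_to_wt(table, table)
        assert (comp["log2fc"] == 0).all()

    def test_eightfold_ratio_gives_log2fc_three(self, tiny_genes):
        wt = rt.readthrough_table(ramp_coverage(tiny_genes, 10.0, 0.5), tiny_genes)
        mut = rt.readthrough_table(ramp_coverage(tiny_genes, 10.0, 4.0), tiny_genes)
        comp = rt.compare_to_wt(mut, wt)
        assert np.allclose(comp["log2fc"], 3.0)

    def test_zero_wt_index_flagged_infinite(self, tiny_genes):
        wt = rt.readthrough_table(ramp_coverage(tiny_genes, 10.0, 0.0), tiny_genes)
        mut = rt.readthrough_table(ramp_coverage(tiny_genes, 10.0, 2.0), tiny_genes)
        comp = rt.compare_to_wt(mut, wt)
        assert comp["infinite"].all() and comp["excluded"].all()


class TestCohortTest:
    def test_single_gene_errors(self, tiny_genes):
        cov = ramp_coverage(tiny_genes, 10.0, 1.0)
        table = rt.readthrough_table(cov, tiny_genes)
        comp = rt.compare_to_wt(table, table).iloc[:1]
        with pytest.raises(ValueError):
            rt.cohort_test(comp)

    def test_planted_shift_is_detected(self, cohort, filtered_genes):
        cfg, expr = cohort["config"], cohort["expression"]
        wt = rt.readthrough_table(
            sd.simulate_rnaseq(cohort["genes"], cfg, "wt", expr), filtered_genes
        )
        mut = rt.readthrough_table(
            sd.simulate_rnaseq(cohort["genes"], cfg, "mut", expr), filtered_genes
        )
        p = rt.cohort_test(rt.compare_to_wt(mut, wt))
        assert p < 1e-10


class TestPerGeneTest:
    def test_identical_tracks_not_significant(self, tiny_genes):
        cov = ramp_coverage(tiny_genes, 10.0, 1.0)
        p, sig = rt.per_gene_test(cov, cov, tiny_genes[0])
        assert p == 1.0 and not sig

    def test_power_on_planted_shift(self):
        cfg = sd.SimulationConfig(
            seed=21,
            n_genes=60,
            expression=50.0,
            expression_lognorm_sigma=0.0,
            readthrough={"wt": 0.02, "mutA": 0.5, "mutB": 0.5},
        )
        genes = sd.simulate_annotation(cfg)
        expr = sd.gene_expression(genes, cfg)
        wt = sd.simulate_rnaseq(genes, cfg, "wt", expr)
        sig = {}
        for strain in ("mutA", "mutB"):
            mut = sd.simulate_rnaseq(genes, cfg, strain, expr)
            sig[strain] = {
                g.gene_id
                for g in genes
                if rt.per_gene_test(mut, wt, g)[1]
            }
        assert len(sig["mutA"]) > 0.9 * len(genes)
        union = sig["mutA"] | sig["mutB"]
        jaccard = len(sig["mutA"] & sig["mutB"]) / len(union)
        assert jaccard > 0.8


class TestNormalizationAndInvariance:
    def test_housekeeping_scaling_equalizes_reference(self, cohort, filtered_genes):
        cfg, expr = cohort["config"], cohort["expression"]
        genes = cohort["genes"]
        covs = {
            s: sd.simulate_rnaseq(genes, cfg, s, expr) for s in ("wt", "mut")
        }
        ref = genes.by_id(cfg.reference_gene_id)
        normed = {
            s: rt.housekeeping_normalize(c, genes, cfg.reference_gene_id)
            for s, c in covs.items()
        }
        counts = [
            rt.window_count(c, ref, -ref.length, 0) for c in normed.values()
        ]
        assert counts[0] == pytest.approx(counts[1])

    def test_rt_index_invariant_under_global_scaling(self, tiny_genes):
        cov = ramp_coverage(tiny_genes, 10.0, 2.0)
        t1 = rt.readthrough_table(cov, tiny_genes)
        t2 = rt.readthrough_table(cov.scaled(7.3), tiny_genes)
        assert np.allclose(t1["rt_index"], t2["rt_index"])

    def test_statistics_invariant_under_strand_mirroring(self, tiny_genes):
        cov = ramp_coverage(tiny_genes, 10.0, 2.0)
        t1 = rt.readthrough_table(cov, tiny_genes)
        t2 = rt.readthrough_table(cov.mirrored(), tiny_genes.mirrored())
        assert np.allclose(t1["rt_index"], t2["rt_index"])
        assert np.allclose(t1["body"], t2["body"])


class TestSplitAndCorrelation:
    def test_bound_group_shift_detected(self, tiny_genes):
        rng = np.random.default_rng(0)
        n = 200
        log2fc = np.concatenate([rng.normal(2, 0.3, n // 2), rng.normal(0, 0.3, n // 2)])
        comp = pd.DataFrame(
            {
                "log2fc": log2fc,
                "excluded": False,
            },
            index=[f"g{i}" for i in range(n)],
        )
        binding = pd.Series(
            [True] * (n // 2) + [False] * (n // 2), index=comp.index
        )
        stats, p = rt.split_by_binding(comp, binding)
        assert stats.loc["bound", "median"] > stats.loc["unbound", "median"]
        assert p < 1e-6

    def test_empty_group_errors(self):
        comp = pd.DataFrame(
            {"log2fc": [1.0, 2.0], "excluded": [False, False]}, index=["a", "b"]
        )
        with pytest.raises(ValueError):
            rt.split_by_binding(comp, pd.Series([True, True], index=comp.index))

    def test_rank_correlation_extremes(self):
        a = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        assert rt.rt_correlation(a, a) == pytest.approx(1.0)
        assert rt.rt_correlation(a, -a) == pytest.approx(-1.0)


class TestPasUsage:
    def test_full_drop_and_no_drop(self, tiny_genes):
        g = tiny_genes.by_id("plusg")
        full = ramp_coverage(tiny_genes, 10.0, 0.0)
        none = ramp_coverage(tiny_genes, 10.0, 10.0)
        assert rt.pas_usage_index(full, g) == 1.0
        assert rt.pas_usage_index(none, g) == 0.0

    def test_constant_readthrough_closed_form(self, tiny_genes):
        g = tiny_genes.by_id("minusg")
        cov = ramp_coverage(tiny_genes, 10.0, 3.0)
        assert rt.pas_usage_index(cov, g) == pytest.approx(0.7)

    def test_zero_upstream_undefined(self, tiny_genes):
        cov = constant_coverage(tiny_genes, 0.0)
        with pytest.raises(ValueError, match="undefined"):
            rt.pas_usage_index(cov, tiny_genes[0])
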