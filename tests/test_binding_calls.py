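from itertools import product

import numpy as np
import pandas as pd
import pytest

from termscan import binding_calls as bc
from termscan import core_model as cm
from termscan import synthetic_data as sd

from conftest import constant_coverage


class TestCallInWindow:
    def test_no_features_all_false(self, tiny_genes):
        feats = cm.PointFeatures.from_records([])
        calls = bc.call_in_window(feats, tiny_genes)
        assert not calls.any() and len(calls) == len(tiny_genes)

    def test_half_open_window_edges(self, tiny_genes):
        g = tiny_genes.by_id("plusg")  # pas = 700
        # window [pas-10, pas+10): 690 included, 710 excluded
        inside = cm.PointFeatures.from_records([("chr1", "+", 690, 1.0)])
        outside = cm.PointFeatures.from_records([("chr1", "+", 710, 1.0)])
        assert bc.call_in_window(inside, tiny_genes, upstream=10, downstream=10)["plusg"]
        assert not bc.call_in_window(outside, tiny_genes, upstream=10, downstream=10)[
            "plusg"
        ]

    def test_planted_summits_call_pas_not_tss(self):
        cfg = sd.SimulationConfig(seed=7, n_genes=40, gene_length=900, gene_spacing=600)
        genes = sd.simulate_annotation(cfg)
        _, _, summits = sd.simulate_chip(genes, cfg)
        pas_calls = bc.call_in_window(summits, genes, anchor="PAS",
                                      upstream=250, downstream=250)
        tss_calls = bc.call_in_window(summits, genes, anchor="TSS",
                                      upstream=10, downstream=250)
        assert pas_calls.all()
        assert tss_calls.mean() < 0.1

    def test_invariant_under_strand_mirroring(self, tiny_genes):
        feats = cm.PointFeatures.from_records(
            [("chr1", "+", 720, 1.0), ("chr1", "-", 1150, 2.0)]
        )
        a = bc.call_in_window(feats, tiny_genes)
        b = bc.call_in_window(
            feats.mirrored(tiny_genes.chrom_sizes), tiny_genes.mirrored()
        )
        assert a.equals(b)


class TestOverlapStats:
    def test_identical_and_disjoint_vectors(self):
        idx = [f"g{i}" for i in range(6)]
        same = pd.DataFrame({"x": [True] * 3 + [False] * 3,
                             "y": [True] * 3 + [False] * 3}, index=idx)
        _, cond = bc.overlap_stats(same)
        assert (cond["fraction"] == 1.0).all()
        disjoint = pd.DataFrame({"x": [True] * 3 + [False] * 3,
                                 "y": [False] * 3 + [True] * 3}, index=idx)
        _, cond = bc.overlap_stats(disjoint)
        assert (cond["fraction"] == 0.0).all()

    def test_counts_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        idx = [f"g{i}" for i in range(10)]
        calls = pd.DataFrame(
            {ev: rng.random(10) < 0.5 for ev in ("chip", "parclip", "motif")},
            index=idx,
        )
        regions, cond = bc.overlap_stats(calls)
        assert regions["count"].sum() == 10
        for pattern in product([False, True], repeat=3):
            expected = sum(
                1
                for gid in idx
                if tuple(calls.loc[gid, ["chip", "parclip", "motif"]]) == pattern
            )
            row = regions[
                (regions["chip"] == pattern[0])
                & (regions["parclip"] == pattern[1])
                & (regions["motif"] == pattern[2])
            ]
            assert int(row["count"].iloc[0]) == expected
        for r in cond.itertuples(index=False):
            expected_num = int((calls[r.given] & calls[r.event]).sum())
            assert r.numerator == expected_num
            assert r.denominator == int(calls[r.given].sum())


class TestPeakSummits:
    def test_flat_enrichment_no_peaks(self, tiny_genes):
        ip = constant_coverage(tiny_genes, 10.0)
        ctrl = constant_coverage(tiny_genes, 10.0)
        assert len(bc.peak_summits(ip, ctrl)) == 0

    def test_gaussian_peak_summit_near_center(self, tiny_genes):
        ctrl = constant_coverage(tiny_genes, 10.0)
        ip = constant_coverage(tiny_genes, 10.0)
        x = np.arange(2000)
        ip.get("chr1", "+")[:] = 10.0 * (1 + 8 * np.exp(-0.5 * ((x - 900) / 40) ** 2))
        summits = bc.peak_summits(ip, ctrl, min_enrichment=2.0, min_width=50)
        assert len(summits) == 1
        assert abs(summits.frame["position"].iloc[0] - 900) <= 2

    def test_tied_maxima_take_leftmost(self, tiny_genes):
        ctrl = constant_coverage(tiny_genes, 1.0)
        ip = constant_coverage(tiny_genes, 1.0)
        vec = ip.get("chr1", "+")
        vec[100:200] = 5.0  # flat-topped peak, summit should be position 100
        summits = bc.peak_summits(ip, ctrl, min_enrichment=2.0, min_width=50)
        assert summits.frame["position"].iloc[0] == 100

    def test_recovers_planted_binding_fraction(self):
        cfg = sd.SimulationConfig(seed=13, n_genes=60, gene_length=900,
                                  gene_spacing=700)
        genes = sd.simulate_annotation(cfg)
        ip, ctrl, _ = sd.simulate_chip(genes, cfg)
        summits = bc.peak_summits(ip, ctrl, min_enrichment=2.0, min_width=30)
        calls = bc.call_in_window(summits, genes, anchor="PAS",
                                  upstream=250, downstream=250, match_strand=False)
        assert calls.mean() > 0.95  # every gene carries a planted peak


class TestLengthGroupTest:
    def test_planted_long_gene_bias_detected(self):
        rng = np.random.default_rng(4)
        genes = []
        pos = 0
        lengths = np.concatenate([rng.integers(3000, 6000, 50),
                                  rng.integers(600, 1200, 50)])
        for i, L in enumerate(lengths):
            genes.append(cm.GeneModel(f"g{i}", "chr1", "+", pos, pos + int(L)))
            pos += int(L) + 500
        gs = cm.GeneSet(genes, {"chr1": pos})
        calls_a = pd.Series([True] * 50 + [False] * 50, index=gs.gene_ids)
        calls_b = pd.Series([False] * 100, index=gs.gene_ids)
        summary, p = bc.length_group_test(gs, calls_a, calls_b)
        assert summary.loc["a_not_b", "median_length"] > summary.loc["rest",
                                                                     "median_length"]
        assert p < 0.01

    def test_empty_group_errors(self, tiny_genes):
        calls = pd.Series([False, False], index=tiny_genes.gene_ids)
        with pytest.raises(ValueError):
            bc.length_group_test(tiny_genes, calls, calls)
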