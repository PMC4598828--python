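"""Binned Fisher-exact DMR detection: binning arithmetic, exact-test
oracles, multiple-testing correction, filters and feature association."""

import math

import numpy as np
import pandas as pd
import pytest

from methdiv import dmr as dm
from methdiv.dmr import (DMRParams, adjust_pvalues, associate_dmrs, bin_genome,
                         call_dmrs, dmr_level_difference_by_feature)
from methdiv.dmr import test_bin as fisher_bin
from methdiv.evaluation import fisher_two_sided_enum


def calls_frame(rows):
    """rows: (chrom, pos, strand, m, u, context, is_mc)"""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count_meth",
                                     "count_unmeth", "context", "is_mc"])
    depth = df["count_meth"] + df["count_unmeth"]
    df["level"] = 100.0 * df["count_meth"] / depth.where(depth > 0, 1)
    return df


def feature_frame(rows, kind):
    return pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end",
                                       "strand"]).assign(kind=kind)


class TestBinGenome:
    params = DMRParams()

    def test_pooled_counts_and_levels(self):
        a = calls_frame([("chr1", 10, "+", 10, 0, "CG", True),
                         ("chr1", 20, "+", 8, 2, "CG", True),
                         ("chr1", 30, "+", 0, 10, "CG", False)])
        b = calls_frame([("chr1", 10, "+", 5, 5, "CG", True),
                         ("chr1", 20, "+", 5, 5, "CG", True),
                         ("chr1", 30, "+", 5, 5, "CG", True)])
        bins = bin_genome(a, b, self.params)
        assert len(bins) == 1
        row = bins.iloc[0]
        assert (row["start"], row["end"]) == (1, 100)
        assert (row["meth_a"], row["unmeth_a"]) == (18, 12)
        assert row["level_a"] == pytest.approx(60.0)
        assert row["level_b"] == pytest.approx(50.0)
        assert row["n_sites"] == 3
        assert row["n_mc"] == 3   # union over samples

    def test_low_depth_site_excluded_in_both_samples(self):
        a = calls_frame([("chr1", 10, "+", 10, 0, "CG", True),
                         ("chr1", 20, "+", 10, 0, "CG", True)])
        b = calls_frame([("chr1", 10, "+", 2, 2, "CG", False),   # depth 4 < 5
                         ("chr1", 20, "+", 5, 5, "CG", True)])
        bins = bin_genome(a, b, self.params)
        assert bins.iloc[0]["n_sites"] == 1
        assert bins.iloc[0]["meth_a"] == 10

    def test_empty_region_has_no_bin(self):
        a = calls_frame([("chr1", 950, "+", 10, 0, "CG", True)])
        b = calls_frame([("chr1", 950, "+", 10, 0, "CG", True)])
        bins = bin_genome(a, b, self.params)
        assert bins["start"].tolist() == [901]

    def test_mismatched_chromosomes_rejected(self):
        a = calls_frame([("chr1", 10, "+", 10, 0, "CG", True)])
        b = calls_frame([("chr2", 10, "+", 10, 0, "CG", True)])
        with pytest.raises(ValueError, match="chromosome sets differ"):
            bin_genome(a, b, self.params)

    def test_context_mode_restricts_sites(self):
        a = calls_frame([("chr1", 10, "+", 10, 0, "CG", True),
                         ("chr1", 20, "+", 10, 0, "CHH", True)])
        b = calls_frame([("chr1", 10, "+", 10, 0, "CG", True),
                         ("chr1", 20, "+", 10, 0, "CHH", True)])
        bins = bin_genome(a, b, DMRParams(context_mode="CG"))
        assert bins.iloc[0]["n_sites"] == 1


class TestFisher:
    def test_identical_rows_give_one(self):
        assert fisher_bin(5, 5, 5, 5) == 1.0

    def test_extreme_table(self):
        expected = 2 / math.comb(20, 10)
        assert fisher_bin(10, 0, 0, 10) == pytest.approx(expected, rel=1e-9)

    def test_zero_depth_sample_warns_p_one(self):
        with pytest.warns(UserWarning, match="zero pooled depth"):
            assert fisher_bin(0, 0, 3, 7) == 1.0

    def test_matches_enumeration_oracle_small_tables(self):
        """Exhaustive check against hypergeometric enumeration for every
        2x2 table with total <= 15."""
        total_max = 15
        for n in range(1, total_max + 1):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        if a + b == 0 or c + d == 0:
                            continue
                        expected = fisher_two_sided_enum(a, b, c, d)
                        got = fisher_bin(a, b, c, d)
                        assert got == pytest.approx(expected, rel=1e-12, abs=1e-300), \
                            (a, b, c, d)


class TestAdjustPvalues:
    def test_bh_hand_example(self):
        q = adjust_pvalues([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_one(self):
        assert adjust_pvalues([1.0]).tolist() == [1.0]

    def test_bh_monotone_on_sorted_input(self):
        rng = np.random.default_rng(2)
        p = np.sort(rng.random(50))
        q = adjust_pvalues(p)
        assert (np.diff(q) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])

    def test_slim_mode_never_exceeds_bh(self):
        rng = np.random.default_rng(3)
        p = rng.random(200)
        assert (adjust_pvalues(p, "SLIM") <= adjust_pvalues(p, "BH") + 1e-15).all()


class TestCallDmrs:
    def make_bins(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                           "n_mc", "meth_a", "unmeth_a",
                                           "meth_b", "unmeth_b",
                                           "level_a", "level_b"])

    def test_all_filters(self):
        bins = self.make_bins([
            # passes everything (huge difference, 4 mCs)
            ("chr1", 1, 100, 5, 4, 350, 150, 100, 400, 70.0, 20.0),
            # n_mc = 2: excluded regardless of signal
            ("chr1", 101, 200, 5, 2, 500, 0, 0, 500, 100.0, 0.0),
            # boundary: diff exactly +20 with strong counts -> kept (inclusive)
            ("chr1", 201, 300, 5, 3, 350, 150, 250, 250, 70.0, 50.0),
            # null bin
            ("chr1", 301, 400, 5, 5, 250, 250, 250, 250, 50.0, 50.0),
        ])
        out = call_dmrs(bins, DMRParams())
        assert set(out["start"]) == {1, 201}
        assert (out["direction"] == "hyper").all()

    def test_direction_follows_sign(self):
        bins = self.make_bins([
            ("chr1", 1, 100, 5, 4, 100, 400, 350, 150, 20.0, 70.0)])
        out = call_dmrs(bins, DMRParams())
        assert out.iloc[0]["direction"] == "hypo"
        assert out.iloc[0]["diff"] == pytest.approx(-50.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(30):
            ma, ua = rng.integers(0, 300, 2)
            mb, ub = rng.integers(0, 300, 2)
            la = 100 * ma / max(ma + ua, 1)
            lb = 100 * mb / max(mb + ub, 1)
            rows.append(("chr1", i * 100 + 1, (i + 1) * 100, 5, 5,
                         ma, ua, mb, ub, la, lb))
        bins = self.make_bins(rows)
        fwd = call_dmrs(bins, DMRParams())
        swapped = bins.rename(columns={"meth_a": "meth_b", "meth_b": "meth_a",
                                       "unmeth_a": "unmeth_b", "unmeth_b": "unmeth_a",
                                       "level_a": "level_b", "level_b": "level_a"})
        rev = call_dmrs(swapped, DMRParams())
        assert fwd["start"].tolist() == rev["start"].tolist()
        assert np.allclose(fwd["diff"].to_numpy(), -rev["diff"].to_numpy())
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert [flip[d] for d in fwd["direction"]] == rev["direction"].tolist()


class TestAssociate:
    genes = feature_frame([("g1", "chr1", 900, 2000, "+")], "gene")
    genes_minus = feature_frame([("g1", "chr1", 900, 2000, "-")], "gene")
    tes = feature_frame([], "TE")

    def dmr_at(self, start, end):
        return pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [end],
                             "direction": ["hyper"], "diff": [30.0]})

    def test_genic_by_midpoint(self):
        out = associate_dmrs(self.dmr_at(1001, 1100), self.genes, self.tes)
        assert out.iloc[0]["placement"] == "genic"

    def test_upstream_flank_plus_strand(self):
        out = associate_dmrs(self.dmr_at(800, 900), self.genes, self.tes)
        # midpoint 850, 50 bp left of the gene start on + strand
        assert out.iloc[0]["placement"] == "flank_upstream"

    def test_strand_flip_makes_it_downstream(self):
        out = associate_dmrs(self.dmr_at(800, 900), self.genes_minus, self.tes)
        assert out.iloc[0]["placement"] == "flank_downstream"

    def test_beyond_flank_not_associated(self):
        out = associate_dmrs(self.dmr_at(4200, 4300), self.genes, self.tes)
        assert out.empty

    def test_multiple_features_kept(self):
        genes2 = feature_frame([("g1", "chr1", 900, 2000, "+"),
                                ("g2", "chr1", 1200, 3000, "+")], "gene")
        out = associate_dmrs(self.dmr_at(1201, 1300), genes2, self.tes)
        assert set(out["feature_id"]) == {"g1", "g2"}


class TestLevelDifferenceByFeature:
    def make_assoc(self, gene_diffs, te_diffs):
        rows = []
        for i, d in enumerate(gene_diffs):
            rows.append((i, "chr1", 1, 100, "hyper", d, f"g{i}", "gene", "genic"))
        for i, d in enumerate(te_diffs):
            rows.append((100 + i, "chr1", 1, 100, "hyper", d, f"t{i}", "TE", "genic"))
        return pd.DataFrame(rows, columns=["dmr_index", "chrom", "start", "end",
                                           "direction", "abs_diff", "feature_id",
                                           "feature_kind", "placement"])

    def test_exact_rank_sum_example(self):
        out = dmr_level_difference_by_feature(
            self.make_assoc([25, 30], [60, 70, 80]))
        assert out["gene"]["median"] == 27.5
        assert out["TE"]["median"] == 70
        assert out["p_value"] == pytest.approx(0.2)

    def test_identical_groups_p_one(self):
        out = dmr_level_difference_by_feature(
            self.make_assoc([10, 20, 30], [10, 20, 30]))
        assert out["p_value"] == pytest.approx(1.0)

    def test_empty_group_reports_undefined(self):
        out = dmr_level_difference_by_feature(self.make_assoc([10, 20], []))
        assert out["TE"]["n"] == 0
        assert out["p_value"] is None


class TestCohortRecoveryProperties:
    def test_te_dmr_deltas_larger_shows_in_medians(self, default_cohort,
                                                   default_recovery, default_assoc):
        """On the default cohort deltas are equal, so gene and TE medians
        must agree closely (sanity for the grouped comparison)."""
        out = dmr_level_difference_by_feature(default_assoc)
        assert out["gene"]["n"] > 0 and out["TE"]["n"] > 0
        assert abs(out["gene"]["median"] - out["TE"]["median"]) < 5.0

    def test_filter_monotonicity(self, default_recovery):
        bins = default_recovery["bins"]
        base = set(map(tuple, call_dmrs(bins, DMRParams())[["chrom", "start"]].values))
        stricter_diff = set(map(tuple, call_dmrs(
            bins, DMRParams(min_diff=35.0))[["chrom", "start"]].values))
        stricter_q = set(map(tuple, call_dmrs(
            bins, DMRParams(max_q=1e-6))[["chrom", "start"]].values))
        assert stricter_diff <= base
        assert stricter_q <= base

    def test_null_cohort_yields_almost_no_dmrs(self):
        import dataclasses
        from methdiv.evaluation import build_calls, dmr_recovery
        from methdiv.synth import SimulationConfig, generate_cohort
        cfg = SimulationConfig(seed=13, chrom_length=400_000, gene_count=60,
                               te_count=60, n_planted_dmrs=0)
        co = generate_cohort(cfg)
        calls = build_calls(co)
        rec = dmr_recovery(co, calls)
        assert rec["n_dmrs"] / max(rec["n_bins_tested"], 1) <= 0.001
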