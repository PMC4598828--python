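"""Synthetic cohort generator: determinism, conservation laws, planted
truth consistency, and parameter recovery at the generative level."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdiv import io as mio
from methdiv.methcall import classify_context
from methdiv.synth import (CONTROL_CONTIG, SimulationConfig, assign_true_methylome,
                           generate_cohort, generate_genome, plant_dmrs,
                           shift_level, simulate_counts, simulate_expression,
                           simulate_smrna, write_cohort)

SMALL = dict(chrom_length=100_000, control_length=5_000, gene_count=25,
             te_count=15, n_planted_dmrs=20)


def small_config(**kw):
    return SimulationConfig(**{**SMALL, **kw, "seed": kw.pop("seed", 3)})


class TestGenome:
    def test_counts_match_config(self):
        g = generate_genome(small_config(gene_count=50, te_count=30,
                                         gene_length_range=(500, 1_000),
                                         te_length_range=(300, 800)))
        assert len(g.sequences["chr1"]) == 100_000
        assert len(g.genes) == 50
        assert len(g.tes) == 30
        assert CONTROL_CONTIG in g.sequences

    def test_determinism_byte_identical(self, tmp_path):
        cfg = small_config(n_planted_dmrs=10)
        paths = []
        for d in ("a", "b"):
            co = generate_cohort(dataclasses.replace(cfg))
            paths.append(write_cohort(co, str(tmp_path / d)))
        for key in paths[0]:
            b0 = open(paths[0][key], "rb").read()
            b1 = open(paths[1][key], "rb").read()
            assert b0 == b1, f"{key} differs between identical runs"

    def test_zero_genes_is_valid(self):
        g = generate_genome(small_config(gene_count=0))
        assert len(g.genes) == 0
        assert len(g.sequences["chr1"]) == 100_000

    def test_infeasible_packing_raises(self):
        cfg = small_config(gene_count=200, gene_length_range=(2_000, 2_000))
        with pytest.raises(ValueError, match="infeasible packing"):
            generate_genome(cfg)

    def test_features_do_not_overlap(self):
        g = generate_genome(small_config())
        f = g.features.sort_values("start")
        assert (f["start"].to_numpy()[1:] > f["end"].to_numpy()[:-1]).all()

    def test_gc_fraction_realised(self):
        g = generate_genome(small_config())
        seq = g.sequences["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.43) < 0.01


class TestTrueMethylome:
    def test_methylated_count_in_binomial_interval(self):
        cfg = small_config(te_count=0, te_level_multiplier=1.0,
                           methylated_site_fraction_by_context={
                               "CG": 0.5, "CHG": 0.5, "CHH": 0.5})
        g = generate_genome(cfg)
        truth = assign_true_methylome(g, cfg)
        main = truth[truth["chrom"] != CONTROL_CONTIG]
        n = len(main)
        k = int((main["true_level_A"] > 0).sum())
        lo, hi = stats.binom.interval(0.99, n, 0.5)
        assert lo <= k <= hi

    def test_te_multiplier_identity(self):
        cfg = small_config(te_level_multiplier=1.0)
        g = generate_genome(cfg)
        truth = assign_true_methylome(g, cfg)
        main = truth[(truth["chrom"] != CONTROL_CONTIG) & (truth["context"] == "CG")]
        te = g.tes
        in_te = np.zeros(len(main), dtype=bool)
        for r in te.itertuples(index=False):
            in_te |= ((main["pos"] >= r.start) & (main["pos"] <= r.end)).to_numpy()
        frac_te = (main.loc[in_te, "true_level_A"] > 0).mean()
        frac_out = (main.loc[~in_te, "true_level_A"] > 0).mean()
        # same Bernoulli rate: two-proportion z-test should not reject
        count = np.array([(main.loc[in_te, "true_level_A"] > 0).sum(),
                          (main.loc[~in_te, "true_level_A"] > 0).sum()])
        nobs = np.array([in_te.sum(), (~in_te).sum()])
        from statsmodels.stats.proportion import proportions_ztest
        _, p = proportions_ztest(count, nobs)
        assert p > 0.01, (frac_te, frac_out)

    def test_zero_fractions_give_all_zero(self):
        cfg = small_config(methylated_site_fraction_by_context={
            "CG": 0.0, "CHG": 0.0, "CHH": 0.0})
        g = generate_genome(cfg)
        truth = assign_true_methylome(g, cfg)
        assert (truth["true_level_A"] == 0).all()
        assert (truth["true_level_B"] == 0).all()

    def test_control_contig_fully_unmethylated(self):
        cfg = small_config()
        g = generate_genome(cfg)
        truth = assign_true_methylome(g, cfg)
        ctl = truth[truth["chrom"] == CONTROL_CONTIG]
        assert len(ctl) > 0
        assert (ctl["true_level_A"] == 0).all()

    def test_context_audit_against_fasta(self, tmp_path, small_cohort):
        """Re-deriving the context from the written FASTA for sampled rows
        matches the emitted context exactly."""
        paths = write_cohort(small_cohort, str(tmp_path / "cohort"))
        seqs = mio.read_fasta(paths["fasta"])
        cx = mio.read_cx_report(paths["cx_A"])
        rng = np.random.default_rng(0)
        sample = cx.sample(n=min(1000, len(cx)), random_state=12)
        for row in sample.itertuples(index=False):
            assert classify_context(seqs, row.chrom, row.pos, row.strand) == row.context


class TestPlantDMRs:
    def test_half_hyper_half_hypo(self, small_cohort):
        rec = small_cohort.dmr_truth
        assert len(rec) == 20
        assert (rec["direction"] == "hyper").sum() == 10
        assert (rec["direction"] == "hypo").sum() == 10

    def test_odd_remainder_is_hyper(self):
        cfg = small_config(n_planted_dmrs=5)
        g = generate_genome(cfg)
        truth = assign_true_methylome(g, cfg)
        _, rec = plant_dmrs(truth, g, cfg)
        assert (rec["direction"] == "hyper").sum() == 3

    def test_truth_delta_reproduced(self, small_cohort):
        truth = small_cohort.site_truth
        for rec in small_cohort.dmr_truth.itertuples(index=False):
            sub = truth[(truth["chrom"] == rec.chrom) &
                        (truth["pos"] >= rec.start) & (truth["pos"] <= rec.end)]
            d = sub["true_level_A"].mean() - sub["true_level_B"].mean()
            expected = rec.planted_delta if rec.direction == "hyper" else -rec.planted_delta
            assert d == pytest.approx(expected, abs=1.0)

    def test_region_width_is_whole_bins(self, small_cohort):
        widths = small_cohort.dmr_truth["end"] - small_cohort.dmr_truth["start"] + 1
        assert (widths % 100 == 0).all()

    def test_no_dmrs_leaves_methylome_untouched(self):
        cfg = small_config(n_planted_dmrs=0)
        g = generate_genome(cfg)
        truth = assign_true_methylome(g, cfg)
        out, rec = plant_dmrs(truth, g, cfg)
        assert rec.empty
        pd.testing.assert_frame_equal(out, truth)

    def test_nonpositive_delta_rejected(self):
        cfg = small_config(planted_delta=0.0)
        with pytest.raises(ValueError, match="planted_delta"):
            generate_genome(cfg)

    def test_shift_clips_to_bounds(self):
        assert shift_level(90.0, 40.0) == 100.0
        assert shift_level(10.0, -40.0) == 0.0
        assert shift_level(30.0, 40.0) == 70.0


class TestCounts:
    def test_counts_conservation_and_row_count(self, small_cohort):
        cx = small_cohort.counts["A"]
        truth = small_cohort.site_truth
        assert len(cx) == len(truth)
        # every row: m + u equals the drawn depth by construction (non-negative)
        assert (cx["count_meth"] >= 0).all()
        assert (cx["count_unmeth"] >= 0).all()
        seq = small_cohort.genome.sequences["chr1"]
        n_c = seq.count("C") + seq.count("G")
        assert (cx["chrom"] == "chr1").sum() == n_c

    def test_fully_methylated_site_has_no_unmethylated_reads(self):
        truth = pd.DataFrame({
            "chrom": ["chr1"] * 200, "pos": np.arange(1, 201), "strand": "+",
            "context": "CG", "tri": "CGA",
            "true_level_A": 100.0, "true_level_B": 100.0})
        cx = simulate_counts(truth, small_config(), "A")
        assert (cx["count_unmeth"] == 0).all()

    def test_null_sites_realise_error_rate(self):
        n = 4000
        truth = pd.DataFrame({
            "chrom": ["chr1"] * n, "pos": np.arange(1, n + 1), "strand": "+",
            "context": "CG", "tri": "CGA",
            "true_level_A": 0.0, "true_level_B": 0.0})
        cfg = small_config(depth_mean=30.0, error_rate=0.0005)
        cx = simulate_counts(truth, cfg, "A")
        total = int((cx["count_meth"] + cx["count_unmeth"]).sum())
        m = int(cx["count_meth"].sum())
        lo, hi = stats.binom.interval(0.99, total, 0.0005)
        assert lo <= m <= hi

    def test_mean_depth_near_target(self):
        n = 10_000
        truth = pd.DataFrame({
            "chrom": ["chr1"] * n, "pos": np.arange(1, n + 1), "strand": "+",
            "context": "CG", "tri": "CGA",
            "true_level_A": 0.0, "true_level_B": 0.0})
        cx = simulate_counts(truth, small_config(depth_mean=30.0), "A")
        mean_depth = float((cx["count_meth"] + cx["count_unmeth"]).mean())
        assert 29.0 <= mean_depth <= 31.0


class TestExpression:
    def test_zero_coupling_centred_at_zero(self):
        cfg = SimulationConfig(seed=9, chrom_length=1_000_000, gene_count=150,
                               te_count=0, n_planted_dmrs=0,
                               expression_coupling_strength=0.0)
        g = generate_genome(cfg)
        truth = assign_true_methylome(g, cfg)
        _, rec = plant_dmrs(truth, g, cfg)
        expr, _ = simulate_expression(g.genes, rec, cfg)
        log2 = np.log2(expr["abundance"])
        means = expr.assign(_l=log2).groupby(["gene_id", "sample"])["_l"].mean().unstack()
        diff = (means["A"] - means["B"]).to_numpy()
        assert abs(diff.mean()) < 0.05

    def test_coupled_gene_shift_equals_strength(self, small_cohort):
        et = small_cohort.expression_truth
        c = small_cohort.config.expression_coupling_strength
        down = et[et["expected_direction"] == "down"]
        assert len(down) > 0
        assert (down["log2_shift"] == -c).all()
        none = et[et["expected_direction"] == "none"]
        assert (none["log2_shift"] == 0.0).all()

    def test_requires_two_replicates(self):
        cfg = small_config(replicates_per_sample=1)
        g = generate_genome(cfg)
        with pytest.raises(ValueError, match="replicates_per_sample"):
            simulate_expression(g.genes, pd.DataFrame(), cfg)


class TestSmRNA:
    def test_locus_lengths_in_range(self, small_cohort):
        for s in ("A", "B"):
            assert small_cohort.smrna[s]["length"].between(21, 24).all()

    def test_unit_fold_gives_flat_density(self):
        cfg = SimulationConfig(seed=4, smrna_hyper_fold=1.0, smrna_rate_per_kb=4.0)
        co = generate_cohort(cfg)
        from methdiv.evaluation import smrna_recovery
        rec = smrna_recovery(co)
        assert 0.8 <= rec["fold_hyper"] <= 1.2

    def test_abundance_positive(self, small_cohort):
        assert (small_cohort.smrna["A"]["abundance"] >= 1).all()
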