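"""Validation oracles and cohort-recovery measurements.

The enumeration oracles are deliberately naive, dependency-free reference
implementations (binomial tail by pmf summation, Fisher's exact test by
exact hypergeometric enumeration over integer weights, Wilcoxon rank-sum by
full permutation enumeration).  They exist to cross-check the fast
scipy-backed routines used by the pipeline and are only feasible at tiny
problem sizes.

The recovery functions measure how well the pipeline recovers the synthetic
generator's planted truth (DMR sensitivity/false-discovery proportion,
context-level recovery, expression-coupling statistics, smRNA fold) and are
what the analysis drivers and the acceptance script report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
import os
from itertools import combinations

import numpy as np
import pandas as pd

from . import dmr as dmr_mod
from . import integrate as integ
from . import methcall as mc
from . import profiles as prof
from . import synth

# ------------------------------------------------------------------ oracles

def binomial_tail_enum(m: int, x: int, p: float) -> float:
    """P(X >= m), X ~ Binomial(x, p), by direct pmf summation."""
    if m <= 0:
        return 1.0
    total = 0.0
    for k in range(m, x + 1):
        total += math.comb(x, k) * p ** k * (1.0 - p) ** (x - k)
    return min(1.0, total)


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P by exact hypergeometric enumeration.

    Works on integer table weights C(r1,k)*C(r2,c1-k), so the "probability
    at most that of the observed table" comparison is exact.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(weights.values())
    return sum(w for w in weights.values() if w <= w_obs) / total


def mannwhitney_u(x, y) -> float:
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def wilcoxon_two_sided_enum(x, y) -> float:
    """Two-sided rank-sum P by full enumeration of group assignments."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)
    u_obs = mannwhitney_u(x, y)
    idx = range(len(pooled))
    n_le = n_ge = total = 0
    for comb in combinations(idx, n1):
        grp = set(comb)
        xs = [pooled[i] for i in grp]
        ys = [pooled[i] for i in idx if i not in grp]
        u = mannwhitney_u(xs, ys)
        total += 1
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


# --------------------------------------------------------- cohort evaluation

def build_calls(cohort: synth.Cohort, alpha: float = 0.001,
                min_depth: int = 5) -> dict:
    """Methylation calls for both samples, each against its own
    control-contig error-rate estimate; control contig excluded."""
    calls = {}
    for s in ("A", "B"):
        err = mc.estimate_error_rate(cohort.counts[s], synth.CONTROL_CONTIG)
        params = mc.CallParams(alpha=alpha, min_depth=min_depth, error_rate=err)
        c = mc.call_methylcytosines(cohort.counts[s], params)
        calls[s] = c[c["chrom"] != synth.CONTROL_CONTIG].reset_index(drop=True)
    return calls


def dmr_recovery(cohort: synth.Cohort, calls: dict,
                 params: dmr_mod.DMRParams = dmr_mod.DMRParams()) -> dict:
    """Sensitivity and false-discovery proportion against the planted truth."""
    bins = dmr_mod.bin_genome(calls["A"], calls["B"], params)
    dmrs = dmr_mod.call_dmrs(bins, params)
    truth = set(zip(cohort.dmr_truth["chrom"], cohort.dmr_truth["start"]))
    detected = set(zip(dmrs["chrom"], dmrs["start"]))
    tp = len(truth & detected)
    return {
        "bins": bins, "dmrs": dmrs,
        "n_bins_tested": len(bins), "n_dmrs": len(dmrs),
        "sensitivity": tp / len(truth) if truth else float("nan"),
        "fdp": (len(detected) - tp) / len(detected) if detected else 0.0,
    }


def level_recovery(calls_one_sample: pd.DataFrame) -> dict:
    summ = mc.summarize_methylome(calls_one_sample)
    return {"mean_level_by_context": summ.mean_level_by_context,
            "context_fraction_of_mcs": summ.context_fraction_of_mcs,
            "mc_frequency": summ.mc_frequency}


def coupling_stats(cohort: synth.Cohort, associations: pd.DataFrame,
                   expression: pd.DataFrame | None = None) -> dict:
    """Expression-coupling statistics: hyper-class log2fc median, Wilcoxon P
    vs all genes, and genic hyper->down / hypo->up Fisher enrichment."""
    expr = expression if expression is not None else cohort.expression
    deg = integ.call_degs(expr)
    by_class = integ.compare_expression_by_methylation(deg, associations)
    enr = integ.enrichment_direction(deg, associations, placement="genic")
    return {
        "hyper_median_log2fc": by_class["hyper"]["median"],
        "hyper_wilcoxon_p": by_class["hyper"]["p_vs_all"],
        "hypo_median_log2fc": by_class["hypo"]["median"],
        "genic_hyper_down_or": enr["hyper_down"]["odds_ratio"],
        "genic_hyper_down_p": enr["hyper_down"]["p_value"],
        "genic_hypo_up_p": enr["hypo_up"]["p_value"],
    }


def null_coupling_replicates(cohort: synth.Cohort, associations: pd.DataFrame,
                             n_reps: int = 100, base_seed: int = 10_000,
                             level: float = 0.01) -> dict:
    """Re-simulate expression with zero coupling ``n_reps`` times and count
    replicates where all coupling tests are non-significant at ``level``."""
    n_clean = 0
    for i in range(n_reps):
        cfg = dataclasses.replace(cohort.config,
                                  expression_coupling_strength=0.0,
                                  seed=(base_seed + i) % (2 ** 31))
        expr, _ = synth.simulate_expression(cohort.genome.genes,
                                            cohort.dmr_truth, cfg)
        st = coupling_stats(cohort, associations, expression=expr)
        ps = [st["hyper_wilcoxon_p"], st["genic_hyper_down_p"], st["genic_hypo_up_p"]]
        if all(p is None or p >= level for p in ps):
            n_clean += 1
    return {"n_reps": n_reps, "n_all_nonsignificant": n_clean}


def truth_gene_classes(cohort: synth.Cohort) -> dict:
    """Planted hyper/hypo gene classes from the generator truth
    (body or 2-kb flank contains a planted DMR midpoint, single direction)."""
    g = synth._coupled_genes(cohort.genome.genes, cohort.dmr_truth)
    return {
        "hyper": g.loc[(g["n_hyper"] > 0) & (g["n_hypo"] == 0), "feature_id"].tolist(),
        "hypo": g.loc[(g["n_hypo"] > 0) & (g["n_hyper"] == 0), "feature_id"].tolist(),
    }


def smrna_recovery(cohort: synth.Cohort) -> dict:
    """Recovered smRNA density folds of the planted gene classes, plus the
    identity check (class = all genes -> fold exactly 1)."""
    classes = truth_gene_classes(cohort)
    classes = {k: v for k, v in classes.items() if v}
    enr = integ.smrna_dmr_enrichment(cohort.smrna["A"], cohort.genome.genes, classes)
    ident = integ.smrna_dmr_enrichment(
        cohort.smrna["A"], cohort.genome.genes,
        {"all": cohort.genome.genes["feature_id"].tolist()})
    return {
        "fold_hyper": enr.get("hyper", {}).get("fold"),
        "fold_hypo": enr.get("hypo", {}).get("fold"),
        "fold_hyper_p": enr.get("hyper", {}).get("p_value"),
        "identity_fold": ident["all"]["fold"],
    }


def density_stats(cohort: synth.Cohort, calls: dict, window: int = 50_000) -> dict:
    """Spearman correlations between mC, TE and gene density tracks."""
    mcs = calls["A"][calls["A"]["is_mc"]]
    items = {"mC": mcs, "gene": cohort.genome.genes, "TE": cohort.genome.tes}
    lengths = {k: v for k, v in cohort.genome.chrom_lengths.items()
               if k != synth.CONTROL_CONTIG}
    dens = prof.chromosome_density(items, lengths, window=window)
    corr = prof.density_correlation(dens)
    key = {tuple(sorted(k)): v for k, v in corr.items()}
    return {
        "rho_mc_te": key[("TE", "mC")]["rho"],
        "rho_mc_gene": key[("gene", "mC")]["rho"],
        "density": dens,
    }


def output_hashes(outdir: str, exclude: tuple = ("manifest.json",)) -> dict:
    out = {}
    for f in sorted(os.listdir(outdir)):
        path = os.path.join(outdir, f)
        if f in exclude or not os.path.isfile(path):
            continue
        with open(path, "rb") as fh:
            out[f] = hashlib.sha256(fh.read()).hexdigest()
    return out
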