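"""Coupling of differential methylation to expression and smRNA abundance.

Implements the expression side (a replacement differential-expression
filter, methylation-class expression shift tests, directional enrichment,
on/off classification, TE density by gene class) and the smRNA side
(mC-smRNA overlap, hyper/hypo territory enrichment) of the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class DEGParams:
    """Differential-expression thresholds (two-fold, P < 0.05 by default)
    and the abundance cutoffs defining transcriptional on/off status."""

    min_fold_change: float = 2.0
    max_p: float = 0.05
    on_threshold: float = 1.0
    off_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.min_fold_change <= 1.0:
            raise ValueError("min_fold_change must be > 1")
        if self.off_threshold >= self.on_threshold:
            raise ValueError("off_threshold must be < on_threshold")


def call_degs(expression: pd.DataFrame, params: DEGParams = DEGParams()) -> pd.DataFrame:
    """Simple DEG caller over a replicate expression table.

    log2 fold change (sample A over B) from replicate means with a 0.01
    pseudocount; P from a two-sided two-sample t-test on log2 abundances.
    de_status is 'up' when log2fc >= log2(min_fold_change) and p <= max_p,
    'down' for the mirror case, else 'not_de'.  With a single replicate per
    sample the P-value is undefined and status is decided on fold change
    alone (with a warning).
    """
    log2 = np.log2(expression["abundance"].to_numpy(dtype=float) + PSEUDOCOUNT)
    df = expression.assign(_log2=log2)
    wide = df.groupby(["gene_id", "sample"])["_log2"].agg(list).unstack("sample")
    rows = []
    single_warned = False
    lfc_cut = np.log2(params.min_fold_change)
    for gene_id, row in wide.iterrows():
        a = np.asarray(row.get("A", []), dtype=float)
        b = np.asarray(row.get("B", []), dtype=float)
        mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
        lfc = mean_a - mean_b
        if len(a) < 2 or len(b) < 2:
            if not single_warned:
                warnings.warn("single replicate: DE decided on fold change alone")
                single_warned = True
            p = np.nan
            sig = True
        else:
            if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
                p = 1.0
            else:
                p = float(stats.ttest_ind(a, b).pvalue)
            sig = p <= params.max_p
        if sig and lfc >= lfc_cut:
            status = "up"
        elif sig and lfc <= -lfc_cut:
            status = "down"
        else:
            status = "not_de"
        rows.append((gene_id, 2.0 ** mean_a, 2.0 ** mean_b, lfc, p, status))
    return pd.DataFrame(rows, columns=[
        "gene_id", "abundance_a", "abundance_b", "log2fc", "p_value", "de_status"])


def rank_sum_test(x, y, exact_limit: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum P.

    Exact when the combined sample is small (<= ``exact_limit``) and
    tie-free, else a normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    if pooled.size <= exact_limit and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method, use_continuity=True).pvalue)


def gene_dmr_classes(associations: pd.DataFrame) -> pd.DataFrame:
    """Per-gene hyper/hypo DMR class from a DMR association table.

    A gene touched by both directions is assigned the direction of its
    largest-|diff| DMR; an exact tie excludes the gene.
    """
    g = associations[associations["feature_kind"] == "gene"]
    rows = []
    for gene_id, sub in g.groupby("feature_id"):
        best = {}
        for direction in ("hyper", "hypo"):
            d = sub[sub["direction"] == direction]
            if len(d):
                best[direction] = float(d["abs_diff"].max())
        if len(best) == 1:
            rows.append((gene_id, next(iter(best))))
        elif len(best) == 2:
            if best["hyper"] > best["hypo"]:
                rows.append((gene_id, "hyper"))
            elif best["hypo"] > best["hyper"]:
                rows.append((gene_id, "hypo"))
            # exact tie: excluded
    return pd.DataFrame(rows, columns=["gene_id", "dmr_class"])


def compare_expression_by_methylation(deg: pd.DataFrame,
                                      associations: pd.DataFrame,
                                      expressed_only: bool = True) -> dict:
    """log2fc distributions of hyper-/hypo-DMR-associated genes vs all genes.

    Reports n, median and quartiles per class and a two-sided Wilcoxon
    rank-sum P against the all-genes distribution.  ``expressed_only``
    restricts the baseline to genes with nonzero mean abundance.
    """
    base = deg
    if expressed_only:
        base = deg[(deg["abundance_a"] > 0) | (deg["abundance_b"] > 0)]
    classes = gene_dmr_classes(associations)
    all_vals = base["log2fc"].to_numpy(dtype=float)
    out = {"all": _dist_summary(all_vals)}
    for direction in ("hyper", "hypo"):
        ids = classes.loc[classes["dmr_class"] == direction, "gene_id"]
        vals = base.loc[base["gene_id"].isin(ids), "log2fc"].to_numpy(dtype=float)
        summ = _dist_summary(vals)
        summ["p_vs_all"] = rank_sum_test(vals, all_vals) if vals.size else None
        out[direction] = summ
    return out


def _dist_summary(vals: np.ndarray) -> dict:
    if vals.size == 0:
        return {"n": 0, "median": None, "q1": None, "q3": None}
    return {"n": int(vals.size), "median": float(np.median(vals)),
            "q1": float(np.percentile(vals, 25)), "q3": float(np.percentile(vals, 75))}


def enrichment_direction(deg: pd.DataFrame, associations: pd.DataFrame,
                         placement: str = "genic") -> dict:
    """Directional enrichment: hyper-DMR genes among downregulated genes and
    hypo-DMR genes among upregulated genes, over all tested genes.

    ``placement`` restricts the associations used: 'genic' (DMR midpoint in
    the gene body), 'flanking', or 'any'.  Returns, per direction, the 2x2
    table, the odds ratio (cross-product; None on a zero margin, with P = 1)
    and the two-sided Fisher P.
    """
    a = associations[associations["feature_kind"] == "gene"]
    if placement == "genic":
        a = a[a["placement"] == "genic"]
    elif placement == "flanking":
        a = a[a["placement"].str.startswith("flank")]
    classes = gene_dmr_classes(a)
    out = {}
    for direction, de_dir in (("hyper", "down"), ("hypo", "up")):
        in_class = deg["gene_id"].isin(classes.loc[classes["dmr_class"] == direction,
                                                   "gene_id"]).to_numpy()
        is_de = (deg["de_status"] == de_dir).to_numpy()
        n11 = int(np.sum(in_class & is_de))
        n10 = int(np.sum(in_class & ~is_de))
        n01 = int(np.sum(~in_class & is_de))
        n00 = int(np.sum(~in_class & ~is_de))
        table = [[n11, n10], [n01, n00]]
        if min(n11 + n10, n01 + n00, n11 + n01, n10 + n00) == 0:
            out[f"{direction}_{de_dir}"] = {"table": table, "odds_ratio": None,
                                            "p_value": 1.0}
            continue
        if n10 * n01 == 0:
            orr = np.inf if n11 * n00 > 0 else None
        else:
            orr = (n11 * n00) / (n10 * n01)
        p = float(stats.fisher_exact(table)[1])
        out[f"{direction}_{de_dir}"] = {"table": table, "odds_ratio": orr, "p_value": p}
    return out


def classify_on_off(deg: pd.DataFrame, params: DEGParams = DEGParams()) -> pd.DataFrame:
    """On/off expression states per gene from replicate-mean abundances.

    on: mean >= on_threshold; off: mean < off_threshold; genes with either
    sample in the dead zone [off_threshold, on_threshold) are excluded.
    """
    rows = []
    for r in deg.itertuples(index=False):
        states = []
        for ab in (r.abundance_a, r.abundance_b):
            if ab >= params.on_threshold:
                states.append("on")
            elif ab < params.off_threshold:
                states.append("off")
            else:
                states.append(None)
        if None in states:
            continue
        label = {("on", "off"): "A_on_B_off", ("off", "on"): "A_off_B_on",
                 ("on", "on"): "both_on", ("off", "off"): "both_off"}[tuple(states)]
        rows.append((r.gene_id, label))
    return pd.DataFrame(rows, columns=["gene_id", "on_off_class"])


def _te_counts_per_gene(genes: pd.DataFrame, tes: pd.DataFrame,
                        flank: int = 2000) -> np.ndarray:
    """Number of TEs overlapping each gene's flank-extended interval."""
    counts = np.zeros(len(genes), dtype=int)
    for chrom, gsub in genes.groupby("chrom"):
        t = tes[tes["chrom"] == chrom].sort_values("start")
        ts = t["start"].to_numpy()
        te_ = t["end"].to_numpy()
        order = np.argsort(te_)
        te_sorted = te_[order]
        for i, g in zip(gsub.index, gsub.itertuples(index=False)):
            lo, hi = g.start - flank, g.end + flank
            n_start_ok = np.searchsorted(ts, hi, side="right")
            n_end_lt = np.searchsorted(te_sorted, lo, side="left")
            counts[genes.index.get_loc(i)] = n_start_ok - n_end_lt
    return counts


def te_density_by_gene_class(genes: pd.DataFrame, tes: pd.DataFrame,
                             gene_classes: dict, flank: int = 2000,
                             n_perm: int = 10_000, seed: int = 0) -> dict:
    """Mean TEs per gene for each gene class, with a permutation P-value.

    A TE counts for a gene when it overlaps the gene interval extended by
    ``flank`` on both sides.  Each class P is a two-sided label-shuffle
    permutation test of (class mean - complement mean).
    """
    counts = _te_counts_per_gene(genes, tes, flank)
    universe = genes["feature_id"].to_numpy()
    rng = np.random.default_rng(seed)
    out = {"all_genes": {"n": len(universe), "mean_tes_per_gene": float(counts.mean())
                         if len(universe) else None}}
    for name, ids in gene_classes.items():
        ids = set(ids)
        if not ids.issubset(set(universe)):
            raise ValueError(f"gene class {name!r} is not a subset of the gene table")
        mask = np.isin(universe, list(ids))
        m = int(mask.sum())
        if m == 0 or m == len(universe):
            out[name] = {"n": m, "mean_tes_per_gene": float(counts[mask].mean())
                         if m else None, "p_value": None}
            continue
        obs = counts[mask].mean() - counts[~mask].mean()
        perm = np.empty(n_perm)
        for k in range(n_perm):
            sel = rng.choice(len(universe), size=m, replace=False)
            csel = counts[sel]
            perm[k] = csel.mean() - (counts.sum() - csel.sum()) / (len(universe) - m)
        p = (1 + np.sum(np.abs(perm) >= abs(obs))) / (1 + n_perm)
        out[name] = {"n": m, "mean_tes_per_gene": float(counts[mask].mean()),
                     "p_value": float(p)}
    return out


def smrna_mc_overlap(loci: pd.DataFrame, calls: pd.DataFrame) -> dict:
    """mC / smRNA-locus overlap statistics.

    Per context and overall: the fraction of mCs lying inside any smRNA
    locus, and the fraction of loci containing at least one mC.
    """
    mcs = calls[calls["is_mc"]]
    inside = np.zeros(len(mcs), dtype=bool)
    loci_with_mc = 0
    for chrom, lsub in loci.groupby("chrom"):
        msub = mcs[mcs["chrom"] == chrom]
        pos = np.sort(msub["pos"].to_numpy())
        ls = lsub["start"].to_numpy()
        le = lsub["end"].to_numpy()
        n_in = np.searchsorted(pos, le, side="right") - np.searchsorted(pos, ls, side="left")
        loci_with_mc += int(np.sum(n_in > 0))
        # membership of each mC in the merged locus set
        order = np.argsort(ls)
        ms, me = ls[order], le[order]
        merged_s, merged_e = [], []
        for s, e in zip(ms, me):
            if merged_e and s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        merged_s = np.asarray(merged_s)
        merged_e = np.asarray(merged_e)
        p = msub["pos"].to_numpy()
        if merged_s.size:
            i = np.searchsorted(merged_s, p, side="right") - 1
            ok = i >= 0
            hit = np.zeros(p.size, dtype=bool)
            hit[ok] = p[ok] <= merged_e[i[ok]]
            inside[mcs["chrom"].to_numpy() == chrom] = hit
    mcs = mcs.assign(_inside=inside)
    out = {
        "fraction_mcs_in_loci": {"overall": float(inside.mean()) if len(mcs) else 0.0},
        "fraction_loci_with_mc": float(loci_with_mc / len(loci)) if len(loci) else 0.0,
    }
    for ctx in ("CG", "CHG", "CHH"):
        sub = mcs[mcs["context"] == ctx]
        out["fraction_mcs_in_loci"][ctx] = float(sub["_inside"].mean()) if len(sub) else 0.0
    return out


def _territory(genes: pd.DataFrame) -> tuple[dict, float]:
    """Per-chromosome sorted gene intervals and total length in kb."""
    by_chrom = {}
    total = 0
    for chrom, sub in genes.groupby("chrom"):
        s = sub.sort_values("start")
        by_chrom[chrom] = (s["start"].to_numpy(), s["end"].to_numpy())
        total += int((s["end"] - s["start"] + 1).sum())
    return by_chrom, total / 1000.0


def _loci_in_territory(loci: pd.DataFrame, territory: dict) -> int:
    n = 0
    for chrom, (ts, te) in territory.items():
        sub = loci[loci["chrom"] == chrom]
        mid = ((sub["start"] + sub["end"]) // 2).to_numpy()
        i = np.searchsorted(ts, mid, side="right") - 1
        ok = i >= 0
        n += int(np.sum(np.where(ok, mid <= te[np.maximum(i, 0)], False)))
    return n


def smrna_dmr_enrichment(loci: pd.DataFrame, genes: pd.DataFrame,
                         class_gene_ids: dict) -> dict:
    """smRNA locus-density enrichment of DMR gene classes vs all genes.

    fold = (loci per kb of class-gene territory) / (loci per kb of all-gene
    territory); loci are assigned by midpoint.  P is a two-sided Fisher test
    on locus counts vs territory sizes discretised to kb.
    """
    all_terr, all_kb = _territory(genes)
    if all_kb == 0:
        raise ValueError("zero gene territory")
    n_all = _loci_in_territory(loci, all_terr)
    dens_all = n_all / all_kb
    out = {"all_genes": {"n_loci": n_all, "territory_kb": all_kb,
                         "density_per_kb": dens_all}}
    for name, ids in class_gene_ids.items():
        sub = genes[genes["feature_id"].isin(set(ids))]
        if sub.empty:
            raise ValueError(f"gene class {name!r} has zero territory")
        terr, kb = _territory(sub)
        n_cls = _loci_in_territory(loci, terr)
        fold = (n_cls / kb) / dens_all if dens_all > 0 else np.nan
        table = [[n_cls, max(0, n_all - n_cls)],
                 [int(round(kb)), max(1, int(round(all_kb - kb)))]]
        p = float(stats.fisher_exact(table)[1])
        out[name] = {"n_loci": n_cls, "territory_kb": kb,
                     "density_per_kb": n_cls / kb, "fold": float(fold), "p_value": p}
    return out
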