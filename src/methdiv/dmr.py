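"""Binned differential-methylation-region (DMR) detection.

The genome is tiled into fixed non-overlapping bins (default 100 bp).  For
each bin, read counts of the two samples are pooled over the cytosines
covered by at least ``min_site_depth`` reads in BOTH samples, a two-sided
Fisher exact test compares the pooled methylated/unmethylated counts, and
P-values are corrected genome-wide (Benjamini-Hochberg by default, a
simplified SLIM variant optionally).  A bin is a DMR when it holds at least
``min_mcs`` methylcytosines (called in either sample), the pooled level
difference reaches ``min_diff`` percentage points, and q <= ``max_q``; all
thresholds inclusive.  ``diff`` is level(A) - level(B): positive = hyper in
the test sample A relative to the reference B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methcall import CONTEXTS


@dataclass(frozen=True)
class DMRParams:
    bin_size: int = 100
    min_site_depth: int = 5    # per sample, per site
    min_mcs: int = 3
    min_diff: float = 20.0     # percentage points
    max_q: float = 0.01
    correction: str = "BH"     # or "SLIM"
    context_mode: str = "combined"   # or one of CG/CHG/CHH
    mc_count_mode: str = "union"     # sites called mC in either sample; or "per_sample"
    level_mode: str = "pooled"       # pooled read counts; or "mean_of_sites"

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if not 0.0 < self.min_diff <= 100.0:
            raise ValueError("min_diff must be in (0,100]")
        if not 0.0 < self.max_q < 1.0:
            raise ValueError("max_q must be in (0,1)")
        if self.context_mode not in ("combined",) + CONTEXTS:
            raise ValueError(f"unknown context_mode {self.context_mode!r}")


def bin_genome(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
               params: DMRParams) -> pd.DataFrame:
    """Pool per-site counts of both samples into fixed-width genomic bins.

    Only sites with depth >= min_site_depth in both samples contribute; bins
    with no qualifying site are omitted.  ``n_mc`` counts sites called mC in
    either sample (union) or in both, per ``mc_count_mode``.
    """
    ca, cb = set(calls_a["chrom"]), set(calls_b["chrom"])
    if ca != cb:
        raise ValueError(f"chromosome sets differ between samples: "
                         f"only in A: {sorted(ca - cb)}; only in B: {sorted(cb - ca)}")
    key = ["chrom", "pos", "strand"]
    cols = key + ["context", "count_meth", "count_unmeth", "is_mc"]
    merged = calls_a[cols].merge(calls_b[cols], on=key, suffixes=("_a", "_b"))
    if params.context_mode != "combined":
        merged = merged[merged["context_a"] == params.context_mode]
    depth_a = merged["count_meth_a"] + merged["count_unmeth_a"]
    depth_b = merged["count_meth_b"] + merged["count_unmeth_b"]
    merged = merged[(depth_a >= params.min_site_depth) & (depth_b >= params.min_site_depth)]
    if merged.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_sites", "n_mc",
                                     "meth_a", "unmeth_a", "meth_b", "unmeth_b",
                                     "level_a", "level_b"])
    bs = params.bin_size
    merged = merged.assign(_bin=(merged["pos"] - 1) // bs)
    if params.mc_count_mode == "union":
        mc = merged["is_mc_a"] | merged["is_mc_b"]
    else:
        mc = merged["is_mc_a"] & merged["is_mc_b"]
    merged = merged.assign(_mc=mc.astype(int))
    grp = merged.groupby(["chrom", "_bin"], sort=True)
    agg = grp.agg(
        n_sites=("pos", "size"), n_mc=("_mc", "sum"),
        meth_a=("count_meth_a", "sum"), unmeth_a=("count_unmeth_a", "sum"),
        meth_b=("count_meth_b", "sum"), unmeth_b=("count_unmeth_b", "sum"),
    ).reset_index()
    agg["start"] = agg["_bin"] * bs + 1
    agg["end"] = (agg["_bin"] + 1) * bs
    if params.level_mode == "pooled":
        agg["level_a"] = 100.0 * agg["meth_a"] / (agg["meth_a"] + agg["unmeth_a"])
        agg["level_b"] = 100.0 * agg["meth_b"] / (agg["meth_b"] + agg["unmeth_b"])
    else:
        la = 100.0 * merged["count_meth_a"] / (merged["count_meth_a"] + merged["count_unmeth_a"])
        lb = 100.0 * merged["count_meth_b"] / (merged["count_meth_b"] + merged["count_unmeth_b"])
        site_lvl = merged.assign(_la=la, _lb=lb).groupby(["chrom", "_bin"])[["_la", "_lb"]].mean()
        agg = agg.merge(site_lvl.rename(columns={"_la": "level_a", "_lb": "level_b"}),
                        on=["chrom", "_bin"])
    return agg[["chrom", "start", "end", "n_sites", "n_mc",
                "meth_a", "unmeth_a", "meth_b", "unmeth_b", "level_a", "level_b"]]


def test_bin(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> float:
    """Two-sided Fisher exact P on [[meth_a, unmeth_a], [meth_b, unmeth_b]].

    A sample with zero pooled depth yields P = 1 with a warning.
    """
    if meth_a + unmeth_a == 0 or meth_b + unmeth_b == 0:
        warnings.warn("zero pooled depth in one sample; Fisher P set to 1")
        return 1.0
    return float(stats.fisher_exact([[meth_a, unmeth_a], [meth_b, unmeth_b]],
                                    alternative="two-sided")[1])


def test_bins(bins: pd.DataFrame) -> np.ndarray:
    p = np.ones(len(bins))
    cols = bins[["meth_a", "unmeth_a", "meth_b", "unmeth_b"]].to_numpy(dtype=np.int64)
    for i, (ma, ua, mb, ub) in enumerate(cols):
        if ma + ua == 0 or mb + ub == 0:
            warnings.warn("zero pooled depth in one sample; Fisher P set to 1")
            continue
        p[i] = stats.fisher_exact([[ma, ua], [mb, ub]])[1]
    return p


def estimate_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    """Conservative null-proportion estimate (Pounds-Cheng style)."""
    p = np.asarray(p, dtype=float)
    pi0 = np.mean(p > lam) / (1.0 - lam)
    return float(min(1.0, max(pi0, 1.0 / max(len(p), 1))))


def adjust_pvalues(p, correction: str = "BH") -> np.ndarray:
    """Multiple-testing correction: BH q-values, or a simplified SLIM mode.

    The SLIM mode scales BH q-values by an estimated null proportion pi0;
    it is a pragmatic stand-in, not a faithful reimplementation of the
    published sliding-linear-model procedure (whose settings are
    under-determined), and BH is the default.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    q = multipletests(p, method="fdr_bh")[1]
    if correction.upper() == "BH":
        return q
    if correction.upper() == "SLIM":
        return np.minimum(1.0, estimate_pi0(p) * q)
    raise ValueError(f"unknown correction {correction!r}")


def call_dmrs(bins: pd.DataFrame, params: DMRParams) -> pd.DataFrame:
    """Fisher-test every bin, correct genome-wide, apply the DMR filters.

    q-values are computed over ALL tested bins, not post-filter.  Output
    rows carry p_value, q_value, diff (level_a - level_b) and direction
    (hyper when diff > 0: higher methylation in the test sample A).
    """
    bins = bins.reset_index(drop=True)
    if bins.empty:
        out = bins.copy()
        for c in ("p_value", "q_value", "diff", "direction"):
            out[c] = pd.Series(dtype=float if c != "direction" else str)
        return out
    p = test_bins(bins)
    q = adjust_pvalues(p, params.correction)
    out = bins.copy()
    out["p_value"] = p
    out["q_value"] = q
    out["diff"] = out["level_a"] - out["level_b"]
    keep = (out["n_mc"] >= params.min_mcs) & \
           (out["diff"].abs() >= params.min_diff) & \
           (out["q_value"] <= params.max_q)
    out = out[keep].copy()
    out["direction"] = np.where(out["diff"] > 0, "hyper", "hypo")
    return out.reset_index(drop=True)


def associate_dmrs(dmrs: pd.DataFrame, genes: pd.DataFrame, tes: pd.DataFrame,
                   flank: int = 2000) -> pd.DataFrame:
    """Position each DMR relative to genes and TEs by its midpoint.

    genic when the midpoint lies within the feature body; otherwise
    flank_upstream / flank_downstream when within ``flank`` bases of the
    strand-appropriate end (genomic left/right for unstranded features,
    with a warning).  One row per (DMR, feature) pair; DMRs may associate
    with several features, unassociated DMRs are absent.
    """
    feats = pd.concat([genes.assign(kind="gene"), tes.assign(kind="TE")],
                      ignore_index=True)
    rows = []
    warned = False
    for di, d in dmrs.reset_index(drop=True).iterrows():
        mid = (int(d["start"]) + int(d["end"])) // 2
        near = feats[(feats["chrom"] == d["chrom"]) &
                     (feats["start"] - flank <= mid) & (mid <= feats["end"] + flank)]
        for _, f in near.iterrows():
            if f["start"] <= mid <= f["end"]:
                placement = "genic"
            else:
                left = mid < f["start"]
                strand = f["strand"]
                if strand not in ("+", "-"):
                    if not warned:
                        warnings.warn("unstranded feature: flank placement uses genomic left/right")
                        warned = True
                    strand = "+"
                if strand == "+":
                    placement = "flank_upstream" if left else "flank_downstream"
                else:
                    placement = "flank_downstream" if left else "flank_upstream"
            rows.append((di, d["chrom"], int(d["start"]), int(d["end"]),
                         d.get("direction"), abs(float(d.get("diff", np.nan))),
                         f["feature_id"], f["kind"], placement))
    return pd.DataFrame(rows, columns=[
        "dmr_index", "chrom", "start", "end", "direction", "abs_diff",
        "feature_id", "feature_kind", "placement"])


def dmr_level_difference_by_feature(associations: pd.DataFrame) -> dict:
    """|diff| distributions of gene- vs TE-associated DMRs + rank-sum P.

    A DMR associated with both kinds contributes to both groups (per-feature
    association is independent).  Returns per-group n/median/quartiles and a
    two-sided Wilcoxon rank-sum P (None when a group is empty).
    """
    uniq = associations.drop_duplicates(["dmr_index", "feature_kind"])
    out = {}
    groups = {}
    for kind in ("gene", "TE"):
        vals = uniq.loc[uniq["feature_kind"] == kind, "abs_diff"].to_numpy(dtype=float)
        groups[kind] = vals
        out[kind] = {
            "n": int(vals.size),
            "median": float(np.median(vals)) if vals.size else None,
            "q1": float(np.percentile(vals, 25)) if vals.size else None,
            "q3": float(np.percentile(vals, 75)) if vals.size else None,
        }
    if groups["gene"].size and groups["TE"].size:
        from .integrate import rank_sum_test
        out["p_value"] = rank_sum_test(groups["gene"], groups["TE"])
    else:
        out["p_value"] = None
    return out


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """BED6-shaped frame: name = direction, score = min(1000, -10*log10 q)."""
    q = np.clip(dmrs["q_value"].to_numpy(dtype=float), 1e-300, 1.0)
    score = np.minimum(1000, np.round(-10.0 * np.log10(q)).astype(int))
    return pd.DataFrame({
        "chrom": dmrs["chrom"], "start": dmrs["start"], "end": dmrs["end"],
        "direction": dmrs["direction"], "score": score, "strand": ".",
    })
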