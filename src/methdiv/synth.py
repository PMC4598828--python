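"""Synthetic two-cultivar methylome cohort generator.

Emulates the statistical structure of a whole-genome bisulphite study of two
rice-like cultivars (a "test" sample A and a "reference" sample B):

* a random genome with gene-rich chromosome arms and a TE-rich
  pericentromere, so methylcytosine density is positively coupled to TE
  density and negatively to gene density;
* context-specific methylation: methylated sites carry the canonical plant
  levels (CG highest, then CHG, then CHH), with the methylated-site fraction
  per context chosen so the cohort reproduces field-typical mC context
  fractions (~48/29/23% CG/CHG/CHH of all mCs) and an overall mC frequency
  near 11-12% of covered cytosines;
* TE hypermethylation via an elevated methylated-site fraction inside TEs;
* planted differentially methylated regions (whole 100-bp bins, half hyper /
  half hypo in A relative to B) with a machine-readable truth table;
* gene expression negatively coupled to gene-proximal hypermethylation;
* small-RNA loci enriched inside hyper-DMR genes and depleted in hypo-DMR
  genes (RdDM-like behaviour);
* an always-present fully unmethylated control contig standing in for the
  chloroplast, from which the bisulphite non-conversion (error) rate is
  estimated.

Read counts are the generative inverse of the downstream binomial caller:
depth ~ Poisson(depth_mean) and methylated reads ~ Binomial(depth, p_eff)
with p_eff = level/100 + (1 - level/100) * error_rate, so a truly
unmethylated site realises the caller's null exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import os

import numpy as np
import pandas as pd

from . import io as mio
from .methcall import CONTEXTS, enumerate_cytosines

CONTROL_CONTIG = "control"
BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Percentages are in [0, 100]; probabilities in [0, 1].  The same config
    and seed always produce byte-identical output files.
    """

    n_chroms: int = 1
    chrom_length: int = 1_000_000
    control_length: int = 20_000
    gene_count: int = 150
    te_count: int = 150
    gene_length_range: tuple = (800, 2_200)
    te_length_range: tuple = (500, 2_000)
    gc_fraction: float = 0.43
    # per-site methylation level (percent) of a methylated site, by context
    true_level_by_context: dict = field(default_factory=lambda: {
        "CG": 87.5, "CHG": 67.5, "CHH": 42.0})
    # probability that a cytosine of each context is methylated at all;
    # chosen so mC context fractions and overall mC frequency land in the
    # field-typical ranges given a 43%-GC random genome and the TE elevation
    methylated_site_fraction_by_context: dict = field(default_factory=lambda: {
        "CG": 0.18, "CHG": 0.14, "CHH": 0.029})
    te_level_multiplier: float = 2.5   # scales methylated-site fraction in TEs (capped at 1)
    depth_mean: float = 30.0
    error_rate: float = 0.0005         # bisulphite non-conversion rate
    n_planted_dmrs: int = 200
    planted_delta: float = 40.0        # percentage points, A vs B inside a planted bin
    dmr_bin_size: int = 100
    dmr_gene_fraction: float = 0.375   # share of planted DMRs placed inside gene bodies
    dmr_te_fraction: float = 0.25      # share placed inside TE bodies
    offset_dmrs: bool = False          # shift planted regions by 50 nt to straddle bins
    expression_coupling_strength: float = 2.0   # |log2| shift for DMR-coupled genes
    expr_log2_mean: float = 5.0
    expr_log2_sd: float = 2.0
    replicate_log2_sd: float = 0.25
    replicates_per_sample: int = 3
    smrna_rate_per_kb: float = 4.0
    smrna_hyper_fold: float = 1.7
    seed: int = 0

    def validate(self) -> None:
        probs = {"gc_fraction": self.gc_fraction, "error_rate": self.error_rate,
                 **{f"fraction[{k}]": v for k, v in
                    self.methylated_site_fraction_by_context.items()}}
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for ctx, lvl in self.true_level_by_context.items():
            if not 0.0 <= lvl <= 100.0:
                raise ValueError(f"level[{ctx}] must be in [0,100], got {lvl}")
        if self.te_level_multiplier < 1.0:
            raise ValueError("te_level_multiplier must be >= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.n_planted_dmrs and not 0.0 < self.planted_delta <= 100.0:
            raise ValueError("planted_delta must be in (0,100]")
        if self.chrom_length < max(self.gene_length_range[1], self.te_length_range[1]):
            raise ValueError("chrom_length must exceed the longest feature")
        if self.smrna_hyper_fold <= 0:
            raise ValueError("smrna_hyper_fold must be > 0")


@dataclass
class GenomeBundle:
    sequences: dict            # chrom -> sequence string (incl. control contig)
    genes: pd.DataFrame        # feature table, kind='gene'
    tes: pd.DataFrame          # feature table, kind='TE'
    chrom_lengths: dict

    @property
    def features(self) -> pd.DataFrame:
        return pd.concat([self.genes, self.tes], ignore_index=True)


def _rng_tree(seed: int, n: int) -> list:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_sequence(rng, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode("ascii")


def _pack_interval_lengths(rng, region_start: int, region_end: int,
                           lengths: np.ndarray, what: str) -> np.ndarray:
    """Place non-overlapping intervals of given lengths inside a region by
    distributing the free space as random gaps; always succeeds when the
    lengths fit, else raises naming the violated packing constraint."""
    span = region_end - region_start + 1
    free = span - int(lengths.sum())
    if free < 0:
        raise ValueError(
            f"infeasible packing: {what} total length {int(lengths.sum())} nt "
            f"exceeds region span {span} nt [{region_start},{region_end}]")
    w = rng.exponential(size=lengths.size + 1)
    gaps = np.floor(free * np.cumsum(w) / w.sum()).astype(np.int64)
    gaps = np.diff(np.concatenate([[0], gaps]))
    starts = region_start + np.cumsum(gaps)[:-1] + \
        np.concatenate([[0], np.cumsum(lengths[:-1])]).astype(np.int64)
    return starts


def generate_genome(config: SimulationConfig) -> GenomeBundle:
    """Random genome with arm-resident genes and pericentromeric TEs.

    Genes occupy the outer 30% of each chromosome, TEs the central 40%;
    features never overlap.  A fully unmethylated control contig is always
    appended.  Feature counts match the config exactly.
    """
    config.validate()
    rng_seq, rng_feat = _rng_tree(config.seed, 8)[:2]
    sequences = {}
    genes_rows, tes_rows = [], []
    L = config.chrom_length
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        sequences[chrom] = _random_sequence(rng_seq, L, config.gc_fraction)
        # split genes between the two arms, proportional to arm length
        n_genes = config.gene_count if config.n_chroms == 1 else (
            config.gene_count // config.n_chroms + (c < config.gene_count % config.n_chroms))
        n_tes = config.te_count if config.n_chroms == 1 else (
            config.te_count // config.n_chroms + (c < config.te_count % config.n_chroms))
        arm = int(0.30 * L)
        # most TEs sit in the pericentromeric middle; a minority is
        # interspersed with the genes on the arms
        n_arm_tes = int(round(0.2 * n_tes))
        gl = rng_feat.integers(config.gene_length_range[0],
                               config.gene_length_range[1] + 1, size=n_genes)
        atl = rng_feat.integers(config.te_length_range[0],
                                config.te_length_range[1] + 1, size=n_arm_tes)
        items = [("gene", int(x)) for x in gl] + [("TE", int(x)) for x in atl]
        if items:
            order = rng_feat.permutation(len(items))
            items = [items[i] for i in order]
        half = len(items) // 2
        gi = ti = 0
        for rs, re, part in ((1, arm, items[:half]), (L - arm + 1, L, items[half:])):
            if not part:
                continue
            lens = np.array([ln for _, ln in part], dtype=np.int64)
            starts = _pack_interval_lengths(rng_feat, rs, re, lens, "arm features")
            for (kind, ln), s in zip(part, starts):
                strand = "+" if rng_feat.random() < 0.5 else "-"
                if kind == "gene":
                    genes_rows.append((f"{chrom}g{gi:04d}", chrom, int(s),
                                       int(s + ln - 1), strand, "gene"))
                    gi += 1
                else:
                    tes_rows.append((f"{chrom}te{ti:04d}", chrom, int(s),
                                     int(s + ln - 1), strand, "TE"))
                    ti += 1
        n_center = n_tes - n_arm_tes
        tl = rng_feat.integers(config.te_length_range[0],
                               config.te_length_range[1] + 1, size=n_center)
        if n_center:
            cs, ce = int(0.30 * L) + 1, int(0.70 * L)
            starts = _pack_interval_lengths(rng_feat, cs, ce, tl, "TEs")
            for s, ln in zip(starts, tl):
                tes_rows.append((f"{chrom}te{ti:04d}", chrom, int(s), int(s + ln - 1),
                                 "+" if rng_feat.random() < 0.5 else "-", "TE"))
                ti += 1
    sequences[CONTROL_CONTIG] = _random_sequence(rng_seq, config.control_length,
                                                 config.gc_fraction)
    cols = mio.FEATURE_COLUMNS
    genes = pd.DataFrame(genes_rows, columns=cols)
    tes = pd.DataFrame(tes_rows, columns=cols)
    return GenomeBundle(sequences=sequences, genes=genes, tes=tes,
                        chrom_lengths={k: len(v) for k, v in sequences.items()})


def _in_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Membership of positions in sorted non-overlapping 1-based intervals."""
    if starts.size == 0:
        return np.zeros(pos.size, dtype=bool)
    i = np.searchsorted(starts, pos, side="right") - 1
    ok = i >= 0
    out = np.zeros(pos.size, dtype=bool)
    out[ok] = pos[ok] <= ends[i[ok]]
    return out


def assign_true_methylome(genome: GenomeBundle, config: SimulationConfig) -> pd.DataFrame:
    """Enumerate every cytosine on both strands and assign true levels.

    Each cytosine is methylated (level = context default) with the context's
    methylated-site fraction, scaled by ``te_level_multiplier`` (capped at 1)
    for TE-resident sites, else unmethylated (level 0).  Samples A and B are
    identical until DMRs are planted.  The control contig is all zero.
    """
    config.validate()
    rng = _rng_tree(config.seed, 8)[2]
    frames = []
    for chrom, seq in genome.sequences.items():
        sites = enumerate_cytosines(seq, chrom)
        n = len(sites)
        level = np.zeros(n)
        if chrom != CONTROL_CONTIG:
            frac = sites["context"].map(config.methylated_site_fraction_by_context).to_numpy()
            te = genome.tes[genome.tes["chrom"] == chrom]
            in_te = _in_intervals(sites["pos"].to_numpy(),
                                  te["start"].to_numpy(), te["end"].to_numpy())
            frac = np.where(in_te, np.minimum(1.0, frac * config.te_level_multiplier), frac)
            methylated = rng.random(n) < frac
            lvl_map = sites["context"].map(config.true_level_by_context).to_numpy()
            level = np.where(methylated, lvl_map, 0.0)
        df = sites.copy()
        df["true_level_A"] = level
        df["true_level_B"] = level.copy()
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def plant_dmrs(truth: pd.DataFrame, genome: GenomeBundle,
               config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant ``n_planted_dmrs`` bin-aligned differential regions.

    Half hyper, half hypo in sample A relative to B (odd remainder hyper).
    Every site in a planted region receives a context-anchored level pair
    (context level -/+ delta/2, shifted into [0,100] preserving the width
    delta): the high member goes to sample A in a hyper region and to sample
    B in a hypo region.  Each site's A-B difference is therefore exactly
    +/- delta (so the region's realised mean difference equals the planted
    delta), and because hyper and hypo regions are planted in equal numbers
    the per-context mean level of either sample's methylome is unbiased.
    Regions are drawn from gene bodies, TE bodies and intergenic space in
    the configured proportions; the covering gene, if any, is recorded.
    """
    truth = truth.copy()
    if config.n_planted_dmrs == 0:
        return truth, pd.DataFrame(columns=[
            "chrom", "start", "end", "direction", "planted_delta", "overlapped_gene_id"])
    if not 0.0 < config.planted_delta <= 100.0:
        raise ValueError("planted_delta must be in (0,100]")
    rng = _rng_tree(config.seed, 8)[3]
    bs = config.dmr_bin_size
    n = config.n_planted_dmrs
    n_gene = int(round(n * config.dmr_gene_fraction))
    n_te = int(round(n * config.dmr_te_fraction))
    n_inter = n - n_gene - n_te

    chosen: list[tuple[str, int, str | None]] = []   # (chrom, bin_start, gene_id)
    used: set[tuple[str, int]] = set()

    def pick_in_features(feats: pd.DataFrame, k: int, record_gene: bool) -> None:
        cand = feats[feats["end"] - feats["start"] + 1 >= 2 * bs]
        order = rng.permutation(cand.index.to_numpy())
        taken = 0
        for idx in order:
            if taken == k:
                break
            f = cand.loc[idx]
            first_bin = (f["start"] - 1 + bs - 1) // bs      # first whole bin inside
            last_bin = (f["end"] - bs) // bs
            if last_bin < first_bin:
                continue
            b = int(rng.integers(first_bin, last_bin + 1))
            key = (f["chrom"], b)
            if key in used:
                continue
            used.add(key)
            chosen.append((f["chrom"], b * bs + 1,
                           f["feature_id"] if record_gene else None))
            taken += 1
        if taken < k:
            raise ValueError(f"infeasible packing: only {taken}/{k} planted DMRs "
                             f"fit inside {'genes' if record_gene else 'TEs'}")

    pick_in_features(genome.genes, n_gene, record_gene=True)
    pick_in_features(genome.tes, n_te, record_gene=False)

    # intergenic bins: away from all features and from gene 2-kb flanks, so
    # the planted truth categories (gene-coupled / TE / background) stay
    # unambiguous for recovery tests
    feats = genome.features
    gene_margin = 2_000
    chroms = [c for c in genome.sequences if c != CONTROL_CONTIG]
    taken = 0
    attempts = 0
    while taken < n_inter and attempts < 100_000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        L = genome.chrom_lengths[chrom]
        b = int(rng.integers(0, L // bs))
        key = (chrom, b)
        if key in used:
            continue
        s, e = b * bs + 1, (b + 1) * bs
        f = feats[feats["chrom"] == chrom]
        margin = np.where(f["kind"].to_numpy() == "gene", gene_margin, 0)
        if ((f["start"] - margin <= e) & (f["end"] + margin >= s)).any():
            continue
        used.add(key)
        chosen.append((chrom, s, None))
        taken += 1
    if taken < n_inter:
        raise ValueError("infeasible packing: could not place intergenic planted DMRs")

    order = rng.permutation(len(chosen))
    n_hyper = (len(chosen) + 1) // 2
    records = []
    delta = config.planted_delta
    pos = truth["pos"].to_numpy()
    chrom_arr = truth["chrom"].to_numpy()
    lvl_a = truth["true_level_A"].to_numpy().copy()
    lvl_b = truth["true_level_B"].to_numpy().copy()
    # context-anchored (low, high) level pair of width delta
    lo_by_ctx, hi_by_ctx = {}, {}
    for ctx, lvl in config.true_level_by_context.items():
        lo = max(0.0, lvl - delta / 2.0)
        hi = lo + delta
        if hi > 100.0:
            hi, lo = 100.0, 100.0 - delta
        lo_by_ctx[ctx], hi_by_ctx[ctx] = lo, hi
    site_lo = truth["context"].map(lo_by_ctx).to_numpy()
    site_hi = truth["context"].map(hi_by_ctx).to_numpy()
    for rank, ci in enumerate(order):
        chrom, start, gene_id = chosen[ci]
        if config.offset_dmrs:
            start += bs // 2
        end = start + bs - 1
        direction = "hyper" if rank < n_hyper else "hypo"
        mask = (chrom_arr == chrom) & (pos >= start) & (pos <= end)
        if direction == "hyper":
            lvl_a[mask] = site_hi[mask]
            lvl_b[mask] = site_lo[mask]
        else:
            lvl_a[mask] = site_lo[mask]
            lvl_b[mask] = site_hi[mask]
        records.append((chrom, start, end, direction, delta, gene_id))
    truth["true_level_A"] = lvl_a
    truth["true_level_B"] = lvl_b
    rec = pd.DataFrame(records, columns=[
        "chrom", "start", "end", "direction", "planted_delta", "overlapped_gene_id"])
    rec = rec.sort_values(["chrom", "start"]).reset_index(drop=True)
    return truth, rec


def shift_level(level: float, delta: float) -> float:
    """Signed level shift with clipping to [0, 100]."""
    return float(np.clip(level + delta, 0.0, 100.0))


def simulate_counts(truth: pd.DataFrame, config: SimulationConfig,
                    sample: str) -> pd.DataFrame:
    """Draw per-site read counts for one sample (CX-report rows).

    depth ~ Poisson(depth_mean); methylated reads ~ Binomial(depth, p_eff)
    with p_eff = level/100 + (1 - level/100) * error_rate.
    """
    if config.depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    idx = {"A": 4, "B": 5}[sample]
    rng = _rng_tree(config.seed, 8)[idx]
    level = truth[f"true_level_{sample}"].to_numpy() / 100.0
    p_eff = level + (1.0 - level) * config.error_rate
    depth = rng.poisson(config.depth_mean, size=len(truth))
    m = rng.binomial(depth, p_eff)
    out = truth[["chrom", "pos", "strand", "context", "tri"]].copy()
    out["count_meth"] = m
    out["count_unmeth"] = depth - m
    return out[mio.CX_COLUMNS]


def _coupled_genes(genes: pd.DataFrame, dmr_truth: pd.DataFrame,
                   flank: int = 2000) -> pd.DataFrame:
    """Per-gene planted-DMR direction: midpoint within body or flank.

    Returns genes with columns n_hyper, n_hypo.
    """
    g = genes.copy()
    g["n_hyper"] = 0
    g["n_hypo"] = 0
    if dmr_truth.empty:
        return g
    mid = (dmr_truth["start"] + dmr_truth["end"]) // 2
    for i, row in g.iterrows():
        near = (dmr_truth["chrom"] == row["chrom"]) & \
               (mid >= row["start"] - flank) & (mid <= row["end"] + flank)
        sub = dmr_truth[near]
        g.at[i, "n_hyper"] = int((sub["direction"] == "hyper").sum())
        g.at[i, "n_hypo"] = int((sub["direction"] == "hypo").sum())
    return g


def simulate_expression(genes: pd.DataFrame, dmr_truth: pd.DataFrame,
                        config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM-like replicate abundances with methylation-coupled shifts.

    Baseline log2 abundance per gene ~ Normal(expr_log2_mean, expr_log2_sd),
    shared by both samples.  Genes whose body/2-kb flank contains a planted
    hyper (hypo) DMR midpoint get their sample-A log2 abundance shifted by
    -c (+c), c = expression_coupling_strength; genes touched by both
    directions are left unshifted.  Lognormal replicate noise is added.
    Returns (long expression table, per-gene truth with expected direction).
    """
    if config.replicates_per_sample < 2:
        raise ValueError("replicates_per_sample must be >= 2")
    rng = _rng_tree(config.seed, 8)[6]
    g = _coupled_genes(genes, dmr_truth)
    base = rng.normal(config.expr_log2_mean, config.expr_log2_sd, size=len(g))
    c = config.expression_coupling_strength
    shift = np.where((g["n_hyper"] > 0) & (g["n_hypo"] == 0), -c,
                     np.where((g["n_hypo"] > 0) & (g["n_hyper"] == 0), c, 0.0))
    rows = []
    for sample, mean_log2 in (("A", base + shift), ("B", base)):
        for rep in range(1, config.replicates_per_sample + 1):
            noise = rng.normal(0.0, config.replicate_log2_sd, size=len(g))
            ab = np.power(2.0, mean_log2 + noise)
            rows.append(pd.DataFrame({
                "gene_id": g["feature_id"], "sample": sample,
                "replicate": rep, "abundance": ab}))
    expr = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame({
        "gene_id": g["feature_id"],
        "expected_direction": np.where(shift < 0, "down",
                                       np.where(shift > 0, "up", "none")),
        "log2_shift": shift,
    })
    return expr, truth


def simulate_smrna(genome: GenomeBundle, dmr_truth: pd.DataFrame,
                   config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """21-24 nt smRNA loci for each sample.

    Loci arrive at ``smrna_rate_per_kb`` genome-wide; inside genes carrying
    a planted hyper DMR the rate is multiplied by ``smrna_hyper_fold`` and
    inside hypo-DMR genes divided by it (sample A only; sample B is
    uniform).  Per-locus abundance is geometric (>= 1).
    """
    if config.smrna_hyper_fold <= 0:
        raise ValueError("smrna_hyper_fold must be > 0")
    rng = _rng_tree(config.seed, 8)[7]
    g = _coupled_genes(genome.genes, dmr_truth)
    hyper_g = g[(g["n_hyper"] > 0) & (g["n_hypo"] == 0)]
    hypo_g = g[(g["n_hypo"] > 0) & (g["n_hyper"] == 0)]
    out = {}
    for sample in ("A", "B"):
        fold = config.smrna_hyper_fold if sample == "A" else 1.0
        loci = []
        counter = 0
        for chrom, L in genome.chrom_lengths.items():
            if chrom == CONTROL_CONTIG:
                continue
            regions = []   # (start, end, rate multiplier)
            for _, r in hyper_g[hyper_g["chrom"] == chrom].iterrows():
                regions.append((r["start"], r["end"], fold))
            for _, r in hypo_g[hypo_g["chrom"] == chrom].iterrows():
                regions.append((r["start"], r["end"], 1.0 / fold))
            special_len = sum(e - s + 1 for s, e, _ in regions)
            regions.append((1, L, 1.0))   # background; rejection removes overlaps
            starts = np.array([s for s, _, _ in regions[:-1]])
            ends = np.array([e for _, e, _ in regions[:-1]])
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            for ri, (s, e, mult) in enumerate(regions):
                if ri == len(regions) - 1:
                    span = L - special_len
                else:
                    span = e - s + 1
                lam = config.smrna_rate_per_kb * span / 1000.0 * mult
                k = rng.poisson(lam)
                if k == 0:
                    continue
                if ri == len(regions) - 1:
                    pos = rng.integers(1, L - 24 + 1, size=4 * k + 20)
                    keep = ~_in_intervals(pos, starts, ends)
                    pos = pos[keep][:k]
                    while pos.size < k:   # rare top-up
                        extra = rng.integers(1, L - 24 + 1, size=4 * k)
                        extra = extra[~_in_intervals(extra, starts, ends)]
                        pos = np.concatenate([pos, extra])[:k]
                else:
                    pos = rng.integers(s, max(s + 1, e - 24 + 1), size=k)
                lens = rng.integers(21, 25, size=pos.size)
                abund = rng.geometric(0.5, size=pos.size)
                for p_, ln, ab in zip(pos, lens, abund):
                    loci.append((f"s{sample}{counter:06d}", chrom, int(p_),
                                 int(p_ + ln - 1), "+", "smrna", int(ab)))
                    counter += 1
        df = pd.DataFrame(loci, columns=mio.FEATURE_COLUMNS + ["abundance"])
        df["length"] = df["end"] - df["start"] + 1
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        out[sample] = df
    return out


@dataclass
class Cohort:
    """In-memory synthetic cohort: the inputs every downstream stage needs."""
    config: SimulationConfig
    genome: GenomeBundle
    site_truth: pd.DataFrame
    dmr_truth: pd.DataFrame
    counts: dict               # sample -> CX table
    expression: pd.DataFrame
    expression_truth: pd.DataFrame
    smrna: dict                # sample -> locus table


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Run the full generator; deterministic in ``config.seed``."""
    genome = generate_genome(config)
    truth = assign_true_methylome(genome, config)
    truth, dmr_truth = plant_dmrs(truth, genome, config)
    counts = {s: simulate_counts(truth, config, s) for s in ("A", "B")}
    expr, expr_truth = simulate_expression(genome.genes, dmr_truth, config)
    smrna = simulate_smrna(genome, dmr_truth, config)
    return Cohort(config=config, genome=genome, site_truth=truth,
                  dmr_truth=dmr_truth, counts=counts, expression=expr,
                  expression_truth=expr_truth, smrna=smrna)


def write_cohort(cohort: Cohort, outdir: str) -> dict[str, str]:
    """Serialise a cohort to disk; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    p = {}
    p["fasta"] = os.path.join(outdir, "genome.fa")
    mio.write_fasta(p["fasta"], cohort.genome.sequences)
    p["genes"] = os.path.join(outdir, "genes.gff3")
    mio.write_gff3(p["genes"], cohort.genome.genes)
    p["tes"] = os.path.join(outdir, "tes.gff3")
    mio.write_gff3(p["tes"], cohort.genome.tes)
    for s in ("A", "B"):
        p[f"cx_{s}"] = os.path.join(outdir, f"cx_{s}.tsv")
        mio.write_cx_report(p[f"cx_{s}"], cohort.counts[s])
        p[f"smrna_{s}"] = os.path.join(outdir, f"smrna_{s}.bed")
        mio.write_smrna_bed(p[f"smrna_{s}"], cohort.smrna[s])
    p["expression"] = os.path.join(outdir, "expression.tsv")
    mio.write_table(p["expression"], cohort.expression,
                    comment="synthetic expression (FPKM-like)")
    p["dmr_truth"] = os.path.join(outdir, "dmr_truth.tsv")
    mio.write_table(p["dmr_truth"], cohort.dmr_truth, comment="planted DMR truth")
    p["expression_truth"] = os.path.join(outdir, "expression_truth.tsv")
    mio.write_table(p["expression_truth"], cohort.expression_truth,
                    comment="planted expression-coupling truth")
    p["site_truth"] = os.path.join(outdir, "site_truth.tsv")
    mio.write_table(p["site_truth"], cohort.site_truth.drop(columns=["tri"]),
                    comment="true per-site methylation levels")
    return p
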