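"""Metagene/meta-TE profiles and chromosomal density tracks.

Profiles aggregate positional items (methylation calls or smRNA loci) over
a feature set: fixed-width bins across 1-kb flanks plus a length-normalised
body split into equal relative segments, mirrored for minus-strand features
so bin 0 is always the 5'-most upstream bin.  Density tracks count items in
fixed windows (default 100 kb) along each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ProfileParams:
    flank: int = 1000
    flank_bin: int = 50
    body_bins: int = 40
    value_mode: str = "mc_fraction"   # or mean_level, smrna_fraction

    def __post_init__(self) -> None:
        if self.flank % self.flank_bin != 0:
            raise ValueError("flank must be divisible by flank_bin")
        if self.body_bins < 1:
            raise ValueError("body_bins must be >= 1")

    @property
    def n_flank_bins(self) -> int:
        return self.flank // self.flank_bin

    @property
    def n_bins(self) -> int:
        return 2 * self.n_flank_bins + self.body_bins


@dataclass
class ProfileResult:
    positions: list            # bin labels: upstream, body, downstream
    values: pd.DataFrame       # bin x track
    n_features_used: int = 0
    n_features_skipped: int = 0


def _bin_labels(params: ProfileParams) -> list:
    nf = params.n_flank_bins
    return ([f"up{i}" for i in range(nf)] +
            [f"body{i}" for i in range(params.body_bins)] +
            [f"down{i}" for i in range(nf)])


def metagene_profile(items: pd.DataFrame, features: pd.DataFrame,
                     params: ProfileParams = ProfileParams(),
                     track_col: str | None = "context") -> ProfileResult:
    """Aggregate item positions over features into a flank/body/flank profile.

    ``items`` needs chrom and either pos (single-base items such as mC
    calls) or start/end (interval items such as smRNA loci, assigned by
    midpoint).  In mean_level mode items must carry a ``level`` column.
    Features shorter than ``body_bins`` bases are skipped and counted.
    Minus-strand features are mirrored.
    """
    nf = params.n_flank_bins
    labels = _bin_labels(params)
    if "pos" in items.columns:
        ipos = items["pos"].to_numpy()
    else:
        ipos = ((items["start"] + items["end"]) // 2).to_numpy()
    tracks = items[track_col].to_numpy() if track_col and track_col in items else \
        np.full(len(items), "all")
    track_names = sorted(set(tracks))
    sums = {t: np.zeros(params.n_bins) for t in track_names}
    cnts = {t: np.zeros(params.n_bins) for t in track_names}
    levels = items["level"].to_numpy() if "level" in items.columns else None

    used = skipped = 0
    for chrom, fsub in features.groupby("chrom"):
        cmask = items["chrom"].to_numpy() == chrom
        cpos = ipos[cmask]
        ctrk = tracks[cmask]
        clvl = levels[cmask] if levels is not None else None
        order = np.argsort(cpos)
        cpos, ctrk = cpos[order], ctrk[order]
        if clvl is not None:
            clvl = clvl[order]
        for f in fsub.itertuples(index=False):
            flen = f.end - f.start + 1
            if flen <= params.body_bins:
                skipped += 1
                continue
            used += 1
            lo, hi = f.start - params.flank, f.end + params.flank
            a = np.searchsorted(cpos, lo, side="left")
            b = np.searchsorted(cpos, hi, side="right")
            if a == b:
                continue
            p = cpos[a:b]
            minus = f.strand == "-"
            # distance into the window, 5'->3' of the feature
            upstream = (p < f.start) if not minus else (p > f.end)
            downstream = (p > f.end) if not minus else (p < f.start)
            body = ~upstream & ~downstream
            idx = np.empty(p.size, dtype=int)
            if not minus:
                idx[upstream] = (p[upstream] - lo) // params.flank_bin
                rel = (p[body] - f.start) / flen
                idx[downstream] = nf + params.body_bins + \
                    (p[downstream] - (f.end + 1)) // params.flank_bin
            else:
                idx[upstream] = (hi - p[upstream]) // params.flank_bin
                rel = (f.end - p[body]) / flen
                idx[downstream] = nf + params.body_bins + \
                    ((f.start - 1) - p[downstream]) // params.flank_bin
            idx[body] = nf + np.minimum((rel * params.body_bins).astype(int),
                                        params.body_bins - 1)
            for t in track_names:
                sel = ctrk[a:b] == t
                if not sel.any():
                    continue
                np.add.at(cnts[t], idx[sel], 1.0)
                if clvl is not None:
                    np.add.at(sums[t], idx[sel], clvl[a:b][sel])
    if used == 0:
        raise ValueError("no usable features (all shorter than body_bins?)")
    vals = {}
    for t in track_names:
        if params.value_mode == "mean_level":
            with np.errstate(invalid="ignore"):
                vals[t] = np.where(cnts[t] > 0, sums[t] / np.maximum(cnts[t], 1), np.nan)
        else:
            total = cnts[t].sum()
            vals[t] = cnts[t] / total if total > 0 else cnts[t]
    return ProfileResult(positions=labels,
                         values=pd.DataFrame(vals, index=labels),
                         n_features_used=used, n_features_skipped=skipped)


def feature_body_levels(calls: pd.DataFrame, genes: pd.DataFrame,
                        tes: pd.DataFrame, te_priority: bool = True,
                        min_depth: int = 5) -> dict:
    """Per-class (gene body vs TE body), per-context methylation summary.

    Sites inside both a gene and a TE go to the TE class when
    ``te_priority`` (the default), else to the gene class.  Reports, per
    class and context: mC count, mean level over covered sites, and the
    read-weighted methylation 100*sum(m)/sum(m+u).  An empty class is
    reported as absent (None), not zero.
    """
    depth = calls["count_meth"] + calls["count_unmeth"]
    covered = calls[depth >= min_depth].copy()

    def member(feats: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(covered), dtype=bool)
        for chrom, sub in feats.groupby("chrom"):
            s = sub.sort_values("start")
            ts, te_ = s["start"].to_numpy(), s["end"].to_numpy()
            cmask = covered["chrom"].to_numpy() == chrom
            p = covered["pos"].to_numpy()[cmask]
            i = np.searchsorted(ts, p, side="right") - 1
            ok = i >= 0
            hit = np.zeros(p.size, dtype=bool)
            hit[ok] = p[ok] <= te_[i[ok]]
            out[cmask] = hit
        return out

    in_gene = member(genes)
    in_te = member(tes)
    if te_priority:
        in_gene = in_gene & ~in_te
    else:
        in_te = in_te & ~in_gene
    out = {}
    for cls, mask in (("gene", in_gene), ("TE", in_te)):
        sub = covered[mask]
        if sub.empty:
            out[cls] = None
            continue
        ctx_stats = {}
        for ctx in ("CG", "CHG", "CHH"):
            c = sub[sub["context"] == ctx]
            if c.empty:
                ctx_stats[ctx] = None
                continue
            m = int(c["count_meth"].sum())
            u = int(c["count_unmeth"].sum())
            ctx_stats[ctx] = {
                "n_mcs": int(c["is_mc"].sum()) if "is_mc" in c else None,
                "mean_level": float(c["level"].mean()),
                "weighted_level": 100.0 * m / (m + u) if m + u else None,
            }
        out[cls] = ctx_stats
    return out


def chromosome_density(item_tables: dict, chrom_lengths: dict,
                       window: int = 100_000) -> pd.DataFrame:
    """Counts of each item table per fixed window along each chromosome.

    ``item_tables`` maps track name -> frame with chrom and pos (or
    start/end; intervals counted by midpoint).  The last window of a
    chromosome is truncated.  Returns a long frame
    (chrom, window_start, window_end, track, count).
    """
    rows = []
    for chrom, L in chrom_lengths.items():
        n_win = int(np.ceil(L / window))
        edges_start = np.arange(n_win) * window + 1
        edges_end = np.minimum((np.arange(n_win) + 1) * window, L)
        for track, df in item_tables.items():
            sub = df[df["chrom"] == chrom]
            if "pos" in sub.columns:
                p = sub["pos"].to_numpy()
            else:
                p = ((sub["start"] + sub["end"]) // 2).to_numpy()
            counts = np.bincount((p - 1) // window, minlength=n_win)[:n_win]
            for ws, we, c in zip(edges_start, edges_end, counts):
                rows.append((chrom, int(ws), int(we), track, int(c)))
    return pd.DataFrame(rows, columns=["chrom", "window_start", "window_end",
                                       "track", "count"])


def density_correlation(density: pd.DataFrame, pairs: list | None = None) -> dict:
    """Spearman rank correlation between density tracks on shared windows."""
    wide = density.pivot_table(index=["chrom", "window_start"], columns="track",
                               values="count")
    tracks = list(wide.columns)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(tracks) for b in tracks[i + 1:]]
    out = {}
    for a, b in pairs:
        if len(wide) < 3:
            out[(a, b)] = {"rho": None, "p_value": None}
            continue
        rho, p = stats.spearmanr(wide[a], wide[b])
        out[(a, b)] = {"rho": float(rho), "p_value": float(p)}
    return out


def plot_profile(result: ProfileResult, path: str, title: str = "") -> None:
    """Line plot of a profile result (one line per track)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(7, 3.5))
    x = np.arange(len(result.positions))
    for t in result.values.columns:
        ax.plot(x, result.values[t], label=str(t))
    nf = sum(1 for lbl in result.positions if lbl.startswith("up"))
    nb = sum(1 for lbl in result.positions if lbl.startswith("body"))
    for xc in (nf - 0.5, nf + nb - 0.5):
        ax.axvline(xc, color="grey", lw=0.8, ls="--")
    ax.set_xticks([0, nf, nf + nb, len(x) - 1])
    ax.set_xticklabels(["-flank", "TSS", "TTS", "+flank"])
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_density(density: pd.DataFrame, chrom: str, path: str) -> None:
    """Stacked per-track density lines along one chromosome."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    sub = density[density["chrom"] == chrom]
    tracks = sorted(sub["track"].unique())
    fig, axes = plt.subplots(len(tracks), 1, figsize=(8, 1.2 * len(tracks)),
                             sharex=True, squeeze=False)
    for ax, t in zip(axes[:, 0], tracks):
        tt = sub[sub["track"] == t]
        ax.fill_between(tt["window_start"], tt["count"], step="post", alpha=0.7)
        ax.set_ylabel(t, rotation=0, ha="right", fontsize=8)
    axes[-1, 0].set_xlabel(f"{chrom} position")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
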