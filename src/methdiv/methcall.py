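"""Methylcytosine calling from bisulphite cytosine reports.

Bisulphite treatment converts unmethylated cytosines to uracil (read as T)
while methylated cytosines resist conversion.  At each cytosine we observe
``m`` reads calling methylated and ``u`` reads calling unmethylated; under
the null hypothesis that the site is unmethylated, methylated calls arise
only from incomplete conversion at rate ``error_rate`` (estimated from an
unmethylated control contig, the chloroplast in real data).  A site is
called a methylcytosine (mC) when the upper binomial tail probability
``P(X >= m)`` with ``X ~ Binomial(m + u, error_rate)`` falls below a cutoff
and the site is covered by a minimum read depth.

Cytosine sequence contexts follow the plant convention: CG, CHG and CHH
(H = A, C or T), read 5'->3' on the strand carrying the cytosine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONTEXTS = ("CG", "CHG", "CHH")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class CallParams:
    """Thresholds for methylcytosine calling.

    alpha : binomial P-value cutoff (inclusive).
    min_depth : minimum read depth for a site to be callable (inclusive).
    error_rate : bisulphite non-conversion rate, the binomial null parameter.
    """

    alpha: float = 0.001
    min_depth: int = 5
    error_rate: float = 0.0005

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_depth < 1:
            raise ValueError(f"min_depth must be >= 1, got {self.min_depth}")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate must be in [0,1), got {self.error_rate}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_context(sequences, chrom: str, pos: int, strand: str) -> str:
    """Context of the cytosine at ``(chrom, pos, strand)`` (1-based).

    ``sequences`` is any mapping from chromosome name to its plus-strand
    sequence string.  On the minus strand the cytosine sits at a plus-strand
    G and its downstream bases run leftward on the complement.  Sites too
    close to a chromosome end to see two downstream bases are classified on
    the available bases (CHH when undecidable).
    """
    seq = sequences[chrom]
    n = len(seq)
    if not 1 <= pos <= n:
        raise ValueError(f"position {chrom}:{pos} out of range 1..{n}")
    i = pos - 1
    base = seq[i].upper()
    if strand == "+":
        if base != "C":
            raise ValueError(f"base at {chrom}:{pos}:+ is {base}, not C")
        nxt = seq[i + 1].upper() if i + 1 < n else None
        nxt2 = seq[i + 2].upper() if i + 2 < n else None
    elif strand == "-":
        if base != "G":
            raise ValueError(f"base at {chrom}:{pos}:- is {base.translate(_COMPLEMENT)}, not C")
        nxt = seq[i - 1].upper().translate(_COMPLEMENT) if i - 1 >= 0 else None
        nxt2 = seq[i - 2].upper().translate(_COMPLEMENT) if i - 2 >= 0 else None
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if nxt == "G":
        return "CG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def enumerate_cytosines(seq: str, chrom: str) -> pd.DataFrame:
    """All cytosines of a chromosome on both strands, context-classified.

    Returns a frame with columns chrom, pos (1-based), strand, context,
    trinucleotide (5'->3' on the cytosine's strand, N-padded at ends).
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    n = arr.size
    pad = np.concatenate([np.full(2, b"N"), arr, np.full(2, b"N")])
    lut = np.full(256, b"N", dtype="S1")
    for a, b in zip(b"ACGTN", b"TGCAN"):
        lut[a] = bytes([b])
    comp_pad = lut[pad.view(np.uint8)]

    def tri(idx: np.ndarray, minus: bool) -> np.ndarray:
        if minus:
            b0, b1, b2 = comp_pad[idx + 2], comp_pad[idx + 1], comp_pad[idx]
        else:
            b0, b1, b2 = pad[idx + 2], pad[idx + 3], pad[idx + 4]
        return np.char.add(np.char.add(b0, b1), b2).astype("U3")

    frames = []
    # plus strand: C at i; CG if seq[i+1]==G, CHG if seq[i+2]==G
    idx = np.nonzero(arr == b"C")[0]
    if idx.size:
        nxt = pad[idx + 3]
        nxt2 = pad[idx + 4]
        ctx = np.where(nxt == b"G", "CG", np.where(nxt2 == b"G", "CHG", "CHH"))
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": idx + 1, "strand": "+",
            "context": ctx, "tri": tri(idx, minus=False),
        }))
    # minus strand: C sits at a plus-strand G; downstream bases are the
    # complements of seq[i-1], seq[i-2]
    idx = np.nonzero(arr == b"G")[0]
    if idx.size:
        nxt = pad[idx + 1]   # seq[i-1]
        nxt2 = pad[idx]      # seq[i-2]
        ctx = np.where(nxt == b"C", "CG", np.where(nxt2 == b"C", "CHG", "CHH"))
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": idx + 1, "strand": "-",
            "context": ctx, "tri": tri(idx, minus=True),
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "tri"])
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)
    return out


def estimate_error_rate(sites: pd.DataFrame, control_contig: str | None = None) -> float:
    """Read-weighted pooled non-conversion rate from an unmethylated contig.

    Returns ``sum(m) / sum(m + u)`` over the control-contig sites.  Pooling
    reads (rather than averaging per-site rates) is robust at low per-site
    depth.
    """
    sub = sites
    if control_contig is not None:
        sub = sites[sites["chrom"] == control_contig]
    total = int(sub["count_meth"].sum() + sub["count_unmeth"].sum())
    if total == 0:
        raise ValueError("cannot estimate error rate: zero total depth on control contig")
    return float(sub["count_meth"].sum()) / total


def binomial_pvalue(m: int, x: int, error_rate: float) -> float:
    """Upper-tail P(X >= m) for X ~ Binomial(x, error_rate); P(X >= 0) = 1."""
    if m > x:
        raise ValueError(f"m={m} exceeds depth x={x}")
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    if m == 0:
        return 1.0
    return float(stats.binom.sf(m - 1, x, error_rate))


def binomial_pvalues(m: np.ndarray, x: np.ndarray, error_rate: float) -> np.ndarray:
    """Vectorised inclusive upper binomial tail."""
    m = np.asarray(m)
    x = np.asarray(x)
    if np.any(m > x) or np.any(m < 0):
        raise ValueError("require 0 <= m <= x elementwise")
    p = np.ones(m.shape, dtype=float)
    pos = m > 0
    p[pos] = stats.binom.sf(m[pos] - 1, x[pos], error_rate)
    return p


def call_methylcytosines(sites: pd.DataFrame, params: CallParams) -> pd.DataFrame:
    """Per-site methylation calls.

    Every input row yields an output row with columns level (percentage of
    reads methylated; NaN at depth 0), p_value, and is_mc (depth >=
    min_depth AND p_value <= alpha, both inclusive).
    """
    out = sites.copy()
    m = out["count_meth"].to_numpy(dtype=np.int64)
    u = out["count_unmeth"].to_numpy(dtype=np.int64)
    depth = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(depth > 0, 100.0 * m / np.where(depth > 0, depth, 1), np.nan)
    p = binomial_pvalues(m, depth, params.error_rate)
    out["level"] = level
    out["p_value"] = p
    out["is_mc"] = (depth >= params.min_depth) & (p <= params.alpha)
    return out


@dataclass
class MethylomeSummary:
    """Genome-wide methylation summary statistics.

    context_fraction_of_mcs : percentage of all mCs in each context.
    mean_level_by_context : mean per-site methylation level over mCs; a
        context with no mCs is absent from the map.
    mc_frequency : mCs as a percentage of covered cytosines (depth >= min_depth).
    per_strand_counts : mC counts per strand.
    """

    context_fraction_of_mcs: dict = field(default_factory=dict)
    mean_level_by_context: dict = field(default_factory=dict)
    mc_frequency: float = 0.0
    per_strand_counts: dict = field(default_factory=dict)
    n_mcs: int = 0
    n_covered: int = 0

    def to_dict(self) -> dict:
        return {
            "context_fraction_of_mcs": self.context_fraction_of_mcs,
            "mean_level_by_context": self.mean_level_by_context,
            "mc_frequency": self.mc_frequency,
            "per_strand_counts": self.per_strand_counts,
            "n_mcs": self.n_mcs,
            "n_covered": self.n_covered,
        }


def summarize_methylome(calls: pd.DataFrame, min_depth: int = 5,
                        denominator: str = "covered") -> MethylomeSummary:
    """Context fractions, mean levels, mC frequency and strand counts.

    ``denominator`` selects the base of mC frequency: "covered" (cytosines
    with depth >= min_depth, the default) or "all" (every reported cytosine).
    """
    if calls.empty:
        raise ValueError("call table is empty")
    depth = calls["count_meth"] + calls["count_unmeth"]
    covered = int((depth >= min_depth).sum())
    mcs = calls[calls["is_mc"]]
    n_mc = len(mcs)
    frac = {}
    mean_lvl = {}
    for ctx in CONTEXTS:
        sub = mcs[mcs["context"] == ctx]
        frac[ctx] = 100.0 * len(sub) / n_mc if n_mc else 0.0
        if len(sub):
            mean_lvl[ctx] = float(sub["level"].mean())
    denom = covered if denominator == "covered" else len(calls)
    strand_counts = mcs["strand"].value_counts().to_dict()
    return MethylomeSummary(
        context_fraction_of_mcs=frac,
        mean_level_by_context=mean_lvl,
        mc_frequency=100.0 * n_mc / denom if denom else 0.0,
        per_strand_counts={s: int(c) for s, c in strand_counts.items()},
        n_mcs=n_mc,
        n_covered=covered,
    )
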