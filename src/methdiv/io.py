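"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 1-based inclusive everywhere (the convention of
GFF3 and of Bismark cytosine reports); BED's 0-based half-open coordinates
are converted only at the I/O boundary.  All bespoke tables are plain TSV
with '#'-prefixed header comments so outputs stay diffable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STRANDS = {"+", "-"}
CONTEXT_VOCAB = {"CG", "CHG", "CHH"}

CX_COLUMNS = ["chrom", "pos", "strand", "count_meth", "count_unmeth", "context", "tri"]
FEATURE_COLUMNS = ["feature_id", "chrom", "start", "end", "strand", "kind"]


class FormatError(ValueError):
    """Malformed input file; the message names the first offending line."""


# ---------------------------------------------------------------- FASTA

def write_fasta(path: str, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    """Whole-genome FASTA into a name -> sequence dict.

    Uses pyfaidx when an index is wanted elsewhere; for the modest genomes
    this pipeline handles, materialising strings is simplest and fast.
    """
    try:
        from pyfaidx import Fasta
        fa = Fasta(path, as_raw=True, sequence_always_upper=True, rebuild=True)
        return {name: str(fa[name][:]) for name in fa.keys()}
    except ImportError:  # pragma: no cover
        seqs: dict[str, list[str]] = {}
        name = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    name = line[1:].split()[0]
                    seqs[name] = []
                elif name is not None:
                    seqs[name].append(line)
        return {k: "".join(v).upper() for k, v in seqs.items()}


# ---------------------------------------------------------------- CX report

def read_cx_report(path) -> pd.DataFrame:
    """Bismark-style cytosine report: chrom, pos, strand, count_meth,
    count_unmeth, context, trinucleotide (tab-separated, no header).

    Malformed rows raise :class:`FormatError` naming the first offending
    1-based line number.  An empty file yields an empty typed table.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str,
                         na_filter=False)
    except pd.errors.EmptyDataError:
        import warnings
        warnings.warn(f"empty CX report: {path}")
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            CX_COLUMNS, [str, np.int64, str, np.int64, np.int64, str, str])})
    if df.shape[1] != 7:
        raise FormatError(f"{path}: expected 7 tab-separated columns, found {df.shape[1]}")
    df.columns = CX_COLUMNS
    for col in ("pos", "count_meth", "count_unmeth"):
        converted = pd.to_numeric(df[col], errors="coerce")
        nonint = converted.isna() | (np.mod(converted.fillna(0.5), 1) != 0)
        if nonint.any():
            line = int(np.nonzero(nonint.to_numpy())[0][0]) + 1
            raise FormatError(f"{path}: non-integer {col} at line {line}")
        df[col] = converted.astype(np.int64)
    bad = ~df["strand"].isin(STRANDS)
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 1
        raise FormatError(f"{path}: unknown strand at line {line}")
    bad = ~df["context"].isin(CONTEXT_VOCAB)
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 1
        raise FormatError(f"{path}: unknown context {df['context'].iloc[int(np.nonzero(bad.to_numpy())[0][0])]!r} at line {line}")
    if (df["pos"] < 1).any() or (df[["count_meth", "count_unmeth"]] < 0).any().any():
        bad = (df["pos"] < 1) | (df["count_meth"] < 0) | (df["count_unmeth"] < 0)
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 1
        raise FormatError(f"{path}: negative count or position at line {line}")
    return df


def write_cx_report(path: str, sites: pd.DataFrame) -> None:
    sites.to_csv(path, sep="\t", header=False, index=False, columns=CX_COLUMNS)


# ---------------------------------------------------------------- annotations

def read_annotation(path, kind: str = "gff3", feature_kind: str | None = None) -> pd.DataFrame:
    """Gene/TE annotation into the unified 1-based inclusive feature table.

    GFF3 rows are taken as-is; BED (6 columns) start is converted (+1).
    A '.' strand is kept and downstream flank placement falls back to
    genomic left/right with a warning at use sites.
    """
    if kind == "gff3":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "source", "type", "start", "end",
                                "score", "strand", "phase", "attributes"],
                         dtype={"chrom": str})
        ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
        ids = ids.fillna(pd.Series([f"feat{i}" for i in range(len(df))], index=df.index))
        out = pd.DataFrame({
            "feature_id": ids, "chrom": df["chrom"],
            "start": df["start"].astype(np.int64), "end": df["end"].astype(np.int64),
            "strand": df["strand"],
            "kind": feature_kind if feature_kind else df["type"],
        })
    elif kind == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        ncol = df.shape[1]
        out = pd.DataFrame({
            "feature_id": df[3] if ncol > 3 else [f"feat{i}" for i in range(len(df))],
            "chrom": df[0],
            "start": df[1].astype(np.int64) + 1,
            "end": df[2].astype(np.int64),
            "strand": df[5] if ncol > 5 else ".",
            "kind": feature_kind if feature_kind else "feature",
        })
        if ncol > 6:
            out["abundance"] = df[6]
    else:
        raise ValueError(f"unknown annotation kind {kind!r}")
    if (out["end"] < out["start"]).any():
        bad = out.index[out["end"] < out["start"]][0]
        raise FormatError(f"{path}: end < start at record {bad + 1}")
    return out


def write_gff3(path: str, features: pd.DataFrame, source: str = "methdiv") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            fh.write(f"{row.chrom}\t{source}\t{row.kind}\t{row.start}\t{row.end}"
                     f"\t.\t{row.strand}\t.\tID={row.feature_id}\n")


def write_bed(path: str, intervals: pd.DataFrame, name_col: str | None = None,
              score_col: str | None = None, extra_cols: list[str] | None = None) -> None:
    """BED6(+N) export; internal 1-based inclusive -> 0-based half-open."""
    with open(path, "w") as fh:
        for i, row in enumerate(intervals.itertuples(index=False)):
            d = row._asdict()
            name = d[name_col] if name_col else f"iv{i}"
            score = d[score_col] if score_col else 0
            strand = d.get("strand", ".")
            line = [d["chrom"], str(int(d["start"]) - 1), str(int(d["end"])),
                    str(name), str(score), str(strand)]
            for c in extra_cols or []:
                line.append(str(d[c]))
            fh.write("\t".join(line) + "\n")


# ---------------------------------------------------------------- smRNA / expression

def read_smrna_bed(path) -> pd.DataFrame:
    """smRNA loci: BED6+1, column 7 = read abundance."""
    df = read_annotation(path, kind="bed", feature_kind="smrna")
    if "abundance" not in df.columns:
        raise FormatError(f"{path}: smRNA BED requires a 7th abundance column")
    df["abundance"] = df["abundance"].astype(np.int64)
    df["length"] = df["end"] - df["start"] + 1
    return df


def write_smrna_bed(path: str, loci: pd.DataFrame) -> None:
    write_bed(path, loci, name_col="feature_id" if "feature_id" in loci else None,
              extra_cols=["abundance"])


def read_expression(path) -> pd.DataFrame:
    """Long-format expression table: gene_id, sample, replicate, abundance."""
    df = read_table(path)
    need = {"gene_id", "sample", "replicate", "abundance"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: expression table needs columns {sorted(need)}")
    df["abundance"] = df["abundance"].astype(float)
    return df


# ---------------------------------------------------------------- generic TSV

def write_table(path: str, df: pd.DataFrame, comment: str | None = None,
                float_format: str = "%.6g") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def sha256_file(path: str) -> str:
    import hashlib
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
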