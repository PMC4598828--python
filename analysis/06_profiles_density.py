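"""Metagene/meta-TE methylation profiles and chromosome density tracks.

Builds the mC fraction profile over gene and TE bodies (1-kb flanks, 40
body bins), per-class body methylation levels, 50-kb density tracks for
mCs/genes/TEs, and their Spearman rank correlations; writes tables and SVG
plots to results/.
"""

import argparse
import os

from methdiv import io as mio
from methdiv import profiles as prof


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--results", default="results")
    ap.add_argument("--window", type=int, default=50_000)
    args = ap.parse_args()

    calls = mio.read_table(os.path.join(args.results, "calls_A.tsv"))
    calls = calls[calls["chrom"] != "control"]
    mcs = calls[calls["is_mc"]]
    genes = mio.read_annotation(os.path.join(args.cohort, "genes.gff3"),
                                feature_kind="gene")
    tes = mio.read_annotation(os.path.join(args.cohort, "tes.gff3"),
                              feature_kind="TE")
    seqs = mio.read_fasta(os.path.join(args.cohort, "genome.fa"))

    for name, feats in (("genes", genes), ("tes", tes)):
        res = prof.metagene_profile(mcs, feats)
        long = res.values.reset_index(names="bin").melt(
            id_vars="bin", var_name="track", value_name="value")
        mio.write_table(os.path.join(args.results, f"profile_{name}.tsv"), long)
        prof.plot_profile(res, os.path.join(args.results, f"profile_{name}.svg"),
                          title=f"mC fraction over {name}")
        print(f"{name} profile over {res.n_features_used} features "
              f"({res.n_features_skipped} skipped)")

    body = prof.feature_body_levels(calls, genes, tes)
    for cls in ("gene", "TE"):
        print(f"{cls} body weighted methylation: " + ", ".join(
            f"{ctx} {body[cls][ctx]['weighted_level']:.1f}%"
            for ctx in ("CG", "CHG", "CHH")))

    lengths = {k: len(v) for k, v in seqs.items() if k != "control"}
    dens = prof.chromosome_density({"mC": mcs, "gene": genes, "TE": tes},
                                   lengths, window=args.window)
    mio.write_table(os.path.join(args.results, "density.tsv"), dens)
    prof.plot_density(dens, "chr1", os.path.join(args.results, "density_chr1.svg"))
    corr = prof.density_correlation(dens)
    for (a, b), st in sorted(corr.items()):
        print(f"spearman({a}, {b}): rho {st['rho']:.3f} (P {st['p_value']:.3g})")


if __name__ == "__main__":
    main()
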