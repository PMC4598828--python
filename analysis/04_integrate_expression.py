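"""Couple DMRs to differential gene expression.

Calls differentially expressed genes (>=2-fold, P <= 0.05 on replicate
log2 abundances), contrasts log2 fold changes of hyper-/hypo-DMR-associated
genes against all genes (two-tailed Wilcoxon rank-sum), tests directional
enrichment (genic hyper DMR -> downregulation, hypo -> upregulation) by
Fisher's exact test, tabulates on/off expression switches, and compares TE
density across gene classes.
"""

import argparse
import json
import os

from methdiv import integrate as integ
from methdiv import io as mio


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--results", default="results")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    expr = mio.read_expression(os.path.join(args.cohort, "expression.tsv"))
    assoc = mio.read_table(os.path.join(args.results, "dmr_associations.tsv"))
    genes = mio.read_annotation(os.path.join(args.cohort, "genes.gff3"),
                                feature_kind="gene")
    tes = mio.read_annotation(os.path.join(args.cohort, "tes.gff3"),
                              feature_kind="TE")

    deg = integ.call_degs(expr)
    mio.write_table(os.path.join(args.results, "deg.tsv"), deg)
    n_up = (deg["de_status"] == "up").sum()
    n_down = (deg["de_status"] == "down").sum()
    print(f"DEGs: {n_up + n_down} of {len(deg)} genes "
          f"({n_up} up, {n_down} down in A vs B)")

    by_class = integ.compare_expression_by_methylation(deg, assoc)
    for cls in ("hyper", "hypo"):
        c = by_class[cls]
        print(f"{cls}-DMR genes (n={c['n']}): median log2fc {c['median']:.2f} "
              f"vs all genes {by_class['all']['median']:.2f} "
              f"(Wilcoxon P {c['p_vs_all']:.3g})")

    enr = integ.enrichment_direction(deg, assoc, placement="genic")
    for key, lab in (("hyper_down", "genic hyper -> down"),
                     ("hypo_up", "genic hypo -> up")):
        e = enr[key]
        print(f"{lab}: OR {e['odds_ratio']:.2f}, Fisher P {e['p_value']:.3g}")

    onoff = integ.classify_on_off(deg)
    print("on/off classes:", onoff["on_off_class"].value_counts().to_dict())

    classes = integ.gene_dmr_classes(assoc)
    deg_ids = set(deg.loc[deg["de_status"] != "not_de", "gene_id"])
    dmr_ids = set(classes["gene_id"])
    gene_classes = {
        "DEG": sorted(deg_ids),
        "DMR-DEG": sorted(deg_ids & dmr_ids),
        "non-DEG": sorted(set(genes["feature_id"]) - deg_ids),
    }
    te_dens = integ.te_density_by_gene_class(genes, tes, gene_classes,
                                             seed=args.seed)
    for name in ("non-DEG", "DEG", "DMR-DEG"):
        d = te_dens[name]
        print(f"TE density, {name}: {d['mean_tes_per_gene']:.2f} TEs/gene "
              f"(n={d['n']}, permutation P {d['p_value']:.3g})")

    out = {"deg_counts": {"up": int(n_up), "down": int(n_down)},
           "by_class": by_class, "enrichment_genic": enr,
           "te_density": {k: v for k, v in te_dens.items()}}
    with open(os.path.join(args.results, "expression_stats.json"), "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True, default=str)


if __name__ == "__main__":
    main()
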