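"""Relate small-RNA loci to methylation and differential methylation.

Computes the fraction of mCs inside smRNA loci (per context), the fraction
of loci containing a methylcytosine, and the smRNA density enrichment of
hyper- vs hypo-DMR-associated genes relative to all genes.
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
    args = ap.parse_args()

    loci = mio.read_smrna_bed(os.path.join(args.cohort, "smrna_A.bed"))
    calls = mio.read_table(os.path.join(args.results, "calls_A.tsv"))
    calls = calls[calls["chrom"] != "control"]
    genes = mio.read_annotation(os.path.join(args.cohort, "genes.gff3"),
                                feature_kind="gene")
    assoc = mio.read_table(os.path.join(args.results, "dmr_associations.tsv"))

    overlap = integ.smrna_mc_overlap(loci, calls)
    print(f"{len(loci):,} smRNA loci (21-24 nt)")
    print(f"loci containing >=1 mC: {100*overlap['fraction_loci_with_mc']:.1f}%")
    print("fraction of mCs inside loci: " + ", ".join(
        f"{k} {100*v:.2f}%" for k, v in overlap["fraction_mcs_in_loci"].items()))

    classes = integ.gene_dmr_classes(assoc)
    class_ids = {d: classes.loc[classes["dmr_class"] == d, "gene_id"].tolist()
                 for d in ("hyper", "hypo")}
    enr = integ.smrna_dmr_enrichment(loci, genes, class_ids)
    for d in ("hyper", "hypo"):
        e = enr[d]
        print(f"{d}-DMR genes: smRNA density {e['density_per_kb']:.2f}/kb, "
              f"fold {e['fold']:.2f} vs all genes "
              f"({enr['all_genes']['density_per_kb']:.2f}/kb), "
              f"Fisher P {e['p_value']:.3g}")

    with open(os.path.join(args.results, "smrna_stats.json"), "w") as fh:
        json.dump({"overlap": overlap, "enrichment": enr}, fh, indent=1,
                  sort_keys=True, default=str)


if __name__ == "__main__":
    main()
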