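"""Generate the default synthetic two-cultivar methylome cohort.

Writes the cohort inputs (genome FASTA, gene/TE GFF3, per-sample CX
reports, expression table, smRNA BED) plus the planted truth tables to
results/cohort/, and prints the headline cohort dimensions.
"""

import argparse

from methdiv.synth import SimulationConfig, generate_cohort, write_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/cohort")
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    cohort = generate_cohort(cfg)
    paths = write_cohort(cohort, args.out)

    print(f"cohort written to {args.out}")
    print(f"  genome: {cfg.n_chroms} x {cfg.chrom_length/1e6:.1f} Mb "
          f"+ {cfg.control_length/1e3:.0f} kb control contig")
    print(f"  cytosines (both strands): {len(cohort.site_truth):,}")
    print(f"  genes: {len(cohort.genome.genes)}, TEs: {len(cohort.genome.tes)}")
    print(f"  planted DMRs: {len(cohort.dmr_truth)} "
          f"({(cohort.dmr_truth['direction'] == 'hyper').sum()} hyper / "
          f"{(cohort.dmr_truth['direction'] == 'hypo').sum()} hypo, "
          f"delta {cfg.planted_delta:g} points)")
    print(f"  smRNA loci: A={len(cohort.smrna['A'])}, B={len(cohort.smrna['B'])}")
    for key in ("fasta", "cx_A", "cx_B", "dmr_truth"):
        print(f"  {key}: {paths[key]}")


if __name__ == "__main__":
    main()
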