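"""Top-level pipeline driver: simulate -> call-mc -> call-dmr -> associate ->
integrate-expr -> integrate-smrna -> profiles/density, with a run manifest.

All randomness flows from the single config seed, so two runs with the same
config produce byte-identical data outputs (the manifest's timestamps are
the only non-deterministic field; its config/input hashes are reproducible).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import dmr as dmr_mod
from . import integrate as integ
from . import io as mio
from . import methcall as mc
from . import profiles as prof
from . import synth

log = logging.getLogger("methdiv")


@dataclasses.dataclass
class PipelineConfig:
    """Flat, text-serialisable pipeline configuration."""

    outdir: str = "methdiv_out"
    seed: int = 0
    simulate: bool = True
    # externally supplied inputs (used when simulate is False)
    fasta: str | None = None
    cx_a: str | None = None
    cx_b: str | None = None
    genes: str | None = None
    tes: str | None = None
    expression: str | None = None
    smrna: str | None = None
    control_contig: str = synth.CONTROL_CONTIG
    # stage parameters
    alpha: float = 0.001
    min_depth: int = 5
    bin_size: int = 100
    min_mcs: int = 3
    min_diff: float = 20.0
    max_q: float = 0.01
    correction: str = "BH"
    context_mode: str = "combined"
    flank: int = 2000
    min_fold_change: float = 2.0
    max_p: float = 0.05
    on_threshold: float = 1.0
    off_threshold: float = 0.1
    profile_flank: int = 1000
    profile_flank_bin: int = 50
    body_bins: int = 40
    density_window: int = 100_000

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if v is not None:
                    fh.write(f"{f.name}={v}\n")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                k = k.strip()
                v = v.strip()
                if k not in types:
                    raise ValueError(f"unknown config key {k!r}")
                cur = getattr(defaults, k)
                if isinstance(cur, bool):
                    kwargs[k] = v.lower() in ("1", "true", "yes")
                elif isinstance(cur, int):
                    kwargs[k] = int(v)
                elif isinstance(cur, float):
                    kwargs[k] = float(v)
                else:
                    kwargs[k] = v
        return cls(**kwargs)


def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def run_pipeline(config: PipelineConfig,
                 sim_config: synth.SimulationConfig | None = None) -> dict:
    """Execute all stages; returns the run manifest (also written to disk).

    Any stage failure propagates with the stage name; prior outputs remain
    on disk.
    """
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "tool": "methdiv 0.1.0",
        "timestamps": {"start": time.strftime("%Y-%m-%dT%H:%M:%S")},
        "stages": {},
        "input_hashes": {},
    }
    cfg_text = "\n".join(f"{f.name}={getattr(config, f.name)}"
                         for f in dataclasses.fields(config))
    manifest["config_hash"] = _sha256_text(cfg_text)

    stage = "simulate"
    try:
        if config.simulate:
            sc = sim_config or synth.SimulationConfig(seed=config.seed)
            cohort = synth.generate_cohort(sc)
            paths = synth.write_cohort(cohort, config.outdir)
            genome_seqs = cohort.genome.sequences
            genes, tes = cohort.genome.genes, cohort.genome.tes
            cx = {s: cohort.counts[s] for s in ("A", "B")}
            expression = cohort.expression
            smrna = cohort.smrna["A"]
            manifest["stages"][stage] = {
                "n_sites": len(cohort.site_truth), "n_genes": len(genes),
                "n_tes": len(tes), "n_planted_dmrs": len(cohort.dmr_truth)}
            for k, v in paths.items():
                manifest["input_hashes"][k] = mio.sha256_file(v)
        else:
            for name, path in (("fasta", config.fasta), ("cx_a", config.cx_a),
                               ("cx_b", config.cx_b), ("genes", config.genes),
                               ("tes", config.tes)):
                if path is None or not os.path.exists(path):
                    raise FileNotFoundError(f"required input {name} missing: {path}")
                manifest["input_hashes"][name] = mio.sha256_file(path)
            genome_seqs = mio.read_fasta(config.fasta)
            genes = mio.read_annotation(config.genes, feature_kind="gene")
            tes = mio.read_annotation(config.tes, feature_kind="TE")
            cx = {"A": mio.read_cx_report(config.cx_a),
                  "B": mio.read_cx_report(config.cx_b)}
            expression = mio.read_expression(config.expression) \
                if config.expression else None
            smrna = mio.read_smrna_bed(config.smrna) if config.smrna else None
            manifest["stages"][stage] = {"skipped": True}
        chrom_lengths = {k: len(v) for k, v in genome_seqs.items()}

        stage = "call-mc"
        err = mc.estimate_error_rate(cx["A"], config.control_contig) \
            if (cx["A"]["chrom"] == config.control_contig).any() else 0.0005
        params = mc.CallParams(alpha=config.alpha, min_depth=config.min_depth,
                               error_rate=err)
        calls = {}
        for s in ("A", "B"):
            e = mc.estimate_error_rate(cx[s], config.control_contig) \
                if (cx[s]["chrom"] == config.control_contig).any() else err
            p = mc.CallParams(alpha=config.alpha, min_depth=config.min_depth,
                              error_rate=e)
            calls[s] = mc.call_methylcytosines(cx[s], p)
            mio.write_table(os.path.join(config.outdir, f"calls_{s}.tsv"),
                            calls[s].drop(columns=["tri"], errors="ignore"),
                            comment=f"methylation calls sample {s}, error_rate={e:.6g}")
            summ = mc.summarize_methylome(calls[s], min_depth=config.min_depth)
            with open(os.path.join(config.outdir, f"summary_{s}.json"), "w") as fh:
                json.dump(summ.to_dict(), fh, indent=1, sort_keys=True)
        manifest["stages"][stage] = {s: int(calls[s]["is_mc"].sum()) for s in calls}

        stage = "call-dmr"
        dparams = dmr_mod.DMRParams(
            bin_size=config.bin_size, min_site_depth=config.min_depth,
            min_mcs=config.min_mcs, min_diff=config.min_diff, max_q=config.max_q,
            correction=config.correction, context_mode=config.context_mode)
        main = {s: c[c["chrom"] != config.control_contig] for s, c in calls.items()}
        bins = dmr_mod.bin_genome(main["A"], main["B"], dparams)
        dmrs = dmr_mod.call_dmrs(bins, dparams)
        mio.write_table(os.path.join(config.outdir, "dmrs.tsv"), dmrs,
                        comment="DMRs (A vs B)")
        mio.write_bed(os.path.join(config.outdir, "dmrs.bed"),
                      dmr_mod.dmrs_to_bed(dmrs), name_col="direction",
                      score_col="score")
        manifest["stages"][stage] = {"n_bins_tested": len(bins), "n_dmrs": len(dmrs)}

        stage = "associate"
        assoc = dmr_mod.associate_dmrs(dmrs, genes, tes, flank=config.flank)
        mio.write_table(os.path.join(config.outdir, "dmr_associations.tsv"), assoc)
        manifest["stages"][stage] = {"n_associations": len(assoc)}

        stage = "integrate-expr"
        if expression is not None:
            eparams = integ.DEGParams(
                min_fold_change=config.min_fold_change, max_p=config.max_p,
                on_threshold=config.on_threshold, off_threshold=config.off_threshold)
            deg = integ.call_degs(expression, eparams)
            mio.write_table(os.path.join(config.outdir, "deg.tsv"), deg)
            expr_stats = {
                "by_class": integ.compare_expression_by_methylation(deg, assoc),
                "enrichment_genic": integ.enrichment_direction(deg, assoc, "genic"),
                "enrichment_flanking": integ.enrichment_direction(deg, assoc, "flanking"),
                "on_off_counts": integ.classify_on_off(deg, eparams)[
                    "on_off_class"].value_counts().to_dict(),
            }
            with open(os.path.join(config.outdir, "expression_stats.json"), "w") as fh:
                json.dump(expr_stats, fh, indent=1, sort_keys=True, default=str)
            manifest["stages"][stage] = {
                "n_genes": len(deg),
                "n_degs": int((deg["de_status"] != "not_de").sum())}
        else:
            manifest["stages"][stage] = {"skipped": True}
            deg = None

        stage = "integrate-smrna"
        if smrna is not None:
            classes = integ.gene_dmr_classes(assoc)
            class_ids = {d: classes.loc[classes["dmr_class"] == d, "gene_id"].tolist()
                         for d in ("hyper", "hypo")}
            class_ids = {k: v for k, v in class_ids.items() if v}
            sm_stats = {
                "overlap": integ.smrna_mc_overlap(smrna, main["A"]),
                "enrichment": integ.smrna_dmr_enrichment(smrna, genes, class_ids)
                if class_ids else {},
            }
            with open(os.path.join(config.outdir, "smrna_stats.json"), "w") as fh:
                json.dump(sm_stats, fh, indent=1, sort_keys=True, default=str)
            manifest["stages"][stage] = {"n_loci": len(smrna)}
        else:
            manifest["stages"][stage] = {"skipped": True}

        stage = "profiles"
        pparams = prof.ProfileParams(flank=config.profile_flank,
                                     flank_bin=config.profile_flank_bin,
                                     body_bins=config.body_bins)
        mcs_a = main["A"][main["A"]["is_mc"]]
        gene_prof = prof.metagene_profile(mcs_a, genes, pparams)
        long = gene_prof.values.reset_index(names="bin").melt(
            id_vars="bin", var_name="track", value_name="value")
        mio.write_table(os.path.join(config.outdir, "profile_genes.tsv"), long)
        items = {"mC": mcs_a, "gene": genes, "TE": tes}
        dens = prof.chromosome_density(
            items, {k: v for k, v in chrom_lengths.items()
                    if k != config.control_contig},
            window=config.density_window)
        mio.write_table(os.path.join(config.outdir, "density.tsv"), dens)
        manifest["stages"][stage] = {
            "profile_bins": len(gene_prof.positions),
            "density_rows": len(dens)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["timestamps"]["end"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    for name, info in manifest["stages"].items():
        log.info("stage %s: %s", name, info)
    return manifest
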