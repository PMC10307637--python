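"""End-to-end orchestration: config handling, the fixed stage order
(reproducibility -> quantification -> differential -> classification ->
super-enhancers -> genes/enrichment -> motifs), and bundle simulation.

Every threshold defaults to the decision rules of the underlying study
design (distal >3 kb, +/-500 bp H3K27ac windows, >16 normalized-tag activity
floor, FC >2 at p-adj <0.05, >10-fold signature rule, 4-bit motif matches,
r > 0.6 motif clustering, 2 TPM expression filter, 12.5 kb stitching), so a
bare config reproduces them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import expression as expr
from . import intervals as iv
from . import motifs as mo
from . import signal as sig
from . import simulate as sim

log = logging.getLogger("enhancerkit")

REQUIRED_THRESHOLDS = (
    "distal_bp", "k27_window", "tf_window", "activity_floor", "fc", "alpha",
    "expr_floor", "signature_fold", "pwm_threshold", "cluster_r", "tpm_filter",
    "stitch_bp",
)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    # inputs
    peaks_bed: str = "peaks.bed"
    genes_tsv: str = "genes.tsv"
    tf_peaks_bed: str = "tf_peaks.bed"
    h3k27ac_counts: str = "h3k27ac_counts.tsv"
    atac_counts: str = "atac_counts.tsv"
    expression_counts: str = "expression_counts.tsv"
    positive_fasta: str = "positive.fa"
    negative_fasta: str = "negative.fa"
    pwms_jaspar: str = "pwms.jaspar"
    se_peaks_bed: str = "se_peaks.bed"  # optional scored landscape for SE calling
    # thresholds (defaults are the study's printed decision rules)
    distal_bp: int = 3000
    k27_window: int = 1000
    tf_window: int = 500
    activity_floor: float = 16.0
    fc: float = 2.0
    alpha: float = 0.05
    expr_floor: float = 2.0
    signature_fold: float = 10.0
    pwm_threshold: float = 4.0
    cluster_r: float = 0.6
    tpm_filter: float = 2.0
    stitch_bp: int = 12500
    # run control
    seed: int = 1
    outdir: str = "results"
    input_dir: str = "."
    expr_contrast: tuple[str, str] = ("microglia_wt", "microglia_ko")
    focal_group: str = "microglia_wt"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        missing = [k for k in REQUIRED_THRESHOLDS if k not in raw]
        if missing:
            raise ValueError(f"config missing required threshold fields: {missing}")
        if "expr_contrast" in raw:
            raw["expr_contrast"] = tuple(raw["expr_contrast"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["expr_contrast"] = list(d["expr_contrast"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def input_path(self, name: str) -> Path:
        return Path(self.input_dir) / getattr(self, name)


def _groups_from_samples(sample_ids: list[str]) -> dict[str, str]:
    """Derive group labels from the ``<group>_repN`` sample-naming convention."""
    return {s: s.rsplit("_rep", 1)[0] for s in sample_ids}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in fixed order and write per-stage tables plus a
    consolidated summary into ``config.outdir``.

    Raises before any computation if a required input file is missing."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_used.yaml")
    required = [
        "peaks_bed", "genes_tsv", "tf_peaks_bed", "h3k27ac_counts",
        "expression_counts", "positive_fasta", "negative_fasta", "pwms_jaspar",
    ]
    missing = [n for n in required if not config.input_path(n).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing inputs: {[str(config.input_path(n)) for n in missing]}"
        )
    log.info("seed=%d outdir=%s", config.seed, outdir)
    summary: dict = {"seed": config.seed}

    # stage 1: load peaks and genes, distal filtering
    peaks = iv.read_bed(config.input_path("peaks_bed"), name="peaks")
    genes = iv.read_genes_tsv(config.input_path("genes_tsv"))
    tf_peaks = iv.read_bed(config.input_path("tf_peaks_bed"), name="tf")
    distal = iv.filter_distal(peaks, genes, config.distal_bp)
    log.info("stage=distal in=%d out=%d", len(peaks), len(distal))
    summary["n_peaks"] = len(peaks)
    summary["n_distal"] = len(distal)

    # stage 2: H3K27ac quantification (precomputed counts) + differential
    k27 = sig.CountMatrix.from_tsv(config.input_path("h3k27ac_counts"))
    conds = list(dict.fromkeys(k27.conditions.values()))
    diff = sig.nb_wald_test(k27, conds[0], conds[1],
                            fc_threshold=config.fc, alpha=config.alpha)
    sig.write_diff_results(diff, outdir / "h3k27ac_diff.tsv")
    log.info("stage=diff features=%d up=%d down=%d", len(diff),
             (diff["verdict"] == "up").sum(), (diff["verdict"] == "down").sum())

    # stage 3: active-enhancer selection and four-class taxonomy
    active = clf.select_active_enhancers(distal, k27, config.activity_floor)
    records = clf.classify_enhancers(
        active, diff, tf_peaks, h3k27ac=k27,
        cond_wt=conds[0], cond_ko=conds[1], genes=genes,
    )
    clf.write_enhancer_table(records, outdir / "enhancer_classes.tsv")
    class_counts = (
        clf.records_to_frame(records)["enh_class"].value_counts().to_dict()
    )
    summary["n_active"] = len(active)
    summary["class_counts"] = {c: int(class_counts.get(c, 0))
                               for c in clf.ENHANCER_CLASSES}
    log.info("stage=classify active=%d classes=%s", len(active),
             summary["class_counts"])

    # overlap summaries of differential enhancers vs TF binding
    rec_frame = clf.records_to_frame(records)
    for direction in ("up", "down"):
        sub = rec_frame[rec_frame["diff_verdict"] == direction]
        if len(sub):
            s = clf.overlap_summary(len(sub), int(sub["tf_bound"].sum()))
            summary[f"tf_overlap_pct_{direction}"] = s.percent
            summary[f"tf_overlap_counts_{direction}"] = [s.overlapping, s.total]

    # stage 4: super-enhancers, on the dedicated scored landscape when
    # provided, otherwise on the active peaks' WT H3K27ac signal
    if config.input_path("se_peaks_bed").exists():
        scored = iv.read_bed(config.input_path("se_peaks_bed"), name="se_landscape")
    else:
        cond_means = k27.condition_means()
        scored = iv.PeakSet(
            "k27_scored",
            [
                iv.Peak(p.interval, p.peak_id, p.summit,
                        float(cond_means.loc[p.peak_id, conds[0]]))
                for p in active
            ],
        )
    ses = clf.call_super_enhancers(scored, stitch_bp=config.stitch_bp)
    clf.write_superenhancer_table(ses, outdir / "super_enhancers.tsv")
    summary["n_stitched_regions"] = len(ses)
    summary["n_super_enhancers"] = int(sum(s.is_super for s in ses))
    log.info("stage=superenh regions=%d super=%d", len(ses),
             summary["n_super_enhancers"])

    # stage 5: expression — TPM, DEGs, signature, set overlap
    counts, lengths = expr.read_counts_tsv(config.input_path("expression_counts"))
    table = expr.compute_tpm(counts, lengths, _groups_from_samples(list(counts.columns)))
    g1, g2 = config.expr_contrast
    degs = expr.call_degs(table, g1, g2, fc=config.fc, alpha=config.alpha,
                          floor=config.expr_floor)
    sig.write_diff_results(degs, outdir / "expression_diff.tsv")
    up_genes = set(degs.index[degs["verdict"] == "up"])
    down_genes = set(degs.index[degs["verdict"] == "down"])
    all_groups = dict.fromkeys(table.groups.values())
    comparison_groups = [g for g in all_groups if g not in config.expr_contrast]
    signature = expr.define_signature(table, config.focal_group,
                                      other_groups=comparison_groups or None,
                                      fold=config.signature_fold)
    expr.write_gene_set(signature, outdir / "signature_genes.txt")
    universe = len(table.gene_ids)
    ov_down = expr.gene_set_overlap(signature,
                                    expr.GeneSet("down", down_genes), universe)
    ov_up = expr.gene_set_overlap(signature, expr.GeneSet("up", up_genes), universe)
    summary["n_deg_up"] = len(up_genes)
    summary["n_deg_down"] = len(down_genes)
    summary["n_signature"] = len(signature)
    summary["signature_down_overlap"] = ov_down.overlap
    summary["signature_down_fisher_p"] = ov_down.fisher_p
    summary["signature_up_overlap"] = ov_up.overlap
    summary["signature_up_fisher_p"] = ov_up.fisher_p
    log.info("stage=expression degs=%d/%d signature=%d", len(up_genes),
             len(down_genes), len(signature))

    # stage 6: class-to-gene report
    reports = clf.class_gene_report(records, up_genes, down_genes, universe)
    pd.DataFrame(
        [
            {
                "enh_class": r.enh_class, "n_genes": r.n_genes,
                "n_up": r.n_up, "n_down": r.n_down,
                "frac_up": r.frac_up, "frac_down": r.frac_down,
                "fisher_p_up": r.fisher_p_up, "fisher_p_down": r.fisher_p_down,
            }
            for r in reports
        ]
    ).to_csv(outdir / "class_gene_report.tsv", sep="\t", index=False)

    # stage 7: motif-mutation association
    pairs = mo.VariantPairSet.from_fastas(
        config.input_path("positive_fasta"), config.input_path("negative_fasta")
    )
    pwms = mo.read_jaspar(config.input_path("pwms_jaspar"))
    assoc, d_matrix = mo.motif_mutation_association(
        pairs, pwms, expression=table, focal_group=config.focal_group,
        tpm_filter=config.tpm_filter,
    )
    assoc = mo.cluster_motifs(assoc, d_matrix, r_threshold=config.cluster_r)
    mo.write_association_table(assoc, outdir / "motif_association.tsv")
    top = assoc.sort_values("p").index[0]
    summary["n_motifs_tested"] = len(assoc)
    summary["top_motif"] = str(top)
    summary["top_motif_signed_logp"] = float(assoc.loc[top, "signed_logp"])
    summary["n_motif_clusters"] = int(assoc["cluster_id"].nunique())
    log.info("stage=motifs n=%d top=%s", len(assoc), top)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    pd.Series(
        {k: json.dumps(v) if isinstance(v, (dict, list)) else v
         for k, v in summary.items()}
    ).rename_axis("key").rename("value").to_csv(outdir / "summary.tsv", sep="\t")
    return summary


PRESETS = {
    "tiny": dict(n_peaks=300, n_loci=40, n_decoys=8, n_signature=60, n_deg=80),
    "default": dict(n_peaks=2000, n_loci=100, n_decoys=20, n_signature=300,
                    n_deg=400),
}


def simulate_bundle(seed: int, outdir: str | Path, preset: str = "default") -> PipelineConfig:
    """Write a complete synthetic input bundle plus planted truth and a
    ready-to-run config into ``outdir``."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = sim.generate_enhancer_study(seed, n_peaks=p["n_peaks"])
    truth: sim.SyntheticTruth = bundle["truth"]
    iv.write_bed(bundle["peaks"], outdir / "peaks.bed")
    iv.write_genes_tsv(bundle["genes"], outdir / "genes.tsv")
    iv.write_bed(bundle["tf_peaks"], outdir / "tf_peaks.bed")
    bundle["h3k27ac"].to_tsv(outdir / "h3k27ac_counts.tsv")
    bundle["atac"].to_tsv(outdir / "atac_counts.tsv")

    se_peaks, se_truth = sim.generate_se_landscape(seed + 30)
    iv.write_bed(se_peaks, outdir / "se_peaks.bed")
    truth.super_enhancers = se_truth.super_enhancers

    # plant DEGs at the genes nearest to the planted activated/repressed
    # classes so class-gene enrichment is non-trivial
    nearest = iv.nearest_gene(bundle["peaks"], bundle["genes"])
    down_ids = sorted(
        {nearest[pid].gene_id for pid, c in truth.peak_class.items()
         if c.endswith("activated")} - {iv.UNASSIGNED}
    )
    up_ids = sorted(
        {nearest[pid].gene_id for pid, c in truth.peak_class.items()
         if c.endswith("repressed")} - {iv.UNASSIGNED}
    )
    gene_ids = [g.gene_id for g in bundle["genes"]]
    table, etruth = sim.generate_expression(
        seed + 10,
        n_genes=len(gene_ids),
        n_signature=min(p["n_signature"], len(gene_ids) - len(up_ids) - len(down_ids)),
        gene_ids=gene_ids,
        deg_up_ids=up_ids,
        deg_down_ids=down_ids,
    )
    expr.write_counts_tsv(table, outdir / "expression_counts.tsv")

    pairs, mtruth, causal, decoys = sim.generate_strain_pairs(
        seed + 20, n_loci=p["n_loci"],
        decoy_pwms=sim.random_pwms(seed + 21, p["n_decoys"]),
    )
    pairs.to_fastas(outdir / "positive.fa", outdir / "negative.fa")
    mo.write_jaspar([causal] + list(decoys), outdir / "pwms.jaspar")

    truth.deg_up = etruth.deg_up
    truth.deg_down = etruth.deg_down
    truth.signature_genes = etruth.signature_genes
    truth.causal_motif = mtruth.causal_motif
    truth.mutated_loci = mtruth.mutated_loci
    truth.to_json(outdir / "truth.json")

    config = PipelineConfig(seed=seed, input_dir=str(outdir),
                            outdir=str(outdir / "results"))
    config.to_yaml(outdir / "config.yaml")
    return config
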