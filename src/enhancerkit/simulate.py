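"""Seeded synthetic-data generators with planted ground truth.

Every generator is a pure function of (seed, parameters): the same seed
reproduces the same data bit for bit. The generators emulate the structure of
a TF-knockout regulatory study — replicated peak calls with summit jitter,
negative-binomial tag counts with planted fold changes, TF-occupancy patterns
defining four enhancer classes, a ranked enhancer landscape with planted
super-enhancers, expression tables with planted signature genes and DEGs, and
strain sequence pairs carrying motif-disrupting variants — without claiming
fragment-level or sequence-composition realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .intervals import GeneAnnotation, GenomicInterval, Peak, PeakSet
from .motifs import BASES, PWM, VariantPairSet
from .repro import ReplicatePeakCalls
from .signal import CountMatrix, NORM_SCALE

CHIP_DISPERSION = 0.05
RNA_DISPERSION = 0.1


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated bundle."""

    seed: int
    peak_class: dict[str, str] = field(default_factory=dict)
    planted_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    active_peaks: list[str] = field(default_factory=list)
    tf_bound_peaks: list[str] = field(default_factory=list)
    distal_peaks: list[str] = field(default_factory=list)
    deg_up: list[str] = field(default_factory=list)
    deg_down: list[str] = field(default_factory=list)
    signature_genes: list[str] = field(default_factory=list)
    causal_motif: str | None = None
    mutated_loci: list[str] = field(default_factory=list)
    super_enhancers: list[list[str]] = field(default_factory=list)
    strain_specific: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _nb(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with mean mu and Var = mu + dispersion * mu^2 (Poisson at 0)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    return rng.poisson(rng.gamma(size, mu / size))


# ---------------------------------------------------------------------------
# Peak universe
# ---------------------------------------------------------------------------


def generate_peak_universe(
    seed: int,
    n_peaks: int = 2000,
    genome_size: int = 10_000_000,
    n_chroms: int = 2,
    distal_fraction: float = 0.8,
    peak_width: int = 200,
    tss_distance: int = 3000,
) -> tuple[PeakSet, list[GeneAnnotation]]:
    """Non-overlapping peaks on a regular grid plus one gene per peak.

    Exactly ``round(distal_fraction * n_peaks)`` peaks get their nearest TSS
    placed beyond ``tss_distance`` of the summit (the rest within it), so the
    distal count after filtering is deterministic."""
    rng = np.random.default_rng(seed)
    if n_peaks == 0:
        return PeakSet("universe", []), []
    per_chrom = int(np.ceil(n_peaks / n_chroms))
    spacing = genome_size // (per_chrom + 1)
    max_offset = tss_distance + 1500
    if spacing < 2 * max_offset + peak_width:
        raise ValueError("peaks cannot be packed without distance interference")
    n_distal = int(round(distal_fraction * n_peaks))
    is_distal = np.zeros(n_peaks, dtype=bool)
    is_distal[rng.permutation(n_peaks)[:n_distal]] = True
    peaks, genes = [], []
    for i in range(n_peaks):
        chrom = f"chr{i // per_chrom + 1}"
        center = spacing * (i % per_chrom + 1)
        start = center - peak_width // 2
        summit = center + int(rng.integers(-peak_width // 4, peak_width // 4 + 1))
        pid = f"peak_{i:05d}"
        peaks.append(
            Peak(GenomicInterval(chrom, start, start + peak_width), pid, summit)
        )
        if is_distal[i]:
            offset = int(rng.integers(tss_distance + 500, tss_distance + 1500))
        else:
            offset = int(rng.integers(200, tss_distance - 500))
        sign = -1 if rng.random() < 0.5 else 1
        tss = summit + sign * offset
        genes.append(
            GeneAnnotation(
                gene_id=f"gene_{i:05d}",
                symbol=f"Gene{i:05d}",
                tss=GenomicInterval(chrom, tss, tss + 1),
                length=int(rng.integers(500, 3000)),
            )
        )
    return PeakSet("universe", peaks), genes


# ---------------------------------------------------------------------------
# NB count matrices with planted fold changes
# ---------------------------------------------------------------------------


def generate_counts(
    seed: int,
    feature_ids: Sequence[str],
    base_mean: np.ndarray | float,
    log2fc: np.ndarray | float = 0.0,
    n_reps: int = 2,
    dispersion: float = CHIP_DISPERSION,
    conditions: tuple[str, str] = ("wt", "ko"),
    lib_size_sigma: float = 0.15,
    window: int = 1000,
) -> CountMatrix:
    """NB counts for two conditions with planted per-feature log2 fold change.

    ``base_mean`` is the expected normalized signal (tags per 10^7) in the
    first condition; fold changes apply to the second. Library sizes are
    log-normal around 10^7 so raw counts differ from normalized ones."""
    rng = np.random.default_rng(seed)
    n = len(feature_ids)
    base = np.broadcast_to(np.asarray(base_mean, dtype=float), (n,))
    lfc = np.broadcast_to(np.asarray(log2fc, dtype=float), (n,))
    data, cond_map, totals = {}, {}, {}
    for ci, cond in enumerate(conditions):
        mu_cond = base * (2.0**lfc if ci == 1 else 1.0)
        for r in range(n_reps):
            lib = float(np.exp(rng.normal(np.log(NORM_SCALE), lib_size_sigma)))
            sid = f"{cond}_rep{r + 1}"
            counts = _nb(rng, mu_cond * lib / NORM_SCALE, dispersion)
            data[sid] = counts.astype(np.int64)
            cond_map[sid] = cond
            totals[sid] = int(round(lib))
    return CountMatrix(
        pd.DataFrame(data, index=list(feature_ids)), cond_map, totals, window=window
    )


# ---------------------------------------------------------------------------
# Full enhancer study with planted four-class truth
# ---------------------------------------------------------------------------

CLASS_LFC = {
    "direct_activated": -2.0,  # bound, loses H3K27ac on knockout
    "direct_repressed": 2.0,  # bound, gains H3K27ac
    "indirect_activated": -2.0,
    "indirect_repressed": 2.0,
    "unclassified": 0.0,
}


def generate_enhancer_study(
    seed: int,
    n_peaks: int = 2000,
    distal_fraction: float = 0.8,
    active_fraction: float = 0.85,
    class_fraction: float = 0.12,
    n_reps: int = 2,
    effect_log2fc: float = 2.0,
    dispersion: float = CHIP_DISPERSION,
    active_mean: float = 120.0,
    inactive_mean: float = 3.0,
) -> dict:
    """Generate the full classification-stage bundle with planted truth.

    Among distal active peaks, each of the four classes receives
    ``class_fraction`` of peaks (the rest are unchanged); direct classes and
    half of the unchanged peaks carry a TF peak at their summit. Returns a
    dict with peaks, genes, tf_peaks, h3k27ac and atac count matrices, and
    the SyntheticTruth."""
    rng = np.random.default_rng(seed)
    peaks, genes = generate_peak_universe(
        seed + 1, n_peaks=n_peaks, distal_fraction=distal_fraction
    )
    truth = SyntheticTruth(seed=seed)
    from .intervals import filter_distal

    distal = filter_distal(peaks, genes)
    truth.distal_peaks = distal.peak_ids

    distal_ids = np.array(distal.peak_ids)
    rng.shuffle(distal_ids)
    n_active = int(round(active_fraction * distal_ids.size))
    active_ids = distal_ids[:n_active]
    truth.active_peaks = sorted(active_ids)
    n_class = int(round(class_fraction * n_active))
    classes = ("direct_activated", "direct_repressed",
               "indirect_activated", "indirect_repressed")
    assign: dict[str, str] = {}
    pos = 0
    for cls in classes:
        for pid in active_ids[pos : pos + n_class]:
            assign[pid] = cls
        pos += n_class
    for pid in active_ids[pos:]:
        assign[pid] = "unclassified"
    truth.peak_class = dict(sorted(assign.items()))

    # TF occupancy: direct classes bound; also half of the unchanged actives
    bound = {pid for pid, cls in assign.items() if cls.startswith("direct")}
    unchanged = [pid for pid, cls in assign.items() if cls == "unclassified"]
    bound.update(unchanged[: len(unchanged) // 2])
    truth.tf_bound_peaks = sorted(bound)
    tf_peaks = PeakSet(
        "tf",
        [
            Peak(p.interval, f"tf_{p.peak_id}", p.summit, 100.0)
            for p in peaks
            if p.peak_id in bound
        ],
    )

    # H3K27ac counts across the whole universe; activity floor separates
    # active from inactive peaks, planted lfc drives the verdicts
    base = np.empty(len(peaks))
    lfc = np.zeros(len(peaks))
    active_set = set(active_ids)
    for i, p in enumerate(peaks):
        if p.peak_id in active_set:
            base[i] = float(np.exp(rng.normal(np.log(active_mean), 0.35)))
            sign = np.sign(CLASS_LFC[assign[p.peak_id]])
            lfc[i] = sign * effect_log2fc
        else:
            base[i] = float(np.exp(rng.normal(np.log(inactive_mean), 0.3)))
            lfc[i] = 0.0
    truth.planted_log2fc["h3k27ac"] = {
        p.peak_id: float(lfc[i]) for i, p in enumerate(peaks)
    }
    h3k27ac = generate_counts(
        seed + 2, peaks.peak_ids, base, lfc, n_reps=n_reps,
        dispersion=dispersion, window=1000,
    )
    atac = generate_counts(
        seed + 3, peaks.peak_ids, np.maximum(base, 20.0), lfc * 0.5,
        n_reps=max(n_reps, 2), dispersion=dispersion, window=1000,
    )
    return {
        "peaks": peaks,
        "genes": genes,
        "tf_peaks": tf_peaks,
        "h3k27ac": h3k27ac,
        "atac": atac,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# Replicated peak calls with summit jitter (reproducibility stage)
# ---------------------------------------------------------------------------


def generate_replicate_calls(
    seed: int,
    condition: str = "wt",
    n_loci: int = 300,
    n_reps: int = 2,
    reproducible_fraction: float = 0.8,
    summit_jitter: int = 30,
    peak_width: int = 200,
    spacing: int = 5000,
    chrom: str = "chr1",
) -> tuple[ReplicatePeakCalls, list[str]]:
    """Replicate peak sets where a planted fraction of loci appears (with
    summit jitter) in every replicate and the rest in exactly one.

    Returns the calls plus the list of reproducible locus names."""
    rng = np.random.default_rng(seed)
    n_repro = int(round(reproducible_fraction * n_loci))
    reproducible = []
    rep_peaks: list[list[Peak]] = [[] for _ in range(n_reps)]
    for i in range(n_loci):
        center = spacing * (i + 1)
        locus = f"{condition}_locus_{i:04d}"
        score = float(np.exp(rng.normal(np.log(50), 0.5)))
        if i < n_repro:
            reproducible.append(locus)
            for r in range(n_reps):
                jit = int(rng.integers(-summit_jitter, summit_jitter + 1))
                summit = center + jit
                rep_peaks[r].append(
                    Peak(
                        GenomicInterval(chrom, summit - peak_width // 2,
                                        summit + peak_width // 2),
                        f"{locus}_r{r}",
                        summit,
                        score * float(np.exp(rng.normal(0, 0.1))),
                    )
                )
        else:
            r = int(rng.integers(0, n_reps))
            rep_peaks[r].append(
                Peak(
                    GenomicInterval(chrom, center - peak_width // 2,
                                    center + peak_width // 2),
                    f"{locus}_r{r}",
                    center,
                    score,
                )
            )
    calls = ReplicatePeakCalls(
        condition,
        [PeakSet(f"{condition}_rep{r + 1}", ps) for r, ps in enumerate(rep_peaks)],
    )
    return calls, reproducible


def generate_strain_study(
    seed: int,
    n_shared: int = 200,
    n_specific: int = 50,
    n_reps: int = 2,
    summit_jitter: int = 20,
    spacing: int = 6000,
) -> dict:
    """Two strains sharing ``n_shared`` loci plus ``n_specific`` planted
    strain-specific loci each; all loci reproducible within their strain."""
    rng = np.random.default_rng(seed)
    width = 200
    total = n_shared + 2 * n_specific
    owners = (["both"] * n_shared + ["a"] * n_specific + ["b"] * n_specific)
    centers = [spacing * (i + 1) for i in range(total)]
    truth_a, truth_b = [], []

    def build(strain: str) -> ReplicatePeakCalls:
        rep_peaks: list[list[Peak]] = [[] for _ in range(n_reps)]
        for i, (owner, center) in enumerate(zip(owners, centers)):
            if owner not in ("both", strain):
                continue
            locus = f"locus_{i:04d}"
            score = float(np.exp(rng.normal(np.log(50), 0.4)))
            for r in range(n_reps):
                jit = int(rng.integers(-summit_jitter, summit_jitter + 1))
                summit = center + jit
                rep_peaks[r].append(
                    Peak(
                        GenomicInterval("chr1", summit - width // 2, summit + width // 2),
                        f"{strain}_{locus}_r{r}",
                        summit,
                        score,
                    )
                )
        return ReplicatePeakCalls(
            strain,
            [PeakSet(f"{strain}_rep{r + 1}", ps) for r, ps in enumerate(rep_peaks)],
        )

    calls_a = build("a")
    calls_b = build("b")
    truth_a = [f"locus_{i:04d}" for i, o in enumerate(owners) if o == "a"]
    truth_b = [f"locus_{i:04d}" for i, o in enumerate(owners) if o == "b"]
    centers_by_locus = {f"locus_{i:04d}": c for i, c in enumerate(centers)}
    truth = SyntheticTruth(seed=seed, strain_specific={"a": truth_a, "b": truth_b})
    return {
        "calls_a": calls_a,
        "calls_b": calls_b,
        "truth": truth,
        "locus_centers": centers_by_locus,
    }


# ---------------------------------------------------------------------------
# Super-enhancer landscape
# ---------------------------------------------------------------------------


def generate_se_landscape(
    seed: int,
    n_typical: int = 200,
    n_super: int = 5,
    constituents_per_super: int = 4,
    typical_mean: float = 10.0,
    super_constituent_mean: float = 250.0,
    stitch_gap: int = 8000,
    region_spacing: int = 50_000,
) -> tuple[PeakSet, SyntheticTruth]:
    """A scored enhancer landscape with planted super-enhancer clusters.

    Typical enhancers are isolated low-signal peaks; each planted
    super-enhancer is a cluster of high-signal constituents within stitching
    distance of each other but far from everything else."""
    rng = np.random.default_rng(seed)
    peaks = []
    truth = SyntheticTruth(seed=seed)
    pos = region_spacing
    for i in range(n_typical):
        # bounded typical signal: keeps a clean elbow below the planted SEs
        score = float(rng.uniform(1.0, 5.0 * typical_mean))
        peaks.append(
            Peak(GenomicInterval("chr1", pos, pos + 500), f"typ_{i:04d}",
                 pos + 250, score)
        )
        pos += region_spacing
    for s in range(n_super):
        members = []
        for c in range(constituents_per_super):
            score = float(np.exp(rng.normal(np.log(super_constituent_mean), 0.2)))
            pid = f"se{s}_{c}"
            peaks.append(
                Peak(GenomicInterval("chr1", pos, pos + 1000), pid, pos + 500, score)
            )
            members.append(pid)
            pos += 1000 + stitch_gap
        truth.super_enhancers.append(members)
        pos += region_spacing
    return PeakSet("se_landscape", peaks), truth


# ---------------------------------------------------------------------------
# Expression with planted signature genes and DEGs
# ---------------------------------------------------------------------------


def generate_expression(
    seed: int,
    n_genes: int = 5000,
    n_signature: int = 300,
    n_deg: int = 400,
    signature_fold: float = 50.0,
    deg_log2fc: float = 2.0,
    dispersion: float = RNA_DISPERSION,
    focal_groups: tuple[str, str] = ("microglia_wt", "microglia_ko"),
    n_other_groups: int = 7,
    n_reps_focal: int = 3,
    n_reps_other: int = 2,
    gene_ids: Sequence[str] | None = None,
    mean_count: float = 200.0,
    deg_up_ids: Sequence[str] | None = None,
    deg_down_ids: Sequence[str] | None = None,
) -> tuple[ExpressionTable, SyntheticTruth]:
    """NB expression table with planted cell-type signature genes and DEGs.

    Signature genes are elevated ``signature_fold``-fold in both focal
    (microglia) groups relative to the comparison cell types; DEGs change
    ``deg_log2fc`` between the two focal conditions (half up, half down).
    Signature and DEG gene sets are disjoint."""
    explicit_degs = deg_up_ids is not None or deg_down_ids is not None
    n_deg_eff = (
        len(deg_up_ids or []) + len(deg_down_ids or []) if explicit_degs else n_deg
    )
    if n_signature + n_deg_eff > n_genes:
        raise ValueError("n_signature + n_deg must not exceed n_genes")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    else:
        gene_ids = list(gene_ids)[:n_genes]
        if len(gene_ids) < n_genes:
            gene_ids += [f"gene_x{i:05d}" for i in range(n_genes - len(gene_ids))]
    lengths = pd.Series(rng.integers(500, 3000, size=n_genes).astype(float),
                        index=gene_ids)
    id_to_idx = {g: i for i, g in enumerate(gene_ids)}
    if explicit_degs:
        up_idx = np.array([id_to_idx[g] for g in (deg_up_ids or []) if g in id_to_idx],
                          dtype=int)
        down_idx = np.array([id_to_idx[g] for g in (deg_down_ids or []) if g in id_to_idx],
                            dtype=int)
        taken = set(up_idx) | set(down_idx)
        free = np.array([i for i in rng.permutation(n_genes) if i not in taken])
        sig_idx = free[:n_signature]
    else:
        order = rng.permutation(n_genes)
        sig_idx = order[:n_signature]
        deg_idx = order[n_signature : n_signature + n_deg]
        up_idx = deg_idx[: n_deg // 2]
        down_idx = deg_idx[n_deg // 2 :]

    base = np.exp(rng.normal(np.log(mean_count), 0.8, size=n_genes))
    # signature genes sit at a low baseline outside the focal cell type
    # (marker-gene regime), keeping the library-composition shift small so
    # the planted fold survives TPM renormalization
    base[sig_idx] *= 0.02
    groups = list(focal_groups) + [f"mac{i + 1}" for i in range(n_other_groups)]
    data: dict[str, np.ndarray] = {}
    group_map: dict[str, str] = {}
    for g in groups:
        mult = np.ones(n_genes)
        if g in focal_groups:
            mult[sig_idx] *= signature_fold
            if g == focal_groups[1]:
                mult[up_idx] *= 2.0**deg_log2fc
                mult[down_idx] /= 2.0**deg_log2fc
        n_reps = n_reps_focal if g in focal_groups else n_reps_other
        for r in range(n_reps):
            lib_scale = float(np.exp(rng.normal(0, 0.1)))
            sid = f"{g}_rep{r + 1}"
            data[sid] = _nb(rng, base * mult * lib_scale, dispersion).astype(np.int64)
            group_map[sid] = g
    counts = pd.DataFrame(data, index=gene_ids)
    table = ExpressionTable(counts, lengths, group_map)
    truth = SyntheticTruth(
        seed=seed,
        signature_genes=sorted(np.array(gene_ids)[sig_idx]),
        deg_up=sorted(np.array(gene_ids)[up_idx]),
        deg_down=sorted(np.array(gene_ids)[down_idx]),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Strain sequence pairs with motif-disrupting variants
# ---------------------------------------------------------------------------


def consensus_pwm(name: str, consensus: str, p_match: float = 0.97) -> PWM:
    """PWM concentrated on a consensus sequence."""
    L = len(consensus)
    probs = np.full((L, 4), (1.0 - p_match) / 3.0)
    for i, b in enumerate(consensus.upper()):
        probs[i, BASES.index(b)] = p_match
    return PWM(name, probs)


def random_pwms(seed: int, n: int, length: int = 10, prefix: str = "decoy") -> list[PWM]:
    """Random informative PWMs (consensus-style with random consensus)."""
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n):
        consensus = "".join(rng.choice(list(BASES), size=length))
        pwms.append(consensus_pwm(f"{prefix}_{i:02d}", consensus))
    return pwms


def generate_strain_pairs(
    seed: int,
    n_loci: int = 100,
    causal_pwm: PWM | None = None,
    decoy_pwms: Sequence[PWM] | None = None,
    mutation_rate: float = 0.8,
    seq_len: int = 100,
    background_snp_rate: float = 0.02,
    n_disrupt: int = 3,
) -> tuple[VariantPairSet, SyntheticTruth, PWM, list[PWM]]:
    """Homologous positive/negative sequence pairs with planted causal-motif
    mutations.

    The positive (bound-strain) sequence at every locus carries the causal
    consensus; the negative homolog differs by background SNPs and, with
    probability ``mutation_rate``, by substitutions at the causal motif's
    most informative positions. Decoy motifs are planted identically in both
    sequences (uncorrelated with the bound/unbound labels)."""
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if causal_pwm is None:
        causal_pwm = consensus_pwm("causal", "TGACGTCAAT")
    if decoy_pwms is None:
        decoy_pwms = random_pwms(seed + 1, 20)
    causal_cons = "".join(BASES[i] for i in causal_pwm.probs.argmax(axis=1))
    L = len(causal_cons)
    loci = []
    truth = SyntheticTruth(seed=seed, causal_motif=causal_pwm.name)
    for i in range(n_loci):
        lid = f"locus_{i:04d}"
        seq = rng.choice(list(BASES), size=seq_len)
        start = int(rng.integers(5, seq_len - L - 5))
        seq[start : start + L] = list(causal_cons)
        # plant one random decoy consensus identically in both homologs
        decoy = decoy_pwms[int(rng.integers(len(decoy_pwms)))]
        d_cons = "".join(BASES[j] for j in decoy.probs.argmax(axis=1))
        d_start = int(rng.integers(5, seq_len - len(d_cons) - 5))
        if not (start - len(d_cons) < d_start < start + L):
            seq[d_start : d_start + len(d_cons)] = list(d_cons)
        positive = "".join(seq)
        neg = seq.copy()
        snps = rng.random(seq_len) < background_snp_rate
        for j in np.nonzero(snps)[0]:
            if start <= j < start + L:
                continue  # background SNPs stay off the causal site
            neg[j] = rng.choice([b for b in BASES if b != neg[j]])
        mutated = bool(rng.random() < mutation_rate)
        if mutated:
            truth.mutated_loci.append(lid)
            info = causal_pwm.probs.max(axis=1)
            targets = np.argsort(-info)[:n_disrupt]
            for j in targets:
                neg[start + j] = rng.choice([b for b in BASES if b != causal_cons[j]])
        loci.append((lid, positive, "".join(neg)))
    return VariantPairSet(loci), truth, causal_pwm, list(decoy_pwms)
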