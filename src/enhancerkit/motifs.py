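"""PWM scoring and scanning, known-motif enrichment with GC-matched
background, cross-species conserved-motif mapping through pairwise
alignments, and motif-mutation association across strain sequence pairs.

Scores are log2-odds in bits against a background base composition, so the
match threshold of 4 bits corresponds to a sequence 2^4 = 16-fold more likely
under the motif model than under background. The mutation association is a
paired design: per locus, the best motif score in the bound-strain (positive)
sequence minus the best score in the unbound-strain (negative) homolog, with
a Wilcoxon signed-rank test over loci per motif.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .expression import ExpressionTable
from .stats import bh_adjust, binom_upper_tail, wilcoxon_signed_rank

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)  # anything unrecognized scores as N
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

DEFAULT_MATCH_THRESHOLD = 4.0  # bits: 16-fold likelihood ratio
DEFAULT_PSEUDOCOUNT = 0.001
MIN_INFORMATIVE_LOCI = 6


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


@dataclass
class PWM:
    """Position weight matrix with probabilities per column and a background.

    ``probs`` has shape (L, 4) in A,C,G,T order; a pseudocount is mixed into
    each cell (then renormalized) before taking log-odds so no cell is zero.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must have shape (L, 4)")
        if self.probs.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM column must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        p = self.probs + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):  # -inf allowed at pseudocount 0
            lo = np.log2(p / self.background)
        # column 4 = N: contributes 0 bits (background-equivalent evidence)
        self._log_odds = np.hstack([lo, np.zeros((lo.shape[0], 1))])
        rc = lo[::-1, ::-1]
        self._log_odds_rc = np.hstack([rc, np.zeros((rc.shape[0], 1))])

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 4) log2-odds matrix (pseudocounted)."""
        return self._log_odds[:, :4].copy()

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.probs[::-1, ::-1], self.background[::-1],
                   self.pseudocount)


@dataclass(frozen=True)
class MotifMatch:
    pwm_name: str
    start: int  # 0-based, half-open [start, start + L)
    end: int
    strand: str
    score: float


def pwm_score(pwm: PWM, window: str) -> float:
    """Log2-odds score of one window (forward strand); N bases contribute 0."""
    codes = encode(window)
    if codes.size != len(pwm):
        raise ValueError(f"window length {codes.size} != motif length {len(pwm)}")
    return float(pwm._log_odds[np.arange(len(pwm)), codes].sum())


def _window_scores(pwm: PWM, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every window on the forward and reverse strands."""
    L = len(pwm)
    if codes.size < L:
        empty = np.empty(0)
        return empty, empty
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    idx = np.arange(L)
    fwd = pwm._log_odds[idx, win].sum(axis=1)
    rev = pwm._log_odds_rc[idx, win].sum(axis=1)
    return fwd, rev


def scan_sequence(
    pwm: PWM, seq: str, threshold: float = DEFAULT_MATCH_THRESHOLD
) -> list[MotifMatch]:
    """All windows on both strands scoring strictly above ``threshold``.

    Overlapping matches are all reported; a sequence shorter than the motif
    yields an empty list."""
    codes = encode(seq)
    fwd, rev = _window_scores(pwm, codes)
    L = len(pwm)
    matches = [
        MotifMatch(pwm.name, int(i), int(i) + L, "+", float(s))
        for i, s in zip(np.nonzero(fwd > threshold)[0], fwd[fwd > threshold])
    ]
    matches += [
        MotifMatch(pwm.name, int(i), int(i) + L, "-", float(s))
        for i, s in zip(np.nonzero(rev > threshold)[0], rev[rev > threshold])
    ]
    return sorted(matches, key=lambda m: (m.start, m.strand))


def best_score(pwm: PWM, seq: str) -> float:
    """Maximum log2-odds score over all windows and both strands."""
    fwd, rev = _window_scores(pwm, encode(seq))
    if fwd.size == 0:
        return float("-inf")
    return float(max(fwd.max(), rev.max()))


# ---------------------------------------------------------------------------
# JASPAR I/O
# ---------------------------------------------------------------------------


def read_jaspar(path: str | Path, background: np.ndarray | None = None) -> list[PWM]:
    """Read a JASPAR-format PWM library into a list of PWMs."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    pwms = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float).T
        col_sums = counts.sum(axis=1, keepdims=True)
        if (col_sums <= 0).any():
            raise ValueError(f"motif {m.name}: column with zero total count")
        kwargs = {} if background is None else {"background": background}
        pwms.append(PWM(m.name or m.matrix_id, counts / col_sums, **kwargs))
    return pwms


def write_jaspar(pwms: Sequence[PWM], path: str | Path, scale: int = 100) -> None:
    """Write PWMs as JASPAR count matrices (probabilities x ``scale``)."""
    with open(path, "w") as fh:
        for i, pwm in enumerate(pwms, start=1):
            fh.write(f">MA{i:04d}.1\t{pwm.name}\n")
            counts = pwm.probs * scale
            for bi, base in enumerate(BASES):
                vals = " ".join(f"{v:.2f}" for v in counts[:, bi])
                fh.write(f"{base}  [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Motif enrichment with GC-matched background
# ---------------------------------------------------------------------------


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    codes = encode(seq)
    return float(((codes == 1) | (codes == 2)).mean())


def _gc_matched_sample(
    targets: Sequence[str], background: Sequence[str], rng: np.random.Generator
) -> list[str]:
    """Sample background sequences so their GC profile matches the targets'.

    Target GC values are binned into deciles; the background is resampled
    (with replacement within a bin when short) proportionally to the target
    bin occupancy, preserving the background sample size."""
    t_gc = np.array([gc_fraction(s) for s in targets])
    b_gc = np.array([gc_fraction(s) for s in background])
    edges = np.quantile(t_gc, np.linspace(0, 1, 11))
    edges[0], edges[-1] = -np.inf, np.inf
    t_bins = np.clip(np.searchsorted(edges, t_gc, side="right") - 1, 0, 9)
    b_bins = np.clip(np.searchsorted(edges, b_gc, side="right") - 1, 0, 9)
    n_out = len(background)
    chosen: list[str] = []
    for bin_i in range(10):
        want = int(round(n_out * (t_bins == bin_i).mean()))
        pool = np.nonzero(b_bins == bin_i)[0]
        if want == 0:
            continue
        if pool.size == 0:
            # no background in this GC bin: fall back to nearest-GC sequences
            center = t_gc[t_bins == bin_i].mean()
            pool = np.argsort(np.abs(b_gc - center))[: max(1, want)]
        picks = rng.choice(pool, size=want, replace=True)
        chosen.extend(background[i] for i in picks)
    return chosen if chosen else list(background)


def motif_enrichment(
    targets: Sequence[str],
    background: Sequence[str],
    pwms: Sequence[PWM],
    threshold: float = DEFAULT_MATCH_THRESHOLD,
    gc_match: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Known-motif enrichment of target over background sequences.

    Per motif: fraction of target/background sequences carrying >= 1 match
    above ``threshold`` and a one-sided binomial upper-tail p with success
    probability %bkgd, n = #targets, k = targets with a match.
    """
    if not targets:
        raise ValueError("empty target sequence set")
    if not background:
        raise ValueError("empty background sequence set")
    if len(background) < len(targets):
        warnings.warn("background smaller than target set; p-values will be coarse")
    rng = np.random.default_rng(seed)
    bkgd = _gc_matched_sample(targets, background, rng) if gc_match else list(background)
    rows = []
    for pwm in pwms:
        k = sum(1 for s in targets if best_score(pwm, s) > threshold)
        kb = sum(1 for s in bkgd if best_score(pwm, s) > threshold)
        pct_t = k / len(targets)
        pct_b = kb / len(bkgd)
        p = 1.0 if k == 0 else binom_upper_tail(k, len(targets), max(pct_b, 1e-12))
        rows.append(
            {"motif": pwm.name, "pct_target": pct_t, "pct_bkgd": pct_b,
             "n_target_with_match": k, "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows).set_index("motif")
    df["padj"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values("p")


# ---------------------------------------------------------------------------
# Cross-species conserved-motif mapping
# ---------------------------------------------------------------------------


@dataclass
class AlignmentMap:
    """Aligned (gap-free) column pairs between two sequences.

    ``a_positions`` and ``b_positions`` are equal-length arrays, strictly
    increasing, giving matched coordinates; gapped columns are absent.
    """

    seq_a_id: str
    seq_b_id: str
    a_positions: np.ndarray
    b_positions: np.ndarray

    def __post_init__(self) -> None:
        self.a_positions = np.asarray(self.a_positions, dtype=np.int64)
        self.b_positions = np.asarray(self.b_positions, dtype=np.int64)
        if self.a_positions.shape != self.b_positions.shape:
            raise ValueError("aligned coordinate arrays differ in length")
        if self.a_positions.size and (
            (np.diff(self.a_positions) <= 0).any() or (np.diff(self.b_positions) <= 0).any()
        ):
            raise ValueError("aligned positions must be strictly increasing")

    @classmethod
    def from_gapped(cls, a_gapped: str, b_gapped: str,
                    seq_a_id: str = "a", seq_b_id: str = "b") -> "AlignmentMap":
        if len(a_gapped) != len(b_gapped):
            raise ValueError("gapped sequences differ in alignment length")
        a_pos = b_pos = 0
        pa, pb = [], []
        for ca, cb in zip(a_gapped, b_gapped):
            if ca != "-" and cb != "-":
                pa.append(a_pos)
                pb.append(b_pos)
            if ca != "-":
                a_pos += 1
            if cb != "-":
                b_pos += 1
        return cls(seq_a_id, seq_b_id, np.array(pa), np.array(pb))

    @classmethod
    def from_blocks(cls, blocks: Iterable[tuple[int, int, int]],
                    seq_a_id: str = "a", seq_b_id: str = "b") -> "AlignmentMap":
        """Build from (a_start, b_start, length) gap-free blocks."""
        pa, pb = [], []
        for a0, b0, ln in blocks:
            pa.extend(range(a0, a0 + ln))
            pb.extend(range(b0, b0 + ln))
        return cls(seq_a_id, seq_b_id, np.array(pa), np.array(pb))

    @classmethod
    def from_blocks_tsv(cls, path: str | Path) -> "AlignmentMap":
        df = pd.read_csv(path, sep="\t")
        return cls.from_blocks(
            df[["a_start", "b_start", "length"]].itertuples(index=False, name=None)
        )

    def reversed(self) -> "AlignmentMap":
        return AlignmentMap(self.seq_b_id, self.seq_a_id,
                           self.b_positions, self.a_positions)

    def project(self, a_pos: int) -> int | None:
        """b-coordinate aligned to ``a_pos``, or None if gapped."""
        i = np.searchsorted(self.a_positions, a_pos)
        if i < self.a_positions.size and self.a_positions[i] == a_pos:
            return int(self.b_positions[i])
        return None

    def aligned_in(self, start: int, end: int) -> np.ndarray:
        """a-positions within [start, end) that are aligned."""
        lo = np.searchsorted(self.a_positions, start)
        hi = np.searchsorted(self.a_positions, end)
        return self.a_positions[lo:hi]


def align_pair(seq_a: str, seq_b: str, seq_a_id: str = "a",
               seq_b_id: str = "b") -> AlignmentMap:
    """Convenience local aligner for building fixture AlignmentMaps
    (match +1, mismatch -2, gap open 5, gap extend 2; no E-values)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    aln = aligner.align(seq_a, seq_b)[0]
    blocks = [
        (int(a0), int(b0), int(a1 - a0))
        for (a0, a1), (b0, b1) in zip(aln.aligned[0], aln.aligned[1])
    ]
    return AlignmentMap.from_blocks(blocks, seq_a_id, seq_b_id)


def map_conserved_motifs(
    matches_a: Sequence[MotifMatch],
    seq_b: str,
    amap: AlignmentMap,
    pwms: Sequence[PWM] | Mapping[str, PWM],
    threshold: float = DEFAULT_MATCH_THRESHOLD,
    tolerance: int = 3,
) -> list[MotifMatch]:
    """Subset of ``matches_a`` conserved at homologous positions in seq_b.

    A match is conserved iff at least half of its positions are aligned
    (non-gap) and seq_b contains a same-PWM match whose start lies within
    ``tolerance`` bases of the start projected through the alignment, on
    either strand."""
    if isinstance(pwms, Mapping):
        pwm_by_name = dict(pwms)
    else:
        pwm_by_name = {p.name: p for p in pwms}
    if amap.a_positions.size == 0:
        raise ValueError("empty alignment map")
    a_min = int(amap.a_positions[0])
    a_max = int(amap.a_positions[-1])
    b_starts: dict[str, np.ndarray] = {}
    conserved = []
    for m in matches_a:
        if m.end <= a_min or m.start > a_max + 1:
            raise ValueError(
                f"match {m.pwm_name}@{m.start} lies outside the alignment range"
            )
        aligned = amap.aligned_in(m.start, m.end)
        if 2 * aligned.size < (m.end - m.start):
            continue
        first = int(aligned[0])
        proj_start = amap.project(first) - (first - m.start)
        if m.pwm_name not in b_starts:
            pwm = pwm_by_name[m.pwm_name]
            b_starts[m.pwm_name] = np.array(
                sorted(mm.start for mm in scan_sequence(pwm, seq_b, threshold))
            )
        starts = b_starts[m.pwm_name]
        if starts.size and np.abs(starts - proj_start).min() <= tolerance:
            conserved.append(m)
    return conserved


# ---------------------------------------------------------------------------
# Motif-mutation association (strain variation)
# ---------------------------------------------------------------------------


@dataclass
class VariantPairSet:
    """Homologous sequence pairs per locus: positive = bound strain,
    negative = unbound strain."""

    loci: list[tuple[str, str, str]]  # (locus_id, positive_seq, negative_seq)

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("need >= 1 locus")
        ids = [l[0] for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids")

    def __len__(self) -> int:
        return len(self.loci)

    @classmethod
    def from_fastas(cls, positive_path: str | Path, negative_path: str | Path) -> "VariantPairSet":
        from .intervals import read_fasta

        pos = read_fasta(positive_path)
        neg = read_fasta(negative_path)
        common = sorted(set(pos) & set(neg))
        if not common:
            raise ValueError("no shared locus ids between positive and negative FASTAs")
        return cls([(lid, pos[lid], neg[lid]) for lid in common])

    def to_fastas(self, positive_path: str | Path, negative_path: str | Path) -> None:
        from .intervals import write_fasta

        write_fasta({lid: s for lid, s, _ in self.loci}, positive_path)
        write_fasta({lid: s for lid, _, s in self.loci}, negative_path)


def motif_score_differences(
    pairs: VariantPairSet, pwms: Sequence[PWM]
) -> pd.DataFrame:
    """Per-locus bestScore(positive) - bestScore(negative), loci x motifs."""
    data = {}
    for pwm in pwms:
        data[pwm.name] = [
            best_score(pwm, pos) - best_score(pwm, neg) for _, pos, neg in pairs.loci
        ]
    return pd.DataFrame(data, index=[lid for lid, _, _ in pairs.loci])


def motif_mutation_association(
    pairs: VariantPairSet,
    pwms: Sequence[PWM],
    expression: ExpressionTable | None = None,
    focal_group: str | None = None,
    tf_gene_map: Mapping[str, str] | None = None,
    tpm_filter: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Associate motif-score mutations with strain-differential binding.

    Per motif: paired differences d = bestScore(positive) - bestScore
    (negative) per locus; zero differences are uninformative and dropped;
    two-sided Wilcoxon signed-rank over the rest (exact by sign enumeration
    for small n); BH across motifs; signed_logp = sign(median d) * -log10 p.
    A positive sign means the motif scores higher in the bound strain, i.e.
    its mutation associates with loss of binding.

    With an ExpressionTable, each motif's cognate TF is looked up (via
    ``tf_gene_map`` or case-insensitive name match) and flagged ``expressed``
    when its mean TPM in ``focal_group`` exceeds ``tpm_filter``.

    Returns (results, d_matrix): per-motif statistics and the loci x motifs
    difference matrix used downstream for clustering.
    """
    d_matrix = motif_score_differences(pairs, pwms)
    expr_means = None
    if expression is not None:
        groups = list(dict.fromkeys(expression.groups.values()))
        focal = focal_group or groups[0]
        expr_means = expression.group_mean_tpm()[focal]
        lower_index = {g.lower(): g for g in expr_means.index}
    rows = []
    for pwm in pwms:
        d = d_matrix[pwm.name].to_numpy()
        nz = d[d != 0]
        w, p, n = wilcoxon_signed_rank(d)
        sign = float(np.sign(np.median(nz))) if nz.size else 0.0
        expressed: bool | None = None
        if expr_means is not None:
            gene = None
            if tf_gene_map and pwm.name in tf_gene_map:
                gene = tf_gene_map[pwm.name]
            elif pwm.name.lower() in lower_index:
                gene = lower_index[pwm.name.lower()]
            expressed = bool(gene and expr_means[gene] > tpm_filter)
        rows.append(
            {
                "motif": pwm.name,
                "n_informative": n,
                "W": w,
                "p": p,
                "signed_logp": sign * -np.log10(max(p, 1e-300)),
                "underpowered": n < MIN_INFORMATIVE_LOCI,
                "expressed": expressed,
            }
        )
    res = pd.DataFrame(rows).set_index("motif")
    res.insert(3, "padj", bh_adjust(res["p"].to_numpy()))
    return res, d_matrix


def cluster_motifs(
    results: pd.DataFrame,
    d_matrix: pd.DataFrame,
    r_threshold: float = 0.6,
) -> pd.DataFrame:
    """Group motifs into clusters by correlation of their score-difference
    vectors and average the signed log p within each cluster.

    Clusters are connected components of the graph with an edge wherever the
    Pearson correlation exceeds ``r_threshold`` (single linkage). A cluster
    is flagged biologically relevant when at least one member's cognate TF is
    expressed. Motifs with a constant difference vector (undefined
    correlation) become singletons."""
    names = list(results.index)
    d = d_matrix[names]
    constant = d.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant score-difference vectors (singleton clusters): "
            f"{list(d.columns[constant])}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = d.corr().to_numpy()
    adj = np.nan_to_num(corr, nan=-1.0) > r_threshold
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    out = results.copy()
    # deterministic cluster ids ordered by smallest member name
    rep = {
        comp: min(names[i] for i in range(len(names)) if labels[i] == comp)
        for comp in range(n_comp)
    }
    order = {comp: rank for rank, comp in
             enumerate(sorted(rep, key=lambda c: rep[c]))}
    out["cluster_id"] = [f"c{order[labels[i]] + 1}" for i in range(len(names))]
    cluster_mean = out.groupby("cluster_id")["signed_logp"].mean()
    out["cluster_signed_logp"] = out["cluster_id"].map(cluster_mean)
    if out["expressed"].notna().any():
        relevant = out.groupby("cluster_id")["expressed"].agg(
            lambda s: bool(s.fillna(False).any())
        )
        out["cluster_relevant"] = out["cluster_id"].map(relevant)
    else:
        out["cluster_relevant"] = pd.NA
    return out


def write_association_table(results: pd.DataFrame, path: str | Path) -> None:
    cols = ["n_informative", "W", "p", "padj", "signed_logp"]
    for extra in ("cluster_id", "cluster_signed_logp", "expressed", "cluster_relevant"):
        if extra in results.columns:
            cols.append(extra)
    results[cols].reset_index().to_csv(path, sep="\t", index=False)
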