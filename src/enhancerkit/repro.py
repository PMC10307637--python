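"""Replicate-reproducibility filtering of peak calls and strain-differential
peak definition.

The reproducibility filter is a deterministic surrogate for a replicate-
consistency criterion: a peak is kept only when every other replicate carries
a peak whose summit lies within ``summit_dist`` and all partners sit in the
top ``rank_fraction`` of their replicate by signal. Supported peaks are then
clustered by summit proximity (single linkage) and each cluster is merged
into one output peak, making the result invariant to replicate ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval, Peak, PeakSet, overlap_peaks

DEFAULT_SUMMIT_DIST = 100
DEFAULT_RANK_FRACTION = 0.9


@dataclass
class ReplicatePeakCalls:
    """Peak calls for >=2 replicates of one condition."""

    condition: str
    replicates: list[PeakSet]

    def __post_init__(self) -> None:
        genomes = {r.genome for r in self.replicates}
        if len(genomes) > 1:
            raise ValueError(f"replicates span genome builds: {sorted(genomes)}")


@dataclass
class StrainPair:
    """Reproducible peaks unique to each of two strains."""

    strain_a: str
    strain_b: str
    differential_a: PeakSet  # reproducible in a, no overlap with reproducible-in-b
    differential_b: PeakSet


def _top_fraction_ids(peaks: PeakSet, rank_fraction: float) -> set[str]:
    """Peak ids in the top ``rank_fraction`` of the replicate by score.

    Rank 1 is the strongest peak; ties break by peak_id for determinism.
    """
    ordered = sorted(peaks, key=lambda p: (-p.score, p.peak_id))
    n_keep = int(np.ceil(rank_fraction * len(ordered)))
    return {p.peak_id for p in ordered[:n_keep]}


def reproducible_peaks(
    calls: ReplicatePeakCalls,
    summit_dist: int = DEFAULT_SUMMIT_DIST,
    rank_fraction: float = DEFAULT_RANK_FRACTION,
    allow_single: bool = False,
) -> PeakSet:
    """Filter to peaks supported in every replicate and merge them by locus.

    The merged peak spans the union of cluster members, its summit is the
    score-weighted mean member summit, and its score the mean member score.
    """
    reps = calls.replicates
    if len(reps) < 2:
        if allow_single and len(reps) == 1:
            return PeakSet(f"{calls.condition}_repro", list(reps[0]), genome=reps[0].genome)
        raise ValueError(
            "need >= 2 replicates for reproducibility filtering; "
            "pass allow_single=True for single-replicate passthrough"
        )
    top_ids = [_top_fraction_ids(r, rank_fraction) for r in reps]
    # per replicate: chrom -> sorted array of top-fraction summits
    summits_by_rep: list[dict[str, np.ndarray]] = []
    for r, ids in zip(reps, top_ids):
        d: dict[str, list[int]] = {}
        for p in r:
            if p.peak_id in ids:
                d.setdefault(p.chrom, []).append(p.summit)
        summits_by_rep.append({c: np.sort(np.array(v)) for c, v in d.items()})

    supported: list[tuple[int, Peak]] = []  # (replicate index, peak)
    for ri, (r, ids) in enumerate(zip(reps, top_ids)):
        for p in r:
            if p.peak_id not in ids:
                continue
            ok = True
            for rj, other in enumerate(summits_by_rep):
                if rj == ri:
                    continue
                arr = other.get(p.chrom)
                if arr is None or arr.size == 0:
                    ok = False
                    break
                i = np.searchsorted(arr, p.summit)
                near = min(
                    abs(int(arr[j]) - p.summit)
                    for j in (i - 1, i)
                    if 0 <= j < arr.size
                )
                if near > summit_dist:
                    ok = False
                    break
            if ok:
                supported.append((ri, p))

    # single-linkage clustering of supported peaks by summit distance
    supported.sort(key=lambda t: (t[1].chrom, t[1].summit, t[0], t[1].peak_id))
    merged: list[Peak] = []
    cluster: list[Peak] = []

    def flush() -> None:
        if not cluster:
            return
        start = min(p.start for p in cluster)
        end = max(p.end for p in cluster)
        weights = np.array([max(p.score, 1e-12) for p in cluster])
        summit = int(round(np.average([p.summit for p in cluster], weights=weights)))
        summit = min(max(summit, start), end - 1)
        score = float(np.mean([p.score for p in cluster]))
        merged.append(
            Peak(
                GenomicInterval(cluster[0].chrom, start, end),
                f"{calls.condition}_r{len(merged) + 1}",
                summit,
                score,
            )
        )

    for _, p in supported:
        if cluster and (p.chrom != cluster[-1].chrom or p.summit - cluster[-1].summit > summit_dist):
            flush()
            cluster = []
        cluster.append(p)
    flush()
    return PeakSet(f"{calls.condition}_repro", merged, genome=reps[0].genome)


def write_repro_report(
    calls: ReplicatePeakCalls,
    path,
    summit_dist: int = DEFAULT_SUMMIT_DIST,
    rank_fraction: float = DEFAULT_RANK_FRACTION,
) -> None:
    """Write a per-peak reproducibility report TSV: replicate, peak_id,
    signal rank within the replicate, and verdict (kept/dropped)."""
    reps = calls.replicates
    top_ids = [_top_fraction_ids(r, rank_fraction) for r in reps]
    kept = reproducible_peaks(calls, summit_dist, rank_fraction)
    kept_summits: dict[str, list[int]] = {}
    for p in kept:
        kept_summits.setdefault(p.chrom, []).append(p.summit)
    for v in kept_summits.values():
        v.sort()
    with open(path, "w") as fh:
        fh.write("replicate\tpeak_id\trank\ttop_fraction\tverdict\n")
        for r, ids in zip(reps, top_ids):
            ordered = sorted(r, key=lambda p: (-p.score, p.peak_id))
            for rank, p in enumerate(ordered, start=1):
                summits = kept_summits.get(p.chrom, [])
                i = np.searchsorted(summits, p.summit)
                near = min(
                    (abs(summits[j] - p.summit) for j in (i - 1, i)
                     if 0 <= j < len(summits)),
                    default=summit_dist + 1,
                )
                verdict = "kept" if near <= summit_dist else "dropped"
                fh.write(
                    f"{r.name}\t{p.peak_id}\t{rank}\t"
                    f"{str(p.peak_id in ids).lower()}\t{verdict}\n"
                )


def merge_pairwise_sets(sets: list[PeakSet], name: str = "merged") -> PeakSet:
    """Union overlapping peaks across sets into single records (transitive).

    The merged record keeps the interval union; its summit, id and score come
    from the highest-scoring constituent (score = max, preserving
    most-confident-call semantics)."""
    if not sets:
        raise ValueError("need >= 1 peak set to merge")
    genomes = {s.genome for s in sets}
    if len(genomes) > 1:
        raise ValueError(f"cannot merge across genomes: {sorted(genomes)}")
    all_peaks = sorted(
        (p for s in sets for p in s), key=lambda p: (p.chrom, p.start, p.end, p.peak_id)
    )
    merged: list[Peak] = []
    cluster: list[Peak] = []

    def flush() -> None:
        if not cluster:
            return
        best = max(cluster, key=lambda p: (p.score, p.peak_id))
        merged.append(
            Peak(
                GenomicInterval(cluster[0].chrom, min(p.start for p in cluster),
                                max(p.end for p in cluster)),
                best.peak_id,
                best.summit,
                best.score,
            )
        )

    cur_end = None
    for p in all_peaks:
        if cluster and (p.chrom != cluster[-1].chrom or p.start >= cur_end):
            flush()
            cluster = []
            cur_end = None
        cluster.append(p)
        cur_end = p.end if cur_end is None else max(cur_end, p.end)
    flush()
    ids = [p.peak_id for p in merged]
    if len(set(ids)) != len(ids):  # same id can win two disjoint clusters
        merged = [
            Peak(p.interval, f"{p.peak_id}_m{i}", p.summit, p.score) if ids.count(p.peak_id) > 1 else p
            for i, p in enumerate(merged)
        ]
    return PeakSet(name, merged, genome=sets[0].genome)


def strain_differential(
    calls_a: ReplicatePeakCalls,
    calls_b: ReplicatePeakCalls,
    summit_dist: int = DEFAULT_SUMMIT_DIST,
    rank_fraction: float = DEFAULT_RANK_FRACTION,
) -> StrainPair:
    """Peaks reproducible in one strain with zero overlap (min 1 bp) against
    the other strain's reproducible set, and symmetrically."""
    rep_a = reproducible_peaks(calls_a, summit_dist, rank_fraction)
    rep_b = reproducible_peaks(calls_b, summit_dist, rank_fraction)
    only_a = ~overlap_peaks(rep_a, rep_b, min_bp=1) if len(rep_b) else np.ones(len(rep_a), bool)
    only_b = ~overlap_peaks(rep_b, rep_a, min_bp=1) if len(rep_a) else np.ones(len(rep_b), bool)
    diff_a = rep_a.subset(
        [p.peak_id for p, f in zip(rep_a, only_a) if f], name=f"{calls_a.condition}_only"
    )
    diff_b = rep_b.subset(
        [p.peak_id for p, f in zip(rep_b, only_b) if f], name=f"{calls_b.condition}_only"
    )
    return StrainPair(calls_a.condition, calls_b.condition, diff_a, diff_b)
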