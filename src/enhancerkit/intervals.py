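"""Core genomic data types, BED/FASTA/TSV I/O, and interval algebra.

Coordinates are 0-based half-open everywhere. Peak summits are parsed from an
optional 7th BED column as an offset from the interval start (narrowPeak
convention); when absent the summit defaults to the interval midpoint.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +,-,. got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Peak:
    """A peak: an interval with a summit and a normalized tag-density score.

    ``score`` is in tags per 10^7 library tags, the scale on which activity
    cutoffs such as the >16 normalized H3K27ac tag floor are expressed.
    """

    interval: GenomicInterval
    peak_id: str
    summit: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end}) for {self.peak_id}"
            )
        if self.score < 0:
            raise ValueError(f"score must be >= 0 for {self.peak_id}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


class PeakSet:
    """An ordered, id-unique collection of peaks on one genome build."""

    def __init__(self, name: str, peaks: Iterable[Peak], genome: str = "synthetic"):
        self.name = name
        self.genome = genome
        self.peaks: list[Peak] = list(peaks)
        ids = [p.peak_id for p in self.peaks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate peak_ids in PeakSet {name!r}: {dupes[:5]}")
        self._by_id = {p.peak_id: p for p in self.peaks}

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, peak_id: str) -> Peak:
        return self._by_id[peak_id]

    def __contains__(self, peak_id: str) -> bool:
        return peak_id in self._by_id

    @property
    def peak_ids(self) -> list[str]:
        return [p.peak_id for p in self.peaks]

    def sorted(self) -> "PeakSet":
        return PeakSet(
            self.name,
            sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end, p.peak_id)),
            genome=self.genome,
        )

    def subset(self, keep_ids: Iterable[str], name: str | None = None) -> "PeakSet":
        keep = set(keep_ids)
        return PeakSet(
            name or self.name,
            [p for p in self.peaks if p.peak_id in keep],
            genome=self.genome,
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its TSS (width-1 interval) and transcript length."""

    gene_id: str
    symbol: str
    tss: GenomicInterval
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"transcript length must be > 0 for {self.gene_id}")
        if len(self.tss) != 1:
            raise ValueError(f"TSS interval must have width 1 for {self.gene_id}")

    @property
    def tss_pos(self) -> int:
        return self.tss.start


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, name: str | None = None, genome: str = "synthetic") -> PeakSet:
    """Read BED3/BED6(+summit-offset) into a PeakSet.

    Column 7, when present, is the summit offset from ``start``; otherwise the
    summit is the interval midpoint. Raises ValueError naming the offending
    line number on malformed input.
    """
    path = Path(path)
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            peak_id = fields[3] if len(fields) > 3 and fields[3] else f"peak_{lineno}"
            score = float(fields[4]) if len(fields) > 4 and fields[4] not in ("", ".") else 0.0
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            if len(fields) > 6 and fields[6] not in ("", "."):
                try:
                    summit = start + int(fields[6])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer summit offset") from exc
                if not (start <= summit < end):
                    raise ValueError(f"{path}:{lineno}: summit offset outside interval")
            else:
                summit = start + (end - start) // 2
            peaks.append(
                Peak(GenomicInterval(chrom, start, end, strand), peak_id, summit, score)
            )
    return PeakSet(name or path.stem, peaks, genome=genome)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED6 + summit-offset column (round-trips read_bed)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{p.score:g}\t"
                f"{p.interval.strand}\t{p.summit - p.start}\n"
            )


def read_genes_tsv(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from a headered TSV.

    Columns: gene_id, symbol, chrom, tss (0-based position), strand, length.
    """
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        required = {"gene_id", "symbol", "chrom", "tss", "strand", "length"}
        missing = required - set(idx)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            pos = int(f[idx["tss"]])
            genes.append(
                GeneAnnotation(
                    gene_id=f[idx["gene_id"]],
                    symbol=f[idx["symbol"]],
                    tss=GenomicInterval(f[idx["chrom"]], pos, pos + 1, f[idx["strand"]]),
                    length=int(f[idx["length"]]),
                )
            )
    return genes


def write_genes_tsv(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsymbol\tchrom\ttss\tstrand\tlength\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.symbol}\t{g.tss.chrom}\t{g.tss_pos}\t"
                f"{g.tss.strand}\t{g.length}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def _build_tree(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p.peak_id)
    return trees


def overlap_peaks(a: PeakSet, b: PeakSet, min_bp: int = 1) -> np.ndarray:
    """Boolean flag per peak of ``a``: shares >= ``min_bp`` bases with some b-peak.

    Raises on mismatched genome labels. Order of flags follows ``a.peaks``.
    """
    if a.genome != b.genome:
        raise ValueError(f"genome mismatch: {a.genome!r} vs {b.genome!r}")
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = _build_tree(b)
    flags = np.zeros(len(a), dtype=bool)
    for i, p in enumerate(a):
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(p.start, p.end):
            if min(p.end, hit.end) - max(p.start, hit.begin) >= min_bp:
                flags[i] = True
                break
    return flags


def overlap_counts(a: PeakSet, b: PeakSet, min_bp: int = 1) -> tuple[int, int]:
    """Symmetric overlap counts: (#a-peaks overlapping b, #b-peaks overlapping a)."""
    return int(overlap_peaks(a, b, min_bp).sum()), int(overlap_peaks(b, a, min_bp).sum())


UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class NearestGene:
    gene_id: str  # UNASSIGNED when the chromosome carries no gene
    distance: int | None  # summit - TSS; None when unassigned


def nearest_gene(
    peaks: PeakSet, genes: Iterable[GeneAnnotation]
) -> dict[str, NearestGene]:
    """Map each peak to its nearest gene by |summit - TSS|.

    Ties break to the lexicographically smaller gene_id. Peaks on a chromosome
    with no annotated gene are labelled ``unassigned`` rather than dropped.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.tss.chrom, []).append((g.tss_pos, g.gene_id))
    for entries in by_chrom.values():
        entries.sort()
    result: dict[str, NearestGene] = {}
    for p in peaks:
        entries = by_chrom.get(p.chrom)
        if not entries:
            result[p.peak_id] = NearestGene(UNASSIGNED, None)
            continue
        positions = [e[0] for e in entries]
        i = bisect.bisect_left(positions, p.summit)
        # candidates around the insertion point; widen to catch equidistant ties
        best: tuple[int, str] | None = None
        for j in range(max(0, i - 2), min(len(entries), i + 2)):
            pos, gid = entries[j]
            key = (abs(p.summit - pos), gid)
            if best is None or key < best:
                best = key
                chosen = (pos, gid)
        result[p.peak_id] = NearestGene(chosen[1], p.summit - chosen[0])
    return result


def filter_distal(
    peaks: PeakSet,
    genes: Iterable[GeneAnnotation],
    min_tss_distance: int = 3000,
) -> PeakSet:
    """Retain peaks whose summit lies strictly more than ``min_tss_distance``
    bases from the nearest TSS (default 3,000 bp, the distal-enhancer rule).

    Peaks on chromosomes with no gene are retained (infinitely distal).
    """
    nearest = nearest_gene(peaks, genes)
    keep = [
        p.peak_id
        for p in peaks
        if nearest[p.peak_id].distance is None
        or abs(nearest[p.peak_id].distance) > min_tss_distance
    ]
    return peaks.subset(keep, name=f"{peaks.name}_distal")
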