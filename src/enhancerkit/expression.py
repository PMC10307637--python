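"""Gene-expression quantification (TPM), DEG calling, cell-type signature
definition, and gene-set overlap enrichment.

TPM for gene g in a sample is 10^6 * (count_g / length_g) / sum_j
(count_j / length_j): length-normalized rates rescaled to sum to one million
per sample. A signature gene is one expressed more than ``fold`` times higher
in the focal cell type than the average of the per-group mean TPMs across the
comparison cell types.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signal import CountMatrix, nb_wald_test
from .stats import hypergeom_upper_tail

SIGNATURE_PSEUDOCOUNT = 0.01  # TPM added to the comparison-group denominator


@dataclass
class ExpressionTable:
    """Raw counts plus derived TPM for genes x samples with group labels."""

    counts: pd.DataFrame  # genes x samples, raw integers
    lengths: pd.Series  # transcript length per gene (bases)
    groups: dict[str, str]  # sample_id -> group label

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("every gene needs a transcript length")
        if (self.lengths <= 0).any():
            raise ValueError("transcript lengths must be > 0")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples missing group labels: {sorted(missing)}")
        zero = [s for s in self.counts.columns if self.counts[s].sum() == 0]
        if zero:
            raise ValueError(f"all-zero sample(s), TPM undefined: {zero}")
        rates = self.counts.div(self.lengths, axis=0)
        self.tpm = rates / rates.sum(axis=0) * 1e6

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def samples_for(self, group: str) -> list[str]:
        ss = [s for s in self.counts.columns if self.groups[s] == group]
        if not ss:
            raise ValueError(f"unknown group label {group!r}")
        return ss

    def group_mean_tpm(self) -> pd.DataFrame:
        """Mean TPM per group (one column per group label)."""
        return pd.DataFrame(
            {
                g: self.tpm[self.samples_for(g)].mean(axis=1)
                for g in dict.fromkeys(self.groups.values())
            }
        )


@dataclass
class GeneSet:
    name: str
    gene_ids: set[str]

    def __len__(self) -> int:
        return len(self.gene_ids)


def compute_tpm(
    counts: pd.DataFrame, lengths: pd.Series, groups: Mapping[str, str]
) -> ExpressionTable:
    """Build an ExpressionTable; TPM is derived on construction."""
    return ExpressionTable(counts.copy(), pd.Series(lengths, dtype=float), dict(groups))


def call_degs(
    table: ExpressionTable,
    g1: str,
    g2: str,
    fc: float = 2.0,
    alpha: float = 0.05,
    floor: float = 2.0,
) -> pd.DataFrame:
    """Differential expression g2 vs g1 with the NB Wald test plus an
    expression floor: a gene is a DEG only when padj < alpha, |FC| > fc and
    mean log2(TPM+1) exceeds ``floor`` in at least one of the two groups.

    Returns the differential frame with the floor applied to the verdict.
    """
    s1, s2 = table.samples_for(g1), table.samples_for(g2)
    cm = CountMatrix(
        table.counts[s1 + s2].round().astype(int),
        conditions={s: g1 for s in s1} | {s: g2 for s in s2},
        totals={s: int(table.counts[s].sum()) for s in s1 + s2},
    )
    res = nb_wald_test(cm, g1, g2, fc_threshold=fc, alpha=alpha)
    log_tpm = np.log2(table.tpm + 1.0)
    mean1 = log_tpm[s1].mean(axis=1)
    mean2 = log_tpm[s2].mean(axis=1)
    passes_floor = (mean1 > floor) | (mean2 > floor)
    res.loc[~passes_floor.reindex(res.index).fillna(False), "verdict"] = "unchanged"
    return res


def define_signature(
    table: ExpressionTable,
    focal_group: str,
    other_groups: Sequence[str] | None = None,
    fold: float = 10.0,
    name: str | None = None,
) -> GeneSet:
    """Genes expressed > ``fold`` times higher (strict) in the focal group
    than the average of per-group mean TPMs across the other groups.

    A 0.01 TPM pseudocount in the denominator keeps genes silent elsewhere
    well-defined (and included, since their ratio is then enormous).
    """
    means = table.group_mean_tpm()
    if focal_group not in means.columns:
        raise ValueError(f"unknown focal group {focal_group!r}")
    if other_groups is None:
        other_groups = [g for g in means.columns if g != focal_group]
    if not other_groups:
        raise ValueError("need >= 1 comparison group")
    denom = means[list(other_groups)].mean(axis=1) + SIGNATURE_PSEUDOCOUNT
    included = means[focal_group] > fold * denom
    return GeneSet(name or f"{focal_group}_signature", set(means.index[included]))


@dataclass(frozen=True)
class GeneSetOverlap:
    overlap: int
    frac_a: float
    frac_b: float
    fisher_p: float


def gene_set_overlap(a: GeneSet, b: GeneSet, universe: int) -> GeneSetOverlap:
    """Overlap count, fractions, and one-tailed Fisher (hypergeometric
    upper-tail) enrichment p for two gene sets in an explicit universe."""
    if universe < len(a.gene_ids | b.gene_ids):
        raise ValueError("universe smaller than |a U b|")
    k = len(a.gene_ids & b.gene_ids)
    p = hypergeom_upper_tail(k, universe, len(a), len(b))
    return GeneSetOverlap(
        overlap=k,
        frac_a=k / len(a) if len(a) else 0.0,
        frac_b=k / len(b) if len(b) else 0.0,
        fisher_p=p,
    )


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a counts TSV with columns gene_id, length, then one per sample."""
    df = pd.read_csv(path, sep="\t").set_index("gene_id")
    lengths = df.pop("length").astype(float)
    return df, lengths


def write_counts_tsv(table: ExpressionTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.insert(0, "length", table.lengths.astype(int))
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    with open(path) as fh:
        ids = {line.strip() for line in fh if line.strip()}
    return GeneSet(name or Path(path).stem, ids)


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(gs.gene_ids):
            fh.write(gid + "\n")
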