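"""Windowed tag quantification and negative-binomial differential testing.

The differential test follows the standard RNA-seq/ChIP-seq count model:
median-of-ratios size factors, per-feature method-of-moments dispersion shrunk
halfway toward a fitted mean-dispersion trend, and a Wald test
on the log2 fold change with Benjamini-Hochberg correction. Features whose
mean normalized count falls below an independent-filter floor receive no
adjusted p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import PeakSet
from .stats import bh_adjust

NORM_SCALE = 1e7  # normalized counts are tags per 10^7 library tags
LFC_PSEUDOCOUNT = 0.5  # normalized counts added before taking log2 ratios
DISPERSION_FLOOR = 1e-8


@dataclass
class TagLibrary:
    """Sequenced-fragment 5' end positions for one sample."""

    sample_id: str
    condition: str
    positions: dict[str, np.ndarray]  # chrom -> sorted positions

    def __post_init__(self) -> None:
        self.positions = {
            c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in self.positions.items()
        }

    @property
    def total_tags(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))


def read_tag_library(path: str | Path, sample_id: str, condition: str) -> TagLibrary:
    """Read a 2-column TSV (chrom, position) of fragment 5' ends."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos"], comment="#")
    positions = {
        str(chrom): grp["pos"].to_numpy(dtype=np.int64)
        for chrom, grp in df.groupby("chrom")
    }
    return TagLibrary(sample_id, condition, positions)


@dataclass
class CountMatrix:
    """Raw tag counts per (feature, sample) with library totals for
    normalization to tags per 10^7."""

    counts: pd.DataFrame  # features x samples, integer
    conditions: dict[str, str]  # sample_id -> condition label
    totals: dict[str, int]  # sample_id -> library size
    window: int = 0

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples missing condition labels: {sorted(missing)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.conditions[s] == condition]

    def normalized(self) -> pd.DataFrame:
        """Counts rescaled to tags per 10^7 library tags."""
        totals = pd.Series(self.totals)[self.counts.columns].astype(float)
        return self.counts / totals * NORM_SCALE

    def condition_means(self) -> pd.DataFrame:
        """Mean normalized count per condition (one column per condition)."""
        norm = self.normalized()
        return pd.DataFrame(
            {
                cond: norm[self.samples_for(cond)].mean(axis=1)
                for cond in dict.fromkeys(self.conditions.values())
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "feature_id", out.index)
        with open(path, "w") as fh:
            fh.write(f"# window={self.window}\n")
            fh.write(
                "# conditions="
                + ",".join(f"{s}:{c}" for s, c in self.conditions.items())
                + "\n"
            )
            fh.write("# totals=" + ",".join(f"{s}:{t}" for s, t in self.totals.items()) + "\n")
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t")
        df = df.set_index("feature_id")
        conditions = dict(kv.split(":") for kv in meta["conditions"].split(","))
        totals = {s: int(t) for s, t in (kv.split(":") for kv in meta["totals"].split(","))}
        return cls(df, conditions, totals, window=int(meta.get("window", 0)))


def quantify(
    peaks: PeakSet, libs: Sequence[TagLibrary], window: int
) -> CountMatrix:
    """Count tag 5' ends in [summit - window//2, summit + window//2) per sample.

    Odd windows round the half-width down. Normalization to tags per 10^7 is
    available through the returned matrix's ``normalized`` view.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    half = window // 2
    data = {}
    for lib in libs:
        if lib.total_tags == 0:
            warnings.warn(f"tag library {lib.sample_id} is empty; zero column")
        col = np.zeros(len(peaks), dtype=np.int64)
        for i, p in enumerate(peaks):
            pos = lib.positions.get(p.chrom)
            if pos is None:
                continue
            lo = np.searchsorted(pos, p.summit - half, side="left")
            hi = np.searchsorted(pos, p.summit + half, side="left")
            col[i] = hi - lo
        data[lib.sample_id] = col
    counts = pd.DataFrame(data, index=peaks.peak_ids)
    return CountMatrix(
        counts,
        conditions={lib.sample_id: lib.condition for lib in libs},
        totals={lib.sample_id: lib.total_tags for lib in libs},
        window=window,
    )


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios size factors (fallback: column totals)."""
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    usable = np.isfinite(log_counts).all(axis=1)
    if usable.sum() >= 10:
        log_geo = log_counts[usable].mean(axis=1, keepdims=True)
        sf = np.exp(np.median(log_counts[usable] - log_geo, axis=0))
    else:
        tot = counts.sum(axis=0).astype(float)
        sf = tot / np.exp(np.mean(np.log(np.maximum(tot, 1.0))))
    return sf / np.exp(np.mean(np.log(sf)))


def _dispersion_trend(base_mean: np.ndarray, disp_raw: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu on features with a positive raw estimate."""
    ok = (disp_raw > 0) & (base_mean > 0)
    if ok.sum() < 10:
        fallback = max(np.median(disp_raw[disp_raw > 0]) if (disp_raw > 0).any() else 0.01,
                       DISPERSION_FLOOR)
        return np.full_like(base_mean, fallback)
    x = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
    coef, *_ = np.linalg.lstsq(x, disp_raw[ok], rcond=None)
    a0, a1 = np.maximum(coef, 0.0)
    if a0 == 0.0 and a1 == 0.0:
        a0 = max(np.median(disp_raw[ok]), DISPERSION_FLOOR)
    trend = a0 + a1 / np.maximum(base_mean, 1e-6)
    return np.maximum(trend, DISPERSION_FLOOR)


def nb_wald_test(
    m: CountMatrix,
    cond1: str,
    cond2: str,
    min_base_mean: float = 1.0,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature NB Wald test of cond2 vs cond1.

    Returns a DataFrame indexed by feature_id with columns baseMean, log2fc,
    p, padj, verdict. log2fc > 0 means higher signal in ``cond2``. Features
    with baseMean below ``min_base_mean`` (on the size-factor-normalized
    scale) are excluded from BH (padj = NaN).
    """
    s1 = m.samples_for(cond1)
    s2 = m.samples_for(cond2)
    for cond, ss in ((cond1, s1), (cond2, s2)):
        if len(ss) < 2:
            raise ValueError(f"condition {cond!r} has {len(ss)} sample(s); need >= 2")
    samples = s1 + s2
    k = m.counts[samples].to_numpy(dtype=float)
    sf = _size_factors(k)
    q = k / sf  # size-factor normalized counts
    n1, n2 = len(s1), len(s2)
    q1, q2 = q[:, :n1], q[:, n1:]
    mu1 = q1.mean(axis=1)
    mu2 = q2.mean(axis=1)
    base_mean = q.mean(axis=1)

    # method-of-moments dispersion from within-condition variability
    dof = n1 + n2 - 2
    ss_within = ((q1 - mu1[:, None]) ** 2).sum(axis=1) + ((q2 - mu2[:, None]) ** 2).sum(axis=1)
    var_within = ss_within / dof
    mu_bar = (n1 * mu1 + n2 * mu2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_raw = (var_within - mu_bar) / np.square(mu_bar)
    disp_raw = np.where(np.isfinite(disp_raw), np.maximum(disp_raw, 0.0), 0.0)
    trend = _dispersion_trend(base_mean, disp_raw)
    # average toward the trend with weight 0.5
    disp = np.maximum(0.5 * disp_raw + 0.5 * trend, DISPERSION_FLOOR)

    c = LFC_PSEUDOCOUNT
    log2fc = np.log2((mu2 + c) / (mu1 + c))

    inv_sf1 = (1.0 / sf[:n1]).sum()
    inv_sf2 = (1.0 / sf[n1:]).sum()
    # delta-method variance of log2 of each condition mean under the NB model
    var_mu1 = (mu1 * inv_sf1 / n1**2) + disp * mu1**2 / n1
    var_mu2 = (mu2 * inv_sf2 / n2**2) + disp * mu2**2 / n2
    ln2sq = np.log(2.0) ** 2
    var_lfc = var_mu1 / ((mu1 + c) ** 2 * ln2sq) + var_mu2 / ((mu2 + c) ** 2 * ln2sq)
    se = np.sqrt(np.maximum(var_lfc, 1e-12))
    from scipy import stats as sps

    z = log2fc / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    p_for_bh = np.where(base_mean >= min_base_mean, p, np.nan)
    padj = bh_adjust(p_for_bh)

    res = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
        },
        index=pd.Index(m.feature_ids, name="feature_id"),
    )
    res["verdict"] = call_differential_peaks(res, fc_threshold, alpha)
    return res


def call_differential_peaks(
    results: pd.DataFrame, fc_threshold: float = 2.0, alpha: float = 0.05
) -> pd.Series:
    """Partition features into up/down/unchanged by |FC| > fc_threshold and
    padj < alpha (strict inequalities; missing padj means unchanged)."""
    lfc_cut = np.log2(fc_threshold)
    lfc = results["log2fc"]
    padj = results["padj"]
    sig = padj.notna() & (padj < alpha)
    verdict = pd.Series("unchanged", index=results.index, name="verdict")
    verdict[sig & (lfc > lfc_cut)] = "up"
    verdict[sig & (lfc < -lfc_cut)] = "down"
    return verdict


def write_diff_results(results: pd.DataFrame, path: str | Path) -> None:
    out = results.reset_index()
    out.columns = ["feature_id", "baseMean", "log2FC", "p", "padj", "verdict"]
    out.to_csv(path, sep="\t", index=False)
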