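import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from enhancerkit.classify import (
    ENHANCER_CLASSES,
    EnhancerRecord,
    call_super_enhancers,
    class_gene_report,
    classify_enhancers,
    overlap_summary,
    select_active_enhancers,
    superenhancer_cutoff,
)
from enhancerkit.intervals import GenomicInterval, Peak, PeakSet, filter_distal
from enhancerkit.signal import CountMatrix, nb_wald_test
from enhancerkit.simulate import generate_enhancer_study, generate_se_landscape


def mk_peak(pid, summit, chrom="chr1", width=200, score=0.0):
    return Peak(GenomicInterval(chrom, summit - width // 2, summit + width // 2),
                pid, summit, score)


def mk_matrix(levels_by_condition, peak_ids):
    """CountMatrix whose normalized values equal the given levels exactly."""
    data, conds, totals = {}, {}, {}
    for cond, levels in levels_by_condition.items():
        for r in (1, 2):
            sid = f"{cond}_rep{r}"
            data[sid] = np.asarray(levels, dtype=int)
            conds[sid] = cond
            totals[sid] = 10**7
    return CountMatrix(pd.DataFrame(data, index=peak_ids), conds, totals, window=1000)


class TestActiveSelection:
    @pytest.mark.parametrize(
        "wt,ko,kept",
        [
            (20, 3, True),  # above the floor in WT only
            (16, 16, False),  # exactly at the floor: strict >
            (0, 30, True),  # active in at least one condition
        ],
    )
    def test_floor_semantics(self, wt, ko, kept):
        peaks = PeakSet("p", [mk_peak("p1", 1000)])
        cm = mk_matrix({"wt": [wt], "ko": [ko]}, ["p1"])
        out = select_active_enhancers(peaks, cm, floor=16.0)
        assert (len(out) == 1) == kept

    def test_mismatched_matrix_errors(self):
        peaks = PeakSet("p", [mk_peak("p1", 1000)])
        cm = mk_matrix({"wt": [20], "ko": [20]}, ["other"])
        with pytest.raises(ValueError, match="absent"):
            select_active_enhancers(peaks, cm)


class TestClassification:
    @pytest.mark.parametrize(
        "bound,verdict,expected",
        [
            (True, "down", "direct_activated"),
            (True, "up", "direct_repressed"),
            (False, "down", "indirect_activated"),
            (False, "up", "indirect_repressed"),
            (True, "unchanged", "unclassified"),
            (False, "unchanged", "unclassified"),
        ],
    )
    def test_truth_table(self, bound, verdict, expected):
        peaks = PeakSet("p", [mk_peak("p1", 1000)])
        tf = PeakSet("tf", [mk_peak("t1", 1000)] if bound else [])
        diff = pd.DataFrame({"verdict": [verdict]}, index=["p1"])
        [rec] = classify_enhancers(peaks, diff, tf)
        assert rec.enh_class == expected

    def test_missing_diff_entry_errors_with_ids(self):
        peaks = PeakSet("p", [mk_peak("p1", 1000)])
        diff = pd.DataFrame({"verdict": []}, index=pd.Index([], dtype=object))
        with pytest.raises(ValueError, match="p1"):
            classify_enhancers(peaks, diff, PeakSet("tf", []))

    def test_partition_is_exhaustive_and_exclusive(self):
        bundle = generate_enhancer_study(2, n_peaks=300)
        res = nb_wald_test(bundle["h3k27ac"], "wt", "ko")
        distal = filter_distal(bundle["peaks"], bundle["genes"])
        active = select_active_enhancers(distal, bundle["h3k27ac"])
        records = classify_enhancers(active, res, bundle["tf_peaks"])
        assert len(records) == len(active)
        assert all(r.enh_class in ENHANCER_CLASSES for r in records)

    def test_planted_class_recovery_at_default_effect_size(self):
        """>= 95% of planted four-class labels recovered at 4-fold H3K27ac
        effects, dispersion 0.05, two replicates per condition."""
        bundle = generate_enhancer_study(21, n_peaks=2000)
        truth = bundle["truth"].peak_class
        res = nb_wald_test(bundle["h3k27ac"], "wt", "ko")
        distal = filter_distal(bundle["peaks"], bundle["genes"])
        active = select_active_enhancers(distal, bundle["h3k27ac"])
        records = classify_enhancers(active, res, bundle["tf_peaks"])
        by_id = {r.peak_id: r.enh_class for r in records}
        planted = {p: c for p, c in truth.items() if c != "unclassified"}
        hits = sum(1 for p, c in planted.items() if by_id.get(p) == c)
        assert hits / len(planted) >= 0.95


class TestSuperEnhancers:
    def test_stitching_distance(self):
        near = PeakSet("p", [mk_peak("a", 5000, width=500),
                             mk_peak("b", 5000 + 10_000, width=500)])
        far = PeakSet("p", [mk_peak("a", 5000, width=500),
                            mk_peak("b", 5000 + 20_500, width=500)])
        assert len(call_super_enhancers(near)) == 1
        assert len(call_super_enhancers(far)) == 2

    def test_elbow_flags_exactly_the_high_plateau(self):
        # two dominant regions over a flat background of small ones
        signals = [1000, 900] + list(range(10, 0, -1))
        peaks = PeakSet("p", [mk_peak(f"p{i}", 100_000 * (i + 1), score=s)
                              for i, s in enumerate(signals)])
        ses = call_super_enhancers(peaks)
        supers = [se for se in ses if se.is_super]
        assert sorted(se.total_signal for se in supers) == [900, 1000]

    def test_elbow_matches_brute_force_tangent_scan(self):
        rng = np.random.default_rng(8)
        signals = np.concatenate([rng.uniform(1, 50, 100), rng.uniform(400, 800, 6)])
        cutoff = superenhancer_cutoff(signals)
        y = np.sort(signals)
        ys = (y - y[0]) / (y[-1] - y[0])
        xs = np.arange(y.size) / (y.size - 1)
        best = min(range(y.size), key=lambda i: ys[i] - xs[i])
        assert cutoff == y[best]

    def test_degenerate_all_equal_flags_none(self):
        peaks = PeakSet("p", [mk_peak(f"p{i}", 100_000 * (i + 1), score=5.0)
                              for i in range(10)])
        assert not any(se.is_super for se in call_super_enhancers(peaks))

    def test_fewer_than_three_regions_warns_and_flags_none(self):
        peaks = PeakSet("p", [mk_peak("a", 5000, score=10),
                              mk_peak("b", 10**6, score=1000)])
        with pytest.warns(UserWarning, match="elbow"):
            ses = call_super_enhancers(peaks)
        assert not any(se.is_super for se in ses)

    def test_order_invariance_and_signal_conservation(self):
        peaks, _ = generate_se_landscape(4, n_typical=50, n_super=3)
        shuffled = PeakSet("s", list(peaks)[::-1])
        a = call_super_enhancers(peaks)
        b = call_super_enhancers(shuffled)
        key = lambda se: (se.region.chrom, se.region.start)
        assert [(key(x), x.is_super) for x in sorted(a, key=key)] == [
            (key(x), x.is_super) for x in sorted(b, key=key)]
        for se in a:
            expected = sum(peaks[pid].score for pid in se.constituents)
            assert se.total_signal == pytest.approx(expected)

    def test_planted_super_enhancers_recovered_exactly(self):
        peaks, truth = generate_se_landscape(31)
        ses = call_super_enhancers(peaks)
        called = {frozenset(se.constituents) for se in ses if se.is_super}
        assert called == {frozenset(m) for m in truth.super_enhancers}


def brute_force_hypergeom_upper(k, N, K, n):
    return sum(
        comb(K, j, exact=True) * comb(N - K, n - j, exact=True)
        for j in range(k, min(K, n) + 1)
    ) / comb(N, n, exact=True)


class TestClassGeneReport:
    def make_records(self, genes, cls="direct_activated"):
        return [
            EnhancerRecord(f"p{i}", 20, 5, "down", True, cls, g)
            for i, g in enumerate(genes)
        ]

    def test_counts_fractions_and_fisher_p(self):
        records = self.make_records([f"g{i}" for i in range(1, 11)])
        down = {f"g{i}" for i in range(1, 6)} | {f"g{i}" for i in range(90, 100)}
        reports = {r.enh_class: r for r in class_gene_report(records, set(), down, 100)}
        r = reports["direct_activated"]
        assert (r.n_genes, r.n_down, r.frac_down) == (10, 5, 0.5)
        assert r.fisher_p_down == pytest.approx(
            brute_force_hypergeom_upper(5, 100, 15, 10))

    def test_no_overlap_and_full_overlap(self):
        records = self.make_records(["a", "b"])
        rep = {r.enh_class: r for r in class_gene_report(records, set(), {"x", "y"}, 50)}
        assert rep["direct_activated"].frac_down == 0.0
        assert rep["direct_activated"].fisher_p_down >= 0.5
        rep2 = {r.enh_class: r
                for r in class_gene_report(records, set(), {"a", "b"}, 50)}
        assert rep2["direct_activated"].frac_down == 1.0

    def test_fisher_matches_oracle_over_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            N = int(rng.integers(10, 200))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(0, min(K, n) + 1))
            from enhancerkit.stats import hypergeom_upper_tail
            assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(
                brute_force_hypergeom_upper(k, N, K, n), rel=1e-9)

    def test_universe_smaller_than_margin_errors(self):
        records = self.make_records(["a", "b", "c"])
        with pytest.raises(ValueError, match="universe"):
            class_gene_report(records, set(), {"a", "b", "c", "d"}, 2)


class TestOverlapSummary:
    @pytest.mark.parametrize(
        "total,overlapping,pct",
        [(7985, 5750, 72), (645, 484, 75), (667, 309, 46), (3213, 714, 22),
         (2493, 1058, 42), (560, 200, 36), (439, 153, 35), (100, 0, 0)],
    )
    def test_printed_percentage_pairs(self, total, overlapping, pct):
        assert overlap_summary(total, overlapping).percent == pct

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            overlap_summary(0, 0)
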