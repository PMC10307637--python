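import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from enhancerkit.motifs import (
    PWM,
    AlignmentMap,
    MotifMatch,
    VariantPairSet,
    align_pair,
    cluster_motifs,
    map_conserved_motifs,
    motif_enrichment,
    motif_mutation_association,
    pwm_score,
    read_jaspar,
    reverse_complement,
    scan_sequence,
    write_jaspar,
)
from enhancerkit.simulate import consensus_pwm, generate_strain_pairs, random_pwms
from enhancerkit.stats import wilcoxon_signed_rank


class TestPwmScore:
    def test_background_matched_columns_score_zero(self):
        pwm = PWM("flat", np.full((6, 4), 0.25), pseudocount=0.0)
        assert pwm_score(pwm, "ACGTAC") == pytest.approx(0.0)

    def test_four_bits_means_sixteen_fold(self):
        """Two perfectly informative columns against uniform background score
        2 * log2(4) = 4 bits, a 2^4 = 16-fold likelihood ratio."""
        probs = np.full((4, 4), 0.25)
        probs[0] = probs[1] = [1.0, 0.0, 0.0, 0.0]
        pwm = PWM("m", probs, pseudocount=0.0)
        score = sum(pwm._log_odds[i, 0] for i in range(2))
        assert score == pytest.approx(4.0)
        assert 2.0**score == pytest.approx(16.0)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(2)
        probs = rng.dirichlet(np.ones(4), size=8)
        pwm = PWM("m", probs)
        window = "ACGTTGCA"
        assert pwm_score(pwm.reverse_complement(), reverse_complement(window)) == (
            pytest.approx(pwm_score(pwm, window)))

    def test_ambiguous_base_contributes_zero_bits(self):
        pwm = consensus_pwm("m", "ACGT", p_match=0.97)
        with_n = pwm_score(pwm, "NCGT")
        without_first = sum(pwm._log_odds[i, "ACGT".index(b)]
                            for i, b in enumerate("ACGT") if i > 0)
        assert with_n == pytest.approx(without_first)


class TestScan:
    def test_planted_consensus_found_at_position(self):
        rng = np.random.default_rng(4)
        pwm = consensus_pwm("m", "TGACGTCA")
        seq = list(rng.choice(list("ACGT"), size=100))
        seq[37:45] = list("TGACGTCA")
        matches = scan_sequence(pwm, "".join(seq), threshold=4.0)
        assert any(m.start == 37 and m.strand == "+" for m in matches)

    def test_all_n_sequence_yields_nothing(self):
        pwm = consensus_pwm("m", "ACGTACGT")
        assert scan_sequence(pwm, "N" * 50, threshold=4.0) == []

    def test_minus_infinity_threshold_counts_all_windows(self):
        pwm = consensus_pwm("m", "ACGTAC")
        seq = "ACGT" * 10
        matches = scan_sequence(pwm, seq, threshold=-np.inf)
        assert len(matches) == 2 * (len(seq) - len(pwm) + 1)

    def test_short_sequence_yields_empty(self):
        pwm = consensus_pwm("m", "ACGTACGT")
        assert scan_sequence(pwm, "ACG") == []

    def test_matches_naive_window_oracle(self):
        rng = np.random.default_rng(11)
        pwm = PWM("m", rng.dirichlet(np.ones(4) * 0.4, size=9))
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        got = {(m.start, m.strand): m.score for m in scan_sequence(pwm, seq, 2.0)}
        expect = {}
        rc_pwm = pwm.reverse_complement()
        for i in range(len(seq) - len(pwm) + 1):
            win = seq[i : i + len(pwm)]
            for strand, score in (("+", pwm_score(pwm, win)),
                                  ("-", pwm_score(rc_pwm, win))):
                if score > 2.0:
                    expect[(i, strand)] = score
        assert set(got) == set(expect)
        for k in got:
            assert got[k] == pytest.approx(expect[k])


class TestJasparIO:
    def test_round_trip(self, tmp_path):
        pwms = random_pwms(3, 4, length=8)
        path = tmp_path / "lib.jaspar"
        write_jaspar(pwms, path)
        back = read_jaspar(path)
        assert [p.name for p in back] == [p.name for p in pwms]
        for a, b in zip(pwms, back):
            assert np.allclose(a.probs, b.probs, atol=1e-3)


class TestEnrichment:
    def test_exact_binomial_example(self):
        """All 10 targets carry the motif while half of the background does:
        p = 0.5^10."""
        pwm = consensus_pwm("m", "TGACGTCAGT")
        hit = "A" * 20 + "TGACGTCAGT" + "A" * 20
        miss = "A" * 50
        targets = [hit] * 10
        background = [hit] * 50 + [miss] * 50
        res = motif_enrichment(targets, background, [pwm], gc_match=False)
        assert res.loc["m", "pct_target"] == 1.0
        assert res.loc["m", "pct_bkgd"] == pytest.approx(0.5)
        assert res.loc["m", "p"] == pytest.approx(0.5**10)

    def test_null_motif_is_not_significant(self):
        rng = np.random.default_rng(6)
        seqs = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(60)]
        pwm = consensus_pwm("m", "TGACGTCAGT")
        res = motif_enrichment(seqs[:30], seqs[30:], [pwm], seed=1)
        assert res.loc["m", "p"] >= 0.4

    def test_zero_target_matches_reports_p_one(self):
        pwm = consensus_pwm("m", "TGACGTCAGT")
        res = motif_enrichment(["A" * 40] * 5, ["A" * 40] * 10, [pwm])
        assert res.loc["m", "p"] == 1.0

    def test_empty_targets_error(self):
        with pytest.raises(ValueError, match="target"):
            motif_enrichment([], ["ACGT"], [consensus_pwm("m", "ACGTA")])

    def test_gc_matching_shifts_background_composition(self):
        rng = np.random.default_rng(8)
        gc_rich = ["".join(rng.choice(list("GC"), size=60)) for _ in range(40)]
        at_rich = ["".join(rng.choice(list("AT"), size=60)) for _ in range(40)]
        from enhancerkit.motifs import _gc_matched_sample, gc_fraction
        sample = _gc_matched_sample(gc_rich, gc_rich + at_rich,
                                    np.random.default_rng(0))
        mean_gc = np.mean([gc_fraction(s) for s in sample])
        assert mean_gc > 0.9


class TestConservation:
    def setup_method(self):
        self.pwm = consensus_pwm("m", "TGACGTCA")
        rng = np.random.default_rng(5)
        seq = list(rng.choice(list("ACGT"), size=60))
        seq[20:28] = list("TGACGTCA")
        self.seq_a = "".join(seq)

    def test_identity_alignment_conserves_everything(self):
        matches = scan_sequence(self.pwm, self.seq_a, 4.0)
        amap = AlignmentMap.from_blocks([(0, 0, len(self.seq_a))])
        out = map_conserved_motifs(matches, self.seq_a, amap, [self.pwm])
        assert out == matches

    def test_identity_symmetry(self):
        matches = scan_sequence(self.pwm, self.seq_a, 4.0)
        amap = AlignmentMap.from_blocks([(0, 0, len(self.seq_a))])
        fwd = map_conserved_motifs(matches, self.seq_a, amap, [self.pwm])
        rev = map_conserved_motifs(matches, self.seq_a, amap.reversed(), [self.pwm])
        assert fwd == rev

    def test_upstream_insertion_shifts_projection(self):
        seq_b = self.seq_a[:10] + "GG" + self.seq_a[10:]
        a_g = self.seq_a[:10] + "--" + self.seq_a[10:]
        amap = AlignmentMap.from_gapped(a_g, seq_b)
        matches = scan_sequence(self.pwm, self.seq_a, 4.0)
        out = map_conserved_motifs(matches, seq_b, amap, [self.pwm])
        assert out == matches  # still conserved, projected +2

    def test_motif_straddling_gap_is_not_conserved(self):
        # delete 5 of the 8 motif bases in b: majority unaligned
        seq_b = self.seq_a[:21] + self.seq_a[26:]
        a_g = self.seq_a
        b_g = self.seq_a[:21] + "-" * 5 + self.seq_a[26:]
        amap = AlignmentMap.from_gapped(a_g, b_g)
        matches = scan_sequence(self.pwm, self.seq_a, 4.0)
        out = map_conserved_motifs(matches, seq_b, amap, [self.pwm])
        assert out == []

    def test_match_outside_alignment_errors(self):
        amap = AlignmentMap.from_blocks([(40, 40, 10)])
        m = MotifMatch("m", 0, 8, "+", 10.0)
        with pytest.raises(ValueError, match="outside"):
            map_conserved_motifs([m], self.seq_a, amap, [self.pwm])

    def test_convenience_aligner_recovers_identity(self):
        amap = align_pair(self.seq_a, self.seq_a)
        assert np.array_equal(amap.a_positions, amap.b_positions)
        assert amap.a_positions.size == len(self.seq_a)


class TestWilcoxon:
    def test_three_positive_differences(self):
        w, p, n = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert (w, n) == (6.0, 3)
        assert p == pytest.approx(2 * (1 / 8))

    def test_all_zero_differences(self):
        w, p, n = wilcoxon_signed_rank(np.zeros(5))
        assert (p, n) == (1.0, 0)

    def test_exact_matches_full_sign_enumeration(self):
        rng = np.random.default_rng(13)
        for n in (4, 7, 10, 12):
            d = rng.normal(size=n)
            d = np.where(d == 0, 0.1, d)
            _, p, _ = wilcoxon_signed_rank(d)
            ranks = sps.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            total = [sum(r for r, s in zip(ranks, signs) if s)
                     for signs in itertools.product([False, True], repeat=n)]
            total = np.array(total)
            p_ge = (total >= w_obs - 1e-9).mean()
            p_le = (total <= w_obs + 1e-9).mean()
            expect = min(1.0, 2 * min(p_ge, p_le))
            assert p == pytest.approx(expect)

    def test_agrees_with_scipy_exact_when_no_ties(self):
        rng = np.random.default_rng(14)
        d = rng.normal(size=15)
        _, p, _ = wilcoxon_signed_rank(d)
        assert p == pytest.approx(sps.wilcoxon(d, method="exact").pvalue)

    def test_large_n_normal_approximation_is_sane(self):
        rng = np.random.default_rng(15)
        d = rng.normal(0.5, 1.0, size=200)
        _, p, _ = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, correction=True, method="approx").pvalue
        assert p == pytest.approx(ref, rel=1e-6)


class TestMutationAssociation:
    def test_planted_causal_motif_ranks_first(self):
        """With 80% causal-site mutation across 100 loci the causal PWM beats
        20 decoys and carries a positive sign (motif loss tracks binding loss)."""
        pairs, truth, causal, decoys = generate_strain_pairs(
            7, n_loci=100, mutation_rate=0.8)
        res, _ = motif_mutation_association(pairs, [causal] + decoys)
        ranked = res["signed_logp"].abs().sort_values(ascending=False)
        assert ranked.index[0] == "causal"
        assert res.loc["causal", "signed_logp"] > 0
        assert res.loc["causal", "padj"] < 0.001

    def test_null_mutation_rate_gives_calibrated_p(self):
        rej = []
        for rep in range(20):
            pairs, *_ = generate_strain_pairs(500 + rep, n_loci=150,
                                              mutation_rate=0.0)
            decoys = random_pwms(999, 10)
            res, _ = motif_mutation_association(pairs, decoys)
            rej.extend(res["p"] < 0.05)
        assert 0.03 <= np.mean(rej) <= 0.07

    def test_underpowered_flag(self):
        pairs = VariantPairSet([("l1", "ACGTACGTAC", "ACGTACGTAC"),
                                ("l2", "TTTTGACGTC", "TTTTGACGAA")])
        res, _ = motif_mutation_association(pairs, [consensus_pwm("m", "TGACGTCA")])
        assert bool(res.loc["m", "underpowered"])

    def test_identical_pairs_give_p_one(self):
        pairs = VariantPairSet([(f"l{i}", "ACGTACGTACGT", "ACGTACGTACGT")
                                for i in range(10)])
        res, _ = motif_mutation_association(pairs, [consensus_pwm("m", "ACGTACGT")])
        assert res.loc["m", "p"] == 1.0
        assert res.loc["m", "n_informative"] == 0

    def test_expressed_flag_from_tpm(self):
        from enhancerkit.simulate import generate_expression
        table, _ = generate_expression(3, n_genes=50, n_signature=0, n_deg=0)
        gene = table.gene_ids[0]
        pairs, _, causal, _ = generate_strain_pairs(8, n_loci=10)
        pwm = PWM(gene.upper(), causal.probs)
        res, _ = motif_mutation_association(pairs, [pwm], expression=table,
                                            focal_group="microglia_wt")
        assert res.loc[gene.upper(), "expressed"] in (True, False)
        assert res.loc[gene.upper(), "expressed"] == bool(
            table.group_mean_tpm().loc[gene, "microglia_wt"] > 2)


class TestClusterMotifs:
    def mk_results(self, names):
        return pd.DataFrame(
            {"n_informative": 10, "W": 1.0, "p": 0.5, "padj": 0.5,
             "signed_logp": np.arange(1.0, len(names) + 1.0),
             "underpowered": False, "expressed": True},
            index=pd.Index(names, name="motif"),
        )

    def test_two_blocks_make_two_clusters(self):
        rng = np.random.default_rng(17)
        base1 = rng.normal(size=200)
        base2 = rng.normal(size=200)
        d = pd.DataFrame({
            "a1": base1 + rng.normal(0, 0.2, 200),
            "a2": base1 + rng.normal(0, 0.2, 200),
            "b1": base2 + rng.normal(0, 0.2, 200),
            "b2": base2 + rng.normal(0, 0.2, 200),
        })
        out = cluster_motifs(self.mk_results(d.columns), d)
        assert out.loc["a1", "cluster_id"] == out.loc["a2", "cluster_id"]
        assert out.loc["b1", "cluster_id"] == out.loc["b2", "cluster_id"]
        assert out.loc["a1", "cluster_id"] != out.loc["b1", "cluster_id"]
        members = out[out["cluster_id"] == out.loc["a1", "cluster_id"]]
        assert out.loc["a1", "cluster_signed_logp"] == pytest.approx(
            members["signed_logp"].mean())

    def test_uncorrelated_vectors_stay_singletons(self):
        rng = np.random.default_rng(18)
        d = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("wxyz"))
        out = cluster_motifs(self.mk_results(d.columns), d)
        assert out["cluster_id"].nunique() == 4

    def test_chain_links_into_one_cluster_under_single_linkage(self):
        n = 400
        rng = np.random.default_rng(19)
        a = rng.normal(size=n)
        c = rng.normal(size=n)
        b = (a + c) / np.sqrt(2) + rng.normal(0, 0.35, n)
        d = pd.DataFrame({"A": a, "B": b, "C": c})
        corr = d.corr()
        assert corr.loc["A", "B"] > 0.6 and corr.loc["B", "C"] > 0.6
        assert corr.loc["A", "C"] < 0.6
        out = cluster_motifs(self.mk_results(d.columns), d)
        assert out["cluster_id"].nunique() == 1

    def test_constant_vector_becomes_singleton_with_warning(self):
        rng = np.random.default_rng(20)
        d = pd.DataFrame({"flat": np.zeros(50), "x": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="constant"):
            out = cluster_motifs(self.mk_results(d.columns), d)
        assert out["cluster_id"].nunique() == 2
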