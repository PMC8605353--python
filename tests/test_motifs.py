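import numpy as np
import pytest
from scipy import stats

from rbpsite.motifs import (ConsensusScanner, KmerSeedResult, MotifDiscovery,
                            PrimeMotif, cluster_prime_motifs,
                            consensus_identity, enumerate_seed_spectrum,
                            expand_seed, find_mutually_exclusive,
                            mismatch_budget, null_probability, seed_enrichment,
                            seed_presence_counts, select_prime)
from rbpsite.simulate import SimulationConfig, null_corpus, simulate_peakset


def make_motif(consensus, coverage=0.9, identity=1.0, pvalue=1e-10,
               kind="primary"):
    pwm = np.zeros((4, len(consensus)))
    idx = {"A": 0, "C": 1, "G": 2, "U": 3}
    for j, ch in enumerate(consensus):
        pwm[idx[ch], j] = 100
    return PrimeMotif(consensus, pwm, coverage, set(), kind, pvalue, identity)


class TestSeedSpectrum:
    def test_full_6mer_spectrum(self):
        spectrum = enumerate_seed_spectrum()
        assert len(spectrum) == 4096
        assert spectrum[0] == "AAAAAA"
        assert len(set(spectrum)) == 4096


class TestMismatchBudget:
    def test_seed_stage_allows_two(self):
        assert mismatch_budget(6) == 2

    @pytest.mark.parametrize("k,budget", [(7, 2), (8, 2), (9, 2), (10, 3)])
    def test_thirty_percent_rule_for_expanded(self, k, budget):
        assert mismatch_budget(k) == budget


class TestNullProbability:
    def test_plain_fraction(self):
        corpus = ["GGGACGUACGGG"] * 23 + ["GGGGGGGGGGGG"] * 77
        assert null_probability("ACGUAC", corpus, 0) == pytest.approx(0.23)

    def test_zero_count_floored_at_pseudo_probability(self):
        corpus = ["GGGGGGGGGG"] * 1000
        assert null_probability("AAAAAA", corpus, 0) == pytest.approx(1 / 2000)

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(1)
        corpus = ["".join(rng.choice(list("ACGU"), size=40)) for _ in range(200)]
        p0 = null_probability("ACGUAC", corpus, 0)
        p2 = null_probability("ACGUAC", corpus, 2)
        assert p0 <= p2


class TestSeedEnrichment:
    def test_exact_binomial_tail_all_successes(self):
        peaks = ["GGGACGUACGGG"] * 10  # every peak carries the seed exactly
        res = seed_enrichment(peaks, "ACGUAC", 0, p0=0.5)
        assert res.x == 10
        assert res.pvalue == pytest.approx(0.5**10)

    def test_zero_hits_give_pvalue_one(self):
        peaks = ["GGGGGGGGGGGG"] * 10
        res = seed_enrichment(peaks, "AAAAAA", 0, p0=0.3)
        assert res.x == 0
        assert res.pvalue == pytest.approx(1.0)

    def test_coverage_without_enrichment_is_not_significant(self):
        # 70/100 peaks carry the seed but the null rate is also 0.7
        peaks = ["GGGACGUACGGG"] * 70 + ["GGGGGGGGGGGG"] * 30
        res = seed_enrichment(peaks, "ACGUAC", 0, p0=0.7)
        expected = stats.binom.sf(69, 100, 0.7)
        assert res.pvalue == pytest.approx(expected)
        assert res.pvalue > 0.4  # ~0.53: nowhere near the 0.01 cutoff
        assert not res.significant

    def test_p0_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            seed_enrichment(["ACGUAC"], "ACGUAC", 0, p0=1.0)

    def test_pvalue_decreases_with_x(self):
        pv = [float(stats.binom.sf(x - 1, 50, 0.2)) for x in range(0, 51, 5)]
        assert all(a >= b for a, b in zip(pv, pv[1:]))


class TestSeedPresenceCounts:
    def test_agrees_with_fm_inexact_search(self, rng):
        """The ball-intersection counting route must equal FM-searching
        every relative of every seed."""
        from rbpsite.fm import MultiSequenceIndex
        from rbpsite.kmercode import encode_kmer

        seqs = ["".join(rng.choice(list("ACGU"), size=30)) for _ in range(15)]
        counts = seed_presence_counts(seqs, 4, 1)
        idx = MultiSequenceIndex(seqs)
        for seed in ("ACGU", "AAAA", "GCGC", "UGCA"):
            fm_count = len(idx.inexact_locate(seed, 1))
            assert counts[encode_kmer(seed)] == fm_count


class TestExpansion:
    def test_exact_recovery_with_zero_noise(self):
        rng = np.random.default_rng(5)
        peaks = []
        for _ in range(60):
            left = "".join(rng.choice(list("ACGU"), size=12))
            right = "".join(rng.choice(list("ACGU"), size=12))
            peaks.append(left + "UGCAUGCC" + right)
        sr = KmerSeedResult("GCAUGC", 2, 60, 60, 0.1, 1e-20, True)
        motif = expand_seed(sr, peaks)
        assert motif.consensus == "UGCAUGCC"
        assert motif.coverage >= 0.95

    def test_unexpandable_seed_returned_unchanged(self):
        # seed present exactly, but flanks are maximally discordant
        rng = np.random.default_rng(6)
        peaks = []
        for i in range(40):
            left = "ACGU"[i % 4] * 5
            right = "UGCA"[i % 4] * 5
            peaks.append(left + "ACGUAC" + right)
        sr = KmerSeedResult("ACGUAC", 2, 40, 40, 0.1, 1e-20, True)
        motif = expand_seed(sr, peaks, min_coverage=0.95)
        assert motif.consensus == "ACGUAC"

    def test_seed_absent_raises(self):
        sr = KmerSeedResult("AAAAAA", 2, 0, 5, 0.1, 1.0, False)
        with pytest.raises(ValueError):
            expand_seed(sr, ["GGGGGGGGGG", "CCCCCCCCCC"], min_coverage=0.5)

    def test_pwm_column_sums_equal_matched_instances(self):
        peaks = ["GGGGUGCAUGCCGGGG"] * 30
        sr = KmerSeedResult("GCAUGC", 2, 30, 30, 0.1, 1e-20, True)
        motif = expand_seed(sr, peaks)
        assert np.all(motif.pwm.sum(axis=0) == len(motif.matched_peak_ids))

    def test_expansion_never_increases_coverage_at_fixed_budget(
            self, planted_corpus):
        """Coverage is monotone non-increasing along the expansion path
        wherever the mismatch budget stays constant (lengths 6..9 share
        budget 2; the 30% rule raises it to 3 only at length 10)."""
        peaks = planted_corpus["peak_seqs"]
        scanner = ConsensusScanner(peaks)
        cons = "GCAUGC"
        prev = None
        while len(cons) <= 10:
            budget = mismatch_budget(len(cons))
            m, _, _ = scanner.best_matches(cons, budget)
            cov = m.mean()
            if prev is not None and budget == prev[1]:
                assert cov <= prev[0] + 1e-12
            prev = (cov, budget)
            cons = "U" + cons if len(cons) % 2 == 0 else cons + "C"


class TestSelectPrime:
    def test_higher_coverage_wins(self):
        a, b = make_motif("ACGUAC", 0.92), make_motif("UGCAUG", 0.75)
        assert select_prime([a, b]) is a

    def test_equal_coverage_longer_wins(self):
        a, b = make_motif("ACGUACGA", 0.8), make_motif("ACGUACG", 0.8)
        assert select_prime([a, b]) is a

    def test_full_tie_alphabetical(self):
        a, b = make_motif("ACGUAC", 0.8), make_motif("UGCAUG", 0.8)
        assert select_prime([b, a]) is a

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_prime([])


class TestClustering:
    def test_identical_motifs_one_cluster(self):
        motifs = [make_motif("UGCAUG"), make_motif("UGCAUG")]
        assert cluster_prime_motifs(motifs) == [[0, 1]]

    def test_dissimilar_motifs_separate(self):
        # best-offset identity 2/6 < 0.7
        assert consensus_identity("UGCAUG", "ACGACG") < 0.7
        motifs = [make_motif("UGCAUG"), make_motif("ACGACG")]
        assert cluster_prime_motifs(motifs) == [[0], [1]]

    def test_single_linkage_transitivity(self):
        # A~B and B~C above threshold, A~C below: one cluster
        a, b, c = (make_motif("AAAAAA"), make_motif("AAAACC"),
                   make_motif("CCAACC"))
        assert consensus_identity("AAAAAA", "AAAACC") >= 0.65
        clusters = cluster_prime_motifs([a, b, c], min_similarity=0.6)
        assert clusters == [[0, 1, 2]]


class TestDiscovery:
    def test_planted_motif_recovered(self, planted_corpus):
        disc = MotifDiscovery(find_exclusive=False)
        disc.fit(planted_corpus["peak_seqs"], null_corpus=planted_corpus["null"])
        assert disc.prime_motif_.consensus == planted_corpus["config"].motif
        assert disc.prime_motif_.coverage >= 0.70
        assert disc.prime_motif_.pvalue <= 0.01

    def test_requires_null_corpus(self, planted_corpus):
        with pytest.raises(TypeError):
            MotifDiscovery().fit(planted_corpus["peak_seqs"])

    def test_get_set_params_round_trip(self):
        disc = MotifDiscovery()
        params = disc.get_params()
        disc.set_params(p_cutoff=0.05)
        assert disc.get_params()["p_cutoff"] == 0.05
        with pytest.raises(ValueError):
            disc.set_params(bogus=1)
        assert set(params) >= {"seed_k", "seed_radius", "p_cutoff"}

    def test_two_planted_motifs_yield_mutually_exclusive_partition(self):
        """Two motifs planted in disjoint halves of the corpus: the
        primary motif covers one, the recursive residual pass the other,
        with small instance overlap."""
        cfgA = SimulationConfig(rng_seed=7, n_peaks=250, coverage=0.9)
        cfgB = SimulationConfig(rng_seed=8, n_peaks=250, coverage=0.8,
                                motif="AAGGUAAG")
        txA, pkA, _ = simulate_peakset(cfgA)
        txB, pkB, _ = simulate_peakset(cfgB)
        seqs = ([txA[p.chrom][p.start : p.end] for p in pkA]
                + [txB[p.chrom][p.start : p.end] for p in pkB])
        null = null_corpus(cfgA, [len(s) for s in seqs])
        disc = MotifDiscovery().fit(seqs, null_corpus=null)
        kinds = [m.kind for m in disc.motifs_]
        assert kinds[0] == "primary"
        assert "mutually_exclusive" in kinds[1:]
        recovered = [m.consensus for m in disc.motifs_[:2]]
        for planted in (cfgA.motif, cfgB.motif):
            assert any(consensus_identity(planted, c) >= 6 / 7
                       for c in recovered), (planted, recovered)
        # pairwise instance overlap (Jaccard on peak ids) is small
        ids0 = disc.motifs_[0].matched_peak_ids
        ids1 = disc.motifs_[1].matched_peak_ids
        jacc = len(ids0 & ids1) / len(ids0 | ids1)
        assert jacc < 0.35

    def test_single_motif_data_gives_no_exclusive_motifs(self, planted_corpus):
        found = find_mutually_exclusive(
            planted_corpus["peak_seqs"],
            set(range(len(planted_corpus["peak_seqs"]))),
            planted_corpus["null"])
        assert found == []
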