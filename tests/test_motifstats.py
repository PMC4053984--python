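"""Motif match counting, binomial tails, alignments and three-way tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfbind import motifstats as ms
from zfbind.errors import IncompleteAlignmentError

BASES = "ACGT"


def _consensus_motif(consensus, defined_freq=0.7):
    return ms.FrequencyMotif.from_consensus(consensus, defined_freq)


class TestStrongMatchCount:
    def test_perfect_match_counts_all_defined_positions(self):
        motif = _consensus_motif("ACGTACGTACGTACG")  # 15 defined positions
        site = ms.SiteSequence("s", "ACGTACGTACGTACG")
        assert ms.strong_match_count(site, motif) == 15

    def test_complementary_site_matches_nothing(self):
        motif = _consensus_motif("AAAA")
        site = ms.SiteSequence("s", "TTTT")
        assert ms.strong_match_count(site, motif) == 0

    def test_undefined_positions_ignored(self):
        freq = [{b: 0.25 for b in BASES}] * 3  # nothing defined
        motif = ms.FrequencyMotif(freq)
        site = ms.SiteSequence("s", "ACG")
        assert motif.defined_positions == {}
        assert ms.strong_match_count(site, motif) == 0

    def test_uncovered_defined_position_raises(self):
        motif = _consensus_motif("ACGT")
        with pytest.raises(IncompleteAlignmentError):
            ms.strong_match_count(ms.SiteSequence("s", "ACG"), motif, offset=0)

    def test_random_sites_average_chance_expectation(self):
        """Monte-Carlo check of the 0.25-per-defined-position chance rate."""
        motif = _consensus_motif("A" * 15)
        rng = np.random.default_rng(42)
        counts = [
            ms.strong_match_count(
                ms.SiteSequence("r", "".join(rng.choice(list(BASES), 15))), motif
            )
            for _ in range(3000)
        ]
        assert np.mean(counts) == pytest.approx(3.75, abs=0.15)


class TestExpectedChanceMatches:
    @pytest.mark.parametrize("n_defined,expected", [(15, 3.75), (14, 3.5), (0, 0.0)])
    def test_uniform_background(self, n_defined, expected):
        consensus = "A" * n_defined
        if n_defined:
            motif = _consensus_motif(consensus)
        else:
            motif = ms.FrequencyMotif([{b: 0.25 for b in BASES}])
        assert ms.expected_chance_matches(motif) == expected

    def test_skewed_background(self):
        motif = _consensus_motif("AA")
        bg = {"A": 0.4, "C": 0.2, "G": 0.2, "T": 0.2}
        assert ms.expected_chance_matches(motif, bg) == pytest.approx(0.8)


class TestBinomialUpperTail:
    def test_full_support(self):
        assert ms.binomial_upper_tail(0, 15, 0.25) == pytest.approx(1.0)

    def test_exact_values(self):
        assert ms.binomial_upper_tail(12, 30, 0.25) == pytest.approx(0.0507, abs=5e-4)
        assert ms.binomial_upper_tail(30, 30, 0.25) == pytest.approx(0.25 ** 30)

    @pytest.mark.parametrize("n", [1, 4, 8, 12])
    def test_matches_brute_force_enumeration(self, n):
        """Agree exactly with enumeration of all 2^n Bernoulli outcomes."""
        p = 0.25
        for k in range(n + 1):
            brute = 0.0
            for outcome in itertools.product([0, 1], repeat=n):
                s = sum(outcome)
                if s >= k:
                    brute += p ** s * (1 - p) ** (n - s)
            assert ms.binomial_upper_tail(k, n, p) == pytest.approx(brute, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(n=st.integers(1, 40), p=st.floats(0.01, 0.99))
    def test_non_increasing_in_k(self, n, p):
        tails = [ms.binomial_upper_tail(k, n, p) for k in range(n + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))


class TestAlignment:
    def test_identical_sequences(self):
        a = ms.SiteSequence("a", "ACGTACGTACGTAC")
        offset, matches, overlap = ms.best_ungapped_alignment(a, a)
        assert (offset, matches, overlap) == (0, len(a), len(a))

    def test_planted_shared_block_recovers_offset(self):
        rng = np.random.default_rng(1)
        block = "ACGTTGCACG"
        a = ms.SiteSequence("a", "".join(rng.choice(list(BASES), 10)) + block)
        b = ms.SiteSequence("b", block + "".join(rng.choice(list(BASES), 10)))
        offset, matches, overlap = ms.best_ungapped_alignment(a, b, min_overlap=5)
        assert offset == 10
        assert matches >= 10

    def test_random_pairs_match_about_quarter_of_overlap(self):
        rng = np.random.default_rng(3)
        ratios = []
        for _ in range(300):
            a = ms.SiteSequence("a", "".join(rng.choice(list(BASES), 30)))
            # alignment at fixed full overlap: no offset optimization bias
            matches = sum(x == y for x, y in zip(a.sequence, rng.choice(list(BASES), 30)))
            ratios.append(matches / 30)
        assert np.mean(ratios) == pytest.approx(0.25, abs=0.02)

    def test_pairwise_similarity_identical(self):
        a = ms.SiteSequence("a", "ACGTACGTACGTACGTACGTACGTACGTAC")
        res = ms.pairwise_similarity_test(a, ms.SiteSequence("b", a.sequence))
        assert res["p_value"] == pytest.approx(0.25 ** 30)
        assert res["matches"] == res["n"] == 30

    def test_pairwise_similarity_counts(self):
        # 12 matches over 30 aligned columns
        assert ms.binomial_upper_tail(12, 30, 0.25) == pytest.approx(0.0507, abs=5e-4)
        # 6 matches over 30 aligned columns
        assert ms.binomial_upper_tail(6, 30, 0.25) == pytest.approx(0.797, abs=5e-3)


class TestThreewayMatch:
    def test_identical_sequences_all_triple(self):
        a = ms.SiteSequence("a", "ACGTACGTACGTACGT")
        res = ms.threeway_match_test(a, a, a)
        assert res["counts"] == {"triple": 16, "pair": 0, "none": 0}

    def test_expected_category_probabilities_sum_to_one(self):
        assert sum(ms.THREEWAY_EXPECTED.values()) == pytest.approx(1.0)

    def test_random_triples_match_independence_expectations(self):
        rng = np.random.default_rng(5)
        totals = np.zeros(3)
        n_reps = 400
        for _ in range(n_reps):
            seqs = [
                ms.SiteSequence(str(i), "".join(rng.choice(list(BASES), 32)))
                for i in range(3)
            ]
            res = ms.threeway_match_test(*seqs)
            totals += [res["counts"][k] for k in ("triple", "pair", "none")]
        mean = totals / n_reps
        assert mean == pytest.approx([2.0, 18.0, 12.0], abs=0.5)

    def test_planted_conserved_columns(self):
        rng = np.random.default_rng(11)
        # three unrelated 31-mers sharing exactly four planted triple columns
        while True:
            seqs = [rng.choice(list(BASES), 31) for _ in range(3)]
            planted = [2, 9, 17, 25]
            for i in planted:
                seqs[1][i] = seqs[2][i] = seqs[0][i]
            sites = [ms.SiteSequence(str(i), "".join(s)) for i, s in enumerate(seqs)]
            res = ms.threeway_match_test(*sites)
            if res["counts"]["triple"] == 4:  # no accidental extra triples
                break
        assert res["counts"]["triple"] == 4
        assert res["n_columns"] == 31
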