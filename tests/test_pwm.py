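"""PWM construction, exact score distributions and scanning."""

import itertools

import numpy as np
import pytest

from zfbind import pwm as pw
from zfbind.errors import SiteNotFoundError
from zfbind.motifstats import SiteSequence
from zfbind.mutscan import SpecificityProfile

BASES = "ACGT"


def _profile(b_values):
    """Profile with identical substitution B values at every position."""
    L = len(b_values)
    changes = {
        i + 1: {"A": 0.0, "C": b_values[i][0], "G": b_values[i][1], "T": b_values[i][2]}
        for i in range(L)
    }
    return SpecificityProfile(site_length=L, reference="A" * L, changes=changes)


def _random_pwm(rng, length):
    weights = rng.normal(0, 1.5, size=(length, 4))
    probs = 2.0 ** weights * 0.25
    probs /= probs.sum(axis=1, keepdims=True)
    return pw.Pwm(np.log2(probs / 0.25), np.full(4, 0.25))


class TestAffinities:
    def test_uninformative_profile(self):
        aff = pw.affinities_from_profile(
            _profile([(0.0, 0.0, 0.0)] * 4), SiteSequence("s", "AAAA")
        )
        assert np.all(aff == 1.0)

    def test_complete_loss_position_floors(self):
        aff = pw.affinities_from_profile(
            _profile([(-1.0, -1.0, -1.0)]), SiteSequence("s", "A")
        )
        assert aff[0, 0] == 1.0
        assert np.all(aff[0, 1:] == 0.01)

    def test_half_loss(self):
        aff = pw.affinities_from_profile(
            _profile([(-0.5, -0.5, -0.5)]), SiteSequence("s", "A")
        )
        assert np.all(aff[0, 1:] == 0.5)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pw.affinities_from_profile(
                _profile([(0.0, 0.0, 0.0)]), SiteSequence("s", "AA")
            )


class TestPwmFromAffinities:
    def test_small_beta_flattens_toward_background(self):
        aff = np.array([[1.0, 0.01, 0.01, 0.01]])
        matrix = pw.pwm_from_affinities(aff, beta=1e-9)
        assert matrix.weights == pytest.approx(np.zeros((1, 4)), abs=1e-6)

    def test_consensus_probability_beta_one(self):
        aff = np.array([[1.0, 0.01, 0.01, 0.01]])
        matrix = pw.pwm_from_affinities(aff, beta=1.0)
        assert matrix.probabilities[0, 0] == pytest.approx(1 / 1.03, abs=1e-6)

    def test_beta_two_sharpens(self):
        aff = np.array([[1.0, 0.3, 0.2, 0.1]])
        p1 = pw.pwm_from_affinities(aff, beta=1.0).probabilities[0, 0]
        p2 = pw.pwm_from_affinities(aff, beta=2.0).probabilities[0, 0]
        assert p2 > p1

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        aff = rng.uniform(0.01, 1.0, size=(6, 4))
        matrix = pw.pwm_from_affinities(aff, beta=1.7)
        assert matrix.probabilities.sum(axis=1) == pytest.approx(np.ones(6))


class TestScoreDistribution:
    def test_length_one_matches_base_probabilities(self):
        matrix = _random_pwm(np.random.default_rng(1), 1)
        dist = pw.score_distribution(matrix)
        assert dist.pmf.sum() == pytest.approx(1.0)
        assert np.count_nonzero(dist.pmf) <= 4

    @pytest.mark.parametrize("length", [4, 6, 8])
    def test_matches_exhaustive_enumeration(self, length):
        """DP pmf and tails agree with brute force over all 4^L windows."""
        rng = np.random.default_rng(length)
        matrix = _random_pwm(rng, length)
        dist = pw.score_distribution(matrix)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        tail = {}
        for window in itertools.product(range(4), repeat=length):
            b = int(dist.binned[np.arange(length), list(window)].sum())
            prob = float(np.prod(matrix.background[list(window)]))
            tail[b] = tail.get(b, 0.0) + prob
        # brute-force survival at every achieved binned score
        scores = sorted(tail)
        sf = 0.0
        brute_sf = {}
        for b in reversed(scores):
            sf += tail[b]
            brute_sf[b] = sf
        for b, expected_sf in brute_sf.items():
            assert dist.p_value_binned(b) == pytest.approx(expected_sf, abs=1e-10)

    def test_tail_at_minimum_score_is_one(self):
        matrix = _random_pwm(np.random.default_rng(2), 5)
        dist = pw.score_distribution(matrix)
        assert dist.p_value_binned(dist.min_bin) == pytest.approx(1.0)

    def test_tail_non_increasing_in_score(self):
        matrix = _random_pwm(np.random.default_rng(3), 5)
        dist = pw.score_distribution(matrix)
        assert np.all(np.diff(dist.sf) <= 1e-15)


class TestScan:
    def test_consensus_hit_has_minimal_p(self):
        rng = np.random.default_rng(4)
        matrix = _random_pwm(rng, 8)
        consensus = matrix.consensus()
        flank = "".join(rng.choice(list(BASES), 20))
        seq = SiteSequence("s", flank + consensus + flank)
        hits = pw.scan(seq, matrix, p_threshold=1.1)
        best = max(hits, key=lambda h: h.score)
        assert best.start == 20
        assert best.score == pytest.approx(matrix.score(consensus))

    def test_strand_symmetry(self):
        """Scanning the reverse complement mirrors hits with equal scores."""
        rng = np.random.default_rng(5)
        matrix = _random_pwm(rng, 7)
        seq = "".join(rng.choice(list(BASES), 300))
        fwd = pw.scan(SiteSequence("f", seq), matrix, p_threshold=0.05)
        rev = pw.scan(SiteSequence("r", pw.revcomp(seq)), matrix, p_threshold=0.05)
        L = len(matrix)
        mirror = {
            (len(seq) - L - h.start, {"+": "-", "-": "+"}[h.strand], round(h.score, 9))
            for h in rev
        }
        assert {(h.start, h.strand, round(h.score, 9)) for h in fwd} == mirror

    def test_short_sequence_warns_and_returns_empty(self):
        matrix = _random_pwm(np.random.default_rng(6), 10)
        with pytest.warns(UserWarning):
            assert pw.scan(SiteSequence("s", "ACGT"), matrix) == []

    def test_hit_rate_matches_exact_tail_probability(self):
        """Observed hit rate on random sequence agrees with the exact
        per-window tail mass above the threshold."""
        rng = np.random.default_rng(7)
        matrix = _random_pwm(rng, 6)
        thr = 1e-2
        dist_f = pw.ScoreDistribution(matrix)
        dist_r = pw.ScoreDistribution(matrix.reverse_complement())
        per_window = sum(
            float(d.pmf[d.sf < thr].sum()) for d in (dist_f, dist_r)
        )
        n = 60_000
        seq = "".join(rng.choice(list(BASES), n))
        hits = pw.scan(SiteSequence("s", seq), matrix, p_threshold=thr,
                       distributions=(dist_f, dist_r))
        expected = per_window * (n - len(matrix) + 1)
        assert expected > 20
        assert len(hits) == pytest.approx(expected, rel=0.35)


class TestCalibration:
    def test_planted_site_ranks_first(self, clean_profile, hotspot):
        region = SiteSequence(hotspot.name, hotspot.sequence)
        beta = pw.calibrate_beta(clean_profile, hotspot.site, region)
        matrix = pw.build_pwm(clean_profile, hotspot.site, beta=beta)
        hits = pw.scan(region, matrix, p_threshold=1e-5)
        assert hits
        best = max(hits, key=lambda h: h.score)
        assert (best.start, best.strand) == (hotspot.site_start, "+")

    def test_uninformative_profile_returns_smallest_beta(self):
        prof = _profile([(0.0, 0.0, 0.0)] * 6)
        site = SiteSequence("site", "A" * 6)
        region = SiteSequence("region", "C" * 30 + "A" * 6 + "C" * 30)
        beta = pw.calibrate_beta(prof, site, region, beta_grid=[0.5, 1.0, 2.0])
        assert beta == 0.5

    def test_single_value_grid(self, clean_profile, hotspot):
        region = SiteSequence(hotspot.name, hotspot.sequence)
        assert pw.calibrate_beta(clean_profile, hotspot.site, region, beta_grid=[1.5]) == 1.5

    def test_missing_site_raises(self, clean_profile, hotspot):
        with pytest.raises(SiteNotFoundError):
            pw.calibrate_beta(
                clean_profile, hotspot.site, SiteSequence("r", "ACGT" * 100)
            )


class TestEnrichment:
    def test_planted_sites_only_in_hotspots(self, clean_profile, hotspot, world):
        matrix = pw.build_pwm(clean_profile, hotspot.site, beta=2.0)
        # chromosome = empty flank + hotspot + empty flank
        rng = np.random.default_rng(8)
        flank = "".join(rng.choice(list(BASES), 2000))
        chrom = flank + hotspot.sequence + flank
        import pandas as pd

        bed = pd.DataFrame(
            [{"chrom": "chr1", "start": 2000, "end": 2000 + len(hotspot.sequence),
              "name": "hs"}]
        )
        table = pw.enrichment({"chr1": chrom}, bed, matrix, p_threshold=1e-5)
        assert table.loc[0, "hotspot_hits"] >= 1
        assert table.loc[0, "left_control_hits"] == 0
        assert table.loc[0, "right_control_hits"] == 0

    def test_truncated_control_warns(self, clean_profile, hotspot):
        import pandas as pd

        matrix = pw.build_pwm(clean_profile, hotspot.site, beta=1.0)
        bed = pd.DataFrame(
            [{"chrom": "c", "start": 10, "end": 600, "name": "edge"}]
        )
        with pytest.warns(UserWarning, match="truncated"):
            pw.enrichment({"c": hotspot.sequence}, bed, matrix)
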