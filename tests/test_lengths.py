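import math

import numpy as np
import pytest

from cdr3profile.io import Group
from cdr3profile.lengths import (LengthDistribution, length_distribution,
                                 length_summary)
from cdr3profile.simulate import SampleSpec, SimulationConfig, simulate_repertoire
from tests.conftest import make_repertoire


def junction(n_codons, filler="GCC"):
    return "TGT" + filler * (n_codons - 2) + "TTT"


class TestLengthDistribution:
    def test_same_length_clones_merge_to_one_entry(self):
        rep = make_repertoire([(junction(15), 3), (junction(15, "GGG"), 1)])
        dist = length_distribution(rep, scale="nt")
        assert dist.lengths == [45]
        assert dist.frequencies == [pytest.approx(1.0)]
        assert dist.unique_counts == [2]

    def test_template_weighted_frequencies(self):
        rep = make_repertoire([(junction(14), 1), (junction(16), 3)])
        dist = length_distribution(rep, scale="nt")
        assert dist.lengths == [42, 48]
        assert dist.frequencies == [pytest.approx(0.25), pytest.approx(0.75)]

    def test_frequencies_sum_to_one_and_scale_invariant(self):
        clones = [(junction(k), t) for k, t in [(7, 5), (9, 2), (12, 13)]]
        d1 = length_distribution(make_repertoire(clones))
        d2 = length_distribution(
            make_repertoire([(nt, 10 * t) for nt, t in clones]))
        assert math.fsum(d1.frequencies) == pytest.approx(1.0, abs=1e-9)
        assert d1.frequencies == pytest.approx(d2.frequencies)

    def test_only_productive_records_contribute(self):
        rep = make_repertoire([(junction(15), 1), ("TGTTAATTT", 99),
                               ("TGTGCCA", 99)])
        dist = length_distribution(rep)
        assert dist.lengths == [45]
        assert dist.frequencies == [pytest.approx(1.0)]

    def test_aa_scale_is_nt_over_three(self):
        rep = make_repertoire([(junction(14), 1), (junction(16), 3)])
        dist = length_distribution(rep, scale="aa")
        assert dist.lengths == [14, 16]

    def test_no_productive_records_gives_empty_distribution(self, caplog):
        rep = make_repertoire([("TGTTAATTT", 5)])
        with caplog.at_level("WARNING"):
            dist = length_distribution(rep)
        assert dist.lengths == []
        assert any("productive" in m for m in caplog.messages)

    def test_non_ards_like_sample_respects_length_bounds(self, rng):
        spec = SampleSpec("163", Group.NON_ARDS, 150, alpha=1.0,
                          length_range=(30, 66))
        config = SimulationConfig(seed=5, samples=[spec], shared_plan=[])
        rep, _ = simulate_repertoire(config, spec, rng)
        dist = length_distribution(rep, scale="nt")
        assert dist.min_length >= 30
        assert dist.max_length <= 66

    def test_merged_repertoire_is_weighted_mixture(self):
        a = [(junction(10), 2), (junction(12), 4)]
        b = [(junction(12), 2), (junction(20), 2)]
        merged = make_repertoire(a + b)
        da = length_distribution(make_repertoire(a))
        db = length_distribution(make_repertoire(b))
        dm = length_distribution(merged)
        wa, wb = 6 / 10, 4 / 10  # productive template shares
        mixture = {}
        for d, w in ((da, wa), (db, wb)):
            for L, f in zip(d.lengths, d.frequencies):
                mixture[L] = mixture.get(L, 0.0) + w * f
        assert dm.lengths == sorted(mixture)
        assert dm.frequencies == pytest.approx(
            [mixture[L] for L in dm.lengths])


class TestLengthSummary:
    def test_point_mass(self):
        dist = LengthDistribution(scale="nt", lengths=[45], frequencies=[1.0],
                                  unique_counts=[3])
        s = length_summary(dist)
        assert s.mean == 45 and s.variance == 0
        assert math.isnan(s.skewness) and math.isnan(s.kurtosis)

    def test_symmetric_two_point(self):
        dist = LengthDistribution(scale="nt", lengths=[30, 60],
                                  frequencies=[0.5, 0.5], unique_counts=[1, 1])
        s = length_summary(dist)
        assert s.mean == pytest.approx(45)
        assert s.skewness == pytest.approx(0, abs=1e-12)
        # two equal point masses: kurtosis of a Bernoulli-type shape
        assert s.kurtosis == pytest.approx(-2.0)

    def test_moments_match_bruteforce_on_large_sample(self, rng):
        # draws from a discrete distribution; compare against direct
        # moment sums over the raw draws
        support = np.array([30, 36, 42, 48, 54, 60])
        probs = np.array([0.05, 0.15, 0.3, 0.25, 0.15, 0.1])
        draws = rng.choice(support, size=1000, p=probs)
        vals, counts = np.unique(draws, return_counts=True)
        dist = LengthDistribution(
            scale="nt", lengths=list(map(int, vals)),
            frequencies=list(counts / counts.sum()),
            unique_counts=list(map(int, counts)))
        s = length_summary(dist, weighted=True)
        x = draws.astype(float)
        mean = x.mean()
        var = ((x - mean) ** 2).mean()
        skew = (((x - mean) / math.sqrt(var)) ** 3).mean()
        kurt = (((x - mean) / math.sqrt(var)) ** 4).mean() - 3
        assert s.mean == pytest.approx(mean, abs=1e-12)
        assert s.variance == pytest.approx(var, abs=1e-12)
        assert s.skewness == pytest.approx(skew, abs=1e-12)
        assert s.kurtosis == pytest.approx(kurt, abs=1e-12)

    def test_weighted_and_unweighted_differ_when_templates_skewed(self):
        rep = make_repertoire([(junction(10), 99), (junction(20), 1)])
        dist = length_distribution(rep)
        sw = length_summary(dist, weighted=True)
        su = length_summary(dist, weighted=False)
        assert sw.mean < su.mean  # mass sits on the short clone
        assert su.mean == pytest.approx(45)

    def test_empty_distribution_raises(self):
        with pytest.raises(ValueError):
            length_summary(LengthDistribution(scale="nt"))
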