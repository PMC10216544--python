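import numpy as np
import pytest
from scipy import stats

from cdr3profile.clonality import sample_clonality
from cdr3profile.io import Group
from cdr3profile.simulate import (SampleSpec, SimulationConfig,
                                  alpha_for_clonality, simulate_cohort,
                                  simulate_repertoire, write_truth)
from cdr3profile.io import write_metadata, write_rearrangements
from cdr3profile.translate import productive, translate_cdr3


def one_sample_config(n, alpha, seed=3, frac=0.1, length_range=(21, 69)):
    spec = SampleSpec("S", Group.UNLABELED, n, alpha=alpha,
                      length_range=length_range)
    return SimulationConfig(seed=seed, samples=[spec], shared_plan=[],
                            nonproductive_fraction=frac), spec


class TestSimulateRepertoire:
    def test_near_uniform_limit_has_low_clonality(self):
        config, spec = one_sample_config(10_000, alpha=1e6, frac=0.0)
        rep, _ = simulate_repertoire(config, spec,
                                     np.random.default_rng(config.seed))
        assert sample_clonality(rep).clonality < 0.05

    def test_small_alpha_gives_high_clonality(self):
        config, spec = one_sample_config(200, alpha=0.02, frac=0.0)
        rep, _ = simulate_repertoire(config, spec,
                                     np.random.default_rng(config.seed))
        assert 0.2 < sample_clonality(rep).clonality <= 1.0

    def test_nonproductive_fraction_recovered_by_classifier(self):
        config, spec = one_sample_config(1000, alpha=1.0, frac=0.1)
        rep, truth = simulate_repertoire(config, spec,
                                         np.random.default_rng(config.seed))
        frac_productive = len(productive(rep)) / len(rep)
        assert frac_productive == pytest.approx(0.9, abs=0.03)
        assert len(truth["nonproductive"]) == 100

    def test_productive_junctions_obey_length_and_anchor_rules(self):
        config, spec = one_sample_config(300, alpha=1.0)
        rep, _ = simulate_repertoire(config, spec,
                                     np.random.default_rng(config.seed))
        for r in productive(rep):
            assert len(r.cdr3_nt) % 3 == 0
            assert 21 <= len(r.cdr3_nt) <= 69
            assert r.cdr3_aa[0] == "C" and r.cdr3_aa[-1] == "F"

    def test_ground_truth_labels_match_classifier(self):
        config, spec = one_sample_config(400, alpha=1.0, frac=0.2)
        rep, truth = simulate_repertoire(config, spec,
                                         np.random.default_rng(config.seed))
        bad = set(truth["nonproductive"])
        for r in rep.rearrangements:
            tr = translate_cdr3(r.cdr3_nt)
            expected_bad = r.cdr3_nt in bad
            assert (not r.productive) == expected_bad
            if expected_bad:
                assert (not tr.in_frame) or tr.has_stop

    def test_powerlaw_mode_heavier_tailed_than_even_dirichlet(self):
        config, spec = one_sample_config(300, alpha=1.5, frac=0.0)
        spec.freq_model = "powerlaw"
        rep, truth = simulate_repertoire(config, spec,
                                         np.random.default_rng(8))
        p = np.sort(truth["true_frequencies"])[::-1]
        assert p[0] > 0.2  # rank-1 clone dominates under exponent 1.5
        spec.freq_model = "nope"
        with pytest.raises(ValueError, match="freq_model"):
            simulate_repertoire(config, spec, np.random.default_rng(8))

    def test_clonality_monotone_in_concentration(self):
        alphas = [0.02, 0.1, 0.5, 2.0, 10.0]
        mean_clonality = []
        for alpha in alphas:
            vals = []
            for seed in range(5):
                config, spec = one_sample_config(300, alpha=alpha, seed=seed,
                                                 frac=0.0)
                rep, _ = simulate_repertoire(
                    config, spec, np.random.default_rng(seed))
                vals.append(sample_clonality(rep).clonality)
            mean_clonality.append(np.mean(vals))
        rho, _ = stats.spearmanr(alphas, mean_clonality)
        assert rho < 0
        # strict decrease across the grid means rho = -1
        assert all(a > b for a, b in
                   zip(mean_clonality, mean_clonality[1:]))


class TestSimulateCohort:
    def test_default_preset_shape(self):
        cohort, truth = simulate_cohort(SimulationConfig(seed=2))
        assert len(cohort.repertoires) == 7
        groups = [rep.group for rep in cohort.repertoires]
        assert groups.count(Group.ARDS) == 4
        assert groups.count(Group.NON_ARDS) == 3
        sizes = sorted(len(rep) for rep in cohort.repertoires)
        assert sizes == [25, 56, 118, 169, 202, 1485, 1560]
        assert sum(sizes) == 3615

    def test_same_seed_byte_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            (tmp_path / sub).mkdir()
            cohort, truth = simulate_cohort(SimulationConfig(seed=9))
            write_rearrangements(cohort, tmp_path / sub / "r.tsv")
            write_metadata(cohort, tmp_path / sub / "m.tsv")
            write_truth(truth, tmp_path / sub / "t.json")
        for name in ("r.tsv", "m.tsv", "t.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        c1, _ = simulate_cohort(SimulationConfig(seed=1))
        c2, _ = simulate_cohort(SimulationConfig(seed=2))
        assert [r.cdr3_nt for r in c1.repertoires[0].rearrangements] != \
               [r.cdr3_nt for r in c2.repertoires[0].rearrangements]

    def test_planted_shared_clones_productive_and_deduplicated(self):
        cohort, truth = simulate_cohort(SimulationConfig(seed=4))
        for entry in truth["planted_shared"]:
            for sid in entry["samples"]:
                rep = cohort[sid]
                matches = [r for r in rep.rearrangements
                           if r.cdr3_nt == entry["cdr3_nt"]]
                assert len(matches) == 1
                assert matches[0].productive is True

    def test_infeasible_configs_rejected(self):
        spec = SampleSpec("S", Group.ARDS, 3, alpha=1.0)
        with pytest.raises(ValueError, match="budget"):
            SimulationConfig(seed=1, samples=[spec],
                             shared_plan=[(3, ("S",))])
        with pytest.raises(ValueError, match="multiple"):
            SimulationConfig(seed=1, samples=[
                SampleSpec("S", Group.ARDS, 10, alpha=1.0,
                           length_range=(22, 66))], shared_plan=[])
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, nonproductive_fraction=1.0)

    def test_alpha_for_clonality_inverts_expectation(self):
        # E[sum p^2] under Dirichlet(alpha) is (alpha+1)/(n alpha+1)
        for n, c in [(200, 0.2336), (1560, 0.095), (25, 0.2082)]:
            a = alpha_for_clonality(n, c)
            assert (a + 1) / (n * a + 1) == pytest.approx(c ** 2, rel=1e-12)
        with pytest.raises(ValueError, match="uniform floor"):
            alpha_for_clonality(25, 0.19)  # below 1/sqrt(25)
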