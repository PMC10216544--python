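import math

import numpy as np
import pytest

from cdr3profile.biochem import (DEFAULT_PKA, DEFAULT_SCHEME, CompositionTable,
                                 isoelectric_point, load_pka, net_charge,
                                 residue_composition, validate_pka)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class TestNetCharge:
    def test_strictly_decreasing_in_pH(self, rng):
        for _ in range(20):
            pep = "".join(rng.choice(list(AA20), size=12))
            phs = np.linspace(0.5, 13.5, 27)
            charges = [net_charge(pep, ph) for ph in phs]
            assert all(a > b for a, b in zip(charges, charges[1:]))

    def test_glycine_dipeptide_limits(self):
        # no ionizable side chains: termini only
        assert net_charge("GG", 0.0) == pytest.approx(1.0, abs=1e-3)
        assert net_charge("GG", 14.0) == pytest.approx(-1.0, abs=1e-3)

    def test_ddk_matches_hand_expanded_sum(self):
        # four ionizable-group families: N-term, K; C-term, 2xD
        pH = 7.0
        expected = (
            1 / (1 + 10 ** (pH - DEFAULT_PKA["N_terminus"]))
            + 1 / (1 + 10 ** (pH - DEFAULT_PKA["K"]))
            - 1 / (1 + 10 ** (DEFAULT_PKA["C_terminus"] - pH))
            - 2 / (1 + 10 ** (DEFAULT_PKA["D"] - pH))
        )
        assert net_charge("DDK", pH) == pytest.approx(expected, abs=1e-15)

    def test_nonstandard_residue_named_in_error(self):
        with pytest.raises(ValueError, match="'B'"):
            net_charge("CAB", 7.0)


class TestIsoelectricPoint:
    def test_sidechain_free_peptide_has_closed_form_pI(self):
        # only termini titrate; symmetric crossing at the pKa midpoint
        expected = (DEFAULT_PKA["N_terminus"] + DEFAULT_PKA["C_terminus"]) / 2
        assert isoelectric_point("GG").pI == pytest.approx(expected, abs=1e-3)
        assert isoelectric_point("GGAPG").pI == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("pep", ["CASSF", "GG", "CASSLGQAYEQYF"])
    def test_appending_acidic_lowers_and_basic_raises_pI(self, pep):
        base = isoelectric_point(pep).pI
        assert isoelectric_point(pep + "D").pI <= base + 1e-6
        assert isoelectric_point(pep + "K").pI >= base - 1e-6

    def test_pI_bounded_and_extremes_representable(self, rng):
        for _ in range(50):
            pep = "".join(rng.choice(list(AA20), size=int(rng.integers(3, 20))))
            pI = isoelectric_point(pep).pI
            assert 0.0 < pI < 14.0
        # reported repertoire extremes (3.17 low, 12.98 high) lie inside
        # the representable range of the model
        assert isoelectric_point("DDDDDDDD").pI < 3.17
        assert isoelectric_point("RRRRRRRR").pI > 12.98

    def test_root_is_a_sign_change_of_net_charge(self):
        pI = isoelectric_point("CASSLGQAYEQYF").pI
        assert net_charge("CASSLGQAYEQYF", pI - 0.01) > 0
        assert net_charge("CASSLGQAYEQYF", pI + 0.01) < 0

    def test_ambiguous_residues_rejected(self):
        with pytest.raises(ValueError, match="pKa"):
            isoelectric_point("CAZB")


class TestPkaTable:
    def test_load_override_and_validation(self, tmp_path):
        p = tmp_path / "pka.tsv"
        p.write_text("# custom\nK\t10.0\nH\t6.0\n")
        table = load_pka(p)
        assert table["K"] == 10.0 and table["H"] == 6.0
        assert table["R"] == DEFAULT_PKA["R"]
        with pytest.raises(ValueError, match="unknown"):
            (tmp_path / "bad.tsv").write_text("X\t7.0\n")
            load_pka(tmp_path / "bad.tsv")
        with pytest.raises(ValueError):
            validate_pka({"K": 10.0})  # missing groups


class TestResidueComposition:
    def test_single_peptide_counts(self):
        table = residue_composition(["CASSF"])
        assert table.total_residues == 5
        assert table.counts["Sulphur"] == 1
        assert table.percentages["Sulphur"] == pytest.approx(20.0)
        assert table.counts["Aliphatic"] == 1          # A
        assert table.counts["Aliphatic hydroxyl"] == 2  # S, S
        assert table.counts["Aromatic"] == 1           # F

    def test_synthetase_classes_partition_everything(self, rng):
        for _ in range(10):
            peps = ["".join(rng.choice(list(AA20), size=8)) for _ in range(5)]
            t = residue_composition(peps)
            assert (t.counts["tRNA synthetase class I"]
                    + t.counts["tRNA synthetase class II"]) == t.total_residues
            pct = t.percentages
            assert pct["tRNA synthetase class I"] + \
                pct["tRNA synthetase class II"] == pytest.approx(100.0)

    def test_six_property_groups_cover_all_but_proline(self):
        peps = ["CASSPGF", "KDYWMTH"]
        t = residue_composition(peps)
        non_trna = ["Aliphatic", "Aromatic", "Sulphur", "Basic", "Acidic",
                    "Aliphatic hydroxyl"]
        covered = sum(t.percentages[g] for g in non_trna)
        n_proline = sum(p.count("P") for p in peps)
        assert covered == pytest.approx(
            100.0 - 100.0 * n_proline / t.total_residues)

    def test_counts_additive_over_disjoint_sets(self):
        a, b = ["CASSF", "CAWF"], ["KKDE"]
        ta, tb = residue_composition(a), residue_composition(b)
        tab = residue_composition(a + b)
        for g, _ in DEFAULT_SCHEME:
            assert tab.counts[g] == ta.counts[g] + tb.counts[g]

    def test_template_weighted_mode(self):
        unw = residue_composition(["CF", "KK"])
        wt = residue_composition(["CF", "KK"], weights=[3, 1])
        assert unw.counts["Basic"] == 2
        assert wt.counts["Basic"] == 2
        assert wt.counts["Sulphur"] == 3
        assert wt.total_residues == 8

    def test_from_counts_reproduces_percentages(self):
        # times-found bookkeeping: percentage on the class I + class II total
        counts = {"Aliphatic": 1270, "tRNA synthetase class I": 1668,
                  "tRNA synthetase class II": 2957}
        t = CompositionTable.from_counts(counts)
        assert t.total_residues == 4625
        assert round(t.percentages["Aliphatic"], 2) == 27.46

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="'X'"):
            residue_composition(["CAXF"])

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            residue_composition([])
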