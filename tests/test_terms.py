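"""The ten scoring features: closed forms, counting rules, assembly."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import ddgbind as dg
from ddgbind.terms import MissingComponentError, EnergyComponents
from conftest import hbond_oracle, energy_table


class TestDeltaDelta:
    def test_hand_arithmetic(self):
        assert dg.delta_delta(-10, -4, -3, -8, -4, -3) == pytest.approx(-2.0)

    def test_identity_and_zero(self):
        assert dg.delta_delta(-8, -4, -3, -8, -4, -3) == 0.0
        assert dg.delta_delta(0, 0, 0, 0, 0, 0) == 0.0

    def test_missing_slot_named(self):
        with pytest.raises(MissingComponentError, match="e_a_mt"):
            dg.delta_delta(-10, None, -3, -8, -4, -3)


class TestEntropyHydrophobicity:
    @pytest.mark.parametrize("aa,rsasa,expected", [
        ("K", 1.0, math.log(81)),     # fully exposed Lys samples all rotamers
        ("A", 0.7, 0.0),              # single-rotamer residue contributes 0
        ("D", 0.5, math.log(9.5)),    # 0.5 * (18 - 1) + 1
    ])
    def test_entropy_closed_form(self, aa, rsasa, expected):
        assert dg.rotamer_entropy([(aa, rsasa)]) == pytest.approx(expected)

    @pytest.mark.parametrize("pairs,expected", [
        ([("W", 1.0)], -1.9),
        ([("A", 0.0), ("K", 0.0)], 0.0),
        ([("D", 0.5), ("K", 1.0)], 1.2 * 0.5 + 1.0),
    ])
    def test_hydrophobicity_closed_form(self, pairs, expected):
        assert dg.hydrophobicity(pairs) == pytest.approx(expected)

    def test_rsasa_clipped_to_unit_interval(self):
        assert dg.rotamer_entropy([("K", 1.3)]) == pytest.approx(math.log(81))
        assert dg.hydrophobicity([("W", -0.2)]) == 0.0

    def test_additive_over_disjoint_sets(self):
        part1 = [("K", 0.8), ("D", 0.3)]
        part2 = [("W", 0.6), ("Q", 0.9)]
        for fn in (dg.rotamer_entropy, dg.hydrophobicity):
            assert fn(part1 + part2) == pytest.approx(fn(part1) + fn(part2))


class TestHbonds:
    def _planted(self, distance, hydrogens=True):
        return dg.make_toy_complex(
            {"A": "GSG", "B": "GDG"},
            mutation=dg.MutationDescriptor("A", 1, "G", "G"),
            gap=12.0, seed=5, hydrogens=hydrogens,
            hbond={"donor": ("A", 2), "acceptor": ("B", 2),
                   "distance": distance})

    def test_planted_bond_within_cutoff(self):
        case = self._planted(2.3)
        counts = dg.count_hbonds(case.wt_complex, {"A"}, {"B"})
        assert counts.inter_ab == 1

    def test_beyond_cutoff_not_counted(self):
        case = self._planted(2.5)
        counts = dg.count_hbonds(case.wt_complex, {"A"}, {"B"})
        assert counts.inter_ab == 0

    def test_nonpolar_backbone_hydrogens_excluded(self):
        # place an HA right next to a partner oxygen: must not count
        case = self._planted(2.3)
        model = case.wt_complex.copy()
        acc = model.residue("B", 2).atom_coord("OD1")
        arr = model.array
        import biotite.structure as struc
        extra = struc.AtomArray(1)
        extra.coord = np.asarray([acc + np.array([0, 2.0, 0])],
                                 dtype=np.float32)
        extra.chain_id = np.array(["B"])
        extra.res_id = np.array([3])
        extra.res_name = np.array(["GLY"])
        extra.atom_name = np.array(["HA"])
        extra.element = np.array(["H"])
        extra.hetero = np.array([False])
        merged = dg.StructureModel(arr + extra)
        before = dg.count_hbonds(case.wt_complex, {"A"}, {"B"})
        after = dg.count_hbonds(merged, {"A"}, {"B"})
        assert after == before

    def test_own_hydroxyl_pair_not_counted(self):
        # Ser HG sits ~1 A from its own OG; intra-residue pairs never count
        case = dg.make_toy_complex(
            {"A": "GSG", "B": "GGG"},
            mutation=dg.MutationDescriptor("A", 1, "G", "G"),
            gap=40.0, seed=6)
        counts = dg.count_hbonds(case.wt_complex, {"A"}, {"B"})
        assert counts == dg.HBCounts(0, 0, 0)

    def test_requires_hydrogens(self):
        # gap tuned so Ser OG ... Asp OD1 sit ~2.5 A apart across partners
        case = dg.make_toy_complex(
            {"A": "GSG", "B": "GDG"},
            mutation=dg.MutationDescriptor("A", 1, "G", "G"),
            gap=9.1, seed=5, hydrogens=False)
        with pytest.raises(ValueError, match="hydrogens"):
            dg.count_hbonds(case.wt_complex, {"A"}, {"B"})
        # heavy-atom proxy mode is the documented fallback
        counts = dg.count_hbonds(case.wt_complex, {"A"}, {"B"},
                                 heavy_proxy=True)
        assert counts.inter_ab >= 1

    def test_matches_allpairs_oracle(self):
        """KD-tree counting equals a brute-force all-pairs scan."""
        case = dg.make_toy_complex(
            {"A": "SKDTQNY", "B": "YNQTDKS"},
            mutation=dg.MutationDescriptor("A", 1, "S", "A"),
            gap=14.0, seed=7,
            hbond={"donor": ("A", 5), "acceptor": ("B", 5),
                   "distance": 2.2})
        for model in (case.wt_complex, case.mt_complex):
            assert model.n_atoms <= 500
            got = dg.count_hbonds(model, {"A"}, {"B"})
            assert got == hbond_oracle(model, {"A"}, {"B"})

    def test_hbond_delta_arithmetic(self):
        wt = dg.HBCounts(inter_ab=3, intra_aa=2, intra_bb=1)
        mt = dg.HBCounts(inter_ab=4, intra_aa=2, intra_bb=1)
        assert dg.hbond_delta(wt, mt) == 1
        assert dg.hbond_delta(wt, wt) == 0
        assert dg.hbond_delta(dg.HBCounts(0, 0, 0), dg.HBCounts(0, 1, 0)) == -1


class TestCoulomb:
    def _two_charges(self, aa1, aa2, separation):
        case = dg.make_toy_complex(
            {"A": aa1, "B": aa2},
            mutation=dg.MutationDescriptor("A", 1, aa1, aa1),
            gap=separation, seed=8)
        return case.wt_complex

    def test_opposite_charges_closed_form(self):
        # one +1 (Lys NZ) and one -1 (Asp carboxylate midpoint) at eps=7:
        # E = 332.0636 * (-1) / (7 * r)
        model = self._two_charges("K", "D", 30.0)
        from ddgbind.terms import formal_charge_sites
        sites = formal_charge_sites(model)
        assert sorted(q for _, q, _ in sites) == [-1.0, 1.0]
        r = float(np.linalg.norm(sites[0][2] - sites[1][2]))
        expected = 332.0636 * (-1.0) / (7.0 * r)
        assert dg.coulomb_ee(model) == pytest.approx(expected, rel=1e-9)
        assert expected < 0

    def test_like_charges_symmetric(self):
        model_pm = self._two_charges("K", "D", 30.0)
        model_pp = self._two_charges("K", "K", 30.0)
        from ddgbind.terms import formal_charge_sites
        r_pm = np.linalg.norm(np.subtract(*[s[2] for s in
                                            formal_charge_sites(model_pm)]))
        r_pp = np.linalg.norm(np.subtract(*[s[2] for s in
                                            formal_charge_sites(model_pp)]))
        e_pm = dg.coulomb_ee(model_pm) * r_pm
        e_pp = dg.coulomb_ee(model_pp) * r_pp
        assert e_pp == pytest.approx(-e_pm, rel=1e-6)

    def test_single_charge_zero(self):
        model = self._two_charges("K", "G", 30.0)
        assert dg.coulomb_ee(model) == 0.0

    def test_bad_dielectric(self):
        model = self._two_charges("K", "D", 30.0)
        with pytest.raises(ValueError):
            dg.coulomb_ee(model, epsilon_uniform=0.0)


class TestEnergyComponentsIO:
    def _write(self, tmp_path, text):
        path = tmp_path / "energies.tsv"
        path.write_text(text)
        return path

    def test_full_case_roundtrip(self, tmp_path):
        text = ("case_id\tstate\tpart\tIE\tEE\tVE\tSP\n"
                + "\n".join(f"c1\t{s}\t{p}\t-1.0\t-2.0\t-3.0\t-4.0"
                            for s in ("WT", "MT") for p in ("AB", "A", "B")))
        comps = dg.load_energy_components(self._write(tmp_path, text))
        assert comps["c1"].dd("EE") == 0.0
        assert comps["c1"].get("WT", "AB", "IE") == -1.0

    def test_missing_column_warns_and_absent(self, tmp_path):
        text = ("case_id\tstate\tpart\tIE\tEE\tVE\n"
                "c1\tWT\tAB\t-1.0\t-2.0\t-3.0\n")
        with pytest.warns(UserWarning, match="SP"):
            comps = dg.load_energy_components(self._write(tmp_path, text))
        assert not comps["c1"].has("WT", "AB", "SP")
        with pytest.raises(MissingComponentError):
            comps["c1"].get("WT", "AB", "SP")

    def test_duplicate_row_rejected(self, tmp_path):
        text = ("case_id\tstate\tpart\tIE\tEE\tVE\tSP\n"
                "c1\tWT\tAB\t-1\t-2\t-3\t-4\n"
                "c1\tWT\tAB\t-1\t-2\t-3\t-4\n")
        with pytest.raises(ValueError, match="duplicate"):
            dg.load_energy_components(self._write(tmp_path, text))

    def test_malformed_number_rejected(self, tmp_path):
        text = ("case_id\tstate\tpart\tIE\tEE\tVE\tSP\n"
                "c1\tWT\tAB\tbad\t-2\t-3\t-4\n")
        with pytest.raises(ValueError, match="malformed|bad"):
            dg.load_energy_components(self._write(tmp_path, text))


class TestAssembleTerms:
    def test_self_mutation_zero_vector(self, self_case, full_energies):
        en = energy_table(d_ie=0.0, dd_ee=0.0, dd_ve=0.0, dd_sp=0.0)
        tv = dg.assemble_terms(self_case, energies=en)
        d = tv.as_dict()
        for name in ("d_ie", "dd_ee", "dd_ve", "dd_sp", "dd_sn", "dd_s",
                     "dd_hydr", "d_hb", "dd_sasa_over_interface"):
            assert d[name] == pytest.approx(0.0, abs=1e-9), name
        assert d["interface_mt"] > 0

    def test_imported_deltas_propagate(self, contact_case, full_energies):
        tv = dg.assemble_terms(contact_case, energies=full_energies)
        assert tv.d_ie == pytest.approx(2.0)
        assert tv.dd_ee == pytest.approx(0.5)
        assert tv.dd_ve == pytest.approx(0.5)
        assert tv.dd_sp == pytest.approx(0.5)
        assert tv.provenance["dd_ee"] == "imported"

    def test_internal_coulomb_fallback(self, contact_case):
        tv = dg.assemble_terms(contact_case)
        assert tv.dd_ee is not None
        assert tv.provenance["dd_ee"] == "internal"
        assert tv.dd_ve is None and tv.dd_sp is None

    def test_antisymmetry_under_state_swap(self, contact_case, full_energies):
        """Relabelling WT<->MT negates every mutation-difference term."""
        fwd = dg.assemble_terms(contact_case, energies=full_energies)
        swapped_case = dg.ComplexCase(
            wt_complex=contact_case.mt_complex,
            mt_complex=contact_case.wt_complex,
            partner_a_chains=contact_case.partner_a_chains,
            partner_b_chains=contact_case.partner_b_chains,
            mutation=dg.MutationDescriptor(
                contact_case.mutation.chain_id, contact_case.mutation.site,
                contact_case.mutation.mt_aa, contact_case.mutation.wt_aa))
        swapped_en = EnergyComponents()
        for (st_, pt), comps in full_energies.values.items():
            other = "MT" if st_ == "WT" else "WT"
            for comp, v in comps.items():
                swapped_en.set(other, pt, comp, v)
        rev = dg.assemble_terms(swapped_case, energies=swapped_en)
        for name in ("d_ie", "dd_ee", "dd_ve", "dd_sp", "dd_sn", "dd_s",
                     "dd_hydr", "d_hb"):
            assert rev.as_dict()[name] == pytest.approx(
                -fwd.as_dict()[name], abs=1e-9), name
        # the interface term now refers to the new "MT" (= old WT)
        wt_feats = dg.surface_features(contact_case)
        assert rev.interface_mt == pytest.approx(wt_feats["interface_wt"])

    def test_hbond_gain_detected(self):
        """A mutation creating an inter-partner hydrogen bond gives d_hb=1."""
        base = dict(chains={"A": "GSG", "B": "GDG"},
                    mutation=dg.MutationDescriptor("A", 2, "S", "S"),
                    gap=12.0, seed=5)
        wt_case = dg.make_toy_complex(**base)
        mt_case = dg.make_toy_complex(
            **base, hbond={"donor": ("A", 2), "acceptor": ("B", 2),
                           "distance": 2.2})
        hybrid = dg.ComplexCase(
            wt_complex=wt_case.wt_complex, mt_complex=mt_case.mt_complex,
            partner_a_chains={"A"}, partner_b_chains={"B"},
            mutation=wt_case.mutation)
        tv = dg.assemble_terms(hybrid)
        assert tv.d_hb == 1.0
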