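import numpy as np
import pytest

import emcharge as ec
from emcharge import methods2d
from emcharge.errors import CoverageError

from conftest import permute
from oracles import peoe_two_atoms


def diatomic(el_a="C", el_b="O", charge=0):
    spec = ec.FixtureSpec("diatomic", elements=(el_a, el_b), total_charge=charge)
    return ec.make_fixture(spec)


class TestPeoe:
    def test_homonuclear_diatomic_is_neutral(self):
        ps = ec.make_toy_parameters("peoe", ["C"], seed=0)
        r = ec.peoe_charges(diatomic("C", "C"), ps)
        assert np.abs(r.charges).max() < 1e-12

    def test_methane_symmetry_and_conservation(self, methane, registry):
        r = ec.peoe_charges(methane, registry["peoe-gasteiger"])
        h = r.charges[1:]
        assert np.ptp(h) < 1e-12
        assert r.charges[0] == pytest.approx(-4 * h[0], abs=1e-10)

    def test_two_cycles_match_hand_iterated_oracle(self):
        ps = ec.make_toy_parameters("peoe", ["C", "O"], seed=3)
        pa = ps.lookup_atom(ec.AtomTypeKey("C", "plain", "*"))
        pb = ps.lookup_atom(ec.AtomTypeKey("O", "plain", "*"))
        expect = peoe_two_atoms((pa["a"], pa["b"], pa["c"]),
                                (pb["a"], pb["b"], pb["c"]), cycles=2)
        r = ec.peoe_charges(diatomic("C", "O"), ps, tol=0.0, max_iter=2)
        assert r.charges == pytest.approx(expect, abs=1e-14)

    def test_hydrogen_uses_cation_electronegativity(self, registry):
        expect = peoe_two_atoms((7.17, 6.24, -0.56), (14.18, 12.92, 1.39),
                                cycles=2, h_like=(True, False))
        r = ec.peoe_charges(diatomic("H", "O"), registry["peoe-gasteiger"],
                            tol=0.0, max_iter=2)
        assert r.charges == pytest.approx(expect, abs=1e-14)

    def test_transfer_shrinks_geometrically(self, phenol, registry):
        # increments must decay monotonically after the first cycles
        ps = registry["peoe-gasteiger"]
        deltas = []
        prev = None
        for k in (2, 3, 4, 5, 6, 7, 8):
            q = ec.peoe_charges(phenol, ps, tol=0.0, max_iter=k).charges
            if prev is not None:
                deltas.append(np.abs(q - prev).max())
            prev = q
        assert all(a > b for a, b in zip(deltas, deltas[1:]))

    def test_uncovered_atom_raises(self):
        ps = ec.make_toy_parameters("peoe", ["C"], seed=0)
        with pytest.raises(CoverageError, match="O"):
            ec.peoe_charges(diatomic("C", "O"), ps)


class TestMgc:
    def test_single_atom_gets_total_charge(self):
        mol = ec.Molecule("na", [ec.Atom(0, "Na", formal_charge=1)], [])
        assert ec.mgc_charges(mol).charges[0] == pytest.approx(1.0)

    def test_homonuclear_chain_all_zero(self):
        mol = ec.make_fixture(ec.FixtureSpec("chain", n_atoms=6, elements=("C",)))
        assert np.abs(ec.mgc_charges(mol).charges).max() < 1e-12

    def test_less_electronegative_atom_positive(self):
        r = ec.mgc_charges(diatomic("Na", "F"))
        q_na, q_f = r.charges
        assert q_na > 0 > q_f
        assert q_na == pytest.approx(-q_f)

    def test_disconnected_components_equalize_separately(self):
        atoms = [ec.Atom(0, "C"), ec.Atom(1, "O"), ec.Atom(2, "N"), ec.Atom(3, "H")]
        mol = ec.Molecule("two", atoms, [ec.Bond(0, 1), ec.Bond(2, 3)])
        q = ec.mgc_charges(mol).charges
        assert q[0] + q[1] == pytest.approx(0, abs=1e-12)
        assert q[2] + q[3] == pytest.approx(0, abs=1e-12)


class TestVeem:
    def test_homonuclear_diatomic_zero(self):
        assert np.abs(ec.veem_charges(diatomic("N", "N")).charges).max() < 1e-14

    def test_conservation_on_neutral_input(self, phenol):
        assert abs(ec.veem_charges(phenol).charges.sum()) < 1e-10

    def test_ion_charge_distributed(self, ammonium):
        q = ec.veem_charges(ammonium).charges
        assert q.sum() == pytest.approx(1.0, abs=1e-10)

    def test_orbit_symmetry(self, methane):
        q = ec.veem_charges(methane).charges
        assert np.ptp(q[1:]) < 1e-12

    def test_electron_rich_element_negative(self):
        q = ec.veem_charges(diatomic("C", "F")).charges
        assert q[0] > 0 > q[1]


class TestDelre:
    def test_homonuclear_symmetric_zero(self):
        ps = ec.make_toy_parameters("delre", ["C"], seed=1)
        assert np.abs(ec.delre_charges(diatomic("C", "C"), ps).charges).max() < 1e-14

    def test_three_atom_chain_matches_matrix_oracle(self):
        from oracles import gaussian_elimination

        ps = ec.make_toy_parameters("delre", ["C", "O"], seed=2)
        mol = ec.make_fixture(ec.FixtureSpec("chain", n_atoms=3,
                                             elements=("C", "O")))
        # independent solve of delta = delta0 + Gamma delta
        d0 = [ps.lookup_atom(ec.AtomTypeKey(a.element, "plain", "*"))["delta0"]
              for a in mol.atoms]
        gam = {}
        eps = {}
        for b in mol.bonds:
            row, _ = ps.lookup_bond(mol.atoms[b.i].element,
                                    mol.atoms[b.j].element, b.order)
            gam[(b.i, b.j)] = row["gamma"]
            eps[(b.i, b.j)] = row["eps"]
        m = [[1.0, -gam[(0, 1)], 0.0],
             [-gam[(0, 1)], 1.0, -gam[(1, 2)]],
             [0.0, -gam[(1, 2)], 1.0]]
        delta = gaussian_elimination(m, d0)
        t01 = (delta[1] - delta[0]) / (2 * eps[(0, 1)])
        t12 = (delta[2] - delta[1]) / (2 * eps[(1, 2)])
        expect = [t01, -t01 + t12, -t12]
        r = ec.delre_charges(mol, ps)
        assert r.charges == pytest.approx(expect, abs=1e-10)

    def test_bond_transfer_antisymmetry_conserves(self, methane):
        ps = ec.make_toy_parameters("delre", ["C", "H"], seed=3)
        assert abs(ec.delre_charges(methane, ps).charges.sum()) < 1e-12


class TestSharedProperties:
    METHODS_2D = ["peoe", "mgc", "veem", "delre"]

    @pytest.mark.parametrize("mid", METHODS_2D)
    def test_permutation_equivariance(self, mid):
        mol = ec.make_fixture(ec.FixtureSpec("chain", n_atoms=7,
                                             elements=("C", "O", "N", "H")))
        ps = ec.make_toy_parameters(mid, ["C", "O", "N", "H"], seed=4)
        desc = ec.METHODS[mid]
        q = ec.compute_charges(mol, desc, ps if desc.needs_parameters else None).charges
        perm = [3, 0, 6, 2, 5, 1, 4]
        mol_p = permute(mol, perm)
        q_p = ec.compute_charges(mol_p, desc,
                                 ps if desc.needs_parameters else None).charges
        assert q_p == pytest.approx([q[old] for old in perm], abs=1e-10)
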