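import numpy as np
import pytest

import emcharge as ec
from emcharge import methods3d as m3
from emcharge.errors import GeometryError, SingularSystemError

from conftest import permute, rigid_transform
from oracles import eem_system, gaussian_elimination

ELS = ["C", "H", "O", "N"]

LINEAR_3D = {
    "eem": ec.eem_charges, "sfkeem": ec.sfkeem_charges,
    "qeq": ec.qeq_charges, "eqeq": ec.eqeq_charges, "eqeqc": ec.eqeqc_charges,
}


def diatomic(a="C", b="C", charge=0, length=1.5):
    return ec.make_fixture(ec.FixtureSpec("diatomic", elements=(a, b),
                                          total_charge=charge,
                                          bond_length=length))


def random_cluster(n, seed, elements=ELS):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 6.0, size=(n, 3))
    # keep pairs at physically plausible separations
    while True:
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, 9.9)
        if d.min() > 1.9:
            break
        coords = rng.uniform(0, 6.0, size=(n, 3))
    atoms = [ec.Atom(i, elements[i % len(elements)], coords[i]) for i in range(n)]
    bonds = [ec.Bond(i, i + 1) for i in range(n - 1)]
    return ec.Molecule(f"cluster{n}", atoms, bonds)


class TestBuildSystem:
    def test_single_atom_constraint_forces_charge(self):
        mol = ec.Molecule("ion", [ec.Atom(0, "C", np.zeros(3), formal_charge=1)], [])
        ps = ec.make_toy_parameters("eem", ["C"], seed=0)
        system = m3.build_system(mol, m3.eem_kernel(mol, ps))
        assert system.matrix.shape == (2, 2)
        q, chi = m3.solve_equalization(system)
        assert q[0] == pytest.approx(1.0, abs=1e-12)

    def test_eem_entries_by_direct_substitution(self):
        mol = diatomic("C", "O", length=1.0)
        ps = ec.make_toy_parameters("eem", ["C", "O"], seed=1)
        ps.common["kappa"] = 1.0
        b_c = ps.lookup_atom(ec.AtomTypeKey("C", "plain", "*"))["B"]
        b_o = ps.lookup_atom(ec.AtomTypeKey("O", "plain", "*"))["B"]
        system = m3.build_system(mol, m3.eem_kernel(mol, ps))
        assert np.allclose(system.matrix[:2, :2], [[b_c, 1.0], [1.0, b_o]])
        assert list(system.matrix[2]) == [1.0, 1.0, 0.0]
        assert list(system.matrix[:2, 2]) == [-1.0, -1.0]

    @pytest.mark.parametrize("mid", ["eem", "sfkeem", "eqeq"])
    def test_charge_block_symmetric(self, mid):
        mol = random_cluster(5, seed=7)
        ps = ec.make_toy_parameters(mid, ELS, seed=2)
        system = m3.build_system(mol, m3.KERNELS[mid](mol, ps))
        block = system.matrix[:5, :5]
        assert np.abs(block - block.T).max() < 1e-12

    def test_coincident_atoms_rejected_with_pair(self):
        atoms = [ec.Atom(0, "C", np.zeros(3)), ec.Atom(1, "C", np.zeros(3))]
        mol = ec.Molecule("bad", atoms, [])
        ps = ec.make_toy_parameters("eem", ["C"], seed=0)
        with pytest.raises(GeometryError, match="0 and 1"):
            m3.build_system(mol, m3.eem_kernel(mol, ps))


class TestSolve:
    def test_homonuclear_diatomic_splits_charge(self):
        ps = ec.make_toy_parameters("eem", ["C"], seed=0)
        r = ec.eem_charges(diatomic("C", "C", charge=2), ps)
        assert r.charges == pytest.approx([1.0, 1.0], abs=1e-10)

    def test_three_atom_system_matches_gaussian_oracle(self):
        mol = random_cluster(3, seed=11)
        ps = ec.make_toy_parameters("eem", ELS, seed=5)
        arrs = [ps.lookup_atom(ec.AtomTypeKey(a.element, "plain", "*"))
                for a in mol.atoms]
        m, rhs = eem_system([a.coords for a in mol.atoms],
                            [p["A"] for p in arrs], [p["B"] for p in arrs],
                            ps.common["kappa"], 0)
        expect = gaussian_elimination(m, rhs)
        got = ec.eem_charges(mol, ps)
        assert got.charges == pytest.approx(expect[:3], abs=1e-10)
        assert got.chi_bar == pytest.approx(expect[3], abs=1e-10)

    def test_singular_system_is_structured_error(self):
        system = m3.EqualizationSystem(np.zeros((3, 3)), np.zeros(3))
        with pytest.raises(SingularSystemError):
            m3.solve_equalization(system)


class TestSfkeem:
    def test_large_sigma_decouples_atoms(self):
        # sech(sigma R) -> 0: off-diagonals vanish, closed-form solution
        mol = diatomic("C", "O", length=2.0)
        ps = ec.make_toy_parameters("sfkeem", ["C", "O"], seed=1)
        ps.common["sigma"] = 50.0
        pc = ps.lookup_atom(ec.AtomTypeKey("C", "plain", "*"))
        po = ps.lookup_atom(ec.AtomTypeKey("O", "plain", "*"))
        # decoupled equations: 2 B_i q_i - chi = -A_i with q_C + q_O = 0
        chi = (po["A"] * pc["B"] + pc["A"] * po["B"]) / (pc["B"] + po["B"])
        q_c = (chi - pc["A"]) / (2 * pc["B"])
        r = ec.sfkeem_charges(mol, ps)
        assert r.charges == pytest.approx([q_c, -q_c], abs=1e-10)

    def test_three_atom_vs_oracle(self):
        mol = random_cluster(3, seed=13)
        ps = ec.make_toy_parameters("sfkeem", ELS, seed=3)
        kern = m3.sfkeem_kernel(mol, ps)
        system = m3.build_system(mol, kern)
        expect = gaussian_elimination(system.matrix.tolist(), system.rhs.tolist())
        r = ec.sfkeem_charges(mol, ps)
        assert r.charges == pytest.approx(expect[:3], abs=1e-10)


class TestQeq:
    def test_no_hydrogen_single_outer_iteration(self):
        mol = random_cluster(4, seed=17, elements=["C", "O", "N"])
        r = ec.qeq_charges(mol, ec.make_toy_parameters("qeq", ["C", "O", "N"], 1))
        assert r.iterations == 1 and r.converged

    def test_symmetric_h2_neutral(self, registry):
        r = ec.qeq_charges(diatomic("H", "H", length=0.74), registry["qeq-rappe-goddard"])
        assert np.abs(r.charges).max() < 1e-10

    def test_chi_gap_widening_increases_polarity(self):
        qs = []
        for gap in (1.0, 2.0, 4.0, 6.0):
            ps = ec.ParameterSet(
                id="scan", method="qeq", scheme="plain",
                atom={("C", "plain", "*"): {"chi": 5.0, "J": 10.0},
                      ("O", "plain", "*"): {"chi": 5.0 + gap, "J": 11.0}})
            r = ec.qeq_charges(diatomic("C", "O"), ps)
            qs.append(abs(r.charges[0]))
        assert all(a < b for a, b in zip(qs, qs[1:]))

    def test_coulomb_tail_at_long_range(self, registry):
        kern = m3.qeq_kernel(diatomic("C", "O"), registry["qeq-rappe-goddard"])
        r = 60.0
        assert kern.offdiagonal(0, 1, r) == pytest.approx(m3.K_E / r, rel=1e-3)

    def test_hydrogen_hardness_responds_to_charge(self, registry):
        # positive H becomes harder, so |q_H| shrinks vs the fixed-J solve
        mol = diatomic("H", "F", length=0.92)
        ps = registry["qeq-rappe-goddard"]
        fixed = m3.solve_equalization(
            m3.build_system(mol, m3.qeq_kernel(mol, ps)))[0]
        sc = ec.qeq_charges(mol, ps)
        assert sc.converged
        assert 0 < sc.charges[0] < fixed[0]


class TestEqeq:
    def test_homonuclear_split(self, registry):
        r = ec.eqeq_charges(diatomic("C", "C", charge=-2), registry["eqeq-ionization"])
        assert r.charges == pytest.approx([-1.0, -1.0], abs=1e-10)

    def test_three_atom_vs_oracle(self, registry):
        mol = random_cluster(3, seed=19, elements=["C", "O", "H"])
        kern = m3.eqeq_kernel(mol, registry["eqeq-ionization"])
        system = m3.build_system(mol, kern)
        expect = gaussian_elimination(system.matrix.tolist(), system.rhs.tolist())
        r = ec.eqeq_charges(mol, registry["eqeq-ionization"])
        assert r.charges == pytest.approx(expect[:3], abs=1e-10)

    def test_zero_corrections_reduce_eqeqc_to_eqeq(self, registry):
        mol = random_cluster(4, seed=23, elements=["C", "O", "H"])
        plain = ec.eqeq_charges(mol, registry["eqeq-ionization"]).charges
        corr = ec.eqeqc_charges(mol, registry["eqeqc-ionization"]).charges
        assert corr == pytest.approx(plain, abs=1e-14)

    def test_bond_corrections_conserve_total(self):
        ps = ec.make_toy_parameters("eqeqc", ["C", "O", "H"], seed=5)
        mol = random_cluster(5, seed=29, elements=["C", "O", "H"])
        r = ec.eqeqc_charges(mol, ps)
        assert abs(r.charges.sum()) < 1e-10

    def test_eqeqc_requires_bonds(self, registry):
        atoms = [ec.Atom(0, "C", np.zeros(3)), ec.Atom(1, "O", np.array([0, 0, 2.0]))]
        with pytest.raises(GeometryError, match="bond"):
            ec.eqeqc_charges(ec.Molecule("nb", atoms, []), registry["eqeqc-ionization"])


class TestGdac:
    def test_homonuclear_neutral(self):
        ps = ec.make_toy_parameters("gdac", ["C"], seed=1)
        assert np.abs(ec.gdac_charges(diatomic("C", "C"), ps).charges).max() < 1e-12

    def test_compression_strengthens_transfer(self):
        ps = ec.make_toy_parameters("gdac", ["C", "O"], seed=2)
        mags = []
        for length in (1.9, 1.7, 1.5, 1.3):
            r = ec.gdac_charges(diatomic("C", "O", length=length), ps)
            mags.append(abs(r.charges[0]))
        assert all(a < b for a, b in zip(mags, mags[1:]))

    def test_conservation_on_charged_fixture(self):
        ps = ec.make_toy_parameters("gdac", ELS, seed=3)
        mol = ec.make_fixture(ec.FixtureSpec("helix", n_atoms=30, elements=ELS,
                                             total_charge=2))
        assert ec.gdac_charges(mol, ps).charges.sum() == pytest.approx(2.0, abs=1e-8)


class TestSharedProperties:
    @pytest.mark.parametrize("mid", sorted(LINEAR_3D))
    def test_rigid_motion_invariance(self, mid, registry):
        mol = random_cluster(6, seed=31, elements=["C", "O", "H"])
        ps = ec.make_toy_parameters(mid, ["C", "O", "H"], seed=6)
        q0 = LINEAR_3D[mid](mol, ps).charges
        q1 = LINEAR_3D[mid](rigid_transform(mol, seed=1), ps).charges
        assert q1 == pytest.approx(q0, abs=1e-9)

    @pytest.mark.parametrize("mid", sorted(LINEAR_3D) + ["gdac"])
    def test_permutation_equivariance(self, mid, registry):
        mol = random_cluster(6, seed=37, elements=["C", "O", "H"])
        ps = ec.make_toy_parameters(mid, ["C", "O", "H"], seed=7)
        fn = dict(LINEAR_3D, gdac=ec.gdac_charges)[mid]
        q = fn(mol, ps).charges
        perm = [5, 2, 0, 4, 1, 3]
        q_p = fn(permute(mol, perm), ps).charges
        assert q_p == pytest.approx([q[old] for old in perm], abs=1e-9)

    @pytest.mark.parametrize("mid", ["eem", "sfkeem", "qeq", "eqeq"])
    def test_equalization_certificate(self, mid, registry):
        mol = random_cluster(6, seed=41, elements=["C", "O", "H"])
        ps = ec.make_toy_parameters(mid, ["C", "O", "H"], seed=8)
        fn = LINEAR_3D[mid]
        res = fn(mol, ps)
        chi_eff = m3.effective_electronegativities(mol, ps, mid, res.charges)
        assert np.abs(chi_eff - res.chi_bar).max() < 1e-6

    def test_apolar_region_nearly_neutral(self):
        # uniform-element, uniform-geometry region: charges around zero
        mol = ec.make_fixture(ec.FixtureSpec("helix", n_atoms=40))
        ps = ec.make_toy_parameters("eem", ["C"], seed=9)
        r = ec.eem_charges(mol, ps)
        assert np.abs(r.charges).max() < 0.02


class TestWorkedPhenolExample:
    def test_phenolic_hydrogen_most_positive(self, phenol, registry):
        r = ec.eem_charges(phenol, registry["eem2015ha"])
        h_idx = [a.index for a in phenol.atoms if a.element == "H"]
        charges = {i: r.charges[i] for i in h_idx}
        assert max(charges, key=charges.get) == 7  # the O-H hydrogen
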