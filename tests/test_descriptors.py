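"""Descriptor panel: formulas, invariances, determinism."""

import numpy as np
import pytest
from rdkit import Chem

from faahscreen.chem_io import CompoundRecord
from faahscreen.descriptors import (
    Conformer,
    burden_spmax5,
    compute_descriptors,
    cpsa_wpsa,
    crippen_logp,
    embed_3d,
    rdf_descriptor,
    shrake_rupley_sasa,
    spmad_distance,
    whim_size,
    wpsa_from_sasa,
)
from conftest import record


def toy_conformer(coords, charges=None, masses=None, elements=None):
    n = len(coords)
    return Conformer(
        coords=np.asarray(coords, dtype=float),
        charges=np.zeros(n) if charges is None else np.asarray(charges, float),
        masses=np.full(n, 12.011) if masses is None else np.asarray(masses, float),
        elements=np.full(n, 6) if elements is None else np.asarray(elements),
        estate=np.ones(n),
        seed=0,
    )


def renumbered(rec: CompoundRecord) -> CompoundRecord:
    order = list(range(rec.mol.GetNumAtoms()))[::-1]
    mol = Chem.RenumberAtoms(rec.mol, order)
    out = CompoundRecord.from_smiles(Chem.MolToSmiles(mol, canonical=False), rec.id)
    assert out is not None
    return out


class TestCrippenLogP:
    def test_benzene_against_hand_summed_contributions(self):
        # 6 aromatic CH: carbon class 0.1581 each, aromatic-attached H 0.1230 each
        assert crippen_logp(record("c1ccccc1")) == pytest.approx(
            6 * 0.1581 + 6 * 0.1230, abs=0.1
        )

    def test_additive_over_fragments(self):
        ethanol = crippen_logp(record("CCO"))
        # largest-fragment selection is bypassed by building the mol directly
        double = CompoundRecord.from_smiles("CCO", "x")
        double._mol = Chem.MolFromSmiles("CCO.CCO")
        assert crippen_logp(double) == pytest.approx(2 * ethanol, abs=1e-9)


class TestSpMAD:
    def test_two_atom_molecule(self):
        # D = [[0,1],[1,0]]; spectrum {1,-1}; mean 0 -> SpMAD 1
        assert spmad_distance(record("CC")) == pytest.approx(1.0)

    def test_single_heavy_atom(self):
        assert spmad_distance(record("C")) == 0.0

    def test_renumbering_invariance(self):
        rec = record("CC(=O)Oc1ccccc1C(=O)O")
        assert spmad_distance(renumbered(rec)) == pytest.approx(spmad_distance(rec))


class TestBurden:
    def test_small_molecule_returns_smallest_eigenvalue(self):
        rec = record("CCO")  # 3 heavy atoms < 5
        value = burden_spmax5(rec)
        from faahscreen.descriptors import burden_matrix
        from faahscreen import _elements

        diag = np.array(
            [_elements.relative_ionization(a.GetAtomicNum()) for a in rec.mol.GetAtoms()]
        )
        eig = np.sort(np.abs(np.linalg.eigvalsh(burden_matrix(rec, diag))))
        assert value == pytest.approx(eig[0])

    def test_two_carbon_spectrum_by_hand(self):
        # B = [[1, 0.11], [0.11, 1]] (single bond + terminal increment)
        from faahscreen.descriptors import burden_matrix

        b = burden_matrix(record("CC"), np.ones(2))
        eig = np.sort(np.linalg.eigvalsh(b))
        assert eig == pytest.approx([1 - 0.11, 1 + 0.11])

    def test_homonuclear_chain_spectrum_symmetric_about_diagonal(self):
        # exactly symmetric up to the 0.001 non-bonded fill
        rec = record("CCCCC")
        from faahscreen.descriptors import burden_matrix

        b = burden_matrix(rec, np.ones(5))
        eig = np.linalg.eigvalsh(b) - 1.0
        assert np.allclose(sorted(eig), sorted(-eig), atol=5e-3)

    def test_renumbering_invariance(self):
        rec = record("O=C(O)c1ccc(N)cc1")
        assert burden_spmax5(renumbered(rec)) == pytest.approx(burden_spmax5(rec))


class TestWHIM:
    def test_unit_tetrahedron_closed_form(self):
        # covariance of the 4 alternating-sign vertices is the identity
        coords = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]
        assert whim_size(toy_conformer(coords)) == pytest.approx(3.0)

    def test_planar_molecule_rank_two(self):
        coords = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)]
        conf = toy_conformer(coords)
        cov_eig = np.sort(np.linalg.eigvalsh(np.cov(np.array(coords).T, bias=True)))
        assert whim_size(conf) == pytest.approx(cov_eig[1] * cov_eig[2])

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(8, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = coords @ q.T + np.array([5.0, -3.0, 2.0])
        for weighting in ("unweighted", "sanderson_en", "vdw_volume"):
            a = whim_size(toy_conformer(coords), weighting)
            b = whim_size(toy_conformer(moved), weighting)
            assert b == pytest.approx(a, rel=1e-9)


class TestRDF:
    def test_single_atom_is_zero(self):
        assert rdf_descriptor(toy_conformer([(0, 0, 0)])) == 0.0

    def test_two_carbons_at_target_radius(self):
        conf = toy_conformer([(0, 0, 0), (8.5, 0, 0)])
        assert rdf_descriptor(conf, r=8.5) == pytest.approx(1.0)

    def test_decay_away_from_target_radius(self):
        values = [
            rdf_descriptor(toy_conformer([(0, 0, 0), (d, 0, 0)]), r=8.5)
            for d in (8.5, 8.3, 8.0, 7.0)
        ]
        assert values == sorted(values, reverse=True)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(6, 3)) * 4
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a = rdf_descriptor(toy_conformer(coords))
        b = rdf_descriptor(toy_conformer(coords @ q.T + 1.0))
        assert b == pytest.approx(a, rel=1e-9)


class TestCPSA:
    def test_two_atom_toy_table(self):
        wpsa1, wpsa2 = wpsa_from_sasa([10.0, 20.0], [0.2, -0.2])
        assert wpsa1 == pytest.approx(0.3)  # PPSA1 10 * TMSA 30 / 1000
        assert wpsa2 == pytest.approx(0.06)

    def test_no_positive_atoms(self):
        assert wpsa_from_sasa([10.0, 20.0], [-0.1, -0.2]) == (0.0, 0.0)

    def test_doubling_surface_quadruples_wpsa1(self):
        a, _ = wpsa_from_sasa([10.0, 20.0], [0.2, -0.2])
        b, _ = wpsa_from_sasa([20.0, 40.0], [0.2, -0.2])
        assert b == pytest.approx(4 * a)

    def test_isolated_atom_surface_is_full_sphere(self):
        sasa = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.7]))
        assert sasa[0] == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=1e-6)

    def test_buried_atom_has_no_surface(self):
        coords = np.array([[0.0, 0, 0], [0.1, 0, 0]])
        sasa = shrake_rupley_sasa(coords, np.array([0.5, 5.0]))
        assert sasa[0] == 0.0


class TestEmbedding:
    def test_determinism(self):
        rec = record("CC(=O)Nc1ccc(O)cc1")
        a = embed_3d(rec, seed=42)
        b = embed_3d(rec, seed=42)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.charges, b.charges)

    def test_ethane_bond_length(self):
        conf = embed_3d(record("CC"), seed=0)
        dist = np.linalg.norm(conf.coords[0] - conf.coords[1])
        assert 1.45 <= dist <= 1.60

    def test_single_heavy_atom_at_origin(self):
        conf = embed_3d(record("C"), seed=0)
        assert np.allclose(conf.coords, 0.0)

    def test_panel_deterministic(self):
        rec = record("O=C(O)c1ccc(N2CCNCC2)cc1")
        assert compute_descriptors(rec, seed=3) == compute_descriptors(rec, seed=3)

    def test_charges_required_for_cpsa(self):
        conf = toy_conformer([(0, 0, 0), (1, 0, 0)])
        conf.charges = np.array([np.nan, 0.1])
        with pytest.raises(ValueError):
            cpsa_wpsa(conf)
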