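import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eemkit import fixtures as fx
from eemkit.chem_io import (
    Atom,
    Bond,
    Molecule,
    ParameterSet,
    assign_atom_types,
    parse_sdf,
    read_charges,
    read_parameter_set,
    write_charges,
    write_parameter_set,
    write_sdf,
)
from eemkit.errors import AtomTypingError, ChargeFileError, ParameterFileError, SdfParseError


def molfile(atoms, bonds, props=(), name="test"):
    lines = [name, "  prog", "", f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000"]
    for x, y, z, el in atoms:
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, order in bonds:
        lines.append(f"{i:3d}{j:3d}{order:3d}  0")
    lines.extend(props)
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


class TestParseSdf:
    def test_two_atom_record(self):
        text = molfile([(0, 0, 0, "O"), (0.96, 0, 0, "H")], [(1, 2, 1)])
        (mol,) = parse_sdf(io.StringIO(text))
        assert mol.name == "test"
        assert mol.n_atoms == 2
        assert len(mol.bonds) == 1
        assert mol.total_charge == 0
        assert mol.atoms[1].x == pytest.approx(0.96)

    def test_chg_property_line(self):
        text = molfile([(0, 0, 0, "N"), (1.2, 0, 0, "O")], [(1, 2, 1)],
                       props=["M  CHG  1   2  -1"])
        (mol,) = parse_sdf(io.StringIO(text))
        assert mol.atoms[1].formal_charge == -1
        assert mol.total_charge == -1

    def test_no_charge_lines_means_neutral(self):
        text = molfile([(0, 0, 0, "C"), (1.5, 0, 0, "C")], [(1, 2, 1)])
        (mol,) = parse_sdf(io.StringIO(text))
        assert all(a.formal_charge == 0 for a in mol.atoms)
        assert mol.total_charge == 0

    def test_non_numeric_atom_count(self):
        text = molfile([(0, 0, 0, "C")], [])
        bad = text.replace("  1  0  0", "  x  0  0", 1)
        with pytest.raises(SdfParseError, match="atom count"):
            parse_sdf(io.StringIO(bad))

    def test_v3000_rejected(self):
        text = molfile([(0, 0, 0, "C")], []).replace("V2000", "V3000")
        with pytest.raises(SdfParseError, match="V3000"):
            parse_sdf(io.StringIO(text))

    def test_bond_index_out_of_range(self):
        text = molfile([(0, 0, 0, "C"), (1.5, 0, 0, "C")], [(1, 5, 1)])
        with pytest.raises(SdfParseError, match="out of range"):
            parse_sdf(io.StringIO(text))

    def test_unknown_element(self):
        text = molfile([(0, 0, 0, "Xx")], [])
        with pytest.raises(SdfParseError, match="element"):
            parse_sdf(io.StringIO(text))

    def test_multi_record_order(self):
        text = molfile([(0, 0, 0, "C")], [], name="a") + molfile(
            [(0, 0, 0, "N")], [], name="b"
        )
        mols = parse_sdf(io.StringIO(text))
        assert [m.name for m in mols] == ["a", "b"]

    def test_roundtrip_through_writer(self, small_dataset):
        molecules, _, _ = small_dataset
        buf = io.StringIO()
        write_sdf(molecules, buf)
        back = parse_sdf(io.StringIO(buf.getvalue()))
        assert len(back) == len(molecules)
        for orig, re in zip(molecules, back):
            assert re.n_atoms == orig.n_atoms
            assert [(b.i, b.j, b.order) for b in re.bonds] == [
                (b.i, b.j, b.order) for b in orig.bonds
            ]
            assert [a.formal_charge for a in re.atoms] == [
                a.formal_charge for a in orig.atoms
            ]
            np.testing.assert_allclose(
                re.coordinates(), orig.coordinates(), atol=5.1e-5
            )

    def test_rdkit_agrees_on_valid_molecule(self):
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem

        text = molfile(
            [(0, 0, 0, "C"), (1.52, 0, 0, "C"), (2.2, 1.2, 0, "O")],
            [(1, 2, 1), (2, 3, 1)],
            name="propanol-fragment",
        )
        (ours,) = parse_sdf(io.StringIO(text))
        theirs = Chem.MolFromMolBlock(text.replace("$$$$\n", ""), sanitize=False, removeHs=False)
        assert theirs.GetNumAtoms() == ours.n_atoms
        conf = theirs.GetConformer()
        for k, atom in enumerate(ours.atoms):
            assert theirs.GetAtomWithIdx(k).GetSymbol() == atom.element
            p = conf.GetAtomPosition(k)
            assert (p.x, p.y, p.z) == pytest.approx((atom.x, atom.y, atom.z), abs=1e-4)
        assert theirs.GetNumBonds() == len(ours.bonds)


class TestAtomTyping:
    def make(self, elements, bonds):
        atoms = [Atom(e, float(k), 0.0, 0.0) for k, e in enumerate(elements)]
        return Molecule("m", atoms, [Bond(*b) for b in bonds])

    def test_triple_bond_gives_n3(self):
        mol = self.make(["N", "C", "H"], [(1, 2, 3), (1, 3, 1)])
        assign_atom_types(mol)
        assert mol.atoms[0].atom_type == "N3"

    def test_all_single_gives_c1(self):
        mol = self.make(["C", "H", "H", "H", "H"],
                        [(1, 2, 1), (1, 3, 1), (1, 4, 1), (1, 5, 1)])
        assign_atom_types(mol)
        assert mol.atoms[0].atom_type == "C1"

    def test_isolated_atom_order_one(self):
        mol = self.make(["Na"], [])
        assign_atom_types(mol)
        assert mol.atoms[0].atom_type == "Na1"

    def test_aromatic_strict_rejected(self):
        mol = self.make(["C", "C"], [(1, 2, 4)])
        with pytest.raises(AtomTypingError, match="kekulized"):
            assign_atom_types(mol)

    def test_aromatic_mapped_to_double(self):
        mol = self.make(["C", "C"], [(1, 2, 4)])
        assign_atom_types(mol, map_aromatic=True)
        assert mol.atoms[0].atom_type == "C2"

    @given(seed=st.integers(0, 50))
    def test_permutation_equivariant(self, seed):
        rng = np.random.default_rng(seed)
        config = fx.FixtureConfig(atoms_min=4, atoms_max=8)
        mol = fx.random_molecule(config, rng, "m")
        perm = rng.permutation(mol.n_atoms)
        inverse = np.empty_like(perm)
        inverse[perm] = np.arange(mol.n_atoms)
        atoms = [Atom(mol.atoms[p].element, mol.atoms[p].x, mol.atoms[p].y,
                      mol.atoms[p].z) for p in perm]
        bonds = [Bond(int(inverse[b.i - 1]) + 1, int(inverse[b.j - 1]) + 1, b.order)
                 for b in mol.bonds]
        permuted = assign_atom_types(Molecule("p", atoms, bonds))
        assert [permuted.atoms[int(inverse[k])].atom_type for k in range(mol.n_atoms)] \
            == mol.atom_types()


class TestChargeFiles:
    def test_basic_block(self):
        text = "mol1\n2\n1 O -0.4\n2 H 0.4\n"
        charges = read_charges(io.StringIO(text))
        np.testing.assert_allclose(charges["mol1"], [-0.4, 0.4])

    def test_duplicate_name_rejected(self):
        text = "m\n1\n1 H 0.0\n\nm\n1\n1 H 0.1\n"
        with pytest.raises(ChargeFileError, match="duplicate"):
            read_charges(io.StringIO(text))

    def test_empty_file(self):
        assert read_charges(io.StringIO("")) == {}

    def test_count_mismatch(self):
        text = "m\n3\n1 H 0.0\n2 H 0.0\n"
        with pytest.raises(ChargeFileError, match="3 atoms"):
            read_charges(io.StringIO(text))

    def test_non_numeric_charge(self):
        text = "m\n1\n1 H abc\n"
        with pytest.raises(ChargeFileError, match="non-numeric"):
            read_charges(io.StringIO(text))

    def test_roundtrip_full_precision(self, rng):
        charges = {"a": rng.normal(size=5), "b": rng.normal(size=3)}
        buf = io.StringIO()
        write_charges(charges, buf)
        back = read_charges(io.StringIO(buf.getvalue()))
        for name in charges:
            np.testing.assert_array_equal(back[name], charges[name])


class TestParameterSetFiles:
    def make_set(self):
        return ParameterSet(
            name="demo", qm_label="B3LYP/6-311G/NPA", kappa=0.44,
            entries={"H1": (2.4, 1.0), "C2": (2.7, 3.1415926535897931)},
        )

    def test_roundtrip_identity(self):
        pset = self.make_set()
        buf = io.StringIO()
        write_parameter_set(pset, buf)
        back = read_parameter_set(io.StringIO(buf.getvalue()))
        assert back == pset

    def test_duplicate_type_rejected(self):
        text = (
            '{"name": "x", "qm_label": "", "kappa": 0.4, "parameters": ['
            '{"element": "C", "order": 2, "A": 1.0, "B": 2.0},'
            '{"element": "C", "order": 2, "A": 1.1, "B": 2.1}]}'
        )
        with pytest.raises(ParameterFileError, match="duplicate"):
            read_parameter_set(io.StringIO(text))

    def test_nonpositive_b_rejected(self):
        text = (
            '{"kappa": 0.4, "parameters": ['
            '{"element": "H", "order": 1, "A": 1.0, "B": 0.0}]}'
        )
        with pytest.raises(ParameterFileError, match="B must be > 0"):
            read_parameter_set(io.StringIO(text))

    def test_missing_kappa_rejected(self):
        with pytest.raises(ParameterFileError, match="kappa"):
            read_parameter_set(io.StringIO('{"parameters": []}'))
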