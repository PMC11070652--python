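"""Structure reading, curation predicates and in-place RMSD."""

import itertools

import numpy as np
import pytest

from shellscore.structures import (
    ComplexPose, CurationRules, EmptyStructureError, IncompatibleMoleculesError,
    LigandParseError, compute_rmsd, ligand_automorphisms, ligand_to_rdkit,
    passes_curation, read_ligand, read_protein, read_rmsd_labels,
    write_ligand_sdf, write_protein_pdb, write_rmsd_labels,
)
from shellscore.synthetic import ligand_template, make_toy_complex

PDB_TEXT = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
HETATM    4 ZN    ZN A   2       5.000   5.000   5.000  1.00  0.00          ZN
HETATM    5  O   HOH A   3       8.000   8.000   8.000  1.00  0.00           O
END
"""

MOL2_BENZENE = """\
@<TRIPOS>MOLECULE
benzene
 6 6 1
SMALL
NO_CHARGES

@<TRIPOS>ATOM
      1 C1          1.3900    0.0000    0.0000 C.ar    1  BNZ1
      2 C2          0.6950    1.2037    0.0000 C.ar    1  BNZ1
      3 C3         -0.6950    1.2037    0.0000 C.ar    1  BNZ1
      4 C4         -1.3900    0.0000    0.0000 C.ar    1  BNZ1
      5 C5         -0.6950   -1.2037    0.0000 C.ar    1  BNZ1
      6 C6          0.6950   -1.2037    0.0000 C.ar    1  BNZ1
@<TRIPOS>BOND
     1    1    2 ar
     2    2    3 ar
     3    3    4 ar
     4    4    5 ar
     5    5    6 ar
     6    6    1 ar
"""


@pytest.fixture()
def pdb_file(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(PDB_TEXT)
    return path


class TestReadProtein:
    def test_waters_always_removed(self, pdb_file):
        prot = read_protein(pdb_file)
        assert all(a.res_name not in ("HOH", "WAT") for a in prot.atoms)
        assert len(prot.atoms) == 4  # 3 ATOM + ZN, water gone

    def test_hetatm_flag_semantics(self, pdb_file):
        with_het = read_protein(pdb_file, keep_hetatm=True)
        zn = [a for a in with_het.atoms if a.element.upper() == "ZN"]
        assert len(zn) == 1 and zn[0].is_hetatm
        without = read_protein(pdb_file, keep_hetatm=False)
        assert all(a.element.upper() != "ZN" for a in without.atoms)
        assert len(without.atoms) == 3

    def test_atom_names_preserved(self, pdb_file):
        names = [a.name for a in read_protein(pdb_file).atoms]
        assert names[:3] == ["N", "CA", "C"]

    def test_empty_after_filtering_raises(self, tmp_path):
        p = tmp_path / "only_water.pdb"
        p.write_text("HETATM    1  O   HOH A   1       0.0     0.0     0.0"
                     "  1.00  0.00           O\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_protein(p)


class TestReadLigand:
    def test_mol2_benzene(self, tmp_path):
        path = tmp_path / "benzene.mol2"
        path.write_text(MOL2_BENZENE)
        (lig,) = read_ligand(path)
        assert len(lig.atoms) == 6
        assert all(a.aromatic for a in lig.atoms)
        assert all(a.ring_size == 6 for a in lig.atoms)

    def test_multi_record_sdf_gives_pose_list(self, tmp_path):
        ligs = [ligand_template("benzene").translated([i, 0, 0])
                for i in range(10)]
        path = tmp_path / "poses.sdf"
        write_ligand_sdf(ligs, path)
        assert len(read_ligand(path)) == 10

    def test_malformed_sdf_names_record(self, tmp_path):
        path = tmp_path / "bad.sdf"
        # atom count in the counts line disagrees with the atom block
        path.write_text("bad\n\n\n  3  1  0  0  0  0  0  0  0  0999 V2000\n"
                        "    0.0000    0.0000    0.0000 C   0  0\n"
                        "  1  2  1  0\nM  END\n$$$$\n")
        with pytest.raises(LigandParseError):
            read_ligand(path)


class TestCuration:
    def test_small_ligand_fails_atom_count(self):
        cplx = make_toy_complex(seed=0, ligand="butane", complex_id="c")
        res = passes_curation(cplx)
        assert not res.passed and res.failures == ["ligand_atom_count"]

    def test_good_complex_passes(self, toy_complex):
        res = passes_curation(toy_complex)
        assert res.passed and not res.failures

    def test_resolution_limit(self, toy_complex):
        cplx = ComplexPose(toy_complex.protein, toy_complex.ligand, "p", "c")
        cplx.protein.resolution = 3.5
        try:
            res = passes_curation(cplx)
            assert "resolution" in res.failures
        finally:
            cplx.protein.resolution = 2.0

    def test_unknown_resolution_skips_predicate(self, toy_complex):
        old = toy_complex.protein.resolution
        toy_complex.protein.resolution = None
        try:
            res = passes_curation(toy_complex)
            assert "resolution" in res.skipped and res.passed
        finally:
            toy_complex.protein.resolution = old

    def test_covalent_contact_detected(self):
        cplx = make_toy_complex(seed=0, pocket_radius=1.2, radial_jitter=0.0,
                                complex_id="cov")
        res = passes_curation(cplx)
        assert "covalent_bond" in res.failures

    def test_all_failures_reported_not_just_first(self):
        cplx = make_toy_complex(seed=0, ligand="butane", pocket_radius=1.2,
                                radial_jitter=0.0, complex_id="c")
        res = passes_curation(cplx, CurationRules())
        assert set(res.failures) >= {"ligand_atom_count", "covalent_bond"}


def _rotate_benzene(lig, degrees):
    theta = np.deg2rad(degrees)
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    out = lig.translated([0, 0, 0])
    for atom in out.atoms:
        atom.coord = rot @ atom.coord
    return out


class TestRmsd:
    def test_identity_is_zero(self):
        lig = ligand_template("benzene")
        assert compute_rmsd(lig, lig) == 0.0

    def test_translation_gives_exact_norm(self):
        lig = ligand_template("toluene")
        assert compute_rmsd(lig.translated([3, 0, 0]), lig) == pytest.approx(3.0)
        t = np.array([1.0, -2.0, 2.0])
        assert compute_rmsd(lig.translated(t), lig) == pytest.approx(3.0)

    def test_benzene_rotation_symmetry(self):
        lig = ligand_template("benzene")
        rotated = _rotate_benzene(lig, 60)
        assert compute_rmsd(rotated, lig, symmetry=False) > 1.0
        assert compute_rmsd(rotated, lig, symmetry=True) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_never_exceeds_plain(self, rng):
        lig = ligand_template("toluene")
        for _ in range(10):
            pose = lig.translated(rng.normal(scale=1.5, size=3))
            for atom in pose.atoms:
                atom.coord = atom.coord + rng.normal(scale=0.3, size=3)
            assert compute_rmsd(pose, lig, symmetry=True) <= \
                compute_rmsd(pose, lig, symmetry=False) + 1e-12

    def test_rmsd_symmetric_in_arguments(self, rng):
        lig = ligand_template("benzene")
        pose = lig.translated(rng.normal(size=3))
        assert compute_rmsd(pose, lig) == pytest.approx(compute_rmsd(lig, pose))

    def test_incompatible_molecules_raise(self):
        with pytest.raises(IncompatibleMoleculesError):
            compute_rmsd(ligand_template("benzene"), ligand_template("butane"))

    def test_automorphism_minimum_matches_brute_force(self, rng):
        """Exhaustive search over element/bond preserving permutations."""
        lig = ligand_template("benzene")
        pose = _rotate_benzene(lig, 60)
        for atom in pose.atoms:
            atom.coord = atom.coord + rng.normal(scale=0.1, size=3)
        ref_xyz, pose_xyz = lig.coords(), pose.coords()
        bonds = {frozenset((i, j)) for i, j, _ in lig.bonds}
        best = np.inf
        for perm in itertools.permutations(range(6)):
            if {frozenset((perm[i], perm[j])) for i, j in
                    (tuple(b) for b in bonds)} != bonds:
                continue
            best = min(best, float(np.sqrt(np.mean(
                np.sum((pose_xyz[list(perm)] - ref_xyz) ** 2, axis=1)))))
        assert compute_rmsd(pose, lig, symmetry=True) == pytest.approx(best)

    def test_automorphisms_match_rdkit(self):
        """Independent route: RDKit substructure self-matches."""
        lig = ligand_template("benzene")
        ours = {tuple(m[i] for i in range(6))
                for m in ligand_automorphisms(lig)}
        mol = ligand_to_rdkit(lig)
        theirs = set(mol.GetSubstructMatches(mol, uniquify=False,
                                             useChirality=False))
        assert ours == theirs
        assert len(ours) == 12  # dihedral symmetry of the hexagon


class TestLabelIO:
    def test_roundtrip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({"pose_id": ["a", "b"], "complex_id": ["c", "c"],
                           "rmsd": [0.0, 2.5]})
        path = tmp_path / "labels.tsv"
        write_rmsd_labels(df, path)
        back = read_rmsd_labels(path)
        assert back["rmsd"].tolist() == [0.0, 2.5]

    def test_negative_rmsd_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("pose_id\tcomplex_id\trmsd\na\tc\t-1.0\n")
        with pytest.raises(ValueError):
            read_rmsd_labels(path)


def test_protein_pdb_roundtrip(tmp_path, toy_complex):
    path = tmp_path / "protein.pdb"
    write_protein_pdb(toy_complex.protein, path)
    back = read_protein(path)
    assert len(back.atoms) == len(toy_complex.protein.atoms)
    np.testing.assert_allclose(back.coords(), toy_complex.protein.coords(),
                               atol=1.5e-3)  # PDB stores 3 decimals
    assert [a.name for a in back.atoms] == \
        [a.name for a in toy_complex.protein.atoms]
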