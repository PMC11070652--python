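"""Reading protein and ligand structures, curation predicates and RMSD labels.

Proteins come from PDB files (via gemmi; first model only, waters stripped,
altloc 'A'/blank kept, atom names preserved verbatim apart from whitespace).
Ligands and docked pose sets come from TRIPOS Mol2 or multi-record V2000 SDF
files (via RDKit), with the bond-graph-derived atom properties the node
featurization needs.

Docking RMSD is computed in the common coordinate frame -- no superposition --
optionally minimized over graph automorphisms of the ligand so that chemically
equivalent atoms (e.g. the two orientations of a phenyl ring) do not inflate
the deviation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "ProteinAtom", "ProteinStructure", "LigandAtom", "LigandMolecule",
    "ComplexPose", "CurationRules", "CurationResult",
    "read_protein", "read_ligand", "passes_curation", "compute_rmsd",
    "read_rmsd_labels", "write_rmsd_labels", "write_protein_pdb",
    "write_ligand_sdf", "ligand_to_rdkit",
    "StructureError", "EmptyStructureError", "LigandParseError",
    "IncompatibleMoleculesError",
]

WATER_RESIDUES = frozenset({"HOH", "WAT", "H2O", "DOD"})


class StructureError(ValueError):
    """A structure file could not be parsed."""


class EmptyStructureError(StructureError):
    """No atoms survived loading/filtering."""


class LigandParseError(StructureError):
    """A ligand record failed to parse or sanitize."""


class IncompatibleMoleculesError(ValueError):
    """RMSD requested between molecules with different graphs."""


@dataclass
class ProteinAtom:
    element: str
    name: str            # PDB columns 13-16, whitespace-stripped
    res_name: str
    res_id: int
    chain: str
    coord: np.ndarray    # (3,) Angstrom
    is_hetatm: bool = False


@dataclass
class ProteinStructure:
    atoms: list[ProteinAtom]
    resolution: float | None = None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class LigandAtom:
    element: str
    formal_charge: int
    coord: np.ndarray
    degree: int | None = None
    implicit_valence: int | None = None
    num_h: int | None = None
    hybridization: str | None = None
    ring_size: int | None = None   # largest ring containing the atom
    aromatic: bool = False


@dataclass
class LigandMolecule:
    atoms: list[LigandAtom]
    bonds: list[tuple[int, int, str]]  # (i, j, order: single/double/triple/aromatic)

    def __post_init__(self):
        n = len(self.atoms)
        if sum(1 for a in self.atoms if a.element.upper() != "H") < 1:
            raise ValueError("ligand must contain at least one heavy atom")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"bond ({i},{j}) has invalid atom indices")

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element.upper() != "H"]

    def graph(self, heavy_only: bool = False) -> nx.Graph:
        g = nx.Graph()
        keep = set(self.heavy_indices()) if heavy_only else set(range(len(self.atoms)))
        for i in keep:
            g.add_node(i, element=self.atoms[i].element.upper())
        for i, j, order in self.bonds:
            if i in keep and j in keep:
                g.add_edge(i, j, order=order)
        return g

    def translated(self, vec) -> "LigandMolecule":
        vec = np.asarray(vec, dtype=float)
        atoms = [LigandAtom(a.element, a.formal_charge, a.coord + vec, a.degree,
                            a.implicit_valence, a.num_h, a.hybridization,
                            a.ring_size, a.aromatic)
                 for a in self.atoms]
        return LigandMolecule(atoms, list(self.bonds))


@dataclass
class ComplexPose:
    """One protein structure plus one ligand pose; the unit being scored."""

    protein: ProteinStructure
    ligand: LigandMolecule
    pose_id: str = "pose0"
    complex_id: str | None = None
    rmsd_label: float | None = None

    def __post_init__(self):
        if self.rmsd_label is not None and self.rmsd_label < 0:
            raise ValueError("rmsd_label must be >= 0")


# --------------------------------------------------------------------------
# readers

def read_protein(path, keep_hetatm: bool = True) -> ProteinStructure:
    """Load a PDB file: first model, waters removed, altloc 'A'/blank only.

    HETATM small molecules (co-factors, metals) are part of the receptor when
    ``keep_hetatm`` is set; otherwise they are dropped.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, FileNotFoundError) as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    atoms: list[ProteinAtom] = []
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    for chain in model:
        for residue in chain:
            res = residue.name.strip().upper()
            if res in WATER_RESIDUES:
                continue
            is_het = residue.het_flag == "H"
            if is_het and not keep_hetatm:
                continue
            for atom in residue:
                if atom.altloc not in ("", "A", "\0"):
                    continue
                coord = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if not np.all(np.isfinite(coord)):
                    raise StructureError(f"{path}: non-finite coordinates")
                atoms.append(ProteinAtom(
                    element=atom.element.name,
                    name=atom.name.strip(),
                    res_name=res,
                    res_id=residue.seqid.num,
                    chain=chain.name,
                    coord=coord,
                    is_hetatm=is_het,
                ))
    if not atoms:
        raise EmptyStructureError(f"{path}: zero atoms after filtering")
    return ProteinStructure(atoms=atoms, resolution=resolution)


_BOND_ORDER_FROM_RDKIT = {
    "SINGLE": "single", "DOUBLE": "double", "TRIPLE": "triple",
    "AROMATIC": "aromatic",
}


def _ligand_from_rdkit(mol) -> LigandMolecule:
    from rdkit import Chem  # local import keeps module import light

    if mol.GetNumConformers() == 0:
        raise LigandParseError("ligand record has no 3D coordinates")
    conf = mol.GetConformer()
    ring_info = mol.GetRingInfo()
    atoms = []
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        sizes = [len(ring) for ring in ring_info.AtomRings() if idx in ring]
        pos = conf.GetAtomPosition(idx)
        atoms.append(LigandAtom(
            element=atom.GetSymbol(),
            formal_charge=atom.GetFormalCharge(),
            coord=np.array([pos.x, pos.y, pos.z]),
            degree=atom.GetDegree(),
            implicit_valence=atom.GetNumImplicitHs(),
            num_h=atom.GetTotalNumHs(),
            hybridization=str(atom.GetHybridization()),
            ring_size=max(sizes) if sizes else None,
            aromatic=atom.GetIsAromatic(),
        ))
    bonds = []
    for bond in mol.GetBonds():
        order = _BOND_ORDER_FROM_RDKIT.get(str(bond.GetBondType()), "other")
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order))
    return LigandMolecule(atoms=atoms, bonds=bonds)


def read_ligand(path) -> list[LigandMolecule]:
    """Read one Mol2 molecule or every record of a (multi-pose) SDF file."""
    from rdkit import Chem

    path = Path(path)
    suffix = path.suffix.lower()
    if not path.exists():
        raise StructureError(f"no such ligand file: {path}")
    if suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False)
        if mol is None:
            raise LigandParseError(f"{path}: Mol2 record 0 failed to parse")
        return [_ligand_from_rdkit(mol)]
    if suffix in (".sdf", ".sd", ".mol"):
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        mols = []
        for idx, mol in enumerate(supplier):
            if mol is None:
                raise LigandParseError(f"{path}: SDF record {idx} failed to parse")
            mols.append(_ligand_from_rdkit(mol))
        if not mols:
            raise LigandParseError(f"{path}: SDF file contains no records")
        return mols
    raise StructureError(f"unsupported ligand format: {path.suffix}")


# --------------------------------------------------------------------------
# curation

@dataclass
class CurationRules:
    """Receptor/ligand quality predicates applied before training or scoring."""

    max_resolution: float | None = 3.0       # Angstrom
    min_ligand_atoms: int = 5
    max_ligand_atoms: int = 60
    max_rotatable_bonds: int | None = 20
    covalent_cutoff: float | None = 1.8      # Angstrom, heavy non-metal pairs


@dataclass
class CurationResult:
    passed: bool
    failures: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


def count_rotatable_bonds(lig: LigandMolecule) -> int:
    """Single acyclic bonds between heavy atoms that each have >=2 heavy neighbors."""
    g = lig.graph(heavy_only=True)
    count = 0
    for i, j, order in lig.bonds:
        if order != "single" or i not in g or j not in g:
            continue
        if g.degree[i] < 2 or g.degree[j] < 2:
            continue
        g.remove_edge(i, j)
        in_ring = nx.has_path(g, i, j)
        g.add_edge(i, j, order=order)
        if not in_ring:
            count += 1
    return count


def passes_curation(cplx: ComplexPose,
                    rules: CurationRules | None = None) -> CurationResult:
    """Evaluate every enabled predicate; report all failures, not just the first.

    Predicates with missing metadata (e.g. unknown resolution) are skipped and
    listed as such rather than failing.
    """
    rules = rules or CurationRules()
    failures: list[str] = []
    skipped: list[str] = []

    if rules.max_resolution is not None:
        if cplx.protein.resolution is None:
            skipped.append("resolution")
        elif cplx.protein.resolution > rules.max_resolution:
            failures.append("resolution")

    n_atoms = len(cplx.ligand.atoms)
    if not (rules.min_ligand_atoms <= n_atoms <= rules.max_ligand_atoms):
        failures.append("ligand_atom_count")

    if rules.max_rotatable_bonds is not None:
        if count_rotatable_bonds(cplx.ligand) > rules.max_rotatable_bonds:
            failures.append("rotatable_bonds")

    if rules.covalent_cutoff is not None:
        from .features import PROTEIN_METALS
        lig_heavy = cplx.ligand.heavy_indices()
        lig_xyz = cplx.ligand.coords()[lig_heavy]
        excluded = {"H"} | set(PROTEIN_METALS)
        prot = [a for a in cplx.protein.atoms if a.element.upper() not in excluded]
        if prot and len(lig_xyz):
            prot_xyz = np.array([a.coord for a in prot])
            if cdist(lig_xyz, prot_xyz).min() < rules.covalent_cutoff:
                failures.append("covalent_bond")

    return CurationResult(passed=not failures, failures=failures, skipped=skipped)


# --------------------------------------------------------------------------
# RMSD

def _check_compatible(pose: LigandMolecule, reference: LigandMolecule) -> None:
    if len(pose.atoms) != len(reference.atoms):
        raise IncompatibleMoleculesError(
            f"atom count mismatch: {len(pose.atoms)} vs {len(reference.atoms)}")
    elems_p = sorted(a.element.upper() for a in pose.atoms)
    elems_r = sorted(a.element.upper() for a in reference.atoms)
    if elems_p != elems_r:
        raise IncompatibleMoleculesError("element multisets differ")


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def ligand_automorphisms(lig: LigandMolecule, heavy_only: bool = True,
                         limit: int = 10000):
    """Yield element- and bond-preserving permutations of the ligand graph."""
    g = lig.graph(heavy_only=heavy_only)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g,
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"])
    yield from itertools.islice(matcher.isomorphisms_iter(), limit)


def compute_rmsd(pose: LigandMolecule, reference: LigandMolecule,
                 symmetry: bool = False, heavy_only: bool = True) -> float:
    """In-place (no superposition) RMSD between a pose and the native ligand.

    With ``symmetry`` the RMSD is minimized over graph automorphisms of the
    ligand, so topologically equivalent atoms may be swapped; the result is
    therefore never larger than the identity-mapping RMSD.
    """
    _check_compatible(pose, reference)
    idx = reference.heavy_indices() if heavy_only else list(range(len(reference.atoms)))
    ref_xyz = reference.coords()[idx]
    pose_xyz_all = pose.coords()
    plain = _rmsd(pose_xyz_all[idx], ref_xyz)
    if not symmetry:
        return plain
    best = plain
    for mapping in ligand_automorphisms(reference, heavy_only=heavy_only):
        permuted = np.array([pose_xyz_all[mapping[i]] for i in idx])
        best = min(best, _rmsd(permuted, ref_xyz))
    return best


# --------------------------------------------------------------------------
# labels and writers

def read_rmsd_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"pose_id", "complex_id", "rmsd"}
    if not required.issubset(df.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    if (df["rmsd"] < 0).any():
        raise ValueError("rmsd labels must be >= 0")
    return df


def write_rmsd_labels(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_protein_pdb(protein: ProteinStructure, path) -> None:
    """Write the structure back out as a minimal single-model PDB file."""
    st = gemmi.Structure()
    st.name = "shellscore"
    if protein.resolution is not None:
        st.resolution = protein.resolution
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple, gemmi.Residue] = {}
    for a in protein.atoms:
        if a.chain not in chains:
            chains[a.chain] = gemmi.Chain(a.chain)
        key = (a.chain, a.res_id, a.res_name)
        if key not in residues:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_id, " ")
            res.het_flag = "H" if a.is_hetatm else "A"
            chains[a.chain].add_residue(res)
            residues[key] = chains[a.chain][-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.coord)
        residues[key].add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


_BOND_ORDER_TO_RDKIT = {"single": 1, "double": 2, "triple": 3}


def ligand_to_rdkit(lig: LigandMolecule):
    """Build an RDKit molecule (with conformer) from a LigandMolecule."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for a in lig.atoms:
        atom = Chem.Atom(a.element.capitalize())
        atom.SetFormalCharge(a.formal_charge)
        atom.SetNoImplicit(False)
        if a.aromatic:
            atom.SetIsAromatic(True)
        rw.AddAtom(atom)
    for i, j, order in lig.bonds:
        if order == "aromatic":
            rw.AddBond(i, j, Chem.BondType.AROMATIC)
            rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
        else:
            rw.AddBond(i, j, Chem.BondType.values[_BOND_ORDER_TO_RDKIT.get(order, 1)])
    mol = rw.GetMol()
    conf = Chem.Conformer(len(lig.atoms))
    for i, a in enumerate(lig.atoms):
        conf.SetAtomPosition(i, Point3D(*map(float, a.coord)))
    mol.AddConformer(conf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)
    return mol


def write_ligand_sdf(ligands: list[LigandMolecule], path,
                     names: list[str] | None = None) -> None:
    """Write a (multi-record) V2000 SDF pose set."""
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for i, lig in enumerate(ligands):
        mol = ligand_to_rdkit(lig)
        if names is not None:
            mol.SetProp("_Name", names[i])
        writer.write(mol)
    writer.close()
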