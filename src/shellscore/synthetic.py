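"""Synthetic complexes and pose sets with analytically exact RMSD labels.

Decoys are rigid whole-ligand translations: translating every atom by a
vector t changes the in-place RMSD by exactly |t|, so every label is known in
closed form and the featurization -> scoring -> metric pipeline can be tested
without any docking run or download.

The learnable dataset emulates a re-docking study at desk scale: each complex
is a small aromatic ligand inside a spherical pocket of protein atoms whose
nearest-ligand distances sit around the first shell boundaries.  Displacing
the ligand shifts pocket atoms between shells, so shell-occupancy patterns
carry a recoverable, smoothly varying signal about the displacement magnitude
-- which *is* the RMSD label.  Radial jitter of the pocket atoms makes the
expected occupancy a strictly monotone function of the displacement instead
of a hard threshold.  Native poses are replicated four times per complex so
every ensemble part retains natives after splitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .structures import ComplexPose, LigandAtom, LigandMolecule, ProteinAtom, \
    ProteinStructure, write_ligand_sdf, write_protein_pdb, write_rmsd_labels, \
    read_protein, read_ligand, read_rmsd_labels

__all__ = [
    "FixtureSpec", "ligand_template", "make_toy_complex", "make_pose_set",
    "make_learnable_dataset", "write_fixture_tree", "load_fixture_tree",
]

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 5, "F": 1, "CL": 1,
            "BR": 1, "I": 1, "H": 1}
_ORDER_VALUE = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one toy complex and its pose set."""

    seed: int = 0
    n_protein_atoms: int = 48
    ligand: str = "benzene"
    pocket_radius: float = 3.5      # nearest-ligand distance of pocket atoms, A
    radial_jitter: float = 0.4      # uniform jitter of that distance, A
    pose_count: int = 20
    target_rmsds: tuple = ()        # explicit targets override pose_count


def _finalize_ligand(elements, coords, bonds) -> LigandMolecule:
    """Derive degrees, hydrogen counts, hybridization and ring sizes from the
    bond graph (simple valence bookkeeping; adequate for template molecules)."""
    import networkx as nx

    n = len(elements)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((i, j) for i, j, _ in bonds)
    order_sum = np.zeros(n)
    aromatic = [False] * n
    max_order = [0.0] * n
    for i, j, order in bonds:
        val = _ORDER_VALUE[order]
        order_sum[i] += val
        order_sum[j] += val
        if order == "aromatic":
            aromatic[i] = aromatic[j] = True
        max_order[i] = max(max_order[i], val)
        max_order[j] = max(max_order[j], val)
    cycles = nx.cycle_basis(g)
    ring_size = [None] * n
    for cycle in cycles:
        for i in cycle:
            ring_size[i] = max(ring_size[i] or 0, len(cycle))
    atoms = []
    for i, (el, xyz) in enumerate(zip(elements, coords)):
        valence = _VALENCE.get(el.upper(), 4)
        num_h = max(0, int(round(valence - order_sum[i])))
        if aromatic[i]:
            hyb = "SP2"
        elif max_order[i] >= 3:
            hyb = "SP"
        elif max_order[i] >= 2:
            hyb = "SP2"
        else:
            hyb = "SP3"
        atoms.append(LigandAtom(
            element=el, formal_charge=0, coord=np.asarray(xyz, dtype=float),
            degree=int(g.degree[i]), implicit_valence=num_h, num_h=num_h,
            hybridization=hyb, ring_size=ring_size[i], aromatic=aromatic[i]))
    return LigandMolecule(atoms=atoms, bonds=list(bonds))


def ligand_template(name: str = "benzene") -> LigandMolecule:
    """Small rigid template molecules centered at the origin."""
    if name == "benzene":
        r = 1.39
        ang = np.arange(6) * np.pi / 3
        coords = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(6)], axis=1)
        bonds = [(i, (i + 1) % 6, "aromatic") for i in range(6)]
        return _finalize_ligand(["C"] * 6, coords, bonds)
    if name == "butane":
        coords = np.array([[-2.3, 0, 0], [-0.8, 0.4, 0], [0.8, -0.4, 0],
                           [2.3, 0, 0]])
        bonds = [(0, 1, "single"), (1, 2, "single"), (2, 3, "single")]
        return _finalize_ligand(["C"] * 4, coords, bonds)
    if name == "methane":
        return _finalize_ligand(["C"], np.zeros((1, 3)), [])
    if name == "toluene":
        benz = ligand_template("benzene")
        coords = np.vstack([benz.coords(), [[2.9, 0.0, 0.0]]])
        bonds = list(benz.bonds) + [(0, 6, "single")]
        return _finalize_ligand(["C"] * 7, coords, bonds)
    raise ValueError(f"unknown ligand template {name!r}")


_RESIDUE_CYCLE = ("ALA", "GLY", "SER", "LEU", "VAL", "THR")
_ATOM_CYCLE = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"))


def _place_at_min_distance(lig_xyz: np.ndarray, direction: np.ndarray,
                           target: float) -> np.ndarray:
    """Point along ``direction`` from the ligand centroid whose min distance
    to the ligand atoms equals ``target`` (solved by bracketing)."""
    center = lig_xyz.mean(axis=0)

    def min_dist(t):
        p = center + t * direction
        return float(np.min(np.linalg.norm(lig_xyz - p, axis=1))) - target

    extent = float(np.max(np.linalg.norm(lig_xyz - center, axis=1)))
    if min_dist(0.0) > 0:
        # target below the centroid-to-atom distance: anchor on an atom
        # instead (distance to the anchor is exact, to the rest >= close)
        return lig_xyz[0] + target * direction
    # at t=0 the point is inside the ligand (min_dist < 0); at
    # t = target + extent + 1 every atom is farther than target
    t = brentq(min_dist, 0.0, target + extent + 1.0, xtol=1e-12)
    # land at-or-just-inside the target so an exact-boundary placement stays
    # in the inner shell of the half-open (lower, upper] convention
    while min_dist(t) > 0:
        t = np.nextafter(t, 0.0)
    return center + t * direction


def make_toy_complex(spec: FixtureSpec | None = None, *, seed: int | None = None,
                     complex_id: str = "toy", resolution: float = 2.0,
                     **overrides) -> ComplexPose:
    """A template ligand at the origin inside a spherical shell of protein
    atoms whose nearest-ligand distance is pocket_radius (+- jitter)."""
    if spec is None:
        spec = FixtureSpec(seed=seed if seed is not None else 0, **overrides)
    rng = np.random.default_rng(spec.seed)
    lig = ligand_template(spec.ligand)
    lig_xyz = lig.coords()
    atoms = []
    for i in range(spec.n_protein_atoms):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        target = spec.pocket_radius + rng.uniform(-spec.radial_jitter,
                                                  spec.radial_jitter)
        pos = _place_at_min_distance(lig_xyz, u, target)
        name, element = _ATOM_CYCLE[i % len(_ATOM_CYCLE)]
        atoms.append(ProteinAtom(
            element=element, name=name,
            res_name=_RESIDUE_CYCLE[(i // len(_ATOM_CYCLE)) % len(_RESIDUE_CYCLE)],
            res_id=1 + i // len(_ATOM_CYCLE), chain="A", coord=pos))
    protein = ProteinStructure(atoms=atoms, resolution=resolution)
    return ComplexPose(protein=protein, ligand=lig, pose_id=f"{complex_id}:native",
                       complex_id=complex_id, rmsd_label=0.0)


def make_pose_set(reference: ComplexPose, target_rmsds, seed: int = 0) -> list[ComplexPose]:
    """Rigid-translation decoys: pose i is the reference ligand moved by a
    random unit vector scaled to target_rmsds[i], so its exact in-place RMSD
    equals the target."""
    rng = np.random.default_rng(seed)
    poses = []
    for i, target in enumerate(target_rmsds):
        if target < 0:
            raise ValueError("target RMSD must be >= 0")
        if target == 0:
            vec = np.zeros(3)
        else:
            vec = rng.normal(size=3)
            vec *= target / np.linalg.norm(vec)
        poses.append(ComplexPose(
            protein=reference.protein, ligand=reference.ligand.translated(vec),
            pose_id=f"{reference.complex_id}:pose{i}",
            complex_id=reference.complex_id, rmsd_label=float(target)))
    return poses


def make_learnable_dataset(n_complexes: int = 10, poses_per_complex: int = 20,
                           seed: int = 0, max_displacement: float = 2.5,
                           native_replicates: int = 4,
                           spec: FixtureSpec | None = None) -> list[ComplexPose]:
    """Labeled pose sets whose RMSD is a smooth function of displacement.

    Returns n_complexes * (poses_per_complex + native_replicates) poses; each
    complex contributes ``native_replicates`` exact copies of its native pose
    (label 0) plus decoys with labels drawn uniformly from
    (0, max_displacement].
    """
    if n_complexes < 4:
        raise ValueError("need >= 4 complexes for ensemble splitting")
    base = spec or FixtureSpec()
    rng = np.random.default_rng(seed)
    dataset: list[ComplexPose] = []
    for c in range(n_complexes):
        cid = f"cplx{c:03d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cspec = FixtureSpec(seed=sub_seed, n_protein_atoms=base.n_protein_atoms,
                            ligand=base.ligand, pocket_radius=base.pocket_radius,
                            radial_jitter=base.radial_jitter)
        native = make_toy_complex(cspec, complex_id=cid)
        for rep in range(native_replicates):
            dataset.append(ComplexPose(
                protein=native.protein, ligand=native.ligand,
                pose_id=f"{cid}:native{rep}", complex_id=cid, rmsd_label=0.0))
        targets = rng.uniform(0.0, max_displacement, size=poses_per_complex)
        dataset.extend(make_pose_set(native, targets,
                                     seed=int(rng.integers(0, 2**31 - 1))))
    return dataset


# --------------------------------------------------------------------------
# on-disk fixture trees (standard PDB + SDF, exercising the real I/O path)

def write_fixture_tree(poses: list[ComplexPose], outdir) -> Path:
    """One subdirectory per complex: protein.pdb + poses.sdf, plus labels.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_complex: dict[str, list[ComplexPose]] = {}
    for p in poses:
        by_complex.setdefault(p.complex_id or p.pose_id, []).append(p)
    rows = []
    for cid, group in by_complex.items():
        cdir = outdir / cid
        cdir.mkdir(exist_ok=True)
        write_protein_pdb(group[0].protein, cdir / "protein.pdb")
        write_ligand_sdf([p.ligand for p in group], cdir / "poses.sdf",
                         names=[p.pose_id for p in group])
        for p in group:
            rows.append({"pose_id": p.pose_id, "complex_id": cid,
                         "rmsd": p.rmsd_label})
    write_rmsd_labels(pd.DataFrame(rows), outdir / "labels.tsv")
    return outdir


def load_fixture_tree(indir) -> list[ComplexPose]:
    """Read a fixture tree back through the standard structure readers."""
    indir = Path(indir)
    labels = read_rmsd_labels(indir / "labels.tsv")
    by_key = {(r.complex_id, r.pose_id): float(r.rmsd)
              for r in labels.itertuples()}
    poses: list[ComplexPose] = []
    for cdir in sorted(d for d in indir.iterdir() if d.is_dir()):
        protein = read_protein(cdir / "protein.pdb")
        ligands = read_ligand(cdir / "poses.sdf")
        ids = [r.pose_id for r in labels.itertuples() if r.complex_id == cdir.name]
        for pid, lig in zip(ids, ligands):
            poses.append(ComplexPose(
                protein=protein, ligand=lig, pose_id=pid, complex_id=cdir.name,
                rmsd_label=by_key.get((cdir.name, pid))))
    return poses
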