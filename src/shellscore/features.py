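"""One-hot featurization of atoms and edges in shell interface graphs.

Every node is a 171-dimensional vector split into a protein block (the first
97 dimensions) and a ligand block (the last 74): protein atoms populate only
the leading block, ligand atoms only the trailing block, so the elementwise
product of a protein row and a ligand row is identically zero.  Edges are
8-dimensional: a 7-way interaction-category one-hot plus one raw distance in
Angstrom.

Block widths are fixed; the category vocabularies behind them live in one
:class:`FeatureSchema` so they can be revised without touching encoder code.
A category outside its vocabulary lands in the block's explicit OTHER slot
where one exists; the elemental atom-type block instead encodes OTHER as
all-zeros, which is what makes the 7/97/74 widths add up.  A property that is
simply unknown (e.g. hybridization of a protein atom read from a PDB file,
which carries no bond graph) leaves its block all-zero as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureSchema", "DEFAULT_SCHEMA", "EDGE_CATEGORIES",
    "classify_element", "encode_protein_node", "encode_ligand_node",
    "encode_edge", "NODE_DIM", "PROTEIN_DIM", "LIGAND_DIM", "EDGE_DIM",
]

NODE_DIM = 171
PROTEIN_DIM = 97
LIGAND_DIM = 74
EDGE_DIM = 8

#: Elements grouped as "metal" for protein atoms.
PROTEIN_METALS = frozenset({"CA", "FE", "K", "MG", "MN", "NA", "ZN"})
#: Elements grouped as "halogen" for ligand atoms.
LIGAND_HALOGENS = frozenset({"F", "CL", "BR", "I"})

_SIMPLE_ELEMENTS = ("H", "C", "N", "O", "P", "S")

STANDARD_AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
#: Modified residues that still behave as amino acids; they share one slot.
NONSTANDARD_AMINO_ACIDS = frozenset({
    "MSE", "SEC", "PYL", "HYP", "PTR", "SEP", "TPO", "CSO", "KCX", "LLP",
})

PDB_ATOM_NAMES = (
    "N", "CA", "C", "O", "CB", "CG", "CG1", "CG2", "CD", "CD1", "CD2",
    "CE", "CE1", "CE2", "CE3", "CZ", "CZ2", "CZ3", "CH2", "ND1", "ND2",
    "NE", "NE1", "NE2", "NH1", "NH2", "NZ", "OD1", "OD2", "OE1", "OE2",
    "OG", "OG1", "OH", "SD", "SG",
)

HYBRIDIZATIONS = ("S", "SP", "SP2", "SP3", "SP3D", "SP3D2", "AROMATIC",
                  "UNSPECIFIED")

EDGE_CATEGORIES = ("single", "double", "triple", "aromatic", "noncovalent",
                   "other", "unknown")


@dataclass(frozen=True)
class FeatureSchema:
    """Fixed block layout producing 171-dim nodes and 8-dim edges."""

    atom_type_width: int = 7
    degree_values: tuple = tuple(range(9))          # 0-8, +OTHER -> 10
    valence_values: tuple = tuple(range(5))         # 0-4, +OTHER -> 6
    num_h_values: tuple = tuple(range(5))           # 0-4, +OTHER -> 6
    hybridizations: tuple = HYBRIDIZATIONS          # 8, +OTHER -> 9
    amino_acids: tuple = STANDARD_AMINO_ACIDS       # 20, +NONSTD+OTHER -> 22
    atom_names: tuple = PDB_ATOM_NAMES              # 36, +OTHER -> 37
    formal_charges: tuple = tuple(range(-10, 11))   # 21, +OTHER -> 22
    ring_sizes: tuple = tuple(range(3, 11))         # none+3-10+OTHER+2 pad -> 12
    ring_block_width: int = 12
    edge_categories: tuple = EDGE_CATEGORIES

    def __post_init__(self):
        if self.protein_widths() != (7, 10, 6, 6, 9, 22, 37):
            raise ValueError("protein block widths inconsistent with layout")
        if self.ligand_widths() != (7, 10, 6, 6, 9, 22, 12, 2):
            raise ValueError("ligand block widths inconsistent with layout")
        assert sum(self.protein_widths()) == PROTEIN_DIM
        assert sum(self.ligand_widths()) == LIGAND_DIM
        assert len(self.edge_categories) + 1 == EDGE_DIM

    def protein_widths(self) -> tuple:
        return (self.atom_type_width, len(self.degree_values) + 1,
                len(self.valence_values) + 1, len(self.num_h_values) + 1,
                len(self.hybridizations) + 1, len(self.amino_acids) + 2,
                len(self.atom_names) + 1)

    def ligand_widths(self) -> tuple:
        return (self.atom_type_width, len(self.degree_values) + 1,
                len(self.valence_values) + 1, len(self.num_h_values) + 1,
                len(self.hybridizations) + 1, len(self.formal_charges) + 1,
                self.ring_block_width, 2)

    @property
    def node_dim(self) -> int:
        return sum(self.protein_widths()) + sum(self.ligand_widths())

    @property
    def edge_dim(self) -> int:
        return len(self.edge_categories) + 1

    def to_json(self) -> str:
        """Serialize the vocabularies for provenance next to cached features."""
        return json.dumps({
            "protein_widths": self.protein_widths(),
            "ligand_widths": self.ligand_widths(),
            "degree_values": self.degree_values,
            "valence_values": self.valence_values,
            "num_h_values": self.num_h_values,
            "hybridizations": self.hybridizations,
            "amino_acids": self.amino_acids,
            "atom_names": self.atom_names,
            "formal_charges": self.formal_charges,
            "ring_sizes": self.ring_sizes,
            "edge_categories": self.edge_categories,
        }, indent=1)


DEFAULT_SCHEMA = FeatureSchema()


def classify_element(element: str, role: str) -> int | None:
    """Map an element symbol to its 7-way category index, or None for OTHER.

    Protein atoms: H, C, N, O, P, S, metal (Ca, Fe, K, Mg, Mn, Na, Zn).
    Ligand atoms:  H, C, N, O, P, S, halogen (F, Cl, Br, I).
    """
    sym = element.strip().upper()
    if role not in ("protein", "ligand"):
        raise ValueError(f"role must be 'protein' or 'ligand', got {role!r}")
    if sym in _SIMPLE_ELEMENTS:
        return _SIMPLE_ELEMENTS.index(sym)
    if role == "protein" and sym in PROTEIN_METALS:
        return 6
    if role == "ligand" and sym in LIGAND_HALOGENS:
        return 6
    return None


def _one_hot(width: int, index: int | None) -> np.ndarray:
    block = np.zeros(width)
    if index is not None:
        block[index] = 1.0
    return block


def _vocab_slot(values: tuple, value) -> int | None:
    """Index into a vocabulary with a trailing OTHER slot; None stays zero."""
    if value is None:
        return None
    if value in values:
        return values.index(value)
    return len(values)  # OTHER


def _shared_blocks(schema: FeatureSchema, element: str, role: str,
                   degree, implicit_valence, num_h, hybridization) -> list:
    blocks = [_one_hot(schema.atom_type_width, classify_element(element, role))]
    blocks.append(_one_hot(len(schema.degree_values) + 1,
                           _vocab_slot(schema.degree_values, degree)))
    blocks.append(_one_hot(len(schema.valence_values) + 1,
                           _vocab_slot(schema.valence_values, implicit_valence)))
    blocks.append(_one_hot(len(schema.num_h_values) + 1,
                           _vocab_slot(schema.num_h_values, num_h)))
    hyb = hybridization.upper() if isinstance(hybridization, str) else hybridization
    blocks.append(_one_hot(len(schema.hybridizations) + 1,
                           _vocab_slot(schema.hybridizations, hyb)))
    return blocks


def encode_protein_node(atom, schema: FeatureSchema = DEFAULT_SCHEMA) -> np.ndarray:
    """Encode a protein atom into the leading 97 of the 171 node dimensions.

    ``atom`` needs: element, name, res_name, and optionally degree,
    implicit_valence, num_h, hybridization (None when unknown).
    """
    blocks = _shared_blocks(schema, atom.element, "protein",
                            getattr(atom, "degree", None),
                            getattr(atom, "implicit_valence", None),
                            getattr(atom, "num_h", None),
                            getattr(atom, "hybridization", None))
    # amino-acid block: 20 standard + shared nonstandard slot + OTHER
    res = atom.res_name.strip().upper()
    width = len(schema.amino_acids) + 2
    if res in schema.amino_acids:
        aa = schema.amino_acids.index(res)
    elif res in NONSTANDARD_AMINO_ACIDS:
        aa = len(schema.amino_acids)
    else:
        aa = width - 1
    blocks.append(_one_hot(width, aa))
    name = atom.name.strip().upper()
    blocks.append(_one_hot(len(schema.atom_names) + 1,
                           _vocab_slot(schema.atom_names, name)))
    vec = np.zeros(schema.node_dim)
    vec[:PROTEIN_DIM] = np.concatenate(blocks)
    return vec


def encode_ligand_node(atom, schema: FeatureSchema = DEFAULT_SCHEMA) -> np.ndarray:
    """Encode a ligand atom into the trailing 74 of the 171 node dimensions.

    Ring-size block: slot 0 = not in a ring, slots 1-8 = largest ring of size
    3-10 containing the atom, slot 9 = larger than 10 (OTHER); the final two
    slots of the 12-wide block are reserved and stay zero.
    """
    blocks = _shared_blocks(schema, atom.element, "ligand",
                            getattr(atom, "degree", None),
                            getattr(atom, "implicit_valence", None),
                            getattr(atom, "num_h", None),
                            getattr(atom, "hybridization", None))
    blocks.append(_one_hot(len(schema.formal_charges) + 1,
                           _vocab_slot(schema.formal_charges,
                                       getattr(atom, "formal_charge", None))))
    ring = np.zeros(schema.ring_block_width)
    size = getattr(atom, "ring_size", None)
    if size is None:
        ring[0] = 1.0
    elif size in schema.ring_sizes:
        ring[1 + schema.ring_sizes.index(size)] = 1.0
    else:
        ring[1 + len(schema.ring_sizes)] = 1.0  # OTHER: rings beyond 10 atoms
    blocks.append(ring)
    blocks.append(_one_hot(2, 1 if getattr(atom, "aromatic", False) else 0))
    vec = np.zeros(schema.node_dim)
    vec[PROTEIN_DIM:] = np.concatenate(blocks)
    return vec


def encode_edge(category: str, distance: float,
                schema: FeatureSchema = DEFAULT_SCHEMA) -> np.ndarray:
    """Encode an edge: 7-way category one-hot plus one distance entry.

    Within a shell graph ``distance`` is the shell's outer boundary (DistMax)
    for protein-ligand contacts and exactly 1 for ligand covalent bonds.
    """
    if category not in schema.edge_categories:
        raise ValueError(
            f"unknown edge category {category!r}; expected one of "
            f"{schema.edge_categories}")
    if not distance > 0:
        raise ValueError("edge distance feature must be positive")
    vec = np.zeros(schema.edge_dim)
    vec[schema.edge_categories.index(category)] = 1.0
    vec[-1] = float(distance)
    return vec
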