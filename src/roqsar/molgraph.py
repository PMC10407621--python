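"""Molecular graph primitives.

Parses SMILES/SDF input into :class:`Molecule` objects and derives the graph
structures consumed by the descriptor layer: the hydrogen-included graph,
the hydrogen-depleted (heavy-atom) graph, bond-indexed edge-adjacency
matrices and topological distance matrices.

Conventions (verified against the reference descriptor values):

* bond orders are kept as edge attributes but never enter adjacency
  structure — a double bond is a single graph edge;
* hydrogens are excluded from edge-adjacency descriptors and included in
  information-content descriptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from .exceptions import EmptyGraphError, ParseError, TableLookupError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: canonical bond-order labels
BOND_ORDERS = ("single", "double", "triple", "aromatic")

_RDKIT_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}

_ORDER_SYMBOL = {"single": "-", "double": "=", "triple": "#", "aromatic": ":"}


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int = 0
    coords: tuple[float, float, float] | None = None


@dataclass(frozen=True)
class Bond:
    endpoints: tuple[int, int]
    order: str

    def __post_init__(self) -> None:
        i, j = self.endpoints
        if i == j:
            raise ValueError(f"bond endpoints must be distinct, got {self.endpoints}")
        if self.order not in BOND_ORDERS:
            raise ValueError(f"unknown bond order {self.order!r}")


@dataclass
class Molecule:
    """A single connected molecule with explicit hydrogens."""

    name: str
    abbrev: str
    atoms: list[Atom]
    bonds: list[Bond]
    smiles: str
    _rdmol: Chem.Mol = field(repr=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_heavy_atoms(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")

    @property
    def has_coordinates(self) -> bool:
        return all(a.coords is not None for a in self.atoms)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


def _molecule_from_rdkit(rdmol: Chem.Mol, name: str, abbrev: str) -> Molecule:
    if len(Chem.GetMolFrags(rdmol)) > 1:
        raise ParseError(f"disconnected multi-fragment input for {name or 'molecule'}")
    conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
    use_coords = conf is not None and conf.Is3D()
    atoms = []
    for a in rdmol.GetAtoms():
        xyz = None
        if use_coords:
            p = conf.GetAtomPosition(a.GetIdx())
            xyz = (p.x, p.y, p.z)
        atoms.append(Atom(a.GetSymbol(), a.GetFormalCharge(), xyz))
    bonds = [
        Bond((b.GetBeginAtomIdx(), b.GetEndAtomIdx()), _RDKIT_ORDER[b.GetBondType()])
        for b in rdmol.GetBonds()
    ]
    smiles = Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(rdmol)))
    return Molecule(name=name, abbrev=abbrev, atoms=atoms, bonds=bonds,
                    smiles=smiles, _rdmol=rdmol)


def parse_structure(source: str, name: str = "", abbrev: str = "") -> Molecule:
    """Parse a SMILES string or a single V2000/V3000 SDF record.

    Hydrogens are made explicit; 3D coordinates are retained when the SDF
    record carries them. Disconnected (multi-fragment) inputs are rejected.
    """
    if "V2000" in source or "V3000" in source:
        rdmol = Chem.MolFromMolBlock(source, removeHs=False)
        if rdmol is None:
            raise ParseError(f"unparsable SDF record for {name or 'input'}")
        rdmol = Chem.AddHs(rdmol, addCoords=rdmol.GetNumConformers() > 0)
    else:
        token = source.strip()
        rdmol = Chem.MolFromSmiles(token)
        if rdmol is None:
            raise ParseError(f"unparsable SMILES {token!r}")
        rdmol = Chem.AddHs(rdmol)
    return _molecule_from_rdkit(rdmol, name=name, abbrev=abbrev)


def read_smiles_file(path) -> list[Molecule]:
    """Read a one-SMILES-per-line file with an optional name column."""
    mols = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            nm = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            mols.append(parse_structure(smi, name=nm, abbrev=nm))
    return mols


def read_sdf_file(path) -> list[Molecule]:
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    mols = []
    for idx, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ParseError(f"unparsable SDF record #{idx + 1} in {path}")
        nm = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else f"mol{idx + 1}"
        rdmol = Chem.AddHs(rdmol, addCoords=rdmol.GetNumConformers() > 0)
        mols.append(_molecule_from_rdkit(rdmol, name=nm, abbrev=nm))
    return mols


def ensure_coordinates(mol: Molecule, seed: int = 2023) -> Molecule:
    """Return a molecule that has 3D coordinates for every atom.

    When the input already carries coordinates it is returned unchanged.
    Otherwise a deterministic distance-geometry embedding (seeded ETKDG)
    followed by MMFF refinement generates them; geometry-dependent
    descriptors computed from embedded coordinates will deviate slightly
    from values obtained with quantum-optimised geometries.
    """
    if mol.has_coordinates:
        return mol
    logger.warning(
        "embedding 3D coordinates for %s (seed=%d); geometry-dependent "
        "descriptors will deviate from quantum-optimised geometries",
        mol.name or mol.smiles, seed,
    )
    rdmol = Chem.Mol(mol._rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        raise ParseError(f"3D embedding failed for {mol.name or mol.smiles}")
    try:
        AllChem.MMFFOptimizeMolecule(rdmol)
    except Exception:  # pragma: no cover - MMFF missing params for exotic atoms
        logger.warning("MMFF refinement failed for %s; using raw embedding", mol.name)
    return _molecule_from_rdkit(rdmol, name=mol.name, abbrev=mol.abbrev)


def hydrogen_included_graph(mol: Molecule) -> nx.Graph:
    g = nx.Graph()
    for idx, atom in enumerate(mol.atoms):
        g.add_node(idx, element=atom.element)
    for bond in mol.bonds:
        g.add_edge(*bond.endpoints, order=bond.order)
    return g


def heavy_atom_graph(mol: Molecule) -> nx.Graph:
    """Hydrogen-depleted graph; bond orders kept as edge attributes only."""
    g = hydrogen_included_graph(mol)
    hydrogens = [n for n, d in g.nodes(data=True) if d["element"] == "H"]
    g.remove_nodes_from(hydrogens)
    if g.number_of_edges() == 0:
        raise EmptyGraphError(
            f"{mol.name or mol.smiles}: no heavy-atom bonds (monoatomic skeleton)"
        )
    return g


def bond_key(element_a: str, element_b: str, order: str) -> str:
    """Canonical lookup key for a bond type, e.g. ``C-Cl``, ``C=O``, ``C:C``."""
    lo, hi = sorted((element_a, element_b))
    return f"{lo}{_ORDER_SYMBOL[order]}{hi}"


@dataclass
class EdgeAdjacency:
    """Bond-indexed adjacency: B[e,f]=1 iff distinct bonds e,f share an atom.

    For dipole weighting the per-bond weights sit on the diagonal.
    """

    matrix: np.ndarray
    edges: list[tuple[int, int]]
    weighting: str

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix).copy()


def edge_adjacency(
    graph: nx.Graph,
    weighting: str = "unweighted",
    dipole_table: dict[str, float] | None = None,
) -> EdgeAdjacency:
    """Build the edge-adjacency matrix of ``graph``.

    ``weighting='dipole'`` places per-bond dipole weights on the diagonal;
    every bond type occurring in the graph must then have an entry in
    ``dipole_table`` (keyed as by :func:`bond_key`).
    """
    if weighting not in ("unweighted", "dipole"):
        raise ValueError(f"unknown weighting {weighting!r}")
    edges = list(graph.edges())
    n_edges = len(edges)
    if n_edges == 0:
        raise EmptyGraphError("edge adjacency undefined for an edgeless graph")
    B = np.zeros((n_edges, n_edges))
    for i in range(n_edges):
        si = set(edges[i])
        for j in range(i + 1, n_edges):
            if si & set(edges[j]):
                B[i, j] = B[j, i] = 1.0
    if weighting == "dipole":
        if dipole_table is None:
            raise TableLookupError("dipole weighting requested without a dipole table")
        for i, (u, v) in enumerate(edges):
            key = bond_key(graph.nodes[u]["element"], graph.nodes[v]["element"],
                           graph.edges[u, v]["order"])
            if key not in dipole_table:
                raise TableLookupError(f"bond type {key!r} missing from dipole table")
            B[i, i] = dipole_table[key]
    return EdgeAdjacency(matrix=B, edges=edges, weighting=weighting)


def topological_distance_matrix(mol: Molecule, include_h: bool = True) -> np.ndarray:
    """Shortest-path bond-count matrix over atoms (optionally heavy only)."""
    g = hydrogen_included_graph(mol) if include_h else heavy_atom_graph(mol)
    nodes = sorted(g.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    D = np.zeros((n, n), dtype=int)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            D[index[src], index[dst]] = d
    return D
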