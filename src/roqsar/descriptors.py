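"""Molecular descriptors: SIC, ESpm, EEig and R-autocorrelation families.

The four default descriptors are

* ``SIC1`` — structural information content of order 1, computed on the
  hydrogen-included graph;
* ``ESpm14u`` — log-transformed 14th spectral moment of the unweighted
  edge-adjacency matrix of the hydrogen-depleted graph;
* ``EEig03d`` — third-largest eigenvalue of the dipole-weighted
  edge-adjacency matrix;
* ``R2e`` — geometry/topology autocorrelation of lag 2 weighted by
  carbon-scaled Sanderson electronegativities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import molgraph
from .exceptions import DescriptorError, GeometryError, TableLookupError
from .molgraph import Molecule

logger = logging.getLogger(__name__)

#: descriptor column order used in all tables
DESCRIPTOR_COLUMNS = ("SIC1", "R2e", "EEig03d", "ESpm14u")


@dataclass
class ElementTables:
    """Element/bond parameter tables.

    ``sanderson_en`` is carbon-scaled (EN(C) == 1 exactly); ``bond_dipole``
    maps :func:`roqsar.molgraph.bond_key` keys to diagonal weights.
    """

    sanderson_en: dict[str, float]
    bond_dipole: dict[str, float]
    version: int = 1

    def __post_init__(self) -> None:
        if not math.isclose(self.sanderson_en.get("C", 0.0), 1.0, abs_tol=1e-12):
            raise ValueError("sanderson_en must be carbon-scaled (C == 1)")
        for key in ("C-C", "C=C", "C:C"):
            if self.bond_dipole.get(key, 0.0) != 0.0:
                raise ValueError(f"carbon-carbon dipole weight {key} must be 0")

    @classmethod
    def from_yaml(cls, path=None) -> "ElementTables":
        if path is None:
            ref = resources.files("roqsar.data") / "element_tables.yaml"
            raw = yaml.safe_load(ref.read_text())
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        en = dict(raw["sanderson_electronegativity"])
        carbon = en["C"]
        en = {el: val / carbon for el, val in en.items()}
        return cls(sanderson_en=en,
                   bond_dipole=dict(raw["bond_dipole"]),
                   version=int(raw.get("version", 1)))


_default_tables: ElementTables | None = None


def default_tables() -> ElementTables:
    global _default_tables
    if _default_tables is None:
        _default_tables = ElementTables.from_yaml()
    return _default_tables


@dataclass
class DescriptorVector:
    sic1: float
    r2e: float
    eeig03d: float
    espm14u: float
    provenance: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {"SIC1": self.sic1, "R2e": self.r2e,
                "EEig03d": self.eeig03d, "ESpm14u": self.espm14u}


def _neighborhood_classes(mol: Molecule, order: int) -> list[int]:
    """Atom equivalence classes under m-th order neighborhood symmetry.

    Order 0 partitions by element; each refinement step splits classes by
    the multiset of neighbor classes (bond orders deliberately ignored).
    """
    g = molgraph.hydrogen_included_graph(mol)
    labels: list = [mol.atoms[i].element for i in range(mol.n_atoms)]
    for _ in range(order):
        refined = [
            (labels[i], tuple(sorted(str(labels[j]) for j in g.neighbors(i))))
            for i in range(mol.n_atoms)
        ]
        relabel = {key: rank for rank, key in enumerate(sorted(set(refined), key=str))}
        labels = [relabel[key] for key in refined]
    relabel = {key: rank for rank, key in enumerate(sorted(set(labels), key=str))}
    return [relabel[key] for key in labels]


def sic(mol: Molecule, order: int = 1) -> float:
    """Structural information content of the given neighborhood order.

    ``IC_m = -sum_g (n_g/A) log2(n_g/A)`` over atom equivalence classes of
    the hydrogen-included graph, normalised by ``log2(A)``.
    """
    n_atoms = mol.n_atoms
    if n_atoms < 2:
        raise DescriptorError("SIC undefined for a single-atom molecule")
    classes = _neighborhood_classes(mol, order)
    _, counts = np.unique(classes, return_counts=True)
    p = counts / n_atoms
    ic = float(-(p * np.log2(p)).sum())
    return ic / math.log2(n_atoms)


def espm(mol: Molecule, k: int = 14, method: str = "power") -> float:
    """Log-transformed k-th spectral moment of the unweighted edge adjacency.

    Returns ``ln(1 + trace(B^k))`` where B indexes heavy-atom bonds.  The
    trace is available via exact integer matrix powers (default) or via the
    eigenvalues of the symmetric matrix; both routes agree to ~1e-9.
    """
    if k < 1:
        raise ValueError(f"spectral moment order must be >= 1, got {k}")
    g = molgraph.heavy_atom_graph(mol)
    B = molgraph.edge_adjacency(g).matrix
    if method == "power":
        trace = float(np.trace(np.linalg.matrix_power(B.astype(np.int64), k)))
    elif method == "eigen":
        trace = float((np.linalg.eigvalsh(B) ** k).sum())
    else:
        raise ValueError(f"unknown method {method!r}")
    return math.log1p(trace)


def eeig(mol: Molecule, rank: int = 3, weighting: str = "dipole",
         tables: ElementTables | None = None) -> float:
    """rank-th largest eigenvalue of the (dipole-)weighted edge adjacency.

    Eigenvalues are sorted descending by value.  Molecules with fewer
    heavy-atom bonds than ``rank`` return 0 with a logged warning.
    """
    tables = tables or default_tables()
    g = molgraph.heavy_atom_graph(mol)
    if g.number_of_edges() < rank:
        logger.warning("%s has %d < %d heavy-atom bonds; EEig%02d set to 0",
                       mol.name or mol.smiles, g.number_of_edges(), rank, rank)
        return 0.0
    dipole = tables.bond_dipole if weighting == "dipole" else None
    ea = molgraph.edge_adjacency(g, weighting=weighting, dipole_table=dipole)
    eigenvalues = np.sort(np.linalg.eigvalsh(ea.matrix))[::-1]
    return float(eigenvalues[rank - 1])


def influence_diagonal(coords: np.ndarray, sv_tol: float = 1e-10) -> np.ndarray:
    """Diagonal of the molecular influence matrix H = M (MᵀM)⁻¹ Mᵀ.

    ``coords`` are centred in place of M; rank-deficient (planar/linear)
    geometries are handled by discarding singular values below ``sv_tol``.
    """
    M = np.asarray(coords, dtype=float)
    M = M - M.mean(axis=0)
    u, s, _ = np.linalg.svd(M, full_matrices=False)
    u = u[:, s > sv_tol]
    return np.einsum("ij,ij->i", u, u)


def r2e(mol: Molecule, tables: ElementTables | None = None) -> float:
    """Lag-2 R autocorrelation weighted by Sanderson electronegativity.

    Sums ``sqrt(h_i h_j) / r_ij * e_i * e_j`` over unordered atom pairs at
    topological distance 2 on the hydrogen-included graph, with h the
    influence-matrix leverages, r the Euclidean distance in Å and e the
    carbon-scaled electronegativities.
    """
    tables = tables or default_tables()
    if not mol.has_coordinates:
        raise GeometryError(
            f"{mol.name or mol.smiles} lacks 3D coordinates; run "
            "molgraph.ensure_coordinates() for an embedding fallback"
        )
    for atom in mol.atoms:
        if atom.element not in tables.sanderson_en:
            raise TableLookupError(
                f"element {atom.element!r} missing from electronegativity table"
            )
    M = np.array([a.coords for a in mol.atoms], dtype=float)
    h = influence_diagonal(M)
    en = np.array([tables.sanderson_en[a.element] for a in mol.atoms])
    D = molgraph.topological_distance_matrix(mol, include_h=True)
    total = 0.0
    n = mol.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] == 2:
                r_ij = float(np.linalg.norm(M[i] - M[j]))
                total += math.sqrt(h[i] * h[j]) / r_ij * en[i] * en[j]
    return total


def compute_vector(mol: Molecule, tables: ElementTables | None = None,
                   embed_seed: int = 2023) -> DescriptorVector:
    """All four default descriptors for one molecule."""
    tables = tables or default_tables()
    provenance = {"tables_version": str(tables.version)}
    if not mol.has_coordinates:
        mol = molgraph.ensure_coordinates(mol, seed=embed_seed)
        provenance["geometry"] = f"etkdg+mmff(seed={embed_seed})"
    else:
        provenance["geometry"] = "input"
    return DescriptorVector(
        sic1=sic(mol, order=1),
        r2e=r2e(mol, tables),
        eeig03d=eeig(mol, rank=3, tables=tables),
        espm14u=espm(mol, k=14),
        provenance=provenance,
    )


def descriptor_table(mols: list[Molecule], which: tuple[str, ...] = DESCRIPTOR_COLUMNS,
                     tables: ElementTables | None = None,
                     embed_seed: int = 2023) -> pd.DataFrame:
    """Descriptor table (one row per compound, Table-2 column order).

    Per-compound failures are collected and reported together; a partial
    table is never returned.
    """
    unknown = set(which) - set(DESCRIPTOR_COLUMNS)
    if unknown:
        raise ValueError(f"unknown descriptors requested: {sorted(unknown)}")
    tables = tables or default_tables()
    rows, failures = [], []
    for mol in mols:
        key = mol.name or mol.smiles
        try:
            needs_geometry = "R2e" in which and not mol.has_coordinates
            m = molgraph.ensure_coordinates(mol, seed=embed_seed) if needs_geometry else mol
            row = {"compound": key}
            if "SIC1" in which:
                row["SIC1"] = sic(m, order=1)
            if "R2e" in which:
                row["R2e"] = r2e(m, tables)
            if "EEig03d" in which:
                row["EEig03d"] = eeig(m, rank=3, tables=tables)
            if "ESpm14u" in which:
                row["ESpm14u"] = espm(m, k=14)
            rows.append(row)
        except Exception as exc:  # collected, re-raised together
            failures.append(f"{key}: {exc}")
    if failures:
        raise DescriptorError(
            "descriptor computation failed for "
            f"{len(failures)} compound(s):\n  " + "\n  ".join(failures)
        )
    columns = ["compound"] + [c for c in DESCRIPTOR_COLUMNS if c in which]
    frame = pd.DataFrame(rows, columns=columns)
    return frame.set_index("compound")
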