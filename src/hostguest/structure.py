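"""Geometry analysis of optimized host-guest structures: hydrogen bonds.

Structures come in as XYZ or PDB files. Atoms are partitioned into molecules
by covalent connectivity (two atoms are bonded when their distance is below
1.2 x the sum of their covalent radii); chain/residue bookkeeping in PDB
files is ignored in favor of pure geometry, which is what matters for a
docked complex written out by a modeling package.

A hydrogen bond D–H···A is declared when
  * H is covalently bound to a donor heavy atom D (O or N by default),
  * the acceptor A (O or N) lies in a *different* molecule,
  * the H···A distance is within a configured range (default 0.8–2.8 Å), and
  * the D–H···A angle exceeds a configured minimum (default 120°).
The distance criterion applies to the H···acceptor separation; the lower
bound exists only to exclude covalent contacts. Bond classes follow the
acceptor's chemical environment: an O acceptor bonded to phosphorus is a
phosphonate oxygen — rendered "P=O···H–O" when it is that phosphorus'
shortest P–O contact (a bond-length heuristic for the formal double bond,
flagged as such) and "P–O···H–O" otherwise; an N acceptor gives "N···H–O";
anything else is a conventional hydroxyl-hydroxyl "O–H···O".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "COVALENT_RADII",
    "AtomRecord",
    "StructureModel",
    "HBond",
    "read_structure",
    "read_xyz",
    "read_pdb",
    "detect_hbonds",
    "hbond_table",
]

# Cordero consensus covalent radii (Å) for the supported elements.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "P": 1.07,
    "Na": 1.66,
}

BOND_SCALE = 1.2


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element, Cartesian coordinates (Å), 1-based molecule id."""

    element: str
    xyz: tuple[float, float, float]
    molecule: int = 0

    def __post_init__(self) -> None:
        if self.element not in COVALENT_RADII:
            raise ValueError(f"unknown element {self.element!r}")
        if not all(math.isfinite(c) for c in self.xyz):
            raise ValueError("non-finite coordinates")


@dataclass(frozen=True)
class StructureModel:
    """Atoms of one or more molecules, partitioned by covalent connectivity."""

    atoms: tuple[AtomRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("structure contains no atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def n_molecules(self) -> int:
        return max(a.molecule for a in self.atoms)


def _bond_pairs(elements: list[str], coords: np.ndarray) -> list[tuple[int, int]]:
    """Covalently bonded atom pairs under the scaled covalent-radius rule."""
    radii = np.array([COVALENT_RADII[e] for e in elements])
    cutoff = BOND_SCALE * 2.0 * radii.max()
    tree = cKDTree(coords)
    pairs = []
    for i, j in tree.query_pairs(cutoff):
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        if dist < BOND_SCALE * (radii[i] + radii[j]):
            pairs.append((i, j))
    return pairs


def _partition(elements: list[str], coords: np.ndarray) -> np.ndarray:
    """1-based molecule ids, contiguous, ordered by first atom occurrence."""
    n = len(elements)
    pairs = _bond_pairs(elements, coords)
    if pairs:
        rows = [p[0] for p in pairs]
        cols = [p[1] for p in pairs]
        graph = coo_matrix((np.ones(len(pairs)), (rows, cols)), shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    _, labels = connected_components(graph, directed=False)
    order: dict[int, int] = {}
    ids = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order) + 1
        ids[i] = order[lab]
    return ids


def _build(elements: list[str], coords: np.ndarray, provenance: str) -> StructureModel:
    ids = _partition(elements, coords)
    atoms = tuple(
        AtomRecord(e, tuple(map(float, c)), int(m))
        for e, c, m in zip(elements, coords, ids)
    )
    return StructureModel(atoms, provenance)


def read_xyz(path: str | Path) -> StructureModel:
    """Read a standard XYZ file (count line, comment line, element x y z)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: malformed atom-count line {lines[0]!r}")
    if n <= 0:
        raise ValueError(f"{path}: zero atoms")
    if len(lines) < n + 2:
        raise ValueError(f"{path}: expected {n} atom records, file truncated")
    elements: list[str] = []
    coords: list[list[float]] = []
    for ln in lines[2 : 2 + n]:
        fields = ln.split()
        if len(fields) < 4:
            raise ValueError(f"{path}: malformed atom record {ln!r}")
        elements.append(fields[0].capitalize())
        coords.append([float(v) for v in fields[1:4]])
    return _build(elements, np.array(coords), str(path))


def read_pdb(path: str | Path) -> StructureModel:
    """Read ATOM/HETATM records from the first model of a PDB file.

    Occupancy and altloc are ignored; molecule partitioning is geometric, so
    chain identifiers play no role.
    """
    import warnings

    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        model = PDBParser(QUIET=True).get_structure("s", str(path))[0]
    elements: list[str] = []
    coords: list[np.ndarray] = []
    for atom in model.get_atoms():
        elem = (atom.element or atom.get_name()[:1]).strip().capitalize()
        elements.append(elem)
        coords.append(atom.coord.astype(float))
    if not elements:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return _build(elements, np.array(coords), str(path))


def read_structure(path: str | Path) -> StructureModel:
    """Dispatch on extension: ``.xyz`` or ``.pdb``/``.ent``."""
    suffix = Path(path).suffix.lower()
    if suffix == ".xyz":
        return read_xyz(path)
    if suffix in (".pdb", ".ent"):
        return read_pdb(path)
    raise ValueError(f"unsupported structure format {suffix!r}")


@dataclass(frozen=True)
class HBond:
    """A detected intermolecular hydrogen bond D–H···A."""

    donor: int
    hydrogen: int
    acceptor: int
    length: float
    angle: float
    klass: str


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _classify(
    acceptor: int,
    donor_elem: str,
    elements: list[str],
    coords: np.ndarray,
    neighbors: dict[int, list[int]],
) -> str:
    a_elem = elements[acceptor]
    if a_elem == "N":
        return f"N···H–{donor_elem}"
    p_neighbors = [j for j in neighbors.get(acceptor, []) if elements[j] == "P"]
    if a_elem == "O" and p_neighbors:
        p = p_neighbors[0]
        o_dists = {
            j: float(np.linalg.norm(coords[p] - coords[j]))
            for j in neighbors.get(p, [])
            if elements[j] == "O"
        }
        shortest = min(o_dists, key=o_dists.get)
        bond_order = "=" if shortest == acceptor else "–"
        return f"P{bond_order}O···H–{donor_elem}"
    return "O–H···O"


def detect_hbonds(
    s: StructureModel,
    d_range: tuple[float, float] = (0.8, 2.8),
    angle_min: float = 120.0,
    donors: frozenset[str] | set[str] = frozenset({"O", "N"}),
    acceptors: frozenset[str] | set[str] = frozenset({"O", "N"}),
) -> list[HBond]:
    """All intermolecular D–H···A contacts satisfying the geometric criterion.

    Returns bonds sorted by (donor, hydrogen, acceptor) indices; empty list
    when nothing qualifies.
    """
    d_min, d_max = d_range
    coords = s.coords
    elements = s.elements
    mol = np.array([a.molecule for a in s.atoms])
    neighbors: dict[int, list[int]] = {i: [] for i in range(len(elements))}
    for i, j in _bond_pairs(elements, coords):
        neighbors[i].append(j)
        neighbors[j].append(i)

    tree = cKDTree(coords)
    bonds: list[HBond] = []
    for h, elem in enumerate(elements):
        if elem != "H":
            continue
        donors_of_h = [j for j in neighbors[h] if elements[j] in donors]
        if not donors_of_h:
            continue
        for a in tree.query_ball_point(coords[h], d_max):
            if a == h or elements[a] not in acceptors:
                continue
            if mol[a] == mol[h]:
                continue
            dist = float(np.linalg.norm(coords[h] - coords[a]))
            if not (d_min <= dist <= d_max):
                continue
            for d in donors_of_h:
                ang = _angle_deg(coords[d], coords[h], coords[a])
                if ang > angle_min:
                    klass = _classify(a, elements[d], elements, coords, neighbors)
                    bonds.append(HBond(d, h, a, dist, ang, klass))
    bonds.sort(key=lambda b: (b.donor, b.hydrogen, b.acceptor))
    return bonds


def hbond_table(s: StructureModel, bonds: list[HBond]):
    """Hydrogen-bond report as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = [
        {
            "donor": f"{s.atoms[b.donor].element}{b.donor}",
            "hydrogen": f"H{b.hydrogen}",
            "acceptor": f"{s.atoms[b.acceptor].element}{b.acceptor}",
            "length_A": round(b.length, 4),
            "angle_deg": round(b.angle, 2),
            "class": b.klass,
        }
        for b in bonds
    ]
    return pd.DataFrame(
        rows, columns=["donor", "hydrogen", "acceptor", "length_A", "angle_deg", "class"]
    )
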