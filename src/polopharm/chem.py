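"""Lightweight molecular graph used for chemical feature typing.

Ligands arrive either as parsed small-molecule records (with bond orders) or
as bare HETATM coordinate sets from crystal structures (no hydrogens, no bond
orders).  ``MolGraph`` normalises both into one heavy-atom graph carrying, per
atom: element, formal charge, explicit hydrogen count and bond orders, from
which implied hydrogens are filled in by default valence.  All downstream
feature rules (donor/acceptor/hydrophobic/ionizable) work on this graph so
they behave identically on both input classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["MolGraph", "COVALENT_RADII", "perceive_bonds_by_distance"]

# single-bond covalent radii (Å), Cordero et al. consensus values
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "SI": 1.11, "P": 1.07, "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "SE": 1.20,
}

_DEFAULT_VALENCE: dict[str, int] = {
    "C": 4, "N": 3, "O": 2, "S": 2, "P": 5, "F": 1, "CL": 1, "BR": 1, "I": 1,
    "B": 3, "SI": 4, "SE": 2,
}

_HALOGENS = {"F", "CL", "BR", "I"}
_POLAR = {"N", "O", "S", "P"}


def perceive_bonds_by_distance(
    elements: list[str],
    coords: np.ndarray,
    tolerance: float = 0.45,
) -> list[tuple[int, int, float]]:
    """Distance-based bond perception: bond iff d <= r_i + r_j + tolerance.

    All perceived bonds get order 1 (crystal-structure HETATM blocks carry no
    reliable order information).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(elements)
    bonds: list[tuple[int, int, float]] = []
    radii = [COVALENT_RADII.get(e.upper(), 0.77) for e in elements]
    for i in range(n):
        for j in range(i + 1, n):
            cutoff = radii[i] + radii[j] + tolerance
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if 0.4 < d <= cutoff:
                bonds.append((i, j, 1.0))
    return bonds


@dataclass
class MolGraph:
    """Heavy-atom molecular graph with hydrogen bookkeeping.

    ``elements`` are upper-cased symbols; ``bonds`` are (i, j, order) over the
    heavy atoms; ``explicit_h[i]`` counts hydrogens given explicitly in the
    source; implied hydrogens are derived from default valence minus the bond
    order sum, never negative.
    """

    elements: list[str]
    bonds: list[tuple[int, int, float]]
    formal_charges: list[int] = field(default_factory=list)
    explicit_h: list[int] = field(default_factory=list)
    orders_known: bool = True

    def __post_init__(self) -> None:
        n = len(self.elements)
        self.elements = [e.upper() for e in self.elements]
        if not self.formal_charges:
            self.formal_charges = [0] * n
        if not self.explicit_h:
            self.explicit_h = [0] * n
        self._graph = nx.Graph()
        self._graph.add_nodes_from(range(n))
        self._order_sum = [0.0] * n
        for i, j, order in self.bonds:
            self._graph.add_edge(i, j, order=order)
            self._order_sum[i] += order
            self._order_sum[j] += order
        self._rings = nx.cycle_basis(self._graph)
        self._ring_atoms = set().union(*self._rings) if self._rings else set()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol) -> "MolGraph":
        from rdkit import Chem

        if any(a.GetAtomicNum() == 1 for a in mol.GetAtoms()):
            try:
                mol = Chem.RemoveHs(mol)
            except Exception:
                mol = Chem.RemoveHs(mol, sanitize=False)
        elements = []
        charges = []
        h_counts = []
        for atom in mol.GetAtoms():
            elements.append(atom.GetSymbol())
            charges.append(atom.GetFormalCharge())
            h_counts.append(atom.GetTotalNumHs(includeNeighbors=True))
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in mol.GetBonds()
        ]
        g = cls(elements, bonds, charges, h_counts)
        # RDKit already resolved hydrogen counts; trust them verbatim
        g._total_h = list(h_counts)
        return g

    @classmethod
    def from_atoms(
        cls,
        elements: list[str],
        coords: np.ndarray,
        bonds: list[tuple[int, int, float]] | None = None,
        formal_charges: list[int] | None = None,
    ) -> "MolGraph":
        """Build from bare atoms; hydrogens in ``elements`` are folded into
        explicit H counts of their nearest heavy partner."""
        coords = np.asarray(coords, dtype=float)
        heavy = [i for i, e in enumerate(elements) if e.upper() != "H"]
        remap = {old: new for new, old in enumerate(heavy)}
        orders_known = bonds is not None
        if bonds is None:
            bonds = perceive_bonds_by_distance(list(elements), coords)
        h_counts = [0] * len(heavy)
        heavy_bonds = []
        for i, j, order in bonds:
            ei, ej = elements[i].upper(), elements[j].upper()
            if ei == "H" and ej != "H":
                h_counts[remap[j]] += 1
            elif ej == "H" and ei != "H":
                h_counts[remap[i]] += 1
            elif ei != "H" and ej != "H":
                heavy_bonds.append((remap[i], remap[j], order))
        charges = None
        if formal_charges is not None:
            charges = [formal_charges[i] for i in heavy]
        g = cls(
            [elements[i] for i in heavy],
            heavy_bonds,
            charges or [],
            h_counts,
            orders_known=orders_known,
        )
        g.heavy_indices = heavy
        return g

    # -- per-atom queries ----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def heavy_degree(self, i: int) -> int:
        return self._graph.degree[i]

    def neighbors(self, i: int) -> list[int]:
        return sorted(self._graph.neighbors(i))

    def total_h(self, i: int) -> int:
        """Explicit plus valence-implied hydrogen count."""
        if hasattr(self, "_total_h"):
            return self._total_h[i]
        val = _DEFAULT_VALENCE.get(self.elements[i], 4) + self.formal_charges[i]
        implied = max(0, int(round(val - self._order_sum[i])) - self.explicit_h[i])
        return self.explicit_h[i] + implied

    def in_ring(self, i: int) -> bool:
        return i in self._ring_atoms

    def rings(self) -> list[list[int]]:
        return [sorted(r) for r in self._rings]

    def is_terminal_oxygen(self, i: int) -> bool:
        return self.elements[i] == "O" and self.heavy_degree(i) == 1

    def is_amide_nitrogen(self, i: int) -> bool:
        """N bonded to a carbon that carries a C=O (requires known bond orders)."""
        if self.elements[i] != "N" or not self.orders_known:
            return False
        for c in self.neighbors(i):
            if self.elements[c] != "C":
                continue
            for o in self.neighbors(c):
                if (
                    self.elements[o] == "O"
                    and self._graph.edges[c, o]["order"] >= 2
                ):
                    return True
        return False

    def is_quaternary_nitrogen(self, i: int) -> bool:
        if self.elements[i] != "N":
            return False
        connections = self.heavy_degree(i) + self.total_h(i)
        return connections >= 4 or self.formal_charges[i] > 0 or self._order_sum[i] >= 4

    def has_polar_neighbor(self, i: int) -> bool:
        return any(self.elements[j] in _POLAR for j in self.neighbors(i))

    def is_halogen(self, i: int) -> bool:
        return self.elements[i] in _HALOGENS
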