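"""Receptor–ligand interaction perception and structure-based pharmacophores.

From a prepared complex this module detects, on heavy atoms (crystal
structures mostly lack hydrogens):

* hydrogen bonds — ligand donor/acceptor vs receptor acceptor/donor, heavy
  donor–acceptor distance within a window (default 2.5–3.5 Å), with a
  D–H···A angle test that activates only when an explicit hydrogen exists;
* hydrophobic contacts — ligand apolar group centroid within 5.0 Å of a
  hydrophobic side-chain atom;
* ionic contacts — ligand ionizable group centroid within 5.6 Å of a
  complementary charged receptor center.

Each contact then becomes one pharmacophore feature at the ligand-side
centroid (H-bond features keep a direction toward the receptor partner), and
receptor atoms lining the site become excluded-volume spheres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .chem import MolGraph
from .pharmacophore import FeatureKind, Pharmacophore, PharmacophoreFeature
from .structures import ComplexStructure

__all__ = [
    "ContactKind",
    "InteractionContact",
    "PerceptionConfig",
    "perceive_ligand_feature_atoms",
    "detect_hbonds",
    "detect_hydrophobic_contacts",
    "detect_ionic_contacts",
    "detect_all_contacts",
    "build_structure_pharmacophore",
    "contact_table",
]


class ContactKind(str, Enum):
    HBOND_LIG_DONOR = "HBOND_LIG_DONOR"
    HBOND_LIG_ACCEPTOR = "HBOND_LIG_ACCEPTOR"
    HYDROPHOBIC = "HYDROPHOBIC"
    POS_IONIZABLE = "POS_IONIZABLE"
    NEG_IONIZABLE = "NEG_IONIZABLE"


@dataclass(frozen=True)
class InteractionContact:
    """One perceived receptor–ligand interaction."""

    kind: ContactKind
    ligand_atoms: tuple[int, ...]  # indices into complex.ligand_atoms
    receptor_atom: tuple[str, int, str, str]  # chain, resnum, resname, atom
    distance: float
    ligand_centroid: np.ndarray = field(compare=False, default=None)
    receptor_point: np.ndarray = field(compare=False, default=None)

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be > 0")

    @property
    def residue(self) -> tuple[str, int, str]:
        return self.receptor_atom[:3]


@dataclass
class PerceptionConfig:
    """Geometric cutoffs (Å / degrees) for interaction perception.

    The defaults are standard structure-based perception windows; every value
    is exposed because different software draws these lines differently.
    """

    hbond_min: float = 2.5
    hbond_max: float = 3.5
    hbond_angle_min_deg: float = 120.0
    hydrophobic_max: float = 5.0
    ionic_max: float = 5.6
    merge_radius: float = 0.5
    excluded_volume_radius: float = 1.3
    excluded_volume_shell: float = 5.0
    tolerances: dict = field(
        default_factory=lambda: {kind: 1.5 for kind in FeatureKind}
    )

    def tolerance(self, kind: FeatureKind) -> float:
        return self.tolerances.get(kind, 1.5)


# --------------------------------------------------------------------------
# ligand-side feature typing


def perceive_ligand_feature_atoms(graph: MolGraph) -> dict[FeatureKind, list[list[int]]]:
    """Assign chemical feature groups on a ligand graph (heavy-atom indices).

    HBD: N/O bearing ≥1 hydrogen (explicit or implied by valence).
    HBA: N/O with an available lone pair; quaternary and amide N excluded.
    HYDROPHOBIC: maximal connected sets of carbons/halogens with no attached
    polar atom, of size ≥3.
    POS_ION: amines (1°/2°/3°), amidine and guanidine groups.
    NEG_ION: carboxylate, phosphate/phosphonate, sulfate/sulfonate, tetrazole.
    """
    out: dict[FeatureKind, list[list[int]]] = {kind: [] for kind in FeatureKind}

    # donors / acceptors
    for i in range(graph.n_atoms):
        el = graph.elements[i]
        if el not in ("N", "O"):
            continue
        if graph.total_h(i) >= 1 and graph.formal_charges[i] >= 0:
            out[FeatureKind.HBD].append([i])
        if el == "O":
            if graph.formal_charges[i] <= 0:
                out[FeatureKind.HBA].append([i])
        else:  # N
            if not graph.is_quaternary_nitrogen(i) and not graph.is_amide_nitrogen(i):
                out[FeatureKind.HBA].append([i])

    # hydrophobic groups: apolar C/halogen connected components
    apolar = {
        i
        for i in range(graph.n_atoms)
        if (graph.elements[i] == "C" or graph.is_halogen(i))
        and not graph.has_polar_neighbor(i)
        and graph.formal_charges[i] == 0
    }
    seen: set[int] = set()
    for i in sorted(apolar):
        if i in seen:
            continue
        component = {i}
        stack = [i]
        while stack:
            a = stack.pop()
            for b in graph.neighbors(a):
                if b in apolar and b not in component:
                    component.add(b)
                    stack.append(b)
        seen |= component
        if len(component) >= 3:
            out[FeatureKind.HYDROPHOBIC].append(sorted(component))

    # negative ionizable groups
    neg_atoms: set[int] = set()
    for i in range(graph.n_atoms):
        el = graph.elements[i]
        if el == "C":
            terminal_o = [j for j in graph.neighbors(i) if graph.is_terminal_oxygen(j)]
            if len(terminal_o) == 2 and graph.heavy_degree(i) <= 3:
                group = sorted([i] + terminal_o)
                out[FeatureKind.NEG_ION].append(group)
                neg_atoms |= set(group)
        elif el == "P":
            oxygens = [j for j in graph.neighbors(i) if graph.elements[j] == "O"]
            terminal_o = [j for j in oxygens if graph.is_terminal_oxygen(j)]
            if len(terminal_o) >= 2:
                group = sorted([i] + oxygens)
                out[FeatureKind.NEG_ION].append(group)
                neg_atoms |= set(group)
        elif el == "S":
            oxygens = [j for j in graph.neighbors(i) if graph.elements[j] == "O"]
            terminal_o = [j for j in oxygens if graph.is_terminal_oxygen(j)]
            if len(oxygens) >= 3 and len(terminal_o) >= 2:
                group = sorted([i] + oxygens)
                out[FeatureKind.NEG_ION].append(group)
                neg_atoms |= set(group)
    for ring in graph.rings():
        if len(ring) == 5:
            n_count = sum(1 for i in ring if graph.elements[i] == "N")
            if n_count == 4:
                out[FeatureKind.NEG_ION].append(sorted(ring))
                neg_atoms |= set(ring)

    # positive ionizable groups: guanidine / amidine first, then plain amines
    pos_nitrogens: set[int] = set()
    for i in range(graph.n_atoms):
        if graph.elements[i] != "C":
            continue
        n_neighbors = [
            j
            for j in graph.neighbors(i)
            if graph.elements[j] == "N"
            and not graph.is_amide_nitrogen(j)
            and all(graph.elements[k] in ("C",) for k in graph.neighbors(j))
        ]
        if len(n_neighbors) >= 2 and not any(
            graph.elements[j] == "O" for j in graph.neighbors(i)
        ):
            group = sorted([i] + n_neighbors)
            out[FeatureKind.POS_ION].append(group)
            pos_nitrogens |= set(n_neighbors)
    for i in range(graph.n_atoms):
        if graph.elements[i] != "N" or i in pos_nitrogens:
            continue
        if graph.is_amide_nitrogen(i) or graph._order_sum[i] > graph.heavy_degree(i):
            continue  # unsaturated / amide N is not a chargeable amine
        neighbors = graph.neighbors(i)
        if neighbors and all(graph.elements[j] == "C" for j in neighbors):
            if graph.heavy_degree(i) + graph.total_h(i) == 4 or graph.total_h(i) >= 1:
                if not graph.in_ring(i) or graph.total_h(i) >= 1:
                    out[FeatureKind.POS_ION].append([i])

    for kind in out:
        out[kind].sort()
    return out


# --------------------------------------------------------------------------
# receptor-side typing tables (by residue / atom name, author conventions)

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

_SIDECHAIN_DONORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
    "TRP": {"NE1"}, "HIS": {"ND1"},  # default His protonation: ND1 donor
}

_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "HIS": {"NE2"},  # default His protonation: NE2 acceptor
}

_HYDROPHOBIC_RESIDUES = {
    "ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR",
}

_HIS_RING = ["CG", "ND1", "CD2", "CE1", "NE2"]


def _receptor_donors(complex_: ComplexStructure):
    for a in complex_.receptor_atoms:
        if a.element == "H":
            continue
        if a.name == "N" and a.residue_name != "PRO":
            yield a
        elif a.name in _SIDECHAIN_DONORS.get(a.residue_name, ()):
            yield a


def _receptor_acceptors(complex_: ComplexStructure):
    for a in complex_.receptor_atoms:
        if a.element == "H":
            continue
        if a.name in ("O", "OXT"):
            yield a
        elif a.name in _SIDECHAIN_ACCEPTORS.get(a.residue_name, ()):
            yield a


# --------------------------------------------------------------------------
# contact detection


def _ligand_heavy_map(complex_: ComplexStructure) -> tuple[MolGraph, list[int]]:
    graph = complex_.ligand_graph()
    heavy = getattr(graph, "heavy_indices", list(range(graph.n_atoms)))
    return graph, heavy


def _explicit_hydrogens(complex_: ComplexStructure, donor_idx: int) -> list[np.ndarray]:
    """Positions of explicit H atoms covalently close (≤1.3 Å) to a donor."""
    donor = complex_.ligand_atoms[donor_idx]
    out = []
    for a in complex_.ligand_atoms:
        if a.element == "H" and np.linalg.norm(a.coords - donor.coords) <= 1.3:
            out.append(a.coords)
    return out


def _dha_angle_ok(
    donor: np.ndarray, hydrogens: list[np.ndarray], acceptor: np.ndarray, min_deg: float
) -> bool:
    if not hydrogens:
        return True  # heavy-atom-only criterion
    for h in hydrogens:
        v1 = donor - h
        v2 = acceptor - h
        cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
        angle = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
        if angle >= min_deg:
            return True
    return False


def detect_hbonds(
    complex_: ComplexStructure, config: PerceptionConfig | None = None
) -> list[InteractionContact]:
    """Ligand–receptor hydrogen bonds by the heavy-atom distance window.

    A donor/acceptor pair bonds iff its heavy-atom distance lies in
    [hbond_min, hbond_max]; when the donor carries an explicit hydrogen the
    D–H···A angle must additionally reach ``hbond_angle_min_deg``.
    """
    config = config or PerceptionConfig()
    graph, heavy = _ligand_heavy_map(complex_)
    features = perceive_ligand_feature_atoms(graph)
    lig_donors = [heavy[g[0]] for g in features[FeatureKind.HBD]]
    lig_acceptors = [heavy[g[0]] for g in features[FeatureKind.HBA]]

    contacts: list[InteractionContact] = []
    for d_idx in lig_donors:
        d_atom = complex_.ligand_atoms[d_idx]
        hydrogens = _explicit_hydrogens(complex_, d_idx)
        for r in _receptor_acceptors(complex_):
            dist = float(np.linalg.norm(d_atom.coords - r.coords))
            if not (config.hbond_min <= dist <= config.hbond_max):
                continue
            if not _dha_angle_ok(
                d_atom.coords, hydrogens, r.coords, config.hbond_angle_min_deg
            ):
                continue
            contacts.append(
                InteractionContact(
                    ContactKind.HBOND_LIG_DONOR,
                    (d_idx,),
                    (r.chain_id, r.residue_number, r.residue_name, r.name),
                    dist,
                    ligand_centroid=d_atom.coords.copy(),
                    receptor_point=r.coords.copy(),
                )
            )
    for a_idx in lig_acceptors:
        a_atom = complex_.ligand_atoms[a_idx]
        for r in _receptor_donors(complex_):
            dist = float(np.linalg.norm(a_atom.coords - r.coords))
            if not (config.hbond_min <= dist <= config.hbond_max):
                continue
            contacts.append(
                InteractionContact(
                    ContactKind.HBOND_LIG_ACCEPTOR,
                    (a_idx,),
                    (r.chain_id, r.residue_number, r.residue_name, r.name),
                    dist,
                    ligand_centroid=a_atom.coords.copy(),
                    receptor_point=r.coords.copy(),
                )
            )
    contacts.sort(key=lambda c: (c.kind.value, c.ligand_atoms, c.receptor_atom))
    return contacts


def detect_hydrophobic_contacts(
    complex_: ComplexStructure, config: PerceptionConfig | None = None
) -> list[InteractionContact]:
    """Apolar ligand group centroid ≤ cutoff from a hydrophobic side-chain
    C/S atom of Ala/Val/Leu/Ile/Met/Phe/Trp/Pro/Tyr; one contact per
    (group, residue), anchored at the nearest such atom."""
    config = config or PerceptionConfig()
    graph, heavy = _ligand_heavy_map(complex_)
    groups = perceive_ligand_feature_atoms(graph)[FeatureKind.HYDROPHOBIC]

    receptor_atoms = [
        a
        for a in complex_.receptor_atoms
        if a.residue_name in _HYDROPHOBIC_RESIDUES
        and a.element in ("C", "S")
        and a.name not in _BACKBONE
    ]
    contacts: list[InteractionContact] = []
    for group in groups:
        orig = [heavy[i] for i in group]
        centroid = np.mean([complex_.ligand_atoms[i].coords for i in orig], axis=0)
        best: dict[tuple, tuple[float, object]] = {}
        for r in receptor_atoms:
            dist = float(np.linalg.norm(centroid - r.coords))
            if dist > config.hydrophobic_max:
                continue
            key = r.residue_key
            if key not in best or dist < best[key][0]:
                best[key] = (dist, r)
        for dist, r in best.values():
            contacts.append(
                InteractionContact(
                    ContactKind.HYDROPHOBIC,
                    tuple(orig),
                    (r.chain_id, r.residue_number, r.residue_name, r.name),
                    dist,
                    ligand_centroid=centroid,
                    receptor_point=r.coords.copy(),
                )
            )
    contacts.sort(key=lambda c: (c.ligand_atoms, c.receptor_atom))
    return contacts


def _receptor_charge_centers(complex_: ComplexStructure):
    """Yield (sign, chain, resnum, resname, label, point) charged centers."""
    by_residue: dict[tuple, dict[str, np.ndarray]] = {}
    meta: dict[tuple, tuple[str, int, str]] = {}
    for a in complex_.receptor_atoms:
        key = a.residue_key
        by_residue.setdefault(key, {})[a.name] = a.coords
        meta[key] = (a.chain_id, a.residue_number, a.residue_name)
    for key, atoms in by_residue.items():
        chain, resnum, resname = meta[key]
        if resname == "LYS" and "NZ" in atoms:
            yield ("+", chain, resnum, resname, "NZ", atoms["NZ"])
        elif resname == "ARG" and "CZ" in atoms:
            yield ("+", chain, resnum, resname, "CZ", atoms["CZ"])
        elif resname == "HIS":
            ring = [atoms[n] for n in _HIS_RING if n in atoms]
            if len(ring) >= 3:
                yield ("+", chain, resnum, resname, "ring", np.mean(ring, axis=0))
        elif resname == "ASP" and "OD1" in atoms and "OD2" in atoms:
            point = (atoms["OD1"] + atoms["OD2"]) / 2
            yield ("-", chain, resnum, resname, "carboxylate", point)
        elif resname == "GLU" and "OE1" in atoms and "OE2" in atoms:
            point = (atoms["OE1"] + atoms["OE2"]) / 2
            yield ("-", chain, resnum, resname, "carboxylate", point)


def detect_ionic_contacts(
    complex_: ComplexStructure, config: PerceptionConfig | None = None
) -> list[InteractionContact]:
    """Ionizable ligand group centroid ≤ cutoff from a complementary charged
    receptor center (Lys NZ / Arg CZ / His ring vs. Asp/Glu carboxylate)."""
    config = config or PerceptionConfig()
    graph, heavy = _ligand_heavy_map(complex_)
    features = perceive_ligand_feature_atoms(graph)
    centers = list(_receptor_charge_centers(complex_))

    contacts: list[InteractionContact] = []
    for lig_kind, contact_kind, wanted_sign in (
        (FeatureKind.NEG_ION, ContactKind.NEG_IONIZABLE, "+"),
        (FeatureKind.POS_ION, ContactKind.POS_IONIZABLE, "-"),
    ):
        for group in features[lig_kind]:
            orig = [heavy[i] for i in group]
            centroid = np.mean([complex_.ligand_atoms[i].coords for i in orig], axis=0)
            for sign, chain, resnum, resname, label, point in centers:
                if sign != wanted_sign:
                    continue
                dist = float(np.linalg.norm(centroid - point))
                if dist > config.ionic_max:
                    continue
                contacts.append(
                    InteractionContact(
                        contact_kind,
                        tuple(orig),
                        (chain, resnum, resname, label),
                        dist,
                        ligand_centroid=centroid,
                        receptor_point=np.asarray(point, dtype=float),
                    )
                )
    contacts.sort(key=lambda c: (c.kind.value, c.ligand_atoms, c.receptor_atom))
    return contacts


def detect_all_contacts(
    complex_: ComplexStructure, config: PerceptionConfig | None = None
) -> list[InteractionContact]:
    config = config or PerceptionConfig()
    return (
        detect_hbonds(complex_, config)
        + detect_hydrophobic_contacts(complex_, config)
        + detect_ionic_contacts(complex_, config)
    )


# --------------------------------------------------------------------------
# pharmacophore construction

_CONTACT_TO_FEATURE = {
    ContactKind.HBOND_LIG_DONOR: FeatureKind.HBD,
    ContactKind.HBOND_LIG_ACCEPTOR: FeatureKind.HBA,
    ContactKind.HYDROPHOBIC: FeatureKind.HYDROPHOBIC,
    ContactKind.POS_IONIZABLE: FeatureKind.POS_ION,
    ContactKind.NEG_IONIZABLE: FeatureKind.NEG_ION,
}


def build_structure_pharmacophore(
    complex_: ComplexStructure,
    config: PerceptionConfig | None = None,
    contacts: list[InteractionContact] | None = None,
) -> Pharmacophore:
    """One pharmacophore feature per contact (duplicates merged), plus
    excluded-volume spheres on receptor atoms lining the binding site.

    Two contacts of the same feature kind whose ligand centroids coincide
    within ``merge_radius`` collapse into one feature that keeps every
    interaction direction.
    """
    config = config or PerceptionConfig()
    if contacts is None:
        contacts = detect_all_contacts(complex_, config)

    buckets: list[dict] = []
    for c in contacts:
        kind = _CONTACT_TO_FEATURE[c.kind]
        direction = None
        if c.kind in (ContactKind.HBOND_LIG_DONOR, ContactKind.HBOND_LIG_ACCEPTOR):
            v = c.receptor_point - c.ligand_centroid
            direction = v / np.linalg.norm(v)
        merged = False
        for b in buckets:
            if b["kind"] is kind and (
                np.linalg.norm(b["centroid"] - c.ligand_centroid) <= config.merge_radius
            ):
                if direction is not None:
                    b["directions"].append(direction)
                merged = True
                break
        if not merged:
            buckets.append(
                {
                    "kind": kind,
                    "centroid": c.ligand_centroid.copy(),
                    "directions": [direction] if direction is not None else [],
                }
            )

    features = [
        PharmacophoreFeature(
            kind=b["kind"],
            centroid=b["centroid"],
            tolerance=config.tolerance(b["kind"]),
            directions=tuple(b["directions"]),
        )
        for b in buckets
    ]
    features.sort(key=PharmacophoreFeature.sort_key)
    if not features:
        warnings.warn(f"{complex_.pdb_id}: no contacts found; empty pharmacophore")

    lig_xyz = complex_.ligand_coords
    volumes = []
    for a in complex_.receptor_atoms:
        if a.element == "H":
            continue
        if np.min(np.linalg.norm(lig_xyz - a.coords, axis=1)) <= config.excluded_volume_shell:
            volumes.append((a.coords.copy(), config.excluded_volume_radius))

    model = Pharmacophore(
        name=f"{complex_.pdb_id}_sbp",
        features=features,
        excluded_volumes=volumes,
        provenance=[complex_.pdb_id],
    )
    return model.with_default_constraints()


def contact_table(
    complexes: list[ComplexStructure], config: PerceptionConfig | None = None
) -> pd.DataFrame:
    """Long-form contact report: one row per contact (pdb_id, kind, residue,
    atom, distance) — the machine-readable form of a key-residue table."""
    rows = []
    for c in complexes:
        for contact in detect_all_contacts(c, config):
            chain, resnum, resname, atom = contact.receptor_atom
            rows.append(
                {
                    "pdb_id": c.pdb_id,
                    "kind": contact.kind.value,
                    "chain": chain,
                    "residue_number": resnum,
                    "residue_name": resname,
                    "receptor_atom": atom,
                    "distance": round(contact.distance, 3),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "pdb_id", "kind", "chain", "residue_number", "residue_name",
            "receptor_atom", "distance",
        ],
    )
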