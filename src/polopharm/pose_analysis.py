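"""Post-docking pose evaluation.

Docked poses (with their score tags) are consumed from files — pose
generation and scoring belong to the docking program.  This module answers
three questions about them: does the docking setup reproduce the co-crystal
binding mode (redocking RMSD, < 2 Å being the conventional success bar)?
does a pose hydrogen-bond the key binding-site residues (for the polo-box
domain: Trp414, Asp416, His538, Lys540, Leu491)?  and does it survive the
combined key-residue + dock-score gate?
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .perception import PerceptionConfig, detect_hbonds
from .structures import AtomRecord, ComplexStructure, SmallMolecule

__all__ = [
    "PoseRecord",
    "DEFAULT_KEY_RESIDUES",
    "redock_rmsd",
    "key_residue_contacts",
    "filter_poses",
    "conserved_residue_table",
]

# author-numbered key residues of the Plk1 polo-box phosphopeptide cleft
DEFAULT_KEY_RESIDUES: tuple[int, ...] = (414, 416, 538, 540, 491)
OPTIONAL_KEY_RESIDUES: tuple[int, ...] = (489, 516)


@dataclass(eq=False)
class PoseRecord:
    """One docked pose of one molecule, with its parsed score tag."""

    molecule: SmallMolecule
    pose_index: int = 0
    conformer: int = 0
    dock_score: float | None = None
    hbond_residues: set = field(default_factory=set)

    @property
    def molecule_id(self) -> str:
        return self.molecule.id

    @property
    def coordinates(self) -> np.ndarray:
        return self.molecule.conformers[self.conformer]


def _element_graph(mol: SmallMolecule) -> nx.Graph:
    g = nx.Graph()
    for i, e in enumerate(mol.elements):
        g.add_node(i, element=e.upper())
    for i, j, _ in mol.bonds:
        g.add_edge(i, j)
    return g


def redock_rmsd(
    reference: SmallMolecule,
    pose: SmallMolecule,
    reference_conformer: int = 0,
    pose_conformer: int = 0,
    symmetry_aware: bool = False,
    max_permutations: int = 100_000,
) -> float:
    """In-place heavy-atom RMSD between a pose and the co-crystal ligand (Å).

    No realignment — both are assumed to sit in the receptor frame already.
    Atoms are matched by canonical order; ``symmetry_aware`` minimizes over
    graph automorphisms so topologically equivalent atoms (e.g. a flipped
    aromatic ring) do not inflate the deviation.
    """
    ref_heavy = reference.heavy_indices()
    pose_heavy = pose.heavy_indices()
    if len(ref_heavy) != len(pose_heavy) or [
        reference.elements[i].upper() for i in ref_heavy
    ] != [pose.elements[i].upper() for i in pose_heavy]:
        raise ValueError(
            f"atom sets differ: reference {[reference.elements[i] for i in ref_heavy]} "
            f"vs pose {[pose.elements[i] for i in pose_heavy]}"
        )
    a = reference.conformers[reference_conformer][ref_heavy]
    b = pose.conformers[pose_conformer][pose_heavy]

    def rms(perm: list[int]) -> float:
        return float(np.sqrt(np.mean(np.sum((a - b[perm]) ** 2, axis=1))))

    identity = list(range(len(ref_heavy)))
    best = rms(identity)
    if not symmetry_aware:
        return best

    g_ref = _element_graph(reference).subgraph(ref_heavy)
    g_pose = _element_graph(pose).subgraph(pose_heavy)
    ref_order = {n: k for k, n in enumerate(ref_heavy)}
    pose_order = {n: k for k, n in enumerate(pose_heavy)}
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g_ref, g_pose,
        node_match=lambda x, y: x["element"] == y["element"],
    )
    for count, mapping in enumerate(matcher.isomorphisms_iter()):
        if count >= max_permutations:
            break
        perm = [0] * len(ref_heavy)
        for rn, pn in mapping.items():
            perm[ref_order[rn]] = pose_order[pn]
        best = min(best, rms(perm))
    return best


def _as_pose_complex(receptor: ComplexStructure, pose: PoseRecord) -> ComplexStructure:
    """Receptor plus pose ligand, packaged for contact perception."""
    coords = pose.coordinates
    atoms = [
        AtomRecord(
            serial=i + 1, name=f"{e.upper()}{i + 1}", element=e,
            residue_name="LIG", chain_id="X", residue_number=1,
            coords=coords[i], is_hetero=True,
            formal_charge=pose.molecule.formal_charges[i],
        )
        for i, e in enumerate(pose.molecule.elements)
    ]
    return ComplexStructure(
        pdb_id=receptor.pdb_id,
        receptor_atoms=receptor.receptor_atoms,
        ligand_atoms=atoms,
        ligand_bonds=list(pose.molecule.bonds),
    )


def key_residue_contacts(
    receptor: ComplexStructure,
    pose: PoseRecord | SmallMolecule,
    key_residues: list[int] | None = None,
    config: PerceptionConfig | None = None,
) -> dict[int, bool]:
    """Hydrogen-bond booleans for the listed key residues (a table row).

    ``key_residues`` entries are author residue numbers; each must resolve in
    the receptor.  Detection reuses the standard H-bond perception restricted
    to those residues.
    """
    if isinstance(pose, SmallMolecule):
        pose = PoseRecord(pose)
    residues = list(key_residues or DEFAULT_KEY_RESIDUES)
    present = {a.residue_number for a in receptor.receptor_atoms}
    for r in residues:
        if r not in present:
            raise ValueError(f"key residue {r} not found in receptor {receptor.pdb_id}")
    contacts = detect_hbonds(_as_pose_complex(receptor, pose), config)
    bonded = {c.receptor_atom[1] for c in contacts}
    return {r: (r in bonded) for r in residues}


def filter_poses(
    receptor: ComplexStructure,
    poses: list[PoseRecord],
    min_key_hbonds: int = 3,
    min_score: float = 60.0,
    key_residues: list[int] | None = None,
    config: PerceptionConfig | None = None,
) -> tuple[list[PoseRecord], pd.DataFrame]:
    """Keep poses hydrogen-bonding ≥ ``min_key_hbonds`` key residues with a
    dock score strictly above ``min_score``.

    Poses without a parseable score are excluded and counted, never fatal.
    Returns the kept poses (best-scoring pose per molecule first in the
    ranking) and a per-pose report table.
    """
    rows = []
    kept: list[PoseRecord] = []
    for pose in poses:
        flags = key_residue_contacts(receptor, pose, key_residues, config)
        pose.hbond_residues = {r for r, ok in flags.items() if ok}
        n_hb = len(pose.hbond_residues)
        has_score = pose.dock_score is not None and np.isfinite(pose.dock_score)
        passed = has_score and n_hb >= min_key_hbonds and pose.dock_score > min_score
        rows.append(
            {
                "molecule_id": pose.molecule_id,
                "pose_index": pose.pose_index,
                "n_key_hbonds": n_hb,
                "dock_score": pose.dock_score if has_score else np.nan,
                "no_score": not has_score,
                "kept": bool(passed),
            }
        )
        if passed:
            kept.append(pose)
    report = pd.DataFrame(
        rows,
        columns=["molecule_id", "pose_index", "n_key_hbonds", "dock_score", "no_score", "kept"],
    )
    # best pose of each molecule first (score descending, deterministic ties)
    kept.sort(key=lambda p: (-(p.dock_score or 0.0), p.molecule_id, p.pose_index))
    return kept, report


def parse_poses(
    library, score_tag: str = "dock_score"
) -> list[PoseRecord]:
    """Wrap library molecules as poses, parsing the named SDF score tag."""
    poses = []
    for idx, mol in enumerate(library):
        score: float | None = None
        raw = mol.properties.get(score_tag)
        if raw is not None:
            try:
                score = float(raw)
            except (TypeError, ValueError):
                score = None
        poses.append(PoseRecord(mol, pose_index=idx, dock_score=score))
    return poses


def conserved_residue_table(
    complexes: list[ComplexStructure],
    residues: list[int] | None = None,
    config: PerceptionConfig | None = None,
) -> pd.DataFrame:
    """Boolean matrix (rows = pdb ids, columns = residues): does the
    co-crystal ligand hydrogen-bond each residue?  The machine-readable form
    of a key-residue conservation table (X/− convention in print)."""
    if not complexes:
        raise ValueError("need at least one complex")
    residues = list(DEFAULT_KEY_RESIDUES + OPTIONAL_KEY_RESIDUES) if residues is None else list(residues)
    rows = {}
    for c in complexes:
        contacts = detect_hbonds(c, config)
        bonded = {ct.receptor_atom[1] for ct in contacts}
        rows[c.pdb_id] = [r in bonded for r in residues]
    return pd.DataFrame.from_dict(rows, orient="index", columns=residues)
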