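"""Deterministic synthetic fixtures for every input class.

Each generator is a pure function of its arguments (same seed ⇒ byte-identical
output) and returns, next to the artifact, a *truth record* sufficient for a
consumer test to assert against without re-deriving geometry:

* :func:`make_toy_complex` — a mini receptor (template residues with an anchor
  atom exposed toward the ligand) plus ligand fragments placed at designed
  contact distances, as PDB text;
* :func:`make_key_site_complex` / :func:`make_poses` — a five-residue
  phosphopeptide-cleft mock (author numbers 414/416/538/540/491) with partner
  fragments per requested residue, and docked-pose sets with designed
  pass/fail gating;
* :func:`make_feature_sets` — families of pharmacophores sharing a jittered
  common core (default: 3 acceptors, 1 donor, 1 hydrophobic) plus per-model
  decoy features guaranteed not to cluster across models;
* :func:`make_pseudo_ligand` / :func:`make_library` — minimal
  chemically-valid fragment molecules whose feature points land exactly on a
  model's centroids (fit value known in closed form), and screening libraries
  of exact matchers plus provably unmatchable scrambled decoys;
* :func:`make_fp_plate` / :func:`make_screen_plate` — fluorescence
  polarization plates simulated from the bound/free polarization window and a
  4PL displacement model.

The fixtures are chemically minimal, not realistic: they exist so that every
pipeline stage can be verified against construction or brute force.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .assay import FPReading, WellRole
from .pharmacophore import FeatureKind, Pharmacophore, PharmacophoreFeature
from .pose_analysis import PoseRecord
from .structures import Library, SmallMolecule

__all__ = [
    "make_toy_complex",
    "make_key_site_complex",
    "make_feature_sets",
    "make_pseudo_ligand",
    "make_library",
    "make_poses",
    "make_fp_plate",
    "make_screen_plate",
    "plate_to_csv",
]

# --------------------------------------------------------------------------
# residue templates: anchor atom at the local origin, every other atom kept
# at y ≤ -0.8 so a ligand fragment placed on +y only sees the anchor

_T = {
    # partner for a ligand ACCEPTOR: backbone N-H donor exposed
    "GLY_N": dict(
        resname="GLY",
        atoms=[
            ("N", "N", (0.0, 0.0, 0.0)),
            ("CA", "C", (0.7, -1.3, 0.0)),
            ("C", "C", (0.0, -2.6, 0.3)),
            ("O", "O", (0.5, -3.6, 0.8)),
        ],
        donors=["N"], acceptors=["O"], hydrophobic=[],
    ),
    # partner for a ligand DONOR: backbone carbonyl O exposed
    "GLY_O": dict(
        resname="GLY",
        atoms=[
            ("O", "O", (0.0, 0.0, 0.0)),
            ("C", "C", (0.0, -1.23, 0.0)),
            ("CA", "C", (1.2, -2.1, 0.0)),
            ("N", "N", (1.5, -3.5, 0.2)),
        ],
        donors=["N"], acceptors=["O"], hydrophobic=[],
    ),
    # hydrophobic side chain, CD1 exposed
    "LEU_CD1": dict(
        resname="LEU",
        atoms=[
            ("CD1", "C", (0.0, 0.0, 0.0)),
            ("CG", "C", (0.8, -1.3, 0.0)),
            ("CD2", "C", (2.2, -1.4, 0.4)),
            ("CB", "C", (0.3, -2.5, -0.5)),
            ("CA", "C", (1.0, -3.7, -0.3)),
            ("N", "N", (2.3, -4.0, 0.0)),
            ("C", "C", (0.2, -4.9, -0.6)),
            ("O", "O", (0.5, -6.0, -0.9)),
        ],
        donors=["N"], acceptors=["O"], hydrophobic=["CD1", "CG", "CD2", "CB"],
    ),
    # positive center, NZ exposed
    "LYS_NZ": dict(
        resname="LYS",
        atoms=[
            ("NZ", "N", (0.0, 0.0, 0.0)),
            ("CE", "C", (0.5, -1.4, 0.0)),
            ("CD", "C", (-0.3, -2.6, 0.3)),
            ("CG", "C", (0.4, -3.9, 0.2)),
            ("CB", "C", (-0.5, -5.0, 0.6)),
            ("CA", "C", (0.2, -6.4, 0.5)),
            ("N", "N", (1.5, -6.9, 0.3)),
            ("C", "C", (-0.7, -7.4, 0.9)),
            ("O", "O", (-0.4, -8.5, 1.2)),
        ],
        donors=["NZ", "N"], acceptors=["O"], hydrophobic=[],
        pos_center="NZ",
    ),
    # negative center (carboxylate), OD1 exposed
    "ASP_OD1": dict(
        resname="ASP",
        atoms=[
            ("OD1", "O", (0.0, 0.0, 0.0)),
            ("CG", "C", (0.6, -1.1, 0.0)),
            ("OD2", "O", (1.9, -1.3, 0.2)),
            ("CB", "C", (0.0, -2.4, -0.3)),
            ("CA", "C", (0.6, -3.6, 0.2)),
            ("N", "N", (1.9, -4.0, 0.1)),
            ("C", "C", (-0.3, -4.7, 0.4)),
            ("O", "O", (0.0, -5.8, 0.8)),
        ],
        donors=["N"], acceptors=["OD1", "OD2", "O"], hydrophobic=[],
        neg_center=("OD1", "OD2"),
    ),
    # indole N-H donor
    "TRP_NE1": dict(
        resname="TRP",
        atoms=[
            ("NE1", "N", (0.0, 0.0, 0.0)),
            ("CD1", "C", (1.1, -0.9, 0.2)),
            ("CE2", "C", (-1.1, -1.0, 0.1)),
            ("CD2", "C", (-0.6, -2.3, 0.0)),
            ("CG", "C", (0.8, -2.25, 0.1)),
            ("CB", "C", (1.5, -3.4, 0.2)),
        ],
        donors=["NE1"], acceptors=[], hydrophobic=["CD1", "CE2", "CD2", "CG", "CB"],
    ),
    # imidazole with ND1 donor exposed (default protonation convention)
    "HIS_ND1": dict(
        resname="HIS",
        atoms=[
            ("ND1", "N", (0.0, 0.0, 0.0)),
            ("CE1", "C", (1.1, -0.85, 0.0)),
            ("NE2", "N", (0.68, -2.2, 0.0)),
            ("CD2", "C", (-0.72, -2.18, 0.0)),
            ("CG", "C", (-1.12, -0.83, 0.0)),
        ],
        donors=["ND1"], acceptors=["NE2"], hydrophobic=[],
        pos_center=("ND1", "CE1", "NE2", "CD2", "CG"),
    ),
    # backbone carbonyl of a leucine (key residue 491 binds via backbone)
    "LEU_O": dict(
        resname="LEU",
        atoms=[
            ("O", "O", (0.0, 0.0, 0.0)),
            ("C", "C", (0.0, -1.23, 0.0)),
            ("CA", "C", (1.2, -2.1, 0.0)),
            ("N", "N", (1.5, -3.5, 0.2)),
            ("CB", "C", (2.3, -1.9, -0.9)),
            ("CG", "C", (3.0, -3.0, -1.5)),
        ],
        donors=["N"], acceptors=["O"], hydrophobic=["CB", "CG"],
    ),
}


# ligand fragments: local coordinates with the feature point at (0, d, 0);
# typing mirrors what heavy-atom perception with unknown bond orders assigns
def _fragment(kind: str, d: float) -> dict:
    if kind == "acceptor":  # carbonyl; O is acceptor (and valence-implied donor)
        return dict(
            elements=["O", "C"],
            coords=[(0.0, d, 0.0), (0.6, d + 1.05, 0.0)],
            donors=[0], acceptors=[0], hydrophobic=[], neg=[], pos=[],
            point_atom=0,
        )
    if kind == "donor":  # hydroxyl; O is donor and acceptor
        return dict(
            elements=["O", "C"],
            coords=[(0.0, d, 0.0), (-0.5, d + 1.33, 0.0)],
            donors=[0], acceptors=[0], hydrophobic=[], neg=[], pos=[],
            point_atom=0,
        )
    if kind == "hydrophobic":  # cyclopropane; centroid at the feature point
        r = 0.866
        return dict(
            elements=["C", "C", "C"],
            coords=[
                (r, d, 0.0),
                (-r / 2, d, r * math.sqrt(3) / 2),
                (-r / 2, d, -r * math.sqrt(3) / 2),
            ],
            donors=[], acceptors=[], hydrophobic=[[0, 1, 2]], neg=[], pos=[],
            point_atom=None,
        )
    if kind == "neg":  # phosphate; group centroid at the feature point (= P)
        b = 1.54 / math.sqrt(3)
        dirs = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]
        coords = [(0.0, d, 0.0)] + [
            (b * x, d + b * y, b * z) for x, y, z in dirs
        ]
        return dict(
            elements=["P", "O", "O", "O", "O"],
            coords=coords,
            donors=[1, 2, 3, 4], acceptors=[1, 2, 3, 4], hydrophobic=[],
            neg=[[0, 1, 2, 3, 4]], pos=[],
            point_atom=0,
        )
    if kind == "pos":  # primary amine; N is the ionizable point
        return dict(
            elements=["N", "C"],
            coords=[(0.0, d, 0.0), (-0.5, d + 1.38, 0.0)],
            donors=[0], acceptors=[0], hydrophobic=[], neg=[], pos=[[0]],
            point_atom=0,
        )
    raise ValueError(f"unknown fragment kind: {kind!r}")


_CONTACT_SETUPS = {
    # contact request -> (residue template, ligand fragment, default distance)
    "hbond_lig_acceptor": ("GLY_N", "acceptor", 2.9),
    "hbond_lig_donor": ("GLY_O", "donor", 2.9),
    "hydrophobic": ("LEU_CD1", "hydrophobic", 4.0),
    "neg_ionizable": ("LYS_NZ", "neg", 3.5),
    # 4.0 keeps the amine clear of the H-bond window edge while well inside
    # the ionic cutoff to the carboxylate midpoint
    "pos_ionizable": ("ASP_OD1", "pos", 4.0),
}

_HBOND_WINDOW = (2.5, 3.5)
_HYDROPHOBIC_MAX = 5.0
_IONIC_MAX = 5.6


@dataclass
class ToyComplex:
    """PDB text of a designed mini-complex plus its intended-contact truth."""

    pdb_text: str
    truth: list[dict]
    pdb_id: str = "TOY1"


def _pdb_lines(atoms: list[tuple], hetero: bool) -> list[str]:
    lines = []
    for serial, name, element, resname, chain, resnum, (x, y, z) in atoms:
        record = "HETATM" if hetero else "ATOM"
        pname = name if len(name) >= 4 else f" {name}"
        lines.append(
            f"{record:<6}{serial:>5} {pname:<4} {resname:<3} {chain:1}{resnum:>4}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}"
        )
    return lines


def _expected_contacts(residues: list[dict], fragments: list[dict]) -> list[dict]:
    """Intended contacts from the designed coordinates: every typed ligand
    atom/group against every typed receptor atom/center, by distance window.
    Pure arithmetic on the generator's own typing annotations."""
    truth = []
    for res in residues:
        for frag in fragments:
            # hydrogen bonds: ligand donor vs receptor acceptor & vice versa
            for li in frag["donors"]:
                for aname in res["acceptors"]:
                    dist = float(np.linalg.norm(frag["xyz"][li] - res["xyz"][aname]))
                    if _HBOND_WINDOW[0] <= dist <= _HBOND_WINDOW[1]:
                        truth.append(
                            dict(kind="HBOND_LIG_DONOR", residue_number=res["resnum"],
                                 residue_name=res["resname"], atom=aname,
                                 distance=round(dist, 3))
                        )
            for li in frag["acceptors"]:
                for dname in res["donors"]:
                    dist = float(np.linalg.norm(frag["xyz"][li] - res["xyz"][dname]))
                    if _HBOND_WINDOW[0] <= dist <= _HBOND_WINDOW[1]:
                        truth.append(
                            dict(kind="HBOND_LIG_ACCEPTOR", residue_number=res["resnum"],
                                 residue_name=res["resname"], atom=dname,
                                 distance=round(dist, 3))
                        )
            # hydrophobic group centroid vs hydrophobic receptor atoms
            for group in frag["hydrophobic"]:
                centroid = np.mean([frag["xyz"][i] for i in group], axis=0)
                best = None
                for hname in res["hydrophobic"]:
                    dist = float(np.linalg.norm(centroid - res["xyz"][hname]))
                    if dist <= _HYDROPHOBIC_MAX and (best is None or dist < best[0]):
                        best = (dist, hname)
                if best:
                    truth.append(
                        dict(kind="HYDROPHOBIC", residue_number=res["resnum"],
                             residue_name=res["resname"], atom=best[1],
                             distance=round(best[0], 3))
                    )
            # ionizable group centroid vs charged receptor centers
            for group in frag["neg"]:
                if res.get("pos_center") is None:
                    continue
                centroid = np.mean([frag["xyz"][i] for i in group], axis=0)
                dist = float(np.linalg.norm(centroid - res["pos_center"]))
                if dist <= _IONIC_MAX:
                    truth.append(
                        dict(kind="NEG_IONIZABLE", residue_number=res["resnum"],
                             residue_name=res["resname"],
                             atom=res.get("pos_center_label", "center"),
                             distance=round(dist, 3))
                    )
            for group in frag["pos"]:
                if res.get("neg_center") is None:
                    continue
                centroid = np.mean([frag["xyz"][i] for i in group], axis=0)
                dist = float(np.linalg.norm(centroid - res["neg_center"]))
                if dist <= _IONIC_MAX:
                    truth.append(
                        dict(kind="POS_IONIZABLE", residue_number=res["resnum"],
                             residue_name=res["resname"], atom="carboxylate",
                             distance=round(dist, 3))
                    )
    truth.sort(key=lambda t: (t["kind"], t["residue_number"], t["atom"]))
    return truth


def _assemble_complex(
    units: list[tuple[str, str, float, int, str]],
    pdb_id: str,
    spacing: float = 15.0,
) -> ToyComplex:
    """Place (template, fragment, distance, resnum) units ``spacing`` Å apart
    on the x axis and emit PDB text plus the arithmetic contact truth."""
    placed = []
    receptor_atoms = []
    ligand_atoms = []
    serial = 1
    for k, (template_name, fragment_kind, distance, resnum, chain) in enumerate(units):
        offset = np.array([k * spacing, 0.0, 0.0])
        template = _T[template_name]
        res_xyz = {
            name: np.array(xyz) + offset for name, _, xyz in template["atoms"]
        }
        for name, element, xyz in template["atoms"]:
            receptor_atoms.append(
                (serial, name, element, template["resname"], chain, resnum, tuple(res_xyz[name]))
            )
            serial += 1
        res = dict(
            resnum=resnum, resname=template["resname"], xyz=res_xyz,
            donors=template["donors"], acceptors=template["acceptors"],
            hydrophobic=template["hydrophobic"],
        )
        if "pos_center" in template:
            names = template["pos_center"]
            if isinstance(names, str):
                res["pos_center"] = res_xyz[names]
                res["pos_center_label"] = names
            else:
                res["pos_center"] = np.mean([res_xyz[n] for n in names], axis=0)
                res["pos_center_label"] = "ring"
        if "neg_center" in template:
            res["neg_center"] = np.mean(
                [res_xyz[n] for n in template["neg_center"]], axis=0
            )
        unit = dict(residue=res, fragment=None)
        if fragment_kind is not None:
            frag = _fragment(fragment_kind, distance)
            frag["xyz"] = [np.array(c) + offset for c in frag["coords"]]
            unit["fragment"] = frag
        placed.append(unit)

    lig_index = 0
    for unit in placed:
        frag = unit["fragment"]
        if frag is None:
            continue
        for element, xyz in zip(frag["elements"], frag["xyz"]):
            lig_index += 1
            ligand_atoms.append(
                (serial, f"{element}{lig_index}", element, "LIG", "L", 900, tuple(xyz))
            )
            serial += 1

    truth = _expected_contacts(
        [u["residue"] for u in placed],
        [u["fragment"] for u in placed if u["fragment"] is not None],
    )
    lines = _pdb_lines(receptor_atoms, hetero=False) + _pdb_lines(ligand_atoms, hetero=True)
    lines.append("END")
    return ToyComplex("\n".join(lines) + "\n", truth, pdb_id)


def make_toy_complex(
    contacts: list[tuple[str, float]] | list[str],
    pdb_id: str = "TOY1",
    spacing: float = 15.0,
) -> ToyComplex:
    """A mini-complex with one designed contact per requested entry.

    ``contacts`` entries are contact kinds (``"hbond_lig_acceptor"``,
    ``"hbond_lig_donor"``, ``"hydrophobic"``, ``"neg_ionizable"``,
    ``"pos_ionizable"``) or (kind, distance Å) pairs.  Residue/fragment pairs
    are spaced far enough apart that only same-index interactions are within
    any cutoff; the truth record lists every intended contact.
    """
    units = []
    for k, entry in enumerate(contacts):
        if isinstance(entry, str):
            kind, distance = entry, None
        else:
            kind, distance = entry
        template, fragment, default_d = _CONTACT_SETUPS[kind.lower()]
        units.append(
            (template, fragment, distance if distance is not None else default_d,
             401 + k, "A")
        )
    return _assemble_complex(units, pdb_id, spacing)


_KEY_SITE = {
    414: ("TRP_NE1", "acceptor"),
    416: ("ASP_OD1", "donor"),
    538: ("HIS_ND1", "acceptor"),
    540: ("LYS_NZ", "acceptor"),
    491: ("LEU_O", "donor"),
}


def make_key_site_complex(
    contact_residues: list[int] | None = None,
    pdb_id: str = "KEYSITE",
    distance: float = 2.9,
) -> ToyComplex:
    """Mock phosphopeptide cleft: residues 414/416/538/540/491 (author
    numbers), with a hydrogen-bonding ligand fragment opposite each residue
    listed in ``contact_residues`` (default: all five)."""
    wanted = list(contact_residues) if contact_residues is not None else sorted(_KEY_SITE)
    units = []
    for resnum in sorted(_KEY_SITE):
        template, fragment = _KEY_SITE[resnum]
        frag = fragment if resnum in wanted else None
        units.append((template, frag, distance, resnum, "A"))
    return _assemble_complex(units, pdb_id)


# --------------------------------------------------------------------------
# pharmacophore feature-set families

_CORE_KINDS = (
    FeatureKind.HBA, FeatureKind.HBA, FeatureKind.HBA,
    FeatureKind.HBD, FeatureKind.HYDROPHOBIC,
)
_CORE_CENTROIDS = np.array(
    [
        [0.0, 0.0, 0.0],
        [5.2, 0.0, 0.0],
        [2.4, 4.6, 0.5],
        [1.2, 1.8, 3.6],
        [4.2, 3.1, -3.2],
    ]
)
_CORE_DIRECTIONS = {
    0: np.array([0.0, 0.0, 1.0]),
    1: np.array([0.0, 1.0, 0.0]),
    2: np.array([1.0, 1.0, 0.0]) / math.sqrt(2),
    3: np.array([0.0, 0.0, 1.0]),
}


@dataclass
class FeatureSetFamily:
    models: list[Pharmacophore]
    core_kinds: list[FeatureKind]
    core_centroids: np.ndarray
    extras_per_model: list[int] = field(default_factory=list)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_feature_sets(
    n_models: int = 9,
    jitter: float = 0.3,
    n_extra_range: tuple[int, int] = (0, 4),
    seed: int = 0,
    core_kinds: tuple[FeatureKind, ...] = _CORE_KINDS,
    core_centroids: np.ndarray | None = None,
    tolerance: float = 1.5,
) -> FeatureSetFamily:
    """Per-complex pharmacophores sharing one designed common core.

    Each model carries the core features (centroids jittered uniformly within
    ``jitter`` Å) plus 0–4 decoy features.  Decoys for model *m* sit on a
    shell of radius ``16 + 3 m`` Å around the core, so decoys of different
    models are ≥3 Å apart and can never form a cross-model cluster, while the
    core clusters remain within 2·jitter.  An empty ``core_kinds`` yields
    models with nothing in common.
    """
    rng = np.random.default_rng(seed)
    centroids = (
        np.asarray(core_centroids, dtype=float)
        if core_centroids is not None
        else _CORE_CENTROIDS[: len(core_kinds)]
    )
    center = centroids.mean(axis=0) if len(centroids) else np.zeros(3)
    models = []
    extras_count = []
    all_kinds = list(FeatureKind)
    for m in range(n_models):
        features = []
        for i, kind in enumerate(core_kinds):
            delta = _random_unit(rng) * rng.uniform(0.0, jitter) if jitter > 0 else 0.0
            directions = ()
            if i in _CORE_DIRECTIONS and kind in (FeatureKind.HBA, FeatureKind.HBD):
                directions = (_CORE_DIRECTIONS[i],)
            features.append(
                PharmacophoreFeature(
                    kind=kind,
                    centroid=centroids[i] + delta,
                    tolerance=tolerance,
                    directions=directions,
                )
            )
        n_extra = int(rng.integers(n_extra_range[0], n_extra_range[1] + 1))
        extras_count.append(n_extra)
        radius = 16.0 + 3.0 * m
        for _ in range(n_extra):
            features.append(
                PharmacophoreFeature(
                    kind=all_kinds[int(rng.integers(len(all_kinds)))],
                    centroid=center + _random_unit(rng) * radius,
                    tolerance=tolerance,
                )
            )
        models.append(
            Pharmacophore(
                name=f"model_{m}", features=features, provenance=[f"model_{m}"]
            ).with_default_constraints()
        )
    return FeatureSetFamily(
        models=models,
        core_kinds=list(core_kinds),
        core_centroids=centroids,
        extras_per_model=extras_count,
    )


# --------------------------------------------------------------------------
# pseudo-ligands and screening libraries

def _known_fragment(kind: FeatureKind) -> dict:
    """Fragments with explicit bond orders (connection tables, not PDB), so
    e.g. a carbonyl O types as a pure acceptor."""
    if kind == FeatureKind.HBA:  # carbonyl with C=O
        return dict(elements=["O", "C"], coords=[(0, 0, 0), (0.6, 1.05, 0)],
                    bonds=[(0, 1, 2.0)], point_atoms=[0])
    if kind == FeatureKind.HBD:  # hydroxyl (donor; also an acceptor point)
        return dict(elements=["O", "C"], coords=[(0, 0, 0), (-0.5, 1.33, 0)],
                    bonds=[(0, 1, 1.0)], point_atoms=[0])
    if kind == FeatureKind.HYDROPHOBIC:  # cyclopropane, centroid at origin
        r = 0.866
        return dict(
            elements=["C", "C", "C"],
            coords=[(r, 0, 0), (-r / 2, 0, r * math.sqrt(3) / 2),
                    (-r / 2, 0, -r * math.sqrt(3) / 2)],
            bonds=[(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)],
            point_atoms=[0, 1, 2],
        )
    if kind == FeatureKind.POS_ION:  # primary amine
        return dict(elements=["N", "C"], coords=[(0, 0, 0), (-0.5, 1.38, 0)],
                    bonds=[(0, 1, 1.0)], point_atoms=[0])
    if kind == FeatureKind.NEG_ION:  # carboxylate
        return dict(
            elements=["C", "O", "O"],
            coords=[(0, 0.83, 0), (1.1, 1.4, 0), (-1.1, 1.4, 0)],
            bonds=[(0, 1, 2.0), (0, 2, 1.0)],
            point_atoms=[0, 1, 2],
        )
    raise ValueError(kind)


def _orthonormal_to(u: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, u)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    v = trial - np.dot(trial, u) * u
    return v / np.linalg.norm(v)


def make_pseudo_ligand(
    model: Pharmacophore,
    omit: tuple[int, ...] = (),
    displace: dict[int, float] | None = None,
    mol_id: str = "pseudo",
) -> tuple[SmallMolecule, float]:
    """A fragment molecule whose feature points land on the model centroids.

    ``omit`` drops whole features; ``displace`` moves a feature's fragment by
    exactly the given distance (Å), perpendicular to its outward axis.
    Returns the molecule (one conformer, in the model frame) and the
    closed-form in-place fit value Σ max(0, 1 − (d/tol)²) over non-omitted
    features.
    """
    displace = displace or {}
    center = model.centroids().mean(axis=0)
    elements: list[str] = []
    bonds: list[tuple[int, int, float]] = []
    coords: list[np.ndarray] = []
    truth_fit = 0.0
    for fi, feature in enumerate(model.features):
        if fi in omit:
            continue
        d = float(displace.get(fi, 0.0))
        truth_fit += feature.weight * max(0.0, 1.0 - (d / feature.tolerance) ** 2)
        frag = _known_fragment(feature.kind)
        u = feature.centroid - center
        norm = np.linalg.norm(u)
        u = u / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        v = _orthonormal_to(u)
        w = np.cross(u, v)
        base = len(elements)
        # local frame: fragment +y along u (outward), displacement along v
        for (lx, ly, lz) in frag["coords"]:
            coords.append(feature.centroid + ly * u + lx * v + lz * w + d * v)
        elements.extend(frag["elements"])
        bonds.extend((base + i, base + j, order) for i, j, order in frag["bonds"])
    mol = SmallMolecule(
        id=mol_id, elements=elements, bonds=bonds,
        conformers=[np.array(coords)] if coords else [np.zeros((0, 3))],
    )
    return mol, truth_fit


def make_library(
    model: Pharmacophore,
    n_match: int = 20,
    n_decoy: int = 80,
    seed: int = 0,
) -> tuple[Library, dict]:
    """Screening library: exact matchers (randomly re-posed, so only rigid
    refitting can recover them) plus scrambled-geometry decoys.

    Decoys are the same fragments with all pairwise feature distances scaled
    past every model distance-plus-tolerance window, so no two decoy points
    can satisfy any pairwise constraint: they are unmatchable by construction
    whenever at least 2 matched features are required.
    """
    from .geometry import random_rigid_transform

    rng = np.random.default_rng(seed)
    centroids = model.centroids()
    n = len(centroids)
    dists = [
        float(np.linalg.norm(centroids[i] - centroids[j]))
        for i in range(n) for j in range(i + 1, n)
    ]
    tolsum = max(
        model.features[i].tolerance + model.features[j].tolerance
        for i in range(n) for j in range(i + 1, n)
    )
    scale = (max(dists) + 1.5 * tolsum) / min(dists)

    molecules: list[SmallMolecule] = []
    for k in range(n_match):
        mol, _ = make_pseudo_ligand(model, mol_id=f"match_{k:03d}")
        tf = random_rigid_transform(rng, max_shift=20.0)
        mol.conformers[0] = tf.apply(mol.conformers[0])
        molecules.append(mol)

    scaled_features = [
        PharmacophoreFeature(
            kind=f.kind, centroid=f.centroid * scale, tolerance=f.tolerance,
            directions=f.directions,
        )
        for f in model.features
    ]
    scaled = Pharmacophore(name="scaled", features=scaled_features)
    for k in range(n_decoy):
        mol, _ = make_pseudo_ligand(scaled, mol_id=f"decoy_{k:03d}")
        tf = random_rigid_transform(rng, max_shift=20.0)
        mol.conformers[0] = tf.apply(mol.conformers[0])
        molecules.append(mol)

    truth = {
        "match_ids": [f"match_{k:03d}" for k in range(n_match)],
        "decoy_ids": [f"decoy_{k:03d}" for k in range(n_decoy)],
        "decoy_scale": scale,
    }
    return Library(molecules, source="synthetic"), truth


# --------------------------------------------------------------------------
# docked-pose sets


def make_poses(
    n_pass: int = 4,
    n_fail_geometry: int = 3,
    n_fail_score: int = 2,
    n_no_score: int = 1,
    pass_score: float = 70.0,
    fail_score: float = 50.0,
    seed: int = 0,
) -> tuple[ToyComplex, list[PoseRecord], dict]:
    """Pose set over the key-site mock: passing poses keep the designed
    five-residue hydrogen bonding and a score above threshold; failures are
    either translated out of the site, under-scored, or score-less."""
    from .structures import read_complex
    import tempfile, os

    toy = make_key_site_complex()
    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
        fh.write(toy.pdb_text)
        path = fh.name
    try:
        complex_ = read_complex(path, "LIG", pdb_id=toy.pdb_id)
    finally:
        os.unlink(path)

    base = SmallMolecule(
        id="ligand",
        elements=[a.element for a in complex_.ligand_atoms],
        bonds=list(complex_.ligand_bonds),
        conformers=[complex_.ligand_coords],
    )
    poses: list[PoseRecord] = []
    truth_pass = []
    idx = 0

    def clone(mol_id: str, shift: np.ndarray, score: float | None) -> PoseRecord:
        nonlocal idx
        mol = SmallMolecule(
            id=mol_id, elements=list(base.elements), bonds=list(base.bonds),
            conformers=[base.conformers[0] + shift],
        )
        pose = PoseRecord(mol, pose_index=idx, dock_score=score)
        idx += 1
        return pose

    for k in range(n_pass):
        pose = clone(f"pass_{k}", np.zeros(3), pass_score + k)
        poses.append(pose)
        truth_pass.append(pose.molecule_id)
    for k in range(n_fail_geometry):
        poses.append(clone(f"far_{k}", np.array([0.0, 10.0 + k, 0.0]), pass_score))
    for k in range(n_fail_score):
        poses.append(clone(f"low_{k}", np.zeros(3), fail_score - k))
    for k in range(n_no_score):
        poses.append(clone(f"noscore_{k}", np.zeros(3), None))

    truth = {"pass_ids": truth_pass, "n_poses": len(poses)}
    return toy, poses, truth


# --------------------------------------------------------------------------
# fluorescence polarization plates

_DOSE_LADDER = tuple(100e-6 / 2**k for k in range(12))  # 100 µM … ~49 nM
MP_BOUND = 300.0  # mP of the fully bound tracer (DMSO control)
MP_FREE = 50.0  # mP of the displaced (free) tracer
_TOTAL_INTENSITY = 10_000.0
_G_FACTOR = 0.998


def _intensities_for_mp(mp: float) -> tuple[float, float]:
    r = mp / (_G_FACTOR * 1000.0)
    return _TOTAL_INTENSITY * (1 + r) / 2, _TOTAL_INTENSITY * (1 - r) / 2


def make_fp_plate(
    truths: list[tuple[str, float, float]],
    noise: float = 0.0,
    seed: int = 0,
    doses: tuple[float, ...] = _DOSE_LADDER,
    n_control_wells: int = 4,
) -> tuple[list[FPReading], dict]:
    """Dose–response FP plate simulated from a 4PL displacement model.

    ``truths`` entries are (compound, IC50 molar, hill).  Responses run from
    the bound-tracer polarization (300 mP) down to the free-tracer floor
    (50 mP); Gaussian noise with σ = ``noise`` × (window) is added to each
    test-well mP.  DMSO and free-peptide control wells are noise-free so the
    normalization anchors are exact.
    """
    rng = np.random.default_rng(seed)
    window = MP_BOUND - MP_FREE
    plate: list[FPReading] = []
    well = 0

    def add(compound: str, conc: float, mp: float, role: WellRole) -> None:
        nonlocal well
        well += 1
        par, perp = _intensities_for_mp(mp)
        plate.append(
            FPReading(
                well=f"W{well:04d}", compound=compound, concentration=conc,
                int_parallel=par, int_perpendicular=perp, role=role,
            )
        )

    for _ in range(n_control_wells):
        add("DMSO", 0.0, MP_BOUND, WellRole.DMSO_CONTROL)
    for _ in range(n_control_wells):
        add("FREE", 0.0, MP_FREE, WellRole.FREE_PEPTIDE_CONTROL)

    truth = {"compounds": {}, "doses": list(doses)}
    for compound, ic50, hill in truths:
        truth["compounds"][compound] = {"ic50": ic50, "hill": hill}
        for x in doses:
            frac = 1.0 / (1.0 + (ic50 / x) ** hill)
            mp = MP_BOUND - window * frac
            if noise > 0:
                mp += rng.normal(0.0, noise * window)
            add(compound, x, mp, WellRole.TEST)
    return plate, truth


def make_screen_plate(
    n_compounds: int = 93,
    n_hits: int = 28,
    dose: float = 100e-6,
    hit_ic50: float = 20e-6,
    miss_ic50: float = 400e-6,
    noise: float = 0.01,
    seed: int = 0,
) -> tuple[list[FPReading], dict]:
    """Single-dose screen: ``n_hits`` compounds get an IC50 well below the
    test dose (>50% displacement), the rest well above (<50%)."""
    truths = []
    hit_ids = []
    for k in range(n_compounds):
        is_hit = k < n_hits
        compound = f"cpd_{k:03d}"
        truths.append((compound, hit_ic50 if is_hit else miss_ic50, 1.0))
        if is_hit:
            hit_ids.append(compound)
    plate, _ = make_fp_plate(truths, noise=noise, seed=seed, doses=(dose,))
    truth = {
        "hit_ids": hit_ids,
        "n_hits": n_hits,
        "expected_inhibition": {
            True: 100.0 / (1.0 + hit_ic50 / dose),
            False: 100.0 / (1.0 + miss_ic50 / dose),
        },
    }
    return plate, truth


def plate_to_csv(plate: list[FPReading]) -> str:
    """Deterministic plate CSV (columns well, compound, role, conc_M,
    int_par, int_perp)."""
    buf = io.StringIO()
    buf.write("well,compound,role,conc_M,int_par,int_perp\n")
    for r in plate:
        buf.write(
            f"{r.well},{r.compound},{r.role.value},{r.concentration:.6e},"
            f"{r.int_parallel:.6f},{r.int_perpendicular:.6f}\n"
        )
    return buf.getvalue()
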