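"""3D pharmacophore matching and fit-value virtual screening.

Matching is the classic correspondence-graph formulation: nodes pair a model
feature with a kind-compatible ligand feature point; an edge connects two
pairs whose model-side and ligand-side distances agree within the summed
feature tolerances.  Cliques of size ≥ (n_features − max_omitted) are
geometrically consistent assignments.  Each assignment is scored after a
least-squares rigid alignment of the matched points onto the model centroids:

    fit = Σ_matched  w_f · max(0, 1 − (d_f / tol_f)²)

so a perfectly placed feature contributes its weight (1 by default), a
feature displaced to its tolerance contributes nothing and becomes omitted.
With every feature matched exactly the fit equals the feature count — a
5-feature model tops out at 5.0, and the familiar "fit ≥ 3 with ≥3 of 5
features" screening gate means "three or more features matched with small
displacements".

Two scoring frames are provided: ``refit=True`` (default for conformer
screening; alignment is recomputed, so the fit is pose-invariant) and
``refit=False`` (the pose is already in the model frame, e.g. docked poses or
receptor-frame fitting; displacements are taken as-is).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import MolGraph
from .geometry import RigidTransform, kabsch
from .pharmacophore import FeatureKind, Pharmacophore
from .perception import perceive_ligand_feature_atoms
from .structures import Library, SmallMolecule

__all__ = [
    "FeaturePoint",
    "MatchResult",
    "MatchAborted",
    "ligand_feature_points",
    "find_assignments",
    "score_fit",
    "best_match",
    "screen_library",
]


@dataclass(frozen=True)
class FeaturePoint:
    """A typed ligand feature location for one conformer."""

    kind: FeatureKind
    position: np.ndarray
    atoms: tuple[int, ...]


@dataclass
class MatchResult:
    """One scored assignment of model features to ligand feature points.

    ``assignment`` maps each model feature index either to a ligand point
    index or to None (omitted — unmatched, or displaced past tolerance).
    """

    molecule_id: str
    conformer: int
    assignment: dict[int, int | None]
    transform: RigidTransform | None
    fit_value: float
    n_matched: int
    clash: bool = False

    @property
    def omitted(self) -> list[int]:
        return sorted(i for i, p in self.assignment.items() if p is None)


class MatchAborted(RuntimeError):
    """Combinatorial guard tripped for one molecule."""


def ligand_feature_points(
    mol: SmallMolecule, conformer: int = 0
) -> list[FeaturePoint]:
    """Typed 3D feature points for one conformer: donor/acceptor points sit on
    their atom, group features (hydrophobic, ionizable) on the group centroid."""
    if conformer >= len(mol.conformers):
        raise IndexError(f"{mol.id}: conformer {conformer} does not exist")
    graph = mol.graph()
    # graph indices run over heavy atoms only; map back to conformer rows
    heavy = getattr(graph, "heavy_indices", None) or mol.heavy_indices()
    if len(heavy) != graph.n_atoms:
        raise ValueError(f"{mol.id}: heavy-atom bookkeeping mismatch")
    coords = mol.conformers[conformer]
    points: list[FeaturePoint] = []
    for kind, groups in perceive_ligand_feature_atoms(graph).items():
        for group in groups:
            orig = tuple(heavy[i] for i in group)
            position = np.mean([coords[i] for i in orig], axis=0)
            points.append(FeaturePoint(kind, position, orig))
    points.sort(key=lambda p: (p.kind.value, p.atoms))
    return points


def find_assignments(
    model: Pharmacophore,
    points: list[FeaturePoint],
    max_omitted: int = 2,
    max_expansions: int = 1_000_000,
) -> list[dict[int, int]]:
    """Enumerate geometrically consistent assignments (correspondence-graph
    cliques) of size ≥ n_features − max_omitted, in deterministic order.

    Raises :class:`MatchAborted` when the clique enumeration exceeds
    ``max_expansions`` node expansions.
    """
    n_feat = len(model.features)
    if max_omitted >= n_feat:
        raise ValueError("max_omitted must be < number of model features")
    min_size = n_feat - max_omitted

    pairs: list[tuple[int, int]] = [
        (fi, pi)
        for fi, f in enumerate(model.features)
        for pi, p in enumerate(points)
        if f.kind == p.kind
    ]
    n = len(pairs)
    if n == 0:
        return []

    centroids = model.centroids()
    model_d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    pt = np.array([p.position for p in points])
    point_d = np.linalg.norm(pt[:, None, :] - pt[None, :, :], axis=-1)
    tol = np.array([f.tolerance for f in model.features])

    adj: list[set[int]] = [set() for _ in range(n)]
    for a in range(n):
        fa, pa = pairs[a]
        for b in range(a + 1, n):
            fb, pb = pairs[b]
            if fa == fb or pa == pb:
                continue
            if abs(model_d[fa, fb] - point_d[pa, pb]) <= tol[fa] + tol[fb]:
                adj[a].add(b)
                adj[b].add(a)

    assignments: list[dict[int, int]] = []
    expansions = 0

    def extend(clique: list[int], candidates: list[int]) -> None:
        nonlocal expansions
        for idx, v in enumerate(candidates):
            expansions += 1
            if expansions > max_expansions:
                raise MatchAborted(
                    f"assignment enumeration exceeded {max_expansions} expansions"
                )
            new_clique = clique + [v]
            if len(new_clique) >= min_size:
                assignments.append(dict(pairs[i] for i in new_clique))
            new_candidates = [w for w in candidates[idx + 1:] if w in adj[v]]
            # prune: even taking every candidate cannot reach min_size
            if len(new_clique) + len(new_candidates) >= min_size:
                extend(new_clique, new_candidates)

    extend([], list(range(n)))
    assignments.sort(key=lambda a: (-len(a), sorted(a.items())))
    return assignments


def score_fit(
    model: Pharmacophore,
    points: list[FeaturePoint],
    assignment: dict[int, int],
    molecule_id: str = "",
    conformer: int = 0,
    refit: bool = True,
    ligand_coords: np.ndarray | None = None,
) -> MatchResult:
    """Score one assignment.

    With ``refit`` the matched ligand points are rigidly aligned onto the
    model centroids (Kabsch; translation-only fallback for <3 or collinear
    points).  Per-feature displacements then price each feature by
    ``max(0, 1 − (d/tol)²)``; a feature displaced past its tolerance is
    re-marked as omitted.  When ``ligand_coords`` (heavy-atom positions of
    the whole conformer) are supplied, a match whose transformed atoms
    penetrate any excluded-volume sphere is flagged as a clash.
    """
    matched = sorted((fi, pi) for fi, pi in assignment.items() if pi is not None)
    if not matched:
        raise ValueError("assignment has no matched features")
    lig = np.array([points[pi].position for _, pi in matched])
    ref = np.array([model.features[fi].centroid for fi, _ in matched])

    if refit:
        tf, _ = kabsch(lig, ref, allow_translation_only=True)
    else:
        tf = RigidTransform()
    moved = tf.apply(lig)
    displacement = np.linalg.norm(moved - ref, axis=1)

    fit = 0.0
    n_matched = 0
    final_assignment: dict[int, int | None] = {
        fi: None for fi in range(len(model.features))
    }
    for (fi, pi), d in zip(matched, displacement):
        f = model.features[fi]
        # at/past tolerance the contribution is 0 and the feature is omitted
        if d >= f.tolerance - 1e-9:
            continue
        final_assignment[fi] = pi
        fit += f.weight * (1.0 - (d / f.tolerance) ** 2)
        n_matched += 1

    clash = False
    if ligand_coords is not None and model.excluded_volumes:
        atoms = tf.apply(np.asarray(ligand_coords, dtype=float))
        for center, radius in model.excluded_volumes:
            if np.any(np.linalg.norm(atoms - center, axis=1) < radius):
                clash = True
                break

    return MatchResult(
        molecule_id=molecule_id,
        conformer=conformer,
        assignment=final_assignment,
        transform=tf,
        fit_value=float(fit),
        n_matched=n_matched,
        clash=clash,
    )


def best_match(
    model: Pharmacophore,
    mol: SmallMolecule,
    max_omitted: int = 2,
    refit: bool = True,
    check_clash: bool = True,
    max_expansions: int = 1_000_000,
) -> MatchResult | None:
    """Best non-clashing match over all conformers and assignments."""
    min_matched = len(model.features) - max_omitted
    best: MatchResult | None = None
    for ci in range(len(mol.conformers)):
        points = ligand_feature_points(mol, ci)
        if not points:
            continue
        assignments = find_assignments(model, points, max_omitted, max_expansions)
        heavy = mol.heavy_indices()
        lig_xyz = mol.conformers[ci][heavy] if check_clash else None
        for assignment in assignments:
            result = score_fit(
                model, points, assignment,
                molecule_id=mol.id, conformer=ci, refit=refit,
                ligand_coords=lig_xyz,
            )
            if result.clash or result.n_matched < min_matched:
                continue
            if best is None or result.fit_value > best.fit_value:
                best = result
    return best


def screen_library(
    model: Pharmacophore,
    library: Library | list[SmallMolecule],
    max_omitted: int = 2,
    min_fit: float = 3.0,
    refit: bool = True,
    check_clash: bool = True,
    max_expansions: int = 1_000_000,
) -> tuple[pd.DataFrame, dict]:
    """Screen a multi-conformer library against a pharmacophore model.

    Returns the ranked hit table (fit descending, molecule id as the
    deterministic tie-break) and a report dict with per-stage counts and the
    ids of molecules aborted by the combinatorial guard.
    """
    molecules = list(library)
    rows = []
    aborted: list[str] = []
    for mol in molecules:
        try:
            result = best_match(
                model, mol, max_omitted=max_omitted, refit=refit,
                check_clash=check_clash, max_expansions=max_expansions,
            )
        except MatchAborted:
            aborted.append(mol.id)
            continue
        if result is None or result.fit_value < min_fit:
            continue
        rows.append(
            {
                "molecule_id": result.molecule_id,
                "conformer": result.conformer,
                "fit_value": result.fit_value,
                "n_matched": result.n_matched,
                "omitted_kinds": ",".join(
                    model.features[i].kind.value for i in result.omitted
                ),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["molecule_id", "conformer", "fit_value", "n_matched", "omitted_kinds"],
    )
    if len(table):
        table = table.sort_values(
            ["fit_value", "molecule_id"], ascending=[False, True]
        ).reset_index(drop=True)
    report = {
        "n_molecules": len(molecules),
        "n_hits": len(table),
        "min_fit": min_fit,
        "max_omitted": max_omitted,
        "aborted": aborted,
    }
    return table, report
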