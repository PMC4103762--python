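"""Pharmacophore data model, `.phjson` serialization and consensus building.

A pharmacophore is a set of typed 3D chemical features (H-bond acceptor /
donor, hydrophobic, positive / negative ionizable) with spherical tolerances,
optional interaction directions, excluded-volume spheres marking
receptor-occupied space, and pairwise distance constraints.  The consensus
operation keeps only the features shared — within a clustering radius — by
enough of the per-complex models, which is how a multi-structure family of
hypotheses is reduced to one common model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FeatureKind",
    "PharmacophoreFeature",
    "Pharmacophore",
    "build_consensus",
    "ConsensusError",
    "serialize",
    "deserialize",
    "save",
    "load",
    "geometry_report",
]

SCHEMA_VERSION = "polopharm-pharmacophore/1"


class FeatureKind(str, Enum):
    HBA = "HBA"
    HBD = "HBD"
    HYDROPHOBIC = "HYDROPHOBIC"
    POS_ION = "POS_ION"
    NEG_ION = "NEG_ION"


class ConsensusError(ValueError):
    """No feature cluster reached the requested support."""

    def __init__(self, message: str, support_histogram: dict[int, int]):
        super().__init__(message)
        self.support_histogram = support_histogram


@dataclass
class PharmacophoreFeature:
    """One typed chemical feature: centroid + tolerance sphere (+ directions).

    ``directions`` holds every interaction direction contributed by merged
    contacts (an acceptor hydrogen-bonding to two receptor donors keeps both);
    ``direction`` exposes the first as the primary one.  ``support`` counts
    the source complexes behind a consensus feature.
    """

    kind: FeatureKind
    centroid: np.ndarray
    tolerance: float = 1.5
    directions: tuple = ()
    weight: float = 1.0
    support: int = 1

    def __post_init__(self) -> None:
        self.kind = FeatureKind(self.kind)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        normed = []
        for d in self.directions:
            v = np.asarray(d, dtype=float)
            norm = np.linalg.norm(v)
            if not math.isclose(norm, 1.0, abs_tol=1e-6):
                if norm < 1e-12:
                    raise ValueError("zero-length feature direction")
                v = v / norm
            normed.append(v)
        self.directions = tuple(normed)

    @property
    def direction(self) -> np.ndarray | None:
        return self.directions[0] if self.directions else None

    def sort_key(self) -> tuple:
        return (self.kind.value, tuple(np.round(self.centroid, 6)))


@dataclass
class Pharmacophore:
    """A named feature set with excluded volumes and distance constraints."""

    name: str
    features: list[PharmacophoreFeature]
    excluded_volumes: list[tuple[np.ndarray, float]] = field(default_factory=list)
    distance_constraints: list[tuple[int, int, float, float]] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.excluded_volumes = [
            (np.asarray(c, dtype=float), float(r)) for c, r in self.excluded_volumes
        ]

    @property
    def n_features(self) -> int:
        return len(self.features)

    def kind_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.features:
            counts[f.kind.value] = counts.get(f.kind.value, 0) + 1
        return counts

    def centroids(self) -> np.ndarray:
        return np.array([f.centroid for f in self.features])

    def with_default_constraints(self) -> "Pharmacophore":
        """All pairwise centroid distances, tolerance = sum of the two radii."""
        constraints = []
        for i in range(len(self.features)):
            for j in range(i + 1, len(self.features)):
                d = float(
                    np.linalg.norm(self.features[i].centroid - self.features[j].centroid)
                )
                tol = self.features[i].tolerance + self.features[j].tolerance
                constraints.append((i, j, d, tol))
        return replace(self, distance_constraints=constraints)


# --------------------------------------------------------------------------
# consensus


def build_consensus(
    models: list[Pharmacophore],
    min_support: int | None = None,
    cluster_radius: float = 2.0,
    name: str = "consensus",
) -> Pharmacophore:
    """Keep the features common to at least ``min_support`` of the models.

    Features of identical kind across models are single-linkage clustered
    (centroid distance ≤ ``cluster_radius``; directional features pointing
    >90° apart never merge).  A cluster supported by ≥ ``min_support``
    distinct models becomes one consensus feature: mean centroid, maximum
    member tolerance, normalized mean direction, support recorded.  All other
    features are discarded.  ``min_support=None`` means "all models".

    Excluded volumes are the union of the first (reference) model's volumes;
    distance constraints are rebuilt over the consensus features.

    The result is independent of the order of ``models`` (single-linkage
    clusters are connected components; features are sorted by kind then
    centroid).
    """
    if len(models) < 2:
        raise ValueError("consensus needs at least 2 models")
    if min_support is None:
        min_support = len(models)
    if min_support > len(models):
        raise ValueError(
            f"min_support {min_support} exceeds number of models {len(models)}"
        )

    nodes = []  # (model_index, feature)
    for mi, model in enumerate(models):
        for f in model.features:
            nodes.append((mi, f))

    graph = nx.Graph()
    graph.add_nodes_from(range(len(nodes)))
    for a in range(len(nodes)):
        mi, fa = nodes[a]
        for b in range(a + 1, len(nodes)):
            mj, fb = nodes[b]
            if fa.kind != fb.kind:
                continue
            if np.linalg.norm(fa.centroid - fb.centroid) > cluster_radius:
                continue
            if fa.direction is not None and fb.direction is not None:
                if float(np.dot(fa.direction, fb.direction)) < 0.0:
                    continue  # opposite-pointing interactions stay distinct
            graph.add_edge(a, b)

    histogram: dict[int, int] = {}
    consensus_features: list[PharmacophoreFeature] = []
    for component in nx.connected_components(graph):
        members = [nodes[i] for i in component]
        support = len({mi for mi, _ in members})
        histogram[support] = histogram.get(support, 0) + 1
        if support < min_support:
            continue
        feats = [f for _, f in members]
        centroid = np.mean([f.centroid for f in feats], axis=0)
        tolerance = max(f.tolerance for f in feats)
        all_dirs = [d for f in feats for d in f.directions]
        directions: tuple = ()
        if all_dirs:
            mean_dir = np.mean(all_dirs, axis=0)
            norm = np.linalg.norm(mean_dir)
            if norm > 1e-9:
                directions = (mean_dir / norm,)
        consensus_features.append(
            PharmacophoreFeature(
                kind=feats[0].kind,
                centroid=centroid,
                tolerance=tolerance,
                directions=directions,
                weight=1.0,
                support=support,
            )
        )

    if not consensus_features:
        raise ConsensusError(
            f"no common features at min_support={min_support}, "
            f"cluster_radius={cluster_radius} (support histogram: {histogram})",
            histogram,
        )

    consensus_features.sort(key=PharmacophoreFeature.sort_key)
    volumes = list(models[0].excluded_volumes)
    provenance = sorted({p for m in models for p in m.provenance})
    model = Pharmacophore(
        name=name,
        features=consensus_features,
        excluded_volumes=volumes,
        provenance=provenance,
    )
    return model.with_default_constraints()


# --------------------------------------------------------------------------
# serialization (.phjson)


def serialize(model: Pharmacophore) -> str:
    doc = {
        "schema": SCHEMA_VERSION,
        "name": model.name,
        "provenance": list(model.provenance),
        "features": [
            {
                "kind": f.kind.value,
                "centroid": [float(x) for x in f.centroid],
                "tolerance": float(f.tolerance),
                "directions": [[float(x) for x in d] for d in f.directions],
                "weight": float(f.weight),
                "support": int(f.support),
            }
            for f in model.features
        ],
        "excluded_volumes": [
            {"center": [float(x) for x in c], "radius": float(r)}
            for c, r in model.excluded_volumes
        ],
        "distance_constraints": [
            [int(i), int(j), float(d), float(t)]
            for i, j, d, t in model.distance_constraints
        ],
    }
    return json.dumps(doc, indent=2)


def deserialize(text: str) -> Pharmacophore:
    doc = json.loads(text)
    schema = doc.get("schema")
    if schema != SCHEMA_VERSION:
        raise ValueError(f"unknown pharmacophore schema: {schema!r}")
    features = []
    for idx, fd in enumerate(doc.get("features", [])):
        try:
            features.append(
                PharmacophoreFeature(
                    kind=FeatureKind(fd["kind"]),
                    centroid=np.array(fd["centroid"], dtype=float),
                    tolerance=float(fd.get("tolerance", 1.5)),
                    directions=tuple(
                        np.array(d, dtype=float) for d in fd.get("directions", [])
                    ),
                    weight=float(fd.get("weight", 1.0)),
                    support=int(fd.get("support", 1)),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"invalid feature at index {idx}: {exc}") from exc
    return Pharmacophore(
        name=doc.get("name", ""),
        features=features,
        excluded_volumes=[
            (np.array(v["center"], dtype=float), float(v["radius"]))
            for v in doc.get("excluded_volumes", [])
        ],
        distance_constraints=[
            (int(i), int(j), float(d), float(t))
            for i, j, d, t in doc.get("distance_constraints", [])
        ],
        provenance=list(doc.get("provenance", [])),
    )


def save(model: Pharmacophore, path: str | Path) -> None:
    Path(path).write_text(serialize(model))


def load(path: str | Path) -> Pharmacophore:
    return deserialize(Path(path).read_text())


# --------------------------------------------------------------------------
# reporting


def geometry_report(model: Pharmacophore) -> pd.DataFrame:
    """Symmetric table of pairwise feature-centroid distances (Å)."""
    labels = [f"{f.kind.value}_{i}" for i, f in enumerate(model.features)]
    if len(labels) < 2:
        return pd.DataFrame(dtype=float)
    xyz = model.centroids()
    dist = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    return pd.DataFrame(np.round(dist, 3), index=labels, columns=labels)
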