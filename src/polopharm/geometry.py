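"""Rigid-body geometry: Kabsch superposition, transforms, RMSD."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "kabsch", "rmsd"]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform ``x -> R @ x + t`` (rotation then translation)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @property
    def is_identity(self) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=1e-9)
            and np.allclose(self.translation, 0.0, atol=1e-9)
        )


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two equally sized coordinate sets (Å)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty coordinate sets")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch(
    moving: np.ndarray,
    reference: np.ndarray,
    allow_translation_only: bool = False,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``moving`` onto ``reference``.

    Returns the optimal proper rotation + translation and the residual RMSD.
    With ``allow_translation_only``, point sets that cannot determine a unique
    rotation (fewer than 3 points, or collinear) are aligned by centroid
    translation alone instead of raising.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("expected matching (n, 3) coordinate arrays")
    n = moving.shape[0]
    if n == 0:
        raise ValueError("cannot superpose empty point sets")

    cm = moving.mean(axis=0)
    cr = reference.mean(axis=0)
    p = moving - cm
    q = reference - cr

    degenerate = n < 3 or np.linalg.matrix_rank(p, tol=1e-8) < 2
    if degenerate:
        if not allow_translation_only:
            raise ValueError(
                "rotation underdetermined (<3 points or collinear); "
                "pass allow_translation_only=True for a centroid shift"
            )
        tf = RigidTransform(np.eye(3), cr - cm)
        return tf, rmsd(tf.apply(moving), reference)

    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    tf = RigidTransform(rot, cr - rot @ cm)
    return tf, rmsd(tf.apply(moving), reference)


def random_rigid_transform(rng: np.random.Generator, max_shift: float = 10.0) -> RigidTransform:
    """Uniformly random rotation (QR of a Gaussian matrix) plus a random shift."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-max_shift, max_shift, size=3)
    return RigidTransform(q, t)
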