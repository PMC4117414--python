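"""Optimal rigid-body superposition (Kabsch) and RMSD.

The Kabsch algorithm gives the closed-form proper rotation + translation
minimising the RMSD between two equal-length ordered point sets. The
determinant-correction branch (sign flip of the smallest singular vector)
is applied so a reflection is never returned: structural chirality is
respected even for near-planar point sets.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .structure import Atom

__all__ = ["RigidTransform", "Superposition", "kabsch", "superpose", "rmsd", "apply_transform"]

_ORTHO_TOL = 1e-8


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation; rotation is proper (det = +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection) rejected")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclasses.dataclass(frozen=True)
class Superposition:
    transform: RigidTransform
    rmsd: float


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unfitted) RMSD between two equal-length coordinate arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Superpose ``mobile`` onto ``target`` minimising RMSD.

    Both arguments are (n, 3) arrays in identical point order, n >= 3.
    Returns the minimising proper rigid transform and the residual RMSD.
    For degenerate (collinear) inputs the rotation about the line is
    arbitrary but the returned transform is still a minimiser.
    """
    P = np.asarray(mobile, dtype=float)
    if P.ndim == 2 and P.shape[0] < 3:
        raise ValueError(f"need at least 3 points, got {P.shape[0]}")
    return superpose(P, target)


def superpose(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Kabsch core accepting n >= 2.

    The two-point case (the smallest word size) is degenerate — any
    rotation carrying one segment onto the other is optimal — and the
    SVD solution remains a minimiser there.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must be matching (n, 3) arrays, got {P.shape} vs {Q.shape}")
    if P.shape[0] < 2:
        raise ValueError("need at least 2 points")

    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    transform = RigidTransform(R, t)
    return Superposition(transform=transform, rmsd=rmsd(transform.apply(P), Q))


def apply_transform(transform: RigidTransform, atoms: list[Atom]) -> list[Atom]:
    """Map atom coordinates through a rigid transform; all other fields kept."""
    out = []
    for a in atoms:
        new = transform.apply(np.asarray(a.coords))
        out.append(dataclasses.replace(a, coords=(float(new[0]), float(new[1]), float(new[2]))))
    return out
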