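"""Rigid-body geometry: transforms, Kabsch superposition, RMSD.

All coordinates are Cartesian angstroms.  Rotations are proper (det = +1);
reflections are never returned by :func:`kabsch`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body motion ``x -> R x + t``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array or a single 3-vector."""
        xyz = np.asarray(coords, dtype=float)
        return xyz @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares superposition of paired point sets.

    Finds the proper rigid transform minimising the RMSD of the transformed
    ``P`` onto ``Q`` (closed-form SVD solution).

    Parameters
    ----------
    P, Q : (n, 3) arrays, n >= 3, row i of P paired with row i of Q.

    Returns
    -------
    (transform, rmsd) where ``transform.apply(P)`` best matches ``Q``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be paired (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("insufficient points: Kabsch needs n >= 3")

    cP = P.mean(axis=0)
    cQ = Q.mean(axis=0)
    H = (P - cP).T @ (Q - cQ)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP
    tf = RigidTransform(R, t)
    rmsd = rmsd_no_fit(tf.apply(P), Q)
    return tf, rmsd


def rmsd_no_fit(A: np.ndarray, B: np.ndarray) -> float:
    """Plain RMSD between already-superposed coordinate sets (no refit)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("correspondence: coordinate arrays differ in shape")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=-1))))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    M = rng.normal(size=(3, 3))
    Qm, Rm = np.linalg.qr(M)
    Qm = Qm @ np.diag(np.sign(np.diag(Rm)))
    if np.linalg.det(Qm) < 0:
        Qm[:, 0] = -Qm[:, 0]
    return Qm
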