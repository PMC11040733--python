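"""Vectorized internal-coordinate geometry: bonds, angles, dihedrals, RMSD.

Dihedral angles use the IUPAC right-handed sign convention with values in
(-pi, pi]; mirrored structures therefore yield dihedrals of opposite sign.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def distances(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Pairwise distances for an (m, 2) index array."""
    idx = np.asarray(idx)
    if idx.size == 0:
        return np.zeros(0)
    d = coords[idx[:, 1]] - coords[idx[:, 0]]
    return np.linalg.norm(d, axis=1)


def angles(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Bond angles (radians, [0, pi]) for an (m, 3) index array."""
    idx = np.asarray(idx)
    if idx.size == 0:
        return np.zeros(0)
    u = coords[idx[:, 0]] - coords[idx[:, 1]]
    v = coords[idx[:, 2]] - coords[idx[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def dihedrals(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Proper dihedral angles (radians, (-pi, pi]) for an (m, 4) index array."""
    idx = np.asarray(idx)
    if idx.size == 0:
        return np.zeros(0)
    b1 = coords[idx[:, 1]] - coords[idx[:, 0]]
    b2 = coords[idx[:, 2]] - coords[idx[:, 1]]
    b3 = coords[idx[:, 3]] - coords[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(y, x)


def wrap_angle(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    out = np.mod(np.asarray(phi) + np.pi, 2.0 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal superposition of *mobile* onto *reference*.

    Returns ``(rotation, mobile_centroid, reference_centroid)`` such that
    ``(mobile - mobile_centroid) @ rotation.T + reference_centroid``
    minimizes the RMSD to *reference*.
    """
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - cr, mobile - cm)
    return rot.as_matrix(), cm, cr


def superposed_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets after optimal superposition."""
    if mobile.shape != reference.shape:
        raise ValueError("coordinate sets must have identical shapes")
    rot, cm, cr = kabsch_superpose(mobile, reference)
    moved = (mobile - cm) @ rot.T + cr
    return float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))


def rmsd_no_fit(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
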