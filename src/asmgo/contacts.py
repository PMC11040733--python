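"""Native-pair (contact) detection via an atom-level van-der-Waals cutoff.

Two residues form a native pair when any interatomic distance between them
is within ``contact_scale * (r_vdw_a + r_vdw_b)``. Contacts are split into
intramolecular pairs (within one chain, sequence separation at least the
exclusion window) and intermolecular pairs (between chains). Detection runs
in two steps: chain pairs are first prefiltered by bounding-box distance,
then atom distances are scanned with a k-d tree (exact, not approximate).

The pair's stored equilibrium distance r0 is the native Calpha-Calpha
distance; the 12-6 Lennard-Jones zero crossing is sigma = r0 / 2^(1/6).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .constants import SIXTH_ROOT_OF_TWO
from .params import ForceFieldParams
from .structure_io import Conformation

__all__ = ["NativePair", "detect_native_pairs", "filter_chain_pairs", "write_contact_map"]


@dataclass
class NativePair:
    """One native contact between two Calpha beads.

    Indices are global bead indices within the conformation (bead_i < bead_j);
    chain/residue coordinates identify the pair independently of the global
    numbering. ``epsilon_scale`` multiplies the generic contact depth.
    """

    bead_i: int
    bead_j: int
    chain_i: int
    chain_j: int
    res_i: int
    res_j: int
    r0: float
    kind: str                      # "intra" | "inter"
    epsilon_scale: float = 1.0
    group_id: int | None = None

    def __post_init__(self):
        if self.bead_i >= self.bead_j:
            raise ValueError("native pair requires bead_i < bead_j")
        if self.r0 <= 0:
            raise ValueError("native pair requires r0 > 0")
        if self.kind not in ("intra", "inter"):
            raise ValueError(f"unknown pair kind {self.kind!r}")

    @property
    def sigma(self) -> float:
        return self.r0 / SIXTH_ROOT_OF_TWO


@dataclass
class _ChainAtoms:
    coords: np.ndarray     # (n_atoms, 3)
    radii: np.ndarray      # (n_atoms,)
    res: np.ndarray        # (n_atoms,) residue index within chain
    tree: cKDTree = field(init=False)

    def __post_init__(self):
        self.tree = cKDTree(self.coords)


def _collect_atoms(conformation: Conformation, heavy_only: bool) -> list[_ChainAtoms]:
    out = []
    for chain in conformation.chains:
        coords, radii, res = [], [], []
        for residue in chain.residues:
            for atom in residue.atoms:
                if heavy_only and atom.is_hydrogen:
                    continue
                coords.append(atom.coords)
                radii.append(atom.vdw_radius)
                res.append(residue.index)
        if not coords:
            raise ValueError(f"chain {chain.chain_id}: no atoms for contact detection")
        out.append(_ChainAtoms(np.array(coords), np.array(radii), np.array(res)))
    return out


def filter_chain_pairs(conformation: Conformation, margin: float) -> list[tuple[int, int]]:
    """Chain pairs whose axis-aligned bounding boxes approach within *margin* A.

    The box-to-box distance is a lower bound on the minimum interatomic
    distance, so with *margin* at least the contact cutoff this is a
    guaranteed superset of the chain pairs containing any native pair.
    """
    boxes = []
    for chain in conformation.chains:
        xyz = np.array([a.coords for r in chain.residues for a in r.atoms])
        boxes.append((xyz.min(axis=0), xyz.max(axis=0)))
    pairs = []
    for a, b in combinations(range(len(boxes)), 2):
        (lo_a, hi_a), (lo_b, hi_b) = boxes[a], boxes[b]
        gap = np.maximum(0.0, np.maximum(lo_b - hi_a, lo_a - hi_b))
        if np.linalg.norm(gap) <= margin:
            pairs.append((a, b))
    return pairs


def _contact_residue_pairs(a: _ChainAtoms, b: _ChainAtoms | None, scale: float) -> set[tuple[int, int]]:
    """Residue pairs of chains a, b (or within a if b is None) in atomic contact."""
    max_cut = scale * 2.0 * max(a.radii.max(), (b or a).radii.max())
    found: set[tuple[int, int]] = set()
    if b is None:
        candidates = a.tree.query_pairs(max_cut, output_type="ndarray")
        coords_b, radii_b, res_b = a.coords, a.radii, a.res
        coords_a, radii_a, res_a = a.coords, a.radii, a.res
    else:
        pairs = a.tree.query_ball_tree(b.tree, max_cut)
        candidates = np.array(
            [(i, j) for i, hits in enumerate(pairs) for j in hits], dtype=int
        ).reshape(-1, 2)
        coords_a, radii_a, res_a = a.coords, a.radii, a.res
        coords_b, radii_b, res_b = b.coords, b.radii, b.res
    if candidates.size == 0:
        return found
    i, j = candidates[:, 0], candidates[:, 1]
    d = np.linalg.norm(coords_a[i] - coords_b[j], axis=1)
    ok = d <= scale * (radii_a[i] + radii_b[j])
    for ii, jj in zip(res_a[i[ok]], res_b[j[ok]]):
        if b is None and ii == jj:
            continue
        key = (int(min(ii, jj)), int(max(ii, jj))) if b is None else (int(ii), int(jj))
        found.add(key)
    return found


def detect_native_pairs(
    conformation: Conformation,
    params: ForceFieldParams | None = None,
) -> list[NativePair]:
    """All native pairs of a conformation, intra and inter, sorted and unique.

    Intra-chain pairs with sequence separation below ``exclusion_window``
    are dropped (short-range geometry is governed by the bonded terms).
    """
    params = params or ForceFieldParams()
    chains = _collect_atoms(conformation, params.heavy_atoms_only)
    offsets = np.cumsum([0] + [len(c.residues) for c in conformation.chains])
    ca = [chain.ca_coords for chain in conformation.chains]

    pairs: list[NativePair] = []
    # intramolecular
    for c, atoms in enumerate(chains):
        for i, j in sorted(_contact_residue_pairs(atoms, None, params.contact_scale)):
            if j - i < params.exclusion_window:
                continue
            r0 = float(np.linalg.norm(ca[c][i] - ca[c][j]))
            pairs.append(NativePair(
                bead_i=int(offsets[c] + i), bead_j=int(offsets[c] + j),
                chain_i=c, chain_j=c, res_i=i, res_j=j, r0=r0, kind="intra",
            ))
    # intermolecular, with the chain-distance prefilter
    max_radius = max(c.radii.max() for c in chains)
    margin = params.contact_scale * 2.0 * max_radius + params.chain_filter_margin
    for a, b in filter_chain_pairs(conformation, margin):
        for i, j in sorted(_contact_residue_pairs(chains[a], chains[b], params.contact_scale)):
            r0 = float(np.linalg.norm(ca[a][i] - ca[b][j]))
            pairs.append(NativePair(
                bead_i=int(offsets[a] + i), bead_j=int(offsets[b] + j),
                chain_i=a, chain_j=b, res_i=i, res_j=j, r0=r0, kind="inter",
            ))
    return pairs


def write_contact_map(pairs: list[NativePair], path: str | Path) -> None:
    """Plain-text contact map: one 'chain_i res_i chain_j res_j r0 kind' per line."""
    lines = [
        f"{p.chain_i} {p.res_i} {p.chain_j} {p.res_j} {p.r0:.4f} {p.kind}"
        for p in pairs
    ]
    Path(path).write_text("\n".join(lines) + "\n")
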