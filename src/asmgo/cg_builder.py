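"""Calpha bead model and bonded terms from a native conformation.

One pseudobead per residue, placed on the Calpha atom; all beads share the
same mass and radius and differ only in their interactions. Equilibrium
values of the harmonic bond, harmonic angle and periodic dihedral terms are
measured directly on the native conformation:

* bonds (i, i+1): V = k_b (r - b0)^2
* angles (i, i+1, i+2): V = k_a (theta - theta0)^2
* dihedrals (i..i+3): V = k1 [1 - cos(phi - phi0)] + k3 [1 - cos 3(phi - phi0)]

The two dihedral multiplicities (n = 1, 3) share the native equilibrium
value phi0; because dihedrals of mirrored conformations have opposite
signs, this term prevents refolding into the mirror image. Dihedrals whose
flanking bond angle is nearly straight are numerically ill-defined and are
suppressed (dropped, with a record of the reason).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .params import ForceFieldParams
from .structure_io import Conformation

logger = logging.getLogger(__name__)

__all__ = ["CGBead", "BondedTerms", "build_beads", "build_bonded_terms"]


@dataclass
class CGBead:
    bead_index: int
    chain_index: int
    residue_index: int
    coords: np.ndarray
    mass: float = 1.0


@dataclass
class BondedTerms:
    """Bonded terms of one conformation (indices are global bead indices)."""

    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, float, float, float]] = field(default_factory=list)
    suppressed_dihedrals: list[tuple[tuple[int, int, int, int], str]] = field(default_factory=list)


def build_beads(conformation: Conformation) -> list[CGBead]:
    """One bead per residue, at the Calpha position."""
    beads = []
    for c, chain in enumerate(conformation.chains):
        for residue in chain.residues:
            beads.append(CGBead(
                bead_index=len(beads),
                chain_index=c,
                residue_index=residue.index,
                coords=residue.ca.coords.copy(),
            ))
    return beads


def build_bonded_terms(beads: list[CGBead], params: ForceFieldParams | None = None) -> BondedTerms:
    """Measure bond/angle/dihedral equilibrium values on the bead chain(s).

    Consecutive beads within one chain define the terms; a chain of N beads
    yields N-1 bonds, N-2 angles and at most N-3 dihedrals. A dihedral is
    suppressed when either of its two flanking bond angles exceeds
    ``params.angle_dihedral_cutoff`` (near-straight angles make the dihedral
    direction numerically unstable).
    """
    params = params or ForceFieldParams()
    coords = np.array([b.coords for b in beads])
    terms = BondedTerms()
    cutoff = params.angle_dihedral_cutoff_rad

    by_chain: dict[int, list[CGBead]] = {}
    for bead in beads:
        by_chain.setdefault(bead.chain_index, []).append(bead)

    for chain_index, chain_beads in by_chain.items():
        n = len(chain_beads)
        if n < 2:
            warnings.warn(f"chain {chain_index}: fewer than 2 beads, no bonded terms")
            continue
        gi = [b.bead_index for b in chain_beads]

        bond_idx = np.array([(gi[i], gi[i + 1]) for i in range(n - 1)])
        b0 = geometry.distances(coords, bond_idx)
        for (i, j), length in zip(bond_idx, b0):
            if not 2.5 <= length <= 4.5:
                warnings.warn(
                    f"bond {i}-{j}: equilibrium length {length:.2f} A outside "
                    "the 2.5-4.5 A range typical of Calpha virtual bonds"
                )
            terms.bonds.append((int(i), int(j), float(length), params.k_bond))

        angle_values = np.zeros(0)
        if n >= 3:
            angle_idx = np.array([(gi[i], gi[i + 1], gi[i + 2]) for i in range(n - 2)])
            angle_values = geometry.angles(coords, angle_idx)
            for (i, j, k), theta in zip(angle_idx, angle_values):
                terms.angles.append((int(i), int(j), int(k), float(theta), params.k_angle))

        if n >= 4:
            dih_idx = np.array([(gi[i], gi[i + 1], gi[i + 2], gi[i + 3]) for i in range(n - 3)])
            phi = geometry.dihedrals(coords, dih_idx)
            for t, (quad, phi0) in enumerate(zip(dih_idx, phi)):
                # flanking angles of dihedral t are chain angles t and t+1
                flank = angle_values[t:t + 2]
                if np.any(flank > cutoff):
                    worst = float(np.degrees(flank.max()))
                    terms.suppressed_dihedrals.append(
                        (tuple(int(x) for x in quad),
                         f"flanking bond angle {worst:.1f} deg exceeds "
                         f"{params.angle_dihedral_cutoff:.1f} deg cutoff"))
                    continue
                terms.dihedrals.append((
                    *(int(x) for x in quad), float(phi0),
                    params.k_dihedral_1, params.k_dihedral_3,
                ))
    return terms
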