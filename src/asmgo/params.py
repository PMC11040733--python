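"""Model parameters and configuration-file handling.

A single :class:`ForceFieldParams` object carries every tunable of the
pipeline, from contact detection to file export. It can be loaded from a
YAML config file whose keys may use either underscores or hyphens
(``angle-dihedral-cutoff`` and ``angle_dihedral_cutoff`` are equivalent).
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .constants import SIXTH_ROOT_OF_TWO


@dataclass
class ForceFieldParams:
    """All tunable parameters of the coarse-grained model.

    Energies are in the generic unit eps, distances in Angstrom, angles in
    degrees where noted (converted to radians internally where needed).
    """

    # -- energy scales ----------------------------------------------------
    #: global multiplier for intramolecular native-pair depths
    epsilon_intra: float = 1.0
    #: global multiplier for intermolecular native-pair depths
    epsilon_inter: float = 1.0

    # -- bonded force constants (V = k (x - x0)^2 convention) -------------
    k_bond: float = 100.0        # eps / A^2
    k_angle: float = 20.0        # eps / rad^2
    k_dihedral_1: float = 1.0    # eps, multiplicity-1 term
    k_dihedral_3: float = 0.5    # eps, multiplicity-3 term

    # -- nonbonded --------------------------------------------------------
    #: repulsive bead radius in A; non-native pairs repel below ~this range
    repulsive_radius: float = 4.0
    #: scale on the sum of vdW radii in the atom-level contact criterion
    contact_scale: float = 1.0
    #: ignore hydrogens during contact detection
    heavy_atoms_only: bool = False
    #: minimum |i - j| for an intra-chain native pair
    exclusion_window: int = 4
    #: chain-pair prefilter margin (A) added on top of the contact cutoff
    chain_filter_margin: float = 2.0

    # -- merging / multi-conformation -------------------------------------
    #: max Calpha RMSD (A) for two same-sequence chains to share a conformer
    rmsd_cutoff: float = 1.5
    #: grid sizes of tabulated multi-minimum potentials
    angle_table_points: int = 1000
    dihedral_table_points: int = 1440

    # -- stability --------------------------------------------------------
    #: suppress dihedrals whose flanking bond angle exceeds this (degrees)
    angle_dihedral_cutoff: float = 170.0

    # -- interaction groups ------------------------------------------------
    #: eps multipliers per interaction group type id
    group_factors: dict[int, float] = field(default_factory=dict)
    #: if > 0, merge group types whose residue-pair sets have a Jaccard
    #: similarity >= this value (0 disables the tolerance)
    group_jaccard_merge: float = 0.0

    @property
    def sigma_repulsive(self) -> float:
        """Zero-crossing sigma of the repulsive potential, A."""
        return self.repulsive_radius / SIXTH_ROOT_OF_TWO

    @property
    def angle_dihedral_cutoff_rad(self) -> float:
        return math.radians(self.angle_dihedral_cutoff)

    def replace(self, **kwargs) -> "ForceFieldParams":
        return dataclasses.replace(self, **kwargs)

    # -- config I/O --------------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "ForceFieldParams":
        known = {f.name for f in dataclasses.fields(cls)}
        clean: dict = {}
        for key, value in data.items():
            name = str(key).replace("-", "_")
            if name == "interaction_groups":
                name, value = "group_factors", {int(k): float(v) for k, v in value.items()}
            if name not in known:
                raise KeyError(f"unknown configuration key: {key!r}")
            clean[name] = value
        params = cls(**clean)
        params.validate()
        return params

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ForceFieldParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def validate(self) -> None:
        positive = (
            "k_bond", "k_angle", "k_dihedral_1", "k_dihedral_3",
            "repulsive_radius", "contact_scale", "rmsd_cutoff",
            "epsilon_intra", "epsilon_inter",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.exclusion_window < 1:
            raise ValueError("exclusion_window must be >= 1")
        if not 0.0 < self.angle_dihedral_cutoff <= 180.0:
            raise ValueError("angle_dihedral_cutoff must be in (0, 180] degrees")
        for factor in self.group_factors.values():
            if factor <= 0:
                raise ValueError("interaction group factors must be positive")
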