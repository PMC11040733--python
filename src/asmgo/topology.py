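"""The coarse-grained topology container and the build pipeline.

:func:`build_topology` takes the parsed native conformations (one or more
models of the same system) through the whole pipeline: chain merging,
bonded-term extraction, native-pair detection, interaction-group detection
and strength scaling. The result is a :class:`CGTopology` — merged molecule
types with their intra-chain terms, plus type-level intermolecular native
pairs that apply between *any* two copies (the permutation-invariant
encoding) — which the export and energy modules consume.

:meth:`CGTopology.expand` flattens the topology into global-bead-index
arrays for single-point energy evaluation and desk-scale dynamics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import detect_native_pairs
from .interfaces import (InteractionGroup, TypedPair, apply_group_scaling,
                         canonical_typed_pair, detect_interaction_groups)
from .merging import (MergedChainType, TabulatedPotential,
                      group_identical_chains, merge_intra_topology,
                      _sorted_mean)
from .params import ForceFieldParams
from .structure_io import Conformation

__all__ = ["ChainInstance", "TypeLevelPair", "CGTopology", "ExpandedSystem", "build_topology"]


@dataclass
class ChainInstance:
    """One physical chain copy in the simulated system."""

    instance_id: int
    type_id: int
    copy_index: int
    n_residues: int
    offset: int            # global bead index of residue 0


@dataclass
class TypeLevelPair:
    """One intermolecular native pair in merged-type coordinates.

    Applies between the named residue positions of *any* two distinct chain
    copies of the matching types (both orientations when the two endpoints
    share a type), which is what makes identical subunits exchangeable.
    """

    type_a: int
    res_a: int
    type_b: int
    res_b: int
    r0: float
    epsilon_scale: float = 1.0

    @property
    def key(self) -> TypedPair:
        return canonical_typed_pair((self.type_a, self.res_a), (self.type_b, self.res_b))


@dataclass
class ExpandedSystem:
    """Flat per-bead arrays of every interaction, ready for evaluation."""

    n_beads: int
    # bonded
    bond_idx: np.ndarray
    bond_b0: np.ndarray
    bond_k: np.ndarray
    angle_idx: np.ndarray
    angle_theta0: np.ndarray
    angle_k: np.ndarray
    dihedral_idx: np.ndarray
    dihedral_phi0: np.ndarray
    dihedral_k1: np.ndarray
    dihedral_k3: np.ndarray
    tab_angle_idx: np.ndarray
    tab_angle_tables: list[TabulatedPotential]
    tab_dihedral_idx: np.ndarray
    tab_dihedral_tables: list[TabulatedPotential]
    # native pairs (eps already includes global and per-pair scaling)
    intra_idx: np.ndarray
    intra_r0: np.ndarray
    intra_eps: np.ndarray
    inter_idx: np.ndarray
    inter_r0: np.ndarray
    inter_eps: np.ndarray
    # nonbonded defaults
    sigma_repulsive: float
    epsilon_repulsive: float
    #: pairs excluded from the default repulsion (sorted (i, j) tuples):
    #: bonded neighbors within 3 bonds plus all native pairs
    exclusions: set[tuple[int, int]] = field(default_factory=set)
    chain_of_bead: np.ndarray | None = None


def _as_idx(rows: list[tuple], width: int) -> np.ndarray:
    if not rows:
        return np.zeros((0, width), dtype=int)
    return np.array(rows, dtype=int)


@dataclass
class CGTopology:
    """Merged molecule types + chain instances + intermolecular pairs."""

    types: list[MergedChainType]
    instances: list[ChainInstance]
    inter_pairs: list[TypeLevelPair]
    groups: list[InteractionGroup]
    group_types: dict[int, frozenset[TypedPair]]
    params: ForceFieldParams
    #: native Calpha coordinates of the first model, (n_beads, 3) A
    native_coords: np.ndarray

    @property
    def n_beads(self) -> int:
        return sum(inst.n_residues for inst in self.instances)

    def type_of_instance(self, instance_id: int) -> MergedChainType:
        return self.types[self.instances[instance_id].type_id]

    def chain_slices(self) -> list[slice]:
        return [
            slice(inst.offset, inst.offset + inst.n_residues)
            for inst in self.instances
        ]

    # ------------------------------------------------------------------
    def expand(self) -> ExpandedSystem:
        """Replicate per-type terms over all chain copies.

        Intermolecular type-level pairs are instantiated between every
        unordered pair of instances whose types match, in both orientations
        where applicable — mirroring the semantics of atom-type-level
        nonbonded overrides in the exported files.
        """
        p = self.params
        bonds, angles, dihedrals = [], [], []
        tab_angles: list[tuple[tuple, TabulatedPotential]] = []
        tab_dihedrals: list[tuple[tuple, TabulatedPotential]] = []
        intra, exclusions = [], set()
        chain_of = np.zeros(self.n_beads, dtype=int)

        for inst in self.instances:
            ctype = self.types[inst.type_id]
            off = inst.offset
            chain_of[off:off + inst.n_residues] = inst.instance_id
            for i, j, b0, k in ctype.bonds:
                bonds.append((off + i, off + j, b0, k))
            for term in ctype.angles:
                idx = tuple(off + x for x in term.idx)
                if term.is_tabulated:
                    tab_angles.append((idx, term.table))
                else:
                    angles.append((*idx, term.equilibria[0], ctype.k_angle))
            for term in ctype.dihedrals:
                idx = tuple(off + x for x in term.idx)
                if term.is_tabulated:
                    tab_dihedrals.append((idx, term.table))
                else:
                    dihedrals.append((*idx, term.equilibria[0],
                                      ctype.k_dihedral_1, ctype.k_dihedral_3))
            for i, j, r0, scale in ctype.intra_pairs:
                intra.append((off + i, off + j, r0, p.epsilon_intra * scale))
            # nrexcl = 3: bonded neighbors up to 3 bonds apart are excluded
            for i in range(inst.n_residues):
                for j in range(i + 1, min(i + 4, inst.n_residues)):
                    exclusions.add((off + i, off + j))

        inter = []
        seen = set()
        for a in self.instances:
            for b in self.instances:
                if a.instance_id >= b.instance_id:
                    continue
                for pair in self.inter_pairs:
                    for (ta, ra, tb, rb) in (
                        (pair.type_a, pair.res_a, pair.type_b, pair.res_b),
                        (pair.type_b, pair.res_b, pair.type_a, pair.res_a),
                    ):
                        if a.type_id == ta and b.type_id == tb:
                            gi, gj = a.offset + ra, b.offset + rb
                            key = (min(gi, gj), max(gi, gj))
                            if key not in seen:
                                seen.add(key)
                                inter.append((*key, pair.r0,
                                              p.epsilon_inter * pair.epsilon_scale))

        intra_arr = _as_idx([(i, j) for i, j, *_ in intra], 2)
        inter_arr = _as_idx([(i, j) for i, j, *_ in inter], 2)
        for i, j, *_ in intra + inter:
            exclusions.add((min(i, j), max(i, j)))

        return ExpandedSystem(
            n_beads=self.n_beads,
            bond_idx=_as_idx([(i, j) for i, j, *_ in bonds], 2),
            bond_b0=np.array([r[2] for r in bonds]),
            bond_k=np.array([r[3] for r in bonds]),
            angle_idx=_as_idx([r[:3] for r in angles], 3),
            angle_theta0=np.array([r[3] for r in angles]),
            angle_k=np.array([r[4] for r in angles]),
            dihedral_idx=_as_idx([r[:4] for r in dihedrals], 4),
            dihedral_phi0=np.array([r[4] for r in dihedrals]),
            dihedral_k1=np.array([r[5] for r in dihedrals]),
            dihedral_k3=np.array([r[6] for r in dihedrals]),
            tab_angle_idx=_as_idx([idx for idx, _t in tab_angles], 3),
            tab_angle_tables=[t for _idx, t in tab_angles],
            tab_dihedral_idx=_as_idx([idx for idx, _t in tab_dihedrals], 4),
            tab_dihedral_tables=[t for _idx, t in tab_dihedrals],
            intra_idx=intra_arr,
            intra_r0=np.array([r for *_ij, r, _e in intra]),
            intra_eps=np.array([e for *_ijr, e in intra]),
            inter_idx=inter_arr,
            inter_r0=np.array([r for *_ij, r, _e in inter]),
            inter_eps=np.array([e for *_ijr, e in inter]),
            sigma_repulsive=p.sigma_repulsive,
            epsilon_repulsive=1.0,
            exclusions=exclusions,
            chain_of_bead=chain_of,
        )


def build_topology(
    conformations: list[Conformation] | Conformation,
    params: ForceFieldParams | None = None,
) -> CGTopology:
    """Full pipeline: merging, bonded terms, native pairs, interface groups.

    Multiple models of the input define multiple native conformations; the
    first model provides the reference coordinates and the chain layout.
    """
    if isinstance(conformations, Conformation):
        conformations = [conformations]
    params = params or ForceFieldParams()

    types = group_identical_chains(conformations, params=params)
    for ctype in types:
        merge_intra_topology(ctype, conformations, params)

    # chain instances follow the chain order of the first model
    type_of_chain: dict[int, tuple[int, int]] = {}
    for ctype in types:
        for copy_index, chain_index in enumerate(ctype.member_chains):
            type_of_chain[chain_index] = (ctype.type_id, copy_index)

    instances, offset = [], 0
    for chain_index, chain in enumerate(conformations[0].chains):
        type_id, copy_index = type_of_chain[chain_index]
        instances.append(ChainInstance(
            instance_id=chain_index,
            type_id=type_id,
            copy_index=copy_index,
            n_residues=len(chain),
            offset=offset,
        ))
        offset += len(chain)

    # intermolecular native pairs over all models, mapped to type level
    occurrence_r0: dict[TypedPair, list[float]] = {}
    instance_pair_sets: dict[tuple[int, int], set[TypedPair]] = {}
    for conf in conformations:
        for pair in detect_native_pairs(conf, params):
            if pair.kind != "inter":
                continue
            ta, _ = type_of_chain[pair.chain_i]
            tb, _ = type_of_chain[pair.chain_j]
            key = canonical_typed_pair((ta, pair.res_i), (tb, pair.res_j))
            occurrence_r0.setdefault(key, []).append(pair.r0)
            ipair = (min(pair.chain_i, pair.chain_j), max(pair.chain_i, pair.chain_j))
            instance_pair_sets.setdefault(ipair, set()).add(key)

    inter_pairs = [
        TypeLevelPair(
            type_a=key[0][0], res_a=key[0][1],
            type_b=key[1][0], res_b=key[1][1],
            r0=_sorted_mean(occurrence_r0[key]),
        )
        for key in sorted(occurrence_r0)
    ]

    groups, group_types = detect_interaction_groups(
        {k: frozenset(v) for k, v in instance_pair_sets.items()},
        jaccard_merge=params.group_jaccard_merge,
    )
    if params.group_factors:
        scales = apply_group_scaling(groups, params.group_factors)
        for pair in inter_pairs:
            pair.epsilon_scale = scales.get(pair.key, 1.0)
    else:
        # groups keep scale 1.0; still annotate pair membership
        apply_group_scaling(groups, {})

    native_coords = np.concatenate(
        [chain.ca_coords for chain in conformations[0].chains]
    ) if conformations[0].chains else np.zeros((0, 3))

    return CGTopology(
        types=types,
        instances=instances,
        inter_pairs=inter_pairs,
        groups=groups,
        group_types=group_types,
        params=params,
        native_coords=native_coords,
    )
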