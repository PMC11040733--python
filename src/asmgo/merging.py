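"""Chain merging and multi-conformation (multi-minimum) potentials.

Chains with exactly identical one-letter sequences are merged into a single
molecule type so that identical subunits become exchangeable: the exported
topology holds one molecule description plus a copy count, and assembly can
proceed in any permutation of the copies.

Within one merged type, the native conformations of the member chains (over
all structure models) are clustered by pairwise Calpha RMSD after optimal
superposition. Clusters within the user RMSD cutoff form one conformer whose
equilibrium values are averaged over members; distinct clusters become
separate conformers and the type's angle and dihedral potentials turn into
multi-minimum terms: a dense grid tabulating the pointwise minimum over the
per-conformer potentials. Native pairs are the union over conformers (the
short range of the contact potential keeps the basins nearly independent),
and bond lengths are taken from the first conformer.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .cg_builder import build_beads, build_bonded_terms
from .contacts import detect_native_pairs
from .params import ForceFieldParams
from .structure_io import Chain, Conformation

__all__ = [
    "TabulatedPotential", "MultiConfTerm", "MergedChainType",
    "group_identical_chains", "merge_intra_topology", "build_min_table",
]


def _angle_potential(theta, theta0, k_a):
    return k_a * (theta - theta0) ** 2


def _angle_derivative(theta, theta0, k_a):
    return 2.0 * k_a * (theta - theta0)


def _dihedral_potential(phi, phi0, k1, k3):
    d = phi - phi0
    return k1 * (1.0 - np.cos(d)) + k3 * (1.0 - np.cos(3.0 * d))


def _dihedral_derivative(phi, phi0, k1, k3):
    d = phi - phi0
    return k1 * np.sin(d) + 3.0 * k3 * np.sin(3.0 * d)


@dataclass
class TabulatedPotential:
    """Dense grid of a (possibly multi-minimum) angle or dihedral potential.

    ``minus_derivative`` holds -dE/dx (the force column of GROMACS-style
    table files). At branch crossings the derivative comes from the
    lower-energy branch; the resulting force discontinuity at the crossing
    is accepted and interpolated over by the simulator.
    """

    kind: str                     # "angle" | "dihedral"
    x: np.ndarray                 # radians, ascending, uniform spacing
    energy: np.ndarray
    minus_derivative: np.ndarray

    @property
    def periodic(self) -> bool:
        return self.kind == "dihedral"

    def _wrap(self, value: np.ndarray) -> np.ndarray:
        if self.periodic:
            return geometry.wrap_angle(value)
        return np.clip(value, self.x[0], self.x[-1])

    def _hermite(self, value):
        """Cubic Hermite interpolation using the stored derivatives.

        Energy and force are derivatives of the same piecewise polynomial,
        so the evaluated force is exactly consistent with the evaluated
        energy (the way simulation engines consume such tables).
        """
        v = np.atleast_1d(self._wrap(value))
        dx = self.x[1] - self.x[0]
        k = np.clip(((v - self.x[0]) / dx).astype(int), 0, self.x.size - 2)
        t = (v - self.x[k]) / dx
        e0, e1 = self.energy[k], self.energy[k + 1]
        d0, d1 = -self.minus_derivative[k] * dx, -self.minus_derivative[k + 1] * dx
        h00 = 2 * t ** 3 - 3 * t ** 2 + 1
        h10 = t ** 3 - 2 * t ** 2 + t
        h01 = -2 * t ** 3 + 3 * t ** 2
        h11 = t ** 3 - t ** 2
        energy = h00 * e0 + h10 * d0 + h01 * e1 + h11 * d1
        dh00 = 6 * t ** 2 - 6 * t
        dh10 = 3 * t ** 2 - 4 * t + 1
        dh01 = -dh00
        dh11 = 3 * t ** 2 - 2 * t
        deriv = (dh00 * e0 + dh10 * d0 + dh01 * e1 + dh11 * d1) / dx
        return energy, deriv

    def evaluate(self, value):
        """Interpolated energy at *value* (radians)."""
        energy, _ = self._hermite(value)
        return energy if np.ndim(value) else float(energy[0])

    def derivative(self, value):
        """Interpolated dE/dx at *value* (consistent with :meth:`evaluate`)."""
        _, deriv = self._hermite(value)
        return deriv if np.ndim(value) else float(deriv[0])


def build_min_table(
    kind: str,
    equilibria: list[float],
    params: ForceFieldParams | None = None,
    n_points: int | None = None,
) -> TabulatedPotential:
    """Pointwise minimum over per-conformer potentials on a dense grid.

    For angles the per-conformer branches are harmonic wells on [0, pi];
    for dihedrals periodic two-multiplicity wells on (-pi, pi]. The table
    energy at every grid point is exactly ``min_m V_m(x)`` and the
    derivative is taken from the branch achieving the minimum.
    """
    if kind not in ("angle", "dihedral"):
        raise ValueError(f"unknown term kind {kind!r}")
    if len(equilibria) < 2:
        raise ValueError("a minimum table needs at least two conformer values")
    params = params or ForceFieldParams()
    if n_points is None:
        n_points = params.angle_table_points if kind == "angle" else params.dihedral_table_points
    if n_points < 100:
        raise ValueError("table grid too coarse: need at least 100 points")

    if kind == "angle":
        x = np.linspace(0.0, np.pi, n_points)
        branches = np.stack([_angle_potential(x, t0, params.k_angle) for t0 in equilibria])
        derivs = np.stack([_angle_derivative(x, t0, params.k_angle) for t0 in equilibria])
    else:
        x = np.linspace(-np.pi, np.pi, n_points + 1)
        branches = np.stack([
            _dihedral_potential(x, p0, params.k_dihedral_1, params.k_dihedral_3)
            for p0 in equilibria
        ])
        derivs = np.stack([
            _dihedral_derivative(x, p0, params.k_dihedral_1, params.k_dihedral_3)
            for p0 in equilibria
        ])
    active = np.argmin(branches, axis=0)
    cols = np.arange(x.size)
    return TabulatedPotential(
        kind=kind,
        x=x,
        energy=branches[active, cols],
        minus_derivative=-derivs[active, cols],
    )


@dataclass
class MultiConfTerm:
    """One angle or dihedral with per-conformer equilibrium values.

    With a single conformer the term stays analytic (``table is None``);
    with several it carries the tabulated-minimum combined potential.
    """

    kind: str                       # "angle" | "dihedral"
    idx: tuple[int, ...]            # local residue indices within the type
    equilibria: list[float]         # one per conformer, radians
    table: TabulatedPotential | None = None

    @property
    def is_tabulated(self) -> bool:
        return self.table is not None


@dataclass
class MergedChainType:
    """One molecule type: all chains sharing an exact sequence.

    ``member_chains`` are the chain indices (within each model) of the
    copies; ``conformers`` groups the (model, chain) coordinate sets into
    RMSD clusters. Bonded terms and native pairs live in local residue
    indices (0 .. len(sequence) - 1).
    """

    type_id: int
    sequence: str
    member_chains: list[int]
    #: conformer clusters: each a list of (model_id, chain_index)
    conformers: list[list[tuple[int, int]]]
    #: representative Calpha coordinates, one (n_res, 3) array per conformer
    conformer_coords: list[np.ndarray] = field(default_factory=list)

    # merged topology (filled by merge_intra_topology)
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[MultiConfTerm] = field(default_factory=list)
    dihedrals: list[MultiConfTerm] = field(default_factory=list)
    suppressed_dihedrals: list[tuple[tuple[int, ...], str]] = field(default_factory=list)
    #: intra native pairs: (res_i, res_j, r0, epsilon_scale)
    intra_pairs: list[tuple[int, int, float, float]] = field(default_factory=list)
    k_angle: float = 0.0
    k_dihedral_1: float = 0.0
    k_dihedral_3: float = 0.0

    @property
    def n_copies(self) -> int:
        return len(self.member_chains)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)


def _check_consistent_models(conformations: list[Conformation]) -> None:
    ref = conformations[0].sequences
    for conf in conformations[1:]:
        if conf.sequences != ref:
            raise ValueError(
                "all models must contain the same chains (same count, order "
                "and sequences); each model is one native conformation of "
                "the same system"
            )


def group_identical_chains(
    conformations: list[Conformation],
    rmsd_cutoff: float | None = None,
    params: ForceFieldParams | None = None,
) -> list[MergedChainType]:
    """Group chains into merged types and cluster their native conformers.

    Chains merge only on exact sequence equality (gapped or modified chains
    never merge). Within a type, all (model, chain) coordinate sets whose
    pairwise superposed Calpha RMSD is within the cutoff share a conformer
    (single-linkage); sets beyond the cutoff become additional conformers,
    i.e. additional minima of the type's force field.
    """
    params = params or ForceFieldParams()
    cutoff = params.rmsd_cutoff if rmsd_cutoff is None else rmsd_cutoff
    _check_consistent_models(conformations)

    sequences = conformations[0].sequences
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for c, seq in enumerate(sequences):
        if seq not in members:
            members[seq] = []
            order.append(seq)
        members[seq].append(c)

    types = []
    for type_id, seq in enumerate(order):
        chains = members[seq]
        items = [(conf.model_id, c) for conf in conformations for c in chains]
        coords = {
            (conf.model_id, c): conf.chains[c].ca_coords
            for conf in conformations for c in chains
        }
        # single-linkage clustering by superposed RMSD
        clusters: list[list[tuple[int, int]]] = []
        for item in items:
            hit = None
            for cluster in clusters:
                if any(
                    geometry.superposed_rmsd(coords[item], coords[other]) <= cutoff
                    for other in cluster
                ):
                    if hit is None:
                        hit = cluster
                    else:  # single linkage: item bridges two clusters
                        hit.extend(cluster)
                        clusters.remove(cluster)
            if hit is None:
                clusters.append([item])
            else:
                hit.append(item)
        types.append(MergedChainType(
            type_id=type_id,
            sequence=seq,
            member_chains=chains,
            conformers=clusters,
            conformer_coords=[coords[cluster[0]] for cluster in clusters],
        ))
    return types


def _single_chain_conformation(conf_chain: Chain, model_id: int) -> Conformation:
    return Conformation(model_id=model_id, chains=[Chain(conf_chain.chain_id, conf_chain.residues)])


def _sorted_mean(values: list[float]) -> float:
    # order-independent averaging keeps merged output bit-identical under
    # permutations of the member chains
    return float(np.mean(np.sort(np.asarray(values))))


def _circular_mean(values: list[float]) -> float:
    values = np.sort(np.asarray(values))
    return float(np.arctan2(np.mean(np.sin(values)), np.mean(np.cos(values))))


def merge_intra_topology(
    chain_type: MergedChainType,
    conformations: list[Conformation],
    params: ForceFieldParams | None = None,
) -> MergedChainType:
    """Fill a merged type with averaged bonded terms and native intra pairs.

    Per conformer, equilibrium values are averaged over the member chains
    and the native-pair set is the union over members (r0 averaged over the
    members that share a pair). Across conformers, bond lengths come from
    the first conformer, angle/dihedral terms become multi-minimum tabulated
    terms, and native pairs are the union over conformers with duplicate r0
    values averaged. A dihedral suppressed (near-straight flanking angle) in
    any member is suppressed in the merged topology.
    """
    params = params or ForceFieldParams()
    by_model = {conf.model_id: conf for conf in conformations}
    chain_type.k_angle = params.k_angle
    chain_type.k_dihedral_1 = params.k_dihedral_1
    chain_type.k_dihedral_3 = params.k_dihedral_3

    per_conformer = []
    for cluster in chain_type.conformers:
        bonds: dict[tuple, list[float]] = {}
        angles: dict[tuple, list[float]] = {}
        dihedrals: dict[tuple, list[float]] = {}
        suppressed: dict[tuple, str] = {}
        pair_r0: dict[tuple, list[float]] = {}
        for model_id, chain_index in cluster:
            chain = by_model[model_id].chains[chain_index]
            sub = _single_chain_conformation(chain, model_id)
            terms = build_bonded_terms(build_beads(sub), params)
            for i, j, b0, _k in terms.bonds:
                bonds.setdefault((i, j), []).append(b0)
            for i, j, k, theta0, _k in terms.angles:
                angles.setdefault((i, j, k), []).append(theta0)
            for i, j, k, l, phi0, _k1, _k3 in terms.dihedrals:
                dihedrals.setdefault((i, j, k, l), []).append(phi0)
            for quad, reason in terms.suppressed_dihedrals:
                suppressed[quad] = reason
            for pair in detect_native_pairs(sub, params):
                pair_r0.setdefault((pair.res_i, pair.res_j), []).append(pair.r0)
        if len({len(by_model[m].chains[c].residues) for m, c in cluster}) > 1:
            raise ValueError("cannot merge member chains of different lengths")
        per_conformer.append({
            "bonds": {k: _sorted_mean(v) for k, v in bonds.items()},
            "angles": {k: _sorted_mean(v) for k, v in angles.items()},
            "dihedrals": {k: _circular_mean(v) for k, v in dihedrals.items()},
            "suppressed": suppressed,
            "pairs": {k: _sorted_mean(v) for k, v in pair_r0.items()},
        })

    multi = len(per_conformer) > 1
    first = per_conformer[0]

    # bond lengths are assumed conformation-independent: first conformer
    chain_type.bonds = [
        (i, j, first["bonds"][(i, j)], params.k_bond) for (i, j) in sorted(first["bonds"])
    ]

    chain_type.angles = []
    for key in sorted(first["angles"]):
        eq = [conf["angles"][key] for conf in per_conformer]
        table = build_min_table("angle", eq, params) if multi else None
        chain_type.angles.append(MultiConfTerm("angle", key, eq, table))

    suppressed_all: dict[tuple, str] = {}
    for conf in per_conformer:
        suppressed_all.update(conf["suppressed"])
    chain_type.suppressed_dihedrals = sorted(suppressed_all.items())
    chain_type.dihedrals = []
    for key in sorted(first["dihedrals"]):
        if key in suppressed_all:
            continue
        if any(key not in conf["dihedrals"] for conf in per_conformer):
            # suppressed in some conformer: drop everywhere
            chain_type.suppressed_dihedrals.append(
                (key, "suppressed in at least one conformer"))
            continue
        eq = [conf["dihedrals"][key] for conf in per_conformer]
        table = build_min_table("dihedral", eq, params) if multi else None
        chain_type.dihedrals.append(MultiConfTerm("dihedral", key, eq, table))
    chain_type.suppressed_dihedrals.sort()

    # native pairs: union over conformers, duplicates averaged
    merged_pairs: dict[tuple, list[float]] = {}
    for conf in per_conformer:
        for key, r0 in conf["pairs"].items():
            merged_pairs.setdefault(key, []).append(r0)
    chain_type.intra_pairs = [
        (i, j, _sorted_mean(merged_pairs[(i, j)]), 1.0)
        for (i, j) in sorted(merged_pairs)
    ]
    return chain_type
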