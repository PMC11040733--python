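"""Synthetic structures and trajectories with known ground truth.

Everything the test-suite and the acceptance checks need is generated here
programmatically: idealized alpha-helical chains with a small all-atom-like
backbone (N, CA, C, O, CB), Cn-symmetric ring complexes with engineered
inter-chain contacts, stacked double rings, two-conformation chains, and
schematic binding trajectories. Generation is deterministic given a seed,
and every structure passes the package's own validation.

These fixtures emulate the geometric features contact detection and
topology merging rely on (atom-level packing, exact symmetry, identical
sequences); they make no claim to full physical realism.
"""
from __future__ import annotations

import numpy as np

from .constants import ONE_TO_THREE
from .structure_io import AtomRecord, Chain, Conformation, Residue

__all__ = [
    "make_helix_chain", "make_hairpin_chain", "make_cn_ring", "make_stacked_rings",
    "make_two_state_chain", "make_heterodimer", "make_single_contact_dimer",
    "make_binding_trajectory", "conformation_from_ca",
]

# idealized alpha-helix parameters
_HELIX_RADIUS = 2.3        # A, Calpha distance from the helix axis
_HELIX_RISE = 1.5          # A per residue along the axis
_HELIX_TWIST = np.deg2rad(100.0)  # per residue

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _helix_point(t: float, radius: float = _HELIX_RADIUS) -> np.ndarray:
    """Point on the idealized helix at fractional residue position *t*."""
    return np.array([
        radius * np.cos(_HELIX_TWIST * t),
        radius * np.sin(_HELIX_TWIST * t),
        _HELIX_RISE * t,
    ])


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA_ALPHABET), size=n))


def _build_residue(i: int, name: str, with_hydrogens: bool) -> list[AtomRecord]:
    """Backbone + pseudo-sidechain atoms of residue *i* on the ideal helix."""
    ca = _helix_point(i)
    axis_dir = np.array([0.0, 0.0, 1.0])
    outward = ca - np.array([0.0, 0.0, ca[2]])
    outward /= np.linalg.norm(outward)
    n_at = _helix_point(i - 0.38, radius=1.65)
    c_at = _helix_point(i + 0.36, radius=1.65)
    o_at = c_at + 1.23 * (0.8 * outward + 0.6 * axis_dir) / np.linalg.norm(0.8 * outward + 0.6 * axis_dir)
    atoms = [
        AtomRecord("N", "N", n_at, i),
        AtomRecord("CA", "C", ca, i),
        AtomRecord("C", "C", c_at, i),
        AtomRecord("O", "O", o_at, i),
    ]
    if name != "GLY":
        atoms.append(AtomRecord("CB", "C", ca + 1.53 * outward, i))
    if with_hydrogens:
        atoms.append(AtomRecord("H", "H", n_at + 1.0 * outward, i))
        atoms.append(AtomRecord("HA", "H", ca + 1.09 * (outward + axis_dir) / np.sqrt(2.0), i))
    return atoms


def make_helix_chain(
    n_residues: int,
    seed: int = 0,
    chain_id: str = "A",
    sequence: str | None = None,
    with_hydrogens: bool = True,
    jitter: float = 0.0,
) -> Conformation:
    """One idealized alpha-helical chain as an all-atom-like conformation.

    Consecutive Calpha atoms are ~3.8 A apart; each residue carries
    N/CA/C/O plus a CB pseudo-sidechain (and two hydrogens by default).
    *jitter* adds seeded Gaussian noise (A) to every atom.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = _random_sequence(n_residues, rng)
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    residues = []
    for i, one in enumerate(sequence):
        name = ONE_TO_THREE[one]
        atoms = _build_residue(i, name, with_hydrogens)
        if jitter > 0:
            for atom in atoms:
                atom.coords = atom.coords + rng.normal(0.0, jitter, 3)
        residues.append(Residue(name=name, atoms=atoms, index=i))
    conf = Conformation(model_id=0, chains=[Chain(chain_id, residues)])
    conf.validate()
    return conf


def _hairpin_candidates(n_residues: int, seed: int, chain_id: str,
                        sequence: str | None) -> list[Conformation]:
    """Valid helix-turn-helix geometries, best (most contacts) first.

    A candidate is valid when every virtual bond stays in the 2.8-4.5 A
    range, Calpha pairs at sequence separation 2-3 stay sterically relaxed
    (>= 4.8 A, keeping the bead repulsion small at the native state), and at
    least three intramolecular contacts form between the two helices.
    """
    conf = make_helix_chain(n_residues, seed=seed, chain_id=chain_id, sequence=sequence)
    chain = conf.chains[0]
    h = n_residues // 2
    pivot = chain.residues[h].ca.coords.copy()
    flip = np.array([[1.0, 0, 0], [0, -1.0, 0], [0, 0, -1.0]])

    def assemble(alpha: float, shift: np.ndarray) -> Conformation:
        c, s = np.cos(alpha), np.sin(alpha)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]) @ flip
        residues = []
        for res in chain.residues:
            atoms = []
            for a in res.atoms:
                xyz = a.coords.copy()
                if res.index >= h:
                    xyz = rot @ (xyz - pivot) + pivot + shift
                atoms.append(AtomRecord(a.name, a.element, xyz, a.residue_index))
            residues.append(Residue(res.name, atoms, res.index))
        return Conformation(model_id=0, chains=[Chain(chain_id, residues)])

    from .contacts import detect_native_pairs

    seps = np.abs(np.arange(n_residues)[:, None] - np.arange(n_residues)[None, :])
    scored = []
    for alpha in np.linspace(0.0, 2.0 * np.pi, 16, endpoint=False):
        for sy in (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0):
            for sz in (-2.0, -1.0, 0.0, 1.0, 2.0):
                cand = assemble(alpha, np.array([6.0, sy, sz]))
                ca = cand.chains[0].ca_coords
                bonds = np.linalg.norm(np.diff(ca, axis=0), axis=1)
                if bonds.max() > 4.5 or bonds.min() < 2.8:
                    continue
                dists = np.linalg.norm(ca[:, None] - ca[None, :], axis=2)
                near = dists[(seps >= 2) & (seps < 4)]
                if near.min() < 4.8:
                    continue
                n_intra = sum(
                    1 for p in detect_native_pairs(cand)
                    if p.kind == "intra" and p.r0 >= 4.2
                )
                if n_intra < 3:
                    continue
                scored.append(((n_intra, float(near.min())), cand))
    if not scored:
        raise RuntimeError(f"no stable hairpin geometry found for {n_residues} residues")
    scored.sort(key=lambda item: item[0], reverse=True)
    return [cand for _score, cand in scored]


def make_hairpin_chain(
    n_residues: int = 16,
    seed: int = 0,
    chain_id: str = "A",
    sequence: str | None = None,
) -> Conformation:
    """A helix-turn-helix chain with intramolecular native contacts.

    The second half of an ideal helix is flipped antiparallel and packed
    against the first half; the junction placement comes from a small
    deterministic search (see :func:`_hairpin_candidates`), giving a
    foldable two-helix bundle at the coarse-grained level.
    """
    if n_residues < 10:
        raise ValueError("need at least 10 residues for a hairpin")
    best = _hairpin_candidates(n_residues, seed, chain_id, sequence)[0]
    best.validate()
    return best


def _chain_coords(chain: Chain) -> np.ndarray:
    return np.array([a.coords for r in chain.residues for a in r.atoms])


def _transform_chain(chain: Chain, rot: np.ndarray, shift: np.ndarray, chain_id: str) -> Chain:
    residues = []
    for res in chain.residues:
        atoms = [
            AtomRecord(a.name, a.element, rot @ a.coords + shift, a.residue_index)
            for a in res.atoms
        ]
        residues.append(Residue(res.name, atoms, res.index))
    return Chain(chain_id, residues)


def _rotz(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _min_interchain_distance(a: Chain, b: Chain) -> float:
    xa, xb = _chain_coords(a), _chain_coords(b)
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    return float(d.min())


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"


def make_cn_ring(
    n_copies: int,
    n_residues: int = 16,
    seed: int = 0,
    target_gap: float = 3.0,
    template_kind: str = "helix",
) -> Conformation:
    """Cn-symmetric ring of identical chains with adjacent contacts.

    The ring radius is solved (bisection) so that the minimum interatomic
    distance between adjacent copies equals *target_gap* (A), which is
    within the default van-der-Waals contact cutoff, guaranteeing engineered
    interface contacts while avoiding severe clashes. Symmetry is exact:
    copies are rigid rotations of one template chain about the z axis.
    ``template_kind="hairpin"`` uses a folded two-helix chain, giving ring
    subunits with intramolecular contacts as well.
    """
    if n_copies < 3:
        raise ValueError("a ring needs at least 3 copies")
    if template_kind == "helix":
        template = make_helix_chain(n_residues, seed=seed, chain_id="A").chains[0]
    elif template_kind == "hairpin":
        template = make_hairpin_chain(n_residues, seed=seed, chain_id="A").chains[0]
    else:
        raise ValueError(f"unknown template kind {template_kind!r}")
    # center template on its own axis-of-mass for clean placement
    center = _chain_coords(template).mean(axis=0)
    template = _transform_chain(template, np.eye(3), -center, "A")
    step = 2.0 * np.pi / n_copies

    def gap(radius: float) -> float:
        a = _transform_chain(template, np.eye(3), np.array([radius, 0, 0]), "A")
        b = _transform_chain(a, _rotz(step), np.zeros(3), "B")
        return _min_interchain_distance(a, b)

    lo, hi = 1.0, 200.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if gap(mid) < target_gap:
            lo = mid
        else:
            hi = mid
    radius = 0.5 * (lo + hi)

    base = _transform_chain(template, np.eye(3), np.array([radius, 0.0, 0.0]), "A")
    chains = [
        _transform_chain(base, _rotz(step * k), np.zeros(3), _CHAIN_IDS[k])
        for k in range(n_copies)
    ]
    conf = Conformation(model_id=0, chains=chains)
    conf.validate()
    return conf


def make_stacked_rings(
    n_per_ring: int = 3,
    n_residues: int = 16,
    seed: int = 0,
    target_gap: float = 3.0,
    stack_gap: float = 3.0,
) -> Conformation:
    """Two identical Cn rings stacked along z with engineered ring-ring contacts.

    Yields (at least) two interface classes: within-ring and between-ring.
    """
    ring = make_cn_ring(n_per_ring, n_residues, seed=seed, target_gap=target_gap)

    def gap(dz: float) -> float:
        moved = _transform_chain(ring.chains[0], np.eye(3), np.array([0.0, 0.0, dz]), "X")
        return min(_min_interchain_distance(c, moved) for c in ring.chains)

    zs = np.array([a.coords[2] for c in ring.chains for r in c.residues for a in r.atoms])
    lo, hi = 1.0, (zs.max() - zs.min()) + 50.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if gap(mid) < stack_gap:
            lo = mid
        else:
            hi = mid
    shift = np.array([0.0, 0.0, 0.5 * (lo + hi)])
    top = [
        _transform_chain(c, np.eye(3), shift, _CHAIN_IDS[n_per_ring + k])
        for k, c in enumerate(ring.chains)
    ]
    conf = Conformation(model_id=0, chains=ring.chains + top)
    conf.validate()
    return conf


def make_two_state_chain(
    n_residues: int = 16,
    seed: int = 0,
    min_rmsd: float = 2.0,
) -> list[Conformation]:
    """Two native conformations (models) of one chain with identical sequence.

    Both models are valid hairpin packings of the same sequence with
    superposed Calpha RMSD of at least *min_rmsd* A (well above the default
    conformer-merging cutoff), so topology building yields one merged type
    with two conformers and multi-minimum angle/dihedral potentials.
    """
    from .geometry import superposed_rmsd

    candidates = _hairpin_candidates(n_residues, seed, "A", None)
    conf0 = candidates[0]
    ca0 = conf0.chains[0].ca_coords
    for cand in candidates[1:]:
        if superposed_rmsd(cand.chains[0].ca_coords, ca0) >= min_rmsd:
            conf1 = Conformation(model_id=1, chains=cand.chains)
            conf0.validate()
            conf1.validate()
            return [conf0, conf1]
    raise RuntimeError("no sufficiently distinct second hairpin conformation found")


def make_heterodimer(
    n_a: int = 14,
    n_b: int = 14,
    seed: int = 0,
    target_gap: float = 3.0,
) -> Conformation:
    """Two different-sequence helical chains packed side by side."""
    a = make_helix_chain(n_a, seed=seed, chain_id="A").chains[0]
    b = make_helix_chain(n_b, seed=seed + 1, chain_id="B").chains[0]

    def gap(dist: float) -> float:
        moved = _transform_chain(b, np.eye(3), np.array([dist, 0, 0]), "B")
        return _min_interchain_distance(a, moved)

    lo, hi = 0.0, 100.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if gap(mid) < target_gap:
            lo = mid
        else:
            hi = mid
    b = _transform_chain(b, np.eye(3), np.array([0.5 * (lo + hi), 0.0, 0.0]), "B")
    conf = Conformation(model_id=0, chains=[a, b])
    conf.validate()
    return conf


def make_single_contact_dimer(seed: int = 0) -> Conformation:
    """Two well-separated chains with exactly one engineered atom clash.

    The CB atoms of residue 2 (chain A) and residue 3 (chain B) are moved
    to 2.9 A apart halfway between the chains; every other interatomic
    distance stays far beyond the contact cutoff, so contact detection must
    report exactly one intermolecular native pair.
    """
    a = make_helix_chain(8, seed=seed, chain_id="A", with_hydrogens=False).chains[0]
    b0 = make_helix_chain(8, seed=seed + 1, chain_id="B", with_hydrogens=False).chains[0]
    b = _transform_chain(b0, np.eye(3), np.array([40.0, 0.0, 0.0]), "B")
    mid = np.array([20.0, 0.0, 3.0])
    for res, offset in ((a.residues[2], -1.45), (b.residues[3], +1.45)):
        for atom in res.atoms:
            if atom.name == "CB":
                atom.coords = mid + np.array([offset, 0.0, 0.0])
    conf = Conformation(model_id=0, chains=[a, b])
    conf.validate()
    return conf


def conformation_from_ca(
    ca_per_chain: list[np.ndarray],
    model_id: int = 0,
    sequences: list[str] | None = None,
) -> Conformation:
    """Build a CA-only conformation from raw coordinates (testing helper)."""
    chains = []
    for c, coords in enumerate(ca_per_chain):
        coords = np.asarray(coords, dtype=float)
        seq = sequences[c] if sequences else "A" * len(coords)
        residues = [
            Residue(ONE_TO_THREE[seq[i]], [AtomRecord("CA", "C", coords[i], i)], i)
            for i in range(len(coords))
        ]
        chains.append(Chain(_CHAIN_IDS[c], residues))
    conf = Conformation(model_id=model_id, chains=chains)
    conf.validate()
    return conf


def make_binding_trajectory(
    n_frames: int,
    bind_frame: int | None,
    seed: int = 0,
    n_residues: int = 5,
    unbound_distance: float = 60.0,
    bound_distance: float = 12.0,
):
    """Schematic two-chain trajectory with a known binding frame.

    Both chains random-walk independently; from *bind_frame* on, chain B
    co-moves rigidly with chain A at a fixed *bound_distance* offset (plus
    small seeded noise). ``bind_frame=None`` produces a never-binding
    trajectory. Returns ``(trajectory, chain_slices)`` with trajectory of
    shape (n_frames, 2 * n_residues, 3) in Angstrom.
    """
    if bind_frame is not None and not 0 < bind_frame < n_frames:
        raise ValueError("bind_frame must lie strictly inside the trajectory")
    rng = np.random.default_rng(seed)
    body = np.stack([_helix_point(i) for i in range(n_residues)])
    body -= body.mean(axis=0)
    frames = np.zeros((n_frames, 2 * n_residues, 3))
    pos_a = np.zeros(3)
    pos_b = np.array([unbound_distance, 0.0, 0.0])
    offset = np.array([bound_distance, 0.0, 0.0])
    for f in range(n_frames):
        pos_a = pos_a + rng.normal(0.0, 0.6, 3)
        if bind_frame is not None and f >= bind_frame:
            pos_b = pos_a + offset + rng.normal(0.0, 0.05, 3)
        else:
            pos_b = pos_b + rng.normal(0.0, 0.6, 3)
        frames[f, :n_residues] = body + pos_a
        frames[f, n_residues:] = body + pos_b
    chain_slices = [slice(0, n_residues), slice(n_residues, 2 * n_residues)]
    return frames, chain_slices
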