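"""Reference energy/force evaluation and a minimal Langevin integrator.

The evaluator computes every term of the coarse-grained potential exactly
(tabulated multi-minimum terms via linear interpolation on their grid) and
returns a per-term breakdown. Forces are analytic and are cross-checked
against finite differences in the test-suite.

The integrator is a BAOAB-splitting Langevin scheme with uniform bead mass;
it exists to make the generated force fields testable end to end (folding
and binding smoke tests) without an external simulation engine — it makes
no attempt to compete with one. With friction zero it reduces exactly to
velocity Verlet, which the energy-conservation test exploits.

Units: distances A, energies eps, temperature kappa (kT = KB * T), time tau.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import KB
from .topology import ExpandedSystem

__all__ = ["EnergyBreakdown", "evaluate_energy", "evaluate_forces", "run_langevin"]

# beyond this multiple of sigma the r^-12 repulsion is negligible
_REPULSION_CUTOFF_FACTOR = 3.0


@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    native_intra: float = 0.0
    native_inter: float = 0.0
    repulsive: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.dihedral
                + self.native_intra + self.native_inter + self.repulsive)


def _minimum_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)



def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # manual cross product: avoids np.cross's axis-normalization overhead
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out

def _bond_terms(coords, sys_, box, forces):
    if sys_.bond_idx.size == 0:
        return 0.0
    i, j = sys_.bond_idx[:, 0], sys_.bond_idx[:, 1]
    d = _minimum_image(coords[j] - coords[i], box)
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    dr = r - sys_.bond_b0
    energy = float(np.sum(sys_.bond_k * dr ** 2))
    if forces is not None:
        f = (2.0 * sys_.bond_k * dr / r)[:, None] * d   # dV/dr * dhat on i
        np.add.at(forces, i, f)
        np.add.at(forces, j, -f)
    return energy


def _angle_geometry(coords, idx, box):
    u = _minimum_image(coords[idx[:, 0]] - coords[idx[:, 1]], box)
    v = _minimum_image(coords[idx[:, 2]] - coords[idx[:, 1]], box)
    nu = np.sqrt(np.einsum("ij,ij->i", u, u))
    nv = np.sqrt(np.einsum("ij,ij->i", v, v))
    cos_t = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(cos_t)
    return u, v, nu, nv, cos_t, theta


def _apply_angle_forces(forces, idx, u, v, nu, nv, cos_t, theta, dV_dtheta):
    sin_t = np.maximum(np.sqrt(1.0 - cos_t ** 2), 1e-8)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    dtheta_di = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
    dtheta_dk = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
    fi = -dV_dtheta[:, None] * dtheta_di
    fk = -dV_dtheta[:, None] * dtheta_dk
    np.add.at(forces, idx[:, 0], fi)
    np.add.at(forces, idx[:, 2], fk)
    np.add.at(forces, idx[:, 1], -(fi + fk))


def _angle_terms(coords, sys_, box, forces):
    energy = 0.0
    if sys_.angle_idx.size:
        u, v, nu, nv, cos_t, theta = _angle_geometry(coords, sys_.angle_idx, box)
        dt = theta - sys_.angle_theta0
        energy += float(np.sum(sys_.angle_k * dt ** 2))
        if forces is not None:
            _apply_angle_forces(forces, sys_.angle_idx, u, v, nu, nv, cos_t,
                                theta, 2.0 * sys_.angle_k * dt)
    if sys_.tab_angle_idx.size:
        u, v, nu, nv, cos_t, theta = _angle_geometry(coords, sys_.tab_angle_idx, box)
        values = np.array([t.evaluate(th) for t, th in zip(sys_.tab_angle_tables, theta)])
        energy += float(np.sum(values))
        if forces is not None:
            dV = np.array([t.derivative(th) for t, th in zip(sys_.tab_angle_tables, theta)])
            _apply_angle_forces(forces, sys_.tab_angle_idx, u, v, nu, nv, cos_t, theta, dV)
    return energy


def _dihedral_geometry(coords, idx, box):
    b1 = _minimum_image(coords[idx[:, 1]] - coords[idx[:, 0]], box)
    b2 = _minimum_image(coords[idx[:, 2]] - coords[idx[:, 1]], box)
    b3 = _minimum_image(coords[idx[:, 3]] - coords[idx[:, 2]], box)
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    nb2 = np.sqrt(np.einsum("ij,ij->i", b2, b2))
    m1 = _cross(n1, b2 / nb2[:, None])
    phi = np.arctan2(np.einsum("ij,ij->i", m1, n2), np.einsum("ij,ij->i", n1, n2))
    return b1, b2, b3, n1, n2, nb2, phi


def _apply_dihedral_forces(forces, idx, b1, b2, b3, n1, n2, nb2, dV_dphi):
    sq1 = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-12)
    sq2 = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-12)
    dphi_di = (nb2 / sq1)[:, None] * n1
    dphi_dl = -(nb2 / sq2)[:, None] * n2
    s12 = (np.einsum("ij,ij->i", b1, b2) / nb2 ** 2)[:, None]
    s32 = (np.einsum("ij,ij->i", b3, b2) / nb2 ** 2)[:, None]
    dphi_dj = -(1.0 + s12) * dphi_di + s32 * dphi_dl
    dphi_dk = s12 * dphi_di - (1.0 + s32) * dphi_dl
    g = -dV_dphi[:, None]
    np.add.at(forces, idx[:, 0], g * dphi_di)
    np.add.at(forces, idx[:, 1], g * dphi_dj)
    np.add.at(forces, idx[:, 2], g * dphi_dk)
    np.add.at(forces, idx[:, 3], g * dphi_dl)


def _dihedral_terms(coords, sys_, box, forces):
    energy = 0.0
    if sys_.dihedral_idx.size:
        b1, b2, b3, n1, n2, nb2, phi = _dihedral_geometry(coords, sys_.dihedral_idx, box)
        d = phi - sys_.dihedral_phi0
        energy += float(np.sum(
            sys_.dihedral_k1 * (1.0 - np.cos(d))
            + sys_.dihedral_k3 * (1.0 - np.cos(3.0 * d))
        ))
        if forces is not None:
            dV = sys_.dihedral_k1 * np.sin(d) + 3.0 * sys_.dihedral_k3 * np.sin(3.0 * d)
            _apply_dihedral_forces(forces, sys_.dihedral_idx, b1, b2, b3, n1, n2, nb2, dV)
    if sys_.tab_dihedral_idx.size:
        b1, b2, b3, n1, n2, nb2, phi = _dihedral_geometry(coords, sys_.tab_dihedral_idx, box)
        values = np.array([t.evaluate(p) for t, p in zip(sys_.tab_dihedral_tables, phi)])
        energy += float(np.sum(values))
        if forces is not None:
            dV = np.array([t.derivative(p) for t, p in zip(sys_.tab_dihedral_tables, phi)])
            _apply_dihedral_forces(forces, sys_.tab_dihedral_idx, b1, b2, b3, n1, n2, nb2, dV)
    return energy


def _lj_pairs(coords, idx, r0, eps, box, forces):
    """12-6 Lennard-Jones with minimum -eps at r0: eps[(r0/r)^12 - 2(r0/r)^6]."""
    if idx.size == 0:
        return 0.0
    i, j = idx[:, 0], idx[:, 1]
    d = _minimum_image(coords[j] - coords[i], box)
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    s6 = (r0 / r) ** 6
    energy = float(np.sum(eps * (s6 ** 2 - 2.0 * s6)))
    if forces is not None:
        dV_dr = -12.0 * eps * (s6 ** 2 - s6) / r
        f = (dV_dr / r)[:, None] * d
        np.add.at(forces, i, f)
        np.add.at(forces, j, -f)
    return energy


def _repulsion(coords, sys_, box, forces):
    """Pure r^-12 repulsion between all non-excluded, non-native pairs.

    Energy-shifted at the cutoff so truncation keeps the dynamics
    conservative; the shift (~(1/3)^12 eps) is negligible.
    """
    sigma = sys_.sigma_repulsive
    cutoff = _REPULSION_CUTOFF_FACTOR * sigma
    n = sys_.n_beads
    if box is not None and np.any(cutoff >= box / 2.0):
        raise ValueError("repulsion cutoff exceeds half the box length")
    if n <= 400:
        # static candidate list: all non-excluded pairs, cached on the system
        cached = getattr(sys_, "_rep_candidates", None)
        if cached is None:
            ii, jj = np.triu_indices(n, k=1)
            keep = np.fromiter(
                ((int(a), int(b)) not in sys_.exclusions for a, b in zip(ii, jj)),
                dtype=bool, count=ii.size,
            )
            cached = (ii[keep], jj[keep])
            sys_._rep_candidates = cached
        ii, jj = cached
        d = _minimum_image(coords[jj] - coords[ii], box)
        r2 = np.einsum("ij,ij->i", d, d)
        keep = r2 <= cutoff ** 2
        ii, jj, d, r2 = ii[keep], jj[keep], d[keep], r2[keep]
    else:
        if box is not None:
            tree = cKDTree(np.mod(coords, box), boxsize=box)
        else:
            tree = cKDTree(coords)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        ii = np.minimum(pairs[:, 0], pairs[:, 1])
        jj = np.maximum(pairs[:, 0], pairs[:, 1])
        if ii.size:
            excluded = np.fromiter(
                ((int(a), int(b)) in sys_.exclusions for a, b in zip(ii, jj)),
                dtype=bool, count=ii.size,
            )
            ii, jj = ii[~excluded], jj[~excluded]
        d = _minimum_image(coords[jj] - coords[ii], box)
        r2 = np.einsum("ij,ij->i", d, d)
    if ii.size == 0:
        return 0.0
    inv12 = (sigma ** 2 / r2) ** 6
    shift = (1.0 / _REPULSION_CUTOFF_FACTOR) ** 12
    energy = float(sys_.epsilon_repulsive * np.sum(inv12 - shift))
    if forces is not None:
        dV_dr_over_r = -12.0 * sys_.epsilon_repulsive * inv12 / r2
        f = dV_dr_over_r[:, None] * d
        np.add.at(forces, ii, f)
        np.add.at(forces, jj, -f)
    return energy


def evaluate_energy(
    coords: np.ndarray,
    system: ExpandedSystem,
    box: np.ndarray | None = None,
    forces: np.ndarray | None = None,
) -> EnergyBreakdown:
    """Exact single-point energy (and optionally forces) of the potential.

    Parameters
    ----------
    coords
        (n_beads, 3) positions in A.
    box
        Optional orthorhombic box lengths (3,) in A; enables the minimum
        image convention.
    forces
        If given, an (n_beads, 3) array accumulated in place (must be zeroed
        by the caller).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (system.n_beads, 3):
        raise ValueError(
            f"coordinate shape {coords.shape} does not match bead count {system.n_beads}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    if box is not None:
        box = np.asarray(box, dtype=float)

    return EnergyBreakdown(
        bond=_bond_terms(coords, system, box, forces),
        angle=_angle_terms(coords, system, box, forces),
        dihedral=_dihedral_terms(coords, system, box, forces),
        native_intra=_lj_pairs(coords, system.intra_idx, system.intra_r0,
                               system.intra_eps, box, forces),
        native_inter=_lj_pairs(coords, system.inter_idx, system.inter_r0,
                               system.inter_eps, box, forces),
        repulsive=_repulsion(coords, system, box, forces),
    )


def evaluate_forces(coords: np.ndarray, system: ExpandedSystem,
                    box: np.ndarray | None = None) -> np.ndarray:
    forces = np.zeros((system.n_beads, 3))
    evaluate_energy(coords, system, box=box, forces=forces)
    return forces


def run_langevin(
    coords: np.ndarray,
    system: ExpandedSystem,
    temperature: float,
    n_steps: int,
    dt: float = 0.002,
    seed: int = 0,
    friction: float = 1.0,
    box: np.ndarray | None = None,
    save_every: int = 100,
    mass: float = 1.0,
):
    """BAOAB Langevin dynamics; returns (frames, times, energies).

    *temperature* is in kappa (kT = KB * T eps); *friction* in 1/tau. With
    ``friction=0`` the scheme is plain velocity Verlet (NVE). Frames are
    stored every *save_every* steps, including the initial one; *energies*
    are total (potential + kinetic) at the stored frames.

    Raises
    ------
    FloatingPointError
        If coordinates diverge — typically a too-long time step; reduce dt.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(coords, dtype=float).copy()
    if box is not None:
        box = np.asarray(box, dtype=float)
    kT = KB * temperature
    v = (rng.normal(0.0, np.sqrt(kT / mass), x.shape)
         if temperature > 0 else np.zeros_like(x))
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(max(0.0, (1.0 - c1 ** 2)) * kT / mass)

    def kinetic():
        return 0.5 * mass * float(np.sum(v ** 2))

    forces = np.zeros_like(x)
    potential = evaluate_energy(x, system, box=box, forces=forces).total
    frames = [x.copy()]
    times = [0.0]
    energies = [potential + kinetic()]

    for step in range(1, n_steps + 1):
        v += 0.5 * dt * forces / mass
        x += 0.5 * dt * v
        if friction > 0.0:
            v = c1 * v + c2 * rng.normal(size=x.shape)
        x += 0.5 * dt * v
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > 1e7):
            raise FloatingPointError(
                f"simulation diverged at step {step}; reduce the time step")
        forces[:] = 0.0
        potential = evaluate_energy(x, system, box=box, forces=forces).total
        v += 0.5 * dt * forces / mass
        if step % save_every == 0:
            frames.append(x.copy())
            times.append(step * dt)
            energies.append(potential + kinetic())
    return np.array(frames), np.array(times), np.array(energies)
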