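import dataclasses

import numpy as np
import pytest

from asmgo import (ForceFieldParams, build_topology, evaluate_energy,
                   evaluate_forces, fixtures, run_langevin)
from asmgo.topology import ExpandedSystem


def _empty_system(n, sigma=3.5):
    z2 = np.zeros((0, 2), int)
    return ExpandedSystem(
        n_beads=n,
        bond_idx=z2, bond_b0=np.zeros(0), bond_k=np.zeros(0),
        angle_idx=np.zeros((0, 3), int), angle_theta0=np.zeros(0), angle_k=np.zeros(0),
        dihedral_idx=np.zeros((0, 4), int), dihedral_phi0=np.zeros(0),
        dihedral_k1=np.zeros(0), dihedral_k3=np.zeros(0),
        tab_angle_idx=np.zeros((0, 3), int), tab_angle_tables=[],
        tab_dihedral_idx=np.zeros((0, 4), int), tab_dihedral_tables=[],
        intra_idx=z2, intra_r0=np.zeros(0), intra_eps=np.zeros(0),
        inter_idx=z2, inter_r0=np.zeros(0), inter_eps=np.zeros(0),
        sigma_repulsive=sigma, epsilon_repulsive=1.0,
        exclusions=set(), chain_of_bead=np.zeros(n, int),
    )


def test_native_state_energies(hairpin_topology):
    """At the native conformation every bonded term is exactly at its
    equilibrium and every native pair sits at its minimum -eps."""
    sys_ = hairpin_topology.expand()
    bd = evaluate_energy(hairpin_topology.native_coords, sys_)
    assert bd.bond == pytest.approx(0.0, abs=1e-18)
    assert bd.angle == pytest.approx(0.0, abs=1e-18)
    assert bd.dihedral == pytest.approx(0.0, abs=1e-18)
    assert bd.native_intra == pytest.approx(-float(np.sum(sys_.intra_eps)), rel=1e-12)
    assert bd.total == pytest.approx(
        bd.bond + bd.angle + bd.dihedral + bd.native_intra
        + bd.native_inter + bd.repulsive, rel=1e-9)


def test_isolated_native_pair_depth():
    sys_ = _empty_system(2)
    sys_ = dataclasses.replace(
        sys_, intra_idx=np.array([[0, 1]]), intra_r0=np.array([6.0]),
        intra_eps=np.array([1.0]), exclusions={(0, 1)})
    at_min = evaluate_energy(np.array([[0.0, 0, 0], [6.0, 0, 0]]), sys_)
    assert at_min.native_intra == pytest.approx(-1.0, rel=1e-12)
    far = evaluate_energy(np.array([[0.0, 0, 0], [600.0, 0, 0]]), sys_)
    assert far.native_intra == pytest.approx(0.0, abs=1e-9)


def test_repulsion_positive_and_vanishing():
    sys_ = _empty_system(2)
    near = evaluate_energy(np.array([[0.0, 0, 0], [3.0, 0, 0]]), sys_)
    assert near.repulsive > 0.1
    far = evaluate_energy(np.array([[0.0, 0, 0], [40.0, 0, 0]]), sys_)
    assert far.repulsive == 0.0


@pytest.mark.parametrize("fixture_name", ["ring5", "hairpin", "two_state"])
def test_forces_match_finite_differences(fixture_name, request):
    """Analytic forces agree with central differences to 1e-5 eps/A on
    randomly perturbed coordinates (all term classes exercised)."""
    conf = request.getfixturevalue(fixture_name)
    confs = conf if isinstance(conf, list) else [conf]
    top = build_topology(confs)
    sys_ = top.expand()
    rng = np.random.default_rng(0)
    x = top.native_coords + rng.normal(0, 0.3, (top.n_beads, 3))
    f = evaluate_forces(x, sys_)
    h = 1e-5
    for _ in range(40):
        i, d = rng.integers(0, top.n_beads), rng.integers(0, 3)
        xp, xm = x.copy(), x.copy()
        xp[i, d] += h
        xm[i, d] -= h
        numeric = -(evaluate_energy(xp, sys_).total
                    - evaluate_energy(xm, sys_).total) / (2 * h)
        assert f[i, d] == pytest.approx(numeric, abs=1e-5)


def test_native_is_local_minimum(hairpin_topology):
    """Random 0.01 A perturbations never lower the total energy."""
    sys_ = hairpin_topology.expand()
    e0 = evaluate_energy(hairpin_topology.native_coords, sys_).total
    for seed in range(30):
        x = hairpin_topology.native_coords + \
            np.random.default_rng(seed).normal(0, 0.01, (hairpin_topology.n_beads, 3))
        assert evaluate_energy(x, sys_).total >= e0


def test_zero_temperature_relaxation_stays_at_native(hairpin_topology):
    """At T = 0 the native state is (numerically) stationary: energy does
    not increase and beads barely move."""
    sys_ = hairpin_topology.expand()
    frames, _, energies = run_langevin(
        hairpin_topology.native_coords, sys_, temperature=0.0,
        n_steps=2000, dt=0.002, seed=1, friction=1.0)
    assert energies[-1] <= energies[0] + 1e-9
    assert np.abs(frames[-1] - hairpin_topology.native_coords).max() < 0.1


def test_nve_energy_conservation(heterodimer):
    """With friction and noise off the integrator is velocity Verlet; total
    energy drifts by less than 1e-4 eps over 10^4 steps."""
    top = build_topology(heterodimer)
    sys_ = top.expand()
    # thermalize briefly, then run NVE
    frames, _, _ = run_langevin(top.native_coords, sys_, temperature=30.0,
                                n_steps=500, dt=0.002, seed=2, friction=1.0)
    _, _, energies = run_langevin(frames[-1], sys_, temperature=30.0,
                                  n_steps=10000, dt=0.0005, seed=3,
                                  friction=0.0, save_every=500)
    assert np.max(np.abs(energies - energies[0])) < 1e-4


def test_high_temperature_unfolds_hairpin(hairpin_topology):
    """Strong thermal noise melts the fold: the intramolecular fraction of
    native contacts collapses."""
    from asmgo.analysis import q_fraction
    sys_ = hairpin_topology.expand()
    frames, _, _ = run_langevin(hairpin_topology.native_coords, sys_,
                                temperature=200.0, n_steps=20000, dt=0.002,
                                seed=4, friction=1.0, save_every=5000)
    assert q_fraction(frames[-1], sys_.intra_idx, sys_.intra_r0) < 0.3


def test_input_validation(hairpin_topology):
    sys_ = hairpin_topology.expand()
    with pytest.raises(ValueError, match="does not match"):
        evaluate_energy(np.zeros((3, 3)), sys_)
    bad = hairpin_topology.native_coords.copy()
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        evaluate_energy(bad, sys_)


def test_divergence_raises(hairpin_topology):
    sys_ = hairpin_topology.expand()
    with pytest.raises(FloatingPointError, match="time step"):
        run_langevin(hairpin_topology.native_coords, sys_, temperature=50.0,
                     n_steps=5000, dt=0.5, seed=5, friction=0.1)


def test_minimum_image_convention(hairpin_topology):
    """Shifting a configuration by a box vector leaves the energy unchanged
    when a box is given."""
    sys_ = hairpin_topology.expand()
    box = np.array([80.0, 80.0, 80.0])
    x = hairpin_topology.native_coords + 30.0
    e0 = evaluate_energy(x, sys_, box=box)
    e1 = evaluate_energy(x + box, sys_, box=box)
    assert e1.total == pytest.approx(e0.total, rel=1e-12)
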