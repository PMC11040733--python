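import numpy as np
import pytest

from asmgo import (ForceFieldParams, build_min_table, build_topology, fixtures,
                   group_identical_chains, merge_intra_topology)
from asmgo.merging import _angle_potential, _dihedral_potential


def test_identical_ring_chains_one_type(ring3):
    types = group_identical_chains([ring3])
    assert len(types) == 1
    assert types[0].n_copies == 3
    assert types[0].n_conformers == 1


def test_two_state_one_type_two_conformers(two_state):
    types = group_identical_chains(two_state, rmsd_cutoff=1.5)
    assert len(types) == 1
    assert types[0].n_conformers == 2


def test_heterodimer_two_types(heterodimer):
    types = group_identical_chains([heterodimer])
    assert len(types) == 2
    assert all(t.n_copies == 1 for t in types)


def test_large_cutoff_collapses_conformers(two_state):
    types = group_identical_chains(two_state, rmsd_cutoff=100.0)
    assert types[0].n_conformers == 1


def test_merged_values_equal_members_for_identical_copies(ring3):
    """Averaging over exactly identical member chains reproduces each
    member's equilibrium values."""
    from asmgo import build_beads, build_bonded_terms, detect_native_pairs
    types = group_identical_chains([ring3])
    merged = merge_intra_topology(types[0], [ring3])
    from asmgo.structure_io import Conformation, Chain
    single = Conformation(0, [ring3.chains[0]])
    ref = build_bonded_terms(build_beads(single))
    assert len(merged.bonds) == len(ref.bonds)
    for (i, j, b0, _), (ri, rj, rb0, _) in zip(merged.bonds, ref.bonds):
        assert (i, j) == (ri, rj)
        assert b0 == pytest.approx(rb0, abs=1e-9)
    ref_pairs = {(p.res_i, p.res_j): p.r0 for p in detect_native_pairs(single)}
    assert {(i, j) for i, j, _, _ in merged.intra_pairs} == set(ref_pairs)
    for i, j, r0, _ in merged.intra_pairs:
        assert r0 == pytest.approx(ref_pairs[(i, j)], abs=1e-9)


def test_multiconf_union_of_native_pairs(two_state):
    """With two conformers the merged pair list is the union over the
    conformers' pair sets, duplicates averaged."""
    from asmgo import detect_native_pairs
    sets = []
    r0s = []
    for conf in two_state:
        pairs = {(p.res_i, p.res_j): p.r0 for p in detect_native_pairs(conf)}
        sets.append(set(pairs))
        r0s.append(pairs)
    types = group_identical_chains(two_state)
    merged = merge_intra_topology(types[0], two_state)
    merged_pairs = {(i, j): r0 for i, j, r0, _ in merged.intra_pairs}
    assert set(merged_pairs) == sets[0] | sets[1]
    for key, r0 in merged_pairs.items():
        values = [m[key] for m in r0s if key in m]
        assert r0 == pytest.approx(np.mean(values), abs=1e-9)


def test_mergeing_different_lengths_rejected():
    a = fixtures.make_helix_chain(8, seed=0, sequence="AAAAAAAA")
    b = fixtures.make_helix_chain(8, seed=1, sequence="AAAAAAAA")
    # same sequence, same length: merging fine
    from asmgo.structure_io import Conformation
    conf = Conformation(0, [a.chains[0], b.chains[0]])
    types = group_identical_chains([conf])
    assert len(types) == 1 and types[0].n_copies == 2


def test_min_table_identical_equilibria_matches_analytic(params):
    table = build_min_table("dihedral", [0.5, 0.5], params)
    expected = _dihedral_potential(table.x, 0.5, params.k_dihedral_1, params.k_dihedral_3)
    np.testing.assert_allclose(table.energy, expected, atol=1e-12)


def test_min_table_two_basins_zero_at_both_minima(params):
    phi_a, phi_b = np.deg2rad(-60.0), np.deg2rad(60.0)
    table = build_min_table("dihedral", [phi_a, phi_b], params)
    assert table.evaluate(phi_a) == pytest.approx(0.0, abs=1e-6)
    assert table.evaluate(phi_b) == pytest.approx(0.0, abs=1e-6)
    assert np.all(table.energy >= 0.0)


@pytest.mark.parametrize("kind,eq", [
    ("dihedral", [-1.1, 0.7]),
    ("dihedral", [-2.5, 0.3, 2.0]),
    ("angle", [1.0, 2.2]),
])
def test_min_table_pointwise_oracle(kind, eq, params):
    """At every grid point the table equals the minimum over branch
    potentials exactly, and never exceeds any single branch."""
    table = build_min_table(kind, eq, params)
    if kind == "angle":
        branches = np.stack([_angle_potential(table.x, e, params.k_angle) for e in eq])
    else:
        branches = np.stack([
            _dihedral_potential(table.x, e, params.k_dihedral_1, params.k_dihedral_3)
            for e in eq])
    np.testing.assert_array_equal(table.energy, branches.min(axis=0))
    assert np.all(table.energy <= branches + 1e-15)


def test_min_table_validation(params):
    with pytest.raises(ValueError, match="at least two"):
        build_min_table("angle", [1.0], params)
    with pytest.raises(ValueError, match="coarse"):
        build_min_table("angle", [1.0, 2.0], params, n_points=50)
    with pytest.raises(ValueError, match="kind"):
        build_min_table("bond", [1.0, 2.0], params)


def test_degenerate_two_identical_models_reduce_to_single(hairpin):
    """Feeding the same model twice must reproduce the single-model topology
    exactly (the multi-conformer machinery degenerates cleanly)."""
    from asmgo.structure_io import Conformation
    clone = Conformation(1, hairpin.chains)
    t1 = build_topology([hairpin])
    t2 = build_topology([hairpin, clone])
    assert t2.types[0].n_conformers == 1
    a, b = t1.types[0], t2.types[0]
    assert a.bonds == b.bonds
    assert [(t.idx, t.equilibria) for t in a.dihedrals] == \
           [(t.idx, t.equilibria) for t in b.dihedrals]
    assert a.intra_pairs == b.intra_pairs


def test_permutation_of_identical_chains_bitidentical_topology(ring5, tmp_path):
    """Reordering identical chains in the input must not change the merged
    topology output at all (exchangeable subunits)."""
    from asmgo import write_topology
    from asmgo.structure_io import Conformation
    perm = Conformation(0, [ring5.chains[i] for i in (2, 0, 4, 1, 3)])
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_topology(build_topology(ring5), d1)
    write_topology(build_topology(perm), d2)
    for name in ("system.top", "mol_0.itp"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
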