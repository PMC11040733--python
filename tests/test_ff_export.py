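import numpy as np
import pytest

from asmgo import (ForceFieldParams, build_topology, evaluate_energy, fixtures,
                   load_system, place_random, read_gro, write_gro, write_topology)


def test_molecules_section_ring(ring5_topology, tmp_path):
    write_topology(ring5_topology, tmp_path)
    text = (tmp_path / "system.top").read_text()
    mol_section = text.split("[ molecules ]")[1]
    entries = [l.split() for l in mol_section.splitlines() if l.strip() and not l.startswith(";")]
    assert entries == [["MOL0", "5"]]


def test_pair_and_override_bookkeeping(hairpin_topology, ring5_topology, tmp_path):
    """The pairs section carries exactly the intra native pairs; the
    nonbonded overrides carry exactly the distinct merged inter pairs."""
    write_topology(hairpin_topology, tmp_path / "h")
    itp = (tmp_path / "h" / "mol_0.itp").read_text()
    pairs_lines = [
        l for l in itp.split("[ pairs ]")[1].split("[")[0].splitlines()
        if l.strip() and not l.strip().startswith(";")
    ]
    assert len(pairs_lines) == len(hairpin_topology.types[0].intra_pairs)

    write_topology(ring5_topology, tmp_path / "r")
    top = (tmp_path / "r" / "system.top").read_text()
    nb_lines = [
        l for l in top.split("[ nonbond_params ]")[1].split("[")[0].splitlines()
        if l.strip() and not l.strip().startswith(";") and not l.startswith("#")
    ]
    assert len(nb_lines) == len(ring5_topology.inter_pairs)


@pytest.mark.parametrize("fixture_name", ["ring5", "hairpin", "stacked_rings", "two_state"])
def test_roundtrip_energy_oracle(fixture_name, request, tmp_path):
    """Re-evaluating the native state from the written files reproduces the
    in-memory reference energy to 1e-6 eps (export encodes the same model)."""
    conf = request.getfixturevalue(fixture_name)
    confs = conf if isinstance(conf, list) else [conf]
    top = build_topology(confs)
    write_topology(top, tmp_path)
    loaded = load_system(tmp_path)
    e_mem = evaluate_energy(top.native_coords, top.expand())
    e_file = evaluate_energy(top.native_coords, loaded)
    assert e_file.total == pytest.approx(e_mem.total, abs=1e-6)
    for term in ("bond", "angle", "dihedral", "native_intra", "native_inter", "repulsive"):
        assert getattr(e_file, term) == pytest.approx(getattr(e_mem, term), abs=1e-6)


def test_roundtrip_energy_at_random_coords(ring5_topology, tmp_path):
    write_topology(ring5_topology, tmp_path)
    loaded = load_system(tmp_path)
    mem = ring5_topology.expand()
    rng = np.random.default_rng(4)
    for _ in range(3):
        x = ring5_topology.native_coords + rng.normal(0, 0.5, (ring5_topology.n_beads, 3))
        assert evaluate_energy(x, loaded).total == pytest.approx(
            evaluate_energy(x, mem).total, abs=1e-6)


def test_roundtrip_with_group_scaling(stacked_rings, tmp_path):
    params = ForceFieldParams(epsilon_inter=2.0)
    top0 = build_topology(stacked_rings, params)
    factors = {t: 0.5 + 0.5 * k for k, t in enumerate(sorted(top0.group_types))}
    top = build_topology(stacked_rings, params.replace(group_factors=factors))
    write_topology(top, tmp_path)
    loaded = load_system(tmp_path)
    e_mem = evaluate_energy(top.native_coords, top.expand())
    e_file = evaluate_energy(top.native_coords, loaded)
    assert e_file.native_inter == pytest.approx(e_mem.native_inter, abs=1e-6)


def test_deterministic_output(ring5_topology, tmp_path):
    write_topology(ring5_topology, tmp_path / "a")
    write_topology(ring5_topology, tmp_path / "b")
    for name in ("system.top", "mol_0.itp", "interaction_groups.txt"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_default_nonbonded_purely_repulsive(ring5_topology, tmp_path):
    """Atom types carry C6 = 0: non-native interactions have no attractive
    well, decay to zero from above and blow up at short range."""
    write_topology(ring5_topology, tmp_path)
    text = (tmp_path / "system.top").read_text()
    at_lines = [
        l.split() for l in text.split("[ atomtypes ]")[1].split("[")[0].splitlines()
        if l.strip() and not l.strip().startswith(";")
    ]
    assert all(float(f[4]) == 0.0 for f in at_lines)   # C6
    assert all(float(f[5]) > 0.0 for f in at_lines)    # C12
    sigma_nm = ring5_topology.params.sigma_repulsive / 10.0
    assert float(at_lines[0][5]) == pytest.approx(sigma_nm ** 12, rel=1e-9)


def test_gro_units_and_roundtrip(ring5_topology, tmp_path):
    """GRO distances are nm = internal A / 10; re-reading recovers the
    coordinates to file precision (0.001 nm)."""
    path = tmp_path / "native.gro"
    write_gro(ring5_topology, ring5_topology.native_coords, path, box=180.0)
    line = path.read_text().splitlines()[2]
    assert float(line[20:28]) == pytest.approx(ring5_topology.native_coords[0, 0] / 10.0, abs=1e-3)
    coords, box = read_gro(path)
    np.testing.assert_allclose(coords, ring5_topology.native_coords, atol=1e-2)
    np.testing.assert_allclose(box, [180.0] * 3)


def test_random_placement_reproducible_and_separated(ring5_topology, tmp_path):
    box = 180.0
    c1 = place_random(ring5_topology, box, seed=3, min_dist=4.0)
    c2 = place_random(ring5_topology, box, seed=3, min_dist=4.0)
    np.testing.assert_array_equal(c1, c2)
    p1, p2 = tmp_path / "a.gro", tmp_path / "b.gro"
    write_gro(ring5_topology, c1, p1, box=box)
    write_gro(ring5_topology, c2, p2, box=box)
    assert p1.read_bytes() == p2.read_bytes()
    # inter-chain separation respects min_dist under the minimum image
    slices = ring5_topology.chain_slices()
    b = np.array([box] * 3)
    for a in range(len(slices)):
        for c in range(a + 1, len(slices)):
            d = c1[slices[a]][:, None] - c1[slices[c]][None, :]
            d -= b * np.round(d / b)
            assert np.linalg.norm(d, axis=2).min() >= 4.0


def test_random_placement_box_too_small(ring5_topology):
    with pytest.raises(RuntimeError, match="too small|overlaps"):
        place_random(ring5_topology, 25.0, seed=0, min_dist=6.0, max_attempts=20)


def test_export_rejects_empty_topology(ring5_topology, tmp_path):
    import dataclasses
    empty = dataclasses.replace(ring5_topology, instances=[])
    with pytest.raises(ValueError, match="zero beads"):
        write_topology(empty, tmp_path)
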