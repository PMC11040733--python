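import numpy as np
import pytest

from asmgo import analysis, build_topology, fixtures
from asmgo.analysis import (AssemblyState, assembly_time, detect_bound_chains,
                            enumerate_assembly_states, frame_to_state,
                            is_single_event, permutation_invariant_rmsd,
                            q_fraction, transition_statistics, unwrap_trajectory)
from asmgo.geometry import superposed_rmsd


# -- Q -----------------------------------------------------------------------

def test_q_native_is_one(hairpin_topology):
    sys_ = hairpin_topology.expand()
    assert q_fraction(hairpin_topology.native_coords, sys_.intra_idx, sys_.intra_r0) == 1.0


def test_q_dispersed_is_zero(ring5_topology):
    sys_ = ring5_topology.expand()
    coords = ring5_topology.native_coords.copy()
    for k, s in enumerate(ring5_topology.chain_slices()):
        coords[s] += np.array([500.0 * k, 300.0 * k, 0.0])
    assert q_fraction(coords, sys_.inter_idx, sys_.inter_r0) == 0.0


def test_q_half_formed_constructed():
    """Half of the pairs at r0, half pushed to 10 r0 -> Q = 0.5 exactly."""
    idx = np.array([[0, 1], [2, 3], [4, 5], [6, 7]])
    r0 = np.full(4, 5.0)
    coords = np.zeros((8, 3))
    coords[1] = [5.0, 0, 0]
    coords[3] = [0, 5.0, 0]
    coords[5] = [50.0, 0, 0]
    coords[7] = [0, 50.0, 0]
    coords[4] = [200, 0, 0]; coords[5] += [200, 0, 0]
    coords[6] = [300, 0, 0]; coords[7] += [300, 0, 0]
    assert q_fraction(coords, idx, r0) == 0.5


def test_q_empty_pairs_rejected():
    with pytest.raises(ValueError, match="empty"):
        q_fraction(np.zeros((2, 3)), np.zeros((0, 2), int), np.zeros(0))


# -- bound-chain detection -----------------------------------------------------

def test_rigidly_comoving_chains_bound_everywhere():
    body = np.random.default_rng(0).normal(0, 2, (4, 3))
    traj = np.zeros((30, 8, 3))
    for f in range(30):
        shift = np.array([0.1 * f, 0.0, 0.0])
        traj[f, :4] = body + shift
        traj[f, 4:] = body + shift + [15.0, 0, 0]
    flags = detect_bound_chains(traj, slice(0, 4), slice(4, 8),
                                distance_threshold=20.0, std_threshold=1.0, window=5)
    assert flags.all()


def test_drifting_apart_unbinds():
    body = np.zeros((3, 3))
    traj = np.zeros((60, 6, 3))
    for f in range(60):
        traj[f, :3] = body
        traj[f, 3:] = body + [5.0 + 1.0 * f, 0, 0]
    flags = detect_bound_chains(traj, slice(0, 3), slice(3, 6),
                                distance_threshold=20.0, std_threshold=50.0, window=5)
    assert flags[0]
    assert not flags[-1]
    # once the mean distance passes the threshold the flag stays off
    first_off = int(np.argmin(flags))
    assert not flags[first_off:].any()


def test_binding_event_onset_near_ground_truth():
    """On a synthetic trajectory with a known binding frame the detector
    fires within half a window of the truth."""
    window = 11
    traj, (a, b) = fixtures.make_binding_trajectory(200, bind_frame=120, seed=3)
    flags = detect_bound_chains(traj, a, b, distance_threshold=20.0,
                                std_threshold=1.5, window=window)
    onset = int(np.argmax(flags))
    assert flags[onset:].all()
    assert abs(onset - 120) <= window // 2 + 1


def test_never_binding_trajectory_never_flags():
    traj, (a, b) = fixtures.make_binding_trajectory(150, bind_frame=None, seed=5)
    flags = detect_bound_chains(traj, a, b, distance_threshold=20.0,
                                std_threshold=1.5, window=11)
    assert not flags.any()


def test_window_validation():
    traj, (a, b) = fixtures.make_binding_trajectory(10, bind_frame=5, seed=0)
    with pytest.raises(ValueError, match="at least 3"):
        detect_bound_chains(traj, a, b, 20.0, window=2)
    with pytest.raises(ValueError, match="longer than"):
        detect_bound_chains(traj, a, b, 20.0, window=11)


# -- states --------------------------------------------------------------------

def test_frame_to_state_labels():
    assert frame_to_state(5, [(0, 1), (2, 3), (3, 4)]).label == "3+2"
    assert frame_to_state(5, []).label == "0"
    assert frame_to_state(5, [(a, b) for a in range(5) for b in range(a + 1, 5)]).label == "5"
    assert frame_to_state(6, [(0, 1), (4, 5)]).label == "2+2"


def test_state_label_canonical_under_relabeling():
    s1 = frame_to_state(5, [(0, 1), (2, 3), (3, 4)])
    s2 = frame_to_state(5, [(4, 3), (1, 0), (0, 2)])  # relabeled chains
    assert s1.label == s2.label == "3+2"


def test_enumerate_states_pentamer():
    labels = enumerate_assembly_states(5)
    assert set(labels) == {"0", "2", "2+2", "3", "3+2", "4", "5"}
    assert len(labels) == 7


@pytest.mark.parametrize("n,expected", [(1, 1), (2, 2), (3, 3), (4, 5)])
def test_enumerate_states_small(n, expected):
    assert len(enumerate_assembly_states(n)) == expected


@pytest.mark.parametrize("n", [2, 3, 4, 5])
def test_enumerate_states_matches_graph_bruteforce(n):
    """Independent oracle: component-size multisets over all graphs on n
    nodes equal the enumerated label set."""
    import itertools
    import networkx as nx
    edges = list(itertools.combinations(range(n), 2))
    seen = set()
    for mask in range(2 ** len(edges)):
        chosen = [e for k, e in enumerate(edges) if mask >> k & 1]
        seen.add(frame_to_state(n, chosen).label)
    assert seen == set(enumerate_assembly_states(n))


# -- transitions ---------------------------------------------------------------

def test_transition_probabilities_simple_sequence():
    stats = transition_statistics(["0", "2", "2", "5"], lag=1)
    assert stats.transition_prob["0"]["2"] == pytest.approx(100.0)
    assert stats.transition_prob["2"]["5"] == pytest.approx(100.0)
    assert sum(stats.occupancy.values()) == pytest.approx(100.0)


def test_outgoing_rows_sum_to_100():
    rng = np.random.default_rng(8)
    labels = [str(x) for x in rng.integers(0, 4, 500)]
    stats = transition_statistics(labels, lag=1)
    for state, targets in stats.transition_prob.items():
        assert sum(targets.values()) == pytest.approx(100.0, abs=1e-9)
    assert sum(stats.occupancy.values()) == pytest.approx(100.0, abs=1e-9)


def test_absorbing_state_has_no_outgoing():
    stats = transition_statistics(["0", "2", "3", "5", "5", "5"], lag=1)
    assert "5" not in stats.transition_prob


def test_multi_event_transitions_flagged():
    stats = transition_statistics(["0", "2+2", "2+2", "3+2"], lag=1, n_chains=5)
    assert ("0", "2+2") in stats.multi_event        # needs two binding events
    assert ("2+2", "3+2") not in stats.multi_event  # single binding event
    assert is_single_event("3+2", "5", 5)
    assert not is_single_event("0", "4", 5)
    assert is_single_event("5", "3+2", 5)           # one unbinding event


def test_transition_lag_validation():
    with pytest.raises(ValueError):
        transition_statistics(["0", "2"], lag=2)
    with pytest.raises(ValueError):
        transition_statistics([], lag=1)


def test_assembly_time():
    times = np.arange(10.0)
    labels = ["0", "2", "2", "3", "3+2", "3+2", "4", "5", "5", "5"]
    assert assembly_time(labels, times, 5) == 7.0
    assert assembly_time(["5"] + labels[1:], times, 5) == 0.0
    assert assembly_time(labels[:-3], times[:-3], 5) is None


# -- permutation-invariant RMSD ------------------------------------------------

def test_perm_rmsd_relabeled_chains_is_zero(ring5_topology):
    ref = ring5_topology.native_coords
    slices = ring5_topology.chain_slices()
    perm = [1, 2, 3, 4, 0]
    coords = np.concatenate([ref[slices[p]] for p in perm])
    value = permutation_invariant_rmsd(coords, ref, slices, [[0, 1, 2, 3, 4]])
    assert value == pytest.approx(0.0, abs=1e-9)


def test_perm_rmsd_single_chain_equals_plain(hairpin_topology):
    ref = hairpin_topology.native_coords
    rng = np.random.default_rng(2)
    coords = ref + rng.normal(0, 1.0, ref.shape)
    plain = superposed_rmsd(coords, ref)
    assert permutation_invariant_rmsd(coords, ref, hairpin_topology.chain_slices()) \
        == pytest.approx(plain, abs=1e-12)


def test_perm_rmsd_never_exceeds_plain(ring5_topology):
    ref = ring5_topology.native_coords
    slices = ring5_topology.chain_slices()
    rng = np.random.default_rng(3)
    for _ in range(5):
        coords = ref + rng.normal(0, 2.0, ref.shape)
        perm = rng.permutation(5)
        coords = np.concatenate([coords[slices[p]] for p in perm])
        value = permutation_invariant_rmsd(coords, ref, slices, [[0, 1, 2, 3, 4]])
        assert value <= superposed_rmsd(coords, ref) + 1e-12


def test_perm_rmsd_assignment_matches_exhaustive(ring5_topology):
    """The Hungarian-assignment path reproduces the exhaustive 5! search on
    perturbed, permuted ring frames."""
    ref = ring5_topology.native_coords
    slices = ring5_topology.chain_slices()
    rng = np.random.default_rng(4)
    for trial in range(5):
        coords = ref + rng.normal(0, 1.0, ref.shape)
        perm = rng.permutation(5)
        coords = np.concatenate([coords[slices[p]] for p in perm])
        exhaustive = permutation_invariant_rmsd(coords, ref, slices, [[0, 1, 2, 3, 4]])
        heuristic = permutation_invariant_rmsd(coords, ref, slices, [[0, 1, 2, 3, 4]],
                                               max_exhaustive=1)
        assert heuristic == pytest.approx(exhaustive, abs=1e-9)


def test_perm_rmsd_shape_mismatch():
    with pytest.raises(ValueError):
        permutation_invariant_rmsd(np.zeros((4, 3)), np.zeros((5, 3)), [slice(0, 4)])


# -- unwrapping and end-to-end state assignment ---------------------------------

def test_unwrap_restores_continuity():
    box = np.array([30.0, 30.0, 30.0])
    body = np.random.default_rng(1).normal(0, 1.5, (5, 3)) + 15.0
    true = np.zeros((40, 5, 3))
    for f in range(40):
        true[f] = body + [0.9 * f, 0.0, 0.0]   # drifts across the boundary
    wrapped = np.mod(true, box)
    unwrapped = unwrap_trajectory(wrapped, [slice(0, 5)], box)
    steps = np.diff(unwrapped[:, 0, 0])
    assert np.all(np.abs(steps - 0.9) < 1.0)


def test_states_for_trajectory_binding_fixture():
    traj, slices = fixtures.make_binding_trajectory(120, bind_frame=60, seed=9)
    states = analysis.states_for_trajectory(traj, slices, distance_threshold=20.0,
                                            std_threshold=1.5, window=11)
    assert states[0].label == "0"
    assert states[-1].label == "2"


def test_load_trajectory_multimodel_pdb(tmp_path):
    """Multi-model PDB trajectories load into (frames, n, 3) Angstrom arrays."""
    from asmgo import write_pdb
    from asmgo.structure_io import Conformation
    conf0 = fixtures.make_helix_chain(6, seed=0, with_hydrogens=False)
    chains1 = []
    import copy
    conf1 = copy.deepcopy(conf0)
    for res in conf1.chains[0].residues:
        for atom in res.atoms:
            atom.coords = atom.coords + [2.0, 0.0, 0.0]
    conf1.model_id = 1
    path = tmp_path / "traj.pdb"
    write_pdb([conf0, conf1], path)
    frames, times = analysis.load_trajectory(path)
    assert frames.shape[0] == 2
    np.testing.assert_allclose(frames[1] - frames[0],
                               np.broadcast_to([2.0, 0, 0], frames[0].shape),
                               atol=1e-2)


def test_output_writers(tmp_path):
    labels = ["0", "2", "2", "5", "5"]
    stats = transition_statistics(labels, lag=1)
    analysis.write_state_csv(labels, np.arange(5.0), tmp_path / "states.csv")
    analysis.write_transition_csv(stats, tmp_path / "trans.csv")
    analysis.write_state_graph_dot(stats, tmp_path / "graph.dot")
    import pandas as pd
    assert len(pd.read_csv(tmp_path / "states.csv")) == 5
    dot = (tmp_path / "graph.dot").read_text()
    assert dot.startswith("digraph") and '"0" -> "2"' in dot
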