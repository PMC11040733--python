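"""Assembly-trajectory analysis: native contacts, bound chains, states, paths.

The analysis reduces a multichain trajectory to a discrete assembly process:

1. per frame, two chains are *bound* when the moving-window mean of their
   centroid distance is below a distance threshold and its moving-window
   standard deviation is below a fluctuation threshold (stable proximity,
   not a chance fly-by);
2. the bound relation defines a graph (one node per chain); connected
   components of size >= 2 are subassemblies, and the multiset of their
   sizes labels the frame's assembly state — "3+2" is a trimer plus a
   dimer, "0" the fully disassembled state, "n" the complete complex;
3. state sequences give occupancies, lag-time transition statistics and
   assembly times; structural accuracy is measured by a chain-permutation
   invariant RMSD (identical copies are exchangeable, so the best
   assignment of chains to the reference is part of the metric).

Fractions of native contacts Q (intra or inter) quantify folding and
binding progress against the native pair lists.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import geometry

__all__ = [
    "AssemblyState", "TransitionStats",
    "q_fraction", "chain_distance_series", "detect_bound_chains",
    "frame_to_state", "states_for_trajectory", "enumerate_assembly_states",
    "transition_statistics", "assembly_time", "permutation_invariant_rmsd",
    "unwrap_trajectory", "load_trajectory",
    "write_state_csv", "write_transition_csv", "write_state_graph_dot",
]


# ---------------------------------------------------------------------------
# fraction of native contacts
# ---------------------------------------------------------------------------

def q_fraction(
    coords: np.ndarray,
    pair_idx: np.ndarray,
    pair_r0: np.ndarray,
    tol_factor: float = 1.2,
    box: np.ndarray | None = None,
) -> float:
    """Fraction of native pairs currently formed.

    A pair counts as formed when its distance is within ``tol_factor * r0``.

    Raises
    ------
    ValueError
        If the pair list is empty (Q is undefined).
    """
    pair_idx = np.asarray(pair_idx)
    if pair_idx.size == 0:
        raise ValueError("empty native pair list: Q is undefined")
    d = coords[pair_idx[:, 1]] - coords[pair_idx[:, 0]]
    if box is not None:
        box = np.asarray(box, dtype=float)
        d = d - box * np.round(d / box)
    r = np.linalg.norm(d, axis=1)
    return float(np.mean(r <= tol_factor * np.asarray(pair_r0)))


# ---------------------------------------------------------------------------
# bound-chain detection
# ---------------------------------------------------------------------------

def chain_distance_series(
    trajectory: np.ndarray,
    chain_a: slice,
    chain_b: slice,
    box: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame distance between the two chains' centroids (geometry centers)."""
    ca = trajectory[:, chain_a].mean(axis=1)
    cb = trajectory[:, chain_b].mean(axis=1)
    d = cb - ca
    if box is not None:
        box = np.asarray(box, dtype=float)
        d = d - box * np.round(d / box)
    return np.linalg.norm(d, axis=1)


def _rolling(values: np.ndarray, window: int):
    """Centered rolling mean and std with edge windows truncated."""
    series = pd.Series(values)
    mean = series.rolling(window, center=True, min_periods=1).mean().to_numpy()
    std = series.rolling(window, center=True, min_periods=1).std(ddof=0).to_numpy()
    return mean, std


def detect_bound_chains(
    trajectory: np.ndarray,
    chain_a: slice,
    chain_b: slice,
    distance_threshold: float,
    std_threshold: float = 1.5,
    window: int = 11,
    box: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame bound flag for one chain pair.

    Bound means: moving-window mean centroid distance below
    *distance_threshold* AND moving-window standard deviation below
    *std_threshold* (the chains co-move rather than merely pass by).
    """
    if window < 3:
        raise ValueError("window must be at least 3 frames")
    if window > trajectory.shape[0]:
        raise ValueError("window longer than the trajectory")
    dist = chain_distance_series(trajectory, chain_a, chain_b, box=box)
    mean, std = _rolling(dist, window)
    return (mean < distance_threshold) & (std < std_threshold)


# ---------------------------------------------------------------------------
# assembly states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssemblyState:
    """Multiset of bound-cluster sizes, canonically labeled.

    Cluster sizes (>= 2 chains) sorted descending and joined with "+";
    a frame without any bound pair is state "0".
    """

    label: str
    clusters: tuple[tuple[int, ...], ...] = field(default=(), compare=False)

    @staticmethod
    def from_sizes(sizes) -> "AssemblyState":
        sizes = sorted((s for s in sizes if s >= 2), reverse=True)
        return AssemblyState("+".join(map(str, sizes)) if sizes else "0")


def frame_to_state(n_chains: int, bound_pairs) -> AssemblyState:
    """Connected components of the bound-chain graph -> assembly state."""
    graph = nx.Graph()
    graph.add_nodes_from(range(n_chains))
    graph.add_edges_from(bound_pairs)
    components = [tuple(sorted(c)) for c in nx.connected_components(graph) if len(c) >= 2]
    components.sort(key=len, reverse=True)
    state = AssemblyState.from_sizes(len(c) for c in components)
    return AssemblyState(state.label, tuple(components))


def states_for_trajectory(
    trajectory: np.ndarray,
    chain_slices: list[slice],
    distance_threshold: float,
    std_threshold: float = 1.5,
    window: int = 11,
    box: np.ndarray | None = None,
) -> list[AssemblyState]:
    """Assembly state per frame from pairwise bound-chain detection."""
    n = len(chain_slices)
    flags = {}
    for a, b in itertools.combinations(range(n), 2):
        flags[(a, b)] = detect_bound_chains(
            trajectory, chain_slices[a], chain_slices[b],
            distance_threshold, std_threshold, window, box=box)
    states = []
    for f in range(trajectory.shape[0]):
        edges = [(a, b) for (a, b), flag in flags.items() if flag[f]]
        states.append(frame_to_state(n, edges))
    return states


def enumerate_assembly_states(n_chains: int) -> list[str]:
    """All possible assembly-state labels for *n_chains* chains.

    These are the partitions of m into parts >= 2 for every m <= n_chains
    (the remaining chains are free monomers), plus the empty state "0".
    For 5 chains: 0, 2, 2+2, 3, 3+2, 4, 5 — seven states.
    """
    if n_chains < 1:
        raise ValueError("need at least one chain")

    def partitions(m: int, max_part: int):
        if m == 0:
            yield ()
            return
        for part in range(min(m, max_part), 1, -1):
            for rest in partitions(m - part, part):
                yield (part, *rest)

    labels = set()
    for m in range(0, n_chains + 1):
        for parts in partitions(m, n_chains):
            labels.add("+".join(map(str, parts)) if parts else "0")
    return sorted(labels, key=lambda s: [] if s == "0" else [int(x) for x in s.split("+")])


def _full_partition(label: str, n_chains: int) -> tuple[int, ...]:
    parts = [] if label == "0" else [int(x) for x in label.split("+")]
    monomers = n_chains - sum(parts)
    return tuple(sorted(parts + [1] * monomers, reverse=True))


def is_single_event(label_a: str, label_b: str, n_chains: int) -> bool:
    """True if one binding or unbinding event converts state a into state b.

    A binding event merges two clusters (monomers count as size-1 clusters)
    into one; an unbinding event is the reverse split.
    """
    pa = _full_partition(label_a, n_chains)
    pb = _full_partition(label_b, n_chains)
    small, large = (pa, pb) if len(pa) > len(pb) else (pb, pa)
    if len(small) != len(large) + 1:
        return False
    # large must equal small with two parts merged
    ca, cb = list(small), list(large)
    for p, q in itertools.combinations(range(len(ca)), 2):
        merged = sorted(ca[:p] + ca[p + 1:q] + ca[q + 1:] + [ca[p] + ca[q]], reverse=True)
        if tuple(merged) == tuple(sorted(cb, reverse=True)):
            return True
    return False


@dataclass
class TransitionStats:
    """Occupancies and outgoing transition probabilities of a state sequence."""

    occupancy: dict[str, float]                       # % of frames
    transition_prob: dict[str, dict[str, float]]      # % outgoing, per source
    counts: dict[tuple[str, str], int]
    lag: int
    #: observed transitions spanning more than one binding/unbinding event
    multi_event: set[tuple[str, str]] = field(default_factory=set)


def transition_statistics(
    labels: list[str],
    lag: int = 1,
    n_chains: int | None = None,
) -> TransitionStats:
    """Empirical lag-time transition statistics of an assembly-state sequence.

    Only frames where the state changes count as transitions; probabilities
    are normalized per source state, so every state's outgoing probabilities
    sum to 100%. If *n_chains* is given, transitions that cannot be a single
    binding/unbinding event are flagged in ``multi_event``.
    """
    if not labels:
        raise ValueError("empty state sequence")
    if lag < 1 or lag >= len(labels):
        raise ValueError("lag must satisfy 1 <= lag < sequence length")

    occupancy = {
        label: 100.0 * count / len(labels)
        for label, count in pd.Series(labels).value_counts().items()
    }
    counts: dict[tuple[str, str], int] = {}
    for t in range(len(labels) - lag):
        a, b = labels[t], labels[t + lag]
        if a != b:
            counts[(a, b)] = counts.get((a, b), 0) + 1

    out_total: dict[str, int] = {}
    for (a, _b), c in counts.items():
        out_total[a] = out_total.get(a, 0) + c
    probs: dict[str, dict[str, float]] = {}
    for (a, b), c in counts.items():
        probs.setdefault(a, {})[b] = 100.0 * c / out_total[a]

    multi = set()
    if n_chains is not None:
        multi = {key for key in counts if not is_single_event(*key, n_chains)}
    return TransitionStats(occupancy=occupancy, transition_prob=probs,
                           counts=counts, lag=lag, multi_event=multi)


def assembly_time(labels: list[str], times: np.ndarray, n_chains: int) -> float | None:
    """Time of the first frame in the fully assembled state, or None."""
    target = str(n_chains)
    for label, t in zip(labels, times):
        if label == target:
            return float(t)
    return None


# ---------------------------------------------------------------------------
# permutation-invariant RMSD
# ---------------------------------------------------------------------------

def _apply_permutation(coords: np.ndarray, chain_slices: list[slice], perm: list[int]) -> np.ndarray:
    return np.concatenate([coords[chain_slices[p]] for p in perm])


def _grouped_permutations(groups: list[list[int]], n_chains: int):
    """All chain orderings permuting only within identical-chain groups."""
    perms_per_group = [list(itertools.permutations(g)) for g in groups]
    for combo in itertools.product(*perms_per_group):
        perm = [None] * n_chains
        for group, assigned in zip(groups, combo):
            for slot, chain in zip(group, assigned):
                perm[slot] = chain
        yield perm


def permutation_invariant_rmsd(
    coords: np.ndarray,
    reference: np.ndarray,
    chain_slices: list[slice],
    identical_groups: list[list[int]] | None = None,
    max_exhaustive: int = 6,
) -> float:
    """Minimum RMSD over relabelings of identical chains, after superposition.

    For groups of up to *max_exhaustive* identical copies every permutation
    is tried (exact); larger groups use a Hungarian assignment on chain
    centroids refined by iterated superposition, which may be suboptimal in
    pathological cases but matches the exhaustive search on the sizes it is
    tested against.
    """
    if coords.shape != reference.shape:
        raise ValueError("frame and reference have different sizes")
    n = len(chain_slices)
    if identical_groups is None:
        identical_groups = [[i] for i in range(n)]
    sizes = {len(coords[s]) for g in identical_groups for s in (chain_slices[c] for c in g)}
    for group in identical_groups:
        lengths = {chain_slices[c].stop - chain_slices[c].start for c in group}
        if len(lengths) > 1:
            raise ValueError("chains within an identical group differ in length")
    del sizes

    if all(len(g) <= max_exhaustive for g in identical_groups):
        best = np.inf
        for perm in _grouped_permutations(identical_groups, n):
            permuted = _apply_permutation(coords, chain_slices, perm)
            best = min(best, geometry.superposed_rmsd(permuted, reference))
        return float(best)

    # assignment heuristic: Hungarian on chain centroids + Kabsch refinement
    perm = list(range(n))
    best = geometry.superposed_rmsd(_apply_permutation(coords, chain_slices, perm), reference)
    for _ in range(10):
        permuted = _apply_permutation(coords, chain_slices, perm)
        rot, cm, cr = geometry.kabsch_superpose(permuted, reference)
        moved = (coords - cm) @ rot.T + cr
        new_perm = list(range(n))
        for group in identical_groups:
            ref_centroids = np.array([reference[chain_slices[c]].mean(axis=0) for c in group])
            mov_centroids = np.array([moved[chain_slices[c]].mean(axis=0) for c in group])
            cost = np.linalg.norm(ref_centroids[:, None] - mov_centroids[None, :], axis=2)
            rows, cols = linear_sum_assignment(cost)
            for slot, chain in zip(rows, cols):
                new_perm[group[slot]] = group[chain]
        value = geometry.superposed_rmsd(
            _apply_permutation(coords, chain_slices, new_perm), reference)
        if value < best:
            best, perm = value, new_perm
        else:
            break
    return float(best)


# ---------------------------------------------------------------------------
# periodic boundary handling & trajectory I/O
# ---------------------------------------------------------------------------

def unwrap_trajectory(
    trajectory: np.ndarray,
    chain_slices: list[slice],
    box: np.ndarray,
) -> np.ndarray:
    """Undo periodic wrapping chain-wise before analysis.

    Each chain is first made whole (consecutive beads follow the minimum
    image); each whole chain is then shifted by box vectors so its centroid
    moves continuously (minimum-image displacement) between frames.
    """
    box = np.asarray(box, dtype=float)
    out = trajectory.copy()
    for s in chain_slices:
        for f in range(out.shape[0]):
            chain = out[f, s]
            steps = np.diff(chain, axis=0)
            steps -= box * np.round(steps / box)
            chain[1:] = chain[0] + np.cumsum(steps, axis=0)
        for f in range(1, out.shape[0]):
            disp = out[f, s].mean(axis=0) - out[f - 1, s].mean(axis=0)
            out[f, s] -= box * np.round(disp / box)
    return out


def load_trajectory(topology_file: str | Path, trajectory_file: str | Path | None = None):
    """Load a GRO/XTC/TRR/multi-model-PDB trajectory via MDAnalysis.

    Returns ``(frames, times)`` with frames (n_frames, n_atoms, 3) in A and
    times in the file's time unit.
    """
    import MDAnalysis as mda

    if trajectory_file is None:
        universe = mda.Universe(str(topology_file))
    else:
        universe = mda.Universe(str(topology_file), str(trajectory_file))
    frames, times = [], []
    for ts in universe.trajectory:
        frames.append(universe.atoms.positions.copy())
        times.append(ts.time)
    return np.array(frames), np.array(times)


def write_state_csv(labels: list[str], times, path: str | Path) -> None:
    pd.DataFrame({"time": times, "state": labels}).to_csv(path, index=False)


def write_transition_csv(stats: TransitionStats, path: str | Path) -> None:
    rows = [
        {"from": a, "to": b, "count": c,
         "probability_pct": stats.transition_prob[a][b],
         "multi_event": (a, b) in stats.multi_event}
        for (a, b), c in sorted(stats.counts.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_state_graph_dot(stats: TransitionStats, path: str | Path) -> None:
    """Assembly-state graph in DOT format (occupancy on nodes, % on edges)."""
    lines = ["digraph assembly {"]
    for state, occ in sorted(stats.occupancy.items()):
        lines.append(f'  "{state}" [label="{state}\\n{occ:.1f}%"];')
    for a, targets in sorted(stats.transition_prob.items()):
        for b, p in sorted(targets.items()):
            lines.append(f'  "{a}" -> "{b}" [label="{p:.1f}%"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
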