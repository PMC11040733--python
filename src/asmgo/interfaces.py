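"""Interaction groups: chain-chain interfaces and their strength scaling.

An interaction group is the cluster of intermolecular native pairs forming
the attractive interface between one pair of chains. After chain merging,
symmetry-equivalent interfaces (e.g. the five identical neighbor interfaces
of a C5 ring) collapse onto identical residue-pair sets in merged-type
coordinates and receive the same group *type*. Users can scale the contact
strength of every interface class independently (e.g. weaken ring-ring
stacking relative to in-ring contacts) via per-type factors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = ["InteractionGroup", "detect_interaction_groups", "apply_group_scaling"]

#: canonical typed endpoint: (merged type id, residue index within type)
Endpoint = tuple[int, int]
#: canonical typed residue pair: (endpoint_a, endpoint_b), endpoint_a <= endpoint_b
TypedPair = tuple[Endpoint, Endpoint]


def canonical_typed_pair(a: Endpoint, b: Endpoint) -> TypedPair:
    """Symmetrized (orientation-free) form of a typed residue pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionGroup:
    """All intermolecular native pairs between one pair of chain instances."""

    group_id: int
    instance_a: int
    instance_b: int
    pair_set: frozenset[TypedPair]
    group_type_id: int = -1
    scale: float = 1.0

    @property
    def n_pairs(self) -> int:
        return len(self.pair_set)


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 1.0


def detect_interaction_groups(
    instance_pair_sets: dict[tuple[int, int], frozenset[TypedPair]],
    jaccard_merge: float = 0.0,
) -> tuple[list[InteractionGroup], dict[int, frozenset[TypedPair]]]:
    """Group interfaces and classify symmetry-equivalent group types.

    Parameters
    ----------
    instance_pair_sets
        For every unordered chain-instance pair sharing at least one native
        pair, the set of its contacts in symmetrized merged-type residue
        coordinates.
    jaccard_merge
        If > 0, interfaces whose pair sets are not identical but overlap
        with a Jaccard similarity >= this value share a type (tolerates
        boundary-residue differences from slightly asymmetric inputs).

    Returns
    -------
    (groups, group_types)
        Groups (one per interfacing instance pair) and the mapping from
        group type id to the representative residue-pair set. Type ids are
        assigned from the canonically sorted signatures, so they do not
        depend on the chain order of the input file.
    """
    signatures = sorted(
        set(instance_pair_sets.values()),
        key=lambda s: (len(s), sorted(s)),
    )
    if jaccard_merge > 0.0:
        representatives: list[frozenset] = []
        sig_to_rep: dict[frozenset, frozenset] = {}
        for sig in signatures:
            for rep in representatives:
                if _jaccard(sig, rep) >= jaccard_merge:
                    sig_to_rep[sig] = rep
                    break
            else:
                representatives.append(sig)
                sig_to_rep[sig] = sig
        type_ids = {rep: i for i, rep in enumerate(representatives)}
        type_of = {sig: type_ids[sig_to_rep[sig]] for sig in signatures}
        group_types = {i: rep for rep, i in type_ids.items()}
    else:
        type_of = {sig: i for i, sig in enumerate(signatures)}
        group_types = {i: sig for sig, i in type_of.items()}

    groups = []
    for (a, b) in sorted(instance_pair_sets):
        sig = instance_pair_sets[(a, b)]
        groups.append(InteractionGroup(
            group_id=len(groups),
            instance_a=a,
            instance_b=b,
            pair_set=sig,
            group_type_id=type_of[sig],
        ))
    return groups, group_types


def apply_group_scaling(
    groups: list[InteractionGroup],
    factors: dict[int, float],
) -> dict[TypedPair, float]:
    """Per-type strength factors -> per-contact epsilon multipliers.

    Every group's scale is multiplied by its type's factor (types without an
    entry keep factor 1). Returns the resulting scale for every typed
    residue pair; a pair claimed by differently scaled group types (possible
    when distinct interfaces of the same two molecule types overlap) gets
    the mean of the conflicting scales, with a warning — the exported
    type-level parameters cannot distinguish such interfaces.

    Raises
    ------
    KeyError
        If *factors* names a group type id that does not exist.
    """
    known = {g.group_type_id for g in groups}
    unknown = set(factors) - known
    if unknown:
        raise KeyError(f"unknown interaction group type id(s): {sorted(unknown)}")

    scales: dict[TypedPair, list[float]] = {}
    for group in groups:
        group.scale *= factors.get(group.group_type_id, 1.0)
        for pair in group.pair_set:
            scales.setdefault(pair, []).append(group.scale)

    result: dict[TypedPair, float] = {}
    for pair, values in scales.items():
        if len(set(values)) > 1:
            logger.warning(
                "typed pair %s belongs to interfaces with conflicting scales "
                "%s; using their mean", pair, values,
            )
        result[pair] = float(sum(values) / len(values))
    return result
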