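"""Mapping genomic alteration profiles onto network node statuses.

A sample (cell line or patient) is described by a binary set of functional
genomic alterations.  Each alteration maps to one network node and a
resulting status: constantly activated (A) or constantly inactivated (I);
unaltered nodes stay input-dependent (N).  Samples with identical resulting
status profiles collapse onto a single "differentially wired" network, which
is then kept only if its spontaneous basin of apoptosis does not exceed half
of the state space (a network that dies on its own is not a usable disease
model).  Similarity between two profiles is the Pearson correlation of their
ternary encodings (A=+1, N=0, I=-1).
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    NetworkDefinition,
    SimulationConfig,
    StatusProfile,
    basin_of_apoptosis,
)

__all__ = [
    "AlterationProfile",
    "GeneNodeMap",
    "UniqueNetwork",
    "StatusConflictError",
    "alterations_to_status",
    "dedupe_profiles",
    "filter_by_basin",
    "similarity",
    "common_networks",
]


class StatusConflictError(ValueError):
    """Two alterations of one sample assign conflicting statuses to a node."""


@dataclass(frozen=True)
class AlterationProfile:
    """One sample's binarized functional alterations."""

    sample_id: str
    source: str  # "cell_line" | "patient"
    alterations: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alterations", frozenset(self.alterations))


@dataclass(frozen=True)
class GeneNodeMap:
    """alteration id -> (node, status in {A, I})."""

    entries: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for alt, (node, status) in self.entries.items():
            if status not in ("A", "I"):
                raise ValueError(
                    f"alteration {alt!r}: mapped status must be A or I, got {status!r}"
                )

    def validate_against(self, net: NetworkDefinition) -> None:
        for alt, (node, _) in self.entries.items():
            if node not in net.names:
                raise KeyError(f"alteration {alt!r} maps to unknown node {node!r}")

    @property
    def alteration_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.entries))


@dataclass(frozen=True)
class UniqueNetwork:
    """A deduplicated differentially wired network and its member samples."""

    network_id: str
    profile: StatusProfile
    members: tuple[str, ...]


def alterations_to_status(
    profile: AlterationProfile,
    gene_map: GeneNodeMap,
    on_unknown: str = "error",
) -> StatusProfile:
    """Project a sample's alterations onto node statuses.

    Unknown alteration ids raise by default (``on_unknown="skip"`` ignores
    them); two alterations assigning different statuses to the same node
    raise :class:`StatusConflictError` listing the culprits.
    """
    statuses: dict[str, str] = {}
    by_node: dict[str, list[str]] = {}
    for alt in sorted(profile.alterations):
        if alt not in gene_map.entries:
            if on_unknown == "skip":
                continue
            raise KeyError(
                f"sample {profile.sample_id!r}: unknown alteration id {alt!r}"
            )
        node, status = gene_map.entries[alt]
        if node in statuses and statuses[node] != status:
            raise StatusConflictError(
                f"sample {profile.sample_id!r}: node {node!r} assigned both "
                f"{statuses[node]} and {status} by {by_node[node] + [alt]}"
            )
        statuses[node] = status
        by_node.setdefault(node, []).append(alt)
    return StatusProfile.from_dict(statuses)


def dedupe_profiles(
    pairs: Iterable[tuple[AlterationProfile, StatusProfile]],
) -> list[UniqueNetwork]:
    """Partition samples by exact status-profile equality.

    Network ids are assigned in order of first appearance (``NW_1``, ...);
    samples with identical profiles map to one network regardless of source.
    """
    groups: dict[StatusProfile, list[str]] = {}
    order: list[StatusProfile] = []
    for sample, status in pairs:
        if status not in groups:
            groups[status] = []
            order.append(status)
        groups[status].append(sample.sample_id)
    return [
        UniqueNetwork(f"NW_{i + 1}", status, tuple(groups[status]))
        for i, status in enumerate(order)
    ]


def source_counts(
    pairs: Sequence[tuple[AlterationProfile, StatusProfile]],
) -> dict[str, int]:
    """Unique-network counts per sample source (cell_line vs patient)."""
    out: dict[str, int] = {}
    for src in sorted({p.source for p, _ in pairs}):
        sub = [(p, s) for p, s in pairs if p.source == src]
        out[src] = len(dedupe_profiles(sub))
    return out


def filter_by_basin(
    networks: Sequence[UniqueNetwork],
    net: NetworkDefinition,
    config: SimulationConfig,
    cutoff: float = 0.5,
) -> tuple[list[UniqueNetwork], pd.DataFrame]:
    """Drop networks whose spontaneous basin of apoptosis exceeds ``cutoff``.

    The boundary is strict ("larger than half" excluded): basin == cutoff is
    retained.  Returns the retained networks and an audit table.
    """
    kept: list[UniqueNetwork] = []
    rows = []
    for nw in networks:
        basin = basin_of_apoptosis(net, nw.profile, config)
        keep = basin <= cutoff
        rows.append({"network_id": nw.network_id, "basin": basin, "kept": keep})
        if keep:
            kept.append(nw)
    return kept, pd.DataFrame(rows, columns=["network_id", "basin", "kept"])


_ENCODING = {"A": 1.0, "N": 0.0, "I": -1.0}


def similarity(a: StatusProfile, b: StatusProfile, nodes: Sequence[str]) -> float:
    """Pearson correlation of ternary encodings over a shared node universe.

    Returns NaN when either profile is constant over ``nodes`` (e.g. the
    all-N control), for which the correlation is undefined.
    """
    for prof in (a, b):
        for n, _ in prof.entries:
            if n not in nodes:
                raise KeyError(f"profile names node {n!r} outside the node universe")
    va = np.array([_ENCODING[a.status(n)] for n in nodes])
    vb = np.array([_ENCODING[b.status(n)] for n in nodes])
    if va.std() == 0.0 or vb.std() == 0.0:
        return math.nan
    return float(np.corrcoef(va, vb)[0, 1])


def common_networks(
    cell_nets: Sequence[UniqueNetwork],
    patient_nets: Sequence[UniqueNetwork],
) -> list[UniqueNetwork]:
    """Networks whose status profile occurs in both sources.

    Matches are merged (cell-line members first) and labelled ``NT_1`` ...
    ``NT_k`` ordered by descending total member count, ties broken by the
    lexicographic status profile.
    """
    by_profile = {nw.profile: nw for nw in patient_nets}
    merged = []
    for cnw in cell_nets:
        pnw = by_profile.get(cnw.profile)
        if pnw is not None:
            merged.append((cnw.profile, cnw.members + pnw.members))
    merged.sort(key=lambda item: (-len(item[1]), item[0].entries))
    return [
        UniqueNetwork(f"NT_{i + 1}", profile, members)
        for i, (profile, members) in enumerate(merged)
    ]
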