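"""Synthetic networks, cohorts and ground-truth plans for testing.

Everything here is generated or hand-designed; nothing is measured data.
The module ships:

* :func:`toy_network` -- a 3-node single-path network whose stochastic
  dose-response has a closed-form binomial oracle;
* :func:`load_p53` -- a 16-node p53-like network.  This is a *synthetic
  stand-in* (see ``data/p53_synthetic.tsv``): a hand-built weighted-sum model
  over the canonical p53 pathway players.  Only the structural facts that fix
  the screening combinatorics are taken as given (16 nodes; the six
  drug-target nodes AKT, BCL2, CYCE, MDM2, WIP1, ATM carrying 27 outgoing
  links in total); every weight and basal level is designed here, not
  transcribed from a reference model;
* :func:`dominance_demo` -- a purpose-built 10-node network with a designed
  desirable determinant, a dynamically dominant undesirable determinant and
  structurally neutral passenger nodes, used to ground-truth stratification;
* :func:`random_network` / :func:`random_alteration_profiles` -- seeded
  generators for arbitrary valid networks and cohorts;
* :func:`find_causal_plan` / :func:`confounded_cohort` -- implant a causal
  alteration whose effect on the drug response is verified by simulation,
  then emit a cohort in which a passenger alteration co-occurs with it.
"""

from __future__ import annotations

import itertools
from collections.abc import Sequence
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np

from .categorize import ThresholdConfig, categorize, _SweepCache
from .dose import efficacy, ic50
from .genomics import AlterationProfile, GeneNodeMap, alterations_to_status
from .model import (
    CONTROL_PROFILE,
    Link,
    NetworkDefinition,
    Perturbation,
    SimulationConfig,
    Target,
)
from .stratify import EfficacyPotencyPoint

__all__ = [
    "FixtureSpec",
    "CausalPlan",
    "InfeasiblePlanError",
    "toy_network",
    "load_p53",
    "p53_target_nodes",
    "dominance_demo",
    "random_network",
    "default_gene_map",
    "random_alteration_profiles",
    "find_causal_plan",
    "confounded_cohort",
]

P53_TARGET_NODES = ("AKT", "BCL2", "CYCE", "MDM2", "WIP1", "ATM")


class InfeasiblePlanError(RuntimeError):
    """The requested causal plan has no verifiable effect on the drug response."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for the random generators; generation is pure in (spec, seed)."""

    n_nodes: int = 16
    link_density: float = 0.25
    weight_magnitudes: tuple[int, ...] = (1, 2)
    n_profiles: int = 100
    min_alterations: int = 1
    max_alterations: int = 4
    n_sink_nodes: int = 2  # nodes downstream of the readout (passenger sites)
    seed: int = 0


@dataclass(frozen=True)
class CausalPlan:
    """An implanted ground truth for a cohort.

    ``causal`` flips the drug response relative to the control network;
    ``dominant`` (optional) is an undesirable set that overrides it;
    ``passengers`` are alterations on nodes with no path to the death
    readout, hence verifiably neutral.  The first passenger co-occurs with
    the causal set at rate ``co_occurrence``.
    """

    target: Target
    causal: frozenset[str]
    passengers: tuple[str, ...]
    dominant: frozenset[str] | None = None
    co_occurrence: float = 1.0


def toy_network() -> NetworkDefinition:
    """X (basal 1) -> Z <- Y (basal 0): Z copies X one step later.

    With X inhibited at dose x, Z's activity is the fraction of un-suppressed
    steps, so the death probability has the closed form
    P(Binomial(steady_steps, x) <= floor((1 - threshold) * steady_steps) - ...)
    evaluated in the tests.
    """
    return NetworkDefinition(
        nodes=(("X", 1, "internal"), ("Y", 0, "internal"), ("Z", 0, "output")),
        links=(Link("X", "Z", 1), Link("Y", "Z", -1)),
    )


def load_p53() -> NetworkDefinition:
    """The packaged 16-node synthetic p53-like network (see module docstring)."""
    from .io import load_network

    with resources.as_file(
        resources.files("netwin").joinpath("data/p53_synthetic.tsv")
    ) as path:
        return load_network(path)


def load_p53_gene_map() -> GeneNodeMap:
    from .io import read_gene_node_map

    with resources.as_file(
        resources.files("netwin").joinpath("data/gene_node_map_synthetic.tsv")
    ) as path:
        return read_gene_node_map(path)


def p53_target_nodes() -> tuple[str, ...]:
    return P53_TARGET_NODES


def dominance_demo() -> tuple[NetworkDefinition, GeneNodeMap, CausalPlan]:
    """A designed network realizing a two-level dominance structure.

    The drug target is the node ``guard``, which tonically silences the
    kill route ``kinase -> death``.  The death readout additionally needs
    either both memory nodes ON (a quarter of the initial states) or the
    ``bypass`` node:

    * control: inhibiting guard fires the kinase, but only memory-ON states
      die, and only at near-total inhibition -- efficacy 0.25, no category;
    * ``bypass_act`` (the desirable determinant): every state dies once the
      guard is inhibited -- high efficacy, low toxicity (O1);
    * ``shield_act`` (the dominant undesirable determinant): the death node
      is vetoed outright, so the drug can never work, regardless of bypass.

    ``rep1``/``rep2`` hang downstream of the kinase with no path to the death
    readout: alterations on them are structurally neutral passengers.
    """
    net = NetworkDefinition(
        nodes=(
            ("signal", 0, "input"),
            ("guard", 1, "internal"),
            ("kinase", 0, "internal"),
            ("mem1", 0, "internal"),
            ("mem2", 0, "internal"),
            ("bypass", 0, "internal"),
            ("shield", 0, "internal"),
            ("rep1", 0, "internal"),
            ("rep2", 0, "internal"),
            ("death", -4, "output"),
        ),
        links=(
            Link("signal", "kinase", 1),
            Link("guard", "kinase", -1),
            Link("kinase", "death", 3),
            Link("mem1", "mem1", 1),
            Link("mem2", "mem2", 1),
            Link("mem1", "death", 1),
            Link("mem2", "death", 1),
            Link("bypass", "death", 2),
            Link("shield", "death", -7),
            Link("kinase", "rep1", 1),
            Link("rep1", "rep2", 1),
        ),
    )
    gene_map = GeneNodeMap(
        {
            "bypass_act": ("bypass", "A"),
            "shield_act": ("shield", "A"),
            "rep1_act": ("rep1", "A"),
            "rep2_act": ("rep2", "A"),
        }
    )
    plan = CausalPlan(
        target=Target.of_node("guard"),
        causal=frozenset({"bypass_act"}),
        passengers=("rep1_act", "rep2_act"),
        dominant=frozenset({"shield_act"}),
        co_occurrence=1.0,
    )
    return net, gene_map, plan


# ---------------------------------------------------------------------------
# random generators
# ---------------------------------------------------------------------------


def random_network(spec: FixtureSpec) -> NetworkDefinition:
    """A random valid weighted-sum network: input -> ... -> output backbone,
    extra random links (feedback allowed), and ``n_sink_nodes`` reporter
    nodes downstream of the readout that cannot influence it."""
    if spec.n_nodes < 3:
        raise ValueError("need at least 3 nodes (input, internal, output)")
    rng = np.random.default_rng(spec.seed)
    n_core = spec.n_nodes
    names = ["IN"] + [f"V{i}" for i in range(1, n_core - 1)] + ["OUT"]
    internal = names[1:-1]

    links: dict[tuple[str, str], int] = {}

    def add(src: str, tgt: str, w: int) -> None:
        if src != tgt or src in internal:  # self-loops only on internal nodes
            links.setdefault((src, tgt), int(w))

    # backbone guarantees OUT reachable from IN
    order = list(internal)
    rng.shuffle(order)
    chain = ["IN"] + order + ["OUT"]
    for a, b in zip(chain, chain[1:]):
        add(a, b, int(rng.choice(spec.weight_magnitudes)))
    # one feedback edge when there is room
    if len(order) >= 2:
        add(order[-1], order[0], -int(rng.choice(spec.weight_magnitudes)))
    # density-driven extra links among internal nodes (either sign)
    candidates = [
        (a, b)
        for a in internal
        for b in internal + ["OUT"]
        if a != b and (a, b) not in links
    ]
    rng.shuffle(candidates)
    n_extra = int(spec.link_density * len(candidates))
    for a, b in candidates[:n_extra]:
        sign = -1 if rng.random() < 0.5 else 1
        add(a, b, sign * int(rng.choice(spec.weight_magnitudes)))
    # reporter sinks: fed by OUT, feeding nothing upstream
    sink_names = [f"R{i}" for i in range(1, spec.n_sink_nodes + 1)]
    prev = "OUT"
    for s in sink_names:
        links[(prev, s)] = 1
        prev = s

    basal = {n: int(rng.integers(-1, 2)) for n in names + sink_names}
    basal["IN"] = 0
    nodes = [("IN", 0, "input")]
    nodes += [(n, basal[n], "internal") for n in internal]
    nodes += [("OUT", basal["OUT"], "output")]
    nodes += [(s, basal[s], "internal") for s in sink_names]
    net = NetworkDefinition(
        tuple(nodes), tuple(Link(a, b, w) for (a, b), w in links.items())
    )
    # sanity: reachability holds by construction
    g = nx.DiGraph([(lk.source, lk.target) for lk in net.links])
    assert nx.has_path(g, "IN", "OUT")
    return net


def default_gene_map(net: NetworkDefinition) -> GeneNodeMap:
    """A generic map offering activating and inactivating alterations for
    every internal node."""
    entries = {}
    for name, _, role in net.nodes:
        if role != "internal":
            continue
        entries[f"{name}_act"] = (name, "A")
        entries[f"{name}_inact"] = (name, "I")
    return GeneNodeMap(entries)


def random_alteration_profiles(
    net: NetworkDefinition,
    n: int = 100,
    spec: FixtureSpec | None = None,
    gene_map: GeneNodeMap | None = None,
) -> tuple[list[AlterationProfile], GeneNodeMap]:
    """``n`` random profiles: 1-4 alterations (uniform) on distinct nodes.

    Node distinctness guarantees conflict-free status profiles.  The
    alteration-count range is configurable via the spec; the default mirrors
    a sparsely altered cohort.
    """
    spec = spec or FixtureSpec()
    gene_map = gene_map or default_gene_map(net)
    rng = np.random.default_rng(spec.seed)
    by_node: dict[str, list[str]] = {}
    for alt, (node, _) in gene_map.entries.items():
        by_node.setdefault(node, []).append(alt)
    nodes = sorted(by_node)
    profiles = []
    for i in range(n):
        lo = min(spec.min_alterations, len(nodes))
        hi = min(spec.max_alterations, len(nodes))
        k = int(rng.integers(lo, hi + 1))
        chosen_nodes = rng.choice(nodes, size=k, replace=False)
        alts = frozenset(
            str(rng.choice(sorted(by_node[str(nd)]))) for nd in chosen_nodes
        )
        profiles.append(AlterationProfile(f"S{i + 1:03d}", "patient", alts))
    return profiles, gene_map


# ---------------------------------------------------------------------------
# causal implants and confounded cohorts
# ---------------------------------------------------------------------------


def _response_point(
    cache: _SweepCache,
    gene_map: GeneNodeMap,
    alterations: frozenset[str],
    target: Target,
) -> EfficacyPotencyPoint:
    profile = AlterationProfile("plan", "cell_line", alterations)
    status = alterations_to_status(profile, gene_map)
    curve = cache.curve(status, (target,))
    return EfficacyPotencyPoint(efficacy(curve), ic50(curve), alterations)


def find_causal_plan(
    net: NetworkDefinition,
    gene_map: GeneNodeMap,
    target: Target,
    config: SimulationConfig,
    margin: float = 0.3,
    n_passengers: int = 2,
) -> CausalPlan | None:
    """Search for a single alteration that verifiably moves the drug response.

    The candidate must shift the efficacy-potency point at least ``margin``
    away from the control network's point; passenger slots need nodes with no
    directed path to the death readout.  Returns ``None`` when the network
    offers no such implant (callers then draw a new network).
    """
    g = nx.DiGraph([(lk.source, lk.target) for lk in net.links])
    g.add_nodes_from(net.names)
    readout = net.death_readout
    neutral_nodes = [
        n
        for n, _, role in net.nodes
        if role == "internal" and (n not in g or not nx.has_path(g, n, readout))
    ]
    passenger_alts = [
        alt
        for alt, (node, status) in sorted(gene_map.entries.items())
        if node in neutral_nodes and status == "A"
    ]
    if len(passenger_alts) < n_passengers:
        return None
    cache = _SweepCache(net, config)
    control_pt = _response_point(cache, gene_map, frozenset(), target)
    for alt, (node, _) in sorted(gene_map.entries.items()):
        if node in neutral_nodes or node in net.input_nodes or node == readout:
            continue
        if target.kind == "node" and node == target.node:
            continue
        pt = _response_point(cache, gene_map, frozenset({alt}), target)
        if pt.distance(control_pt) >= margin:
            return CausalPlan(
                target=target,
                causal=frozenset({alt}),
                passengers=tuple(passenger_alts[:n_passengers]),
            )
    return None


def confounded_cohort(
    net: NetworkDefinition,
    gene_map: GeneNodeMap,
    plan: CausalPlan,
    n: int = 40,
    config: SimulationConfig | None = None,
    th: ThresholdConfig | None = None,
    seed: int = 0,
) -> tuple[list[AlterationProfile], list[str]]:
    """A cohort with the plan's alterations plus confounded passengers.

    Each sample carries the causal set with probability 1/2, the dominant
    set (when the plan has one) with probability 0.4, the first passenger
    whenever the causal set is present (at rate ``co_occurrence``; otherwise
    at a background 0.15), and the remaining passengers at 0.3.  Labels are
    the D/U category of each sample's network, computed by simulation; the
    plan is verified first and an ineffective causal set raises
    :class:`InfeasiblePlanError`.
    """
    config = config or SimulationConfig()
    th = th or ThresholdConfig()
    cache = _SweepCache(net, config)
    pert = Perturbation.single(plan.target)

    def label_of(alterations: frozenset[str]) -> str:
        profile = AlterationProfile("probe", "patient", alterations)
        status = alterations_to_status(profile, gene_map)
        cat = categorize(net, status, CONTROL_PROFILE, pert, config, th, cache)
        return cat.response

    control_label = label_of(frozenset())
    if label_of(plan.causal) == control_label:
        raise InfeasiblePlanError(
            f"causal set {sorted(plan.causal)} does not change the drug response"
        )
    rng = np.random.default_rng(seed)
    profiles: list[AlterationProfile] = []
    label_cache: dict[frozenset, str] = {}
    labels: list[str] = []
    for i in range(n):
        alts: set[str] = set()
        if rng.random() < 0.5:
            alts |= plan.causal
        if plan.dominant is not None and rng.random() < 0.4:
            alts |= plan.dominant
        if plan.passengers:
            p_first = plan.co_occurrence if plan.causal <= alts else 0.15
            if rng.random() < p_first:
                alts.add(plan.passengers[0])
            for p in plan.passengers[1:]:
                if rng.random() < 0.3:
                    alts.add(p)
        profile = AlterationProfile(f"C{i + 1:03d}", "patient", frozenset(alts))
        profiles.append(profile)
        key = profile.alterations
        if key not in label_cache:
            label_cache[key] = label_of(key)
        labels.append(label_cache[key])
    return profiles, labels
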