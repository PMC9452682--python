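"""Weighted-sum Boolean network core.

The dynamical model: each node ``i`` carries a binary state ``s_i`` and an
integer basal level ``b_i``; each directed link ``j -> i`` carries a nonzero
integer weight ``w_ij``.  Under the synchronous update rule the next state is

    s_i(t+1) = 1  iff  sum_j w_ij * s_j(t) + b_i > 0

(strict by default; the comparison is configurable to ``>=`` for sensitivity
checks).  Genomic alterations enter as ternary node statuses: ``A`` clamps a
node ON, ``I`` clamps it OFF, ``N`` leaves it input-dependent.  Drugs enter as
per-step suppression of nodes (state forced to 0) or links (weight contributes
0 for that step).

Precedence per step: the weighted sums are evaluated first, then ``A``/``I``
status clamps, then input-node clamps, and finally suppression, which wins
over everything else.

Everything here is deterministic given its inputs; stochastic dosing lives in
:mod:`netwin.dose` and reuses the batch kernel exposed at the bottom of this
module.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkSchemaError",
    "EnumerationCapError",
    "Link",
    "NetworkDefinition",
    "StatusProfile",
    "CONTROL_PROFILE",
    "NetworkState",
    "SimulationConfig",
    "SimulationResult",
    "Target",
    "Perturbation",
    "step",
    "simulate",
    "enumerate_initial_states",
    "initial_state_matrix",
    "basin_of_apoptosis",
    "ergodic_set",
]

ROLES = ("input", "output", "internal")


class NetworkSchemaError(ValueError):
    """A network definition violates the schema (names the offending record)."""


class EnumerationCapError(RuntimeError):
    """Raised when the free state space exceeds the enumeration cap.

    Callers should switch to sampled initial states (``n_samples`` in
    :class:`SimulationConfig`; see :func:`initial_state_matrix`).
    """


@dataclass(frozen=True)
class Link:
    source: str
    target: str
    weight: int

    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class NetworkDefinition:
    """An immutable weighted-sum Boolean network.

    ``nodes`` is an ordered tuple of ``(name, basal, role)`` triples; the file
    order of nodes is the canonical node order used for state encoding.
    Exactly one node has role ``output`` (the death readout, CASP3 in the p53
    model); any number of nodes (including zero) may have role ``input``.
    """

    nodes: tuple[tuple[str, int, str], ...]
    links: tuple[Link, ...]

    def __post_init__(self) -> None:
        names = [n for n, _, _ in self.nodes]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise NetworkSchemaError(f"duplicate node name: {dup!r}")
        for name, basal, role in self.nodes:
            if role not in ROLES:
                raise NetworkSchemaError(f"node {name!r}: unknown role {role!r}")
            if int(basal) != basal:
                raise NetworkSchemaError(f"node {name!r}: basal level must be integer")
        outputs = [n for n, _, r in self.nodes if r == "output"]
        if len(outputs) != 1:
            raise NetworkSchemaError(
                f"exactly one output (death readout) node required, found {outputs!r}"
            )
        declared = set(names)
        seen: set[tuple[str, str]] = set()
        for lk in self.links:
            if lk.source not in declared:
                raise NetworkSchemaError(f"link source {lk.source!r} is not a declared node")
            if lk.target not in declared:
                raise NetworkSchemaError(f"link target {lk.target!r} is not a declared node")
            if lk.weight == 0 or int(lk.weight) != lk.weight:
                raise NetworkSchemaError(
                    f"link {lk.source!r}->{lk.target!r}: weight must be a nonzero integer"
                )
            if lk.key() in seen:
                raise NetworkSchemaError(f"duplicate link {lk.source!r}->{lk.target!r}")
            seen.add(lk.key())

    # -- derived views -----------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _, _ in self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown node {name!r}") from None

    @property
    def death_readout(self) -> str:
        return next(n for n, _, r in self.nodes if r == "output")

    @property
    def input_nodes(self) -> tuple[str, ...]:
        return tuple(n for n, _, r in self.nodes if r == "input")

    @property
    def basal(self) -> np.ndarray:
        return np.array([b for _, b, _ in self.nodes], dtype=np.int64)

    def weight_matrix(self) -> np.ndarray:
        """W with ``W[target, source] = weight`` (zero where no link)."""
        W = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int64)
        for lk in self.links:
            W[self.index(lk.target), self.index(lk.source)] = lk.weight
        return W

    def outgoing(self, node: str) -> tuple[Link, ...]:
        self.index(node)
        return tuple(lk for lk in self.links if lk.source == node)

    def find_link(self, source: str, target: str) -> Link:
        for lk in self.links:
            if lk.source == source and lk.target == target:
                return lk
        raise KeyError(f"no link {source!r}->{target!r}")


@dataclass(frozen=True)
class StatusProfile:
    """Ternary A/I/N clamping of nodes; nodes not mentioned are ``N``.

    The all-N profile is the control network (no genomic alterations).
    Equality is exact equality of the non-N assignments, which is what the
    unique-network deduplication relies on.
    """

    entries: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        canon = tuple(sorted((n, s) for n, s in self.entries if s != "N"))
        for n, s in canon:
            if s not in ("A", "I"):
                raise ValueError(f"status for {n!r} must be A, I or N, got {s!r}")
        names = [n for n, _ in canon]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node in status profile")
        object.__setattr__(self, "entries", canon)

    @classmethod
    def from_dict(cls, statuses: Mapping[str, str]) -> "StatusProfile":
        return cls(tuple(statuses.items()))

    def status(self, node: str) -> str:
        for n, s in self.entries:
            if n == node:
                return s
        return "N"

    def as_dict(self) -> dict[str, str]:
        return dict(self.entries)

    @property
    def is_control(self) -> bool:
        return not self.entries

    def validate_against(self, net: NetworkDefinition) -> None:
        for n, _ in self.entries:
            if n not in net.names:
                raise KeyError(f"status profile names unknown node {n!r}")


CONTROL_PROFILE = StatusProfile()


@dataclass(frozen=True)
class NetworkState:
    """A binary network state, one bit per node in canonical node order."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("state bits must be 0 or 1")

    def __getitem__(self, i: int) -> int:
        return self.bits[i]

    def as_array(self) -> np.ndarray:
        return np.array(self.bits, dtype=np.int8)


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation parameters.

    transient_steps / steady_steps
        Synchronous update counts: the transient phase is discarded, node
        activity is the mean state over the steady window (defaults 100/100;
        all trajectories of the 16-node model converge well within 100 steps).
    death_threshold
        A state trajectory is scored as cell death when the death readout's
        activity exceeds this (default 0.9).
    input_clamp
        Scenario values for input nodes (e.g. DNA damage ON for
        therapeutic-window runs, OFF for sensitivity validation and the
        basin filter).  Unlisted inputs default to 0.
    strict_threshold
        ``True`` uses ``sum > 0`` for the update rule, ``False`` uses ``>=``.
    enumeration_cap
        Max number of free (N-status, non-input) nodes for exhaustive state
        enumeration; beyond it ``n_samples`` uniform states are drawn.
    """

    transient_steps: int = 100
    steady_steps: int = 100
    death_threshold: float = 0.9
    input_clamp: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0
    n_replicates: int = 1
    strict_threshold: bool = True
    enumeration_cap: int = 22
    n_samples: int = 4096

    def __post_init__(self) -> None:
        if self.transient_steps <= 0 or self.steady_steps <= 0:
            raise ValueError("step counts must be positive")
        if not 0.0 < self.death_threshold < 1.0:
            raise ValueError("death_threshold must lie in (0, 1)")

    def with_clamp(self, **clamp: int) -> "SimulationConfig":
        merged = dict(self.input_clamp)
        merged.update(clamp)
        return replace(self, input_clamp=merged)


@dataclass(frozen=True)
class SimulationResult:
    """Per-node activities over the steady window plus the death call."""

    activity: Mapping[str, float]
    death: bool


@dataclass(frozen=True)
class Target:
    """A druggable element: a node, or a single directed link."""

    kind: str  # "node" | "link"
    node: str | None = None
    link: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind == "node":
            if not self.node or self.link is not None:
                raise ValueError("node target requires node=... only")
        elif self.kind == "link":
            if not self.link or self.node is not None:
                raise ValueError("link target requires link=(source, target) only")
        else:
            raise ValueError(f"unknown target kind {self.kind!r}")

    @classmethod
    def of_node(cls, name: str) -> "Target":
        return cls(kind="node", node=name)

    @classmethod
    def of_link(cls, source: str, target: str) -> "Target":
        return cls(kind="link", link=(source, target))

    @property
    def label(self) -> str:
        if self.kind == "node":
            return self.node  # type: ignore[return-value]
        return f"{self.link[0]}->{self.link[1]}"  # type: ignore[index]


@dataclass(frozen=True)
class Perturbation:
    """A drug (or drug combination): targets with doses in [0, 1].

    The dose is the per-step probability that the target is suppressed
    (node state, or link weight, forced to 0 for that step) -- the in-silico
    analog of drug concentration.
    """

    components: tuple[tuple[Target, float], ...]

    def __post_init__(self) -> None:
        labels = [t.label for t, _ in self.components]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate targets in perturbation")
        for t, dose in self.components:
            if not 0.0 <= dose <= 1.0:
                raise ValueError(f"dose for {t.label} out of [0, 1]: {dose}")

    @classmethod
    def single(cls, target: Target, dose: float = 1.0) -> "Perturbation":
        return cls(((target, dose),))

    @classmethod
    def of(cls, targets: Iterable[Target], dose: float = 1.0) -> "Perturbation":
        return cls(tuple((t, dose) for t in targets))

    @property
    def targets(self) -> tuple[Target, ...]:
        return tuple(t for t, _ in self.components)

    def at_dose(self, dose: float) -> "Perturbation":
        """The same targets with one shared dose on every component."""
        return Perturbation.of(self.targets, dose)

    @property
    def label(self) -> str:
        return "+".join(t.label for t, _ in self.components)


# ---------------------------------------------------------------------------
# compiled clamps and the batch step kernel
# ---------------------------------------------------------------------------


class _Compiled:
    """Pre-resolved index arrays for one (network, profile, clamp) context."""

    def __init__(
        self,
        net: NetworkDefinition,
        profile: StatusProfile,
        input_clamp: Mapping[str, int],
    ):
        profile.validate_against(net)
        self.net = net
        self.W_T = net.weight_matrix().T.copy()
        self.basal = net.basal
        names = net.names
        self.force_one = np.array([profile.status(n) == "A" for n in names])
        self.force_zero = np.array([profile.status(n) == "I" for n in names])
        self.input_idx = np.array([net.index(n) for n in net.input_nodes], dtype=np.intp)
        self.input_val = np.array(
            [int(input_clamp.get(n, 0)) for n in net.input_nodes], dtype=np.int8
        )
        self.output_idx = net.index(net.death_readout)
        # free nodes: input-dependent and not scenario-clamped
        self.free_idx = np.array(
            [
                i
                for i, n in enumerate(names)
                if profile.status(n) == "N" and n not in net.input_nodes
            ],
            dtype=np.intp,
        )

    def clamp_state(self, S: np.ndarray) -> np.ndarray:
        S = S.astype(np.int8, copy=True)
        S[:, self.force_one] = 1
        S[:, self.force_zero] = 0
        if len(self.input_idx):
            S[:, self.input_idx] = self.input_val
        return S

    def step(
        self,
        S: np.ndarray,
        strict: bool,
        node_off: Sequence[tuple[int, np.ndarray]] = (),
        link_off: Sequence[tuple[int, int, int, np.ndarray]] = (),
    ) -> np.ndarray:
        """One synchronous update of a batch of states S (m, n).

        ``node_off``: (node index, row mask) pairs -- rows where the node is
        suppressed this step.  ``link_off``: (source, target, weight, row
        mask) -- rows where the link contributes 0 this step.
        """
        total = S @ self.W_T + self.basal
        for s_i, t_i, w, mask in link_off:
            if mask is None:
                total[:, t_i] -= w * S[:, s_i].astype(np.int64)
            else:
                total[mask, t_i] -= w * S[mask, s_i].astype(np.int64)
        nxt = (total > 0) if strict else (total >= 0)
        nxt = nxt.astype(np.int8)
        nxt[:, self.force_one] = 1
        nxt[:, self.force_zero] = 0
        if len(self.input_idx):
            nxt[:, self.input_idx] = self.input_val
        for idx, mask in node_off:
            if mask is None:
                nxt[:, idx] = 0
            else:
                nxt[mask, idx] = 0
        return nxt


def _compile(net, profile, config) -> _Compiled:
    return _Compiled(net, profile, config.input_clamp)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def step(
    net: NetworkDefinition,
    profile: StatusProfile,
    state: NetworkState,
    suppressed_nodes: Iterable[str] = (),
    suppressed_links: Iterable[tuple[str, str]] = (),
    *,
    strict: bool = True,
) -> NetworkState:
    """One synchronous update of a single state.

    Input nodes hold the value they carry in ``state`` (scenario clamping is
    the caller's responsibility when constructing the state).
    """
    clamp = {n: state.bits[net.index(n)] for n in net.input_nodes}
    ctx = _Compiled(net, profile, clamp)
    node_off = [(net.index(n), None) for n in suppressed_nodes]
    link_off = []
    for src, tgt in suppressed_links:
        lk = net.find_link(src, tgt)
        link_off.append((net.index(src), net.index(tgt), lk.weight, None))
    S = state.as_array()[None, :]
    nxt = ctx.step(S, strict, node_off, link_off)
    return NetworkState(tuple(int(b) for b in nxt[0]))


def simulate(
    net: NetworkDefinition,
    profile: StatusProfile,
    initial: NetworkState,
    config: SimulationConfig,
    schedule: Sequence[tuple[Iterable[str], Iterable[tuple[str, str]]]] | None = None,
) -> SimulationResult:
    """Run transient + steady synchronous updates from one initial state.

    ``schedule`` optionally gives, per step, the suppressed node names and
    suppressed links; it must cover every step.  Activity is the per-node
    mean over the steady window only.
    """
    total_steps = config.transient_steps + config.steady_steps
    if schedule is not None and len(schedule) < total_steps:
        raise ValueError("suppression schedule shorter than the simulation")
    ctx = _compile(net, profile, config)
    S = ctx.clamp_state(initial.as_array()[None, :])
    acc = np.zeros(net.n_nodes, dtype=np.int64)
    for t in range(total_steps):
        if schedule is None:
            node_off: list = []
            link_off: list = []
        else:
            nodes_t, links_t = schedule[t]
            node_off = [(net.index(n), None) for n in nodes_t]
            link_off = []
            for src, tgt in links_t:
                lk = net.find_link(src, tgt)
                link_off.append((net.index(src), net.index(tgt), lk.weight, None))
        S = ctx.step(S, config.strict_threshold, node_off, link_off)
        if t >= config.transient_steps:
            acc += S[0]
    activity = acc / config.steady_steps
    death = bool(activity[ctx.output_idx] > config.death_threshold)
    return SimulationResult(
        activity=dict(zip(net.names, activity.tolist())), death=death
    )


def free_nodes(net: NetworkDefinition, profile: StatusProfile) -> tuple[str, ...]:
    """Nodes whose initial state is unconstrained (N status, not an input)."""
    profile.validate_against(net)
    return tuple(
        n
        for n, _, _ in net.nodes
        if profile.status(n) == "N" and n not in net.input_nodes
    )


def enumerate_initial_states(
    net: NetworkDefinition,
    profile: StatusProfile,
    config: SimulationConfig,
) -> np.ndarray:
    """All 2^k initial states over the free nodes, as an (m, n) int8 matrix.

    Row order is binary counting: row index ``i`` assigns bit
    ``(i >> (k-1-j)) & 1`` to the j-th free node in canonical node order, so
    the first free node is the most significant bit.  Clamped nodes (A/I
    status, scenario inputs) are fixed to their clamp values in every row.
    """
    ctx = _compile(net, profile, config)
    k = len(ctx.free_idx)
    if k > config.enumeration_cap:
        raise EnumerationCapError(
            f"{k} free nodes exceed the enumeration cap of {config.enumeration_cap}; "
            "use sampled initial states (initial_state_matrix / n_samples)"
        )
    m = 1 << k
    S = np.zeros((m, net.n_nodes), dtype=np.int8)
    if k:
        counters = np.arange(m, dtype=np.int64)
        shifts = np.arange(k - 1, -1, -1, dtype=np.int64)
        S[:, ctx.free_idx] = ((counters[:, None] >> shifts) & 1).astype(np.int8)
    return ctx.clamp_state(S)


def initial_state_matrix(
    net: NetworkDefinition,
    profile: StatusProfile,
    config: SimulationConfig,
) -> np.ndarray:
    """Exhaustive enumeration when it fits the cap, else seeded uniform samples."""
    try:
        return enumerate_initial_states(net, profile, config)
    except EnumerationCapError:
        ctx = _compile(net, profile, config)
        rng = np.random.default_rng(config.seed)
        S = np.zeros((config.n_samples, net.n_nodes), dtype=np.int8)
        S[:, ctx.free_idx] = rng.integers(
            0, 2, size=(config.n_samples, len(ctx.free_idx)), dtype=np.int8
        )
        return ctx.clamp_state(S)


def _deterministic_output_activity(
    ctx: _Compiled, S: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Output-node activity for every row of S under unperturbed dynamics."""
    acc = np.zeros(S.shape[0], dtype=np.int64)
    for t in range(config.transient_steps + config.steady_steps):
        S = ctx.step(S, config.strict_threshold)
        if t >= config.transient_steps:
            acc += S[:, ctx.output_idx]
    return acc / config.steady_steps


def basin_of_apoptosis(
    net: NetworkDefinition,
    profile: StatusProfile,
    config: SimulationConfig,
) -> float:
    """Fraction of initial states whose unperturbed trajectory is cell death.

    "Basin of apoptosis": initial states whose death-readout activity over
    the steady window exceeds the death threshold.
    """
    ctx = _compile(net, profile, config)
    S = initial_state_matrix(net, profile, config)
    activity = _deterministic_output_activity(ctx, S, config)
    return float(np.mean(activity > config.death_threshold))


def _draw_suppression(
    ctx: _Compiled,
    perturbation: Perturbation,
    m: int,
    steps: int,
    rng: np.random.Generator,
):
    """Per-step Bernoulli suppression masks, independent across steps/rows.

    Returns (node_plan, link_plan): node_plan is a list of (node index, (T, m)
    bool array); link_plan of (src, tgt, weight, (T, m) bool array).  A dose
    of exactly 0 or 1 is materialised without consuming random draws so that
    the dose-0 run is bit-identical to the unperturbed one.
    """
    net = ctx.net
    node_plan = []
    link_plan = []
    for target, dose in perturbation.components:
        if dose == 0.0:
            continue
        mask = None if dose == 1.0 else rng.random((steps, m)) < dose
        if target.kind == "node":
            node_plan.append((net.index(target.node), mask))
        else:
            lk = net.find_link(*target.link)
            link_plan.append(
                (net.index(lk.source), net.index(lk.target), lk.weight, mask)
            )
    return node_plan, link_plan


def stochastic_batch_run(
    net: NetworkDefinition,
    profile: StatusProfile,
    S0: np.ndarray,
    perturbation: Perturbation,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Output-node activity per row of S0 under probabilistic suppression.

    The suppression schedule is drawn independently per step, per component
    and per row (initial state), with suppression probability equal to the
    component's dose; it applies during both the transient and the steady
    phase.
    """
    ctx = _compile(net, profile, config)
    S = ctx.clamp_state(S0)
    m = S.shape[0]
    steps = config.transient_steps + config.steady_steps
    node_plan, link_plan = _draw_suppression(ctx, perturbation, m, steps, rng)
    acc = np.zeros(m, dtype=np.int64)
    for t in range(steps):
        node_off = [(idx, mask if mask is None else mask[t]) for idx, mask in node_plan]
        link_off = [
            (s, d, w, mask if mask is None else mask[t]) for s, d, w, mask in link_plan
        ]
        S = ctx.step(S, config.strict_threshold, node_off, link_off)
        if t >= config.transient_steps:
            acc += S[:, ctx.output_idx]
    return acc / config.steady_steps


def ergodic_set(
    net: NetworkDefinition,
    profile: StatusProfile,
    perturbation: Perturbation,
    initial: NetworkState,
    config: SimulationConfig,
    length: int | None = None,
) -> set[tuple[int, ...]]:
    """States visited during the steady window of a long stochastic run.

    Under stochastic dosing the trajectory wanders between the unperturbed
    attractor and the fully-perturbed one; the visited set is this "ergodic
    set".  With every dose at 0 it is exactly the deterministic attractor.
    """
    steady = length if length is not None else config.steady_steps
    ctx = _compile(net, profile, config)
    rng = np.random.default_rng(config.seed)
    S = ctx.clamp_state(initial.as_array()[None, :])
    steps = config.transient_steps + steady
    node_plan, link_plan = _draw_suppression(ctx, perturbation, 1, steps, rng)
    visited: set[tuple[int, ...]] = set()
    for t in range(steps):
        node_off = [(idx, mask if mask is None else mask[t]) for idx, mask in node_plan]
        link_off = [
            (s, d, w, mask if mask is None else mask[t]) for s, d, w, mask in link_plan
        ]
        S = ctx.step(S, config.strict_threshold, node_off, link_off)
        if t >= config.transient_steps:
            visited.add(tuple(int(b) for b in S[0]))
    return visited
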