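"""Twelve-way (S_n, O_m) drug-response categorization and the triangle map.

Selective control (node-vs-link efficacy, from the cancer network):

* S1 -- node inhibition and some outgoing-link inhibition are both effective
* S2 -- only node inhibition is effective
* S3 -- only link inhibition is effective
* S4 -- neither is effective

where "effective" means the normalized curve's efficacy exceeds 0.8.  For a
link target, its node test uses the source node's own sweep.  For a
combination, a test counts when at least one component drug satisfies it.

Optimal control (cancer f vs control g):

* O1 -- toxicity test: max f - max g > 0.5 (low toxicity at all doses)
* O2 -- else potency test: some dose with f(x) - g(x) > 0.5 (window via
  higher potency in the cancer network)
* O3 -- neither: no therapeutic window

All comparisons are strict, as defined.  Categories (S1-S3, O1-O2) are
desirable (D); anything with S4 or O3 is undesirable (U).

The screening set for the six designated drug-target nodes enumerates single
nodes, their outgoing links, node pairs, link pairs (excluding two links from
one node) and node-link pairs (excluding a node with its own link); the
triangle map records a category for every cell and NA for the excluded
pairs.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd

from .dose import DoseResponseCurve, dose_sweep, efficacy, normalize_curve
from .model import (
    NetworkDefinition,
    Perturbation,
    SimulationConfig,
    StatusProfile,
    Target,
)

__all__ = [
    "ThresholdConfig",
    "ResponseCategory",
    "TriangleMap",
    "enumerate_perturbations",
    "selective_class",
    "optimal_class",
    "categorize",
    "triangle_map",
    "sensitivity_classify",
    "agreement_rate",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """All classification thresholds (strict comparisons throughout)."""

    efficacy_cut: float = 0.8
    toxicity_gap: float = 0.5
    potency_gap: float = 0.5
    window_threshold: float = 0.25
    death_threshold: float = 0.9
    sens_cut_ic50: float = 0.5
    sens_cut_auc: float = 0.5
    sens_cut_efficacy: float = 0.8

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class ResponseCategory:
    s: str  # S1..S4
    o: str  # O1..O3

    def __post_init__(self) -> None:
        if self.s not in ("S1", "S2", "S3", "S4"):
            raise ValueError(f"bad selective class {self.s!r}")
        if self.o not in ("O1", "O2", "O3"):
            raise ValueError(f"bad optimal class {self.o!r}")

    @property
    def desirable(self) -> bool:
        return self.s != "S4" and self.o != "O3"

    @property
    def response(self) -> str:
        return "D" if self.desirable else "U"

    def __str__(self) -> str:  # ("S1","O2") prints as (S1,O2)
        return f"({self.s},{self.o})"


def enumerate_perturbations(
    net: NetworkDefinition, target_nodes: Sequence[str]
) -> list[Perturbation]:
    """The full screening set for the designated drug-target nodes.

    Order: node singles, link singles (grouped by source node), node pairs,
    link pairs (same-source pairs excluded), node-link pairs (a node with its
    own outgoing link excluded).  Doses default to 1; sweeps re-dose.
    """
    for n in target_nodes:
        net.index(n)
    links = [lk for n in target_nodes for lk in net.outgoing(n)]
    node_ts = [Target.of_node(n) for n in target_nodes]
    link_ts = [Target.of_link(lk.source, lk.target) for lk in links]
    perts = [Perturbation.single(t) for t in node_ts + link_ts]
    perts += [Perturbation.of(pair) for pair in itertools.combinations(node_ts, 2)]
    perts += [
        Perturbation.of(pair)
        for pair in itertools.combinations(link_ts, 2)
        if pair[0].link[0] != pair[1].link[0]
    ]
    perts += [
        Perturbation.of((n, l))
        for n, l in itertools.product(node_ts, link_ts)
        if l.link[0] != n.node
    ]
    return perts


def selective_class(
    node_curves: Sequence[DoseResponseCurve],
    link_curves: Sequence[DoseResponseCurve],
    th: ThresholdConfig,
) -> str:
    """S1-S4 from node-side and link-side efficacy tests."""
    if not node_curves and not link_curves:
        raise ValueError("no curves supplied")
    node_pass = any(efficacy(c) > th.efficacy_cut for c in node_curves)
    link_pass = any(efficacy(c) > th.efficacy_cut for c in link_curves)
    if node_pass:
        return "S1" if link_pass else "S2"
    return "S3" if link_pass else "S4"


def optimal_class(
    f_curve: DoseResponseCurve,
    g_curve: DoseResponseCurve,
    th: ThresholdConfig,
) -> str:
    """O1-O3: toxicity test first, then potency test, else O3."""
    if f_curve.doses != g_curve.doses:
        raise ValueError("cancer and control curves must share the dose grid")
    if efficacy(f_curve) - efficacy(g_curve) > th.toxicity_gap:
        return "O1"
    if any(f - g > th.potency_gap for f, g in zip(f_curve.values, g_curve.values)):
        return "O2"
    return "O3"


class _SweepCache:
    """Memoizes normalized single-target sweeps per (profile, target)."""

    def __init__(self, net: NetworkDefinition, config: SimulationConfig):
        self.net = net
        self.config = config
        self._store: dict = {}

    def curve(self, profile: StatusProfile, targets: tuple[Target, ...]) -> DoseResponseCurve:
        key = (profile, targets)
        if key not in self._store:
            self._store[key] = normalize_curve(
                dose_sweep(self.net, profile, targets, self.config)
            )
        return self._store[key]


def _component_tests(
    cache: _SweepCache,
    profile: StatusProfile,
    perturbation: Perturbation,
) -> tuple[list[DoseResponseCurve], list[DoseResponseCurve]]:
    """Node-side and link-side curves feeding the S test.

    Node component: its own single sweep on the node side and each of its
    outgoing links on the link side.  Link component: its source node's
    sweep on the node side and its own sweep on the link side.
    """
    node_curves: list[DoseResponseCurve] = []
    link_curves: list[DoseResponseCurve] = []
    for target in perturbation.targets:
        if target.kind == "node":
            node_curves.append(cache.curve(profile, (target,)))
            for lk in cache.net.outgoing(target.node):
                link_curves.append(
                    cache.curve(profile, (Target.of_link(lk.source, lk.target),))
                )
        else:
            src = target.link[0]
            node_curves.append(cache.curve(profile, (Target.of_node(src),)))
            link_curves.append(cache.curve(profile, (target,)))
    return node_curves, link_curves


def categorize(
    net: NetworkDefinition,
    cancer_profile: StatusProfile,
    control_profile: StatusProfile,
    perturbation: Perturbation,
    config: SimulationConfig,
    th: ThresholdConfig | None = None,
    cache: _SweepCache | None = None,
) -> ResponseCategory:
    """Classify one perturbation into its (S_n, O_m) category.

    Categorization runs under the caller's scenario clamp (DNA damage ON for
    therapeutic-window screening).  ``cache`` lets a screening loop share
    single-target sweeps.
    """
    th = th or ThresholdConfig()
    cache = cache or _SweepCache(net, config)
    f = cache.curve(cancer_profile, perturbation.targets)
    g = cache.curve(control_profile, perturbation.targets)
    node_curves, link_curves = _component_tests(cache, cancer_profile, perturbation)
    s = selective_class(node_curves, link_curves, th)
    o = optimal_class(f, g, th)
    return ResponseCategory(s, o)


@dataclass
class TriangleMap:
    """Category (or NA) for every single and pairwise perturbation.

    ``entries`` maps perturbation labels to categories; ``na`` lists the
    structurally excluded pairs (two links from one node; a node paired with
    its own outgoing link), which depend only on the topology.
    """

    entries: dict[str, ResponseCategory] = field(default_factory=dict)
    na: tuple[str, ...] = ()
    metrics: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, cat in self.entries.items():
            row = {
                "perturbation": label,
                "S": cat.s,
                "O": cat.o,
                "desirable": cat.desirable,
            }
            row.update(self.metrics.get(label, {}))
            rows.append(row)
        for label in self.na:
            rows.append(
                {"perturbation": label, "S": "NA", "O": "NA", "desirable": False}
            )
        return pd.DataFrame(rows)


def _na_pairs(net: NetworkDefinition, target_nodes: Sequence[str]) -> list[str]:
    links = [lk for n in target_nodes for lk in net.outgoing(n)]
    link_ts = [Target.of_link(lk.source, lk.target) for lk in links]
    na = [
        f"{a.label}+{b.label}"
        for a, b in itertools.combinations(link_ts, 2)
        if a.link[0] == b.link[0]
    ]
    na += [
        f"{n}+{l.label}"
        for n, l in itertools.product(target_nodes, link_ts)
        if l.link[0] == n
    ]
    return na


def triangle_map(
    net: NetworkDefinition,
    cancer_profile: StatusProfile,
    control_profile: StatusProfile,
    target_nodes: Sequence[str],
    config: SimulationConfig,
    th: ThresholdConfig | None = None,
    with_metrics: bool = False,
) -> TriangleMap:
    """Categorize the full screening set of one cancer network."""
    from .dose import response_metrics

    th = th or ThresholdConfig()
    cache = _SweepCache(net, config)
    tm = TriangleMap(na=tuple(_na_pairs(net, target_nodes)))
    for pert in enumerate_perturbations(net, target_nodes):
        cat = categorize(net, cancer_profile, control_profile, pert, config, th, cache)
        tm.entries[pert.label] = cat
        if with_metrics:
            f = cache.curve(cancer_profile, pert.targets)
            g = cache.curve(control_profile, pert.targets)
            m = response_metrics(f, g, th.window_threshold)
            tm.metrics[pert.label] = {
                "efficacy": m.efficacy,
                "ic50": m.ic50,
                "toxicity": m.toxicity,
                "smed": m.smed,
                "smtd": m.smtd,
            }
    return tm


_SENSITIVE_IF_BELOW = {"sim_ic50", "exp_ic50", "exp_auc", "gr50", "grmax"}
_SENSITIVE_IF_ABOVE = {"sim_auc", "sim_efficacy", "gr_aoc"}


def sensitivity_classify(
    value: float,
    metric_kind: str,
    th: ThresholdConfig | None = None,
    reference: float | None = None,
) -> str:
    """Binary sensitive/resistant call for one (pre-normalized) metric value.

    Experimental IC50 must already be min-max normalized to [0, 1];
    experimental (viability) AUC is compared against the cohort mean passed
    as ``reference``; GR50/GRmax/GR_AOC use 0.5; simulated IC50 and AUC use
    0.5 and simulated efficacy uses 0.8.  Non-finite values (e.g. infinite
    GR50) must be excluded by the caller beforehand and raise here.
    """
    import math

    th = th or ThresholdConfig()
    if not math.isfinite(value):
        raise ValueError(
            f"non-finite {metric_kind} value; exclude it before classification"
        )
    cuts = {
        "sim_ic50": th.sens_cut_ic50,
        "sim_auc": th.sens_cut_auc,
        "sim_efficacy": th.sens_cut_efficacy,
        "exp_ic50": 0.5,
        "exp_auc": reference,
        "gr50": 0.5,
        "grmax": 0.5,
        "gr_aoc": 0.5,
    }
    if metric_kind not in cuts:
        raise ValueError(f"unknown metric kind {metric_kind!r}")
    cut = cuts[metric_kind]
    if cut is None:
        raise ValueError("exp_auc requires the cohort mean as reference")
    if metric_kind in _SENSITIVE_IF_BELOW:
        return "sensitive" if value < cut else "resistant"
    return "sensitive" if value > cut else "resistant"


def agreement_rate(pairs: Sequence[tuple[str, str]]) -> float:
    """Fraction of (simulated label, experimental label) pairs that match."""
    if not pairs:
        raise ValueError("no label pairs supplied")
    return sum(a == b for a, b in pairs) / len(pairs)
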