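"""Critical determinants, dominance hierarchy and patient stratification.

For a fixed drug, a cancer network's response is summarized by a point in the
efficacy-potency plane (efficacy = max of the normalized curve; potency = its
IC50, which is 1 when efficacy < 0.5).  The *critical determinant* of a
network's response is the minimal alteration subset that pins the network's
point: among all subnetworks (every subset of the network's alterations,
including the empty control), take those whose point lies within Euclidean
distance 0.1 of the full network's point and intersect their alteration sets;
the intersection, when nonempty and itself a neighbor, is the determinant.

Determinants carry the D/U response of their source network.  When one
desirable and one undesirable determinant co-occur, simulating their union
decides which *dominates*; stacking these pairwise outcomes yields a leveled
hierarchy (level 1 lowest, higher levels dominant).  Prediction for a new
profile follows its highest-level determinant, falling back to the control
response when none is present.  The conventional-biomarker baseline ranks
single alterations by Fisher's exact association with the D/U labels.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .categorize import ThresholdConfig, categorize, _SweepCache
from .dose import efficacy, ic50
from .genomics import AlterationProfile, GeneNodeMap, alterations_to_status
from .model import (
    CONTROL_PROFILE,
    NetworkDefinition,
    Perturbation,
    SimulationConfig,
)

__all__ = [
    "EfficacyPotencyPoint",
    "CriticalDeterminant",
    "DominanceHierarchy",
    "DominanceCycleError",
    "SameLevelConflictError",
    "subnetworks",
    "efficacy_potency_map",
    "critical_determinant",
    "dominance",
    "predict_response",
    "marker_enrichment_baseline",
    "evaluate_prediction",
    "stratify",
    "stratification_report",
]


class DominanceCycleError(RuntimeError):
    """Pairwise dominance results form a cycle; no consistent leveling exists."""


class SameLevelConflictError(RuntimeError):
    """Two same-level determinants with conflicting labels are both present."""


@dataclass(frozen=True)
class EfficacyPotencyPoint:
    efficacy: float
    potency: float  # IC50 in (0, 1]
    alterations: frozenset[str]

    def distance(self, other: "EfficacyPotencyPoint") -> float:
        return math.hypot(
            self.efficacy - other.efficacy, self.potency - other.potency
        )


@dataclass(frozen=True)
class CriticalDeterminant:
    alterations: frozenset[str]
    response: str  # "D" | "U"
    level: int = 1

    def __post_init__(self) -> None:
        if not self.alterations:
            raise ValueError("a critical determinant is a nonempty alteration set")
        if self.response not in ("D", "U"):
            raise ValueError(f"response must be D or U, got {self.response!r}")

    @property
    def label(self) -> str:
        return "{" + ",".join(sorted(self.alterations)) + "}"


@dataclass
class DominanceHierarchy:
    determinants: list[CriticalDeterminant]
    pairwise_results: dict[tuple[frozenset, frozenset], frozenset] = field(
        default_factory=dict
    )


def subnetworks(profile: AlterationProfile, cap: int = 12) -> list[AlterationProfile]:
    """All 2^k alteration subsets, from the empty control to the full set.

    Subsets are ordered by size then lexicographically, so index 0 is the
    control and the last entry is the original profile.
    """
    alts = sorted(profile.alterations)
    if len(alts) > cap:
        raise ValueError(
            f"{len(alts)} alterations exceed the subset cap of {cap} "
            f"(2^{len(alts)} subnetworks)"
        )
    subsets = []
    for r in range(len(alts) + 1):
        for combo in itertools.combinations(alts, r):
            subsets.append(
                AlterationProfile(
                    sample_id=f"{profile.sample_id}|{'+'.join(combo) or 'control'}",
                    source=profile.source,
                    alterations=frozenset(combo),
                )
            )
    return subsets


def _point(
    cache: _SweepCache,
    gene_map: GeneNodeMap,
    sub: AlterationProfile,
    perturbation: Perturbation,
) -> EfficacyPotencyPoint:
    status = alterations_to_status(sub, gene_map)
    curve = cache.curve(status, perturbation.targets)
    return EfficacyPotencyPoint(
        efficacy=efficacy(curve), potency=ic50(curve), alterations=sub.alterations
    )


def efficacy_potency_map(
    subnets: Sequence[AlterationProfile],
    net: NetworkDefinition,
    gene_map: GeneNodeMap,
    perturbation: Perturbation,
    config: SimulationConfig,
    cache: _SweepCache | None = None,
) -> list[EfficacyPotencyPoint]:
    """One efficacy-potency point per subnetwork (deterministic given seed)."""
    cache = cache or _SweepCache(net, config)
    return [_point(cache, gene_map, sub, perturbation) for sub in subnets]


def critical_determinant(
    points: Sequence[EfficacyPotencyPoint],
    original: EfficacyPotencyPoint,
    radius: float = 0.1,
    response: str | None = None,
) -> CriticalDeterminant | None:
    """The common, minimal alteration set among the original's neighbors.

    Neighbors are subnetwork points within Euclidean distance ``radius`` of
    the original (the original itself included).  The determinant is the
    intersection of the neighbors' alteration sets, required to itself be a
    neighbor; ``None`` when the intersection is empty or not a neighbor --
    the network then responds like whichever neighbor governs it (the
    control, when the control is a neighbor).
    """
    if not any(p.alterations == original.alterations for p in points):
        raise ValueError("points must include the original network's point")
    neighbors = [p for p in points if p.distance(original) < radius]
    common: frozenset[str] | None = None
    for p in neighbors:
        common = p.alterations if common is None else common & p.alterations
    if not common:
        return None
    if not any(p.alterations == common for p in neighbors):
        return None
    return CriticalDeterminant(
        alterations=common, response=response or "U", level=1
    )


def dominance(
    determinants: Sequence[CriticalDeterminant],
    net: NetworkDefinition,
    gene_map: GeneNodeMap,
    perturbation: Perturbation,
    config: SimulationConfig,
    th: ThresholdConfig | None = None,
    cache: _SweepCache | None = None,
) -> DominanceHierarchy:
    """Leveled dominance hierarchy from pairwise D-vs-U union simulations.

    For every (desirable, undesirable) determinant pair the union profile is
    simulated and categorized; the determinant whose label matches the
    union's outcome wins and sits above the loser.  Levels follow the longest
    chain below each determinant (level 1 lowest).  Inconsistent pairwise
    results that form a cycle raise :class:`DominanceCycleError`.
    """
    th = th or ThresholdConfig()
    cache = cache or _SweepCache(net, config)
    dets = list(determinants)
    pairwise: dict[tuple[frozenset, frozenset], frozenset] = {}
    beats: dict[frozenset, set[frozenset]] = {d.alterations: set() for d in dets}
    for d, u in itertools.product(
        [x for x in dets if x.response == "D"],
        [x for x in dets if x.response == "U"],
    ):
        union = AlterationProfile(
            sample_id=f"test|{d.label}+{u.label}",
            source="cell_line",
            alterations=d.alterations | u.alterations,
        )
        status = alterations_to_status(union, gene_map)
        cat = categorize(net, status, CONTROL_PROFILE, perturbation, config, th, cache)
        winner, loser = (d, u) if cat.response == "D" else (u, d)
        pairwise[(d.alterations, u.alterations)] = winner.alterations
        beats[winner.alterations].add(loser.alterations)

    # longest-chain leveling over the "dominates" DAG
    levels: dict[frozenset, int] = {}

    def level_of(key: frozenset, stack: tuple = ()) -> int:
        if key in stack:
            cycle = " -> ".join(sorted(",".join(sorted(k)) for k in stack + (key,)))
            raise DominanceCycleError(f"dominance cycle detected: {cycle}")
        if key not in levels:
            below = beats[key]
            levels[key] = (
                1 + max(level_of(k, stack + (key,)) for k in below) if below else 1
            )
        return levels[key]

    leveled = [
        CriticalDeterminant(d.alterations, d.response, level_of(d.alterations))
        for d in dets
    ]
    return DominanceHierarchy(determinants=leveled, pairwise_results=pairwise)


def predict_response(
    profile: AlterationProfile,
    hierarchy: DominanceHierarchy,
    control_response: str,
) -> str:
    """D/U prediction: the highest-level determinant contained in the profile.

    A profile containing no determinant responds like the control network.
    Conflicting labels at the governing level raise
    :class:`SameLevelConflictError`.
    """
    present = [
        d
        for d in hierarchy.determinants
        if d.alterations <= profile.alterations
    ]
    if not present:
        return control_response
    top = max(d.level for d in present)
    labels = {d.response for d in present if d.level == top}
    if len(labels) > 1:
        raise SameLevelConflictError(
            f"profile {profile.sample_id!r}: conflicting level-{top} determinants"
        )
    return labels.pop()


@dataclass(frozen=True)
class Marker:
    alteration: str
    p_value: float
    enriched_class: str  # class over-represented among carriers


def marker_enrichment_baseline(
    labeled: Sequence[tuple[AlterationProfile, str]],
    k: int = 5,
) -> list[Marker]:
    """Top-k single-alteration biomarkers by Fisher's exact D/U association.

    A marker predicts its enriched class for carriers and the opposite class
    otherwise.  Requires both classes present.
    """
    labels = [lab for _, lab in labeled]
    if len(set(labels)) < 2:
        raise ValueError("both D and U classes are required for enrichment")
    alts = sorted({a for p, _ in labeled for a in p.alterations})
    markers = []
    for alt in alts:
        carrier = np.array([alt in p.alterations for p, _ in labeled])
        is_d = np.array([lab == "D" for lab in labels])
        table = [
            [int(np.sum(carrier & is_d)), int(np.sum(carrier & ~is_d))],
            [int(np.sum(~carrier & is_d)), int(np.sum(~carrier & ~is_d))],
        ]
        _, p = fisher_exact(table, alternative="two-sided")
        rate_carrier = table[0][0] / max(1, table[0][0] + table[0][1])
        rate_rest = table[1][0] / max(1, table[1][0] + table[1][1])
        enriched = "D" if rate_carrier >= rate_rest else "U"
        markers.append(Marker(alt, float(p), enriched))
    markers.sort(key=lambda m: (m.p_value, m.alteration))
    return markers[:k]


def marker_predict(profile: AlterationProfile, marker: Marker) -> str:
    if marker.alteration in profile.alterations:
        return marker.enriched_class
    return "U" if marker.enriched_class == "D" else "D"


def evaluate_prediction(
    predicted: Sequence[str], actual: Sequence[str], positive: str = "D"
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) with ``positive`` as the D class."""
    if len(predicted) != len(actual):
        raise ValueError("prediction and truth lengths differ")
    pred = np.array([p == positive for p in predicted])
    act = np.array([a == positive for a in actual])
    tp = int(np.sum(pred & act))
    tn = int(np.sum(~pred & ~act))
    fp = int(np.sum(pred & ~act))
    fn = int(np.sum(~pred & act))
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (tn + fp) if tn + fp else math.nan
    acc = (tp + tn) / len(actual)
    return sens, spec, acc


def stratify(
    profiles: Sequence[AlterationProfile],
    hierarchy: DominanceHierarchy,
    control_response: str = "U",
) -> dict[str, list[str]]:
    """Partition samples by their governing determinant.

    Cluster keys are determinant labels ordered by (level desc, alterations);
    samples without any determinant form the ``"none"`` cluster.  Every
    cluster is response-pure by construction.
    """
    ordered = sorted(
        hierarchy.determinants, key=lambda d: (-d.level, sorted(d.alterations))
    )
    clusters: dict[str, list[str]] = {}
    for p in profiles:
        governing = None
        present = [d for d in ordered if d.alterations <= p.alterations]
        if present:
            top = max(d.level for d in present)
            at_top = [d for d in present if d.level == top]
            if len({d.response for d in at_top}) > 1:
                raise SameLevelConflictError(
                    f"profile {p.sample_id!r}: conflicting level-{top} determinants"
                )
            governing = at_top[0]
        key = governing.label if governing else "none"
        clusters.setdefault(key, []).append(p.sample_id)
    return clusters


@dataclass
class StratificationReport:
    hierarchy: DominanceHierarchy
    determinant_table: pd.DataFrame
    prediction_table: pd.DataFrame
    clusters: dict[str, list[str]]
    control_response: str


def stratification_report(
    net: NetworkDefinition,
    gene_map: GeneNodeMap,
    profiles: Sequence[AlterationProfile],
    perturbation: Perturbation,
    config: SimulationConfig,
    th: ThresholdConfig | None = None,
    radius: float = 0.1,
    subset_cap: int = 12,
) -> StratificationReport:
    """End-to-end stratification for one drug over a cohort.

    Identifies each profile's critical determinant from its subnetwork
    efficacy-potency map, labels it with the profile's D/U category, builds
    the dominance hierarchy over the distinct determinants and emits
    determinant/prediction tables plus the response-pure clusters.
    """
    th = th or ThresholdConfig()
    cache = _SweepCache(net, config)
    control_curve = cache.curve(CONTROL_PROFILE, perturbation.targets)
    control_cat = categorize(
        net, CONTROL_PROFILE, CONTROL_PROFILE, perturbation, config, th, cache
    )
    control_response = control_cat.response

    found: dict[frozenset, CriticalDeterminant] = {}
    for p in profiles:
        if not p.alterations:
            continue
        subs = subnetworks(p, cap=subset_cap)
        points = efficacy_potency_map(subs, net, gene_map, perturbation, config, cache)
        original = points[-1]
        status = alterations_to_status(p, gene_map)
        cat = categorize(net, status, CONTROL_PROFILE, perturbation, config, th, cache)
        det = critical_determinant(points, original, radius, response=cat.response)
        if det is not None and det.alterations not in found:
            found[det.alterations] = det
    hierarchy = dominance(
        list(found.values()), net, gene_map, perturbation, config, th, cache
    )
    det_rows = [
        {
            "alterations": ";".join(sorted(d.alterations)),
            "response": d.response,
            "level": d.level,
        }
        for d in sorted(hierarchy.determinants, key=lambda d: (-d.level, d.label))
    ]
    pred_rows = []
    for p in profiles:
        pred = predict_response(p, hierarchy, control_response)
        pred_rows.append({"sample_id": p.sample_id, "predicted": pred})
    clusters = stratify(profiles, hierarchy, control_response)
    return StratificationReport(
        hierarchy=hierarchy,
        determinant_table=pd.DataFrame(
            det_rows, columns=["alterations", "response", "level"]
        ),
        prediction_table=pd.DataFrame(pred_rows, columns=["sample_id", "predicted"]),
        clusters=clusters,
        control_response=control_response,
    )
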