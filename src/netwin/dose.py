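"""Dose-dependent perturbation simulation and dose-response metrics.

A drug at dose ``x`` suppresses its target (node state or link weight forced
to 0) independently at each simulation step with probability ``x``.  The
response at a dose is the fraction of initial states whose stochastic
trajectory ends in the cell-death phenotype; sweeping the dose grid
0, 0.1, ..., 1 yields the dose-response curve ``f(x)`` of a cancer network
and ``g(x)`` of the alteration-free control network.  Curves are normalized
by shifting the dose-0 value to 0 (and clipping to [0, 1]).

Scalar metrics:

* efficacy  = max f(x)                     (toxicity = efficacy of g)
* IC50      = linearly interpolated dose where f crosses 0.5
              (1 when efficacy < 0.5)
* AUC       = trapezoidal area of f over [0, 1]
* sMED/sMTD = interpolated doses where f resp. g first reach 0.25;
              therapeutic window = sMTD - sMED
* CI        = IC50_AB/IC50_A + IC50_AB/IC50_B  (<1 synergy, 1 additive,
              >1 antagonism)

Two IC50 modes exist: ``scaled`` (default) interpolates dimensionally,
``x1 + (0.5 - f(x1))/(f(x2) - f(x1)) * (x2 - x1)``; ``literal`` evaluates the
printed formula ``(0.5 - f(x1))/(f(x2) - f(x1)) + x1``, which omits the grid
spacing and is kept verbatim for comparison.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import (
    NetworkDefinition,
    Perturbation,
    SimulationConfig,
    StatusProfile,
    Target,
    initial_state_matrix,
    stochastic_batch_run,
)

__all__ = [
    "DOSE_GRID",
    "DoseResponseCurve",
    "DoseResponseLandscape",
    "ResponseMetrics",
    "death_ratio",
    "dose_sweep",
    "normalize_curve",
    "efficacy",
    "toxicity",
    "ic50",
    "auc",
    "smed_smtd",
    "landscape",
    "combination_index",
    "response_metrics",
    "curve_frame",
]

DOSE_GRID: tuple[float, ...] = tuple(round(i / 10, 1) for i in range(11))


@dataclass(frozen=True)
class DoseResponseCurve:
    doses: tuple[float, ...]
    values: tuple[float, ...]
    normalized: bool = False
    seed: int | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if len(self.doses) != len(self.values):
            raise ValueError("doses and values must have equal length")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("dose grid must be strictly increasing")
        if self.normalized and self.values and self.values[0] != 0.0:
            raise ValueError("normalized curve must start at 0")

    def value_at(self, dose: float) -> float:
        return self.values[self.doses.index(dose)]


@dataclass(frozen=True)
class DoseResponseLandscape:
    """Cell-death ratio over a 2-D dose grid for cancer and control."""

    x_doses: tuple[float, ...]
    y_doses: tuple[float, ...]
    cancer: np.ndarray  # shape (len(y_doses), len(x_doses))
    control: np.ndarray
    normalized: bool = False

    @property
    def optimality(self) -> np.ndarray:
        """f(x, y) - g(x, y): positive cells are the therapeutic window."""
        return self.cancer - self.control


@dataclass(frozen=True)
class ResponseMetrics:
    efficacy: float
    ic50: float
    auc: float
    toxicity: float
    smed: float
    smtd: float
    window: float


def death_ratio(
    net: NetworkDefinition,
    profile: StatusProfile,
    perturbation: Perturbation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Fraction of initial states converging to cell death under a drug.

    Every initial state gets an independent per-step Bernoulli suppression
    schedule per drug component; with ``config.n_replicates > 1`` the death
    indicator is averaged over that many schedules per state.  Called without
    an explicit generator the draw stream restarts from ``config.seed``, so
    repeated calls are reproducible and identical profiles compared under
    identical perturbations share their schedules exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    S0 = initial_state_matrix(net, profile, config)
    deaths = 0.0
    for _ in range(config.n_replicates):
        activity = stochastic_batch_run(net, profile, S0, perturbation, config, rng)
        deaths += float(np.mean(activity > config.death_threshold))
    return deaths / config.n_replicates


def dose_sweep(
    net: NetworkDefinition,
    profile: StatusProfile,
    targets: Sequence[Target] | Perturbation,
    config: SimulationConfig,
    doses: Sequence[float] = DOSE_GRID,
) -> DoseResponseCurve:
    """Raw dose-response curve: death ratio at every grid dose.

    All components share the single grid dose (combination curves are
    single-axis with equal component doses; the 2-D landscape is the general
    object for independent dosing).
    """
    if isinstance(targets, Perturbation):
        targets = targets.targets
    values = []
    for dose in doses:
        pert = Perturbation.of(targets, dose)
        values.append(death_ratio(net, profile, pert, config))
    return DoseResponseCurve(
        doses=tuple(doses),
        values=tuple(values),
        normalized=False,
        seed=config.seed,
        n_replicates=config.n_replicates,
    )


def normalize_curve(curve: DoseResponseCurve) -> DoseResponseCurve:
    """Shift the dose-0 value to 0 and clip to [0, 1]."""
    if curve.normalized:
        raise ValueError("curve is already normalized")
    base = curve.values[0]
    vals = tuple(min(1.0, max(0.0, v - base)) for v in curve.values)
    return replace(curve, values=vals, normalized=True)


def _require_normalized(curve: DoseResponseCurve) -> None:
    if not curve.normalized:
        raise ValueError("metric requires a normalized curve")


def efficacy(curve: DoseResponseCurve) -> float:
    """Maximal effect over the dose grid."""
    _require_normalized(curve)
    return max(curve.values)


def toxicity(control_curve: DoseResponseCurve) -> float:
    """Toxicity is, by definition, the efficacy of the control network curve."""
    return efficacy(control_curve)


def _first_crossing(curve: DoseResponseCurve, level: float) -> tuple[float, float, float, float]:
    """(x1, x2, f1, f2) around the first from-below crossing of ``level``."""
    for j in range(1, len(curve.doses)):
        if curve.values[j] >= level:
            return (
                curve.doses[j - 1],
                curve.doses[j],
                curve.values[j - 1],
                curve.values[j],
            )
    raise ValueError(f"curve never reaches {level}")


def ic50(curve: DoseResponseCurve, mode: str = "scaled") -> float:
    """Interpolated dose of half-maximal response; 1 when efficacy < 0.5.

    ``x1``/``x2`` are the largest/smallest grid doses before/after the curve
    crosses 0.5.
    """
    _require_normalized(curve)
    if mode not in ("scaled", "literal"):
        raise ValueError(f"unknown IC50 mode {mode!r}")
    if efficacy(curve) < 0.5:
        return 1.0
    x1, x2, f1, f2 = _first_crossing(curve, 0.5)
    if f2 == f1:
        raise ZeroDivisionError("degenerate crossing: f(x2) == f(x1) at 0.5")
    frac = (0.5 - f1) / (f2 - f1)
    if mode == "scaled":
        return x1 + frac * (x2 - x1)
    return frac + x1


def auc(curve: DoseResponseCurve) -> float:
    """Trapezoidal area under the normalized curve over the dose interval."""
    _require_normalized(curve)
    return float(np.trapezoid(curve.values, curve.doses))


def smed_smtd(
    f_curve: DoseResponseCurve,
    g_curve: DoseResponseCurve,
    threshold: float = 0.25,
) -> tuple[float, float, float]:
    """(sMED, sMTD, window).

    sMED: interpolated dose where the cancer curve first reaches the
    threshold (NaN when it never does, leaving the window undefined).
    sMTD: same for the control curve, with ``inf`` when the control never
    becomes toxic -- the window is then unbounded above.
    """
    _require_normalized(f_curve)
    _require_normalized(g_curve)
    if f_curve.doses != g_curve.doses:
        raise ValueError("cancer and control curves must share the dose grid")

    def crossing(curve: DoseResponseCurve, missing: float) -> float:
        try:
            x1, x2, f1, f2 = _first_crossing(curve, threshold)
        except ValueError:
            return missing
        if f2 == f1:
            return x2
        return x1 + (threshold - f1) / (f2 - f1) * (x2 - x1)

    smed = crossing(f_curve, math.nan)
    smtd = crossing(g_curve, math.inf)
    window = smtd - smed if not math.isnan(smed) else math.nan
    return smed, smtd, window


def landscape(
    net: NetworkDefinition,
    cancer_profile: StatusProfile,
    control_profile: StatusProfile,
    target_a: Target,
    target_b: Target,
    config: SimulationConfig,
    x_doses: Sequence[float] = DOSE_GRID,
    y_doses: Sequence[float] = DOSE_GRID,
    normalized: bool = True,
) -> DoseResponseLandscape:
    """2-D dose-response landscape f(x, y) and g(x, y) for a target pair.

    Row ``y = 0`` reproduces the single-target sweep of ``target_a`` exactly
    (dose-0 components draw nothing from the random stream).
    """
    if target_a == target_b:
        raise ValueError("landscape requires two distinct targets")
    f = np.zeros((len(y_doses), len(x_doses)))
    g = np.zeros_like(f)
    for i, y in enumerate(y_doses):
        for j, x in enumerate(x_doses):
            pert = Perturbation(((target_a, x), (target_b, y)))
            f[i, j] = death_ratio(net, cancer_profile, pert, config)
            g[i, j] = death_ratio(net, control_profile, pert, config)
    if normalized:
        f = np.clip(f - f[0, 0], 0.0, 1.0)
        g = np.clip(g - g[0, 0], 0.0, 1.0)
    return DoseResponseLandscape(
        x_doses=tuple(x_doses),
        y_doses=tuple(y_doses),
        cancer=f,
        control=g,
        normalized=normalized,
    )


def combination_index(ic50_a: float, ic50_b: float, ic50_ab: float) -> float:
    """CI = IC50_AB/IC50_A + IC50_AB/IC50_B (<1 synergistic, >1 antagonistic)."""
    for name, v in (("ic50_a", ic50_a), ("ic50_b", ic50_b), ("ic50_ab", ic50_ab)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1], got {v}")
    return ic50_ab / ic50_a + ic50_ab / ic50_b


def response_metrics(
    f_curve: DoseResponseCurve,
    g_curve: DoseResponseCurve,
    window_threshold: float = 0.25,
) -> ResponseMetrics:
    """Bundle all scalar metrics for one cancer/control curve pair."""
    smed, smtd, window = smed_smtd(f_curve, g_curve, window_threshold)
    return ResponseMetrics(
        efficacy=efficacy(f_curve),
        ic50=ic50(f_curve),
        auc=auc(f_curve),
        toxicity=toxicity(g_curve),
        smed=smed,
        smtd=smtd,
        window=window,
    )


def curve_frame(curve: DoseResponseCurve) -> pd.DataFrame:
    return pd.DataFrame({"dose": curve.doses, "value": curve.values})
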