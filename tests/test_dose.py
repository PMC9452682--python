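"""Dose-response curves, metrics and the binomial oracle for the toy network."""

import math

import numpy as np
import pytest
from scipy.stats import binom

from netwin import (
    CONTROL_PROFILE,
    DoseResponseCurve,
    Perturbation,
    SimulationConfig,
    StatusProfile,
    Target,
    auc,
    basin_of_apoptosis,
    combination_index,
    death_ratio,
    dose_sweep,
    efficacy,
    ic50,
    landscape,
    normalize_curve,
    response_metrics,
    smed_smtd,
    toxicity,
)


def curve(values, doses=None, normalized=True):
    doses = doses if doses is not None else tuple(
        round(i / (len(values) - 1), 3) for i in range(len(values))
    )
    return DoseResponseCurve(tuple(doses), tuple(values), normalized=normalized)


def toy_death_oracle(dose, steady_steps=100, threshold=0.9):
    """Closed form for the toy: Z mirrors X one step later, so death
    (activity strictly above the threshold) allows at most
    ceil(steps*(1-threshold)) - 1 suppressed steps in the window."""
    max_off = math.ceil(steady_steps * (1 - threshold)) - 1
    return float(binom.cdf(max_off, steady_steps, dose))


class TestDeathRatio:
    def test_zero_dose_equals_basin(self, toy, config):
        pert = Perturbation.single(Target.of_node("X"), dose=0.0)
        assert death_ratio(toy, CONTROL_PROFILE, pert, config) == basin_of_apoptosis(
            toy, CONTROL_PROFILE, config
        )

    def test_full_dose_abolishes_death(self, toy, config):
        pert = Perturbation.single(Target.of_node("X"), dose=1.0)
        assert death_ratio(toy, CONTROL_PROFILE, pert, config) == 0.0

    def test_half_dose_matches_binomial_oracle(self, toy):
        cfg = SimulationConfig(seed=2, n_replicates=50)
        pert = Perturbation.single(Target.of_node("X"), dose=0.5)
        # P(Bin(100, 0.5) <= 10) is astronomically small
        assert death_ratio(toy, CONTROL_PROFILE, pert, cfg) == pytest.approx(
            toy_death_oracle(0.5), abs=1e-3
        )

    def test_reproducible_given_seed(self, toy):
        cfg = SimulationConfig(seed=9)
        pert = Perturbation.single(Target.of_node("X"), dose=0.3)
        assert death_ratio(toy, CONTROL_PROFILE, pert, cfg) == death_ratio(
            toy, CONTROL_PROFILE, pert, cfg
        )


class TestDoseSweep:
    def test_toy_sweep_tracks_oracle_and_monotonicity(self, toy):
        cfg = SimulationConfig(seed=4, n_replicates=30)
        c = dose_sweep(toy, CONTROL_PROFILE, [Target.of_node("X")], cfg)
        assert c.values[0] == 1.0 and c.values[-1] == 0.0
        for dose, value in zip(c.doses, c.values):
            se = math.sqrt(max(toy_death_oracle(dose) * (1 - toy_death_oracle(dose)), 1e-6) / (8 * 30))
            assert value == pytest.approx(toy_death_oracle(dose), abs=max(4 * se, 0.02))

    def test_empty_target_list_gives_flat_basin_curve(self, toy, config):
        c = dose_sweep(toy, CONTROL_PROFILE, [], config)
        assert set(c.values) == {basin_of_apoptosis(toy, CONTROL_PROFILE, config)}

    def test_curve_values_are_proportions(self, p53, dd_on):
        cfg = SimulationConfig(
            input_clamp={"DNA_damage": 1}, seed=1, enumeration_cap=10, n_samples=256
        )
        c = dose_sweep(p53, CONTROL_PROFILE, [Target.of_node("AKT")], cfg)
        assert all(0.0 <= v <= 1.0 for v in c.values)


class TestNormalize:
    def test_shifts_baseline_to_zero(self):
        raw = curve((0.2, 0.2, 0.9), normalized=False)
        out = normalize_curve(raw)
        assert out.values == pytest.approx((0.0, 0.0, 0.7))
        assert out.normalized

    def test_all_zero_curve_unchanged(self):
        out = normalize_curve(curve((0.0, 0.0, 0.0), normalized=False))
        assert out.values == (0.0, 0.0, 0.0)

    def test_clipping_below_zero(self):
        out = normalize_curve(curve((0.3, 0.1), normalized=False))
        assert out.values == (0.0, 0.0)

    def test_double_normalization_rejected(self):
        with pytest.raises(ValueError, match="already"):
            normalize_curve(normalize_curve(curve((0.1, 0.5), normalized=False)))


class TestMetrics:
    def test_efficacy_is_max(self):
        assert efficacy(curve((0.0, 0.2, 0.8, 0.6))) == 0.8
        assert efficacy(curve((0.0, 0.0))) == 0.0

    def test_toxicity_is_control_efficacy(self):
        g = curve((0.0, 0.3, 0.4))
        assert toxicity(g) == efficacy(g)

    def test_ic50_worked_grid_scaled_and_literal(self):
        c = curve((0.0, 0.0, 0.4, 0.6, 1.0), doses=(0.0, 0.1, 0.2, 0.3, 0.4))
        assert ic50(c, mode="scaled") == pytest.approx(0.25)
        assert ic50(c, mode="literal") == pytest.approx(0.7)

    def test_ic50_low_efficacy_is_one(self):
        assert ic50(curve((0.0, 0.2, 0.4))) == 1.0

    def test_ic50_linear_curve(self):
        c = curve(tuple(i / 10 for i in range(11)))
        assert ic50(c, mode="scaled") == pytest.approx(0.5)

    def test_auc_values(self):
        linear = curve(tuple(i / 10 for i in range(11)))
        assert auc(linear) == pytest.approx(0.5)
        step_up = curve((0.0,) + (1.0,) * 10)
        assert auc(step_up) == pytest.approx(0.95)
        assert auc(curve((0.0,) * 11)) == 0.0

    def test_unnormalized_curve_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            efficacy(curve((0.1, 0.9), normalized=False))


class TestTherapeuticWindow:
    def test_smed_interpolation(self):
        f = curve((0.0, 0.2, 0.3, 0.9), doses=(0.0, 0.1, 0.2, 0.3))
        g = curve((0.0, 0.0, 0.0, 0.5), doses=(0.0, 0.1, 0.2, 0.3))
        smed, smtd, window = smed_smtd(f, g)
        assert smed == pytest.approx(0.15)
        assert smtd == pytest.approx(0.25)
        assert window == pytest.approx(0.1)

    def test_tolerant_control_gives_unbounded_window(self):
        f = curve((0.0, 0.5, 1.0), doses=(0.0, 0.5, 1.0))
        g = curve((0.0, 0.0, 0.1), doses=(0.0, 0.5, 1.0))
        smed, smtd, window = smed_smtd(f, g)
        assert math.isinf(smtd) and math.isinf(window)

    def test_equal_curves_close_the_window(self):
        f = curve((0.0, 0.5, 1.0), doses=(0.0, 0.5, 1.0))
        smed, smtd, window = smed_smtd(f, f)
        assert window <= 0.0

    def test_ineffective_drug_has_undefined_window(self):
        f = curve((0.0, 0.1, 0.2), doses=(0.0, 0.5, 1.0))
        g = curve((0.0, 0.5, 0.9), doses=(0.0, 0.5, 1.0))
        smed, smtd, window = smed_smtd(f, g)
        assert math.isnan(smed) and math.isnan(window)


class TestLandscape:
    def test_marginal_row_matches_single_target_sweep(self, toy):
        cfg = SimulationConfig(seed=6)
        grid = (0.0, 0.5, 1.0)
        land = landscape(
            toy,
            CONTROL_PROFILE,
            CONTROL_PROFILE,
            Target.of_node("X"),
            Target.of_node("Y"),
            cfg,
            x_doses=grid,
            y_doses=grid,
            normalized=False,
        )
        single = dose_sweep(toy, CONTROL_PROFILE, [Target.of_node("X")], cfg, doses=grid)
        np.testing.assert_allclose(land.cancer[0, :], single.values)

    def test_normalized_origin_and_optimality(self, toy):
        cfg = SimulationConfig(seed=6)
        grid = (0.0, 1.0)
        land = landscape(
            toy,
            CONTROL_PROFILE,
            CONTROL_PROFILE,
            Target.of_node("X"),
            Target.of_node("Y"),
            cfg,
            x_doses=grid,
            y_doses=grid,
        )
        assert land.cancer[0, 0] == 0.0
        assert land.optimality[0, 0] == 0.0

    def test_identical_targets_rejected(self, toy, config):
        with pytest.raises(ValueError, match="distinct"):
            landscape(
                toy,
                CONTROL_PROFILE,
                CONTROL_PROFILE,
                Target.of_node("X"),
                Target.of_node("X"),
                config,
            )


class TestCombinationIndex:
    @pytest.mark.parametrize(
        "a,b,ab,expected",
        [(0.4, 0.4, 0.2, 1.0), (0.4, 0.4, 0.1, 0.5), (0.2, 0.2, 0.3, 3.0)],
    )
    def test_worked_values(self, a, b, ab, expected):
        assert combination_index(a, b, ab) == pytest.approx(expected)

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            combination_index(0.0, 0.5, 0.5)


def test_response_metrics_bundle(toy):
    cfg = SimulationConfig(seed=8, n_replicates=5)
    f = normalize_curve(dose_sweep(toy, StatusProfile.from_dict({"Y": "A"}), [Target.of_node("Y")], cfg))
    g = normalize_curve(dose_sweep(toy, CONTROL_PROFILE, [Target.of_node("Y")], cfg))
    m = response_metrics(f, g)
    assert 0.0 <= m.efficacy <= 1.0
    assert 0.0 < m.ic50 <= 1.0
    assert m.toxicity == efficacy(g)
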