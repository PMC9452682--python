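"""Critical determinants, dominance hierarchy, prediction and stratification."""

import pytest

from netwin import (
    AlterationProfile,
    CriticalDeterminant,
    Perturbation,
    SimulationConfig,
    critical_determinant,
    dominance,
    evaluate_prediction,
    marker_enrichment_baseline,
    predict_response,
    stratification_report,
    stratify,
    subnetworks,
)
from netwin.stratify import (
    DominanceHierarchy,
    EfficacyPotencyPoint,
    SameLevelConflictError,
    marker_predict,
)


def prof(*alts, sample="s1"):
    return AlterationProfile(sample, "patient", frozenset(alts))


def point(eff, pot, *alts):
    return EfficacyPotencyPoint(eff, pot, frozenset(alts))


class TestSubnetworks:
    def test_powerset_sizes(self):
        assert len(subnetworks(prof("a", "b"))) == 4
        assert len(subnetworks(prof("a", "b", "c"))) == 8
        assert len(subnetworks(prof())) == 1

    def test_ordering_control_first_full_last(self):
        subs = subnetworks(prof("a", "b"))
        assert subs[0].alterations == frozenset()
        assert subs[-1].alterations == {"a", "b"}

    def test_cap_enforced(self):
        big = prof(*[f"x{i}" for i in range(13)])
        with pytest.raises(ValueError, match="cap"):
            subnetworks(big)


class TestCriticalDeterminant:
    def test_four_subset_toy_recovers_causal(self):
        # {a1} and {a1,a2} are neighbors of the original; {a2} and {} are not
        pts = [
            point(0.0, 1.0),
            point(0.9, 0.2, "a1"),
            point(0.05, 1.0, "a2"),
            point(0.92, 0.21, "a1", "a2"),
        ]
        det = critical_determinant(pts, pts[-1], response="D")
        assert det is not None and det.alterations == {"a1"}

    def test_control_profile_has_none(self):
        pts = [point(0.1, 1.0)]
        assert critical_determinant(pts, pts[0]) is None

    def test_irrelevant_alterations_give_none(self):
        # all subsets cluster together: intersection is empty
        pts = [
            point(0.5, 0.5),
            point(0.51, 0.5, "a1"),
            point(0.5, 0.51, "a2"),
            point(0.52, 0.5, "a1", "a2"),
        ]
        assert critical_determinant(pts, pts[-1]) is None

    def test_intersection_must_itself_be_neighbor(self):
        # {a1,a2} and full set are neighbors, but their intersection {a1,a2}
        # equals the smaller neighbor -> fine; remove it and the determinant
        # falls back to None
        pts = [
            point(0.0, 1.0),
            point(0.9, 0.2, "a1"),
            point(0.9, 0.2, "a2"),
            point(0.91, 0.2, "a1", "a2"),
        ]
        det = critical_determinant(pts, pts[-1])
        assert det is None  # intersection of {a1},{a2},{a1,a2} is empty

    def test_minimality_on_exhaustive_toy(self, demo):
        """Removing any alteration from the determinant leaves the neighborhood."""
        net, gmap, plan = demo
        cfg = SimulationConfig(input_clamp={"signal": 1}, seed=7)
        from netwin.stratify import efficacy_potency_map

        p = prof(*(plan.causal | set(plan.passengers)))
        subs = subnetworks(p)
        pts = efficacy_potency_map(subs, net, gmap, Perturbation.single(plan.target), cfg)
        original = pts[-1]
        det = critical_determinant(pts, original, response="D")
        assert det is not None and det.alterations == plan.causal
        for sub in det.alterations:
            reduced = det.alterations - {sub}
            reduced_pt = next(p for p in pts if p.alterations == reduced)
            assert reduced_pt.distance(original) >= 0.1


class TestDominance:
    def test_single_determinant_is_level_one(self, demo):
        net, gmap, plan = demo
        cfg = SimulationConfig(input_clamp={"signal": 1}, seed=7)
        d = CriticalDeterminant(plan.causal, "D")
        h = dominance([d], net, gmap, Perturbation.single(plan.target), cfg)
        assert [x.level for x in h.determinants] == [1]

    def test_union_decides_winner(self, demo):
        net, gmap, plan = demo
        cfg = SimulationConfig(input_clamp={"signal": 1}, seed=7)
        d = CriticalDeterminant(plan.causal, "D")
        u = CriticalDeterminant(plan.dominant, "U")
        h = dominance([d, u], net, gmap, Perturbation.single(plan.target), cfg)
        levels = {x.response: x.level for x in h.determinants}
        assert levels["U"] > levels["D"]
        assert h.pairwise_results[(plan.causal, plan.dominant)] == plan.dominant


class TestPredictResponse:
    HIERARCHY = DominanceHierarchy(
        determinants=[
            CriticalDeterminant(frozenset({"d1"}), "D", 2),
            CriticalDeterminant(frozenset({"u1"}), "U", 3),
            CriticalDeterminant(frozenset({"d2"}), "D", 1),
        ]
    )

    def test_highest_level_wins(self):
        assert predict_response(prof("d1", "u1"), self.HIERARCHY, "U") == "U"
        assert predict_response(prof("d1", "d2"), self.HIERARCHY, "U") == "D"

    def test_empty_profile_follows_control(self):
        assert predict_response(prof(), self.HIERARCHY, "U") == "U"
        assert predict_response(prof(), self.HIERARCHY, "D") == "D"

    def test_single_determinant_prediction(self):
        assert predict_response(prof("d2", "x"), self.HIERARCHY, "U") == "D"

    def test_same_level_conflict_raises(self):
        clash = DominanceHierarchy(
            determinants=[
                CriticalDeterminant(frozenset({"a"}), "D", 1),
                CriticalDeterminant(frozenset({"b"}), "U", 1),
            ]
        )
        with pytest.raises(SameLevelConflictError):
            predict_response(prof("a", "b"), clash, "U")

    def test_monotone_under_hierarchy(self):
        """Adding alterations changes the call only via a higher level."""
        base = predict_response(prof("d2"), self.HIERARCHY, "U")
        extended = predict_response(prof("d2", "d1"), self.HIERARCHY, "U")
        assert base == "D" and extended == "D"
        overridden = predict_response(prof("d2", "d1", "u1"), self.HIERARCHY, "U")
        assert overridden == "U"


class TestEnrichmentBaseline:
    def test_perfect_association_ranks_first(self):
        labeled = [
            (prof("m", sample=f"d{i}"), "D") for i in range(5)
        ] + [(prof(sample=f"u{i}"), "U") for i in range(5)]
        markers = marker_enrichment_baseline(labeled, k=2)
        assert markers[0].alteration == "m"
        assert markers[0].enriched_class == "D"
        preds = [marker_predict(p, markers[0]) for p, _ in labeled]
        sens, spec, acc = evaluate_prediction(preds, [l for _, l in labeled])
        assert (sens, spec, acc) == (1.0, 1.0, 1.0)

    def test_degenerate_single_class_rejected(self):
        labeled = [(prof("m"), "D"), (prof(), "D")]
        with pytest.raises(ValueError, match="class"):
            marker_enrichment_baseline(labeled)


class TestStratify:
    def test_clusters_partition_and_purity(self):
        h = self_h = DominanceHierarchy(
            determinants=[
                CriticalDeterminant(frozenset({"d"}), "D", 1),
                CriticalDeterminant(frozenset({"u"}), "U", 2),
            ]
        )
        profiles = [
            prof("d", sample="p1"),
            prof("d", "u", sample="p2"),
            prof(sample="p3"),
            prof("u", sample="p4"),
        ]
        clusters = stratify(profiles, h)
        assert clusters == {"{d}": ["p1"], "{u}": ["p2", "p4"], "none": ["p3"]}
        # purity: every member of a cluster shares its predicted response
        for key, members in clusters.items():
            calls = {
                predict_response(p, h, "U") for p in profiles if p.sample_id in members
            }
            assert len(calls) == 1


def test_stratification_report_end_to_end(demo):
    """Full chain on the designed fixture: recover both determinants, level
    them correctly, and predict every profile from the hierarchy."""
    net, gmap, plan = demo
    cfg = SimulationConfig(input_clamp={"signal": 1}, seed=7)
    profiles = [
        prof(*plan.causal, sample="p1"),
        prof(*(plan.causal | plan.dominant), sample="p2"),
        prof(*plan.dominant, sample="p3"),
        prof(plan.passengers[0], sample="p4"),
        prof(sample="p5"),
    ]
    report = stratification_report(
        net, gmap, profiles, Perturbation.single(plan.target), cfg, subset_cap=8
    )
    table = report.determinant_table
    assert set(table.alterations) == {
        ";".join(sorted(plan.causal)),
        ";".join(sorted(plan.dominant)),
    }
    by_alt = dict(zip(table.alterations, table.level))
    assert by_alt[";".join(sorted(plan.dominant))] > by_alt[";".join(sorted(plan.causal))]
    preds = dict(
        zip(report.prediction_table.sample_id, report.prediction_table.predicted)
    )
    assert preds == {"p1": "D", "p2": "U", "p3": "U", "p4": "U", "p5": "U"}
    assert report.control_response == "U"
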