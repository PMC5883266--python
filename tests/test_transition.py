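import numpy as np
import pytest

from doseshift import (
    DVH,
    Beam,
    DecisionRules,
    PlanRecord,
    TransitionReport,
    ValidationError,
    build_plan3,
    compare_plans,
    d95_adjustment_flag,
    delta_mu,
    dose_at_volume,
    dvh_delta_report,
    recommend_prescription,
    scale_dose,
)
from doseshift.radbio import OrganModel, eud
from doseshift.simulate import make_sigmoid_dvh
from doseshift.transition import GammaSummary

MODELS = {
    "PTV": OrganModel("PTV", "target", 50.0, 2.0, -10.0, "Control"),
    "Lungs": OrganModel("Lungs", "parallel", 24.5, 2.0, 1.2, "Pneumonitis"),
}


def make_plan(label, mus, dvh_scale=1.0, dpr=60.0, algorithm="ref"):
    dvhs = {
        "PTV": scale_dose(make_sigmoid_dvh("PTV", dpr, 2.0), dvh_scale),
        "Lungs": scale_dose(make_sigmoid_dvh("Lungs", 0.22 * dpr, 0.3), dvh_scale),
    }
    return PlanRecord(
        label=label,
        algorithm=algorithm,
        dose_mode="Dw",
        dpr=dpr,
        diso=dpr * dvh_scale,
        beams=tuple(Beam(f"B{i}", m) for i, m in enumerate(mus, 1)),
        dvhs=dvhs,
    )


class TestDeltaMU:
    def test_identical_plans_zero_delta(self):
        p1 = make_plan("plan1", [100, 100])
        p2 = make_plan("plan2", [100, 100])
        dm = delta_mu(p1, p2)
        assert dm.total == 0
        assert all(v == 0 for v in dm.per_beam.values())

    def test_sign_and_percent(self):
        p1 = make_plan("plan1", [100, 100])
        p2 = make_plan("plan2", [104, 104])
        dm = delta_mu(p1, p2)
        assert dm.total == pytest.approx(-8.0)
        assert dm.total_percent == pytest.approx(-4.0)

    def test_beam_mismatch_rejected(self):
        p1 = make_plan("plan1", [100, 100])
        p2 = PlanRecord(
            "plan2", "new", "Dm", 60.0, 60.0, (Beam("X1", 100.0), Beam("X2", 100.0))
        )
        with pytest.raises(ValidationError):
            delta_mu(p1, p2)


class TestBuildPlan3:
    def test_equal_mus_reproduce_plan2(self):
        p1 = make_plan("plan1", [100, 100])
        p2 = make_plan("plan2", [100, 100], algorithm="new")
        p3 = build_plan3(p1, p2)
        assert p3.diso == p2.diso
        np.testing.assert_allclose(
            p3.dvhs["PTV"].dose_bins, p2.dvhs["PTV"].dose_bins
        )

    def test_diso_rescaled_by_mu_transfer(self):
        p1 = make_plan("plan1", [100, 100])
        p2 = make_plan("plan2", [104, 104], algorithm="new")
        p3 = build_plan3(p1, p2)
        assert p3.diso == pytest.approx(60.0 * 200 / 208)  # 57.69 Gy
        # exact inverse relation when both plans are normalized at Dpr
        assert p3.diso / p1.diso == pytest.approx(p1.total_mu / p2.total_mu)

    def test_negative_delta_mu_lowers_plan3_diso(self):
        p1 = make_plan("plan1", [100, 100])
        p2 = make_plan("plan2", [110, 106], algorithm="new")
        assert build_plan3(p1, p2).diso < p1.diso

    def test_missing_dvhs_rejected(self):
        p1 = make_plan("plan1", [100, 100])
        p2 = PlanRecord(
            "plan2", "new", "Dm", 60.0, 60.0, tuple(p1.beams), dvhs={}
        )
        with pytest.raises(ValidationError):
            build_plan3(p1, p2)


class TestDVHDeltas:
    def test_identical_plans_zero_deltas(self):
        p1 = make_plan("plan1", [100, 100])
        rows = dvh_delta_report(p1, p1, MODELS)
        for row in rows.values():
            for md in row.metrics.values():
                assert md.delta == 0
            assert row.eud.delta == 0

    def test_uniform_scaling_shifts_every_dose_metric_equally(self):
        p1 = make_plan("plan1", [100, 100])
        p2 = make_plan("plan2", [100, 100], dvh_scale=0.97)
        rows = dvh_delta_report(p1, p2, MODELS)
        for row in rows.values():
            for name, md in row.metrics.items():
                if name.startswith("D"):
                    assert md.delta_percent == pytest.approx(-3.0, abs=1e-9)
            # EUD scales with dose too, so its sign matches the D95% shift
            assert row.eud.delta < 0

    def test_structure_without_model_is_flagged(self):
        p1 = make_plan("plan1", [100, 100])
        rows = dvh_delta_report(p1, p1, {"PTV": MODELS["PTV"]})
        assert rows["Lungs"].model_missing
        assert rows["Lungs"].eud is None
        assert not rows["PTV"].model_missing


class TestD95Flag:
    @pytest.mark.parametrize(
        "scale,expected",
        [
            (0.99, "no_adjustment"),  # ~1% shift
            (0.96, "consider_adjustment"),  # ~4% shift
            (0.98, "consider_adjustment"),  # exactly 2%: strict boundary
        ],
    )
    def test_tolerance_boundary(self, scale, expected):
        p1 = make_plan("plan1", [100, 100])
        p2 = make_plan("plan2", [100, 100], dvh_scale=scale)
        flag, pct = d95_adjustment_flag(p1, p2, DecisionRules())
        assert flag == expected
        assert pct == pytest.approx(100 * (scale - 1), abs=1e-9)


def _report(p=0.5, d95=1.0, pass_rates=(0.99, 0.99)):
    rep = TransitionReport(target_structure="PTV")
    rep.wilcoxon_p = p
    rep.d95_delta_percent = d95
    rep.d95_flag = "no_adjustment" if abs(d95) < 2 else "consider_adjustment"
    rep.gamma_summaries = [
        GammaSummary(2.0, 2.0, pass_rates[0], 100),
        GammaSummary(3.0, 3.0, pass_rates[1], 100),
    ]
    return rep


class TestDecision:
    def setup_method(self):
        self.p1 = make_plan("plan1", [100, 100])
        p2 = make_plan("plan2", [100, 100], algorithm="new")
        self.p3 = build_plan3(self.p1, p2)
        self.rules = DecisionRules()

    def test_all_good_keeps_dpr(self):
        out = recommend_prescription(_report(), self.p1, self.p3, self.rules, MODELS)
        assert out.decision == "keep_dpr"

    def test_significant_difference_triggers_adjustment(self):
        out = recommend_prescription(
            _report(p=0.01), self.p1, self.p3, self.rules, MODELS
        )
        assert out.decision == "consider_adjustment"
        assert out.suggested_dpr == pytest.approx(
            eud(self.p3.dvhs["PTV"], -10.0), rel=1e-12
        )

    def test_suggested_dpr_in_band_example(self):
        # prescription 60 Gy, plan3 target EUD near 55 Gy: inside the 5-10% band
        p2 = make_plan("plan2", [100 / 0.92] * 2, algorithm="new")
        p3 = build_plan3(self.p1, p2)
        out = recommend_prescription(_report(p=0.01), self.p1, p3, self.rules, MODELS)
        assert out.decision == "consider_adjustment"
        assert out.suggested_dpr == pytest.approx(55.0, abs=0.5)
        assert out.in_5_10_band

    def test_small_shift_flagged_below_band(self):
        p2 = make_plan("plan2", [100 / 0.967] * 2, algorithm="new")
        p3 = build_plan3(self.p1, p2)
        out = recommend_prescription(_report(p=0.01), self.p1, p3, self.rules, MODELS)
        assert out.suggested_dpr == pytest.approx(58.0, abs=0.5)
        assert out.in_5_10_band is False

    def test_missing_evidence(self):
        rep = _report()
        rep.gamma_summaries = []
        out = recommend_prescription(rep, self.p1, self.p3, self.rules, MODELS)
        assert out.decision == "insufficient_evidence"

    def test_decision_is_monotone_in_each_input(self):
        # worsening any one input never flips consider -> keep
        base = dict(p=0.5, d95=1.0, pass_rates=(0.99, 0.99))
        worse = [
            dict(base, p=0.01),
            dict(base, d95=4.0),
            dict(base, pass_rates=(0.90, 0.99)),
        ]
        for kw in worse:
            out = recommend_prescription(
                _report(**kw), self.p1, self.p3, self.rules, MODELS
            )
            assert out.decision == "consider_adjustment"
            # worsening a second input keeps it at consider
            kw2 = dict(kw, p=0.001)
            out2 = recommend_prescription(
                _report(**kw2), self.p1, self.p3, self.rules, MODELS
            )
            assert out2.decision == "consider_adjustment"


class TestComparePlans:
    def test_identical_plans_keep_dpr(self):
        p1 = make_plan("plan1", [100, 105, 98, 102])
        p2 = make_plan("plan2", [100, 105, 98, 102], algorithm="new")
        grid = np.full((8, 8), 60.0)
        from doseshift.gamma import DoseGrid
        from dataclasses import replace

        p1 = replace(p1, dose_grid=DoseGrid(grid, (3, 3), (0, 0)))
        p2 = replace(p2, dose_grid=DoseGrid(grid, (3, 3), (0, 0)))
        rep = compare_plans(p1, p2, MODELS)
        assert rep.wilcoxon_p == 1.0
        assert rep.decision.decision == "keep_dpr"
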