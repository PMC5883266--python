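import numpy as np
import pytest

from doseshift import DVH, DomainError, dose_at_volume, mean_dose
from doseshift.radbio import (
    DoseLimitRecord,
    OrganModel,
    ZeroDoseWarning,
    check_dose_limits,
    default_dose_limits,
    default_organ_models,
    derive_gamma50,
    eud,
    eud_for_probability,
    eud_interval,
    load_organ_table,
    ntcp,
    tcp,
)

from conftest import random_clinical_dvh

CORD = OrganModel("Spinal cord", "serial", 66.5, 4.0, 20.0, "Necrosis")
TARGET = OrganModel("Target", "target", 50.0, 2.0, -10.0, "Control")


class TestEUD:
    def test_uniform_dose_is_fixed_point(self, uniform_dvh):
        for a in (-10, -1, 0.5, 1, 2, 15):
            assert eud(uniform_dvh, a) == pytest.approx(10.0, rel=1e-6)

    def test_a1_equals_mean_dose(self, two_level_dvh):
        assert eud(two_level_dvh, 1.0) == pytest.approx(15.0, rel=1e-12)
        assert eud(two_level_dvh, 1.0) == pytest.approx(mean_dose(two_level_dvh), rel=1e-12)

    def test_quadratic_power_mean(self, two_level_dvh):
        assert eud(two_level_dvh, 2.0) == pytest.approx(np.sqrt(250.0), rel=1e-12)

    def test_a_zero_rejected(self, two_level_dvh):
        with pytest.raises(DomainError):
            eud(two_level_dvh, 0.0)

    def test_zero_dose_with_negative_a_warns_and_returns_zero(self):
        dvh = DVH("x", "differential", [0.0, 20.0], [0.1, 0.9])
        with pytest.warns(ZeroDoseWarning):
            assert eud(dvh, -10.0) == 0.0

    def test_monotone_in_a(self, rng):
        # power-mean inequality, grid scan over random clinical DVHs
        for _ in range(20):
            dvh = random_clinical_dvh(rng)
            values = [eud(dvh, a) for a in np.linspace(-10, 20, 16) if a != 0]
            assert np.all(np.diff(values) >= -1e-9)

    def test_extreme_exponents_are_finite(self, rng):
        dvh = random_clinical_dvh(rng)
        assert np.isfinite(eud(dvh, 20.0))
        assert np.isfinite(eud(dvh, -10.0))


class TestDoseResponse:
    def test_midpoint_probability_is_half(self):
        assert tcp(50.0, TARGET) == pytest.approx(0.5, abs=1e-15)
        assert ntcp(66.5, CORD) == pytest.approx(0.5, abs=1e-15)

    def test_zero_eud_gives_zero_probability(self):
        assert tcp(0.0, TARGET) == 0.0
        assert ntcp(0.0, CORD) == 0.0

    def test_tcp_example_value(self):
        # high-precision evaluation of the logistic form
        assert tcp(55.0, TARGET) == pytest.approx(0.6819, abs=5e-5)

    def test_cord_necrosis_ntcp_near_one_percent(self):
        assert ntcp(49.9, CORD) == pytest.approx(0.010, abs=1e-3)

    def test_class_guards(self):
        with pytest.raises(DomainError):
            tcp(50.0, CORD)
        with pytest.raises(DomainError):
            ntcp(50.0, TARGET)

    def test_strictly_increasing_in_eud(self):
        doses = np.linspace(1, 120, 60)
        probs = [ntcp(d, CORD) for d in doses]
        assert np.all(np.diff(probs) > 0)


class TestInverse:
    def test_half_probability_returns_d50(self):
        assert eud_for_probability(0.5, CORD) == pytest.approx(66.5, rel=1e-14)

    def test_round_trip_identity(self):
        for p in (0.01, 0.05, 0.3, 0.7, 0.99):
            assert ntcp(eud_for_probability(p, CORD), CORD) == pytest.approx(p, abs=1e-10)

    def test_domain(self):
        for p in (0.0, 1.0, -0.1):
            with pytest.raises(DomainError):
                eud_for_probability(p, CORD)


class TestDeriveGamma50:
    def test_cord_and_lung_inversions(self):
        assert derive_gamma50(66.5, 49.9, 0.01) == pytest.approx(4.00, abs=0.01)
        assert derive_gamma50(24.5, 13.9, 0.01) == pytest.approx(2.02, abs=0.02)

    def test_forward_round_trip(self):
        g = derive_gamma50(60.0, 30.0, 0.07)
        model = OrganModel("x", "serial", 60.0, g, 10.0)
        assert ntcp(30.0, model) == pytest.approx(0.07, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(DomainError):
            derive_gamma50(60.0, 60.0, 0.01)
        with pytest.raises(DomainError):
            derive_gamma50(60.0, 30.0, 0.5)


class TestEUDInterval:
    def test_uniform_dvh_degenerate_interval(self, uniform_dvh):
        iv = eud_interval(uniform_dvh, "serial")
        assert iv.low == pytest.approx(10.0, rel=1e-6)
        assert iv.high == pytest.approx(10.0, rel=1e-6)

    def test_serial_interval_uses_endpoints(self, two_level_dvh):
        iv = eud_interval(two_level_dvh, "serial")
        assert iv.low == pytest.approx(eud(two_level_dvh, 4.0))
        assert iv.high == pytest.approx(eud(two_level_dvh, 15.0))
        # grid-scan confirmation that the a-range endpoints bound the interval
        for a in np.linspace(4.0, 15.0, 12):
            assert iv.low - 1e-9 <= eud(two_level_dvh, a) <= iv.high + 1e-9

    def test_parallel_interval_within_dvh_support(self, rng):
        dvh = random_clinical_dvh(rng)
        iv = eud_interval(dvh, "parallel")
        assert dvh.dose_bins[0] - 1e-9 <= iv.low <= iv.high <= dvh.dose_bins[-1] + 1e-9

    def test_target_class_rejected(self, two_level_dvh):
        with pytest.raises(DomainError):
            eud_interval(two_level_dvh, "target")


class TestDoseLimits:
    LUNG = OrganModel("Lungs", "parallel", 24.5, 2.0, 1.2, "Pneumonitis")
    LUNG_LIMITS = DoseLimitRecord(
        organ="Lungs", eud_max_1pct=13.9, eud_max_5pct=17.1,
        classic_limits=(("Dmean", "<", (15.0, 20.0)),),
    )

    def test_lung_dmean_conservative_bound(self):
        dvh = DVH("Lungs", "differential", [13.0, 15.0], [0.5, 0.5])  # Dmean 14
        rep = check_dose_limits(dvh, self.LUNG_LIMITS, self.LUNG)
        assert rep.limit_checks[0].passed
        assert rep.limit_checks[0].limit == 15.0

    def test_cord_d2_limit_fails(self):
        rec = DoseLimitRecord("Spinal cord", 49.9, 55.3, (("D2%", "<", 50.0),))
        dvh = DVH("cord", "cumulative", [0.0, 52.0, 53.0], [1.0, 0.5, 0.0])
        rep = check_dose_limits(dvh, rec, CORD)
        assert not rep.limit_checks[0].passed

    def test_near_zero_dose_dvh_passes_everything(self):
        rec = DoseLimitRecord("Spinal cord", 49.9, 55.3, (("D2%", "<", 50.0),))
        dvh = DVH("cord", "cumulative", [0.01, 0.02], [1.0, 0.0])
        rep = check_dose_limits(dvh, rec, CORD)
        assert rep.all_pass
        assert rep.eud_class == "within_1pct"


class TestBundledTable:
    def test_table_loads_and_models_validate(self):
        table = load_organ_table()
        assert {"Spinal cord", "Lungs", "Heart", "Target"} <= set(table["name"])
        models = default_organ_models()
        assert models["Spinal cord"].gamma50 == 4.0
        assert models["Target"].a < 0

    def test_limit_records_parse(self):
        limits = default_dose_limits()
        cord = limits["Spinal cord"]
        assert cord.classic_limits == (("D2%", "<", 50.0),)
        heart = limits["Heart"]
        assert ("Dmean", "<", 26.0) in heart.classic_limits

    def test_table_eud_caps_consistent_with_derived_slopes(self):
        # every EUD cap in the table is reproduced to within 0.15 Gy by the
        # shipped (derived) gamma50 for that organ
        models = default_organ_models()
        for name, rec in default_dose_limits().items():
            model = models[name]
            assert eud_for_probability(0.01, model) == pytest.approx(
                rec.eud_max_1pct, abs=0.15
            )
            assert eud_for_probability(0.05, model) == pytest.approx(
                rec.eud_max_5pct, abs=0.15
            )
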