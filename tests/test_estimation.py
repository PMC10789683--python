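"""κ calibration, corrected-CVP estimation, compliances, exclusion cascade."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvp2ppl import (
    CalibrationError,
    ConditionSpec,
    DeltaSet,
    SubjectParams,
    VentilatorSettings,
    apply_exclusions,
    calibrate_ot,
    compute_compliances,
    extract_condition,
    simulate_condition,
    tidal_deltas,
)


class TestCalibrateOT:
    def test_kappa_from_deltas(self):
        cal = calibrate_ot({"paw": 6.0, "cvp": 10.0}, {"paw": 16.0, "cvp": 15.0})
        assert cal.kappa == pytest.approx(2.0)
        assert cal.d_paw == pytest.approx(10.0)
        assert cal.d_cvp == pytest.approx(5.0)

    def test_noise_free_simulation_inverts_transmission(self):
        subject = SubjectParams()
        cond = ConditionSpec(transmission=0.45)
        rec = simulate_condition(subject, cond, seed=1, noise_free=True)
        ds = extract_condition(rec)
        assert ds.kappa == pytest.approx(1.0 / 0.45, abs=1e-9)

    @pytest.mark.parametrize("ratio,expected", [
        (0.79, False), (0.8, True), (0.9, True), (1.2, True), (1.21, False),
    ])
    def test_validity_band_inclusive(self, ratio, expected):
        cal = calibrate_ot(
            {"paw": 0.0, "cvp": 0.0, "pes": 0.0, "dppl": 0.0},
            {"paw": 10.0, "cvp": 5.0, "pes": 10.0 * ratio, "dppl": 10.0})
        assert cal.valid_pes is expected
        assert cal.valid_dppl is True

    def test_small_cvp_delta_is_calibration_failure(self):
        with pytest.raises(CalibrationError):
            calibrate_ot({"paw": 0.0, "cvp": 10.0}, {"paw": 10.0, "cvp": 10.4})

    def test_low_pes_transmission_flagged_invalid(self):
        # an esophageal balloon transmitting only 75% fails the 0.8-1.2 check
        subject = SubjectParams(pes_transmission=0.75)
        rec = simulate_condition(subject, ConditionSpec(), seed=2, noise_free=True)
        ds = extract_condition(rec)
        assert ds.valid_pes is False
        assert ds.valid_dppl is True


class TestTidalDeltas:
    def test_corrected_cvp_arithmetic(self):
        cal = calibrate_ot({"paw": 0.0, "cvp": 0.0}, {"paw": 11.0, "cvp": 5.0})
        ds = tidal_deltas({"paw": 21.0, "cvp": 3.0 + 10.0},
                          {"paw": 6.0, "cvp": 10.0}, cal)
        assert ds.kappa == pytest.approx(2.2)
        assert ds.est_dppl == pytest.approx(2.2 * 3.0)

    def test_zero_cvp_delta_gives_zero_estimate(self):
        cal = calibrate_ot({"paw": 0.0, "cvp": 0.0}, {"paw": 10.0, "cvp": 5.0})
        ds = tidal_deltas({"paw": 20.0, "cvp": 8.0}, {"paw": 6.0, "cvp": 8.0}, cal)
        assert ds.est_dppl == 0.0

    def test_missing_channel_excludes_only_that_comparison(self):
        cal = calibrate_ot({"paw": 0.0, "cvp": 0.0, "dppl": 0.0},
                           {"paw": 10.0, "cvp": 5.0, "dppl": 10.0})
        ds = tidal_deltas({"paw": 20.0, "cvp": 9.0}, {"paw": 6.0, "cvp": 8.0}, cal)
        assert ds.d_pes is None
        assert ds.est_dppl is not None

    @pytest.mark.parametrize("transmission", [0.3, 0.45, 0.8, 1.2])
    def test_exact_recovery_identity(self, transmission):
        # the method's correctness core: noise-free, est_dppl == d_dppl
        subject = SubjectParams()
        cond = ConditionSpec(transmission=transmission)
        rec = simulate_condition(subject, cond, seed=3, noise_free=True)
        ds = extract_condition(rec)
        assert ds.est_dppl == pytest.approx(ds.d_dppl, abs=1e-9)

    def test_kappa_scale_invariance(self):
        # rescaling the CVP channel (unit change) cancels out of est_dppl
        subject = SubjectParams()
        rec = simulate_condition(subject, ConditionSpec(), seed=4, noise_free=True)
        ds = extract_condition(rec)
        scaled = dataclasses.replace(rec)
        scaled.channels = dict(rec.channels)
        scaled.channels["cvp"] = rec.channels["cvp"] / 1.36
        ds2 = extract_condition(scaled)
        assert ds2.kappa == pytest.approx(ds.kappa * 1.36, rel=1e-9)
        assert ds2.est_dppl == pytest.approx(ds.est_dppl, abs=1e-9)


class TestCompliances:
    def test_toy_partition(self):
        crs, ccw, cl = compute_compliances(300.0, plateau=21.0, total_peep=6.0,
                                           d_dppl=3.0)
        assert (crs, ccw, cl) == (20.0, 100.0, 25.0)
        assert 1.0 / crs == pytest.approx(1.0 / cl + 1.0 / ccw)

    def test_degenerate_lung_compliance_is_missing(self):
        crs, ccw, cl = compute_compliances(300.0, plateau=21.0, total_peep=6.0,
                                           d_dppl=15.0)
        assert cl is None
        assert crs == pytest.approx(20.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_compliances(300.0, plateau=6.0, total_peep=6.0, d_dppl=3.0)
        with pytest.raises(ValueError):
            compute_compliances(300.0, plateau=21.0, total_peep=6.0, d_dppl=0.0)

    def test_noise_free_recovery_of_simulator_truth(self):
        subject = SubjectParams(lung_compliance=34.0)
        cond = ConditionSpec(ccw=37.0, ccw_level="L")
        rec = simulate_condition(subject, cond, seed=5, noise_free=True)
        ds = extract_condition(rec)
        assert ds.ccw == pytest.approx(37.0, rel=1e-6)
        assert ds.cl == pytest.approx(34.0, rel=1e-6)
        assert 1.0 / ds.crs == pytest.approx(1.0 / 34.0 + 1.0 / 37.0, abs=1e-9)

    @given(cl=st.floats(15.0, 60.0), ccw=st.floats(20.0, 150.0),
           tv=st.floats(200.0, 500.0))
    @settings(max_examples=25, deadline=None)
    def test_partition_inverts_any_mechanics(self, cl, ccw, tv):
        crs_true = 1.0 / (1.0 / cl + 1.0 / ccw)
        crs, ccw_hat, cl_hat = compute_compliances(
            tv, plateau=6.0 + tv / crs_true, total_peep=6.0, d_dppl=tv / ccw)
        assert crs == pytest.approx(crs_true, rel=1e-9)
        assert ccw_hat == pytest.approx(ccw, rel=1e-9)
        assert cl_hat == pytest.approx(cl, rel=1e-9)


def _ds(valid_dppl=True, valid_pes=True, ot_ok=True) -> DeltaSet:
    return DeltaSet(d_paw=10.0, d_pes=9.0, d_dppl=10.0, d_cvp=4.5,
                    est_dppl=9.9 if ot_ok else None, kappa=2.2,
                    valid_dppl=valid_dppl, valid_pes=valid_pes, ot_ok=ot_ok)


class TestExclusions:
    def test_boundary_inclusive_ratios(self):
        # ratios 0.8 and 1.2 retained; 0.75 and 1.25 excluded
        sets = []
        for ratio in [0.75, 0.8, 0.9, 1.0, 1.2, 1.25]:
            sets.append(_ds(valid_dppl=0.8 <= ratio <= 1.2))
        report = apply_exclusions(sets)
        assert len(report.ccvp_vs_dppl) == 4
        assert report.dppl_failures == 2

    def test_all_valid_study_keeps_everything(self):
        report = apply_exclusions([_ds() for _ in range(60)])
        assert report.sizes == {"pes_vs_dppl": 60, "ccvp_vs_dppl": 60,
                                "pes_vs_ccvp": 60}

    def test_study_failure_pattern_reproduces_comparison_sizes(self):
        # synthetic 60-record fixture with the same failure pattern as the
        # study: 5 direct-Ppl measurement failures (4 of them with
        # concurrent CVP failures), 14 invalid esophageal ratios (1 among
        # the failed-Ppl records), and 2 further CVP failures
        sets = []
        for i in range(60):
            dppl_fail = i < 5
            pes_fail = i in {4, *range(5, 18)}       # 14 total, 1 overlap
            cvp_fail = i in {0, 1, 2, 3, 20, 21}     # 6 total, 4 overlap
            sets.append(_ds(valid_dppl=not dppl_fail,
                            valid_pes=not pes_fail,
                            ot_ok=not cvp_fail))
        report = apply_exclusions(sets)
        assert report.sizes == {"pes_vs_dppl": 42, "ccvp_vs_dppl": 53,
                                "pes_vs_ccvp": 40}
        assert report.dppl_failures == 5
        assert report.pes_invalid == 13
        assert report.cvp_failures == 2

    def test_accounting_conserves_records(self):
        rng = np.random.default_rng(8)
        sets = [_ds(valid_dppl=rng.random() > 0.1,
                    valid_pes=rng.random() > 0.25,
                    ot_ok=rng.random() > 0.05) for _ in range(200)]
        report = apply_exclusions(sets)
        counted = (report.dppl_failures + report.pes_invalid
                   + report.cvp_failures)
        survivors = sum(1 for s in sets
                        if s.valid_dppl and s.valid_pes and s.ot_ok)
        assert counted + survivors == report.n_total
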