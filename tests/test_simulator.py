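"""Simulator: single-compartment mechanics, occlusion identity, study draws."""
import dataclasses

import numpy as np
import pytest

from cvp2ppl import (
    ConditionSpec,
    SubjectParams,
    VentilatorSettings,
    draw_study,
    simulate_condition,
    simulate_occlusion_test,
)
from cvp2ppl.simulator import PROTOCOL, StudyPriors, respiratory_system_compliance

from conftest import windows_by_label


def channel_mean(record, window, channel):
    sl = record.slice(window.t_start, window.t_end)
    return sl[channel].mean()


class TestSingleCompartment:
    def test_plateau_minus_peep_is_tv_over_crs(self, noise_free_record):
        # TV 300, CL 25, Ccw 100 -> Crs 20 -> driving pressure 15 cmH2O
        w = windows_by_label(noise_free_record)
        paw_plat = channel_mean(noise_free_record, w["insp_hold"], "paw")
        paw_peep = channel_mean(noise_free_record, w["exp_hold"], "paw")
        assert paw_peep == pytest.approx(6.0, abs=1e-12)  # total PEEP exactly
        assert paw_plat - paw_peep == pytest.approx(15.0, abs=1e-9)

    def test_tidal_pleural_swing_is_tv_over_ccw(self, noise_free_record):
        w = windows_by_label(noise_free_record)
        d = (channel_mean(noise_free_record, w["insp_hold"], "dppl")
             - channel_mean(noise_free_record, w["exp_hold"], "dppl"))
        assert d == pytest.approx(3.0, abs=1e-9)

    def test_linear_cvp_transmission(self, noise_free_record):
        # T = 0.5: a 3 cmH2O pleural swing moves CVP by 1.5
        w = windows_by_label(noise_free_record)
        d = (channel_mean(noise_free_record, w["insp_hold"], "cvp")
             - channel_mean(noise_free_record, w["exp_hold"], "cvp"))
        assert d == pytest.approx(1.5, abs=1e-9)

    def test_elastance_additivity_from_record(self, noise_free_record):
        w = windows_by_label(noise_free_record)
        driving = (channel_mean(noise_free_record, w["insp_hold"], "paw")
                   - channel_mean(noise_free_record, w["exp_hold"], "paw"))
        dppl = (channel_mean(noise_free_record, w["insp_hold"], "dppl")
                - channel_mean(noise_free_record, w["exp_hold"], "dppl"))
        tv = 300.0
        assert 1.0 / (tv / driving) == pytest.approx(
            1.0 / 25.0 + 1.0 / 100.0, abs=1e-9)
        assert tv / dppl == pytest.approx(100.0, rel=1e-9)

    def test_volume_returns_to_end_expiratory_level(self, noise_free_record):
        starts = [a.t_start for a in noise_free_record.annotations
                  if a.label == "breath_start"]
        vol = noise_free_record.channels["volume"]
        idx = np.searchsorted(noise_free_record.time, starts)
        assert np.abs(vol[idx]).max() < 1e-6 * 300.0
        assert vol.min() >= -1e-12


class TestOcclusionTest:
    def test_occlusion_identity(self, toy_mechanics):
        # airway closed: the squeeze transmits fully, dPaw == dPpl sample-wise
        subject, cond, vent = toy_mechanics
        rec = simulate_occlusion_test(subject, cond, vent, seed=5, noise_free=True)
        paw = rec.channels["paw"] - 6.0
        dppl = rec.channels["dppl"] - cond.end_expiratory_ppl
        assert np.abs(paw - dppl).max() < 1e-9

    def test_squeeze_deltas(self, toy_mechanics):
        subject, cond, vent = toy_mechanics
        rec = simulate_occlusion_test(subject, cond, vent, squeeze_magnitude=10.0,
                                      seed=5, noise_free=True)
        w = windows_by_label(rec)
        d_paw = (channel_mean(rec, w["ot_squeeze"], "paw")
                 - channel_mean(rec, w["ot_baseline"], "paw"))
        d_cvp = (channel_mean(rec, w["ot_squeeze"], "cvp")
                 - channel_mean(rec, w["ot_baseline"], "cvp"))
        d_pes = (channel_mean(rec, w["ot_squeeze"], "pes")
                 - channel_mean(rec, w["ot_baseline"], "pes"))
        assert d_paw == pytest.approx(10.0, abs=1e-9)
        assert d_cvp == pytest.approx(5.0, abs=1e-9)       # T = 0.5
        assert d_pes == pytest.approx(9.0, abs=1e-9)       # transmission 0.9

    def test_rejects_nonpositive_squeeze(self, toy_mechanics):
        subject, cond, vent = toy_mechanics
        with pytest.raises(ValueError):
            simulate_occlusion_test(subject, cond, vent, squeeze_magnitude=0.0)


class TestValidation:
    def test_nonphysical_parameters_rejected(self):
        with pytest.raises(ValueError):
            SubjectParams(lung_compliance=-5.0)
        with pytest.raises(ValueError):
            ConditionSpec(ccw=0.0)
        with pytest.raises(ValueError):
            ConditionSpec(transmission=0.0)
        with pytest.raises(ValueError):
            respiratory_system_compliance(0.0, 100.0)
        with pytest.raises(ValueError):
            VentilatorSettings(sample_rate=10.0)

    def test_min_breaths(self, toy_mechanics):
        subject, cond, vent = toy_mechanics
        with pytest.raises(ValueError):
            simulate_condition(subject, cond, vent, n_breaths=2)


class TestDeterminismAndBaselines:
    def test_same_seed_bit_identical(self, toy_mechanics):
        subject, cond, vent = toy_mechanics
        a = simulate_condition(subject, cond, vent, seed=42)
        b = simulate_condition(subject, cond, vent, seed=42)
        for ch in a.channels:
            np.testing.assert_array_equal(a.channels[ch], b.channels[ch])

    def test_cvp_baseline_shifts_level_not_delta(self, toy_mechanics):
        # the mechanism behind volume status not affecting accuracy
        subject, cond, vent = toy_mechanics
        hi = dataclasses.replace(cond, cvp_baseline=cond.cvp_baseline + 10.0)
        a = simulate_condition(subject, cond, vent, seed=3, noise_free=True)
        b = simulate_condition(subject, hi, vent, seed=3, noise_free=True)
        shift = b.channels["cvp"] - a.channels["cvp"]
        np.testing.assert_allclose(shift, 10.0, atol=1e-12)


class TestDrawStudy:
    def test_study_shape_and_protocol_order(self):
        records = draw_study(10, master_seed=1, noise_free=True)
        assert len(records) == 60
        for i, rec in enumerate(records):
            cond = rec.truth["condition"]
            v, c = PROTOCOL[i % 6]
            assert (cond["volume_status"], cond["ccw_level"]) == (v, c)
        subjects = {rec.meta["subject_id"] for rec in records}
        assert len(subjects) == 10

    def test_master_seed_reproducibility(self):
        a = draw_study(2, master_seed=9)
        b = draw_study(2, master_seed=9)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.channels["cvp"], rb.channels["cvp"])

    def test_zero_variance_priors_make_identical_subjects(self):
        priors = StudyPriors().zero_variance()
        records = draw_study(3, priors=priors, master_seed=2, noise_free=True)
        for k in range(6):
            base = records[k]
            for s in range(1, 3):
                np.testing.assert_array_equal(
                    base.channels["paw"], records[6 * s + k].channels["paw"])

    def test_subject_params_persist_across_conditions(self):
        records = draw_study(2, master_seed=4)
        for s in range(2):
            group = records[6 * s:6 * s + 6]
            weights = {r.truth["subject"]["weight"] for r in group}
            assert len(weights) == 1
            ccw_n = {r.truth["condition"]["ccw"] for r in group
                     if r.truth["condition"]["ccw_level"] == "N"}
            assert len(ccw_n) == 1

    def test_baseline_cvp_monotone_in_volume_status(self):
        records = draw_study(5, master_seed=6)
        for s in range(5):
            group = records[6 * s:6 * s + 6]
            for lvl in ("N", "L"):
                vals = [r.truth["condition"]["cvp_baseline"] for r in group
                        if r.truth["condition"]["ccw_level"] == lvl]
                assert vals == sorted(vals)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            draw_study(1)
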