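"""Controller state machine, control laws, convergence and causality."""

import numpy as np
import pytest

from mbfus.control import (ControllerConfig, ControllerState, Protocol,
                           controller_step, run_session, tracking_update)
from mbfus.mlp import MLPModel
from mbfus.subject import Hazard, Kinetics, Precursor, SubjectModel


def deterministic_subject(**overrides):
    """Noise-free plant: no band noise, no events, negligible decay."""
    defaults = dict(
        kinetics=Kinetics(rise_time=2.0, decay_constant=1e9, injection_time=2.0),
        hazard=Hazard(inertial_pressure=100.0),
        precursor=Precursor(uh1_boost=0.0, noise_sd=0.0))
    defaults.update(overrides)
    return SubjectModel(**defaults)


def constant_predictor(always: bool):
    """A 12-feature model whose output is a constant probability."""
    b2 = 5.0 if always else -5.0
    return MLPModel(w1=np.zeros((12, 2)), b1=np.zeros(2), w2=np.zeros(2), b2=b2,
                    feature_min=np.zeros(12), feature_max=np.ones(12))


def record(h7=30.0, event=False, **extra):
    rec = {f"uh{k}": 10.0 for k in range(1, 8)}
    rec.update({f"h{n}": h7 for n in range(2, 9)})
    rec.update(pressure_mpa=0.2, x_mm=0.0, y_mm=0.0, mb_kinetics=0.8,
               tumor=0, event=event, broadband_db=10.0 if event else 0.0)
    rec.update(extra)
    return rec


class TestTrackingUpdate:
    def test_activation_at_exactly_plus_10_db(self):
        s = ControllerState(h4_baseline=20.0)
        tracking_update(s, 29.9, t=0.0)
        assert s.phase == "waiting"
        tracking_update(s, 30.1, t=1.0)
        assert s.phase == "tracking"

    def test_cease_armed_at_20pct_normalized_decay(self):
        s = ControllerState(h4_baseline=0.0, min_track_window=20.0)
        tracking_update(s, 15.0, t=0.0)  # activates, peak 15
        s.advance("controlling")
        ceased = False
        # linear decay reaching 0.79 of peak after the window
        for i, frac in enumerate(np.linspace(1.0, 0.79, 30), start=1):
            ceased = tracking_update(s, 15.0 * frac, t=float(i))
            if ceased:
                break
        assert ceased
        norm_at_cease = (15.0 * frac) / s.h4_peak
        assert norm_at_cease <= 0.81

    def test_no_cease_before_min_window(self):
        s = ControllerState(h4_baseline=0.0, min_track_window=40.0)
        tracking_update(s, 15.0, t=0.0)
        s.advance("controlling")
        for i, frac in enumerate(np.linspace(1.0, 0.75, 20), start=1):
            assert not tracking_update(s, 15.0 * frac, t=float(i))

    def test_phase_order_enforced(self):
        s = ControllerState()
        s.advance("hold")
        with pytest.raises(ValueError):
            s.advance("controlling")


class TestControllerStep:
    def controlling_state(self, pressure=0.20):
        s = ControllerState(pressure=pressure)
        s.phase = "controlling"
        return s

    def test_requires_controlling_phase(self):
        cfg = ControllerConfig(mode="cl")
        with pytest.raises(ValueError):
            controller_step(cfg, ControllerState(), record())

    def test_cl_zero_error_leaves_pressure(self):
        cfg = ControllerConfig(mode="cl", target_level_db=30.0)
        p, flags = controller_step(cfg, self.controlling_state(), record(h7=30.0))
        assert p == pytest.approx(0.20)
        assert not flags["override"]

    def test_event_drops_five_percent_every_mode(self):
        for mode, kw in [("ol", dict(constant_pressure=0.20)),
                         ("cl", {}),
                         ("mlcl", dict(predictor=constant_predictor(False)))]:
            cfg = ControllerConfig(mode=mode, target_level_db=30.0, **kw)
            p, flags = controller_step(cfg, self.controlling_state(0.20),
                                       record(h7=30.0, event=True))
            assert p == pytest.approx(0.19), mode
            assert flags["event"]

    def test_mlcl_positive_prediction_overrides_upward_update(self):
        cfg = ControllerConfig(mode="mlcl", target_level_db=36.0,
                               predictor=constant_predictor(True))
        p, flags = controller_step(cfg, self.controlling_state(0.20),
                                   record(h7=20.0))  # error would push up
        assert p == pytest.approx(0.19)
        assert flags["prediction"] and flags["override"]

    def test_cl_step_clipped_to_max_fraction(self):
        cfg = ControllerConfig(mode="cl", target_level_db=60.0, max_step_fraction=0.10)
        p, _ = controller_step(cfg, self.controlling_state(0.20), record(h7=10.0))
        assert p == pytest.approx(0.22)  # +10% cap despite huge error

    def test_pressure_bounds_respected(self):
        cfg = ControllerConfig(mode="cl", target_level_db=60.0, max_pressure=0.21)
        p, _ = controller_step(cfg, self.controlling_state(0.20), record(h7=10.0))
        assert p == pytest.approx(0.21)

    def test_mlcl_without_predictor_rejected(self):
        with pytest.raises(ValueError):
            ControllerConfig(mode="mlcl")

    def test_ol_without_pressure_rejected(self):
        with pytest.raises(ValueError):
            ControllerConfig(mode="ol")


class TestRunSession:
    def test_no_injection_never_leaves_waiting(self):
        subj = deterministic_subject(
            kinetics=Kinetics(rise_time=1.0, decay_constant=1e9, injection_time=1e9))
        cfg = ControllerConfig(mode="cl", target_level_db=32.0)
        sess = run_session(cfg, Protocol(), subj, seed=0)
        assert (sess.records["phase"] == "waiting").all()
        assert (sess.records["pressure_mpa"] == Protocol().tracker_pressure).all()

    def test_same_seed_identical_sessions(self):
        subj = SubjectModel.preset("mouse", seed=5)
        cfg = ControllerConfig(mode="cl", target_level_db=32.0)
        a = run_session(cfg, Protocol(), subj, seed=7)
        b = run_session(cfg, Protocol(), subj, seed=7)
        assert a.records.equals(b.records)

    def test_pulse_count_matches_protocol(self):
        subj = SubjectModel.preset("mouse", seed=2)
        cfg = ControllerConfig(mode="cl")
        assert run_session(cfg, Protocol(), subj, seed=1).n_pulses == 130

    def test_cl_converges_on_deterministic_plant(self):
        """Noise-free plant, 32 dB target inside the threshold curve:
        terminal controlled L7 within +/-1 dB of target."""
        subj = deterministic_subject()
        cfg = ControllerConfig(mode="cl", target_level_db=32.0)
        sess = run_session(cfg, Protocol(), subj, seed=0)
        ctl = sess.records[sess.records["phase"] == "controlling"]
        assert abs(ctl["h7"].iloc[-1] - 32.0) <= 1.0

    def test_hold_phase_pressure_constant_without_events(self):
        subj = deterministic_subject(
            kinetics=Kinetics(rise_time=2.0, decay_constant=40.0, injection_time=2.0))
        cfg = ControllerConfig(mode="cl", target_level_db=32.0)
        sess = run_session(cfg, Protocol(), subj, seed=0)
        hold = sess.records[sess.records["phase"] == "hold"]
        assert len(hold) > 0
        assert hold["pressure_mpa"].nunique() == 1  # no events -> frozen pressure

    def test_controlling_entered_only_after_tracking(self):
        subj = SubjectModel.preset("mouse", seed=9)
        cfg = ControllerConfig(mode="cl", target_level_db=32.0)
        phases = run_session(cfg, Protocol(), subj, seed=3).records["phase"]
        order = {"waiting": 0, "tracking": 1, "controlling": 2, "hold": 3}
        codes = phases.map(order).to_numpy()
        assert np.all(np.diff(codes) >= 0)  # phases never regress

    def test_safety_drop_multiplicative_in_closed_loop(self):
        """Each ML-CL positive prediction without event drops pressure by
        exactly the 5% factor (when not at the bounds)."""
        subj = deterministic_subject()
        cfg = ControllerConfig(mode="mlcl", target_level_db=32.0,
                               predictor=constant_predictor(True))
        sess = run_session(cfg, Protocol(), subj, seed=0)
        rec = sess.records
        ctl = rec[rec["phase"].isin(["controlling", "hold"])].reset_index(drop=True)
        for i in range(1, len(ctl)):
            prev_p, cur_p = ctl["pressure_mpa"].iloc[i - 1], ctl["pressure_mpa"].iloc[i]
            if ctl["override"].iloc[i - 1] and prev_p > cfg.min_pressure / 0.95:
                assert cur_p == pytest.approx(max(prev_p * 0.95, cfg.min_pressure))
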