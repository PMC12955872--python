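"""Pressure controllers for microbubble-FUS sonication.

Three controller families share one session loop:

* **OL** (open-loop): constant pressure; reacts to a broadband event with a
  5% multiplicative pressure drop.
* **CL** (closed-loop): targets a 7th-harmonic level; each pulse the pressure
  is multiplied by ``10**(gain * error / 20)`` (error smoothed over the last
  3 pulses, step clipped to +/-``max_step_fraction``), with the same reactive
  5% drop on events.
* **ML-CL**: the CL law plus a predictive safety layer — a trained precursor
  classifier is queried on the current pulse's features, and a positive
  prediction triggers the safety drop *before* any event occurs, skipping the
  upward update for that pulse.

Every controller is gated by the microbubble-kinetics tracker: a low-pressure
tracking pulse monitors the 4th harmonic; the controller turns on at a +10 dB
rise over background, and control ceases (pressure held) once the fitted
decay slope of the normalized H4 level indicates a 20% drop from its maximum,
evaluated only after the minimum tracking window (20 s mouse / 40 s rat).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .bands import DetectionConfig
from .mlp import MLPModel
from .subject import (SubjectModel, SubjectState, mb_concentration,
                      simulate_pulse, tracker_h4_level)

__all__ = [
    "Protocol",
    "ControllerConfig",
    "ControllerState",
    "TreatmentSession",
    "tracking_update",
    "controller_step",
    "run_session",
    "benchmark_controllers",
]


@dataclass(frozen=True)
class Protocol:
    """Sonication protocol: 0.5 MHz, 10 ms pulses at 1 Hz for 130 s, with a
    60 kPa microbubble-tracking pulse interleaved each second."""

    f0: float = 0.5
    pulse_length_ms: float = 10.0
    prf_hz: float = 1.0
    duration_s: float = 130.0
    tracker_pressure: float = 0.06
    controlled_harmonic: int = 7
    species: str = "mouse"

    def __post_init__(self) -> None:
        n = self.duration_s * self.prf_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * prf must give an integer pulse count")

    @property
    def n_pulses(self) -> int:
        return int(round(self.duration_s * self.prf_hz))

    @property
    def min_track_window_s(self) -> float:
        """Minimum slope-establishment window before cessation can trigger."""
        return 20.0 if self.species == "mouse" else 40.0


@dataclass(frozen=True)
class ControllerConfig:
    mode: str = "cl"                      # 'ol' | 'cl' | 'mlcl'
    target_level_db: float = 32.0         # L7 target (CL / ML-CL)
    constant_pressure: float | None = None  # OL only
    gain: float = 0.5
    max_step_fraction: float = 0.10
    safety_drop_fraction: float = 0.05
    min_pressure: float = 0.01
    max_pressure: float = 0.50
    error_smoothing: int = 3              # moving-average window on L7 error
    activation_rise_db: float = 10.0      # H4 rise that turns the controller on
    decay_cease_fraction: float = 0.20    # normalized-H4 decay that ceases control
    predictor: MLPModel | None = None     # ML-CL safety layer

    def __post_init__(self) -> None:
        if self.mode not in ("ol", "cl", "mlcl"):
            raise ValueError("mode must be 'ol', 'cl' or 'mlcl'")
        if self.mode == "mlcl" and self.predictor is None:
            raise ValueError("ML-CL requires a trained predictor")
        if self.mode == "ol" and self.constant_pressure is None:
            raise ValueError("open-loop mode requires constant_pressure")


@dataclass
class ControllerState:
    """Phase machine: waiting -> tracking -> controlling -> hold (absorbing)."""

    phase: str = "waiting"
    pressure: float = 0.06
    h4_baseline: float = 0.0
    h4_peak: float = -np.inf
    decay_slope: float = 0.0        # fitted d(H4_norm)/dt, per second
    activation_pulse: int | None = None
    min_track_window: float = 20.0
    h4_times: list[float] = field(default_factory=list)
    h4_history: list[float] = field(default_factory=list)
    l7_history: list[float] = field(default_factory=list)

    _ORDER = ("waiting", "tracking", "controlling", "hold")

    def advance(self, phase: str) -> None:
        if self._ORDER.index(phase) < self._ORDER.index(self.phase):
            raise ValueError(f"illegal phase transition {self.phase} -> {phase}")
        self.phase = phase


def tracking_update(state: ControllerState, h4_level: float, t: float,
                    activation_rise_db: float = 10.0,
                    decay_cease_fraction: float = 0.20) -> bool:
    """Feed one tracking-pulse H4 reading; returns True if control must cease.

    In ``waiting``, a rise of ``activation_rise_db`` over the H4 baseline
    switches to ``tracking``.  Thereafter the running H4 maximum and a
    least-squares decay slope over the normalized series are maintained; once
    the minimum tracking window has elapsed since activation, a fitted
    normalized level at or below ``1 - decay_cease_fraction`` arms cessation.
    """
    if state.phase == "hold":
        return False
    if state.phase == "waiting":
        if h4_level >= state.h4_baseline + activation_rise_db:
            state.advance("tracking")
            state.activation_pulse = int(t)
            state.h4_peak = h4_level
            state.h4_times = [t]
            state.h4_history = [h4_level]
        return False

    # tracking or controlling: accumulate and fit
    state.h4_times.append(t)
    state.h4_history.append(h4_level)
    state.h4_peak = max(state.h4_peak, h4_level)
    times = np.asarray(state.h4_times)
    norm = np.asarray(state.h4_history) / max(state.h4_peak, 1e-12)
    if len(times) >= 3:
        slope, intercept = np.polyfit(times, norm, 1)
        state.decay_slope = float(slope)
        elapsed = t - times[0]
        if elapsed >= state.min_track_window:
            fitted_now = slope * t + intercept
            if fitted_now <= 1.0 - decay_cease_fraction:
                return True
    return False


def controller_step(config: ControllerConfig, state: ControllerState,
                    last_record: dict[str, Any]) -> tuple[float, dict[str, bool]]:
    """Decide the next therapeutic pressure from the latest pulse record.

    Returns ``(next_pressure, flags)`` with flags ``event`` (reactive drop
    applied), ``prediction`` and ``override`` (ML-CL pre-emptive drop).
    Causality: only data already recorded enters the decision.
    """
    if state.phase != "controlling":
        raise ValueError("controller_step requires the controlling phase")
    p = state.pressure
    event = bool(last_record["event"])
    flags = {"event": event, "prediction": False, "override": False}
    if config.mode in ("cl", "mlcl"):
        state.l7_history.append(float(last_record["h7"]))

    prediction = False
    if config.mode == "mlcl":
        feats = np.array([[last_record[name] for name in config.predictor.feature_names]])
        _, lab = config.predictor.predict(feats)
        prediction = bool(lab[0])
        flags["prediction"] = prediction

    if event or prediction:
        # safety response: rapid multiplicative drop; predicted events are
        # treated as if they had already occurred
        flags["override"] = prediction and not event
        p_next = p * (1.0 - config.safety_drop_fraction)
    elif config.mode == "ol":
        p_next = p  # constant-pressure law: unchanged unless an event drops it
    else:
        window = state.l7_history[-config.error_smoothing:]
        error = config.target_level_db - float(np.mean(window))
        factor = 10.0 ** (config.gain * error / 20.0)
        factor = float(np.clip(factor, 1.0 - config.max_step_fraction,
                               1.0 + config.max_step_fraction))
        p_next = p * factor
    return float(np.clip(p_next, config.min_pressure, config.max_pressure)), flags


def _safety_step(config: ControllerConfig, state: ControllerState,
                 last_record: dict[str, Any]) -> tuple[float, dict[str, bool]]:
    """Safety-only decision for the hold phase: pressure is kept at its last
    value unless an event (any mode) or a positive prediction (ML-CL) triggers
    the multiplicative safety drop."""
    p = state.pressure
    event = bool(last_record["event"])
    flags = {"event": event, "prediction": False, "override": False}
    if config.mode == "mlcl":
        feats = np.array([[last_record[name] for name in config.predictor.feature_names]])
        _, lab = config.predictor.predict(feats)
        flags["prediction"] = bool(lab[0])
    if event or flags["prediction"]:
        flags["override"] = flags["prediction"] and not event
        p = p * (1.0 - config.safety_drop_fraction)
    return float(np.clip(p, config.min_pressure, config.max_pressure)), flags


@dataclass
class TreatmentSession:
    """Per-pulse log of one controlled sonication."""

    records: pd.DataFrame
    config: ControllerConfig
    protocol: Protocol
    seed: int
    cumulative_dose: float

    @property
    def event_count(self) -> int:
        return int(self.records["event"].sum())

    @property
    def prediction_count(self) -> int:
        return int(self.records["prediction"].sum())

    @property
    def n_pulses(self) -> int:
        return len(self.records)


def run_session(config: ControllerConfig, protocol: Protocol,
                subject: SubjectModel, seed: int,
                detection: DetectionConfig | None = None) -> TreatmentSession:
    """Run one full closed-loop sonication against a virtual subject.

    Each second a tracking pulse is simulated first (its H4 reading feeds only
    the kinetics tracker), then the therapeutic pulse at the decided pressure.
    Before activation the therapeutic output stays at the tracker pressure; in
    ``hold`` the last controlled pressure is maintained to the 130 s end.
    """
    detection = detection or DetectionConfig()
    plant = SubjectState.initial(subject, seed=seed)
    ctrl = ControllerState(pressure=protocol.tracker_pressure,
                           min_track_window=protocol.min_track_window_s)
    if config.mode == "ol":
        start_pressure = config.constant_pressure
    else:
        start_pressure = protocol.tracker_pressure

    rows = []
    for t in range(protocol.n_pulses):
        conc = mb_concentration(subject.kinetics, plant.time)
        h4 = tracker_h4_level(subject, conc, rng=plant.rng)
        cease = tracking_update(ctrl, h4, float(t),
                                activation_rise_db=config.activation_rise_db,
                                decay_cease_fraction=config.decay_cease_fraction)
        if ctrl.phase == "tracking" and ctrl.activation_pulse is not None \
                and t > ctrl.activation_pulse:
            ctrl.advance("controlling")
            ctrl.pressure = start_pressure
        if cease and ctrl.phase == "controlling":
            ctrl.advance("hold")

        record, plant = simulate_pulse(subject, plant, ctrl.pressure, detection)
        record["phase"] = ctrl.phase
        record["h4_track"] = h4

        flags = {"event": bool(record["event"]), "prediction": False, "override": False}
        if ctrl.phase == "controlling":
            next_p, flags = controller_step(config, ctrl, record)
            ctrl.pressure = next_p
        elif ctrl.phase == "hold":
            # target tracking has ceased but the safety layer stays armed for
            # the rest of the sonication: reactive (and, for ML-CL,
            # predictive) drops still apply; no upward updates
            next_p, flags = _safety_step(config, ctrl, record)
            ctrl.pressure = next_p
        record.update(prediction=flags["prediction"], override=flags["override"])
        rows.append(record)

    df = pd.DataFrame.from_records(rows)
    return TreatmentSession(records=df, config=config, protocol=protocol,
                            seed=seed, cumulative_dose=plant.cumulative_dose)


def benchmark_controllers(configs: dict[str, ControllerConfig],
                          subjects: list[SubjectModel],
                          seeds: list[int],
                          protocol: Protocol | None = None) -> pd.DataFrame:
    """Run every controller over the same paired (subject, seed) cohort.

    Each controller sees identical subjects and identical plant seeds, so
    differences in event counts are attributable to the control law alone.
    Returns one row per controller with pooled event/prediction rates and
    7th-harmonic summary statistics over controlled pulses.
    """
    if len(configs) < 2:
        raise ValueError("benchmark needs at least two controller configs")
    if len(subjects) != len(seeds):
        raise ValueError("subjects and seeds must pair one-to-one")
    protocol = protocol or Protocol()
    rows = []
    for name, cfg in configs.items():
        events = predictions = pulses = 0
        l7_all: list[float] = []
        dose = 0.0
        for subj, seed in zip(subjects, seeds):
            sess = run_session(cfg, protocol, subj, seed)
            events += sess.event_count
            predictions += sess.prediction_count
            pulses += sess.n_pulses
            dose += sess.cumulative_dose
            ctl = sess.records[sess.records["phase"] == "controlling"]
            l7_all.extend(ctl["h7"].tolist())
        l7 = np.asarray(l7_all) if l7_all else np.array([np.nan])
        rows.append({
            "controller": name, "sessions": len(subjects),
            "total_pulses": pulses, "events": events,
            "event_rate": events / pulses,
            "predictions": predictions, "prediction_rate": predictions / pulses,
            "mean_l7_db": float(np.nanmean(l7)), "sd_l7_db": float(np.nanstd(l7, ddof=1))
            if l7.size > 1 else 0.0,
            "dose_proxy": dose,
        })
    return pd.DataFrame(rows).set_index("controller")
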