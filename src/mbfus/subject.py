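"""Virtual subject: a stochastic acoustic-emission plant for closed-loop work.

The simulator maps (applied pressure, circulating microbubble concentration,
subject covariates) to per-pulse band levels and broadband-emission events,
with the statistical structure a precursor classifier and a pressure
controller assume:

* **Bolus kinetics** — concentration is 0 before injection, rises linearly to
  its peak over ``rise_time`` and decays exponentially with ``decay_constant``.
* **Cavitation threshold curve** — the controlled 7th-harmonic level follows a
  saturating (logistic in log10-pressure) curve scaled by concentration, with
  plateau ``l_max``; other harmonic and ultra-harmonic bands are scaled
  versions of it.
* **Collapse hazard** — the per-pulse probability that a bubble collapse is
  *latched* is logistic in the drive ``pressure * concentration**q``, with an
  odds boost above 70% transient concentration and a tumor odds multiplier.
* **Precursor structure** — a latched collapse boosts the 1st ultra-harmonic
  of the *preceding* pulse by ``uh1_boost`` dB, so a classifier can learn a
  one-step-ahead warning; the collapse fires as a broadband event on the next
  pulse unless the applied pressure was dropped in the meantime (a >=3%
  reduction averts it).

All randomness flows through one seeded generator per subject, so sessions
and corpora are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Any

import numpy as np
import pandas as pd

from .bands import DetectionConfig

__all__ = [
    "ThresholdCurve",
    "Kinetics",
    "Hazard",
    "Precursor",
    "SubjectModel",
    "SubjectState",
    "mb_concentration",
    "harmonic_response",
    "tracker_h4_level",
    "event_hazard",
    "simulate_pulse",
    "generate_training_corpus",
    "CORPUS_COLUMNS",
    "HARMONIC_WEIGHTS",
    "ULTRAHARMONIC_WEIGHTS",
]

# Relative strength of each band vs. the 7th harmonic; peaks near the
# detector's 3.5 MHz sensitivity maximum (7th harmonic at f0 = 0.5 MHz).
HARMONIC_WEIGHTS = np.array([0.50, 0.55, 0.62, 0.70, 0.82, 1.00, 0.90])  # orders 2..8
ULTRAHARMONIC_WEIGHTS = np.array([0.30, 0.32, 0.34, 0.36, 0.38, 0.42, 0.40])  # 1.5..7.5 f0

CORPUS_COLUMNS = (
    ["pulse_index", "pressure_mpa"]
    + [f"uh{k}" for k in range(1, 8)]
    + [f"h{n}" for n in range(2, 9)]
    + ["broadband_db", "mb_kinetics", "x_mm", "y_mm", "tumor", "label"]
)


@dataclass(frozen=True)
class ThresholdCurve:
    """Saturating pressure -> 7th-harmonic curve: logistic in log10(P) with
    plateau ``l_max`` dB, midpoint ``p50`` MPa and steepness ``slope`` per
    decade of pressure."""

    l_max: float = 35.0
    p50: float = 0.15
    slope: float = 8.0

    def __post_init__(self) -> None:
        if self.l_max <= 0 or self.p50 <= 0:
            raise ValueError("l_max and p50 must be positive")

    def level(self, pressure: float) -> float:
        """Noise-free 7th-harmonic level (dB) at unit concentration."""
        if pressure <= 0:
            return 0.0
        z = self.slope * (np.log10(pressure) - np.log10(self.p50))
        return float(self.l_max / (1.0 + np.exp(-z)))


@dataclass(frozen=True)
class Kinetics:
    """Bolus pharmacokinetics, all in seconds."""

    rise_time: float = 5.0
    decay_constant: float = 80.0
    injection_time: float = 5.0

    def __post_init__(self) -> None:
        if self.decay_constant <= 0 or self.rise_time <= 0:
            raise ValueError("rise_time and decay_constant must be positive")


@dataclass(frozen=True)
class Hazard:
    """Per-pulse collapse-latch probability model.

    Odds are ``exp(hazard_slope * (P * C**concentration_exponent -
    inertial_pressure))``, multiplied by ``high_concentration_boost`` when the
    normalized concentration exceeds 0.7 and by ``tumor_odds_multiplier`` in
    tumor-bearing subjects.  Zero pressure or zero concentration gives zero
    hazard (no drive / no bubbles).
    """

    inertial_pressure: float = 0.37
    hazard_slope: float = 16.0
    concentration_exponent: float = 1.0
    high_concentration_boost: float = 3.0
    tumor_odds_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.tumor_odds_multiplier < 1:
            raise ValueError("tumor_odds_multiplier must be >= 1")


@dataclass(frozen=True)
class Precursor:
    """Pre-collapse signature: uh1 boost (dB) on the pulse preceding a latched
    event, and the Gaussian noise SD (dB) shared by all band levels."""

    uh1_boost: float = 6.0
    noise_sd: float = 2.0


@dataclass(frozen=True)
class SubjectModel:
    """Parameters of one virtual subject (the closed-loop plant)."""

    species: str = "mouse"
    tumor: bool = False
    location: tuple[float, float] = (0.0, 0.0)
    threshold_curve: ThresholdCurve = field(default_factory=ThresholdCurve)
    kinetics: Kinetics = field(default_factory=Kinetics)
    hazard: Hazard = field(default_factory=Hazard)
    precursor: Precursor = field(default_factory=Precursor)
    tracker_h4_gain: float = 20.0  # dB at peak concentration, tracking pulse
    avert_fraction: float = 0.97  # latched event averted if P_next < frac * P_latch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species not in ("mouse", "rat"):
            raise ValueError("species must be 'mouse' or 'rat'")

    @classmethod
    def preset(cls, species: str = "mouse", **overrides: Any) -> "SubjectModel":
        """Species presets: rats clear microbubbles faster, so their kinetics
        decay constant is shorter (controllers compensate with a longer
        minimum tracking window)."""
        kin = Kinetics(decay_constant=80.0 if species == "mouse" else 55.0)
        overrides.setdefault("kinetics", kin)
        return cls(species=species, **overrides)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["location"] = list(self.location)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SubjectModel":
        d = dict(d)
        for key, sub in (("threshold_curve", ThresholdCurve), ("kinetics", Kinetics),
                         ("hazard", Hazard), ("precursor", Precursor)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "location" in d:
            d["location"] = tuple(d["location"])
        return cls(**d)


@dataclass
class SubjectState:
    """Evolving state of a virtual subject during a sonication."""

    time: float = 0.0
    pulse_index: int = 0
    pending_event: bool = False  # collapse latched for the next pulse
    latch_pressure: float = 0.0
    cumulative_dose: float = 0.0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    @classmethod
    def initial(cls, model: SubjectModel, seed: int | None = None) -> "SubjectState":
        return cls(rng=np.random.default_rng(model.seed if seed is None else seed))


def mb_concentration(kinetics: Kinetics, t: float) -> float:
    """Normalized circulating microbubble concentration at time ``t`` (s).

    0 before injection, linear rise to 1 over ``rise_time``, exponential
    decay with ``decay_constant`` thereafter; continuous and peak-normalized.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    tau = t - kinetics.injection_time
    if tau <= 0:
        return 0.0
    if tau <= kinetics.rise_time:
        return tau / kinetics.rise_time
    return float(np.exp(-(tau - kinetics.rise_time) / kinetics.decay_constant))


def harmonic_response(model: SubjectModel, concentration: float, pressure: float,
                      rng: np.random.Generator | None = None) -> dict[str, np.ndarray | float]:
    """Band levels of a therapeutic pulse (dB re baseline).

    The 7th-harmonic mean is ``concentration * threshold_curve.level(P)``;
    other harmonics and ultra-harmonics are fixed fractions of it.  With an
    ``rng``, independent Gaussian noise of SD ``precursor.noise_sd`` is added
    per band; without one the expected (noise-free) levels are returned.
    """
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    l7 = concentration * model.threshold_curve.level(pressure)
    harm = HARMONIC_WEIGHTS * l7
    uh = ULTRAHARMONIC_WEIGHTS * l7
    if rng is not None and model.precursor.noise_sd > 0:
        sd = model.precursor.noise_sd
        harm = harm + rng.normal(0.0, sd, size=7)
        uh = uh + rng.normal(0.0, sd, size=7)
    return {"harmonics": harm, "ultraharmonics": uh, "l7": float(harm[5])}


def tracker_h4_level(model: SubjectModel, concentration: float,
                     rng: np.random.Generator | None = None) -> float:
    """4th-harmonic level (dB re background) of the low-pressure tracking
    pulse; proportional to bubble concentration."""
    level = model.tracker_h4_gain * concentration
    if rng is not None and model.precursor.noise_sd > 0:
        level += rng.normal(0.0, model.precursor.noise_sd)
    return float(level)


def event_hazard(model: SubjectModel, concentration: float, pressure: float) -> float:
    """Probability that a collapse is latched on this pulse.

    Monotone non-decreasing in pressure and concentration; exactly 0 at zero
    pressure or zero concentration.
    """
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    if pressure == 0.0 or concentration <= 0.0:
        return 0.0
    hz = model.hazard
    drive = pressure * concentration ** hz.concentration_exponent
    odds = np.exp(hz.hazard_slope * (drive - hz.inertial_pressure))
    if concentration > 0.7:
        odds *= hz.high_concentration_boost
    if model.tumor:
        odds *= hz.tumor_odds_multiplier
    return float(odds / (1.0 + odds))


def simulate_pulse(model: SubjectModel, state: SubjectState, pressure: float,
                   detection: DetectionConfig | None = None) -> tuple[dict[str, Any], SubjectState]:
    """Simulate one therapeutic pulse; returns (record, next_state).

    A collapse latched on the previous pulse fires as a broadband event now
    unless the applied pressure dropped below ``avert_fraction`` times the
    latching pressure.  The hazard drawn *now* decides the next pulse's event
    and, if latched, boosts this pulse's 1st ultra-harmonic by ``uh1_boost``
    (the learnable precursor).  Deterministic given the state's generator.
    """
    detection = detection or DetectionConfig()
    rng = state.rng
    conc = mb_concentration(model.kinetics, state.time)

    fires = state.pending_event and pressure >= model.avert_fraction * state.latch_pressure

    # draw next-pulse latch before emitting bands so the precursor can show
    hz = event_hazard(model, conc, pressure)
    next_pending = bool(rng.random() < hz)

    bands = harmonic_response(model, conc, pressure, rng=rng)
    uh = np.asarray(bands["ultraharmonics"], dtype=float).copy()
    if next_pending:
        uh[0] += model.precursor.uh1_boost

    if fires:
        broadband = detection.event_threshold_db + 0.5 + abs(rng.normal(0.0, 3.0))
    else:
        broadband = rng.normal(0.0, detection.baseline_noise_sd_db)
    event = bool(broadband > detection.event_threshold_db)

    l7 = float(bands["harmonics"][5])
    dose_inc = conc * max(l7, 0.0)

    record: dict[str, Any] = {
        "pulse_index": state.pulse_index,
        "time": state.time,
        "pressure_mpa": float(pressure),
        "broadband_db": float(broadband),
        "event": event,
        "mb_kinetics": conc,
        "x_mm": model.location[0],
        "y_mm": model.location[1],
        "tumor": int(model.tumor),
        "dose_increment": dose_inc,
    }
    for i, n in enumerate(range(2, 9)):
        record[f"h{n}"] = float(bands["harmonics"][i])
    for k in range(1, 8):
        record[f"uh{k}"] = float(uh[k - 1])

    next_state = replace(
        state,
        time=state.time + 1.0,
        pulse_index=state.pulse_index + 1,
        pending_event=next_pending,
        latch_pressure=float(pressure),
        cumulative_dose=state.cumulative_dose + dose_inc,
        rng=rng,
    )
    return record, next_state


def generate_training_corpus(n_subjects: int, pulses_per_target: int = 130,
                             seed: int = 0, targets_per_subject: int = 4,
                             pressure_range: tuple[float, float] = (0.18, 0.33),
                             tumor_fraction: float = 0.5,
                             species: str = "mouse") -> pd.DataFrame:
    """Constant-pressure training corpus with one-step-ahead labels.

    Each target is sonicated at a fixed pressure drawn uniformly from
    ``pressure_range`` (the historical constant-pressure protocol: 130 pulses
    at 1 Hz).  The label of row *t* is the broadband-event flag of pulse
    *t+1*, so the last pulse of every target is dropped (no next-pulse label).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.default_rng(seed)
    frames = []
    for s in range(n_subjects):
        tumor = bool(master.random() < tumor_fraction)
        for tgt in range(targets_per_subject):
            loc = tuple(master.normal(0.0, 2.0, size=2).round(3))
            pressure = float(master.uniform(*pressure_range))
            model = SubjectModel.preset(
                species, tumor=tumor, location=loc,
                seed=int(master.integers(0, 2**31 - 1)))
            state = SubjectState.initial(model)
            records = []
            for _ in range(pulses_per_target):
                rec, state = simulate_pulse(model, state, pressure)
                records.append(rec)
            df = pd.DataFrame.from_records(records)
            df["label"] = df["event"].shift(-1)
            df = df.iloc[:-1].copy()  # last pulse has no next-pulse label
            df["label"] = df["label"].astype(int)
            df["subject_id"] = s
            df["target_id"] = tgt
            frames.append(df)
    corpus = pd.concat(frames, ignore_index=True)
    return corpus[CORPUS_COLUMNS + ["subject_id", "target_id"]]
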