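"""Two-trial delayed-response task: timeline and epoch-dependent inputs.

A simulation is a pair of back-to-back trials.  Each trial presents a tuned
cue current for 1 s, holds the memory over a blank delay, and ends with a
300-ms response period during which a uniform (untuned) reset current is
injected.  An inter-trial interval separates the first response period from
the second cue.  Optionally, the second cue angle is shifted by a
derivative-of-Gaussian function of the angular difference from the first
stimulus, emulating repulsive sensory adaptation upstream of the memory
circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Optional, Sequence

import numpy as np

from .circular import wrap_deg, wrap_360

__all__ = [
    "StimulusParams",
    "ResetPolicy",
    "AdaptationModel",
    "TrialPairSpec",
    "Epoch",
    "EpochSchedule",
    "stimulus_current",
    "adapted_stimulus_angle",
    "build_epoch_schedule",
]

EPOCH_ORDER = (
    "settle",
    "cue1",
    "delay1",
    "response1",
    "iti",
    "cue2",
    "delay2",
    "response2",
)


@dataclass(frozen=True)
class StimulusParams:
    """Tuned cue current: Gaussian bump of peak g_s and width sigma_s."""

    g_s: float = 0.02        # peak cue current, nA
    sigma_s: float = 43.2    # cue tuning width, deg
    duration: float = 1.0    # cue duration, s

    def __post_init__(self) -> None:
        if self.g_s <= 0 or self.sigma_s <= 0:
            raise ValueError("g_s and sigma_s must be > 0")


@dataclass(frozen=True)
class ResetPolicy:
    """Uniform inhibitory current injected during the response period.

    -0.08 nA fully resets the bump (fixed-synapse and plastic models);
    -0.00925 nA (an 88.4% reduction) leaves a residual bump that leaks into
    the ITI; 0 nA lets the bump persist unabated.
    """

    reset_current: float = -0.08   # nA
    reset_duration: float = 300.0  # ms

    def __post_init__(self) -> None:
        if self.reset_current > 0:
            raise ValueError("reset_current must be <= 0")
        if self.reset_duration < 0:
            raise ValueError("reset_duration must be >= 0")


@dataclass(frozen=True)
class AdaptationModel:
    """DoG-shaped repulsive shift applied to the second cue angle.

    The shift is computed on the minimal circular difference between the
    first and second stimulus, expressed in radians (amplitude a_adapt and
    width w_adapt are in radian units; the resulting shift is converted to
    degrees).  Its amplitude is calibrated at the reference ITI and decays
    exponentially with time constant tau_adapt as the ITI grows.
    """

    enabled: bool = True
    a_adapt: float = -0.015    # DoG amplitude, rad
    w_adapt: float = 0.6       # DoG width, 1/rad
    tau_adapt: float = 5.592   # ITI decay constant, s
    reference_iti: float = 1.0  # ITI at which a_adapt is calibrated, s
    decay_from_zero: bool = False  # decay referenced to ITI = 0 instead

    def __post_init__(self) -> None:
        if self.tau_adapt <= 0:
            raise ValueError("tau_adapt must be > 0")


@dataclass(frozen=True)
class TrialPairSpec:
    """Timing and stimulus angles of one trial pair.

    ``decode_times`` are offsets in seconds from the offset of the second
    stimulus (= start of the second delay).
    """

    theta1: float = 180.0
    theta2: float = 90.0
    delay1: float = 1.0
    delay2: float = 10.0
    iti: float = 1.0
    decode_times: tuple = (0.0, 1.0, 3.0, 6.0, 10.0)
    settle: float = 0.5

    def __post_init__(self) -> None:
        for name in ("delay1", "delay2", "iti", "settle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        object.__setattr__(self, "decode_times", tuple(float(t) for t in self.decode_times))
        if any(t < 0 or t > self.delay2 for t in self.decode_times):
            raise ValueError("decode_times must lie within [0, delay2]")

    def with_(self, **kwargs) -> "TrialPairSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Epoch:
    """One contiguous segment of the timeline.

    ``kind`` is "none" (no external drive), "cue" (tuned current at
    ``angle_deg``) or "reset" (uniform ``current_nA``).
    """

    label: str
    t_start_ms: float
    t_end_ms: float
    kind: str = "none"
    angle_deg: Optional[float] = None
    current_nA: Optional[float] = None


@dataclass(frozen=True)
class EpochSchedule:
    """Contiguous, ordered epochs covering the whole simulation span."""

    epochs: tuple

    @property
    def total_ms(self) -> float:
        return self.epochs[-1].t_end_ms

    def epoch(self, label: str) -> Epoch:
        for ep in self.epochs:
            if ep.label == label:
                return ep
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {"epochs": [asdict(ep) for ep in self.epochs]}

    @classmethod
    def from_dict(cls, d: dict) -> "EpochSchedule":
        return cls(epochs=tuple(Epoch(**ep) for ep in d["epochs"]))


def stimulus_current(
    theta_s: float,
    preferred_angles: np.ndarray,
    stim: StimulusParams,
) -> np.ndarray:
    """Tuned cue current g_s * exp(-dtheta^2 / (2 sigma_s^2)) per neuron (nA).

    ``dtheta`` is the minimal circular difference between the cue angle and
    each neuron's preferred angle.
    """
    if not np.isfinite(theta_s):
        raise ValueError("stimulus angle must be finite")
    dtheta = wrap_deg(np.asarray(preferred_angles, dtype=float) - theta_s)
    return stim.g_s * np.exp(-(dtheta ** 2) / (2.0 * stim.sigma_s ** 2))


def _dog_rad(x_rad: float, amp: float, width: float) -> float:
    c = np.sqrt(2.0) * np.exp(0.5)
    return x_rad * amp * width * c * np.exp(-((width * x_rad) ** 2))


def adapted_stimulus_angle(
    theta2: float,
    theta1: float,
    iti: float,
    adapt: AdaptationModel,
) -> float:
    """Second cue angle after the sensory-adaptation shift, in [0°, 360°).

    The shift is DoG(theta1 - theta2) with the amplitude scaled by
    exp(-(iti - reference_iti)/tau_adapt); it is odd in the angle difference
    and vanishes for long ITIs.  With adaptation disabled the angle passes
    through unchanged.
    """
    if not adapt.enabled:
        return wrap_360(theta2)
    ref = 0.0 if adapt.decay_from_zero else adapt.reference_iti
    a_eff = adapt.a_adapt * np.exp(-(iti - ref) / adapt.tau_adapt)
    delta_rad = np.deg2rad(wrap_deg(theta1 - theta2))
    shift_deg = np.rad2deg(_dog_rad(delta_rad, a_eff, adapt.w_adapt))
    return wrap_360(theta2 + shift_deg)


def build_epoch_schedule(
    spec: TrialPairSpec,
    stim: StimulusParams,
    reset: ResetPolicy,
    adapt: Optional[AdaptationModel] = None,
) -> EpochSchedule:
    """Realize the trial-pair timeline as an ordered epoch list.

    The second cue carries the adaptation-shifted angle when an enabled
    adaptation model is supplied; otherwise the presented angle.
    """
    cue_ms = stim.duration * 1000.0
    theta2_eff = spec.theta2
    if adapt is not None and adapt.enabled:
        theta2_eff = adapted_stimulus_angle(spec.theta2, spec.theta1, spec.iti, adapt)

    durations = [
        ("settle", spec.settle * 1000.0, "none", None, None),
        ("cue1", cue_ms, "cue", spec.theta1, None),
        ("delay1", spec.delay1 * 1000.0, "none", None, None),
        ("response1", reset.reset_duration, "reset", None, reset.reset_current),
        ("iti", spec.iti * 1000.0, "none", None, None),
        ("cue2", cue_ms, "cue", theta2_eff, None),
        ("delay2", spec.delay2 * 1000.0, "none", None, None),
        ("response2", reset.reset_duration, "reset", None, reset.reset_current),
    ]
    epochs = []
    t = 0.0
    for label, dur, kind, angle, current in durations:
        if dur < 0:
            raise ValueError(f"negative duration for epoch {label}")
        epochs.append(
            Epoch(
                label=label,
                t_start_ms=t,
                t_end_ms=t + dur,
                kind=kind,
                angle_deg=angle,
                current_nA=current,
            )
        )
        t += dur
    return EpochSchedule(epochs=tuple(epochs))
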