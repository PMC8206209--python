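"""Robotic perturbation protocol: trial timelines aligned to fMRI silent windows.

A session consists of a block of interleaved isometric contractions (used
later for EMG normalization) followed by a sequence of ramp-and-hold (RaH)
wrist perturbations.  Each perturbation is velocity controlled, is held
active for a fixed 200 ms, and must begin inside the silent window that
follows every fMRI volume so that the evoked EMG can be read free of
gradient/RF interference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

FCR = "FCR"  #: flexor carpi radialis (stretched by extension rotations, v > 0)
ECU = "ECU"  #: extensor carpi ulnaris (stretched by flexion rotations, v < 0)
MUSCLES = (FCR, ECU)


class ProtocolError(ValueError):
    """Raised when a protocol specification field is invalid."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Parameters of one perturbation session.

    Defaults reproduce the experimental protocol: 60 RaH perturbations
    drawn from six signed velocities (3 magnitudes x 2 directions, 10
    repetitions each), 400-800 ms torque-hold before triggering, 7-10 s
    rest after each perturbation, a 25 deg/s return movement plus 4 s of
    extra rest, TR = 1.225 s with a 225 ms silent window, and ten 5 s
    isometric contractions (500 mNm, alternating direction) before the
    perturbation sequence.
    """

    velocities: tuple = (-200.0, -125.0, -50.0, 50.0, 125.0, 200.0)
    reps_per_velocity: int = 10
    torque_target: float = 200.0
    torque_tol: float = 25.0
    t_hold_range: tuple = (0.4, 0.8)
    perturbation_duration: float = 0.2
    rest_range: tuple = (7.0, 10.0)
    post_return_rest: float = 4.0
    return_velocity: float = 25.0
    tr: float = 1.225
    silent_window: float = 0.225
    n_contractions: int = 10
    contraction_torque: float = 500.0
    contraction_duration: float = 5.0
    contraction_rest: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if len(self.velocities) != 6:
            raise ProtocolError(
                "velocities: pool must have 6 elements (3 magnitudes x 2 signs), "
                f"got {len(self.velocities)}"
            )
        mags = sorted({abs(v) for v in self.velocities})
        signs = {math.copysign(1.0, v) for v in self.velocities}
        if len(mags) != 3 or signs != {-1.0, 1.0}:
            raise ProtocolError("velocities: expected 3 magnitudes x 2 signs")
        if not (0.0 < self.t_hold_range[0] < self.t_hold_range[1]):
            raise ProtocolError("t_hold_range: bounds must satisfy 0 < lo < hi")
        if not (self.rest_range[0] < self.rest_range[1]):
            raise ProtocolError("rest_range: lower bound must be below upper")
        if not (self.tr > self.silent_window > 0):
            raise ProtocolError("tr: must exceed silent_window")
        if self.reps_per_velocity < 1:
            raise ProtocolError("reps_per_velocity: must be >= 1")
        if self.perturbation_duration <= 0:
            raise ProtocolError("perturbation_duration: must be > 0")
        if self.return_velocity <= 0:
            raise ProtocolError("return_velocity: must be > 0")

    @property
    def n_trials(self) -> int:
        return len(self.velocities) * self.reps_per_velocity

    def with_seed(self, seed: int) -> "ProtocolSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class TrialEvent:
    """One robotic perturbation.

    ``velocity`` is signed: positive rotations stretch FCR, negative
    rotations stretch ECU.  ``onset`` is global session time in seconds.
    """

    index: int
    velocity: float
    onset: float
    t_hold: float

    @property
    def muscle_stretched(self) -> str:
        return FCR if self.velocity > 0 else ECU

    def direction(self, muscle: str) -> str:
        """'stretch' or 'shortening' of the given muscle on this trial."""
        return "stretch" if muscle == self.muscle_stretched else "shortening"


@dataclass(frozen=True)
class ContractionBlock:
    """One isometric contraction interval with its active direction."""

    start: float
    stop: float
    direction: str  # 'flexion' (FCR active) or 'extension' (ECU active)

    @property
    def active_muscle(self) -> str:
        return FCR if self.direction == "flexion" else ECU


@dataclass
class Protocol:
    """A generated session timeline: events, contractions and volume grid."""

    spec: ProtocolSpec
    events: list  # list[TrialEvent]
    contraction_blocks: list  # list[ContractionBlock]
    volume_times: np.ndarray = field(default=None)  # volume acquisition start times
    duration: float = 0.0

    @property
    def acquisition_time(self) -> float:
        """Duration of the gradient-active part of each TR."""
        return self.spec.tr - self.spec.silent_window


def _silent_slot_after(t: float, tr: float, t_acq: float, lag: float = 0.025) -> float:
    """Earliest admissible perturbation onset at or after time ``t``.

    Perturbations start ``lag`` seconds after a volume acquisition
    completes, i.e. at k*tr + t_acq + lag for integer k.
    """
    k = math.ceil((t - t_acq - lag) / tr - 1e-12)
    return max(k, 0) * tr + t_acq + lag


def generate_protocol(spec: ProtocolSpec) -> Protocol:
    """Generate a seeded session timeline.

    The trial order is a seeded permutation of the balanced velocity
    design.  Each onset is delayed to the next silent-window slot so that
    the 200 ms measurement window never overlaps volume acquisition.
    """
    rng = np.random.default_rng(spec.seed)
    t_acq = spec.tr - spec.silent_window

    # isometric contraction block, alternating flexion/extension
    blocks = []
    t = spec.contraction_rest
    for i in range(spec.n_contractions):
        direction = "flexion" if i % 2 == 0 else "extension"
        blocks.append(ContractionBlock(t, t + spec.contraction_duration, direction))
        t += spec.contraction_duration + spec.contraction_rest

    # balanced, seeded-permuted velocity sequence
    order = np.repeat(np.asarray(spec.velocities, dtype=float), spec.reps_per_velocity)
    order = order[rng.permutation(order.size)]

    events = []
    cursor = t + 2.0  # settle time after the contraction set
    for i, v in enumerate(order):
        t_hold = rng.uniform(*spec.t_hold_range)
        onset = _silent_slot_after(cursor + t_hold, spec.tr, t_acq)
        events.append(TrialEvent(index=i, velocity=float(v), onset=onset, t_hold=t_hold))
        rest = rng.uniform(*spec.rest_range)
        return_time = abs(v) * spec.perturbation_duration / spec.return_velocity
        cursor = onset + spec.perturbation_duration + rest + return_time + spec.post_return_rest

    duration = cursor + 2 * spec.tr
    n_volumes = math.ceil(duration / spec.tr)
    volume_times = np.arange(n_volumes) * spec.tr
    return Protocol(
        spec=spec,
        events=events,
        contraction_blocks=blocks,
        volume_times=volume_times,
        duration=n_volumes * spec.tr,
    )
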