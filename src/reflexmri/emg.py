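"""EMG processing: segmentation, filtering, artifact removal, LLR amplitude.

Raw recordings contain a measurement channel ``y`` (muscle activity plus
motion-induced artifact), a co-located reference channel ``r`` (artifact
only), and the robot encoder angle ``theta``.  Trials are segmented to the
200 ms silent window starting at perturbation onset, band-pass filtered
(4th-order Butterworth, 20-250 Hz), cleaned with one of three methods

* STD: ``x_hat = y``          (assume artifacts negligible)
* SUB: ``x_hat = y - r``      (assume reference equals true artifact)
* ANC: ``x_hat = y - f(r)``   (learn the channel nonlinearity, ANFIS)

then rectified, low-pass filtered at 60 Hz, normalized by the mean
contraction-block envelope, and integrated over the [50, 100] ms
long-latency window (time in ms) to give the LLR amplitude H.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import signal

from .protocol import FCR, ECU, MUSCLES, TrialEvent

logger = logging.getLogger(__name__)

METHODS = ("STD", "SUB", "ANC")
LLR_WINDOW_S = (0.050, 0.100)
SEGMENT_DURATION_S = 0.200


@dataclass
class EmgRecording:
    """A continuous single-muscle recording with trial and block markers."""

    fs: float
    y: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    trial_markers: list  # list[(sample_index, TrialEvent)]
    contraction_blocks: list  # list[ContractionBlock]
    muscle: str = FCR

    def __post_init__(self):
        n = len(self.y)
        if not (len(self.r) == n and len(self.theta) == n):
            raise ValueError("channel length mismatch")
        for idx, _ in self.trial_markers:
            if not (0 <= idx < n):
                raise ValueError(f"trial marker {idx} outside recording")


@dataclass
class TrialSegment:
    """A 200 ms trial window; first sample is the perturbation onset."""

    y: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    fs: float
    event: Optional[TrialEvent] = None
    filtered: bool = False

    def __len__(self):
        return len(self.y)


def segment_trials(recording: EmgRecording, duration: float = SEGMENT_DURATION_S) -> list:
    """Extract one 200 ms segment per trial marker.

    Markers too close to the end of the recording are skipped with a
    warning rather than raising.
    """
    n_seg = round(duration * recording.fs)
    segments = []
    for idx, event in recording.trial_markers:
        if idx + n_seg > len(recording.y):
            logger.warning("trial at sample %d too close to recording end; skipped", idx)
            continue
        sl = slice(idx, idx + n_seg)
        segments.append(
            TrialSegment(
                y=recording.y[sl].copy(),
                r=recording.r[sl].copy(),
                theta=recording.theta[sl].copy(),
                fs=recording.fs,
                event=event,
            )
        )
    return segments


def _butter_sos(fs, low=20.0, high=250.0, order=4):
    if fs <= 2 * high:
        raise ValueError(f"fs={fs} Hz cannot support a {high} Hz band edge")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(x, fs, low=20.0, high=250.0, order=4, zero_phase=True):
    """4th-order Butterworth band-pass (20-250 Hz default).

    Zero-phase (forward-backward) by default so burst latency -- which the
    [50, 100] ms LLR window depends on -- is preserved.
    """
    sos = _butter_sos(fs, low, high, order)
    x = np.asarray(x, dtype=float)
    if zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def bandpass_segment(segment: TrialSegment, **kwargs) -> TrialSegment:
    """Band-pass both the measurement and reference channels of a segment."""
    return replace(
        segment,
        y=bandpass(segment.y, segment.fs, **kwargs),
        r=bandpass(segment.r, segment.fs, **kwargs),
        filtered=True,
    )


def apply_method(segment: TrialSegment, method: str, model=None) -> np.ndarray:
    """Return the clean-EMG estimate ``x_hat`` for one filtered segment."""
    if method == "STD":
        return segment.y.copy()
    if method == "SUB":
        return segment.y - segment.r
    if method == "ANC":
        if model is None:
            raise ValueError("ANC requires a trained AnfisRegressor")
        from .anfis import build_inputs

        return segment.y - model.predict(build_inputs(segment))
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def envelope(x, fs, cutoff=60.0, order=4, zero_phase=True):
    """Rectify and low-pass (4th-order Butterworth, 60 Hz); clip at zero."""
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    rect = np.abs(np.asarray(x, dtype=float))
    out = signal.sosfiltfilt(sos, rect) if zero_phase else signal.sosfilt(sos, rect)
    return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class NormalizationConstant:
    muscle: str
    value: float

    def __post_init__(self):
        if not self.value > 0:
            raise ValueError(f"normalization constant for {self.muscle} must be > 0")


def normalization_constant(
    recording: EmgRecording, muscle: str, central_s: float = 3.0
) -> NormalizationConstant:
    """Mean processed envelope over the central 3 s of active contractions.

    Flexion blocks are used for FCR, extension blocks for ECU; the same
    constant normalizes both stretch and shortening responses.  The blocks
    are isometric (no perturbation artifact expected), so the standard
    pipeline (band-pass, rectify, low-pass) is applied to ``y`` directly.
    """
    blocks = [b for b in recording.contraction_blocks if b.active_muscle == muscle]
    if not blocks:
        raise ValueError(f"no contraction blocks with {muscle} active")
    fs = recording.fs
    means = []
    for b in blocks:
        if b.stop - b.start < central_s:
            raise ValueError("contraction block shorter than the central window")
        i0, i1 = round(b.start * fs), round(b.stop * fs)
        env = envelope(bandpass(recording.y[i0:i1], fs), fs)
        mid = (i1 - i0) / 2.0
        half = central_s * fs / 2.0
        c0, c1 = round(mid - half), round(mid + half)
        means.append(float(np.mean(env[c0:c1])))
    return NormalizationConstant(muscle=muscle, value=float(np.mean(means)))


def llr_amplitude(
    env: np.ndarray,
    norm: NormalizationConstant | float,
    fs: float,
    window_s: tuple = LLR_WINDOW_S,
) -> float:
    """LLR amplitude H: area of the normalized envelope over [50, 100] ms.

    Trapezoidal integration with time expressed in milliseconds, both
    window endpoints included; units are normalized-EMG * ms.
    """
    value = norm.value if isinstance(norm, NormalizationConstant) else float(norm)
    i0 = round(window_s[0] * fs)
    i1 = round(window_s[1] * fs)
    if i1 >= len(env):
        raise ValueError("LLR window extends past the segment end")
    t_ms = np.arange(i0, i1 + 1) / fs * 1000.0
    return float(np.trapezoid(np.asarray(env[i0 : i1 + 1]) / value, t_ms))


class LlrTable:
    """Tidy table of LLR amplitudes H.

    One row per (participant, session, filter, muscle, velocity,
    repetition).  ``means()`` collapses repetitions to the cell averages
    used by the group-level agreement analysis.
    """

    COLUMNS = ["participant", "session", "filter", "muscle", "velocity", "repetition", "H"]
    KEY = COLUMNS[:-1]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if df.duplicated(subset=self.KEY).any():
            raise ValueError("duplicate (participant, session, filter, muscle, velocity, repetition) keys")
        if (df["H"] < 0).any():
            raise ValueError("H must be non-negative")
        self.df = df.reset_index(drop=True)[self.COLUMNS]

    def __len__(self):
        return len(self.df)

    def means(self) -> pd.DataFrame:
        """Cell means H-bar over repetitions, with stimulus direction."""
        g = (
            self.df.groupby(["participant", "session", "filter", "muscle", "velocity"])["H"]
            .mean()
            .reset_index(name="H_mean")
        )
        g["direction"] = np.where(
            ((g["muscle"] == FCR) & (g["velocity"] > 0))
            | ((g["muscle"] == ECU) & (g["velocity"] < 0)),
            "stretch",
            "shortening",
        )
        return g

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "LlrTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_rows(cls, rows: Iterable[dict]) -> "LlrTable":
        return cls(pd.DataFrame(list(rows)))


def process_session(
    recordings: dict,
    participant: str,
    session: str,
    methods: Iterable[str] = METHODS,
    anfis_config: Optional[dict] = None,
    seed: int = 0,
) -> list:
    """Run the full per-trial pipeline for one session.

    ``recordings`` maps muscle name to :class:`EmgRecording`.  For ANC a
    fresh ANFIS model is trained on every trial segment (the artifact is
    position dependent, so one model per perturbation time-series).
    Returns tidy rows suitable for :meth:`LlrTable.from_rows`.
    """
    from .anfis import AnfisRegressor, build_inputs

    anfis_config = dict(anfis_config or {})
    rows = []
    for muscle, rec in recordings.items():
        norm = normalization_constant(rec, muscle)
        segments = [bandpass_segment(s) for s in segment_trials(rec)]
        reps: dict = {}
        for seg in segments:
            v = seg.event.velocity
            reps[v] = reps.get(v, -1) + 1
            models = {}
            # a flat reference channel carries no interference evidence, so
            # the canceller has nothing to estimate and w_hat is zero
            if "ANC" in methods and np.ptp(seg.r) > 0:
                model = AnfisRegressor(
                    random_state=seed + 7919 * seg.event.index, **anfis_config
                )
                model.fit(build_inputs(seg), seg.y)
                models["ANC"] = model
            for method in methods:
                if method == "ANC" and method not in models:
                    x_hat = seg.y.copy()
                else:
                    x_hat = apply_method(seg, method, models.get(method))
                H = llr_amplitude(envelope(x_hat, seg.fs), norm, seg.fs)
                rows.append(
                    dict(
                        participant=participant,
                        session=session,
                        filter=method,
                        muscle=muscle,
                        velocity=v,
                        repetition=reps[v],
                        H=max(H, 0.0),
                    )
                )
    return rows


def build_llr_table(
    sessions: Iterable[tuple],
    methods: Iterable[str] = METHODS,
    anfis_config: Optional[dict] = None,
    seed: int = 0,
) -> LlrTable:
    """Build the factorial H table across (participant, session) recordings.

    ``sessions`` yields ``(participant, session, recordings_by_muscle)``.
    """
    rows = []
    for k, (participant, session, recordings) in enumerate(sessions):
        rows.extend(
            process_session(
                recordings,
                participant,
                session,
                methods=methods,
                anfis_config=anfis_config,
                seed=seed + 104729 * k,
            )
        )
    return LlrTable.from_rows(rows)
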