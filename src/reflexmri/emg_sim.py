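"""Synthetic EMG sessions with ground-truth clean signal and motion artifacts.

The generator emulates what the electrode apparatus sees inside the
scanner: the measurement channel records muscle activity plus a
motion-induced artifact ``w`` (flux change through the moving electrode
lead loop), while the co-located reference channel records ``r``.  Both
are driven by a shared motion source derived from the encoder angle, but
pass through *different* nonlinear channels, so ``w = g(r)`` for some
nonlinear ``g`` with ``w != r`` -- plain subtraction is imperfect and the
adaptive canceller has something to learn.

Clean EMG is band-limited Gaussian noise (20-250 Hz) amplitude-modulated
by a burst envelope, so the band-pass stage passes it essentially
unchanged and ground-truth envelope areas have a closed form.  The
conservation ``y = x + w`` holds sample-wise by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .emg import EmgRecording
from .protocol import ECU, FCR, MUSCLES, Protocol, TrialEvent

#: peak/mean velocity ratio of a minimum-jerk profile
_MINJERK_PEAK = 1.875


@dataclass(frozen=True)
class EmgSimParams:
    """Generator parameters for one synthetic session.

    Amplitudes are expressed relative to the isometric-contraction level
    (1.0); LLR burst areas are in normalized-EMG*ms per deg/s of
    perturbation velocity.  ``artifact_gain`` sets the peak artifact to a
    multiple of the largest expected LLR envelope peak (artifacts 5-10x
    the stretch-evoked response are the regime the apparatus faces).
    """

    fs: float = 2000.0
    background_level: float = 0.05
    slr_gain: float = 0.05
    llr_gain: float = 0.1
    llr_cv: float = 0.2
    shortening_scale: float = 0.2
    contraction_level: float = 1.0
    artifact_gain: float = 5.0
    # channel nonlinearities: coefficients of powers m, m^2, m^3
    artifact_coeffs_w: tuple = (1.0, 0.0, 0.3)
    artifact_coeffs_r: tuple = (0.8, 0.2, 0.0)
    artifact_smooth_w_hz: float = 50.0
    artifact_smooth_r_hz: float = 70.0
    jitter_level: float = 0.3
    noise_sd: float = 0.01

    def __post_init__(self):
        if self.fs < 1000.0:
            raise ValueError("fs must be >= 1000 Hz (analysis band extends to 250 Hz)")
        if tuple(self.artifact_coeffs_w) == tuple(self.artifact_coeffs_r) and (
            self.artifact_smooth_w_hz == self.artifact_smooth_r_hz
        ):
            # identical channels are allowed for oracle tests but are not
            # a valid default study condition; no error, callers opt in.
            pass

    @property
    def typical_llr_peak(self) -> float:
        """Raw envelope peak of the largest stretch LLR burst (v = 200)."""
        return self.contraction_level * 2.0 * self.llr_gain * 200.0 / 50.0


@dataclass
class SyntheticEmgTruth:
    """Ground truth for one synthetic session.

    ``clean`` and ``artifact`` are per-muscle sample-wise arrays with
    ``y = clean + artifact`` exactly; ``true_H`` holds the generative LLR
    burst areas (normalized-EMG*ms, excluding background).
    """

    clean: dict
    artifact: dict
    true_H: pd.DataFrame  # columns: trial, muscle, velocity, direction, true_H

    def clean_recording(self, recording: EmgRecording) -> EmgRecording:
        """The same recording with the artifact removed (oracle input)."""
        m = recording.muscle
        return EmgRecording(
            fs=recording.fs,
            y=self.clean[m].copy(),
            r=np.zeros_like(self.clean[m]),
            theta=recording.theta.copy(),
            trial_markers=list(recording.trial_markers),
            contraction_blocks=list(recording.contraction_blocks),
            muscle=m,
        )


def _bandnoise(n, fs, low, high, rng):
    """Unit-variance Gaussian noise band-limited to [low, high] Hz."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    sd = x.std()
    return x / sd if sd > 0 else x


def _onepole(x, fs, cutoff_hz):
    alpha = np.exp(-2.0 * np.pi * cutoff_hz / fs)
    return signal.lfilter([1.0 - alpha], [1.0, -alpha], x)


def _hann_bump(n):
    return np.hanning(n + 2)[1:-1]


def _minjerk(n):
    """Unit minimum-jerk position profile on n samples."""
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def trial_envelope(
    event: TrialEvent, params: EmgSimParams, muscle: str, eps: float = 0.0
) -> tuple:
    """Burst amplitude envelope (raw units) of one 200 ms trial window.

    Returns ``(a, true_H)`` where ``a`` excludes the background level and
    ``true_H = llr_gain * |v| * (1 + eps)`` (scaled down for shortening).
    The short-latency burst occupies [25, 50) ms, the long-latency burst
    [50, 100] ms; areas are exact in normalized-EMG*ms.
    """
    fs, c = params.fs, params.contraction_level
    n = round(0.2 * fs)
    a = np.zeros(n)
    scale = 1.0 if event.direction(muscle) == "stretch" else params.shortening_scale
    true_H = max(params.llr_gain * abs(event.velocity) * (1.0 + eps) * scale, 0.0)
    slr_area = params.slr_gain * abs(event.velocity) * scale
    dt_ms = 1000.0 / fs

    def _insert(lo, hi, area_norm):
        bump = _hann_bump(hi - lo)
        bump_area = np.trapezoid(bump, dx=dt_ms)
        if bump_area > 0:
            a[lo:hi] += c * area_norm / bump_area * bump

    _insert(round(0.025 * fs), round(0.050 * fs), slr_area)
    _insert(round(0.050 * fs), round(0.100 * fs) + 1, true_H)
    return a, true_H


def gen_trial_emg(event: TrialEvent, params: EmgSimParams, rng, muscle: str | None = None):
    """One clean 200 ms trial segment ``x`` and its ground-truth area.

    ``x`` is background plus burst envelope multiplied by a band-limited
    carrier; the normalized envelope area over [50, 100] ms approximates
    ``true_H`` plus the constant background contribution.
    """
    if muscle is None:
        muscle = event.muscle_stretched
    eps = rng.normal(0.0, params.llr_cv) if params.llr_cv > 0 else 0.0
    a, true_H = trial_envelope(event, params, muscle, eps)
    a = a + params.background_level * params.contraction_level
    carrier = _bandnoise(len(a), params.fs, 20.0, 250.0, rng)
    return a * carrier, true_H


def encoder_trajectory(protocol: Protocol, params: EmgSimParams) -> np.ndarray:
    """Encoder angle over the session: minimum-jerk ramps and slow returns."""
    spec = protocol.spec
    fs = params.fs
    n = round(protocol.duration * fs)
    theta = np.zeros(n)
    for ev in protocol.events:
        delta = ev.velocity * spec.perturbation_duration
        i0 = round(ev.onset * fs)
        n_pert = round(spec.perturbation_duration * fs)
        ret_start = ev.onset + spec.perturbation_duration + 0.5 * (
            spec.rest_range[0] + spec.rest_range[1]
        )
        n_ret = max(round(abs(delta) / spec.return_velocity * fs), 2)
        j0 = round(ret_start * fs)
        if i0 + n_pert > n:
            continue
        theta[i0 : i0 + n_pert] += delta * _minjerk(n_pert)
        end = min(j0 + n_ret, n)
        if end > j0:
            theta[i0 + n_pert : j0] += delta
            theta[j0:end] += delta * (1.0 - _minjerk(n_ret))[: end - j0]
        else:
            theta[i0 + n_pert :] += delta
    return theta


def motion_source(theta, params: EmgSimParams, rng) -> np.ndarray:
    """Shared motion source: low-passed encoder velocity plus motion-gated jitter.

    Normalized so the fastest perturbation (200 deg/s commanded, 375 deg/s
    minimum-jerk peak) reaches ~1.
    """
    theta = np.asarray(theta, dtype=float)
    if np.allclose(theta, theta[0]):
        return np.zeros_like(theta)
    fs = params.fs
    vel = np.gradient(theta) * fs
    sos = signal.butter(2, 50.0, btype="lowpass", fs=fs, output="sos")
    m = signal.sosfiltfilt(sos, vel) / (_MINJERK_PEAK * 200.0)
    if params.jitter_level > 0:
        jit = _bandnoise(len(m), fs, 20.0, 150.0, rng)
        m = m + params.jitter_level * jit * np.abs(m)
    return m


def _poly(m, coeffs):
    out = np.zeros_like(m)
    for k, ck in enumerate(coeffs, start=1):
        if ck:
            out += ck * m**k
    return out


def gen_artifact(theta, params: EmgSimParams, rng) -> tuple:
    """Artifact pair ``(w, r)`` from an encoder trajectory.

    ``w`` (measurement-channel interference) and ``r`` (reference channel)
    are distinct low-order polynomials of the shared motion source, each
    smoothed by its own one-pole filter.  A constant trajectory yields
    zero artifact (no motion, no flux change).  Amplitude is calibrated so
    that the peak of ``w`` *within the 20-250 Hz analysis band* -- the
    component the processing pipeline actually sees -- is ``artifact_gain``
    times the largest LLR envelope peak, matching the regime where observed
    artifacts are several times the stretch-evoked response.
    """
    m = motion_source(theta, params, rng)
    if not np.any(m):
        z = np.zeros_like(m)
        return z, z.copy()
    w = _onepole(_poly(m, params.artifact_coeffs_w), params.fs, params.artifact_smooth_w_hz)
    r = _onepole(_poly(m, params.artifact_coeffs_r), params.fs, params.artifact_smooth_r_hz)
    sos = signal.butter(4, [20.0, 250.0], btype="bandpass", fs=params.fs, output="sos")
    inband_peak = np.abs(signal.sosfiltfilt(sos, w)).max()
    if inband_peak <= 0:
        return np.zeros_like(m), np.zeros_like(m)
    kappa = params.artifact_gain * params.typical_llr_peak / inband_peak
    return kappa * w, kappa * r


def generate_session_recording(
    protocol: Protocol, params: EmgSimParams, rng
) -> tuple:
    """Full synthetic session: one recording per muscle, plus ground truth.

    Returns ``(recordings, truth)`` where ``recordings`` maps muscle name
    to :class:`EmgRecording` with continuous channels ``y = x + w``
    (exact), ``r`` and ``theta`` at ``fs``, trial markers, and the ten
    interleaved isometric contraction blocks.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    spec = protocol.spec
    fs = params.fs
    n = round(protocol.duration * fs)
    theta = encoder_trajectory(protocol, params)

    markers = [(round(ev.onset * fs), ev) for ev in protocol.events]
    recordings, clean, artifact = {}, {}, {}
    truth_rows = []
    for muscle in MUSCLES:
        # --- clean EMG: modulated band-limited carrier -------------------
        amp = np.full(n, params.background_level * params.contraction_level)
        ramp_n = round(0.2 * fs)
        for b in protocol.contraction_blocks:
            if b.active_muscle != muscle:
                continue
            i0, i1 = round(b.start * fs), round(b.stop * fs)
            amp[i0:i1] = params.contraction_level
            amp[i0 : i0 + ramp_n] = np.linspace(
                params.background_level * params.contraction_level,
                params.contraction_level,
                ramp_n,
            )
            amp[i1 - ramp_n : i1] = np.linspace(
                params.contraction_level,
                params.background_level * params.contraction_level,
                ramp_n,
            )
        for idx, ev in markers:
            eps = rng.normal(0.0, params.llr_cv) if params.llr_cv > 0 else 0.0
            a, true_H = trial_envelope(ev, params, muscle, eps)
            amp[idx : idx + len(a)] += a[: max(n - idx, 0)]
            truth_rows.append(
                dict(
                    trial=ev.index,
                    muscle=muscle,
                    velocity=ev.velocity,
                    direction=ev.direction(muscle),
                    true_H=true_H,
                )
            )
        carrier = _bandnoise(n, fs, 20.0, 250.0, rng)
        x = amp * carrier
        if params.noise_sd > 0:
            x = x + params.noise_sd * params.contraction_level * rng.standard_normal(n)

        w, r = gen_artifact(theta, params, rng)
        recordings[muscle] = EmgRecording(
            fs=fs,
            y=x + w,
            r=r,
            theta=theta.copy(),
            trial_markers=list(markers),
            contraction_blocks=list(protocol.contraction_blocks),
            muscle=muscle,
        )
        clean[muscle] = x
        artifact[muscle] = w

    truth = SyntheticEmgTruth(
        clean=clean, artifact=artifact, true_H=pd.DataFrame(truth_rows)
    )
    return recordings, truth
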