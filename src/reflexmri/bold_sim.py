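"""Synthetic BOLD phantoms with known muscle-specific effect maps.

Each voxel's series follows the generating GLM: the two LLR-amplitude
regressors (built exactly as in the analysis module) scaled by
ground-truth beta maps, a baseline, and AR(1) noise.  Active voxels form
connected rectangular clusters; effect size is specified as the expected
peak t-statistic of the fitted contrast, from which beta is derived at
generation time given the design and noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import glm as _glm
from .protocol import ECU, FCR, Protocol


@dataclass
class BoldPhantom:
    """4-D phantom with ground-truth effect maps and design columns."""

    data: np.ndarray  # (x, y, z, volumes)
    truth_beta_fcr: np.ndarray
    truth_beta_ecu: np.ndarray
    reg_fcr: np.ndarray
    reg_ecu: np.ndarray
    volume_times: np.ndarray
    noise_ar1: float
    noise_sd: float
    voxel_mm: tuple = (2.0, 2.0, 2.0)
    baseline: float = 100.0

    @property
    def shape(self):
        return self.data.shape[:3]

    def flat(self) -> np.ndarray:
        """Voxels x volumes view for GLM fitting."""
        return self.data.reshape(-1, self.data.shape[-1])


def _ar1_noise(shape, rho, sd, rng):
    eps = rng.standard_normal(shape)
    if rho == 0.0:
        return sd * eps
    out = np.empty_like(eps)
    out[..., 0] = eps[..., 0] / np.sqrt(1.0 - rho**2)
    for t in range(1, shape[-1]):
        out[..., t] = rho * out[..., t - 1] + eps[..., t]
    return sd * out * np.sqrt(1.0 - rho**2)


def _cluster_mask(shape, corner, size):
    m = np.zeros(shape, dtype=bool)
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    m[sl] = True
    return m


def stretch_regressors(
    protocol: Protocol,
    amplitudes: dict,
    hrf: _glm.HrfSpec = _glm.STANDARD_HRF,
    spec: _glm.EventRegressorSpec = _glm.EventRegressorSpec(),
):
    """Per-muscle LLR regressors from the stretch trials of a protocol.

    ``amplitudes`` maps muscle name to per-stretch-trial H values, in
    trial order.  Returns ``(reg_fcr, reg_ecu, volume_times)``.
    """
    vt = protocol.volume_times
    regs = {}
    for muscle in (FCR, ECU):
        events = [ev for ev in protocol.events if ev.muscle_stretched == muscle]
        amps = np.asarray(amplitudes[muscle], dtype=float)
        if len(amps) != len(events):
            raise ValueError(f"{muscle}: {len(events)} stretch trials, {len(amps)} amplitudes")
        regs[muscle] = _glm.build_regressor(
            [ev.onset for ev in events], amps, vt, hrf=hrf, spec=spec
        )
    return regs[FCR], regs[ECU], vt


def generate_bold_phantom(
    protocol: Protocol,
    amplitudes: dict,
    rng,
    shape=(16, 16, 10),
    hrf: _glm.HrfSpec = _glm.STANDARD_HRF,
    cluster_size=(3, 3, 3),
    fcr_corner=None,
    ecu_corner=None,
    target_peak_t: float = 8.0,
    beta: dict | None = None,
    noise_sd: float = 1.0,
    noise_ar1: float = 0.3,
    baseline: float = 100.0,
    voxel_mm=(2.0, 2.0, 2.0),
) -> BoldPhantom:
    """Generate a phantom whose active clusters have known effect size.

    ``target_peak_t`` is the expected t of the generating contrast at an
    active voxel when the generating design is fit by OLS; beta is derived
    from it, the design, and ``noise_sd``.  ``target_peak_t=0`` (or empty
    clusters) gives a null phantom.  An explicit ``beta`` mapping
    (muscle -> effect amplitude) overrides the derived values, which is
    needed e.g. for noiseless phantoms where no t is defined.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    shape = tuple(shape)
    cluster_size = tuple(cluster_size)
    reg_f, reg_e, vt = stretch_regressors(protocol, amplitudes, hrf=hrf)
    n_vol = len(vt)
    if fcr_corner is None:
        fcr_corner = (1, 1, 1)
    if ecu_corner is None:
        ecu_corner = tuple(max(d - s - 1, 0) for d, s in zip(shape, cluster_size))
    for corner in (fcr_corner, ecu_corner):
        if any(c + s > d for c, s, d in zip(corner, cluster_size, shape)):
            raise ValueError("cluster does not fit inside the phantom geometry")

    if beta is not None:
        betas = {FCR: beta.get(FCR, 0.0), ECU: beta.get(ECU, 0.0)}
    else:
        X = np.column_stack([reg_f, reg_e, np.ones(n_vol)])
        xtx_inv = np.linalg.pinv(X.T @ X)
        betas = {}
        for i, muscle in enumerate((FCR, ECU)):
            se = noise_sd * np.sqrt(xtx_inv[i, i])
            betas[muscle] = target_peak_t * se

    mask_f = _cluster_mask(shape, fcr_corner, cluster_size)
    mask_e = _cluster_mask(shape, ecu_corner, cluster_size)
    beta_f = np.where(mask_f, betas[FCR], 0.0)
    beta_e = np.where(mask_e, betas[ECU], 0.0)

    data = np.full(shape + (n_vol,), float(baseline))
    data += beta_f[..., None] * reg_f + beta_e[..., None] * reg_e
    if noise_sd > 0:
        data += _ar1_noise(shape + (n_vol,), noise_ar1, noise_sd, rng)
    return BoldPhantom(
        data=data,
        truth_beta_fcr=beta_f,
        truth_beta_ecu=beta_e,
        reg_fcr=reg_f,
        reg_ecu=reg_e,
        volume_times=vt,
        noise_ar1=noise_ar1,
        noise_sd=noise_sd,
        voxel_mm=tuple(voxel_mm),
        baseline=baseline,
    )
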