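"""Voxelwise GLM analysis of BOLD series with LLR-amplitude regressors.

The neural response at each voxel is modeled as

    y = beta_FCR * H*_FCR + beta_ECU * H*_ECU + beta_0 + beta_R * R

where each H* column is built by convolving, for the stretch trials of
one muscle, a 50 ms rectangular function placed 50 ms after perturbation
onset with height equal to the trial's LLR amplitude, with a
double-gamma hemodynamic response function.  Two HRF parameter sets are
provided: a brainstem-specific kernel (earlier peak, stronger relative
undershoot) and the standard cortical kernel.  Fitting is ordinary least
squares; contrasts give t-maps thresholded voxelwise (uncorrected p or
Bonferroni over the mask) with an optional cluster-extent cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HrfSpec:
    """Double-gamma HRF parameters (SPM-style, seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    onset: float = 0.0
    kernel_length: float = 32.0

    def __post_init__(self):
        if not (self.kernel_length > self.undershoot_delay):
            raise ValueError("kernel_length must exceed undershoot_delay")
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersions must be > 0")


#: standard cortical HRF
STANDARD_HRF = HrfSpec()
#: brainstem-specific HRF: earlier peak and undershoot, higher ratio
BRAINSTEM_HRF = HrfSpec(
    peak_delay=4.5,
    undershoot_delay=10.0,
    peak_dispersion=1.0,
    undershoot_dispersion=1.0,
    peak_undershoot_ratio=15.0,
)


def hrf_kernel(spec: HrfSpec, dt: float) -> np.ndarray:
    """Sampled double-gamma kernel on [0, kernel_length], peak-normalized.

    Difference of two gamma densities with shape = delay/dispersion and
    scale = dispersion, the undershoot scaled by 1/ratio.
    """
    if dt >= spec.kernel_length:
        raise ValueError("dt must be smaller than kernel_length")
    t = np.arange(0.0, spec.kernel_length + dt / 2, dt) - spec.onset
    t = np.maximum(t, 0.0)
    peak = stats.gamma.pdf(
        t, spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion
    )
    under = stats.gamma.pdf(
        t, spec.undershoot_delay / spec.undershoot_dispersion, scale=spec.undershoot_dispersion
    )
    k = peak - under / spec.peak_undershoot_ratio
    return k / k.max()


@dataclass(frozen=True)
class EventRegressorSpec:
    """Boxcar placement for LLR-amplitude-modulated event regressors."""

    boxcar_duration: float = 0.050
    onset_offset: float = 0.050
    microtime_dt: float = 0.005

    def __post_init__(self):
        if self.boxcar_duration <= 0:
            raise ValueError("boxcar_duration must be > 0")
        if self.microtime_dt > self.boxcar_duration / 2:
            raise ValueError("microtime_dt must resolve the boxcar (<= duration/2)")


def build_regressor(
    onsets,
    amplitudes,
    volume_times,
    hrf: HrfSpec = STANDARD_HRF,
    spec: EventRegressorSpec = EventRegressorSpec(),
) -> np.ndarray:
    """One design column: amplitude-modulated boxcars convolved with the HRF.

    A rectangular function of height ``amplitudes[k]`` is placed at
    ``onsets[k] + onset_offset`` for ``boxcar_duration`` seconds on a
    microtime grid, convolved with the sampled HRF, and read out at the
    volume acquisition start times.  Events past the series end simply
    contribute nothing within range.
    """
    onsets = np.asarray(onsets, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    volume_times = np.asarray(volume_times, dtype=float)
    if len(onsets) != len(amplitudes):
        raise ValueError("onsets and amplitudes length mismatch")
    dt = spec.microtime_dt
    t_end = volume_times.max() + dt
    n = int(np.ceil(t_end / dt)) + 1
    stick = np.zeros(n)
    n_box = max(int(round(spec.boxcar_duration / dt)), 1)
    for onset, amp in zip(onsets, amplitudes):
        i0 = int(round((onset + spec.onset_offset) / dt))
        if i0 >= n:
            continue
        stick[i0 : i0 + n_box] += amp
    kernel = hrf_kernel(hrf, dt)
    conv = np.convolve(stick, kernel)[:n] * dt
    return np.interp(volume_times, np.arange(n) * dt, conv)


@dataclass
class DesignMatrix:
    """Design matrix with named columns and volume times."""

    X: np.ndarray
    names: list
    volume_times: np.ndarray

    def __post_init__(self):
        if len(self.names) != self.X.shape[1]:
            raise ValueError("names/column mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("column names must be unique")

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]


def dct_basis(n: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass confound basis.

    Order = floor(2 * T / cutoff) with T the session length; columns are
    unit-norm DCT-II functions (constant term excluded).
    """
    T = n * tr
    order = int(np.floor(2.0 * T / cutoff_s))
    t = np.arange(n)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n)) for k in range(1, order + 1)]
    if not cols:
        return np.empty((n, 0))
    B = np.column_stack(cols)
    return B / np.linalg.norm(B, axis=0)


def build_design(
    regressors: dict,
    volume_times,
    nuisance: np.ndarray | None = None,
    session_lengths: list | None = None,
    highpass_cutoff: float | None = None,
    tr: float | None = None,
) -> DesignMatrix:
    """Assemble the design: regressors of interest, intercept(s), confounds.

    With ``session_lengths`` given (concatenated runs), one mean column
    per session replaces the single intercept; a high-pass DCT block is
    appended when ``highpass_cutoff`` is set (requires ``tr``).  Raises if
    the assembled matrix is rank deficient, naming collinear columns.
    """
    volume_times = np.asarray(volume_times, dtype=float)
    n = len(volume_times)
    cols, names = [], []
    for name, col in regressors.items():
        col = np.asarray(col, dtype=float)
        if len(col) != n:
            raise ValueError(f"regressor {name!r} has wrong length")
        cols.append(col)
        names.append(name)
    if session_lengths:
        if sum(session_lengths) != n:
            raise ValueError("session lengths do not sum to volume count")
        start = 0
        for k, length in enumerate(session_lengths):
            ind = np.zeros(n)
            ind[start : start + length] = 1.0
            cols.append(ind)
            names.append(f"session_{k}")
            start += length
    else:
        cols.append(np.ones(n))
        names.append("intercept")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n:
            nuisance = nuisance.T
        for k in range(nuisance.shape[1]):
            cols.append(nuisance[:, k])
            names.append(f"nuisance_{k}")
    if highpass_cutoff:
        if tr is None:
            raise ValueError("tr required for high-pass basis")
        B = dct_basis(n, tr, highpass_cutoff)
        for k in range(B.shape[1]):
            cols.append(B[:, k])
            names.append(f"dct_{k + 1}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    return DesignMatrix(X=X, names=names, volume_times=volume_times)


def smooth_volume(data4d, fwhm_mm, voxel_mm, mask=None) -> np.ndarray:
    """Separable Gaussian smoothing of each volume (sigma from FWHM).

    Masking, when requested, is applied after smoothing.
    """
    data4d = np.asarray(data4d, dtype=float)
    voxel_mm = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    if fwhm_mm < voxel_mm.min():
        logger.warning("FWHM %.2f mm below voxel size; smoothing anyway", fwhm_mm)
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_mm
    out = np.empty_like(data4d)
    for v in range(data4d.shape[-1]):
        out[..., v] = ndimage.gaussian_filter(data4d[..., v], sigma=sigma_vox)
    if mask is not None:
        out *= np.asarray(mask, dtype=bool)[..., None]
    return out


@dataclass
class GlmFit:
    beta: np.ndarray  # (n_voxels, n_columns)
    mse: np.ndarray  # residual mean square per voxel
    df: int
    design: DesignMatrix
    _xtx_inv: np.ndarray = field(repr=False, default=None)


def fit_glm(Y: np.ndarray, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares per voxel; Y is (n_voxels, n_volumes)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = design.X
    if Y.shape[1] != X.shape[0]:
        raise ValueError("Y volumes do not match design rows")
    rank = np.linalg.matrix_rank(X)
    df = X.shape[0] - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T
    resid = Y - beta @ X.T
    mse = (resid**2).sum(axis=1) / df
    return GlmFit(
        beta=beta, mse=mse, df=df, design=design, _xtx_inv=np.linalg.pinv(X.T @ X)
    )


@dataclass
class StatMap:
    """Voxel t-map with degrees of freedom (flat or 3-D ``t``)."""

    t: np.ndarray
    df: int
    voxel_mm: tuple = (2.0, 2.0, 2.0)
    mask: np.ndarray = None


def contrast_t(fit: GlmFit, c, shape=None, voxel_mm=(2.0, 2.0, 2.0)) -> StatMap:
    """t-map for contrast ``c``: t = c'b / sqrt(mse * c'(X'X)^-1 c)."""
    c = np.asarray(c, dtype=float)
    if len(c) != fit.beta.shape[1]:
        raise ValueError("contrast length mismatch")
    num = fit.beta @ c
    var_unit = float(c @ fit._xtx_inv @ c)
    den = np.sqrt(fit.mse * var_unit)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    if shape is not None:
        t = t.reshape(shape)
    return StatMap(t=t, df=fit.df, voxel_mm=tuple(np.broadcast_to(voxel_mm, (3,))))


def second_level(contrast_maps: list, voxel_mm=(2.0, 2.0, 2.0)) -> StatMap:
    """Voxelwise one-sample t across subjects (df = n - 1).

    Voxels with zero between-subject variance and nonzero mean get an
    infinite-t sentinel.
    """
    maps = np.stack([np.asarray(m, dtype=float) for m in contrast_maps])
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.divide(mean, sd / np.sqrt(n), out=np.zeros_like(mean), where=sd > 0)
    t[(sd == 0) & (mean != 0)] = np.inf
    t = np.where((sd == 0) & (mean > 0), np.inf, t)
    t = np.where((sd == 0) & (mean < 0), -np.inf, t)
    return StatMap(t=t, df=n - 1, voxel_mm=tuple(np.broadcast_to(voxel_mm, (3,))))


@dataclass(frozen=True)
class ThresholdSpec:
    """Voxelwise threshold: uncorrected p or Bonferroni over the mask."""

    method: str = "uncorrected_p"
    level: float = 0.001
    cluster_extent: int = 0

    def __post_init__(self):
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must be in (0, 1)")
        if self.cluster_extent < 0:
            raise ValueError("cluster_extent must be >= 0")
        if self.method not in ("uncorrected_p", "bonferroni"):
            raise ValueError(f"unknown threshold method {self.method!r}")


def critical_t(spec: ThresholdSpec, df: int, n_mask_voxels: int) -> float:
    """Upper-tail critical t for one-sided beta > 0 contrasts."""
    level = spec.level
    if spec.method == "bonferroni":
        level = level / max(n_mask_voxels, 1)
    return float(stats.t.ppf(1.0 - level, df))


_CONN6 = ndimage.generate_binary_structure(3, 1)


def threshold_map(stat_map: StatMap, spec: ThresholdSpec, mask=None):
    """Binary supra-threshold map plus a cluster table.

    Voxels pass when t > t_crit; 6-connected clusters smaller than the
    extent cut are removed.  Returns ``(binary, clusters)`` where
    ``clusters`` is a list of dicts (size, peak t, peak voxel index).
    """
    t = np.asarray(stat_map.t)
    if mask is None:
        mask = stat_map.mask if stat_map.mask is not None else np.ones_like(t, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    m = int(mask.sum())
    tc = critical_t(spec, stat_map.df, m)
    binary = (t > tc) & mask
    clusters = []
    if binary.ndim == 3:
        labels, n_lab = ndimage.label(binary, structure=_CONN6)
        keep = np.zeros_like(binary)
        for lab in range(1, n_lab + 1):
            voxels = labels == lab
            size = int(voxels.sum())
            if size < spec.cluster_extent:
                continue
            keep |= voxels
            tv = np.where(voxels, t, -np.inf)
            peak = np.unravel_index(np.argmax(tv), t.shape)
            clusters.append(
                dict(size=size, peak_t=float(t[peak]), peak_index=tuple(int(i) for i in peak))
            )
        binary = keep
        clusters.sort(key=lambda c: -c["size"])
    return binary, clusters
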