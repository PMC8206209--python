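"""Test-retest reliability of activation maps: Dice overlap and ICC(3,1).

Two sessions of the same protocol yield two t-maps per contrast.  Spatial
congruence of their supra-threshold voxels is scored with the
Sorensen-Dice index S = 2 Vo / (V1 + V2); the continuous maps are scored
with the two-measurement consistency intraclass correlation

    ICC(3,1) = (BMS - EMS) / (BMS + EMS)

from a two-way ANOVA with targets (voxels, or subjects for group maps)
random and session fixed.  ICC is insensitive to a constant session
offset (consistency form).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glm import StatMap, ThresholdSpec, threshold_map

logger = logging.getLogger(__name__)


@dataclass
class DiceResult:
    S: float
    V1: int
    V2: int
    Vo: int
    degenerate: bool = False


def dice(
    map1: StatMap,
    map2: StatMap,
    spec: ThresholdSpec = ThresholdSpec(),
    mask=None,
) -> DiceResult:
    """Sorensen-Dice overlap of two thresholded t-maps on the same grid."""
    if np.shape(map1.t) != np.shape(map2.t):
        raise ValueError("grid mismatch")
    b1, _ = threshold_map(map1, spec, mask=mask)
    b2, _ = threshold_map(map2, spec, mask=mask)
    return dice_binary(b1, b2)


def dice_binary(b1, b2) -> DiceResult:
    """Dice index of two binary maps; S = 0 (flagged) when both are empty."""
    b1 = np.asarray(b1, dtype=bool)
    b2 = np.asarray(b2, dtype=bool)
    if b1.shape != b2.shape:
        raise ValueError("grid mismatch")
    v1, v2 = int(b1.sum()), int(b2.sum())
    vo = int((b1 & b2).sum())
    if v1 + v2 == 0:
        logger.warning("dice: both maps empty; S defined as 0")
        return DiceResult(S=0.0, V1=0, V2=0, Vo=0, degenerate=True)
    return DiceResult(S=2.0 * vo / (v1 + v2), V1=v1, V2=v2, Vo=vo)


@dataclass
class IccResult:
    icc: float
    bms: float
    ems: float
    level: str = "participant"
    roi: int | None = None
    n_targets: int = 0


def icc31(values: np.ndarray, level: str = "participant", roi=None) -> IccResult:
    """ICC(3,1) for a targets x k (sessions) matrix, k-session consistency form.

    BMS is the between-target mean square (k * row variance about the
    grand mean on n-1 df); EMS is the residual mean square after removing
    row and column effects on (n-1)(k-1) df.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D targets x sessions matrix")
    keep = np.all(np.isfinite(m), axis=1)
    m = m[keep]
    n, k = m.shape
    if n < 3:
        raise ValueError("need >= 3 targets")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if bms + ems <= 0:
        raise ValueError("zero total variance; ICC undefined")
    return IccResult(
        icc=float((bms - ems) / (bms + ems)),
        bms=float(bms),
        ems=float(ems),
        level=level,
        roi=roi,
        n_targets=n,
    )


@dataclass
class RoiMask:
    """Integer-labeled ROI volume with a label table (0 = background)."""

    labels: np.ndarray
    table: dict  # id -> {"name": str, "hemisphere": str}

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative")

    def ids(self):
        return sorted(int(i) for i in np.unique(self.labels) if i != 0)

    def hemisphere(self, roi_id: int) -> str:
        return self.table.get(int(roi_id), {}).get("hemisphere", "bilateral")


def icc_participant(roi: RoiMask, map1: StatMap, map2: StatMap) -> list:
    """Per-ROI ICC(3,1) with voxels as random targets, sessions fixed.

    ROIs with fewer than 3 voxels are skipped with a warning.
    """
    t1, t2 = np.asarray(map1.t), np.asarray(map2.t)
    if t1.shape != t2.shape or t1.shape != roi.labels.shape:
        raise ValueError("grid mismatch")
    results = []
    for rid in roi.ids():
        vox = roi.labels == rid
        if vox.sum() < 3:
            logger.warning("ROI %d has < 3 voxels; skipped", rid)
            continue
        values = np.column_stack([t1[vox], t2[vox]])
        results.append(icc31(values, level="participant", roi=rid))
    return results


def icc_group_map(session1_maps: list, session2_maps: list, roi: RoiMask | None = None):
    """Voxelwise group ICC(3,1) with subjects as targets, plus ROI medians.

    ``session*_maps`` are per-subject contrast-value volumes.  Returns
    ``(icc_volume, roi_medians)``; ``roi_medians`` maps ROI id to the
    median voxel ICC inside that label (None when no ROI mask given).
    """
    s1 = np.stack([np.asarray(m, dtype=float) for m in session1_maps])
    s2 = np.stack([np.asarray(m, dtype=float) for m in session2_maps])
    if s1.shape != s2.shape:
        raise ValueError("session map stacks differ in shape")
    n = s1.shape[0]
    if n < 3:
        raise ValueError("need >= 3 subjects")
    grand = (s1.sum(axis=0) + s2.sum(axis=0)) / (2 * n)
    row_means = (s1 + s2) / 2.0
    col1 = s1.mean(axis=0)
    col2 = s2.mean(axis=0)
    ss_rows = 2.0 * ((row_means - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col1 - grand) ** 2 + (col2 - grand) ** 2)
    ss_total = ((s1 - grand) ** 2 + (s2 - grand) ** 2).sum(axis=0)
    ss_err = np.maximum(ss_total - ss_rows - ss_cols, 0.0)
    bms = ss_rows / (n - 1)
    ems = ss_err / (n - 1)
    denom = bms + ems
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (bms - ems) / denom, np.nan)
    medians = None
    if roi is not None:
        medians = {
            rid: float(np.nanmedian(icc[roi.labels == rid])) for rid in roi.ids()
        }
    return icc, medians


def paired_ttest(a, b) -> tuple:
    """Classical paired t-test; returns (t, df, two-sided p).

    Zero difference variance with nonzero mean yields an infinite-t
    sentinel (p = 0); identical inputs give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need paired samples with n >= 2")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        logger.warning("paired_ttest: zero difference variance; infinite t")
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)
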