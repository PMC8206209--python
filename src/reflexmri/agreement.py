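"""Agreement and validation statistics for LLR amplitude tables.

Implements the statistics used to validate in-scanner LLR measurements
against out-of-scanner reference sessions: paired Bland-Altman analysis
with t-based confidence intervals, z-tests on bias differences with
Bonferroni adjustment, the Jaccard index of limits-of-agreement intervals
with a parametric bootstrap, per-trial standardized z-scores against a
reference session, and Bartlett tests of equal variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PairedSet:
    """Paired cell means (A_k, B_k) keyed by (participant, muscle, velocity)."""

    keys: pd.DataFrame
    a: np.ndarray
    b: np.ndarray
    direction: str

    @property
    def n(self) -> int:
        return len(self.a)


def pair_sets(means_a: pd.DataFrame, means_b: pd.DataFrame, direction: str) -> PairedSet:
    """Inner-join two cell-mean tables on (participant, muscle, velocity).

    ``means_a``/``means_b`` are outputs of :meth:`LlrTable.means` (one
    session/filter each); rows are restricted to the given stimulus
    direction and unmatched cells are dropped with a logged count.
    """
    key = ["participant", "muscle", "velocity"]
    a = means_a[means_a["direction"] == direction]
    b = means_b[means_b["direction"] == direction]
    merged = a.merge(b, on=key, suffixes=("_a", "_b"))
    dropped = len(a) + len(b) - 2 * len(merged)
    if dropped:
        logger.warning("pair_sets: dropped %d unmatched cells", dropped)
    if merged.empty:
        raise ValueError("no common (participant, muscle, velocity) cells")
    return PairedSet(
        keys=merged[key].copy(),
        a=merged["H_mean_a"].to_numpy(float),
        b=merged["H_mean_b"].to_numpy(float),
        direction=direction,
    )


@dataclass
class BlandAltmanResult:
    """Bias, limits of agreement, and their 95% confidence intervals."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: tuple
    ci_loa_low: tuple
    ci_loa_high: tuple
    n: int

    @property
    def se_bias(self) -> float:
        return self.sd_diff / np.sqrt(self.n)

    @property
    def se_loa(self) -> float:
        return self.sd_diff * np.sqrt(3.0 / self.n)

    @property
    def loa(self) -> tuple:
        return (self.loa_low, self.loa_high)


def bland_altman(pairs: PairedSet | tuple, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Paired Bland-Altman analysis of differences B - A.

    The bias is the mean difference; the 95% limits of agreement are
    bias +/- 1.96 sd.  Confidence intervals use the classical t-based
    forms: bias +/- t * sd/sqrt(n) and LoA +/- t * sd * sqrt(3/n).
    """
    if isinstance(pairs, PairedSet):
        a, b = pairs.a, pairs.b
    else:
        a, b = (np.asarray(v, dtype=float) for v in pairs)
    n = len(a)
    if n < 3 or len(b) != n:
        raise ValueError("need >= 3 pairs of equal length")
    d = b - a
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low = bias - loa_multiplier * sd
    loa_high = bias + loa_multiplier * sd
    t = stats.t.ppf(0.975, n - 1)
    hw_bias = t * sd / np.sqrt(n)
    hw_loa = t * sd * np.sqrt(3.0 / n)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_bias=(bias - hw_bias, bias + hw_bias),
        ci_loa_low=(loa_low - hw_loa, loa_low + hw_loa),
        ci_loa_high=(loa_high - hw_loa, loa_high + hw_loa),
        n=n,
    )


def compare_bias(
    ba1: BlandAltmanResult, ba2: BlandAltmanResult, n_comparisons: int = 1
) -> tuple:
    """Two-sided z-test on the difference of two independent biases.

    Returns ``(z, p_adjusted)`` with the p-value multiplied by
    ``n_comparisons`` (Bonferroni) and capped at 1.
    """
    se = np.sqrt(ba1.se_bias**2 + ba2.se_bias**2)
    delta = ba1.bias - ba2.bias
    if se == 0:
        if delta == 0:
            return 0.0, 1.0
        logger.warning("compare_bias: zero combined SE with unequal biases")
        return np.inf * np.sign(delta), 0.0
    z = delta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p * n_comparisons, 1.0))


def jaccard(interval1: tuple, interval2: tuple) -> float:
    """Jaccard index of two intervals: |intersection| / |union|.

    For disjoint intervals the intersection is 0 and the union is the sum
    of lengths.  Two degenerate (zero-length) intervals score 1 if
    identical, else 0.
    """
    lo1, hi1 = sorted(interval1)
    lo2, hi2 = sorted(interval2)
    len1, len2 = hi1 - lo1, hi2 - lo2
    if len1 == 0 and len2 == 0:
        return 1.0 if (lo1, hi1) == (lo2, hi2) else 0.0
    inter = max(0.0, min(hi1, hi2) - max(lo1, lo2))
    union = len1 + len2 - inter
    return float(inter / union)


@dataclass
class JaccardResult:
    mean: float
    sem: float
    ci95: tuple
    n_boot: int
    seed: int
    samples: np.ndarray = None


def jaccard_bootstrap(
    ba_test: BlandAltmanResult,
    ba_ref: BlandAltmanResult,
    n_boot: int = 10000,
    seed: int = 0,
) -> JaccardResult:
    """Parametric bootstrap of the LoA Jaccard index.

    Each replicate draws every LoA endpoint of both comparisons from a
    normal distribution centered on its estimate with the Bland-Altman
    standard error (endpoints sampled independently), then recomputes the
    index; reported are the mean, SEM, and percentile 95% CI.
    """
    if n_boot < 100:
        logger.warning("jaccard_bootstrap: n_boot=%d is small", n_boot)
    rng = np.random.default_rng(seed)
    lo_t = rng.normal(ba_test.loa_low, ba_test.se_loa, n_boot)
    hi_t = rng.normal(ba_test.loa_high, ba_test.se_loa, n_boot)
    lo_r = rng.normal(ba_ref.loa_low, ba_ref.se_loa, n_boot)
    hi_r = rng.normal(ba_ref.loa_high, ba_ref.se_loa, n_boot)
    js = np.array(
        [jaccard((lo_t[i], hi_t[i]), (lo_r[i], hi_r[i])) for i in range(n_boot)]
    )
    return JaccardResult(
        mean=float(js.mean()),
        sem=float(js.std(ddof=1) / np.sqrt(n_boot)) if n_boot > 1 else 0.0,
        ci95=(float(np.percentile(js, 2.5)), float(np.percentile(js, 97.5))),
        n_boot=n_boot,
        seed=seed,
        samples=js,
    )


@dataclass
class ZScoreSummary:
    """Per-trial z-scores and their per-(velocity, direction) spread."""

    table: pd.DataFrame  # trial rows with z
    sigma: pd.DataFrame  # columns velocity, direction, sigma
    n_flagged: int = 0


def zscores(test: pd.DataFrame, reference: pd.DataFrame, ddof: int = 1) -> ZScoreSummary:
    """Standardize per-trial H values against a reference session.

    ``test`` and ``reference`` are tidy H tables (rows of
    :class:`~reflexmri.emg.LlrTable`).  Each test trial is standardized by
    the mean and SD of its matched (participant, muscle, velocity)
    reference cell; the per-(velocity, direction) standard deviation of
    the scores is then summarized.  Cells with zero reference SD are
    flagged and excluded from the sigma summary.
    """
    key = ["participant", "muscle", "velocity"]
    ref_stats = (
        reference.groupby(key)["H"]
        .agg(mu="mean", sigma=lambda v: np.std(v, ddof=ddof), n="count")
        .reset_index()
    )
    if (ref_stats["n"] < 2).any():
        raise ValueError("reference cells need >= 2 values")
    merged = test.merge(ref_stats, on=key, how="inner")
    flagged = merged["sigma"] <= 0
    if flagged.any():
        logger.warning("zscores: %d trials with zero reference SD flagged", flagged.sum())
    merged["z"] = np.where(
        flagged, np.nan, (merged["H"] - merged["mu"]) / merged["sigma"]
    )
    from .protocol import ECU, FCR

    merged["direction"] = np.where(
        ((merged["muscle"] == FCR) & (merged["velocity"] > 0))
        | ((merged["muscle"] == ECU) & (merged["velocity"] < 0)),
        "stretch",
        "shortening",
    )
    merged["speed"] = merged["velocity"].abs()
    sigma = (
        merged.dropna(subset=["z"])
        .groupby(["speed", "direction"])["z"]
        .agg(sigma=lambda v: np.std(v, ddof=ddof), n="count")
        .reset_index()
    )
    return ZScoreSummary(table=merged, sigma=sigma, n_flagged=int(flagged.sum()))


@dataclass
class BartlettResult:
    statistic: float
    df: int
    p: float


def bartlett(*groups) -> BartlettResult:
    """Classical Bartlett test of equal variances across k groups."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        g = np.asarray(g, dtype=float)
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
        if np.var(g, ddof=1) == 0:
            raise ValueError("zero-variance group")
    stat, p = stats.bartlett(*groups)
    return BartlettResult(statistic=float(stat), df=len(groups) - 1, p=float(p))
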