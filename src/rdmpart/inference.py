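"""Group-level inference on explained-variance time courses.

For each measure (total or unique variance of a model, or a difference
between two models) the per-participant trajectory is first corrected by
subtracting its mean over the prestimulus baseline window ([-200, 0) ms).
At every time point a Wilcoxon signed-rank test across participants is
performed (one-sided against zero for model evaluation, two-sided for
model comparison).  P-values are corrected by controlling the expected
false discovery rate at 0.05 across time points within each
(measure, ROI) family, and a continuity criterion removes significant
runs shorter than 10 consecutive samples (20 ms at the 2 ms sampling
rate).  The onset latency of an effect is the first time point of the
first surviving run.  A zero-phase Butterworth low-pass (80 Hz, order 6)
is provided for display only and never feeds inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .second_level import TimeCourse

__all__ = [
    "InferenceResult",
    "baseline_subtract",
    "signed_rank_test",
    "fdr_bh",
    "continuity_filter",
    "extract_onset",
    "significant_windows",
    "display_lowpass",
    "run_inference",
]

#: Largest sample size for which the exact signed-rank null is enumerated.
EXACT_N_MAX = 25


@dataclass
class InferenceResult:
    """Group-level significance structure for one measure and ROI."""

    times_ms: np.ndarray
    p_values: np.ndarray
    sig_fdr: np.ndarray
    sig_continuous: np.ndarray
    onset_ms: float | None
    alpha: float = 0.05
    min_run: int = 10
    measure: str = ""
    roi_id: str = ""

    @property
    def windows_ms(self) -> list[tuple[float, float]]:
        return significant_windows(self.times_ms, self.sig_continuous)


def baseline_subtract(
    tc: TimeCourse, window: tuple[float, float] = (-200.0, 0.0)
) -> TimeCourse:
    """Subtract each participant's mean over the baseline window.

    The window is closed-open: times with ``window[0] <= t < window[1]``.
    """
    lo, hi = window
    mask = (tc.times_ms >= lo) & (tc.times_ms < hi)
    if not mask.any():
        raise ValueError(
            f"baseline window [{lo}, {hi}) contains no sample of the time axis"
        )
    base = tc.values[:, mask].mean(axis=1, keepdims=True)
    return TimeCourse(
        times_ms=tc.times_ms,
        values=tc.values - base,
        measure=tc.measure,
        model=tc.model,
        roi_id=tc.roi_id,
    )


@lru_cache(maxsize=4096)
def _signed_rank_sf(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Survival function of the signed-rank sum under the null.

    Enumerates, by dynamic programming over the doubled (integer) ranks,
    the distribution of the sum of a uniformly random subset — each of the
    2**n sign assignments is equally likely under the null.  Average ranks
    from ties are half-integers, hence the doubling.  Entry ``k`` of the
    returned array is ``P(2*W >= k)``.
    """
    total = sum(doubled_ranks)
    dp = np.zeros(total + 1)
    dp[0] = 1.0
    for r in doubled_ranks:
        dp[r:] = dp[r:] + dp[:-r]
    dp /= 2.0 ** len(doubled_ranks)
    return np.cumsum(dp[::-1])[::-1]


def signed_rank_test(values: Sequence[float], alternative: str = "greater") -> float:
    """Wilcoxon signed-rank test of the median against zero.

    Zeros are discarded before ranking (classic signed-rank convention);
    ties receive average ranks.  For up to 25 non-zero values the p-value
    comes from exact enumeration of the sign-permutation null, which
    remains valid under ties; larger samples use the normal approximation
    with tie correction and continuity correction.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    v = v[v != 0]
    n = v.size
    if n == 0:
        raise ValueError("signed-rank test undefined: all values are zero")
    if n < 5:
        raise ValueError(f"need at least 5 non-zero values, got {n}")
    if alternative not in ("greater", "less", "two_sided", "two-sided"):
        raise ValueError(f"unknown alternative '{alternative}'")
    ranks = rankdata(np.abs(v))
    w_plus = float(ranks[v > 0].sum())
    if n <= EXACT_N_MAX:
        doubled = tuple(sorted(int(round(2 * r)) for r in ranks))
        sf = _signed_rank_sf(doubled)
        total = sum(doubled)
        w2 = int(round(2 * w_plus))
        p_ge = float(sf[w2]) if w2 <= total else 0.0
        # P(W <= w) via symmetry of the subset-sum distribution about total/2
        p_le = float(sf[total - w2]) if total - w2 <= total else 0.0
    else:
        t_sum = ranks.sum()
        mu = t_sum / 2.0
        # variance of the subset sum: sum r_i^2 / 4 (tie correction implicit
        # in the use of the actual average ranks)
        sigma = np.sqrt(np.sum(ranks**2) / 4.0)
        p_ge = float(norm.sf((w_plus - 0.5 - mu) / sigma))
        p_le = float(norm.cdf((w_plus + 0.5 - mu) / sigma))
    if alternative == "greater":
        return min(1.0, p_ge)
    if alternative == "less":
        return min(1.0, p_le)
    return min(1.0, 2.0 * min(p_ge, p_le))


def fdr_bh(p_values: Sequence[float], q: float = 0.05, variant: str = "bh") -> np.ndarray:
    """Benjamini–Hochberg step-up FDR control over one family of tests.

    ``variant='by'`` applies the Benjamini–Yekutieli correction for
    arbitrary dependence instead.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    method = {"bh": "fdr_bh", "by": "fdr_by"}[variant]
    reject, *_ = multipletests(p, alpha=q, method=method)
    return reject


def continuity_filter(mask: Sequence[bool], min_run: int = 10) -> np.ndarray:
    """Zero out significant runs shorter than ``min_run`` consecutive samples.

    With 2 ms sampling the default of 10 samples corresponds to requiring
    20 ms of sustained significance.  Idempotent; never adds True values.
    """
    m = np.asarray(mask, dtype=bool).copy()
    if m.ndim != 1:
        raise ValueError("mask must be 1-D")
    out = m.copy()
    k = 0
    while k < m.size:
        if m[k]:
            j = k
            while j < m.size and m[j]:
                j += 1
            if j - k < min_run:
                out[k:j] = False
            k = j
        else:
            k += 1
    return out


def extract_onset(times_ms: np.ndarray, mask: Sequence[bool]) -> float | None:
    """First time of the first surviving significant run, or None."""
    m = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(m)
    return float(np.asarray(times_ms)[idx[0]]) if idx.size else None


def significant_windows(
    times_ms: np.ndarray, mask: Sequence[bool]
) -> list[tuple[float, float]]:
    """Contiguous significant runs as (start_ms, end_ms) intervals."""
    m = np.asarray(mask, dtype=bool)
    t = np.asarray(times_ms, dtype=float)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], m.astype(int), [0]])))
    return [
        (float(t[edges[k]]), float(t[edges[k + 1] - 1]))
        for k in range(0, edges.size, 2)
    ]


def display_lowpass(
    tc: TimeCourse, cutoff_hz: float = 80.0, order: int = 6
) -> TimeCourse:
    """Zero-phase Butterworth low-pass for plotting only.

    Applies the filter forward and backward (no phase shift).  Statistical
    inference must always run on the unsmoothed time courses.
    """
    dt_s = (tc.times_ms[1] - tc.times_ms[0]) / 1000.0
    fs = 1.0 / dt_s
    if cutoff_hz >= fs / 2.0:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is not below the Nyquist frequency {fs / 2} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    smoothed = signal.sosfiltfilt(sos, tc.values, axis=1)
    return TimeCourse(
        times_ms=tc.times_ms,
        values=smoothed,
        measure=tc.measure,
        model=tc.model,
        roi_id=tc.roi_id,
    )


def run_inference(
    tc: TimeCourse,
    alternative: str = "greater",
    alpha: float = 0.05,
    min_run: int = 10,
    baseline_window: tuple[float, float] | None = (-200.0, 0.0),
    fdr_variant: str = "bh",
) -> InferenceResult:
    """Full group inference for one time course (one FDR family).

    Baseline-subtracts (unless ``baseline_window`` is None), tests each
    time point across participants with the signed-rank test, controls the
    FDR across time points, applies the continuity criterion, and extracts
    the onset from the post-continuity mask.
    """
    if baseline_window is not None:
        tc = baseline_subtract(tc, baseline_window)
    p = np.ones(tc.times_ms.size)
    for t in range(tc.times_ms.size):
        col = tc.values[:, t]
        if np.count_nonzero(col) < 5:
            p[t] = 1.0  # no evidence either way at this time point
        else:
            p[t] = signed_rank_test(col, alternative=alternative)
    sig = fdr_bh(p, q=alpha, variant=fdr_variant)
    sig_cont = continuity_filter(sig, min_run=min_run)
    return InferenceResult(
        times_ms=tc.times_ms,
        p_values=p,
        sig_fdr=sig,
        sig_continuous=sig_cont,
        onset_ms=extract_onset(tc.times_ms, sig_cont),
        alpha=alpha,
        min_run=min_run,
        measure=f"{tc.measure}:{tc.model}" if tc.model else tc.measure,
        roi_id=tc.roi_id,
    )
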