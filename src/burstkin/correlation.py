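"""Connected auto/cross-correlation: empirical estimator, probe-aware theory,
and the finite-trace correction.

Short interphases make the empirical connected autocorrelation of a trace
biased: subtracting the per-trace empirical mean correlates the mean with
every sample, the area under the curve is forced to zero, and a spurious
negative valley appears at intermediate lags.  Comparing data against theory
therefore uses the *corrected* model curve: the exact expectation of the
empirical estimator's numerator under the model, computed from the
infinite-trace autocovariance.

Theory curves convolve the promoter autocovariance ``g`` with the probe
geometry: for loop functions ``L^A``, ``L^B`` on the same gene grid,

    C(tau) = sum_{i,j} L^A_i L^B_j g(tau + (i - j) * step_time),

with ``tau`` in seconds; the autocorrelation is the A == B case.  Curves are
normalized at the *second* time point (lag = 1 sampling interval): lag 0
carries temporally uncorrelated noise (shot noise, free fluorophore
fluctuations) and is never used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .construct import LoopFunction
from .models import PromoterModel, promoter_autocovariance
from .traces import TraceSet

__all__ = [
    "CorrelationCurve",
    "empirical_connected_autocorrelation",
    "theoretical_autocorrelation",
    "theoretical_cross_correlation",
    "fluorescence_autocovariance",
    "finite_trace_correction",
    "corrected_model_curve",
]

NORMALIZE_LAG = 1  # "the second time point"


@dataclass(frozen=True)
class CorrelationCurve:
    """Correlation values per lag with sampling metadata.

    ``lags`` are in sampling intervals (may be negative for cross-
    correlations), ``lag_s`` in seconds.  ``pair_counts`` holds the number of
    sample pairs that entered each lag (M * (K - |r|)); ``se`` the
    across-trace standard error (empirical curves only).  ``normalization``
    tags the convention: 'covariance' (unnormalized theory) or
    'second-point' (value 1 at lag 1).
    """

    lags: np.ndarray
    lag_s: np.ndarray
    values: np.ndarray
    pair_counts: np.ndarray | None = None
    se: np.ndarray | None = None
    normalization: str = "second-point"
    trace_values: np.ndarray | None = None  # per-trace curves (resampling)

    def __post_init__(self) -> None:
        for name in ("lags", "lag_s", "values"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))

    def to_frame(self):
        import pandas as pd

        cols = {"lag": self.lags, "lag_s": self.lag_s, "value": self.values}
        if self.pair_counts is not None:
            cols["pair_count"] = self.pair_counts
        if self.se is not None:
            cols["se"] = self.se
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# empirical estimator
# ---------------------------------------------------------------------------

def empirical_connected_autocorrelation(
    traces: TraceSet | np.ndarray,
    max_lag: int | None = None,
    normalize_lag: int = NORMALIZE_LAG,
    variance: str = "pooled",
) -> CorrelationCurve:
    """Connected autocorrelation of a set of equal-length traces.

    Per trace, the empirical mean is subtracted and the lag-r covariance sum
    accumulated with the (K - r)/K pair normalization.  The variance
    denominator is ``'pooled'`` by default: the trace curves share the
    ensemble variance, which is the convention under which the finite-trace
    correction (the expectation of the numerator over realizations, divided
    by a constant variance) is the exact counterpart of this estimator.
    ``variance='per-trace'`` divides each trace by its own empirical
    variance instead, which suppresses nucleus-to-nucleus intensity
    differences but — because a short trace's empirical variance is noisy
    and correlated with its covariance — is biased at intermediate lags;
    prefer calibrating intensities (inference Step 1) and the pooled form.

    The averaged curve is rescaled to 1 at ``normalize_lag`` (per-trace
    curves are stored on the same scale, enabling subset resampling and
    across-trace standard errors).  Constant traces carry no correlation
    information and are excluded with a warning.
    """
    if isinstance(traces, TraceSet):
        ts = traces.steady_state() if traces.steady_window is not None else traces
        v = ts.values
        dt = ts.dt_s
    else:
        v = np.asarray(traces, dtype=float)
        dt = 1.0
    if v.ndim != 2 or v.shape[1] < 2:
        raise ValueError("need a (n_traces, K>=2) matrix of trace values")
    M, K = v.shape
    max_lag = K - 1 if max_lag is None else min(int(max_lag), K - 1)
    if max_lag < normalize_lag:
        raise ValueError("max_lag must reach the normalization lag")
    if variance not in ("pooled", "per-trace"):
        raise ValueError("variance must be 'pooled' or 'per-trace'")

    d = v - v.mean(axis=1, keepdims=True)
    ss = (d**2).sum(axis=1)
    keep = ss > 1e-12 * max(ss.max(), 1e-300)
    if not keep.any():
        raise ValueError("all traces are constant; no correlation to estimate")
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} constant trace(s)")
        d, ss = d[keep], ss[keep]
    Mk = d.shape[0]

    denom = ss if variance == "per-trace" else np.full(Mk, ss.mean())
    lags = np.arange(max_lag + 1)
    curves = np.empty((Mk, max_lag + 1))
    for r in lags:
        num = (d[:, : K - r] * d[:, r:]).sum(axis=1)
        curves[:, r] = num / (denom * (K - r) / K)
    mean_curve = curves.mean(axis=0)
    scale = mean_curve[normalize_lag]
    if scale == 0:
        raise ValueError("zero correlation at the normalization lag")
    curves /= scale
    values = mean_curve / scale
    se = curves.std(axis=0, ddof=1) / np.sqrt(Mk) if Mk > 1 else np.full_like(values, np.nan)
    return CorrelationCurve(
        lags=lags,
        lag_s=lags * dt,
        values=values,
        pair_counts=Mk * (K - lags),
        se=se,
        normalization="second-point",
        trace_values=curves,
    )


# ---------------------------------------------------------------------------
# theory
# ---------------------------------------------------------------------------

def _pair_kernel(
    loop_a: np.ndarray, loop_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weights w_d = sum_i L^A_i L^B_{i-d} over the site offset d = i - j."""
    ra, rb = loop_a.size, loop_b.size
    d = np.arange(-(rb - 1), ra)
    w = np.empty(d.size)
    for idx, dd in enumerate(d):
        i0, i1 = max(0, dd), min(ra, rb + dd)
        w[idx] = loop_a[i0:i1] @ loop_b[i0 - dd : i1 - dd] if i1 > i0 else 0.0
    return d, w


def fluorescence_autocovariance(
    model: PromoterModel,
    loop_fn: LoopFunction,
    lags_s: np.ndarray,
    loop_fn_b: LoopFunction | None = None,
    g: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Infinite-trace autocovariance of the signal at lags in seconds.

    ``loop_fn_b`` switches to the two-color cross-covariance
    Cov(F_A(t), F_B(t + tau)).  A precomputed promoter autocovariance ``g``
    may be supplied (useful inside fit loops, and mandatory plumbing for the
    gamma model's tabulated curve).
    """
    lags_s = np.atleast_1d(np.asarray(lags_s, dtype=float))
    lb = loop_fn if loop_fn_b is None else loop_fn_b
    if lb.step_time_s != loop_fn.step_time_s:
        raise ValueError("both loop functions must share the polymerase step time")
    if g is None:
        span = np.abs(lags_s).max() + (max(len(loop_fn), len(lb)) + 1) * loop_fn.step_time_s
        g = promoter_autocovariance(model, t_max=span * 1.05)
    d, w = _pair_kernel(loop_fn.values, lb.values)
    args = np.abs(lags_s[:, None] + d[None, :] * loop_fn.step_time_s)
    return np.asarray(g(args.ravel())).reshape(args.shape) @ w


def theoretical_autocorrelation(
    model: PromoterModel,
    loop_fn: LoopFunction,
    lags_s: np.ndarray,
    normalize: bool = True,
) -> CorrelationCurve:
    """Infinite-trace connected autocorrelation of the fluorescence signal."""
    lags_s = np.atleast_1d(np.asarray(lags_s, dtype=float))
    values = fluorescence_autocovariance(model, loop_fn, lags_s)
    tag = "covariance"
    if normalize:
        ref = fluorescence_autocovariance(model, loop_fn, np.array([lags_s[NORMALIZE_LAG] if lags_s.size > NORMALIZE_LAG else lags_s[0]]))
        values = values / ref[0]
        tag = "second-point"
    steps = lags_s / loop_fn.step_time_s
    return CorrelationCurve(lags=steps, lag_s=lags_s, values=values, normalization=tag)


def theoretical_cross_correlation(
    model: PromoterModel,
    loop_fn_a: LoopFunction,
    loop_fn_b: LoopFunction,
    lags_s: np.ndarray,
) -> CorrelationCurve:
    """Two-color cross-covariance curve; asymmetric in the lag sign.

    Positive lags correlate channel A at t with channel B at t + tau;
    swapping the channels mirrors the lag axis, and identical loop
    functions recover the autocorrelation.
    """
    lags_s = np.atleast_1d(np.asarray(lags_s, dtype=float))
    values = fluorescence_autocovariance(model, loop_fn_a, lags_s, loop_fn_b=loop_fn_b)
    steps = lags_s / loop_fn_a.step_time_s
    return CorrelationCurve(
        lags=steps, lag_s=lags_s, values=values, normalization="covariance"
    )


# ---------------------------------------------------------------------------
# finite-trace correction
# ---------------------------------------------------------------------------

def finite_trace_correction(
    ctilde: np.ndarray,
    n_samples: int | None = None,
    normalize_lag: int = NORMALIZE_LAG,
) -> np.ndarray:
    """Finite-trace expectation of the empirical connected autocorrelation.

    ``ctilde`` holds the infinite-trace autocovariance of the sampled signal
    at lags 0..K-1 sampling intervals (connected or not: an additive
    constant cancels identically).  For a trace of K samples the empirical
    estimator subtracts the *empirical* mean m, so its lag-r numerator has
    expectation

        E[sum_i (v_i - m)(v_{i+r} - m)]
          = (K-r) [ C_r + Var(m) ] - sum_i ( Cov(v_i, m) + Cov(v_{i+r}, m) )

    with Var(m) and Cov(v_i, m) assembled from ``ctilde``.  The mean-bias
    terms force the corrected curve's area toward zero, reproducing the
    negative valley of short traces; as K -> infinity the corrected curve
    converges to ctilde normalized.  The result is normalized to 1 at
    ``normalize_lag`` (the constant variance denominator of the estimator
    drops out under this normalization).
    """
    C = np.asarray(ctilde, dtype=float)
    K = C.size if n_samples is None else int(n_samples)
    if K < 3:
        raise ValueError("finite-trace correction needs at least K = 3 samples")
    if C.size < K:
        raise ValueError("need the autocovariance at every lag 0..K-1")
    C = C[:K]
    idx = np.arange(K)
    toe = C[np.abs(idx[:, None] - idx[None, :])]
    cov_im = toe.mean(axis=1)  # Cov(v_i, m)
    var_m = toe.mean()  # Var(m)
    cum = np.concatenate([[0.0], np.cumsum(cov_im)])
    corrected = np.empty(K)
    for r in range(K):
        n = K - r
        s = (cum[n] - cum[0]) + (cum[K] - cum[r])  # sum cov_im[i] + cov_im[i+r]
        corrected[r] = C[r] + var_m - s / n
    scale = corrected[normalize_lag]
    if scale == 0:
        raise ValueError("corrected curve vanishes at the normalization lag")
    return corrected / scale


def corrected_model_curve(
    model: PromoterModel,
    loop_fn: LoopFunction,
    dt_s: float,
    n_samples: int,
    g: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Finite-trace-corrected model autocorrelation on the sampling grid.

    Convenience composition used by the inference: evaluates the probe-aware
    autocovariance at lags 0..K-1 times dt and applies the finite-trace
    correction for traces of K samples.
    """
    lags_s = np.arange(n_samples) * dt_s
    ct = fluorescence_autocovariance(model, loop_fn, lags_s, g=g)
    return finite_trace_correction(ct, n_samples)
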