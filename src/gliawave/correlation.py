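"""Normalised lagged cross-correlation and primary-peak lag extraction.

The central statistic is

    C_tau = (1/N) * sum_i (x_i - <x>) (y_{i+tau} - <y>) / (sigma_x sigma_y)

where <.> and sigma are the full-series mean and population standard
deviation, N is the total number of samples, and the sum at lag tau runs
over the overlapping index range.  Dividing by the full N (rather than the
overlap count) guarantees |C_tau| <= 1 for every input by Cauchy-Schwarz,
at the cost of a mild triangular taper toward extreme lags — the standard
estimator trade-off.  The overlap count at each lag is reported alongside.

With this convention a **positive** peak lag means the first series ``x``
leads the second series ``y`` (equivalently: ``y`` is a delayed copy of
``x``).  In the wave/speed analysis the wave-intensity series is therefore
passed as ``x`` and the cell-speed series as ``y``, so the reported
positive lag is the time by which wave passage precedes the movement pulse.
"""
from __future__ import annotations

import itertools
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .datatypes import CorrelationResult, EdgeTrace
from .errors import DegenerateSeriesError, ParameterError

__all__ = ["cross_correlation", "primary_peak", "edge_coherence", "detrend"]

log = logging.getLogger(__name__)


def cross_correlation(
    x: np.ndarray,
    y: np.ndarray,
    dt: float = 1.0,
    max_lag: float | None = None,
) -> CorrelationResult:
    """Normalised cross-correlation of two equally sampled series.

    ``max_lag`` is in the time units of ``dt`` (the lag grid is symmetric,
    integer multiples of ``dt``); it defaults to half the series span.
    Means and standard deviations are those of the full series (population,
    1/N); at each lag the sum runs over the overlapping index range and is
    divided by the total sample count N, so |C_tau| <= 1 always holds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 10:
        raise ParameterError("need at least 10 samples")
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    sx, sy = float(np.std(x)), float(np.std(y))
    if sx == 0 or sy == 0:
        raise DegenerateSeriesError("zero-variance input series")
    if max_lag is None:
        m = (n - 1) // 2
    else:
        m = int(round(max_lag / dt))
        if m >= n:
            raise ParameterError("max_lag must be smaller than the series span")
    xc = x - x.mean()
    yc = y - y.mean()
    lags = np.arange(-m, m + 1)
    values = np.empty(lags.shape)
    counts = np.empty(lags.shape, dtype=int)
    for i, tau in enumerate(lags):
        if tau >= 0:
            a, b = xc[: n - tau], yc[tau:]
        else:
            a, b = xc[-tau:], yc[: n + tau]
        counts[i] = len(a)
        values[i] = float(a @ b) / (n * sx * sy)
    return CorrelationResult(lags=lags * dt, values=values, n_samples=counts)


def primary_peak(
    result: CorrelationResult,
    search: tuple | None = None,
    floor: float | None = None,
    mode: str = "first",
    refine: str = "none",
) -> tuple:
    """Primary peak of a correlation function.

    With ``mode="first"`` (default): the first local maximum of C_tau at
    tau >= 0 (or within the ``search`` lag window) whose value exceeds the
    significance floor — by default twice the white-noise null sd at that
    lag (2 sqrt(N_overlap) / N, i.e. ~2/sqrt(N) near zero lag), roughly the
    95% band.  With ``mode="global"``: the largest qualifying
    peak in the window.  The global maximum over all lags is recorded on
    the result for comparison.  Returns (tau_star, value) or (None, None)
    when no peak clears the floor (a valid no-peak outcome, not an error).

    ``refine="parabolic"`` fits a parabola through the peak sample and its
    two neighbours and reports the vertex lag/value — a sub-sample estimate
    for peaks that fall between grid lags; off by default.
    """
    if mode not in ("first", "global"):
        raise ParameterError("mode must be 'first' or 'global'")
    vals = result.values
    lags = result.lags
    # a candidate peak must also stand out from its surroundings by half the
    # significance floor, so noise wiggles on a broad flank do not qualify
    n_mid = int(result.n_samples.max())
    prom = (1.0 / math.sqrt(n_mid)) if floor is None else 0.5 * floor
    peaks, _ = signal.find_peaks(vals, prominence=prom)
    gi = int(np.argmax(vals))
    result.global_peak_lag = float(lags[gi])
    result.global_peak_value = float(vals[gi])
    lo, hi = (0.0, np.inf) if search is None else search
    cand = []
    for p in peaks:
        if not (lo <= lags[p] <= hi):
            continue
        f = (2.0 * math.sqrt(result.n_samples[p]) / n_mid
             if floor is None else floor)
        if vals[p] > f:
            cand.append(p)
    if not cand:
        result.primary_peak_lag = None
        result.primary_peak_value = None
        return None, None
    if mode == "first":
        p = cand[0]
    else:
        # periodic inputs give repeating peaks of near-equal height; among
        # peaks statistically indistinguishable from the best (within the
        # white-noise band) prefer the smallest |lag|
        vmax = max(vals[i] for i in cand)
        margin = 2.0 / math.sqrt(n_mid)
        near = [i for i in cand if vals[i] >= vmax - margin]
        p = min(near, key=lambda i: abs(lags[i]))
    tau_star, c_star = float(lags[p]), float(vals[p])
    if refine == "parabolic" and 0 < p < len(vals) - 1:
        y0, y1, y2 = vals[p - 1], vals[p], vals[p + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # proper maximum
            delta = 0.5 * (y0 - y2) / denom
            dlag = float(lags[1] - lags[0])
            tau_star = float(lags[p] + delta * dlag)
            c_star = float(y1 - 0.25 * (y0 - y2) * delta)
    elif refine not in ("none", "parabolic"):
        raise ParameterError("refine must be 'none' or 'parabolic'")
    result.primary_peak_lag = tau_star
    result.primary_peak_value = c_star
    return tau_star, c_star


def edge_coherence(
    traces: Sequence[EdgeTrace],
    max_lag: float,
) -> pd.DataFrame:
    """Pairwise primary-peak lags between leading-edge traces.

    Every unordered pair of traces is cross-correlated on a symmetric lag
    window of ±``max_lag`` and the largest significant peak is taken (the
    relevant lag may be of either sign).  A pair is *phase-coherent* when
    |tau*| is at most one sample interval.  Traces must share a common time
    base.
    """
    if len(traces) < 2:
        raise ParameterError("need at least two traces")
    t0 = traces[0].times
    for tr in traces[1:]:
        if len(tr.times) != len(t0) or not np.allclose(tr.times, t0):
            raise ParameterError("traces must share a common time base")
    dt = float(t0[1] - t0[0])
    rows = []
    for i, j in itertools.combinations(range(len(traces)), 2):
        res = cross_correlation(traces[i].edge_position, traces[j].edge_position,
                                dt=dt, max_lag=max_lag)
        tau, val = primary_peak(res, search=(-max_lag, max_lag), mode="global")
        rows.append({
            "i": i, "j": j, "lag": tau, "value": val,
            "coherent": (tau is not None and abs(tau) <= dt + 1e-12),
        })
    return pd.DataFrame(rows)


def detrend(series: np.ndarray, mode: str = "none", param=None) -> np.ndarray:
    """Remove a trend before correlation.

    ``mode="linear"`` subtracts the least-squares line; ``"boxcar_subtract"``
    subtracts a centred moving average of ``param`` points (isolating
    fluctuations faster than the window); ``"none"`` is the identity.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 3:
        raise ParameterError("series too short to detrend")
    if mode == "none":
        return series.copy()
    if mode == "linear":
        t = np.arange(len(series), dtype=float)
        coef = np.polyfit(t, series, 1)
        return series - np.polyval(coef, t)
    if mode == "boxcar_subtract":
        from .wavekinetics import boxcar_filter
        npoints = int(param) if param else max(3, len(series) // 10)
        return series - boxcar_filter(series, npoints)
    raise ParameterError(f"unknown detrend mode {mode!r}")
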