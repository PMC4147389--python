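"""Multiple-time graphical (Patlak) analysis of unidirectional tracer influx.

For a tracer that moves unidirectionally from plasma into tissue, the
tissue/serum ratio is linear in *exposure time*,

    A(t) / Cp(t) = Ki * Theta(t) + Vi,      Theta(t) = Int_0^t Cp(T) dT / Cp(t),

where ``Cp`` is the arterial serum concentration (cpm/ul), ``A`` the tracer
amount per gram of extravascular tissue (cpm/g), ``Ki`` the unidirectional
influx rate (ul/g/min) and ``Vi`` the rapidly equilibrating (functional)
distribution volume (ul/g).  Plotting the ratio against exposure time and
fitting a line over the early, linear phase yields ``Ki`` as the slope and
``Vi`` as the intercept.

This module provides the exposure-time transform, the multiple-time
regression estimator, automatic linear-phase (window) selection, and a
Welch-style comparison of two fitted influx rates (e.g. a labelled-only arm
against a cold-competitor arm, the classic test for saturable transport).

Units package-wide: time in minutes, serum in cpm/ul, tissue in cpm/g,
ratios and Vi in ul/g, Ki in ul/g/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TimeActivitySeries",
    "PatlakFit",
    "LinearPhase",
    "SlopeComparison",
    "InsufficientDataError",
    "DegenerateDesignError",
    "exposure_time",
    "serum_integral",
    "patlak_transform",
    "patlak_fit",
    "fit_series",
    "detect_linear_phase",
    "compare_ki",
]

DEFAULT_MAX_EXPOSURE_MIN = 20.0  # uptake is near-linear for ~20 min of exposure
DEFAULT_R2_THRESHOLD = 0.95


class InsufficientDataError(ValueError):
    """Fewer usable data points than the operation requires."""


class DegenerateDesignError(ValueError):
    """Design matrix is singular (e.g. all exposure times identical)."""


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class TimeActivitySeries:
    """Sampled arterial serum concentration and tissue uptake over time.

    Parameters
    ----------
    times:
        Minutes post-injection, strictly increasing, all >= 0.
    serum_conc:
        Serum tracer concentration at each time (cpm/ul), strictly positive.
    tissue_per_mass:
        Tracer amount in extravascular tissue per unit mass (cpm/g).
        Optional when only tissue/serum ratios are known.
    ratio:
        Tissue/serum ratio (ul/g).  Derived from ``tissue_per_mass`` when not
        given; if both are supplied they must agree elementwise.
    """

    times: np.ndarray
    serum_conc: np.ndarray
    tissue_per_mass: np.ndarray | None = None
    ratio: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        times = _as_array(self.times, "times")
        serum = _as_array(self.serum_conc, "serum_conc")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "serum_conc", serum)
        if times.size < 2:
            raise InsufficientDataError("need at least 2 sampled times")
        if times.size != serum.size:
            raise ValueError("times and serum_conc must have equal length")
        if np.any(times < 0):
            raise ValueError("times must be >= 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing (no duplicates)")
        if np.any(serum <= 0):
            raise ValueError("serum_conc must be strictly positive at every time")
        tissue = self.tissue_per_mass
        if tissue is not None:
            tissue = _as_array(tissue, "tissue_per_mass")
            if tissue.size != times.size:
                raise ValueError("tissue_per_mass length mismatch")
            object.__setattr__(self, "tissue_per_mass", tissue)
        ratio = self.ratio
        if ratio is not None:
            ratio = _as_array(ratio, "ratio")
            if ratio.size != times.size:
                raise ValueError("ratio length mismatch")
            object.__setattr__(self, "ratio", ratio)
            if tissue is not None and not np.allclose(
                ratio, tissue / serum, rtol=1e-6, atol=1e-9
            ):
                raise ValueError("stored ratio inconsistent with tissue/serum")
        elif tissue is not None:
            object.__setattr__(self, "ratio", tissue / serum)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def has_tissue(self) -> bool:
        return self.ratio is not None


def _extended_serum_grid(
    series: TimeActivitySeries, back_extrapolate: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Sampling grid extended to t=0 for the serum integral.

    The unsampled interval [0, first sample] uses linear back-extrapolation of
    the first two samples to t=0, clamped from below at the first observed
    value (conservative for a decaying bolus curve).  With back-extrapolation
    disabled the serum level is held constant at the first observed value.
    """
    t, c = series.times, series.serum_conc
    if t[0] == 0.0:
        return t, c
    if back_extrapolate:
        c0 = c[0] + (c[1] - c[0]) * (0.0 - t[0]) / (t[1] - t[0])
        c0 = max(c0, c[0])
    else:
        c0 = c[0]
    return np.concatenate(([0.0], t)), np.concatenate(([c0], c))


def serum_integral(
    series: TimeActivitySeries, *, back_extrapolate: bool = True
) -> np.ndarray:
    """Cumulative integral of serum concentration, Int_0^t Cp(T) dT, at each
    sampled time (composite trapezoid; cpm*min/ul)."""
    te, ce = _extended_serum_grid(series, back_extrapolate)
    cum = np.concatenate(([0.0], np.cumsum(np.diff(te) * (ce[1:] + ce[:-1]) / 2.0)))
    if te.size > series.times.size:  # drop the synthetic t=0 node
        cum = cum[1:]
    return cum


def exposure_time(
    series: TimeActivitySeries,
    t: float,
    *,
    back_extrapolate: bool = True,
    interpolate: bool = False,
) -> float:
    """Exposure time Theta(t) = Int_0^t Cp(T) dT / Cp(t), in minutes.

    ``t`` must coincide with a sampled time, unless ``interpolate`` is true in
    which case any ``t`` within the sampled range is accepted (serum linearly
    interpolated).  ``t = 0`` returns 0 (empty integral).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0.0:
        return 0.0
    te, ce = _extended_serum_grid(series, back_extrapolate)
    cum = np.concatenate(([0.0], np.cumsum(np.diff(te) * (ce[1:] + ce[:-1]) / 2.0)))
    hit = np.flatnonzero(np.isclose(series.times, t, rtol=1e-9, atol=1e-9))
    if hit.size:
        i = hit[0] + (te.size - series.times.size)
        cp_t = ce[i]
        integral = cum[i]
    elif interpolate:
        if not (te[0] <= t <= te[-1]):
            raise ValueError(f"t={t} outside sampled range [{te[0]}, {te[-1]}]")
        cp_t = float(np.interp(t, te, ce))
        j = int(np.searchsorted(te, t)) - 1
        integral = cum[j] + (t - te[j]) * (ce[j] + cp_t) / 2.0
    else:
        raise ValueError(
            f"t={t} is not a sampled time (pass interpolate=True to allow)"
        )
    if cp_t <= 0:
        raise ValueError("Cp(t) must be positive")
    return float(integral / cp_t)


def patlak_transform(
    series: TimeActivitySeries, *, back_extrapolate: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Transform a time-activity series to Patlak coordinates.

    Returns ``(exposure_times, ratios)`` — one pair per sampled time, ratios
    carried through unchanged.
    """
    if not series.has_tissue:
        raise ValueError("series has no tissue data or ratios to transform")
    integ = serum_integral(series, back_extrapolate=back_extrapolate)
    return integ / series.serum_conc, np.array(series.ratio, copy=True)


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Slope/intercept with standard errors and R^2, with exact edge cases.

    n=2 or zero-residual fits report se=0 and R^2=1; constant y with zero
    residuals is a perfect (flat) fit.
    """
    n = x.size
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0.0:
        raise DegenerateDesignError("exposure times are all identical")
    slope = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xbar)
    resid = y - (slope * x + intercept)
    ssr = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst > 0:
        r2 = max(0.0, 1.0 - ssr / sst)
    else:
        r2 = 1.0 if ssr <= 1e-300 else 0.0
    if n > 2:
        sigma2 = ssr / (n - 2)
        slope_se = math.sqrt(sigma2 / sxx)
        intercept_se = math.sqrt(sigma2 * (1.0 / n + xbar**2 / sxx))
    else:
        slope_se = 0.0
        intercept_se = 0.0
    return slope, intercept, slope_se, intercept_se, r2


@dataclass(frozen=True)
class PatlakFit:
    """Result of a multiple-time regression fit.

    ``ki`` is the slope (ul/g/min), ``vi`` the intercept (ul/g); standard
    errors are the usual OLS ones (0 when the fit is saturated at n=2).
    ``exposure_times``/``ratios`` are the windowed points actually fitted, so
    the fit can be reproduced exactly from the stored pairs.
    """

    ki: float
    vi: float
    ki_se: float
    vi_se: float
    r_squared: float
    n_points: int
    exposure_times: np.ndarray
    ratios: np.ndarray
    phase_window: tuple[float, float]

    @property
    def df(self) -> int:
        return self.n_points - 2


def patlak_fit(
    exposure_times: Sequence[float] | np.ndarray,
    ratios: Sequence[float] | np.ndarray,
    phase_window: tuple[float, float] | None = None,
) -> PatlakFit:
    """Ordinary least-squares line through Patlak-transformed pairs.

    ``phase_window`` restricts the fit to exposure times in the closed
    interval ``(lo, hi)``; default uses all pairs.  Slope is reported as
    ``ki``, intercept as ``vi``.
    """
    x = _as_array(exposure_times, "exposure_times")
    y = _as_array(ratios, "ratios")
    if x.size != y.size:
        raise ValueError("exposure_times and ratios must have equal length")
    if phase_window is None:
        lo, hi = (float(x.min()) if x.size else 0.0, float(x.max()) if x.size else 0.0)
        mask = np.ones(x.size, dtype=bool)
    else:
        lo, hi = float(phase_window[0]), float(phase_window[1])
        mask = (x >= lo) & (x <= hi)
    xw, yw = x[mask], y[mask]
    if xw.size < 2:
        raise InsufficientDataError(
            f"need >= 2 pairs inside the phase window, got {xw.size}"
        )
    ki, vi, ki_se, vi_se, r2 = _ols_line(xw, yw)
    return PatlakFit(
        ki=ki,
        vi=vi,
        ki_se=ki_se,
        vi_se=vi_se,
        r_squared=r2,
        n_points=int(xw.size),
        exposure_times=xw,
        ratios=yw,
        phase_window=(lo, hi),
    )


def fit_series(
    series: TimeActivitySeries,
    phase_window: tuple[float, float] | None = None,
    *,
    back_extrapolate: bool = True,
) -> PatlakFit:
    """Convenience: transform a series and fit in one call."""
    x, y = patlak_transform(series, back_extrapolate=back_extrapolate)
    return patlak_fit(x, y, phase_window)


@dataclass(frozen=True)
class LinearPhase:
    """Detected linear-phase window on the exposure-time axis."""

    window: tuple[float, float]
    n_points: int
    r_squared: float
    warning: bool  # True when forced to the minimal 2-point window


def detect_linear_phase(
    exposure_times: Sequence[float] | np.ndarray,
    ratios: Sequence[float] | np.ndarray,
    max_exposure: float | None = DEFAULT_MAX_EXPOSURE_MIN,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> LinearPhase:
    """Select the early linear phase of a Patlak plot.

    Returns the largest prefix window [0, e*] of the (exposure-sorted) pairs
    whose prefix fit has R^2 >= ``r2_threshold``, with e* capped at
    ``max_exposure`` (``None`` for no cap).  Saturable uptake bends the plot
    downward at late exposure times, so restricting the regression to this
    window keeps the slope an estimate of the initial influx rate.

    If no prefix of >= 3 points meets the threshold, the minimal 2-point
    window is returned with ``warning=True``.
    """
    x = _as_array(exposure_times, "exposure_times")
    y = _as_array(ratios, "ratios")
    if x.size != y.size:
        raise ValueError("exposure_times and ratios must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need >= 3 pairs to detect a linear phase")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    cap = math.inf if max_exposure is None else float(max_exposure)
    k_max = max(int(np.sum(xs <= cap)), 2)
    for k in range(k_max, 2, -1):
        try:
            _, _, _, _, r2 = _ols_line(xs[:k], ys[:k])
        except DegenerateDesignError:
            continue
        if r2 >= r2_threshold:
            return LinearPhase(
                window=(0.0, float(xs[k - 1])), n_points=k, r_squared=r2, warning=False
            )
    if k_max >= 3:
        warning = True  # larger prefixes existed but failed the threshold
    else:
        warning = cap < xs[1]  # cap admitted fewer than the minimal 2 points
    return LinearPhase(
        window=(0.0, float(xs[1])), n_points=2, r_squared=1.0, warning=warning
    )


@dataclass(frozen=True)
class SlopeComparison:
    """Welch-style comparison of two fitted influx rates."""

    estimate: float  # ki_a - ki_b
    se: float
    t_stat: float
    p_value: float
    df: float
    degenerate: bool = False  # a zero-se fit forced the p-value convention


def compare_ki(fit_a: PatlakFit, fit_b: PatlakFit) -> SlopeComparison:
    """Two-sided Welch t comparison of two Patlak slopes.

    Uses the slope standard errors with Welch-Satterthwaite degrees of
    freedom (component df = n_points - 2).  Both fits need n_points >= 3 so
    that their standard errors are estimable.
    """
    if fit_a.n_points < 3 or fit_b.n_points < 3:
        raise InsufficientDataError("both fits need n_points >= 3 to compare slopes")
    diff = fit_a.ki - fit_b.ki
    va, vb = fit_a.ki_se**2, fit_b.ki_se**2
    se = math.sqrt(va + vb)
    if se == 0.0:
        if diff == 0.0:
            return SlopeComparison(0.0, 0.0, 0.0, 1.0, math.inf, degenerate=True)
        return SlopeComparison(
            diff, 0.0, math.copysign(math.inf, diff), 0.0, math.inf, degenerate=True
        )
    dfa, dfb = fit_a.df, fit_b.df
    if va == 0.0 or vb == 0.0:
        df = float(dfa if vb == 0.0 else dfb)
    else:
        df = (va + vb) ** 2 / (va**2 / dfa + vb**2 / dfb)
    t = diff / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return SlopeComparison(diff, se, t, min(p, 1.0), df)
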