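"""Acid-precipitation stability accounting for the radiolabel.

Trichloroacetic-acid precipitation separates intact labelled macromolecule
from free label; the precipitable fraction indexes tracer integrity.  Because
the assay itself degrades some label, each sample's raw precipitated fraction
is expressed as *percent of control* — divided by the fraction obtained from
a spiked control of the same matrix (serum control 0.78, brain control 0.67)
and multiplied by 100.  Values above 100% occur in real data (matrix effects
on precipitation efficiency) and are passed through unclamped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PrecipitationMeasurement",
    "CompartmentProfile",
    "DegradationProfile",
    "percent_of_control",
    "degradation_profile",
]


def percent_of_control(raw_fraction, control_fraction):
    """Precipitable fraction as percent of the matched spiked control.

    ``100 * raw_fraction / control_fraction``; linear in ``raw_fraction`` and
    invariant to rescaling both arguments by the same positive constant.
    Accepts scalars or arrays.  May exceed 100.
    """
    raw = np.asarray(raw_fraction, dtype=float)
    control = np.asarray(control_fraction, dtype=float)
    if np.any(control <= 0):
        raise ValueError("control_fraction must be > 0")
    if np.any(raw < 0):
        raise ValueError("raw_fraction must be >= 0")
    out = 100.0 * raw / control
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PrecipitationMeasurement:
    """One acid-precipitation assay result."""

    compartment: str  # serum | brain | perfusate
    time: float  # min
    raw_fraction: float  # precipitated / total counts, in [0, 1]
    control_fraction: float  # matched spiked control, in (0, 1]

    def __post_init__(self) -> None:
        if not (0.0 <= self.raw_fraction <= 1.0):
            raise ValueError("raw_fraction must be in [0, 1]")
        if not (0.0 < self.control_fraction <= 1.0):
            raise ValueError("control_fraction must be in (0, 1]")
        if self.time < 0:
            raise ValueError("time must be >= 0")

    @property
    def percent_of_control(self) -> float:
        return percent_of_control(self.raw_fraction, self.control_fraction)


@dataclass(frozen=True)
class CompartmentProfile:
    """Percent-of-control time course and fitted first-order rate for one
    compartment."""

    compartment: str
    times: np.ndarray
    percent: np.ndarray
    rate: float  # 1/min, from log-linear OLS of percent vs time
    rate_se: float
    n_points: int


@dataclass(frozen=True)
class DegradationProfile:
    """Per-compartment degradation profiles plus the brain-vs-serum rate
    contrast (Welch t on the fitted log-linear slopes)."""

    compartments: dict[str, CompartmentProfile]
    rate_difference: float | None  # serum rate - brain rate
    t_stat: float | None
    p_value: float | None

    def __getitem__(self, compartment: str) -> CompartmentProfile:
        return self.compartments[compartment]


def _fit_rate(times: np.ndarray, percent: np.ndarray):
    """First-order rate from log-linear OLS: ln(percent) = ln(p0) - rate*t."""
    pos = percent > 0
    if not np.all(pos):
        warnings.warn(
            "nonpositive percent-of-control values excluded from log fit",
            stacklevel=3,
        )
    t, p = times[pos], percent[pos]
    if t.size < 2:
        raise ValueError("need >= 2 positive points per compartment to fit a rate")
    y = np.log(p)
    tbar = t.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    if sxx == 0:
        raise ValueError("degenerate design: all times identical")
    slope = float(np.sum((t - tbar) * (y - y.mean())) / sxx)
    resid = y - (slope * t + (y.mean() - slope * tbar))
    if t.size > 2:
        se = math.sqrt(float(np.sum(resid**2)) / (t.size - 2) / sxx)
    else:
        se = 0.0
    return -slope, se, int(t.size)


def degradation_profile(
    measurements,
) -> DegradationProfile:
    """Per-compartment percent-of-control series and first-order rates.

    ``measurements`` is an iterable of :class:`PrecipitationMeasurement` or a
    DataFrame with columns ``compartment, time_min, raw_fraction,
    control_fraction``.  Each compartment needs >= 2 time points.  When both
    serum and brain are present, their rates are compared with a Welch t test
    on the fitted slopes.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.rename(columns={"time_min": "time"})
    else:
        rows = list(measurements)
        if not rows:
            raise ValueError("no measurements supplied")
        df = pd.DataFrame(
            {
                "compartment": [m.compartment for m in rows],
                "time": [m.time for m in rows],
                "raw_fraction": [m.raw_fraction for m in rows],
                "control_fraction": [m.control_fraction for m in rows],
            }
        )
    profiles: dict[str, CompartmentProfile] = {}
    for compartment, grp in df.groupby("compartment", sort=False):
        grp = grp.sort_values("time")
        times = grp["time"].to_numpy(dtype=float)
        if times.size < 2:
            raise ValueError(
                f"compartment {compartment!r} has fewer than 2 time points"
            )
        pct = percent_of_control(
            grp["raw_fraction"].to_numpy(), grp["control_fraction"].to_numpy()
        )
        rate, se, n = _fit_rate(times, np.asarray(pct, dtype=float))
        profiles[compartment] = CompartmentProfile(
            compartment=compartment,
            times=times,
            percent=np.asarray(pct, dtype=float),
            rate=rate,
            rate_se=se,
            n_points=n,
        )
    diff = t_stat = p_value = None
    if "serum" in profiles and "brain" in profiles:
        s, b = profiles["serum"], profiles["brain"]
        diff = s.rate - b.rate
        se = math.hypot(s.rate_se, b.rate_se)
        if se > 0:
            va, vb = s.rate_se**2, b.rate_se**2
            dfa, dfb = s.n_points - 2, b.n_points - 2
            if va > 0 and vb > 0:
                dof = (va + vb) ** 2 / (va**2 / dfa + vb**2 / dfb)
            else:
                dof = float(dfa if vb == 0 else dfb)
            t_stat = diff / se
            p_value = float(2.0 * stats.t.sf(abs(t_stat), dof))
        else:
            t_stat = 0.0 if diff == 0 else math.copysign(math.inf, diff)
            p_value = 1.0 if diff == 0 else 0.0
    return DegradationProfile(
        compartments=profiles, rate_difference=diff, t_stat=t_stat, p_value=p_value
    )
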