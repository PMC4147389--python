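"""Terminal-tissue analysis: partition ratios, whole-CNS aggregation,
region-vs-whole comparisons, and cold-competitor inhibition statistics.

At the terminal time each dissected region yields an activity (cpm) and a
mass (g); dividing activity per gram by the terminal serum concentration
gives the tissue/serum partition ratio in ul/g.  The whole-CNS value is
formed by summing activities and masses across regions (equivalently, the
mass-weighted mean of regional ratios) — not by averaging ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CNS_REGION_NAMES",
    "KNOWN_TISSUES",
    "RegionalUptakeTable",
    "AnovaResult",
    "InhibitionResult",
    "tissue_serum_ratio",
    "aggregate_whole_cns",
    "region_vs_whole_anova",
    "inhibition_analysis",
]

#: The 10 brain regions and 3 spinal levels of the dissection protocol.
CNS_REGION_NAMES: tuple[str, ...] = (
    "frontal cortex",
    "parietal cortex",
    "occipital cortex",
    "hypothalamus",
    "thalamus",
    "substantia nigra",
    "hippocampus",
    "cerebellum",
    "midbrain",
    "pons medulla",
    "cervical spinal cord",
    "thoracic spinal cord",
    "lumbar spinal cord",
)

KNOWN_TISSUES: frozenset[str] = frozenset(CNS_REGION_NAMES) | {"liver", "kidney"}


def tissue_serum_ratio(activity: float, mass: float, serum_conc: float) -> float:
    """Tissue/serum partition ratio, (activity/mass)/serum_conc, in ul/g.

    ``activity`` in cpm, ``mass`` in g, ``serum_conc`` in cpm/ul.
    """
    if mass <= 0:
        raise ValueError("mass must be > 0")
    if serum_conc <= 0:
        raise ValueError("serum_conc must be > 0")
    if activity < 0:
        raise ValueError("activity must be >= 0")
    return (activity / mass) / serum_conc


@dataclass(frozen=True)
class RegionalUptakeTable:
    """Per-region terminal measurements and ratios for one subject.

    Stored as a DataFrame with columns ``region, activity_cpm, mass_g,
    serum_cpm_per_ul, ratio_ul_per_g``; the whole-CNS aggregate is computed
    on demand from summed activity and mass.
    """

    data: pd.DataFrame

    REQUIRED = ("region", "activity_cpm", "mass_g", "serum_cpm_per_ul")

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("regional table is empty")
        if (df["mass_g"] <= 0).any():
            raise ValueError("all masses must be > 0")
        if (df["serum_cpm_per_ul"] <= 0).any():
            raise ValueError("serum_cpm_per_ul must be > 0")
        unknown = set(df["region"]) - KNOWN_TISSUES
        if unknown:
            warnings.warn(
                f"unrecognised tissue labels accepted: {sorted(unknown)}",
                stacklevel=2,
            )
        df["ratio_ul_per_g"] = [
            tissue_serum_ratio(a, m, s)
            for a, m, s in zip(
                df["activity_cpm"], df["mass_g"], df["serum_cpm_per_ul"]
            )
        ]
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @classmethod
    def from_measurements(
        cls,
        regions: Sequence[str],
        activity_cpm: Sequence[float],
        mass_g: Sequence[float],
        serum_cpm_per_ul: float | Sequence[float],
    ) -> "RegionalUptakeTable":
        n = len(regions)
        serum = (
            [float(serum_cpm_per_ul)] * n
            if np.isscalar(serum_cpm_per_ul)
            else list(serum_cpm_per_ul)
        )
        return cls(
            pd.DataFrame(
                {
                    "region": list(regions),
                    "activity_cpm": list(activity_cpm),
                    "mass_g": list(mass_g),
                    "serum_cpm_per_ul": serum,
                }
            )
        )

    def ratio(self, region: str) -> float:
        row = self.data[self.data["region"] == region]
        if row.empty:
            raise KeyError(region)
        return float(row["ratio_ul_per_g"].iloc[0])

    @property
    def whole_cns_ratio(self) -> float:
        return aggregate_whole_cns(self)


def aggregate_whole_cns(table: RegionalUptakeTable) -> float:
    """Whole-CNS tissue/serum ratio from summed activity and summed mass.

    Equals the mass-weighted mean of the regional ratios; invariant to
    merging or splitting regions.  Uses the mean of the per-row serum
    concentrations (one shared terminal draw in the usual design).
    """
    df = table.data
    serum = float(df["serum_cpm_per_ul"].mean())
    return (float(df["activity_cpm"].sum()) / float(df["mass_g"].sum())) / serum


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA across regions with per-region vs whole-CNS contrasts."""

    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    contrasts: pd.DataFrame  # region, mean_ratio, whole_mean, t_stat, p_value


def region_vs_whole_anova(
    tables: Sequence[RegionalUptakeTable],
    *,
    bonferroni: bool = False,
) -> AnovaResult:
    """Compare regional uptake to the whole-CNS value across subjects.

    One-way ANOVA treats regions as groups and subjects as replicates.
    Post-hoc contrasts compare each region's per-subject ratios to the
    per-subject whole-CNS aggregates with two-sided pooled-variance t tests
    (unadjusted by default; ``bonferroni=True`` multiplies p by the number
    of contrasts).
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 subjects for ANOVA")
    regions = list(tables[0].data["region"])
    if len(regions) < 2:
        raise ValueError("need >= 2 regions for ANOVA")
    values = {
        r: np.array([t.ratio(r) for t in tables], dtype=float) for r in regions
    }
    whole = np.array([t.whole_cns_ratio for t in tables], dtype=float)

    groups = [values[r] for r in regions]
    if all(np.allclose(g, groups[0]) for g in groups[1:]):
        # identical groups: zero between-group variance, F = 0, p = 1
        f_stat, p_value = 0.0, 1.0
    else:
        f_stat, p_value = (float(v) for v in stats.f_oneway(*groups))

    n = len(tables)
    rows = []
    n_contrasts = len(regions)
    for r in regions:
        g = values[r]
        t_stat, p = stats.ttest_ind(g, whole, equal_var=True)
        t_stat, p = float(t_stat), float(p)
        if math.isnan(t_stat):  # zero variance in both samples
            t_stat, p = 0.0, 1.0
        if bonferroni:
            p = min(1.0, p * n_contrasts)
        rows.append(
            {
                "region": r,
                "mean_ratio": float(g.mean()),
                "whole_mean": float(whole.mean()),
                "t_stat": t_stat,
                "p_value": p,
            }
        )
    return AnovaResult(
        f_stat=f_stat,
        p_value=p_value,
        df_between=len(regions) - 1,
        df_within=len(regions) * (n - 1),
        contrasts=pd.DataFrame(rows),
    )


@dataclass(frozen=True)
class InhibitionResult:
    """Cold-competitor inhibition of an uptake rate for one tissue."""

    tissue: str
    rate_labeled: float
    rate_with_cold: float
    percent_inhibition: float  # 100 * (1 - cold/labeled); <= 100, may be < 0
    t_stat: float
    p_value: float
    df: float
    n_labeled: int
    n_cold: int


def inhibition_analysis(
    rates_labeled: Iterable[float],
    rates_cold: Iterable[float],
    tissue: str = "brain",
) -> InhibitionResult:
    """Paired-arm uptake comparison: labelled-only vs labelled + cold.

    Percent inhibition is computed from the arm means; the two arms are
    compared with a two-sided Welch t test across subjects.
    """
    a = np.asarray(list(rates_labeled), dtype=float)
    b = np.asarray(list(rates_cold), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each arm needs >= 2 subjects")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if mean_a == 0:
        raise ValueError("labelled-arm mean rate is zero; inhibition undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    t_stat, p = float(res.statistic), float(res.pvalue)
    if math.isnan(t_stat):  # both arms constant and equal
        t_stat, p = 0.0, 1.0
    return InhibitionResult(
        tissue=tissue,
        rate_labeled=mean_a,
        rate_with_cold=mean_b,
        percent_inhibition=100.0 * (1.0 - mean_b / mean_a),
        t_stat=t_stat,
        p_value=p,
        df=float(getattr(res, "df", a.size + b.size - 2)),
        n_labeled=int(a.size),
        n_cold=int(b.size),
    )
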