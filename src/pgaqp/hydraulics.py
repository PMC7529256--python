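"""Root hydraulic conductivity and aquaporin contribution.

A pressure-chamber series gives xylem sap mass exuded at several applied
pressures. Per plant, sap mass is converted to volumetric flow
(density 1 g/ml), root conductance L0 is the OLS slope of flow against
pressure (free intercept by default, absorbing residual exudation after
the equilibration step), and hydraulic conductivity Lpr = L0 / root
surface area. The aquaporin contribution of an azide-treated plant is
the relative Lpr inhibition

    contribution% = 100 - 100 * Lpr_azide_individual / mean(Lpr_untreated)

computed against the untreated genotype mean. Group summaries use
mean +/- se, with letter classes from an ANOVA-pooled LSD test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import log

WATER_DENSITY_G_PER_M3 = 1e6  # 1 g/ml


@dataclass(frozen=True)
class PressureFluxSeries:
    """Per-plant sap-mass measurements at each applied pressure."""

    plant_id: str
    genotype: str
    treatment: str  # none | azide
    points: tuple[tuple[float, float, float], ...]  # (MPa, g, s)
    root_surface_area: float  # m^2

    def __post_init__(self) -> None:
        if len({p for p, _, _ in self.points}) < 2:
            raise ValueError(f"{self.plant_id}: need >= 2 distinct pressures")
        if any(m < 0 for _, m, _ in self.points):
            raise ValueError(f"{self.plant_id}: negative sap mass")
        if any(d <= 0 for _, _, d in self.points):
            raise ValueError(f"{self.plant_id}: non-positive duration")
        if self.root_surface_area <= 0:
            raise ValueError(f"{self.plant_id}: non-positive root surface area")


@dataclass
class HydraulicsResult:
    plant_id: str
    genotype: str
    treatment: str
    L0: float  # m^3 s^-1 MPa^-1
    Lpr: float  # m^3 m^-2 s^-1 MPa^-1
    contribution_pct: float | None = None


def fit_conductance(series: PressureFluxSeries, free_intercept: bool = True) -> float:
    """Root conductance L0: OLS slope of volumetric flow vs pressure."""
    pressures = np.array([p for p, _, _ in series.points])
    flows = np.array(
        [m / WATER_DENSITY_G_PER_M3 / d for _, m, d in series.points]
    )  # m^3/s
    if free_intercept:
        slope = stats.linregress(pressures, flows).slope
    else:
        slope = float(np.dot(pressures, flows) / np.dot(pressures, pressures))
    return float(slope)


def compute_lpr(L0: float, root_surface_area: float) -> float:
    """Hydraulic conductivity: conductance normalized by root surface area."""
    if root_surface_area <= 0:
        raise ValueError("root surface area must be positive")
    return L0 / root_surface_area


def aqp_contribution(lpr_azide_individual: float, lpr_noazide_variety_mean: float) -> float:
    """Relative Lpr inhibition by azide, in percent.

    100 - (Lpr_azide * 100 / mean untreated Lpr). May be negative when an
    azide-treated plant exceeds the untreated mean; returned as-is.
    """
    if lpr_noazide_variety_mean <= 0:
        raise ValueError("untreated mean Lpr must be positive")
    if lpr_azide_individual < 0:
        raise ValueError("azide Lpr must be non-negative")
    value = 100.0 - (lpr_azide_individual * 100.0 / lpr_noazide_variety_mean)
    if value < 0:
        log.warning("negative aquaporin contribution (%.2f%%)", value)
    return value


def analyze_series(
    all_series: Sequence[PressureFluxSeries], free_intercept: bool = True
) -> list[HydraulicsResult]:
    """Per-plant L0/Lpr for a cohort, plus Eq.-style contribution for azide plants.

    The untreated reference mean is computed per genotype from the same
    cohort; azide-treated plants in a genotype without untreated plants
    get no contribution value.
    """
    results = [
        HydraulicsResult(
            plant_id=s.plant_id,
            genotype=s.genotype,
            treatment=s.treatment,
            L0=(L0 := fit_conductance(s, free_intercept)),
            Lpr=compute_lpr(L0, s.root_surface_area),
        )
        for s in all_series
    ]
    untreated_mean: dict[str, float] = {}
    for genotype in {r.genotype for r in results}:
        vals = [r.Lpr for r in results if r.genotype == genotype and r.treatment == "none"]
        if vals:
            untreated_mean[genotype] = float(np.mean(vals))
    for r in results:
        if r.treatment == "azide" and r.genotype in untreated_mean:
            r.contribution_pct = aqp_contribution(max(r.Lpr, 0.0), untreated_mean[r.genotype])
    return results


@dataclass(frozen=True)
class GroupSummary:
    group: tuple[str, str]  # (genotype, treatment)
    mean: float
    se: float
    n: int
    degenerate: bool = False  # single observation: se not estimable, reported 0


def summarize_groups(
    results: Sequence[HydraulicsResult], value: str = "Lpr"
) -> list[GroupSummary]:
    """Per genotype x treatment mean, standard error (sd/sqrt(n)) and n."""
    groups: dict[tuple[str, str], list[float]] = {}
    for r in results:
        v = getattr(r, value)
        if v is None:
            continue
        groups.setdefault((r.genotype, r.treatment), []).append(v)
    out = []
    for key in sorted(groups):
        vals = np.array(groups[key])
        n = len(vals)
        if n == 1:
            log.warning("group %s has a single observation; se reported as 0", key)
            out.append(GroupSummary(key, float(vals[0]), 0.0, 1, degenerate=True))
        else:
            se = float(np.std(vals, ddof=1) / math.sqrt(n))
            out.append(GroupSummary(key, float(np.mean(vals)), se, n))
    return out


def lsd_groups(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict[str, str]:
    """LSD letter classes after a one-way ANOVA.

    The pooled within-group mean square gives, for each pair (i, j),
    LSD = t(1 - alpha/2, df_error) * sqrt(MSE * (1/n_i + 1/n_j)); groups
    whose means differ by less than their LSD are not separable and share
    a letter. Letters are assigned greedily over means sorted descending
    (agricolae-style line display); the returned label concatenates every
    letter a group belongs to.
    """
    names = sorted(values_by_group)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    data = {g: np.asarray(values_by_group[g], dtype=float) for g in names}
    if any(len(v) < 2 for v in data.values()):
        raise ValueError("each group needs >= 2 observations")
    ns = {g: len(v) for g, v in data.items()}
    df_error = sum(ns.values()) - len(names)
    if df_error <= 0:
        raise ValueError("zero error degrees of freedom")
    sse = sum(float(np.sum((v - v.mean()) ** 2)) for v in data.values())
    mse = sse / df_error
    tcrit = stats.t.ppf(1 - alpha / 2, df_error)

    def separable(a: str, b: str) -> bool:
        lsd = tcrit * math.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
        return abs(data[a].mean() - data[b].mean()) >= lsd

    # order by mean descending, ties by name for determinism
    order = sorted(names, key=lambda g: (-data[g].mean(), g))
    lines: list[tuple[int, int]] = []  # inclusive index ranges sharing a letter
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and not any(
            separable(order[a], order[j + 1]) for a in range(i, j + 1)
        ):
            j += 1
        if not lines or lines[-1] != (i, j):
            if lines and lines[-1][0] <= i and j <= lines[-1][1]:
                continue  # contained in the previous line
            lines.append((i, j))
    labels = {g: "" for g in names}
    for letter_idx, (i, j) in enumerate(lines):
        letter = chr(ord("a") + letter_idx)
        for k in range(i, j + 1):
            labels[order[k]] += letter
    return labels
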