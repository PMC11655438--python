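"""Evaporative-flux shoot hydraulic conductance.

A detached, transpiring shoot stands in a water-filled micro test tube on
a balance; mass is read 8-10 times at ~1-min intervals.  The steady mass
loss rate F (mmol s-1) divided by the magnitude of the end-point plant
water potential gives the absolute shoot conductance

    K_shoot = F / |psi_plant|        (mmol s-1 MPa-1)

which is further normalised by leaf area (K_shoot_L) and, at group
level, by mean xylem area (K_shoot_Axyl).  Group-level ratios of means
carry a propagated standard error and are compared with a Welch test on
the summary statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

WATER_MOLAR_MASS = 0.018015  # g mmol-1

__all__ = [
    "FluxSeries",
    "ConductanceResult",
    "GroupRatioTrait",
    "fit_steady_flow",
    "compute_kshoot",
    "normalize_by_leaf",
    "group_ratio_trait",
    "welch_summary_test",
    "WATER_MOLAR_MASS",
]


@dataclass
class FluxSeries:
    """Balance time series for one shoot plus its normalisation metadata."""

    sample_id: str
    masses: list[tuple[float, float]]  # (time s, mass g)
    leaf_area: float  # m2
    psi_plant: float  # MPa
    species: str | None = None
    age_weeks: int | None = None
    temperature: float | None = None  # degC, metadata only
    rh: float | None = None  # %, metadata only

    def __post_init__(self) -> None:
        if len(self.masses) < 8:
            raise ValueError(
                f"sample {self.sample_id}: need >= 8 mass readings, "
                f"got {len(self.masses)}"
            )
        times = [t for t, _ in self.masses]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"sample {self.sample_id}: times must strictly increase")
        if self.psi_plant >= 0:
            raise ValueError(
                f"sample {self.sample_id}: psi_plant must be negative, "
                f"got {self.psi_plant}"
            )
        if self.leaf_area <= 0:
            raise ValueError(f"sample {self.sample_id}: leaf area must be positive")


@dataclass
class ConductanceResult:
    sample_id: str
    flow: float  # mmol s-1
    k_shoot: float  # mmol s-1 MPa-1
    k_shoot_l: float  # mmol s-1 MPa-1 m-2
    steady: bool
    slope_drift_p: float


def fit_steady_flow(
    series: FluxSeries,
    molar_mass: float = WATER_MOLAR_MASS,
    alpha: float = 0.05,
) -> tuple[float, bool, float]:
    """Transpirational flow from successive mass differences.

    Flow is the mean of the interval-wise loss rates (g s-1) converted to
    mmol s-1.  Steadiness is a two-sided test on the slope of interval
    loss rates against time: the series is flagged non-steady only for a
    significant *decrease* (p < alpha and slope < 0).
    """
    t = np.array([p[0] for p in series.masses], dtype=float)
    m = np.array([p[1] for p in series.masses], dtype=float)
    dm = -np.diff(m)  # mass lost per interval, g
    dt = np.diff(t)
    rates = dm / dt  # g s-1 per interval
    mean_rate = float(np.mean(rates))
    if mean_rate < 0:
        raise ValueError(
            f"sample {series.sample_id}: overall mass gain; cannot interpret "
            "as transpirational flow"
        )
    flow = mean_rate / molar_mass  # mmol s-1

    mids = (t[:-1] + t[1:]) / 2.0
    if np.allclose(rates, rates[0]):
        return flow, True, 1.0
    res = stats.linregress(mids, rates)
    p = float(res.pvalue)
    steady = not (p < alpha and res.slope < 0)
    return flow, steady, p


def compute_kshoot(flow: float, psi_plant: float) -> float:
    """Absolute shoot conductance K = F / |psi_plant| (mmol s-1 MPa-1).

    The driving force is taken as the magnitude of the plant water
    potential (source potential ~ 0 MPa in the tube).
    """
    if psi_plant >= 0:
        raise ValueError(f"psi_plant must be negative, got {psi_plant}")
    if flow < 0:
        raise ValueError(f"flow must be non-negative, got {flow}")
    return flow / abs(psi_plant)


def normalize_by_leaf(k_shoot: float, leaf_area: float) -> float:
    """Leaf-area-specific conductance (mmol s-1 MPa-1 m-2)."""
    if leaf_area <= 0:
        raise ValueError(f"leaf area must be positive, got {leaf_area}")
    return k_shoot / leaf_area


def analyse_series(series: FluxSeries, alpha: float = 0.05) -> ConductanceResult:
    """Full per-sample conductance workup."""
    flow, steady, p = fit_steady_flow(series, alpha=alpha)
    k = compute_kshoot(flow, series.psi_plant)
    return ConductanceResult(
        sample_id=series.sample_id,
        flow=flow,
        k_shoot=k,
        k_shoot_l=normalize_by_leaf(k, series.leaf_area),
        steady=steady,
        slope_drift_p=p,
    )


@dataclass
class GroupRatioTrait:
    """A ratio of two group means with a propagated standard error."""

    value: float
    se: float
    n_num: int
    n_den: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("propagated SE cannot be negative")


def group_ratio_trait(
    num_mean: float,
    num_se: float,
    n_num: int,
    den_mean: float,
    den_se: float,
    n_den: int,
) -> GroupRatioTrait:
    """Ratio of group means with first-order error propagation.

    se = |num/den| * sqrt((num_se/num)^2 + (den_se/den)^2); the numerator
    relative-error term is dropped when the numerator mean is zero.
    """
    if den_mean == 0:
        raise ValueError("denominator mean must be nonzero")
    if num_se < 0 or den_se < 0:
        raise ValueError("standard errors must be non-negative")
    value = num_mean / den_mean
    rel_num_sq = (num_se / num_mean) ** 2 if num_mean != 0 else 0.0
    rel_den_sq = (den_se / den_mean) ** 2
    se = abs(value) * math.sqrt(rel_num_sq + rel_den_sq)
    if num_mean == 0:
        se = num_se / abs(den_mean)
    return GroupRatioTrait(value=value, se=se, n_num=n_num, n_den=n_den)


def welch_summary_test(
    m1: float, se1: float, n1: int, m2: float, se2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's t-test from summary statistics (mean, SE, n) of two groups.

    t = (m1 - m2)/sqrt(se1^2 + se2^2); degrees of freedom by the
    Welch-Satterthwaite approximation on the squared SEs; two-sided p.
    Used for traits that only exist as error-propagated group summaries
    (Huber value, xylem-area-specific conductance).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    denom_sq = se1**2 + se2**2
    if denom_sq == 0:
        raise ValueError("both SEs are zero; test is degenerate")
    t = (m1 - m2) / math.sqrt(denom_sq)
    df = denom_sq**2 / (se1**4 / (n1 - 1) + se2**4 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p
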