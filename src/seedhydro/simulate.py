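"""Seeded synthetic-data generators with exported ground truth.

Every generator is a pure function of its parameters and seed and
returns the ground-truth quantities alongside the data, so that each
pipeline stage can be verified by parameter recovery without external
data.

Models
------
* PV series: a symplastic water model.  With relative symplastic water
  content R_s, osmotic potential follows the Boyle-van't Hoff relation
  psi_pi = psi_osat/R_s and turgor declines linearly,
  psi_p = max(0, -psi_osat + eps*(R_s - 1)), reaching zero at
  R_s,tlp = 1 + psi_osat/eps.  Total water potential is psi_p + psi_pi;
  an apoplastic water fraction dilutes R_s into total relative water
  content.  The closed-form turgor-loss potential is
  psi_osat / R_s,tlp.
* Acoustic emissions: each conduit draws a cavitation threshold from a
  normal distribution truncated to negative potentials and clicks once
  when the declining water potential first crosses it.  Psi(t) decays
  exponentially toward an asymptote below the thresholds.  A background
  Poisson stream whose rate rises linearly as psi falls emulates
  emissions from non-conductive tissue.
* Balance series: linear mass loss at a true molar flow with additive
  Gaussian balance noise.
* Conduit populations: lognormal lumen areas; wall pairs built with
  t = wall_scaling * b so the true (t/b)^2 is wall_scaling^2.
* Cohorts: Gaussian individual trait values around per-group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .acoustics import AEEventStream, PsiTimeline
from .anatomy import diameter_from_area, hydraulic_diameter
from .flux import WATER_MOLAR_MASS, FluxSeries
from .pv import PVSeries

__all__ = [
    "PVGenParams",
    "AEGenParams",
    "gen_pv_series",
    "gen_ae_stream",
    "gen_mass_series",
    "gen_conduit_population",
    "gen_cohort",
]


@dataclass
class PVGenParams:
    """Ground-truth parameters for one synthetic pressure-volume series.

    ``psi_start_frac`` places the first measurement at that fraction of
    the turgor-loss potential (first psychrometer readings are taken on
    mildly dehydrated tissue, not at psi = 0 where the reciprocal scale
    diverges); ``psi_end_frac`` sets how far past turgor loss the series
    dehydrates.
    """

    psi_osat_true: float = -1.0  # MPa, < 0
    epsilon_true: float = 10.0  # MPa, > 0
    apoplastic_fraction: float = 0.2  # of saturated water content
    n_points: int = 16
    psi_noise_sd: float = 0.0  # MPa
    seed: int = 0
    psi_start_frac: float = 0.5
    psi_end_frac: float = 2.0

    def __post_init__(self) -> None:
        if self.psi_osat_true >= 0:
            raise ValueError("psi_osat_true must be negative")
        if self.epsilon_true <= 0:
            raise ValueError("epsilon_true must be positive")
        if not (0 <= self.apoplastic_fraction < 1):
            raise ValueError("apoplastic_fraction must be in [0, 1)")
        if self.r_s_tlp <= 0:
            raise ValueError(
                "no turgor-loss point in (0, 1]: epsilon too small relative "
                "to |psi_osat|"
            )

    @property
    def r_s_tlp(self) -> float:
        """Relative symplastic water content at turgor loss."""
        return 1.0 + self.psi_osat_true / self.epsilon_true

    @property
    def psi_tlp_true(self) -> float:
        """Closed-form turgor-loss potential (MPa)."""
        return self.psi_osat_true / self.r_s_tlp


def _pv_psi_of_rs(rs: float, params: PVGenParams) -> float:
    turgor = max(0.0, -params.psi_osat_true + params.epsilon_true * (rs - 1.0))
    return turgor + params.psi_osat_true / rs


def gen_pv_series(
    params: PVGenParams,
) -> tuple[PVSeries, dict]:
    """Synthetic dehydration series plus ground-truth trait dictionary."""
    rng = np.random.default_rng(params.seed)
    r_tlp = params.r_s_tlp
    psi_tlp = params.psi_tlp_true
    # first point where psi = psi_start_frac * psi_tlp, found in (r_tlp, 1)
    r_hi = brentq(
        lambda r: _pv_psi_of_rs(r, params) - params.psi_start_frac * psi_tlp,
        r_tlp,
        1.0 - 1e-12,
    )
    # dehydrate along the osmotic branch to psi_end_frac * psi_tlp
    r_lo = params.psi_osat_true / (params.psi_end_frac * psi_tlp)
    n_t = params.n_points // 2
    rs = np.concatenate(
        [
            np.linspace(r_hi, r_tlp + 1e-3, n_t),
            np.linspace(r_tlp - 0.005, r_lo, params.n_points - n_t),
        ]
    )
    psi = np.array([_pv_psi_of_rs(r, params) for r in rs])
    psi = psi + rng.normal(0.0, params.psi_noise_sd, size=psi.size)
    psi = np.minimum(psi, -1e-4)  # keep strictly negative under noise
    af = params.apoplastic_fraction
    rwc_total = af + (1.0 - af) * rs
    # unit weight scale: TW = 1 g, DW = 0 g, FW = RWC
    points = [(float(r), float(p)) for r, p in zip(rwc_total, psi)]
    series = PVSeries(
        sample_id=f"synthetic-pv-{params.seed}",
        turgid_weight=1.0,
        dry_weight=0.0,
        points=points,
    )
    truth = {
        "psi_tlp": psi_tlp,
        "psi_osat": params.psi_osat_true,
        "epsilon": params.epsilon_true,
        "wsd_tlp": 1.0 - (af + (1.0 - af) * r_tlp),
    }
    return series, truth


@dataclass
class AEGenParams:
    """Parameters of a synthetic bench-top dehydration recording."""

    n_conduits: int = 500
    threshold_mode: float = -2.5  # MPa
    threshold_sd: float = 0.3  # MPa
    psi_start: float = -0.5  # MPa
    psi_end: float | None = None  # asymptote; default threshold_mode - 1.5
    duration: float = 21600.0  # s
    decay_shape: float = 3.0  # time constants elapsed over `duration`
    background_rate: float = 0.02  # peak events s-1 at lowest psi
    amplitude_mean: float = 45.0  # dB
    amplitude_sd: float = 8.0  # dB
    anchor_interval: float = 1800.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psi_end is None:
            self.psi_end = self.threshold_mode - 1.5
        if not (self.psi_end < self.psi_start < 0):
            raise ValueError("need psi_end < psi_start < 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.threshold_sd < 0:
            raise ValueError("threshold_sd must be >= 0")

    def psi_at(self, t: np.ndarray | float) -> np.ndarray | float:
        tau = self.duration / self.decay_shape
        return self.psi_end + (self.psi_start - self.psi_end) * np.exp(
            -np.asarray(t, dtype=float) / tau
        )


def gen_ae_stream(
    params: AEGenParams,
) -> tuple[AEEventStream, PsiTimeline, dict]:
    """Synthetic acoustic event stream, psi anchors and ground truth."""
    rng = np.random.default_rng(params.seed)
    tau = params.duration / params.decay_shape
    span = params.psi_start - params.psi_end

    if params.threshold_sd == 0:
        thresholds = np.full(params.n_conduits, params.threshold_mode)
    else:
        b = (0.0 - params.threshold_mode) / params.threshold_sd
        thresholds = truncnorm.rvs(
            -np.inf,
            b,
            loc=params.threshold_mode,
            scale=params.threshold_sd,
            size=params.n_conduits,
            random_state=rng,
        )
    # conduits whose threshold lies at/below the asymptote never cavitate;
    # above the start they click immediately at t=0
    thresholds = np.clip(thresholds, None, params.psi_start)
    reachable = thresholds > params.psi_end
    t_click = -tau * np.log((thresholds[reachable] - params.psi_end) / span)
    amp_click = rng.normal(
        params.amplitude_mean, params.amplitude_sd, size=t_click.size
    )

    bg_t = np.empty(0)
    bg_a = np.empty(0)
    if params.background_rate > 0:
        dt = 10.0
        grid = np.arange(0.0, params.duration, dt)
        psi_g = np.asarray(params.psi_at(grid))
        rate = params.background_rate * (params.psi_start - psi_g) / span
        counts = rng.poisson(rate * dt)
        bg_t = np.repeat(grid, counts) + rng.uniform(0.0, dt, int(counts.sum()))
        bg_a = rng.normal(params.amplitude_mean, params.amplitude_sd, bg_t.size)

    t_all = np.concatenate([t_click, bg_t])
    a_all = np.concatenate([amp_click, bg_a])
    a_all = np.clip(a_all, 0.0, None)
    keep = t_all <= params.duration
    t_all, a_all = t_all[keep], a_all[keep]
    order = np.argsort(t_all)
    events = [(float(t), float(a)) for t, a in zip(t_all[order], a_all[order])]

    anchor_t = np.arange(0.0, params.duration + 1e-9, params.anchor_interval)
    if anchor_t[-1] < params.duration:
        anchor_t = np.append(anchor_t, params.duration)
    anchors = [(float(t), float(params.psi_at(t))) for t in anchor_t]

    stream = AEEventStream(sample_id=f"synthetic-ae-{params.seed}", events=events)
    timeline = PsiTimeline(anchors=anchors)
    truth = {
        "threshold_mode": params.threshold_mode,
        "threshold_sd": params.threshold_sd,
        "n_cavitation_events": int(t_click.size),
        "n_background_events": int(bg_t.size),
    }
    return stream, timeline, truth


def gen_mass_series(
    flow_true: float,
    n: int = 10,
    dt: float = 60.0,
    balance_sd: float = 0.0,
    seed: int = 0,
    leaf_area: float = 1e-4,
    psi_plant: float = -0.5,
    mass0: float = 5.0,
) -> tuple[FluxSeries, dict]:
    """Balance series losing ``flow_true`` mmol s-1 with Gaussian noise."""
    if flow_true < 0:
        raise ValueError("flow_true must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    mass = mass0 - flow_true * WATER_MOLAR_MASS * t
    mass = mass + rng.normal(0.0, balance_sd, size=n)
    series = FluxSeries(
        sample_id=f"synthetic-flux-{seed}",
        masses=[(float(a), float(b)) for a, b in zip(t, mass)],
        leaf_area=leaf_area,
        psi_plant=psi_plant,
    )
    return series, {"flow": flow_true}


def gen_conduit_population(
    n: int = 200,
    log_mu: float = math.log(50.0),
    log_sigma: float = 0.4,
    wall_scaling: float = 0.2,
    shape: str = "circular",
    seed: int = 0,
) -> dict:
    """Lognormal conduit lumen areas with matching wall pairs and truth.

    Returns lumen areas (um2), the corresponding diameters under the
    shape convention, wall (t, b) pairs with t = wall_scaling * b, and
    brute-force ground truth for d_h and (t/b)^2.
    """
    if log_sigma < 0:
        raise ValueError("log_sigma must be >= 0")
    if not (0 < wall_scaling < 1):
        raise ValueError("wall_scaling must be in (0, 1)")
    rng = np.random.default_rng(seed)
    areas = np.exp(rng.normal(log_mu, log_sigma, size=n))
    diameters = np.array([diameter_from_area(a, shape) for a in areas])
    b = diameters.copy()
    t = wall_scaling * b
    truth_dh = float(np.sum(diameters**5) / np.sum(diameters**4))
    return {
        "lumen_areas": areas,
        "diameters": diameters,
        "wall_pairs": list(zip(t.tolist(), b.tolist())),
        "shape": shape,
        "truth": {
            "d_h": truth_dh,
            "t_b_sq": wall_scaling**2,
            "d_mean": float(np.mean(diameters)),
            "d_max": float(np.max(diameters)),
        },
    }


def gen_cohort(
    design: list[dict],
    seed: int = 0,
) -> "pd.DataFrame":
    """Long-format cohort table from a per-group design.

    ``design`` rows: dicts with species, lineage, growth_form, age_weeks,
    trait, mean, sd, n.  Individual values are Gaussian around the group
    mean; sd = 0 reproduces the means exactly.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for spec in design:
        vals = rng.normal(spec["mean"], spec["sd"], size=spec["n"])
        for i, v in enumerate(vals):
            rows.append(
                {
                    "species": spec["species"],
                    "lineage": spec["lineage"],
                    "growth_form": spec.get("growth_form", ""),
                    "age_weeks": spec["age_weeks"],
                    "individual_id": f"{spec['species']}-{spec['age_weeks']}-{i}",
                    "trait": spec["trait"],
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows)
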