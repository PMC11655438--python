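"""Xylem anatomy indices of seedling hypocotyl cross sections.

Inputs are already-measured geometries: pith and pith+xylem disc
diameters at four positions, conduit lumen areas, and (double wall
thickness, largest-conduit diameter) pairs per conduit group.  Computed
traits:

* A_xyl  -- annulus xylem area, pi/4 * (d_xp^2 - d_p^2), averaged
  diameters first (mm2),
* d      -- conduit diameter from lumen area under the lineage shape
  convention (square tracheids for conifers, circular vessels for
  angiosperms),
* d_h    -- hydraulically weighted diameter, sum(d^5)/sum(d^4),
* (t/b)^2 -- cell wall reinforcement,
* HV     -- Huber value, mean A_xyl over mean leaf area.

To avoid weighting individuals by their conduit counts, traits are
averaged per individual first and only then per species x age group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .flux import GroupRatioTrait, group_ratio_trait

__all__ = [
    "CrossSection",
    "AnatomyTraits",
    "annulus_area",
    "diameter_from_area",
    "area_from_diameter",
    "hierarchical_mean",
    "hydraulic_diameter",
    "wall_reinforcement",
    "huber_value",
    "section_traits",
]

UM2_PER_MM2 = 1e6
HV_DISPLAY_SCALE = 1e-4  # Huber values reported in units of 1e-4 m2 m-2


@dataclass
class CrossSection:
    """Geometric measurements of one hypocotyl transverse section."""

    individual_id: str
    species: str
    age_weeks: int
    d_xp: Sequence[float]  # pith+xylem disc diameters, 4 directions, um
    d_p: Sequence[float]  # pith diameters, same directions, um
    lumen_areas: Sequence[float] = field(default_factory=list)  # um2
    shape: str = "circular"  # "square" (conifers) | "circular" (angiosperms)
    wall_pairs: Sequence[tuple[float, float]] = field(default_factory=list)  # (t, b) um

    def __post_init__(self) -> None:
        if len(self.d_xp) != 4 or len(self.d_p) != 4:
            raise ValueError("need diameters in 4 directions for disc and pith")
        for dxp, dp in zip(self.d_xp, self.d_p):
            if dxp < dp:
                raise ValueError(
                    f"{self.individual_id}: disc diameter {dxp} um smaller than "
                    f"pith diameter {dp} um"
                )
        if any(a <= 0 for a in self.lumen_areas):
            raise ValueError(f"{self.individual_id}: lumen areas must be positive")
        if self.shape not in ("square", "circular"):
            raise ValueError(f"unknown conduit shape {self.shape!r}")
        for t, b in self.wall_pairs:
            if b <= 0:
                raise ValueError(f"{self.individual_id}: conduit span b must be > 0")
            if t >= b:
                raise ValueError(
                    f"{self.individual_id}: double wall thickness {t} um must be "
                    f"below conduit span {b} um"
                )


@dataclass
class AnatomyTraits:
    a_xyl: float  # mm2
    d_mean: float  # um
    d_h: float  # um
    d_max: float  # um
    t_b_sq: float  # dimensionless

    def __post_init__(self) -> None:
        if self.a_xyl < 0:
            raise ValueError("xylem area cannot be negative")
        tol = 1e-9 * max(self.d_max, 1.0)
        if not (self.d_max >= self.d_h - tol and self.d_h >= self.d_mean - tol and self.d_mean > 0):
            raise ValueError(
                f"conduit diameters must satisfy d_max >= d_h >= d_mean > 0, "
                f"got {self.d_max}, {self.d_h}, {self.d_mean}"
            )
        if not math.isnan(self.t_b_sq) and self.t_b_sq <= 0:
            raise ValueError("wall reinforcement must be positive")


def annulus_area(section: CrossSection) -> float:
    """Xylem area (mm2) as an annulus between averaged disc and pith discs.

    The four directional diameters are averaged first, then
    A_xyl = pi/4 * (mean(d_xp)^2 - mean(d_p)^2).
    """
    d_xp = float(np.mean(section.d_xp))
    d_p = float(np.mean(section.d_p))
    if d_xp < d_p:
        raise ValueError(
            f"{section.individual_id}: averaged disc diameter below pith diameter"
        )
    area_um2 = math.pi / 4.0 * (d_xp**2 - d_p**2)
    return area_um2 / UM2_PER_MM2


def diameter_from_area(area: float, shape: str) -> float:
    """Conduit diameter (um) from lumen area (um2) under a shape convention."""
    if area <= 0:
        raise ValueError(f"lumen area must be positive, got {area}")
    if shape == "square":
        return math.sqrt(area)
    if shape == "circular":
        return 2.0 * math.sqrt(area / math.pi)
    raise ValueError(f"unknown conduit shape {shape!r}")


def area_from_diameter(d: float, shape: str) -> float:
    """Inverse of :func:`diameter_from_area` (round-trip identity)."""
    if shape == "square":
        return d * d
    if shape == "circular":
        return math.pi * (d / 2.0) ** 2
    raise ValueError(f"unknown conduit shape {shape!r}")


def hierarchical_mean(values_by_individual: dict[str, Iterable[float]]) -> float:
    """Mean of per-individual means, unweighted by observation count.

    Guards against the silent pooling that would over-weight individuals
    with many measured conduits.
    """
    if not values_by_individual:
        raise ValueError("no individuals to average")
    means = []
    for ind, vals in values_by_individual.items():
        v = list(vals)
        if not v:
            raise ValueError(f"individual {ind} has no values")
        means.append(float(np.mean(v)))
    return float(np.mean(means))


def hydraulic_diameter(diameters: Sequence[float]) -> float:
    """Hydraulically weighted mean diameter d_h = sum(d^5)/sum(d^4) (um)."""
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("empty diameter list")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    return float(np.sum(d**5) / np.sum(d**4))


def wall_reinforcement(wall_pairs: Sequence[tuple[float, float]]) -> float:
    """Section-level cell wall reinforcement: mean of per-pair (t/b)^2."""
    if not wall_pairs:
        raise ValueError("no wall thickness/span pairs")
    vals = []
    for t, b in wall_pairs:
        if b <= 0:
            raise ValueError(f"conduit span b must be positive, got {b}")
        vals.append((t / b) ** 2)
    return float(np.mean(vals))


def huber_value(
    a_xyl_mean: float,
    a_xyl_se: float,
    n_axyl: int,
    la_mean: float,
    la_se: float,
    n_la: int,
    display_scale: float = HV_DISPLAY_SCALE,
) -> GroupRatioTrait:
    """Huber value: mean xylem area over mean leaf area.

    ``a_xyl_mean``/``a_xyl_se`` in mm2, ``la_mean``/``la_se`` in cm2.  The
    raw ratio is dimensionless (m2 m-2); for reporting it is divided by
    ``display_scale`` (default 1e-4, the scale on which the published
    group values are internally consistent).
    """
    if la_mean <= 0:
        raise ValueError(f"leaf area mean must be positive, got {la_mean}")
    a_m2 = a_xyl_mean * 1e-6
    a_se_m2 = a_xyl_se * 1e-6
    la_m2 = la_mean * 1e-4
    la_se_m2 = la_se * 1e-4
    raw = group_ratio_trait(a_m2, a_se_m2, n_axyl, la_m2, la_se_m2, n_la)
    return GroupRatioTrait(
        value=raw.value / display_scale,
        se=raw.se / display_scale,
        n_num=n_axyl,
        n_den=n_la,
    )


def section_traits(section: CrossSection) -> AnatomyTraits:
    """All per-section anatomy traits for one cross section."""
    diam = [diameter_from_area(a, section.shape) for a in section.lumen_areas]
    if not diam:
        raise ValueError(f"{section.individual_id}: no conduit lumen areas")
    return AnatomyTraits(
        a_xyl=annulus_area(section),
        d_mean=float(np.mean(diam)),
        d_h=hydraulic_diameter(diam),
        d_max=float(np.max(diam)),
        t_b_sq=wall_reinforcement(section.wall_pairs)
        if section.wall_pairs
        else float("nan"),
    )
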