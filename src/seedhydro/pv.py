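"""Pressure-volume curve analysis.

A leaf (or needle) sample is repeatedly weighed and its water potential
measured while it dehydrates on the bench.  Plotting reciprocal water
potential against water saturation deficit (WSD) separates the trajectory
into a curved *turgescent* section (cells still hold turgor) and a linear
*osmotic* section (turgor lost, potential purely osmotic).  From the two
fitted sections we extract

* ``psi_tlp`` -- water potential at the turgor loss point (MPa), the
  intersection of the two fits,
* ``psi_osat`` -- osmotic potential at full saturation (MPa), the osmotic
  line's intercept at WSD = 0, back-transformed from reciprocal scale,
* ``epsilon`` -- bulk modulus of elasticity (MPa), the slope of turgor
  pressure against relative water content over the turgescent points.

The turgescent section is fitted with a parabola and the osmotic section
with an ordinary least-squares line, the boundary between them chosen by
an exhaustive split search minimising the pooled residual sum of squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PVSeries",
    "PVTraits",
    "PsychrometerCalibration",
    "PVFitError",
    "compute_wsd",
    "apply_calibration",
    "pool_series",
    "fit_pv_curve",
    "summarize_pv",
]


class PVFitError(RuntimeError):
    """Raised when no valid turgescent/osmotic segmentation exists."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class PsychrometerCalibration:
    """Linear map from thermocouple psychrometer microvolt output to MPa."""

    slope: float  # MPa per uV
    intercept: float = 0.0  # MPa
    valid_range: tuple[float, float] = (-math.inf, math.inf)  # uV

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")


@dataclass
class PVSeries:
    """One sample's dehydration trajectory.

    ``points`` holds (fresh weight g, water potential MPa) pairs in
    measurement order, i.e. non-increasing fresh weight.
    """

    sample_id: str
    turgid_weight: float  # g
    dry_weight: float  # g
    points: list[tuple[float, float]]
    species: str | None = None
    age_weeks: int | None = None
    pooled_from: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.turgid_weight <= self.dry_weight:
            raise ValueError(
                f"sample {self.sample_id}: turgid weight "
                f"{self.turgid_weight} g must exceed dry weight {self.dry_weight} g"
            )
        fws = [fw for fw, _ in self.points]
        for i, (fw, psi) in enumerate(self.points):
            if not (self.dry_weight < fw <= self.turgid_weight):
                raise ValueError(
                    f"sample {self.sample_id}, point {i}: fresh weight {fw} g "
                    f"outside (DW={self.dry_weight}, TW={self.turgid_weight}]"
                )
            if psi >= 0:
                raise ValueError(
                    f"sample {self.sample_id}, point {i}: water potential {psi} "
                    "MPa must be negative"
                )
        if any(a < b for a, b in zip(fws, fws[1:])):
            raise ValueError(
                f"sample {self.sample_id}: fresh weights must be non-increasing"
            )


@dataclass
class PVTraits:
    """Traits extracted from one (pooled) pressure-volume curve."""

    psi_tlp: float  # MPa
    psi_osat: float  # MPa
    epsilon: float  # MPa
    wsd_tlp: float  # fraction
    split_index: int
    fit_rss: float  # on reciprocal-MPa scale
    n_turgescent: int
    n_osmotic: int
    sample_id: str = ""
    species: str | None = None
    age_weeks: int | None = None

    def __post_init__(self) -> None:
        if not (self.psi_tlp <= self.psi_osat < 0):
            raise ValueError(
                f"invalid PV traits: psi_tlp={self.psi_tlp} must be <= "
                f"psi_osat={self.psi_osat} < 0"
            )
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if not (0 < self.wsd_tlp < 1):
            raise ValueError(f"wsd_tlp must be in (0, 1), got {self.wsd_tlp}")


def compute_wsd(series: PVSeries) -> list[tuple[float, float]]:
    """Water saturation deficit for every point of a dehydration series.

    WSD_i = (TW - FW_i) / (TW - DW); relative water content is 1 - WSD.
    Returns (wsd, psi) pairs in the original measurement order.
    """
    tw, dw = series.turgid_weight, series.dry_weight
    span = tw - dw
    return [((tw - fw) / span, psi) for fw, psi in series.points]


def apply_calibration(
    readings: list[float] | np.ndarray, cal: PsychrometerCalibration
) -> list[float]:
    """Convert raw psychrometer uV readings to water potentials (MPa)."""
    lo, hi = cal.valid_range
    out = []
    for r in readings:
        if not (lo <= r <= hi):
            warnings.warn(
                f"psychrometer reading {r} uV outside calibrated range "
                f"[{lo}, {hi}]",
                stacklevel=2,
            )
        out.append(cal.slope * r + cal.intercept)
    return out


def pool_series(a: PVSeries, b: PVSeries, *more: PVSeries) -> PVSeries:
    """Pool samples of the same species and age class into one curve.

    Each sample is normalised to WSD by its own turgid and dry weights
    before the point sets are merged and re-sorted by increasing WSD.
    The measurement protocol pools exactly two; other counts are
    accepted with a warning.
    """
    samples = (a, b) + more
    key = (a.species, a.age_weeks)
    for s in samples[1:]:
        if (s.species, s.age_weeks) != key:
            raise ValueError(
                f"cannot pool {a.sample_id} ({a.species}, week {a.age_weeks}) "
                f"with {s.sample_id} ({s.species}, week {s.age_weeks})"
            )
    if len(samples) != 2:
        warnings.warn(
            f"pooling {len(samples)} samples; the protocol pools two",
            stacklevel=2,
        )
    merged = []
    for s in samples:
        merged.extend(compute_wsd(s))
    merged.sort(key=lambda p: p[0])
    # Re-express as a pseudo-series on the unit weight scale: TW=1, DW=0,
    # FW = 1 - wsd, so compute_wsd on the pooled series returns the
    # per-sample-normalised WSD values unchanged.
    points = [(1.0 - wsd, psi) for wsd, psi in merged]
    points.sort(key=lambda p: -p[0])
    return PVSeries(
        sample_id="+".join(s.sample_id for s in samples),
        turgid_weight=1.0,
        dry_weight=0.0,
        points=points,
        species=a.species,
        age_weeks=a.age_weeks,
        pooled_from=[s.sample_id for s in samples],
    )


def _segment_fits(x: np.ndarray, y: np.ndarray, k: int):
    # candidate splits routinely produce ill-conditioned segments during
    # the exhaustive search; only the winning split's fit matters
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        quad = np.polyfit(x[:k], y[:k], 2)
        line = np.polyfit(x[k:], y[k:], 1)
    rss = float(
        np.sum((np.polyval(quad, x[:k]) - y[:k]) ** 2)
        + np.sum((np.polyval(line, x[k:]) - y[k:]) ** 2)
    )
    return rss, quad, line


def _intersection(
    x: np.ndarray, quad: np.ndarray, line: np.ndarray, k: int
) -> float | None:
    """Root of quadratic - line nearest the split midpoint, or None.

    Accepts roots inside a one-point-widened bracket around the split so
    that noise cannot push a genuine intersection just outside the
    boundary pair.
    """
    a, b, c = quad
    m, q = line
    roots = np.roots([a, b - m, c - q])
    roots = roots[np.isreal(roots)].real
    n = len(x)
    lo = x[max(k - 2, 0)]
    hi = x[min(k + 1, n - 1)]
    ok = [r for r in roots if lo - 1e-12 <= r <= hi + 1e-12]
    if not ok:
        return None
    mid = 0.5 * (x[k - 1] + x[k])
    return float(min(ok, key=lambda r: abs(r - mid)))


def fit_pv_curve(
    points: list[tuple[float, float]],
    min_segment: int = 3,
    epsilon_mode: str = "turgor",
    sample_id: str = "",
    species: str | None = None,
    age_weeks: int | None = None,
) -> PVTraits:
    """Segment a (wsd, psi) series and extract pressure-volume traits.

    Works on reciprocal scale (y = 1/psi vs x = wsd).  Every admissible
    split with at least ``min_segment`` points per segment is scored by
    the pooled RSS of a quadratic (turgescent) plus line (osmotic) fit;
    the minimum-RSS split wins.  The turgor loss point is the real
    intersection of the two fits nearest the split; if the best split's
    fits do not intersect, later splits are tried in RSS order, and as a
    last resort the closest-approach point of the best split's fits
    inside the bracket is used.

    ``epsilon_mode``: ``"turgor"`` regresses turgor pressure
    psi - psi_pi(wsd) on relative water content over the turgescent
    points (psi_pi back-transformed from the osmotic line);
    ``"raw"`` uses the slope of psi itself vs relative water content.
    """
    if epsilon_mode not in ("turgor", "raw"):
        raise ValueError(f"unknown epsilon_mode {epsilon_mode!r}")
    wsd = np.asarray([p[0] for p in points], dtype=float)
    psi = np.asarray([p[1] for p in points], dtype=float)
    if np.any(psi >= 0):
        raise ValueError("all water potentials must be negative")
    if np.any(wsd < 0) or np.any(wsd >= 1):
        raise ValueError("wsd values must lie in [0, 1)")
    order = np.argsort(wsd)
    x = wsd[order]
    y = 1.0 / psi[order]
    n = len(x)
    if n < 2 * min_segment:
        raise ValueError(
            f"need at least {2 * min_segment} points, got {n}"
        )
    if len(np.unique(x)) < n:
        # exact duplicates are fine for regression; strictly decreasing FW
        # was already enforced upstream, so only warn here
        warnings.warn("duplicate wsd values in PV series", stacklevel=2)

    candidates = []
    for k in range(min_segment, n - min_segment + 1):
        rss, quad, line = _segment_fits(x, y, k)
        candidates.append((rss, k, quad, line))
    candidates.sort(key=lambda t: t[0])

    chosen = None
    for rss, k, quad, line in candidates:
        xs = _intersection(x, quad, line, k)
        if xs is not None:
            chosen = (rss, k, quad, line, xs)
            break
    if chosen is None:
        # closest approach of the best-RSS split's two fits
        rss, k, quad, line = candidates[0]
        lo, hi = x[max(k - 2, 0)], x[min(k + 1, n - 1)]
        res = minimize_scalar(
            lambda t: abs(np.polyval(quad, t) - np.polyval(line, t)),
            bounds=(lo, hi),
            method="bounded",
        )
        if not res.success:
            raise PVFitError(
                "no split yields an intersection between the parabolic and "
                "linear sections",
                diagnostics={"n": n, "best_rss": rss, "best_split": k},
            )
        chosen = (rss, k, quad, line, float(res.x))

    rss, k, quad, line, wsd_tlp = chosen
    m, q = line
    y_tlp = m * wsd_tlp + q
    if y_tlp >= 0 or q >= 0:
        raise PVFitError(
            "osmotic line implies non-negative water potential",
            diagnostics={"line": (m, q), "wsd_tlp": wsd_tlp},
        )
    psi_tlp = 1.0 / y_tlp
    psi_osat = 1.0 / q

    # modulus of elasticity over the turgescent points
    rwc_t = 1.0 - x[:k]
    psi_t = 1.0 / y[:k]
    if epsilon_mode == "turgor":
        psi_pi = 1.0 / (m * x[:k] + q)
        response = psi_t - psi_pi  # turgor pressure
    else:
        response = psi_t
    eps_slope = float(np.polyfit(rwc_t, response, 1)[0])

    return PVTraits(
        psi_tlp=min(psi_tlp, psi_osat),  # numerical guard, equal at worst
        psi_osat=psi_osat,
        epsilon=eps_slope,
        wsd_tlp=wsd_tlp,
        split_index=k,
        fit_rss=rss,
        n_turgescent=k,
        n_osmotic=n - k,
        sample_id=sample_id,
        species=species,
        age_weeks=age_weeks,
    )


def summarize_pv(traits: list[PVTraits]) -> "pd.DataFrame":
    """Mean and SE (SD/sqrt(n)) of PV traits per species x age class."""
    import pandas as pd

    rows = [
        {
            "species": t.species,
            "age_weeks": t.age_weeks,
            "psi_tlp": t.psi_tlp,
            "psi_osat": t.psi_osat,
            "epsilon": t.epsilon,
        }
        for t in traits
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        warnings.warn("no PV traits to summarize", stacklevel=2)
        return df

    def _agg(g):
        out = {}
        for c in ("psi_tlp", "psi_osat", "epsilon"):
            v = g[c].to_numpy(dtype=float)
            out[f"{c}_mean"] = float(np.mean(v))
            out[f"{c}_se"] = (
                float(np.std(v, ddof=1) / math.sqrt(len(v)))
                if len(v) > 1
                else float("nan")
            )
        out["n"] = len(g)
        return pd.Series(out)

    return (
        df.groupby(["species", "age_weeks"], dropna=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
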