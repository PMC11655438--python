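"""End-to-end pipeline over plain CSV inputs.

CSV dialect: UTF-8, comma-separated, '.' decimal, mandatory header row;
water potentials negative MPa; times in seconds from recording start.

Input schemas (any subset of stages may be present):
  pv_points.csv   sample_id, species, age_weeks, turgid_weight_g,
                  dry_weight_g, fresh_weight_g, psi_mpa
  flux.csv        sample_id, species, age_weeks, time_s, mass_g
  flux_meta.csv   sample_id, leaf_area_cm2, psi_plant_mpa
  ae_events.csv   sample_id, time_s, amplitude_db
  psi_anchors.csv sample_id, time_s, psi_mpa
  sections.csv    individual_id, species, age_weeks, direction,
                  d_xp_um, d_p_um
  conduits.csv    individual_id, lumen_area_um2
  walls.csv       individual_id, group_idx, t_um, b_um
  leaf_area.csv   individual_id, la_cm2
  cohort.csv      species, lineage, growth_form, age_weeks,
                  individual_id, trait, value
"""

from __future__ import annotations

import itertools
import json
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acoustics import AEEventStream, PsiTimeline, analyse_stream
from .anatomy import (
    CrossSection,
    annulus_area,
    diameter_from_area,
    hydraulic_diameter,
    wall_reinforcement,
)
from .cohort import screen_and_compare, trait_correlations
from .flux import FluxSeries, analyse_series
from .pv import PVSeries, fit_pv_curve, compute_wsd, pool_series, summarize_pv

__all__ = ["PipelineConfig", "run_pipeline", "run_pv", "run_flux", "run_uae",
           "run_anatomy", "run_cohort"]


@dataclass
class PipelineConfig:
    out_dir: Path
    pv_points: Path | None = None
    flux: Path | None = None
    flux_meta: Path | None = None
    ae_events: Path | None = None
    psi_anchors: Path | None = None
    sections: Path | None = None
    conduits: Path | None = None
    walls: Path | None = None
    leaf_area: Path | None = None
    cohort: Path | None = None
    shape_by_species: dict[str, str] = field(default_factory=dict)
    lineage_by_species: dict[str, str] = field(default_factory=dict)
    min_segment: int = 3
    epsilon_mode: str = "turgor"
    window_bins: int = 11
    polyorder: int = 3
    alpha: float = 0.05
    hv_display_scale: float = 1e-4
    seed: int = 0
    make_plots: bool = True

    def validate(self) -> None:
        for name in ("pv_points", "flux", "flux_meta", "ae_events",
                     "psi_anchors", "sections", "conduits", "walls",
                     "leaf_area", "cohort"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input {name} = {p} does not exist")
        for sp, shape in self.shape_by_species.items():
            if shape not in ("square", "circular"):
                raise ValueError(
                    f"unknown conduit shape {shape!r} for species {sp!r}"
                )


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def run_pv(config: PipelineConfig) -> pd.DataFrame:
    """Fit every pooled pressure-volume curve and write trait tables."""
    df = pd.read_csv(config.pv_points)
    _require_columns(
        df,
        ["sample_id", "species", "age_weeks", "turgid_weight_g",
         "dry_weight_g", "fresh_weight_g", "psi_mpa"],
        config.pv_points,
    )
    series = []
    for sid, grp in df.groupby("sample_id", sort=True):
        series.append(
            PVSeries(
                sample_id=str(sid),
                turgid_weight=float(grp["turgid_weight_g"].iloc[0]),
                dry_weight=float(grp["dry_weight_g"].iloc[0]),
                points=list(zip(grp["fresh_weight_g"], grp["psi_mpa"])),
                species=str(grp["species"].iloc[0]),
                age_weeks=int(grp["age_weeks"].iloc[0]),
            )
        )
    # pool within species x age class in sample order, two at a time
    traits = []
    keyfun = lambda s: (s.species, s.age_weeks)
    for key, members in itertools.groupby(sorted(series, key=keyfun), keyfun):
        members = list(members)
        for i in range(0, len(members) - 1, 2):
            pooled = pool_series(members[i], members[i + 1])
            t = fit_pv_curve(
                compute_wsd(pooled),
                min_segment=config.min_segment,
                epsilon_mode=config.epsilon_mode,
                sample_id=pooled.sample_id,
                species=key[0],
                age_weeks=key[1],
            )
            traits.append(t)
        if len(members) % 2:
            warnings.warn(
                f"{key}: odd sample left unpooled and unfitted", stacklevel=2
            )
    out = pd.DataFrame(
        [
            {
                "sample_id": t.sample_id,
                "species": t.species,
                "age_weeks": t.age_weeks,
                "psi_tlp_mpa": t.psi_tlp,
                "psi_osat_mpa": t.psi_osat,
                "epsilon_mpa": t.epsilon,
                "wsd_tlp": t.wsd_tlp,
                "split_index": t.split_index,
                "fit_rss": t.fit_rss,
                "n_turgescent": t.n_turgescent,
                "n_osmotic": t.n_osmotic,
            }
            for t in traits
        ]
    )
    out.to_csv(config.out_dir / "pv_traits.csv", index=False)
    summarize_pv(traits).to_csv(config.out_dir / "pv_groups.csv", index=False)
    return out


def run_flux(config: PipelineConfig) -> pd.DataFrame:
    df = pd.read_csv(config.flux)
    meta = pd.read_csv(config.flux_meta).set_index("sample_id")
    _require_columns(df, ["sample_id", "time_s", "mass_g"], config.flux)
    _require_columns(
        meta.reset_index(),
        ["sample_id", "leaf_area_cm2", "psi_plant_mpa"],
        config.flux_meta,
    )
    rows = []
    for sid, grp in df.groupby("sample_id", sort=True):
        m = meta.loc[sid]
        fs = FluxSeries(
            sample_id=str(sid),
            masses=list(zip(grp["time_s"], grp["mass_g"])),
            leaf_area=float(m["leaf_area_cm2"]) * 1e-4,
            psi_plant=float(m["psi_plant_mpa"]),
            species=str(grp["species"].iloc[0]) if "species" in grp else None,
            age_weeks=int(grp["age_weeks"].iloc[0]) if "age_weeks" in grp else None,
        )
        r = analyse_series(fs, alpha=config.alpha)
        rows.append(
            {
                "sample_id": r.sample_id,
                "species": fs.species,
                "age_weeks": fs.age_weeks,
                "flow_mmol_s": r.flow,
                "k_shoot": r.k_shoot,
                "k_shoot_l": r.k_shoot_l,
                "steady": r.steady,
                "slope_drift_p": r.slope_drift_p,
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(config.out_dir / "conductance.csv", index=False)
    return out


def run_uae(config: PipelineConfig) -> pd.DataFrame:
    events = pd.read_csv(config.ae_events)
    anchors = pd.read_csv(config.psi_anchors)
    _require_columns(events, ["sample_id", "time_s", "amplitude_db"], config.ae_events)
    _require_columns(anchors, ["sample_id", "time_s", "psi_mpa"], config.psi_anchors)
    rows = []
    traces = []
    for sid, grp in events.groupby("sample_id", sort=True):
        anch = anchors[anchors["sample_id"] == sid].sort_values("time_s")
        if len(anch) < 2:
            raise ValueError(
                f"{config.psi_anchors}: sample {sid} needs >= 2 psi anchors"
            )
        stream = AEEventStream(
            sample_id=str(sid),
            events=list(zip(grp["time_s"], grp["amplitude_db"])),
        )
        timeline = PsiTimeline(anchors=list(zip(anch["time_s"], anch["psi_mpa"])))
        result, series = analyse_stream(
            stream,
            timeline,
            window_bins=config.window_bins,
            polyorder=config.polyorder,
        )
        rows.append(
            {
                "sample_id": result.sample_id,
                "psi_aeamax_mpa": result.psi_aeamax,
                "n_events": result.n_events,
                "tail_monotone": result.tail_monotone,
                "peaks": json.dumps(
                    [[round(p, 6) for p in pk] for pk in result.peaks]
                ),
            }
        )
        tr = pd.DataFrame(
            {
                "sample_id": result.sample_id,
                "t_mid_s": series.t_mid,
                "psi_mid_mpa": series.psi_mid,
                "count": series.counts,
                "smoothed": series.smoothed,
            }
        )
        traces.append(tr)
        if config.make_plots:
            _plot_activity(series, result, config.out_dir)
    out = pd.DataFrame(rows)
    out.to_csv(config.out_dir / "vulnerability.csv", index=False)
    pd.concat(traces).to_csv(config.out_dir / "activity_traces.csv", index=False)
    return out


def _plot_activity(series, result, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(series.psi_mid, series.counts, "ko", ms=3, label="5-min activity")
    ax.plot(series.psi_mid, series.smoothed, "-", color="grey", label="smoothed")
    ax.axvline(result.psi_aeamax, color="red", lw=1)
    ax.set_xlabel("water potential (MPa)")
    ax.set_ylabel("events / 5 min")
    ax.invert_xaxis()
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / f"activity_{series.sample_id}.png", dpi=120)
    plt.close(fig)


def run_anatomy(config: PipelineConfig) -> pd.DataFrame:
    sections = pd.read_csv(config.sections)
    conduits = pd.read_csv(config.conduits)
    _require_columns(
        sections,
        ["individual_id", "species", "age_weeks", "direction", "d_xp_um", "d_p_um"],
        config.sections,
    )
    _require_columns(conduits, ["individual_id", "lumen_area_um2"], config.conduits)
    walls = pd.read_csv(config.walls) if config.walls else None
    species_of = sections.set_index("individual_id")["species"].to_dict()
    for sp in set(species_of.values()):
        if sp not in config.shape_by_species:
            raise ValueError(
                f"no conduit shape configured for species {sp!r}; add it to "
                "shape_by_species"
            )
    rows = []
    for ind, grp in sections.groupby("individual_id", sort=True):
        if len(grp) != 4:
            raise ValueError(
                f"{config.sections}: individual {ind} needs 4 directional "
                f"measurements, got {len(grp)}"
            )
        shape = config.shape_by_species[species_of[ind]]
        lum = conduits.loc[
            conduits["individual_id"] == ind, "lumen_area_um2"
        ].to_numpy(dtype=float)
        wp = []
        if walls is not None:
            w = walls[walls["individual_id"] == ind]
            wp = list(zip(w["t_um"], w["b_um"]))
        sec = CrossSection(
            individual_id=str(ind),
            species=species_of[ind],
            age_weeks=int(grp["age_weeks"].iloc[0]),
            d_xp=grp["d_xp_um"].tolist(),
            d_p=grp["d_p_um"].tolist(),
            lumen_areas=lum.tolist(),
            shape=shape,
            wall_pairs=wp,
        )
        d = [diameter_from_area(a, shape) for a in lum]
        rows.append(
            {
                "individual_id": sec.individual_id,
                "species": sec.species,
                "age_weeks": sec.age_weeks,
                "a_xyl_mm2": annulus_area(sec),
                "d_mean_um": float(np.mean(d)) if d else float("nan"),
                "d_h_um": hydraulic_diameter(d) if d else float("nan"),
                "d_max_um": float(np.max(d)) if d else float("nan"),
                "t_b_sq": wall_reinforcement(wp) if wp else float("nan"),
                "n_conduits": len(d),
            }
        )
    per_ind = pd.DataFrame(rows)
    per_ind.to_csv(config.out_dir / "anatomy_individuals.csv", index=False)
    group = (
        per_ind.groupby(["species", "age_weeks"])
        .agg(
            a_xyl_mm2=("a_xyl_mm2", "mean"),
            a_xyl_se=("a_xyl_mm2", "sem"),
            d_mean_um=("d_mean_um", "mean"),
            d_mean_se=("d_mean_um", "sem"),
            d_h_um=("d_h_um", "mean"),
            d_h_se=("d_h_um", "sem"),
            d_max_um=("d_max_um", "max"),
            t_b_sq=("t_b_sq", "mean"),
            t_b_sq_se=("t_b_sq", "sem"),
            n=("individual_id", "count"),
        )
        .reset_index()
    )
    group.to_csv(config.out_dir / "anatomy_traits.csv", index=False)
    return group


def run_cohort(config: PipelineConfig) -> pd.DataFrame:
    table = pd.read_csv(config.cohort)
    _require_columns(
        table,
        ["species", "age_weeks", "individual_id", "trait", "value"],
        config.cohort,
    )
    rows = []
    for (sp, trait), _ in table.groupby(["species", "trait"]):
        try:
            cmp_ = screen_and_compare(table, trait, sp, alpha=config.alpha)
        except ValueError as e:
            warnings.warn(str(e), stacklevel=2)
            continue
        for g in cmp_.groups:
            sub = table[
                (table["species"] == sp)
                & (table["trait"] == trait)
                & (table["age_weeks"] == g)
            ]["value"]
            rows.append(
                {
                    "species": sp,
                    "trait": trait,
                    "age_weeks": g,
                    "mean": float(sub.mean()),
                    "se": float(sub.sem()),
                    "n": int(len(sub)),
                    "letters": cmp_.letters[g],
                    "test_used": cmp_.test_used,
                    "levene_p": cmp_.levene_p,
                }
            )
    out = pd.DataFrame(rows)
    out.to_csv(config.out_dir / "cohort_comparisons.csv", index=False)

    # group-mean correlations across species x age classes
    means = (
        table.groupby(["species", "age_weeks", "trait"])["value"]
        .mean()
        .unstack("trait")
        .reset_index()
    )
    if "lineage" in table.columns:
        means["lineage"] = means["species"].map(
            table.drop_duplicates("species").set_index("species")["lineage"]
        )
        traits = [c for c in means.columns
                  if c not in ("species", "age_weeks", "lineage")]
        if len(traits) >= 2:
            corr = trait_correlations(means, traits, traits)
            corr.to_csv(config.out_dir / "trait_correlations.csv", index=False)
    return out


_STAGES = {
    "pv": (run_pv, ("pv_points",)),
    "flux": (run_flux, ("flux", "flux_meta")),
    "uae": (run_uae, ("ae_events", "psi_anchors")),
    "anatomy": (run_anatomy, ("sections", "conduits")),
    "cohort": (run_cohort, ("cohort",)),
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are configured; write a run log.

    Returns {stage: output DataFrame}.  Raises on the first stage
    failure after logging it.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = {}
    log = {
        "seedhydro_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "alpha": config.alpha,
        "window_bins": config.window_bins,
        "polyorder": config.polyorder,
        "epsilon_mode": config.epsilon_mode,
        "hv_display_scale": config.hv_display_scale,
        "stages": {},
    }
    try:
        for name, (fn, required) in _STAGES.items():
            if all(getattr(config, r) is not None for r in required):
                results[name] = fn(config)
                log["stages"][name] = "ok"
            else:
                log["stages"][name] = "skipped (inputs not configured)"
    finally:
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2)
    return results
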