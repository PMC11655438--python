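"""Synthetic CSV bundles in the schemas the pipeline stages read.

Convenience layer over :mod:`seedhydro.simulate`: draws a small study
(two species, two age classes) and writes the stage input CSVs plus a
``truth_*.json``-style CSV of generator ground truths, so the full
pipeline can be smoke-tested end to end without any external data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import (
    AEGenParams,
    PVGenParams,
    gen_ae_stream,
    gen_conduit_population,
    gen_mass_series,
    gen_pv_series,
)

__all__ = ["write_synthetic"]

_SPECIES = [("Picea abies", "conifer", "square"),
            ("Acer pseudoplatanus", "angiosperm", "circular")]
_AGES = [4, 22]


def _pv_bundle(out: Path, seed: int) -> list[Path]:
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for si, (sp, lin, _) in enumerate(_SPECIES):
        for ai, age in enumerate(_AGES):
            osat = -0.7 - 0.3 * ai
            for rep in range(4):  # two pooled pairs per group
                sub = int(rng.integers(0, 2**31 - 1))
                params = PVGenParams(
                    psi_osat_true=osat, epsilon_true=8.0 + 4.0 * ai,
                    psi_noise_sd=0.02, seed=sub,
                )
                series, t = gen_pv_series(params)
                sid = f"{sp.split()[0]}-{age}w-{rep}"
                for fw, psi in series.points:
                    rows.append(
                        dict(sample_id=sid, species=sp, age_weeks=age,
                             turgid_weight_g=series.turgid_weight,
                             dry_weight_g=series.dry_weight,
                             fresh_weight_g=fw, psi_mpa=psi)
                    )
                truth.append(dict(sample_id=sid, **t))
    p = out / "pv_points.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    tp = out / "pv_truth.csv"
    pd.DataFrame(truth).to_csv(tp, index=False)
    return [p, tp]


def _flux_bundle(out: Path, seed: int) -> list[Path]:
    rng = np.random.default_rng(seed + 1)
    rows, meta = [], []
    for sp, lin, _ in _SPECIES:
        for age in _AGES:
            for rep in range(3):
                flow = float(10 ** rng.uniform(-3.5, -2.5))  # mmol s-1
                series, t = gen_mass_series(
                    flow_true=flow, n=10, dt=60.0, balance_sd=2e-5,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    leaf_area=float(rng.uniform(1e-4, 5e-4)),
                    psi_plant=float(rng.uniform(-1.5, -0.4)),
                )
                sid = f"{sp.split()[0]}-{age}w-f{rep}"
                for ts, m in series.masses:
                    rows.append(dict(sample_id=sid, species=sp, age_weeks=age,
                                     time_s=ts, mass_g=m))
                meta.append(dict(sample_id=sid,
                                 leaf_area_cm2=series.leaf_area * 1e4,
                                 psi_plant_mpa=series.psi_plant,
                                 flow_true_mmol_s=flow))
    p1 = out / "flux.csv"
    p2 = out / "flux_meta.csv"
    pd.DataFrame(rows).to_csv(p1, index=False)
    pd.DataFrame(meta).to_csv(p2, index=False)
    return [p1, p2]


def _uae_bundle(out: Path, seed: int) -> list[Path]:
    rng = np.random.default_rng(seed + 2)
    ev_rows, an_rows, truth = [], [], []
    for sp, lin, _ in _SPECIES:
        for ai, age in enumerate(_AGES):
            mode = -1.5 - 1.5 * ai
            for rep in range(2):
                params = AEGenParams(
                    threshold_mode=mode, threshold_sd=0.3, n_conduits=400,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                stream, timeline, t = gen_ae_stream(params)
                sid = f"{sp.split()[0]}-{age}w-u{rep}"
                for ts, a in stream.events:
                    ev_rows.append(dict(sample_id=sid, time_s=ts, amplitude_db=a))
                for ts, psi in timeline.anchors:
                    an_rows.append(dict(sample_id=sid, time_s=ts, psi_mpa=psi))
                truth.append(dict(sample_id=sid, **t))
    p1 = out / "ae_events.csv"
    p2 = out / "psi_anchors.csv"
    p3 = out / "ae_truth.csv"
    pd.DataFrame(ev_rows).to_csv(p1, index=False)
    pd.DataFrame(an_rows).to_csv(p2, index=False)
    pd.DataFrame(truth).to_csv(p3, index=False)
    return [p1, p2, p3]


def _anatomy_bundle(out: Path, seed: int) -> list[Path]:
    rng = np.random.default_rng(seed + 3)
    sec_rows, con_rows, wall_rows, truth = [], [], [], []
    for sp, lin, shape in _SPECIES:
        for age in _AGES:
            for rep in range(3):
                ind = f"{sp.split()[0]}-{age}w-a{rep}"
                pop = gen_conduit_population(
                    n=int(rng.integers(60, 150)),
                    log_mu=np.log(40.0 + 30.0 * (lin == "angiosperm")),
                    log_sigma=0.4,
                    wall_scaling=float(rng.uniform(0.12, 0.3)),
                    shape=shape,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                d_p = float(rng.uniform(80, 150))
                d_xp = d_p + float(rng.uniform(100, 400))
                for k, direction in enumerate(("h", "v", "d1", "d2")):
                    sec_rows.append(
                        dict(individual_id=ind, species=sp, age_weeks=age,
                             direction=direction,
                             d_xp_um=d_xp + rng.normal(0, 2),
                             d_p_um=d_p + rng.normal(0, 2))
                    )
                for a in pop["lumen_areas"]:
                    con_rows.append(dict(individual_id=ind, lumen_area_um2=a))
                for gi, (t, b) in enumerate(pop["wall_pairs"][:20]):
                    wall_rows.append(dict(individual_id=ind, group_idx=gi,
                                          t_um=t, b_um=b))
                truth.append(dict(individual_id=ind, **pop["truth"]))
    paths = []
    for name, rows in (("sections.csv", sec_rows), ("conduits.csv", con_rows),
                       ("walls.csv", wall_rows), ("anatomy_truth.csv", truth)):
        p = out / name
        pd.DataFrame(rows).to_csv(p, index=False)
        paths.append(p)
    shapes = {sp: shape for sp, _, shape in _SPECIES}
    sp_path = out / "shapes.json"
    sp_path.write_text(json.dumps(shapes))
    paths.append(sp_path)
    return paths


def _cohort_bundle(out: Path, seed: int) -> list[Path]:
    from .simulate import gen_cohort

    design = []
    for sp, lin, _ in _SPECIES:
        for ai, age in enumerate(_AGES):
            design.append(dict(species=sp, lineage=lin, age_weeks=age,
                               trait="height_cm", mean=3.0 + 8.0 * ai,
                               sd=0.6, n=6))
            design.append(dict(species=sp, lineage=lin, age_weeks=age,
                               trait="psi_tlp_mpa", mean=-0.8 - 0.8 * ai,
                               sd=0.1, n=6))
    df = gen_cohort(design, seed=seed + 4)
    p = out / "cohort.csv"
    df.to_csv(p, index=False)
    return [p]


_BUNDLES = {
    "pv": _pv_bundle,
    "flux": _flux_bundle,
    "uae": _uae_bundle,
    "anatomy": _anatomy_bundle,
    "cohort": _cohort_bundle,
}


def write_synthetic(kind: str, out: Path, seed: int = 0) -> list[Path]:
    """Write one stage's synthetic input bundle; 'all' writes every stage."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "all":
        paths = []
        for fn in _BUNDLES.values():
            paths.extend(fn(out, seed))
        return paths
    if kind not in _BUNDLES:
        raise ValueError(f"unknown synthetic bundle kind {kind!r}")
    return _BUNDLES[kind](out, seed)
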