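"""Cohort statistics: published aggregates and synthetic comparisons.

Recomputes the lineage summaries, Huber values and the Viburnum wall-
reinforcement fold change from the published group summary tables, and
runs the assumption-screened group comparisons (Tukey / Games-Howell
with compact letter displays) on the synthetic cohort table.
"""

from pathlib import Path

import pandas as pd

from seedhydro import tables
from seedhydro.anatomy import huber_value
from seedhydro.cohort import lineage_aggregate
from seedhydro.pipeline import PipelineConfig, run_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "cohort"
    out.mkdir(parents=True, exist_ok=True)

    morph = tables.youngest(tables.morphology())
    rows = []
    for lineage in ("conifer", "angiosperm"):
        sub = morph[morph["lineage"] == lineage]
        for col in ("height_cm", "la_cm2", "axyl_mm2"):
            mean, sd = lineage_aggregate(dict(zip(sub["species"], sub[col])))
            rows.append(dict(lineage=lineage, trait=col, mean=mean, sd=sd))
            print(f"{lineage} youngest {col}: {mean:.3f} +- {sd:.3f} "
                  f"(SD across {len(sub)} species means)")
    pd.DataFrame(rows).to_csv(out / "lineage_summary.csv", index=False)

    m = tables.morphology()
    for sp, age in (("Picea abies", 29), ("Fagus sylvatica", 22)):
        row = m[(m["species"] == sp) & (m["age_weeks"] == age)].iloc[0]
        hv = huber_value(row["axyl_mm2"], row["axyl_se"], tables.N_PER_GROUP,
                         row["la_cm2"], row["la_se"], 6)
        print(f"Huber value {sp} week {age}: {hv.value:.2f} +- {hv.se:.2f} "
              f"(x1e-4 m2 m-2); printed {row['hv_printed']}")

    anat = tables.anatomy()
    vib = anat[anat["species"] == "Viburnum lantana"].set_index("age_weeks")
    print(f"Viburnum (t/b)^2 week-4/week-16 fold change: "
          f"{vib.loc[4, 'tb2'] / vib.loc[16, 'tb2']:.2f}")

    cfg = PipelineConfig(out_dir=out, cohort=ROOT / "synthetic" / "cohort.csv")
    comparisons = run_cohort(cfg)
    print(f"synthetic cohort: {len(comparisons)} comparison rows "
          f"-> {out / 'cohort_comparisons.csv'}")


if __name__ == "__main__":
    main()
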