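"""Generate the synthetic study datasets every later stage consumes.

Writes one CSV bundle per stage (pressure-volume points, balance series,
acoustic events + psi anchors, cross-section geometries, cohort trait
table) under results/synthetic/, each with its generator ground truth
alongside, so the downstream drivers can report parameter recovery.
"""

from pathlib import Path

from seedhydro.datasets import write_synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 20160401  # sowing date of the emulated study


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    paths = write_synthetic("all", OUT, seed=SEED)
    print(f"wrote {len(paths)} files to {OUT}:")
    for p in paths:
        print(f"  {p.name}")


if __name__ == "__main__":
    main()
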