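"""Published species x age-class group summaries used as worked inputs.

Two preset tables of group means (+- SE across individuals) for the six
study species -- three conifer trees (Picea abies, Pinus sylvestris,
Larix decidua), two angiosperm trees (Acer pseudoplatanus, Fagus
sylvatica) and one angiosperm shrub (Viburnum lantana) -- across their
first growing season.  ``morphology()`` carries plant height, total leaf
area, xylem area and the reported Huber value; ``anatomy()`` carries
conduit diameter statistics and cell wall reinforcement.

These group-level summaries are inputs to the aggregate, ratio and
Welch-on-summary operations (lineage means, Huber-value consistency,
fold changes); individual-level raw data are not part of the package and
are emulated by :mod:`seedhydro.simulate` where needed.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "morphology", "anatomy", "youngest",
    "LINEAGE", "GROWTH_FORM", "SHAPE", "N_PER_GROUP",
]

LINEAGE = {
    "Picea abies": "conifer",
    "Pinus sylvestris": "conifer",
    "Larix decidua": "conifer",
    "Acer pseudoplatanus": "angiosperm",
    "Fagus sylvatica": "angiosperm",
    "Viburnum lantana": "angiosperm",
}

GROWTH_FORM = {
    "Picea abies": "evergreen tree",
    "Pinus sylvestris": "evergreen tree",
    "Larix decidua": "deciduous tree",
    "Acer pseudoplatanus": "deciduous tree",
    "Fagus sylvatica": "deciduous tree",
    "Viburnum lantana": "deciduous shrub",
}

# conduit cross-section convention: square tracheids vs circular vessels
SHAPE = {
    "Picea abies": "square",
    "Pinus sylvestris": "square",
    "Larix decidua": "square",
    "Acer pseudoplatanus": "circular",
    "Fagus sylvatica": "circular",
    "Viburnum lantana": "circular",
}

# anatomical sections were measured on three hypocotyls per group
N_PER_GROUP = 3

# species, age_weeks, height_cm, height_se, la_cm2, la_se, axyl_mm2,
# axyl_se, hv_printed, hv_printed_se   (hv in 1e-4 m2 m-2 display units)
_MORPHOLOGY = [
    ("Picea abies", 3, 3.04, 0.14, 0.65, 0.04, 0.006, 0.001, 0.92, 0.16),
    ("Picea abies", 8, 3.31, 0.30, 1.35, 0.12, 0.031, 0.004, 2.30, 0.36),
    ("Picea abies", 12, 4.06, 0.65, 3.39, 0.41, 0.115, 0.013, 3.39, 0.64),
    ("Picea abies", 29, 4.64, 0.28, 4.17, 1.09, 0.366, 0.012, 8.78, 2.34),
    ("Pinus sylvestris", 3, 2.77, 0.19, 0.56, 0.05, 0.007, 0.002, 1.25, 0.37),
    ("Pinus sylvestris", 8, 3.16, 0.11, 1.77, 0.24, 0.029, 0.007, 1.64, 0.45),
    ("Pinus sylvestris", 12, 6.56, 0.37, 6.66, 0.52, 0.225, 0.027, 3.38, 0.48),
    ("Pinus sylvestris", 29, 9.10, 0.52, 9.63, 1.27, 0.665, 0.047, 6.91, 1.03),
    ("Larix decidua", 3, 3.43, 0.13, 0.51, 0.03, 0.003, 0.001, 0.59, 1.96),
    ("Larix decidua", 8, 3.53, 0.24, 1.41, 0.27, 0.042, 0.008, 2.98, 0.80),
    ("Larix decidua", 12, 6.54, 0.60, 6.87, 0.87, 0.172, 0.023, 2.50, 0.46),
    ("Larix decidua", 22, 22.49, 2.08, 28.68, 3.90, 1.193, 0.336, 4.16, 1.30),
    ("Acer pseudoplatanus", 4, 2.86, 0.15, 3.12, 0.18, 0.165, 0.018, 5.29, 0.65),
    ("Acer pseudoplatanus", 7, 6.60, 0.65, 26.56, 2.90, 0.353, 0.058, 1.33, 0.26),
    ("Acer pseudoplatanus", 14, 33.26, 3.01, 329.87, 36.90, 3.869, 0.310, 1.18, 0.16),
    ("Acer pseudoplatanus", 22, 34.95, 2.52, 439.33, 43.96, 12.063, 1.792, 2.75, 0.49),
    ("Fagus sylvatica", 4, 2.79, 0.14, 8.38, 0.63, 0.173, 0.004, 2.06, 0.18),
    ("Fagus sylvatica", 9, 9.54, 0.70, 53.40, 10.70, 0.274, 0.064, 0.51, 0.16),
    ("Fagus sylvatica", 22, 12.88, 1.01, 64.75, 9.03, 2.663, 0.245, 4.11, 0.69),
    ("Viburnum lantana", 4, 1.78, 0.12, 1.71, 0.19, 0.006, 0.002, 0.35, 0.12),
    ("Viburnum lantana", 6, 3.84, 0.47, 10.46, 0.87, 0.071, 0.012, 0.68, 0.13),
    ("Viburnum lantana", 8, 5.72, 0.61, 31.88, 4.49, 0.353, 0.067, 1.11, 0.26),
    ("Viburnum lantana", 16, 10.73, 0.59, 77.39, 7.50, 1.367, 0.026, 1.77, 0.17),
]

# species, age_weeks, d_mean_um, d_mean_se, d_h_um, d_h_se, d_max_um,
# d_max_se, tb2, tb2_se
_ANATOMY = [
    ("Picea abies", 3, 7.9, 0.5, 9.5, 0.5, 10.9, 0.4, 0.025, 0.001),
    ("Picea abies", 8, 6.8, 0.3, 8.6, 0.6, 11.5, 0.9, 0.098, 0.010),
    ("Picea abies", 12, 6.8, 0.4, 8.9, 0.5, 11.6, 0.8, 0.104, 0.002),
    ("Picea abies", 29, 5.2, 0.1, 7.9, 0.7, 11.0, 1.1, 0.377, 0.038),
    ("Pinus sylvestris", 3, 7.8, 0.3, 9.0, 0.3, 9.2, 0.6, 0.057, 0.001),
    ("Pinus sylvestris", 8, 7.8, 0.1, 9.4, 0.2, 12.7, 0.3, 0.098, 0.016),
    ("Pinus sylvestris", 12, 7.7, 0.1, 9.4, 0.1, 12.0, 0.2, 0.106, 0.003),
    ("Pinus sylvestris", 29, 7.7, 0.1, 9.9, 0.4, 12.9, 0.8, 0.116, 0.005),
    ("Larix decidua", 3, 5.8, 0.6, 6.8, 0.6, 8.6, 0.8, 0.069, 0.014),
    ("Larix decidua", 8, 7.5, 0.1, 9.2, 0.6, 11.8, 0.9, 0.133, 0.018),
    ("Larix decidua", 12, 6.3, 0.4, 8.0, 0.3, 10.2, 0.4, 0.137, 0.021),
    ("Larix decidua", 22, 6.6, 0.7, 8.8, 0.6, 11.9, 0.8, 0.141, 0.015),
    ("Acer pseudoplatanus", 4, 10.7, 0.2, 16.4, 1.2, 21.7, 1.4, 0.014, 0.001),
    ("Acer pseudoplatanus", 7, 9.4, 0.2, 16.3, 1.3, 21.4, 1.8, 0.014, 0.002),
    ("Acer pseudoplatanus", 14, 10.7, 0.6, 19.9, 0.6, 31.7, 1.1, 0.017, 0.002),
    ("Acer pseudoplatanus", 22, 10.3, 0.5, 23.0, 1.7, 35.5, 1.3, 0.019, 0.000),
    ("Fagus sylvatica", 4, 6.9, 0.1, 18.5, 1.3, 22.2, 1.4, 0.012, 0.000),
    ("Fagus sylvatica", 9, 6.4, 0.3, 19.4, 0.4, 23.6, 0.3, 0.014, 0.002),
    ("Fagus sylvatica", 22, 7.3, 0.2, 24.0, 1.6, 29.0, 1.7, 0.015, 0.001),
    ("Viburnum lantana", 4, 5.7, 0.3, 6.6, 0.6, 7.9, 0.9, 0.113, 0.010),
    ("Viburnum lantana", 6, 7.1, 0.6, 13.5, 1.9, 17.2, 3.5, 0.018, 0.002),
    ("Viburnum lantana", 8, 7.2, 0.5, 17.0, 0.8, 20.3, 1.7, 0.011, 0.002),
    ("Viburnum lantana", 16, 8.1, 0.3, 22.2, 1.9, 26.6, 1.8, 0.006, 0.001),
]


def morphology() -> pd.DataFrame:
    """Morphology group summaries, one row per species x age class."""
    df = pd.DataFrame(
        _MORPHOLOGY,
        columns=[
            "species", "age_weeks", "height_cm", "height_se", "la_cm2",
            "la_se", "axyl_mm2", "axyl_se", "hv_printed", "hv_printed_se",
        ],
    )
    df["lineage"] = df["species"].map(LINEAGE)
    df["growth_form"] = df["species"].map(GROWTH_FORM)
    return df


def anatomy() -> pd.DataFrame:
    """Conduit diameter and wall reinforcement group summaries."""
    df = pd.DataFrame(
        _ANATOMY,
        columns=[
            "species", "age_weeks", "d_mean_um", "d_mean_se", "d_h_um",
            "d_h_se", "d_max_um", "d_max_se", "tb2", "tb2_se",
        ],
    )
    df["lineage"] = df["species"].map(LINEAGE)
    return df


def youngest(df: pd.DataFrame) -> pd.DataFrame:
    """First measured age class of every species."""
    idx = df.groupby("species")["age_weeks"].idxmin()
    return df.loc[idx].reset_index(drop=True)
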