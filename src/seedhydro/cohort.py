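"""Cohort-level statistics: group comparisons, letters, aggregates.

Raw-value traits are screened per species with Shapiro (normality) and
Levene (variance homogeneity); age classes are then compared all-pairs
with Tukey's HSD under equal variance or Games-Howell otherwise, and the
pairwise significance pattern collapsed into a compact letter display
(groups sharing a letter do not differ at alpha).  Traits that only
exist as error-propagated group summaries (Huber value, xylem-area-
specific conductance) are compared with a Welch test on the summaries.

Lineage aggregates are the mean and sample SD across species-level
means; trait correlations are Pearson product-moment over species x age
group means, computed for all species together and per lineage.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .flux import welch_summary_test

__all__ = [
    "GroupComparison",
    "compact_letter_display",
    "verify_letters",
    "screen_and_compare",
    "compare_summary_trait",
    "lineage_aggregate",
    "trait_correlations",
]


@dataclass
class GroupComparison:
    trait: str
    species: str | None
    groups: list
    test_used: str  # "tukey" | "games_howell" | "welch_summary"
    p_matrix: pd.DataFrame
    letters: dict
    shapiro_p: dict = field(default_factory=dict)
    levene_p: float | None = None
    alpha: float = 0.05


def compact_letter_display(
    groups: list, p_matrix: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Insert-and-absorb compact letter display.

    Returns a letter string per group such that two groups share a
    letter iff their pairwise p-value is >= alpha.
    """
    sig = {
        frozenset((g1, g2))
        for g1, g2 in itertools.combinations(groups, 2)
        if p_matrix.loc[g1, g2] < alpha
    }
    columns: list[set] = [set(groups)]
    for pair in sig:
        g1, g2 = tuple(pair)
        for col in list(columns):
            if g1 in col and g2 in col:
                columns.remove(col)
                c1 = col - {g1}
                c2 = col - {g2}
                for c in (c1, c2):
                    if not any(c <= other for other in columns):
                        columns.append(c)
    # drop absorbed columns and order by best (lowest-index) member
    columns = [c for c in columns if c and not any(c < o for o in columns)]
    order = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda c: min(order[g] for g in c))
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        ch = chr(ord("a") + i)
        for g in groups:
            if g in col:
                letters[g] += ch
    return letters


def verify_letters(
    groups: list, p_matrix: pd.DataFrame, letters: dict, alpha: float = 0.05
) -> bool:
    """Exhaustive check: share a letter iff not significantly different."""
    for g1, g2 in itertools.combinations(groups, 2):
        share = bool(set(letters[g1]) & set(letters[g2]))
        significant = p_matrix.loc[g1, g2] < alpha
        if share == significant:
            return False
    return True


def _games_howell_pmatrix(values: dict, alpha: float) -> pd.DataFrame:
    import pingouin as pg

    rows = []
    for g, v in values.items():
        rows.extend({"group": g, "value": x} for x in v)
    df = pd.DataFrame(rows)
    gh = pg.pairwise_gameshowell(data=df, dv="value", between="group")
    groups = list(values)
    p = pd.DataFrame(np.ones((len(groups), len(groups))), index=groups, columns=groups)
    for _, r in gh.iterrows():
        p.loc[r["A"], r["B"]] = r["pval"]
        p.loc[r["B"], r["A"]] = r["pval"]
    return p


def _tukey_pmatrix(values: dict) -> pd.DataFrame:
    groups = list(values)
    res = stats.tukey_hsd(*[np.asarray(values[g], dtype=float) for g in groups])
    p = pd.DataFrame(res.pvalue, index=groups, columns=groups)
    np.fill_diagonal(p.values, 1.0)
    return p


def screen_and_compare(
    table: pd.DataFrame,
    trait: str,
    species: str,
    alpha: float = 0.05,
    group_col: str = "age_weeks",
) -> GroupComparison:
    """Screen assumptions and compare age classes within one species.

    ``table`` is long format with columns species, age_weeks,
    individual_id, trait, value.
    """
    sub = table[(table["species"] == species) & (table["trait"] == trait)]
    values = {
        g: grp["value"].to_numpy(dtype=float)
        for g, grp in sub.groupby(group_col)
    }
    values = {g: v for g, v in values.items() if len(v) >= 3}
    if len(values) < 2:
        raise ValueError(
            f"{species}/{trait}: need >= 2 age classes with >= 3 individuals"
        )
    groups = sorted(values)
    shapiro_p = {}
    for g in groups:
        v = values[g]
        if np.ptp(v) == 0:
            shapiro_p[g] = float("nan")
        else:
            shapiro_p[g] = float(stats.shapiro(v).pvalue)
    levene_p = float(stats.levene(*[values[g] for g in groups]).pvalue)

    if levene_p >= alpha:
        test_used = "tukey"
        p_matrix = _tukey_pmatrix({g: values[g] for g in groups})
    else:
        test_used = "games_howell"
        p_matrix = _games_howell_pmatrix({g: values[g] for g in groups}, alpha)

    letters = compact_letter_display(groups, p_matrix, alpha)
    return GroupComparison(
        trait=trait,
        species=species,
        groups=groups,
        test_used=test_used,
        p_matrix=p_matrix,
        letters=letters,
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        alpha=alpha,
    )


def compare_summary_trait(
    summaries: dict,
    trait: str,
    species: str | None = None,
    alpha: float = 0.05,
) -> GroupComparison:
    """All-pairs Welch tests on error-propagated (mean, se, n) summaries.

    ``summaries`` maps group -> (mean, se, n).  Used for ratio-of-means
    traits where no individual-level values exist.
    """
    groups = sorted(summaries)
    if len(groups) < 2:
        raise ValueError("need >= 2 group summaries")
    p = pd.DataFrame(
        np.ones((len(groups), len(groups))), index=groups, columns=groups
    )
    for g1, g2 in itertools.combinations(groups, 2):
        m1, se1, n1 = summaries[g1]
        m2, se2, n2 = summaries[g2]
        _, _, pv = welch_summary_test(m1, se1, n1, m2, se2, n2)
        p.loc[g1, g2] = p.loc[g2, g1] = pv
    letters = compact_letter_display(groups, p, alpha)
    return GroupComparison(
        trait=trait,
        species=species,
        groups=groups,
        test_used="welch_summary",
        p_matrix=p,
        letters=letters,
        alpha=alpha,
    )


def lineage_aggregate(
    species_means: dict[str, float],
) -> tuple[float, float]:
    """Mean and sample SD (n-1) across species-level means.

    With a single species the SD is reported missing (NaN).
    """
    vals = np.asarray(list(species_means.values()), dtype=float)
    if vals.size == 0:
        raise ValueError("no species means")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else float("nan")
    return mean, sd


def trait_correlations(
    group_means: pd.DataFrame,
    trait_x: list[str],
    trait_y: list[str],
    lineage_col: str = "lineage",
    alpha_levels: tuple[float, float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Pearson correlations over species x age group means.

    ``group_means`` has one row per species x age class, trait columns,
    and a lineage column.  Correlations are computed for all rows
    together and per lineage; constant vectors yield missing r.  Output
    is tidy with significance stars at the two alpha levels.
    """
    subsets = {"all": group_means}
    for lin, grp in group_means.groupby(lineage_col):
        subsets[str(lin)] = grp
    rows = []
    for name, df in subsets.items():
        for tx in trait_x:
            for ty in trait_y:
                if tx == ty:
                    continue
                sub = df[[tx, ty]].dropna()
                n = len(sub)
                if n < 3:
                    rows.append(
                        dict(subset=name, x=tx, y=ty, r=np.nan, p=np.nan,
                             n=n, stars="")
                    )
                    continue
                x = sub[tx].to_numpy(dtype=float)
                y = sub[ty].to_numpy(dtype=float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    rows.append(
                        dict(subset=name, x=tx, y=ty, r=np.nan, p=np.nan,
                             n=n, stars="")
                    )
                    continue
                r, p = stats.pearsonr(x, y)
                stars = (
                    "**" if p < alpha_levels[1]
                    else "*" if p < alpha_levels[0]
                    else ""
                )
                rows.append(
                    dict(subset=name, x=tx, y=ty, r=float(r), p=float(p),
                         n=n, stars=stars)
                )
    return pd.DataFrame(rows)
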