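"""Group comparisons, compact letter displays, aggregates, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from seedhydro import tables
from seedhydro.cohort import (
    compact_letter_display,
    compare_summary_trait,
    lineage_aggregate,
    screen_and_compare,
    trait_correlations,
    verify_letters,
)
from seedhydro.simulate import gen_cohort


def _pmatrix(groups, sig_pairs):
    p = pd.DataFrame(np.ones((len(groups), len(groups))),
                     index=groups, columns=groups)
    for a, b in sig_pairs:
        p.loc[a, b] = p.loc[b, a] = 0.001
    return p


class TestLetters:
    def test_no_difference_shares_single_letter(self):
        groups = [1, 2]
        p = _pmatrix(groups, [])
        letters = compact_letter_display(groups, p)
        assert letters == {1: "a", 2: "a"}

    def test_chain_pattern_a_ab_b(self):
        groups = [1, 2, 3]
        p = _pmatrix(groups, [(1, 3)])
        letters = compact_letter_display(groups, p)
        assert set(letters[1]) & set(letters[3]) == set()
        assert set(letters[2]) & set(letters[1])
        assert set(letters[2]) & set(letters[3])
        assert verify_letters(groups, p, letters)

    def test_all_distinct(self):
        groups = [1, 2, 3]
        p = _pmatrix(groups, list(itertools.combinations(groups, 2)))
        letters = compact_letter_display(groups, p)
        assert len({frozenset(v) for v in letters.values()}) == 3
        assert verify_letters(groups, p, letters)

    def test_random_significance_graphs_always_verified(self, rng):
        groups = list(range(5))
        pairs = list(itertools.combinations(groups, 2))
        for _ in range(100):
            mask = rng.random(len(pairs)) < 0.4
            sig = [p for p, m in zip(pairs, mask) if m]
            p = _pmatrix(groups, sig)
            letters = compact_letter_display(groups, p)
            assert verify_letters(groups, p, letters), (sig, letters)


class TestScreenAndCompare:
    def _table(self, groups, rng, sd_per_group=None):
        rows = []
        for gi, (age, mean) in enumerate(groups.items()):
            sd = 1.0 if sd_per_group is None else sd_per_group[gi]
            for i, v in enumerate(rng.normal(mean, sd, 10)):
                rows.append(dict(species="X", age_weeks=age,
                                 individual_id=f"{age}-{i}",
                                 trait="h", value=v))
        return pd.DataFrame(rows)

    def test_identical_groups_share_letter(self, rng):
        t = self._table({3: 0.0, 8: 0.0}, rng)
        cmp_ = screen_and_compare(t, "h", "X")
        assert cmp_.letters[3] == cmp_.letters[8] == "a"

    def test_separated_groups_get_distinct_letters(self, rng):
        t = self._table({3: 0.0, 8: 5.0}, rng)
        cmp_ = screen_and_compare(t, "h", "X")
        assert not set(cmp_.letters[3]) & set(cmp_.letters[8])
        assert cmp_.test_used == "tukey"

    def test_unequal_variance_routes_to_games_howell(self, rng):
        t = self._table({3: 0.0, 8: 0.2, 12: 5.0}, rng,
                        sd_per_group=[0.05, 0.05, 4.0])
        cmp_ = screen_and_compare(t, "h", "X")
        assert cmp_.test_used == "games_howell"
        assert verify_letters(cmp_.groups, cmp_.p_matrix, cmp_.letters)

    def test_insufficient_replication_rejected(self, rng):
        t = self._table({3: 0.0}, rng)
        with pytest.raises(ValueError, match="age classes"):
            screen_and_compare(t, "h", "X")

    def test_summary_trait_welch_route(self):
        summaries = {3: (8.78, 2.34, 3), 29: (0.92, 0.16, 3)}
        cmp_ = compare_summary_trait(summaries, "hv")
        assert cmp_.test_used == "welch_summary"
        assert verify_letters(cmp_.groups, cmp_.p_matrix, cmp_.letters)


class TestLineageAggregates:
    def test_conifer_youngest_heights(self):
        mean, sd = lineage_aggregate(
            {"Picea abies": 3.04, "Pinus sylvestris": 2.77,
             "Larix decidua": 3.43}
        )
        assert round(mean, 2) == 3.08
        assert round(sd, 2) == 0.33

    def test_angiosperm_youngest_heights(self):
        mean, sd = lineage_aggregate(
            {"Acer pseudoplatanus": 2.86, "Fagus sylvatica": 2.79,
             "Viburnum lantana": 1.78}
        )
        assert round(mean, 2) == 2.48
        assert round(sd, 2) == 0.60

    def test_single_species_sd_missing(self):
        mean, sd = lineage_aggregate({"X": 5.0})
        assert mean == 5.0
        assert np.isnan(sd)

    def test_all_published_youngest_summaries(self):
        """Lineage means/SDs over first-age species values match the
        reported in-text summaries at printed precision."""
        morph = tables.youngest(tables.morphology())
        expected = {
            "conifer": dict(height_cm=(3.08, 0.33, 2), la_cm2=(0.57, 0.07, 2),
                            axyl_mm2=(0.005, 0.002, 3)),
            "angiosperm": dict(height_cm=(2.48, 0.60, 2),
                               la_cm2=(4.40, 3.52, 2),
                               axyl_mm2=(0.115, 0.094, 3)),
        }
        for lineage, traits in expected.items():
            sub = morph[morph["lineage"] == lineage]
            for col, (em, esd, dec) in traits.items():
                mean, sd = lineage_aggregate(
                    dict(zip(sub["species"], sub[col]))
                )
                assert round(mean, dec) == pytest.approx(em), (lineage, col)
                assert round(sd, dec) == pytest.approx(esd), (lineage, col)

    def test_youngest_conifer_wall_reinforcement_mean(self):
        anat = tables.youngest(tables.anatomy())
        sub = anat[anat["lineage"] == "conifer"]
        mean, _ = lineage_aggregate(dict(zip(sub["species"], sub["tb2"])))
        assert round(mean, 3) == 0.050


class TestCorrelations:
    def _means(self, rng, n=12, slope=2.0, noise=0.0):
        x = rng.uniform(0, 1, n)
        y = slope * x + rng.normal(0, noise, n)
        return pd.DataFrame(dict(
            species=[f"s{i}" for i in range(n)],
            age_weeks=3, lineage=["conifer"] * (n // 2) + ["angiosperm"] * (n - n // 2),
            x=x, y=y,
        ))

    def test_perfect_correlation(self, rng):
        df = self._means(rng)
        out = trait_correlations(df, ["x"], ["y"])
        row = out[(out["subset"] == "all") & (out["x"] == "x")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["stars"] == "**"

    def test_anticorrelation_limit(self, rng):
        df = self._means(rng, slope=-1.0, noise=1e-9)
        out = trait_correlations(df, ["x"], ["y"])
        assert out[out["subset"] == "all"]["r"].iloc[0] == pytest.approx(-1.0,
                                                                         abs=1e-6)

    def test_null_simulation_mostly_nonsignificant(self):
        hits = 0
        big = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            df = pd.DataFrame(dict(
                species=[f"s{i}" for i in range(50)], age_weeks=3,
                lineage="conifer", x=r.normal(size=50), y=r.normal(size=50),
            ))
            out = trait_correlations(df, ["x"], ["y"])
            row = out[out["subset"] == "all"].iloc[0]
            hits += row["p"] <= 0.05
            big += abs(row["r"]) >= 0.4
        assert hits <= 10
        assert big == 0

    def test_constant_vector_reported_missing(self, rng):
        df = self._means(rng)
        df["y"] = 1.0
        out = trait_correlations(df, ["x"], ["y"])
        assert out[out["subset"] == "all"]["r"].isna().all()

    def test_symmetry_and_bounds(self, rng):
        df = self._means(rng, noise=0.5)
        out = trait_correlations(df, ["x", "y"], ["x", "y"])
        sub = out[out["subset"] == "all"].set_index(["x", "y"])
        assert sub.loc[("x", "y"), "r"] == pytest.approx(
            sub.loc[("y", "x"), "r"]
        )
        assert (out["r"].dropna().abs() <= 1.0).all()


class TestGenCohort:
    def test_zero_sd_reproduces_means(self):
        design = [dict(species="X", lineage="conifer", age_weeks=3,
                       trait="h", mean=4.2, sd=0.0, n=5)]
        df = gen_cohort(design, seed=1)
        assert df["value"].unique() == pytest.approx([4.2])

    def test_seeded_determinism(self):
        design = [dict(species="X", lineage="conifer", age_weeks=3,
                       trait="h", mean=4.2, sd=1.0, n=5)]
        a = gen_cohort(design, seed=9)
        b = gen_cohort(design, seed=9)
        pd.testing.assert_frame_equal(a, b)
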