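"""Relative abundance, richness, six-way rarity classification, guilds."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_otu_table
from soilmultifun import (
    OTUTable,
    classify_rarity,
    guild_relative_abundance,
    otu_richness,
    relative_abundance,
)
from soilmultifun.datamodel import GuildMap, ValidationError
from soilmultifun.microbial_community import CATEGORIES


def oracle_category(profile, A=0.01, R=0.0001):
    """Independent re-statement of the six category predicates on a single
    OTU's relative-abundance profile, with the documented boundary
    conventions (abundant side wins at exactly A; ART takes precedence
    over CRT for never-detected OTUs)."""
    mn, mx = min(profile), max(profile)
    if all(v >= A for v in profile):
        return "AAT"
    if any(v < R for v in profile) and any(v >= A for v in profile):
        return "CRAT"
    if all(v >= R for v in profile) and any(v >= A for v in profile):
        return "CAT"
    if all(v < R for v in profile):
        return "ART"
    if any(v < R for v in profile) and all(v < A for v in profile):
        return "CRT"
    assert all(R <= v < A for v in profile)
    return "MT"


def profiles_to_ra(profiles):
    """Pack per-OTU profiles into a relative-abundance frame (filler column
    absorbs the remainder so rows sum to 1)."""
    arr = np.column_stack(profiles)
    filler = 1.0 - arr.sum(axis=1)
    assert (filler > 0).all()
    data = np.column_stack([arr, filler])
    cols = [f"OTU{j}" for j in range(arr.shape[1])] + ["FILLER"]
    return pd.DataFrame(data, index=[f"s{i}" for i in range(arr.shape[0])], columns=cols)


class TestRelativeAbundance:
    def test_direct_division(self):
        t = OTUTable(
            pd.DataFrame([[2, 2], [1, 3]], index=["s1", "s2"], columns=["a", "b"])
        )
        ra = relative_abundance(t)
        np.testing.assert_allclose(ra.to_numpy(), [[0.5, 0.5], [0.25, 0.75]])

    def test_rows_sum_to_one(self, rng):
        ra = relative_abundance(random_otu_table(rng))
        np.testing.assert_allclose(ra.sum(axis=1), 1.0, atol=1e-12)

    def test_single_otu_degenerate(self):
        t = OTUTable(pd.DataFrame({"a": [5, 9]}, index=["s1", "s2"]))
        assert (relative_abundance(t)["a"] == 1.0).all()


class TestRichness:
    def test_counts_positive_otus(self):
        t = OTUTable(
            pd.DataFrame([[3, 0, 1], [1, 1, 1]], index=["s1", "s2"], columns=list("abc"))
        )
        assert list(otu_richness(t)) == [2, 3]

    def test_zero_column_invariance(self, rng):
        t = random_otu_table(rng)
        r1 = otu_richness(t)
        with_zero = t.data.copy()
        with_zero["ZOTU"] = 0
        r2 = otu_richness(OTUTable(with_zero, domain=t.domain))
        assert (r1 == r2).all()


BRANCH_CASES = [
    # (profile over samples as fractions, expected category)
    ([0.02, 0.02, 0.02], "AAT"),
    ([0.00005, 0.00005, 0.00005], "ART"),
    ([0.00005, 0.02, 0.001], "CRAT"),
    ([0.00005, 0.005, 0.001], "CRT"),
    ([0.0005, 0.0005, 0.0005], "MT"),
    ([0.005, 0.005, 0.02], "CAT"),
    # boundary: max exactly 1% -> the abundant-side predicate wins
    ([0.005, 0.005, 0.01], "CAT"),
    ([0.00005, 0.005, 0.01], "CRAT"),
    # boundary: min exactly 0.01% counts as not-rare
    ([0.0001, 0.0005, 0.005], "MT"),
]


class TestClassifyRarity:
    @pytest.mark.parametrize("profile,expected", BRANCH_CASES)
    def test_rule_forced_branches(self, profile, expected):
        ra = profiles_to_ra([np.array(profile)])
        rc = classify_rarity(ra.drop(columns="FILLER"))
        assert rc.per_otu.loc["OTU0", "category"] == expected
        assert oracle_category(profile) == expected

    def test_thresholds_out_of_order(self, rng):
        ra = relative_abundance(random_otu_table(rng))
        with pytest.raises(ValidationError, match="thresholds out of order"):
            classify_rarity(ra, abundant_thr=0.0001, rare_thr=0.01)

    def test_partition_and_oracle_agreement(self, rng):
        # random log-uniform profiles spanning the full classification range
        n_otus, n_samples = 1000, 12
        profiles = 10 ** rng.uniform(-6.5, -1.3, size=(n_samples, n_otus))
        ra = pd.DataFrame(
            profiles, index=[f"s{i}" for i in range(n_samples)],
            columns=[f"OTU{j}" for j in range(n_otus)],
        )
        rc = classify_rarity(ra)
        assert set(rc.per_otu["category"]) <= set(CATEGORIES)
        assert rc.per_otu["category"].notna().all()
        for j, otu in enumerate(ra.columns):
            assert rc.per_otu.loc[otu, "category"] == oracle_category(profiles[:, j])
        assert rc.summary["otu_fraction_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert rc.summary["abundance_fraction_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_threshold_monotonicity(self, rng):
        ra = relative_abundance(random_otu_table(rng, n_otus=200, depth=100_000))
        low = classify_rarity(ra, abundant_thr=0.005)
        high = classify_rarity(ra, abundant_thr=0.02)
        abundant_side = {"AAT", "CAT", "CRAT"}
        moved = (low.per_otu["category"].isin(abundant_side)) & (
            ~high.per_otu["category"].isin(abundant_side)
        )
        # raising the abundant threshold may only move OTUs out of the
        # abundant-touching categories, never into them
        gained = (~low.per_otu["category"].isin(abundant_side)) & (
            high.per_otu["category"].isin(abundant_side)
        )
        assert not gained.any()
        assert high.per_otu.loc[moved, "category"].isin({"MT", "CRT", "ART"}).all()

    def test_scale_invariance(self, rng):
        t = random_otu_table(rng)
        scaled = t.data.copy()
        scaled.iloc[0] = scaled.iloc[0] * 10
        rc1 = classify_rarity(relative_abundance(t))
        rc2 = classify_rarity(relative_abundance(OTUTable(scaled, domain=t.domain)))
        pd.testing.assert_frame_equal(rc1.per_otu, rc2.per_otu)

    def test_supersets(self, default_dataset):
        from soilmultifun import relative_abundance as ra_fn

        rc = classify_rarity(ra_fn(default_dataset.otu_bacteria))
        sup = rc.superset_summary()
        assert sup["otu_fraction_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert set(rc.abundant_otus) == set(
            rc.per_otu.index[rc.per_otu["category"].isin(["AAT", "CAT"])]
        )


class TestGuilds:
    def test_forced_aggregation(self):
        t = OTUTable(
            pd.DataFrame({"a": [60], "b": [40]}, index=["s1"]), domain="fungi"
        )
        gm = GuildMap({"a": "saprotroph", "b": "pathotroph"})
        ga = guild_relative_abundance(t, gm)
        assert ga.loc["s1", "saprotroph"] == pytest.approx(0.6)
        assert ga.loc["s1", "pathotroph"] == pytest.approx(0.4)
        np.testing.assert_allclose(ga.sum(axis=1), 1.0)

    def test_all_unassigned(self):
        t = OTUTable(pd.DataFrame({"a": [5], "b": [5]}, index=["s1"]), domain="fungi")
        ga = guild_relative_abundance(t, GuildMap({}))
        assert ga.loc["s1", "unassigned"] == pytest.approx(1.0)

    def test_unknown_map_entry_warns_but_output_unchanged(self):
        t = OTUTable(pd.DataFrame({"a": [60], "b": [40]}, index=["s1"]), domain="fungi")
        gm1 = GuildMap({"a": "saprotroph"})
        gm2 = GuildMap({"a": "saprotroph", "ghost": "symbiotroph"})
        ga1 = guild_relative_abundance(t, gm1)
        with pytest.warns(UserWarning, match="absent from the OTU table"):
            ga2 = guild_relative_abundance(t, gm2)
        pd.testing.assert_frame_equal(ga1, ga2)
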