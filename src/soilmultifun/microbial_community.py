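"""OTU-level community summaries: relative abundance, richness, the
six-category rarity classification, and fungal guild aggregation.

Rarity classification partitions OTUs by their minimum and maximum relative
abundance across samples, with an abundant threshold of 1% and a rare
threshold of 0.01%:

========  =================================================================
AAT       always abundant: ≥ 1% in every sample
CAT       conditionally abundant: ≥ 0.01% in all samples, ≥ 1% in some
ART       always rare: < 0.01% in every sample
CRT       conditionally rare: < 0.01% in some samples, never reaching 1%
MT        moderate: within [0.01%, 1%) in every sample
CRAT      conditionally rare and abundant: < 0.01% in some, ≥ 1% in others
========  =================================================================

AAT ∪ CAT form the *abundant* superset and ART ∪ CRT the *rare* superset.
At a maximum of exactly 1% the abundant-side predicates win (so CAT/CRAT
rather than CRT/MT), keeping the six categories a true partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GuildMap, GUILDS, OTUTable, ValidationError

CATEGORIES: tuple[str, ...] = ("AAT", "CAT", "ART", "CRT", "MT", "CRAT")

ABUNDANT_THRESHOLD = 0.01   # 1 % relative abundance
RARE_THRESHOLD = 0.0001     # 0.01 % relative abundance


def relative_abundance(table: OTUTable) -> pd.DataFrame:
    """Per-sample OTU proportions; each row sums to 1."""
    counts = table.data
    return counts.div(counts.sum(axis=1), axis=0)


def otu_richness(table: OTUTable) -> pd.Series:
    """Observed OTU richness: number of OTUs with count > 0 per sample."""
    rich = (table.data > 0).sum(axis=1).astype(int)
    rich.name = f"{table.domain}_richness"
    return rich


@dataclass(frozen=True)
class RarityClassification:
    """Per-OTU category assignment plus category summaries.

    ``per_otu`` has columns min_ra, max_ra, category; ``summary`` is indexed
    by category with otu_fraction_pct (% of OTUs) and abundance_fraction_pct
    (% of summed relative abundance).
    """

    per_otu: pd.DataFrame
    summary: pd.DataFrame
    abundant_threshold: float
    rare_threshold: float

    @property
    def abundant_otus(self) -> pd.Index:
        return self.per_otu.index[self.per_otu["category"].isin(["AAT", "CAT"])]

    @property
    def rare_otus(self) -> pd.Index:
        return self.per_otu.index[self.per_otu["category"].isin(["ART", "CRT"])]

    def superset_summary(self) -> pd.DataFrame:
        """Fractions for the abundant / rare / other supersets."""
        cat = self.per_otu["category"]
        groups = {
            "abundant": cat.isin(["AAT", "CAT"]),
            "rare": cat.isin(["ART", "CRT"]),
            "moderate": cat == "MT",
            "conditionally_rare_and_abundant": cat == "CRAT",
        }
        rows = {
            name: {
                "otu_fraction_pct": float(self.summary.loc[cat[mask].unique(), "otu_fraction_pct"].sum())
                if mask.any()
                else 0.0,
                "abundance_fraction_pct": float(
                    self.summary.loc[cat[mask].unique(), "abundance_fraction_pct"].sum()
                )
                if mask.any()
                else 0.0,
            }
            for name, mask in groups.items()
        }
        return pd.DataFrame(rows).T


def classify_rarity(
    ra: pd.DataFrame,
    abundant_thr: float = ABUNDANT_THRESHOLD,
    rare_thr: float = RARE_THRESHOLD,
) -> RarityClassification:
    """Assign each OTU to one of the six rarity categories.

    ``ra`` is a sample × OTU relative-abundance matrix (rows sum to 1).
    The decision tree operates on each OTU's (min, max) across samples::

        min ≥ A                → AAT
        max ≥ A and min < R    → CRAT
        max ≥ A                → CAT     (min in [R, A))
        max < R                → ART
        min < R                → CRT     (max in [R, A))
        otherwise              → MT      (R ≤ min ≤ max < A)

    with A = ``abundant_thr`` and R = ``rare_thr``.
    """
    if not 0 < rare_thr < abundant_thr < 1:
        raise ValidationError(
            f"thresholds out of order: need 0 < rare ({rare_thr}) < abundant ({abundant_thr}) < 1"
        )
    arr = ra.to_numpy(dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValidationError("relative abundances must lie in [0, 1]")
    mn = arr.min(axis=0)
    mx = arr.max(axis=0)

    category = np.empty(arr.shape[1], dtype=object)
    aat = mn >= abundant_thr
    crat = ~aat & (mx >= abundant_thr) & (mn < rare_thr)
    cat = ~aat & ~crat & (mx >= abundant_thr)
    art = mx < rare_thr
    crt = ~art & (mx < abundant_thr) & (mn < rare_thr)
    mt = ~(aat | crat | cat | art | crt)
    for name, mask in zip(CATEGORIES, (aat, cat, art, crt, mt, crat)):
        category[mask] = name

    per_otu = pd.DataFrame(
        {"min_ra": mn, "max_ra": mx, "category": category},
        index=ra.columns.rename("otu_id"),
    )

    mean_ra = arr.mean(axis=0)  # total relative abundance share per OTU
    total = mean_ra.sum()
    summary = pd.DataFrame(
        {
            "otu_fraction_pct": [
                100.0 * float((category == c).sum()) / arr.shape[1] for c in CATEGORIES
            ],
            "abundance_fraction_pct": [
                100.0 * float(mean_ra[category == c].sum()) / total for c in CATEGORIES
            ],
        },
        index=pd.Index(CATEGORIES, name="category"),
    )
    return RarityClassification(
        per_otu=per_otu,
        summary=summary,
        abundant_threshold=abundant_thr,
        rare_threshold=rare_thr,
    )


def guild_relative_abundance(table: OTUTable, guilds: GuildMap) -> pd.DataFrame:
    """Per-sample summed relative abundance of each fungal trophic guild.

    OTUs without a guild annotation count as ``unassigned``; guild-map
    entries for OTUs absent from the table trigger a warning and are
    ignored.  Rows sum to 1.
    """
    guilds.check_against(table)
    ra = relative_abundance(table)
    labels = pd.Series([guilds.guild_of(o) for o in ra.columns], index=ra.columns)
    out = pd.DataFrame(0.0, index=ra.index, columns=list(GUILDS))
    grouped = ra.T.groupby(labels).sum().T
    out[grouped.columns] = grouped
    out.index.name = "sample_id"
    return out
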