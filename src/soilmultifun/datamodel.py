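"""Shared data containers for the plot × function × OTU data model.

All containers wrap a validated :class:`pandas.DataFrame` in a canonical
orientation: plots (or samples) as rows, functions (or OTUs) as columns.
Validation happens at construction so downstream stages can assume clean
inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

#: The ten soil functions of the default profile: four carbon-cycle enzymes
#: (αG, βG, βX, CBH), four nitrogen-cycle measures (LAP, NAG, net
#: nitrification Nn, net N mineralization Nm) and two phosphorus-cycle
#: measures (ALP, AP).  Greek letters are spelled with ASCII initials.
DEFAULT_FUNCTIONS: tuple[str, ...] = (
    "aG", "bG", "bX", "CBH", "LAP", "NAG", "Nn", "Nm", "ALP", "AP",
)

#: Carbon / nitrogen / phosphorus cycle grouping of the default functions.
FUNCTION_CYCLES: dict[str, tuple[str, ...]] = {
    "C": ("aG", "bG", "bX", "CBH"),
    "N": ("LAP", "NAG", "Nn", "Nm"),
    "P": ("ALP", "AP"),
}

#: Unicode aliases accepted in input files for the ASCII canonical names.
FUNCTION_ALIASES: dict[str, str] = {"αG": "aG", "βG": "bG", "βX": "bX"}

GUILDS: tuple[str, ...] = ("pathotroph", "saprotroph", "symbiotroph", "unassigned")

DIVERSITY_LEVELS: tuple[str, ...] = ("low", "high")


class ValidationError(ValueError):
    """A container invariant was violated."""


def _check_unique(ids, what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dups.index))}")


@dataclass(frozen=True)
class FunctionMatrix:
    """Plot × soil-function measurements on their native scales.

    Enzyme activities are in nmol g⁻¹ h⁻¹, the nitrogen rates Nn and Nm may
    be negative, AP is in mg kg⁻¹.  Columns are not required to be the
    default ten-function profile; ``require_default_profile`` enforces it.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "plot id")
        _check_unique(df.columns, "function name")
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValidationError("function matrix must have at least one plot and one function")
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise ValidationError(f"non-numeric function column(s): {', '.join(map(str, bad))}")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"missing or non-finite value at plot {df.index[r]!r}, function {df.columns[c]!r}"
            )
        object.__setattr__(self, "data", df.astype(float))

    @property
    def plot_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def function_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def require_default_profile(self) -> None:
        missing = [f for f in DEFAULT_FUNCTIONS if f not in self.data.columns]
        if missing:
            raise ValidationError(f"missing required function(s): {', '.join(missing)}")

    def subset(self, functions: list[str]) -> "FunctionMatrix":
        missing = [f for f in functions if f not in self.data.columns]
        if missing:
            raise ValidationError(f"function(s) not in matrix: {', '.join(missing)}")
        return FunctionMatrix(self.data[functions].copy())


@dataclass(frozen=True)
class OTUTable:
    """Sample × OTU integer counts, canonically oriented samples as rows.

    ``domain`` tags the table as bacterial (16S) or fungal (ITS); bacterial
    and fungal communities are always analysed separately.
    """

    data: pd.DataFrame
    domain: str = "bacteria"

    def __post_init__(self) -> None:
        if self.domain not in ("bacteria", "fungi"):
            raise ValidationError(f"unknown domain {self.domain!r}; expected 'bacteria' or 'fungi'")
        df = self.data
        _check_unique(df.index, "sample id")
        _check_unique(df.columns, "OTU id")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr.astype(float)).all():
            raise ValidationError("OTU counts must be finite numbers")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[r]!r}, OTU {df.columns[c]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("OTU counts must be integers")
        totals = arr.sum(axis=1)
        zero = np.asarray(totals == 0).nonzero()[0]
        if len(zero):
            raise ValidationError(
                f"sample(s) with zero total counts: {', '.join(str(df.index[i]) for i in zero)}"
            )
        object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def otu_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)


@dataclass(frozen=True)
class PlotRecord:
    """Metadata for one 1 m × 1 m plot.

    AGB/BGB are above-/below-ground plant biomass in g m⁻²; their ratio
    indexes biomass allocation.  ``diversity_level`` is ``low`` (single
    species assemblage) or ``high`` (multiple species assemblage).
    """

    plot_id: str
    site_id: str
    diversity_level: str
    agb: float
    bgb: float
    bgb_agb_ratio: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.diversity_level not in DIVERSITY_LEVELS:
            raise ValidationError(
                f"plot {self.plot_id!r}: diversity_level must be one of {DIVERSITY_LEVELS}"
            )
        if self.agb > 0:
            expected = self.bgb / self.agb
            if np.isnan(self.bgb_agb_ratio):
                object.__setattr__(self, "bgb_agb_ratio", expected)
            elif not np.isclose(self.bgb_agb_ratio, expected, rtol=1e-6):
                raise ValidationError(
                    f"plot {self.plot_id!r}: bgb_agb_ratio {self.bgb_agb_ratio} != BGB/AGB {expected}"
                )


@dataclass(frozen=True)
class PlotMetadata:
    """Collection of :class:`PlotRecord` with frame-style access."""

    records: tuple[PlotRecord, ...]

    def __post_init__(self) -> None:
        _check_unique([r.plot_id for r in self.records], "plot id")
        levels = {r.diversity_level for r in self.records}
        if not levels <= set(DIVERSITY_LEVELS):
            raise ValidationError(f"unknown diversity level(s): {levels - set(DIVERSITY_LEVELS)}")

    def __iter__(self) -> Iterator[PlotRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def plot_ids(self) -> list[str]:
        return [r.plot_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": [r.site_id for r in self.records],
                "diversity_level": [r.diversity_level for r in self.records],
                "agb": [r.agb for r in self.records],
                "bgb": [r.bgb for r in self.records],
                "bgb_agb_ratio": [r.bgb_agb_ratio for r in self.records],
            },
            index=pd.Index(self.plot_ids, name="plot_id"),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlotMetadata":
        records = tuple(
            PlotRecord(
                plot_id=str(idx),
                site_id=str(row["site_id"]),
                diversity_level=str(row["diversity_level"]),
                agb=float(row["agb"]),
                bgb=float(row["bgb"]),
                bgb_agb_ratio=float(row.get("bgb_agb_ratio", np.nan)),
            )
            for idx, row in df.iterrows()
        )
        return cls(records)

    def diversity_groups(self, values: pd.Series) -> tuple[pd.Series, pd.Series]:
        """Split ``values`` (indexed by plot id) into (low, high) groups."""
        frame = self.to_frame()
        aligned = values.reindex(frame.index)
        if aligned.isna().any():
            missing = list(aligned.index[aligned.isna()])
            raise ValidationError(f"values missing for plot(s): {', '.join(map(str, missing))}")
        low = aligned[frame["diversity_level"] == "low"]
        high = aligned[frame["diversity_level"] == "high"]
        return low, high


@dataclass(frozen=True)
class GuildMap:
    """OTU → fungal trophic guild lookup (FUNGuild-style annotation table).

    OTUs absent from the mapping are treated as ``unassigned``.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.mapping.values() if g not in GUILDS}
        if bad:
            raise ValidationError(f"unknown guild label(s): {', '.join(sorted(bad))}")
        object.__setattr__(self, "mapping", dict(self.mapping))

    def guild_of(self, otu_id: str) -> str:
        return self.mapping.get(otu_id, "unassigned")

    def __len__(self) -> int:
        return len(self.mapping)

    def check_against(self, table: OTUTable) -> None:
        """Warn about mapped OTU ids that never occur in ``table``."""
        extra = sorted(set(self.mapping) - set(table.otu_ids))
        if extra:
            warnings.warn(
                f"{len(extra)} guild-map OTU id(s) absent from the OTU table "
                f"(e.g. {extra[0]!r}); they are ignored",
                stacklevel=3,
            )
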