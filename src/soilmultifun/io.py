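"""Delimited-text readers and writers for the pipeline's input/output tables.

TSV is the default dialect (matching the BIOM-TSV convention for OTU
tables); comma-separated files are accepted via ``dialect="csv"``.  Missing
values are hard errors everywhere — plot-level studies have complete tables
and silent imputation would change every downstream index.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    FUNCTION_ALIASES,
    FunctionMatrix,
    GuildMap,
    OTUTable,
    PlotMetadata,
    ValidationError,
)

_SEPS = {"tsv": "\t", "csv": ","}


def _sep(dialect: str) -> str:
    try:
        return _SEPS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'") from None


def _read_table(path, dialect: str, comment: str | None = "#") -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0, comment=comment, dtype=str)
    if df.index.isna().any() or df.columns.isna().any():
        raise ValidationError(f"{path}: ragged or malformed header")
    return df


def _to_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    missing = df.isna()
    problem = bad | missing
    if problem.to_numpy().any():
        r, c = np.argwhere(problem.to_numpy())[0]
        cell = df.iat[r, c]
        what = "missing value" if missing.iat[r, c] else f"non-numeric cell {cell!r}"
        raise ValidationError(
            f"{path}: {what} at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return out


def read_function_matrix(
    path, dialect: str = "tsv", require_default_profile: bool = False
) -> FunctionMatrix:
    """Read a plot × function matrix: header row of function names, first
    column plot ids.  Unicode enzyme symbols (αG, βG, βX) are mapped to their
    ASCII canonical names."""
    df = _read_table(path, dialect)
    df = df.rename(columns=FUNCTION_ALIASES)
    fm = FunctionMatrix(_to_numeric(df, path))
    if require_default_profile:
        fm.require_default_profile()
    return fm


def write_function_matrix(fm: FunctionMatrix, path, dialect: str = "tsv") -> None:
    fm.data.rename_axis("plot_id").to_csv(path, sep=_sep(dialect))


def read_otu_table(
    path,
    dialect: str = "tsv",
    domain: str = "bacteria",
    orientation: str = "otus_by_samples",
) -> OTUTable:
    """Read a BIOM-style TSV OTU table.

    The file default orientation is rows = OTUs, columns = samples (a
    ``#OTU ID`` first header cell is accepted); ``orientation=
    "samples_by_otus"`` accepts transposed input.  The returned table is
    always canonical samples × OTUs.
    """
    # BIOM-TSV files start the header line with "#OTU ID"; a plain comment
    # filter would eat it, so only strip full-line comments elsewhere.
    with open(path) as fh:
        lines = [ln for ln in fh if not (ln.startswith("#") and not ln.startswith("#OTU ID"))]
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines)), sep=_sep(dialect), index_col=0, dtype=str)
    df = _to_numeric(df, path)
    if orientation == "otus_by_samples":
        df = df.T
    elif orientation != "samples_by_otus":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index.name = "sample_id"
    return OTUTable(df, domain=domain)


def write_otu_table(
    table: OTUTable, path, dialect: str = "tsv", orientation: str = "otus_by_samples"
) -> None:
    """Write an OTU table; default file orientation is BIOM-style rows=OTUs."""
    if orientation == "otus_by_samples":
        out = table.data.T
        out.index.name = "#OTU ID"
    else:
        out = table.data.copy()
        out.index.name = "sample_id"
    out.to_csv(path, sep=_sep(dialect))


def read_plot_metadata(path, dialect: str = "tsv") -> PlotMetadata:
    """Read the plot metadata table (site_id, diversity_level, agb, bgb
    [, bgb_agb_ratio]); the ratio is derived when absent."""
    df = _read_table(path, dialect)
    required = ["site_id", "diversity_level", "agb", "bgb"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata column(s): {', '.join(missing)}")
    for col in ("agb", "bgb", "bgb_agb_ratio"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    if "bgb_agb_ratio" not in df.columns:
        df["bgb_agb_ratio"] = np.nan
    return PlotMetadata.from_frame(df)


def write_plot_metadata(meta: PlotMetadata, path, dialect: str = "tsv") -> None:
    meta.to_frame().to_csv(path, sep=_sep(dialect))


def read_guild_map(path, dialect: str = "tsv") -> GuildMap:
    """Read a two-column OTU → guild table (header ``otu_id<TAB>guild``)."""
    df = pd.read_csv(path, sep=_sep(dialect), comment=None, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: guild map needs two columns (otu_id, guild)")
    otu_col, guild_col = df.columns[:2]
    return GuildMap(dict(zip(df[otu_col].astype(str), df[guild_col].astype(str))))


def write_guild_map(gm: GuildMap, path, dialect: str = "tsv") -> None:
    pd.DataFrame(
        {"otu_id": list(gm.mapping), "guild": list(gm.mapping.values())}
    ).to_csv(path, sep=_sep(dialect), index=False)


def write_tsv_with_header(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a result table with ``#``-prefixed header comments recording
    the parameters that produced it."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (params or {}).items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, sep="\t")
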