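"""Pipeline driver: chain the analysis stages and write per-stage TSVs.

Outputs (under ``out_dir``), all tab-separated with ``#`` header comments
recording the parameters that produced them:

* ``multifunctionality.tsv`` — per plot: averaging SMF index and the
  single-threshold counts at each configured threshold;
* ``threshold_curve_<domain>.tsv`` / ``threshold_summary.tsv`` — the
  multiple-threshold slope series and its T_min / T_mde / R_mde summary
  per microbial domain;
* ``rarity_per_otu_<domain>.tsv`` / ``rarity_summary_<domain>.tsv``;
* ``vector_length.tsv`` — per plot L with diversity level;
* ``guild_abundance.tsv`` — per plot fungal guild relative abundances;
* ``regressions.tsv`` and ``group_tests.tsv`` — the standard regression
  set and the low-vs-high comparisons;
* ``run_log.txt`` — config hash, seed, stage status.

A fixed config + seed produces byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .config import config_hash, default_config, parse_grid, validate_config
from .datamodel import FunctionMatrix, GuildMap, OTUTable, PlotMetadata, ValidationError
from .microbial_community import (
    classify_rarity,
    guild_relative_abundance,
    otu_richness,
    relative_abundance,
)
from .multifunctionality import (
    average_multifunctionality,
    function_maxima,
    multiple_threshold_analysis,
    shift_nonneg,
    single_threshold_counts,
    zscore_standardize,
)
from .stats import gated_t_test, ols_regression
from .stoichiometry import compare_c_limitation, vector_length
from .synthetic_data import SimulationConfig, simulate_dataset

logger = logging.getLogger("soilmultifun")


class PipelineStageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    # round-trip-stable text: 12 significant digits everywhere
    return df.map(lambda v: float(f"{v:.12g}") if isinstance(v, float) else v)


def _load_inputs(cfg: dict):
    sim_block = cfg.get("simulation")
    if sim_block is not None:
        sim_cfg = SimulationConfig(**{**sim_block, "seed": cfg["seed"]})
        ds = simulate_dataset(sim_cfg)
        return ds.function_matrix, ds.plot_metadata, ds.otu_bacteria, ds.otu_fungi, ds.guild_map, ds.enzyme_activities
    inputs = cfg["inputs"]
    dialect = cfg.get("dialect", "tsv")
    fm = sio.read_function_matrix(inputs["function_matrix"], dialect)
    meta = sio.read_plot_metadata(inputs["plot_metadata"], dialect) if "plot_metadata" in inputs else None
    otu_b = (
        sio.read_otu_table(inputs["otu_bacteria"], dialect, domain="bacteria")
        if "otu_bacteria" in inputs
        else None
    )
    otu_f = (
        sio.read_otu_table(inputs["otu_fungi"], dialect, domain="fungi")
        if "otu_fungi" in inputs
        else None
    )
    gm = sio.read_guild_map(inputs["guild_map"], dialect) if "guild_map" in inputs else None
    # measured tables double as the enzyme-activity source (bG/NAG/LAP/ALP columns)
    return fm, meta, otu_b, otu_f, gm, fm.data


def run_pipeline(cfg: dict | None = None, out_dir=None) -> dict:
    """Run the configured stages; returns the in-memory result bundle."""
    cfg = cfg or default_config()
    validate_config(cfg)
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    log_lines = [f"config_hash = {config_hash(cfg)}", f"seed = {cfg['seed']}"]
    results: dict = {}

    try:
        fm, meta, otu_b, otu_f, gm, enzymes = _load_inputs(cfg)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineStageError("load_inputs", exc) from exc
    results["function_matrix"] = fm
    results["plot_metadata"] = meta

    richness = {}
    for domain, table in (("bacteria", otu_b), ("fungi", otu_f)):
        if table is not None:
            richness[domain] = otu_richness(table).astype(float)
    results["richness"] = richness

    mf_cfg = cfg["multifunctionality"]
    if "multifunctionality" in stages:
        try:
            sm = zscore_standardize(fm, drop_constant=mf_cfg["drop_constant"])
            smf = average_multifunctionality(sm)
            fm_thr = shift_nonneg(fm) if mf_cfg["shift_nonneg"] else fm
            maxima = function_maxima(fm_thr, top_fraction=mf_cfg["top_fraction"])
            table = pd.DataFrame({"smf_average": smf})
            for t in mf_cfg["single_thresholds"]:
                table[f"count_t{int(round(t * 100))}"] = single_threshold_counts(fm_thr, maxima, t)
            sio.write_tsv_with_header(
                _float_fmt(table.rename_axis("plot_id")),
                out / "multifunctionality.tsv",
                {"single_thresholds": mf_cfg["single_thresholds"],
                 "top_fraction": mf_cfg["top_fraction"],
                 "shift_nonneg": mf_cfg["shift_nonneg"]},
            )
            results["smf_average"] = smf
            results["single_threshold"] = table
            grid = np.array(parse_grid(mf_cfg["grid"]))
            summary_rows = []
            for domain, rich in richness.items():
                curve = multiple_threshold_analysis(
                    fm_thr, maxima, rich.reindex(fm.data.index), grid=grid, alpha=mf_cfg["alpha"]
                )
                sio.write_tsv_with_header(
                    _float_fmt(curve.table.set_index("threshold")),
                    out / f"threshold_curve_{domain}.tsv",
                    {"alpha": mf_cfg["alpha"], "domain": domain},
                )
                summary_rows.append(
                    {"domain": domain,
                     "t_min_pct": np.nan if curve.t_min is None else curve.t_min,
                     "t_mde_pct": curve.t_mde, "r_mde": curve.r_mde}
                )
                results[f"threshold_curve_{domain}"] = curve
            if summary_rows:
                sio.write_tsv_with_header(
                    _float_fmt(pd.DataFrame(summary_rows).set_index("domain")),
                    out / "threshold_summary.tsv",
                    {"alpha": mf_cfg["alpha"]},
                )
            log_lines.append("stage multifunctionality: ok")
        except Exception as exc:
            log_lines.append(f"stage multifunctionality: FAILED ({exc})")
            _write_log(out, log_lines)
            raise PipelineStageError("multifunctionality", exc) from exc

    if "rarity" in stages:
        try:
            if otu_b is None and otu_f is None:
                raise ValidationError("rarity stage requires otu table")
            r_cfg = cfg["rarity"]
            for domain, table in (("bacteria", otu_b), ("fungi", otu_f)):
                if table is None:
                    continue
                rc = classify_rarity(
                    relative_abundance(table), abundant_thr=r_cfg["abundant"], rare_thr=r_cfg["rare"]
                )
                sio.write_tsv_with_header(
                    _float_fmt(rc.per_otu), out / f"rarity_per_otu_{domain}.tsv",
                    {"abundant": r_cfg["abundant"], "rare": r_cfg["rare"]},
                )
                sio.write_tsv_with_header(
                    _float_fmt(rc.summary), out / f"rarity_summary_{domain}.tsv",
                    {"abundant": r_cfg["abundant"], "rare": r_cfg["rare"]},
                )
                results[f"rarity_{domain}"] = rc
            log_lines.append("stage rarity: ok")
        except Exception as exc:
            log_lines.append(f"stage rarity: FAILED ({exc})")
            _write_log(out, log_lines)
            raise PipelineStageError("rarity", exc) from exc

    if "stoichiometry" in stages:
        try:
            st_cfg = cfg["stoichiometry"]
            L = vector_length(enzymes, sqrt=st_cfg["sqrt"], units=st_cfg["units"])
            vl_table = pd.DataFrame({"L": L})
            if meta is not None:
                vl_table["diversity_level"] = meta.to_frame()["diversity_level"]
            sio.write_tsv_with_header(
                _float_fmt(vl_table.rename_axis("plot_id")),
                out / "vector_length.tsv", {"units": st_cfg["units"], "sqrt": st_cfg["sqrt"]},
            )
            results["vector_length"] = L
            log_lines.append("stage stoichiometry: ok")
        except Exception as exc:
            log_lines.append(f"stage stoichiometry: FAILED ({exc})")
            _write_log(out, log_lines)
            raise PipelineStageError("stoichiometry", exc) from exc

    if "guilds" in stages:
        try:
            if otu_f is None or gm is None:
                raise ValidationError("guilds stage requires a fungal OTU table and a guild map")
            ga = guild_relative_abundance(otu_f, gm)
            sio.write_tsv_with_header(_float_fmt(ga), out / "guild_abundance.tsv", {})
            results["guild_abundance"] = ga
            log_lines.append("stage guilds: ok")
        except Exception as exc:
            log_lines.append(f"stage guilds: FAILED ({exc})")
            _write_log(out, log_lines)
            raise PipelineStageError("guilds", exc) from exc

    if "stats" in stages:
        try:
            results.update(_stats_stage(cfg, out, results, meta))
            log_lines.append("stage stats: ok")
        except Exception as exc:
            log_lines.append(f"stage stats: FAILED ({exc})")
            _write_log(out, log_lines)
            raise PipelineStageError("stats", exc) from exc

    _write_log(out, log_lines)
    return results


def _stats_stage(cfg: dict, out: Path, results: dict, meta: PlotMetadata | None) -> dict:
    if meta is None:
        raise ValidationError("stats stage requires plot metadata")
    st = cfg["stats"]
    frame = meta.to_frame()
    smf = results.get("smf_average")
    richness = results.get("richness", {})
    L = results.get("vector_length")
    ga = results.get("guild_abundance")

    reg_rows = []

    def add_reg(name, x, y):
        if x is None or y is None:
            return
        x = x.reindex(frame.index)
        y = y.reindex(frame.index)
        r = ols_regression(x.to_numpy(), y.to_numpy())
        reg_rows.append(
            {"pair": name, "slope": r.slope, "intercept": r.intercept,
             "r_squared": r.r_squared, "pvalue": r.pvalue, "n": r.n}
        )

    add_reg("bacterial_richness~smf", richness.get("bacteria"), smf)
    add_reg("fungal_richness~smf", richness.get("fungi"), smf)
    if ga is not None:
        add_reg("pathotroph_ra~smf", ga["pathotroph"], smf)
        add_reg("saprotroph_ra~smf", ga["saprotroph"], smf)
        add_reg("symbiotroph_ra~smf", ga["symbiotroph"], smf)
    if L is not None:
        add_reg("c_limitation~bacterial_richness", L, richness.get("bacteria"))
        add_reg("c_limitation~fungal_richness", L, richness.get("fungi"))
    if reg_rows:
        sio.write_tsv_with_header(
            _float_fmt(pd.DataFrame(reg_rows).set_index("pair")), out / "regressions.tsv", {}
        )

    test_rows = []
    variables = {"bgb_agb_ratio": frame["bgb_agb_ratio"], "agb": frame["agb"], "bgb": frame["bgb"]}
    if smf is not None:
        variables["smf_average"] = smf
    if L is not None:
        variables["vector_length"] = L
    for name, series in variables.items():
        low, high = meta.diversity_groups(series)
        if len(low) < 3 or len(high) < 3:
            continue
        res = gated_t_test(low.to_numpy(), high.to_numpy(), gate_alpha=st["gate_alpha"], welch=st["welch"])
        test_rows.append(
            {"variable": name, "mean_low": res.mean_a, "mean_high": res.mean_b,
             "t": res.t, "df": res.df, "pvalue": res.pvalue,
             "transform": res.transform_applied}
        )
    if test_rows:
        sio.write_tsv_with_header(
            _float_fmt(pd.DataFrame(test_rows).set_index("variable")), out / "group_tests.tsv", {}
        )
    return {
        "regressions": pd.DataFrame(reg_rows),
        "group_tests": pd.DataFrame(test_rows),
    }


def _write_log(out: Path, lines: list[str]) -> None:
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")
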