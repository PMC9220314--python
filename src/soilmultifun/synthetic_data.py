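"""Study-shaped synthetic data with known ground truth.

The generator emulates the plot-scale grassland design the pipeline is
built for: 6 sites × 5 plots, three sites of single-species (low diversity)
and three of multi-species (high diversity) assemblages, 10 correlated soil
functions driven by a latent fungal-richness effect, plot biomass records,
enzyme activities for the stoichiometry stage, and bacterial + fungal OTU
tables drawn multinomially from a long-tailed (lognormal) species abundance
distribution with explicitly seeded abundance tiers so all six rarity
categories occur.

Every simulated quantity's design value is retained in :class:`GroundTruth`
so recovery tests can compare pipeline estimates against closed-form
expectations rather than against other simulations.

Randomness uses one ``numpy.random.default_rng`` (PCG64) seed; per-component
substreams are spawned deterministically so adding a component never
perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_FUNCTIONS,
    FunctionMatrix,
    GuildMap,
    OTUTable,
    PlotMetadata,
    PlotRecord,
    ValidationError,
)
from .microbial_community import (
    ABUNDANT_THRESHOLD,
    CATEGORIES,
    RARE_THRESHOLD,
)


def _default_slopes() -> tuple[float, ...]:
    return (0.01,) * 10


def _default_noise() -> tuple[float, ...]:
    return (0.5,) * 10


def _default_intercepts() -> tuple[float, ...]:
    return (0.0,) * 10


@dataclass
class SimulationConfig:
    """Parameters of the study-shaped simulation.

    Defaults mirror the emulated design: 30 plots in 6 sites at 2 diversity
    levels; functions F_ij = a_j + b_j·S_f(i) + ε_ij with a common richness
    slope b_j = 0.01 functions per fungal OTU and noise σ_j = 0.5; fungal
    richness ~100 OTUs higher (bacterial ~100 higher) under high diversity;
    β-glucosidase shifted upward under low diversity so the vector length
    (C limitation) is higher there; OTU counts multinomial over a lognormal
    species-abundance distribution plus seeded abundance tiers.
    """

    n_sites: int = 6
    plots_per_site: int = 5
    n_low_sites: int = 3

    # latent per-plot richness (drives functions and OTU-table truncation)
    fungal_richness_mean_low: float = 350.0
    fungal_richness_mean_high: float = 450.0
    fungal_richness_sd: float = 30.0
    bacterial_richness_mean_low: float = 900.0
    bacterial_richness_mean_high: float = 1000.0
    bacterial_richness_sd: float = 50.0

    # function model F_ij = a_j + b_j * S_f(i) + Normal(0, sigma_j)
    function_intercepts: tuple[float, ...] = field(default_factory=_default_intercepts)
    function_slopes: tuple[float, ...] = field(default_factory=_default_slopes)
    function_noise_sd: tuple[float, ...] = field(default_factory=_default_noise)

    # plot biomass (g m^-2); BGB = AGB * (ratio_level + Normal(0, ratio_sd))
    agb_mean: float = 300.0
    agb_sd: float = 40.0
    bgb_ratio_low: float = 1.0
    bgb_ratio_high: float = 1.8
    bgb_ratio_sd: float = 0.25

    # enzyme activities, lognormal per diversity level (nmol g^-1 h^-1);
    # higher betaG at low diversity -> longer vector -> stronger C limitation
    enzyme_meanlog_low: dict = field(
        default_factory=lambda: {
            "bG": math.log(400.0), "NAG": math.log(50.0),
            "LAP": math.log(50.0), "ALP": math.log(150.0),
        }
    )
    enzyme_meanlog_high: dict = field(
        default_factory=lambda: {
            "bG": math.log(75.0), "NAG": math.log(50.0),
            "LAP": math.log(50.0), "ALP": math.log(150.0),
        }
    )
    enzyme_sdlog: float = 0.10

    # OTU count model
    n_otus_fungi: int = 600
    n_otus_bacteria: int = 1200
    sad_meanlog: float = 0.0
    sad_sdlog: float = 3.0
    depth: int = 50_000
    sample_jitter_sdlog: float = 0.6

    # guild annotation (fungi); per-plot multiplicative diversity effect on
    # guild proportions: exp(+effect) at high diversity, exp(-effect) at low
    guild_probs: dict = field(
        default_factory=lambda: {
            "saprotroph": 0.30, "pathotroph": 0.15,
            "symbiotroph": 0.10, "unassigned": 0.45,
        }
    )
    guild_diversity_log_effect: dict = field(
        default_factory=lambda: {"saprotroph": 0.4, "pathotroph": -0.4}
    )

    seed: int = 0

    def validate(self) -> None:
        if self.n_low_sites <= 0 or self.n_low_sites >= self.n_sites:
            raise ValidationError("need at least one site per diversity level")
        n_fun = len(DEFAULT_FUNCTIONS)
        for name, vals in (
            ("function_intercepts", self.function_intercepts),
            ("function_slopes", self.function_slopes),
            ("function_noise_sd", self.function_noise_sd),
        ):
            if len(vals) != n_fun:
                raise ValidationError(f"{name} must have {n_fun} entries")
        for name, val in (
            ("fungal_richness_sd", self.fungal_richness_sd),
            ("bacterial_richness_sd", self.bacterial_richness_sd),
            ("agb_sd", self.agb_sd),
            ("bgb_ratio_sd", self.bgb_ratio_sd),
            ("enzyme_sdlog", self.enzyme_sdlog),
            ("sad_sdlog", self.sad_sdlog),
            ("sample_jitter_sdlog", self.sample_jitter_sdlog),
        ):
            if val <= 0:
                raise ValidationError(f"{name} must be > 0")
        if any(s <= 0 for s in self.function_noise_sd):
            raise ValidationError("function_noise_sd entries must be > 0")
        if self.depth < 1000:
            raise ValidationError("sequencing depth must be >= 1000")
        if not math.isclose(sum(self.guild_probs.values()), 1.0, abs_tol=1e-9):
            raise ValidationError("guild probabilities must sum to 1")

    @property
    def n_plots(self) -> int:
        return self.n_sites * self.plots_per_site


@dataclass(frozen=True)
class GroundTruth:
    """Design values retained for recovery tests."""

    latent_fungal_richness: pd.Series
    latent_bacterial_richness: pd.Series
    function_slopes: tuple[float, ...]
    function_noise_sd: tuple[float, ...]
    designed_bgb_agb_difference: float          # low - high (negative)
    designed_vector_length_difference: float    # low - high (positive)
    guild_effect_signs: dict

    def expected_average_index_slope(self) -> float:
        """Design-implied OLS slope of the averaging SMF index on latent
        fungal richness.

        With F_j = a_j + b_j S + ε_j and Z-scoring by the realized column
        standard deviation ≈ sqrt(b_j² Var(S) + σ_j²), the index slope is
        the mean over functions of b_j / sqrt(b_j² Var(S) + σ_j²), using
        the realized sample variance of the latent richness S.
        """
        var_s = float(self.latent_fungal_richness.var(ddof=1))
        terms = [
            b / math.sqrt(b * b * var_s + s * s)
            for b, s in zip(self.function_slopes, self.function_noise_sd)
        ]
        return float(np.mean(terms))


@dataclass(frozen=True)
class SimulatedDataset:
    """Everything one field campaign would deliver, plus the ground truth."""

    function_matrix: FunctionMatrix
    plot_metadata: PlotMetadata
    enzyme_activities: pd.DataFrame
    otu_fungi: OTUTable
    otu_bacteria: OTUTable
    guild_map: GuildMap
    ground_truth: GroundTruth


def _plot_frame(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for s in range(cfg.n_sites):
        level = "low" if s < cfg.n_low_sites else "high"
        for p in range(cfg.plots_per_site):
            rows.append(
                {
                    "plot_id": f"S{s + 1}P{p + 1}",
                    "site_id": f"S{s + 1}",
                    "diversity_level": level,
                }
            )
    return pd.DataFrame(rows).set_index("plot_id")


def _vector_length_at(meanlogs: dict) -> float:
    bg = math.exp(meanlogs["bG"])
    nl = math.exp(meanlogs["NAG"]) + math.exp(meanlogs["LAP"])
    alp = math.exp(meanlogs["ALP"])
    return math.hypot(math.log(bg) / math.log(nl), math.log(bg) / math.log(alp))


def _simulate_latent_richness(cfg: SimulationConfig, frame: pd.DataFrame, rng) -> tuple[pd.Series, pd.Series]:
    low = frame["diversity_level"] == "low"
    s_f = np.where(low, cfg.fungal_richness_mean_low, cfg.fungal_richness_mean_high)
    s_b = np.where(low, cfg.bacterial_richness_mean_low, cfg.bacterial_richness_mean_high)
    s_f = s_f + rng.normal(0, cfg.fungal_richness_sd, len(frame))
    s_b = s_b + rng.normal(0, cfg.bacterial_richness_sd, len(frame))
    return (
        pd.Series(s_f, index=frame.index, name="latent_fungal_richness"),
        pd.Series(s_b, index=frame.index, name="latent_bacterial_richness"),
    )


def _simulate_functions(cfg: SimulationConfig, s_f: pd.Series, rng) -> FunctionMatrix:
    a = np.asarray(cfg.function_intercepts)
    b = np.asarray(cfg.function_slopes)
    sd = np.asarray(cfg.function_noise_sd)
    noise = rng.normal(0, 1, size=(len(s_f), len(a))) * sd
    values = a + np.outer(s_f.to_numpy(), b) + noise
    return FunctionMatrix(
        pd.DataFrame(values, index=s_f.index, columns=list(DEFAULT_FUNCTIONS))
    )


def _simulate_plots(cfg: SimulationConfig, frame: pd.DataFrame, rng) -> PlotMetadata:
    low = (frame["diversity_level"] == "low").to_numpy()
    agb = rng.normal(cfg.agb_mean, cfg.agb_sd, len(frame))
    agb = np.clip(agb, 50.0, None)
    ratio = np.where(low, cfg.bgb_ratio_low, cfg.bgb_ratio_high)
    ratio = np.clip(ratio + rng.normal(0, cfg.bgb_ratio_sd, len(frame)), 0.05, None)
    bgb = agb * ratio
    records = tuple(
        PlotRecord(
            plot_id=str(idx),
            site_id=str(frame.loc[idx, "site_id"]),
            diversity_level=str(frame.loc[idx, "diversity_level"]),
            agb=float(agb[i]),
            bgb=float(bgb[i]),
        )
        for i, idx in enumerate(frame.index)
    )
    return PlotMetadata(records)


def _simulate_enzymes(cfg: SimulationConfig, frame: pd.DataFrame, rng) -> pd.DataFrame:
    low = (frame["diversity_level"] == "low").to_numpy()
    cols = {}
    for enz in ("bG", "NAG", "LAP", "ALP"):
        mu = np.where(low, cfg.enzyme_meanlog_low[enz], cfg.enzyme_meanlog_high[enz])
        cols[enz] = np.exp(mu + rng.normal(0, cfg.enzyme_sdlog, len(frame)))
    return pd.DataFrame(cols, index=frame.index)


# Seeded abundance tiers (proportion, per-sample lognormal jitter sdlog, count).
# Chosen so every rarity category is populated in expectation at the default
# depth: tier means sit well inside their category's (min, max) band and the
# jitter widths make the "conditionally" categories cross the thresholds.
_TIERS = (
    ("AAT", 0.035, 0.10, 3),
    ("CAT", 0.008, 0.50, 4),
    ("CRAT", 0.002, 2.00, 3),
    ("MT", 0.001, 0.25, 6),
    ("CRT", 0.00015, 0.60, 4),
)


def _simulate_otu_table(
    cfg: SimulationConfig,
    frame: pd.DataFrame,
    latent_richness: pd.Series,
    n_otus: int,
    domain: str,
    rng,
    guild_labels: pd.Series | None = None,
) -> OTUTable:
    n_tier = sum(t[3] for t in _TIERS)
    n_tail = n_otus - n_tier
    if n_tail <= 0:
        raise ValidationError("n_otus too small for the seeded abundance tiers")

    tier_props = np.concatenate([np.full(c, p) for _, p, _, c in _TIERS])
    tier_sdlog = np.concatenate([np.full(c, s) for _, p, s, c in _TIERS])
    tier_mass = tier_props.sum()

    # long-tailed SAD for the tail, ranked most→least abundant, scaled to
    # the remaining proportion mass
    tail_raw = np.sort(rng.lognormal(cfg.sad_meanlog, cfg.sad_sdlog, n_tail))[::-1]
    tail_props = tail_raw / tail_raw.sum() * (1.0 - tier_mass)

    otu_ids = [f"{domain[0].upper()}OTU{k + 1:05d}" for k in range(n_otus)]
    n_samples = len(frame)
    counts = np.zeros((n_samples, n_otus), dtype=np.int64)
    is_low = (frame["diversity_level"] == "low").to_numpy()

    for i in range(n_samples):
        # depth-independent truncation: richer plots draw from more of the
        # SAD tail, so realized richness tracks the latent richness
        keep = int(np.clip(round(latent_richness.iloc[i]) - n_tier, 1, n_tail))
        tail_i = tail_props.copy()
        tail_i[keep:] = 0.0

        jitter_tier = rng.lognormal(0.0, tier_sdlog)
        jitter_tail = rng.lognormal(0.0, cfg.sample_jitter_sdlog, n_tail)
        props = np.concatenate([tier_props * jitter_tier, tail_i * jitter_tail])

        if guild_labels is not None:
            sign = -1.0 if is_low[i] else 1.0
            for guild, eff in cfg.guild_diversity_log_effect.items():
                mask = (guild_labels.to_numpy() == guild)
                props[mask] *= math.exp(sign * eff)

        props /= props.sum()
        counts[i] = rng.multinomial(cfg.depth, props)

    df = pd.DataFrame(counts, index=frame.index.rename("sample_id"), columns=otu_ids)
    observed = df.sum(axis=0) > 0
    return OTUTable(df.loc[:, observed], domain=domain)


def _simulate_guild_labels(cfg: SimulationConfig, n_otus: int, rng) -> pd.Series:
    guilds = list(cfg.guild_probs)
    probs = np.array([cfg.guild_probs[g] for g in guilds])
    labels = rng.choice(guilds, size=n_otus, p=probs)
    ids = [f"FOTU{k + 1:05d}" for k in range(n_otus)]
    return pd.Series(labels, index=ids)


def simulate_dataset(cfg: SimulationConfig | None = None, seed: int | None = None) -> SimulatedDataset:
    """Simulate one full study dataset; reproducible from the seed.

    ``seed`` overrides ``cfg.seed``.  Independent substreams are spawned per
    component in a fixed order.
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    root = np.random.default_rng(cfg.seed if seed is None else seed)
    streams = root.spawn(7)
    (rng_rich, rng_fun, rng_plots, rng_enz, rng_guild, rng_fungi, rng_bact) = streams

    frame = _plot_frame(cfg)
    s_f, s_b = _simulate_latent_richness(cfg, frame, rng_rich)
    fm = _simulate_functions(cfg, s_f, rng_fun)
    meta = _simulate_plots(cfg, frame, rng_plots)
    enzymes = _simulate_enzymes(cfg, frame, rng_enz)

    guild_labels = _simulate_guild_labels(cfg, cfg.n_otus_fungi, rng_guild)
    otu_fungi = _simulate_otu_table(
        cfg, frame, s_f, cfg.n_otus_fungi, "fungi", rng_fungi, guild_labels=guild_labels
    )
    otu_bacteria = _simulate_otu_table(
        cfg, frame, s_b, cfg.n_otus_bacteria, "bacteria", rng_bact
    )
    guild_map = GuildMap(
        {o: guild_labels[o] for o in otu_fungi.otu_ids if guild_labels.get(o, "unassigned") != "unassigned"}
    )

    truth = GroundTruth(
        latent_fungal_richness=s_f,
        latent_bacterial_richness=s_b,
        function_slopes=tuple(cfg.function_slopes),
        function_noise_sd=tuple(cfg.function_noise_sd),
        designed_bgb_agb_difference=cfg.bgb_ratio_low - cfg.bgb_ratio_high,
        designed_vector_length_difference=(
            _vector_length_at(cfg.enzyme_meanlog_low) - _vector_length_at(cfg.enzyme_meanlog_high)
        ),
        guild_effect_signs={
            g: int(np.sign(e)) for g, e in cfg.guild_diversity_log_effect.items()
        },
    )
    return SimulatedDataset(
        function_matrix=fm,
        plot_metadata=meta,
        enzyme_activities=enzymes,
        otu_fungi=otu_fungi,
        otu_bacteria=otu_bacteria,
        guild_map=guild_map,
        ground_truth=truth,
    )


# --- rarity fixtures -------------------------------------------------------

# Per-category margin-safe design levels (proportions): "base" holds in most
# samples, "special" in one designated sample where the category needs a
# cross-sample excursion.  All levels sit at least 2x away from the 1% and
# 0.01% thresholds.
_FIXTURE_LEVELS = {
    "AAT": {"base": 0.04, "special": None},
    "CAT": {"base": 0.002, "special": 0.02},
    "ART": {"base": 4e-5, "special": None},
    "CRT": {"base": 0.002, "special": 4e-5},
    "MT": {"base": 0.002, "special": None},
    "CRAT": {"base": 0.002, "special": (4e-5, 0.02)},
}


@dataclass(frozen=True)
class RarityFixture:
    """An OTU table with analytically planted rarity categories."""

    table: OTUTable
    expected: pd.Series            # intended category per planted OTU
    near_boundary: pd.Series       # True where a level is < 2x from a threshold
    filler_otu: str


def simulate_rarity_fixture(
    tier_spec: dict,
    n_samples: int = 10,
    depth: int = 100_000,
    seed: int = 0,
    domain: str = "fungi",
) -> RarityFixture:
    """Construct an OTU table whose rarity classification is known by design.

    ``tier_spec`` maps category names to OTU counts, e.g.
    ``{"AAT": 10, "MT": 10, "ART": 100}``.  Proportions are planted at least
    2× away from the 1% / 0.01% thresholds and converted to counts at depth
    ``depth``; the smallest planted level must be representable (at least
    one read), otherwise the minimal sufficient depth is reported.
    A filler OTU absorbs the remaining mass in each sample and carries no
    expected category.
    """
    if not tier_spec:
        raise ValidationError("tier_spec must name at least one category")
    bad = set(tier_spec) - set(CATEGORIES)
    if bad:
        raise ValidationError(f"unknown categor(ies): {', '.join(sorted(bad))}")
    if n_samples < 2:
        raise ValidationError("rarity fixtures need at least 2 samples")

    levels = []
    for cat, n in tier_spec.items():
        spec = _FIXTURE_LEVELS[cat]
        levels.append(spec["base"])
        special = spec["special"]
        if special is not None:
            levels.extend(special if isinstance(special, tuple) else (special,))
    min_level = min(levels)
    if min_level * depth < 1:
        need = math.ceil(1 / min_level)
        raise ValidationError(
            f"depth {depth} cannot represent the smallest planted relative "
            f"abundance {min_level:g}; minimal sufficient depth is {need}"
        )

    rng = np.random.default_rng(seed)
    otu_ids, expected, columns = [], [], []
    k = 0
    for cat, n in tier_spec.items():
        spec = _FIXTURE_LEVELS[cat]
        for j in range(n):
            col = np.full(n_samples, spec["base"], dtype=float)
            special = spec["special"]
            if special is not None:
                s1 = (k + j) % n_samples  # rotate the excursion sample
                if isinstance(special, tuple):
                    lo, hi = special
                    col[s1] = lo
                    col[(s1 + 1) % n_samples] = hi
                else:
                    col[s1] = special
            otu_id = f"{cat}_{j + 1:03d}"
            otu_ids.append(otu_id)
            expected.append(cat)
            columns.append(col)
        k += n

    props = np.column_stack(columns)
    if props.sum(axis=1).max() >= 0.9:
        raise ValidationError("planted proportions exceed 90% of a sample; reduce tier counts")
    counts = np.rint(props * depth).astype(np.int64)
    filler_id = "FILLER_000"
    filler = depth - counts.sum(axis=1)
    data = pd.DataFrame(
        np.column_stack([counts, filler]),
        index=pd.Index([f"s{i + 1}" for i in range(n_samples)], name="sample_id"),
        columns=otu_ids + [filler_id],
    )
    # shuffle OTU column order so category is not encoded by position
    order = rng.permutation(data.columns.to_numpy())
    data = data[order]

    exp = pd.Series(expected, index=pd.Index(otu_ids, name="otu_id"), name="expected_category")
    thresholds = (RARE_THRESHOLD, ABUNDANT_THRESHOLD)
    near = pd.Series(
        [
            any(t / 2 < lv < t * 2 for t in thresholds for lv in _level_set(c))
            for c in exp
        ],
        index=exp.index,
        name="near_boundary",
    )
    return RarityFixture(
        table=OTUTable(data, domain=domain),
        expected=exp,
        near_boundary=near,
        filler_otu=filler_id,
    )


def _level_set(cat: str) -> tuple:
    spec = _FIXTURE_LEVELS[cat]
    out = [spec["base"]]
    if spec["special"] is not None:
        s = spec["special"]
        out.extend(s if isinstance(s, tuple) else (s,))
    return tuple(out)


def config_to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)
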