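"""Synthetic cultivar panels, weather, senescence courses, and genotypes.

Everything downstream (curve fitting, mixed models, progress regression,
association scans) is exercised on data generated here with known ground
truth. Observations follow the plot-level decomposition

    P_ijkl = mu + c_i + y_j + cy_ij + YR_jk + YRG_jkl + e_ijkl

with cultivar ``c``, season ``y``, their interaction, season x replication
``YR``, season x replication x sub-group ``YRG``, and a residual. Each
random term draws from its own named stream of the root seed, so terms can
be added or zeroed without perturbing the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import stream
from .canopy_traits import senescence_curve

__all__ = [
    "PanelConfig",
    "SenescenceTruth",
    "GenoSimConfig",
    "GenotypeMatrix",
    "simulate_panel",
    "simulate_release_years",
    "simulate_senescence_course",
    "simulate_senescence_truths",
    "simulate_weather",
    "simulate_genotypes",
    "apply_causal_effect",
]

_VC_NAMES = ("sigma2_c", "sigma2_cy", "sigma2_yr", "sigma2_yrg", "sigma2_e")


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of a simulated cultivar x season x replicate panel."""

    n_cultivars: int = 174
    release_span: tuple[int, int] = (1966, 2013)
    n_seasons: int = 3
    n_reps: int = 2
    n_subgroups: int = 4
    trait_means: Mapping[str, float] = field(default_factory=lambda: {"yield": 8.0})
    trait_slopes: Mapping[str, float] = field(default_factory=lambda: {"yield": 0.0})
    var_components: Mapping[str, tuple] = field(
        default_factory=lambda: {"yield": (0.5, 0.3, 0.05, 0.05, 0.8)}
    )
    season_effects: Mapping[str, Sequence[float]] | None = None
    recent_weight: float = 0.66  # mass of release years in the last two decades
    seed: int = 0

    def __post_init__(self):
        if self.n_cultivars < 1 or self.n_seasons < 1 or self.n_reps < 1:
            raise ValueError("counts must be positive")
        if self.release_span[1] <= self.release_span[0]:
            raise ValueError("release span must be increasing")
        for trait, vc in self.var_components.items():
            if len(vc) != 5:
                raise ValueError(
                    f"{trait}: need 5 variance components {_VC_NAMES}, got {len(vc)}"
                )
            if any(v < 0 for v in vc):
                raise ValueError(f"{trait}: variances must be non-negative")

    @property
    def traits(self) -> list[str]:
        return list(self.trait_means)


@dataclass(frozen=True)
class SenescenceTruth:
    """True senescence parameters for one cultivar."""

    cultivar: str
    gla50: float
    s: float
    tt_heading: float
    lai_max: float

    def __post_init__(self):
        if not (self.gla50 > self.tt_heading > 0):
            raise ValueError("require GLA50 > tt_heading > 0")
        if self.s <= 0 or self.lai_max <= 0:
            raise ValueError("s and lai_max must be positive")


@dataclass(frozen=True)
class GenoSimConfig:
    """Configuration of a structured biallelic genotype simulation."""

    n_markers: int = 2000
    n_groups: int = 5
    missing_rate: float = 0.0
    chromosomes: tuple[str, ...] = ("1A", "2B", "3A", "5B", "6A")
    chrom_length_mbp: float = 800.0
    causal_region: tuple[str, float, float, float] | None = None  # (chrom, start, end, effect)
    n_causal: int = 5
    fst: float = 0.08
    maf_low: float = 0.05
    maf_high: float = 0.5
    hybrid_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.causal_region is not None and self.causal_region[0] not in self.chromosomes:
            raise ValueError("causal region chromosome not in the marker map")


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix (cultivars x markers) with a physical map.

    Dosages count copies of the alternate allele (0/1/2); missing values
    are NaN. ``marker_map`` has one row per marker with columns
    ``marker``, ``chromosome``, ``position_mbp``.
    """

    cultivars: list[str]
    markers: list[str]
    dosages: np.ndarray  # float, NaN = missing
    marker_map: pd.DataFrame
    groups: np.ndarray | None = None  # simulation truth, if known
    causal_markers: list[str] = field(default_factory=list)
    causal_values: pd.Series | None = None  # per-cultivar genetic value of the region

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.cultivars), len(self.markers)):
            raise ValueError("dosage matrix shape must be (n_cultivars, n_markers)")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if set(self.marker_map["marker"]) != set(self.markers) or len(self.marker_map) != len(self.markers):
            raise ValueError("marker map must cover every marker exactly once")

    @property
    def n_cultivars(self) -> int:
        return len(self.cultivars)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_markers(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.markers.index(m) for m in keep]
        mm = self.marker_map.set_index("marker").loc[list(keep)].reset_index()
        return GenotypeMatrix(
            cultivars=list(self.cultivars),
            markers=list(keep),
            dosages=self.dosages[:, idx].copy(),
            marker_map=mm,
            groups=None if self.groups is None else self.groups.copy(),
            causal_markers=[m for m in self.causal_markers if m in set(keep)],
            causal_values=self.causal_values,
        )


def simulate_release_years(config: PanelConfig) -> np.ndarray:
    """Release years over the span, weighted toward the last two decades.

    Mirrors historical panels in which roughly two-thirds of the cultivars
    were released in the final twenty years of the span. Sampling is with
    replacement on the year grid (several cultivars may share a year).
    """
    lo, hi = config.release_span
    years = np.arange(lo, hi + 1)
    recent = years >= hi - 19
    w = np.where(recent, config.recent_weight / max(recent.sum(), 1),
                 (1 - config.recent_weight) / max((~recent).sum(), 1))
    w = w / w.sum()
    rng = stream(config.seed, "release_years")
    drawn = np.sort(rng.choice(years, size=config.n_cultivars, replace=True, p=w))
    return drawn


def simulate_panel(config: PanelConfig) -> pd.DataFrame:
    """Simulate a long-format plot-level phenotype table.

    One row per cultivar x season x replicate x trait with columns
    ``cultivar, year_of_release, season, rep, subgroup, trait, value``.
    Cultivar effects are ``slope x (release year - span start)`` plus a
    draw from N(0, sigma2_c); all other random terms are independent
    mean-zero normals with their configured variances.
    """
    years = simulate_release_years(config)
    cultivars = [f"cv{i + 1:03d}" for i in range(config.n_cultivars)]
    seasons = [2015 + j for j in range(config.n_seasons)]
    reps = list(range(1, config.n_reps + 1))
    subgroups = stream(config.seed, "subgroups").integers(1, config.n_subgroups + 1,
                                                          size=config.n_cultivars)

    frames = []
    base = (
        pd.MultiIndex.from_product(
            [range(config.n_cultivars), range(config.n_seasons), range(config.n_reps)],
            names=["ci", "sj", "rk"],
        )
        .to_frame(index=False)
    )
    for trait in config.traits:
        vc = dict(zip(_VC_NAMES, config.var_components.get(trait, (0, 0, 0, 0, 0))))
        mu = float(config.trait_means[trait])
        slope = float(config.trait_slopes.get(trait, 0.0))

        rc = stream(config.seed, f"{trait}/cultivar")
        rcy = stream(config.seed, f"{trait}/cultivar_season")
        ryr = stream(config.seed, f"{trait}/season_rep")
        ryrg = stream(config.seed, f"{trait}/season_rep_subgroup")
        re_ = stream(config.seed, f"{trait}/residual")

        c = slope * (years - config.release_span[0]) + rc.normal(
            0.0, np.sqrt(vc["sigma2_c"]), config.n_cultivars
        )
        cy = rcy.normal(0.0, np.sqrt(vc["sigma2_cy"]), (config.n_cultivars, config.n_seasons))
        yr = ryr.normal(0.0, np.sqrt(vc["sigma2_yr"]), (config.n_seasons, config.n_reps))
        yrg = ryrg.normal(
            0.0, np.sqrt(vc["sigma2_yrg"]),
            (config.n_seasons, config.n_reps, config.n_subgroups),
        )
        eps = re_.normal(
            0.0, np.sqrt(vc["sigma2_e"]),
            (config.n_cultivars, config.n_seasons, config.n_reps),
        )
        season_eff = np.zeros(config.n_seasons)
        if config.season_effects and trait in config.season_effects:
            season_eff = np.asarray(config.season_effects[trait], dtype=float)
            if len(season_eff) != config.n_seasons:
                raise ValueError(f"{trait}: need {config.n_seasons} season effects")

        ci = base["ci"].to_numpy()
        sj = base["sj"].to_numpy()
        rk = base["rk"].to_numpy()
        sg = subgroups[ci] - 1
        value = (
            mu
            + c[ci]
            + season_eff[sj]
            + cy[ci, sj]
            + yr[sj, rk]
            + yrg[sj, rk, sg]
            + eps[ci, sj, rk]
        )
        frames.append(
            pd.DataFrame(
                {
                    "cultivar": np.asarray(cultivars)[ci],
                    "year_of_release": years[ci],
                    "season": np.asarray(seasons)[sj],
                    "rep": np.asarray(reps)[rk],
                    "subgroup": subgroups[ci],
                    "trait": trait,
                    "value": value,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_senescence_truths(
    panel: pd.DataFrame,
    seed: int = 0,
    gla50_base: float = 1450.0,
    gla50_slope: float = 2.0,
    gla50_sd: float = 30.0,
    s_mean: float = 18.0,
    s_sd: float = 3.0,
    tt_heading: float = 1150.0,
    lai_max_mean: float = 6.0,
) -> dict[str, SenescenceTruth]:
    """Per-cultivar senescence ground truth trending with year of release."""
    meta = panel[["cultivar", "year_of_release"]].drop_duplicates().sort_values("cultivar")
    rng = stream(seed, "senescence_truth")
    span_start = int(meta["year_of_release"].min())
    out = {}
    for _, row in meta.iterrows():
        gla50 = (
            gla50_base
            + gla50_slope * (row["year_of_release"] - span_start)
            + rng.normal(0.0, gla50_sd)
        )
        s = max(rng.normal(s_mean, s_sd), 2.0)
        lai = max(rng.normal(lai_max_mean, 0.5), 0.5)
        out[row["cultivar"]] = SenescenceTruth(
            cultivar=row["cultivar"],
            gla50=float(max(gla50, tt_heading + 50.0)),
            s=float(s),
            tt_heading=float(tt_heading),
            lai_max=float(lai),
        )
    return out


def simulate_senescence_course(
    truth: SenescenceTruth,
    sampling_tts: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Green-leaf observations (%) along a thermal-time sampling schedule.

    Noise-free courses are the senescence curve exactly; with noise, a
    Gaussian perturbation (sd in percentage points) is added and the result
    truncated to [0, 100]. The visual-scoring noise model is not documented
    in the source field protocol; truncated Gaussian is a stand-in.
    """
    tts = np.asarray(sampling_tts, dtype=float)
    if np.any(tts <= 0) or np.any(np.diff(tts) <= 0):
        raise ValueError("sampling thermal times must be positive and increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    y = 100.0 * senescence_curve(tts, truth.gla50, truth.s)
    if noise_sd > 0:
        rng = stream(seed, f"senescence_noise/{truth.cultivar}")
        y = y + rng.normal(0.0, noise_sd, size=len(tts))
    y = np.clip(y, 0.0, 100.0)
    return pd.DataFrame({"cultivar": truth.cultivar, "tt": tts, "green_pct": y})


def simulate_weather(
    n_days: int = 330,
    start: str = "2014-10-15",
    mean: float = 9.0,
    amplitude: float = 9.0,
    daily_sd: float = 2.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily mean temperatures over a winter-wheat season (sinusoid + noise)."""
    rng = stream(seed, "weather")
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = np.arange(n_days)
    # trough in mid winter (~90 days after an autumn sowing)
    tmean = mean - amplitude * np.cos(2 * np.pi * (doy - 90 + 365 / 2) / 365)
    tmean = tmean + rng.normal(0.0, daily_sd, n_days)
    return pd.DataFrame({"date": dates, "tmean": np.round(tmean, 2)})


def simulate_genotypes(config: GenoSimConfig, panel: pd.DataFrame) -> GenotypeMatrix:
    """Structured biallelic dosages for the panel's cultivars.

    Ancestral allele frequencies are uniform on [maf_low, maf_high]; each
    subpopulation's frequency is a Balding-Nichols beta draw around the
    ancestral one (divergence ``fst``). Lines are homozygous (dosage 0/2)
    except an optional hybrid fraction scored as heterozygous draws.
    Missingness is planted completely at random. If a causal region is
    configured, ``n_causal`` markers inside it receive the stated per-allele
    effect; the per-cultivar genetic value of the region is recorded in
    ``causal_values`` (add it to a trait with :func:`apply_causal_effect`).
    """
    cultivars = sorted(panel["cultivar"].unique())
    n = len(cultivars)
    m = config.n_markers
    rng_map = stream(config.seed, "geno/map")
    rng_freq = stream(config.seed, "geno/freq")
    rng_draw = stream(config.seed, "geno/draw")
    rng_miss = stream(config.seed, "geno/missing")
    rng_grp = stream(config.seed, "geno/groups")

    chroms = np.asarray(config.chromosomes)[rng_map.integers(0, len(config.chromosomes), m)]
    pos = rng_map.uniform(0.0, config.chrom_length_mbp, m)
    order = np.lexsort((pos, chroms))
    chroms, pos = chroms[order], pos[order]
    markers = [f"snp{i + 1:05d}" for i in range(m)]
    marker_map = pd.DataFrame(
        {"marker": markers, "chromosome": chroms, "position_mbp": np.round(pos, 4)}
    )

    groups = rng_grp.integers(0, config.n_groups, n)
    p_anc = rng_freq.uniform(config.maf_low, config.maf_high, m)
    if config.n_groups > 1 and config.fst > 0:
        a = p_anc * (1 - config.fst) / config.fst
        b = (1 - p_anc) * (1 - config.fst) / config.fst
        p_grp = rng_freq.beta(a, b, size=(config.n_groups, m))
        p_grp = np.clip(p_grp, 0.01, 0.99)
    else:
        p_grp = np.tile(p_anc, (config.n_groups, 1))

    p_line = p_grp[groups]  # n x m
    hybrids = rng_draw.random(n) < config.hybrid_fraction
    dos = np.where(rng_draw.random((n, m)) < p_line, 2.0, 0.0)
    if hybrids.any():
        # heterozygous lines: two independent gametes
        g1 = rng_draw.random((int(hybrids.sum()), m)) < p_line[hybrids]
        g2 = rng_draw.random((int(hybrids.sum()), m)) < p_line[hybrids]
        dos[hybrids] = g1.astype(float) + g2.astype(float)

    causal_markers: list[str] = []
    causal_values = None
    if config.causal_region is not None:
        chrom, lo, hi, effect = config.causal_region
        in_region = np.nonzero(
            (marker_map["chromosome"] == chrom)
            & (marker_map["position_mbp"] >= lo)
            & (marker_map["position_mbp"] <= hi)
        )[0]
        if len(in_region) == 0:
            raise ValueError("causal region contains no markers")
        chosen = rng_draw.choice(in_region, size=min(config.n_causal, len(in_region)),
                                 replace=False)
        causal_markers = [markers[i] for i in sorted(chosen)]
        value = dos[:, sorted(chosen)].sum(axis=1) * float(effect) / 2.0
        causal_values = pd.Series(value, index=cultivars, name="causal_value")

    if config.missing_rate > 0:
        mask = rng_miss.random((n, m)) < config.missing_rate
        dos[mask] = np.nan

    return GenotypeMatrix(
        cultivars=cultivars,
        markers=markers,
        dosages=dos,
        marker_map=marker_map,
        groups=groups,
        causal_markers=causal_markers,
        causal_values=causal_values,
    )


def apply_causal_effect(panel: pd.DataFrame, geno: GenotypeMatrix, trait: str) -> pd.DataFrame:
    """Add the genotype's causal-region value to one trait of the panel."""
    if geno.causal_values is None:
        raise ValueError("genotype matrix carries no causal region")
    out = panel.copy()
    sel = out["trait"] == trait
    if not sel.any():
        raise KeyError(f"trait {trait!r} not in panel")
    shift = out.loc[sel, "cultivar"].map(geno.causal_values)
    out.loc[sel, "value"] = out.loc[sel, "value"] + shift.to_numpy()
    return out
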