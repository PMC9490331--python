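"""Synthetic dendrometer datasets with known ground truth.

Generates multi-channel series that mimic the statistical structure of real
dendrometer monitoring data: cross-correlated weather channels (seasonal and
diurnal temperature, anti-correlated humidity, solar radiation, Poisson
rainfall, vapour pressure deficit from the Magnus saturation form, a leaky-
integrator soil water potential), a stem-radius channel built as cumulative
intermittent growth minus a reversible water-deficit shrinkage driven by
vpd, and heavy-tailed (log-normal) missing-data gaps per channel. Trees on
the same site share the site's weather; species differ in growth phenology
and shrinkage gain so that a species classifier has signal to learn.

The model is intentionally simple ecophysiology — growth gated by soil
moisture and night hours, shrinkage as a first-order relaxation toward
k * vpd — its purpose is to give the imputer learnable cross-channel
structure, not to simulate stem hydraulics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .timeseries_core import (
    MEASURED_CHANNELS,
    MultiChannelSeries,
    write_metadata,
    write_series,
)

__all__ = [
    "SiteParams",
    "TreeParams",
    "GapProcessParams",
    "SPECIES_PRESETS",
    "generate_weather",
    "generate_sr",
    "generate_dataset",
    "sample_gap_lengths",
    "write_dataset",
]


@dataclass(frozen=True)
class SiteParams:
    """Weather-generator parameters of one site."""

    temp_mean: float = 10.0          # degC annual mean
    seasonal_amp: float = 9.0        # degC amplitude of the annual cycle
    seasonal_phase_days: float = 15.0  # day of year of the annual minimum
    diurnal_amp: float = 5.0         # degC amplitude of the daily cycle
    rh_base: float = 75.0            # % humidity baseline
    rad_peak: float = 800.0          # W m-2 clear-sky midday maximum
    precip_events_per_day: float = 0.35  # episodic storms, not drizzle
    precip_mean_depth: float = 5.0   # mm per event
    noise_scale: float = 1.0         # multiplies all stochastic weather terms
    swp_recharge: float = 20.0       # kPa recovered per mm of rain
    swp_loss: float = 4.0            # kPa lost per kPa*h of vpd at saturation

    def __post_init__(self) -> None:
        if min(self.seasonal_amp, self.diurnal_amp, self.rad_peak,
               self.precip_events_per_day, self.precip_mean_depth) < 0:
            raise ValueError("site amplitudes and rates must be non-negative")


@dataclass(frozen=True)
class TreeParams:
    """Stem-radius-generator parameters of one tree."""

    species: str = "piceoid"
    growth_midpoint_day: float = 150.0   # day of year of peak growth
    growth_width_days: float = 40.0      # s.d. of the seasonal growth bell
    max_growth_rate: float = 2.5         # um/h at the bell peak
    shrinkage_gain: float = 30.0         # um of deficit per kPa of vpd
    relaxation_hours: float = 6.0        # water-deficit time constant
    swp_threshold: float = -450.0        # kPa; growth stops in drier soil
    noise_sigma: float = 1.0             # um measurement noise s.d.

    def __post_init__(self) -> None:
        if self.max_growth_rate < 0:
            raise ValueError("max_growth_rate must be >= 0")
        if self.relaxation_hours <= 0:
            raise ValueError("relaxation_hours must be > 0")


#: Two synthetic species with well-separated phenology and shrinkage response.
SPECIES_PRESETS: dict[str, TreeParams] = {
    "piceoid": TreeParams(
        species="piceoid",
        growth_midpoint_day=150.0,
        growth_width_days=40.0,
        max_growth_rate=2.5,
        shrinkage_gain=30.0,
        relaxation_hours=6.0,
        swp_threshold=-450.0,
    ),
    "fagoid": TreeParams(
        species="fagoid",
        growth_midpoint_day=200.0,
        growth_width_days=30.0,
        max_growth_rate=3.5,
        shrinkage_gain=60.0,
        relaxation_hours=10.0,
        swp_threshold=-300.0,
    ),
}


@dataclass(frozen=True)
class GapProcessParams:
    """Missing-data process: Poisson gap starts, log-normal gap lengths.

    Defaults give a heavy-tailed length distribution matching the tail of
    real acquisition outages: median about 5 h (most gaps are brief
    transmission glitches), 90th percentile below 30 h and 95th percentile
    below 80 h, with a small minority of gaps spanning days.
    """

    events_per_1000h: float = 2.0
    log_mu: float = 1.7
    log_sigma: float = 1.3
    independent_channels: bool = True

    def __post_init__(self) -> None:
        if self.events_per_1000h < 0:
            raise ValueError("gap event rate must be >= 0")


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

_HOURS_PER_YEAR = 8766.0  # 365.25 days


def magnus_vpd(temp_c: np.ndarray, rh_pct: np.ndarray) -> np.ndarray:
    """Vapour pressure deficit (kPa) from the Magnus saturation form:
    es = 0.6108 * exp(17.27 T / (T + 237.3)); vpd = es * (1 - rh/100)."""
    es = 0.6108 * np.exp(17.27 * temp_c / (temp_c + 237.3))
    return es * (1.0 - rh_pct / 100.0)


def _ar1(rng: np.random.Generator, n: int, rho: float, sigma: float) -> np.ndarray:
    eps = rng.normal(0.0, sigma, size=n)
    out = np.empty(n)
    out[0] = eps[0] / np.sqrt(1 - rho * rho)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + eps[i]
    return out


def generate_weather(
    site: SiteParams,
    n_hours: int,
    rng: np.random.Generator | int | None = None,
    start: str | pd.Timestamp = "2020-01-01",
) -> pd.DataFrame:
    """Hourly weather channels temp, rh, vpd, rad, swp, total_precip."""
    if n_hours < 24:
        raise ValueError("n_hours must be >= 24")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    idx = pd.date_range(pd.Timestamp(start), periods=n_hours, freq="h")
    hour = idx.hour.to_numpy(dtype=float)
    doy_h = (idx.dayofyear.to_numpy(dtype=float) - 1) * 24.0 + hour

    seasonal = -site.seasonal_amp * np.cos(
        2 * np.pi * (doy_h - site.seasonal_phase_days * 24.0) / _HOURS_PER_YEAR
    )
    diurnal = -site.diurnal_amp * np.cos(2 * np.pi * (hour - 14.0) / 24.0)
    temp = (
        site.temp_mean
        + seasonal
        + diurnal
        + site.noise_scale * _ar1(rng, n_hours, 0.9, 0.6)
    )

    rh = (
        site.rh_base
        - 2.5 * diurnal  # dry afternoons, humid nights
        - 0.8 * seasonal
        + site.noise_scale * _ar1(rng, n_hours, 0.85, 2.0)
    )
    rh = np.clip(rh, 5.0, 100.0)

    solar_elev = np.maximum(0.0, np.sin(np.pi * (hour - 6.0) / 12.0))
    season_rad = 0.65 + 0.35 * np.sin(
        2 * np.pi * (doy_h - (site.seasonal_phase_days + 91.3) * 24.0) / _HOURS_PER_YEAR
    )
    cloud = np.clip(
        1.0 - 0.5 * np.abs(_ar1(rng, n_hours, 0.95, 0.12 * site.noise_scale + 1e-12)),
        0.15,
        1.0,
    )
    rad = site.rad_peak * solar_elev * season_rad * cloud

    p_rain = min(site.precip_events_per_day / 24.0, 1.0)
    raining = rng.random(n_hours) < p_rain
    precip = np.where(
        raining, rng.exponential(site.precip_mean_depth, size=n_hours), 0.0
    )

    vpd = magnus_vpd(temp, rh)

    # leaky bucket: evaporative loss tapers off as the soil dries (dry soil
    # conducts poorly), so swp is continuously distributed rather than
    # pinned at a floor; rain recharges toward saturation (0 kPa)
    swp = np.empty(n_hours)
    s = -50.0
    dry_floor = 1500.0
    for t in range(n_hours):
        s = s + site.swp_recharge * precip[t] - site.swp_loss * vpd[t] * (1.0 + s / dry_floor)
        s = min(0.0, s)
        swp[t] = s

    return pd.DataFrame(
        {
            "temp": temp,
            "rh": rh,
            "vpd": vpd,
            "rad": rad,
            "swp": swp,
            "total_precip": precip,
        },
        index=idx,
    )


# ---------------------------------------------------------------------------
# Stem radius
# ---------------------------------------------------------------------------


def generate_sr(
    weather: pd.DataFrame,
    tree: TreeParams,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Stem radius (um): cumulative gated growth minus relaxing water deficit.

    Growth rate g(t) = max_rate * seasonal bell * [swp above threshold] *
    [night hours]; the water deficit W relaxes toward shrinkage_gain * vpd
    with the tree's relaxation time and never goes negative. SR = G - W plus
    white measurement noise.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    required = {"vpd", "swp"}
    if not required.issubset(weather.columns):
        raise ValueError(f"weather must contain channels {sorted(required)}")
    idx = weather.index
    n = len(idx)
    hour = idx.hour.to_numpy(dtype=float)
    doy = idx.dayofyear.to_numpy(dtype=float)
    night = (hour < 6.0) | (hour >= 20.0)
    bell = np.exp(-0.5 * ((doy - tree.growth_midpoint_day) / tree.growth_width_days) ** 2)
    wet = weather["swp"].to_numpy() > tree.swp_threshold
    g = tree.max_growth_rate * bell * wet * night
    G = np.cumsum(g)

    vpd = weather["vpd"].to_numpy()
    # saturating demand: stem water storage cannot shrink without bound,
    # so the deficit target levels off at high vpd
    target = tree.shrinkage_gain * vpd / (1.0 + vpd / 2.0)
    W = np.empty(n)
    w = 0.0
    a = 1.0 / tree.relaxation_hours
    for t in range(n):
        w = w + a * (target[t] - w)
        w = max(0.0, w)
        W[t] = w

    noise = rng.normal(0.0, tree.noise_sigma, size=n) if tree.noise_sigma > 0 else 0.0
    return G - W + noise


# ---------------------------------------------------------------------------
# Gaps and full datasets
# ---------------------------------------------------------------------------


def sample_gap_lengths(
    n: int, gp: GapProcessParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw gap lengths in whole hours (>= 1) from the log-normal process."""
    return np.maximum(1, np.round(rng.lognormal(gp.log_mu, gp.log_sigma, size=n))).astype(int)


def _apply_gaps(
    df: pd.DataFrame, gp: GapProcessParams, rng: np.random.Generator
) -> pd.DataFrame:
    out = df.copy()
    n = len(df)
    shared = None
    for col in out.columns:
        if gp.independent_channels or shared is None:
            k = rng.poisson(gp.events_per_1000h * n / 1000.0)
            starts = rng.integers(0, n, size=k)
            lengths = sample_gap_lengths(k, gp, rng)
            shared = (starts, lengths)
        starts, lengths = shared
        for s, L in zip(starts, lengths):
            out.iloc[s : s + L, out.columns.get_loc(col)] = np.nan
    return out


def generate_dataset(
    n_trees: int = 24,
    n_sites: int = 3,
    species: Sequence[str] = ("piceoid", "fagoid"),
    n_hours: int = 8760,
    gap_process: GapProcessParams | None = GapProcessParams(),
    seed: int = 0,
    noise_free: bool = False,
    start: str = "2020-01-01",
) -> tuple[list[MultiChannelSeries], list[MultiChannelSeries], pd.DataFrame]:
    """Generate (observed, clean ground truth, metadata) for a tree cohort.

    Trees are assigned round-robin to sites and species; trees of a site
    share its weather realization. ``noise_free`` zeroes the SR measurement
    noise so SR is a deterministic function of the weather channels. With
    ``gap_process=None`` (or a zero rate) observed equals clean.
    """
    if not (n_trees >= n_sites >= 1):
        raise ValueError("need n_trees >= n_sites >= 1")
    unknown = [s for s in species if s not in SPECIES_PRESETS]
    if unknown:
        raise ValueError(f"unknown species {unknown}; presets: {list(SPECIES_PRESETS)}")
    rng = np.random.default_rng(seed)
    site_weather = []
    for i in range(n_sites):
        site = SiteParams(
            temp_mean=10.0 + 1.5 * (i - (n_sites - 1) / 2),
            seasonal_phase_days=15.0 + 3.0 * i,
        )
        site_weather.append(generate_weather(site, n_hours, rng, start=start))

    observed: list[MultiChannelSeries] = []
    clean: list[MultiChannelSeries] = []
    meta_rows = []
    for j in range(n_trees):
        site_id = f"site{j % n_sites}"
        sp = species[j % len(species)]
        params = SPECIES_PRESETS[sp]
        if noise_free:
            params = replace(params, noise_sigma=0.0)
        weather = site_weather[j % n_sites]
        sr = generate_sr(weather, params, rng)
        df = pd.DataFrame({"SR": sr}, index=weather.index)
        for col in MEASURED_CHANNELS:
            if col != "SR":
                df[col] = weather[col]
        df = df[list(MEASURED_CHANNELS)]
        tree_id = f"tree{j:03d}"
        clean_series = MultiChannelSeries(tree_id, sp, site_id, df)
        if gap_process is not None and gap_process.events_per_1000h > 0:
            obs_df = _apply_gaps(df, gap_process, rng)
        else:
            obs_df = df.copy()
        observed.append(MultiChannelSeries(tree_id, sp, site_id, obs_df))
        clean.append(clean_series)
        meta_rows.append({"tree_id": tree_id, "species": sp, "site_id": site_id})
    return observed, clean, pd.DataFrame(meta_rows)


def write_dataset(
    observed: Sequence[MultiChannelSeries],
    meta: pd.DataFrame,
    out_dir: str | Path,
    clean: Sequence[MultiChannelSeries] | None = None,
) -> None:
    """Write per-tree CSVs plus metadata.csv (and ground truth under truth/)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in observed:
        write_series(s, out_dir / f"{s.tree_id}.csv")
    write_metadata(meta, out_dir / "metadata.csv")
    if clean is not None:
        truth_dir = out_dir / "truth"
        truth_dir.mkdir(exist_ok=True)
        for s in clean:
            write_series(s, truth_dir / f"{s.tree_id}.csv")
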