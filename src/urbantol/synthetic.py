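"""Synthetic observation worlds with known ground truth.

The generator emulates the observation process behind checklist-based
urban-tolerance analyses on a planar-km landscape:

* an artificial-light-at-night (ALAN) radiance surface built from point
  "cities" with exponentially decaying brightness plus non-negative noise;
* checklist effort that is spatially clustered toward bright pixels
  (community-science observers concentrate where people live), with
  realistic per-checklist effort covariates;
* negative-binomial species counts whose log-mean is linear in the local
  buffer-median radiance plus optional smooth effort/time effects — the
  radiance slope ``beta_alan`` is the quantity the downstream pipeline must
  recover;
* a species-trait table in which scaled body mass has a known effect on the
  true tolerance index.

Every generator is a pure function of its seed, so whole replicate worlds
are reproducible bit for bit.
"""

from __future__ import annotations

import datetime as _dt
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .checklists import CHECKLIST_COLUMNS
from .exceptions import ConfigurationError, ExtentError
from .raster import RadianceRaster, median_radiance_at_points


@dataclass
class EffortDistributions:
    """Per-checklist effort covariate distributions.

    Durations are lognormal around ~45 min, travel distances lognormal
    around ~1.5 km (stationary checklists have distance 0), observer counts
    1 + Poisson, start times normal around 08:00 — all clipped to the
    plausible recording ranges of checklist data.
    """

    duration_logmean: float = np.log(45.0)
    duration_logsd: float = 0.7
    distance_logmean: float = np.log(1.5)
    distance_logsd: float = 0.8
    p_stationary: float = 0.4
    observers_rate: float = 0.7
    start_time_mean_min: float = 480.0
    start_time_sd_min: float = 150.0


@dataclass
class ViolationFractions:
    """Fractions of checklists generated to violate each inclusion rule."""

    incomplete: float = 0.0
    protocol: float = 0.0
    duration: float = 0.0
    distance: float = 0.0
    date: float = 0.0


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic world (planar-km coordinates)."""

    extent_km: tuple[float, float] = (100.0, 100.0)
    pixel_km: float = 1.0
    n_cities: int = 5
    city_peak_radiance: float = 6.0
    decay_km: float = 12.0
    noise_sd: float = 0.05
    n_checklists: int = 20_000
    brightness_bias: float = 1.0
    bias_epsilon: float = 0.05
    effort: EffortDistributions = field(default_factory=EffortDistributions)
    violations: ViolationFractions = field(default_factory=ViolationFractions)
    presence_marker_frac: float = 0.01
    start_date: _dt.date = _dt.date(2010, 1, 1)
    end_date: _dt.date = _dt.date(2021, 6, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_km[0] <= 0 or self.extent_km[1] <= 0:
            raise ConfigurationError("extent must be positive")
        if self.pixel_km <= 0:
            raise ConfigurationError("pixel size must be > 0")
        if self.n_cities < 0:
            raise ConfigurationError("n_cities must be >= 0")
        if self.brightness_bias < 0:
            raise ConfigurationError("brightness_bias must be >= 0")
        if self.city_peak_radiance < 0 or self.noise_sd < 0:
            raise ConfigurationError("radiance parameters must be >= 0")


@dataclass
class SpeciesTruth:
    """Ground-truth abundance model for one synthetic species."""

    species_code: str
    beta0: float = -0.5
    beta_alan: float = 0.0
    theta: float = 1.5
    # smooth effort effects on the log-mean; zero by default
    duration_coef: float = 0.0     # per unit log(duration / 60 min)
    observers_coef: float = 0.0    # per unit log(n_observers)
    distance_coef: float = 0.0     # per km travelled
    doy_amp: float = 0.0           # seasonal sinusoid amplitude
    doy_phase: float = 0.0         # day-of-year of the seasonal peak
    tod_amp: float = 0.0           # time-of-day sinusoid amplitude
    tod_phase_min: float = 480.0   # minutes-of-day of the diel peak

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("NB dispersion theta must be > 0")
        if not np.isfinite(self.beta_alan):
            raise ValueError("beta_alan must be finite")


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, stream]))


def make_alan_raster(config: SyntheticConfig) -> RadianceRaster:
    """Build the radiance surface: sum of exponentially decaying city glows
    plus truncated-normal (non-negative) noise."""
    rng = _rng(config.seed, 1)
    w, h = config.extent_km
    ncols = int(round(w / config.pixel_km))
    nrows = int(round(h / config.pixel_km))
    cx = (np.arange(ncols) + 0.5) * config.pixel_km
    cy = (np.arange(nrows) + 0.5) * config.pixel_km
    gx, gy = np.meshgrid(cx, cy)
    vals = np.zeros((nrows, ncols))
    cities = rng.uniform([0, 0], [w, h], size=(config.n_cities, 2))
    for ux, uy in cities:
        d = np.hypot(gx - ux, gy - uy)
        vals += config.city_peak_radiance * np.exp(-d / config.decay_km)
    if config.noise_sd > 0:
        noise = stats.truncnorm.rvs(
            0, np.inf, loc=0.0, scale=config.noise_sd,
            size=vals.shape, random_state=rng,
        )
        vals += noise
    return RadianceRaster(0.0, 0.0, config.pixel_km, vals, crs="planar-km")


def simulate_checklists(
    config: SyntheticConfig, raster: RadianceRaster
) -> pd.DataFrame:
    """Draw checklist locations, dates and effort covariates.

    Location density is proportional to ``(radiance + eps) ** bias``, so a
    positive bias concentrates effort around cities the way community
    scientists do.  Configurable fractions of checklists violate each
    inclusion rule (incomplete, bad protocol, overlong, overdistance,
    off-window date) to exercise the filters downstream.
    """
    rng = _rng(config.seed, 2)
    n = config.n_checklists
    eff = config.effort

    flat = raster.values.ravel()
    weights = (np.nan_to_num(flat) + config.bias_epsilon) ** config.brightness_bias
    weights = weights / weights.sum()
    pix = rng.choice(flat.size, size=n, p=weights)
    rows, cols = np.divmod(pix, raster.ncols)
    x = raster.x0 + (cols + rng.uniform(0, 1, n)) * raster.pixel
    y = raster.y0 + (rows + rng.uniform(0, 1, n)) * raster.pixel

    stationary = rng.uniform(0, 1, n) < eff.p_stationary
    protocol = np.where(stationary, "Stationary", "Traveling").astype(object)
    duration = np.clip(
        rng.lognormal(eff.duration_logmean, eff.duration_logsd, n), 5.0, 300.0
    )
    distance = np.where(
        stationary,
        0.0,
        np.clip(rng.lognormal(eff.distance_logmean, eff.distance_logsd, n), 0.05, 5.0),
    )
    observers = 1 + rng.poisson(eff.observers_rate, n)
    start_min = np.clip(
        rng.normal(eff.start_time_mean_min, eff.start_time_sd_min, n), 0.0, 1439.0
    )
    n_days = (config.end_date - config.start_date).days
    dates = pd.to_datetime(config.start_date) + pd.to_timedelta(
        rng.integers(0, n_days + 1, n), unit="D"
    )
    complete = np.ones(n, dtype=bool)

    # inject rule violations on independently drawn rows
    viol = config.violations
    def _mask(frac: float) -> np.ndarray:
        return rng.uniform(0, 1, n) < frac

    complete[_mask(viol.incomplete)] = False
    protocol[_mask(viol.protocol)] = "Incidental"
    m = _mask(viol.duration)
    duration[m] = rng.uniform(301.0, 600.0, m.sum())
    m = _mask(viol.distance)
    distance[m] = rng.uniform(5.1, 20.0, m.sum())
    protocol[(distance > 0) & stationary] = "Traveling"
    m = _mask(viol.date)
    dates = pd.Series(dates)
    dates[m] = pd.Timestamp(config.start_date) - pd.to_timedelta(
        rng.integers(1, 365, m.sum()), unit="D"
    )

    df = pd.DataFrame(
        {
            "checklist_id": [f"S{i:07d}" for i in range(n)],
            "lon": x,
            "lat": y,
            "date": pd.to_datetime(dates.values),
            "time_started_min": start_min,
            "duration_min": duration,
            "distance_km": distance,
            "n_observers": observers,
            "protocol": protocol,
            "complete": complete,
        }
    )
    return df[CHECKLIST_COLUMNS]


def effort_log_mean(truth: SpeciesTruth, checklists: pd.DataFrame) -> np.ndarray:
    """The smooth effort/time contribution to the log-mean count."""
    doy = pd.to_datetime(checklists["date"]).dt.dayofyear.to_numpy(float)
    tod = checklists["time_started_min"].to_numpy(float)
    dur = checklists["duration_min"].to_numpy(float)
    dist = checklists["distance_km"].to_numpy(float)
    obs = checklists["n_observers"].to_numpy(float)
    return (
        truth.duration_coef * np.log(dur / 60.0)
        + truth.observers_coef * np.log(obs)
        + truth.distance_coef * dist
        + truth.doy_amp * np.cos(2 * np.pi * (doy - truth.doy_phase) / 365.25)
        + truth.tod_amp * np.cos(2 * np.pi * (tod - truth.tod_phase_min) / 1440.0)
    )


def simulate_species_counts(
    checklists: pd.DataFrame,
    raster: RadianceRaster,
    truth: SpeciesTruth,
    buffer_radius_km: float = 5.0,
    seed: int | None = None,
    x_alan: np.ndarray | None = None,
) -> pd.DataFrame:
    """Negative-binomial counts for one species on every checklist.

    ``log mu = beta0 + beta_alan * x_ALAN + effort effects`` with ``x_ALAN``
    the buffer-median radiance at the checklist; counts are drawn from the
    gamma-Poisson mixture equivalent to NB2 with dispersion ``theta``.
    A configurable fraction of positive counts is recorded as a
    presence-only marker, mirroring real checklist data.
    """
    if seed is None:
        seed = 3
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, 1000, zlib.crc32(truth.species_code.encode())])
    )
    if x_alan is None:
        x_alan = median_radiance_at_points(
            raster,
            checklists["lon"].to_numpy(float),
            checklists["lat"].to_numpy(float),
            buffer_radius_km,
        )
    if np.any(np.isnan(x_alan)):
        raise ExtentError("some checklists fall outside the raster extent")
    eta = truth.beta0 + truth.beta_alan * x_alan + effort_log_mean(truth, checklists)
    mu = np.exp(np.clip(eta, -30.0, 15.0))
    lam = rng.gamma(truth.theta, mu / truth.theta)
    y = rng.poisson(lam).astype(float)

    out = checklists.copy()
    out["species_code"] = truth.species_code
    out["x_alan"] = x_alan
    out["count"] = y
    out["detection"] = y >= 1
    out["presence_only"] = False
    return out


def mark_presence_only(
    dataset: pd.DataFrame, frac: float, seed: int
) -> pd.DataFrame:
    """Flag a fraction of detections as presence-only ('X') records."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    out = dataset.copy()
    det = out["detection"].to_numpy()
    mark = det & (rng.uniform(0, 1, len(out)) < frac)
    out.loc[mark, "presence_only"] = True
    return out


def write_synthetic_world(
    config: SyntheticConfig,
    truths: list[SpeciesTruth],
    out_dir,
    buffer_radius_km: float = 5.0,
) -> dict:
    """Generate a world and write it in the pipeline's file formats.

    Produces ``alan.grid`` (text raster) and ``checklists.tsv`` (EBD layout,
    detection rows only — non-detections are implicit in the complete
    checklists, as in real checklist data).  Returns the paths plus the
    in-memory per-species datasets for direct use.
    """
    from pathlib import Path

    from .checklists import write_checklists

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raster = make_alan_raster(config)
    raster.write_text(out / "alan.grid")
    checklists = simulate_checklists(config, raster)
    datasets = {}
    obs_parts = []
    for truth in truths:
        ds = simulate_species_counts(
            checklists, raster, truth, buffer_radius_km, seed=config.seed
        )
        ds = mark_presence_only(ds, config.presence_marker_frac, config.seed)
        datasets[truth.species_code] = ds
        det = ds.loc[
            ds["detection"],
            ["checklist_id", "species_code", "count", "presence_only"],
        ].copy()
        det.loc[det["presence_only"], "count"] = np.nan
        obs_parts.append(det)
    obs = pd.concat(obs_parts, ignore_index=True)
    write_checklists(checklists, obs, out / "checklists.tsv")
    return {
        "raster_path": out / "alan.grid",
        "checklists_path": out / "checklists.tsv",
        "raster": raster,
        "checklists": checklists,
        "datasets": datasets,
    }


def simulate_trait_table(
    n_species: int,
    mass_effect: float = -0.7,
    noise_sd: float = 0.4,
    seed: int = 0,
    intercept: float = 0.3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Trait table plus the true tolerance index per species.

    Body mass is log-uniform on 100-4000 g; breadth traits are integer
    counts over their category vocabularies (6 nesting substrates, 30
    habitat classes); the first species cycle through the guild and
    migratory levels so every factor level is represented.  The true index
    is ``intercept + mass_effect * z(mass) + N(0, noise_sd)`` — only body
    mass carries signal, matching the hypothesis the trait model probes.
    """
    if n_species < 10:
        raise ValueError("need at least 10 species for a trait table")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    mass = np.exp(rng.uniform(np.log(100.0), np.log(4000.0), n_species))
    nest = rng.integers(1, 7, n_species)
    habitat = rng.integers(1, 31, n_species)
    guilds = ["generalist", "bird specialist", "mammal specialist", "fish specialist"]
    guild = np.array(
        [guilds[i % 4] for i in range(4)]
        + list(rng.choice(guilds, n_species - 4, p=[0.4, 0.2, 0.2, 0.2]))
    )
    migratory = np.array(
        ["local dispersal", "partial migrant"]
        + list(rng.choice(["local dispersal", "partial migrant"], n_species - 2))
    )
    codes = [f"sp{i:02d}" for i in range(n_species)]
    traits = pd.DataFrame(
        {
            "species_code": codes,
            "body_mass_g": mass,
            "nest_substrate_breadth": nest,
            "habitat_breadth": habitat,
            "feeding_guild": guild,
            "migratory_status": migratory,
        }
    )
    z = (mass - mass.mean()) / mass.std(ddof=1)
    true_index = intercept + mass_effect * z + rng.normal(0.0, noise_sd, n_species)
    return traits, pd.Series(true_index, index=pd.Index(codes, name="species_code"))
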