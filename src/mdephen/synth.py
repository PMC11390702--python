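"""Synthetic flowering floras and climate series for testing the pipeline.

The generator emulates the shape of a province-level flowering compilation:
multiple regions along a latitude gradient, each with a bounded flowering
season whose length shrinks with latitude (12 months at 19 deg N down to 7 at
47 deg N, echoing the tropical-to-boreal span of the real provinces), species
flowering windows at month resolution with durations drawn from a truncated
geometric (many short, few long flowering periods), and seasonally sinusoidal
monthly climate. Window placement is controllable:

- ``mde_null``: uniform over feasible positions — data that conform to the
  geometric-constraint null.
- ``mid_peaked``: placements concentrated at the domain centre (stronger than
  the null's overlap peak).
- ``edge_peaked``: placements piled at both season edges — detectable
  anti-mid-domain signal.
- ``climate_coupled``: placement probability increases with the (noise-free)
  minimum temperature at the window midpoint, coupling richness to climate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .flora import ClimateRecord, FloweringRecord, TemporalDomain

PLACEMENT_MODES = ("mde_null", "mid_peaked", "edge_peaked", "climate_coupled")

#: latitude span of the emulated study region (tropical island to boreal NE)
_LAT_SOUTH, _LAT_NORTH = 19.2, 46.8


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters for the generator.

    Defaults mirror the emulated compilation: 27 regions spanning 19-47 deg N,
    woody fraction ~0.35 of species, domain length falling linearly from 12
    to 7 months across the gradient, truncated-geometric durations with mean
    around 3 months.
    """

    n_regions: int = 27
    latitudes: tuple[float, ...] | None = None  # ascending; default even grid
    species_per_region: int = 600
    woody_fraction: float = 0.35
    domain_n_south: int = 12  # domain length at the southern end
    domain_n_north: int = 7  # ... and at the northern end
    duration_p: float = 0.35  # geometric success prob; mean duration ~1/p
    durations: tuple[int, ...] | None = None  # empirical multiset override
    placement_mode: str = "mde_null"
    concentration: float = 0.15  # peaking scale for mid/edge modes (fraction of n)
    climate_effect: float = 0.25  # per-degC log-weight for climate_coupled
    noise_scale: float = 1.0  # multiplier on climate noise SDs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.placement_mode not in PLACEMENT_MODES:
            raise ValueError(f"placement_mode must be one of {PLACEMENT_MODES}")
        if not 0 <= self.woody_fraction <= 1:
            raise ValueError("woody_fraction must lie in [0, 1]")
        if self.latitudes is not None:
            lats = self.latitudes
            if len(lats) != self.n_regions:
                raise ValueError("latitudes length must equal n_regions")
            if any(b <= a for a, b in zip(lats, lats[1:])):
                raise ValueError("latitudes must be strictly increasing")
        if self.species_per_region < 0:
            raise ValueError("species_per_region must be >= 0")
        if not 0 < self.duration_p <= 1:
            raise ValueError("duration_p must lie in (0, 1]")

    def region_latitudes(self) -> tuple[float, ...]:
        if self.latitudes is not None:
            return self.latitudes
        if self.n_regions == 1:
            return (_LAT_SOUTH,)
        return tuple(np.linspace(_LAT_SOUTH, _LAT_NORTH, self.n_regions))

    def region_ids(self) -> tuple[str, ...]:
        return tuple(f"R{i+1:02d}" for i in range(self.n_regions))


def demo_config(seed: int = 0, **overrides) -> SynthConfig:
    """Small preset (5 regions x 300 species) that runs end-to-end quickly."""
    cfg = SynthConfig(n_regions=5, species_per_region=300, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Region geometry and climate surfaces
# ---------------------------------------------------------------------------


def domain_for_latitude(config: SynthConfig, lat: float) -> TemporalDomain:
    """Latitude-dependent flowering season: length interpolates linearly from
    the southern to the northern end; the start shifts later as the season
    shortens (full-year at the south, roughly Apr-Oct at the north)."""
    frac = (lat - _LAT_SOUTH) / (_LAT_NORTH - _LAT_SOUTH)
    frac = min(max(frac, 0.0), 1.0)
    n = int(round(config.domain_n_south + frac * (config.domain_n_north - config.domain_n_south)))
    n = max(1, min(12, n))
    start = 1 + int(round(0.6 * (12 - n)))
    return TemporalDomain(start, start + n - 1)


def _tmin_mean(lat: float, month: int) -> float:
    """Noise-free minimum-temperature surface: warmer and flatter in the
    south, colder with larger annual range in the north; peak in July."""
    base = 22.0 - 0.55 * (lat - _LAT_SOUTH)
    amp = 4.0 + 0.35 * (lat - _LAT_SOUTH)
    return base + amp * math.cos(2.0 * math.pi * (month - 7) / 12.0)


def generate_climate(config: SynthConfig) -> list[ClimateRecord]:
    """Seasonal monthly climate per region, reproducible by seed.

    t_min has latitude-dependent mean and amplitude (July peak). Monthly
    precipitation follows a sharply summer-concentrated (von Mises-shaped)
    annual cycle, and sunshine a June-peaked sinusoid with a semi-annual
    harmonic — three distinct waveforms, so the pooled covariates are
    correlated but not collinear (as in real monsoon-climate normals). Noise
    SDs (0.5 degC, 10 mm, 8 h) scale with ``noise_scale``.
    """
    rng = np.random.default_rng([config.seed, 0xC11])
    records: list[ClimateRecord] = []
    for region, lat in zip(config.region_ids(), config.region_latitudes()):
        for month in range(1, 13):
            phase7 = 2.0 * math.pi * (month - 7) / 12.0
            t_min = _tmin_mean(lat, month) + rng.normal(0.0, 0.5 * config.noise_scale)
            # summer-monsoon precipitation: sharp July peak, wetter in the south
            mmp_base = 110.0 - 1.5 * (lat - _LAT_SOUTH)
            mmp = mmp_base * math.exp(1.2 * math.cos(phase7)) / 1.842  # /I0(1.2)
            mmp += rng.normal(0.0, 10.0 * config.noise_scale)
            sunshine = (
                170.0
                + 0.8 * (lat - _LAT_SOUTH)
                + 45.0 * math.cos(2.0 * math.pi * (month - 6) / 12.0)
                + 20.0 * math.cos(4.0 * math.pi * (month - 3) / 12.0)
                + rng.normal(0.0, 8.0 * config.noise_scale)
            )
            records.append(
                ClimateRecord(
                    region_id=region,
                    month=month,
                    t_min=round(t_min, 3),
                    mmp=round(max(mmp, 0.0), 3),
                    sunshine=round(min(max(sunshine, 0.0), 744.0), 3),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Flora generation
# ---------------------------------------------------------------------------


def _truncated_geometric_probs(p: float, n: int) -> np.ndarray:
    d = np.arange(1, n + 1)
    w = p * (1 - p) ** (d - 1)
    return w / w.sum()


def _start_weights(
    config: SynthConfig,
    domain: TemporalDomain,
    d: int,
    tmin_by_month: dict[int, float] | None,
) -> np.ndarray:
    """Unnormalized placement weights over feasible 0-based starts."""
    n = domain.n_bins
    starts = np.arange(n - d + 1)
    mids = starts + (d - 1) / 2.0  # 0-based midpoint position
    mode = config.placement_mode
    if mode == "mde_null":
        return np.ones_like(starts, dtype=float)
    if mode == "mid_peaked":
        center = (n - 1) / 2.0
        sigma = max(config.concentration * n, 1e-6)
        return np.exp(-0.5 * ((mids - center) / sigma) ** 2)
    if mode == "edge_peaked":
        edge_dist = np.minimum(mids, (n - 1) - mids)
        scale = max(config.concentration * n, 1e-6)
        return np.exp(-edge_dist / scale)
    # climate_coupled: flowering favours warm months — weights follow the
    # realized monthly t_min (seasonal cycle plus anomalies) at the window
    # midpoint, so richness carries a genuinely temperature-driven signal
    months = np.asarray(domain.months())
    mid_months = months[np.clip(np.round(mids).astype(int), 0, n - 1)]
    t = np.array([tmin_by_month[int(m)] for m in mid_months])
    return np.exp(config.climate_effect * (t - t.max()))


def generate_flora(config: SynthConfig) -> tuple[list[FloweringRecord], dict]:
    """Draw species flowering windows per region under the configured mode.

    Returns the records and a truth-metadata dict recording the mode, the
    per-region domains and the generator parameters (provenance that result
    files can round-trip).
    """
    rng = np.random.default_rng([config.seed, 0xF10])
    records: list[FloweringRecord] = []
    domains: dict[str, str] = {}
    tmin_series: dict[str, dict[int, float]] = {}
    if config.placement_mode == "climate_coupled":
        # couple to the same realized climate the analysis later regresses on
        for c in generate_climate(config):
            tmin_series.setdefault(c.region_id, {})[c.month] = c.t_min
    for region, lat in zip(config.region_ids(), config.region_latitudes()):
        domain = domain_for_latitude(config, lat)
        domains[region] = str(domain)
        n = domain.n_bins
        if config.durations is not None:
            pool = np.asarray([d for d in config.durations if d <= n], dtype=int)
            if pool.size == 0:
                raise ValueError(f"no feasible durations for domain length {n}")
            durs = pool[rng.integers(0, pool.size, size=config.species_per_region)]
        else:
            probs = _truncated_geometric_probs(config.duration_p, n)
            durs = rng.choice(np.arange(1, n + 1), size=config.species_per_region, p=probs)
        woody = rng.random(config.species_per_region) < config.woody_fraction
        # categorical start draw per distinct duration (weights depend on d)
        for i, (d, w) in enumerate(zip(durs, woody)):
            weights = _start_weights(config, domain, int(d), tmin_series.get(region))
            probs_s = weights / weights.sum()
            s = rng.choice(len(probs_s), p=probs_s)
            first_lin = domain.start_month + int(s)
            last_lin = first_lin + int(d) - 1
            records.append(
                FloweringRecord(
                    species_id=f"{region}_sp{i+1:04d}",
                    region_id=region,
                    growth_form="woody" if w else "herbaceous",
                    first_month=(first_lin - 1) % 12 + 1,
                    last_month=(last_lin - 1) % 12 + 1,
                )
            )
    truth = {
        "placement_mode": config.placement_mode,
        "seed": config.seed,
        "n_regions": config.n_regions,
        "species_per_region": config.species_per_region,
        "woody_fraction": config.woody_fraction,
        "duration_p": config.duration_p,
        "concentration": config.concentration,
        "climate_effect": config.climate_effect,
        "domains": domains,
    }
    return records, truth


@dataclass(frozen=True)
class StudyBundle:
    """Everything the pipeline ingests: flora, climate, latitudes, truth."""

    config: SynthConfig
    flora: tuple[FloweringRecord, ...]
    climate: tuple[ClimateRecord, ...]
    latitudes: dict[str, float] = field(hash=False)
    truth: dict = field(hash=False)


def generate_study(config: SynthConfig | None = None, seed: int | None = None) -> StudyBundle:
    """One call yielding the full synthetic study (flora + climate + latitudes)."""
    config = config or SynthConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    flora, truth = generate_flora(config)
    climate = generate_climate(config)
    latitudes = dict(zip(config.region_ids(), config.region_latitudes()))
    return StudyBundle(
        config=config,
        flora=tuple(flora),
        climate=tuple(climate),
        latitudes=latitudes,
        truth=truth,
    )
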