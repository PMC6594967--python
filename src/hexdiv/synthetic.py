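"""Synthetic occurrence-data generator with known ground truth.

Emulates the statistical structure of a NW-Pacific-style occurrence
extraction: a species pool with log-series abundances and box-shaped
latitude/longitude/depth ranges, a bimodal latitudinal richness gradient
(primary peak near 10°N, equatorial dip, secondary high-latitude rise),
exponential richness decline with depth, strongly clustered sampling
effort, and temperature/salinity/productivity-like covariates that trend
with latitude and depth. The generator returns a :class:`SyntheticTruth`
carrying every surface it used, so parameter-recovery tests can compare
pipeline output against the generating world.

Sampling model
--------------
Sampling *events* (site visits) are drawn from the effort surface (a
mixture of a uniform background and Gaussian hotspots over ocean raster
cells, hotspot centres placed where richness is high, as real campaign
effort is). Each event has one jittered location, one date drawn from
its raster cell's pool of ``dates_per_site`` dates, and
K ~ 1 + Poisson(records_per_sample − 1) records, so per-sample intensity
is independent of local effort and rarefied richness is comparable
across effort levels. Each record draws a depth from the world's depth
profile (uniform above the decay onset, exponential below), then a
species with probability proportional to a tempered abundance among
species whose range covers that position and depth; a small cosmopolitan
contingent guarantees the admissible set is never empty.

Local richness acts through two channels: species-range centres are
placed with density proportional to the richness surface, and — when the
world is environmentally coupled — the abundance distribution is
*tempered* by the local value of the coupling variable (selection
probability ∝ abundance^β, β decreasing with available energy), so that
environmentally favourable locations yield more distinct species per
unit sampling effort: the evenness component of diversity that
rarefaction is designed to detect. At zero coupling β is constant and
richness varies only through range placement.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .grid import STUDY_BBOX, EnvRaster
from .occurrences import OccurrenceRecord

ENV_VARIABLES = ("temperature", "dissolved_oxygen", "productivity", "chlorophyll",
                 "current_velocity", "saturated_oxygen", "salinity", "nitrate")

ENV_UNITS = {
    "temperature": "degC",
    "dissolved_oxygen": "mol.m-3",
    "productivity": "g.m-3.d-1",
    "chlorophyll": "mg.m-3",
    "current_velocity": "m.s-1",
    "saturated_oxygen": "mL.L-1",
    "salinity": "PSS",
    "nitrate": "mol.m-3",
}

MAX_DEPTH_M = 10_900.0


@dataclass
class GeneratorParams:
    """Knobs of the synthetic world; defaults are the stated study structure."""

    n_species: int = 3000
    n_records: int = 50_000
    bbox: tuple[float, float, float, float] = STUDY_BBOX
    # latitudinal richness shape: two Gaussian bumps minus an equatorial dip
    primary_peak_deg: float = 10.0
    primary_sigma_deg: float = 12.0
    secondary_peak_deg: float = 80.0
    secondary_sigma_deg: float = 8.0
    secondary_amplitude: float = 0.5
    dip_depth_fraction: float = 0.6
    dip_sigma_deg: float = 4.0
    baseline: float = 0.15
    # bathymetric decay
    depth_efold_m: float = 800.0
    depth_onset_m: float = 100.0
    # sampling effort
    n_hotspots: int = 5
    hotspot_concentration: float = 0.8      # effort fraction in hotspots
    hotspot_sigma_deg: float = 3.0
    dates_per_site: int = 3
    records_per_sample: float = 5.0         # mean sampling-event intensity
    # environment coupling
    env_coupling: float = 0.0               # 0 = pure latitude/depth shape, 1 = env-driven
    coupling_variable: str = "temperature"
    env_noise_scale: float = 1.0
    # abundance distribution
    log_series_shape: float = 0.98
    # rasters / mask
    raster_arcmin: float = 5.0
    land_strip: tuple[float, float] = (60.0, 70.0)
    land_strip_ocean_lon: tuple[float, float] = (170.0, 180.0)
    seed: int = 0

    def validate(self) -> None:
        lat_min, lat_max, lon_min, lon_max = self.bbox
        if not (lat_min < lat_max and lon_min < lon_max):
            raise ValueError(f"invalid bounding box {self.bbox!r}")
        if self.n_species < 0 or self.n_records < 0 or self.n_hotspots < 0:
            raise ValueError("counts must be nonnegative")
        if self.depth_efold_m <= 0 or self.raster_arcmin <= 0 or self.dates_per_site <= 0:
            raise ValueError("scales must be positive")
        if not 0.0 <= self.env_coupling <= 1.0:
            raise ValueError("env_coupling must lie in [0, 1]")
        if not 0.0 < self.log_series_shape < 1.0:
            raise ValueError("log_series_shape must lie in (0, 1)")
        if self.coupling_variable not in ENV_VARIABLES:
            raise ValueError(f"unknown coupling variable {self.coupling_variable!r}")


@dataclass
class SpeciesRange:
    species_id: str
    lat_center: float
    lat_width: float
    lon_center: float
    lon_width: float
    depth_min: float
    depth_max: float
    abundance: float
    habitat: str                      # "benthic" or "pelagic"

    def covers(self, lat: float, lon: float, depth: float) -> bool:
        return (abs(lat - self.lat_center) <= self.lat_width / 2
                and abs(lon - self.lon_center) <= self.lon_width / 2
                and self.depth_min <= depth <= self.depth_max)


@dataclass
class SyntheticTruth:
    species_pool: list[SpeciesRange]
    richness_surface: Callable        # (lat, lon, depth) -> expected species density
    effort_surface: np.ndarray        # per raster cell, sums to 1 over ocean
    env_rasters: dict[str, EnvRaster]
    env_fields: dict[str, Callable]   # (lat, lon, depth) -> value
    ocean_mask: EnvRaster
    seed: int
    params: GeneratorParams
    evenness_surface: Callable = None  # (lat, lon, depth) -> [0, 1]; 0 = log-series skew
    _pool_arrays: dict = field(default_factory=dict, repr=False)

    def pool_arrays(self) -> dict[str, np.ndarray]:
        if not self._pool_arrays:
            p = self.species_pool
            self._pool_arrays = {
                "lat_c": np.array([s.lat_center for s in p]),
                "lat_w": np.array([s.lat_width for s in p]),
                "lon_c": np.array([s.lon_center for s in p]),
                "lon_w": np.array([s.lon_width for s in p]),
                "z_min": np.array([s.depth_min for s in p]),
                "z_max": np.array([s.depth_max for s in p]),
                "abund": np.array([s.abundance for s in p]),
            }
        return self._pool_arrays


# ---------------------------------------------------------------------------
# Component surfaces
# ---------------------------------------------------------------------------

def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def latitude_shape(lat, p: GeneratorParams):
    """Bimodal latitude profile, floored at a positive baseline."""
    lat = np.asarray(lat, dtype=float)
    s = (p.baseline
         + np.exp(-0.5 * ((lat - p.primary_peak_deg) / p.primary_sigma_deg) ** 2)
         + p.secondary_amplitude * np.exp(-0.5 * ((lat - p.secondary_peak_deg) / p.secondary_sigma_deg) ** 2)
         - p.dip_depth_fraction * np.exp(-0.5 * (lat / p.dip_sigma_deg) ** 2))
    return np.maximum(s, 0.05 * p.baseline)


def depth_factor(depth, p: GeneratorParams):
    """1 above the onset depth, exponential e-folding decay below."""
    depth = np.asarray(depth, dtype=float)
    return np.exp(-np.maximum(depth - p.depth_onset_m, 0.0) / p.depth_efold_m)


def depth_profile_quantile(u, p: GeneratorParams, max_depth: float = MAX_DEPTH_M):
    """Inverse CDF of the record-depth density (flat to onset, exp decay after)."""
    u = np.asarray(u, dtype=float)
    a, e = p.depth_onset_m, p.depth_efold_m
    tail = e * (1.0 - np.exp(-(max_depth - a) / e))
    total = a + tail
    flat = u * total <= a
    z_flat = u * total
    z_tail = a - e * np.log(1.0 - (u * total - a) / e)
    return np.where(flat, z_flat, np.minimum(z_tail, max_depth))


def shallow_fraction_closed_form(threshold: float, p: GeneratorParams,
                                 max_depth: float = MAX_DEPTH_M) -> float:
    """P(record depth <= threshold) under the generator's depth profile."""
    a, e = p.depth_onset_m, p.depth_efold_m
    num = a + e * (1.0 - math.exp(-(threshold - a) / e)) if threshold > a else threshold
    den = a + e * (1.0 - math.exp(-(max_depth - a) / e))
    return num / den


def efold_for_shallow_fraction(fraction: float, threshold: float = 500.0,
                               onset: float = 100.0, max_depth: float = MAX_DEPTH_M) -> float:
    """Depth e-folding scale whose profile puts ``fraction`` of records above ``threshold``."""
    def f(e):
        p = GeneratorParams(depth_efold_m=e, depth_onset_m=onset)
        return shallow_fraction_closed_form(threshold, p, max_depth) - fraction
    return brentq(f, 10.0, 50_000.0)


def _anomaly_field(seed: int, stream: int, bbox, amplitude: float, n_modes: int = 6):
    """Smooth pseudo-random regional anomaly over the box.

    Longitudinal modes (3.5–6 cycles across the box — mesoscale-to-gyre
    wavelengths) modulated by a slow latitudinal envelope. The envelope
    slope is kept small so that adding the anomaly to a basin-scale
    latitude trend never overturns its monotonicity.
    """
    rng = _rng(seed, stream)
    lon_min, lon_max = bbox[2], bbox[3]
    lat_min, lat_max = bbox[0], bbox[1]
    span = lon_max - lon_min
    lat_span = lat_max - lat_min
    freqs = rng.uniform(3.0, 4.5, n_modes)
    phases = rng.uniform(0.0, 2 * math.pi, n_modes)
    amps = np.full(n_modes, amplitude / math.sqrt(n_modes)) * rng.choice([-1, 1], n_modes)
    env_phase = rng.uniform(0.0, 2 * math.pi)

    def g(lat, lon):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        out = np.zeros(np.broadcast(lat, lon).shape, dtype=float)
        for f, ph, a in zip(freqs, phases, amps):
            out = out + a * np.sin(2 * math.pi * f * (lon - lon_min) / span + ph)
        envelope = 1.0 + 0.3 * np.cos(2 * math.pi * (lat - lat_min) / lat_span + env_phase)
        return out * envelope

    return g


def _build_env_fields(p: GeneratorParams) -> dict[str, Callable]:
    """Smooth environmental fields of (lat, lon, depth) with seeded lon-noise.

    Temperature is strictly decreasing in latitude and in depth; other
    variables carry their own latitude/depth trends. Noise is a smooth
    function of longitude only, so it never breaks the latitude trend.
    """
    b = p.bbox
    ns = p.env_noise_scale
    # regional anomalies (western-boundary-current scale, e.g. a few °C
    # for temperature) are carried by the designated coupling variable
    # only; the other variables are smooth basin-scale trends, so that
    # driver recovery is identifiable at the spline sizes used downstream
    amplitudes = {
        "temperature": 5.5, "dissolved_oxygen": 0.05, "productivity": 0.006,
        "chlorophyll": 0.12, "current_velocity": 0.06,
        "saturated_oxygen": 0.8, "salinity": 0.8, "nitrate": 0.006,
    }
    noise = {}
    for k, (v, amp) in enumerate(amplitudes.items()):
        if v == p.coupling_variable:
            noise[v] = _anomaly_field(p.seed, 100 + k, b, amp * ns)
        else:
            noise[v] = lambda la, lo: np.zeros(np.broadcast(np.asarray(la), np.asarray(lo)).shape)

    def fld(fn):
        def wrapped(lat, lon, depth):
            lat = np.asarray(lat, dtype=float)
            lon = np.asarray(lon, dtype=float)
            depth = np.asarray(depth, dtype=float)
            return fn(lat, lon, depth)
        return wrapped

    fields = {
        "temperature": fld(lambda la, lo, z:
                           29.0 - 27.0 * la / 90.0 + noise["temperature"](la, lo)
                           - 6.0 * (1.0 - np.exp(-z / 1500.0)) - 2e-4 * z),
        "salinity": fld(lambda la, lo, z:
                        33.0 + 1.5 * la / 90.0 + noise["salinity"](la, lo)
                        + 0.4 * (1.0 - np.exp(-z / 1000.0))),
        "dissolved_oxygen": fld(lambda la, lo, z:
                                0.25 + 0.10 * la / 90.0 + noise["dissolved_oxygen"](la, lo)
                                - 0.06 * np.exp(-0.5 * ((z - 800.0) / 500.0) ** 2)),
        "saturated_oxygen": fld(lambda la, lo, z:
                                5.5 + 2.5 * la / 90.0 + noise["saturated_oxygen"](la, lo)
                                - 5e-5 * z),
        "productivity": fld(lambda la, lo, z:
                            (0.016 - 0.008 * la / 90.0
                             + noise["productivity"](la, lo)) * np.exp(-z / 250.0) + 1e-4),
        "chlorophyll": fld(lambda la, lo, z:
                           (0.42 - 0.20 * la / 90.0
                            + noise["chlorophyll"](la, lo)) * np.exp(-z / 150.0) + 1e-3),
        "current_velocity": fld(lambda la, lo, z:
                                0.20 - 0.10 * la / 90.0
                                + noise["current_velocity"](la, lo) * np.exp(-z / 500.0)),
        "nitrate": fld(lambda la, lo, z:
                       0.01 + 0.02 * la / 90.0 + noise["nitrate"](la, lo)
                       + 0.015 * (1.0 - np.exp(-z / 800.0))),
    }
    return fields


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

def generate_world(params: GeneratorParams) -> SyntheticTruth:
    """Build the full synthetic world (deterministic given ``params.seed``)."""
    params.validate()
    p = params
    lat_min, lat_max, lon_min, lon_max = p.bbox
    cs = p.raster_arcmin / 60.0
    n_rows = int(round((lat_max - lat_min) / cs))
    n_cols = int(round((lon_max - lon_min) / cs))
    lat_centers = lat_min + cs * (np.arange(n_rows) + 0.5)
    lon_centers = lon_min + cs * (np.arange(n_cols) + 0.5)

    # ocean mask: all ocean except a mostly-land latitude strip
    mask = np.ones((n_rows, n_cols))
    strip = (lat_centers >= p.land_strip[0]) & (lat_centers < p.land_strip[1])
    ocean_window = (lon_centers >= p.land_strip_ocean_lon[0]) & (lon_centers <= p.land_strip_ocean_lon[1])
    mask[np.ix_(strip, ~ocean_window)] = 0.0
    ocean_mask = EnvRaster("ocean_mask", lat_min, lon_min, p.raster_arcmin, mask)

    env_fields = _build_env_fields(p)
    env_rasters = {}
    LA, LO = np.meshgrid(lat_centers, lon_centers, indexing="ij")
    for name in ENV_VARIABLES:
        vals = env_fields[name](LA, LO, np.zeros_like(LA))
        env_rasters[name] = EnvRaster(name, lat_min, lon_min, p.raster_arcmin,
                                      vals, units=ENV_UNITS[name])

    # richness surface: convex mix of the latitude/depth shape and a
    # monotone transform of the coupling variable
    cpl_field = env_fields[p.coupling_variable]
    surf = cpl_field(LA, LO, np.zeros_like(LA))
    ref_hi = float(surf.max())
    # elasticity of log richness with respect to the coupling variable,
    # per unit of its surface range / 30 (≈ per °C for temperature)
    elasticity = 0.12 * 30.0 / max(float(surf.max() - surf.min()), 1e-9)
    shape_max = float(latitude_shape(np.linspace(lat_min, lat_max, 2001), p).max())

    def richness_surface(lat, lon, depth):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        depth = np.asarray(depth, dtype=float)
        base = latitude_shape(lat, p) / shape_max
        env = np.exp(elasticity * (cpl_field(lat, lon, depth * 0.0) - ref_hi))
        mix = (1.0 - p.env_coupling) * base + p.env_coupling * env
        return mix * depth_factor(depth, p)

    ref_lo = float(surf.min())

    def evenness_surface(lat, lon, depth):
        # energy-evenness coupling: favourable environments host more
        # even communities; a linear ramp in the coupling variable so the
        # coupled signal has comparable strength across the whole basin;
        # constant (0) when the world is uncoupled
        val = cpl_field(np.asarray(lat, dtype=float),
                        np.asarray(lon, dtype=float),
                        np.asarray(depth, dtype=float) * 0.0)
        ramp = np.clip((val - ref_lo) / max(ref_hi - ref_lo, 1e-9), 0.0, 1.0)
        return p.env_coupling * ramp

    effort = _effort_surface(p, mask, lat_centers, lon_centers, richness_surface)
    pool = _species_pool(p, richness_surface, mask, lat_centers, lon_centers)
    return SyntheticTruth(species_pool=pool, richness_surface=richness_surface,
                          effort_surface=effort, env_rasters=env_rasters,
                          env_fields=env_fields, ocean_mask=ocean_mask,
                          seed=p.seed, params=p, evenness_surface=evenness_surface)


def _effort_surface(p: GeneratorParams, mask, lat_centers, lon_centers,
                    richness_surface=None) -> np.ndarray:
    """Uniform background + Gaussian hotspots, normalised over ocean cells.

    Hotspot centres are drawn with probability proportional to surface
    richness: sampling campaigns concentrate where biodiversity (reefs,
    marginal seas) concentrates, as in real occurrence archives.
    """
    rng = _rng(p.seed, 1)
    LA, LO = np.meshgrid(lat_centers, lon_centers, indexing="ij")
    ocean = mask == 1
    if not ocean.any():
        raise ValueError("ocean mask has no ocean cells")
    # cos(lat) converts per-km² intensity to per-grid-cell probability on
    # the lat/lon raster (high-latitude cells are smaller)
    coslat = np.cos(np.deg2rad(LA))
    w = np.zeros_like(mask, dtype=float)
    w[ocean] = (1.0 - p.hotspot_concentration) * coslat[ocean] / coslat[ocean].sum()
    if p.n_hotspots > 0 and p.hotspot_concentration > 0:
        oc_idx = np.argwhere(ocean)
        if richness_surface is not None:
            dens = np.asarray(richness_surface(LA[ocean], LO[ocean],
                                               np.zeros(int(ocean.sum()))), dtype=float)
            dens = np.maximum(dens, 0.0) * coslat[ocean]
            dens = dens / dens.sum()
            centers = oc_idx[rng.choice(len(oc_idx), size=p.n_hotspots, p=dens)]
        else:
            centers = oc_idx[rng.integers(0, len(oc_idx), p.n_hotspots)]
        hot = np.zeros_like(w)
        for ci, cj in centers:
            d2 = (LA - lat_centers[ci]) ** 2 + (LO - lon_centers[cj]) ** 2
            hot += np.exp(-0.5 * d2 / p.hotspot_sigma_deg ** 2)
        hot *= coslat
        hot[~ocean] = 0.0
        if hot.sum() > 0:
            w += p.hotspot_concentration * hot / hot.sum()
    total = w.sum()
    if total <= 0:
        raise ValueError("effort surface is identically zero")
    return w / total


def _species_pool(p: GeneratorParams, richness_surface, mask,
                  lat_centers, lon_centers) -> list[SpeciesRange]:
    """Species ranges with centres drawn from the surface richness density."""
    rng = _rng(p.seed, 2)
    if p.n_species == 0:
        return []
    lat_min, lat_max, lon_min, lon_max = p.bbox
    # coarse density over ocean cells (surface, depth 0)
    step = max(1, len(lat_centers) // 120)
    la = lat_centers[::step]
    lo = lon_centers[::step]
    LA, LO = np.meshgrid(la, lo, indexing="ij")
    # cos(lat): per-km² density on a lat/lon grid
    dens = (richness_surface(LA, LO, np.zeros_like(LA)) * mask[::step, ::step]
            * np.cos(np.deg2rad(LA)))
    dens = dens.ravel()
    dens = dens / dens.sum()
    picks = rng.choice(len(dens), size=p.n_species, p=dens)
    ci, cj = np.unravel_index(picks, LA.shape)
    jitter = (rng.random((2, p.n_species)) - 0.5) * (la[1] - la[0] if len(la) > 1 else 1.0)
    lat_c = np.clip(la[ci] + jitter[0], lat_min, lat_max)
    lon_c = np.clip(lo[cj] + jitter[1], lon_min, lon_max)
    # ranges elongated east–west (as basin-scale marine ranges are):
    # narrow in latitude (thermal limits), wide in longitude
    lat_w = np.clip(rng.lognormal(math.log(8.0), 0.3, p.n_species), 2.0, lat_max - lat_min)
    lon_w = np.clip(rng.lognormal(math.log(12.0), 0.3, p.n_species), 4.0, lon_max - lon_min)
    z_c = depth_profile_quantile(rng.random(p.n_species), p)
    z_half = rng.lognormal(math.log(300.0), 0.8, p.n_species)
    z_lo = np.maximum(z_c - z_half, 0.0)
    z_hi = np.minimum(z_c + z_half, MAX_DEPTH_M)
    abund = rng.logseries(p.log_series_shape, p.n_species).astype(float)
    habitat = np.where(rng.random(p.n_species) < 0.5, "benthic", "pelagic")

    # cosmopolitan contingent: full-box, full-depth ranges so every
    # location/depth has at least one admissible species
    n_cosmo = max(2, p.n_species // 1000)
    cosmo = rng.choice(p.n_species, size=min(n_cosmo, p.n_species), replace=False)
    lat_c[cosmo] = (lat_min + lat_max) / 2.0
    lat_w[cosmo] = lat_max - lat_min
    lon_c[cosmo] = (lon_min + lon_max) / 2.0
    lon_w[cosmo] = lon_max - lon_min
    z_lo[cosmo] = 0.0
    z_hi[cosmo] = MAX_DEPTH_M

    # clip ranges into the study box
    lat_w = np.minimum(lat_w, 2 * np.minimum(lat_c - lat_min, lat_max - lat_c))
    lon_w = np.minimum(lon_w, 2 * np.minimum(lon_c - lon_min, lon_max - lon_c))
    return [SpeciesRange(f"sp{k:05d}", float(lat_c[k]), float(lat_w[k]),
                         float(lon_c[k]), float(lon_w[k]), float(z_lo[k]),
                         float(z_hi[k]), float(abund[k]), str(habitat[k]))
            for k in range(p.n_species)]


# ---------------------------------------------------------------------------
# Occurrence sampling
# ---------------------------------------------------------------------------

def sample_occurrences(truth: SyntheticTruth, n_records: int, seed: int
                       ) -> list[OccurrenceRecord]:
    """Draw ``n_records`` occurrence records from the synthetic world."""
    if n_records < 0:
        raise ValueError("n_records must be nonnegative")
    if n_records == 0:
        return []
    if truth.effort_surface.sum() <= 0:
        raise ValueError("effort surface is identically zero")
    p = truth.params
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 777]))
    lat_min, lat_max, lon_min, lon_max = p.bbox
    cs = p.raster_arcmin / 60.0

    w = truth.effort_surface.ravel()
    n_rows, n_cols = truth.effort_surface.shape

    # effort scales the number of sampling events, not their intensity:
    # events (site visits) are drawn from the effort surface, each event
    # yields K ~ 1 + Poisson(records_per_sample - 1) records at one
    # jittered location on one date, so per-sample intensity is
    # independent of local effort (ES50 can be compared across effort)
    rps = max(p.records_per_sample, 1.0)
    n_draw = int(math.ceil(n_records / rps * 1.6)) + 20
    ev_cells = rng.choice(len(w), size=n_draw, p=w)
    ev_k = 1 + rng.poisson(rps - 1.0, n_draw)
    cum = np.cumsum(ev_k)
    n_events = int(np.searchsorted(cum, n_records)) + 1
    while cum[n_events - 1] < n_records:          # extremely unlikely top-up
        extra_c = rng.choice(len(w), size=n_draw, p=w)
        extra_k = 1 + rng.poisson(rps - 1.0, n_draw)
        ev_cells = np.r_[ev_cells, extra_c]
        ev_k = np.r_[ev_k, extra_k]
        cum = np.cumsum(ev_k)
        n_events = int(np.searchsorted(cum, n_records)) + 1
    ev_cells = ev_cells[:n_events]
    ev_k = ev_k[:n_events]
    ev_k[-1] -= int(cum[n_events - 1] - n_records)

    ci, cj = np.unravel_index(ev_cells, (n_rows, n_cols))
    jit = (rng.random((n_events, 2)) - 0.5) * 0.9 * cs
    ev_lat = np.clip(lat_min + cs * (ci + 0.5) + jit[:, 0], lat_min, lat_max)
    ev_lon = np.clip(lon_min + cs * (cj + 0.5) + jit[:, 1], lon_min, lon_max)

    # per-raster-cell pools of dates_per_site dates (2000–2019)
    base = _dt.date(2000, 1, 1)
    pool_offsets = {}
    for c in np.unique(ev_cells):
        pool_offsets[int(c)] = rng.integers(0, 7305, size=p.dates_per_site)
    d_idx = rng.integers(0, p.dates_per_site, n_events)
    ev_date = [base + _dt.timedelta(days=int(pool_offsets[int(c)][k]))
               for c, k in zip(ev_cells, d_idx)]

    rec_event = np.repeat(np.arange(n_events), ev_k)
    lats = ev_lat[rec_event]
    lons = ev_lon[rec_event]
    dates = [ev_date[e] for e in rec_event]
    depths = depth_profile_quantile(rng.random(n_records), p)

    arr = truth.pool_arrays()
    # energy-tempered evenness. The base tempering 0.7 reflects that
    # occurrence archives under-sample dominance (presence is recorded
    # once seen); energy coupling flattens the distribution further,
    # down to beta = 0.3 where the evenness surface peaks.
    if truth.evenness_surface is not None:
        ev = np.clip(np.asarray(truth.evenness_surface(lats, lons, depths),
                                dtype=float), 0.0, 1.0)
    else:
        ev = np.zeros(n_records)
    beta = 0.7 - 0.45 * ev
    log_abund = np.log(arr["abund"])
    species_idx = np.empty(n_records, dtype=int)
    chunk = 512
    for s in range(0, n_records, chunk):
        sl = slice(s, min(s + chunk, n_records))
        la, lo, z = lats[sl, None], lons[sl, None], depths[sl, None]
        ok = ((np.abs(la - arr["lat_c"]) <= arr["lat_w"] / 2)
              & (np.abs(lo - arr["lon_c"]) <= arr["lon_w"] / 2)
              & (z >= arr["z_min"]) & (z <= arr["z_max"]))
        probs = ok * np.exp(beta[sl, None] * log_abund[None, :])
        totals = probs.sum(axis=1)
        if np.any(totals <= 0):  # cosmopolitans make this unreachable
            raise RuntimeError("no admissible species at a sampled location")
        cum = np.cumsum(probs, axis=1)
        u = rng.random(cum.shape[0]) * totals
        species_idx[sl] = (cum < u[:, None]).sum(axis=1)

    pool = truth.species_pool
    records = []
    for k in range(n_records):
        records.append(OccurrenceRecord(
            record_id=f"r{k}",
            raw_name=pool[species_idx[k]].species_id,
            accepted_name=pool[species_idx[k]].species_id,
            latitude=float(lats[k]), longitude=float(lons[k]),
            depth=float(depths[k]),
            event_date=dates[k],
            dataset_id="synthetic",
        ))
    return records


# ---------------------------------------------------------------------------
# Log-series fitting (generator self-check)
# ---------------------------------------------------------------------------

def fit_log_series(abundances) -> float:
    """Maximum-likelihood log-series shape from integer abundances.

    The log-series MLE solves  mean(n) = −x / ((1−x)·ln(1−x))  for x.
    """
    n = np.asarray(abundances, dtype=float)
    if np.any(n < 1):
        raise ValueError("abundances must be >= 1")
    mean = n.mean()
    if mean <= 1.0 + 1e-12:
        return 1e-9

    def f(x):
        return -x / ((1.0 - x) * math.log(1.0 - x)) - mean

    return brentq(f, 1e-9, 1.0 - 1e-12)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_world(truth: SyntheticTruth, out_dir) -> dict:
    """Write rasters, mask and a truth summary; returns the summary dict."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    for name, raster in truth.env_rasters.items():
        raster.write_ascii(os.path.join(out_dir, f"{name}.asc"))
    truth.ocean_mask.write_ascii(os.path.join(out_dir, "ocean_mask.asc"))
    summary = {
        "seed": truth.seed,
        "params": dataclasses.asdict(truth.params),
        "n_species": len(truth.species_pool),
        "env_variables": list(truth.env_rasters),
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
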