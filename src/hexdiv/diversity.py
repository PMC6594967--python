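"""Alpha, gamma and rarefied (ES50) species richness per spatial unit.

A *sample* is a unique combination of event date and (rounded) location
at which at least one species was recorded. Sample-based rarefaction
gives the expected number of species in a random draw of m samples
(Hurlbert's expectation over incidences):

    E[S_m] = S_obs − Σ_i C(N − n_i, m) / C(N, m)

where N is the number of samples in the unit and n_i the number of
samples containing species i. ES50 is E[S_50]. A record-based mode using
per-species record counts (classic individual-based rarefaction) is also
provided. Binomial-coefficient ratios are evaluated in log-gamma space;
standard errors come from a seeded bootstrap over samples.

Aggregation levels mirror the analysis design: hexagonal cells (alpha =
observed species per cell), 5° latitude bands (gamma = total species per
band, plus the mean cell-level ES50), and 100-m depth intervals.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .grid import (BAND_WIDTH, DEPTH_INTERVAL, HexGrid, assign_band,
                   assign_depth_interval, assign_to_cell, band_edges,
                   band_ocean_area)
from .occurrences import SHALLOW_DEEP_THRESHOLD_M, OccurrenceRecord

DEFAULT_M = 50
DEFAULT_BOOTSTRAP_B = 200
LOCATION_DECIMALS = 4  # ~11 m; sample identity = (date, rounded lat/lon)


@dataclass
class SampleEvent:
    """One sampling event: all records sharing a date and a location."""

    sample_id: str
    cell_id: str | None
    date: object
    location: tuple[float, float]
    species: frozenset
    record_count: int


@dataclass
class IncidenceSummary:
    """Incidence (and record-count) structure of one spatial unit."""

    N: int                      # number of samples
    S_obs: int                  # observed species
    n_i: np.ndarray             # per-species incidence, len S_obs
    R: int                      # total records
    r_i: np.ndarray | None = None          # per-species record counts (records mode)
    sample_species: list | None = None     # list of species-index arrays, for bootstrap

    def __post_init__(self):
        self.n_i = np.asarray(self.n_i, dtype=int)
        if self.N and len(self.n_i) and (self.n_i.min() < 1 or self.n_i.max() > self.N):
            raise ValueError("incidences must satisfy 1 <= n_i <= N")
        if self.S_obs != len(self.n_i):
            raise ValueError("S_obs must equal the number of incidence entries")


def incidence_from_samples(samples: Sequence[SampleEvent]) -> IncidenceSummary:
    """Build the incidence summary of a set of samples."""
    species = sorted({sp for s in samples for sp in s.species})
    index = {sp: i for i, sp in enumerate(species)}
    n_i = np.zeros(len(species), dtype=int)
    sample_species = []
    for s in samples:
        idx = np.array([index[sp] for sp in s.species], dtype=int)
        n_i[idx] += 1
        sample_species.append(idx)
    R = int(sum(s.record_count for s in samples))
    return IncidenceSummary(N=len(samples), S_obs=len(species), n_i=n_i, R=R,
                            sample_species=sample_species)


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def _log_choose(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _expected_species(counts: np.ndarray, total: int, m: int) -> float:
    """E[S_m] from per-unit counts (incidences or abundances)."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    keep = total - counts >= m          # otherwise C(total-n_i, m) = 0
    log_ratio = _log_choose(total - counts[keep], m) - _log_choose(total, m)
    # underflow clamps to 0 via exp of very negative values
    return float(len(counts) - np.sum(np.exp(log_ratio)))


def rarefied_richness(inc: IncidenceSummary, m: int = DEFAULT_M,
                      mode: str = "samples") -> float | None:
    """Expected species richness in m random samples (or records).

    Returns None (missing, not an error) when the unit has fewer than m
    samples (samples mode) or records (records mode).
    """
    if m <= 0:
        raise ValueError("m must be a positive integer")
    if mode == "samples":
        if m > inc.N:
            return None
        return _expected_species(inc.n_i, inc.N, m)
    if mode == "records":
        if inc.r_i is None:
            raise ValueError("records mode requires per-species record counts r_i")
        if m > inc.R:
            return None
        return _expected_species(inc.r_i, inc.R, m)
    raise ValueError(f"unknown rarefaction mode {mode!r}")


def rarefied_se(inc: IncidenceSummary, m: int = DEFAULT_M,
                B: int = DEFAULT_BOOTSTRAP_B, seed: int = 0) -> float | None:
    """Bootstrap SE of E[S_m]: resample the N samples with replacement B times."""
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if m > inc.N:
        return None
    if inc.sample_species is None:
        raise ValueError("bootstrap requires per-sample species lists")
    rng = np.random.default_rng(seed)
    N, S = inc.N, inc.S_obs
    if S == 0:
        return 0.0
    # sample x species membership, dense bool (units are small enough)
    M = np.zeros((N, S), dtype=np.int64)
    for j, idx in enumerate(inc.sample_species):
        M[j, idx] = 1
    draws = rng.integers(0, N, size=(B, N))
    counts = np.apply_along_axis(np.bincount, 1, draws, minlength=N)  # B x N
    n_star = counts @ M                                               # B x S
    est = np.empty(B)
    logCNm = _log_choose(float(N), m)
    for b in range(B):
        ns = n_star[b]
        ns = ns[ns > 0]
        keep = N - ns >= m
        est[b] = len(ns) - np.sum(np.exp(_log_choose((N - ns[keep]).astype(float), m) - logCNm))
    return float(np.std(est, ddof=1))


# ---------------------------------------------------------------------------
# Sample construction
# ---------------------------------------------------------------------------

def build_samples(records: Sequence[OccurrenceRecord],
                  rounding: int = LOCATION_DECIMALS,
                  cell_assignment: dict[str, str] | None = None
                  ) -> tuple[list[SampleEvent], int]:
    """Group records into samples keyed by (date, rounded lat, rounded lon).

    Dateless records cannot form samples and are excluded. Returns
    (samples, n_dateless).
    """
    groups: dict[tuple, list[OccurrenceRecord]] = {}
    n_dateless = 0
    for rec in records:
        if rec.event_date is None:
            n_dateless += 1
            continue
        key = (rec.event_date, round(rec.latitude, rounding), round(rec.longitude, rounding))
        groups.setdefault(key, []).append(rec)
    samples = []
    for k, (key, recs) in enumerate(sorted(groups.items(), key=lambda kv: (str(kv[0][0]), kv[0][1], kv[0][2]))):
        cell_id = None
        if cell_assignment is not None:
            cell_id = cell_assignment.get(recs[0].record_id)
        samples.append(SampleEvent(
            sample_id=f"s{k}",
            cell_id=cell_id,
            date=key[0],
            location=(key[1], key[2]),
            species=frozenset(r.name for r in recs),
            record_count=len(recs),
        ))
    return samples, n_dateless


# ---------------------------------------------------------------------------
# Aggregations
# ---------------------------------------------------------------------------

@dataclass
class CellDiversity:
    cell_id: str
    stratum: str                # "all", "shallow" or "deep"
    alpha: int
    es50: float | None
    es50_se: float | None
    N: int                      # samples
    R: int                      # records


@dataclass
class BandDiversity:
    band: int
    band_lat: tuple[float, float]
    stratum: str
    gamma: int
    mean_es50: float | None
    se_es50: float | None
    n_cells_es50: int
    records: int
    ocean_area_km2: float | None


@dataclass
class DepthDiversity:
    interval: int
    depth: tuple[float, float]
    records: int
    gamma: int
    mean_alpha: float | None
    mean_es50: float | None
    se_es50: float | None


def _stratum_of(depth: float | None, threshold: float) -> str | None:
    if depth is None:
        return None
    return "shallow" if depth <= threshold else "deep"


def cell_diversity(records: Sequence[OccurrenceRecord], grid: HexGrid,
                   m: int = DEFAULT_M, mode: str = "samples",
                   B: int = DEFAULT_BOOTSTRAP_B, seed: int = 0,
                   depth_threshold: float = SHALLOW_DEEP_THRESHOLD_M,
                   strata: Iterable[str] = ("all", "shallow", "deep"),
                   compute_se: bool = True) -> list[CellDiversity]:
    """Per-cell, per-stratum record counts, alpha, and ES50 (±SE).

    Cells with fewer than m samples get a missing ES50; cells with no
    records at all are still reported (alpha 0). Records without a depth
    enter only the "all" stratum.
    """
    assignment = assign_to_cell(records, grid)
    out: list[CellDiversity] = []
    for stratum in strata:
        if stratum == "all":
            recs = list(records)
        else:
            recs = [r for r in records
                    if _stratum_of(r.depth, depth_threshold) == stratum]
        by_cell: dict[str, list[OccurrenceRecord]] = {c.cell_id: [] for c in grid.cells}
        for r in recs:
            by_cell[assignment[r.record_id]].append(r)
        for cell in grid.cells:
            cell_recs = by_cell[cell.cell_id]
            if not cell_recs:
                out.append(CellDiversity(cell.cell_id, stratum, 0, None, None, 0, 0))
                continue
            samples, _ = build_samples(cell_recs)
            inc = incidence_from_samples(samples)
            if mode == "records":
                names, counts = np.unique([r.name for r in cell_recs], return_counts=True)
                inc.r_i = counts
            alpha = len({r.name for r in cell_recs})
            es = rarefied_richness(inc, m, mode=mode)
            se = None
            if es is not None and compute_se and mode == "samples":
                se = rarefied_se(inc, m, B=B, seed=_cell_seed(seed, cell.cell_id))
            out.append(CellDiversity(cell.cell_id, stratum, alpha, es, se,
                                     inc.N, len(cell_recs)))
    return out


def _cell_seed(seed: int, cell_id: str) -> int:
    # stable across processes (str.hash is salted)
    h = zlib.crc32(cell_id.encode())
    return (seed * 1_000_003 + h) % (2 ** 31 - 1)


def band_diversity(records: Sequence[OccurrenceRecord],
                   cell_divs: Sequence[CellDiversity], grid: HexGrid,
                   ocean_mask=None, stratum: str = "all",
                   width: float = BAND_WIDTH,
                   depth_threshold: float = SHALLOW_DEEP_THRESHOLD_M
                   ) -> list[BandDiversity]:
    """Per-5°-band gamma richness, mean cell ES50 ± SE, records and ocean area.

    Gamma is the number of distinct species among the band's records;
    the ES50 summary averages over the band's cells (assigned by centroid
    latitude) that have a defined ES50, with SE = SD/sqrt(n_cells).
    """
    if stratum == "all":
        recs = list(records)
    else:
        recs = [r for r in records if _stratum_of(r.depth, depth_threshold) == stratum]
    lat_min, lat_max = grid.bbox[0], grid.bbox[1]
    n_bands = int(round((lat_max - lat_min) / width))
    species_by_band: dict[int, set] = {b: set() for b in range(n_bands)}
    records_by_band = {b: 0 for b in range(n_bands)}
    for r in recs:
        b = assign_band(r.latitude, width, lat_max)
        species_by_band[b].add(r.name)
        records_by_band[b] += 1
    cell_band = {c.cell_id: assign_band(min(max(c.centroid[0], lat_min), lat_max), width, lat_max)
                 for c in grid.cells}
    es_by_band: dict[int, list[float]] = {b: [] for b in range(n_bands)}
    for cd in cell_divs:
        if cd.stratum != stratum or cd.es50 is None:
            continue
        es_by_band[cell_band[cd.cell_id]].append(cd.es50)
    out = []
    for b in range(n_bands):
        es = es_by_band[b]
        mean_es = float(np.mean(es)) if es else None
        se_es = float(np.std(es, ddof=1) / math.sqrt(len(es))) if len(es) > 1 else (0.0 if es else None)
        area = band_ocean_area(b, ocean_mask, grid.bbox, width) if ocean_mask is not None else None
        out.append(BandDiversity(
            band=b, band_lat=band_edges(b, width), stratum=stratum,
            gamma=len(species_by_band[b]), mean_es50=mean_es, se_es50=se_es,
            n_cells_es50=len(es), records=records_by_band[b],
            ocean_area_km2=area))
    return out


def depth_profile(records: Sequence[OccurrenceRecord], grid: HexGrid,
                  m: int = DEFAULT_M, width: float = DEPTH_INTERVAL,
                  max_depth: float = 11_000.0) -> list[DepthDiversity]:
    """Per-100-m-interval records, gamma, mean per-hexagon alpha and ES50.

    Only depth-bearing records enter; the ES50 average is over
    (cell × interval) groups with at least m samples.
    """
    recs = [r for r in records if r.depth is not None]
    assignment = assign_to_cell(recs, grid)
    n_int = int(round(max_depth / width))
    by_interval: dict[int, list[OccurrenceRecord]] = {}
    for r in recs:
        by_interval.setdefault(assign_depth_interval(r.depth, width, max_depth), []).append(r)
    out = []
    for k in range(n_int):
        group = by_interval.get(k, [])
        if not group:
            out.append(DepthDiversity(k, (k * width, (k + 1) * width), 0, 0, None, None, None))
            continue
        gamma = len({r.name for r in group})
        by_cell: dict[str, list[OccurrenceRecord]] = {}
        for r in group:
            by_cell.setdefault(assignment[r.record_id], []).append(r)
        alphas = [len({r.name for r in cr}) for cr in by_cell.values()]
        es_vals = []
        for cr in by_cell.values():
            samples, _ = build_samples(cr)
            inc = incidence_from_samples(samples)
            es = rarefied_richness(inc, m)
            if es is not None:
                es_vals.append(es)
        mean_es = float(np.mean(es_vals)) if es_vals else None
        se_es = (float(np.std(es_vals, ddof=1) / math.sqrt(len(es_vals)))
                 if len(es_vals) > 1 else (0.0 if es_vals else None))
        out.append(DepthDiversity(k, (k * width, (k + 1) * width), len(group),
                                  gamma, float(np.mean(alphas)), mean_es, se_es))
    return out
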