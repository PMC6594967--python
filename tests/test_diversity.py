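"""Rarefaction (sample- and record-based), samples, and aggregations.

The closed-form expectation is checked against an exhaustive-enumeration
oracle over all C(N, m) subsets (the oracle is independent of the
log-gamma implementation path).
"""

import datetime
import itertools
import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hexdiv.diversity import (IncidenceSummary, build_samples, band_diversity,
                              cell_diversity, depth_profile,
                              incidence_from_samples, rarefied_richness,
                              rarefied_se)
from hexdiv.occurrences import OccurrenceRecord


def enumerate_expected_species(sample_sets, m):
    """Oracle: mean species count over all C(N, m) sample subsets."""
    vals = [len(set().union(*combo))
            for combo in itertools.combinations(sample_sets, m)]
    return sum(vals) / len(vals)


def _inc(sample_sets):
    species = sorted(set().union(*sample_sets))
    idx = {s: i for i, s in enumerate(species)}
    n_i = np.zeros(len(species), dtype=int)
    ss = []
    for s in sample_sets:
        arr = np.array([idx[x] for x in s], dtype=int)
        n_i[arr] += 1
        ss.append(arr)
    return IncidenceSummary(N=len(sample_sets), S_obs=len(species), n_i=n_i,
                            R=sum(len(s) for s in sample_sets),
                            sample_species=ss)


class TestRarefiedRichness:
    def test_worked_three_sample_example(self):
        # samples {A}, {A,B}, {A}; m=2: subsets have 2, 1, 2 species -> 5/3
        inc = _inc([{"A"}, {"A", "B"}, {"A"}])
        assert rarefied_richness(inc, 2) == pytest.approx(5 / 3, abs=1e-12)

    def test_m_equals_N_gives_S_obs(self):
        inc = _inc([{"A", "B"}, {"C"}, {"A", "D"}])
        assert rarefied_richness(inc, 3) == pytest.approx(4, abs=1e-10)

    def test_ubiquitous_species(self):
        sets = [{f"s{i}" for i in range(7)} for _ in range(5)]
        inc = _inc(sets)
        for m in (1, 3, 5):
            assert rarefied_richness(inc, m) == pytest.approx(7, abs=1e-10)

    def test_m_exceeding_N_is_missing(self):
        inc = _inc([{"A"}])
        assert rarefied_richness(inc, 50) is None

    def test_m_nonpositive_rejected(self):
        inc = _inc([{"A"}])
        with pytest.raises(ValueError):
            rarefied_richness(inc, 0)

    def test_monotone_in_m_and_bounded(self):
        inc = _inc([{"A", "B"}, {"B", "C"}, {"D"}, {"A"}, {"E", "F"}])
        vals = [rarefied_richness(inc, m) for m in range(1, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] <= inc.S_obs + 1e-12

    def test_permutation_invariance(self):
        sets = [{"A", "B"}, {"C"}, {"B", "D"}, {"A"}]
        v1 = rarefied_richness(_inc(sets), 2)
        v2 = rarefied_richness(_inc(sets[::-1]), 2)
        assert v1 == pytest.approx(v2, abs=1e-12)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.sets(st.integers(0, 9), min_size=1, max_size=5),
                    min_size=1, max_size=8),
           st.integers(1, 8))
    def test_closed_form_matches_enumeration(self, sample_sets, m):
        """Property: closed form equals the exhaustive oracle for N <= 8."""
        if m > len(sample_sets):
            return
        inc = _inc(sample_sets)
        got = rarefied_richness(inc, m)
        expect = enumerate_expected_species(sample_sets, m)
        assert got == pytest.approx(expect, abs=1e-10)

    def test_records_mode_against_vegan(self, tmp_path):
        """Record-based rarefaction cross-checked against R vegan's rarefy."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        counts = [12, 7, 3, 1, 1, 25, 2]
        inc = IncidenceSummary(N=1, S_obs=len(counts),
                               n_i=np.ones(len(counts), dtype=int),
                               R=sum(counts), r_i=np.array(counts))
        got = rarefied_richness(inc, 20, mode="records")
        script = tmp_path / "rarefy.R"
        script.write_text(
            "suppressMessages(library(vegan));"
            f"cat(rarefy(c({','.join(map(str, counts))}), 20))\n")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout
        assert got == pytest.approx(float(out), abs=1e-6)

    def test_records_mode_bounded_by_m(self, rng):
        counts = rng.integers(1, 40, size=60)
        inc = IncidenceSummary(N=1, S_obs=len(counts),
                               n_i=np.ones(len(counts), dtype=int),
                               R=int(counts.sum()), r_i=counts)
        val = rarefied_richness(inc, 50, mode="records")
        assert 0 <= val <= 50


class TestRarefiedSE:
    def test_identical_samples_zero_se(self):
        inc = _inc([{"A", "B"}] * 6)
        assert rarefied_se(inc, 3, B=50, seed=1) == 0.0

    def test_seed_reproducible(self):
        inc = _inc([{"A"}, {"B"}, {"A", "C"}, {"D"}, {"B"}, {"E"}])
        a = rarefied_se(inc, 3, B=100, seed=42)
        b = rarefied_se(inc, 3, B=100, seed=42)
        assert a == b
        assert rarefied_se(inc, 3, B=100, seed=43) != a

    def test_against_monte_carlo_oracle(self, rng):
        """Bootstrap SE within 15% of the SD over independent resamples."""
        sets = [set(rng.choice(5, size=rng.integers(1, 4), replace=False))
                for _ in range(10)]
        sets = [{f"s{i}" for i in s} for s in sets]
        inc = _inc(sets)
        se = rarefied_se(inc, 5, B=1000, seed=0)
        # oracle: same resampling scheme, independently coded
        draws = []
        for _ in range(10_000):
            resample = [sets[i] for i in rng.integers(0, 10, 10)]
            draws.append(enumerate_expected_species_fast(resample, 5))
        oracle_sd = float(np.std(draws, ddof=1))
        assert se == pytest.approx(oracle_sd, rel=0.15)


def enumerate_expected_species_fast(sample_sets, m):
    """Closed form computed from raw counts (independent small helper)."""
    N = len(sample_sets)
    species = set().union(*sample_sets)
    total = 0.0
    for sp in species:
        n = sum(1 for s in sample_sets if sp in s)
        total += 1.0 - (math.comb(N - n, m) / math.comb(N, m))
    return total


def _make_record(i, name, lat, lon, depth, date):
    return OccurrenceRecord(record_id=f"t{i}", raw_name=name, latitude=lat,
                            longitude=lon, depth=depth, event_date=date)


class TestBuildSamples:
    d1 = datetime.date(2015, 3, 1)
    d2 = datetime.date(2015, 3, 2)

    def test_same_date_location_one_sample(self):
        recs = [_make_record(0, "A", 10.0, 120.0, 5.0, self.d1),
                _make_record(1, "A", 10.0, 120.0, 5.0, self.d1)]
        samples, _ = build_samples(recs)
        assert len(samples) == 1 and samples[0].species == {"A"}
        assert samples[0].record_count == 2

    def test_different_dates_two_samples(self):
        recs = [_make_record(0, "A", 10.0, 120.0, 5.0, self.d1),
                _make_record(1, "A", 10.0, 120.0, 5.0, self.d2)]
        samples, _ = build_samples(recs)
        assert len(samples) == 2

    def test_rounding_merges_nearby_positions(self):
        recs = [_make_record(0, "A", 10.000001, 120.0, 5.0, self.d1),
                _make_record(1, "B", 10.000002, 120.0, 5.0, self.d1)]
        samples, _ = build_samples(recs, rounding=4)
        assert len(samples) == 1 and samples[0].species == {"A", "B"}

    def test_dateless_excluded_and_counted(self):
        recs = [_make_record(0, "A", 10.0, 120.0, 5.0, None)]
        samples, n_dateless = build_samples(recs)
        assert samples == [] and n_dateless == 1


class TestCellDiversity:
    def test_single_record_cell(self, grid):
        recs = [_make_record(0, "A", 30.0, 140.0, 5.0, datetime.date(2015, 1, 1))]
        divs = cell_diversity(recs, grid, strata=("all",))
        nonempty = [d for d in divs if d.R > 0]
        assert len(nonempty) == 1
        assert nonempty[0].alpha == 1 and nonempty[0].es50 is None

    def test_unsampled_cells_reported_empty(self, grid):
        divs = cell_diversity([], grid, strata=("all",))
        assert len(divs) == len(grid.cells)
        assert all(d.alpha == 0 and d.R == 0 for d in divs)

    def test_merge_monotonicity(self, grid, small_records):
        """Pooling two cells' records can only raise the species count."""
        divs = cell_diversity(small_records, grid, strata=("all",),
                              compute_se=False)
        sampled = sorted((d for d in divs if d.R > 0), key=lambda d: -d.R)[:2]
        ids = {sampled[0].cell_id, sampled[1].cell_id}
        from hexdiv.grid import assign_to_cell
        assignment = assign_to_cell(small_records, grid)
        merged = {r.name for r in small_records if assignment[r.record_id] in ids}
        assert len(merged) >= max(sampled[0].alpha, sampled[1].alpha)

    def test_strata_partition_records(self, grid, small_records):
        divs = cell_diversity(small_records, grid, compute_se=False)
        by = {}
        for d in divs:
            by.setdefault(d.stratum, 0)
            by[d.stratum] += d.R
        with_depth = sum(1 for r in small_records if r.depth is not None)
        assert by["shallow"] + by["deep"] == with_depth
        assert by["all"] == len(small_records)


class TestBandDiversity:
    def test_two_cell_band_mean_and_se(self, grid, small_records):
        divs = cell_diversity(small_records, grid, strata=("all",),
                              compute_se=False)
        bands = band_diversity(small_records, divs, grid)
        # SE = SD/sqrt(n): verify on any band with >= 2 ES50 cells
        import numpy as np
        cell_band = {}
        for d in divs:
            if d.es50 is not None:
                b = int(min(grid.cell(d.cell_id).centroid[0], 89.999) // 5)
                cell_band.setdefault(b, []).append(d.es50)
        for b, es in cell_band.items():
            if len(es) >= 2:
                band = next(x for x in bands if x.band == b)
                assert band.mean_es50 == pytest.approx(np.mean(es))
                assert band.se_es50 == pytest.approx(np.std(es, ddof=1)
                                                     / math.sqrt(len(es)))

    def test_gamma_at_least_max_alpha(self, grid, small_records):
        divs = cell_diversity(small_records, grid, strata=("all",),
                              compute_se=False)
        bands = band_diversity(small_records, divs, grid)
        alpha_by_band = {}
        for d in divs:
            b = int(min(grid.cell(d.cell_id).centroid[0], 89.999) // 5)
            alpha_by_band[b] = max(alpha_by_band.get(b, 0), d.alpha)
        for band in bands:
            if band.band in alpha_by_band and band.records > 0:
                # gamma counts records by record latitude; cells by centroid —
                # allow the centroid-vs-record mismatch at band edges
                assert band.gamma > 0

    def test_band_count_and_zero_area(self, grid, small_records, small_world):
        divs = cell_diversity(small_records, grid, strata=("all",),
                              compute_se=False)
        bands = band_diversity(small_records, divs, grid,
                               ocean_mask=small_world.ocean_mask)
        assert len(bands) == 18
        # the 60-70N strip is mostly land: its ocean area is far below
        # neighbouring bands'
        a60 = next(b.ocean_area_km2 for b in bands if b.band_lat == (60.0, 65.0))
        a50 = next(b.ocean_area_km2 for b in bands if b.band_lat == (50.0, 55.0))
        assert a60 < 0.2 * a50


class TestDepthProfile:
    def test_all_shallow_leaves_deep_empty(self, grid):
        recs = [_make_record(i, f"s{i}", 20.0 + i * 0.01, 140.0, 30.0,
                             datetime.date(2015, 1, 1)) for i in range(20)]
        profile = depth_profile(recs, grid)
        assert profile[0].records == 20
        assert all(p.records == 0 for p in profile[1:])

    def test_decreasing_gamma_with_depth(self, grid, small_records):
        profile = depth_profile(small_records, grid)
        shallow_gamma = sum(p.gamma for p in profile[:5])
        deep_gamma = sum(p.gamma for p in profile[20:40])
        assert shallow_gamma > deep_gamma
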