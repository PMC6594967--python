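"""Occurrence-record ingestion and cleaning.

Darwin-Core-style occurrence tables (CSV) are read into
:class:`OccurrenceRecord` objects, then passed through a rule-based
cleaning pipeline: exact-duplicate removal, synonym reconciliation
against a user-supplied table, study-area filtering, and depth/habitat
categorisation (shallow ≤ 500 m vs deep > 500 m; benthic vs pelagic).
Every dropped record is counted so that input totals are conserved.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import STUDY_BBOX

#: Default Darwin-Core column names.
DEFAULT_DIALECT = {
    "name": "scientificName",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "depth": "depth",
    "event_date": "eventDate",
    "dataset_id": "datasetID",
}

#: Alternative depth column accepted when "depth" is absent.
DEPTH_FALLBACK = "minimumDepthInMeters"

MAX_DEPTH_M = 11_000.0

SHALLOW_DEEP_THRESHOLD_M = 500.0

CATEGORIES = ("shallow-pelagic", "shallow-benthic", "deep-pelagic", "deep-benthic")


@dataclass
class OccurrenceRecord:
    """One species observation (cleaned or in the process of being cleaned)."""

    record_id: str
    raw_name: str
    latitude: float
    longitude: float
    depth: float | None = None          # metres; None if not reported
    event_date: _dt.date | None = None
    dataset_id: str = ""
    accepted_name: str = ""             # empty until reconciled
    flags: set = field(default_factory=set)

    @property
    def name(self) -> str:
        return self.accepted_name or self.raw_name

    @property
    def usable(self) -> bool:
        return not self.flags


@dataclass
class SynonymTable:
    """raw_name -> accepted name mapping; accepted names map to themselves."""

    mapping: dict[str, str]

    def __post_init__(self):
        # enforce idempotence: every accepted name is its own key
        for accepted in list(self.mapping.values()):
            self.mapping.setdefault(accepted, accepted)

    def resolve(self, raw_name: str) -> str | None:
        return self.mapping.get(raw_name)

    @classmethod
    def read_csv(cls, path) -> "SynonymTable":
        df = pd.read_csv(path, dtype=str)
        cols = list(df.columns[:2])
        return cls(dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str))))


@dataclass
class TraitTable:
    """accepted name -> habitat in {benthic, pelagic, both}."""

    habitat: dict[str, str]

    def __post_init__(self):
        bad = {v for v in self.habitat.values()} - {"benthic", "pelagic", "both"}
        if bad:
            raise ValueError(f"unknown habitat values: {sorted(bad)}")

    @classmethod
    def read_csv(cls, path) -> "TraitTable":
        df = pd.read_csv(path, dtype=str)
        cols = list(df.columns[:2])
        return cls(dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str))))


class FormatError(ValueError):
    """A required column is missing or the file is malformed."""


def read_occurrences(path, dialect: dict[str, str] | None = None,
                     strict: bool = False) -> list[OccurrenceRecord]:
    """Read a Darwin-Core-style occurrence CSV.

    Parameters
    ----------
    dialect : optional mapping from the logical field names
        (name/latitude/longitude/depth/event_date/dataset_id) to the CSV's
        column names; defaults to Darwin-Core names.
    strict : if True, unparseable coordinates/depth/date raise; if False
        (lenient, the default) the record is flagged ``dubious`` (bad
        coordinates) or the offending field set missing (depth/date).
    """
    cols = dict(DEFAULT_DIALECT)
    cols.update(dialect or {})
    df = pd.read_csv(path, dtype=str)
    for key in ("name", "latitude", "longitude"):
        if cols[key] not in df.columns:
            raise FormatError(f"required column {cols[key]!r} (field {key!r}) not found")
    depth_col = cols["depth"] if cols["depth"] in df.columns else (
        DEPTH_FALLBACK if DEPTH_FALLBACK in df.columns else None)

    records: list[OccurrenceRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        flags: set[str] = set()
        lat = _parse_float(row.get(cols["latitude"]), strict, flags, "latitude")
        lon = _parse_float(row.get(cols["longitude"]), strict, flags, "longitude")
        if lat is None or lon is None:
            flags.add("dubious")
            lat = lat if lat is not None else float("nan")
            lon = lon if lon is not None else float("nan")
        else:
            if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
                if strict:
                    raise FormatError(f"row {i}: coordinates out of bounds ({lat}, {lon})")
                flags.add("dubious")
        depth = _parse_float(row.get(depth_col) if depth_col else None, strict, flags, "depth")
        if depth is not None and (depth < 0 or depth > MAX_DEPTH_M):
            if strict:
                raise FormatError(f"row {i}: depth out of bounds ({depth})")
            flags.add("dubious")
        date = _parse_date(row.get(cols["event_date"]), strict)
        basis = str(row.get("basisOfRecord", "") or "")
        if "fossil" in basis.lower():
            flags.add("fossil")
        records.append(OccurrenceRecord(
            record_id=str(row.get("occurrenceID", "") or f"row{i}"),
            raw_name=str(row.get(cols["name"], "")),
            latitude=lat, longitude=lon, depth=depth, event_date=date,
            dataset_id=str(row.get(cols["dataset_id"], "") or ""),
            flags=flags,
        ))
    return records


def _parse_float(value, strict, flags, what):
    if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        if strict:
            raise FormatError(f"unparseable {what}: {value!r}") from None
        flags.add("dubious")
        return None


def _parse_date(value, strict):
    if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
        return None
    text = str(value).strip()[:10]
    try:
        return _dt.date.fromisoformat(text)
    except ValueError:
        if strict:
            raise FormatError(f"unparseable date: {value!r}") from None
        return None


# ---------------------------------------------------------------------------
# Cleaning pipeline
# ---------------------------------------------------------------------------

def deduplicate(records: list[OccurrenceRecord]) -> tuple[list[OccurrenceRecord], int]:
    """Collapse exact duplicates, keeping the first by input order.

    Duplicate key: (name after any reconciliation, latitude, longitude,
    depth, event_date). Returns (kept, n_removed).
    """
    seen = set()
    kept = []
    for rec in records:
        key = (rec.name, rec.latitude, rec.longitude, rec.depth, rec.event_date)
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    return kept, len(records) - len(kept)


def reconcile_names(records: list[OccurrenceRecord], synonyms: SynonymTable,
                    unmatched_policy: str = "keep_raw") -> tuple[list[OccurrenceRecord], int]:
    """Fill accepted names from the synonym table.

    ``unmatched_policy``: "drop" removes records with unmatched names,
    "keep_raw" keeps them with accepted_name = raw_name. Returns
    (records, n_unmatched).
    """
    if unmatched_policy not in ("drop", "keep_raw"):
        raise ValueError(f"unknown unmatched_policy {unmatched_policy!r}")
    out = []
    n_unmatched = 0
    for rec in records:
        accepted = synonyms.resolve(rec.accepted_name or rec.raw_name)
        if accepted is None:
            n_unmatched += 1
            if unmatched_policy == "drop":
                continue
            accepted = rec.accepted_name or rec.raw_name
        out.append(replace(rec, accepted_name=accepted, flags=set(rec.flags)))
    return out, n_unmatched


def filter_study_area(records: list[OccurrenceRecord],
                      bbox: tuple[float, float, float, float] = STUDY_BBOX
                      ) -> tuple[list[OccurrenceRecord], int]:
    """Keep records inside the study box (closed edges), dropping flagged ones.

    Records outside the box get an ``out_of_area`` flag and are excluded,
    as are records already flagged fossil or dubious. Returns
    (kept, n_dropped).
    """
    lat_min, lat_max, lon_min, lon_max = bbox
    kept = []
    dropped = 0
    for rec in records:
        in_box = (lat_min <= rec.latitude <= lat_max) and (lon_min <= rec.longitude <= lon_max)
        if not in_box:
            rec.flags.add("out_of_area")
        if rec.flags:
            dropped += 1
            continue
        kept.append(rec)
    return kept, dropped


def classify_records(records: list[OccurrenceRecord], traits: TraitTable,
                     depth_threshold: float = SHALLOW_DEEP_THRESHOLD_M
                     ) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Assign each record its depth/habitat categories.

    A record at depth ≤ threshold is shallow, deeper is deep; habitat
    comes from the trait table, and habitat "both" contributes to both
    the pelagic and benthic category, so category totals can exceed the
    record count. Returns (record_id -> category set, counters) where
    counters reports ``missing_depth`` and ``unclassified`` (no trait
    entry) records, both excluded from depth-stratified outputs.
    """
    cats: dict[str, set[str]] = {}
    counters = {"missing_depth": 0, "unclassified": 0}
    for rec in records:
        if rec.depth is None:
            counters["missing_depth"] += 1
            cats[rec.record_id] = set()
            continue
        habitat = traits.habitat.get(rec.name)
        if habitat is None:
            counters["unclassified"] += 1
            cats[rec.record_id] = set()
            continue
        stratum = "shallow" if rec.depth <= depth_threshold else "deep"
        habitats = ("benthic", "pelagic") if habitat == "both" else (habitat,)
        cats[rec.record_id] = {f"{stratum}-{h}" for h in habitats}
    return cats, counters


def clean_pipeline(records: list[OccurrenceRecord], synonyms: SynonymTable | None = None,
                   bbox: tuple[float, float, float, float] = STUDY_BBOX,
                   unmatched_policy: str = "keep_raw") -> tuple[list[OccurrenceRecord], dict[str, int]]:
    """read → reconcile → dedupe → filter, with record-conservation accounting."""
    n_in = len(records)
    if synonyms is not None:
        records, n_unmatched = reconcile_names(records, synonyms, unmatched_policy)
    else:
        records = [replace(r, accepted_name=r.accepted_name or r.raw_name, flags=set(r.flags))
                   for r in records]
        n_unmatched = 0
    records, n_dup = deduplicate(records)
    records, n_area = filter_study_area(records, bbox)
    dropped_unmatched = n_unmatched if unmatched_policy == "drop" else 0
    counts = {
        "input": n_in,
        "kept": len(records),
        "dropped_unmatched": dropped_unmatched,
        "dropped_duplicate": n_dup,
        "dropped_out_of_area_or_flagged": n_area,
    }
    assert counts["input"] == counts["kept"] + dropped_unmatched + n_dup + n_area
    return records, counts


# ---------------------------------------------------------------------------
# DataFrame bridges
# ---------------------------------------------------------------------------

def records_to_frame(records: list[OccurrenceRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "record_id": [r.record_id for r in records],
        "name": [r.name for r in records],
        "latitude": [r.latitude for r in records],
        "longitude": [r.longitude for r in records],
        "depth": [np.nan if r.depth is None else r.depth for r in records],
        "event_date": [r.event_date for r in records],
        "dataset_id": [r.dataset_id for r in records],
    })


def write_occurrences_csv(records: list[OccurrenceRecord], path) -> None:
    """Write records with Darwin-Core default column names."""
    df = pd.DataFrame({
        "occurrenceID": [r.record_id for r in records],
        "scientificName": [r.name for r in records],
        "decimalLatitude": [r.latitude for r in records],
        "decimalLongitude": [r.longitude for r in records],
        "depth": [np.nan if r.depth is None else r.depth for r in records],
        "eventDate": [r.event_date.isoformat() if r.event_date else "" for r in records],
        "datasetID": [r.dataset_id for r in records],
    })
    df.to_csv(path, index=False)
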