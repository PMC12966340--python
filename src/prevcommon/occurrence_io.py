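"""Occurrence-record ingestion, deduplication, and spatio-temporal context.

Records are kept in a pandas DataFrame with canonical columns
``species, lon, lat, date, count, dataset`` (plus ``cell_x, cell_y,
time_unit`` once :func:`assign_context` has run). Darwin-Core column
names are accepted on input. Area polygons ("datasets") come from a
GeoJSON FeatureCollection or a WKT-per-line file.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as _geo_shape
from shapely import wkt as _wkt

from .config import StudyConfig

__all__ = [
    "RecordSet", "DARWIN_CORE_MAP", "read_occurrences", "write_occurrences",
    "deduplicate", "assign_context", "read_polygons", "polygon_cells",
]

CANONICAL_COLUMNS = ["species", "lon", "lat", "date", "count", "dataset"]

#: Darwin-Core header dialect -> canonical fields.
DARWIN_CORE_MAP = {
    "scientificName": "species",
    "decimalLongitude": "lon",
    "decimalLatitude": "lat",
    "eventDate": "date",
    "individualCount": "count",
    "datasetKey": "dataset",
}

_DEDUP_KEY = ["species", "dataset", "lon", "lat", "date"]


@dataclass
class RecordSet:
    """A collection of occurrence records plus a provenance/filter log."""

    records: pd.DataFrame
    log: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())


def _validate(df: pd.DataFrame, log: list[str]) -> pd.DataFrame:
    bad_lon = ~df["lon"].between(-180.0, 180.0)
    bad_lat = ~df["lat"].between(-90.0, 90.0)
    bad = bad_lon | bad_lat
    if bad.any():
        log.append(f"dropped {int(bad.sum())} rows with out-of-range coordinates")
        df = df[~bad]
    return df


def read_occurrences(path: str | Path,
                     column_map: dict[str, str] | None = None) -> RecordSet:
    """Read an occurrence CSV into a :class:`RecordSet`.

    Canonical and Darwin-Core header dialects are auto-detected; a custom
    ``column_map`` (source name -> canonical field) overrides both. Rows
    lacking coordinates or a parseable date are dropped and counted in the
    provenance log; a missing individual count is imputed as 1 (an
    occurrence implies at least one individual).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except OSError as exc:  # pragma: no cover - passthrough
        raise IOError(f"cannot read occurrence file {path}: {exc}") from exc
    if column_map is None:
        column_map = {c: DARWIN_CORE_MAP[c] for c in df.columns if c in DARWIN_CORE_MAP}
    df = df.rename(columns=column_map)
    missing = {"species", "lon", "lat", "date"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence file lacks required columns: {sorted(missing)}")
    if "count" not in df.columns:
        df["count"] = np.nan
    if "dataset" not in df.columns:
        df["dataset"] = ""

    log = [f"read {len(df)} rows from {path}"]
    n0 = len(df)
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["date"] = pd.to_datetime(df["date"], errors="coerce").dt.date
    ok = df["lon"].notna() & df["lat"].notna() & df["date"].notna()
    if (~ok).any():
        log.append(f"dropped {int((~ok).sum())} rows missing coordinates or date")
    df = df[ok]
    df = _validate(df, log)

    n_imputed = int(df["count"].isna().sum())
    if n_imputed:
        log.append(f"imputed individual count 1 for {n_imputed} rows")
    df["count"] = pd.to_numeric(df["count"], errors="coerce").fillna(1).astype(int)
    df.loc[df["count"] < 1, "count"] = 1
    df["dataset"] = df["dataset"].fillna("").astype(str)
    df["species"] = df["species"].astype(str)

    if len(df) == 0:
        raise ValueError(f"no valid occurrence rows in {path} (started with {n0})")
    return RecordSet(df[CANONICAL_COLUMNS].reset_index(drop=True), log)


def write_occurrences(rs: RecordSet, path: str | Path) -> None:
    """Write canonical columns (plus any context columns) to CSV.

    Reading the file back round-trips all canonical fields exactly: floats
    are serialised with :func:`repr` precision.
    """
    rs.records.to_csv(path, index=False)


def fetch_gbif(species: list[str], polygon, time_start, time_end) -> RecordSet:
    """Extension point for live GBIF retrieval (not implemented).

    The pipeline consumes local occurrence tables; an adapter pulling the
    same canonical fields (species, lon, lat, date, count, dataset) from
    the GBIF API would slot in here and feed :func:`deduplicate` /
    :func:`assign_context` unchanged.
    """
    raise NotImplementedError(
        "live GBIF retrieval is out of scope; export records to CSV and use "
        "read_occurrences()")


def deduplicate(rs: RecordSet) -> RecordSet:
    """Collapse duplicates — equal (species, dataset, coordinates, timestamp).

    Among duplicates the record with the largest individual count survives
    (first occurrence on ties), preserving the abundance signal. Idempotent.
    """
    df = rs.records
    # stable sort keeps the first-seen row on count ties
    order = df["count"].values
    keep = (
        df.assign(_o=np.arange(len(df)), _c=order)
        .sort_values(["_c", "_o"], ascending=[False, True], kind="stable")
        .drop_duplicates(subset=_DEDUP_KEY, keep="first")
        .sort_values("_o", kind="stable")
        .drop(columns=["_o", "_c"])
        .reset_index(drop=True)
    )
    log = list(rs.log)
    removed = len(df) - len(keep)
    if removed:
        log.append(f"deduplicated {removed} records")
    return RecordSet(keep, log)


# ---------------------------------------------------------------------------
# polygons and spatial/temporal context


def read_polygons(path: str | Path) -> list[tuple[str, shapely.Geometry]]:
    """Load dataset polygons from GeoJSON (property ``dataset_id``) or WKT lines.

    WKT files carry one ``dataset_id<TAB>WKT`` entry per line.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        gj = json.loads(text)
        out = []
        for i, feat in enumerate(gj.get("features", [])):
            props = feat.get("properties") or {}
            ds = str(props.get("dataset_id", f"dataset_{i}"))
            out.append((ds, _geo_shape(feat["geometry"])))
        return out
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        ds, wkt_str = line.split("\t", 1)
        out.append((ds, _wkt.loads(wkt_str)))
    return out


def polygon_cells(poly: shapely.Geometry, res: float) -> int:
    """Number of grid cells whose centre lies inside the polygon.

    Cells are half-open squares [k*res, (k+1)*res) in each axis; this count
    is the "No. cells" denominator of the extent feature E.
    """
    minx, miny, maxx, maxy = poly.bounds
    i0, i1 = int(np.floor(minx / res)), int(np.floor(maxx / res))
    j0, j1 = int(np.floor(miny / res)), int(np.floor(maxy / res))
    xs = (np.arange(i0, i1 + 1) + 0.5) * res
    ys = (np.arange(j0, j1 + 1) + 0.5) * res
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
    return int(inside.sum())


def assign_context(rs: RecordSet, cfg: StudyConfig) -> RecordSet:
    """Filter to the study frame and annotate dataset / grid cell / time-unit.

    Records outside every dataset polygon or outside the time frame are
    removed. A record falling inside two overlapping polygons is assigned
    to the first by dataset order (with a warning). Cell indices are floor
    divisions of the coordinates by the resolution; the time-unit index is
    the calendar-year offset from the study start.
    """
    if not cfg.datasets:
        raise ValueError("StudyConfig.datasets is empty")
    df = rs.records.copy()
    log = list(rs.log)

    in_frame = (df["date"] >= cfg.time_start) & (df["date"] <= cfg.time_end)
    if (~in_frame).any():
        log.append(f"dropped {int((~in_frame).sum())} records outside the time frame")
    df = df[in_frame]

    lon = df["lon"].to_numpy(float)
    lat = df["lat"].to_numpy(float)
    assigned = np.full(len(df), -1, dtype=int)
    overlap = 0
    for k, (_, poly) in enumerate(cfg.datasets):
        inside = shapely.contains_xy(poly, lon, lat)
        overlap += int((inside & (assigned >= 0)).sum())
        assigned = np.where(inside & (assigned < 0), k, assigned)
    if overlap:
        msg = f"{overlap} records fell in overlapping polygons; kept first dataset by order"
        warnings.warn(msg)
        log.append(msg)
    outside = assigned < 0
    if outside.any():
        log.append(f"dropped {int(outside.sum())} records outside all dataset polygons")
    df = df[~outside]
    assigned = assigned[~outside]

    ids = np.array(cfg.dataset_ids, dtype=object)
    df["dataset"] = ids[assigned]
    res = cfg.cell_resolution
    df["cell_x"] = np.floor(df["lon"].to_numpy(float) / res).astype(int)
    df["cell_y"] = np.floor(df["lat"].to_numpy(float) / res).astype(int)
    df["time_unit"] = np.array([cfg.time_unit_index(d) for d in df["date"]], dtype=int)
    return RecordSet(df.reset_index(drop=True), log)
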