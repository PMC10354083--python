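"""Reading, filtering and range-clipping of community-science checklists.

Input tables follow the eBird-Basic-Dataset layout: one tab-separated row
per species per checklist, with effort metadata repeated on every row.
``read_checklists`` splits this into a checklist-level table (one row per
survey event) and an observation table (checklist_id, species_code, count).

Filtering implements the standard best-practice inclusion rules for
checklist data: complete checklists only, an allowed protocol set, effort
caps (duration <= 300 min, distance <= 5 km, boundary inclusive — the
removal criterion is "greater than"), and a closed date window.  The
filter report accounts for every input row exactly once, attributing each
removal to the first failing rule in a documented fixed order; because the
rules are conjunctive the surviving set does not depend on that order.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .exceptions import EmptyRangeError, SchemaError

log = logging.getLogger(__name__)

#: Mapping from EBD column names to internal canonical names.
EBD_COLUMNS = {
    "SAMPLING EVENT IDENTIFIER": "checklist_id",
    "SPECIES CODE": "species_code",
    "OBSERVATION COUNT": "count",
    "LATITUDE": "lat",
    "LONGITUDE": "lon",
    "OBSERVATION DATE": "date",
    "TIME OBSERVATIONS STARTED": "time_started",
    "DURATION MINUTES": "duration_min",
    "EFFORT DISTANCE KM": "distance_km",
    "NUMBER OBSERVERS": "n_observers",
    "PROTOCOL TYPE": "protocol",
    "ALL SPECIES REPORTED": "complete",
}

CHECKLIST_COLUMNS = [
    "checklist_id",
    "lon",
    "lat",
    "date",
    "time_started_min",
    "duration_min",
    "distance_km",
    "n_observers",
    "protocol",
    "complete",
]

#: Presence-only marker used in place of a numeric count.
PRESENCE_MARKER = "X"

DEFAULT_PROTOCOLS = (
    "Stationary",
    "Traveling",
    "Travelling",
    "Birdlife Australia 20min-2ha survey",
    "Birdlife Australia 500m radius search",
    "Birdlife Australia 5km radius search",
)


def _parse_time_to_minutes(s: pd.Series) -> pd.Series:
    """'HH:MM:SS' (or 'HH:MM') -> minutes since midnight; malformed -> NaN."""
    parts = s.astype("string").str.split(":", expand=True)
    if parts.shape[1] < 2:
        return pd.Series(np.nan, index=s.index)
    h = pd.to_numeric(parts[0], errors="coerce")
    m = pd.to_numeric(parts[1], errors="coerce")
    sec = (
        pd.to_numeric(parts[2], errors="coerce")
        if parts.shape[1] > 2
        else pd.Series(0.0, index=s.index)
    )
    minutes = h * 60 + m + sec.fillna(0) / 60.0
    bad = (minutes < 0) | (minutes >= 1440)
    return minutes.where(~bad)


def read_checklists(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an EBD-layout TSV into (checklist table, observation table).

    One checklist row per unique sampling-event identifier; observation rows
    keep the raw count, with the ``X`` presence marker preserved as
    ``presence_only=True`` and a missing numeric count.  Malformed numeric
    fields become missing values and are logged, never fatal.

    Raises
    ------
    SchemaError
        If a required EBD column is absent (the message names it).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in EBD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.rename(columns=EBD_COLUMNS)

    for col in ("lat", "lon", "duration_min", "distance_km", "n_observers"):
        raw = df[col]
        df[col] = pd.to_numeric(raw, errors="coerce")
        n_bad = int((df[col].isna() & raw.notna()).sum())
        if n_bad:
            log.warning("column %s: %d malformed numeric value(s) set to missing", col, n_bad)
    df["date"] = pd.to_datetime(df["date"], errors="coerce")
    df["time_started_min"] = _parse_time_to_minutes(df["time_started"])
    df["complete"] = df["complete"].astype(str).isin(("1", "1.0", "True", "true"))

    # stationary protocols report no distance travelled
    stationary = df["protocol"].str.casefold() == "stationary"
    df.loc[stationary & df["distance_km"].isna(), "distance_km"] = 0.0

    checklists = (
        df[CHECKLIST_COLUMNS]
        .drop_duplicates(subset="checklist_id", keep="first")
        .reset_index(drop=True)
    )
    obs = df[["checklist_id", "species_code", "count"]].copy()
    obs["presence_only"] = obs["count"].astype("string").str.strip().eq(PRESENCE_MARKER)
    obs["count"] = pd.to_numeric(obs["count"], errors="coerce")
    obs = obs.reset_index(drop=True)
    return checklists, obs


def write_checklists(
    checklists: pd.DataFrame, obs: pd.DataFrame, path: str | Path
) -> None:
    """Write (checklist, observation) tables back to the EBD TSV layout."""
    merged = obs.merge(checklists, on="checklist_id", how="left")
    out = pd.DataFrame()
    inv = {v: k for k, v in EBD_COLUMNS.items()}
    out[inv["checklist_id"]] = merged["checklist_id"]
    out[inv["species_code"]] = merged["species_code"]
    count = merged["count"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    if "presence_only" in merged:
        count = count.where(~merged["presence_only"].fillna(False), PRESENCE_MARKER)
    out[inv["count"]] = count
    out[inv["lat"]] = merged["lat"]
    out[inv["lon"]] = merged["lon"]
    out[inv["date"]] = merged["date"].dt.strftime("%Y-%m-%d")
    tmin = merged["time_started_min"]
    out[inv["time_started"]] = tmin.map(
        lambda m: ""
        if pd.isna(m)
        else f"{int(m) // 60:02d}:{int(m) % 60:02d}:{round((m - int(m)) * 60):02d}"
    )
    out[inv["duration_min"]] = merged["duration_min"]
    out[inv["distance_km"]] = merged["distance_km"]
    out[inv["n_observers"]] = merged["n_observers"]
    out[inv["protocol"]] = merged["protocol"]
    out[inv["complete"]] = merged["complete"].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterConfig:
    """Inclusion rules for checklists; defaults follow standard practice."""

    require_complete: bool = True
    allowed_protocols: tuple[str, ...] = DEFAULT_PROTOCOLS
    max_duration_min: float = 300.0
    max_distance_km: float = 5.0
    start_date: _dt.date = _dt.date(2010, 1, 1)
    end_date: _dt.date = _dt.date(2021, 6, 30)


#: Fixed documented order in which removals are attributed.
FILTER_RULE_ORDER = (
    "incomplete",
    "protocol",
    "duration_missing",
    "duration",
    "distance_missing",
    "distance",
    "date_window",
)


@dataclass
class FilterReport:
    """Accounting of one filtering pass: removals per rule plus survivors."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0

    def check(self) -> None:
        assert self.n_input == self.n_retained + sum(self.removed.values())

    def to_json(self) -> str:
        return json.dumps(
            {"n_input": self.n_input, "removed": self.removed, "n_retained": self.n_retained},
            indent=2,
        )


def filter_checklists(
    checklists: pd.DataFrame, rules: FilterConfig | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the conjunctive inclusion rules; return survivors and a report.

    Boundary semantics: duration 300 min and distance 5.0 km are retained
    (only strictly greater effort is removed); the date window is closed at
    both ends.  Missing duration or distance removes the checklist under its
    own reason code.  Filtering is idempotent.
    """
    if rules is None:
        rules = FilterConfig()
    df = checklists
    n_input = len(df)
    fail = {}
    fail["incomplete"] = ~df["complete"].astype(bool) if rules.require_complete else pd.Series(False, index=df.index)
    fail["protocol"] = ~df["protocol"].isin(rules.allowed_protocols)
    fail["duration_missing"] = df["duration_min"].isna()
    fail["duration"] = df["duration_min"] > rules.max_duration_min
    fail["distance_missing"] = df["distance_km"].isna()
    fail["distance"] = df["distance_km"] > rules.max_distance_km
    dates = pd.to_datetime(df["date"]).dt.date
    fail["date_window"] = dates.isna() | (dates < rules.start_date) | (dates > rules.end_date)

    report = FilterReport(n_input=n_input)
    attributed = pd.Series(False, index=df.index)
    for rule in FILTER_RULE_ORDER:
        hit = fail[rule].fillna(True) & ~attributed
        report.removed[rule] = int(hit.sum())
        attributed |= hit
    survivors = df.loc[~attributed].reset_index(drop=True)
    report.n_retained = len(survivors)
    report.check()
    return survivors, report


# ---------------------------------------------------------------------------
# range clipping


def load_range_geojson(path: str | Path):
    """Read a (Multi)Polygon range map from a GeoJSON file."""
    with Path(path).open() as fh:
        gj = json.load(fh)
    geoms = []
    if gj.get("type") == "FeatureCollection":
        geoms = [shapely.geometry.shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [shapely.geometry.shape(gj["geometry"])]
    else:
        geoms = [shapely.geometry.shape(gj)]
    return geoms


def clip_to_range(checklists: pd.DataFrame, range_polygons) -> pd.DataFrame:
    """Retain checklists whose point lies inside or on a range polygon.

    Boundary points count as inside (``covers`` semantics), keeping
    assignment deterministic.  Invalid polygons are repaired with a
    zero-width buffer before use.

    Raises
    ------
    EmptyRangeError
        If the polygon set is empty — an absent range map is an input
        error, distinct from a species whose (valid) range excludes all
        checklists.
    """
    polys = list(range_polygons) if not hasattr(range_polygons, "geom_type") else [range_polygons]
    polys = [p if p.is_valid else p.buffer(0) for p in polys]
    polys = [p for p in polys if not p.is_empty]
    if not polys:
        raise EmptyRangeError("empty range polygon set")
    union = shapely.union_all(polys)
    pts = shapely.points(checklists["lon"].to_numpy(), checklists["lat"].to_numpy())
    mask = shapely.covers(union, pts)
    return checklists.loc[mask].reset_index(drop=True)


def resolve_counts(obs: pd.DataFrame, x_handling: str = "as_one") -> pd.DataFrame:
    """Resolve presence-only markers in the observation table.

    ``as_one`` maps each marker to count 1 (the minimal abundance consistent
    with a detection); ``drop`` removes those rows instead.
    """
    if x_handling not in ("as_one", "drop"):
        raise ValueError(f"unknown x_handling {x_handling!r}")
    out = obs.copy()
    if x_handling == "as_one":
        out.loc[out["presence_only"].fillna(False), "count"] = 1.0
    else:
        out = out.loc[~out["presence_only"].fillna(False)].reset_index(drop=True)
    out = out.loc[out["count"].notna() & (out["count"] >= 1)].reset_index(drop=True)
    return out
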