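"""Checklist tables to occupancy-ready detection histories.

Citizen-science checklists (one row per survey: who-cares, where,
when, protocol, completeness, species detected or not) become
detection/non-detection histories for single-season occupancy
analysis. The preparation steps mirror a standard eBird workflow:

1. keep only stationary-protocol, *complete* checklists inside the
   season window (non-reporting on a complete checklist is treated as
   a non-detection, not missing data);
2. group checklists into sites by unique location id, visits ordered
   by date — histories are ragged, sites differ in visit count;
3. randomly thin each city to a maximum number of sites to balance
   effort across regions;
4. scale survey date so one unit is ten calendar days from the season
   start (April 1 -> 0.0);
5. attach site-level landscape gradient covariates (hard-to-soft HS,
   brown-to-green BG) by nearest-pixel extraction from gradient
   surfaces.

Expected CSV header:
``checklist_id,site_id,city,x,y,date,protocol,complete,detected``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import PointSet, extract_at_points

__all__ = [
    "ChecklistTable",
    "OccuData",
    "read_checklists",
    "filter_checklists",
    "build_histories",
    "thin_sites",
    "scale_date",
    "attach_covariates",
]

REQUIRED_COLUMNS = [
    "checklist_id",
    "site_id",
    "city",
    "x",
    "y",
    "date",
    "protocol",
    "complete",
    "detected",
]

#: pandas is the checklist container; ChecklistTable is a semantic alias.
ChecklistTable = pd.DataFrame


def read_checklists(path) -> ChecklistTable:
    """Read a checklist CSV and validate its schema."""
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"checklist CSV missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    return df


@dataclass
class OccuData:
    """Sites, ragged detection histories, and visit covariates.

    ``sites`` has one row per site (site_id, city, x, y, plus any
    attached covariate columns such as HS and BG); ``visits`` has one
    row per survey (site_id, date, scaled date, y in {0, 1}), ordered
    by date within site.
    """

    sites: pd.DataFrame
    visits: pd.DataFrame
    season_start: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        counts = self.visits.groupby("site_id").size()
        empty = set(self.sites["site_id"]) - set(counts.index)
        if empty:
            raise ValueError(f"sites with zero visits: {sorted(empty)[:5]}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def histories(self) -> dict:
        """site_id -> 0/1 numpy detection history (visits in date order)."""
        return {
            sid: grp["y"].to_numpy(dtype=int)
            for sid, grp in self.visits.groupby("site_id", sort=False)
        }

    def naive_occupancy(self) -> float:
        """Share of sites with at least one detection (no correction)."""
        det = self.visits.groupby("site_id")["y"].max()
        return float(det.reindex(self.sites["site_id"]).mean())

    def to_dir(self, path) -> None:
        """Serialize as sites.csv + visits.csv + manifest.json."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.sites.to_csv(path / "sites.csv", index=False)
        self.visits.to_csv(path / "visits.csv", index=False)
        manifest = {
            "n_sites": self.n_sites,
            "n_visits": self.n_visits,
            "season_start": str(self.season_start.date()) if self.season_start is not None else None,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def from_dir(cls, path) -> "OccuData":
        path = Path(path)
        sites = pd.read_csv(path / "sites.csv")
        visits = pd.read_csv(path / "visits.csv", parse_dates=["date"])
        manifest = json.loads((path / "manifest.json").read_text())
        start = manifest.get("season_start")
        return cls(sites, visits, pd.Timestamp(start) if start else None)


def filter_checklists(
    table: ChecklistTable,
    start_date,
    end_date,
    protocol: str = "stationary",
) -> ChecklistTable:
    """Keep stationary, complete checklists within [start, end] inclusive."""
    start = pd.Timestamp(start_date)
    end = pd.Timestamp(end_date)
    if end < start:
        raise ValueError("end_date precedes start_date")
    dates = pd.to_datetime(table["date"])
    keep = (
        (table["protocol"].astype(str).str.lower() == protocol.lower())
        & table["complete"].astype(bool)
        & (dates >= start)
        & (dates <= end)
    )
    out = table.loc[keep].copy()
    out["date"] = dates[keep]
    if out.empty:
        warnings.warn("no checklists survive filtering", stacklevel=2)
    return out


def build_histories(table: ChecklistTable, season_start=None) -> OccuData:
    """Group filtered checklists into per-site detection histories.

    One site per unique ``site_id``; visits are ordered by date and
    non-reporting on a complete checklist counts as a zero.
    """
    if table["checklist_id"].duplicated().any():
        dupes = table.loc[table["checklist_id"].duplicated(), "checklist_id"].tolist()
        raise ValueError(f"duplicate checklist ids: {dupes[:5]}")
    t = table.copy()
    t["date"] = pd.to_datetime(t["date"])
    if season_start is None:
        season_start = t["date"].min()
    season_start = pd.Timestamp(season_start)
    t = t.sort_values(["site_id", "date", "checklist_id"], kind="stable")
    visits = pd.DataFrame(
        {
            "site_id": t["site_id"].to_numpy(),
            "date": t["date"].to_numpy(),
            "scaled_date": scale_date(t["date"], season_start),
            "y": t["detected"].astype(int).to_numpy(),
        }
    )
    sites = (
        t.groupby("site_id", sort=True)
        .agg(city=("city", "first"), x=("x", "first"), y_coord=("y", "first"))
        .reset_index()
        .rename(columns={"y_coord": "y"})
    )
    return OccuData(sites, visits, season_start)


def thin_sites(data: OccuData, max_per_city: int = 250, seed: int = 0) -> OccuData:
    """Randomly thin each city to at most ``max_per_city`` sites.

    Cities at or under the cap are untouched; others are subsampled
    uniformly without replacement. Deterministic for a given seed.
    """
    if max_per_city < 1:
        raise ValueError("max_per_city must be at least 1")
    rng = np.random.default_rng(seed)
    kept = []
    for city, grp in data.sites.groupby("city", sort=True):
        if len(grp) <= max_per_city:
            kept.append(grp)
        else:
            idx = rng.choice(len(grp), size=max_per_city, replace=False)
            kept.append(grp.iloc[np.sort(idx)])
    sites = pd.concat(kept, ignore_index=True)
    visits = data.visits[data.visits["site_id"].isin(set(sites["site_id"]))].reset_index(
        drop=True
    )
    return OccuData(sites, visits, data.season_start)


def scale_date(date, season_start):
    """Days since season start divided by ten.

    One unit of the scaled covariate is ten calendar days; April 1
    maps to 0.0 and September 30 of the same year to 18.2.
    """
    date = pd.to_datetime(date)
    start = pd.Timestamp(season_start)
    delta = (date - start) / pd.Timedelta(days=1)
    scalar = np.isscalar(delta) or isinstance(delta, (float, int))
    arr = np.atleast_1d(np.asarray(delta, dtype=float))
    if np.any(arr < 0):
        raise ValueError("date precedes season start")
    out = arr / 10.0
    return float(out[0]) if scalar else out


def attach_covariates(data: OccuData, surfaces: dict) -> OccuData:
    """Join named gradient surfaces to sites by nearest-pixel extraction.

    ``surfaces`` maps covariate name (e.g. ``"HS"``, ``"BG"``) to a
    ContinuousRaster. Sites falling outside any surface or on nodata
    are dropped with a warning.
    """
    sites = data.sites.copy()
    points = PointSet(list(sites["site_id"]), sites["x"].to_numpy(), sites["y"].to_numpy())
    ok = np.ones(len(sites), dtype=bool)
    for name, surface in surfaces.items():
        ext = extract_at_points(surface, points)
        sites[name] = ext["value"].to_numpy()
        ok &= ext["inside"].to_numpy() & ~np.isnan(ext["value"].to_numpy())
    if not ok.all():
        dropped = sites.loc[~ok, "site_id"].tolist()
        warnings.warn(
            f"dropping {len(dropped)} site(s) outside surface extents: {dropped[:5]}",
            stacklevel=2,
        )
        sites = sites.loc[ok].reset_index(drop=True)
    visits = data.visits[data.visits["site_id"].isin(set(sites["site_id"]))].reset_index(
        drop=True
    )
    return OccuData(sites, visits, data.season_start)
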