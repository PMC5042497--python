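"""Readers and writers for telemetry tables, camera records, habitat maps and UD grids.

Conventions (documented, not configurable):

* Coordinates are planar projected metres (e.g. UTM); no geodetic transforms
  are performed — callers must pre-project.
* Grids have their origin at the lower-left cell *corner*, row 0 is the
  southernmost row, cells are square, and cell membership uses the half-open
  interval ``[x0 + i*c, x0 + (i+1)*c)``.
* Delimited files are comma-separated UTF-8 with a mandatory header; column
  names are supplied through a mapping rather than fixed.
* Timestamps are naive local time; any UTC offset is handled by the caller.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

logger = logging.getLogger("nichekit.io")

DEFAULT_LOCATION_COLUMNS = {
    "animal_id": "animal_id",
    "species": "species",
    "x": "x",
    "y": "y",
    "timestamp": "timestamp",
    "habitat": "habitat",
    "active": "active",
}

DEFAULT_CAMERA_COLUMNS = {
    "station_id": "station_id",
    "species": "species",
    "datetime": "datetime",
}


class SchemaError(ValueError):
    """A mandatory column is missing or a file violates its declared dialect."""


@dataclass
class LocationSet:
    """One animal's timestamped planar locations.

    Parameters
    ----------
    animal_id, species : str
        Labels identifying the individual and its species.
    x, y : ndarray of float
        Easting / northing in projected metres.
    t : pandas.DatetimeIndex
        Acquisition times, strictly increasing.
    habitat : list of str, optional
        Habitat class recorded at each location.
    active : ndarray of bool, optional
        Whether the animal was active at each location.
    """

    animal_id: str
    species: str
    x: np.ndarray
    y: np.ndarray
    t: pd.DatetimeIndex
    habitat: list | None = None
    active: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not isinstance(self.t, pd.DatetimeIndex):
            self.t = pd.DatetimeIndex(self.t)
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError(f"{self.animal_id}: non-finite coordinates")
        if len(self.x) != len(self.y) or len(self.x) != len(self.t):
            raise ValueError(f"{self.animal_id}: ragged columns")
        if len(self.t) > 1 and not self.t.is_monotonic_increasing:
            raise ValueError(f"{self.animal_id}: timestamps not sorted")
        if len(self.t) > 1 and self.t.has_duplicates:
            raise ValueError(f"{self.animal_id}: duplicate timestamps")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of coordinates."""
        return np.column_stack([self.x, self.y])


@dataclass
class CameraRecord:
    """A single camera-trap detection."""

    station_id: str
    species: str
    datetime: pd.Timestamp
    station_coords: tuple | None = None


@dataclass
class HabitatMap:
    """Categorical habitat raster.

    ``grid`` holds indices into ``classes`` (row 0 = southernmost row);
    nodata cells are ``-1``.
    """

    grid: np.ndarray
    cell_size: float
    origin: tuple
    classes: list
    nodata_code: int = -9999

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=int)
        if self.grid.ndim != 2:
            raise ValueError("habitat grid must be 2-D")
        if len(self.classes) < 1:
            raise ValueError("need at least one habitat class")
        valid = self.grid[self.grid >= 0]
        if valid.size and valid.max() >= len(self.classes):
            raise ValueError("grid contains a code outside the class legend")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    def class_proportions(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Proportion of each class over non-nodata cells (optionally within mask)."""
        g = self.grid if mask is None else self.grid[mask]
        g = g[g >= 0]
        if g.size == 0:
            return np.zeros(self.n_classes)
        counts = np.bincount(g, minlength=self.n_classes).astype(float)
        return counts / counts.sum()

    def cell_centers(self) -> tuple:
        """(X, Y) meshgrid arrays of cell-centre coordinates."""
        nrows, ncols = self.grid.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def class_at(self, x, y) -> np.ndarray:
        """Class index at coordinates (−1 outside the map or on nodata)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        nrows, ncols = self.grid.shape
        inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
        out = np.full(x.shape, -1, dtype=int)
        out[inside] = self.grid[row[inside], col[inside]]
        return out


# ---------------------------------------------------------------------------
# telemetry / camera readers


def read_locations(path, columns: dict | None = None,
                   timestamp_format: str | None = None) -> list:
    """Read a telemetry CSV into one :class:`LocationSet` per animal.

    Rows with unparseable coordinates or timestamps are rejected and logged;
    a missing mandatory column raises :class:`SchemaError`.
    """
    cols = dict(DEFAULT_LOCATION_COLUMNS, **(columns or {}))
    df = pd.read_csv(path, dtype=str)
    mandatory = ["animal_id", "species", "x", "y", "timestamp"]
    missing = [cols[k] for k in mandatory if cols[k] not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    x = pd.to_numeric(df[cols["x"]], errors="coerce")
    y = pd.to_numeric(df[cols["y"]], errors="coerce")
    t = pd.to_datetime(df[cols["timestamp"]], format=timestamp_format,
                       errors="coerce")
    bad = x.isna() | y.isna() | t.isna()
    for idx in df.index[bad]:
        reason = ("coordinate" if (x.isna()[idx] or y.isna()[idx])
                  else "timestamp")
        logger.warning("rejected row %d of %s: unparseable %s", idx, path, reason)
    keep = df.index[~bad]

    out = []
    clean = pd.DataFrame({
        "animal_id": df.loc[keep, cols["animal_id"]],
        "species": df.loc[keep, cols["species"]],
        "x": x[keep], "y": y[keep], "t": t[keep],
    })
    if cols["habitat"] in df.columns:
        clean["habitat"] = df.loc[keep, cols["habitat"]]
    if cols["active"] in df.columns:
        clean["active"] = df.loc[keep, cols["active"]].astype(str).str.lower().isin(
            ["1", "true", "yes"])
    for (aid, sp), grp in clean.groupby(["animal_id", "species"], sort=True):
        grp = grp.sort_values("t")
        out.append(LocationSet(
            animal_id=str(aid), species=str(sp),
            x=grp["x"].to_numpy(), y=grp["y"].to_numpy(),
            t=pd.DatetimeIndex(grp["t"]),
            habitat=list(grp["habitat"]) if "habitat" in grp else None,
            active=grp["active"].to_numpy() if "active" in grp else None,
        ))
    return out


def write_locations(locsets: list, path) -> None:
    rows = []
    for ls in locsets:
        for i in range(len(ls)):
            row = {"animal_id": ls.animal_id, "species": ls.species,
                   "x": ls.x[i], "y": ls.y[i], "timestamp": ls.t[i].isoformat()}
            if ls.habitat is not None:
                row["habitat"] = ls.habitat[i]
            if ls.active is not None:
                row["active"] = bool(ls.active[i])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_camera_records(path, columns: dict | None = None,
                        datetime_format: str | None = None) -> list:
    """Read camera-trap detections; returns a list of :class:`CameraRecord`."""
    cols = dict(DEFAULT_CAMERA_COLUMNS, **(columns or {}))
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    t = pd.to_datetime(df[cols["datetime"]], format=datetime_format,
                       errors="coerce")
    records = []
    for idx in df.index:
        if pd.isna(t[idx]):
            logger.warning("rejected camera row %d of %s: unparseable datetime",
                           idx, path)
            continue
        records.append(CameraRecord(
            station_id=str(df.loc[idx, cols["station_id"]]),
            species=str(df.loc[idx, cols["species"]]),
            datetime=t[idx]))
    return records


def write_camera_records(records: list, path) -> None:
    pd.DataFrame([{"station_id": r.station_id, "species": r.species,
                   "datetime": r.datetime.isoformat()} for r in records]
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII grids


def _read_ascii_grid(path):
    header = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise SchemaError(f"ESRI ASCII grid missing header field {key}")
    body = " ".join(lines[i:])
    data = np.array(body.split(), dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.size != nrows * ncols:
        raise SchemaError(
            f"grid body has {data.size} values, expected {nrows * ncols}")
    # file rows run north to south; flip so row 0 is the southernmost
    grid = data.reshape(nrows, ncols)[::-1]
    return grid, header


def _write_ascii_grid(grid, cell_size, origin, path, nodata, fmt="%.10g"):
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin[0]!r}\n")
        fh.write(f"yllcorner {origin[1]!r}\n")
        fh.write(f"cellsize {cell_size!r}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in grid[::-1]:
            fh.write(" ".join(fmt % v for v in row) + "\n")


def read_habitat_map(path, legend=None, cell_size: float | None = None) -> HabitatMap:
    """Read a habitat map from an ESRI ASCII grid (+ legend CSV) or GeoJSON.

    Parameters
    ----------
    path : str
        ``.asc``/``.grd`` raster or ``.geojson``/``.json`` FeatureCollection
        whose features carry a ``habitat`` property.
    legend : str or list, optional
        For rasters: a legend CSV with columns ``code,name``, or an ordered
        list of class names (codes 0..D-1). Mandatory for rasters.
    cell_size : float, optional
        Rasterization resolution for GeoJSON input (metres). Mandatory there.
    """
    p = str(path)
    if p.endswith((".geojson", ".json")):
        if cell_size is None:
            raise ValueError("cell_size is required to rasterize GeoJSON input")
        return _rasterize_geojson(p, cell_size)
    if legend is None:
        raise ValueError("a class legend is required for raster input")
    raw, header = _read_ascii_grid(p)
    nodata = header.get("nodata_value", -9999)
    if isinstance(legend, (list, tuple)):
        code_to_name = {i: str(n) for i, n in enumerate(legend)}
    else:
        ldf = pd.read_csv(legend)
        if not {"code", "name"} <= set(ldf.columns):
            raise SchemaError("legend CSV must have columns code,name")
        code_to_name = dict(zip(ldf["code"].astype(int), ldf["name"].astype(str)))
    classes = [code_to_name[c] for c in sorted(code_to_name)]
    index_of = {c: i for i, c in enumerate(sorted(code_to_name))}
    grid = np.full(raw.shape, -1, dtype=int)
    mask = raw != nodata
    codes = raw[mask].astype(int)
    unknown = set(codes) - set(index_of)
    if unknown:
        raise SchemaError(
            f"unknown class code(s) {sorted(unknown)}; legend defines "
            f"{sorted(index_of)}")
    grid[mask] = [index_of[c] for c in codes]
    return HabitatMap(grid=grid, cell_size=header["cellsize"],
                      origin=(header["xllcorner"], header["yllcorner"]),
                      classes=classes, nodata_code=int(nodata))


def _rasterize_geojson(path, cell_size):
    with open(path) as fh:
        gj = json.load(fh)
    geoms, labels = [], []
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if "habitat" not in props:
            raise SchemaError("GeoJSON feature lacks a 'habitat' property")
        geoms.append(shapely.geometry.shape(feat["geometry"]))
        labels.append(str(props["habitat"]))
    classes = sorted(set(labels))
    minx = min(g.bounds[0] for g in geoms)
    miny = min(g.bounds[1] for g in geoms)
    maxx = max(g.bounds[2] for g in geoms)
    maxy = max(g.bounds[3] for g in geoms)
    ncols = max(1, int(np.ceil((maxx - minx) / cell_size)))
    nrows = max(1, int(np.ceil((maxy - miny) / cell_size)))
    xs = minx + (np.arange(ncols) + 0.5) * cell_size
    ys = miny + (np.arange(nrows) + 0.5) * cell_size
    X, Y = np.meshgrid(xs, ys)
    grid = np.full((nrows, ncols), -1, dtype=int)
    for geom, lab in zip(geoms, labels):
        inside = shapely.contains_xy(geom, X.ravel(), Y.ravel()).reshape(grid.shape)
        grid[inside] = classes.index(lab)
    return HabitatMap(grid=grid, cell_size=float(cell_size),
                      origin=(minx, miny), classes=classes)


def write_habitat_map(hmap: HabitatMap, path, legend_path=None) -> None:
    """Write a habitat map as an ESRI ASCII grid plus an optional legend CSV."""
    out = np.where(hmap.grid >= 0, hmap.grid, hmap.nodata_code)
    _write_ascii_grid(out.astype(float), hmap.cell_size, hmap.origin, path,
                      nodata=hmap.nodata_code, fmt="%d")
    if legend_path is not None:
        pd.DataFrame({"code": range(hmap.n_classes), "name": hmap.classes}
                     ).to_csv(legend_path, index=False)


def write_ud_grid(ud, path) -> None:
    """Write a utilization distribution as an ESRI ASCII grid (densities per m^2)."""
    _write_ascii_grid(ud.grid, ud.cell_size, ud.origin, path, nodata=-9999,
                      fmt="%.9e")


def read_ud_grid(path, animal_id="", bandwidth=(np.nan, np.nan), n_points=0):
    """Read a UD written by :func:`write_ud_grid`."""
    from .homerange import UtilizationDistribution

    raw, header = _read_ascii_grid(str(path))
    nodata = header.get("nodata_value", -9999)
    grid = np.where(raw == nodata, 0.0, raw)
    return UtilizationDistribution(
        grid=grid, cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        bandwidth=tuple(bandwidth), n_points=n_points, animal_id=animal_id)
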