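"""Fixed-kernel utilization distributions and home-range geometry.

The estimator is the classical fixed bivariate Gaussian kernel with a
diagonal bandwidth matrix chosen per axis by the two-stage direct plug-in
rule (Sheather–Jones family).  Home ranges are highest-density regions of
the gridded UD: cells are ranked by density and accumulated until the
requested probability mass is reached, so the 95% isopleth is the smallest
cell set holding 95% of the UD mass.  Minimum convex polygons (MCP-100%)
and their accumulation curves support sampling-effort diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from .io import LocationSet

MIN_LOCATIONS = 20  # inclusion rule for home-range estimation

_SQRT2PI = np.sqrt(2.0 * np.pi)


class TooFewLocationsError(ValueError):
    """Fewer locations than the inclusion rule requires."""


@dataclass
class UtilizationDistribution:
    """Gridded utilization density (per m^2), unit mass over the grid."""

    grid: np.ndarray
    cell_size: float
    origin: tuple
    bandwidth: tuple
    n_points: int
    animal_id: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    @property
    def total_mass(self) -> float:
        return float(self.grid.sum() * self.cell_area)

    def cell_centers(self):
        nrows, ncols = self.grid.shape
        xs = self.origin[0] + (np.arange(ncols) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class HomeRange:
    """Highest-density isopleth region of a UD at a stated probability level."""

    level: float
    mask: np.ndarray            # boolean, same shape as the source UD grid
    cell_size: float
    origin: tuple
    animal_id: str = ""

    @property
    def area_m2(self) -> float:
        return float(self.mask.sum()) * self.cell_size ** 2

    @property
    def area_km2(self) -> float:
        return self.area_m2 / 1e6

    def contains_xy(self, x, y) -> np.ndarray:
        """Whether points fall inside the home-range cell union."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        nrows, ncols = self.mask.shape
        ok = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
        out = np.zeros(x.shape, dtype=bool)
        out[ok] = self.mask[row[ok], col[ok]]
        return out

    def cell_center_coords(self) -> np.ndarray:
        """(k, 2) coordinates of the centres of included cells."""
        rows, cols = np.nonzero(self.mask)
        xs = self.origin[0] + (cols + 0.5) * self.cell_size
        ys = self.origin[1] + (rows + 0.5) * self.cell_size
        return np.column_stack([xs, ys])


@dataclass
class AccumulationCurve:
    """MCP-100% area versus number of time-ordered locations (k = 3..n)."""

    animal_id: str
    n_locations: np.ndarray
    areas_km2: np.ndarray


# ---------------------------------------------------------------------------
# plug-in bandwidth (two-stage direct plug-in, per axis)


def _phi_deriv(x, order):
    # Gaussian density derivatives via Hermite polynomials
    phi = np.exp(-0.5 * x * x) / _SQRT2PI
    if order == 4:
        return (x ** 4 - 6 * x ** 2 + 3) * phi
    if order == 6:
        return (x ** 6 - 15 * x ** 4 + 45 * x ** 2 - 15) * phi
    raise ValueError(order)


def _psi_hat(x, g, order):
    # kernel estimator of the density functional psi_r at pilot bandwidth g
    d = (x[:, None] - x[None, :]) / g
    return _phi_deriv(d, order).sum() / (len(x) ** 2 * g ** (order + 1))


def _dpik_1d(x):
    """Two-stage direct plug-in bandwidth for one axis (Gaussian kernel)."""
    n = len(x)
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25])) / 1.349
    sigma = min(sd, iqr) if iqr > 0 else sd
    if sigma <= 0:
        raise ValueError("zero variance on an axis; cannot select a bandwidth")
    # normal-scale start for psi_8, then two functional-estimation stages
    psi8 = 105.0 / (32.0 * np.sqrt(np.pi) * sigma ** 9)
    g6 = (30.0 / (_SQRT2PI * psi8 * n)) ** (1.0 / 9.0)
    psi6 = _psi_hat(x, g6, 6)                      # negative
    g4 = (-6.0 / (_SQRT2PI * psi6 * n)) ** (1.0 / 7.0)
    psi4 = _psi_hat(x, g4, 4)                      # positive
    if psi4 <= 0:
        # fall back to the Gaussian-reference rule on degenerate samples
        return 1.06 * sigma * n ** (-0.2)
    return (1.0 / (2.0 * np.sqrt(np.pi) * psi4 * n)) ** 0.2


def plug_in_bandwidth(points: LocationSet | np.ndarray) -> tuple:
    """Per-axis direct plug-in bandwidths (h_x, h_y) in metres.

    Requires at least 10 points with nonzero variance on each axis.
    """
    xy = points.xy if isinstance(points, LocationSet) else np.asarray(points, float)
    if len(xy) < 10:
        raise ValueError(f"need >= 10 points for plug-in bandwidth, got {len(xy)}")
    return (_dpik_1d(xy[:, 0]), _dpik_1d(xy[:, 1]))


# ---------------------------------------------------------------------------
# kernel UD


def estimate_ud(points: LocationSet | np.ndarray,
                bandwidth: tuple | None = None,
                cell_size: float = 50.0,
                extent: tuple | None = None,
                pad_factor: float = 3.0,
                min_locations: int = MIN_LOCATIONS,
                allow_few: bool = False,
                animal_id: str | None = None) -> UtilizationDistribution:
    """Fixed Gaussian-kernel utilization distribution on a regular grid.

    Parameters
    ----------
    points : LocationSet or (n, 2) array
        Planar locations in metres.
    bandwidth : (h_x, h_y), optional
        Kernel bandwidths; selected by :func:`plug_in_bandwidth` when omitted.
    cell_size : float
        Grid resolution in metres (default 50 m).
    extent : (xmin, xmax, ymin, ymax), optional
        Grid extent override; default is the point bounding box padded by
        ``pad_factor * max(h_x, h_y)``.
    min_locations : int
        Inclusion rule (default 20 locations); ``allow_few=True`` overrides it
        for the occasional slightly-short individual.

    The gridded density is renormalized to unit mass over the grid.
    """
    if isinstance(points, LocationSet):
        xy = points.xy
        if animal_id is None:
            animal_id = points.animal_id
    else:
        xy = np.asarray(points, dtype=float)
    n = len(xy)
    if n < min_locations and not allow_few:
        raise TooFewLocationsError(
            f"{animal_id or 'point set'}: {n} locations < the >= {min_locations}"
            f"-location rule (pass allow_few=True to override)")
    if bandwidth is None:
        bandwidth = plug_in_bandwidth(xy)
    hx, hy = float(bandwidth[0]), float(bandwidth[1])
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidths must be positive")

    if extent is None:
        pad = pad_factor * max(hx, hy)
        extent = (xy[:, 0].min() - pad, xy[:, 0].max() + pad,
                  xy[:, 1].min() - pad, xy[:, 1].max() + pad)
    xmin, xmax, ymin, ymax = extent
    ncols = max(8, int(np.ceil((xmax - xmin) / cell_size)))
    nrows = max(8, int(np.ceil((ymax - ymin) / cell_size)))
    xs = xmin + (np.arange(ncols) + 0.5) * cell_size
    ys = ymin + (np.arange(nrows) + 0.5) * cell_size

    # separable product kernel: density = Ky @ Kx^T / n
    kx = np.exp(-0.5 * ((xs[:, None] - xy[None, :, 0]) / hx) ** 2) / (hx * _SQRT2PI)
    ky = np.exp(-0.5 * ((ys[:, None] - xy[None, :, 1]) / hy) ** 2) / (hy * _SQRT2PI)
    grid = (ky @ kx.T) / n
    mass = grid.sum() * cell_size ** 2
    if mass <= 0:
        raise ValueError("UD mass is zero on the requested grid")
    grid /= mass
    return UtilizationDistribution(grid=grid, cell_size=float(cell_size),
                                   origin=(xmin, ymin), bandwidth=(hx, hy),
                                   n_points=n, animal_id=animal_id or "")


def isopleth(ud: UtilizationDistribution, level: float = 0.95) -> HomeRange:
    """Highest-density region containing ``level`` of the UD mass.

    Cells are ranked by density (ties broken by row-major order) and
    accumulated until the cumulative mass first reaches ``level``.
    """
    if not (0.0 < level <= 1.0):
        raise ValueError("level must be in (0, 1]")
    dens = ud.grid.ravel()
    rows, cols = np.unravel_index(np.arange(dens.size), ud.grid.shape)
    order = np.lexsort((cols, rows, -dens))
    mass = np.cumsum(dens[order]) * ud.cell_area
    if level >= 1.0:
        k = int((dens > 0).sum())
    else:
        k = int(np.searchsorted(mass, level * ud.total_mass)) + 1
        k = min(k, dens.size)
    mask = np.zeros(dens.size, dtype=bool)
    mask[order[:k]] = dens[order[:k]] > 0
    return HomeRange(level=level, mask=mask.reshape(ud.grid.shape),
                     cell_size=ud.cell_size, origin=ud.origin,
                     animal_id=ud.animal_id)


def ud_mass_in(ud: UtilizationDistribution, hr: HomeRange) -> float:
    """Integrate a UD over a home range defined on the same grid."""
    if ud.grid.shape != hr.mask.shape or ud.origin != hr.origin:
        raise ValueError("UD and home range are on different grids; resample first")
    return float(ud.grid[hr.mask].sum() * ud.cell_area)


# ---------------------------------------------------------------------------
# minimum convex polygon


def mcp(points: LocationSet | np.ndarray, fraction: float = 1.0):
    """Minimum convex polygon of the locations; returns (polygon, area_km2).

    ``fraction`` < 1 drops the most-peripheral points (farthest from the
    centroid) before taking the hull. Fewer than 3 non-collinear points
    yield a degenerate polygon with zero area (with a warning).
    """
    xy = points.xy if isinstance(points, LocationSet) else np.asarray(points, float)
    if fraction < 1.0:
        ctr = xy.mean(axis=0)
        d = np.hypot(*(xy - ctr).T)
        keep = np.argsort(d)[: max(3, int(np.ceil(fraction * len(xy))))]
        xy = xy[keep]
    hull = shapely.MultiPoint(xy).convex_hull
    if hull.area == 0:
        warnings.warn("fewer than 3 non-collinear points: MCP area is 0")
    return hull, hull.area / 1e6


def accumulation_curve(points: LocationSet) -> AccumulationCurve:
    """MCP-100% area after the first k time-ordered locations, k = 3..n."""
    xy = points.xy
    if len(xy) < 3:
        raise ValueError("need >= 3 locations for an accumulation curve")
    ks = np.arange(3, len(xy) + 1)
    areas = np.empty(len(ks))
    for i, k in enumerate(ks):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            areas[i] = mcp(xy[:k])[1]
    return AccumulationCurve(animal_id=points.animal_id,
                             n_locations=ks, areas_km2=areas)


def summarize_home_ranges(areas_km2, species) -> pd.DataFrame:
    """Median / min / max home-range area per species (areas in km^2).

    The median is used because home-range sizes are typically right-skewed.
    """
    df = pd.DataFrame({"species": list(species), "area_km2": list(areas_km2)})
    out = df.groupby("species")["area_km2"].agg(
        n="count", median_km2="median", min_km2="min", max_km2="max")
    return out.reset_index()


def apply_location_rule(counts: dict, min_locations: int = MIN_LOCATIONS) -> list:
    """IDs meeting the inclusion rule (>= ``min_locations`` locations)."""
    return [k for k, v in counts.items() if v >= min_locations]


# ---------------------------------------------------------------------------
# model-style front end


class KernelHomeRange:
    """Fixed-kernel home-range model for one individual.

    A thin statsmodels-style front end: construct from a
    :class:`~nichekit.io.LocationSet`, call :meth:`fit`, and read the
    estimates off the returned :class:`HomeRangeResult`.
    """

    def __init__(self, locations: LocationSet, cell_size: float = 50.0,
                 min_locations: int = MIN_LOCATIONS, allow_few: bool = False):
        self.locations = locations
        self.cell_size = cell_size
        self.min_locations = min_locations
        self.allow_few = allow_few

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, animal_id: str, species: str = "",
                       **kw) -> "KernelHomeRange":
        ls = LocationSet(animal_id=animal_id, species=species,
                         x=df["x"].to_numpy(), y=df["y"].to_numpy(),
                         t=pd.DatetimeIndex(df["timestamp"]))
        return cls(ls, **kw)

    def fit(self, bandwidth: tuple | None = None,
            levels: tuple = (0.95, 0.5)) -> "HomeRangeResult":
        ud = estimate_ud(self.locations, bandwidth=bandwidth,
                         cell_size=self.cell_size,
                         min_locations=self.min_locations,
                         allow_few=self.allow_few)
        ranges = {lv: isopleth(ud, lv) for lv in levels}
        _, mcp_area = mcp(self.locations)
        return HomeRangeResult(model=self, ud=ud, home_ranges=ranges,
                               mcp_area_km2=mcp_area)


@dataclass
class HomeRangeResult:
    """Fitted utilization distribution with its isopleth home ranges."""

    model: KernelHomeRange
    ud: UtilizationDistribution
    home_ranges: dict
    mcp_area_km2: float

    @property
    def bandwidth(self) -> tuple:
        return self.ud.bandwidth

    def area_km2(self, level: float = 0.95) -> float:
        return self.home_ranges[level].area_km2

    def accumulation_curve(self) -> AccumulationCurve:
        return accumulation_curve(self.model.locations)

    def summary(self) -> pd.DataFrame:
        rows = [{"animal_id": self.ud.animal_id,
                 "n_locations": self.ud.n_points,
                 "h_x_m": self.ud.bandwidth[0],
                 "h_y_m": self.ud.bandwidth[1],
                 "mcp100_km2": self.mcp_area_km2}]
        for lv, hr in sorted(self.home_ranges.items()):
            rows[0][f"ud{int(round(lv * 100))}_km2"] = hr.area_km2
        return pd.DataFrame(rows)
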