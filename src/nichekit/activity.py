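"""Diel activity analysis on the sun-adjusted 24-hour circle.

Camera-trap detection times are first rescaled to *sun time*: a
double-anchored transform mapping sunrise to 06:00 and sunset to 18:00,
with the light and dark periods each divided into twelve equal "hours".
This removes seasonal day-length variation before any circular analysis.
Sunrise and sunset are computed from the standard NOAA solar-position
equations (zenith 90.833 deg, i.e. including refraction and solar radius).

Per-species activity densities are circular kernel estimates built from
von Mises kernels on the 24-hour circle; the concentration kappa is chosen
by leave-one-out log-likelihood over a logarithmic grid when not supplied.
Active periods are highest-density isopleths (95% and 50% by convention),
and pairwise activity overlap is the intersection-over-union of the two
species' isopleth interval sets (directed intersection/duration variants
are also reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd
from scipy.special import i0e

HOURS = 24.0
DEFAULT_GRID = 1440  # one-minute resolution
KAPPA_GRID = 2.0 ** np.arange(0, 11)  # 1 .. 1024


@dataclass
class SunClock:
    """Sunrise and sunset (local clock hours) for one date and site."""

    date: _date
    sunrise: float
    sunset: float
    latitude: float
    longitude: float

    def __post_init__(self):
        if not (0.0 <= self.sunrise < HOURS and 0.0 <= self.sunset < HOURS):
            raise ValueError("sunrise/sunset must lie in [0, 24)")
        if self.sunrise >= self.sunset:
            raise ValueError("sunrise must precede sunset within the day")

    @property
    def day_length(self) -> float:
        return self.sunset - self.sunrise


@dataclass
class ActivitySample:
    """A species' detection times on the sun-time circle, hours in [0, 24)."""

    species: str
    sun_times: np.ndarray

    def __post_init__(self):
        self.sun_times = np.asarray(self.sun_times, dtype=float) % HOURS

    def __len__(self):
        return len(self.sun_times)


@dataclass
class CircularDensity:
    """Periodic activity density sampled on an equispaced sun-time grid.

    ``density[k]`` is the per-hour density at ``times[k]``; the mean of the
    density times 24 equals 1 (unit mass on the circle).
    """

    times: np.ndarray
    density: np.ndarray
    kappa: float
    n: int
    species: str = ""

    @property
    def grid_step(self) -> float:
        return HOURS / len(self.times)

    def mass(self) -> float:
        return float(self.density.mean() * HOURS)

    def mode_hour(self) -> float:
        return float(self.times[int(np.argmax(self.density))])


@dataclass
class ActivityIsopleth:
    """Highest-density sun-time intervals holding a stated probability mass."""

    level: float
    selected: np.ndarray       # boolean minute mask on the density grid
    grid_step: float
    species: str = ""

    @property
    def total_duration(self) -> float:
        return float(self.selected.sum() * self.grid_step)

    @property
    def intervals(self) -> list:
        """Disjoint (start, end) sun-hour intervals; a wrap past midnight
        appears as end > 24."""
        sel = self.selected
        m = len(sel)
        if sel.all():
            return [(0.0, HOURS)]
        if not sel.any():
            return []
        # rotate so index 0 is outside any run, then collect runs
        off = int(np.argmin(sel))
        rolled = np.roll(sel, -off)
        edges = np.flatnonzero(np.diff(np.concatenate([[0], rolled.astype(int),
                                                       [0]])))
        out = []
        for s, e in zip(edges[::2], edges[1::2]):
            start = (s + off) % m * self.grid_step
            end = start + (e - s) * self.grid_step
            out.append((start, end))
        return sorted(out)


# ---------------------------------------------------------------------------
# NOAA solar geometry


def _noaa_sun_utc(latitude, longitude, date):
    """(sunrise, sunset) in fractional UTC hours from NOAA equations."""
    day_of_year = date.timetuple().tm_yday
    gamma = 2.0 * np.pi / 365.0 * (day_of_year - 1 + (12 - 12) / 24.0)
    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(gamma)
                       - 0.032077 * np.sin(gamma)
                       - 0.014615 * np.cos(2 * gamma)
                       - 0.040849 * np.sin(2 * gamma))
    decl = (0.006918 - 0.399912 * np.cos(gamma) + 0.070257 * np.sin(gamma)
            - 0.006758 * np.cos(2 * gamma) + 0.000907 * np.sin(2 * gamma)
            - 0.002697 * np.cos(3 * gamma) + 0.00148 * np.sin(3 * gamma))
    lat = np.radians(latitude)
    zenith = np.radians(90.833)
    cos_ha = (np.cos(zenith) / (np.cos(lat) * np.cos(decl))
              - np.tan(lat) * np.tan(decl))
    if not -1.0 < cos_ha < 1.0:
        raise ValueError("sun never rises/sets at this latitude and date")
    ha = np.degrees(np.arccos(cos_ha))
    sunrise = (720.0 - 4.0 * (longitude + ha) - eqtime) / 60.0
    sunset = (720.0 - 4.0 * (longitude - ha) - eqtime) / 60.0
    return sunrise, sunset


def solar_times(latitude: float, longitude: float, date: _date,
                utc_offset: float = 0.0) -> SunClock:
    """Sunrise/sunset for a site and date (NOAA equations, zenith 90.833 deg).

    ``utc_offset`` converts to local clock hours (e.g. -4 for the Pantanal).
    Polar latitudes (|lat| >= 66.5 deg) are rejected.
    """
    if abs(latitude) >= 66.5:
        raise ValueError("polar latitudes are not supported")
    sr, ss = _noaa_sun_utc(latitude, longitude, date)
    return SunClock(date=date, sunrise=(sr + utc_offset) % HOURS,
                    sunset=(ss + utc_offset) % HOURS,
                    latitude=latitude, longitude=longitude)


def sun_adjust(clock_time: float, sun: SunClock) -> float:
    """Map a clock hour to sun time: sunrise -> 6.0, sunset -> 18.0.

    Daytime is stretched linearly onto [6, 18); night onto [18, 30) mod 24.
    The transform is a strictly increasing circular bijection; with a 12-hour
    day it is the identity.
    """
    t = float(clock_time) % HOURS
    sr, ss = sun.sunrise, sun.sunset
    day = ss - sr
    night = HOURS - day
    if sr <= t < ss:
        return (6.0 + 12.0 * (t - sr) / day) % HOURS
    since_sunset = (t - ss) % HOURS
    return (18.0 + 12.0 * since_sunset / night) % HOURS


def sun_adjust_records(timestamps, latitude, longitude,
                       utc_offset: float = 0.0) -> np.ndarray:
    """Sun-adjust a sequence of timestamps (one solar computation per date)."""
    ts = pd.DatetimeIndex(timestamps)
    clocks = {}
    out = np.empty(len(ts))
    for i, t in enumerate(ts):
        d = t.date()
        if d not in clocks:
            clocks[d] = solar_times(latitude, longitude, d, utc_offset)
        hour = t.hour + t.minute / 60.0 + t.second / 3600.0
        out[i] = sun_adjust(hour, clocks[d])
    return out


# ---------------------------------------------------------------------------
# circular kernel density


def _vm_kernel_matrix(theta_eval, theta_obs, kappa):
    # exp(kappa*(cos-1)) / i0e(kappa) is overflow-safe for large kappa
    c = np.cos(theta_eval[:, None] - theta_obs[None, :])
    return np.exp(kappa * (c - 1.0)) / (2.0 * np.pi * i0e(kappa))


def _loo_log_likelihood(theta, kappa):
    n = len(theta)
    k = _vm_kernel_matrix(theta, theta, kappa)
    np.fill_diagonal(k, 0.0)
    f = k.sum(axis=1) / (n - 1)
    return float(np.log(np.maximum(f, 1e-300)).sum())


def select_kappa(sun_times: np.ndarray,
                 grid: np.ndarray = KAPPA_GRID) -> float:
    """Leave-one-out maximum-likelihood kappa over a logarithmic grid."""
    theta = np.asarray(sun_times, float) * (2.0 * np.pi / HOURS)
    scores = [_loo_log_likelihood(theta, k) for k in grid]
    return float(grid[int(np.argmax(scores))])


def circular_kde(sample: ActivitySample, kappa: float | None = None,
                 m: int = DEFAULT_GRID) -> CircularDensity:
    """von Mises kernel density of activity on the sun-time circle.

    Needs at least 10 observations.  When ``kappa`` is omitted it is chosen
    by leave-one-out likelihood; a degenerate all-identical sample gets the
    top of the kappa grid with a warning.
    """
    times = np.asarray(sample.sun_times, dtype=float)
    if len(times) < 10:
        raise ValueError(f"need >= 10 observations, got {len(times)}")
    if kappa is None:
        if np.allclose(times, times[0]):
            import warnings
            warnings.warn("all observations identical; using maximum grid kappa")
            kappa = float(KAPPA_GRID[-1])
        else:
            kappa = select_kappa(times)
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    grid_hours = np.arange(m) * (HOURS / m)
    theta_grid = grid_hours * (2.0 * np.pi / HOURS)
    theta_obs = times * (2.0 * np.pi / HOURS)
    dens_angle = _vm_kernel_matrix(theta_grid, theta_obs, kappa).mean(axis=1)
    density = dens_angle * (2.0 * np.pi / HOURS)   # per sun-hour
    density /= density.mean() * HOURS              # exact unit mass on the grid
    return CircularDensity(times=grid_hours, density=density, kappa=float(kappa),
                           n=len(times), species=sample.species)


def activity_isopleth(d: CircularDensity, level: float = 0.95) -> ActivityIsopleth:
    """Highest-density sun-time region holding ``level`` of the activity mass."""
    if not (0.0 < level <= 1.0):
        raise ValueError("level must be in (0, 1]")
    step = d.grid_step
    order = np.argsort(-d.density, kind="stable")
    mass = np.cumsum(d.density[order]) * step
    k = int(np.searchsorted(mass, level * d.mass())) + 1
    k = min(k, len(order))
    sel = np.zeros(len(order), dtype=bool)
    sel[order[:k]] = True
    return ActivityIsopleth(level=level, selected=sel, grid_step=step,
                            species=d.species)


def activity_overlap(a: ActivityIsopleth, b: ActivityIsopleth) -> dict:
    """Percent overlap of two activity isopleths at the same level.

    Returns the symmetric intersection-over-union percentage under
    ``'percent'`` plus the two directed shares ``'a_in_b'`` / ``'b_in_a'``
    (intersection over each species' own active period).
    """
    if abs(a.level - b.level) > 1e-9:
        raise ValueError("isopleths must be at the same level")
    if len(a.selected) != len(b.selected):
        raise ValueError("isopleths must share the time grid")
    inter = float((a.selected & b.selected).sum())
    union = float((a.selected | b.selected).sum())
    out = {
        "percent": 100.0 * inter / union if union else 0.0,
        "a_in_b": 100.0 * inter / a.selected.sum() if a.selected.any() else 0.0,
        "b_in_a": 100.0 * inter / b.selected.sum() if b.selected.any() else 0.0,
    }
    return out


def overlap_matrix(isopleths: dict) -> pd.DataFrame:
    """Symmetric activity-overlap (%) matrix over species isopleths."""
    labels = list(isopleths)
    out = pd.DataFrame(np.full((len(labels),) * 2, 100.0), index=labels,
                       columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            v = activity_overlap(isopleths[a], isopleths[b])["percent"]
            out.loc[a, b] = out.loc[b, a] = v
    return out


# ---------------------------------------------------------------------------
# camera summary


def camera_summary(records: list, trap_days: float | None = None) -> pd.DataFrame:
    """Per-species record counts, percent of total, and capture success.

    ``trap_days`` (camera-days of effort) enables the records-per-100-trap-
    days column.  An empty record list returns an empty table.
    """
    if not records:
        cols = ["species", "n", "percent"]
        if trap_days:
            cols.append("per_100_trap_days")
        return pd.DataFrame(columns=cols)
    species = pd.Series([r.species for r in records])
    counts = species.value_counts()
    out = pd.DataFrame({"species": counts.index, "n": counts.to_numpy()})
    out["percent"] = 100.0 * out["n"] / out["n"].sum()
    if trap_days:
        out["per_100_trap_days"] = 100.0 * out["n"] / trap_days
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# model-style front end


class CircularActivity:
    """Circular activity model for one species' detection times."""

    def __init__(self, sample: ActivitySample, m: int = DEFAULT_GRID):
        self.sample = sample
        self.m = m

    @classmethod
    def from_records(cls, records: list, species: str, latitude: float,
                     longitude: float, utc_offset: float = 0.0,
                     **kw) -> "CircularActivity":
        ts = [r.datetime for r in records if r.species == species]
        sun = sun_adjust_records(ts, latitude, longitude, utc_offset)
        return cls(ActivitySample(species=species, sun_times=sun), **kw)

    def fit(self, kappa: float | None = None,
            levels: tuple = (0.95, 0.5)) -> "ActivityResult":
        dens = circular_kde(self.sample, kappa=kappa, m=self.m)
        iso = {lv: activity_isopleth(dens, lv) for lv in levels}
        return ActivityResult(model=self, density=dens, isopleths=iso)


@dataclass
class ActivityResult:
    """Fitted circular activity density with its isopleth active periods."""

    model: CircularActivity
    density: CircularDensity
    isopleths: dict

    @property
    def kappa(self) -> float:
        return self.density.kappa

    def summary(self) -> pd.DataFrame:
        rows = []
        for lv, iso in sorted(self.isopleths.items(), reverse=True):
            rows.append({
                "species": self.density.species,
                "level": lv,
                "active_hours": iso.total_duration,
                "intervals": "; ".join(f"{s:05.2f}-{e:05.2f}"
                                       for s, e in iso.intervals),
            })
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Circular (polar) activity plot in the style of diel-activity figures."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(subplot_kw={"projection": "polar"})
        theta = self.density.times * (2 * np.pi / HOURS)
        ax.plot(np.append(theta, theta[0]),
                np.append(self.density.density, self.density.density[0]))
        ax.set_theta_zero_location("N")
        ax.set_theta_direction(-1)
        ax.set_xticks(np.arange(0, 2 * np.pi, np.pi / 4))
        ax.set_xticklabels([f"{h:02d}:00" for h in range(0, 24, 3)])
        ax.set_title(self.density.species)
        return ax
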