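"""Space-use overlap indices between utilization distributions.

Two indices are provided:

* **PHR** — the probability of animal *j* being located inside animal *i*'s
  home range: the UD of *j* integrated over *i*'s isopleth region.
  Asymmetric by construction.
* **UDOI** — the utilization distribution overlap index:
  ``A_ij * sum over hr_i∩hr_j of ud_i * ud_j * cell_area`` where ``A_ij`` is
  the area of the home-range intersection.  Zero when the home ranges are
  disjoint, 1 for two identical uniform UDs, and possibly > 1 when two
  non-uniform UDs concentrate use in the same places.

Species-level matrices pool all locations of a species into a single UD;
the individual-level variant is also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .homerange import (HomeRange, UtilizationDistribution, estimate_ud,
                        isopleth, plug_in_bandwidth, ud_mass_in,
                        MIN_LOCATIONS, TooFewLocationsError)


def _same_grid(a: UtilizationDistribution, b) -> bool:
    return (a.grid.shape == (b.grid if hasattr(b, "grid") else b.mask).shape
            and a.origin == b.origin
            and np.isclose(a.cell_size,
                           b.cell_size, rtol=1e-12))


def resample_ud(ud: UtilizationDistribution, cell_size: float,
                extent: tuple) -> UtilizationDistribution:
    """Bilinearly resample a UD onto a new grid and renormalize to unit mass."""
    xmin, xmax, ymin, ymax = extent
    ncols = max(2, int(np.round((xmax - xmin) / cell_size)))
    nrows = max(2, int(np.round((ymax - ymin) / cell_size)))
    xs_old = ud.origin[0] + (np.arange(ud.grid.shape[1]) + 0.5) * ud.cell_size
    ys_old = ud.origin[1] + (np.arange(ud.grid.shape[0]) + 0.5) * ud.cell_size
    interp = RegularGridInterpolator((ys_old, xs_old), ud.grid,
                                     bounds_error=False, fill_value=0.0)
    xs = xmin + (np.arange(ncols) + 0.5) * cell_size
    ys = ymin + (np.arange(nrows) + 0.5) * cell_size
    X, Y = np.meshgrid(xs, ys)
    grid = interp(np.column_stack([Y.ravel(), X.ravel()])).reshape(nrows, ncols)
    grid = np.clip(grid, 0.0, None)
    mass = grid.sum() * cell_size ** 2
    if mass <= 0:
        raise ValueError("resampled UD has zero mass inside the target extent")
    grid /= mass
    return UtilizationDistribution(grid=grid, cell_size=float(cell_size),
                                   origin=(xmin, ymin), bandwidth=ud.bandwidth,
                                   n_points=ud.n_points, animal_id=ud.animal_id)


def align_uds(ud_i: UtilizationDistribution, ud_j: UtilizationDistribution):
    """Resample two UDs onto a common grid (union extent, finer cell size)."""
    cell = min(ud_i.cell_size, ud_j.cell_size)

    def _ext(ud):
        return (ud.origin[0], ud.origin[0] + ud.grid.shape[1] * ud.cell_size,
                ud.origin[1], ud.origin[1] + ud.grid.shape[0] * ud.cell_size)

    e1, e2 = _ext(ud_i), _ext(ud_j)
    extent = (min(e1[0], e2[0]), max(e1[1], e2[1]),
              min(e1[2], e2[2]), max(e1[3], e2[3]))
    return resample_ud(ud_i, cell, extent), resample_ud(ud_j, cell, extent)


def phr(ud_j: UtilizationDistribution, hr_i: HomeRange,
        resample: bool = False) -> float:
    """Probability of animal *j* being inside animal *i*'s home range.

    Both inputs must share a grid; with ``resample=True`` the UD is
    resampled onto the home range's grid first.
    """
    if not _same_grid(ud_j, hr_i):
        if not resample:
            raise ValueError("UD and home range on different grids; "
                             "pass resample=True or align first")
        extent = (hr_i.origin[0],
                  hr_i.origin[0] + hr_i.mask.shape[1] * hr_i.cell_size,
                  hr_i.origin[1],
                  hr_i.origin[1] + hr_i.mask.shape[0] * hr_i.cell_size)
        ud_j = resample_ud(ud_j, hr_i.cell_size, extent)
    p = ud_mass_in(ud_j, hr_i)
    return float(min(max(p, 0.0), 1.0))


def udoi(ud_i: UtilizationDistribution, ud_j: UtilizationDistribution,
         hr_i: HomeRange, hr_j: HomeRange) -> float:
    """Utilization distribution overlap index over the home-range intersection."""
    for ud, hr in ((ud_i, hr_i), (ud_j, hr_j)):
        if not _same_grid(ud, hr):
            raise ValueError("each UD must share its home range's grid")
    if not _same_grid(ud_i, hr_j):
        raise ValueError("the two animals must be on a common grid; "
                         "use align_uds first")
    inter = hr_i.mask & hr_j.mask
    if not inter.any():
        return 0.0
    cell_area = ud_i.cell_area
    a_ij = inter.sum() * cell_area
    integral = float((ud_i.grid[inter] * ud_j.grid[inter]).sum() * cell_area)
    return float(a_ij * integral)


@dataclass
class OverlapMatrix:
    """Pairwise PHR (%) and UDOI between animals or species."""

    labels: list
    phr: pd.DataFrame       # row i, col j: P(j in HR of i), percent
    udoi: pd.DataFrame
    level: float

    def to_table(self) -> pd.DataFrame:
        """Printed-style table: 'PHR (UDOI)' strings, rows = HR owner."""
        out = pd.DataFrame(index=self.labels, columns=self.labels, dtype=object)
        for i in self.labels:
            for j in self.labels:
                out.loc[i, j] = (f"{self.phr.loc[i, j]:.1f} "
                                 f"({self.udoi.loc[i, j]:.2f})")
        return out


def overlap_matrix(uds: dict, level: float = 0.95) -> OverlapMatrix:
    """Pairwise PHR/UDOI for UDs already living on one common grid."""
    labels = list(uds)
    first = uds[labels[0]]
    for ud in uds.values():
        if not _same_grid(first, ud):
            raise ValueError("all UDs must share one grid; use align_uds "
                             "or estimate on a shared extent")
    ranges = {k: isopleth(ud, level) for k, ud in uds.items()}
    phr_m = pd.DataFrame(index=labels, columns=labels, dtype=float)
    udoi_m = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for i in labels:
        for j in labels:
            phr_m.loc[i, j] = 100.0 * phr(uds[j], ranges[i])
            udoi_m.loc[i, j] = udoi(uds[i], uds[j], ranges[i], ranges[j])
    return OverlapMatrix(labels=labels, phr=phr_m, udoi=udoi_m, level=level)


def species_overlap_matrix(locsets: list, level: float = 0.95,
                           cell_size: float = 50.0,
                           min_locations: int = MIN_LOCATIONS) -> OverlapMatrix:
    """Species-by-species PHR/UDOI from pooled per-species locations.

    All locations of a species are pooled into a single UD; all species UDs
    are estimated on one shared grid so the overlap integrals are exact over
    the discrete densities.  Species with fewer than ``min_locations`` pooled
    locations are skipped with a warning.
    """
    import warnings

    pooled: dict = {}
    for ls in locsets:
        pooled.setdefault(ls.species, []).append(ls.xy)
    pooled = {sp: np.vstack(chunks) for sp, chunks in pooled.items()}
    drop = [sp for sp, xy in pooled.items() if len(xy) < min_locations]
    for sp in drop:
        warnings.warn(f"species {sp!r}: {len(pooled[sp])} pooled locations "
                      f"< {min_locations}; skipped")
        del pooled[sp]
    if not pooled:
        raise TooFewLocationsError("no species passes the location rule")

    bws = {sp: plug_in_bandwidth(xy) for sp, xy in pooled.items()}
    pad = 3.0 * max(max(bw) for bw in bws.values())
    allxy = np.vstack(list(pooled.values()))
    extent = (allxy[:, 0].min() - pad, allxy[:, 0].max() + pad,
              allxy[:, 1].min() - pad, allxy[:, 1].max() + pad)
    uds = {sp: estimate_ud(xy, bandwidth=bws[sp], cell_size=cell_size,
                           extent=extent, min_locations=min_locations,
                           animal_id=sp)
           for sp, xy in pooled.items()}
    return overlap_matrix(uds, level=level)


def individual_overlap_matrix(locsets: list, level: float = 0.95,
                              cell_size: float = 50.0,
                              min_locations: int = MIN_LOCATIONS,
                              allow_few: bool = False) -> OverlapMatrix:
    """Animal-by-animal PHR/UDOI on one shared grid."""
    usable = [ls for ls in locsets
              if len(ls) >= min_locations or allow_few]
    if not usable:
        raise TooFewLocationsError("no individual passes the location rule")
    bws = {ls.animal_id: plug_in_bandwidth(ls) for ls in usable}
    pad = 3.0 * max(max(bw) for bw in bws.values())
    allxy = np.vstack([ls.xy for ls in usable])
    extent = (allxy[:, 0].min() - pad, allxy[:, 0].max() + pad,
              allxy[:, 1].min() - pad, allxy[:, 1].max() + pad)
    uds = {ls.animal_id: estimate_ud(ls, bandwidth=bws[ls.animal_id],
                                     cell_size=cell_size, extent=extent,
                                     min_locations=min_locations,
                                     allow_few=allow_few)
           for ls in usable}
    return overlap_matrix(uds, level=level)
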