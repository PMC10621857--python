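"""Terrain reconstruction from accumulated GPS fixes.

Focal-follow tracklogs record elevation once per minute.  Because observers
cross the same ground on many days, each ~10 m patch of forest accumulates
several elevation readings; the median of those readings is a robust local
elevation estimate.  This module bins fixes onto a square lattice anchored at
the arithmetic center of all fixes, takes per-cell medians, and derives two
landscape features used downstream:

* *peripheral hills* — connected clusters of supra-threshold cells (default
  230 m, the 99th percentile of the reconstructed range), single-linkage
  merged within 50 m so that cells along one ridge count as one hill;
* *low locations* — rest-stop sites at most 180 m a.s.l., deduplicated by
  merging stops within 50 m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

FIX_COLUMNS = ["time", "x", "y", "elev", "group", "follow_id"]

#: plausibility cap on consecutive-fix displacement (meters per minute)
MAX_SPEED = 1000.0


class FixValidationError(ValueError):
    pass


def validate_fixes(fixes: pd.DataFrame, max_speed: float = MAX_SPEED) -> pd.DataFrame:
    """Validate a fix table (one row per minute of focal follow).

    Checks required columns, finite coordinates/elevation, strict time
    ordering within each follow, and a per-minute displacement cap.
    Returns the input (unchanged) for chaining.
    """
    missing = [c for c in FIX_COLUMNS if c not in fixes.columns]
    if missing:
        raise FixValidationError(f"fix table missing columns: {missing}")
    bad = ~np.isfinite(fixes[["x", "y", "elev"]].to_numpy(dtype=float)).all(axis=1)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise FixValidationError(f"non-finite coordinate/elevation at row {idx}")
    for fid, sub in fixes.groupby("follow_id", sort=False):
        t = pd.to_datetime(sub["time"]).to_numpy()
        if len(t) > 1:
            dt = np.diff(t).astype("timedelta64[s]").astype(float)
            if (dt <= 0).any():
                raise FixValidationError(f"follow {fid!r}: fixes not strictly time-ordered")
            dx = np.diff(sub["x"].to_numpy(float))
            dy = np.diff(sub["y"].to_numpy(float))
            speed = np.hypot(dx, dy) / (dt / 60.0)
            if (speed > max_speed).any():
                i = int(np.flatnonzero(speed > max_speed)[0])
                raise FixValidationError(
                    f"follow {fid!r}: implausible displacement "
                    f"{speed[i]:.0f} m/min at step {i}"
                )
    return fixes


@dataclass(frozen=True)
class GridSpec:
    """Square binning lattice: centers at (ref_x + i*bin_size, ref_y + j*bin_size)."""

    bin_size: float = 10.0
    ref_x: float = 0.0
    ref_y: float = 0.0

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    def index_of(self, x, y):
        """Nearest-center bin index; half-way ties go to the lower index."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        b = self.bin_size
        # ceil(t - 0.5) rounds to nearest with exact .5 ties to the lower integer
        ix = np.ceil((x - self.ref_x) / b - 0.5).astype(int)
        iy = np.ceil((y - self.ref_y) / b - 0.5).astype(int)
        return ix, iy

    def center_of(self, ix, iy):
        return (self.ref_x + np.asarray(ix) * self.bin_size,
                self.ref_y + np.asarray(iy) * self.bin_size)


@dataclass
class ElevationGrid:
    """Binned median-elevation raster.

    ``cells`` has index (ix, iy) and columns ``median_elev``, ``n``,
    ``x_center``, ``y_center``.
    """

    spec: GridSpec
    cells: pd.DataFrame

    def lookup(self, x, y, on_missing: str = "error"):
        """Median elevation of the cell containing each (x, y).

        ``on_missing``: 'error' raises for points in cells the grid never
        saw; 'nearest' falls back to the nearest populated cell center.
        """
        ix, iy = self.spec.index_of(x, y)
        key = pd.MultiIndex.from_arrays([np.atleast_1d(ix), np.atleast_1d(iy)])
        out = self.cells["median_elev"].reindex(key).to_numpy(dtype=float)
        miss = ~np.isfinite(out)
        if miss.any():
            if on_missing == "error":
                raise KeyError(
                    f"{int(miss.sum())} point(s) fall in cells absent from the grid"
                )
            if on_missing != "nearest":
                raise ValueError("on_missing must be 'error' or 'nearest'")
            tree = cKDTree(self.cells[["x_center", "y_center"]].to_numpy(float))
            pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]).astype(float)
            _, j = tree.query(pts[miss])
            out[miss] = self.cells["median_elev"].to_numpy(float)[j]
        return out if out.size > 1 else float(out[0])

    def to_frame(self) -> pd.DataFrame:
        df = self.cells.reset_index()
        df.columns = ["bin_ix", "bin_iy", "median_elev", "n", "x_center", "y_center"]
        return df[["bin_ix", "bin_iy", "x_center", "y_center", "median_elev", "n"]]


def build_grid(fixes: pd.DataFrame, spec: GridSpec | None = None,
               bin_size: float = 10.0) -> ElevationGrid:
    """Bin fixes to the reference-anchored lattice and take per-cell medians.

    The lattice reference defaults to the arithmetic center (mean x, mean y)
    of the input fixes; each fix joins the bin whose center is nearest.
    """
    if len(fixes) == 0:
        raise ValueError("cannot build a grid from zero fixes")
    xs = fixes["x"].to_numpy(dtype=float)
    ys = fixes["y"].to_numpy(dtype=float)
    es = fixes["elev"].to_numpy(dtype=float)
    bad = ~(np.isfinite(xs) & np.isfinite(ys) & np.isfinite(es))
    if bad.any():
        raise ValueError(f"non-finite fix at row {int(np.flatnonzero(bad)[0])}")
    if spec is None:
        spec = GridSpec(bin_size=bin_size, ref_x=float(xs.mean()), ref_y=float(ys.mean()))
    ix, iy = spec.index_of(xs, ys)
    df = pd.DataFrame({"ix": ix, "iy": iy, "elev": es})
    cells = df.groupby(["ix", "iy"]).agg(median_elev=("elev", "median"),
                                         n=("elev", "size"))
    cx, cy = spec.center_of(cells.index.get_level_values(0),
                            cells.index.get_level_values(1))
    cells["x_center"] = cx
    cells["y_center"] = cy
    return ElevationGrid(spec=spec, cells=cells)


def annotate_elevation(fixes: pd.DataFrame, grid: ElevationGrid,
                       on_missing: str = "error") -> pd.DataFrame:
    """Attach the cell-median ('smoothed') elevation to each fix.

    Raw elevation is retained in ``elev``; the reconstructed value is added
    as ``smoothed_elev``.
    """
    out = fixes.copy()
    vals = grid.lookup(out["x"].to_numpy(float), out["y"].to_numpy(float),
                       on_missing=on_missing)
    out["smoothed_elev"] = np.atleast_1d(vals)
    return out


def elevation_percentile(grid: ElevationGrid, q: float) -> float:
    """q-th percentile of cell median elevations (linear interpolation).

    This is the percentile over *bins*, not over raw fixes, so heavily
    re-visited ground is not over-weighted.
    """
    if not 0 <= q <= 100:
        raise ValueError("q must be in [0, 100]")
    if len(grid.cells) == 0:
        raise ValueError("empty grid")
    return float(np.percentile(grid.cells["median_elev"].to_numpy(float), q,
                               method="linear"))


@dataclass
class Hill:
    hill_id: int
    member_cells: frozenset
    summit_xy: tuple
    summit_elev: float


@dataclass
class HillSet:
    hills: list = field(default_factory=list)

    def __len__(self):
        return len(self.hills)

    def __iter__(self):
        return iter(self.hills)

    def summits(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"hill_id": h.hill_id, "x": h.summit_xy[0], "y": h.summit_xy[1],
              "elev": h.summit_elev, "n_cells": len(h.member_cells)}
             for h in self.hills]
        )


def _single_linkage_components(xy: np.ndarray, link_dist: float) -> np.ndarray:
    """Connected-component labels under the <= link_dist pairing relation."""
    n = len(xy)
    if n == 0:
        return np.array([], dtype=int)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(link_dist, output_type="ndarray")
    if len(pairs):
        g = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        g = coo_matrix((n, n))
    _, labels = connected_components(g, directed=False)
    return labels


def detect_hills(grid: ElevationGrid, elev_threshold: float = 230.0,
                 link_dist: float = 50.0,
                 mask: pd.Series | np.ndarray | None = None) -> HillSet:
    """Cluster supra-threshold cells into hills by single linkage.

    Cells at or above ``elev_threshold`` whose centers lie within
    ``link_dist`` of one another (transitively) form one hill; the summit is
    the highest member cell, ties broken by smallest y then smallest x.
    ``mask`` (boolean, aligned with ``grid.cells``) restricts the candidate
    cells — callers use it to limit hills to the inter-group overlap band.
    """
    cells = grid.cells
    sel = cells["median_elev"].to_numpy(float) >= elev_threshold
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    sub = cells[sel]
    xy = sub[["x_center", "y_center"]].to_numpy(float)
    labels = _single_linkage_components(xy, link_dist)
    hills = []
    for lab in np.unique(labels):
        members = sub[labels == lab]
        order = members.sort_values(
            ["median_elev", "y_center", "x_center"],
            ascending=[False, True, True],
        )
        top = order.iloc[0]
        hills.append(Hill(
            hill_id=len(hills),
            member_cells=frozenset(members.index.tolist()),
            summit_xy=(float(top["x_center"]), float(top["y_center"])),
            summit_elev=float(top["median_elev"]),
        ))
    hills.sort(key=lambda h: (-h.summit_elev, h.summit_xy[1], h.summit_xy[0]))
    for i, h in enumerate(hills):
        h.hill_id = i
    return HillSet(hills)


@dataclass
class LowLocation:
    loc_id: int
    xy: tuple
    elev: float
    n_stops: int


@dataclass
class LowLocationSet:
    locations: list = field(default_factory=list)

    def __len__(self):
        return len(self.locations)

    def __iter__(self):
        return iter(self.locations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"loc_id": l.loc_id, "x": l.xy[0], "y": l.xy[1], "elev": l.elev,
              "n_stops": l.n_stops} for l in self.locations]
        )


def detect_low_locations(rest_stops: pd.DataFrame, grid: ElevationGrid,
                         max_elev: float = 180.0,
                         merge_dist: float = 50.0) -> LowLocationSet:
    """Low-elevation rest sites from stop events inside the overlap band.

    ``rest_stops`` needs columns ``x``, ``y`` (stop location).  Smoothed
    elevation is looked up from the grid; stops above ``max_elev`` are
    dropped, and the rest are merged by single linkage within
    ``merge_dist``.  A merged location sits at the mean of its stops.
    """
    if len(rest_stops) == 0:
        return LowLocationSet([])
    xs = rest_stops["x"].to_numpy(float)
    ys = rest_stops["y"].to_numpy(float)
    elev = np.atleast_1d(grid.lookup(xs, ys, on_missing="nearest"))
    keep = elev <= max_elev
    xy = np.column_stack([xs[keep], ys[keep]])
    ev = elev[keep]
    labels = _single_linkage_components(xy, merge_dist)
    locs = []
    for lab in np.unique(labels):
        m = labels == lab
        locs.append(LowLocation(
            loc_id=len(locs),
            xy=(float(xy[m, 0].mean()), float(xy[m, 1].mean())),
            elev=float(np.median(ev[m])),
            n_stops=int(m.sum()),
        ))
    return LowLocationSet(locs)
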