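"""Sampling-point allocation within a polygon frame or along a route network.

Two frames (the sea polygon, a route network) crossed with two strategies
(random, regular).  Polygon-regular uses a square lattice with spacing
sqrt(sea_area / n) and a uniformly random origin, clipped to the sea mask,
so the realized count can differ slightly from n.  Network sampling
concatenates the routes into a single chainage in listed order; regular
spacing is total_length / n with a uniformly random offset, which allocates
points across routes proportionally to their lengths.  A per-route switch
draws the same design independently on each route instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import interpolate_chainage, polyline_lengths_km
from .grid import GridSpec, RouteNetwork, TruthSSDM


@dataclass(frozen=True)
class SamplingDesign:
    frame: str          # 'polygon' | 'network'
    strategy: str       # 'random' | 'regular'
    n_points: int
    seed: int

    def __post_init__(self):
        if self.frame not in ("polygon", "network"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.strategy not in ("random", "regular"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


@dataclass(frozen=True)
class PointSet:
    points: np.ndarray  # (n, 2) lon/lat
    design: SamplingDesign
    chainage: np.ndarray | None = None
    route_names: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.points)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=["lon", "lat"])
        if self.chainage is not None:
            df["chainage_km"] = self.chainage
        if self.route_names is not None:
            df["route_name"] = self.route_names
        return df

    def to_geojson(self, path=None) -> dict:
        """MultiPoint feature with the design echoed in its properties."""
        import json
        from pathlib import Path

        obj = {
            "type": "Feature",
            "properties": {"frame": self.design.frame,
                           "strategy": self.design.strategy,
                           "n_points": self.design.n_points,
                           "seed": self.design.seed,
                           "n_realized": self.n},
            "geometry": {"type": "MultiPoint",
                         "coordinates": [[float(x), float(y)]
                                         for x, y in self.points]},
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj))
        return obj


def sample_polygon(mask: GridSpec, strategy: str, n: int, seed: int) -> PointSet:
    """Allocate points over the sea polygon.

    random: rejection sampling, uniform over the sea area.  regular: square
    lattice with spacing sqrt(sea_area / n) (degree units) and a uniformly
    random origin, clipped to sea; the realized count may differ from n.
    """
    design = SamplingDesign("polygon", strategy, n, seed)
    rng = np.random.default_rng(seed)
    lon0, lat0 = mask.origin_lon, mask.origin_lat
    lon1, lat1 = mask.lon_max, mask.lat_max

    if strategy == "random":
        pts = []
        got = 0
        for _ in range(1000):
            take = max(4 * (n - got), 32)
            lon = rng.uniform(lon0, lon1, take)
            lat = rng.uniform(lat0, lat1, take)
            col = ((lon - lon0) / mask.cell_size).astype(int)
            row = ((lat - lat0) / mask.cell_size).astype(int)
            col = np.clip(col, 0, mask.n_cols - 1)
            row = np.clip(row, 0, mask.n_rows - 1)
            keep = mask.sea_mask[row, col]
            pts.append(np.column_stack([lon, lat])[keep])
            got = sum(len(p) for p in pts)
            if got >= n:
                break
        pts = np.vstack(pts)
        if len(pts) < n:
            raise RuntimeError("rejection sampling failed to reach n points")
        return PointSet(pts[:n], design)

    # regular lattice
    sea_area = mask.n_sea * mask.cell_size ** 2
    spacing = float(np.sqrt(sea_area / n))
    ox = lon0 + rng.uniform(0, spacing)
    oy = lat0 + rng.uniform(0, spacing)
    xs = np.arange(ox, lon1, spacing)
    ys = np.arange(oy, lat1, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    col = ((pts[:, 0] - lon0) / mask.cell_size).astype(int)
    row = ((pts[:, 1] - lat0) / mask.cell_size).astype(int)
    inside = (row < mask.n_rows) & (col < mask.n_cols)
    keep = np.zeros(len(pts), dtype=bool)
    keep[inside] = mask.sea_mask[row[inside], col[inside]]
    return PointSet(pts[keep], design)


def sample_network(net: RouteNetwork, strategy: str, n: int, seed: int,
                   per_route: bool = False) -> PointSet:
    """Allocate points along a route network by chainage.

    random: n independent U(0, L) chainage draws over the concatenated
    network of total length L.  regular: spacing s = L/n with a uniform
    random offset u in [0, s), points at u + i*s.  ``per_route`` applies the
    design independently to every route (n points per route).
    """
    design = SamplingDesign("network", strategy, n, seed)
    rng = np.random.default_rng(seed)
    if per_route:
        parts = [_sample_single(verts, name, strategy, n,
                                np.random.default_rng(rng.integers(0, 2**31 - 1)))
                 for name, verts in net.routes]
        pts = np.vstack([p for p, _, _ in parts])
        ch = np.concatenate([c for _, c, _ in parts])
        names = np.concatenate([nm for _, _, nm in parts])
        return PointSet(pts, design, ch, names)

    lengths = net.lengths_km
    L = float(lengths.sum())
    if L <= 0:
        raise ValueError("zero-length network")
    if strategy == "random":
        s = np.sort(rng.uniform(0.0, L, n))
    else:
        step = L / n
        u = rng.uniform(0.0, step)
        s = u + step * np.arange(n)
    # map global chainage to (route, local chainage)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    ridx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(lengths) - 1)
    pts = np.empty((n, 2))
    names = np.empty(n, dtype=object)
    for r in np.unique(ridx):
        sel = ridx == r
        local = s[sel] - cum[r]
        pts[sel] = interpolate_chainage(net.routes[r][1], local)
        names[sel] = net.routes[r][0]
    return PointSet(pts, design, s, names)


def _sample_single(verts, name, strategy, n, rng):
    seg = polyline_lengths_km(verts)
    L = float(seg.sum())
    if strategy == "random":
        s = np.sort(rng.uniform(0.0, L, n))
    else:
        step = L / n
        s = rng.uniform(0.0, step) + step * np.arange(n)
    return interpolate_chainage(verts, s), s, np.full(n, name, dtype=object)


def extract_occurrences(points: PointSet, truth: TruthSSDM) -> pd.DataFrame:
    """Perfect-detection extraction from the truth community.

    For every point and every species occupying the point's cell, one record
    is emitted at the point's raw coordinates (points are snapped to cells
    only for the lookup).  Co-located points yield repeated records — the
    rebuild pipeline deliberately does not thin them.
    """
    grid = truth.grid
    row, col = grid.cell_of(points.points[:, 0], points.points[:, 1])
    if not grid.sea_mask[row, col].all():
        raise ValueError("sampling point maps to a land cell")
    occ = truth.occupancy[:, row, col]  # (n_species, n_points)
    s_idx, p_idx = np.nonzero(occ)
    names = np.array(truth.names, dtype=object)
    return pd.DataFrame({
        "species": names[s_idx],
        "lon": points.points[p_idx, 0],
        "lat": points.points[p_idx, 1],
        "year": pd.array([pd.NA] * len(s_idx)),
        "month": pd.array([pd.NA] * len(s_idx)),
    })


def detection_filter(occ: pd.DataFrame, min_occ: int = 20) -> pd.DataFrame:
    """Per-species record counts with a strict > min_occ retention flag."""
    if min_occ < 0:
        raise ValueError("min_occ must be >= 0")
    if len(occ) == 0:
        return pd.DataFrame(columns=["species", "count", "kept"])
    counts = occ.groupby("species", sort=True).size().rename("count").reset_index()
    counts["kept"] = counts["count"] > min_occ
    return counts


def retained_records(occ: pd.DataFrame, min_occ: int = 20) -> pd.DataFrame:
    """Subset of records belonging to species retained by detection_filter."""
    counts = detection_filter(occ, min_occ)
    keep = set(counts.loc[counts["kept"], "species"])
    return occ[occ["species"].isin(keep)].reset_index(drop=True)
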