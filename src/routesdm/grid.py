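"""Core spatial containers: the raster world, virtual communities, route networks.

The grid is a plain lon/lat raster.  Cells are indexed 0-based as (row, col)
with row 0 at the southern edge; a point maps to the cell containing it under
half-open bounds [edge, edge + cell_size).  Land cells carry NaN in
environmental layers and False in occupancy rasters.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import polyline_length_km


@dataclass(frozen=True)
class GridSpec:
    """Raster geometry plus the sea mask.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; must be positive.
    origin_lon, origin_lat : float
        Lon/lat of the outer corner of cell (0, 0) (south-west corner).
    cell_size : float
        Cell edge length in degrees (square cells).
    sea_mask : ndarray of bool, shape (n_rows, n_cols)
        True where the cell is sea (analysis domain).
    """

    n_rows: int
    n_cols: int
    origin_lon: float
    origin_lat: float
    cell_size: float
    sea_mask: np.ndarray

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        mask = np.asarray(self.sea_mask, dtype=bool)
        if mask.shape != (self.n_rows, self.n_cols):
            raise ValueError("sea_mask shape does not match grid dimensions")
        if not mask.any():
            raise ValueError("sea_mask must contain at least one sea cell")
        object.__setattr__(self, "sea_mask", mask)

    # -- coordinate transforms -------------------------------------------------

    @property
    def n_sea(self) -> int:
        return int(self.sea_mask.sum())

    @property
    def lon_max(self) -> float:
        return self.origin_lon + self.n_cols * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.origin_lat + self.n_rows * self.cell_size

    def cell_of(self, lon, lat):
        """Map lon/lat to (row, col) under half-open cell bounds.

        Vectorized; raises ValueError if any point falls outside the grid.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((lat - self.origin_lat) / self.cell_size).astype(int)
        if np.any((col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)):
            raise ValueError("point outside grid extent")
        return row, col

    def cell_center(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat + (row + 0.5) * self.cell_size
        return lon, lat

    def sea_indices(self):
        """(rows, cols) arrays of all sea cells, row-major order."""
        return np.nonzero(self.sea_mask)

    def is_sea(self, lon, lat):
        row, col = self.cell_of(lon, lat)
        return self.sea_mask[row, col]

    def sea_cell_centers(self):
        rows, cols = self.sea_indices()
        return self.cell_center(rows, cols)


@dataclass(frozen=True)
class EnvStack:
    """Named environmental layers on a shared grid, normalized to [0, 1] at sea."""

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        sea = self.grid.sea_mask
        clean = {}
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != sea.shape:
                raise ValueError(f"layer {name!r} shape mismatch")
            vals = arr[sea]
            if np.any(~np.isfinite(vals)):
                raise ValueError(f"layer {name!r} has non-finite sea values")
            if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
                raise ValueError(f"layer {name!r} not normalized to [0, 1] on sea cells")
            clean[name] = arr
        object.__setattr__(self, "layers", clean)

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def sea_matrix(self) -> np.ndarray:
        """(n_sea, n_layers) matrix of layer values over sea cells (row-major)."""
        sea = self.grid.sea_mask
        return np.column_stack([self.layers[k][sea] for k in self.layers])

    def to_csv_dir(self, directory):
        """Write one CSV grid per layer (NaN on land) plus a grid metadata JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        g = self.grid
        meta = {
            "n_rows": g.n_rows, "n_cols": g.n_cols,
            "origin_lon": g.origin_lon, "origin_lat": g.origin_lat,
            "cell_size": g.cell_size, "layers": self.layer_names,
        }
        (directory / "grid.json").write_text(json.dumps(meta, indent=1))
        np.savetxt(directory / "sea_mask.csv", g.sea_mask.astype(int), fmt="%d", delimiter=",")
        for name, arr in self.layers.items():
            out = np.where(g.sea_mask, arr, np.nan)
            np.savetxt(directory / f"layer_{name}.csv", out, fmt="%.8g", delimiter=",")

    @classmethod
    def from_csv_dir(cls, directory) -> "EnvStack":
        directory = Path(directory)
        meta = json.loads((directory / "grid.json").read_text())
        mask = np.loadtxt(directory / "sea_mask.csv", dtype=int, delimiter=",").astype(bool)
        grid = GridSpec(meta["n_rows"], meta["n_cols"], meta["origin_lon"],
                        meta["origin_lat"], meta["cell_size"], mask)
        layers = {}
        for name in meta["layers"]:
            arr = np.loadtxt(directory / f"layer_{name}.csv", delimiter=",")
            layers[name] = np.where(mask, arr, np.nan)
        return cls(grid, layers)


@dataclass(frozen=True)
class TruthSSDM:
    """The 'perfect knowledge' community: per-species binary occupancy rasters.

    ``occupancy`` is (n_species, n_rows, n_cols) boolean, False on land.
    ``species`` pairs each name with a class label (e.g. teleost /
    elasmobranch / mammal).  ``response_params`` optionally retains the
    generating response coefficients for parameter-recovery tests.
    """

    grid: GridSpec
    species: list[tuple[str, str]]
    occupancy: np.ndarray
    response_params: dict | None = None

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != (len(self.species), self.grid.n_rows, self.grid.n_cols):
            raise ValueError("occupancy shape mismatch")
        if occ[:, ~self.grid.sea_mask].any():
            raise ValueError("occupancy asserted on land cells")
        object.__setattr__(self, "occupancy", occ)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.species]

    @property
    def labels(self) -> list[str]:
        return [c for _, c in self.species]

    @property
    def richness(self) -> np.ndarray:
        """Integer species richness per cell (0 on land)."""
        return self.occupancy.sum(axis=0).astype(int)

    def prevalence(self) -> np.ndarray:
        """Fraction of sea cells occupied, per species."""
        sea = self.grid.sea_mask
        return self.occupancy[:, sea].mean(axis=1)

    def species_index(self, name: str) -> int:
        return self.names.index(name)

    def subset(self, keep: Sequence[int]) -> "TruthSSDM":
        keep = list(keep)
        return TruthSSDM(self.grid, [self.species[i] for i in keep],
                         self.occupancy[keep])

    def to_csv_dir(self, directory):
        """One CSV occupancy grid per species plus a species table."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "species.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "class"])
            w.writerows(self.species)
        for i, (name, _) in enumerate(self.species):
            np.savetxt(directory / f"occ_{name}.csv",
                       self.occupancy[i].astype(int), fmt="%d", delimiter=",")

    @classmethod
    def from_csv_dir(cls, directory, grid: GridSpec) -> "TruthSSDM":
        directory = Path(directory)
        species = []
        with open(directory / "species.csv", newline="") as fh:
            for row in list(csv.reader(fh))[1:]:
                species.append((row[0], row[1]))
        occ = np.stack([
            np.loadtxt(directory / f"occ_{name}.csv", dtype=int, delimiter=",")
            for name, _ in species
        ]).astype(bool)
        return cls(grid, species, occ & grid.sea_mask[None])


@dataclass(frozen=True)
class RouteNetwork:
    """Named port-to-port polylines used as a constrained sampling frame."""

    routes: list[tuple[str, np.ndarray]]

    def __post_init__(self):
        clean = []
        for name, verts in self.routes:
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[0] < 2 or verts.shape[1] != 2:
                raise ValueError(f"route {name!r} must have >= 2 lon/lat vertices")
            clean.append((str(name), verts))
        object.__setattr__(self, "routes", clean)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.routes]

    @property
    def n_routes(self) -> int:
        return len(self.routes)

    @property
    def lengths_km(self) -> np.ndarray:
        return np.array([polyline_length_km(v) for _, v in self.routes])

    @property
    def total_length_km(self) -> float:
        return float(self.lengths_km.sum())

    def subset(self, names: Iterable[str]) -> "RouteNetwork":
        wanted = list(names)
        byname = dict(self.routes)
        missing = [n for n in wanted if n not in byname]
        if missing:
            raise KeyError(f"unknown routes: {missing}")
        return RouteNetwork([(n, byname[n]) for n in wanted])

    def to_geojson(self, path=None) -> dict:
        """GeoJSON FeatureCollection of LineStrings with a 'name' property."""
        features = [
            {
                "type": "Feature",
                "properties": {"name": name, "length_km": float(polyline_length_km(v))},
                "geometry": {"type": "LineString",
                             "coordinates": [[float(x), float(y)] for x, y in v]},
            }
            for name, v in self.routes
        ]
        obj = {"type": "FeatureCollection", "features": features}
        if path is not None:
            Path(path).write_text(json.dumps(obj))
        return obj

    @classmethod
    def from_geojson(cls, source) -> "RouteNetwork":
        if isinstance(source, (str, Path)):
            obj = json.loads(Path(source).read_text())
        else:
            obj = source
        routes = []
        for feat in obj["features"]:
            geom = feat["geometry"]
            if geom["type"] != "LineString":
                raise ValueError("route features must be LineStrings")
            name = feat.get("properties", {}).get("name", f"route_{len(routes)}")
            routes.append((name, np.asarray(geom["coordinates"], dtype=float)))
        return cls(routes)
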