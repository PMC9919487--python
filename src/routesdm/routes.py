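"""Route-level community composition, ordination and subnetwork construction.

Each route's species composition is summarized by the number of grid cells
it traverses in which each species occurs (a cell-count abundance).  Rows
are Hellinger-transformed to damp the inflated abundances of longer routes,
turned into a Bray-Curtis dissimilarity matrix, and ordinated with
nonmetric multidimensional scaling.  Subnetworks are built from the
ordination structure: the largest compositional cluster (a deliberately
biased frame), one route per cluster (a community-representative frame), a
greedy set cover of the environmental-variability bins (an
environment-covering frame), or k routes at random.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import LineString, box
from sklearn.manifold import smacof

from .bias import EnvVariabilityIndex
from .errors import GenerationError
from .grid import GridSpec, RouteNetwork, TruthSSDM

logger = logging.getLogger(__name__)


def traversed_cells(grid: GridSpec, vertices: np.ndarray) -> np.ndarray:
    """Distinct (row, col) cells traversed by a polyline.

    Exact line-rectangle intersection (shapely); a polyline touching only a
    cell corner (a zero-length intersection) does not count as traversal.
    Returns cells in row-major order, land cells included.
    """
    line = LineString(np.asarray(vertices, dtype=float))
    lon0, lat0, cs = grid.origin_lon, grid.origin_lat, grid.cell_size
    minx, miny, maxx, maxy = line.bounds
    c0 = max(0, int(np.floor((minx - lon0) / cs)) - 1)
    c1 = min(grid.n_cols - 1, int(np.floor((maxx - lon0) / cs)) + 1)
    r0 = max(0, int(np.floor((miny - lat0) / cs)) - 1)
    r1 = min(grid.n_rows - 1, int(np.floor((maxy - lat0) / cs)) + 1)
    hits = []
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            cell = box(lon0 + c * cs, lat0 + r * cs,
                       lon0 + (c + 1) * cs, lat0 + (r + 1) * cs)
            inter = line.intersection(cell)
            if not inter.is_empty and inter.length > 0:
                hits.append((r, c))
    return np.array(sorted(hits), dtype=int).reshape(-1, 2)


def route_community(net: RouteNetwork, truth: TruthSSDM) -> pd.DataFrame:
    """Route x species cell-count abundance matrix.

    abundance(route, species) = number of distinct sea cells traversed by
    the route in which the species is present.  Routes overlapping no sea
    cell yield a zero row (with a warning).
    """
    rows = {}
    for name, verts in net.routes:
        cells = traversed_cells(truth.grid, verts)
        if len(cells):
            sea = truth.grid.sea_mask[cells[:, 0], cells[:, 1]]
            cells = cells[sea]
        if len(cells) == 0:
            warnings.warn(f"route {name!r} overlaps no sea cell; zero row")
            rows[name] = np.zeros(truth.n_species, dtype=int)
        else:
            rows[name] = truth.occupancy[:, cells[:, 0], cells[:, 1]].sum(axis=1)
    return pd.DataFrame.from_dict(rows, orient="index", columns=truth.names)


def hellinger(matrix) -> pd.DataFrame:
    """Hellinger transformation: sqrt of row-relative abundance.

    y'_ij = sqrt(y_ij / row_total_i); all-zero rows map to all-zero rows.
    Every transformed non-zero row has unit sum of squares.
    """
    df = pd.DataFrame(matrix).astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = df.sum(axis=1)
    out = df.div(totals.replace(0, np.nan), axis=0).pow(0.5).fillna(0.0)
    return out


def bray_curtis(matrix) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between rows: sum|x-y| / sum(x+y).

    A pair of all-zero rows has undefined dissimilarity; it is reported as 0
    (identical emptiness) with a log notice.
    """
    df = pd.DataFrame(matrix).astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    d = squareform(pdist(df.to_numpy(), metric="braycurtis"))
    if np.isnan(d).any():
        logger.info("all-zero row pair: Bray-Curtis defined as 0")
        d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(d, index=df.index, columns=df.index)


@dataclass(frozen=True)
class Ordination:
    """NMDS configuration: coordinates (centered), Kruskal stress-1, convergence."""

    coordinates: pd.DataFrame
    stress: float
    converged: bool


def _classical_scaling(d: np.ndarray, dims: int) -> np.ndarray:
    """Classical (Torgerson) scaling: the standard NMDS starting point."""
    n = len(d)
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (d ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    if coords.shape[1] < dims:
        coords = np.pad(coords, ((0, 0), (0, dims - coords.shape[1])))
    return coords


def nmds(dissim, dims: int = 2, n_starts: int = 10, seed: int = 0,
         max_iter: int = 500) -> Ordination:
    """Nonmetric multidimensional scaling of a dissimilarity matrix.

    SMACOF with isotonic regression (monotone disparities, ties averaged)
    run from a classical-scaling configuration plus ``n_starts - 1`` random
    starts — the metric initialization avoids the partially degenerate
    (tied-disparity) solutions random starts can settle into.  The best
    configuration by normalized Kruskal stress-1 is returned with
    coordinates centered at the origin.  Deterministic for a fixed seed.
    """
    df = pd.DataFrame(dissim).astype(float)
    d = df.to_numpy()
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T) or \
            not np.allclose(np.diag(d), 0):
        raise ValueError("dissimilarity must be symmetric with zero diagonal")
    if dims < 1:
        raise ValueError("dims must be >= 1")
    common = dict(metric=False, n_components=dims, max_iter=max_iter,
                  eps=1e-9, normalized_stress=True, n_jobs=1)
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords, stress, n_iter = smacof(
            d, init=_classical_scaling(d, dims), n_init=1,
            random_state=seed, return_n_iter=True, **common)
        best = (stress, coords, n_iter)
        if n_starts > 1:
            coords, stress, n_iter = smacof(
                d, n_init=n_starts - 1, random_state=seed,
                return_n_iter=True, **common)
            if stress < best[0]:
                best = (stress, coords, n_iter)
    stress, coords, n_iter = best
    coords = coords - coords.mean(axis=0)
    return Ordination(pd.DataFrame(coords, index=df.index,
                                   columns=[f"nmds{i+1}" for i in range(dims)]),
                      float(stress), converged=n_iter < max_iter)


def _clusters(dissim: pd.DataFrame, cut: float,
              relative: bool = True) -> dict[int, list[str]]:
    d = dissim.to_numpy()
    if len(d) == 1:
        return {1: [dissim.index[0]]}
    Z = linkage(squareform(d, checks=False), method="average")
    height = cut * Z[:, 2].max() if relative else cut
    labels = fcluster(Z, t=height, criterion="distance")
    out: dict[int, list[str]] = {}
    for name, lab in zip(dissim.index, labels):
        out.setdefault(int(lab), []).append(name)
    return out


def cluster_and_select(dissim, cut: float = 0.5, seed: int = 0,
                       relative: bool = True) -> list[str]:
    """Average-linkage clustering cut at ``cut``; one random route per cluster.

    The reproducible analogue of picking one route per cluster off an NMDS
    plot by eye.  With ``relative=True`` (default) the tree is cut at
    ``cut`` times the maximum merge height, making the cut dimensionless
    with respect to the overall dissimilarity scale; ``relative=False``
    cuts at the absolute height ``cut``.
    """
    if not 0 < cut <= 1:
        raise ValueError("cut must be in (0, 1]")
    df = pd.DataFrame(dissim).astype(float)
    rng = np.random.default_rng(seed)
    chosen = [members[int(rng.integers(0, len(members)))]
              for _, members in sorted(_clusters(df, cut, relative).items())]
    return chosen


def route_env_bins(net: RouteNetwork, index: EnvVariabilityIndex) -> dict[str, set[int]]:
    """Occupied 0.2-wide variability bins per route (over traversed sea cells)."""
    out = {}
    for name, verts in net.routes:
        cells = traversed_cells(index.grid, verts)
        if len(cells):
            sea = index.grid.sea_mask[cells[:, 0], cells[:, 1]]
            cells = cells[sea]
        out[name] = set(index.bin_of_cells(cells[:, 0], cells[:, 1]).tolist()) \
            if len(cells) else set()
    return out


def build_subnetwork(net: RouteNetwork, mode: str, *, truth: TruthSSDM | None = None,
                     index: EnvVariabilityIndex | None = None, k: int | None = None,
                     seed: int = 0, cut: float = 0.5) -> RouteNetwork:
    """Construct a route subnetwork.

    mode='biased': the largest compositional cluster (requires ``truth``).
    'community': one route per compositional cluster (requires ``truth``).
    'environment': greedy set cover of the occupied variability-index bins
    (requires ``index``).  'random_k': k routes uniform without replacement.
    """
    if mode == "random_k":
        if k is None or not 1 <= k <= net.n_routes:
            raise ValueError("random_k requires 1 <= k <= n_routes")
        rng = np.random.default_rng(seed)
        names = [net.names[i] for i in
                 sorted(rng.choice(net.n_routes, size=k, replace=False))]
        return net.subset(names)

    if mode in ("biased", "community"):
        if truth is None:
            raise ValueError(f"mode {mode!r} requires the truth community")
        dis = bray_curtis(hellinger(route_community(net, truth)))
        clusters = _clusters(dis, cut)
        if mode == "biased":
            largest = max(clusters.values(), key=len)
            return net.subset(largest)
        return net.subset(cluster_and_select(dis, cut=cut, seed=seed))

    if mode == "environment":
        if index is None:
            raise ValueError("environment mode requires the variability index")
        per_route = route_env_bins(net, index)
        sea_r, sea_c = index.grid.sea_indices()
        target = set(index.bin_of_cells(sea_r, sea_c).tolist())
        chosen: list[str] = []
        covered: set[int] = set()
        while covered != target:
            best, gain = None, 0
            for name in net.names:
                if name in chosen:
                    continue
                g = len(per_route[name] - covered)
                if g > gain:
                    best, gain = name, g
            if best is None:
                missing = sorted(target - covered)
                raise GenerationError(
                    f"environment subnetwork infeasible: bins {missing} "
                    "not traversed by any route")
            chosen.append(best)
            covered |= per_route[best]
        return net.subset(chosen)

    raise ValueError(f"unknown subnetwork mode {mode!r}")
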