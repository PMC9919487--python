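"""Synthetic world generator: environment, virtual community, route network.

The generator emulates the statistical structure of a semi-enclosed marine
basin surveyed by commercial vessels: up to six environmental predictors
normalized to [0, 1] over a connected sea mask, a community of ~40 virtual
predator species in three unequally sized classes whose occupancy follows a
coastal-to-offshore and a basin-scale (west-east) richness gradient, and a
network of port-to-port polyline routes of varying length that cross those
gradients unevenly.

Virtual species are defined by logistic responses to the environmental
layers thresholded at species-specific prevalence quantiles, so each species
is a binary occupancy raster — the same currency as a thresholded stacked
species distribution model, which is all the downstream sampling machinery
sees.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import GenerationError
from .grid import EnvStack, GridSpec, RouteNetwork, TruthSSDM

#: Default layer roster, in the order they are generated.  The first layer is
#: always the distance-from-shore analogue so a coastal gradient exists; the
#: second carries the basin-scale (west-east) trend.
DEFAULT_LAYER_NAMES = ("dist_shore", "sst_mean", "sst_range", "chla_mean",
                       "bathymetry", "slope")

DEFAULT_CLASS_LABELS = ("teleost", "elasmobranch", "mammal")
#: Default community: three unequal classes of large marine predators.
DEFAULT_CLASS_SIZES = (20, 13, 9)

_ROUTE_RETRY_CAP = 200


def _make_sea_mask(rng: np.random.Generator, n_rows: int, n_cols: int) -> np.ndarray:
    """Connected, roughly convex sea blob with a land margin.

    Union of three jittered ellipses spanning the grid.  Near-convexity keeps
    straight port-to-port chords mostly at sea, mirroring an open basin.
    """
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    y = (rr + 0.5) / n_rows
    x = (cc + 0.5) / n_cols
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    centers = np.array([[0.5, 0.35], [0.5, 0.65], [0.5, 0.5]])
    centers += rng.uniform(-0.04, 0.04, size=centers.shape)
    semi = np.array([[0.33, 0.30], [0.33, 0.30], [0.36, 0.42]])
    semi *= rng.uniform(0.92, 1.08, size=semi.shape)
    for (cy, cx), (ay, ax) in zip(centers, semi):
        mask |= ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0
    # keep the largest connected component only
    lab, nlab = ndimage.label(mask)
    if nlab > 1:
        sizes = ndimage.sum(mask, lab, index=np.arange(1, nlab + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def _smooth_field(rng: np.random.Generator, shape, trend: np.ndarray,
                  noise_sigma: float, noise_weight: float) -> np.ndarray:
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), noise_sigma, mode="nearest")
    return trend + noise_weight * noise


def _minmax_over_sea(field: np.ndarray, sea: np.ndarray) -> np.ndarray:
    vals = field[sea]
    lo, hi = vals.min(), vals.max()
    if hi - lo <= 0:
        out = np.zeros_like(field)
    else:
        out = (field - lo) / (hi - lo)
    out = np.where(sea, np.clip(out, 0.0, 1.0), np.nan)
    return out


def make_world(seed: int, n_rows: int = 30, n_cols: int = 70, n_layers: int = 6,
               origin_lon: float = -6.0, origin_lat: float = 30.0,
               cell_size: float = 0.5) -> EnvStack:
    """Generate a synthetic environmental stack.

    Layers are smooth spatial fields (low-order trend plus spatially
    correlated noise) min-max normalized to [0, 1] over sea cells.  The
    distance-from-shore layer is always present so downstream coastal
    gradients are well defined.  Deterministic for a fixed seed.
    """
    if n_rows < 10 or n_cols < 10:
        raise ValueError("grid must be at least 10x10")
    if not 1 <= n_layers <= len(DEFAULT_LAYER_NAMES):
        raise ValueError(f"n_layers must be in 1..{len(DEFAULT_LAYER_NAMES)}")
    rng = np.random.default_rng(seed)
    sea = _make_sea_mask(rng, n_rows, n_cols)
    grid = GridSpec(n_rows, n_cols, origin_lon, origin_lat, cell_size, sea)

    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    y = (rr + 0.5) / n_rows
    x = (cc + 0.5) / n_cols
    sigma = max(2.0, min(n_rows, n_cols) / 10.0)

    # distance from shore: Euclidean distance transform of the sea mask
    dist = ndimage.distance_transform_edt(sea)
    layers: dict[str, np.ndarray] = {"dist_shore": _minmax_over_sea(dist, sea)}

    trends = {
        # west-east basin gradient with a mild meridional tilt
        "sst_mean": 1.5 * x + 0.3 * y,
        "sst_range": 1.2 * (1 - y) + 0.5 * x * x,
        "chla_mean": None,  # filled below: coastal proxy + noise
        "bathymetry": None,  # offshore-deep proxy
        "slope": 0.0 * x,    # pure correlated noise
    }
    dist_norm = layers["dist_shore"]
    dist_filled = np.where(sea, dist_norm, 0.0)
    trends["chla_mean"] = 1.4 * (1 - dist_filled) + 0.4 * y
    trends["bathymetry"] = 1.6 * dist_filled + 0.2 * x

    for name in DEFAULT_LAYER_NAMES[1:n_layers]:
        field = _smooth_field(rng, sea.shape, trends[name], sigma,
                              noise_weight=0.45 if name != "slope" else 1.0)
        layers[name] = _minmax_over_sea(field, sea)

    return EnvStack(grid, layers)


def make_species(env: EnvStack, seed: int, n_species: int = sum(DEFAULT_CLASS_SIZES),
                 class_sizes: tuple[int, ...] = DEFAULT_CLASS_SIZES,
                 class_labels: tuple[str, ...] = DEFAULT_CLASS_LABELS,
                 prevalence_range: tuple[float, float] = (0.05, 0.60)) -> TruthSSDM:
    """Generate a virtual community with class-structured niches.

    Each species has a logistic-scale suitability: a random linear plus
    quadratic combination of the layers, with a class-specific affinity for
    the coastal gradient (teleosts and elasmobranchs prefer nearshore cells,
    mammals prefer offshore cells — the structure reported for Mediterranean
    predator classes).  Suitability is thresholded at a species-specific
    quantile so prevalences span roughly ``prevalence_range``.  The response
    parameters are retained for parameter-recovery tests.
    """
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    if sum(class_sizes) != n_species:
        raise ValueError("class_sizes must sum to n_species")
    if len(class_sizes) != len(class_labels):
        raise ValueError("class_sizes and class_labels length mismatch")
    rng = np.random.default_rng(seed)
    grid = env.grid
    sea = grid.sea_mask
    X = env.sea_matrix()  # (n_sea, n_layers)
    names_layers = env.layer_names
    i_shore = names_layers.index("dist_shore") if "dist_shore" in names_layers else None
    i_basin = names_layers.index("sst_mean") if "sst_mean" in names_layers else None

    labels = [lab for lab, k in zip(class_labels, class_sizes) for _ in range(k)]
    occupancy = np.zeros((n_species, grid.n_rows, grid.n_cols), dtype=bool)
    params = {"linear": [], "quadratic": [], "quantile": [], "label": labels}
    lo_q, hi_q = 1.0 - prevalence_range[1], 1.0 - prevalence_range[0]
    species = []
    for s in range(n_species):
        lab = labels[s]
        beta = rng.normal(0.0, 1.0, size=X.shape[1])
        gamma = rng.normal(0.0, 0.5, size=X.shape[1])
        if i_shore is not None:
            # coastal classes avoid high distance-from-shore; the mammal-like
            # class tilts offshore, but mildly — its richness gradient
            # diverges from the rest without inverting the community's
            bias = -2.5 if lab in class_labels[:2] else 0.5
            beta[i_shore] = bias + rng.normal(0.0, 0.5)
        if i_basin is not None:
            # basin-scale turnover: most species favour one basin end (a net
            # richness gradient), a minority the other (composition clusters)
            sign = 1.0 if rng.random() < 0.7 else -1.0
            beta[i_basin] += sign * rng.normal(1.4, 0.5)
        suit = X @ beta + ((X - 0.5) ** 2) @ gamma
        q = rng.uniform(lo_q, hi_q)
        # occupy the top (1 - q) fraction of sea cells by suitability, so the
        # threshold quantile maps to an exact prevalence (q = 1 -> empty,
        # q = 0 -> all sea cells)
        k = int(round((1.0 - q) * len(suit)))
        occ_sea = np.zeros(len(suit), dtype=bool)
        if k > 0:
            occ_sea[np.argsort(suit, kind="stable")[-k:]] = True
        occupancy[s][sea] = occ_sea
        species.append((f"sp{s:03d}", lab))
        params["linear"].append(beta)
        params["quadratic"].append(gamma)
        params["quantile"].append(q)
    params["linear"] = np.array(params["linear"])
    params["quadratic"] = np.array(params["quadratic"])
    params["quantile"] = np.array(params["quantile"])
    return TruthSSDM(grid, species, occupancy, response_params=params)


# -- route generation ---------------------------------------------------------


def _port_cells(grid: GridSpec) -> np.ndarray:
    """Sea cells on the mask edge (adjacent to land or the grid boundary)."""
    sea = grid.sea_mask
    interior = ndimage.binary_erosion(sea, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
                                      border_value=0)
    edge = sea & ~interior
    return np.argwhere(edge)  # (k, 2) rows of (row, col)


def _chord_at_sea(grid: GridSpec, vertices: np.ndarray) -> bool:
    """True if a dense sampling of the polyline lies entirely on sea cells."""
    step = grid.cell_size / 4.0
    pts = []
    for a, b in zip(vertices[:-1], vertices[1:]):
        seg_len = float(np.hypot(b[0] - a[0], b[1] - a[1]))
        n = max(2, int(np.ceil(seg_len / step)) + 1)
        t = np.linspace(0.0, 1.0, n)
        pts.append(a[None, :] + t[:, None] * (b - a)[None, :])
    pts = np.vstack(pts)
    try:
        row, col = grid.cell_of(pts[:, 0], pts[:, 1])
    except ValueError:
        return False
    return bool(grid.sea_mask[row, col].all())


def make_routes(env: EnvStack, seed: int, n_routes: int = 15,
                coverage: str = "representative",
                min_length_cells: float = 5.0,
                hub_frac: float = 0.6) -> RouteNetwork:
    """Generate a network of port-to-port polyline routes.

    coverage='representative' emulates a commercial network that crosses the
    environmental gradient unevenly: all routes are port-to-port chords with
    lengths skewed short (coastal hops through the nearshore high-richness
    band, a few longer crossings), and a ``hub_frac`` share of them have
    both ports in the western half of the basin — the high-traffic hub — so
    route density is biased toward one basin while the rest of the network
    still reaches the other.  'clustered' confines both endpoints of every route
    to one quadrant (an analogue of a deliberately biased subnetwork);
    'extremes' threads routes through the lowest and highest cells of the
    environmental-variability index so the network spans the full
    environmental gradient.  Routes whose chord crosses land are rejected
    and redrawn (capped retries).
    """
    if n_routes < 1:
        raise ValueError("n_routes must be >= 1")
    if coverage not in ("representative", "clustered", "extremes"):
        raise ValueError(f"unknown coverage mode {coverage!r}")
    rng = np.random.default_rng(seed)
    grid = env.grid
    ports = _port_cells(grid)
    if len(ports) < 2:
        raise GenerationError("no valid port cells on the mask edge")

    if coverage == "clustered":
        # densest quadrant of port cells
        mid_r, mid_c = grid.n_rows / 2, grid.n_cols / 2
        quads = [(ports[:, 0] < mid_r) & (ports[:, 1] < mid_c),
                 (ports[:, 0] < mid_r) & (ports[:, 1] >= mid_c),
                 (ports[:, 0] >= mid_r) & (ports[:, 1] < mid_c),
                 (ports[:, 0] >= mid_r) & (ports[:, 1] >= mid_c)]
        counts = [int(q.sum()) for q in quads]
        sel = quads[int(np.argmax(counts))]
        if sel.sum() >= 2:
            ports = ports[sel]

    waypoints = None
    if coverage == "extremes":
        from .bias import env_variability_index
        evi = env_variability_index(env)
        sea_r, sea_c = grid.sea_indices()
        vals = evi.value[sea_r, sea_c]
        lo = (sea_r[int(np.argmin(vals))], sea_c[int(np.argmin(vals))])
        hi = (sea_r[int(np.argmax(vals))], sea_c[int(np.argmax(vals))])
        waypoints = [lo, hi]

    min_len_deg = min_length_cells * grid.cell_size
    diag_deg = np.hypot(grid.n_cols, grid.n_rows) * grid.cell_size
    west_ports = ports[ports[:, 1] < grid.n_cols / 2]
    routes = []
    for i in range(n_routes):
        # varying lengths, skewed short: most routes are coastal hops that
        # stay in the richer nearshore band, a few are long basin crossings
        if coverage == "representative":
            hi_len = min_len_deg + (diag_deg - min_len_deg) * rng.beta(1.2, 3.0)
        else:
            hi_len = diag_deg
        pool = ports
        if coverage == "representative" and len(west_ports) >= 2 \
                and rng.random() < hub_frac:
            pool = west_ports
        ok = False
        for _ in range(_ROUTE_RETRY_CAP):
            a, b = rng.choice(len(pool), size=2, replace=False)
            (ra, ca), (rb, cb) = pool[a], pool[b]
            pa = np.array(grid.cell_center(ra, ca))
            pb = np.array(grid.cell_center(rb, cb))
            chord = np.hypot(*(pb - pa))
            if chord < min_len_deg or chord > hi_len:
                continue
            if waypoints is not None:
                wr, wc = waypoints[i % len(waypoints)]
                pw = np.array(grid.cell_center(wr, wc))
                verts = np.vstack([pa, pw, pb])
            else:
                verts = np.vstack([pa, pb])
            if _chord_at_sea(grid, verts):
                routes.append((f"route_{i:02d}", verts))
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not place route {i} after {_ROUTE_RETRY_CAP} attempts")
    return RouteNetwork(routes)


def default_world(seed: int):
    """Convenience: the default study conditions (world, community, network)."""
    env = make_world(seed)
    truth = make_species(env, seed + 1)
    net = make_routes(env, seed + 2)
    return env, truth, net
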