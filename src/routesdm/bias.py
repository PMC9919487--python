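"""Environmental-variability index, climatic bias index, richness correlation.

The environmental-variability index collapses the predictor stack into one
scalar per cell: a PCA of the per-cell layer vectors, keeping the smallest
number of components whose cumulative explained variance exceeds a target
(default 0.8), summing their site scores weighted by each component's share
of the retained variance, then min-max normalizing so 0 and 1 mark the most
different environments.

The climatic bias index (CBI) of a sampling frame is the sum over five
0.2-wide bins of the absolute difference between the frame's and the whole
study area's cell-proportion histograms of that index; 0 means the frame
matches the whole area's environmental density, 2 is maximal mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, UndefinedCorrelationError
from .grid import EnvStack, GridSpec

BIN_EDGES = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])


@dataclass(frozen=True)
class EnvVariabilityIndex:
    """Per-cell scalar environmental index in [0, 1] (NaN on land)."""

    grid: GridSpec
    value: np.ndarray
    n_components: int
    component_weights: np.ndarray
    explained_variance_ratio: np.ndarray

    def sea_values(self) -> np.ndarray:
        return self.value[self.grid.sea_mask]

    def to_csv(self, path) -> None:
        """Write the index as a CSV grid (NaN on land)."""
        np.savetxt(path, self.value, fmt="%.8g", delimiter=",")

    def bin_of_cells(self, rows, cols) -> np.ndarray:
        """Histogram bin (0..4) of given cells; index 1.0 falls in the top bin."""
        v = self.value[rows, cols]
        return np.minimum((v / 0.2).astype(int), 4)


@dataclass(frozen=True)
class BiasReport:
    """CBI decomposition: per-bin densities for the whole area and the frame."""

    bin_edges: np.ndarray
    density_whole: np.ndarray
    density_frame: np.ndarray
    cbi: float

    def as_dict(self) -> dict:
        return {
            "cbi": self.cbi,
            "density_whole": self.density_whole.tolist(),
            "density_frame": self.density_frame.tolist(),
        }


def env_variability_index(env: EnvStack, var_target: float = 0.8,
                          use_correlation: bool = False) -> EnvVariabilityIndex:
    """PCA-collapsed environmental-variability index, min-max normalized.

    PCA is on the covariance matrix of the already-[0,1] layers (the layers
    are normalized upstream precisely so that no re-standardization is
    needed); set ``use_correlation`` to rescale to unit variances instead.
    Component signs are oriented so each component's largest-magnitude
    loading is positive, which fixes the otherwise arbitrary score sign.
    """
    if env.n_layers < 1:
        raise ValueError("need at least one layer")
    X = env.sea_matrix()
    sd = X.std(axis=0, ddof=1)
    if np.all(sd <= 1e-12):
        raise DegenerateInputError("all layers constant over sea cells")
    Xc = X - X.mean(axis=0)
    if use_correlation:
        ok = sd > 1e-12
        Xc = Xc[:, ok] / sd[ok]
    cov = np.cov(Xc, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise DegenerateInputError("zero total variance")
    ratio = evals / total
    k = int(np.searchsorted(np.cumsum(ratio) > var_target, True)) + 1
    k = min(k, len(evals))
    # orient: largest-|loading| entry of each kept component made positive
    for j in range(k):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Xc @ evecs[:, :k]
    w = evals[:k] / evals[:k].sum()
    raw = scores @ w
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        raise DegenerateInputError("index constant over sea cells")
    norm = (raw - lo) / (hi - lo)
    value = np.full(env.grid.sea_mask.shape, np.nan)
    value[env.grid.sea_mask] = norm
    return EnvVariabilityIndex(env.grid, value, k, w, ratio)


def _frame_mask(grid: GridSpec, frame_cells) -> np.ndarray:
    """Normalize a frame-cell specification to a boolean grid mask."""
    arr = np.asarray(frame_cells)
    if arr.dtype == bool and arr.shape == grid.sea_mask.shape:
        mask = arr
    elif arr.ndim == 2 and arr.shape[1] == 2:
        mask = np.zeros_like(grid.sea_mask)
        mask[arr[:, 0], arr[:, 1]] = True
    else:
        raise ValueError("frame_cells must be a boolean grid mask or (k,2) indices")
    if not mask.any():
        raise ValueError("frame is empty")
    if np.any(mask & ~grid.sea_mask):
        raise ValueError("frame contains land cells")
    return mask


def climatic_bias_index(index: EnvVariabilityIndex, frame_cells) -> BiasReport:
    """CBI of a frame: sum of |frame - whole| bin-proportion differences.

    Bins are [0,0.2), ..., [0.8,1.0]; cells with index exactly 1.0 go to the
    top bin.  CBI is bounded by [0, 2] (triangle inequality on two
    probability vectors).
    """
    grid = index.grid
    mask = _frame_mask(grid, frame_cells)

    def density(cell_mask):
        r, c = np.nonzero(cell_mask)
        bins = index.bin_of_cells(r, c)
        return np.bincount(bins, minlength=5) / len(bins)

    d_whole = density(grid.sea_mask)
    d_frame = density(mask)
    cbi = float(np.abs(d_frame - d_whole).sum())
    return BiasReport(BIN_EDGES.copy(), d_whole, d_frame, cbi)


def richness_correlation(map_a: np.ndarray, map_b: np.ndarray,
                         grid: GridSpec) -> float:
    """Pearson r between two richness maps over sea cells."""
    a = np.asarray(map_a, dtype=float)[grid.sea_mask]
    b = np.asarray(map_b, dtype=float)[grid.sea_mask]
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need >= 3 common sea cells on a shared grid")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("a richness map is constant over sea cells")
    return float(stats.pearsonr(a, b)[0])
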