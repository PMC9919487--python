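"""Per-species ensemble distribution models and binary stacking.

The modelling core follows the Model/Results convention: :class:`EnsembleSDM`
is built from presence points plus the environmental stack; ``fit`` returns
an :class:`EnsembleSDMResults` holding the fitted learners, their AUC
weights, the sensitivity = specificity binarization threshold, and the
cross-validation table.  :class:`StackedSDM` lifts this to a community:
one ensemble per species with enough records, binarized and summed into a
species-richness surface (a binary stacked species distribution model).

Three learner families are fitted by default, mirroring the common
presence-only ensemble recipe:

* a regularized logistic model trained on presences versus random background
  points (a maximum-entropy-style surrogate; the learner contract is
  pluggable so a true MaxEnt can be dropped in),
* a piecewise-linear spline model with first-order interactions (an adaptive
  regression splines analogue) trained on 1000 pseudo-absences drawn beyond
  a two-degree exclusion buffer,
* bagged regression trees (random-forest regression, 5000 trees / terminal
  node 5 by default) trained on an equal number of pseudo-absences as
  presences, same buffer rule.

Each learner is evaluated on three random 70/30 presence/pseudo-absence
splits; its weight is the mean test AUC, and the ensemble probability is the
AUC-weighted mean of the refit learners' predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import SplineTransformer

from .errors import FitError, GenerationError
from .geometry import KM_PER_DEGREE, haversine_km
from .grid import EnvStack, GridSpec, TruthSSDM

# ---------------------------------------------------------------------------
# scalar statistics


def auc(pos_scores, neg_scores) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    The fraction of (positive, negative) score pairs with positive > negative,
    ties counting one half.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


THRESHOLD_GRID = np.round(np.linspace(0.0, 1.0, 1001), 3)


def select_threshold(pos_scores, neg_scores) -> float:
    """Sensitivity = specificity binarization threshold.

    Scans t over {0.000, 0.001, ..., 1.000} with rule predict-present iff
    p >= t and returns the smallest t minimizing |sensitivity - specificity|.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    t = THRESHOLD_GRID
    sens = (pos[None, :] >= t[:, None]).mean(axis=1)
    spec = (neg[None, :] < t[:, None]).mean(axis=1)
    return float(t[int(np.argmin(np.abs(sens - spec)))])


# ---------------------------------------------------------------------------
# pseudo-absences


@dataclass(frozen=True)
class PseudoAbsenceSet:
    points: np.ndarray  # (n, 2) lon/lat
    scheme: str


def env_at_points(env: EnvStack, points: np.ndarray) -> np.ndarray:
    """Environmental feature matrix at lon/lat points (must be sea cells)."""
    pts = np.asarray(points, dtype=float)
    row, col = env.grid.cell_of(pts[:, 0], pts[:, 1])
    if not env.grid.sea_mask[row, col].all():
        raise ValueError("points fall on land cells")
    return np.column_stack([env.layers[k][row, col] for k in env.layers])


def generate_pseudo_absences(presences: np.ndarray, env: EnvStack, scheme: str,
                             n: int = 1000, buffer_deg: float = 2.0,
                             seed: int = 0) -> PseudoAbsenceSet:
    """Draw pseudo-absence points on the sea mask.

    scheme='background': uniform over all sea cells.  'exclusion_buffer':
    uniform over sea cells farther than the great-circle equivalent of
    ``buffer_deg`` degrees (the two-degree method by default) from every
    presence.  'equal_n': the buffer rule with n set to the presence count.
    Points are drawn by picking a cell uniformly and jittering uniformly
    within it, then re-checked against the exact buffer distance.
    """
    if scheme not in ("background", "exclusion_buffer", "equal_n"):
        raise ValueError(f"unknown pseudo-absence scheme {scheme!r}")
    presences = np.asarray(presences, dtype=float)
    if scheme == "equal_n":
        n = len(presences)
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = env.grid
    rng = np.random.default_rng(seed)
    rows, cols = grid.sea_indices()
    buffer_km = buffer_deg * KM_PER_DEGREE

    if scheme != "background" and buffer_deg > 0 and len(presences):
        clon, clat = grid.cell_center(rows, cols)
        dmin = haversine_km(clon[:, None], clat[:, None],
                            presences[None, :, 0], presences[None, :, 1]).min(axis=1)
        # keep cells whose center clears the buffer minus the half-diagonal,
        # then enforce the exact rule per sampled point
        half_diag_km = grid.cell_size * np.sqrt(2) / 2 * KM_PER_DEGREE
        ok = dmin >= buffer_km - half_diag_km
        if not ok.any():
            raise GenerationError(
                f"no sea cell beyond the {buffer_deg} degree exclusion buffer")
        rows, cols = rows[ok], cols[ok]

    out = []
    need = n
    for _ in range(200):
        take = max(need * 2, 32)
        idx = rng.integers(0, len(rows), size=take)
        lon = grid.origin_lon + (cols[idx] + rng.random(take)) * grid.cell_size
        lat = grid.origin_lat + (rows[idx] + rng.random(take)) * grid.cell_size
        pts = np.column_stack([lon, lat])
        if scheme != "background" and buffer_deg > 0 and len(presences):
            dmin = haversine_km(pts[:, 0:1], pts[:, 1:2],
                                presences[None, :, 0], presences[None, :, 1]).min(axis=1)
            pts = pts[dmin >= buffer_km]
        out.append(pts)
        need = n - sum(len(p) for p in out)
        if need <= 0:
            break
    pts = np.vstack(out)
    if len(pts) < n:
        raise GenerationError(
            f"could not draw {n} pseudo-absences beyond the {buffer_deg} degree buffer")
    return PseudoAbsenceSet(pts[:n], scheme)


# ---------------------------------------------------------------------------
# learners


class LogisticBackgroundLearner:
    """Regularized logistic model on presences vs background points.

    A maximum-entropy-style surrogate: with a large random background sample
    the logistic fit estimates the same relative suitability surface.
    """

    name = "logistic_background"
    pa_scheme = "background"

    def __init__(self, C: float = 1.0):
        self.C = C
        self._model = None

    def fit(self, X, y):
        self._model = LogisticRegression(C=self.C, max_iter=1000)
        self._model.fit(X, y)
        return self

    def predict(self, X):
        return self._model.predict_proba(X)[:, 1]


class SplineInteractionLearner:
    """Piecewise-linear splines per predictor plus first-order interactions.

    An adaptive-regression-splines analogue: degree-1 spline (hinge) basis
    per layer and pairwise products of the raw layers, combined in a
    regularized logistic fit.
    """

    name = "spline_interactions"
    pa_scheme = "exclusion_buffer"

    def __init__(self, n_knots: int = 4, C: float = 1.0):
        self.n_knots = n_knots
        self.C = C
        self._spline = None
        self._model = None

    def _features(self, X):
        S = self._spline.transform(X)
        p = X.shape[1]
        inter = [X[:, i] * X[:, j] for i in range(p) for j in range(i + 1, p)]
        return np.column_stack([S] + inter) if inter else S

    def fit(self, X, y):
        self._spline = SplineTransformer(n_knots=self.n_knots, degree=1,
                                         include_bias=False)
        self._spline.fit(X)
        self._model = LogisticRegression(C=self.C, max_iter=1000)
        self._model.fit(self._features(X), y)
        return self

    def predict(self, X):
        return self._model.predict_proba(self._features(X))[:, 1]


class BaggedTreesLearner:
    """Bagged regression trees (random-forest regression on 0/1 labels)."""

    name = "bagged_trees"
    pa_scheme = "equal_n"

    def __init__(self, n_trees: int = 5000, min_samples_leaf: int = 5,
                 random_state: int | None = None):
        self.n_trees = n_trees
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state
        self._model = None

    def fit(self, X, y):
        self._model = RandomForestRegressor(
            n_estimators=self.n_trees, min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state, n_jobs=1)
        self._model.fit(X, y)
        return self

    def predict(self, X):
        return np.clip(self._model.predict(X), 0.0, 1.0)


@dataclass(frozen=True)
class SDMConfig:
    """Ensemble configuration.

    ``pa_n`` maps learner names to pseudo-absence counts (ignored for the
    equal_n scheme).  The default profile matches the standard recipe
    (10,000 background points, 1000 buffered pseudo-absences, 5000 trees);
    :meth:`fast` returns a reduced profile for simulation campaigns.
    """

    learner_names: tuple[str, ...] = ("logistic_background",
                                      "spline_interactions", "bagged_trees")
    pa_n: dict = field(default_factory=lambda: {"logistic_background": 10_000,
                                                "spline_interactions": 1000})
    buffer_deg: float = 2.0
    n_trees: int = 5000
    min_samples_leaf: int = 5
    train_frac: float = 0.7
    n_splits: int = 3
    min_presences: int = 5
    eval_pa_n: int = 1000

    @classmethod
    def fast(cls) -> "SDMConfig":
        return cls(pa_n={"logistic_background": 1000, "spline_interactions": 200},
                   n_trees=100, eval_pa_n=300)

    def make_learner(self, name: str, seed: int):
        if name == "logistic_background":
            return LogisticBackgroundLearner()
        if name == "spline_interactions":
            return SplineInteractionLearner()
        if name == "bagged_trees":
            return BaggedTreesLearner(self.n_trees, self.min_samples_leaf,
                                      random_state=seed)
        raise ValueError(f"unknown learner {name!r}")


# ---------------------------------------------------------------------------
# ensemble model / results


@dataclass(frozen=True)
class BinaryPrediction:
    """Per-species prediction: probability surface, threshold, binary map."""

    grid: GridSpec
    probability: np.ndarray  # grid-shaped, NaN on land
    threshold: float
    species: str = ""

    @property
    def presence(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.grid.sea_mask,
                            self.probability >= self.threshold, False)

    def to_csv_dir(self, directory) -> None:
        """Probability and binary CSV grids (NaN / 0 on land)."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tag = self.species or "species"
        np.savetxt(directory / f"prob_{tag}.csv", self.probability,
                   fmt="%.6g", delimiter=",")
        np.savetxt(directory / f"bin_{tag}.csv", self.presence.astype(int),
                   fmt="%d", delimiter=",")


class EnsembleSDM:
    """Ensemble species distribution model for one species.

    Parameters
    ----------
    presences : (n, 2) array of lon/lat presence points
    env : EnvStack
    config : SDMConfig
    species : display name carried into results
    """

    def __init__(self, presences, env: EnvStack, config: SDMConfig | None = None,
                 species: str = ""):
        self.presences = np.asarray(presences, dtype=float).reshape(-1, 2)
        self.env = env
        self.config = config or SDMConfig()
        self.species = species

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, env: EnvStack,
                       config: SDMConfig | None = None, species: str | None = None):
        """Build from an occurrence table (columns lon, lat[, species])."""
        if species is None:
            uniq = records["species"].unique() if "species" in records else [""]
            if len(uniq) != 1:
                raise ValueError("records contain multiple species; pass species=")
            species = str(uniq[0])
        pts = records[["lon", "lat"]].apply(pd.to_numeric).to_numpy(float)
        return cls(pts, env, config, species=species)

    def fit(self, seed: int = 0) -> "EnsembleSDMResults":
        cfg = self.config
        if len(self.presences) < cfg.min_presences:
            raise FitError(f"{self.species or 'species'}: "
                           f"{len(self.presences)} presences < {cfg.min_presences}")
        rng = np.random.default_rng(seed)
        X_pres = env_at_points(self.env, self.presences)

        fitted, weights, cv_rows = [], [], []
        for name in cfg.learner_names:
            sub = int(rng.integers(0, 2**31 - 1))
            try:
                learner, w, aucs = self._fit_one(name, X_pres, sub)
            except Exception as exc:  # degenerate data for one learner only
                warnings.warn(f"learner {name} failed for {self.species!r}: {exc}")
                continue
            fitted.append(learner)
            weights.append(w)
            cv_rows.extend({"learner": name, "split": i, "auc": a}
                           for i, a in enumerate(aucs))
        if not fitted:
            raise FitError(f"all learners failed for {self.species!r}")

        # sensitivity = specificity threshold from ensemble scores at the
        # presences vs an evaluation background sample restricted to cells
        # with no recorded presence (known non-absence cells are masked out)
        eval_pts = self._eval_background(cfg.eval_pa_n,
                                         int(rng.integers(0, 2**31 - 1)))
        w = np.asarray(weights)
        pos = self._ensemble_scores(fitted, w, X_pres)
        neg = self._ensemble_scores(fitted, w, env_at_points(self.env, eval_pts))
        threshold = select_threshold(pos, neg)
        return EnsembleSDMResults(self, fitted, w, threshold,
                                  pd.DataFrame(cv_rows), seed)

    # -- internals --------------------------------------------------------

    def _eval_background(self, n: int, seed: int) -> np.ndarray:
        """Background evaluation points avoiding cells with a presence record."""
        grid = self.env.grid
        rng = np.random.default_rng(seed)
        rows, cols = grid.sea_indices()
        pr, pc = grid.cell_of(self.presences[:, 0], self.presences[:, 1])
        occupied = np.zeros_like(grid.sea_mask)
        occupied[pr, pc] = True
        free = ~occupied[rows, cols]
        if free.any():
            rows, cols = rows[free], cols[free]
        idx = rng.integers(0, len(rows), size=n)
        lon = grid.origin_lon + (cols[idx] + rng.random(n)) * grid.cell_size
        lat = grid.origin_lat + (rows[idx] + rng.random(n)) * grid.cell_size
        return np.column_stack([lon, lat])

    def _fit_one(self, name: str, X_pres: np.ndarray, seed: int):
        cfg = self.config
        rng = np.random.default_rng(seed)
        scheme = {"logistic_background": "background",
                  "spline_interactions": "exclusion_buffer",
                  "bagged_trees": "equal_n"}.get(name, "background")
        n_pa = cfg.pa_n.get(name, 1000)
        pa = generate_pseudo_absences(self.presences, self.env, scheme, n=n_pa,
                                      buffer_deg=cfg.buffer_deg,
                                      seed=int(rng.integers(0, 2**31 - 1)))
        X_abs = env_at_points(self.env, pa.points)
        X = np.vstack([X_pres, X_abs])
        y = np.concatenate([np.ones(len(X_pres)), np.zeros(len(X_abs))])

        aucs = []
        for _ in range(cfg.n_splits):
            tr, te = self._split(len(X_pres), len(X_abs), rng)
            learner = cfg.make_learner(name, int(rng.integers(0, 2**31 - 1)))
            learner.fit(X[tr], y[tr])
            scores = learner.predict(X[te])
            aucs.append(auc(scores[y[te] == 1], scores[y[te] == 0]))
        final = cfg.make_learner(name, int(rng.integers(0, 2**31 - 1)))
        final.fit(X, y)
        return final, float(np.mean(aucs)), aucs

    def _split(self, n_pos: int, n_neg: int, rng):
        """70/30 split stratified on presences and pseudo-absences separately."""
        frac = self.config.train_frac

        def part(n, offset):
            idx = rng.permutation(n) + offset
            k = max(1, min(n - 1, int(round(frac * n))))
            return idx[:k], idx[k:]

        tr_p, te_p = part(n_pos, 0)
        tr_a, te_a = part(n_neg, n_pos)
        return np.concatenate([tr_p, tr_a]), np.concatenate([te_p, te_a])

    @staticmethod
    def _ensemble_scores(fitted, weights, X):
        w = np.asarray(weights, dtype=float)
        if w.sum() <= 0:
            raise FitError("all-zero AUC weights")
        preds = np.column_stack([m.predict(X) for m in fitted])
        return preds @ (w / w.sum())


class EnsembleSDMResults:
    """Fitted ensemble: learners, AUC weights, threshold, CV table."""

    def __init__(self, model: EnsembleSDM, learners, weights, threshold,
                 cv_table: pd.DataFrame, seed: int):
        self.model = model
        self.species = model.species
        self.learners = list(learners)
        self.weights = np.asarray(weights, dtype=float)
        self.threshold = float(threshold)
        self.cv_table = cv_table
        self.seed = seed

    def predict(self, env: EnvStack | None = None) -> BinaryPrediction:
        """AUC-weighted ensemble probability over sea cells, binarized."""
        env = env or self.model.env
        X = env.sea_matrix()
        p = EnsembleSDM._ensemble_scores(self.learners, self.weights, X)
        prob = np.full(env.grid.sea_mask.shape, np.nan)
        prob[env.grid.sea_mask] = p
        return BinaryPrediction(env.grid, prob, self.threshold, self.species)

    def predict_at(self, points) -> np.ndarray:
        X = env_at_points(self.model.env, np.asarray(points, float))
        return EnsembleSDM._ensemble_scores(self.learners, self.weights, X)

    def summary(self) -> str:
        lines = [f"Ensemble SDM results: {self.species or '(unnamed species)'}",
                 f"  presences: {len(self.model.presences)}",
                 f"  threshold (sens = spec): {self.threshold:.3f}"]
        for m, w in zip(self.learners, self.weights):
            lines.append(f"  {m.name:<22s} weight (mean CV AUC) = {w:.3f}")
        return "\n".join(lines)


def ensemble_predict(results: EnsembleSDMResults, env: EnvStack) -> np.ndarray:
    """Weighted-mean ensemble probability per sea cell (grid-shaped, NaN land)."""
    return results.predict(env).probability


# ---------------------------------------------------------------------------
# stacking


def stack(binaries: list[BinaryPrediction], grid: GridSpec | None = None) -> np.ndarray:
    """Sum binary maps into a species-richness surface (0 on land).

    An empty list yields the all-zero map (``grid`` must then be supplied to
    define the raster).
    """
    if not binaries:
        if grid is None:
            raise ValueError("empty stack needs an explicit grid")
        return np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    grid = binaries[0].grid
    for b in binaries:
        if (b.grid.n_rows, b.grid.n_cols) != (grid.n_rows, grid.n_cols) or \
                not np.array_equal(b.grid.sea_mask, grid.sea_mask):
            raise ValueError("all binary predictions must share one grid")
    return np.sum([b.presence for b in binaries], axis=0).astype(int)


def stack_occupancy(occupancy: np.ndarray) -> np.ndarray:
    """Richness from a boolean (n_species, rows, cols) occupancy array."""
    return np.asarray(occupancy, dtype=bool).sum(axis=0).astype(int)


class StackedSDM:
    """Community-level model: one ensemble per species, summed after binarization.

    Built from a multi-species occurrence table; species with fewer than
    ``min_records`` records are not modelled (they are listed in the results'
    ``skipped``).
    """

    def __init__(self, records: pd.DataFrame, env: EnvStack,
                 config: SDMConfig | None = None, min_records: int = 21):
        self.records = records
        self.env = env
        self.config = config or SDMConfig()
        self.min_records = min_records

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, env: EnvStack, **kw):
        return cls(records, env, **kw)

    def fit(self, seed: int = 0) -> "StackedSDMResults":
        rng = np.random.default_rng(seed)
        per_species, skipped = {}, []
        for name, sub in self.records.groupby("species", sort=True):
            if len(sub) < self.min_records:
                skipped.append((str(name), len(sub)))
                continue
            model = EnsembleSDM.from_dataframe(sub, self.env, self.config,
                                               species=str(name))
            try:
                per_species[str(name)] = model.fit(int(rng.integers(0, 2**31 - 1)))
            except FitError as exc:
                warnings.warn(str(exc))
                skipped.append((str(name), len(sub)))
        return StackedSDMResults(self, per_species, skipped, seed)


class StackedSDMResults:
    def __init__(self, model: StackedSDM, per_species: dict, skipped, seed: int):
        self.model = model
        self.per_species = per_species
        self.skipped = list(skipped)
        self.seed = seed
        self._binaries = None

    @property
    def n_species_modeled(self) -> int:
        return len(self.per_species)

    def binaries(self) -> list[BinaryPrediction]:
        if self._binaries is None:
            self._binaries = [r.predict() for r in self.per_species.values()]
        return self._binaries

    def richness(self) -> np.ndarray:
        if not self.per_species:
            raise FitError("no species were modelled")
        return stack(self.binaries())

    def summary(self) -> str:
        lines = [f"Stacked SDM: {self.n_species_modeled} species modelled, "
                 f"{len(self.skipped)} below the record threshold"]
        for name, res in self.per_species.items():
            w = ", ".join(f"{m.name}={wt:.2f}" for m, wt in
                          zip(res.learners, res.weights))
            lines.append(f"  {name}: threshold={res.threshold:.3f}  {w}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class SSDMEvaluation:
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    richness_error_mean: float
    richness_error_sd: float
    per_species: pd.DataFrame


def evaluate_ssdm(binaries: dict[str, BinaryPrediction], truth: TruthSSDM,
                  eval_cells: tuple[np.ndarray, np.ndarray] | None = None) -> SSDMEvaluation:
    """Evaluate binary predictions against the truth community.

    Per-species sensitivity/specificity at the evaluation cells (defaults to
    all sea cells), summarized mean +/- SD across species; species with no
    evaluation presences (or no absences, for specificity) are excluded from
    the respective mean.  Richness error is signed (predicted - true)
    richness per evaluation cell, over the modelled species set versus the
    full truth community.
    """
    if eval_cells is None:
        eval_cells = truth.grid.sea_indices()
    rows, cols = eval_cells
    if len(rows) == 0:
        raise ValueError("evaluation cells must be non-empty")
    recs = []
    pred_rich = np.zeros(len(rows), dtype=int)
    for name, pred in binaries.items():
        s = truth.species_index(name)
        t = truth.occupancy[s, rows, cols]
        p = pred.presence[rows, cols]
        pred_rich += p.astype(int)
        sens = float((p & t).sum() / t.sum()) if t.any() else np.nan
        spec = float((~p & ~t).sum() / (~t).sum()) if (~t).any() else np.nan
        recs.append({"species": name, "sensitivity": sens, "specificity": spec})
    df = pd.DataFrame(recs)
    err = pred_rich - truth.richness[rows, cols]
    return SSDMEvaluation(
        float(np.nanmean(df["sensitivity"])), float(np.nanstd(df["sensitivity"], ddof=1)),
        float(np.nanmean(df["specificity"])), float(np.nanstd(df["specificity"], ddof=1)),
        float(err.mean()), float(err.std(ddof=1) if len(err) > 1 else 0.0),
        df)
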