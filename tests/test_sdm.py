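"""Ensemble SDM engine: AUC, thresholding, pseudo-absences, stacking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from routesdm.errors import FitError, GenerationError
from routesdm.geometry import KM_PER_DEGREE, haversine_km
from routesdm.grid import GridSpec
from routesdm.sdm import (THRESHOLD_GRID, BinaryPrediction, EnsembleSDM,
                          SDMConfig, auc, ensemble_predict, evaluate_ssdm,
                          generate_pseudo_absences, select_threshold, stack)


def brute_force_auc(pos, neg):
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_complete_tie(self):
        assert auc([0.5], [0.5]) == 0.5

    def test_pair_enumeration_example(self):
        assert auc([0.8, 0.3], [0.6, 0.1]) == pytest.approx(0.75)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1, width=32), min_size=1, max_size=25),
           st.lists(st.floats(0, 1, width=32), min_size=1, max_size=25))
    def test_matches_exhaustive_pair_enumeration(self, pos, neg):
        assert auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        pos, neg = rng.random(20), rng.random(30)
        assert auc(pos, neg) == pytest.approx(auc(np.exp(3 * pos), np.exp(3 * neg)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.1])


class TestSelectThreshold:
    def test_hand_example(self):
        # |sens - spec| = 0 on [0.201, 0.800]; smallest grid value wins
        assert select_threshold([0.9, 0.8], [0.1, 0.2]) == pytest.approx(0.201)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pos = rng.random(rng.integers(1, 12))
            neg = rng.random(rng.integers(1, 12))
            best, best_d = None, np.inf
            for t in THRESHOLD_GRID:
                sens = np.mean(pos >= t)
                spec = np.mean(neg < t)
                d = abs(sens - spec)
                if d < best_d - 1e-12:
                    best, best_d = t, d
            assert select_threshold(pos, neg) == pytest.approx(best)

    def test_degenerate_single_tied_score(self):
        t = select_threshold([0.5], [0.5])
        d = abs(np.mean(np.array([0.5]) >= t) - np.mean(np.array([0.5]) < t))
        assert d == min(abs(np.mean(np.array([0.5]) >= u) -
                            np.mean(np.array([0.5]) < u)) for u in THRESHOLD_GRID)

    def test_separated_scores_threshold_in_gap(self):
        t = select_threshold([0.7, 0.9], [0.2, 0.3])
        assert 0.3 < t <= 0.7


class TestPseudoAbsences:
    def test_oversized_buffer_fails(self, small_env):
        pres = np.column_stack(small_env.grid.sea_cell_centers())[:5]
        with pytest.raises(GenerationError):
            generate_pseudo_absences(pres, small_env, "exclusion_buffer",
                                     n=10, buffer_deg=90.0, seed=1)

    def test_points_respect_buffer(self, small_env):
        pres = np.column_stack(small_env.grid.sea_cell_centers())[::9]
        buffer_deg = 1.0
        pa = generate_pseudo_absences(pres, small_env, "exclusion_buffer",
                                      n=50, buffer_deg=buffer_deg, seed=2)
        d = haversine_km(pa.points[:, 0:1], pa.points[:, 1:2],
                         pres[None, :, 0], pres[None, :, 1]).min(axis=1)
        assert (d >= buffer_deg * KM_PER_DEGREE).all()
        assert small_env.grid.is_sea(pa.points[:, 0], pa.points[:, 1]).all()

    def test_zero_buffer_uniform_over_cells(self, small_env):
        """Chi-square uniformity of cell occupancy, pooled over 10 seeds."""
        grid = small_env.grid
        pres = np.column_stack(grid.sea_cell_centers())[:3]
        counts = np.zeros(grid.n_sea)
        rows, cols = grid.sea_indices()
        lookup = {rc: i for i, rc in enumerate(zip(rows.tolist(), cols.tolist()))}
        for seed in range(10):
            pa = generate_pseudo_absences(pres, small_env, "exclusion_buffer",
                                          n=500, buffer_deg=0.0, seed=seed)
            r, c = grid.cell_of(pa.points[:, 0], pa.points[:, 1])
            for rc in zip(r.tolist(), c.tolist()):
                counts[lookup[rc]] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_equal_n_matches_presence_count(self, small_env):
        pres = np.column_stack(small_env.grid.sea_cell_centers())[:7]
        pa = generate_pseudo_absences(pres, small_env, "equal_n", seed=3,
                                      buffer_deg=0.5)
        assert len(pa.points) == 7


class _ConstLearner:
    def __init__(self, value, name="const"):
        self.value = value
        self.name = name

    def predict(self, X):
        return np.full(len(X), self.value)


def _results_with(env, learners, weights):
    model = EnsembleSDM(np.column_stack(env.grid.sea_cell_centers())[:6], env,
                        SDMConfig.fast(), species="stub")
    from routesdm.sdm import EnsembleSDMResults
    return EnsembleSDMResults(model, learners, weights, 0.5,
                              pd.DataFrame(), seed=0)


class TestEnsemblePredict:
    def test_weighted_mean_example(self, small_env):
        res = _results_with(small_env, [_ConstLearner(0.2), _ConstLearner(0.8)],
                            [0.5, 1.0])
        p = ensemble_predict(res, small_env)
        assert p[small_env.grid.sea_mask] == pytest.approx(0.6)

    def test_equal_weights_arithmetic_mean(self, small_env):
        res = _results_with(small_env, [_ConstLearner(0.2), _ConstLearner(0.6)],
                            [0.7, 0.7])
        assert ensemble_predict(res, small_env)[small_env.grid.sea_mask] == \
            pytest.approx(0.4)

    def test_single_model_identity(self, small_env):
        res = _results_with(small_env, [_ConstLearner(0.37)], [0.9])
        assert ensemble_predict(res, small_env)[small_env.grid.sea_mask] == \
            pytest.approx(0.37)

    def test_zero_weights_invalid(self, small_env):
        res = _results_with(small_env, [_ConstLearner(0.3)], [0.0])
        with pytest.raises(FitError):
            ensemble_predict(res, small_env)

    def test_convex_combination_bounds(self, small_truth, small_env):
        """Fitted ensemble probability lies between learner extremes per cell."""
        sea_r, sea_c = small_env.grid.sea_indices()
        lon, lat = small_env.grid.sea_cell_centers()
        occ = small_truth.occupancy[0, sea_r, sea_c]
        pres = np.column_stack([lon, lat])[occ]
        res = EnsembleSDM(pres, small_env, SDMConfig.fast(), "sp0").fit(5)
        X = small_env.sea_matrix()
        per = np.column_stack([m.predict(X) for m in res.learners])
        ens = res.predict().probability[small_env.grid.sea_mask]
        assert (ens >= per.min(axis=1) - 1e-9).all()
        assert (ens <= per.max(axis=1) + 1e-9).all()


class TestEnsembleFit:
    def test_separable_species_high_cv_auc(self, small_env):
        """A species that is a hard threshold on one layer is easy to learn."""
        grid = small_env.grid
        layer = small_env.layers[small_env.layer_names[1]][grid.sea_mask]
        lon, lat = grid.sea_cell_centers()
        pres_all = np.column_stack([lon, lat])[layer > 0.55]
        aucs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            pres = pres_all[rng.choice(len(pres_all), size=min(200, len(pres_all)),
                                       replace=True)]
            res = EnsembleSDM(pres, small_env, SDMConfig.fast(), "thr").fit(seed)
            aucs.append(res.weights.mean())
        assert np.mean(aucs) >= 0.9

    def test_same_seed_identical_weights(self, small_env, small_truth):
        sea_r, sea_c = small_env.grid.sea_indices()
        lon, lat = small_env.grid.sea_cell_centers()
        occ = small_truth.occupancy[1, sea_r, sea_c]
        pres = np.column_stack([lon, lat])[occ]
        m = EnsembleSDM(pres, small_env, SDMConfig.fast(), "sp1")
        r1, r2 = m.fit(11), m.fit(11)
        np.testing.assert_array_equal(r1.weights, r2.weights)
        assert r1.threshold == r2.threshold

    def test_too_few_presences(self, small_env):
        with pytest.raises(FitError):
            EnsembleSDM(np.column_stack(small_env.grid.sea_cell_centers())[:2],
                        small_env, SDMConfig.fast()).fit(0)

    def test_binarization_consistent_with_threshold(self, small_env, small_truth):
        sea_r, sea_c = small_env.grid.sea_indices()
        lon, lat = small_env.grid.sea_cell_centers()
        occ = small_truth.occupancy[2, sea_r, sea_c]
        pres = np.column_stack([lon, lat])[occ]
        pred = EnsembleSDM(pres, small_env, SDMConfig.fast(), "sp2").fit(4).predict()
        sea = small_env.grid.sea_mask
        np.testing.assert_array_equal(pred.presence[sea],
                                      pred.probability[sea] >= pred.threshold)


def _binary(grid, presence_flags, species="s"):
    prob = np.where(np.asarray(presence_flags, bool), 1.0, 0.0).astype(float)
    return BinaryPrediction(grid, prob, 0.5, species)


class TestStack:
    def test_empty_stack_is_zero_map(self, line_grid):
        out = stack([], grid=line_grid)
        assert out.shape == (1, 3) and out.sum() == 0

    def test_shared_cell_counts_two(self, line_grid):
        b1 = _binary(line_grid, [[1, 1, 0]], "a")
        b2 = _binary(line_grid, [[0, 1, 0]], "b")
        np.testing.assert_array_equal(stack([b1, b2]), [[1, 2, 0]])

    def test_recount_oracle_and_bounds(self, small_truth):
        grid = small_truth.grid
        binaries = [_binary(grid, small_truth.occupancy[s], small_truth.names[s])
                    for s in range(small_truth.n_species)]
        rich = stack(binaries)
        assert rich.max() <= small_truth.n_species
        np.testing.assert_array_equal(rich, small_truth.richness)

    def test_grid_mismatch(self, line_grid):
        other = GridSpec(1, 3, 0, 0, 1.0, np.array([[True, True, False]]))
        with pytest.raises(ValueError):
            stack([_binary(line_grid, [[1, 0, 0]]), _binary(other, [[1, 0, 0]])])


class TestEvaluateSSDM:
    def _truth(self, line_grid):
        from routesdm.grid import TruthSSDM
        occ = np.array([[[1, 1, 0]], [[0, 1, 0]]], dtype=bool)  # richness 1,2,0
        return TruthSSDM(line_grid, [("a", "x"), ("b", "x")], occ)

    def test_perfect_prediction(self, line_grid):
        truth = self._truth(line_grid)
        binaries = {"a": _binary(line_grid, [[1, 1, 0]], "a"),
                    "b": _binary(line_grid, [[0, 1, 0]], "b")}
        ev = evaluate_ssdm(binaries, truth)
        assert ev.sensitivity_mean == 1.0 and ev.specificity_mean == 1.0
        assert ev.richness_error_mean == 0.0

    def test_inverted_prediction(self, line_grid):
        truth = self._truth(line_grid)
        binaries = {"a": _binary(line_grid, [[0, 0, 1]], "a"),
                    "b": _binary(line_grid, [[1, 0, 1]], "b")}
        ev = evaluate_ssdm(binaries, truth)
        assert ev.sensitivity_mean == 0.0 and ev.specificity_mean == 0.0

    def test_hand_computed_richness_error(self, line_grid):
        # truth richness (1,2,0), predicted (2,2,1) -> mean error 2/3
        truth = self._truth(line_grid)
        binaries = {"a": _binary(line_grid, [[1, 1, 1]], "a"),
                    "b": _binary(line_grid, [[1, 1, 0]], "b")}
        ev = evaluate_ssdm(binaries, truth)
        assert ev.richness_error_mean == pytest.approx(2 / 3)
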