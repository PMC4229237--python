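"""Weighted-Euclidean ALS fitter: stress, fit quality, weirdness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import line_stack
from spamscale.proximity import ItemSet, ProximityMatrix, ProximityStack
from spamscale.scaling import (
    ScalingConfig,
    fit,
    model_distances,
    profile,
    rsq,
    stress1,
    weirdness,
    _subject_distances,
)
from spamscale.simulate import NullSpec, StructuredSpec, gen_null_stack, gen_structured_stack

TIGHT = dict(stress_delta_tol=1e-9, stress_floor=1e-7, max_iter=300)


class TestModelDistances:
    def test_unit_weights_euclidean(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        d = model_distances(X, np.ones(2))
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_zero_weight_projects_out_dimension(self):
        X = np.array([[0.0, 10.0], [3.0, -7.0], [6.0, 2.0]])
        d = model_distances(X, np.array([1.0, 0.0]))
        expected = np.abs(X[:, [0]] - X[:, 0])
        np.testing.assert_allclose(d, expected, atol=1e-12)

    def test_matches_per_pair_brute_force(self, rng):
        X = rng.normal(size=(6, 2))
        for w in (np.array([4.0, 1.0]), np.array([1.0, 1.0])):
            d = model_distances(X, w)
            for i in range(6):
                for j in range(6):
                    ref = np.sqrt(np.sum(w * (X[i] - X[j]) ** 2))
                    assert d[i, j] == pytest.approx(ref, abs=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            model_distances(np.zeros((3, 2)), np.array([1.0, -0.5]))


class TestStress1:
    def test_perfect_match_is_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        assert stress1(v, v) == 0.0

    def test_hand_computed_toy_vector(self):
        # disparities (1,2,3) against distances (2,4,6):
        # sqrt(((1)^2+(2)^2+(3)^2) / (4+16+36)) = sqrt(14/56) = 1/2
        assert stress1(np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])) == pytest.approx(0.5)

    def test_all_zero_model_distances_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            stress1(np.array([1.0, 2.0]), np.zeros(2))


class TestWeirdness:
    def test_group_average_direction_scores_zero(self, rng):
        rest = rng.uniform(0.5, 2.0, size=(7, 3))
        unit = rest / np.linalg.norm(rest, axis=1, keepdims=True)
        # a subject whose profile points along the group-average weight
        # direction scores exactly zero
        W = np.vstack([2.5 * unit.mean(axis=0), rest])
        assert weirdness(W)[0] == pytest.approx(0.0, abs=1e-6)

    def test_proportional_rows_all_zero(self):
        base = np.array([1.0, 2.0, 0.5])
        W = np.outer([1.0, 3.0, 0.2], base)
        np.testing.assert_allclose(weirdness(W), 0.0, atol=1e-6)

    def test_symmetric_axes_get_equal_positive_scores(self):
        W = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])
        s = weirdness(W)
        assert s[0] == pytest.approx(s[2])
        assert s[0] > 0
        assert s[1] == pytest.approx(0.0, abs=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(arrays(float, (6, 3), elements=st.floats(0.01, 10.0)),
           st.floats(0.1, 50.0), st.integers(0, 5))
    def test_range_and_row_scale_invariance(self, W, c, row):
        s = weirdness(W)
        assert np.all((s >= 0) & (s <= 1))
        # rescaling one subject's row leaves every score unchanged: only
        # the direction of a weight profile matters
        W2 = W.copy()
        W2[row] *= c
        np.testing.assert_allclose(weirdness(W2), s, atol=1e-6)

    def test_all_zero_row_rejected(self):
        W = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="all-zero"):
            weirdness(W)


class TestFit:
    def test_perfect_recovery_from_planted_structure(self, rng):
        Xs = rng.normal(size=(10, 2))
        Ws = rng.uniform(0.5, 2.0, size=(6, 2))
        stack = gen_structured_stack(StructuredSpec(X=Xs, W=Ws, noise_sd=0.0, seed=5))
        sol = fit(stack, ScalingConfig(dims=2, **TIGHT))
        assert sol.stress1 <= 1e-3
        assert sol.rsq >= 0.999
        # model distances reproduce the generating distances up to the
        # per-subject ratio slope
        d_fit = _subject_distances(sol.X, sol.W)
        d_true = stack.condensed()
        b = (d_true * d_fit).sum(1) / (d_true**2).sum(1)
        rel = np.abs(d_fit - b[:, None] * d_true) / np.maximum(b[:, None] * d_true, 1e-12)
        assert rel.max() <= 1e-3

    def test_stress_path_monotone_nonincreasing(self):
        stack = gen_null_stack(NullSpec(method="spam", seed=9), np.random.default_rng(9))
        for k in (1, 3, 5):
            sol = fit(stack, ScalingConfig(dims=k))
            path = np.array(sol.stress_path)
            assert np.all(np.diff(path) <= 1e-12)
            assert sol.stress1 == pytest.approx(path[-1])

    def test_1d_line_fit_matches_grid_search_oracle(self):
        """ALS finds the global optimum for a tiny 1-D problem.

        Data are genuine line distances (positions 0, 1, 3, 7), so the
        global stress-1 minimum is 0; a dense grid search over
        configurations (scale fixed by pinning the extremes, slope
        optimised per configuration) bounds it from above.
        """
        stack = line_stack([0.0, 1.0, 3.0, 7.0])
        delta = stack.condensed()[0]

        # brute-force oracle: x0=0, x3=1 (scale/translation freedom),
        # grid over the two interior coordinates
        grid = np.linspace(0.0, 1.0, 201)
        a, b_ = np.meshgrid(grid, grid, indexing="ij")
        best = np.inf
        pos = np.stack([np.zeros_like(a), a, b_, np.ones_like(a)], axis=-1)
        iu, ju = np.triu_indices(4, k=1)
        d = np.abs(pos[..., iu] - pos[..., ju])
        slope = (delta * d).sum(-1) / (delta**2).sum()
        resid = slope[..., None] * delta - d
        stress = np.sqrt((resid**2).sum(-1) / np.maximum((d**2).sum(-1), 1e-300))
        grid_min = float(stress.min())
        assert grid_min <= 0.02  # the grid resolves the optimum closely

        sol = fit(stack, ScalingConfig(dims=1, **TIGHT))
        assert sol.stress1 <= grid_min + 1e-3

    def test_dims_at_least_n_items_rejected(self, small_items):
        vals = np.ones((5, 5)) - np.eye(5)
        stack = ProximityStack(small_items, (ProximityMatrix("s1", small_items, vals),))
        with pytest.raises(ValueError, match="dims"):
            fit(stack, ScalingConfig(dims=5))

    def test_all_zero_matrix_rejected(self, small_items):
        stack = ProximityStack(
            small_items, (ProximityMatrix("s1", small_items, np.zeros((5, 5))),)
        )
        with pytest.raises(ValueError, match="all-zero"):
            fit(stack, ScalingConfig(dims=2))

    def test_all_equal_distances_degenerate_warns(self, small_items):
        vals = np.ones((5, 5)) - np.eye(5)
        stack = ProximityStack(small_items, (ProximityMatrix("s1", small_items, vals),))
        with pytest.warns(UserWarning, match="equal"):
            sol = fit(stack, ScalingConfig(dims=2, seed=11))
        assert sol.stop_reason == "degenerate"
        assert sol.X.shape == (5, 2)

    def test_weights_nonnegative_and_axes_ordered(self):
        stack = gen_null_stack(NullSpec(method="spam", seed=21), np.random.default_rng(21))
        sol = fit(stack, ScalingConfig(dims=3))
        assert np.all(sol.W >= 0)
        mean_w = sol.W.mean(axis=0)
        assert np.all(np.diff(mean_w) <= 1e-9)  # dimension 1 is primary
        # columns have unit mean square
        np.testing.assert_allclose(np.mean(sol.X**2, axis=0), 1.0, atol=1e-9)


class TestRsq:
    def test_perfect_fit_gives_one(self, rng):
        Xs = rng.normal(size=(8, 2))
        Ws = rng.uniform(0.5, 2.0, size=(4, 2))
        stack = gen_structured_stack(StructuredSpec(X=Xs, W=Ws, noise_sd=0.0, seed=2))
        sol = fit(stack, ScalingConfig(dims=2, **TIGHT))
        assert rsq(sol, stack) == pytest.approx(1.0, abs=1e-6)

    def test_nondecreasing_in_dimensionality_on_average(self):
        """More dimensions cannot explain less variance, in expectation."""
        curves = []
        for seed in range(5):
            stack = gen_null_stack(
                NullSpec(method="spam", n_items=12, n_subjects=8, seed=seed),
                np.random.default_rng(seed),
            )
            prof = profile(stack, dims=(1, 2, 3, 4), cfg=ScalingConfig(seed=seed))
            curves.append([prof.rsq_by_dim[k] for k in (1, 2, 3, 4)])
        mean_curve = np.mean(curves, axis=0)
        assert np.all(np.diff(mean_curve) >= -1e-6)


class TestProfile:
    def test_planted_3d_scree_shape(self):
        """A 3-D planted structure shows its elbow: the largest stress
        drop is from 1 to 2 dimensions and fit plateaus beyond 3."""
        drops_12, plateaus = [], []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            Xs = rng.normal(size=(12, 3)) * 2.0
            Ws = rng.uniform(0.8, 1.2, size=(8, 3))
            stack = gen_structured_stack(
                StructuredSpec(X=Xs, W=Ws, noise_sd=0.1, seed=seed)
            )
            prof = profile(stack, cfg=ScalingConfig(seed=seed))
            s = [prof.stress_by_dim[k] for k in (1, 2, 3, 4, 5)]
            drops_12.append(s[0] - s[1])
            plateaus.append(s[2] - s[4])
        assert np.mean(drops_12) > 4 * np.mean(plateaus)

    def test_contains_each_dimensionality_once(self):
        stack = gen_null_stack(
            NullSpec(method="pairwise", n_items=10, n_subjects=5, seed=1),
            np.random.default_rng(1),
        )
        prof = profile(stack, dims=(1, 2, 3), cfg=ScalingConfig(seed=1))
        assert prof.dims == [1, 2, 3]
        assert set(prof.stress_by_dim) == {1, 2, 3}
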