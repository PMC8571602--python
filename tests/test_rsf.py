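"""Weighted RSF estimation, suitability prediction, and map comparison."""

import numpy as np
import pandas as pd
import pytest

from rsfdebias.grids import CovariateStack, Grid
from rsfdebias.observer import LogisticFit
from rsfdebias.rsf import (
    SuitabilityMap,
    build_design,
    fit_three_models,
    fit_weighted_rsf,
    map_correlation,
    predict_suitability,
)
from rsfdebias.sampling import compute_mcp, sample_random_availability
from rsfdebias.simulate import sample_points


@pytest.fixture(scope="module")
def gradient_stack():
    rng = np.random.default_rng(0)
    x = np.tile(np.linspace(0, 1, 50), (50, 1))
    return CovariateStack({"x_grad": Grid(x), "noise": Grid(rng.uniform(0, 1, (50, 50)))})


def make_fit(terms, coefficients, intercept=0.0, transform_log=None):
    k = len(terms)
    return LogisticFit(terms=list(terms), intercept=intercept,
                       coefficients=list(coefficients), standard_errors=[0.0] * k,
                       vcov=np.zeros((k + 1, k + 1)), n_cases=1, n_controls=1,
                       converged=True, transform_log=transform_log or {})


class TestBuildDesign:
    def test_row_counts_and_weights(self, gradient_stack):
        use = pd.DataFrame({"x": np.full(10, 5.5), "y": np.full(10, 5.5)})
        avail = pd.DataFrame({"x": np.full(30, 20.5), "y": np.full(30, 20.5)})
        design = build_design(use, avail, gradient_stack, ["x_grad"])
        assert len(design.X) == 40
        assert design.response.sum() == 10
        np.testing.assert_array_equal(np.unique(design.weights), [1.0, 100.0])
        assert (design.weights == 100.0).sum() == 30

    def test_log_transform_applied_except_excluded(self, gradient_stack):
        use = pd.DataFrame({"x": [10.5], "y": [10.5]})
        avail = pd.DataFrame({"x": [30.5], "y": [30.5]})
        eps = 0.01
        design = build_design(use, avail, gradient_stack, ["x_grad", "noise"],
                              transform_log={"x_grad": eps})
        raw_use = gradient_stack["x_grad"].value_at(np.array([10.5]), np.array([10.5]))[0]
        assert design.X["x_grad"].iloc[0] == pytest.approx(np.log(raw_use + eps))
        raw_noise = gradient_stack["noise"].value_at(np.array([10.5]), np.array([10.5]))[0]
        assert design.X["noise"].iloc[0] == raw_noise  # untransformed

    def test_zero_distance_transform_finite(self, gradient_stack):
        use = pd.DataFrame({"x": [0.2], "y": [0.2]})  # x_grad = 0 at left edge
        avail = pd.DataFrame({"x": [30.5], "y": [30.5]})
        design = build_design(use, avail, gradient_stack, ["x_grad"],
                              transform_log={"x_grad": 0.01})
        assert np.isfinite(design.X["x_grad"]).all()

    def test_empty_availability_raises(self, gradient_stack):
        use = pd.DataFrame({"x": [5.5], "y": [5.5]})
        with pytest.raises(ValueError, match="availability"):
            build_design(use, use.iloc[:0], gradient_stack, ["x_grad"])


class TestFitWeightedRSF:
    def test_null_selection_slopes_near_zero(self, gradient_stack):
        # use and availability both uniform -> slope within 2 SE of 0 in
        # >= 90% of seeds
        domain = compute_mcp(pd.DataFrame({"x": [0, 50, 50, 0], "y": [0, 0, 50, 50]}))
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            use = sample_random_availability(domain, 150, seed=seed)
            avail = sample_random_availability(domain, 1500, seed=500 + seed)
            fit = fit_weighted_rsf(build_design(use, avail, gradient_stack, ["x_grad"]))
            hits += abs(fit.coef("x_grad")) < 2 * fit.se("x_grad")
        assert hits >= 0.9 * n_seeds

    def test_recovers_exponential_selection_coefficient(self, gradient_stack):
        # use points sampled with density proportional to exp(2x) against
        # uniform availability: the RSF slope estimates 2
        beta_true = 2.0
        weight = Grid(np.exp(beta_true * gradient_stack["x_grad"].values))
        ests = []
        for seed in range(20):
            use = sample_points(weight, 400, seed=seed)
            avail = sample_points(Grid(np.ones((50, 50))), 4000, seed=900 + seed)
            fit = fit_weighted_rsf(build_design(use, avail, gradient_stack, ["x_grad"]))
            ests.append(fit.coef("x_grad"))
        assert np.mean(ests) == pytest.approx(beta_true, abs=0.1)

    def test_weight_100_matches_large_unweighted_availability(self, gradient_stack):
        # infinitely weighted likelihood (W=100, 3x availability) agrees with
        # an unweighted fit against 20x availability within combined SEs
        weight = Grid(np.exp(1.5 * gradient_stack["x_grad"].values))
        use = sample_points(weight, 300, seed=1)
        avail_3x = sample_points(Grid(np.ones((50, 50))), 900, seed=2)
        avail_20x = sample_points(Grid(np.ones((50, 50))), 6000, seed=3)
        fit_w = fit_weighted_rsf(build_design(use, avail_3x, gradient_stack, ["x_grad"],
                                              background_weight=100.0))
        fit_u = fit_weighted_rsf(build_design(use, avail_20x, gradient_stack, ["x_grad"],
                                              background_weight=1.0))
        diff = abs(fit_w.coef("x_grad") - fit_u.coef("x_grad"))
        assert diff < 2 * np.hypot(fit_w.se("x_grad"), fit_u.se("x_grad"))

    def test_estimates_invariant_to_weight_scaling(self, gradient_stack):
        weight = Grid(np.exp(gradient_stack["x_grad"].values))
        use = sample_points(weight, 200, seed=4)
        avail = sample_points(Grid(np.ones((50, 50))), 600, seed=5)
        d1 = build_design(use, avail, gradient_stack, ["x_grad"], background_weight=100.0)
        d2 = build_design(use, avail, gradient_stack, ["x_grad"], background_weight=100.0)
        d2.weights = d2.weights * 3.0  # scale *all* weights
        f1, f2 = fit_weighted_rsf(d1), fit_weighted_rsf(d2)
        assert f1.coef("x_grad") == pytest.approx(f2.coef("x_grad"), abs=1e-6)

    def test_availability_size_stabilizes_estimates(self, gradient_stack):
        # naive-availability fits converge: 10x vs 30x estimates differ < 0.05
        weight = Grid(np.exp(1.2 * gradient_stack["x_grad"].values))
        use = sample_points(weight, 400, seed=6)
        diffs = []
        for seed in range(5):
            a10 = sample_points(Grid(np.ones((50, 50))), 4000, seed=100 + seed)
            a30 = sample_points(Grid(np.ones((50, 50))), 12000, seed=200 + seed)
            f10 = fit_weighted_rsf(build_design(use, a10, gradient_stack, ["x_grad"]))
            f30 = fit_weighted_rsf(build_design(use, a30, gradient_stack, ["x_grad"]))
            diffs.append(abs(f10.coef("x_grad") - f30.coef("x_grad")))
        assert np.mean(diffs) < 0.05

    def test_constant_response_raises(self, gradient_stack):
        use = pd.DataFrame({"x": [5.5, 6.5], "y": [5.5, 6.5]})
        design = build_design(use, use, gradient_stack, ["x_grad"])
        design.response[:] = 1.0
        with pytest.raises(ValueError):
            fit_weighted_rsf(design)


class TestFitThreeModels:
    def test_identical_availability_gives_identical_naive_and_corrected(self, gradient_stack):
        rng = np.random.default_rng(9)
        weight = Grid(np.exp(gradient_stack["x_grad"].values))
        tel = sample_points(weight, 150, seed=10)
        opp = sample_points(weight, 100, seed=11)
        avail = sample_points(Grid(np.ones((50, 50))), 1000, seed=12)
        fits = fit_three_models(tel, opp, avail, avail, avail, gradient_stack, ["x_grad"])
        assert fits["naive"].coef("x_grad") == fits["corrected"].coef("x_grad")
        assert [f.terms for f in fits.values()] == [["x_grad"]] * 3


class TestPredictSuitability:
    def test_zero_coefficients_constant_map(self, gradient_stack):
        fit = make_fit(["x_grad"], [0.0], intercept=-1.5)
        smap = predict_suitability(fit, gradient_stack)
        np.testing.assert_allclose(smap.values, -1.5)

    def test_hand_computed_log_transformed_cells(self, gradient_stack):
        eps = 0.01
        fit = make_fit(["x_grad"], [2.0], intercept=0.5, transform_log={"x_grad": eps})
        smap = predict_suitability(fit, gradient_stack)
        vals = gradient_stack["x_grad"].values
        for i, j in [(0, 0), (10, 25), (49, 49)]:
            assert smap.values[i, j] == pytest.approx(0.5 + 2.0 * np.log(vals[i, j] + eps))

    def test_mask_sets_nodata_outside(self, gradient_stack):
        fit = make_fit(["x_grad"], [1.0])
        mask = compute_mcp(pd.DataFrame({"x": [0, 25, 25, 0], "y": [0, 0, 50, 50]}))
        smap = predict_suitability(fit, gradient_stack, mask=mask)
        assert smap.grid.nodata_mask is not None
        assert smap.grid.nodata_mask[25, 40]      # right half excluded
        assert not smap.grid.nodata_mask[25, 10]  # left half inside

    def test_missing_layer_raises(self, gradient_stack):
        fit = make_fit(["absent"], [1.0])
        with pytest.raises(KeyError, match="absent"):
            predict_suitability(fit, gradient_stack)


class TestMapCorrelation:
    def wrap(self, values, mask=None):
        return SuitabilityMap(Grid(np.asarray(values, float), nodata_mask=mask), fit=None)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        a = self.wrap(rng.normal(size=(4, 4)))
        assert map_correlation(a, a) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(4, 4))
        assert map_correlation(self.wrap(v), self.wrap(-v)) == pytest.approx(-1.0)

    def test_two_by_two_textbook_formula(self):
        # x = {1,2,3,4}, y = {2,4,5,9}: r = 11 / sqrt(5 * 26) = 0.964764...
        a = self.wrap([[1.0, 2.0], [3.0, 4.0]])
        b = self.wrap([[2.0, 4.0], [5.0, 9.0]])
        assert map_correlation(a, b) == pytest.approx(11 / np.sqrt(130), abs=1e-12)

    def test_joint_mask_respected(self):
        mask_a = np.zeros((2, 2), bool)
        mask_a[0, 0] = True
        a = self.wrap([[99.0, 2.0], [3.0, 4.0]], mask=mask_a)
        b = self.wrap([[2.0, 4.0], [5.0, 9.0]])
        # correlation over the 3 jointly valid cells only
        expected = np.corrcoef([2, 3, 4], [4, 5, 9])[0, 1]
        assert map_correlation(a, b) == pytest.approx(expected)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            map_correlation(self.wrap(np.ones((2, 2))), self.wrap([[1.0, 2.0], [3.0, 4.0]]))
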