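import math
import warnings

import numpy as np
import pytest

import allelewave as aw
from allelewave.inference import (
    AnnealConfig,
    FitConfig,
    ParameterBounds,
    SurfaceLikelihood,
    anneal_fit,
    default_origin_candidates,
    fisher_ci_from_loglik,
    fisher_confints,
    fit,
    lhs_starts,
    profile_allele_age,
    refine_fit,
    theta_to_epochs,
)
from allelewave.likelihood import Dataset, Observation
from allelewave.pde import ModelSpec
from allelewave.simulate import SamplingDesign, sample_from_surface

GEN = 29.0

SMALL_CFG = FitConfig(
    n_starts=3,
    anneal=AnnealConfig(iters=15),
    lbfgs_maxfun=40,
    output_dt=4.0,
)


@pytest.fixture(scope="module")
def toy_problem():
    """Single land region, single epoch, informative simulated data."""
    ls = aw.Landscape.from_mask(np.ones((10, 10), bool))
    total = 150.0
    spec = ModelSpec(variant="A", allele_age_years_bp=total * GEN,
                     origin_cell=(5, 5), epoch_boundary_years_bp=0.0)
    truth = theta_to_epochs(np.array([0.05, 30.0]), spec)
    surf = aw.solve_surface(ls, spec, truth, np.linspace(0, total, 40))
    design = SamplingDesign(n_samples=300, seed=7, age_max_years_bp=total * GEN * 0.9,
                            temporal_split=0.5)
    data = sample_from_surface(surf, design, epoch_boundary=2000.0)
    return ls, spec, data


class TestLhsStarts:
    def test_paper_default_count(self):
        b = np.array([[0.001, 0.1], [1.0, 100.0]])
        starts = lhs_starts(b, 50, seed=1)
        assert starts.shape == (50, 2)

    def test_stratification(self):
        b = np.array([[0.0, 1.0], [10.0, 20.0]])
        n = 16
        starts = lhs_starts(b, n, seed=3)
        for j, (lo, hi) in enumerate(b):
            strata = np.floor((starts[:, j] - lo) / (hi - lo) * n).astype(int)
            assert sorted(strata) == list(range(n))  # one point per stratum

    def test_single_point_within_bounds(self):
        b = np.array([[-2.5, 2.5]])
        (pt,) = lhs_starts(b, 1, seed=0)
        assert -2.5 <= pt[0] <= 2.5

    def test_determinism(self):
        b = np.array([[0.001, 0.1], [1.0, 100.0], [-2.5, 2.5]])
        assert np.array_equal(lhs_starts(b, 9, 11), lhs_starts(b, 9, 11))

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            lhs_starts(np.array([[1.0, 1.0]]), 5, 0)


class _FakeEvaluator:
    """Quadratic log-likelihood peaked at a known theta; duck-types loglik."""

    def __init__(self, peak, curvature=(1e4, 1.0)):
        self.peak = np.asarray(peak, dtype=float)
        self.curvature = np.asarray(curvature, dtype=float)
        self.ids = ["x"]

    def loglik(self, origin, theta):
        d = np.asarray(theta, dtype=float) - self.peak
        return -0.5 * float(self.curvature @ (d * d))


class TestAnnealFit:
    def test_recovers_selection_within_grid_oracle(self, toy_problem):
        ls, spec, data = toy_problem
        bounds = ParameterBounds(sigma2=(29.999, 30.001))  # s effectively free
        cfg = FitConfig(n_starts=4, anneal=AnnealConfig(iters=25), output_dt=4.0)
        ev = SurfaceLikelihood(data, ls, spec, cfg)
        starts = lhs_starts(bounds.layout("A", 1)[1], 4, seed=2)
        origin, theta, ll = anneal_fit(
            data, ls, spec, starts, [(5, 5)], seed=2, bounds=bounds,
            config=cfg, evaluator=ev,
        )
        # brute-force 1-D grid scan over s at fixed sigma
        grid = np.linspace(0.001, 0.1, 60)
        lls = [ev.loglik((5, 5), np.array([s, 30.0])) for s in grid]
        s_star = grid[int(np.argmax(lls))]
        assert abs(theta[0] - s_star) / s_star < 0.10

    def test_start_containing_optimum_never_worse(self, toy_problem):
        ls, spec, data = toy_problem
        bounds = ParameterBounds()
        cfg = SMALL_CFG
        ev = SurfaceLikelihood(data, ls, spec, cfg)
        good = np.array([0.05, 30.0])
        ll_good = ev.loglik((5, 5), good)
        _, _, ll = anneal_fit(data, ls, spec, np.array([good]), [(5, 5)],
                              seed=0, bounds=bounds, config=cfg, evaluator=ev)
        assert ll >= ll_good

    def test_single_origin_candidate_returned(self, toy_problem):
        ls, spec, data = toy_problem
        origin, _, _ = anneal_fit(
            data, ls, spec, np.array([[0.03, 20.0]]), [(4, 4)], seed=0,
            config=SMALL_CFG,
        )
        assert origin == (4, 4)

    def test_water_candidate_rejected(self, toy_problem):
        ls, spec, data = toy_problem
        mask = ls.land_mask.copy()
        mask[0, 0] = False
        ls2 = aw.Landscape.from_mask(mask)
        with pytest.raises(ValueError, match="water"):
            anneal_fit(data, ls2, spec, np.array([[0.03, 20.0]]), [(0, 0)],
                       seed=0, config=SMALL_CFG)


class TestRefineFit:
    def test_quadratic_converges_to_analytic_maximum(self, toy_problem):
        ls, spec, data = toy_problem
        peak = np.array([0.042, 55.0])
        ev = _FakeEvaluator(peak, curvature=(1e6, 10.0))
        incumbent = ((5, 5), np.array([0.03, 40.0]), ev.loglik(None, [0.03, 40.0]))
        cfg = FitConfig(lbfgs_eps=1e-7, lbfgs_maxfun=300)
        theta, ll, flags = refine_fit(data, ls, spec, incumbent,
                                      config=cfg, evaluator=ev)
        assert abs(theta[0] - peak[0]) < 1e-6
        assert abs(theta[1] - peak[1]) < 1e-3
        assert not flags["refine_failed"]

    def test_boundary_optimum_flagged(self, toy_problem):
        ls, spec, data = toy_problem

        class Linear(_FakeEvaluator):
            def loglik(self, origin, theta):
                return float(theta[0])  # increasing in s: optimum at s upper bound

        ev = Linear([0.0, 0.0])
        incumbent = ((5, 5), np.array([0.09, 50.0]), 0.09)
        theta, ll, flags = refine_fit(data, ls, spec, incumbent,
                                      config=SMALL_CFG, evaluator=ev)
        assert theta[0] == pytest.approx(0.1)
        assert "e0.s" in flags["at_boundary"]

    def test_refit_from_refined_point_is_stable(self, toy_problem):
        ls, spec, data = toy_problem
        ev = _FakeEvaluator([0.05, 30.0])
        incumbent = ((5, 5), np.array([0.02, 10.0]), ev.loglik(None, [0.02, 10.0]))
        theta1, ll1, _ = refine_fit(data, ls, spec, incumbent,
                                    config=SMALL_CFG, evaluator=ev)
        theta2, ll2, _ = refine_fit(data, ls, spec, ((5, 5), theta1, ll1),
                                    config=SMALL_CFG, evaluator=ev)
        assert ll2 - ll1 < 1e-6

    def test_nonfinite_incumbent_rejected(self, toy_problem):
        ls, spec, data = toy_problem
        with pytest.raises(ValueError, match="finite"):
            refine_fit(data, ls, spec, ((5, 5), np.array([0.05, 30.0]), -math.inf))


class TestFisherCI:
    def test_binomial_matches_textbook_formula(self):
        n, k = 400, 130
        p_hat = k / n

        def ll(theta):
            p = theta[0]
            return k * math.log(p) + (n - k) * math.log(1.0 - p)

        lo, hi = fisher_ci_from_loglik(ll, np.array([p_hat]), rel_step=1e-3)
        se = math.sqrt(p_hat * (1 - p_hat) / n)
        assert lo[0] == pytest.approx(p_hat - 1.96 * se, abs=1e-4)
        assert hi[0] == pytest.approx(p_hat + 1.96 * se, abs=1e-4)

    def test_flat_parameter_gives_nan(self):
        def ll(theta):
            return -0.5 * 1e4 * theta[0] ** 2  # theta[1] flat

        with pytest.warns(RuntimeWarning):
            lo, hi = fisher_ci_from_loglik(ll, np.array([0.01, 5.0]))
        assert np.isnan(lo[1]) and np.isnan(hi[1])
        assert np.isfinite(lo[0]) and np.isfinite(hi[0])

    def test_ci_contains_estimate(self):
        def ll(theta):
            d = theta - np.array([0.3, 1.7])
            return -50.0 * float(d @ d)

        lo, hi = fisher_ci_from_loglik(ll, np.array([0.3, 1.7]))
        assert np.all(lo <= np.array([0.3, 1.7])) and np.all(hi >= np.array([0.3, 1.7]))

    def test_full_pipeline_cis(self, toy_problem):
        ls, spec, data = toy_problem
        cis = fisher_confints(data, ls, spec, np.array([0.05, 30.0]), (5, 5),
                              config=SMALL_CFG)
        assert set(cis) == {"e0.s", "e0.sigma2"}
        lo, hi = cis["e0.s"]
        assert lo <= 0.05 <= hi


class TestFit:
    def test_zero_diffusion_matches_logistic_grid_mle(self):
        # single land cell: diffusion is inert and the fit reduces to the
        # logistic trajectory at the origin
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        ls = aw.Landscape.from_mask(mask)
        total = 200.0
        spec = ModelSpec(variant="A", allele_age_years_bp=total * GEN,
                         origin_cell=(1, 1), epoch_boundary_years_bp=0.0)
        truth = theta_to_epochs(np.array([0.06, 10.0]), spec)
        surf = aw.solve_surface(ls, spec, truth, np.linspace(0, total, 50))
        design = SamplingDesign(n_samples=250, seed=5,
                                age_max_years_bp=total * GEN * 0.9)
        data = sample_from_surface(surf, design, epoch_boundary=1000.0)
        cfg = FitConfig(n_starts=3, anneal=AnnealConfig(iters=20),
                        lbfgs_maxfun=60, output_dt=4.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit(data, ls, spec, config=cfg, seed=4,
                      origin_candidates=[(1, 1)])
        ev = SurfaceLikelihood(data, ls, spec, cfg)
        grid = np.linspace(0.001, 0.1, 80)
        lls = [ev.loglik((1, 1), np.array([s, 10.0])) for s in grid]
        s_star = grid[int(np.argmax(lls))]
        assert abs(res.estimates["e0.s"] - s_star) <= 2 * (grid[1] - grid[0])

    def test_determinism(self, toy_problem):
        ls, spec, data = toy_problem
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit(data, ls, spec, config=SMALL_CFG, seed=9,
                    origin_candidates=[(5, 5), (2, 2)])
            b = fit(data, ls, spec, config=SMALL_CFG, seed=9,
                    origin_candidates=[(5, 5), (2, 2)])
        assert a.estimates == b.estimates
        assert a.origin_cell == b.origin_cell
        assert a.loglik == b.loglik

    def test_loglik_nondecreasing_through_stages(self, toy_problem):
        ls, spec, data = toy_problem
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit(data, ls, spec, config=SMALL_CFG, seed=3,
                      origin_candidates=[(5, 5), (7, 2)])
        assert res.loglik >= res.trace["anneal_loglik"]

    def test_estimates_within_bounds(self, toy_problem):
        ls, spec, data = toy_problem
        bounds = ParameterBounds()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit(data, ls, spec, bounds=bounds, config=SMALL_CFG, seed=3,
                      origin_candidates=[(5, 5)])
        names, barr = bounds.layout("A", 1)
        for n, (lo, hi) in zip(names, barr):
            assert lo - 1e-12 <= res.estimates[n] <= hi + 1e-12

    def test_empty_dataset_rejected(self, toy_problem):
        ls, spec, _ = toy_problem
        with pytest.raises(ValueError, match="empty"):
            fit(Dataset([]), ls, spec, config=SMALL_CFG)


class TestSigmaParameterisation:
    def test_sigma_scale_layout_names_and_bounds(self):
        b = ParameterBounds(sigma_param="sigma", sigma=(1.0, 100.0))
        names, arr = b.layout("B", 1)
        assert names == ["e0.s", "e0.sigma_x", "e0.sigma_y"]
        assert arr[1].tolist() == [1.0, 100.0]

    def test_theta_unpacking_squares_sigma(self):
        spec = ModelSpec(variant="B", allele_age_years_bp=100 * GEN,
                         origin_cell=(0, 0), epoch_boundary_years_bp=0.0)
        eps = theta_to_epochs(np.array([0.05, 20.0, 10.0]), spec, "sigma")
        assert eps[0].sigma_x ** 2 == pytest.approx(400.0)
        assert eps[0].sigma_y ** 2 == pytest.approx(100.0)


class TestProfileAge:
    def test_single_age_equals_fit(self, toy_problem):
        ls, spec, data = toy_problem
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit(data, ls, spec, config=SMALL_CFG, seed=6,
                      origin_candidates=[(5, 5)])
            prof = profile_allele_age(data, ls, spec,
                                      [spec.allele_age_years_bp],
                                      config=SMALL_CFG, seed=6,
                                      origin_candidates=[(5, 5)])
        assert prof[spec.allele_age_years_bp]["loglik"] == pytest.approx(
            res.loglik
        )

    def test_age_younger_than_oldest_sample_flagged(self, toy_problem):
        ls, spec, data = toy_problem
        oldest = max(o.age_years_bp for o in data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = profile_allele_age(data, ls, spec, [oldest / 10.0],
                                      config=SMALL_CFG, seed=6,
                                      origin_candidates=[(5, 5)])
        entry = prof[oldest / 10.0]
        assert entry["loglik"] == -math.inf
        assert "error" in entry

    def test_no_ages_rejected(self, toy_problem):
        ls, spec, data = toy_problem
        with pytest.raises(ValueError):
            profile_allele_age(data, ls, spec, [])


class TestOriginCandidates:
    def test_default_lattice_all_land(self, europe_grid):
        cand = default_origin_candidates(europe_grid)
        assert len(cand) == 9 * 18
        assert all(europe_grid.land_mask[r, c] for r, c in cand)

    def test_no_land_rejected(self):
        ls = aw.Landscape.from_mask(np.zeros((5, 5), bool))
        with pytest.raises(ValueError, match="no land"):
            default_origin_candidates(ls)
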