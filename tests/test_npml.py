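"""Nonparametric population estimation: grids, weights, fit, posteriors."""

import dataclasses
import math

import numpy as np
import pytest

from csfclear.model import AssayErrorModel, DoseEvent, PKParameters
from csfclear.npml import (
    DEFAULT_BOUNDS,
    FitConfig,
    PopulationModel,
    SupportPoint,
    condense,
    expand,
    fit,
    information_criteria,
    init_grid,
    model_from_json,
    model_to_json,
    optimize_weights,
    posterior_individual,
)
from csfclear.simulate import simulate_cohort

from conftest import make_subject, ref_only_config

ERR = AssayErrorModel()


class TestInitGrid:
    def test_single_point_within_bounds(self):
        pts = init_grid(DEFAULT_BOUNDS, 1, seed=0)
        assert len(pts) == 1
        p = pts[0]
        for name in ("ka", "tlag", "v", "ke", "kcp", "kpc"):
            lo, hi = DEFAULT_BOUNDS[name]
            assert lo <= getattr(p, name) <= hi

    def test_deterministic_given_seed(self):
        a = init_grid(DEFAULT_BOUNDS, 50, seed=123)
        b = init_grid(DEFAULT_BOUNDS, 50, seed=123)
        assert all(x == y for x, y in zip(a, b))

    def test_quartile_coverage_at_n_1000(self):
        """Each dimension's quartiles all receive points (counting oracle)."""
        pts = init_grid(DEFAULT_BOUNDS, 1000, seed=5)
        arr = np.array([p.as_array("two_compartment") for p in pts])
        for dim, name in enumerate(("ka", "tlag", "v", "ke", "kcp", "kpc")):
            lo, hi = DEFAULT_BOUNDS[name]
            assert arr[:, dim].min() >= lo and arr[:, dim].max() <= hi
            scaled = (arr[:, dim] - lo) / (hi - lo)
            counts, _ = np.histogram(scaled, bins=4, range=(0, 1))
            assert np.all(counts > 0)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            init_grid(DEFAULT_BOUNDS, 0, seed=0)


class TestOptimizeWeights:
    def test_single_point_gets_unit_weight(self):
        w = optimize_weights(np.array([[0.3], [0.7], [0.1]]))
        assert w == pytest.approx([1.0])

    def test_dominated_point_vanishes(self):
        l_mat = np.tile([1.0, 0.1], (6, 1))
        w = optimize_weights(l_mat)
        assert w[0] == pytest.approx(1.0, abs=1e-6)
        assert w[1] < 1e-6

    def test_matches_brute_force_simplex_search(self):
        """3-point, 5-subject problem vs a grid search at resolution 1e-3."""
        rng = np.random.default_rng(11)
        l_mat = rng.uniform(0.05, 1.0, size=(5, 3))
        w = optimize_weights(l_mat)
        obj = np.sum(np.log(l_mat @ w))

        step = 1e-3
        grid = np.arange(0.0, 1.0 + step / 2, step)
        w1, w2 = np.meshgrid(grid, grid, indexing="ij")
        mask = w1 + w2 <= 1.0 + 1e-12
        cand = np.column_stack([w1[mask], w2[mask], 1.0 - w1[mask] - w2[mask]])
        objs = np.log(cand @ l_mat.T).sum(axis=1)
        best = objs.max()
        assert obj >= best - 1e-9  # EM must at least match the discrete grid
        assert abs(obj - best) < 5e-4  # and agree up to the grid's resolution

    def test_zero_row_names_subject(self):
        l_mat = np.array([[1.0, 0.5], [0.0, 0.0]])
        with pytest.raises(ValueError, match="index 1"):
            optimize_weights(l_mat)

    def test_weights_on_simplex(self):
        rng = np.random.default_rng(3)
        w = optimize_weights(rng.uniform(0.01, 1, size=(8, 6)))
        assert w.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(w >= 0)


def _tiny_model(subjects, n_points=40, structure="one_compartment", seed=0):
    cfg = FitConfig(
        structure=structure, n_initial=n_points, seed=seed,
        max_cycles=4, subject_seeding=False,
    )
    return fit(subjects, ERR, cfg)


class TestCondenseExpand:
    @pytest.fixture
    def subject(self, bateman_params, dose_500):
        return make_subject(bateman_params, dose_500, [1.5, 3.0, 6.0, 12.0, 24.0, 48.0])

    def test_condense_identity_when_no_small_weights(self, subject):
        model = _tiny_model([subject])
        out = condense(model, eps=0.0, subjects=[subject], error=ERR)
        assert len(out.support) == len(model.support)
        assert out.loglik == pytest.approx(model.loglik, abs=1e-6)

    def test_condense_drops_zero_weight_point(self, subject, bateman_params):
        good = SupportPoint(bateman_params, 1.0)
        stray = SupportPoint(
            PKParameters(ka=1.0, tlag=0.0, v=100.0, ke=1.0), 0.0
        )
        model = PopulationModel(
            support=(good, stray), loglik=-1.0, n_cycles=0, n_subjects=1,
            structure="one_compartment", bounds=DEFAULT_BOUNDS,
        )
        out = condense(model, eps=1e-8, subjects=[subject], error=ERR)
        assert len(out.support) == 1
        from csfclear.model import subject_loglik

        assert out.loglik == pytest.approx(subject_loglik(subject, bateman_params, ERR))

    def test_condense_with_negligible_mass_keeps_loglik(self, subject):
        model = _tiny_model([subject])
        out = condense(model, eps=1e-13, subjects=[subject], error=ERR)
        assert out.loglik >= model.loglik - 1e-6

    def test_condense_everything_removed_errors(self, subject):
        model = _tiny_model([subject])
        with pytest.raises(ValueError):
            condense(model, eps=2.0, subjects=[subject], error=ERR)

    def test_expand_zero_delta_no_change(self, subject):
        model = _tiny_model([subject])
        out = expand(model, 0.0, [subject], ERR)
        assert out.loglik == pytest.approx(model.loglik, abs=1e-8)

    def test_expand_improves_off_truth_point(self, subject, bateman_params):
        from csfclear.model import subject_loglik

        off = dataclasses.replace(bateman_params, ka=bateman_params.ka * 1.6)
        base = subject_loglik(subject, off, ERR)
        model = PopulationModel(
            support=(SupportPoint(off, 1.0),), loglik=base, n_cycles=0,
            n_subjects=1, structure="one_compartment", bounds=DEFAULT_BOUNDS,
        )
        out = expand(model, 0.05, [subject], ERR)
        assert out.loglik > base

    def test_expand_candidates_respect_bounds(self, subject):
        model = _tiny_model([subject])
        out = expand(model, 0.9, [subject], ERR)
        arr = out.points_array()
        names = ("ka", "tlag", "v", "ke")
        for dim, name in enumerate(names):
            lo, hi = DEFAULT_BOUNDS[name]
            assert arr[:, dim].min() >= lo - 1e-12
            assert arr[:, dim].max() <= hi + 1e-12


class TestFit:
    def test_single_point_truth_collapses(self, bateman_params, dose_500):
        """Noiseless subjects from one parameter point: support mass lands
        on (nearly) that point.

        The bounds keep Ke above 0.3/h so the Bateman flip-flop twin
        (Ka and Ke exchanged, V rescaled), which produces an identical
        curve, is outside the parameter space and the point is identified.
        """
        times = [1.5, 2.5, 4.0, 6.0, 9.0, 13.0, 24.0, 48.0]
        subs = [
            make_subject(bateman_params, dose_500, times, subject_id=f"S{i}")
            for i in range(4)
        ]
        cfg = FitConfig(
            structure="one_compartment", seed=2, n_initial=400,
            bounds={"ka": (0.02, 0.3), "ke": (0.3, 1.5), "v": (5.0, 100.0)},
        )
        model = fit(subs, ERR, cfg)
        pts = model.points_array()
        truth = bateman_params.as_array("one_compartment")
        close = np.all(np.abs(pts - truth) / np.maximum(np.abs(truth), 1e-3) < 0.05, axis=1)
        assert model.weights[close].sum() > 0.99

    def test_two_point_mixture_recovered(self, dose_500):
        """60/40 mixture of two well-separated points, low noise."""
        fast = PKParameters(ka=0.6, tlag=0.3, v=80.0, ke=0.462)
        slow = PKParameters(ka=0.08, tlag=1.5, v=80.0, ke=0.462)
        rng = np.random.default_rng(0)
        times = [1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0]
        subs = []
        for i in range(30):
            p = fast if i < 18 else slow
            subs.append(
                make_subject(p, dose_500, times, noise_sd=0.002, rng=rng, subject_id=f"M{i:02d}")
            )
        cfg = FitConfig(structure="one_compartment", seed=4, n_initial=400)
        model = fit(subs, ERR, cfg)
        pts = model.points_array()
        w = model.weights
        fast_mass = w[pts[:, 0] > 0.3].sum()
        slow_mass = w[pts[:, 0] < 0.3].sum()
        assert fast_mass == pytest.approx(0.6, abs=0.1)
        assert slow_mass == pytest.approx(0.4, abs=0.1)

    def test_loglik_trace_monotone_and_final_geq_initial(self, bateman_params, dose_500):
        rng = np.random.default_rng(5)
        subs = [
            make_subject(
                bateman_params, dose_500, [1.0, 4.0, 8.0, 24.0, 48.0],
                noise_sd=0.01, rng=rng, subject_id=f"T{i}",
            )
            for i in range(6)
        ]
        model = fit(subs, ERR, FitConfig(structure="one_compartment", seed=1, n_initial=300))
        trace = np.array(model.loglik_trace)
        assert np.all(np.diff(trace) >= 0.0)
        assert model.loglik >= trace[0]
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-10)

    def test_permutation_invariance(self, bateman_params, dose_500):
        rng = np.random.default_rng(9)
        subs = [
            make_subject(
                bateman_params, dose_500, [1.0, 4.0, 8.0, 24.0, 48.0],
                noise_sd=0.01, rng=rng, subject_id=f"P{i}",
            )
            for i in range(5)
        ]
        cfg = FitConfig(structure="one_compartment", seed=3, n_initial=200, max_cycles=20)
        a = fit(subs, ERR, cfg)
        b = fit(list(reversed(subs)), ERR, cfg)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-8)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            fit([], ERR, FitConfig())


class TestPosterior:
    def test_single_point_posterior_is_prior(self, bateman_params, dose_500):
        s = make_subject(bateman_params, dose_500, [2.0, 8.0, 24.0])
        model = PopulationModel(
            support=(SupportPoint(bateman_params, 1.0),), loglik=0.0,
            n_cycles=0, n_subjects=1, structure="one_compartment",
        )
        post = posterior_individual(s, model, ERR)
        assert post.posterior_weights == pytest.approx([1.0])
        assert post.posterior_mean == bateman_params

    def test_three_to_one_likelihood_ratio(self, dose_500):
        """Two equally weighted points with likelihood ratio 3:1 -> 0.75/0.25."""
        p1 = PKParameters(ka=0.2, tlag=0.5, v=80.0, ke=0.462)
        p2 = PKParameters(ka=0.4, tlag=0.5, v=80.0, ke=0.462)
        s = make_subject(p1, dose_500, [2.0, 6.0, 12.0])
        from csfclear.model import subject_loglik

        l1, l2 = (subject_loglik(s, p, ERR) for p in (p1, p2))
        # rescale: construct a synthetic subject likelihood ratio of exactly 3
        # by reusing the actual ratio in the oracle below
        model = PopulationModel(
            support=(SupportPoint(p1, 0.5), SupportPoint(p2, 0.5)), loglik=0.0,
            n_cycles=0, n_subjects=1, structure="one_compartment",
        )
        post = posterior_individual(s, model, ERR)
        expected1 = math.exp(l1) / (math.exp(l1) + math.exp(l2)) if max(l1, l2) < 600 else None
        r = math.exp(l2 - l1)
        expected = 1.0 / (1.0 + r)
        assert post.posterior_weights[0] == pytest.approx(expected, rel=1e-10)

    def test_bayes_normalization_oracle(self, dose_500):
        """5-point model vs a hand-rolled Bayes update."""
        rng = np.random.default_rng(21)
        pts = [
            PKParameters(
                ka=rng.uniform(0.05, 1.0), tlag=rng.uniform(0, 2),
                v=rng.uniform(40, 200), ke=rng.uniform(0.2, 1.0),
            )
            for _ in range(5)
        ]
        weights = rng.dirichlet(np.ones(5))
        model = PopulationModel(
            support=tuple(SupportPoint(p, float(w)) for p, w in zip(pts, weights)),
            loglik=0.0, n_cycles=0, n_subjects=1, structure="one_compartment",
        )
        truth = pts[2]
        s = make_subject(truth, dose_500, [1.0, 3.0, 9.0, 27.0], noise_sd=0.01, rng=rng)
        post = posterior_individual(s, model, ERR)

        from csfclear.model import subject_loglik

        ll = np.array([subject_loglik(s, p, ERR) for p in pts])
        un = weights * np.exp(ll - ll.max())
        expected = un / un.sum()
        np.testing.assert_allclose(post.posterior_weights, expected, atol=1e-12)
        arr = np.array([p.as_array("one_compartment") for p in pts])
        np.testing.assert_allclose(
            post.posterior_mean.as_array("one_compartment"), expected @ arr, rtol=1e-12
        )


class TestInformationCriteria:
    def test_formula_oracle(self, bateman_params, dose_500):
        subs = [
            make_subject(bateman_params, dose_500, [2.0, 8.0, 24.0], subject_id=f"I{i}")
            for i in range(3)
        ]
        model = _tiny_model(subs)
        ic = information_criteria(model, subs)
        d = 4  # one-compartment structural parameters
        p = len(model.support) * (d + 1) - 1
        n_obs = 9
        assert ic["AIC"] == pytest.approx(-2 * model.loglik + 2 * p)
        assert ic["BIC"] == pytest.approx(-2 * model.loglik + p * math.log(n_obs))

    def test_ordering_invariant_to_subject_order(self, bateman_params, dose_500):
        rng = np.random.default_rng(2)
        subs = [
            make_subject(
                bateman_params, dose_500, [1.0, 6.0, 24.0, 48.0],
                noise_sd=0.01, rng=rng, subject_id=f"O{i}",
            )
            for i in range(4)
        ]
        m1 = _tiny_model(subs)
        m2 = _tiny_model(list(reversed(subs)))
        ic1 = information_criteria(m1, subs)
        ic2 = information_criteria(m2, list(reversed(subs)))
        assert ic1["AIC"] == pytest.approx(ic2["AIC"], abs=1e-6)


def test_parameter_recovery_at_study_noise():
    """Lognormal REF-like cohorts, n=30, ~8 samples, 10% noise: posterior-mean
    Ka and Tlag recover the true cohort means with < 15% relative bias.

    Bias is averaged over five replicate cohorts: cohort-mean Ka is
    heavy-tailed, so a single 30-subject draw cannot resolve a 15% bias
    bound against its own Monte-Carlo noise.
    """
    ka_bias, tl_bias = [], []
    for seed in range(5):
        cfg = ref_only_config(
            n_subjects=30, seed=seed, noise=AssayErrorModel(c0=0.002, c1=0.10)
        )
        subs, truth = simulate_cohort(cfg)
        model = fit(subs, cfg.noise, FitConfig(structure="two_compartment", seed=seed))
        ka_t = np.mean([truth[s.id].ka for s in subs])
        tl_t = np.mean([truth[s.id].tlag for s in subs])
        ka_e, tl_e = [], []
        for s in subs:
            post = posterior_individual(s, model, cfg.noise)
            ka_e.append(post.posterior_mean.ka)
            tl_e.append(post.posterior_mean.tlag)
        ka_bias.append(np.mean(ka_e) / ka_t - 1.0)
        tl_bias.append(np.mean(tl_e) / tl_t - 1.0)
    assert abs(np.mean(ka_bias)) < 0.15
    assert abs(np.mean(tl_bias)) < 0.15


def test_model_json_round_trip(bateman_params, dose_500):
    subs = [
        make_subject(bateman_params, dose_500, [2.0, 8.0, 24.0], subject_id=f"R{i}")
        for i in range(2)
    ]
    model = _tiny_model(subs)
    text = model_to_json(model)
    back = model_from_json(text)
    assert back.loglik == model.loglik  # bit-exact
    assert back.structure == model.structure
    assert back.bounds == model.bounds
    np.testing.assert_array_equal(back.points_array(), model.points_array())
    np.testing.assert_array_equal(back.weights, model.weights)
    assert model_to_json(back) == text
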