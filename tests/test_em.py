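"""EM fitting of the bivariate Gamma mixture: steps, convergence,
recovery, symmetry and the L1 discrepancy."""

import numpy as np
import pandas as pd
import pytest

from fibrinpull import bigamma, em, fx, synthetic
from fibrinpull.em import GammaMixtureModel, model_from_components
from fibrinpull.synthetic import ComponentSpec


def _two_component_model(sep=120.0):
    comps = [
        ComponentSpec(0, 40.0, 10.0, 5.0, 1.5, 0.0, 0.5),
        ComponentSpec(1, 40.0 + sep, 12.0, 15.0, 4.0, 0.0, 0.5),
    ]
    return comps, model_from_components(comps)


class TestEStep:
    def test_single_component_responsibilities_one(self, mixture_5000):
        comps = [ComponentSpec(0, 50.0, 25.0, 12.0, 4.0, 0.0, 1.0)]
        model = model_from_components(comps)
        g, ll = em.e_step(mixture_5000, model)
        assert np.allclose(g, 1.0)
        s = model.shapes()[0]
        direct = bigamma.logpdf(
            mixture_5000["force_pN"].to_numpy(),
            mixture_5000["distance_nm"].to_numpy(),
            s,
        ).sum()
        assert ll == pytest.approx(direct)

    def test_far_separated_components_hard_assignment(self):
        comps, model = _two_component_model(sep=300.0)
        data = synthetic.sample_mixture(comps, 400, seed=2)
        g, _ = em.e_step(data, model)
        assert np.all(g.max(axis=1) > 0.999)

    def test_rows_normalized(self, mixture_5000, truth_model):
        g, _ = em.e_step(mixture_5000, truth_model)
        assert np.allclose(g.sum(axis=1), 1.0, atol=1e-9)
        assert (g >= 0).all() and (g <= 1).all()

    def test_component_permutation_permutes_columns(self, mixture_5000, truth_model):
        g, ll = em.e_step(mixture_5000, truth_model)
        perm = [4, 0, 3, 1, 2]
        g2, ll2 = em.e_step(mixture_5000, truth_model.permuted(perm))
        assert ll2 == pytest.approx(ll)
        np.testing.assert_allclose(g2, g[:, perm], atol=1e-12)


class TestMStep:
    def test_hard_responsibilities_give_sample_moments(self, mixture_5000, truth_model):
        lab = mixture_5000["true_type"].to_numpy()
        g = np.zeros((len(lab), 5))
        g[np.arange(len(lab)), lab] = 1.0
        new = em.m_step(mixture_5000, g, truth_model)
        for t in range(5):
            sel = mixture_5000[lab == t]
            assert new.mu_f[t] == pytest.approx(sel["force_pN"].mean())
            assert new.mu_x[t] == pytest.approx(sel["distance_nm"].mean())
            assert new.priors[t] == pytest.approx((lab == t).mean())

    def test_uniform_responsibilities_pool_moments(self, mixture_5000):
        comps = [
            ComponentSpec(0, 40.0, 10.0, 5.0, 1.5, 0.0, 0.5),
            ComponentSpec(1, 80.0, 12.0, 15.0, 4.0, 0.0, 0.5),
        ]
        model = model_from_components(comps)
        g = np.full((len(mixture_5000), 2), 0.5)
        new = em.m_step(mixture_5000, g, model)
        f = mixture_5000["force_pN"].to_numpy()
        assert new.mu_f[0] == pytest.approx(new.mu_f[1]) == pytest.approx(f.mean())

    def test_degenerate_component_frozen(self, mixture_5000):
        comps, model = _two_component_model()
        g = np.zeros((len(mixture_5000), 2))
        g[:, 0] = 1.0  # component 1 gets ~0 effective events
        new = em.m_step(mixture_5000, g, model)
        assert new.frozen[1]
        assert new.mu_f[1] == model.mu_f[1]  # untouched
        assert new.priors.sum() == pytest.approx(1.0)


class TestFit:
    def test_fixed_point_reconverges_fast(self):
        comps, init = _two_component_model()
        data = synthetic.sample_mixture(comps, 2000, seed=3)
        fitted, _ = em.fit(data, init)
        again, _ = em.fit(data, fitted)
        assert again.n_iter <= 2
        assert np.allclose(again.mu_f, fitted.mu_f, atol=0.2)

    def test_two_component_recovery_within_2pct(self):
        comps, init = _two_component_model()
        data = synthetic.sample_mixture(comps, 5000, seed=4)
        fitted, _ = em.fit(data, init)
        m = em.match_components(fitted, init)
        assert np.allclose(m.mu_f, [40.0, 160.0], rtol=0.02)
        assert np.allclose(m.mu_x, [5.0, 15.0], rtol=0.02)

    def test_label_swap_invariance(self):
        comps, init = _two_component_model()
        data = synthetic.sample_mixture(comps, 1500, seed=5)
        a, _ = em.fit(data, init)
        b, _ = em.fit(data, init.permuted([1, 0]))
        b_matched = em.match_components(b, a)
        assert np.allclose(b_matched.mu_f, a.mu_f, atol=1e-6)
        assert np.allclose(b_matched.priors, a.priors, atol=1e-9)

    def test_loglik_trace_monotone_on_default_data(self, mixture_5000, truth_model):
        init = truth_model.permuted(list(range(5)))
        init.mu_f = init.mu_f * 1.1
        init.mu_x = init.mu_x * 1.1
        fitted, _ = em.fit(mixture_5000, init)
        ll = np.array(fitted.loglik_trace)
        assert np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))

    def test_non_convergence_warns(self, mixture_5000, truth_model):
        init = truth_model.permuted(list(range(5)))
        init.mu_f = init.mu_f * 1.2
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fitted, _ = em.fit(mixture_5000, init, max_iter=2)
        assert not fitted.converged

    def test_priors_remain_probability_vector(self, mixture_5000, truth_model):
        fitted, g = em.fit(mixture_5000, truth_model)
        assert fitted.priors.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(g.sum(axis=1), 1.0, atol=1e-9)


class TestSerialization:
    def test_model_json_round_trip(self, truth_model, tmp_path):
        path = tmp_path / "model.json"
        truth_model.save(path)
        back = GammaMixtureModel.load(path)
        np.testing.assert_allclose(back.mu_f, truth_model.mu_f)
        np.testing.assert_allclose(back.cov_fx, truth_model.cov_fx)
        np.testing.assert_array_equal(back.type_ids, truth_model.type_ids)

    def test_classify_appends_posteriors(self, mixture_5000, truth_model):
        out = em.classify(mixture_5000.head(100), truth_model)
        post = out[[f"post_type{t}" for t in range(5)]].to_numpy()
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert set(out["assigned_type"]) <= {0, 1, 2, 3, 4}


class TestL1:
    def test_identical_densities_zero(self):
        g = np.linspace(0, 10, 100)
        d = np.exp(-g)
        assert em.l1_norm(d, d, g[1] - g[0]) == 0.0

    def test_disjoint_supports_two(self):
        grid = np.linspace(0.0, 10.0, 2001)
        df = grid[1] - grid[0]
        a = np.where(grid < 5, 0.2, 0.0)
        b = np.where(grid >= 5, 0.2, 0.0)
        assert em.l1_norm(a, b, df) == pytest.approx(2.0, abs=1e-2)

    def test_mismatched_grids_error(self):
        with pytest.raises(ValueError, match="grid"):
            em.l1_norm(np.zeros(5), np.zeros(6), 0.1)

    def test_model_vs_kde_of_own_sample(self, components, truth_model):
        df = synthetic.sample_mixture(components, 100_000, seed=6)
        grid = np.linspace(0.25, 250.0, 500)
        model_dens = em.combined_force_density(truth_model, grid)
        kde_dens = fx.kde(df["force_pN"].to_numpy(), grid)
        assert em.l1_norm(model_dens, kde_dens, grid[1] - grid[0]) < 0.05
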