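import numpy as np
import pytest

from spotcount.models import (
    FAMILIES,
    PHI_CAP,
    ModelFit,
    fit_gene,
    fit_nb_gee,
    fit_nb_with_fallback,
    log_likelihood,
    model_moments,
)

TOL = 1e-4  # optimizer tolerance for likelihood comparisons


class TestLogLikelihood:
    def test_poisson_hand_sum(self):
        # mu_i = 1 for both points, y = [1, 1]: sum(y log mu - mu - log y!) = -2
        assert log_likelihood("poisson", {"beta0": 0.0}, [1, 1], [1, 1]) == pytest.approx(-2.0)

    def test_zip_pi_zero_degenerates_to_poisson(self):
        y, off = [0, 1, 3, 2], [1.0, 2.0, 1.5, 1.0]
        a = log_likelihood("zip", {"beta0": 0.2, "pi": 0.0}, y, off)
        b = log_likelihood("poisson", {"beta0": 0.2}, y, off)
        assert a == pytest.approx(b, abs=1e-10)

    def test_zinb_large_phi_approaches_zip(self):
        y, off = [0, 1, 2], [1.0, 1.0, 1.0]
        a = log_likelihood("zinb", {"beta0": 0.3, "pi": 0.2, "phi": 1e6}, y, off)
        b = log_likelihood("zip", {"beta0": 0.3, "pi": 0.2}, y, off)
        assert abs(a - b) < 1e-3

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            log_likelihood("poisson", {"beta0": 0.0}, [-1, 1], [1, 1])

    def test_rejects_non_integer_counts(self):
        with pytest.raises(ValueError, match="integer"):
            log_likelihood("poisson", {"beta0": 0.0}, [0.5, 1], [1, 1])

    def test_rejects_zero_offset(self):
        with pytest.raises(ValueError, match="offsets"):
            log_likelihood("poisson", {"beta0": 0.0}, [1, 1], [0, 1])

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            log_likelihood("gaussian", {"beta0": 0.0}, [1], [1])


class TestFitGene:
    def test_poisson_closed_form_unit_mean(self):
        f = fit_gene("poisson", [1, 1], [1, 1])
        assert f.beta0 == pytest.approx(0.0)
        assert f.loglik == pytest.approx(-2.0)
        assert f.aic == pytest.approx(6.0)
        assert f.converged

    def test_poisson_closed_form_hand_value(self):
        f = fit_gene("poisson", [2, 4], [1, 1])
        assert np.exp(f.beta0) == pytest.approx(3.0)
        assert f.loglik == pytest.approx(6 * np.log(3) - 6 - np.log(48))
        assert f.aic == pytest.approx(8.559, abs=1e-3)

    def test_nb_dispersion_recovery(self):
        r = np.random.default_rng(42)
        lam, phi, n = 5.0, 2.0, 2000
        y = r.negative_binomial(phi, phi / (phi + lam), n)
        f = fit_gene("nb", y, np.ones(n))
        assert f.converged
        assert abs(f.phi - phi) / phi < 0.15

    def test_all_zero_gene_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_gene("poisson", [0, 0, 0], [1, 1, 1])

    def test_aic_invariant(self):
        r = np.random.default_rng(3)
        y = r.poisson(2, 100)
        y[r.random(100) < 0.2] = 0
        for fam in FAMILIES:
            f = fit_gene(fam, y, np.ones(100))
            assert f.aic == pytest.approx(2 * f.n_params - 2 * f.loglik)

    def test_param_counts(self):
        r = np.random.default_rng(4)
        y = r.poisson(3, 80)
        covs = r.normal(size=(80, 2))
        expected = {"poisson": 3, "nb": 4, "zip": 4, "zinb": 5}
        for fam, k in expected.items():
            assert fit_gene(fam, y, np.ones(80), covs).n_params == k

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_likelihood_nesting(self, seed):
        r = np.random.default_rng(seed)
        y = r.negative_binomial(1.0, 1 / 3.0, 300)
        y[r.random(300) < 0.25] = 0
        off = np.exp(r.normal(0, 0.3, 300))
        ll = {fam: fit_gene(fam, y, off).loglik for fam in FAMILIES}
        assert ll["nb"] >= ll["poisson"] - TOL
        assert ll["zip"] >= ll["poisson"] - TOL
        assert ll["zinb"] >= ll["nb"] - TOL
        assert ll["zinb"] >= ll["zip"] - TOL

    @pytest.mark.parametrize("fam", FAMILIES)
    def test_offset_equivariance(self, fam):
        # doubling offsets while halving exp(beta0) leaves the likelihood alone
        r = np.random.default_rng(9)
        y = r.poisson(2, 50)
        y[0] = 0
        off = np.ones(50)
        params = {"beta0": 0.4}
        if fam in ("nb", "zinb"):
            params["phi"] = 1.5
        if fam in ("zip", "zinb"):
            params["pi"] = 0.2
        a = log_likelihood(fam, params, y, off)
        params2 = dict(params, beta0=params["beta0"] - np.log(2))
        b = log_likelihood(fam, params2, y, 2 * off)
        assert a == pytest.approx(b, abs=1e-10)


class TestGee:
    def test_hand_solved_phi(self):
        # mu = 1, residual variance 2/(2-1) = 2, phi from 2 = 1 + 1/phi
        f = fit_nb_gee([0, 2], [1, 1])
        assert np.exp(f.beta0) == pytest.approx(1.0)
        assert f.phi == pytest.approx(1.0)
        assert not f.phi_capped
        assert f.method == "gee_plugin"

    def test_zero_residual_variance_caps_phi(self):
        f = fit_nb_gee([1, 1], [1, 1])
        assert f.phi_capped
        assert f.phi == PHI_CAP

    def test_phi_recovery(self):
        r = np.random.default_rng(8)
        lam, phi, n = 2.0, 1.0, 5000
        y = r.negative_binomial(phi, phi / (phi + lam), n)
        f = fit_nb_gee(y, np.ones(n))
        assert abs(f.phi - phi) / phi < 0.20

    def test_mean_matches_poisson_mle_exactly(self):
        r = np.random.default_rng(10)
        y = r.poisson(3, 200)
        off = np.exp(r.normal(0, 0.5, 200))
        assert fit_nb_gee(y, off).beta0 == pytest.approx(
            fit_gene("poisson", y, off).beta0, abs=1e-12
        )


class TestFallback:
    def test_mle_path_on_good_nb_data(self):
        r = np.random.default_rng(5)
        y = r.negative_binomial(1.0, 1 / 4.0, 1000)
        f = fit_nb_with_fallback(y, np.ones(1000))
        assert f.method == "mle"
        assert f.converged

    def test_underdispersed_triggers_fallback(self):
        y = np.array([3, 3, 3, 3])
        mle = fit_gene("nb", y, np.ones(4))
        assert not mle.converged  # phi diverges on variance < mean
        f = fit_nb_with_fallback(y, np.ones(4))
        assert f.aic <= mle.aic + 1e-9

    def test_result_is_min_aic_of_candidates(self):
        r = np.random.default_rng(6)
        y = r.poisson(4, 50)  # equidispersed: MLE usually diverges
        mle = fit_gene("nb", y, np.ones(50))
        gee = fit_nb_gee(y, np.ones(50))
        f = fit_nb_with_fallback(y, np.ones(50))
        if mle.converged:
            assert f.aic == pytest.approx(mle.aic)
        else:
            assert f.aic <= min(mle.aic, gee.aic) + 1e-9


class TestMoments:
    def _fit(self, family, mu, phi=None, pi=None):
        return ModelFit(family, np.log(mu), [], phi, pi, 0.0, 1, 0.0, True)

    def test_nb_formulas(self):
        mo = model_moments(self._fit("nb", 2.0, phi=1.0), 1.0)
        assert mo.variance == pytest.approx(6.0)
        assert mo.zero_prop == pytest.approx(1 / 3, abs=1e-4)

    def test_poisson_zero_mass(self):
        mo = model_moments(self._fit("poisson", 1.0), 1.0)
        assert mo.zero_prop == pytest.approx(np.exp(-1), abs=1e-4)

    def test_zip_mixture_zero_mass(self):
        mo = model_moments(self._fit("zip", 1.0, pi=0.5), 1.0)
        assert mo.mean == pytest.approx(0.5)
        assert mo.zero_prop == pytest.approx(0.5 + 0.5 * np.exp(-1), abs=1e-4)

    @pytest.mark.parametrize(
        "family,phi,pi", [("nb", 2.0, None), ("zip", None, 0.3), ("zinb", 1.5, 0.3)]
    )
    def test_overdispersed_variance_at_least_mean(self, family, phi, pi):
        mo = model_moments(self._fit(family, 3.0, phi=phi, pi=pi), 1.0)
        assert mo.variance >= mo.mean

    def test_rejects_nonpositive_offset(self):
        with pytest.raises(ValueError):
            model_moments(self._fit("poisson", 1.0), 0.0)
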