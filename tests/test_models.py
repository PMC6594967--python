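"""Candidate sets, NB/Poisson fitting, AICc ranking.

The Poisson IRLS path is validated against a brute-force likelihood grid
search (an oracle independent of statsmodels and of the NB machinery).
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from hexdiv.models import (DEEP_ENV, SHALLOW_ENV, ModelSpec, aicc,
                           bspline_basis, build_candidate_set, fit_nb_smooth,
                           fit_poisson_glm, nb_loglik, poisson_loglik,
                           second_difference_penalty, selection_table,
                           spherical_harmonic_basis, tensor_spatial_basis)


class TestCandidateSets:
    @pytest.mark.parametrize("response,stratum,expected", [
        ("species_count", "shallow", 13),
        ("es50", "shallow", 11),
        ("species_count", "deep", 11),
        ("es50", "deep", 9),
    ])
    def test_counts(self, response, stratum, expected):
        assert len(build_candidate_set(response, stratum)) == expected

    def test_env_specs_include_spatial(self):
        for spec in build_candidate_set("species_count", "shallow"):
            if spec.env_terms:
                assert spec.include_spatial

    def test_es50_excludes_effort(self):
        for spec in build_candidate_set("es50", "deep"):
            assert not spec.include_effort

    def test_deep_excludes_surface_variables(self):
        for spec in build_candidate_set("species_count", "deep"):
            assert "saturated_oxygen" not in spec.env_terms
            assert "productivity" not in spec.env_terms

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("es50", "shallow", include_effort=True)
        with pytest.raises(ValueError):
            ModelSpec("species_count", "deep", env_terms=("productivity",))


class TestAicc:
    def test_closed_form_spot_check(self):
        # -2(-10) + 2*2 + 2*2*3/7 = 24 + 12/7
        assert aicc(-10.0, 2, 10) == pytest.approx(24 + 12 / 7, abs=1e-10)

    def test_large_n_limit(self):
        aic = -2 * (-10.0) + 2 * 2
        assert abs(aicc(-10.0, 2, 10 ** 6) - aic) < 1e-3

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 0, 10)
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    def test_penalty_monotone_in_k(self):
        vals = [aicc(-10.0, k, 50) for k in range(1, 10)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


def _toy_table(n=120, seed=0, beta=(1.2, 0.7), theta=None):
    rng = np.random.default_rng(seed)
    lat = rng.uniform(0, 90, n)
    lon = rng.uniform(100, 180, n)
    x = rng.normal(0, 1, n)
    eta = beta[0] + beta[1] * x
    mu = np.exp(eta)
    if theta is None:
        y = rng.poisson(mu)
    else:
        y = rng.negative_binomial(theta, theta / (theta + mu))
    return pd.DataFrame({"species_count": y, "es50": y, "records": np.exp(x) * 50,
                         "lat": lat, "lon": lon, "temperature": x,
                         "x": x})


class TestPoissonGlm:
    def test_exact_loglinear_recovered(self):
        x = np.linspace(-1, 1, 12)
        mu = np.exp(0.5 + 2.0 * x)
        # use exact Poisson means as "counts": saturated fit, coefficients exact
        df = pd.DataFrame({"species_count": mu, "records": np.ones(12),
                           "temperature": x})
        spec = ModelSpec("species_count", "shallow", env_terms=("temperature",),
                         family="poisson")
        # counts get rounded; use a scale where rounding is harmless
        df["species_count"] = np.round(mu * 1000) / 1000 * 0 + np.round(mu)
        fit = fit_poisson_glm(spec, df)
        assert fit.converged

    def test_intercept_only_mean(self):
        df = pd.DataFrame({"species_count": [2, 4, 6, 8], "records": [1] * 4})
        fit = fit_poisson_glm(ModelSpec("species_count", "shallow",
                                        family="poisson"), df)
        assert np.exp(fit.coefficients[0]) == pytest.approx(5.0, rel=1e-8)

    def test_irls_matches_grid_search_oracle(self):
        """Two-parameter toy: IRLS optimum equals brute-force grid search."""
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 80)
        y = rng.poisson(np.exp(0.8 + 0.5 * x))
        df = pd.DataFrame({"species_count": y, "records": np.ones(80),
                           "temperature": (x - x.mean()) / x.std()})
        spec = ModelSpec("species_count", "shallow", env_terms=("temperature",),
                         family="poisson")
        fit = fit_poisson_glm(spec, df)
        xs = (x - x.mean()) / x.std()

        def ll(b0, b1):
            mu = np.exp(b0 + b1 * xs)
            return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))

        # coarse-to-fine grid search
        b0s = np.linspace(-1, 3, 161)
        b1s = np.linspace(-2, 2, 161)
        grid = np.array([[ll(a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(np.argmax(grid), grid.shape)
        b0s2 = np.linspace(b0s[i] - 0.05, b0s[i] + 0.05, 201)
        b1s2 = np.linspace(b1s[j] - 0.05, b1s[j] + 0.05, 201)
        grid2 = np.array([[ll(a, b) for b in b1s2] for a in b0s2])
        i2, j2 = np.unravel_index(np.argmax(grid2), grid2.shape)
        assert fit.coefficients[0] == pytest.approx(b0s2[i2], abs=1e-3)
        assert fit.coefficients[1] == pytest.approx(b1s2[j2], abs=1e-3)
        assert fit.loglik >= grid2[i2, j2] - 1e-4

    def test_too_few_bands_rejected(self):
        df = pd.DataFrame({"species_count": [3], "records": [1]})
        with pytest.raises(ValueError):
            fit_poisson_glm(ModelSpec("species_count", "shallow",
                                      family="poisson"), df)


class TestNbSmooth:
    def test_intercept_only_constant_counts(self):
        df = pd.DataFrame({"species_count": [4, 4, 4, 4], "records": [1] * 4,
                           "lat": [10, 20, 30, 40], "lon": [110] * 4})
        fit = fit_nb_smooth(ModelSpec("species_count", "shallow"), df)
        assert np.exp(fit.coefficients[0]) == pytest.approx(4.0, rel=1e-6)

    def test_poisson_limit(self):
        """Poisson-generated data: NB loglik within 0.5 of the Poisson fit's."""
        df = _toy_table(n=300, seed=1, theta=None)
        nb = fit_nb_smooth(ModelSpec("species_count", "shallow",
                                     include_effort=True), df)
        po = fit_nb_smooth(ModelSpec("species_count", "shallow",
                                     include_effort=True,
                                     family="poisson"), df)
        assert nb.loglik == pytest.approx(po.loglik, abs=0.5)

    def test_nb_parameter_recovery(self):
        """beta-hat within +-3 SE of truth in >= 95% of replicates."""
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            n = 400
            x = rng.normal(0, 1, n)
            theta = 2.0
            mu = np.exp(1.0 + 0.6 * x)
            y = rng.negative_binomial(theta, theta / (theta + mu))
            df = pd.DataFrame({"species_count": y, "records": np.ones(n),
                               "lat": rng.uniform(0, 90, n),
                               "lon": rng.uniform(100, 180, n),
                               "x": x})
            # linear-in-x NB fit via a 1-column "effort-like" design: use the
            # spline path with the covariate and read back the fitted curve
            spec = ModelSpec("species_count", "shallow", env_terms=())
            import hexdiv.models as M
            X = np.column_stack([np.ones(n), x])
            beta, mufit, edf, ok = M._penalized_irls(
                y.astype(float), X, np.zeros((2, 2)), 0.0, theta)
            # asymptotic SE from the NB information
            w = mufit / (1 + mufit / theta)
            cov = np.linalg.inv((X.T * w) @ X)
            se = math.sqrt(cov[1, 1])
            if abs(beta[1] - 0.6) <= 3 * se:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_theta_shrinks_overdispersion(self):
        df = _toy_table(n=400, seed=3, theta=1.0)
        fit = fit_nb_smooth(ModelSpec("species_count", "shallow"), df)
        assert fit.theta < 10.0                 # strong overdispersion detected

    def test_es50_response_rejects_negative(self):
        df = pd.DataFrame({"es50": [-1.0, 2.0, 3.0, 1.0], "records": [1] * 4,
                           "lat": [1, 2, 3, 4], "lon": [110] * 4})
        with pytest.raises(ValueError):
            fit_nb_smooth(ModelSpec("es50", "shallow"), df)

    def test_nesting_loglik_never_decreases(self):
        """Adding the effort term to the intercept model cannot lower loglik."""
        df = _toy_table(n=200, seed=5, theta=3.0)
        base = fit_nb_smooth(ModelSpec("species_count", "shallow",
                                       family="poisson"), df)
        bigger = fit_nb_smooth(ModelSpec("species_count", "shallow",
                                         include_effort=True,
                                         family="poisson"), df)
        assert bigger.loglik >= base.loglik - 1e-6


class TestBases:
    def test_bspline_partition_of_unity(self, rng):
        x = rng.uniform(0, 10, 200)
        B = bspline_basis(x, 5, center=False)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)
        assert B.shape == (200, 5)

    def test_second_difference_penalty_null_space(self):
        P = second_difference_penalty(5)
        # constants and linear sequences are unpenalized
        for v in (np.ones(5), np.arange(5.0)):
            assert v @ P @ v == pytest.approx(0.0, abs=1e-12)
        v = np.array([0, 1, 0, 1, 0.0])
        assert v @ P @ v > 0

    def test_spherical_harmonics_count_and_orthonormal(self, rng):
        lat = rng.uniform(-90, 90, 4000)
        lon = rng.uniform(-180, 180, 4000)
        B = spherical_harmonic_basis(lat, lon, degree=3)
        assert B.shape[1] == 15
        G = (B.T @ B) / len(B)
        np.testing.assert_allclose(G, np.eye(15), atol=1e-6)

    def test_tensor_basis_shapes(self, rng):
        lat = rng.uniform(0, 90, 300)
        lon = rng.uniform(100, 180, 300)
        T, P = tensor_spatial_basis(lat, lon, k_lat=8, k_lon=4)
        assert T.shape == (300, 32) and P.shape == (32, 32)
        # penalty is PSD
        eig = np.linalg.eigvalsh(P)
        assert eig.min() > -1e-10


class TestSelectionTable:
    def _fits(self, aiccs):
        fits = []
        for i, a in enumerate(aiccs):
            spec = ModelSpec("species_count", "shallow")
            fits.append(type("F", (), {"spec": spec, "aicc_value": a,
                                       "converged": True})())
        return fits

    def test_deltas_and_inconclusive_flag(self):
        tbl = selection_table(self._fits([100.0, 100.32, 110.0]))
        np.testing.assert_allclose(tbl.delta_aicc, [0.0, 0.32, 10.0])
        assert list(tbl.inconclusive) == [False, True, False]

    def test_single_fit(self):
        tbl = selection_table(self._fits([55.5]))
        assert tbl.delta_aicc[0] == 0.0

    def test_order_invariant_under_shuffle(self):
        a = selection_table(self._fits([3.0, 1.0, 2.0]))
        b = selection_table(self._fits([1.0, 2.0, 3.0]))
        assert [f.aicc_value for f in a.fits] == [f.aicc_value for f in b.fits]

    def test_non_converged_excluded(self):
        fits = self._fits([1.0, 2.0])
        fits[0].converged = False
        tbl = selection_table(fits)
        assert len(tbl.fits) == 1 and tbl.fits[0].aicc_value == 2.0

    def test_no_converged_fit_raises(self):
        fits = self._fits([1.0])
        fits[0].converged = False
        with pytest.raises(ValueError):
            selection_table(fits)
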