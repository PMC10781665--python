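import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit
from scipy.stats import betabinom as scipy_betabinom
from scipy.stats import binom, kstest

import biogeo as bg
from biogeo.enrichment import (
    EnrichmentModel,
    betabinom_loglik,
    classify_enrichment,
    fit_taxon,
)
from biogeo.errors import ParameterError
from biogeo.simulate import simulate_paired_site


def intercept_only_model(c, n):
    c = np.atleast_1d(c)
    n = np.atleast_1d(n)
    return EnrichmentModel(
        np.column_stack([np.ones(len(c)), np.zeros(len(c))]), c, n, ["i", "R"]
    )


class TestLoglik:
    def test_binomial_limit_worked_example(self):
        # N=10, C=5, p=0.5: 252 * 0.5^10 = 0.24609375
        model = intercept_only_model([5], [10])
        assert np.exp(betabinom_loglik(np.zeros(2), 0.0, model)) == pytest.approx(
            0.24609375, abs=1e-12
        )

    @pytest.mark.parametrize("rho", [0.0, 0.1, 0.5, 0.9])
    def test_single_trial_free_of_overdispersion(self, rho):
        model = intercept_only_model([1], [1])
        beta = np.array([logit(0.3), 0.0])
        assert np.exp(betabinom_loglik(beta, rho, model)) == pytest.approx(0.3)

    def test_matches_scipy_betabinom(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(2, 500))
            c = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.01, 0.99))
            rho = float(rng.uniform(0.005, 0.8))
            a, b = p * (1 - rho) / rho, (1 - p) * (1 - rho) / rho
            ours = betabinom_loglik(
                np.array([logit(p), 0.0]), rho, intercept_only_model([c], [n])
            )
            assert ours == pytest.approx(scipy_betabinom.logpmf(c, n, a, b), abs=1e-10)

    @given(
        st.integers(1, 300),
        st.floats(0.02, 0.98),
    )
    @settings(max_examples=40, deadline=None)
    def test_rho_to_zero_approaches_binomial(self, n, p):
        c = int(round(n * p))
        model = intercept_only_model([c], [n])
        beta = np.array([logit(p), 0.0])
        near_zero = betabinom_loglik(beta, 1e-12, model)
        exact = binom.logpmf(c, n, p)
        assert near_zero == pytest.approx(exact, abs=1e-6)

    def test_invalid_corner_returns_neg_inf(self):
        model = intercept_only_model([5], [10])
        assert betabinom_loglik(np.array([np.nan, 0.0]), 0.1, model) == -np.inf


class TestFitTaxon:
    def test_recovers_planted_effect(self):
        est = []
        for rep in range(40):
            c, n, rt, _ = simulate_paired_site(40, 10_000, logit(0.01), 2.0, 0.05, seed=rep)
            model = EnrichmentModel(np.column_stack([np.ones(80), rt]), c, n, ["i", "R"])
            est.append(fit_taxon(model, "t", "s").beta_type)
        assert np.mean(est) == pytest.approx(2.0, abs=0.2)

    def test_niche_recoding_flips_sign(self):
        c, n, rt, _ = simulate_paired_site(30, 5_000, logit(0.02), 1.5, 0.05, seed=3)
        m_fwd = EnrichmentModel(np.column_stack([np.ones(60), rt]), c, n, ["i", "R"])
        m_rev = EnrichmentModel(np.column_stack([np.ones(60), 1 - rt]), c, n, ["i", "R"])
        f_fwd, f_rev = fit_taxon(m_fwd), fit_taxon(m_rev)
        assert f_fwd.beta_type == pytest.approx(-f_rev.beta_type, abs=1e-3)
        assert f_fwd.wald_p == pytest.approx(f_rev.wald_p, abs=1e-4)

    def test_null_wald_p_uniform(self):
        ps = []
        for rep in range(150):
            c, n, rt, _ = simulate_paired_site(40, 10_000, logit(0.01), 0.0, 0.05, seed=3000 + rep)
            model = EnrichmentModel(np.column_stack([np.ones(80), rt]), c, n, ["i", "R"])
            ps.append(fit_taxon(model).wald_p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_all_zero_counts_rejected(self):
        model = EnrichmentModel(
            np.column_stack([np.ones(4), [0, 1, 0, 1]]),
            np.zeros(4, dtype=int),
            np.full(4, 100),
            ["i", "R"],
        )
        with pytest.raises(ParameterError, match="all-zero"):
            fit_taxon(model)

    def test_single_niche_rejected(self):
        model = EnrichmentModel(
            np.column_stack([np.ones(4), np.ones(4)]),
            np.array([1, 2, 3, 4]),
            np.full(4, 100),
            ["i", "R"],
        )
        with pytest.raises(ParameterError, match="both niches"):
            fit_taxon(model)

    def test_rho_recovery_is_sane(self):
        rhos = []
        for rep in range(20):
            c, n, rt, _ = simulate_paired_site(60, 10_000, logit(0.02), 0.0, 0.1, seed=50 + rep)
            model = EnrichmentModel(np.column_stack([np.ones(120), rt]), c, n, ["i", "R"])
            rhos.append(fit_taxon(model).rho_hat)
        assert np.median(rhos) == pytest.approx(0.1, abs=0.04)

    def test_optimum_beats_parameter_grid(self):
        """The optimizer's log-likelihood dominates a dense (beta_type, rho)
        grid on a small instance."""
        c, n, rt, _ = simulate_paired_site(15, 2_000, logit(0.03), 1.0, 0.1, seed=9)
        model = EnrichmentModel(np.column_stack([np.ones(30), rt]), c, n, ["i", "R"])
        fit = fit_taxon(model)
        from biogeo.enrichment import _maximize

        beta_hat, rho_hat, _, _ = _maximize(model, 0.05, 500)
        best = betabinom_loglik(beta_hat, rho_hat, model)
        for beta_type in np.linspace(-2, 3, 26):
            for rho in np.linspace(0.005, 0.5, 20):
                beta = beta_hat.copy()
                beta[1] = beta_type
                assert betabinom_loglik(beta, rho, model) <= best + 1e-6


class TestClassify:
    def _fit(self, p, beta, site="s1"):
        return bg.EnrichmentFit("t", site, beta, 0.1, p, 0.05, True)

    def test_constant_small_p_all_significant(self):
        fits = [self._fit(0.001, 1.0) for _ in range(10)]
        out = classify_enrichment(fits, alpha=0.05)
        assert all(f.enrichment_class == "mucosa_enriched" for f in out)
        assert all(f.fdr_q == pytest.approx(0.001) for f in out)

    def test_single_insignificant_fit(self):
        out = classify_enrichment([self._fit(0.2, 1.0)], alpha=0.05)
        assert out[0].enrichment_class == "ns"

    def test_direction_from_sign(self):
        out = classify_enrichment([self._fit(0.001, -2.0), self._fit(0.001, 2.0)])
        assert {f.enrichment_class for f in out} == {"lumen_enriched", "mucosa_enriched"}

    def test_bh_within_site_by_default(self):
        fits = [self._fit(0.04, 1.0, site="a")] + [
            self._fit(1.0, 1.0, site="b") for _ in range(50)
        ]
        within = classify_enrichment(fits, alpha=0.05)
        pooled = classify_enrichment(fits, alpha=0.05, pool_sites=True)
        assert within[0].enrichment_class == "mucosa_enriched"
        assert pooled[0].enrichment_class == "ns"

    def test_sensitivity_and_fdp_on_planted_mixture(self):
        """100 taxa at one site, 20 with |beta|=2: BH at 0.05 keeps the
        false-discovery proportion low while catching most planted taxa."""
        fits = []
        truth = {}
        for i in range(100):
            beta = 2.0 if i < 10 else (-2.0 if i < 20 else 0.0)
            truth[f"t{i}"] = beta
            c, n, rt, _ = simulate_paired_site(40, 10_000, logit(0.01), beta, 0.05, seed=7000 + i)
            model = EnrichmentModel(np.column_stack([np.ones(80), rt]), c, n, ["i", "R"])
            fit = fit_taxon(model, taxon_id=f"t{i}", site="s1")
            fits.append(fit)
        out = classify_enrichment(fits, alpha=0.05)
        called = {f.taxon_id for f in out if f.enrichment_class != "ns"}
        planted = {t for t, b in truth.items() if b != 0}
        sensitivity = len(called & planted) / len(planted)
        fdp = len(called - planted) / max(len(called), 1)
        assert sensitivity >= 0.8
        assert fdp <= 0.1


class TestEnrichedSets:
    def test_printed_count_arithmetic(self):
        """38 and 16 enriched with 9 shared -> Jaccard 20.0%; 14 and 31 with
        7 shared -> 18.4%."""
        a = {f"m{i}" for i in range(38)}
        b = {f"m{i}" for i in range(9)} | {f"x{i}" for i in range(7)}
        percent, shared = bg.compare_enriched_sets(a, b)
        assert percent == pytest.approx(20.0)
        assert len(shared) == 9
        a2 = {f"l{i}" for i in range(14)}
        b2 = {f"l{i}" for i in range(7)} | {f"y{i}" for i in range(24)}
        percent2, _ = bg.compare_enriched_sets(a2, b2)
        assert percent2 == pytest.approx(100 * 7 / 38)

    def test_identical_and_disjoint_sets(self):
        assert bg.compare_enriched_sets({"a", "b"}, {"a", "b"})[0] == 100.0
        assert bg.compare_enriched_sets({"a"}, {"b"})[0] == 0.0
        assert bg.compare_enriched_sets(set(), set())[0] == 0.0


class TestStudyLevel:
    def test_fit_organ_detects_planted_effects(self, default_study):
        bundle, truth = default_study
        fits = bg.fit_organ(bundle.count_table, bundle.samples, "small intestine")
        out = classify_enrichment(fits, alpha=0.05)
        planted = {
            t for t, info in truth.enrichment.items() if abs(info["beta"]) > 0
        }
        called = {f.taxon_id for f in out if f.enrichment_class != "ns"}
        assert len(called & planted) / len(planted) >= 0.5
        frame = bg.fits_to_frame(out)
        assert set(frame.columns) >= {"taxon_id", "site", "beta_type", "fdr_q", "class"}


class TestSklearnInterface:
    def test_estimator_params_and_fit(self):
        c, n, rt, _ = simulate_paired_site(30, 5_000, logit(0.02), 1.0, 0.05, seed=1)
        est = bg.BetaBinomialLogistic()
        assert est.get_params()["rho_init"] == 0.05
        est.set_params(rho_init=0.1)
        est.fit(rt.reshape(-1, 1), np.column_stack([c, n]))
        assert est.converged_
        assert est.coef_.shape == (1,)
        preds = est.predict(np.array([[0.0], [1.0]]))
        assert preds[1] > preds[0]
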