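import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from bivtwin import (
    GROUPS,
    ModelSpec,
    TwinDataset,
    deviance,
    environmental_correlation,
    fit_biometric,
    genetic_correlation,
    profile_ci,
    simulate_dataset,
    standardize,
)
from bivtwin.biometric_model import (
    BiometricParams,
    UndefinedCorrelationError,
    _pack,
    _unpack,
    profile_interval,
)
from bivtwin.synthetic_data import GroupParams, implied_pair_covariance
from bivtwin.twin_data import TwinPair, group_split
from tests.conftest import small_spec

AE = {"F": ("A", "E"), "M": ("A", "E")}
ACE = {"F": ("A", "CorD", "E"), "M": ("A", "CorD", "E")}


def ae_params(spec):
    """BiometricParams mirroring a simulation spec's AE truth."""
    return BiometricParams(
        components={s: {"A": spec.params_by_sex[s].A,
                        "E": spec.params_by_sex[s].E}
                    for s in ("F", "M")},
        mu={s: spec.params_by_sex[s].mu for s in ("F", "M")},
    )


class TestModelSpec:
    @pytest.mark.parametrize("comps,mode,expected", [
        (ACE, "none", 22),
        (AE, "none", 16),
        (AE, "full", 10),
        (AE, "scalar", 12),
        (ACE, "scalar", 15),
    ])
    def test_free_parameter_counts(self, comps, mode, expected):
        assert ModelSpec("ACE", comps, mode).n_free == expected

    def test_e_required(self):
        with pytest.raises(ValueError, match="E must be present"):
            ModelSpec("ACE", {"F": ("A",), "M": ("A", "E")})

    def test_scalar_requires_same_components(self):
        with pytest.raises(ValueError, match="identical component"):
            ModelSpec("ACE", {"F": ("A", "E"), "M": ("A", "CorD", "E")},
                      "scalar")

    def test_labels(self):
        assert ModelSpec("ACE", ACE, "none").label() == "ACE (sex diff)"
        assert ModelSpec("ADE", ACE, "none").label() == "ADE (sex diff)"
        assert ModelSpec("ACE", AE, "full").label() == "AE (no sex diff)"

    def test_pack_unpack_round_trip(self):
        spec = ModelSpec("ACE", AE, "scalar")
        sim = small_spec()
        p = BiometricParams(
            components={"F": dict(A=sim.params_by_sex["M"].A,
                                  E=sim.params_by_sex["M"].E),
                        "M": dict(A=sim.params_by_sex["M"].A,
                                  E=sim.params_by_sex["M"].E)},
            mu={"F": np.array([0.1, 0.2]), "M": np.array([0.3, 0.4])},
            k=np.array([1.3, 0.8]),
        )
        back = _unpack(_pack(p, spec), spec)
        np.testing.assert_allclose(back.k, p.k, rtol=1e-12)
        np.testing.assert_allclose(back.mu["F"], p.mu["F"])
        np.testing.assert_allclose(back.components["M"]["A"],
                                   p.components["M"]["A"])


class TestDeviance:
    def test_single_pair_matches_scipy_density(self):
        sim = small_spec()
        params = ae_params(sim)
        spec = ModelSpec("ACE", AE, "none")
        y = np.array([0.3, -0.2, 1.1, 0.4])
        ds = TwinDataset.from_pairs([TwinPair("MZ", "F", y)] +
                                    [TwinPair(z, s, [0.0, 0.0, 0.0, 0.0])
                                     for z, s in (("DZ", "F"), ("MZ", "M"),
                                                  ("DZ", "M"))])
        gp = sim.params_by_sex["F"]
        ours = deviance(params, spec, ds)
        expected = 0.0
        for pair in ds:
            p = sim.params_by_sex[pair.sex]
            sigma = implied_pair_covariance(p, "ACE", pair.zygosity)
            mu = np.concatenate([p.mu, p.mu])
            expected += -2.0 * multivariate_normal.logpdf(pair.y, mu, sigma)
        np.testing.assert_allclose(ours, expected, rtol=1e-10)

    def test_marginalization_when_twin2_missing(self):
        sim = small_spec()
        params = ae_params(sim)
        spec = ModelSpec("ACE", AE, "none")
        y_obs = np.array([0.5, -0.1])
        pairs = [TwinPair("MZ", "F", np.concatenate([y_obs, [np.nan, np.nan]]))]
        pairs += [TwinPair(z, s, [0.0] * 4)
                  for z, s in (("DZ", "F"), ("MZ", "M"), ("DZ", "M"))]
        ds = TwinDataset.from_pairs(pairs)
        ours = deviance(params, spec, ds)
        # independent 2-d marginal for the incomplete pair
        expected = 0.0
        for pair in ds:
            p = sim.params_by_sex[pair.sex]
            sigma = implied_pair_covariance(p, "ACE", pair.zygosity)
            mu = np.concatenate([p.mu, p.mu])
            obs = ~np.isnan(pair.y)
            expected += -2.0 * multivariate_normal.logpdf(
                pair.y[obs], mu[obs], sigma[np.ix_(obs, obs)])
        np.testing.assert_allclose(ours, expected, rtol=1e-10)

    def test_non_pd_total_gives_inf(self, tiny_dataset):
        sim = small_spec()
        params = ae_params(sim)
        params.components["F"]["E"] = np.array([[-5.0, 0.0], [0.0, -5.0]])
        spec = ModelSpec("ACE", AE, "none")
        assert deviance(params, spec, tiny_dataset) == math.inf

    def test_oracle_equivalence_on_random_complete_data(self, rng):
        # structural invariant: FIML == closed-form MVN on complete data
        sim = small_spec()
        spec = ModelSpec("ACE", AE, "none")
        params = ae_params(sim)
        for _ in range(10):
            ds = simulate_dataset(small_spec(seed=int(rng.integers(1e6)), n=20))
            ours = deviance(params, spec, ds)
            expected = 0.0
            for g, sub in group_split(ds).items():
                p = sim.params_by_sex[g[2].upper()]
                sigma = implied_pair_covariance(p, "ACE", g[:2])
                mu = np.concatenate([p.mu, p.mu])
                expected += -2.0 * multivariate_normal.logpdf(
                    sub.y, mu, sigma).sum()
            np.testing.assert_allclose(ours, expected, rtol=1e-8)


class TestFitBiometric:
    def test_parameter_recovery_ae(self):
        sim = small_spec(seed=101, n=2000)
        ds = simulate_dataset(sim)
        fit = fit_biometric(ds, ModelSpec("ACE", AE, "none"), n_starts=1)
        est = standardize(fit)
        # female trait-1 heritability truth = 0.5/1.0
        assert est.by_sex["F"].shares["A"][0] == pytest.approx(0.5, abs=0.05)
        assert est.by_sex["M"].shares["A"][0] == pytest.approx(0.35, abs=0.05)

    def test_fixed_point_refit(self, medium_dataset):
        spec = ModelSpec("ACE", AE, "none")
        fit = fit_biometric(medium_dataset, spec, n_starts=1)
        refit = fit_biometric(medium_dataset, spec, starts=fit.params,
                              n_starts=1)
        assert refit.minus2LL == pytest.approx(fit.minus2LL, abs=1e-6)

    def test_nesting_monotonicity(self, medium_dataset):
        ace = fit_biometric(medium_dataset, ModelSpec("ACE", ACE, "none"),
                            n_starts=1)
        ae = fit_biometric(medium_dataset, ModelSpec("ACE", AE, "none"),
                          n_starts=1)
        nosex = fit_biometric(medium_dataset, ModelSpec("ACE", AE, "full"),
                              n_starts=1)
        scalar = fit_biometric(medium_dataset, ModelSpec("ACE", AE, "scalar"),
                               n_starts=1)
        assert ae.minus2LL >= ace.minus2LL - 1e-6
        assert nosex.minus2LL >= ae.minus2LL - 1e-6
        # scalar lies between the sex-difference and no-sex-difference models
        assert ae.minus2LL - 1e-6 <= scalar.minus2LL <= nosex.minus2LL + 1e-6

    def test_df_and_aic_convention(self, tiny_dataset):
        fit = fit_biometric(tiny_dataset, ModelSpec("ACE", AE, "none"),
                            n_starts=1)
        from bivtwin import observed_count
        assert fit.df == observed_count(tiny_dataset) - 16
        assert fit.AIC == pytest.approx(fit.minus2LL - 2 * fit.df)

    def test_scale_equivariance(self, tiny_dataset):
        spec = ModelSpec("ACE", AE, "none")
        fit = fit_biometric(tiny_dataset, spec, n_starts=1)
        c = 3.0
        scaled = TwinDataset(tiny_dataset.zygosity, tiny_dataset.sex,
                             tiny_dataset.y * np.array([c, 1.0, c, 1.0]))
        fit2 = fit_biometric(scaled, spec, n_starts=1)
        np.testing.assert_allclose(
            fit2.params.components["F"]["A"][0, 0],
            c ** 2 * fit.params.components["F"]["A"][0, 0], rtol=1e-3)
        est, est2 = standardize(fit), standardize(fit2)
        for sex in ("F", "M"):
            assert est2.by_sex[sex].shares["A"][0] == pytest.approx(
                est.by_sex[sex].shares["A"][0], abs=1e-4)
            assert est2.by_sex[sex].correlations["A"] == pytest.approx(
                est.by_sex[sex].correlations["A"], abs=1e-4)

    def test_scalar_mode_scales_female_variance(self, medium_dataset):
        fit = fit_biometric(medium_dataset, ModelSpec("ACE", AE, "scalar"),
                            n_starts=1)
        est = standardize(fit)
        comps_f = fit.params.effective_components("F", fit.spec)
        comps_m = fit.params.effective_components("M", fit.spec)
        total_f = comps_f["A"] + comps_f["E"]
        total_m = comps_m["A"] + comps_m["E"]
        np.testing.assert_allclose(np.diag(total_f),
                                   fit.params.k * np.diag(total_m), rtol=1e-8)
        # standardized shares equal across sexes by construction
        for comp in ("A", "E"):
            np.testing.assert_allclose(est.by_sex["F"].shares[comp],
                                       est.by_sex["M"].shares[comp],
                                       rtol=1e-8)


class TestComponentCorrelations:
    def test_printed_female_wb_optimism_rg(self):
        a = np.array([[0.444, 0.663 * 0.403], [0.663 * 0.403, 0.311]])
        assert round(genetic_correlation(a), 2) == 0.72

    def test_printed_female_wb_optimism_re(self):
        e = np.array([[0.556, 0.337 * 0.403], [0.337 * 0.403, 0.689]])
        assert round(environmental_correlation(e), 2) == 0.22

    def test_zero_covariance_gives_zero(self):
        assert genetic_correlation(np.diag([1.0, 2.0])) == 0.0
        assert environmental_correlation(np.diag([0.3, 0.7])) == 0.0

    def test_psd_boundary_hand_case(self):
        assert genetic_correlation(np.array([[4.0, 2.0], [2.0, 1.0]])) == \
            pytest.approx(1.0)

    def test_indefinite_warns_not_truncated(self):
        a = np.array([[1.0, 1.5], [1.5, 1.0]])
        with pytest.warns(UserWarning, match="outside"):
            r = genetic_correlation(a)
        assert r == pytest.approx(1.5)

    def test_non_positive_diagonal_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            genetic_correlation(np.array([[0.0, 0.1], [0.1, 1.0]]))

    def test_normalization_oracle(self, rng):
        for _ in range(20):
            m = rng.normal(size=(2, 2))
            e = m @ m.T + 0.1 * np.eye(2)
            d = np.sqrt(np.diag(e))
            expected = (e / np.outer(d, d))[0, 1]
            assert environmental_correlation(e) == pytest.approx(expected)


class TestStandardize:
    @staticmethod
    def _fit_from_components(comps_f, comps_m=None, family="ACE"):
        comps_m = comps_m or comps_f
        spec = ModelSpec(family,
                         {"F": tuple(comps_f), "M": tuple(comps_m)}, "none")
        params = BiometricParams(
            components={"F": {k: np.asarray(v) for k, v in comps_f.items()},
                        "M": {k: np.asarray(v) for k, v in comps_m.items()}},
            mu={"F": np.zeros(2), "M": np.zeros(2)},
        )
        from bivtwin.biometric_model import FitResult
        return FitResult(spec=spec, params=params, minus2LL=0.0,
                         n_free=spec.n_free, df=0, AIC=0.0, converged=True,
                         n_obs=0)

    def test_equal_components_all_thirds(self):
        m = np.array([[1.0, 0.4], [0.4, 1.0]])
        fit = self._fit_from_components({"A": m, "CorD": m, "E": m})
        est = standardize(fit)
        for sex in ("F", "M"):
            se = est.by_sex[sex]
            for comp in ("A", "CorD", "E"):
                assert se.shares[comp] == pytest.approx((1 / 3, 1 / 3))
                assert se.biv_shares[comp] == pytest.approx(1 / 3)

    def test_table_style_identity(self):
        # female AE shares 0.444/0.556, 0.311/0.689, bivA 0.663, r_ph 0.403
        a = np.array([[0.444, 0.663 * 0.403], [0.663 * 0.403, 0.311]])
        e = np.array([[0.556, 0.337 * 0.403], [0.337 * 0.403, 0.689]])
        est = standardize(self._fit_from_components({"A": a, "E": e}))
        se = est.by_sex["F"]
        assert se.shares["A"] == pytest.approx((0.444, 0.311))
        assert se.biv_shares["A"] == pytest.approx(0.663)
        rg, re = se.correlations["A"], se.correlations["E"]
        assert rg == pytest.approx(0.719, abs=5e-4)
        assert re == pytest.approx(0.219, abs=5e-4)
        h2, e2 = se.shares["A"], se.shares["E"]
        identity = (rg * math.sqrt(h2[0] * h2[1])
                    + re * math.sqrt(e2[0] * e2[1]))
        assert identity == pytest.approx(se.r_ph_implied, abs=1e-10)
        assert se.r_ph_implied == pytest.approx(0.403, abs=1e-10)

    def test_shares_sum_to_one_random(self, rng):
        for _ in range(20):
            def psd():
                m = rng.normal(size=(2, 2))
                return m @ m.T + 0.05 * np.eye(2)
            fit = self._fit_from_components({"A": psd(), "CorD": psd(),
                                             "E": psd()})
            est = standardize(fit)
            for sex in ("F", "M"):
                se = est.by_sex[sex]
                for t in (0, 1):
                    assert sum(se.shares[c][t]
                               for c in ("A", "CorD", "E")) == \
                        pytest.approx(1.0, abs=1e-10)
                assert sum(se.biv_shares.values()) == pytest.approx(1.0,
                                                                    abs=1e-10)

    def test_zero_covariance_flagged(self):
        a = np.diag([0.5, 0.5])
        e = np.diag([0.5, 0.5])
        est = standardize(self._fit_from_components({"A": a, "E": e}))
        assert est.by_sex["F"].biv_shares is None


class TestProfileCI:
    def test_quadratic_objective_matches_wald(self):
        # exactly quadratic deviance: interval is estimate +- 1.96 * SE
        w = np.array([4.0, 1.0, 0.25])
        center = np.array([1.0, -2.0, 0.5])

        def objective(x):
            return float(np.sum(w * (x - center) ** 2))

        crit = 3.841458820694124  # chi2(1) 95% quantile
        iv = profile_interval(objective, center.copy(),
                              lambda x: float(x[0]), crit)
        half = math.sqrt(crit / w[0])
        assert iv.lower == pytest.approx(center[0] - half, abs=1e-4)
        assert iv.upper == pytest.approx(center[0] + half, abs=1e-4)

    def test_interval_brackets_estimate(self):
        ds = simulate_dataset(small_spec(seed=55, n=250))
        fit = fit_biometric(ds, ModelSpec("ACE", AE, "none"), n_starts=1)
        est = standardize(fit)
        h2 = est.by_sex["F"].shares["A"][0]
        iv = profile_ci(fit, "F:share:A:1")
        assert iv.lower <= h2 <= iv.upper
        assert not iv.open_lower and not iv.open_upper
        assert 0.0 < iv.upper - iv.lower < 0.6
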