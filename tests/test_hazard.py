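import math

import numpy as np
import pytest

from ipra._rng import substream
from ipra.exceptions import (
    Ed50UndefinedError,
    ModelError,
    ParameterError,
    SelectionError,
)
from ipra.exposure import DoseMetricSpec, particles_per_mass
from ipra.hazard import (
    MODEL_NAMES,
    BmdUncertaintySet,
    DoseResponseData,
    ExtrapolationModel,
    HazardSample,
    QuantalDoseResponseModel,
    QuantalFitResults,
    aic,
    allometric_ef_inter,
    convert_bmd_metric,
    ed50_numeric,
    fit_quantal_model,
    goodness_of_fit,
    gsd_from_upper_percentile,
    lognormal_from_mean_sd,
    parametric_bootstrap_bmds,
    sample_hazard,
    sample_ibmd,
    select_best,
    solve_intraspecies,
)


def _fit_stub(name, params, loglik=-10.0, k=2, converged=True):
    data = DoseResponseData(doses=(0.0, 1.0), counts=((0,), (1,)))
    return QuantalFitResults(
        model_name=name, params=params, loglik=loglik, k=k,
        converged=converged, boundary=False, data=data,
    )


class TestQuantalFit:
    def test_logistic_ed50_closed_form(self):
        fit = _fit_stub("logistic", {"a": -2.0, "b": 0.001})
        assert fit.ed50 == pytest.approx(2000.0)

    def test_flat_response_has_undefined_ed50(self):
        data = DoseResponseData(
            doses=(0.0, 500.0, 1000.0), counts=((3, 3), (3, 3), (3, 3))
        )
        fit = fit_quantal_model(data, "logistic")
        with pytest.raises(Ed50UndefinedError):
            _ = fit.ed50

    def test_all_zero_response_is_boundary(self):
        data = DoseResponseData(doses=(0.0, 100.0), counts=((0, 0, 0), (0, 0, 0)))
        fit = fit_quantal_model(data, "logistic")
        assert fit.boundary
        with pytest.raises(Ed50UndefinedError):
            _ = fit.ed50

    def test_recovers_simulated_ed50(self, dr_data, seven_fits, bmd_set):
        # the fitted ED50 should sit inside its own bootstrap distribution
        ed50 = seven_fits["logistic"].ed50
        lo, hi = np.quantile(bmd_set.values, [0.025, 0.975])
        assert lo <= ed50 <= hi
        assert ed50 == pytest.approx(1000.0, rel=0.25)

    def test_closed_forms_match_numeric_solver(self, seven_fits):
        for name, fit in seven_fits.items():
            ed = fit.ed50_or_none()
            if ed is None:
                continue
            assert ed == pytest.approx(ed50_numeric(name, fit.theta), rel=1e-8), name

    def test_model_object_interface(self, dr_data):
        res = QuantalDoseResponseModel(dr_data, "probit").fit()
        assert res.converged
        assert "Quantal dose-response fit: probit" in res.summary()

    def test_unknown_model_rejected(self, dr_data):
        with pytest.raises(ModelError):
            fit_quantal_model(dr_data, "hockey-stick")

    def test_overdispersed_fit_adds_parameter(self, dr_data):
        plain = fit_quantal_model(dr_data, "logistic")
        od = fit_quantal_model(dr_data, "logistic", overdispersion=True)
        assert od.k == plain.k + 1
        assert 0 < od.overdispersion < 1


class TestAicSelection:
    def test_aic_identity_from_printed_values(self):
        assert aic(-81.05, k=3) == pytest.approx(168.1)
        assert aic(-86.99, k=2) == pytest.approx(177.98)
        assert aic(0.0, k=0) == 0.0

    def test_aic_identity_on_fits(self, seven_fits):
        for fit in seven_fits.values():
            assert fit.aic == 2 * fit.k - 2 * fit.loglik

    def test_select_best_minimises_aic(self, seven_fits):
        best = select_best(seven_fits)
        assert best.aic == min(f.aic for f in seven_fits.values())

    def test_tie_breaks_prefer_fewer_parameters_then_name_order(self):
        a = _fit_stub("weibull", {"background": 0, "a": 0, "b": 1}, loglik=-9.0, k=3)
        b = _fit_stub("logistic", {"a": 0, "b": 1}, loglik=-10.0, k=2)
        assert select_best([a, b]).model_name == "logistic"  # same AIC 24, fewer params
        c = _fit_stub("probit", {"a": 0, "b": 1}, loglik=-10.0, k=2)
        assert select_best([b, c]).model_name == "logistic"  # name order

    def test_empty_selection_rejected(self):
        with pytest.raises(SelectionError):
            select_best([])


class TestGoodnessOfFit:
    def test_exact_fit_gives_p_one(self):
        from scipy.special import logit

        # fractions 0.2 / 0.5 / 0.8 lie exactly on a logistic in dose
        doses = (0.0, 100.0, 200.0)
        counts = tuple(tuple([2] * 10) for _ in doses)
        counts = (tuple([2] * 10), tuple([5] * 10), tuple([8] * 10))
        data = DoseResponseData(doses=doses, counts=counts)
        fit = fit_quantal_model(data, "logistic")
        p = goodness_of_fit(fit, data)
        assert p == pytest.approx(1.0, abs=1e-5)

    def test_saturated_flag_when_no_df(self, dr_data):
        # background models have 3 parameters; with 3 groups df = 0
        data = DoseResponseData(
            doses=(0.0, 500.0, 1000.0),
            counts=tuple(dr_data.counts[:3]),
        )
        fit = fit_quantal_model(data, "weibull")
        assert fit.gof_saturated
        assert fit.gof_pvalue is None

    def test_fitted_never_beats_saturated(self, seven_fits, dr_data):
        from ipra.hazard import _saturated_loglik

        sat = _saturated_loglik(dr_data)
        for fit in seven_fits.values():
            assert fit.loglik <= sat + 1e-6


class TestParametricBootstrap:
    def test_pool_size_and_determinism(self, seven_fits, dr_data):
        rng = substream(7, 0, "bmd")
        bs = parametric_bootstrap_bmds(seven_fits, dr_data, reps_per_model=10, rng=rng)
        assert len(bs) == 7 * 10 - sum(bs.n_dropped.values())
        bs2 = parametric_bootstrap_bmds(
            seven_fits, dr_data, reps_per_model=10, rng=substream(7, 0, "bmd")
        )
        np.testing.assert_array_equal(bs.values, bs2.values)

    def test_pooled_median_near_nominal(self, bmd_set):
        assert np.median(bmd_set.values) == pytest.approx(bmd_set.nominal, rel=0.25)

    def test_all_values_positive(self, bmd_set):
        assert (bmd_set.values > 0).all()

    def test_empty_set_rejected(self):
        with pytest.raises(Exception):
            BmdUncertaintySet(values=np.array([]), labels=(), nominal=1.0, n_dropped={})


class TestExtrapolationFactors:
    def test_allometric_examples(self):
        assert allometric_ef_inter(70, 0.25) == pytest.approx(4.0906, abs=1e-3)
        assert allometric_ef_inter(5.0, 5.0) == 1.0
        assert allometric_ef_inter(4.0, 1.0) == pytest.approx(math.sqrt(2.0))
        with pytest.raises(ParameterError):
            allometric_ef_inter(-1, 1)

    def test_gsd_from_upper_percentile(self):
        assert gsd_from_upper_percentile(4, 10, 0.99) == pytest.approx(1.4827, abs=1e-4)
        assert gsd_from_upper_percentile(1, 10, 0.95) == pytest.approx(4.055, abs=1e-3)
        # round trip: upper = gm * gsd^z
        from scipy import stats

        gsd = gsd_from_upper_percentile(2.0, 9.0, 0.975)
        assert 2.0 * gsd ** stats.norm.ppf(0.975) == pytest.approx(9.0, rel=1e-12)
        with pytest.raises(ParameterError):
            gsd_from_upper_percentile(4, 3, 0.99)

    def test_lognormal_moment_matching(self):
        mu, s = lognormal_from_mean_sd(1.80, 1.52)
        assert math.exp(mu + s**2 / 2) == pytest.approx(1.80, rel=1e-12)
        assert math.exp(mu + s**2 / 2) * math.sqrt(math.expm1(s**2)) == pytest.approx(
            1.52, rel=1e-12
        )

    def test_intraspecies_joint_solve(self):
        gsd0, nu = solve_intraspecies(2.0, 10.0)
        assert gsd0 == pytest.approx(1.91, abs=0.005)
        assert nu == pytest.approx(6.25, abs=0.15)

    def test_intraspecies_round_trip(self):
        from scipy import stats

        gsd0, nu = solve_intraspecies(2.0, 10.0)
        z = stats.norm.ppf(0.95)
        s0 = math.log(gsd0)
        # P(ratio < 2) and P(ratio > 10) must both be 2.5 %
        p_lo = stats.chi2.sf(s0**2 * nu * z**2 / math.log(2.0) ** 2, nu)
        p_hi = stats.chi2.cdf(s0**2 * nu * z**2 / math.log(10.0) ** 2, nu)
        assert p_lo == pytest.approx(0.025, abs=1e-4)
        assert p_hi == pytest.approx(0.025, abs=1e-4)

    def test_intraspecies_degenerate_bounds(self):
        from scipy import stats

        gsd0, nu = solve_intraspecies(2.0, 2.0)
        assert math.isinf(nu)
        assert gsd0 == pytest.approx(math.exp(math.log(2.0) / stats.norm.ppf(0.95)))


class TestHazardSampling:
    def test_nominal_ibmd_worked_example(self):
        hz = HazardSample(bmd_animal=1160.0, ef_chronic=1.475, ef_inter=4.0, intra_gsd=1.001)
        assert hz.ibmd_geometric_mean == pytest.approx(196.6, abs=0.05)  # 1160 / 5.9

    def test_doubling_ef_inter_halves_draws(self, extrapolation):
        hz1 = HazardSample(1000.0, 1.5, 4.0, 1.91)
        hz2 = HazardSample(1000.0, 1.5, 8.0, 1.91)
        d1 = sample_ibmd(hz1, 1000, np.random.default_rng(3))
        d2 = sample_ibmd(hz2, 1000, np.random.default_rng(3))
        np.testing.assert_allclose(d2, d1 / 2.0, rtol=1e-12)

    def test_geometric_mean_of_ibmd_draws(self):
        hz = HazardSample(1000.0, 1.5, 4.0, 1.91)
        draws = sample_ibmd(hz, 1_000_000, np.random.default_rng(0))
        gm = math.exp(np.log(draws).mean())
        assert gm == pytest.approx(hz.ibmd_geometric_mean, rel=0.005)

    def test_sample_hazard_components(self, bmd_set, extrapolation):
        hz = sample_hazard(bmd_set, extrapolation, np.random.default_rng(1))
        assert hz.bmd_animal in bmd_set.values
        assert hz.ef_chronic > 0 and hz.ef_inter > 0 and hz.intra_gsd > 1

    def test_ef_chronic_draw_moments(self, extrapolation):
        rng = np.random.default_rng(11)
        draws = np.array([extrapolation.draw_ef_chronic(rng) for _ in range(200_000)])
        assert draws.mean() == pytest.approx(1.80, rel=0.02)
        assert draws.std() == pytest.approx(1.52, rel=0.05)

    def test_from_constants_reproduces_nominals(self, extrapolation):
        assert extrapolation.ef_inter_nominal == 4.0
        assert extrapolation.ef_inter_gsd == pytest.approx(1.4827, abs=1e-3)
        assert extrapolation.intra_gsd0 == pytest.approx(1.91, abs=0.005)
        assert extrapolation.ef_chronic_nominal == 1.475


class TestDoseMetricConversion:
    def test_bmd_particle_conversion(self):
        spec = DoseMetricSpec("particle_number", 100.0, 2.2)
        assert convert_bmd_metric(1160.0, spec) == pytest.approx(1007.0, rel=1e-3)
        assert convert_bmd_metric(0.0, spec) == 0.0

    def test_round_trip(self):
        spec = DoseMetricSpec("particle_number", 100.0, 2.2)
        out = convert_bmd_metric(1160.0, spec)
        assert out * 1e12 / particles_per_mass(spec) == pytest.approx(1160.0, rel=1e-12)

    def test_mass_metric_warns_identity(self):
        with pytest.warns(UserWarning):
            assert convert_bmd_metric(5.0, DoseMetricSpec("mass")) == 5.0
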