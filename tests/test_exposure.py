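import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from ipra.exceptions import DataError, LinkageError, ParameterError
from ipra.exposure import (
    ConcentrationTable,
    ConsumptionSurvey,
    DoseMetricSpec,
    ProductLinkTable,
    bootstrap_concentrations,
    bootstrap_survey,
    compute_person_day_exposures,
    exceedance_at,
    exceedance_curve,
    fit_nanofraction,
    link_concentrations,
    particles_per_mass,
)


def _mini_survey(amounts_by_person_day, bw=70.0, n_days=2):
    """amounts_by_person_day: {person: {day: [(food, amount), ...]}}"""
    persons = pd.DataFrame(
        {"person_id": list(amounts_by_person_day), "bw_kg": bw}
    )
    rows = [
        (pid, day, food, amt)
        for pid, days in amounts_by_person_day.items()
        for day, foods in days.items()
        for food, amt in foods
    ]
    records = pd.DataFrame(rows, columns=["person_id", "day", "food_code", "amount_g"])
    return ConsumptionSurvey(persons=persons, records=records, n_days=n_days)


class TestLinkConcentrations:
    def test_single_link_scales_by_fraction(self):
        conc = ConcentrationTable(
            pd.DataFrame(
                {
                    "basic_product": ["Sauce powder"],
                    "measured_product": ["Mix for lasagna sauce"],
                    "total_silica_mg_per_g": [5.4],
                }
            )
        )
        links = ProductLinkTable(
            pd.DataFrame(
                {"food_code": ["sauce"], "basic_product": ["Sauce powder"], "fraction": [0.18]}
            )
        )
        assert link_concentrations(conc, links)["sauce"] == pytest.approx(972.0)

    def test_mean_of_repeated_measurements(self, table1):
        conc, links = table1
        cmap = link_concentrations(conc, links)
        # coffee creamers: mean(5.1, 4.9) mg/g at fraction 1 -> 5000 µg/g
        assert cmap["Pure creamer"] == pytest.approx(5000.0)

    def test_unknown_basic_product_raises(self):
        conc = ConcentrationTable(
            pd.DataFrame(
                {
                    "basic_product": ["a"],
                    "measured_product": ["m"],
                    "total_silica_mg_per_g": [1.0],
                }
            )
        )
        links = ProductLinkTable(
            pd.DataFrame({"food_code": ["f"], "basic_product": ["ghost"], "fraction": [1.0]})
        )
        with pytest.raises(LinkageError):
            link_concentrations(conc, links)


class TestPersonDayExposure:
    def test_worked_example(self):
        survey = _mini_survey({1: {1: [("f", 140.0)]}}, bw=70.0, n_days=1)
        pde = compute_person_day_exposures(survey, {"f": 972.0}, nanofraction=0.5)
        assert pde["idexp"].tolist() == [pytest.approx(972.0)]  # 2 g/kg * 972 * 0.5

    def test_empty_days_and_unlinked_foods_contribute_zero(self):
        survey = _mini_survey({1: {1: [("unlinked", 50.0)]}, 2: {}}, n_days=2)
        pde = compute_person_day_exposures(survey, {"f": 100.0})
        assert len(pde) == 4  # full person-day grid
        assert (pde["idexp"] == 0).all()

    def test_particle_metric_is_exact_rescaling(self):
        survey = _mini_survey({1: {1: [("f", 140.0)], 2: [("f", 30.0)]}})
        spec = DoseMetricSpec("particle_number", 100.0, 2.2)
        mass = compute_person_day_exposures(survey, {"f": 972.0}, 0.5)
        part = compute_person_day_exposures(survey, {"f": 972.0}, 0.5, dose_metric=spec)
        factor = particles_per_mass(spec) / 1000.0 / 1e12
        np.testing.assert_array_equal(part["idexp"], mass["idexp"] * factor)

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_homogeneity_in_amounts_and_nanofraction(self, c):
        survey = _mini_survey({1: {1: [("f", 140.0), ("g", 10.0)]}, 2: {1: [("g", 5.0)]}})
        base = compute_person_day_exposures(survey, {"f": 972.0, "g": 500.0}, 0.5)
        scaled_records = survey.records.assign(amount_g=survey.records["amount_g"] * c)
        scaled = compute_person_day_exposures(
            ConsumptionSurvey(survey.persons, scaled_records, survey.n_days),
            {"f": 972.0, "g": 500.0},
            0.5,
        )
        np.testing.assert_allclose(scaled["idexp"], base["idexp"] * c, rtol=1e-12)
        f_scaled = compute_person_day_exposures(
            survey, {"f": 972.0, "g": 500.0}, 0.5 * min(c, 2.0) / 2.0
        )
        np.testing.assert_allclose(
            f_scaled["idexp"], base["idexp"] * min(c, 2.0) / 2.0, rtol=1e-12
        )

    def test_invalid_nanofraction_rejected(self):
        survey = _mini_survey({1: {1: [("f", 1.0)]}})
        with pytest.raises(ParameterError):
            compute_person_day_exposures(survey, {"f": 1.0}, nanofraction=0.0)


class TestParticlesPerMass:
    def test_unit_density_oracle(self):
        # 100 nm sphere at rho=1: 1/( (pi/6) 1e-15 cm^3 * 1 g/cm^3 ) per g / 1000
        assert particles_per_mass(DoseMetricSpec("mass", 100.0, 1.0)) == pytest.approx(
            1.9099e12, rel=1e-4
        )

    def test_silica_density(self):
        assert particles_per_mass(DoseMetricSpec("mass", 100.0, 2.2)) == pytest.approx(
            8.681e11, rel=1e-4
        )

    def test_cubic_scaling_in_diameter(self):
        small = particles_per_mass(DoseMetricSpec("mass", 100.0, 2.2))
        big = particles_per_mass(DoseMetricSpec("mass", 200.0, 2.2))
        assert small / big == pytest.approx(8.0, rel=1e-12)

    def test_invalid_spec(self):
        with pytest.raises(ParameterError):
            DoseMetricSpec("mass", -1.0, 2.2)
        with pytest.raises(ParameterError):
            DoseMetricSpec("surface_area")


class TestNanofraction:
    def test_fit_from_percentiles(self):
        m = fit_nanofraction(0.5, 0.8)
        assert m.mu == pytest.approx(0.0, abs=1e-12)
        assert m.sigma == pytest.approx(0.8428, abs=2e-4)
        m2 = fit_nanofraction(0.2, 0.8)
        assert m2.mu == pytest.approx(-1.3863, abs=2e-4)
        assert m2.sigma == pytest.approx(1.6857, abs=2e-4)

    def test_degenerate_percentiles_rejected(self):
        with pytest.raises(ParameterError):
            fit_nanofraction(0.5, 0.5 + 1e-12)
        with pytest.raises(ParameterError):
            fit_nanofraction(0.8, 0.5)

    def test_pdf_closed_form_and_normalisation(self):
        m = fit_nanofraction(0.5, 0.8)
        # at the median of a symmetric model: 4 / (sigma sqrt(2 pi))
        assert float(m.pdf(0.5)) == pytest.approx(
            4.0 / (m.sigma * math.sqrt(2 * math.pi)), rel=1e-12
        )
        total, _ = integrate.quad(lambda x: float(m.pdf(x)), 1e-12, 1 - 1e-12)
        assert total == pytest.approx(1.0, abs=1e-6)

    @given(x=st.floats(0.01, 0.99))
    @settings(max_examples=30, deadline=None)
    def test_pdf_symmetry_when_centred(self, x):
        m = fit_nanofraction(0.5, 0.8)
        assert float(m.pdf(x)) == pytest.approx(float(m.pdf(1 - x)), rel=1e-9)

    def test_tail_probabilities(self):
        m = fit_nanofraction(0.5, 0.8)
        up = m.tail_probability(0.85, "upper")
        assert up == pytest.approx(0.0198, abs=5e-4)
        assert m.tail_probability(0.15, "lower") == pytest.approx(up, rel=1e-12)

    def test_sampler_median(self):
        m = fit_nanofraction(0.5, 0.8)
        draws = m.sample(np.random.default_rng(0), 20_000)
        assert np.median(draws) == pytest.approx(0.5, abs=0.01)
        assert ((draws > 0) & (draws < 1)).all()


class TestExceedance:
    def test_strict_exceedance_convention(self):
        assert exceedance_at([1, 2, 3], 0) == 1.0
        assert exceedance_at([1, 2, 3], 2) == pytest.approx(1 / 3)

    def test_curve_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        curve = exceedance_curve(rng.lognormal(size=500))
        frac = curve["fraction_exceeding"].to_numpy()
        assert (np.diff(frac) <= 0).all()
        assert frac.min() >= 0 and frac.max() <= 1

    def test_all_positive_usual_intakes_start_at_one(self):
        assert exceedance_at(np.abs(np.random.default_rng(0).normal(5, 1, 100)), 0) == 1.0


class TestBootstraps:
    def test_survey_bootstrap_preserves_person_count(self, small_survey):
        bs = bootstrap_survey(small_survey, np.random.default_rng(1))
        assert bs.n_persons == small_survey.n_persons
        assert set(bs.records["person_id"]) <= set(bs.persons["person_id"])

    def test_single_person_bootstrap_identical_up_to_relabel(self):
        survey = _mini_survey({7: {1: [("f", 3.0)], 2: [("f", 4.0)]}})
        bs = bootstrap_survey(survey, np.random.default_rng(0))
        assert bs.n_persons == 1
        np.testing.assert_array_equal(
            bs.records["amount_g"].to_numpy(), survey.records["amount_g"].to_numpy()
        )

    def test_two_row_basic_product_resampling_law(self):
        # exact enumeration of the 2^2 resamples: means {4.9, 5.0, 5.1}
        # with probabilities {1/4, 1/2, 1/4}
        conc = ConcentrationTable(
            pd.DataFrame(
                {
                    "basic_product": ["Coffee creamers"] * 2,
                    "measured_product": ["brand a", "brand b"],
                    "total_silica_mg_per_g": [4.9, 5.1],
                }
            )
        )
        rng = np.random.default_rng(12)
        means = [
            bootstrap_concentrations(conc, rng).data["total_silica_mg_per_g"].mean()
            for _ in range(2000)
        ]
        vals, counts = np.unique(np.round(means, 6), return_counts=True)
        freq = dict(zip(vals, counts / 2000))
        assert freq[4.9] == pytest.approx(0.25, abs=0.03)
        assert freq[5.0] == pytest.approx(0.50, abs=0.03)
        assert freq[5.1] == pytest.approx(0.25, abs=0.03)

    def test_concentration_bootstrap_keeps_group_sizes(self, table1):
        conc, _ = table1
        bs = bootstrap_concentrations(conc, np.random.default_rng(5))
        orig = conc.data.groupby("basic_product").size()
        new = bs.data.groupby("basic_product").size()
        pd.testing.assert_series_equal(orig, new)


class TestContainers:
    def test_survey_validation(self):
        with pytest.raises(DataError):
            ConsumptionSurvey(
                pd.DataFrame({"person_id": [1], "bw_kg": [-5.0]}),
                pd.DataFrame(columns=["person_id", "day", "food_code", "amount_g"]),
            )

    def test_link_fraction_domain(self):
        with pytest.raises(DataError):
            ProductLinkTable(
                pd.DataFrame({"food_code": ["f"], "basic_product": ["b"], "fraction": [1.5]})
            )
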