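"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The real inputs of the nanosilica assessment — the Dutch food-consumption
survey (DNFCS 2007-2010) and the rat liver-fibrosis slide counts — are not
public.  This module generates stand-ins that share their structure: a
multi-day 24-h-recall survey with person and day components of log-amount
variation, a measured-product concentration table grouped into basic
products, and Binomial(slides, p(dose)) quantal dose-response data.  It also
loads the packaged concentration/link fixture of the 25 measured products
(13 basic products) with a recorded checksum.

Every generator draws from its own named RNG sub-stream derived from the
seed, so adding generators never perturbs existing outputs and identical
seed + parameters give bitwise-identical tables.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from ._rng import generator_stream
from .exceptions import FixtureIntegrityError, ModelError, ParameterError
from .exposure import ConcentrationTable, ConsumptionSurvey, ProductLinkTable
from .hazard import MODEL_NAMES, DoseResponseData, quantal_response

__all__ = [
    "SurveyParams",
    "DoseResponseParams",
    "generate_survey",
    "generate_concentration_table",
    "generate_dose_response",
    "load_table1_fixture",
    "DEFAULT_FOOD_CODES",
]

_FIXTURE_SHA256 = {
    "table1_concentrations.csv": "528c518d696ed897e3653546f9bcd50d554f06764c778cca59d542ca4608599c",
    "table1_links.csv": "04be427d7be9045410bbdabe38b7aae45f180faca21c2408abe3f979aa811401",
}

#: food codes of the packaged link fixture — the default survey food universe
DEFAULT_FOOD_CODES = (
    "Sauce prepared from sauce powder",
    "Dishes containing sauce",
    "Pure meat seasoning",
    "Dishes containing meat seasoning",
    "Pure cake flour",
    "Cakes containing flour",
    "Noodle dishes",
    "Soup prepared from instant soup powder",
    "Pure creamer",
    "Drinks containing creamer",
    "Pure bread crumbs",
    "Dishes containing bread crumbs",
    "Pure spice mix",
    "Dishes containing spice mix",
    "Dishes containing spice mix and a starch",
    "Pure pancake flour",
    "Pancakes containing pancake flour",
    "Drinks containing cappuccino creamer",
    "Drinks prepared from soy shake",
    "Vitamin C tablets pills and capsules",
    "Multivitamin junior or kid tablets pills and capsules",
)


@dataclass(frozen=True)
class SurveyParams:
    """Parameters of the synthetic two-day recall survey.

    Amounts follow ``exp(log_amount_mean + between_person_sd * z_person(f)
    + within_person_sd * z_day)``; the per-food person effects share a common
    person component with correlation ``person_effect_correlation``, so that
    between- and within-person variation both survive aggregation over foods
    and the usual-intake fit is non-trivial.  Consumption indicators are
    Bernoulli per person-day-food.
    """

    n_persons: int
    n_days: int = 2
    bw_mean_kg: float = 70.0
    bw_sd_kg: float = 12.0
    consumption_prob: float = 0.3
    log_amount_mean: float = math.log(50.0)
    between_person_sd: float = 0.5
    within_person_sd: float = 0.75
    person_effect_correlation: float = 0.5
    food_codes: tuple = DEFAULT_FOOD_CODES
    seed: int = 0

    def __post_init__(self):
        if self.n_persons < 2:
            raise ParameterError("n_persons must be >= 2")
        if self.n_days < 1:
            raise ParameterError("n_days must be >= 1")
        if not 0 <= self.consumption_prob <= 1:
            raise ParameterError("consumption probability must lie in [0, 1]")
        if self.bw_mean_kg <= 0 or self.bw_sd_kg < 0:
            raise ParameterError("body-weight parameters must be positive / non-negative")
        if self.between_person_sd < 0 or self.within_person_sd < 0:
            raise ParameterError("standard deviations must be >= 0")
        if not -1 <= self.person_effect_correlation <= 1:
            raise ParameterError("person-effect correlation must lie in [-1, 1]")
        if len(self.food_codes) == 0:
            raise ParameterError("need at least one food code")


@dataclass(frozen=True)
class DoseResponseParams:
    """Parameters of the synthetic quantal dose-response study.

    ``true_model``/``true_params`` define the simulation truth p(dose) in the
    parameterisation of :mod:`ipra.hazard`; counts are Binomial(slides, p)
    per rat, or beta-binomial with intraclass correlation ``overdispersion``.
    """

    doses: tuple = (0.0, 810.0, 819.0)
    rats_per_group: int = 5
    slides_per_rat: int = 10
    true_model: str = "logistic"
    true_params: dict = field(default_factory=lambda: {"a": -2.0, "b": 2.0 / 1160.0})
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(set(self.doses)) < 2:
            raise ParameterError("need at least 2 distinct dose levels")
        if any(d < 0 for d in self.doses):
            raise ParameterError("doses must be non-negative")
        if self.slides_per_rat < 1:
            raise ParameterError("slides per rat must be >= 1")
        if self.rats_per_group < 1:
            raise ParameterError("rats per group must be >= 1")
        if not 0 <= self.overdispersion < 1:
            raise ParameterError("overdispersion must lie in [0, 1)")
        if self.true_model not in MODEL_NAMES:
            raise ModelError(f"unknown quantal model {self.true_model!r}")


def generate_survey(params: SurveyParams) -> ConsumptionSurvey:
    """Generate a synthetic multi-day recall consumption survey."""
    rng = generator_stream(params.seed, "survey_gen")
    n, ndays = params.n_persons, params.n_days

    bw = params.bw_mean_kg + params.bw_sd_kg * rng.standard_normal(n)
    while (bw <= 1.0).any():  # truncate far-left tail; keep weights physical
        bad = bw <= 1.0
        bw[bad] = params.bw_mean_kg + params.bw_sd_kg * rng.standard_normal(bad.sum())
    persons = pd.DataFrame({"person_id": np.arange(1, n + 1), "bw_kg": bw})

    corr = params.person_effect_correlation
    z_shared = rng.standard_normal(n)
    rows = []
    for food in params.food_codes:
        z_pf = corr * z_shared + math.sqrt(1 - corr**2) * rng.standard_normal(n)
        person_mu = params.log_amount_mean + params.between_person_sd * z_pf
        eats = rng.random((n, ndays)) < params.consumption_prob
        z_day = rng.standard_normal((n, ndays))
        amounts = np.exp(person_mu[:, None] + params.within_person_sd * z_day)
        pid, day = np.nonzero(eats)
        rows.append(
            pd.DataFrame(
                {
                    "person_id": pid + 1,
                    "day": day + 1,
                    "food_code": food,
                    "amount_g": amounts[pid, day],
                }
            )
        )
    records = (
        pd.concat(rows, ignore_index=True).sort_values(
            ["person_id", "day", "food_code"], kind="mergesort", ignore_index=True
        )
        if rows
        else pd.DataFrame(columns=["person_id", "day", "food_code", "amount_g"])
    )
    return ConsumptionSurvey(persons=persons, records=records, n_days=ndays)


def generate_concentration_table(
    n_basic: int,
    reps_range: tuple = (1, 5),
    conc_law: tuple = (5.0, 2.0),
    seed: int = 0,
) -> ConcentrationTable:
    """Synthetic concentration table: ``n_basic`` basic products, each with
    between ``reps_range[0]`` and ``reps_range[1]`` measured products.

    ``conc_law = (median_mg_per_g, gsd)`` is the lognormal law of the
    measured total-silica concentrations; a GSD of 1 is degenerate at the
    median.
    """
    lo, hi = reps_range
    if not (1 <= lo <= hi <= 10):
        raise ParameterError("reps_range must satisfy 1 <= lo <= hi <= 10")
    median, gsd = conc_law
    if median <= 0 or gsd < 1:
        raise ParameterError("concentration law needs median > 0 and GSD >= 1")
    rng = generator_stream(seed, "concentration_gen")
    sdlog = math.log(gsd)
    rows = []
    for b in range(1, n_basic + 1):
        reps = int(rng.integers(lo, hi + 1))
        for r in range(1, reps + 1):
            conc = median * math.exp(sdlog * rng.standard_normal())
            rows.append((f"basic_{b:02d}", f"measured_{b:02d}_{r}", conc))
    return ConcentrationTable(
        pd.DataFrame(rows, columns=["basic_product", "measured_product", "total_silica_mg_per_g"])
    )


def generate_dose_response(params: DoseResponseParams) -> DoseResponseData:
    """Generate per-rat positive-slide counts from a known quantal truth."""
    rng = generator_stream(params.seed, "dose_response_gen")
    m = params.slides_per_rat
    counts = []
    for dose in params.doses:
        p = float(np.clip(quantal_response(params.true_model, params.true_params, [dose])[0], 0, 1))
        if params.overdispersion > 0:
            s = (1.0 - params.overdispersion) / params.overdispersion
            a, b = max(p * s, 1e-9), max((1.0 - p) * s, 1e-9)
            p_rat = rng.beta(a, b, size=params.rats_per_group)
            counts.append(tuple(int(c) for c in rng.binomial(m, p_rat)))
        else:
            counts.append(tuple(int(c) for c in rng.binomial(m, p, size=params.rats_per_group)))
    return DoseResponseData(doses=tuple(float(d) for d in params.doses), counts=tuple(counts),
                            slides_per_rat=m)


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("ipra.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureIntegrityError(f"fixture {name} failed checksum ({digest})")
    import io

    return pd.read_csv(io.BytesIO(raw))


def load_table1_fixture() -> tuple:
    """Packaged concentration and product-link tables of the 25 measured products.

    Returns ``(ConcentrationTable, ProductLinkTable)``.  Left-censored
    nano-range values ("<0.1 mg/g") carry the bound in
    ``nanosilica_mg_per_g`` with ``nano_censored == 1``; the pipeline uses
    only total silica (the nanofraction model replaces nano measurements).
    """
    conc = _read_fixture("table1_concentrations.csv")
    links = _read_fixture("table1_links.csv")
    return ConcentrationTable(conc), ProductLinkTable(links)
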