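"""Dietary exposure assessment for nanosilica.

Person-day exposure combines a two-day recall survey with measured silica
concentrations of "basic" powder products linked to consumed foods:

    IDEXP = sum_k CONS_k * CONC_k,        CONC_k = F * C_k

where CONS_k is consumption of food k in g per kg body weight, C_k the total
silica concentration of the food (from its basic-product composition) and F
the nanofraction — the uncertain fraction of total silica present in
nano-form, modelled logistic-normal on (0, 1).

The canonical internal exposure unit is µg/kg BW/day (mass metric).  The
particle-number metric (10^12 particles/kg BW/day) is a deterministic
monodisperse-sphere conversion at the median particle diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .exceptions import DataError, LinkageError, ParameterError

__all__ = [
    "ConsumptionSurvey",
    "ConcentrationTable",
    "ProductLinkTable",
    "NanofractionModel",
    "DoseMetricSpec",
    "link_concentrations",
    "compute_person_day_exposures",
    "particles_per_mass",
    "fit_nanofraction",
    "nanofraction_pdf",
    "sample_nanofraction",
    "tail_probability",
    "exceedance_curve",
    "exceedance_at",
    "bootstrap_survey",
    "bootstrap_concentrations",
]

SURVEY_PERSON_COLUMNS = ("person_id", "bw_kg")
SURVEY_RECORD_COLUMNS = ("person_id", "day", "food_code", "amount_g")
CONCENTRATION_COLUMNS = ("basic_product", "measured_product", "total_silica_mg_per_g")
LINK_COLUMNS = ("food_code", "basic_product", "fraction")


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ConsumptionSurvey:
    """A two-day (in general ``n_days``-day) 24-hour recall consumption survey.

    Parameters
    ----------
    persons
        One row per respondent: ``person_id``, ``bw_kg`` (body weight, kg).
    records
        One row per consumed food on a person-day: ``person_id``, ``day``
        (1-based), ``food_code``, ``amount_g``.
    n_days
        Number of recall days per respondent.
    """

    persons: pd.DataFrame
    records: pd.DataFrame
    n_days: int = 2

    def __post_init__(self):
        for col in SURVEY_PERSON_COLUMNS:
            if col not in self.persons.columns:
                raise DataError(f"survey persons table missing column {col!r}")
        for col in SURVEY_RECORD_COLUMNS:
            if col not in self.records.columns:
                raise DataError(f"survey records table missing column {col!r}")
        if len(self.persons) == 0:
            raise DataError("survey has no persons")
        if self.persons["person_id"].duplicated().any():
            raise DataError("duplicate person ids")
        if (self.persons["bw_kg"] <= 0).any():
            raise DataError("body weights must be positive")
        if len(self.records):
            if (self.records["amount_g"] < 0).any():
                raise DataError("consumption amounts must be non-negative")
            unknown = set(self.records["person_id"]) - set(self.persons["person_id"])
            if unknown:
                raise DataError(f"records refer to unknown persons: {sorted(unknown)[:5]}")
            days = self.records["day"]
            if (days < 1).any() or (days > self.n_days).any():
                raise DataError("record day index outside 1..n_days")

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def body_weights(self) -> pd.Series:
        return self.persons.set_index("person_id")["bw_kg"]


@dataclass(frozen=True)
class ConcentrationTable:
    """Measured total-silica concentrations (mg/g) grouped into basic products.

    Optional columns ``nanosilica_mg_per_g`` and ``nano_censored`` preserve
    the measured nano-range values; left-censored entries ("<0.1") carry the
    bound with ``nano_censored == 1``.  The pipeline itself uses only total
    silica — the nanofraction model replaces direct nano measurements.
    """

    data: pd.DataFrame

    def __post_init__(self):
        for col in CONCENTRATION_COLUMNS:
            if col not in self.data.columns:
                raise DataError(f"concentration table missing column {col!r}")
        if (self.data["total_silica_mg_per_g"] < 0).any():
            raise DataError("concentrations must be non-negative")
        if self.data.duplicated(["basic_product", "measured_product"]).any():
            raise DataError("duplicate (basic, measured) product pair")

    @property
    def basic_products(self) -> list:
        return sorted(self.data["basic_product"].unique())

    def n_basic_products(self) -> int:
        return self.data["basic_product"].nunique()


@dataclass(frozen=True)
class ProductLinkTable:
    """Composition links: consumed food -> basic product with a mass fraction."""

    data: pd.DataFrame

    def __post_init__(self):
        for col in LINK_COLUMNS:
            if col not in self.data.columns:
                raise DataError(f"link table missing column {col!r}")
        frac = self.data["fraction"]
        if ((frac <= 0) | (frac > 1)).any():
            raise DataError("link fractions must lie in (0, 1]")


# ---------------------------------------------------------------------------
# nanofraction (logistic-normal on (0,1))


@dataclass(frozen=True)
class NanofractionModel:
    """Logistic-normal uncertainty distribution of the nanofraction F.

    ``logit(F) ~ Normal(mu, sigma^2)``; the median is ``expit(mu)``.
    """

    mu: float
    sigma: float
    nominal: float = 0.5

    def __post_init__(self):
        if not self.sigma > 1e-8:
            raise ParameterError("nanofraction sigma must exceed 1e-8")
        if not 0 < self.nominal < 1:
            raise ParameterError("nominal nanofraction must lie in (0, 1)")

    @property
    def median(self) -> float:
        return float(expit(self.mu))

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        if np.any((x <= 0) | (x >= 1)):
            raise ParameterError("nanofraction pdf is defined on (0, 1)")
        z = (logit(x) - self.mu) / self.sigma
        return np.exp(-0.5 * z**2) / (self.sigma * math.sqrt(2 * math.pi)) / (x * (1 - x))

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.empty_like(x)
        out[x <= 0] = 0.0
        out[x >= 1] = 1.0
        inside = (x > 0) & (x < 1)
        out[inside] = stats.norm.cdf((logit(x[inside]) - self.mu) / self.sigma)
        return out if out.ndim else float(out)

    def sample(self, rng: np.random.Generator, size=None):
        z = rng.standard_normal(size)
        return expit(self.mu + self.sigma * z)

    def tail_probability(self, threshold: float, side: str = "upper") -> float:
        if not 0 < threshold < 1:
            raise ParameterError("threshold must lie in (0, 1)")
        z = (logit(threshold) - self.mu) / self.sigma
        if side == "upper":
            return float(stats.norm.sf(z))
        if side == "lower":
            return float(stats.norm.cdf(z))
        raise ParameterError(f"side must be 'upper' or 'lower', got {side!r}")


def fit_nanofraction(p50: float, p95: float) -> NanofractionModel:
    """Fit the logistic-normal nanofraction from its median and 95th percentile."""
    if not (0 < p50 < p95 < 1):
        raise ParameterError("need 0 < p50 < p95 < 1")
    mu = float(logit(p50))
    sigma = float((logit(p95) - mu) / stats.norm.ppf(0.95))
    if sigma <= 1e-8:
        raise ParameterError("degenerate nanofraction: p95 too close to p50")
    return NanofractionModel(mu=mu, sigma=sigma, nominal=p50)


def nanofraction_pdf(model: NanofractionModel, x):
    return model.pdf(x)


def sample_nanofraction(model: NanofractionModel, rng: np.random.Generator, size=None):
    return model.sample(rng, size)


def tail_probability(model: NanofractionModel, threshold: float, side: str = "upper") -> float:
    return model.tail_probability(threshold, side)


# ---------------------------------------------------------------------------
# dose metric


@dataclass(frozen=True)
class DoseMetricSpec:
    """Dose-metric convention: mass (mg/kg BW/day) or particle number.

    Particle counts assume monodisperse spheres at the median diameter
    (default 100 nm) with amorphous-silica density 2.2 g/cm^3; both the
    exposure and the hazard side use the same spec, so the conversion
    cancels in the margin of exposure.
    """

    metric: str = "mass"
    median_diameter_nm: float = 100.0
    particle_density_g_cm3: float = 2.2

    def __post_init__(self):
        if self.metric not in ("mass", "particle_number"):
            raise ParameterError(f"unknown dose metric {self.metric!r}")
        if self.median_diameter_nm <= 0 or self.particle_density_g_cm3 <= 0:
            raise ParameterError("diameter and density must be positive")


def particles_per_mass(spec: DoseMetricSpec) -> float:
    """Number of particles per mg for monodisperse spheres.

    ``1 / (rho * (pi/6) * d^3)`` with d in cm and rho in g/cm^3 gives
    particles per gram; divided by 1000 for per mg.
    """
    d_cm = spec.median_diameter_nm * 1e-7
    mass_per_particle_g = spec.particle_density_g_cm3 * (math.pi / 6.0) * d_cm**3
    return 1.0 / (mass_per_particle_g * 1000.0)


# ---------------------------------------------------------------------------
# linking and person-day exposure


def link_concentrations(conc: ConcentrationTable, links: ProductLinkTable, summary=None) -> dict:
    """Map each linked food code to a silica concentration in µg per g food.

    concentration(food) = sum over linked basics of
    fraction × summary(basic measurements, mg/g) × 1000.  The default
    per-basic-product summary is the arithmetic mean of its measured
    products, matching the bootstrap-of-mean uncertainty logic.
    """
    if summary is None:
        summary = np.mean
    basic_summary = (
        conc.data.groupby("basic_product")["total_silica_mg_per_g"].apply(summary).to_dict()
    )
    out: dict = {}
    for row in links.data.itertuples(index=False):
        if row.basic_product not in basic_summary:
            raise LinkageError(f"link refers to unknown basic product {row.basic_product!r}")
        out[row.food_code] = (
            out.get(row.food_code, 0.0)
            + row.fraction * basic_summary[row.basic_product] * 1000.0
        )
    return out


def compute_person_day_exposures(
    survey: ConsumptionSurvey,
    conc_map: dict,
    nanofraction: float = 0.5,
    dose_metric: DoseMetricSpec | None = None,
) -> pd.DataFrame:
    """Per person-day nanosilica exposure.

    Returns a frame with one row for every (person, day) cell — including
    zero-exposure days — with column ``idexp`` in µg/kg BW/day under the
    mass metric, or 10^12 particles/kg BW/day under the particle-number
    metric.  Foods absent from ``conc_map`` contribute nothing.
    """
    if not 0 < nanofraction <= 1:
        raise ParameterError("nanofraction F must lie in (0, 1]")
    if dose_metric is None:
        dose_metric = DoseMetricSpec()
    bw = survey.body_weights()
    if bw.isna().any():
        raise DataError("missing body weight")

    # full person-day grid so no-consumption days appear with exposure 0
    grid = pd.MultiIndex.from_product(
        [survey.persons["person_id"], range(1, survey.n_days + 1)], names=["person_id", "day"]
    )
    if len(survey.records):
        rec = survey.records.copy()
        rec["conc_ug_per_g"] = rec["food_code"].map(conc_map).fillna(0.0)
        rec["contrib"] = (
            rec["amount_g"] / rec["person_id"].map(bw).to_numpy() * rec["conc_ug_per_g"]
        )
        per_day = rec.groupby(["person_id", "day"])["contrib"].sum()
    else:
        per_day = pd.Series(dtype=float)
    idexp = per_day.reindex(grid, fill_value=0.0) * nanofraction
    out = idexp.rename("idexp").reset_index()
    if dose_metric.metric == "particle_number":
        # µg → particles: per-µg count is the per-mg count / 1000; report in 1e12 N
        out["idexp"] = out["idexp"] * (particles_per_mass(dose_metric) / 1000.0 / 1e12)
    return out


# ---------------------------------------------------------------------------
# exceedance curve


def exceedance_curve(values) -> pd.DataFrame:
    """1 − empirical CDF at the sorted unique values (strict exceedance)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("empty distribution")
    xs = np.unique(v)
    frac = np.array([(v > x).mean() for x in xs])
    return pd.DataFrame({"x": xs, "fraction_exceeding": frac})


def exceedance_at(values, x: float) -> float:
    """Fraction of values strictly greater than ``x``."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("empty distribution")
    return float((v > x).mean())


# ---------------------------------------------------------------------------
# bootstrap resamplers (uncertainty loop)


def bootstrap_survey(survey: ConsumptionSurvey, rng: np.random.Generator) -> ConsumptionSurvey:
    """Resample persons with replacement, keeping each person's full record set.

    Resampled persons receive fresh sequential ids so that a person drawn
    twice remains two distinct respondents.
    """
    ids = survey.persons["person_id"].to_numpy()
    picked = rng.choice(ids, size=len(ids), replace=True)
    persons = survey.persons.set_index("person_id").loc[picked].reset_index()
    persons["person_id"] = np.arange(1, len(picked) + 1)
    rec_by_person = dict(tuple(survey.records.groupby("person_id"))) if len(survey.records) else {}
    chunks = []
    for new_id, old_id in enumerate(picked, start=1):
        rec = rec_by_person.get(old_id)
        if rec is not None:
            rec = rec.copy()
            rec["person_id"] = new_id
            chunks.append(rec)
    records = (
        pd.concat(chunks, ignore_index=True)
        if chunks
        else survey.records.iloc[0:0].copy()
    )
    return ConsumptionSurvey(persons=persons, records=records, n_days=survey.n_days)


def bootstrap_concentrations(
    conc: ConcentrationTable, rng: np.random.Generator
) -> ConcentrationTable:
    """Within each basic product, resample its measured rows with replacement."""
    chunks = []
    for basic, grp in conc.data.groupby("basic_product", sort=True):
        idx = rng.integers(0, len(grp), size=len(grp))
        g = grp.iloc[idx].copy()
        # keep (basic, measured) pairs unique after resampling
        g["measured_product"] = [
            f"{m} [resample {i}]" for i, m in enumerate(g["measured_product"], start=1)
        ]
        chunks.append(g)
    return ConcentrationTable(pd.concat(chunks, ignore_index=True))
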