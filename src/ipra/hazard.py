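"""Hazard characterisation: quantal dose-response models and extrapolation factors.

The animal benchmark dose (BMD) is the ED50 of a quantal model fitted to
rat liver-fibrosis data — the number of positive fibrosis slides out of 10
per rat, Binomial(10, p(dose)).  Seven model families are supported
(logistic, probit, log-logistic, log-probit, weibull, gamma, two-stage);
model uncertainty is carried by pooling parametric-bootstrap ED50s across
all seven families.

The individual benchmark dose divides BMD_animal by three factors:

    IBMD = BMD_animal / (EF_chronic * EF_inter * IEF_intra)

EF_chronic (subchronic-to-chronic) is lognormal-uncertain; EF_inter
(rat-to-average-human) comes from allometric caloric-demand scaling
(bw_human/bw_rat)^0.25 with lognormal uncertainty; IEF_intra is the
per-individual sensitivity factor, lognormal with geometric mean 1 and a
geometric standard deviation that is itself uncertain (scaled chi-square).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammainc, gammaincinv, gammaln, logit, ndtr

from .exceptions import (
    DataError,
    Ed50UndefinedError,
    FitError,
    ModelError,
    ParameterError,
    SelectionError,
    SolverError,
)
from .exposure import DoseMetricSpec, particles_per_mass

__all__ = [
    "MODEL_NAMES",
    "DoseResponseData",
    "QuantalDoseResponseModel",
    "QuantalFitResults",
    "fit_quantal_model",
    "fit_all_models",
    "quantal_response",
    "aic",
    "select_best",
    "goodness_of_fit",
    "parametric_bootstrap_bmds",
    "BmdUncertaintySet",
    "ExtrapolationModel",
    "HazardSample",
    "allometric_ef_inter",
    "gsd_from_upper_percentile",
    "solve_intraspecies",
    "lognormal_from_mean_sd",
    "sample_hazard",
    "sample_ibmd",
    "convert_bmd_metric",
]

#: fixed model-name order; also the tie-break order in model selection
MODEL_NAMES = (
    "logistic",
    "probit",
    "log-logistic",
    "log-probit",
    "weibull",
    "gamma",
    "two-stage",
)

_BACKGROUND_MODELS = frozenset(MODEL_NAMES[2:])
_LN2 = math.log(2.0)
_EPS_P = 1e-12
_EPS_SLOPE = 1e-10


# ---------------------------------------------------------------------------
# data container


@dataclass(frozen=True)
class DoseResponseData:
    """Quantal dose-response data: per-rat positive-slide counts by dose group."""

    doses: tuple  # mg/kg BW/day, one per group
    counts: tuple  # tuple of int tuples, one per group
    slides_per_rat: int = 10

    def __post_init__(self):
        if len(self.doses) != len(self.counts):
            raise DataError("doses and counts must have the same length")
        if len(set(self.doses)) < 2:
            raise DataError("need at least 2 distinct dose levels")
        if any(d < 0 for d in self.doses):
            raise DataError("doses must be non-negative")
        if self.slides_per_rat < 1:
            raise DataError("slides per rat must be >= 1")
        for grp in self.counts:
            if len(grp) == 0:
                raise DataError("each dose group needs at least one rat")
            if any(c < 0 or c > self.slides_per_rat for c in grp):
                raise DataError("slide counts must lie in [0, slides per rat]")

    @classmethod
    def from_groups(cls, groups, slides_per_rat=10):
        doses = tuple(float(d) for d, _ in groups)
        counts = tuple(tuple(int(c) for c in cs) for _, cs in groups)
        return cls(doses=doses, counts=counts, slides_per_rat=slides_per_rat)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame):
        need = {"dose_mg_per_kg_bw_day", "positive_slides", "total_slides"}
        missing = need - set(df.columns)
        if missing:
            raise DataError(f"dose-response table missing columns {sorted(missing)}")
        slides = df["total_slides"].unique()
        if len(slides) != 1:
            raise DataError("total_slides must be constant")
        groups = [
            (dose, grp["positive_slides"].tolist())
            for dose, grp in df.groupby("dose_mg_per_kg_bw_day", sort=True)
        ]
        return cls.from_groups(groups, slides_per_rat=int(slides[0]))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        rat = 1
        for g, (dose, cs) in enumerate(zip(self.doses, self.counts), start=1):
            for c in cs:
                rows.append((g, dose, rat, c, self.slides_per_rat))
                rat += 1
        return pd.DataFrame(
            rows,
            columns=["group", "dose_mg_per_kg_bw_day", "rat_id", "positive_slides", "total_slides"],
        )

    # sufficient statistics for the plain-binomial likelihood
    def group_stats(self):
        doses = np.asarray(self.doses, dtype=float)
        y = np.array([sum(c) for c in self.counts], dtype=float)
        n = np.array([len(c) * self.slides_per_rat for c in self.counts], dtype=float)
        return doses, y, n

    def binomial_constant(self) -> float:
        """sum of ln C(slides, y) over rats (additive constant of the log-likelihood)."""
        m = self.slides_per_rat
        tot = 0.0
        for grp in self.counts:
            for c in grp:
                tot += gammaln(m + 1) - gammaln(c + 1) - gammaln(m - c + 1)
        return float(tot)

    @property
    def n_groups(self) -> int:
        return len(self.doses)


# ---------------------------------------------------------------------------
# model forms


def _response(name, theta, doses):
    d = np.asarray(doses, dtype=float)
    if name == "logistic":
        a, b = theta
        return expit(a + b * d)
    if name == "probit":
        a, b = theta
        return ndtr(a + b * d)
    with np.errstate(divide="ignore"):
        logd = np.where(d > 0, np.log(np.where(d > 0, d, 1.0)), -np.inf)
    if name == "log-logistic":
        p0, a, b = theta
        g = np.where(d > 0, expit(a + b * logd), 0.0)
    elif name == "log-probit":
        p0, a, b = theta
        g = np.where(d > 0, ndtr(a + b * logd), 0.0)
    elif name == "weibull":
        p0, a, b = theta
        g = np.where(d > 0, -np.expm1(-np.exp(a + b * logd)), 0.0)
    elif name == "gamma":
        p0, shape, rate = theta
        g = gammainc(shape, rate * d)
    elif name == "two-stage":
        p0, q1, q2 = theta
        g = -np.expm1(-(q1 * d + q2 * d * d))
    else:
        raise ModelError(f"unknown quantal model {name!r}")
    return p0 + (1.0 - p0) * g


def quantal_response(name: str, params: dict, doses):
    """Response probability p(dose) for a named model and parameter dict."""
    theta = [params[k] for k in _PARAM_NAMES[name]]
    return _response(name, theta, doses)


_PARAM_NAMES = {
    "logistic": ("a", "b"),
    "probit": ("a", "b"),
    "log-logistic": ("background", "a", "b"),
    "log-probit": ("background", "a", "b"),
    "weibull": ("background", "a", "b"),
    "gamma": ("background", "shape", "rate"),
    "two-stage": ("background", "q1", "q2"),
}

_BOUNDS = {
    "logistic": [(-30.0, 30.0), (0.0, None)],
    "probit": [(-15.0, 15.0), (0.0, None)],
    "log-logistic": [(0.0, 0.995), (-60.0, 60.0), (_EPS_SLOPE, 30.0)],
    "log-probit": [(0.0, 0.995), (-40.0, 40.0), (_EPS_SLOPE, 20.0)],
    "weibull": [(0.0, 0.995), (-60.0, 60.0), (1e-3, 20.0)],
    "gamma": [(0.0, 0.995), (0.05, 60.0), (0.0, None)],
    "two-stage": [(0.0, 0.995), (0.0, None), (0.0, None)],
}


def _ed50_closed_form(name, theta):
    """Dose where the response is midway between background and 1."""
    if name in ("logistic", "probit"):
        a, b = theta
        if b <= _EPS_SLOPE:
            raise Ed50UndefinedError(f"{name}: slope at zero boundary")
        d = -a / b
        if d <= 0:
            raise Ed50UndefinedError(f"{name}: halfway dose not positive")
        return float(d)
    if name in ("log-logistic", "log-probit"):
        _, a, b = theta
        if b <= _EPS_SLOPE:
            raise Ed50UndefinedError(f"{name}: slope at zero boundary")
        return float(math.exp(-a / b))
    if name == "weibull":
        _, a, b = theta
        if b <= _EPS_SLOPE:
            raise Ed50UndefinedError("weibull: power at zero boundary")
        return float(math.exp((math.log(_LN2) - a) / b))
    if name == "gamma":
        _, shape, rate = theta
        if rate <= _EPS_SLOPE:
            raise Ed50UndefinedError("gamma: rate at zero boundary")
        return float(gammaincinv(shape, 0.5) / rate)
    if name == "two-stage":
        _, q1, q2 = theta
        if q1 <= _EPS_SLOPE and q2 <= _EPS_SLOPE:
            raise Ed50UndefinedError("two-stage: both stage terms at zero boundary")
        if q2 <= _EPS_SLOPE:
            return float(_LN2 / q1)
        return float((-q1 + math.sqrt(q1 * q1 + 4.0 * q2 * _LN2)) / (2.0 * q2))
    raise ModelError(f"unknown quantal model {name!r}")


def ed50_numeric(name, theta, bracket_hi=1e12):
    """Generic numeric ED50: root of p(d) = (background + 1)/2.

    Cross-checks the closed forms; uses the same midway-to-one convention.
    """
    p0 = theta[0] if name in _BACKGROUND_MODELS else 0.0
    target = (p0 + 1.0) / 2.0

    def f(d):
        return float(_response(name, theta, np.array([d]))[0]) - target

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 10.0
        if hi > bracket_hi:
            raise Ed50UndefinedError(f"{name}: response never reaches halfway point")
    return float(optimize.brentq(f, lo, hi, xtol=1e-14, rtol=1e-13))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class QuantalFitResults:
    """Fit of one quantal model: parameters, likelihood, AIC, ED50, diagnostics."""

    model_name: str
    params: dict
    loglik: float
    k: int
    converged: bool
    boundary: bool
    data: DoseResponseData = field(repr=False)
    gof_pvalue: float | None = None
    gof_saturated: bool = False
    overdispersion: float | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def theta(self):
        return [self.params[k] for k in _PARAM_NAMES[self.model_name]]

    @property
    def ed50(self) -> float:
        if self.boundary:
            raise Ed50UndefinedError(f"{self.model_name}: fit at response boundary")
        p = self.predict(np.asarray(self.data.doses))
        if float(np.ptp(p)) < 1e-8:  # no dose-response signal over the design
            raise Ed50UndefinedError(f"{self.model_name}: fitted curve is flat")
        return _ed50_closed_form(self.model_name, self.theta)

    def ed50_or_none(self):
        try:
            return self.ed50
        except Ed50UndefinedError:
            return None

    def predict(self, doses):
        return _response(self.model_name, self.theta, doses)

    def summary(self) -> str:
        lines = [
            f"Quantal dose-response fit: {self.model_name}",
            f"  parameters : "
            + ", ".join(f"{k}={v:.6g}" for k, v in self.params.items()),
            f"  log-lik    : {self.loglik:.4f}   k={self.k}   AIC={self.aic:.4f}",
            f"  converged  : {self.converged}   boundary: {self.boundary}",
        ]
        ed = self.ed50_or_none()
        lines.append(f"  ED50 (BMD) : {ed:.6g} mg/kg BW/day" if ed else "  ED50 (BMD) : undefined")
        if self.gof_saturated:
            lines.append("  GOF        : saturated (df <= 0)")
        elif self.gof_pvalue is not None:
            lines.append(f"  GOF p      : {self.gof_pvalue:.4f}")
        return "\n".join(lines)


def _neg_loglik_binom(theta, name, doses, y, n):
    p = np.clip(_response(name, theta, doses), _EPS_P, 1.0 - _EPS_P)
    return -float(np.sum(y * np.log(p) + (n - y) * np.log1p(-p)))


def _start_values(name, data: DoseResponseData):
    doses, y, n = data.group_stats()
    frac = np.clip(y / n, 0.01, 0.99)
    p0 = float(frac[np.argmin(doses)])
    p0 = min(max(p0, 0.001), 0.9)
    dpos = doses[doses > 0]
    dmed = float(np.median(dpos)) if dpos.size else 1.0
    starts = []
    if name in ("logistic", "probit"):
        # crude linear fit on the link scale
        link = logit if name == "logistic" else stats.norm.ppf
        z = link(frac)
        b0 = (z[-1] - z[0]) / (doses[-1] - doses[0] + 1e-12)
        b0 = max(b0, 1e-6)
        a0 = float(np.mean(z) - b0 * np.mean(doses))
        starts = [(a0, b0), (z[0], max(b0 * 3, 1e-5)), (-1.0, 1.0 / dmed)]
    elif name in ("log-logistic", "log-probit"):
        for b0 in (1.0, 3.0):
            starts.append((p0, -b0 * math.log(dmed), b0))
    elif name == "weibull":
        for b0 in (1.0, 2.0):
            starts.append((p0, math.log(_LN2) - b0 * math.log(dmed), b0))
    elif name == "gamma":
        for shape in (1.0, 2.0):
            starts.append((p0, shape, gammaincinv(shape, 0.5) / dmed))
    elif name == "two-stage":
        starts = [(p0, _LN2 / dmed, 0.0), (p0, 0.0, _LN2 / dmed**2)]
    return starts


def fit_quantal_model(
    data: DoseResponseData, model_name: str, overdispersion: bool = False
) -> QuantalFitResults:
    """Maximum-likelihood fit of one quantal model (plain binomial by default).

    With ``overdispersion=True`` the per-rat likelihood is beta-binomial with
    an extra intraclass-correlation parameter (one more degree of freedom).
    Slopes are constrained non-negative; backgrounds to [0, 1).
    """
    if model_name not in MODEL_NAMES:
        raise ModelError(f"unknown quantal model {model_name!r}")
    doses, y, n = data.group_stats()
    const = data.binomial_constant()

    all_zero = y.sum() == 0
    all_max = (y == n).all()
    # identical group fractions at every dose: the ML slope is zero and the
    # halfway dose does not exist
    flat = bool(np.ptp(y / n) == 0.0)

    if overdispersion:
        counts = [np.asarray(c) for c in data.counts]
        m = data.slides_per_rat

        def nll(theta):
            rho = theta[-1]
            p = np.clip(_response(model_name, theta[:-1], doses), _EPS_P, 1.0 - _EPS_P)
            s = (1.0 - rho) / max(rho, 1e-9)
            tot = 0.0
            for pi, cs in zip(p, counts):
                tot += float(
                    stats.betabinom.logpmf(cs, m, pi * s, (1.0 - pi) * s).sum()
                )
            return -tot

        extra_bounds = [(1e-6, 0.95)]
        extra_start = [0.05]
    else:
        def nll(theta):
            return _neg_loglik_binom(theta, model_name, doses, y, n)

        extra_bounds, extra_start = [], []

    bounds = _BOUNDS[model_name] + extra_bounds
    starts = [np.array(list(s) + extra_start, dtype=float) for s in _start_values(model_name, data)]
    # optimise from the most promising start first; fall back to the others
    starts.sort(key=lambda x0: nll(x0))
    best = None
    for x0 in starts:
        try:
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-9},
            )
        except (ValueError, FloatingPointError):  # pragma: no cover - defensive
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if best is not None and best.success:
            break
    if best is None:
        raise FitError(f"{model_name}: all optimiser starts failed")
    if not best.success:  # polish an L-BFGS-B stall near machine precision
        x1 = np.clip(
            best.x,
            [lo if lo is not None else -np.inf for lo, _ in bounds],
            [hi if hi is not None else np.inf for _, hi in bounds],
        )
        res_nm = optimize.minimize(
            lambda t: nll(
                np.clip(
                    t,
                    [lo if lo is not None else -np.inf for lo, _ in bounds],
                    [hi if hi is not None else np.inf for _, hi in bounds],
                )
            ),
            x1,
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-11},
        )
        if res_nm.fun <= best.fun + 1e-9:
            res_nm.x = np.clip(
                res_nm.x,
                [lo if lo is not None else -np.inf for lo, _ in bounds],
                [hi if hi is not None else np.inf for _, hi in bounds],
            )
            best = res_nm

    theta = best.x
    if overdispersion:
        core, rho = theta[:-1], float(theta[-1])
        loglik = -best.fun
        k = len(core) + 1
    else:
        core, rho = theta, None
        loglik = -best.fun + const
        k = len(core)
    params = dict(zip(_PARAM_NAMES[model_name], (float(v) for v in core)))
    fit = QuantalFitResults(
        model_name=model_name,
        params=params,
        loglik=float(loglik),
        k=k,
        converged=bool(best.success),
        boundary=bool(all_zero or all_max or flat),
        data=data,
        overdispersion=rho,
    )
    if not overdispersion:
        fit.gof_pvalue, fit.gof_saturated = _gof(fit, data)
    return fit


class QuantalDoseResponseModel:
    """statsmodels-style wrapper: model object built from data, ``fit`` -> results."""

    def __init__(self, data: DoseResponseData, model_name: str = "logistic"):
        if model_name not in MODEL_NAMES:
            raise ModelError(f"unknown quantal model {model_name!r}")
        self.data = data
        self.model_name = model_name

    def fit(self, overdispersion: bool = False) -> QuantalFitResults:
        return fit_quantal_model(self.data, self.model_name, overdispersion=overdispersion)


def fit_all_models(data: DoseResponseData, overdispersion: bool = False) -> dict:
    """Fit all seven model families; returns {name: QuantalFitResults}."""
    return {
        name: fit_quantal_model(data, name, overdispersion=overdispersion)
        for name in MODEL_NAMES
    }


# ---------------------------------------------------------------------------
# AIC, selection, goodness of fit


def aic(fit_or_loglik, k: int | None = None) -> float:
    """AIC = 2k − 2 logL; accepts a results object or (logL, k)."""
    if k is None:
        return float(fit_or_loglik.aic)
    return 2.0 * k - 2.0 * float(fit_or_loglik)


def select_best(fits) -> QuantalFitResults:
    """Lowest-AIC converged fit; ties go to fewer parameters then name order."""
    if isinstance(fits, dict):
        fits = list(fits.values())
    fits = [f for f in fits if f.converged]
    if not fits:
        raise SelectionError("no converged fits to select from")
    order = {name: i for i, name in enumerate(MODEL_NAMES)}
    return min(fits, key=lambda f: (round(f.aic, 9), f.k, order[f.model_name]))


def _saturated_loglik(data: DoseResponseData) -> float:
    _, y, n = data.group_stats()
    with np.errstate(divide="ignore", invalid="ignore"):
        f = y / n
        term = np.where(y > 0, y * np.log(f), 0.0) + np.where(
            n - y > 0, (n - y) * np.log1p(-f), 0.0
        )
    return float(term.sum()) + data.binomial_constant()


def _gof(fit: QuantalFitResults, data: DoseResponseData):
    df = data.n_groups - fit.k
    if df <= 0:
        return None, True
    stat = max(0.0, 2.0 * (_saturated_loglik(data) - fit.loglik))
    return float(stats.chi2.sf(stat, df)), False


def goodness_of_fit(fit: QuantalFitResults, data: DoseResponseData | None = None):
    """Likelihood-ratio GOF p-value vs the saturated (one p per group) model.

    Returns the p-value, or None with ``fit.gof_saturated`` when the model has
    as many dose parameters as groups.
    """
    data = data or fit.data
    p, saturated = _gof(fit, data)
    fit.gof_pvalue, fit.gof_saturated = p, saturated
    return p


# ---------------------------------------------------------------------------
# parametric bootstrap of the BMD


@dataclass(frozen=True)
class BmdUncertaintySet:
    """Pooled parametric-bootstrap ED50s across model families."""

    values: np.ndarray
    labels: tuple
    nominal: float
    n_dropped: dict

    def __post_init__(self):
        if len(self.values) == 0:
            raise DataError("empty BMD set")
        if (np.asarray(self.values) <= 0).any():
            raise DataError("BMD values must be positive")

    def __len__(self):
        return len(self.values)

    def sample(self, rng: np.random.Generator) -> float:
        """One uncertainty draw: uniform with replacement over the pooled set."""
        return float(self.values[rng.integers(0, len(self.values))])


def parametric_bootstrap_bmds(
    fits,
    data: DoseResponseData,
    reps_per_model: int = 100,
    rng: np.random.Generator | None = None,
) -> BmdUncertaintySet:
    """Pool parametric-bootstrap ED50s across the seven fitted models.

    For each model, ``reps_per_model`` datasets are simulated from its fitted
    group probabilities (binomial per rat at the original design) and refitted
    with the same family; non-converged or boundary refits are dropped and
    counted.  With seven models and 100 reps the pooled set holds 700 values.
    """
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(fits, dict):
        fit_list = [fits[name] for name in MODEL_NAMES if name in fits]
    else:
        fit_list = list(fits)
    values, labels = [], []
    n_dropped = {}
    m = data.slides_per_rat
    group_sizes = [len(c) for c in data.counts]
    for fit in fit_list:
        p = np.clip(fit.predict(np.asarray(data.doses)), 0.0, 1.0)
        dropped = 0
        for _ in range(reps_per_model):
            counts = tuple(
                tuple(rng.binomial(m, pi, size=sz)) for pi, sz in zip(p, group_sizes)
            )
            sim = DoseResponseData(doses=data.doses, counts=counts, slides_per_rat=m)
            try:
                refit = fit_quantal_model(sim, fit.model_name)
                if not refit.converged:
                    raise FitError("refit did not converge")
                values.append(refit.ed50)
                labels.append(fit.model_name)
            except (FitError, Ed50UndefinedError):
                dropped += 1
        n_dropped[fit.model_name] = dropped
        if dropped > 0.2 * reps_per_model:
            warnings.warn(
                f"{fit.model_name}: {dropped}/{reps_per_model} bootstrap refits dropped",
                stacklevel=2,
            )
    nominal = select_best(fit_list).ed50
    return BmdUncertaintySet(
        values=np.asarray(values, dtype=float),
        labels=tuple(labels),
        nominal=float(nominal),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# extrapolation factors


def allometric_ef_inter(bw_human: float = 70.0, bw_rat: float = 0.25) -> float:
    """Interspecies factor from caloric-demand scaling: (bw_human/bw_rat)^0.25."""
    if bw_human <= 0 or bw_rat <= 0:
        raise ParameterError("body weights must be positive")
    return float((bw_human / bw_rat) ** 0.25)


def gsd_from_upper_percentile(gm: float, upper: float, level: float = 0.99) -> float:
    """GSD of a lognormal with geometric mean ``gm`` whose ``level`` percentile is ``upper``."""
    if not (upper > gm > 0):
        raise ParameterError("need upper > geometric mean > 0")
    if not 0.5 < level < 1:
        raise ParameterError("percentile level must lie in (0.5, 1)")
    return float(math.exp(math.log(upper / gm) / stats.norm.ppf(level)))


def lognormal_from_mean_sd(mean: float, sd: float):
    """(mu, sigma) of a lognormal from its arithmetic mean and standard deviation."""
    if mean <= 0 or sd <= 0:
        raise ParameterError("mean and sd must be positive")
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def solve_intraspecies(
    lower: float = 2.0,
    upper: float = 10.0,
    coverage: float = 0.95,
    variability_percentile: float = 0.95,
):
    """Joint solve for the intraspecies variability GSD and its chi-square df.

    The sensitive-person ratio exp(z_p * sigma) — how much more sensitive the
    ``variability_percentile`` person is than the average person — is uncertain
    through sigma^2 = sigma0^2 * nu / chi2(nu).  Setting the central
    ``coverage`` uncertainty interval of the ratio to [lower, upper] pins both
    sigma0 and nu: the quantile ratio chi2_{1-a,nu}/chi2_{a,nu} must equal
    (ln upper / ln lower)^2, a 1-D root in nu, after which sigma0 follows in
    closed form.  Returns ``(nominal_gsd, nu)`` with nominal_gsd = exp(sigma0).
    """
    if not 1.0 < lower <= upper:
        raise ParameterError("need 1 < lower <= upper")
    z = stats.norm.ppf(variability_percentile)
    alpha = (1.0 - coverage) / 2.0
    if upper == lower:  # degenerate: no uncertainty, nu -> infinity
        return float(math.exp(math.log(lower) / z)), math.inf
    target = (math.log(upper) / math.log(lower)) ** 2

    def g(nu):
        return stats.chi2.ppf(1 - alpha, nu) / stats.chi2.ppf(alpha, nu) - target

    lo, hi = 0.1, 200.0
    if g(lo) < 0 or g(hi) > 0:
        raise SolverError("no chi-square df root in (0.1, 200)")
    nu = optimize.brentq(g, lo, hi, xtol=1e-12)
    sigma0 = math.log(lower) * math.sqrt(stats.chi2.ppf(1 - alpha, nu) / nu) / z
    return float(math.exp(sigma0)), float(nu)


@dataclass(frozen=True)
class ExtrapolationModel:
    """The three extrapolation-factor models with nominal values and uncertainty.

    Nominal (uncertainty-off) values: EF_chronic 1.475, EF_inter 4 (allometric
    value rounded to the nearest integer), intraspecies GSD 1.91.
    """

    ef_chronic_nominal: float = 1.475
    ef_chronic_mean: float = 1.80
    ef_chronic_sd: float = 1.52
    ef_inter_nominal: float = 4.0
    ef_inter_gsd: float = 1.4827
    intra_gsd0: float = 1.91
    intra_df: float = 6.3
    bw_human: float = 70.0
    bw_rat: float = 0.25

    def __post_init__(self):
        for name in ("ef_chronic_nominal", "ef_inter_nominal", "intra_gsd0", "intra_df"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.ef_inter_gsd <= 1 or self.intra_gsd0 <= 1:
            raise ParameterError("GSDs must exceed 1")

    @classmethod
    def from_constants(
        cls,
        bw_human: float = 70.0,
        bw_rat: float = 0.25,
        ef_chronic_nominal: float = 1.475,
        ef_chronic_mean: float = 1.80,
        ef_chronic_sd: float = 1.52,
        ef_inter_p99: float = 10.0,
        intra_bounds=(2.0, 10.0),
    ) -> "ExtrapolationModel":
        """Derive all factor models from the printed constants."""
        ef_inter = float(np.round(allometric_ef_inter(bw_human, bw_rat)))
        gsd_inter = gsd_from_upper_percentile(ef_inter, ef_inter_p99, 0.99)
        gsd0, df = solve_intraspecies(*intra_bounds)
        return cls(
            ef_chronic_nominal=ef_chronic_nominal,
            ef_chronic_mean=ef_chronic_mean,
            ef_chronic_sd=ef_chronic_sd,
            ef_inter_nominal=ef_inter,
            ef_inter_gsd=gsd_inter,
            intra_gsd0=gsd0,
            intra_df=df,
            bw_human=bw_human,
            bw_rat=bw_rat,
        )

    # uncertainty draws -----------------------------------------------------
    def draw_ef_chronic(self, rng: np.random.Generator) -> float:
        mu, s = lognormal_from_mean_sd(self.ef_chronic_mean, self.ef_chronic_sd)
        return float(math.exp(mu + s * rng.standard_normal()))

    def draw_ef_inter(self, rng: np.random.Generator) -> float:
        return float(
            self.ef_inter_nominal
            * math.exp(math.log(self.ef_inter_gsd) * rng.standard_normal())
        )

    def draw_intra_gsd(self, rng: np.random.Generator) -> float:
        """One draw of the uncertain intraspecies GSD: sigma^2 = sigma0^2 nu / chi2_nu."""
        sigma0 = math.log(self.intra_gsd0)
        if math.isinf(self.intra_df):
            return float(self.intra_gsd0)
        x = rng.chisquare(self.intra_df)
        sigma = sigma0 * math.sqrt(self.intra_df / x)
        return float(math.exp(sigma))


@dataclass(frozen=True)
class HazardSample:
    """One outer-loop (uncertainty) draw of the hazard components."""

    bmd_animal: float
    ef_chronic: float
    ef_inter: float
    intra_gsd: float

    def __post_init__(self):
        if min(self.bmd_animal, self.ef_chronic, self.ef_inter, self.intra_gsd) <= 0:
            raise ParameterError("hazard components must be positive")

    @property
    def ibmd_geometric_mean(self) -> float:
        return self.bmd_animal / (self.ef_chronic * self.ef_inter)


def sample_hazard(
    bmd_set: BmdUncertaintySet, extrapolation: ExtrapolationModel, rng: np.random.Generator
) -> HazardSample:
    """Draw one uncertainty realisation of all four hazard components."""
    return HazardSample(
        bmd_animal=bmd_set.sample(rng),
        ef_chronic=extrapolation.draw_ef_chronic(rng),
        ef_inter=extrapolation.draw_ef_inter(rng),
        intra_gsd=extrapolation.draw_intra_gsd(rng),
    )


def sample_ibmd(sample: HazardSample, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inner (variability) loop: n individual benchmark doses.

    IBMD_i = bmd / (ef_chronic * ef_inter * IEF_i) with the individual
    sensitivity factor IEF_i lognormal, geometric mean 1, GSD = intra draw.
    """
    if n < 1:
        raise ParameterError("need n >= 1 draws")
    ief = np.exp(math.log(sample.intra_gsd) * rng.standard_normal(n))
    return sample.ibmd_geometric_mean / ief


def convert_bmd_metric(bmd_mg: float, spec: DoseMetricSpec) -> float:
    """Convert a BMD in mg/kg BW/day to 10^12 particles/kg BW/day."""
    if spec.metric != "particle_number":
        warnings.warn("mass metric: BMD conversion is the identity", stacklevel=2)
        return float(bmd_mg)
    return float(bmd_mg * particles_per_mass(spec) / 1e12)
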