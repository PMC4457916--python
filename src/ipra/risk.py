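"""Two-dimensional Monte Carlo risk characterisation.

The outer loop samples *uncertainty* — bootstrap resamples of the
consumption survey and of the concentration measurements, a nanofraction
draw, a pooled-BMD draw and extrapolation-factor draws.  The inner loop
samples *variability* — a fresh simulated population of usual exposures
IEXP from the fitted usual-intake model, and individual benchmark doses
IBMD from the intraspecies sensitivity distribution.  Each inner pair gives
an individual margin of exposure

    IMoE = IBMD / IEXP,        at risk when IMoE < 1,

and each outer iteration records the variability percentiles of the IMoE
distribution, so that percentile uncertainty and IMoE "bars" (box between
two variability percentiles, whiskers at one-sided uncertainty bounds) can
be summarised.

Every uncertainty source has its own named RNG sub-stream per outer
iteration, so toggling one source on or off never perturbs the draws of the
others — the factorial sensitivity analysis depends on this.

IMoE is computed on the mass scale; the dose-metric choice converts only the
reported exposure/hazard distributions (the conversion factor cancels in the
ratio, making the two metrics identical by construction for the IMoE).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .exceptions import (
    DataError,
    DegenerateDataError,
    FitError,
    ParameterError,
    RunError,
)
from .exposure import (
    ConcentrationTable,
    ConsumptionSurvey,
    DoseMetricSpec,
    NanofractionModel,
    ProductLinkTable,
    bootstrap_concentrations,
    bootstrap_survey,
    compute_person_day_exposures,
    link_concentrations,
    particles_per_mass,
)
from .hazard import BmdUncertaintySet, ExtrapolationModel, HazardSample, sample_ibmd
from .usual_intake import UsualIntakeModel

__all__ = [
    "SourceToggles",
    "IpraConfig",
    "IpraModel",
    "ImoeResult",
    "ImoeBar",
    "run_ipra",
    "imoe_percentile_bounds",
    "fraction_at_risk",
    "prob_population_safe",
    "PERCENTILE_LEVELS",
]

PERCENTILE_LEVELS = (0.1, 1.0, 5.0, 50.0, 95.0, 99.0, 99.9)

SOURCE_NAMES = ("consumption", "concentration", "nanofraction", "bmd", "chronic", "inter", "intra")


def _plabel(level: float) -> str:
    return f"p{level:g}"


@dataclass(frozen=True)
class SourceToggles:
    """On/off switches for the seven uncertainty sources (fixed order)."""

    consumption: bool = True
    concentration: bool = True
    nanofraction: bool = True
    bmd: bool = True
    chronic: bool = True
    inter: bool = True
    intra: bool = True

    @classmethod
    def all_on(cls) -> "SourceToggles":
        return cls()

    @classmethod
    def all_off(cls) -> "SourceToggles":
        return cls(**{name: False for name in SOURCE_NAMES})

    @classmethod
    def from_tuple(cls, bits) -> "SourceToggles":
        if len(bits) != len(SOURCE_NAMES):
            raise ParameterError("need exactly seven toggle values")
        return cls(**dict(zip(SOURCE_NAMES, (bool(b) for b in bits))))

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, name) for name in SOURCE_NAMES)


@dataclass(frozen=True)
class IpraConfig:
    """Settings of the two-dimensional Monte Carlo scheme."""

    outer: int = 500
    inner: int = 100_000
    master_seed: int = 0
    dose_metric: DoseMetricSpec = field(default_factory=DoseMetricSpec)
    percentile_pairs: tuple = ((0.1, 99.9), (1.0, 99.0), (5.0, 95.0))
    toggles: SourceToggles = field(default_factory=SourceToggles)
    max_skipped_fraction: float = 0.05

    def __post_init__(self):
        if self.outer < 1:
            raise ParameterError("outer iterations must be >= 1")
        if self.inner < 1000:
            raise ParameterError("inner sample size must be >= 1000")
        for lo, hi in self.percentile_pairs:
            if not (0 < lo < hi < 100):
                raise ParameterError("percentile pairs must satisfy 0 < lower < upper < 100")


@dataclass(frozen=True)
class ImoeBar:
    """Box-and-whisker summary of one variability-percentile pair.

    Box edges are the nominal-run variability percentiles; the left whisker
    is the lower one-sided uncertainty bound (across outer iterations) of
    the lower percentile, the right whisker the upper bound of the upper
    percentile; the dashed centre is the nominal median.
    """

    lower_level: float
    upper_level: float
    box_lower: float
    box_upper: float
    whisker_lower: float
    whisker_upper: float
    median: float

    def __post_init__(self):
        if self.whisker_lower > self.whisker_upper:
            raise DataError("lower whisker exceeds upper whisker")


class ImoeResult:
    """Per-outer-iteration IMoE percentiles plus the nominal (all-off) run."""

    def __init__(
        self,
        iterations: pd.DataFrame,
        nominal: pd.Series,
        config: IpraConfig,
        n_skipped: int = 0,
        nominal_iexp: np.ndarray | None = None,
        nominal_ibmd: np.ndarray | None = None,
    ):
        for level in PERCENTILE_LEVELS:
            col = _plabel(level)
            if col not in iterations.columns:
                raise DataError(f"missing percentile column {col}")
        pcols = [_plabel(lv) for lv in PERCENTILE_LEVELS]
        pm = iterations[pcols].to_numpy()
        if len(pm) and (np.diff(pm, axis=1) < -1e-12).any():
            raise DataError("percentiles must be non-decreasing in level")
        if len(pm) and (pm <= 0).any():
            raise DataError("IMoE percentiles must be positive")
        self.iterations = iterations
        self.nominal = nominal
        self.config = config
        self.n_skipped = n_skipped
        self.nominal_iexp = nominal_iexp
        self.nominal_ibmd = nominal_ibmd

    # -- accessors ----------------------------------------------------------

    def percentile(self, level: float) -> pd.Series:
        col = _plabel(level)
        if col not in self.iterations.columns:
            raise ParameterError(f"percentile {level} was not recorded")
        return self.iterations[col]

    def bar(self, pair, levels=(0.05, 0.95)) -> ImoeBar:
        return imoe_percentile_bounds(self, pair, levels)

    def bars(self, levels=(0.05, 0.95)) -> list:
        return [self.bar(pair, levels) for pair in self.config.percentile_pairs]

    def prob_population_safe(self, percentile: float) -> float:
        return prob_population_safe(self, percentile)

    def summary(self) -> str:
        lines = [
            "Two-dimensional Monte Carlo IMoE result",
            f"  outer iterations : {len(self.iterations)} (skipped {self.n_skipped})",
            f"  inner sample     : {self.config.inner}",
            f"  dose metric      : {self.config.dose_metric.metric}",
            f"  toggles on       : "
            + (", ".join(n for n in SOURCE_NAMES if getattr(self.config.toggles, n)) or "none"),
            "",
            "  IMoE bars (box = nominal variability percentiles; whiskers = "
            "5%/95% one-sided uncertainty):",
        ]
        for bar in self.bars():
            lines.append(
                f"    p{bar.lower_level:g}-p{bar.upper_level:g}: "
                f"[{bar.whisker_lower:.3g} | {bar.box_lower:.3g} .. "
                f"{bar.box_upper:.3g} | {bar.whisker_upper:.3g}]  median {bar.median:.3g}"
            )
        p1_safe = self.prob_population_safe(1.0)
        lines.append("")
        lines.append(
            f"  P(p1 of IMoE > 1) across uncertainty iterations: {p1_safe:.3f}"
        )
        return "\n".join(lines)

    # -- serialisation ------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "config": {
                "outer": self.config.outer,
                "inner": self.config.inner,
                "master_seed": self.config.master_seed,
                "dose_metric": {
                    "metric": self.config.dose_metric.metric,
                    "median_diameter_nm": self.config.dose_metric.median_diameter_nm,
                    "particle_density_g_cm3": self.config.dose_metric.particle_density_g_cm3,
                },
                "percentile_pairs": [list(p) for p in self.config.percentile_pairs],
                "toggles": dict(zip(SOURCE_NAMES, self.config.toggles.as_tuple())),
            },
            "n_skipped": self.n_skipped,
            "nominal": self.nominal.to_dict(),
            "iterations": self.iterations.to_dict(orient="list"),
            "bars": [
                {
                    "lower_level": b.lower_level,
                    "upper_level": b.upper_level,
                    "box_lower": b.box_lower,
                    "box_upper": b.box_upper,
                    "whisker_lower": b.whisker_lower,
                    "whisker_upper": b.whisker_upper,
                    "median": b.median,
                }
                for b in self.bars()
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# the engine


class IpraModel:
    """Integrated probabilistic risk assessment model (two-dimensional MC).

    Built from the four data inputs plus the uncertainty models; ``run``
    executes the scheme and returns an :class:`ImoeResult`.
    """

    def __init__(
        self,
        survey: ConsumptionSurvey,
        concentrations: ConcentrationTable,
        links: ProductLinkTable,
        bmd_set: BmdUncertaintySet,
        extrapolation: ExtrapolationModel,
        nanofraction: NanofractionModel,
        config: IpraConfig | None = None,
    ):
        self.survey = survey
        self.concentrations = concentrations
        self.links = links
        self.bmd_set = bmd_set
        self.extrapolation = extrapolation
        self.nanofraction = nanofraction
        self.config = config or IpraConfig()
        self._base_fit = None  # cached usual-intake fit on the unresampled data

    # exposure side ---------------------------------------------------------

    def _fit_usual(self, survey, conc):
        """Fit the usual-intake model on unit-nanofraction exposures.

        The nanofraction multiplies every exposure, which on the log scale
        only shifts the amount intercept; fitting once at F = 1 and scaling
        the simulated usual intakes afterwards is exact.
        """
        conc_map = link_concentrations(conc, self.links)
        pde = compute_person_day_exposures(survey, conc_map, nanofraction=1.0)
        return UsualIntakeModel(pde).fit()

    def _exposure_sample(self, iteration, toggles, master, n):
        if toggles.consumption:
            survey = bootstrap_survey(self.survey, substream(master, iteration, "consumption"))
        else:
            survey = self.survey
        if toggles.concentration:
            conc = bootstrap_concentrations(
                self.concentrations, substream(master, iteration, "concentration")
            )
        else:
            conc = self.concentrations
        if toggles.nanofraction:
            f_draw = float(
                self.nanofraction.sample(substream(master, iteration, "nanofraction"))
            )
        else:
            f_draw = self.nanofraction.nominal

        if not toggles.consumption and not toggles.concentration:
            if self._base_fit is None:
                self._base_fit = self._fit_usual(self.survey, self.concentrations)
            fit = self._base_fit
        else:
            fit = self._fit_usual(survey, conc)
        iexp_ug = fit.simulate(n, substream(master, iteration, "exposure_inner")) * f_draw
        return iexp_ug / 1000.0, f_draw  # mg/kg BW/day

    # hazard side -----------------------------------------------------------

    def _hazard_sample(self, iteration, toggles, master):
        if toggles.bmd:
            bmd = self.bmd_set.sample(substream(master, iteration, "bmd"))
        else:
            bmd = self.bmd_set.nominal
        ex = self.extrapolation
        efc = (
            ex.draw_ef_chronic(substream(master, iteration, "chronic"))
            if toggles.chronic
            else ex.ef_chronic_nominal
        )
        efi = (
            ex.draw_ef_inter(substream(master, iteration, "inter"))
            if toggles.inter
            else ex.ef_inter_nominal
        )
        gsd = (
            ex.draw_intra_gsd(substream(master, iteration, "intra"))
            if toggles.intra
            else ex.intra_gsd0
        )
        return HazardSample(bmd_animal=bmd, ef_chronic=efc, ef_inter=efi, intra_gsd=gsd)

    def _iteration(self, iteration, toggles, master, n):
        iexp, f_draw = self._exposure_sample(iteration, toggles, master, n)
        hz = self._hazard_sample(iteration, toggles, master)
        ibmd = sample_ibmd(hz, n, substream(master, iteration, "hazard_inner"))
        imoe = ibmd / iexp  # independent pairing of variability draws
        row = {
            "iteration": iteration,
            "nanofraction": f_draw,
            "bmd_animal": hz.bmd_animal,
            "ef_chronic": hz.ef_chronic,
            "ef_inter": hz.ef_inter,
            "intra_gsd": hz.intra_gsd,
            "fraction_at_risk": float((imoe < 1.0).mean()),
        }
        pcts = np.percentile(imoe, PERCENTILE_LEVELS)
        row.update({_plabel(lv): v for lv, v in zip(PERCENTILE_LEVELS, pcts)})
        return row, iexp, ibmd

    # run -------------------------------------------------------------------

    def run(self, seed: int | None = None) -> ImoeResult:
        cfg = self.config
        master = cfg.master_seed if seed is None else int(seed)
        # note: _base_fit caches the usual-intake fit on the *unresampled* data
        # with F = 1; it is seed-independent and safe to reuse across runs
        rows, skipped = [], 0
        for i in range(cfg.outer):
            try:
                row, _, _ = self._iteration(i, cfg.toggles, master, cfg.inner)
                rows.append(row)
            except (FitError, DegenerateDataError) as exc:
                skipped += 1
                warnings.warn(f"iteration {i} skipped: {exc}", stacklevel=2)
        if skipped > cfg.max_skipped_fraction * cfg.outer:
            raise RunError(f"{skipped}/{cfg.outer} iterations failed the usual-intake fit")

        nominal_row, iexp, ibmd = self._iteration(
            cfg.outer, SourceToggles.all_off(), master, cfg.inner
        )
        # reported exposure/hazard samples in the configured dose metric
        spec = cfg.dose_metric
        if spec.metric == "particle_number":
            factor = particles_per_mass(spec) / 1e12  # per mg, reported in 1e12 N
            iexp_rep, ibmd_rep = iexp * factor, ibmd * factor
        else:
            iexp_rep, ibmd_rep = iexp, ibmd
        return ImoeResult(
            iterations=pd.DataFrame(rows),
            nominal=pd.Series(nominal_row),
            config=cfg,
            n_skipped=skipped,
            nominal_iexp=iexp_rep,
            nominal_ibmd=ibmd_rep,
        )


def run_ipra(
    config: IpraConfig,
    survey: ConsumptionSurvey,
    concentrations: ConcentrationTable,
    links: ProductLinkTable,
    bmd_set: BmdUncertaintySet,
    extrapolation: ExtrapolationModel,
    nanofraction: NanofractionModel,
    seed: int | None = None,
) -> ImoeResult:
    """Functional entry point for the two-dimensional Monte Carlo run."""
    return IpraModel(
        survey, concentrations, links, bmd_set, extrapolation, nanofraction, config
    ).run(seed=seed)


# ---------------------------------------------------------------------------
# summaries


def imoe_percentile_bounds(result: ImoeResult, pair, levels=(0.05, 0.95)) -> ImoeBar:
    """IMoE bar for one variability-percentile pair.

    Whiskers are empirical quantiles, across outer iterations, of the lower
    and upper variability percentile respectively (linear interpolation of
    order statistics).
    """
    lo_level, hi_level = pair
    for lv in (lo_level, hi_level):
        if _plabel(lv) not in result.iterations.columns:
            raise ParameterError(f"percentile {lv} was not recorded")
    if len(result.iterations) < 20:
        warnings.warn(
            "fewer than 20 outer iterations: whisker quantiles are unstable", stacklevel=2
        )
    lo_vals = result.iterations[_plabel(lo_level)].to_numpy()
    hi_vals = result.iterations[_plabel(hi_level)].to_numpy()
    return ImoeBar(
        lower_level=lo_level,
        upper_level=hi_level,
        box_lower=float(result.nominal[_plabel(lo_level)]),
        box_upper=float(result.nominal[_plabel(hi_level)]),
        whisker_lower=float(np.quantile(lo_vals, levels[0])),
        whisker_upper=float(np.quantile(hi_vals, levels[1])),
        median=float(result.nominal[_plabel(50.0)]),
    )


def fraction_at_risk(imoe_draws) -> float:
    """Fraction of individual margins of exposure strictly below one."""
    v = np.asarray(imoe_draws, dtype=float)
    if v.size == 0:
        raise DataError("empty IMoE sample")
    return float((v < 1.0).mean())


def prob_population_safe(result: ImoeResult, percentile: float) -> float:
    """Uncertainty probability that the given IMoE percentile exceeds one."""
    vals = result.percentile(percentile).to_numpy()
    if vals.size == 0:
        raise DataError("no outer iterations recorded")
    return float((vals > 1.0).mean())
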