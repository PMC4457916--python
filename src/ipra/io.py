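"""Table and configuration I/O.

CSV schemas (headers mandatory, UTF-8, decimal point):

* survey:         person_id,bw_kg,day,food_code,amount_g
* concentration:  basic_product,measured_product,total_silica_mg_per_g
                  [,nanosilica_mg_per_g,nano_censored]
* links:          food_code,basic_product,fraction
* dose-response:  group,dose_mg_per_kg_bw_day,rat_id,positive_slides,total_slides

A surveyed person with no consumption records is preserved through the
survey CSV by a sentinel row with an empty food code and amount 0; the
reader folds it back into a record-less person.  Numeric fields round-trip
losslessly at 12 significant digits.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ParameterError, SchemaError
from .exposure import (
    ConcentrationTable,
    ConsumptionSurvey,
    DoseMetricSpec,
    ProductLinkTable,
)
from .hazard import DoseResponseData
from .risk import SOURCE_NAMES, IpraConfig, SourceToggles

__all__ = [
    "read_survey",
    "write_survey",
    "read_concentrations",
    "write_concentrations",
    "read_links",
    "write_links",
    "read_dose_response",
    "write_dose_response",
    "RunConfig",
    "read_config",
]

logger = logging.getLogger("ipra")

_FLOAT_FMT = "%.12g"
_NO_FOOD = ""  # sentinel food code for record-less persons


def _read_table(path, required, numeric):
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col!r}")
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            row = int(np.argmax(bad.to_numpy())) + 2  # 1-based + header line
            raise SchemaError(f"{path.name}: non-numeric value in {col!r} at line {row}")
    logger.info("read %s: %d rows", path.name, len(df))
    return df


# -- survey -----------------------------------------------------------------


def read_survey(path, n_days: int | None = None) -> ConsumptionSurvey:
    df = _read_table(
        path,
        required=("person_id", "bw_kg", "day", "food_code", "amount_g"),
        numeric=("person_id", "bw_kg", "day", "amount_g"),
    )
    df["food_code"] = df["food_code"].fillna(_NO_FOOD)
    persons = df.groupby("person_id", sort=True)["bw_kg"].first().reset_index()
    records = df[(df["food_code"] != _NO_FOOD)][
        ["person_id", "day", "food_code", "amount_g"]
    ].reset_index(drop=True)
    if n_days is None:
        n_days = int(df["day"].max()) if len(df) else 1
    return ConsumptionSurvey(persons=persons, records=records, n_days=n_days)


def write_survey(survey: ConsumptionSurvey, path) -> None:
    rec = survey.records.merge(survey.persons, on="person_id")
    rec = rec[["person_id", "bw_kg", "day", "food_code", "amount_g"]]
    lonely = set(survey.persons["person_id"]) - set(survey.records["person_id"])
    if lonely:
        extra = survey.persons[survey.persons["person_id"].isin(lonely)].copy()
        extra["day"], extra["food_code"], extra["amount_g"] = 1, _NO_FOOD, 0.0
        rec = pd.concat(
            [rec, extra[["person_id", "bw_kg", "day", "food_code", "amount_g"]]],
            ignore_index=True,
        )
    rec = rec.sort_values(["person_id", "day", "food_code"], kind="mergesort")
    rec.to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")


# -- concentrations, links, dose-response -----------------------------------


def read_concentrations(path) -> ConcentrationTable:
    df = _read_table(
        path,
        required=("basic_product", "measured_product", "total_silica_mg_per_g"),
        numeric=("total_silica_mg_per_g",),
    )
    return ConcentrationTable(df)


def write_concentrations(conc: ConcentrationTable, path) -> None:
    conc.data.to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")


def read_links(path) -> ProductLinkTable:
    df = _read_table(
        path, required=("food_code", "basic_product", "fraction"), numeric=("fraction",)
    )
    return ProductLinkTable(df)


def write_links(links: ProductLinkTable, path) -> None:
    links.data.to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")


def read_dose_response(path) -> DoseResponseData:
    df = _read_table(
        path,
        required=("group", "dose_mg_per_kg_bw_day", "rat_id", "positive_slides", "total_slides"),
        numeric=("dose_mg_per_kg_bw_day", "positive_slides", "total_slides"),
    )
    return DoseResponseData.from_dataframe(df)


def write_dose_response(data: DoseResponseData, path) -> None:
    data.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")


# -- configuration ----------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Run configuration: input locations, Monte Carlo settings, constants."""

    seed: int = 0
    output_dir: str = "ipra_out"
    log_level: str = "INFO"
    # input paths or synthetic-generation blocks (dicts)
    survey: object = None
    concentration: object = "fixture"
    links: object = "fixture"
    dose_response: object = None
    ipra: IpraConfig = dataclasses.field(default_factory=IpraConfig)
    # extrapolation + nanofraction + dose-metric constants
    bw_human: float = 70.0
    bw_rat: float = 0.25
    ef_chronic_nominal: float = 1.475
    ef_chronic_mean: float = 1.80
    ef_chronic_sd: float = 1.52
    ef_inter_p99: float = 10.0
    intra_lower: float = 2.0
    intra_upper: float = 10.0
    nanofraction_p50: float = 0.5
    nanofraction_p95: float = 0.8
    bootstrap_reps_per_model: int = 100

    def __post_init__(self):
        for name in (
            "bw_human",
            "bw_rat",
            "ef_chronic_nominal",
            "ef_chronic_mean",
            "ef_chronic_sd",
            "ef_inter_p99",
            "nanofraction_p50",
            "nanofraction_p95",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"constant {name} must be positive")


def _build_ipra_config(block: dict, seed: int) -> IpraConfig:
    metric_block = block.get("dose_metric", {})
    if isinstance(metric_block, str):
        metric_block = {"metric": metric_block}
    spec = DoseMetricSpec(
        metric=metric_block.get("metric", "mass"),
        median_diameter_nm=float(metric_block.get("median_diameter_nm", 100.0)),
        particle_density_g_cm3=float(metric_block.get("particle_density_g_cm3", 2.2)),
    )
    toggles_block = block.get("toggles", {})
    unknown = set(toggles_block) - set(SOURCE_NAMES)
    if unknown:
        raise SchemaError(f"unknown uncertainty toggles: {sorted(unknown)}")
    toggles = SourceToggles(**{n: bool(toggles_block.get(n, True)) for n in SOURCE_NAMES})
    pairs = tuple(
        tuple(float(v) for v in pair)
        for pair in block.get("percentile_pairs", [(0.1, 99.9), (1.0, 99.0), (5.0, 95.0)])
    )
    return IpraConfig(
        outer=int(block.get("outer", 500)),
        inner=int(block.get("inner", 100_000)),
        master_seed=seed,
        dose_metric=spec,
        percentile_pairs=pairs,
        toggles=toggles,
    )


def read_config(path) -> RunConfig:
    """Load a YAML run configuration; absent blocks fall back to defaults."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError("config root must be a mapping")
    data = raw.get("data", {})
    constants = raw.get("constants", {})
    seed = int(raw.get("seed", 0))
    known_constants = {
        "bw_human", "bw_rat", "ef_chronic_nominal", "ef_chronic_mean", "ef_chronic_sd",
        "ef_inter_p99", "intra_lower", "intra_upper", "nanofraction_p50",
        "nanofraction_p95", "bootstrap_reps_per_model",
    }
    unknown = set(constants) - known_constants
    if unknown:
        raise SchemaError(f"unknown constants: {sorted(unknown)}")
    for block in ("data", "ipra", "constants"):
        if block not in raw:
            logger.info("config: block %r absent, defaults applied", block)
    cfg = RunConfig(
        seed=seed,
        output_dir=str(raw.get("output_dir", "ipra_out")),
        log_level=str(raw.get("log_level", "INFO")),
        survey=data.get("survey"),
        concentration=data.get("concentration", "fixture"),
        links=data.get("links", "fixture"),
        dose_response=data.get("dose_response"),
        ipra=_build_ipra_config(raw.get("ipra", {}), seed),
        **{k: constants[k] for k in constants},
    )
    return cfg
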