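"""Factorial uncertainty-contribution analysis.

Which of the seven uncertainty sources — consumption data, concentration
data, nanofraction, BMD, subchronic-to-chronic factor, interspecies factor,
intraspecies factor — drives the uncertainty of a chosen IMoE percentile?
The full 2^7 on/off factorial design runs the two-dimensional Monte Carlo
once per toggle pattern (with matched RNG sub-streams, so a source's draws
are identical wherever it is on) and summarises each cell by the variance of
the target percentile across uncertainty repetitions.  An additive model

    variance(cell) ≈ beta_0 + sum_j beta_j * on_j

is fitted to the 128 cell variances; the main-effect coefficients measure
each source's contribution and the intercept the residual Monte Carlo
noise.  Variances are taken on log10 of the percentile, since the IMoE
spans orders of magnitude.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import DesignError, ParameterError
from .risk import SOURCE_NAMES, IpraConfig, IpraModel, SourceToggles

__all__ = [
    "factorial_design",
    "run_factorial",
    "fit_additive_variance_model",
    "AdditiveVarianceFit",
    "FactorialResult",
    "SOURCE_LABELS",
]

#: short bar labels, intercept first (Monte Carlo noise), then the sources
SOURCE_LABELS = {
    "mc": "MC",
    "consumption": "Indiv",
    "concentration": "Conc",
    "nanofraction": "Fact",
    "bmd": "BMD",
    "chronic": "Chronic",
    "inter": "Inter",
    "intra": "Intra",
}


def factorial_design() -> list:
    """All 2^7 = 128 toggle patterns in lexicographic order."""
    return [
        SourceToggles.from_tuple(bits)
        for bits in itertools.product((False, True), repeat=len(SOURCE_NAMES))
    ]


@dataclass(frozen=True)
class AdditiveVarianceFit:
    """Least-squares additive decomposition of the 128 cell variances."""

    intercept: float
    main_effects: pd.Series  # raw coefficients, may be negative from MC noise
    contributions: pd.Series  # percent, over bars MC + 7 sources, sums to 100
    variance_explained: float  # R^2 * 100

    def summary(self) -> str:
        lines = ["Additive variance decomposition (2^7 factorial)"]
        for label, value in self.contributions.items():
            lines.append(f"  {label:<8}{value:6.2f} %")
        lines.append(f"  variance explained: {self.variance_explained:.2f} %")
        return "\n".join(lines)


@dataclass(frozen=True)
class FactorialResult:
    """Per-cell variances of the target percentile plus the additive fit."""

    cells: pd.DataFrame  # one row per pattern: seven bools + variance
    fit: AdditiveVarianceFit
    target_percentile: float
    reps_per_cell: int

    def to_json(self, path) -> None:
        payload = {
            "target_percentile": self.target_percentile,
            "reps_per_cell": self.reps_per_cell,
            "cells": self.cells.to_dict(orient="list"),
            "intercept": self.fit.intercept,
            "main_effects": self.fit.main_effects.to_dict(),
            "contributions": self.fit.contributions.to_dict(),
            "variance_explained": self.fit.variance_explained,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def fit_additive_variance_model(patterns, variances) -> AdditiveVarianceFit:
    """Fit ``variance ≈ beta0 + sum_j beta_j on_j`` to the factorial cells.

    Contributions are the clipped-to-zero coefficients normalised to 100 %
    over the eight reported bars (Monte Carlo intercept + seven sources);
    raw (possibly negative) main effects are kept alongside.
    """
    pats = [p.as_tuple() if isinstance(p, SourceToggles) else tuple(bool(b) for b in p)
            for p in patterns]
    if len(set(pats)) != len(pats):
        raise DesignError("duplicated toggle patterns")
    X = np.column_stack([np.ones(len(pats)), np.asarray(pats, dtype=float)])
    y = np.asarray(variances, dtype=float)
    if X.shape[0] < X.shape[1] or np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    raw = pd.Series(beta[1:], index=list(SOURCE_NAMES))
    bars = np.concatenate([[beta[0]], beta[1:]])
    clipped = np.clip(bars, 0.0, None)
    total = clipped.sum()
    shares = clipped / total * 100.0 if total > 0 else np.zeros_like(clipped)
    labels = [SOURCE_LABELS["mc"]] + [SOURCE_LABELS[n] for n in SOURCE_NAMES]
    return AdditiveVarianceFit(
        intercept=float(beta[0]),
        main_effects=raw,
        contributions=pd.Series(shares, index=labels),
        variance_explained=float(r2 * 100.0),
    )


def run_factorial(
    model: IpraModel,
    target_percentile: float = 1.0,
    reps_per_cell: int = 50,
    config: IpraConfig | None = None,
    seed: int | None = None,
) -> FactorialResult:
    """Run the 2^7 factorial sensitivity analysis on a risk model.

    Each cell runs the two-dimensional Monte Carlo for ``reps_per_cell``
    outer iterations with that cell's toggle pattern and the same master
    seed (matched sub-streams), and records the variance of
    log10(target percentile) across iterations.
    """
    if reps_per_cell < 10:
        raise ParameterError("need at least 10 repetitions per cell")
    base_cfg = config or model.config
    master = base_cfg.master_seed if seed is None else int(seed)
    design = factorial_design()
    rows = []
    variances = []
    base_fit_cache = None
    for toggles in design:
        cfg = replace(base_cfg, outer=reps_per_cell, toggles=toggles, master_seed=master)
        cell_model = IpraModel(
            model.survey,
            model.concentrations,
            model.links,
            model.bmd_set,
            model.extrapolation,
            model.nanofraction,
            cfg,
        )
        if base_fit_cache is not None:
            cell_model._base_fit = base_fit_cache
        result = cell_model.run(seed=master)
        if base_fit_cache is None and cell_model._base_fit is not None:
            base_fit_cache = cell_model._base_fit
        vals = result.percentile(target_percentile).to_numpy()
        var = float(np.var(np.log10(vals), ddof=1))
        variances.append(var)
        rows.append({**dict(zip(SOURCE_NAMES, toggles.as_tuple())), "variance": var})
    fit = fit_additive_variance_model(design, variances)
    return FactorialResult(
        cells=pd.DataFrame(rows),
        fit=fit,
        target_percentile=target_percentile,
        reps_per_cell=reps_per_cell,
    )
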