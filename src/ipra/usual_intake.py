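"""Usual (long-term) intake modelling: the two-part logistic-normal-normal model.

Short-term person-day exposures from a 2-day recall survey overstate
long-term between-person variation.  The two-part shrinkage model separates
consumption frequency from consumption amount:

    logit P(positive day | person i)   = alpha + u1_i
    ln(amount | positive, person i, t) = beta + u2_i + eps_it

with (u1, u2) bivariate normal person effects and eps_it a within-person
(day-to-day) normal deviation.  The usual intake of individual i is

    IEXP_i = P(positive | u1_i) * exp(beta + u2_i + sigma_eps^2 / 2).

Person effects are integrated out by fixed-order Gauss-Hermite quadrature.
With two recall days the frequency-amount correlation is weakly identified,
so the default fixes it at zero (the two parts then fit separately:
a logistic random-intercept likelihood and a compound-symmetric Gaussian
likelihood in closed form); ``estimate_correlation=True`` fits the joint
model.  When every person-day is positive the frequency part is fixed at 1
and the amount part reduces to a one-way random-effects decomposition on
the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp
from statsmodels.tools.numdiff import approx_hess1

from .exceptions import DataError, DegenerateDataError, FitError, ParameterError

__all__ = [
    "UsualIntakeModel",
    "UsualIntakeResults",
    "UsualIntakeDistribution",
    "fit_usual_intake",
    "predict_usual_intakes",
]

_PARAM_INDEX = [
    "freq_intercept",
    "freq_sd",
    "log_amount_intercept",
    "between_sd",
    "within_sd",
    "corr",
]


@dataclass(frozen=True)
class UsualIntakeDistribution:
    """Per-individual usual exposures with a provenance tag."""

    values: np.ndarray
    provenance: str  # "shrunken-persons" or "simulated-population"

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.size == 0:
            raise DataError("empty usual-intake distribution")
        if (v < 0).any():
            raise DataError("usual intakes must be non-negative")


def _gh_nodes(order: int):
    """Physicists' Gauss-Hermite nodes mapped for N(0,1) expectation."""
    x, w = np.polynomial.hermite.hermgauss(order)
    return x * math.sqrt(2.0), w / math.sqrt(math.pi)


class UsualIntakeModel:
    """Two-part usual-intake model built from person-day exposures.

    Parameters
    ----------
    person_days
        Frame with columns ``person_id``, ``day``, ``idexp`` — one row per
        person-day, zeros included (output of
        :func:`ipra.exposure.compute_person_day_exposures`).
    """

    def __init__(self, person_days: pd.DataFrame):
        for col in ("person_id", "day", "idexp"):
            if col not in person_days.columns:
                raise DataError(f"person-day table missing column {col!r}")
        if (person_days["idexp"] < 0).any():
            raise DataError("exposures must be non-negative")
        self.person_days = person_days
        by_person = person_days.groupby("person_id", sort=True)
        self._n_days = by_person.size().to_numpy()
        if len(self._n_days) < 2:
            raise DataError("need at least 2 persons")
        pos = person_days[person_days["idexp"] > 0]
        self._n_pos = (
            pos.groupby("person_id", sort=True)
            .size()
            .reindex(by_person.size().index, fill_value=0)
            .to_numpy()
        )
        if self._n_pos.sum() == 0:
            raise DegenerateDataError("no positive exposures")
        logs = pos.assign(y=np.log(pos["idexp"]))
        g = logs.groupby("person_id", sort=True)["y"]
        self._amount_index = g.mean().index
        self._m = g.size().to_numpy()  # positive days per consumer
        self._ybar = g.mean().to_numpy()
        self._ssw = (g.var(ddof=0) * g.size()).fillna(0.0).to_numpy()
        self._person_index = by_person.size().index

    # -- frequency part -----------------------------------------------------

    def _freq_loglik(self, alpha, sigma, nodes):
        x, w = nodes
        u = sigma * x  # (J,)
        eta = alpha + u
        logp = -np.logaddexp(0.0, -eta)
        log1mp = -np.logaddexp(0.0, eta)
        k = self._n_pos[:, None]
        n = self._n_days[:, None]
        li = logsumexp(np.log(w)[None, :] + k * logp[None, :] + (n - k) * log1mp[None, :], axis=1)
        return float(li.sum())

    # -- joint likelihood with correlation ----------------------------------

    def _joint_loglik(self, theta, nodes):
        alpha, s1, beta, s2, se, rho = theta
        x, w = nodes
        J = len(x)
        xa = np.repeat(x, J)
        xb = np.tile(x, J)
        ww = np.log(np.outer(w, w).ravel())
        u1 = s1 * xa
        u2 = s2 * (rho * xa + math.sqrt(max(1.0 - rho**2, 1e-12)) * xb)
        eta = alpha + u1
        logp = -np.logaddexp(0.0, -eta)
        log1mp = -np.logaddexp(0.0, eta)
        k = self._n_pos[:, None]
        n = self._n_days[:, None]
        freq = k * logp[None, :] + (n - k) * log1mp[None, :]
        # amount contribution: persons without positive days contribute 0
        m = np.zeros(len(self._n_days))
        ybar = np.zeros(len(self._n_days))
        ssw = np.zeros(len(self._n_days))
        pos_mask = self._n_pos > 0
        m[pos_mask] = self._m
        ybar[pos_mask] = self._ybar
        ssw[pos_mask] = self._ssw
        v_w = se**2
        amt = -0.5 * (
            m[:, None] * math.log(2 * math.pi * v_w)
            + (ssw[:, None] + m[:, None] * (ybar[:, None] - beta - u2[None, :]) ** 2) / v_w
        )
        li = logsumexp(ww[None, :] + freq + amt, axis=1)
        return float(li.sum())

    # -- fitting ------------------------------------------------------------

    def fit(self, estimate_correlation: bool = False, gh_nodes: int = 21) -> "UsualIntakeResults":
        nodes = _gh_nodes(gh_nodes)
        all_positive = (self._n_pos == self._n_days).all()
        y_all = np.log(
            self.person_days.loc[self.person_days["idexp"] > 0, "idexp"].to_numpy()
        )
        ybar_all = float(y_all.mean())
        yc = self._ybar - ybar_all  # centred person means (scale equivariance)

        # degenerate amounts: a single positive day or identical amounts
        if y_all.size < 2 or np.ptp(y_all) == 0.0:
            beta, s2, se = ybar_all, 0.0, 0.0
            ll_amount = 0.0
            amount_free = False
        else:
            amount_free = True

        if amount_free:
            m = self._m
            v_w0 = float(np.sum(self._ssw) / max(np.sum(m - 1), 1))
            v_b0 = max(float(np.var(yc)) - v_w0 / max(float(np.mean(m)), 1.0), 1e-4)
            x0 = np.array([math.sqrt(v_b0), math.sqrt(max(v_w0, 1e-4))])

            # the amount intercept is profiled out in closed form (GLS mean
            # given the variances), so only the two dispersions are optimised
            nll_amt = lambda t: -self._amount_profile_loglik(yc, abs(t[0]), abs(t[1]))[0]
            res_a = optimize.minimize(
                nll_amt,
                x0,
                method="L-BFGS-B",
                bounds=[(0.0, None), (1e-8, None)],
                options={"maxiter": 500, "ftol": 1e-12},
            )
            if not res_a.success:  # L-BFGS-B can stall near machine precision
                res_a = optimize.minimize(
                    nll_amt,
                    res_a.x,
                    method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 3000},
                )
                res_a.x = np.abs(res_a.x)
            s2, se = float(res_a.x[0]), float(max(res_a.x[1], 1e-8))
            ll_amount, beta_c = self._amount_profile_loglik(yc, s2, se)
            beta = float(beta_c + ybar_all)
            amount_converged = bool(res_a.success)
        else:
            amount_converged = True

        if all_positive:
            params = pd.Series(
                [math.inf, 0.0, beta, s2, se, 0.0], index=_PARAM_INDEX, dtype=float
            )
            llf = ll_amount
            return UsualIntakeResults(
                model=self,
                params=params,
                bse=pd.Series(np.nan, index=_PARAM_INDEX),
                llf=llf,
                converged=amount_converged,
                all_days_positive=True,
                gh_nodes=gh_nodes,
            )

        # frequency part
        k, n = self._n_pos, self._n_days
        phat = np.clip(k.sum() / n.sum(), 1e-6, 1 - 1e-6)
        a0 = math.log(phat / (1 - phat))
        res_f = optimize.minimize(
            lambda t: -self._freq_loglik(t[0], abs(t[1]), nodes),
            np.array([a0, 1.0]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        alpha, s1 = float(res_f.x[0]), abs(float(res_f.x[1]))
        ll_freq = -float(res_f.fun)
        freq_converged = bool(res_f.success)

        if estimate_correlation and amount_free:
            theta0 = np.array([alpha, s1, beta - ybar_all, s2, max(se, 1e-4), 0.0])
            res_j = optimize.minimize(
                lambda t: -self._joint_loglik_c(t, nodes, ybar_all),
                theta0,
                method="Nelder-Mead",
                options={"maxiter": 6000, "xatol": 1e-6, "fatol": 1e-8},
            )
            alpha, s1, beta_c, s2, se, rho = res_j.x
            alpha, s1, se = float(alpha), abs(float(s1)), abs(float(se))
            s2, rho = abs(float(s2)), float(np.clip(res_j.x[5], -0.99, 0.99))
            beta = float(beta_c + ybar_all)
            llf = -float(res_j.fun)
            converged = bool(res_j.success)
            free = np.array([alpha, s1, beta_c, s2, se, rho])
            hess_fun = lambda t: -self._joint_loglik_c(t, nodes, ybar_all)
            bse_vals = _bse_from_hessian(hess_fun, free)
            bse = pd.Series(bse_vals, index=_PARAM_INDEX)
        else:
            rho = 0.0
            llf = ll_freq + ll_amount
            converged = freq_converged and amount_converged
            bse = pd.Series(np.nan, index=_PARAM_INDEX)
            try:
                bse_f = _bse_from_hessian(
                    lambda t: -self._freq_loglik(t[0], abs(t[1]), nodes),
                    np.array([alpha, max(s1, 1e-4)]),
                )
                bse["freq_intercept"], bse["freq_sd"] = bse_f
            except Exception:
                pass
            if amount_free:
                try:
                    bse_a = _bse_from_hessian(
                        lambda t: -self._amount_loglik_c(yc, *t),
                        np.array([beta - ybar_all, max(s2, 1e-4), max(se, 1e-6)]),
                    )
                    bse["log_amount_intercept"] = bse_a[0]
                    bse["between_sd"] = bse_a[1]
                    bse["within_sd"] = bse_a[2]
                except Exception:
                    pass

        params = pd.Series([alpha, s1, beta, s2, se, rho], index=_PARAM_INDEX, dtype=float)
        return UsualIntakeResults(
            model=self,
            params=params,
            bse=bse,
            llf=llf,
            converged=converged,
            all_days_positive=False,
            gh_nodes=gh_nodes,
        )

    def _amount_profile_loglik(self, yc, s_between, s_within):
        """Profile log-likelihood of the amount part: beta at its GLS optimum.

        Returns ``(loglik, beta_c)`` for the compound-symmetric marginal with
        the intercept replaced by its closed-form weighted mean — this keeps
        the fit exactly equivariant under rescaling of the exposures.
        """
        m = self._m
        v_w = max(s_within, 1e-8) ** 2
        v_b = s_between**2
        denom = v_w + m * v_b
        w = m / denom
        beta_c = float(np.sum(w * yc) / np.sum(w))
        ll = -0.5 * (
            m * math.log(2 * math.pi)
            + (m - 1) * np.log(v_w)
            + np.log(denom)
            + self._ssw / v_w
            + m * (yc - beta_c) ** 2 / denom
        )
        return float(ll.sum()), beta_c

    # centred-amount helpers (beta optimised relative to the grand log mean)
    def _amount_loglik_c(self, yc, beta_c, s_between, s_within):
        m = self._m
        v_w = max(s_within, 1e-8) ** 2
        v_b = s_between**2
        denom = v_w + m * v_b
        ll = -0.5 * (
            m * math.log(2 * math.pi)
            + (m - 1) * np.log(v_w)
            + np.log(denom)
            + self._ssw / v_w
            + m * (yc - beta_c) ** 2 / denom
        )
        return float(ll.sum())

    def _joint_loglik_c(self, theta, nodes, ybar_all):
        alpha, s1, beta_c, s2, se, rho = theta
        t = np.array(
            [alpha, abs(s1), beta_c, abs(s2), max(abs(se), 1e-8), np.clip(rho, -0.99, 0.99)]
        )
        # shift centred person means through the joint likelihood
        saved = self._ybar
        try:
            object.__setattr__(self, "_ybar", saved - ybar_all)
            return self._joint_loglik(t, nodes)
        finally:
            object.__setattr__(self, "_ybar", saved)


def _bse_from_hessian(neg_loglik, x):
    h = approx_hess1(x, neg_loglik)
    cov = np.linalg.inv(h)
    d = np.diag(cov)
    return np.sqrt(np.where(d > 0, d, np.nan))


@dataclass
class UsualIntakeResults:
    """Fitted two-part usual-intake model."""

    model: UsualIntakeModel
    params: pd.Series
    bse: pd.Series
    llf: float
    converged: bool
    all_days_positive: bool
    gh_nodes: int

    def __post_init__(self):
        if not self.converged:
            raise FitError(
                "usual-intake fit did not converge",
                {"params": self.params.to_dict(), "llf": self.llf},
            )

    # -- prediction ---------------------------------------------------------

    def _usual_from_effects(self, u1, u2):
        p = self.params
        if self.all_days_positive:
            prob = np.ones_like(np.asarray(u2, dtype=float))
        else:
            prob = expit(p["freq_intercept"] + u1)
        return prob * np.exp(
            p["log_amount_intercept"] + u2 + 0.5 * p["within_sd"] ** 2
        )

    def simulate(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Simulated-population usual intakes: n fresh individuals."""
        if n < 1:
            raise ParameterError("need n >= 1")
        p = self.params
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        rho = p["corr"]
        u1 = p["freq_sd"] * z1
        u2 = p["between_sd"] * (rho * z1 + math.sqrt(1 - rho**2) * z2)
        return self._usual_from_effects(u1, u2)

    def shrunken_usual_intakes(self) -> np.ndarray:
        """Empirical-Bayes posterior-mean usual intake per surveyed person.

        With the default zero frequency-amount correlation the posterior
        factorises; both factors are Gauss-Hermite integrals.
        """
        p = self.params
        x, w = _gh_nodes(self.gh_nodes)
        mdl = self.model
        k, n = mdl._n_pos, mdl._n_days

        # frequency factor: E[expit(alpha + u1) | k, n]
        if self.all_days_positive or p["freq_sd"] == 0.0:
            e_prob = (
                np.ones(len(k))
                if self.all_days_positive
                else np.full(len(k), expit(p["freq_intercept"]))
            )
        else:
            eta = p["freq_intercept"] + p["freq_sd"] * x
            pr = expit(eta)
            lik = pr[None, :] ** k[:, None] * (1 - pr[None, :]) ** (n - k)[:, None]
            e_prob = (lik * pr[None, :] * w[None, :]).sum(axis=1) / (
                lik * w[None, :]
            ).sum(axis=1)

        # amount factor: E[exp(beta + u2) | ybar, m] for consumers;
        # prior mean for never-consumers
        e_amt = np.full(len(k), math.exp(p["log_amount_intercept"] + 0.5 * p["between_sd"] ** 2))
        if p["between_sd"] > 0 and p["within_sd"] > 0:
            m, ybar = mdl._m, mdl._ybar
            u2 = p["between_sd"] * x
            resid = ybar[:, None] - p["log_amount_intercept"] - u2[None, :]
            loglik = -0.5 * m[:, None] * resid**2 / p["within_sd"] ** 2
            lik = np.exp(loglik - loglik.max(axis=1, keepdims=True))
            num = (lik * np.exp(u2)[None, :] * w[None, :]).sum(axis=1)
            den = (lik * w[None, :]).sum(axis=1)
            e_consumer = math.exp(p["log_amount_intercept"]) * num / den
            consumer_mask = k > 0
            e_amt[consumer_mask] = e_consumer
        elif p["between_sd"] > 0:  # no within-day noise: person effect observed exactly
            e_amt[k > 0] = np.exp(self.model._ybar)
        else:
            e_amt[:] = math.exp(p["log_amount_intercept"])
        return e_prob * e_amt * math.exp(0.5 * p["within_sd"] ** 2)

    def predict_usual(
        self, mode: str = "simulated-population", n: int | None = None, rng=None
    ) -> UsualIntakeDistribution:
        if mode == "shrunken-persons":
            return UsualIntakeDistribution(self.shrunken_usual_intakes(), mode)
        if mode == "simulated-population":
            if n is None or n < 1:
                raise ParameterError("simulated-population mode needs n >= 1")
            if rng is None:
                rng = np.random.default_rng()
            return UsualIntakeDistribution(self.simulate(n, rng), mode)
        raise ParameterError(f"unknown prediction mode {mode!r}")

    def mean_usual_intake(self) -> float:
        """Analytic population mean of the usual intake (Gauss-Hermite)."""
        p = self.params
        x, w = _gh_nodes(self.gh_nodes)
        amt = math.exp(
            p["log_amount_intercept"] + 0.5 * (p["between_sd"] ** 2 + p["within_sd"] ** 2)
        )
        if self.all_days_positive:
            return amt
        if p["corr"] == 0:
            e_prob = float((expit(p["freq_intercept"] + p["freq_sd"] * x) * w).sum())
            return e_prob * amt
        # correlated effects: 2-D quadrature
        xa = np.repeat(x, len(x))
        xb = np.tile(x, len(x))
        ww = np.outer(w, w).ravel()
        u1 = p["freq_sd"] * xa
        u2 = p["between_sd"] * (p["corr"] * xa + math.sqrt(1 - p["corr"] ** 2) * xb)
        vals = expit(p["freq_intercept"] + u1) * np.exp(
            p["log_amount_intercept"] + u2 + 0.5 * p["within_sd"] ** 2
        )
        return float((vals * ww).sum())

    def summary(self) -> str:
        p, b = self.params, self.bse
        rows = []
        for name in _PARAM_INDEX:
            se = f"{b[name]:.4g}" if np.isfinite(b[name]) else "-"
            rows.append(f"  {name:<22}{p[name]:>12.5g}  (se {se})")
        head = "Usual-intake (two-part logistic-normal-normal) fit"
        tail = (
            f"  persons: {len(self.model._n_days)}   log-lik: {self.llf:.3f}   "
            f"all-days-positive: {self.all_days_positive}"
        )
        return "\n".join([head, *rows, tail])


# ---------------------------------------------------------------------------
# module-level conveniences


def fit_usual_intake(person_days: pd.DataFrame, **kwargs) -> UsualIntakeResults:
    """Fit the two-part usual-intake model to a person-day exposure table."""
    return UsualIntakeModel(person_days).fit(**kwargs)


def predict_usual_intakes(results: UsualIntakeResults, mode, n=None, rng=None):
    return results.predict_usual(mode=mode, n=n, rng=rng)
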