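"""Proportional-hazards survival contrasts with a shared per-family
gamma frailty.

The model multiplies an unspecified baseline hazard by ``exp(x'beta)``
and by a per-family random effect ``u ~ Gamma(mean 1, variance theta)``.
Estimation is by EM: the E-step replaces each family's frailty with its
posterior mean ``(1/theta + D_i) / (1/theta + Lambda_i)`` given the
family's death count and accumulated cumulative hazard; the M-step
refits a semiparametric Cox partial likelihood (Breslow baseline, left
truncation via entry ages, log-frailty offsets) and, when ``theta`` is
estimated, maximises the gamma-mixture marginal likelihood in ``theta``.
With ``theta`` fixed at 0 the procedure reduces exactly to an ordinary
Cox partial-likelihood fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ConvergenceError",
    "FrailtyFit",
    "fit_frailty_cox",
    "case_control_contrast",
    "sibship_category",
    "SIBSHIP_CATEGORIES",
]


class ConvergenceError(RuntimeError):
    """Model fitting failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[dict] | None = None):
        super().__init__(message)
        self.trace = trace or []


# -- plain Cox partial likelihood (Breslow ties, delayed entry, offsets) --


class _CoxData:
    """Pre-sorted arrays for risk-set sums with delayed entry.

    The risk set at time ``t`` is ``{i : entry_i < t <= time_i}``; sums
    over it are computed as a suffix sum over time-sorted rows minus a
    suffix sum over entry-sorted rows.
    """

    def __init__(self, X: np.ndarray, time: np.ndarray, event: np.ndarray,
                 entry: np.ndarray, offset: np.ndarray):
        self.n, self.p = X.shape
        self.time_order = np.argsort(time, kind="stable")
        self.entry_order = np.argsort(entry, kind="stable")
        self.X_t = X[self.time_order]
        self.time_sorted = time[self.time_order]
        self.event_t = event[self.time_order].astype(bool)
        self.off_t = offset[self.time_order]
        self.X_e = X[self.entry_order]
        self.entry_sorted = entry[self.entry_order]
        self.off_e = offset[self.entry_order]
        self.event_times = self.time_sorted[self.event_t]
        # positions of each event time in the two sorted orders
        self.pos_t = np.searchsorted(self.time_sorted, self.event_times, side="left")
        self.pos_e = np.searchsorted(self.entry_sorted, self.event_times, side="left")

    def _suffix(self, arr: np.ndarray) -> np.ndarray:
        # suffix[i] = sum(arr[i:]); returned with trailing zero row
        out = np.concatenate([np.cumsum(arr[::-1], axis=0)[::-1], np.zeros((1,) + arr.shape[1:])])
        return out

    def risk_sums(self, beta: np.ndarray):
        """S0, S1, S2 at each event time plus per-row exp(lp)."""
        r_t = np.exp(self.X_t @ beta + self.off_t)
        r_e = np.exp(self.X_e @ beta + self.off_e)
        s0 = self._suffix(r_t)[self.pos_t] - self._suffix(r_e)[self.pos_e]
        s1 = (
            self._suffix(r_t[:, None] * self.X_t)[self.pos_t]
            - self._suffix(r_e[:, None] * self.X_e)[self.pos_e]
        )
        xx_t = self.X_t[:, :, None] * self.X_t[:, None, :]
        xx_e = self.X_e[:, :, None] * self.X_e[:, None, :]
        s2 = (
            self._suffix(r_t[:, None, None] * xx_t)[self.pos_t]
            - self._suffix(r_e[:, None, None] * xx_e)[self.pos_e]
        )
        return r_t, s0, s1, s2

    def loglik_grad_hess(self, beta: np.ndarray):
        r_t, s0, s1, s2 = self.risk_sums(beta)
        lp_events = (self.X_t @ beta + self.off_t)[self.event_t]
        if np.any(s0 <= 0):
            raise ConvergenceError("empty risk set at an event time")
        loglik = float(np.sum(lp_events) - np.sum(np.log(s0)))
        mean = s1 / s0[:, None]
        grad = self.X_t[self.event_t].sum(axis=0) - mean.sum(axis=0)
        info = (
            np.einsum("kij->ij", s2 / s0[:, None, None])
            - np.einsum("ki,kj->ij", mean, mean)
        )
        return loglik, grad, info

    def breslow(self, beta: np.ndarray):
        """Breslow baseline: unique event times and cumulative hazard jumps."""
        _, s0, _, _ = self.risk_sums(beta)
        times, inverse, counts = np.unique(
            self.event_times, return_inverse=True, return_counts=True
        )
        # s0 is identical within tied event times; take one per unique time
        first = np.zeros(times.size, dtype=int)
        first[inverse] = np.arange(self.event_times.size)
        d_lambda = counts / s0[first]
        return times, d_lambda


def _cox_newton(
    data: _CoxData,
    beta0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    beta = beta0.copy()
    loglik, grad, info = data.loglik_grad_hess(beta)
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}") from err
        # step-halving line search
        for _ in range(30):
            cand = beta + step
            try:
                ll_new, grad_new, info_new = data.loglik_grad_hess(cand)
            except (FloatingPointError, OverflowError):
                ll_new = -np.inf
            if np.isfinite(ll_new) and ll_new >= loglik - 1e-12:
                break
            step = step / 2.0
        else:
            raise ConvergenceError("line search failed in Cox fit")
        delta = float(np.max(np.abs(cand - beta)))
        beta, loglik, grad, info = cand, ll_new, grad_new, info_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(f"Cox fit did not converge in {max_iter} iterations")
    cov = np.linalg.inv(info)
    return beta, cov, loglik, it


@dataclass
class FrailtyFit:
    """Result of a (frailty) proportional-hazards fit.

    ``params`` has one row per model term with columns ``coef, se, hr,
    ci_low, ci_high, p``; ``frailty`` holds the posterior mean frailty per
    family (all 1 when ``theta == 0``).
    """

    params: pd.DataFrame
    theta: float
    theta_fixed: bool
    loglik: float
    n: int
    n_events: int
    n_families: int
    n_iter: int
    converged: bool
    frailty: pd.Series = field(repr=False, default_factory=lambda: pd.Series(dtype=float))
    alpha: float = 0.05

    def summary(self) -> pd.DataFrame:
        out = self.params.copy()
        out.insert(0, "term", out.index)
        return out.reset_index(drop=True)

    def hazard_ratio(self, term: str) -> tuple[float, float, float]:
        row = self.params.loc[term]
        return float(row["hr"]), float(row["ci_low"]), float(row["ci_high"])


def _design_matrix(
    df: pd.DataFrame,
    covariates: Sequence[str],
    references: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Numeric design matrix; object/categorical columns are dummy-coded
    against a reference level (given per column, else the first level)."""
    references = references or {}
    pieces = []
    for col in covariates:
        if col not in df.columns:
            raise ValueError(f"covariate {col!r} not in records")
        series = df[col]
        if series.dtype.kind in "biufc":
            pieces.append(series.astype(float).rename(col))
        else:
            levels = sorted(series.dropna().unique().tolist())
            ref = references.get(col, levels[0])
            if ref not in levels:
                raise ValueError(f"reference {ref!r} not a level of {col!r}")
            for level in levels:
                if level == ref:
                    continue
                pieces.append(
                    (series == level).astype(float).rename(f"{col}[{level}]")
                )
    X = pd.concat(pieces, axis=1)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing covariate values in columns {bad}")
    return X


def _marginal_loglik_theta(
    nu: float, D: np.ndarray, Lam: np.ndarray
) -> float:
    """Gamma-mixture part of the marginal log-likelihood at 1/theta = nu."""
    return float(
        np.sum(
            nu * math.log(nu)
            - special.gammaln(nu)
            + special.gammaln(nu + D)
            - (nu + D) * np.log(nu + Lam)
        )
    )


def fit_frailty_cox(
    records: pd.DataFrame,
    covariates: Sequence[str],
    *,
    group_col: str = "family_id",
    time_col: str = "t",
    event_col: str = "event",
    entry_col: str | None = None,
    references: Mapping[str, str] | None = None,
    theta: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    alpha: float = 0.05,
    theta_max: float = 50.0,
) -> FrailtyFit:
    """Fit the shared gamma-frailty proportional-hazards model.

    Parameters
    ----------
    records : pandas.DataFrame
        One row per person with the survival columns and covariates.
    covariates : sequence of str
        Columns entering the linear predictor; non-numeric columns are
        dummy-coded against a reference level (see ``references``).
    theta : float, optional
        Frailty variance.  ``None`` (default) estimates it by maximising
        the marginal likelihood; ``0`` fixes it and reduces the model to
        an ordinary Cox partial-likelihood fit.
    tol, max_iter
        EM convergence tolerance on the coefficient (and theta) change,
        and the iteration cap; exceeding the cap raises
        :class:`ConvergenceError` with the iteration trace.

    Raises
    ------
    ConvergenceError
        On non-convergence or degenerate fits.
    ValueError
        On invalid inputs (no events, a single family with frailty
        estimation requested, entry >= time for an event, ...).
    """
    for col in (group_col, time_col, event_col):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    df = records.reset_index(drop=True)
    time = df[time_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy()
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event must be 0 or 1")
    event = event.astype(int)
    if event.sum() == 0:
        raise ValueError("all records censored; model not estimable")
    entry = (
        df[entry_col].fillna(0.0).to_numpy(dtype=float)
        if entry_col is not None
        else np.zeros(len(df))
    )
    if np.any(entry[event == 1] >= time[event == 1]):
        raise ValueError("entry must be strictly before the event time")
    if np.any(entry > time):
        raise ValueError("entry must not exceed the censoring time")

    fam_codes, fam_index = pd.factorize(df[group_col], sort=True)
    n_fam = len(fam_index)
    estimate_theta = theta is None
    if estimate_theta and n_fam < 2:
        raise ValueError(
            "frailty variance is unidentifiable with a single family; "
            "supply theta explicitly or provide >= 2 families"
        )
    if theta is not None and theta < 0:
        raise ValueError("theta must be >= 0")

    X_df = _design_matrix(df, covariates, references)
    X = X_df.to_numpy(dtype=float)
    # centre columns for numerical stability; slopes are unaffected
    X = X - X.mean(axis=0)
    data = _CoxData(X, time, event, entry, np.zeros(len(df)))

    D = np.bincount(fam_codes, weights=event.astype(float), minlength=n_fam)

    def _posterior(nu: float, Lam: np.ndarray) -> np.ndarray:
        return (nu + D) / (nu + Lam)

    beta = np.zeros(X.shape[1])
    w = np.ones(n_fam)
    theta_cur = 0.1 if estimate_theta else float(theta)
    trace: list[dict] = []
    converged = False
    n_iter = 0

    if theta_cur == 0.0 and not estimate_theta:
        beta, cov, loglik, n_iter = _cox_newton(data, beta)
        converged = True
    else:
        for n_iter in range(1, max_iter + 1):
            offset = np.log(w)[fam_codes]
            data_off = _CoxData(X, time, event, entry, offset)
            beta_new, cov, loglik_cox, _ = _cox_newton(data_off, beta)
            # family-accumulated cumulative hazards excluding the frailty
            times_b, d_lambda = data_off.breslow(beta_new)
            cum = np.cumsum(d_lambda)

            def lam0(at: np.ndarray) -> np.ndarray:
                idx = np.searchsorted(times_b, at, side="right")
                return np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)

            mu = np.exp(X @ beta_new) * (lam0(time) - lam0(entry))
            Lam = np.bincount(fam_codes, weights=mu, minlength=n_fam)

            if estimate_theta:
                res = optimize.minimize_scalar(
                    lambda lognu: -_marginal_loglik_theta(math.exp(lognu), D, Lam),
                    bounds=(math.log(1.0 / theta_max), math.log(1e8)),
                    method="bounded",
                    options={"xatol": 1e-8},
                )
                nu = math.exp(res.x)
                theta_new = 1.0 / nu
            else:
                theta_new = theta_cur
                nu = 1.0 / theta_new
            w_new = _posterior(nu, Lam)

            delta = max(
                float(np.max(np.abs(beta_new - beta))),
                abs(theta_new - theta_cur) if estimate_theta else 0.0,
            )
            trace.append(
                {"iter": n_iter, "delta": delta, "theta": theta_new,
                 "beta": beta_new.copy(), "loglik": loglik_cox}
            )
            beta, theta_cur, w = beta_new, theta_new, w_new
            if delta < tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"frailty EM did not converge in {max_iter} iterations "
                f"(last delta {trace[-1]['delta']:.3g})",
                trace,
            )
        # marginal log-likelihood at the solution
        offset = np.log(w)[fam_codes]
        data_off = _CoxData(X, time, event, entry, offset)
        times_b, d_lambda = data_off.breslow(beta)
        cum_b = np.cumsum(d_lambda)

        def _lam0_final(at: np.ndarray) -> np.ndarray:
            idx = np.searchsorted(times_b, at, side="right")
            return np.where(idx > 0, cum_b[np.maximum(idx - 1, 0)], 0.0)

        lp = X @ beta
        mu_final = np.exp(lp) * (_lam0_final(time) - _lam0_final(entry))
        Lam_final = np.bincount(fam_codes, weights=mu_final, minlength=n_fam)
        jump = dict(zip(times_b, d_lambda))
        log_jumps = float(sum(math.log(jump[t_i]) for t_i in time[event == 1]))
        loglik = (
            _marginal_loglik_theta(1.0 / theta_cur, D, Lam_final)
            + float(lp[event == 1].sum())
            + log_jumps
        )

    se = np.sqrt(np.diag(cov))
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    zval = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    params = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - zcrit * se),
            "ci_high": np.exp(beta + zcrit * se),
            "p": 2.0 * stats.norm.sf(np.abs(zval)),
        },
        index=X_df.columns,
    )
    return FrailtyFit(
        params=params,
        theta=float(theta_cur),
        theta_fixed=not estimate_theta,
        loglik=float(loglik),
        n=len(df),
        n_events=int(event.sum()),
        n_families=n_fam,
        n_iter=n_iter,
        converged=converged,
        frailty=pd.Series(w, index=fam_index, name="frailty"),
        alpha=alpha,
    )


# -- the case/control contrast ------------------------------------------

SIBSHIP_CATEGORIES = (
    "single_0",
    "small_1_2",
    "medium_3_5",
    "large_6_8",
    "exceptional_9_15",
)


def sibship_category(n_siblings: int) -> str:
    """Sibship-size category (reference: small, 1-2 siblings)."""
    n = int(n_siblings)
    if n <= 0:
        return "single_0"
    if n <= 2:
        return "small_1_2"
    if n <= 5:
        return "medium_3_5"
    if n <= 8:
        return "large_6_8"
    return "exceptional_9_15"


def case_control_contrast(
    records: pd.DataFrame,
    scheme: str = "A",
    *,
    entry_ages: Mapping[str, float] | None = None,
    theta: float | None = None,
    alpha: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> FrailtyFit:
    """Survival contrast of family cases vs controls (and their spouses).

    ``records`` needs columns ``family_id, group, t, event, birth_year,
    sex, n_siblings``; ``group`` takes values ``family_case``,
    ``family_control`` and, for scheme B, ``spouse_of_case`` /
    ``spouse_of_control``.  Both schemes adjust for sibship size, birth
    year and sex, with ``family_control`` as the reference group.

    Scheme B enters spouse rows at a delayed entry age: the value from
    ``entry_ages`` per spouse group, or by default the floor of the first
    observed death age in that group.  Spouse rows wholly observed before
    their entry age are dropped.
    """
    if scheme not in ("A", "B"):
        raise ValueError("scheme must be 'A' or 'B'")
    required = {"family_id", "group", "t", "event", "birth_year", "sex", "n_siblings"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"contrast records missing columns: {sorted(missing)}")
    groups = (
        ("family_case", "family_control")
        if scheme == "A"
        else ("family_case", "family_control", "spouse_of_case", "spouse_of_control")
    )
    df = records[records["group"].isin(groups)].copy()
    df = df[df["t"].notna()]
    if df.empty:
        raise ValueError("no usable rows for the requested contrast")
    df["sibship"] = df["n_siblings"].map(sibship_category)

    df["entry"] = 0.0
    if scheme == "B":
        for grp in ("spouse_of_case", "spouse_of_control"):
            mask = df["group"] == grp
            if not mask.any():
                continue
            if entry_ages is not None and grp in entry_ages:
                age = float(entry_ages[grp])
            else:
                deaths = df.loc[mask & (df["event"] == 1), "t"]
                age = float(np.floor(deaths.min())) if len(deaths) else 0.0
            df.loc[mask, "entry"] = age
        df = df[df["t"] > df["entry"]]

    return fit_frailty_cox(
        df,
        covariates=["group", "sibship", "birth_year", "sex"],
        references={
            "group": "family_control",
            "sibship": "small_1_2",
            "sex": "male",
        },
        entry_col="entry",
        theta=theta,
        alpha=alpha,
        tol=tol,
        max_iter=max_iter,
    )
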