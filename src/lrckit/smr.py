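"""Standardized mortality ratios against cohort life tables.

Observed deaths are compared with the expected number, the sum of each
person's conditional cumulative hazard ``H(t_i | t0_i)`` from the life
table matching their sex and birth year.  Conditioning on the entry age
``t0`` corrects for left truncation (a subject only observable from some
age must not accrue expected deaths before it); censored persons
contribute their cumulative hazard but no observed death.

Exact confidence limits use the chi-square quantile form

    LL = chi2(alpha/2; 2 d) / (2 e)        (0 when d = 0)
    UL = chi2(1 - alpha/2; 2 (d + 1)) / (2 e)

and a family-resampling percentile bootstrap is available as a
cluster-robust alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .life_tables import LifeTableCollection

__all__ = [
    "SMRResult",
    "validate_smr_inputs",
    "expected_deaths",
    "smr_exact",
    "smr_bootstrap",
    "group_smr_table",
]

REQUIRED_COLUMNS = ("sex", "birth_year", "t", "d")


@dataclass(frozen=True)
class SMRResult:
    observed: int
    expected: float
    smr: float
    ci_low: float
    ci_high: float
    alpha: float
    method: str

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def validate_smr_inputs(inputs: pd.DataFrame) -> pd.DataFrame:
    """Check the per-person input table and normalise it.

    Required columns: ``sex``, ``birth_year``, ``t`` (age at death or last
    observation) and ``d`` (1 dead / 0 censored); ``t0`` (entry age)
    defaults to 0.  Returns a copy with ``t0`` filled in.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in inputs.columns]
    if missing:
        raise ValueError(f"SMR input table missing columns: {missing}")
    df = inputs.copy()
    if "t0" not in df.columns:
        df["t0"] = 0.0
    df["t0"] = df["t0"].fillna(0.0).astype(float)
    df["t"] = df["t"].astype(float)
    if df["t"].isna().any():
        raise ValueError("SMR input table contains missing t; filter persons with unknown age first")
    if not df["d"].isin([0, 1]).all():
        raise ValueError("d must be 0 (censored) or 1 (dead)")
    if (df["t0"] > df["t"]).any():
        bad = df.index[df["t0"] > df["t"]].tolist()[:5]
        raise ValueError(f"t0 > t for rows {bad}")
    return df


def expected_deaths(
    inputs: pd.DataFrame,
    tables: LifeTableCollection,
    tail_policy: str = "hold_last",
) -> float:
    """Sum of individual conditional cumulative hazards ``H(t | t0)``."""
    df = validate_smr_inputs(inputs)
    total = 0.0
    for (sex, by), grp in df.groupby(["sex", "birth_year"], sort=False):
        table = tables.get(sex, int(by))
        t = grp["t"].to_numpy()
        t0 = grp["t0"].to_numpy()
        total += float(
            np.sum(table._cum_vec(t, tail_policy) - table._cum_vec(t0, tail_policy))
        )
    return total


def _exact_ci(observed: int, expected: float, alpha: float) -> tuple[float, float]:
    d, e = observed, expected
    low = stats.chi2.ppf(alpha / 2.0, 2 * d) / (2.0 * e) if d > 0 else 0.0
    high = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * (d + 1)) / (2.0 * e)
    return float(low), float(high)


def smr_exact(
    inputs: pd.DataFrame,
    tables: LifeTableCollection,
    alpha: float = 0.05,
    tail_policy: str = "hold_last",
) -> SMRResult:
    """SMR with exact chi-square confidence limits."""
    df = validate_smr_inputs(inputs)
    observed = int(df["d"].sum())
    expected = expected_deaths(df, tables, tail_policy)
    if expected <= 0.0:
        raise ValueError("expected number of deaths is zero; SMR undefined")
    low, high = _exact_ci(observed, expected, alpha)
    return SMRResult(observed, expected, observed / expected, low, high, alpha, "exact")


def smr_bootstrap(
    inputs: pd.DataFrame,
    tables: LifeTableCollection,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    family_col: str = "family_id",
    tail_policy: str = "hold_last",
) -> SMRResult:
    """SMR with a family-resampling percentile bootstrap CI.

    Families (clusters identified by ``family_col``) are resampled with
    replacement ``B`` times; the CI is the (alpha/2, 1 - alpha/2)
    percentile interval of the replicate SMRs.  Reproducible given
    ``seed``.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    df = validate_smr_inputs(inputs)
    if family_col not in df.columns:
        raise ValueError(f"bootstrap requires a {family_col!r} column")
    # per-family observed and expected contributions
    fam_d = []
    fam_e = []
    for _, grp in df.groupby(family_col, sort=True):
        fam_d.append(float(grp["d"].sum()))
        fam_e.append(expected_deaths(grp, tables, tail_policy))
    n_fam = len(fam_d)
    if n_fam < 2:
        raise ValueError("bootstrap requires at least two families")
    fam_d = np.asarray(fam_d)
    fam_e = np.asarray(fam_e)
    expected = float(fam_e.sum())
    if expected <= 0.0:
        raise ValueError("expected number of deaths is zero; SMR undefined")
    observed = int(round(fam_d.sum()))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, n_fam, size=(B, n_fam))
    rep_d = fam_d[idx].sum(axis=1)
    rep_e = fam_e[idx].sum(axis=1)
    valid = rep_e > 0
    reps = rep_d[valid] / rep_e[valid]
    low, high = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return SMRResult(
        observed, expected, observed / expected, float(low), float(high), alpha, "bootstrap"
    )


def group_smr_table(
    persons: pd.DataFrame,
    tables: LifeTableCollection,
    group_col: str = "group",
    alpha: float = 0.05,
    tail_policy: str = "hold_last",
) -> pd.DataFrame:
    """One exact-CI SMR row per group of persons.

    Persons with a missing ``t`` (unknown age at death or last
    observation) are excluded from the computation but counted in the
    ``n_missing_age`` column, so that group sizes remain auditable.  An
    empty group yields a row with ``n = 0`` and null SMR fields.
    """
    if group_col not in persons.columns:
        raise ValueError(f"persons table has no {group_col!r} column")
    rows = []
    for group, grp in persons.groupby(group_col, sort=True):
        known = grp[grp["t"].notna()]
        n_missing = int(len(grp) - len(known))
        if len(known) == 0:
            rows.append(
                {
                    "group": group, "n": 0, "n_missing_age": n_missing,
                    "observed": np.nan, "expected": np.nan, "smr": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan,
                }
            )
            continue
        result = smr_exact(known, tables, alpha=alpha, tail_policy=tail_policy)
        rows.append(
            {
                "group": group, "n": int(len(known)), "n_missing_age": n_missing,
                "observed": result.observed, "expected": result.expected,
                "smr": result.smr, "ci_low": result.ci_low, "ci_high": result.ci_high,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group", "n", "n_missing_age", "observed", "expected",
                 "smr", "ci_low", "ci_high"],
    )
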