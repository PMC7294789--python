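"""Cohort life tables and survival quantities derived from them.

A cohort life table gives, for one sex and one birth year, the yearly
hazard of dying between exact ages ``x`` and ``x + 1``.  Within a year the
hazard is treated as constant (the piecewise-exponential convention), so
the cumulative hazard is continuous and piecewise linear in age, additive
over adjacent intervals, and the survival function is continuous.

Ages beyond the last tabulated year are handled by an explicit
``tail_policy``:

``"hold_last"`` (default)
    extend the table by holding the final yearly hazard constant, so that
    long-lived individuals who outlive the table still receive finite
    cumulative hazards;
``"error"``
    raise :class:`LifeTableError` for any age beyond ``max_age + 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "LifeTableError",
    "CohortLifeTable",
    "LifeTableCollection",
    "read_life_tables",
    "write_life_tables",
    "cumulative_hazard",
    "survival_probability",
    "survival_percentile",
    "threshold_age",
]

VALID_SEXES = ("female", "male")
TAIL_POLICIES = ("hold_last", "error")


class LifeTableError(ValueError):
    """Invalid life-table input, missing table key, or out-of-range query."""


def _check_tail_policy(tail_policy: str) -> None:
    if tail_policy not in TAIL_POLICIES:
        raise LifeTableError(
            f"unknown tail_policy {tail_policy!r}; expected one of {TAIL_POLICIES}"
        )


@dataclass(frozen=True)
class CohortLifeTable:
    """Yearly death hazards for one sex and one birth year.

    Parameters
    ----------
    sex : str
        Either ``"female"`` or ``"male"``.
    birth_year : int
        Calendar year of birth of the cohort.
    hazard : numpy.ndarray
        ``hazard[x]`` is the yearly hazard of dying between exact ages
        ``x`` and ``x + 1``; ages are contiguous from 0.
    """

    sex: str
    birth_year: int
    hazard: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise LifeTableError(
                f"sex must be one of {VALID_SEXES}, got {self.sex!r}"
            )
        hz = np.asarray(self.hazard, dtype=float)
        if hz.ndim != 1 or hz.size == 0:
            raise LifeTableError("hazard must be a non-empty 1-D array")
        if not np.all(np.isfinite(hz)):
            raise LifeTableError(
                f"non-finite hazard in table ({self.sex}, {self.birth_year})"
            )
        if np.any(hz < 0):
            raise LifeTableError(
                f"negative hazard in table ({self.sex}, {self.birth_year})"
            )
        object.__setattr__(self, "hazard", hz)
        # cumulative hazard at integer ages 0..n (leading zero)
        object.__setattr__(
            self, "_cum", np.concatenate(([0.0], np.cumsum(hz)))
        )

    @property
    def key(self) -> tuple[str, int]:
        return (self.sex, self.birth_year)

    @property
    def max_age(self) -> int:
        """Largest tabulated age ``x`` (the hazard covers ``[x, x + 1)``)."""
        return int(self.hazard.size - 1)

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.hazard.size)

    # -- scalar queries -------------------------------------------------

    def _cum_at(self, t: float, tail_policy: str) -> float:
        if not math.isfinite(t) or t < 0:
            raise LifeTableError(f"age must be finite and >= 0, got {t!r}")
        n = self.hazard.size
        k = int(math.floor(t))
        if k < n:
            return float(self._cum[k] + (t - k) * self.hazard[k])
        if tail_policy == "error" and t > n:
            raise LifeTableError(
                f"age {t} beyond table maximum {self.max_age} for "
                f"({self.sex}, {self.birth_year}); use tail_policy='hold_last' "
                "to extend with the final hazard"
            )
        return float(self._cum[n] + (t - n) * self.hazard[-1])

    def _cum_vec(self, t: np.ndarray, tail_policy: str) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(~np.isfinite(t)) or np.any(t < 0):
            raise LifeTableError("ages must be finite and >= 0")
        n = self.hazard.size
        k = np.minimum(np.floor(t).astype(int), n)
        inside = k < n
        out = np.empty_like(t)
        out[inside] = self._cum[k[inside]] + (t[inside] - k[inside]) * self.hazard[k[inside]]
        if not np.all(inside):
            if tail_policy == "error" and np.any(t[~inside] > n):
                raise LifeTableError(
                    f"age beyond table maximum {self.max_age} for "
                    f"({self.sex}, {self.birth_year}); use tail_policy='hold_last'"
                )
            out[~inside] = self._cum[n] + (t[~inside] - n) * self.hazard[-1]
        return out

    def cumulative_hazard(
        self, t: float, t0: float = 0.0, tail_policy: str = "hold_last"
    ) -> float:
        """Conditional cumulative hazard ``H(t | t0) = H(t) - H(t0)``."""
        _check_tail_policy(tail_policy)
        if t0 > t:
            raise LifeTableError(f"t0 ({t0}) must not exceed t ({t})")
        return self._cum_at(t, tail_policy) - self._cum_at(t0, tail_policy)

    def survival(
        self, t: float, t0: float = 0.0, tail_policy: str = "hold_last"
    ) -> float:
        """Conditional survival probability ``S(t | t0) = exp(-H(t | t0))``."""
        return math.exp(-self.cumulative_hazard(t, t0, tail_policy))

    def percentile(self, age_at_death: float, tail_policy: str = "hold_last") -> float:
        """Survival percentile ``P = 1 - S(age_at_death)`` within this cohort.

        ``P >= 1 - Z`` means the person belongs to the top-``Z`` survivors of
        their sex and birth cohort (``P >= 0.9`` for the top 10%).
        """
        return 1.0 - self.survival(age_at_death, 0.0, tail_policy)

    def threshold_age(self, top_fraction: float, tail_policy: str = "hold_last") -> float:
        """Smallest age ``a`` with ``S(a) <= top_fraction``.

        Linearly interpolated (on the cumulative-hazard scale) within the
        year in which the survival curve crosses ``top_fraction``.
        """
        _check_tail_policy(tail_policy)
        z = top_fraction
        if not (0.0 < z < 1.0):
            raise LifeTableError(f"top_fraction must be in (0, 1), got {z!r}")
        target = -math.log(z)
        cum = self._cum
        n = self.hazard.size
        idx = int(np.searchsorted(cum, target, side="left"))
        if idx <= n:
            x = idx - 1
            return float(x + (target - cum[x]) / self.hazard[x])
        # survival never reaches z within the tabulated range
        last = float(self.hazard[-1])
        if tail_policy == "error" or last <= 0.0:
            raise LifeTableError(
                f"survival never reaches {z} within table range for "
                f"({self.sex}, {self.birth_year}); consider tail_policy='hold_last' "
                "with a positive final hazard"
            )
        return float(n + (target - cum[n]) / last)


class LifeTableCollection:
    """Cohort life tables keyed by ``(sex, birth_year)``.

    Lookup is by exact key only; a missing key raises
    :class:`LifeTableError` rather than silently borrowing a neighbouring
    cohort.
    """

    def __init__(self, tables: Iterable[CohortLifeTable] = (), source: str = ""):
        self._tables: dict[tuple[str, int], CohortLifeTable] = {}
        self.source = source
        for table in tables:
            self.add(table)

    def add(self, table: CohortLifeTable) -> None:
        if table.key in self._tables:
            raise LifeTableError(f"duplicate life table for key {table.key}")
        self._tables[table.key] = table

    def get(self, sex: str, birth_year: int) -> CohortLifeTable:
        key = (sex, int(birth_year))
        try:
            return self._tables[key]
        except KeyError:
            raise LifeTableError(f"no life table for key {key}") from None

    def __contains__(self, key: tuple[str, int]) -> bool:
        return (key[0], int(key[1])) in self._tables

    def __len__(self) -> int:
        return len(self._tables)

    def __iter__(self) -> Iterator[CohortLifeTable]:
        return iter(self._tables.values())

    def keys(self) -> list[tuple[str, int]]:
        return sorted(self._tables.keys())

    @property
    def year_range(self) -> tuple[int, int]:
        years = [by for _, by in self._tables]
        return (min(years), max(years))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sex, by) in self.keys():
            table = self._tables[(sex, by)]
            for age, hz in enumerate(table.hazard):
                rows.append((sex, by, age, hz))
        return pd.DataFrame(rows, columns=["sex", "birth_year", "age", "hazard"])


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_life_tables(
    path: str | Path, convert_qx: bool = False, source: str | None = None
) -> LifeTableCollection:
    """Read cohort life tables from a delimited text file.

    The file must have a header row with columns ``sex``, ``birth_year``,
    ``age`` and either ``hazard`` or, with ``convert_qx=True``, ``qx``
    (yearly death probability, converted via ``h = -ln(1 - q)``).

    Raises
    ------
    LifeTableError
        On non-contiguous ages, negative hazards, or duplicate
        ``(sex, birth_year, age)`` rows, naming the offending key.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path))
    required = {"sex", "birth_year", "age"}
    missing = required - set(df.columns)
    if missing:
        raise LifeTableError(f"life-table file missing columns: {sorted(missing)}")
    if convert_qx:
        if "qx" not in df.columns:
            raise LifeTableError("convert_qx=True requires a 'qx' column")
        q = df["qx"].astype(float)
        if np.any((q < 0) | (q >= 1)):
            raise LifeTableError("qx values must lie in [0, 1)")
        df = df.assign(hazard=-np.log1p(-q))
    elif "hazard" not in df.columns:
        raise LifeTableError("life-table file needs a 'hazard' column (or qx with convert_qx=True)")

    if df.duplicated(subset=["sex", "birth_year", "age"]).any():
        dup = df[df.duplicated(subset=["sex", "birth_year", "age"])].iloc[0]
        raise LifeTableError(
            f"duplicate row for key ({dup['sex']}, {dup['birth_year']}, age {dup['age']})"
        )

    tables = []
    for (sex, by), grp in df.groupby(["sex", "birth_year"], sort=True):
        grp = grp.sort_values("age")
        ages = grp["age"].to_numpy(dtype=int)
        if ages[0] != 0 or np.any(np.diff(ages) != 1):
            raise LifeTableError(
                f"non-contiguous ages for key ({sex}, {by}): ages must run 0..A_max"
            )
        tables.append(CohortLifeTable(str(sex), int(by), grp["hazard"].to_numpy(dtype=float)))
    return LifeTableCollection(tables, source=source or str(path))


def write_life_tables(collection: LifeTableCollection, path: str | Path) -> None:
    """Write a collection in the same dialect :func:`read_life_tables` accepts."""
    path = Path(path)
    collection.to_frame().to_csv(path, sep=_delimiter_for(path), index=False)


# -- module-level operation wrappers -----------------------------------


def cumulative_hazard(
    table: CohortLifeTable, t: float, t0: float = 0.0, tail_policy: str = "hold_last"
) -> float:
    """Conditional cumulative hazard ``H(t | t0)`` for one table."""
    return table.cumulative_hazard(t, t0, tail_policy)


def survival_probability(
    table: CohortLifeTable, t: float, t0: float = 0.0, tail_policy: str = "hold_last"
) -> float:
    """Conditional survival probability ``S(t | t0)`` for one table."""
    return table.survival(t, t0, tail_policy)


def survival_percentile(
    tables: LifeTableCollection,
    sex: str,
    birth_year: int,
    age_at_death: float,
    tail_policy: str = "hold_last",
) -> float:
    """Sex and birth-year specific survival percentile of a death age."""
    return tables.get(sex, birth_year).percentile(age_at_death, tail_policy)


def threshold_age(
    table: CohortLifeTable, top_fraction: float, tail_policy: str = "hold_last"
) -> float:
    """Age at death corresponding to the top-``top_fraction`` survivors."""
    return table.threshold_age(top_fraction, tail_policy)
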