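"""Synthetic cohort life tables and multigenerational families.

The generator emulates the structure of a historical case/control
genealogy: founder index persons (IPs) ascertained either as long-lived
cases (death at or beyond a case age) or as average-lived controls (death
within a mid-life window), two descendant generations with spouses,
right-censoring at a calendar year, and per-role missing-age rates.

Familial longevity is induced by a per-family multiplicative frailty
``u ~ Gamma(mean 1, variance theta)`` on the hazard of the IP and all
blood descendants; spouses are frailty-free (their survival resembles the
general population).  The generating life tables are the exact marginal
law of a non-frail (u = 1) individual; when ``theta > 0`` the observable
population marginal is heavier-tailed, with the closed form
``S_pop(t) = (1 + theta * H(t)) ** (-1 / theta)``, and the matching
"reference" tables (the analogue of national life tables computed on the
whole, frailty-mixed population) are produced alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .life_tables import (
    CohortLifeTable,
    LifeTableCollection,
    write_life_tables,
)
from .pedigree import Pedigree, Person, pedigrees_to_frame, write_pedigree

__all__ = [
    "SimulationError",
    "MortalityLaw",
    "SimScenario",
    "SimOutput",
    "make_life_tables",
    "marginal_population_tables",
    "marginal_lognormal_tables",
    "simulate_cohort",
    "apply_missingness",
    "build_pedigrees",
    "simulate_frailty_records",
    "write_sim_output",
]


class SimulationError(ValueError):
    """Invalid or infeasible simulation scenario."""


@dataclass(frozen=True)
class MortalityLaw:
    """Gompertz-Makeham yearly mortality with an optional secular trend.

    The continuous hazard at age ``x`` for birth year ``y`` is
    ``a + b * exp(-trend * (y - ref_year)) * exp(c * x)``; yearly table
    hazards are the exact integral of this over each one-year age
    interval, so the tabulated cumulative hazard matches the continuous
    law exactly at integer ages.
    """

    makeham: float = 0.008
    gompertz_b: float = 5e-5
    gompertz_c: float = 0.10
    trend: float = 0.0
    ref_year: int = 1860

    def __post_init__(self) -> None:
        if self.makeham < 0 or self.gompertz_b < 0 or self.gompertz_c < 0:
            raise SimulationError("mortality parameters must be nonnegative")
        if self.makeham == 0 and self.gompertz_b == 0:
            raise SimulationError("mortality law is identically zero")

    def yearly_hazards(self, birth_year: int, max_age: int) -> np.ndarray:
        b = self.gompertz_b * math.exp(-self.trend * (birth_year - self.ref_year))
        x = np.arange(max_age + 1, dtype=float)
        if self.gompertz_c > 0:
            gomp = (b / self.gompertz_c) * (
                np.exp(self.gompertz_c * (x + 1)) - np.exp(self.gompertz_c * x)
            )
        else:
            gomp = np.full_like(x, b)
        return self.makeham + gomp


DEFAULT_LAWS: Mapping[str, MortalityLaw] = {
    "male": MortalityLaw(makeham=0.008, gompertz_b=5e-5, gompertz_c=0.10, trend=0.004),
    "female": MortalityLaw(makeham=0.007, gompertz_b=4e-5, gompertz_c=0.10, trend=0.004),
}


def make_life_tables(
    laws: Mapping[str, MortalityLaw],
    birth_years: Iterable[int],
    max_age: int = 110,
) -> LifeTableCollection:
    """Discretise continuous mortality laws into cohort life tables."""
    tables = []
    for sex, law in laws.items():
        for by in birth_years:
            tables.append(CohortLifeTable(sex, int(by), law.yearly_hazards(int(by), max_age)))
    return LifeTableCollection(tables, source="synthetic")


def marginal_population_tables(
    tables: LifeTableCollection, theta: float
) -> LifeTableCollection:
    """Life tables of the gamma-frailty-mixed population.

    Integrating a Gamma(mean 1, variance theta) frailty out of the
    individual law with cumulative hazard ``H`` gives population survival
    ``S_pop(t) = (1 + theta H(t)) ** (-1/theta)``, i.e. population
    cumulative hazard ``log(1 + theta H(t)) / theta``.  The returned
    tables tabulate its exact yearly increments; with ``theta = 0`` the
    input tables are returned unchanged.
    """
    if theta < 0:
        raise SimulationError("theta must be >= 0")
    if theta == 0:
        return tables
    out = []
    for table in tables:
        cum = np.concatenate(([0.0], np.cumsum(table.hazard)))
        cum_pop = np.log1p(theta * cum) / theta
        out.append(CohortLifeTable(table.sex, table.birth_year, np.diff(cum_pop)))
    return LifeTableCollection(out, source=f"{tables.source}:marginal(theta={theta})")


def marginal_lognormal_tables(
    tables: LifeTableCollection, sigma2: float, n_nodes: int = 64
) -> LifeTableCollection:
    """Life tables of a lognormal-frailty-mixed population.

    For ``log u ~ N(-sigma2/2, sigma2)`` (so ``E[u] = 1``) the population
    survival is ``S_pop(t) = E[exp(-u H(t))]``, evaluated by Gauss-Hermite
    quadrature at integer ages; with ``sigma2 = 0`` the input tables are
    returned unchanged.
    """
    if sigma2 < 0:
        raise SimulationError("sigma2 must be >= 0")
    if sigma2 == 0:
        return tables
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    u = np.exp(-sigma2 / 2.0 + math.sqrt(sigma2) * nodes)
    w = weights / weights.sum()
    out = []
    for table in tables:
        cum = np.concatenate(([0.0], np.cumsum(table.hazard)))
        s_pop = np.exp(-np.outer(cum, u)) @ w
        cum_pop = -np.log(s_pop)
        out.append(CohortLifeTable(table.sex, table.birth_year, np.diff(cum_pop)))
    return LifeTableCollection(
        out, source=f"{tables.source}:lognormal_marginal(sigma2={sigma2})"
    )


FRAILTY_MODELS = ("shared", "transmission")


@dataclass(frozen=True)
class SimScenario:
    """Parameters of the synthetic multigenerational cohort.

    ``frailty_model`` selects how familial longevity is induced:

    ``"shared"``
        one multiplicative frailty ``u ~ Gamma(mean 1, var frailty_theta)``
        per family, applied to the IP (unless ``founders_frail=False``)
        and all blood descendants; spouses carry ``u = 1``;
    ``"transmission"``
        per-person lognormal frailty with additive inheritance:
        ``log u`` of a founder or spouse is drawn from
        ``N(-theta/2, theta)`` and a child receives the mean of its
        parents' values plus a ``N(0, theta/2)`` innovation, keeping every
        person marginally population-distributed while relatives correlate
        according to their kinship.
    """

    n_families: int = 200
    p_case: float = 0.65
    case_min_age: float = 80.0
    control_age_range: tuple[float, float] = (40.0, 60.0)
    f1_birth_years: tuple[int, int] = (1860, 1875)
    child_gap: tuple[int, int] = (22, 40)
    mean_children: float = 3.0
    spouse_prob: float = 0.9
    spouse_age_diff: int = 5
    frailty_theta: float = 0.0
    frailty_model: str = "shared"
    founders_frail: bool = True
    censor_year: int = 2020
    max_age: int = 110
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    laws: Mapping[str, MortalityLaw] = field(default_factory=lambda: dict(DEFAULT_LAWS))

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise SimulationError("n_families must be >= 1")
        if not (0.0 <= self.p_case <= 1.0):
            raise SimulationError("p_case must be in [0, 1]")
        if self.frailty_theta < 0:
            raise SimulationError("frailty_theta must be >= 0")
        if self.frailty_model not in FRAILTY_MODELS:
            raise SimulationError(
                f"frailty_model must be one of {FRAILTY_MODELS}"
            )
        if self.mean_children <= 0:
            raise SimulationError("mean_children must be > 0")
        lo, hi = self.control_age_range
        if not (0 <= lo < hi):
            raise SimulationError("control_age_range must satisfy 0 <= lo < hi")
        for rate in self.missing_rates.values():
            if not (0.0 <= rate <= 1.0):
                raise SimulationError("missing rates must lie in [0, 1]")


@dataclass
class SimOutput:
    """Pedigrees, the generating and reference life tables, and the truth
    record (family frailties, uncensored ages, true percentiles)."""

    pedigrees: list[Pedigree]
    tables: LifeTableCollection
    reference_tables: LifeTableCollection
    truth: pd.DataFrame
    scenario: SimScenario

    def persons_frame(self) -> pd.DataFrame:
        """Observed per-person table (post-censoring, post-missingness)."""
        df = pedigrees_to_frame(self.pedigrees)
        out = pd.DataFrame(
            {
                "person_id": df["person_id"],
                "family_id": df["family_id"],
                "role": df["role_tag"],
                "sex": df["sex"],
                "birth_year": pd.to_numeric(df["birth_year"]),
                "t": pd.to_numeric(df["age_end"], errors="coerce"),
                "d": (df["vital_status"] == "dead").astype(int),
                "t0": 0.0,
            }
        )
        return out


class _TableSampler:
    """Inverse-CDF lifetime sampling from a life-table collection.

    Each table's cumulative-hazard grid is extended beyond the tabulated
    maximum age by holding the last hazard, then capped; lifetimes are
    drawn by inverting ``u * H(T) = E`` with ``E ~ Exp(1)``.
    """

    def __init__(self, tables: LifeTableCollection, cap_age: float):
        self.grids: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
        self.cap_age = cap_age
        for table in tables:
            n = table.hazard.size
            extra = int(math.ceil(cap_age - n)) if cap_age > n else 0
            ages = np.arange(n + extra + 1, dtype=float)
            hz = np.concatenate([table.hazard, np.full(extra, table.hazard[-1])])
            cum = np.concatenate(([0.0], np.cumsum(hz)))
            self.grids[table.key] = (ages, cum)

    def cum_at(self, sex: str, birth_year: int, age: float) -> float:
        ages, cum = self.grids[(sex, birth_year)]
        return float(np.interp(age, ages, cum))

    def draw(self, sex: str, birth_year: int, u: float, rng: np.random.Generator) -> float:
        ages, cum = self.grids[(sex, birth_year)]
        e = rng.exponential() / u
        if e >= cum[-1]:
            return float(ages[-1])
        return float(np.interp(e, cum, ages))

    def window_probability(
        self, sex: str, birth_year: int, u: float, lo: float, hi: float | None
    ) -> float:
        """P(lo <= T < hi) for an individual with frailty ``u``."""
        ages, cum = self.grids[(sex, birth_year)]
        s_lo = math.exp(-u * float(np.interp(lo, ages, cum)))
        s_hi = (
            math.exp(-u * float(np.interp(hi, ages, cum)))
            if hi is not None
            else 0.0
        )
        return s_lo - s_hi


def _zt_poisson(mean: float, rng: np.random.Generator) -> int:
    """Zero-truncated Poisson draw by rejection (mean refers to the
    untruncated Poisson parameter)."""
    for _ in range(1000):
        k = rng.poisson(mean)
        if k > 0:
            return int(k)
    return 1


def simulate_cohort(
    scenario: SimScenario, seed: int | np.random.Generator | None = None
) -> SimOutput:
    """Generate one synthetic cohort.

    Founder IPs are ascertained by rejection sampling into their arm
    (case: death at or beyond ``case_min_age``; control: death within
    ``control_age_range``): frailty and lifetime are redrawn until the
    death age falls inside the arm window, so the arm selection tilts the
    family frailty distribution exactly as ascertainment on observed
    longevity does.  An arm that is unattainable under the mortality law
    (or not hit within a bounded number of attempts) raises
    :class:`SimulationError`.  Runs are bit-reproducible given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sc = scenario

    by_lo = sc.f1_birth_years[0] - sc.spouse_age_diff - 1
    by_hi = (
        sc.f1_birth_years[1]
        + 2 * (sc.child_gap[1] + sc.spouse_age_diff)
        + sc.spouse_age_diff
        + 1
    )
    tables = make_life_tables(sc.laws, range(by_lo, by_hi + 1), sc.max_age)
    transmission = sc.frailty_model == "transmission"
    reference = (
        marginal_lognormal_tables(tables, sc.frailty_theta)
        if transmission
        else marginal_population_tables(tables, sc.frailty_theta)
    )
    sampler = _TableSampler(tables, cap_age=sc.max_age + 30.0)
    sig2 = sc.frailty_theta
    sd_half = math.sqrt(sig2 / 2.0) if sig2 > 0 else 0.0

    def _population_u() -> float:
        """Frailty of a founder or spouse drawn from the population."""
        if transmission and sig2 > 0:
            return float(math.exp(-sig2 / 2.0 + math.sqrt(sig2) * rng.normal()))
        return 1.0

    rows: list[dict] = []

    def _emit(
        fam: str,
        pid: str,
        role: str,
        sex: str,
        by: int,
        true_age: float,
        u: float,
        father: str | None = None,
        mother: str | None = None,
        partner: str | None = None,
    ) -> dict:
        dead = by + true_age <= sc.censor_year
        age_end = true_age if dead else float(sc.censor_year - by)
        row = {
            "family_id": fam,
            "person_id": pid,
            "father_id": father,
            "mother_id": mother,
            "sex": sex,
            "birth_year": by,
            "age_end": age_end,
            "vital_status": "dead" if dead else "alive",
            "role_tag": role,
            "partner_id": partner,
            "u": u,
            "true_age": true_age,
        }
        rows.append(row)
        return row

    def _spouse_birth_year(by: int) -> int:
        return int(by + rng.integers(-sc.spouse_age_diff, sc.spouse_age_diff + 1))

    def _sex() -> str:
        return "male" if rng.random() < 0.5 else "female"

    def _child_u(father_u: float, mother_u: float, family_u: float) -> float:
        if not transmission:
            return family_u
        if sig2 == 0:
            return 1.0
        mid = 0.5 * (math.log(father_u) + math.log(mother_u))
        return float(math.exp(mid + sd_half * rng.normal()))

    def _draw_family_u() -> float:
        if sc.frailty_theta > 0 and not transmission:
            return float(rng.gamma(1.0 / sc.frailty_theta, sc.frailty_theta))
        return 1.0

    max_attempts = 10000

    for i in range(sc.n_families):
        fam = f"F{i:05d}"
        arm = "case" if rng.random() < sc.p_case else "control"
        if arm == "case":
            lo, hi = sc.case_min_age, None
        else:
            lo, hi = sc.control_age_range

        ip_sex = _sex()
        ip_by = int(rng.integers(sc.f1_birth_years[0], sc.f1_birth_years[1] + 1))
        # ascertain the IP by rejection: redraw frailty and lifetime until the
        # death age falls in the arm window, so that the arm tilts the frailty
        # distribution exactly as real ascertainment would
        if sampler.window_probability(ip_sex, ip_by, 1.0, lo, hi) < 1e-9:
            raise SimulationError(
                f"{arm} arm window [{lo}, {hi}) unattainable under the "
                f"mortality law for ({ip_sex}, {ip_by})"
            )
        for _ in range(max_attempts):
            u = _draw_family_u()
            if transmission:
                ip_u = _population_u()
            else:
                ip_u = u if sc.founders_frail else 1.0
            ip_age = sampler.draw(ip_sex, ip_by, ip_u, rng)
            if ip_age >= lo and (hi is None or ip_age < hi):
                break
        else:
            raise SimulationError(
                f"could not ascertain an IP into the {arm} arm within "
                f"{max_attempts} attempts for ({ip_sex}, {ip_by})"
            )
        ip_id = f"{fam}_IP"
        sp_id = f"{fam}_IPS"
        sp_sex = "female" if ip_sex == "male" else "male"
        sp_by = _spouse_birth_year(ip_by)
        _emit(fam, ip_id, "IP", ip_sex, ip_by, ip_age, ip_u, partner=sp_id)
        sp_u = _population_u()
        sp_age = sampler.draw(sp_sex, sp_by, sp_u, rng)
        _emit(fam, sp_id, "IP_spouse", sp_sex, sp_by, sp_age, sp_u, partner=ip_id)

        f1_father = ip_id if ip_sex == "male" else sp_id
        f1_mother = sp_id if ip_sex == "male" else ip_id
        mother_age = sp_age if ip_sex == "male" else ip_age
        mother_by = sp_by if ip_sex == "male" else ip_by

        # F2 children of the IP couple
        f2_rows = []
        n_children = _zt_poisson(sc.mean_children, rng)
        base_by = max(ip_by, sp_by)
        for c in range(n_children):
            child_by = int(base_by + rng.integers(sc.child_gap[0], sc.child_gap[1] + 1))
            if child_by > sc.censor_year:
                continue
            # mother must be alive at the child's birth
            if mother_by + mother_age <= child_by:
                continue
            child_sex = _sex()
            child_u = _child_u(ip_u if ip_sex == "male" else sp_u,
                               sp_u if ip_sex == "male" else ip_u, u)
            child_age = sampler.draw(child_sex, child_by, child_u, rng)
            child_id = f"{fam}_2C{c}"
            row = _emit(
                fam, child_id, "F2", child_sex, child_by, child_age, child_u,
                father=f1_father, mother=f1_mother,
            )
            f2_rows.append(row)

        # spouses of F2 and their F3 children
        for row in f2_rows:
            if rng.random() >= sc.spouse_prob:
                continue
            f2_id = row["person_id"]
            f2_sex = row["sex"]
            f2_by = row["birth_year"]
            sp2_id = f"{f2_id}S"
            sp2_sex = "female" if f2_sex == "male" else "male"
            sp2_by = _spouse_birth_year(f2_by)
            sp2_u = _population_u()
            sp2_age = sampler.draw(sp2_sex, sp2_by, sp2_u, rng)
            sp2_row = _emit(
                fam, sp2_id, "F2_spouse", sp2_sex, sp2_by, sp2_age, sp2_u, partner=f2_id
            )
            row["partner_id"] = sp2_id

            father = f2_id if f2_sex == "male" else sp2_id
            mother = sp2_id if f2_sex == "male" else f2_id
            mother_row2 = sp2_row if f2_sex == "male" else row
            n_grand = _zt_poisson(sc.mean_children, rng)
            base2 = max(f2_by, sp2_by)
            for g in range(n_grand):
                f3_by = int(base2 + rng.integers(sc.child_gap[0], sc.child_gap[1] + 1))
                if f3_by > sc.censor_year:
                    continue
                if mother_row2["birth_year"] + mother_row2["true_age"] <= f3_by:
                    continue
                f3_sex = _sex()
                f3_u = _child_u(row["u"] if f2_sex == "male" else sp2_u,
                                sp2_u if f2_sex == "male" else row["u"], u)
                f3_age = sampler.draw(f3_sex, f3_by, f3_u, rng)
                f3_id = f"{f2_id}C{g}"
                f3_row = _emit(
                    fam, f3_id, "F3", f3_sex, f3_by, f3_age, f3_u,
                    father=father, mother=mother,
                )
                if rng.random() < sc.spouse_prob:
                    sp3_id = f"{f3_id}S"
                    sp3_sex = "female" if f3_sex == "male" else "male"
                    sp3_by = _spouse_birth_year(f3_by)
                    if sp3_by <= sc.censor_year:
                        sp3_u = _population_u()
                        sp3_age = sampler.draw(sp3_sex, sp3_by, sp3_u, rng)
                        _emit(
                            fam, sp3_id, "F3_spouse", sp3_sex, sp3_by, sp3_age, sp3_u,
                            partner=f3_id,
                        )
                        f3_row["partner_id"] = sp3_id

    frame = pd.DataFrame(rows)
    truth = frame[
        ["person_id", "family_id", "role_tag", "sex", "birth_year", "u", "true_age"]
    ].copy()
    truth = truth.rename(columns={"role_tag": "role"})
    truth["dead_by_censor"] = (
        truth["birth_year"] + truth["true_age"] <= sc.censor_year
    ).astype(int)
    pct = np.empty(len(truth))
    for j, (sex, by, age) in enumerate(
        zip(truth["sex"], truth["birth_year"], truth["true_age"])
    ):
        pct[j] = reference.get(sex, int(by)).percentile(float(age))
    truth["true_percentile"] = pct

    pedigrees = build_pedigrees(frame)
    output = SimOutput(
        pedigrees=pedigrees,
        tables=tables,
        reference_tables=reference,
        truth=truth,
        scenario=sc,
    )
    if sc.missing_rates:
        output = apply_missingness(output, sc.missing_rates, rng)
    return output


def build_pedigrees(frame: pd.DataFrame) -> list[Pedigree]:
    """Construct validated pedigrees from a per-person record frame."""
    pedigrees = []
    for fam, grp in frame.groupby("family_id", sort=True):
        persons = [
            Person(
                person_id=r.person_id,
                family_id=fam,
                father_id=r.father_id,
                mother_id=r.mother_id,
                sex=r.sex,
                birth_year=int(r.birth_year),
                age_end=None if pd.isna(r.age_end) else float(r.age_end),
                vital_status=r.vital_status,
                role_tag=r.role_tag,
                partner_id=r.partner_id,
            )
            for r in grp.itertuples(index=False)
        ]
        pedigrees.append(Pedigree(fam, persons))
    return pedigrees


def apply_missingness(
    output: SimOutput,
    rates: Mapping[str, float],
    seed: int | np.random.Generator | None = None,
) -> SimOutput:
    """Blank ``age_end`` with the stated probability per role.

    The truth record keeps the original ages.  Rates for roles absent
    from the data are ignored; a rate of 0 is the identity.
    """
    for role, rate in rates.items():
        if not (0.0 <= rate <= 1.0):
            raise SimulationError(f"missing rate for role {role!r} outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frame = pedigrees_to_frame(output.pedigrees)
    frame["age_end"] = pd.to_numeric(frame["age_end"], errors="coerce")
    frame["birth_year"] = pd.to_numeric(frame["birth_year"])
    frame.loc[:, "father_id"] = frame["father_id"].replace("0", None)
    frame.loc[:, "mother_id"] = frame["mother_id"].replace("0", None)
    frame.loc[:, "partner_id"] = frame["partner_id"].replace("0", None)
    for role, rate in rates.items():
        if rate <= 0.0:
            continue
        mask = frame["role_tag"] == role
        blank = rng.random(int(mask.sum())) < rate
        idx = frame.index[mask][blank]
        frame.loc[idx, "age_end"] = np.nan
    return SimOutput(
        pedigrees=build_pedigrees(frame),
        tables=output.tables,
        reference_tables=output.reference_tables,
        truth=output.truth,
        scenario=output.scenario,
    )


def simulate_frailty_records(
    n_families: int,
    mean_family_size: float = 5.0,
    beta_group: float = 0.0,
    theta: float = 0.0,
    gompertz_b: float = 5e-5,
    gompertz_c: float = 0.10,
    censor_age: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Family-clustered survival records for frailty-model calibration.

    Each family draws ``u ~ Gamma(mean 1, variance theta)``; each member a
    Bernoulli(0.5) group indicator and a Gompertz lifetime with hazard
    ``u * exp(beta_group * group) * b * exp(c * t)``; optional
    right-censoring at ``censor_age``.  Returns columns ``family_id, group,
    t, event, entry``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = np.array([_zt_poisson(mean_family_size, rng) for _ in range(n_families)])
    n = int(sizes.sum())
    fam = np.repeat(np.arange(n_families), sizes)
    u = (
        rng.gamma(1.0 / theta, theta, size=n_families)[fam]
        if theta > 0
        else np.ones(n)
    )
    group = (rng.random(n) < 0.5).astype(int)
    rate = u * np.exp(beta_group * group)
    e = rng.exponential(size=n) / rate
    t = np.log1p(gompertz_c * e / gompertz_b) / gompertz_c
    event = np.ones(n, dtype=int)
    if censor_age is not None:
        cens = t > censor_age
        t = np.where(cens, censor_age, t)
        event = (~cens).astype(int)
    return pd.DataFrame(
        {
            "family_id": [f"F{int(i):05d}" for i in fam],
            "group": group,
            "t": t,
            "event": event,
            "entry": 0.0,
        }
    )


def write_sim_output(output: SimOutput, out_dir: str | Path) -> dict[str, Path]:
    """Write pedigree, life-table and truth files; returns their paths.

    ``life_tables.tsv`` holds the reference (population-marginal) tables a
    downstream analysis would use; ``generating_tables.tsv`` the u = 1
    individual law (identical when theta = 0).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": out_dir / "pedigree.tsv",
        "life_tables": out_dir / "life_tables.tsv",
        "generating_tables": out_dir / "generating_tables.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_pedigree(output.pedigrees, paths["pedigree"])
    write_life_tables(output.reference_tables, paths["life_tables"])
    write_life_tables(output.tables, paths["generating_tables"])
    output.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return paths
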