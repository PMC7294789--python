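"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from
the implementation under test: exhaustive allele-transmission enumeration
for relationship coefficients, direct gamma-function quantiles for
chi-square limits, and a from-scratch relative walk for the longevity
score.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import special


def chi2_quantile(q: float, df: int) -> float:
    """Chi-square quantile via the regularised incomplete gamma inverse."""
    return 2.0 * special.gammaincinv(df / 2.0, q)


def kinship_enumeration(parents: dict[str, tuple[str | None, str | None]],
                        a: str, b: str) -> float:
    """Kinship by exhaustive enumeration of all meiosis outcomes.

    ``parents`` maps person id -> (father, mother); persons must have
    either both parents present or none.  Every combination of allele
    transmissions is enumerated (4^k for k non-founders), and the kinship
    coefficient is the average probability that one random allele from
    ``a`` matches one random allele from ``b``.
    """
    order: list[str] = []
    seen: set[str] = set()

    def visit(pid: str) -> None:
        if pid in seen:
            return
        f, m = parents[pid]
        if f is not None:
            visit(f)
            visit(m)
        seen.add(pid)
        order.append(pid)

    for pid in parents:
        visit(pid)
    nonfounders = [pid for pid in order if parents[pid][0] is not None]
    if len(nonfounders) > 9:
        raise ValueError("pedigree too large for exhaustive enumeration")

    total = 0.0
    combos = list(itertools.product((0, 1), repeat=2 * len(nonfounders)))
    for combo in combos:
        alleles: dict[str, tuple] = {}
        for pid in order:
            f, m = parents[pid]
            if f is None:
                alleles[pid] = ((pid, 0), (pid, 1))
        for i, pid in enumerate(nonfounders):
            f, m = parents[pid]
            alleles[pid] = (alleles[f][combo[2 * i]], alleles[m][combo[2 * i + 1]])
        match = sum(
            x == y for x in alleles[a] for y in alleles[b]
        )
        total += match / 4.0
    return total / len(combos)


def lrc_brute_force(
    persons: dict[str, dict],
    focal: str,
    hazards: dict[tuple[str, int], np.ndarray],
    top_fraction: float,
    coefficient,
) -> tuple[float | None, float, float]:
    """From-scratch longevity score: walk the relative classes directly.

    ``persons`` maps id -> dict with keys father, mother, sex, birth_year,
    age_end, vital_status; ``hazards`` maps (sex, birth_year) to the yearly
    hazard vector; ``coefficient`` is a callable giving the relationship
    weight.  Returns (score, weighted_longlived, weighted_total).
    """

    def parents_of(pid):
        p = persons[pid]
        return [x for x in (p["father"], p["mother"]) if x is not None]

    def sibs_of(pid):
        mine = set(parents_of(pid))
        out = []
        for other, rec in persons.items():
            if other == pid:
                continue
            if mine and mine & set(parents_of(other)):
                out.append(other)
        return out

    relatives: set[str] = set()
    for par in parents_of(focal):
        relatives.add(par)
        relatives.update(parents_of(par))
        relatives.update(sibs_of(par))
    relatives.discard(focal)

    num = 0.0
    den = 0.0
    for rid in sorted(relatives):
        rec = persons[rid]
        if rec["age_end"] is None or rec["vital_status"] != "dead":
            continue
        hz = hazards[(rec["sex"], rec["birth_year"])]
        age = rec["age_end"]
        k = int(math.floor(age))
        cum = 0.0
        for x in range(min(k, len(hz))):
            cum += hz[x]
        if k < len(hz):
            cum += (age - k) * hz[k]
        else:
            cum += (age - len(hz)) * hz[-1] + 0.0
        pct = 1.0 - math.exp(-cum)
        w = coefficient(focal, rid)
        den += w
        if pct >= 1.0 - top_fraction:
            num += w
    if den == 0:
        return None, num, den
    return num / den, num, den
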