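"""The family longevity score: a relationship-weighted proportion of a
person's ancestral blood relatives who reached the top survival
percentiles of their own sex and birth cohort, plus the case/control
classification and the nine score bins built on it.

The score for focal person ``i`` is

    score_i = sum_k w_k * 1[P_k >= 1 - Z] / sum_k w_k

over the usable relatives ``k`` of ``i``, where ``w_k`` is the
relationship coefficient and ``P_k`` the relative's survival percentile.
Relatives with an unknown age are excluded from both numerator and
denominator; a person with no usable relatives is "unscorable", never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .life_tables import LifeTableCollection, LifeTableError
from .pedigree import (
    DEFAULT_RELATION_CLASSES,
    Pedigree,
    ancestral_relatives,
)

__all__ = [
    "LRCConfig",
    "RelativeTerm",
    "LRCResult",
    "lrc_score",
    "classify",
    "lrc_bins",
    "bin_label",
    "score_pedigrees",
    "LABELS",
    "BIN_NAMES",
]

#: classification labels, in increasing score order (plus "unscorable")
LABELS = (
    "family_control",
    "unselected_low",
    "nonclassified",
    "family_case",
    "unscorable",
)

BIN_NAMES = tuple(f"g{i}" for i in range(1, 10))

ALIVE_RULES = ("exclude", "alive_if_exceeds")


@dataclass(frozen=True)
class LRCConfig:
    """Configuration of the score and its classification cut-offs.

    ``top_fraction`` is the longevity threshold Z: a relative counts as
    long-lived when its survival percentile is at least ``1 - Z``.
    Scores of exactly 0 are family controls; scores in
    ``[nonclassified_lower, case_cutoff)`` are nonclassified; scores at or
    above ``case_cutoff`` are family cases.
    """

    top_fraction: float = 0.10
    case_cutoff: float = 0.30
    nonclassified_lower: float = 0.20
    relation_classes: tuple[str, ...] = DEFAULT_RELATION_CLASSES
    alive_rule: str = "exclude"
    tail_policy: str = "hold_last"

    def __post_init__(self) -> None:
        if not (0.0 < self.top_fraction < 1.0):
            raise ValueError("top_fraction must be in (0, 1)")
        if not (0.0 < self.nonclassified_lower < self.case_cutoff <= 1.0):
            raise ValueError(
                "need 0 < nonclassified_lower < case_cutoff <= 1 "
                "(the nonclassified band abuts the case cutoff)"
            )
        if self.alive_rule not in ALIVE_RULES:
            raise ValueError(f"alive_rule must be one of {ALIVE_RULES}")


@dataclass(frozen=True)
class RelativeTerm:
    """One relative's contribution to a score (or the reason it was excluded)."""

    person_id: str
    relationship: str
    weight: float
    percentile: float | None
    indicator: bool | None
    used: bool
    exclusion_reason: str | None = None


@dataclass(frozen=True)
class LRCResult:
    person_id: str
    family_id: str
    score: float | None
    weighted_longlived: float
    weighted_total: float
    n_relatives_used: int
    n_relatives_excluded: int
    detail: tuple[RelativeTerm, ...] = field(repr=False, default=())

    @property
    def scorable(self) -> bool:
        return self.score is not None


def lrc_score(
    pedigree: Pedigree,
    focal: str,
    tables: LifeTableCollection,
    config: LRCConfig = LRCConfig(),
) -> LRCResult:
    """Compute the longevity score of ``focal`` within its pedigree.

    Deceased relatives with a known age and birth year contribute their
    relationship coefficient to the denominator and, if their survival
    percentile reaches ``1 - top_fraction``, to the numerator.  Alive (or
    unknown-status) relatives follow ``config.alive_rule``: ``"exclude"``
    drops them; ``"alive_if_exceeds"`` counts them as long-lived when
    their current age already clears the percentile threshold (it can only
    rise) and drops them otherwise.

    Raises
    ------
    LifeTableError
        When a usable relative's ``(sex, birth_year)`` has no life table,
        naming the relative.
    """
    relatives = ancestral_relatives(pedigree, focal, config.relation_classes)
    terms: list[RelativeTerm] = []
    num = 0.0
    den = 0.0
    for entry in relatives:
        person = pedigree[entry.person_id]
        reason = None
        if person.age_end is None:
            reason = "missing_age"
        elif person.birth_year is None:
            reason = "missing_birth_year"
        elif person.sex is None:
            reason = "missing_sex"
        if reason is not None:
            terms.append(
                RelativeTerm(entry.person_id, entry.relationship, entry.weight,
                             None, None, False, reason)
            )
            continue
        try:
            pct = tables.get(person.sex, person.birth_year).percentile(
                person.age_end, config.tail_policy
            )
        except LifeTableError as err:
            raise LifeTableError(
                f"relative {entry.person_id} of focal {focal}: {err}"
            ) from err
        longlived = pct >= 1.0 - config.top_fraction
        if person.vital_status == "dead":
            num += entry.weight * longlived
            den += entry.weight
            terms.append(
                RelativeTerm(entry.person_id, entry.relationship, entry.weight,
                             pct, longlived, True)
            )
        elif config.alive_rule == "alive_if_exceeds" and longlived:
            # already past the threshold while alive: indicator is final
            num += entry.weight
            den += entry.weight
            terms.append(
                RelativeTerm(entry.person_id, entry.relationship, entry.weight,
                             pct, True, True)
            )
        else:
            terms.append(
                RelativeTerm(entry.person_id, entry.relationship, entry.weight,
                             pct, None, False, "not_deceased")
            )

    n_used = sum(t.used for t in terms)
    score = (num / den) if den > 0 else None
    return LRCResult(
        person_id=focal,
        family_id=pedigree.family_id,
        score=score,
        weighted_longlived=num,
        weighted_total=den,
        n_relatives_used=n_used,
        n_relatives_excluded=len(terms) - n_used,
        detail=tuple(terms),
    )


def classify(result: LRCResult, config: LRCConfig = LRCConfig()) -> str:
    """Map a score to its family case/control label.

    score 0 -> ``family_control``; (0, nonclassified_lower) ->
    ``unselected_low``; [nonclassified_lower, case_cutoff) ->
    ``nonclassified``; >= case_cutoff -> ``family_case``; undefined
    scores -> ``unscorable``.
    """
    if not result.scorable:
        return "unscorable"
    s = result.score
    if s == 0.0:
        return "family_control"
    if s < config.nonclassified_lower:
        return "unselected_low"
    if s < config.case_cutoff:
        return "nonclassified"
    return "family_case"


def bin_label(score: float) -> str:
    """Nine-bin label of a score: g1 = {0}, g2 = (0, 0.1), g3 = [0.1, 0.2),
    ..., g8 = [0.6, 0.7), g9 = [0.7, 1.0]."""
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"score outside [0, 1]: {score!r}")
    if score == 0.0:
        return "g1"
    if score < 0.1:
        return "g2"
    if score >= 0.7:
        return "g9"
    return f"g{int(score * 10) + 2}"


def lrc_bins(results: Iterable[LRCResult]) -> dict[str, list[str]]:
    """Partition scorable results into the nine score bins.

    Returns a mapping ``g1``..``g9`` to lists of person ids; the bins are
    mutually exclusive and exhaustive over defined scores in [0, 1].
    Unscorable results are excluded (a 0/0 score must not become a
    control).
    """
    bins: dict[str, list[str]] = {name: [] for name in BIN_NAMES}
    for result in results:
        if not result.scorable:
            continue
        bins[bin_label(result.score)].append(result.person_id)
    return bins


def score_pedigrees(
    pedigrees: Sequence[Pedigree],
    tables: LifeTableCollection,
    config: LRCConfig = LRCConfig(),
    focal_role: str | None = "F3",
) -> pd.DataFrame:
    """Score every focal person across pedigrees and tabulate the results.

    Focal persons are those whose ``role_tag`` equals ``focal_role``; with
    ``focal_role=None``, every person with two known parents is scored.
    Returns one row per focal person with columns ``person_id, family_id,
    score, weighted_longlived, weighted_total, n_used, n_excluded, label,
    bin``.
    """
    rows = []
    for ped in pedigrees:
        for person in ped:
            if focal_role is not None:
                if person.role_tag != focal_role:
                    continue
            elif len(ped.parent_ids(person.person_id)) < 2:
                continue
            result = lrc_score(ped, person.person_id, tables, config)
            rows.append(
                {
                    "person_id": result.person_id,
                    "family_id": result.family_id,
                    "score": result.score,
                    "weighted_longlived": result.weighted_longlived,
                    "weighted_total": result.weighted_total,
                    "n_used": result.n_relatives_used,
                    "n_excluded": result.n_relatives_excluded,
                    "label": classify(result, config),
                    "bin": bin_label(result.score) if result.scorable else "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "person_id", "family_id", "score", "weighted_longlived",
            "weighted_total", "n_used", "n_excluded", "label", "bin",
        ],
    )
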