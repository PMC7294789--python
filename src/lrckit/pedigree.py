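"""Multigenerational pedigrees, kinship-based relationship coefficients,
and enumeration of the relative sets used by the family longevity score.

Pedigree files are PED-like delimited text with one person per row and
columns ``family_id, person_id, father_id, mother_id, sex, birth_year,
age_end, vital_status`` plus optional ``role_tag`` and ``partner_id``
columns.  ``0`` or an empty field means an unknown parent.  Parent links
are taken to be biological; relationship coefficients come from the
standard recursive kinship algorithm with founders assumed unrelated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "PedigreeError",
    "Person",
    "Pedigree",
    "RelativeEntry",
    "RelativeSet",
    "DEFAULT_RELATION_CLASSES",
    "relationship_coefficient",
    "ancestral_relatives",
    "read_pedigree",
    "write_pedigree",
]

VITAL_STATUSES = ("dead", "alive", "unknown")
RELATION_CLASSES = ("parents", "siblings", "grandparents", "aunts_uncles")
#: ancestors of a grandchild-generation focal person: parents, the
#: parents' siblings, and grandparents
DEFAULT_RELATION_CLASSES = ("parents", "aunts_uncles", "grandparents")


class PedigreeError(ValueError):
    """Structural problem in a pedigree or pedigree file."""


@dataclass
class Person:
    """One individual in a pedigree.

    ``age_end`` is the age at death (``vital_status == "dead"``) or age at
    last observation (otherwise), possibly fractional; ``None`` means the
    age is unknown, in which case the person contributes to no percentile
    computation downstream.
    """

    person_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str | None = None
    birth_year: int | None = None
    age_end: float | None = None
    vital_status: str = "unknown"
    role_tag: str | None = None
    partner_id: str | None = None

    def __post_init__(self) -> None:
        if self.vital_status not in VITAL_STATUSES:
            raise PedigreeError(
                f"person {self.person_id}: vital_status must be one of "
                f"{VITAL_STATUSES}, got {self.vital_status!r}"
            )
        if self.sex is not None and self.sex not in ("female", "male"):
            raise PedigreeError(
                f"person {self.person_id}: sex must be 'female', 'male' or None"
            )
        if self.age_end is not None and (
            not math.isfinite(self.age_end) or self.age_end < 0
        ):
            raise PedigreeError(
                f"person {self.person_id}: age_end must be finite and >= 0"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def has_known_age(self) -> bool:
        return self.age_end is not None


@dataclass(frozen=True)
class RelativeEntry:
    person_id: str
    relationship: str
    weight: float


@dataclass(frozen=True)
class RelativeSet:
    """Blood relatives of a focal person with their relationship weights."""

    focal_id: str
    entries: tuple[RelativeEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RelativeEntry]:
        return iter(self.entries)

    def ids(self) -> list[str]:
        return [e.person_id for e in self.entries]


class Pedigree:
    """One family's individuals, indexed by person id.

    Validation enforces: parents referenced must be present; parent links
    must be acyclic; fathers are male and mothers female when sex is
    stated; a parent's birth year precedes the child's when both known.
    """

    def __init__(self, family_id: str, persons: Iterable[Person]):
        self.family_id = str(family_id)
        self.persons: dict[str, Person] = {}
        for p in persons:
            if p.person_id in self.persons:
                raise PedigreeError(
                    f"family {family_id}: duplicate person id {p.person_id!r}"
                )
            self.persons[p.person_id] = p
        self._validate()
        self._kinship_memo: dict[tuple[str, str], float] = {}
        self._depths: dict[str, int] = {}
        self._children: dict[str, list[str]] | None = None

    # -- container protocol ---------------------------------------------

    def __contains__(self, person_id: str) -> bool:
        return person_id in self.persons

    def __getitem__(self, person_id: str) -> Person:
        try:
            return self.persons[person_id]
        except KeyError:
            raise PedigreeError(
                f"unknown person id {person_id!r} in family {self.family_id}"
            ) from None

    def __len__(self) -> int:
        return len(self.persons)

    def __iter__(self) -> Iterator[Person]:
        return iter(self.persons.values())

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        missing: list[str] = []
        for p in self.persons.values():
            for pid in (p.father_id, p.mother_id):
                if pid is not None and pid not in self.persons:
                    missing.append(pid)
        if missing:
            raise PedigreeError(
                f"family {self.family_id}: persons referenced as parents but "
                f"absent: {sorted(set(missing))}"
            )
        for p in self.persons.values():
            if p.father_id is not None:
                father = self.persons[p.father_id]
                if father.sex == "female":
                    raise PedigreeError(
                        f"family {self.family_id}: father {p.father_id} of "
                        f"{p.person_id} is recorded as female"
                    )
            if p.mother_id is not None:
                mother = self.persons[p.mother_id]
                if mother.sex == "male":
                    raise PedigreeError(
                        f"family {self.family_id}: mother {p.mother_id} of "
                        f"{p.person_id} is recorded as male"
                    )
            for pid in (p.father_id, p.mother_id):
                if pid is None:
                    continue
                parent = self.persons[pid]
                if (
                    parent.birth_year is not None
                    and p.birth_year is not None
                    and parent.birth_year >= p.birth_year
                ):
                    raise PedigreeError(
                        f"family {self.family_id}: parent {pid} "
                        f"(born {parent.birth_year}) not older than child "
                        f"{p.person_id} (born {p.birth_year})"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color = {pid: WHITE for pid in self.persons}
        for start in self.persons:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, bool]] = [(start, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    color[node] = BLACK
                    continue
                if color[node] == BLACK:
                    continue
                if color[node] == GREY:
                    raise PedigreeError(
                        f"family {self.family_id}: cycle in parent links "
                        f"involving {node!r}"
                    )
                color[node] = GREY
                stack.append((node, True))
                p = self.persons[node]
                for pid in (p.father_id, p.mother_id):
                    if pid is not None:
                        if color[pid] == GREY:
                            raise PedigreeError(
                                f"family {self.family_id}: cycle in parent "
                                f"links involving {pid!r}"
                            )
                        if color[pid] == WHITE:
                            stack.append((pid, False))

    # -- structure helpers ------------------------------------------------

    def parent_ids(self, person_id: str) -> list[str]:
        p = self[person_id]
        return [pid for pid in (p.father_id, p.mother_id) if pid is not None]

    def children_ids(self, person_id: str) -> list[str]:
        if self._children is None:
            children: dict[str, list[str]] = {pid: [] for pid in self.persons}
            for p in self.persons.values():
                for pid in (p.father_id, p.mother_id):
                    if pid is not None:
                        children[pid].append(p.person_id)
            self._children = children
        self[person_id]
        return list(self._children[person_id])

    def sibling_ids(self, person_id: str, include_half: bool = True) -> list[str]:
        """Ids of individuals sharing at least one known parent (full sibs
        always; half-sibs unless ``include_half=False``)."""
        me = self[person_id]
        my_parents = set(self.parent_ids(person_id))
        if not my_parents:
            return []
        sibs = []
        for other in self.persons.values():
            if other.person_id == person_id:
                continue
            shared = my_parents & set(self.parent_ids(other.person_id))
            if not shared:
                continue
            full = (
                me.father_id is not None
                and me.mother_id is not None
                and other.father_id == me.father_id
                and other.mother_id == me.mother_id
            )
            if full or include_half:
                sibs.append(other.person_id)
        return sorted(sibs)

    def depth(self, person_id: str) -> int:
        """Generation depth: 0 for founders, 1 + max(parent depths) otherwise."""
        if person_id in self._depths:
            return self._depths[person_id]
        stack = [person_id]
        while stack:
            node = stack[-1]
            if node in self._depths:
                stack.pop()
                continue
            parents = self.parent_ids(node)
            pending = [pid for pid in parents if pid not in self._depths]
            if pending:
                stack.extend(pending)
                continue
            stack.pop()
            self._depths[node] = (
                1 + max(self._depths[pid] for pid in parents) if parents else 0
            )
        return self._depths[person_id]

    # -- kinship -----------------------------------------------------------

    def kinship(self, a: str, b: str) -> float:
        """Kinship coefficient phi(a, b) from the recursive algorithm.

        Founders are taken as unrelated and non-inbred; inbreeding arising
        from within-pedigree loops is handled by the recursion itself.
        """
        self[a]
        self[b]
        return self._kinship(a, b)

    def _kinship(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        memo = self._kinship_memo
        if key in memo:
            return memo[key]
        if a == b:
            parents = self.parent_ids(a)
            if len(parents) == 2:
                val = 0.5 + 0.5 * self._kinship(parents[0], parents[1])
            else:
                val = 0.5
        else:
            # recurse on the individual of greater depth: it cannot be an
            # ancestor of the other
            if self.depth(a) < self.depth(b):
                a, b = b, a
            p = self.persons[a]
            val = 0.0
            if p.father_id is not None:
                val += 0.5 * self._kinship(p.father_id, b)
            if p.mother_id is not None:
                val += 0.5 * self._kinship(p.mother_id, b)
        memo[key] = val
        return val

    def relationship_coefficient(self, a: str, b: str) -> float:
        """Twice the kinship coefficient: the expected shared fraction of
        nuclear DNA (parent/sibling 0.5; grandparent, aunt/uncle 0.25)."""
        if a == b:
            raise PedigreeError("relationship coefficient requires two distinct persons")
        return 2.0 * self.kinship(a, b)

    def relationship_label(self, focal: str, relative: str) -> str:
        """Structural label of ``relative`` as seen from ``focal``."""
        parents = set(self.parent_ids(focal))
        if relative in parents:
            return "parent"
        grandparents = {
            gid for pid in parents for gid in self.parent_ids(pid)
        }
        if relative in grandparents:
            return "grandparent"
        if relative in self.sibling_ids(focal):
            full = relative in self.sibling_ids(focal, include_half=False)
            return "sibling" if full else "half_sibling"
        for pid in parents:
            if relative in self.sibling_ids(pid):
                full = relative in self.sibling_ids(pid, include_half=False)
                return "aunt_uncle" if full else "half_aunt_uncle"
        return "other"


def relationship_coefficient(pedigree: Pedigree, a: str, b: str) -> float:
    """Relationship coefficient between two pedigree members (see
    :meth:`Pedigree.relationship_coefficient`)."""
    return pedigree.relationship_coefficient(a, b)


def ancestral_relatives(
    pedigree: Pedigree,
    focal: str,
    relation_classes: Sequence[str] = DEFAULT_RELATION_CLASSES,
) -> RelativeSet:
    """Enumerate the blood relatives of ``focal`` in the selected classes.

    ``relation_classes`` selects among ``"parents"``, ``"siblings"``,
    ``"grandparents"`` and ``"aunts_uncles"`` (full and half).  Spouses and
    other non-blood individuals never appear; each entry carries the
    relationship coefficient as its weight.
    """
    unknown = set(relation_classes) - set(RELATION_CLASSES)
    if unknown:
        raise PedigreeError(
            f"unknown relation classes {sorted(unknown)}; valid: {RELATION_CLASSES}"
        )
    pedigree[focal]
    chosen: dict[str, str] = {}

    def _add(pid: str, label: str) -> None:
        if pid != focal and pid not in chosen:
            chosen[pid] = label

    parents = pedigree.parent_ids(focal)
    if "parents" in relation_classes:
        for pid in parents:
            _add(pid, "parent")
    if "siblings" in relation_classes:
        for pid in pedigree.sibling_ids(focal):
            full = pid in pedigree.sibling_ids(focal, include_half=False)
            _add(pid, "sibling" if full else "half_sibling")
    if "grandparents" in relation_classes:
        for pid in parents:
            for gid in pedigree.parent_ids(pid):
                _add(gid, "grandparent")
    if "aunts_uncles" in relation_classes:
        for pid in parents:
            for aid in pedigree.sibling_ids(pid):
                full = aid in pedigree.sibling_ids(pid, include_half=False)
                _add(aid, "aunt_uncle" if full else "half_aunt_uncle")

    entries = tuple(
        RelativeEntry(pid, label, pedigree.relationship_coefficient(focal, pid))
        for pid, label in sorted(chosen.items())
    )
    return RelativeSet(focal_id=focal, entries=entries)


# -- file I/O -------------------------------------------------------------

PEDIGREE_COLUMNS = [
    "family_id",
    "person_id",
    "father_id",
    "mother_id",
    "sex",
    "birth_year",
    "age_end",
    "vital_status",
    "role_tag",
    "partner_id",
]

_MISSING_TOKENS = {"", "0", "na", "nan", "none"}


def _token_or_none(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    token = str(value).strip()
    return None if token.lower() in _MISSING_TOKENS else token


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_pedigree(path: str | Path) -> list[Pedigree]:
    """Read a PED-like file into one :class:`Pedigree` per family."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
    required = {
        "family_id", "person_id", "father_id", "mother_id",
        "sex", "birth_year", "age_end", "vital_status",
    }
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree file missing columns: {sorted(missing)}")
    pedigrees = []
    for family_id, grp in df.groupby("family_id", sort=True):
        persons = []
        for row in grp.itertuples(index=False):
            sex = _token_or_none(row.sex)
            by = _token_or_none(row.birth_year)
            age = _token_or_none(row.age_end)
            vital = _token_or_none(row.vital_status) or "unknown"
            persons.append(
                Person(
                    person_id=str(row.person_id).strip(),
                    family_id=str(family_id),
                    father_id=_token_or_none(row.father_id),
                    mother_id=_token_or_none(row.mother_id),
                    sex=sex,
                    birth_year=int(float(by)) if by is not None else None,
                    age_end=float(age) if age is not None else None,
                    vital_status=vital,
                    role_tag=_token_or_none(getattr(row, "role_tag", None)),
                    partner_id=_token_or_none(getattr(row, "partner_id", None)),
                )
            )
        pedigrees.append(Pedigree(str(family_id), persons))
    return pedigrees


def pedigrees_to_frame(pedigrees: Iterable[Pedigree]) -> pd.DataFrame:
    rows = []
    for ped in pedigrees:
        for p in ped:
            rows.append(
                {
                    "family_id": p.family_id,
                    "person_id": p.person_id,
                    "father_id": p.father_id or "0",
                    "mother_id": p.mother_id or "0",
                    "sex": p.sex or "",
                    "birth_year": "" if p.birth_year is None else p.birth_year,
                    "age_end": "" if p.age_end is None else p.age_end,
                    "vital_status": p.vital_status,
                    "role_tag": p.role_tag or "",
                    "partner_id": p.partner_id or "0",
                }
            )
    return pd.DataFrame(rows, columns=PEDIGREE_COLUMNS)


def write_pedigree(pedigrees: Iterable[Pedigree], path: str | Path) -> None:
    """Write pedigrees in the dialect :func:`read_pedigree` accepts."""
    path = Path(path)
    pedigrees_to_frame(pedigrees).to_csv(path, sep=_delimiter_for(path), index=False)
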