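from __future__ import annotations

import numpy as np
import pytest

from lrckit.life_tables import CohortLifeTable
from lrckit.pedigree import Pedigree, Person
from lrckit.simulate import MortalityLaw, make_life_tables


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def flat_table():
    """Constant hazard 0.05, ages 0..99."""
    return CohortLifeTable("female", 1900, np.full(100, 0.05))


@pytest.fixture()
def gompertz_collection():
    laws = {
        "female": MortalityLaw(makeham=0.002, gompertz_b=4e-5, gompertz_c=0.1),
        "male": MortalityLaw(makeham=0.003, gompertz_b=6e-5, gompertz_c=0.1),
    }
    return make_life_tables(laws, range(1850, 1991), max_age=105)


def person(pid, fam="FAM1", father=None, mother=None, sex=None, by=None,
           age=None, vital="dead", role=None, partner=None):
    return Person(
        person_id=pid, family_id=fam, father_id=father, mother_id=mother,
        sex=sex, birth_year=by, age_end=age, vital_status=vital,
        role_tag=role, partner_id=partner,
    )


@pytest.fixture()
def nuclear_pedigree():
    """Two founder parents, a focal child and one sibling."""
    return Pedigree("FAM1", [
        person("dad", sex="male", by=1900, age=70.0),
        person("mum", sex="female", by=1902, age=80.0),
        person("kid", father="dad", mother="mum", sex="male", by=1930, age=60.0),
        person("sib", father="dad", mother="mum", sex="female", by=1932, age=85.0),
    ])


@pytest.fixture()
def three_generation_pedigree():
    """Focal person with 2 parents, 3 aunts/uncles, 4 grandparents, plus a
    married-in spouse of an uncle (non-blood)."""
    return Pedigree("FAM1", [
        person("pgf", sex="male", by=1860, age=82.0),
        person("pgm", sex="female", by=1862, age=75.0),
        person("mgf", sex="male", by=1861, age=66.0),
        person("mgm", sex="female", by=1863, age=90.0),
        person("dad", father="pgf", mother="pgm", sex="male", by=1890, age=71.0),
        person("uncle1", father="pgf", mother="pgm", sex="male", by=1892, age=55.0),
        person("uncle2", father="pgf", mother="pgm", sex="male", by=1894, age=88.0),
        person("mom", father="mgf", mother="mgm", sex="female", by=1893, age=79.0),
        person("aunt1", father="mgf", mother="mgm", sex="female", by=1895, age=92.0),
        person("uncle1_wife", sex="female", by=1893, age=81.0, partner="uncle1"),
        person("focal", father="dad", mother="mom", sex="male", by=1920, age=68.0),
    ])


@pytest.fixture()
def cousin_pedigree():
    """Eight persons: the focal pair c1/c2 are first cousins."""
    return Pedigree("FAM1", [
        person("gf", sex="male", by=1860, age=80.0),
        person("gm", sex="female", by=1861, age=82.0),
        person("p1", father="gf", mother="gm", sex="male", by=1890, age=75.0),
        person("p2", father="gf", mother="gm", sex="female", by=1892, age=77.0),
        person("s1", sex="female", by=1891, age=70.0),
        person("s2", sex="male", by=1893, age=72.0),
        person("c1", father="p1", mother="s1", sex="male", by=1920, age=60.0),
        person("c2", father="s2", mother="p2", sex="female", by=1922, age=65.0),
    ])
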