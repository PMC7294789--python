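import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lrckit.life_tables import CohortLifeTable, LifeTableCollection, LifeTableError
from lrckit.lrc import (
    LRCConfig,
    bin_label,
    classify,
    lrc_bins,
    lrc_score,
    score_pedigrees,
)
from lrckit.pedigree import Pedigree

from conftest import person
from oracles import lrc_brute_force


def flat_tables(hazard=0.05, sexes=("female", "male"), years=range(1850, 1951)):
    return LifeTableCollection(
        [CohortLifeTable(s, y, np.full(120, hazard)) for s in sexes for y in years]
    )


TABLES = flat_tables()
# constant hazard 0.05: top-10% threshold age is ln(10)/0.05 ~ 46.05
LL_AGE = math.log(10.0) / 0.05
OLD = LL_AGE + 20.0
YOUNG = LL_AGE - 20.0


def two_parent_pedigree(age_dad, age_mum, extra=()):
    persons = [
        person("dad", sex="male", by=1880, age=age_dad),
        person("mum", sex="female", by=1882, age=age_mum),
        person("kid", father="dad", mother="mum", sex="male", by=1915, age=40.0),
    ]
    return Pedigree("FAM1", list(persons) + list(extra))


class TestLrcScore:
    def test_all_longlived_parents_scores_one(self):
        ped = two_parent_pedigree(OLD, OLD)
        res = lrc_score(ped, "kid", TABLES)
        assert res.score == 1.0
        assert res.weighted_total == 1.0

    def test_one_of_two_equal_relatives_scores_half(self):
        ped = two_parent_pedigree(OLD, YOUNG)
        res = lrc_score(ped, "kid", TABLES)
        assert res.score == 0.5
        assert res.weighted_longlived == 0.5
        assert res.n_relatives_used == 2

    def test_worked_example_quarter(self):
        # 1 long-lived parent (w 0.5) + 1 ordinary parent (w 0.5)
        # + 4 ordinary grandparents (w 0.25 each) -> 0.5 / 2.0 = 0.25
        extra = [
            person("pgf", sex="male", by=1850, age=YOUNG),
            person("pgm", sex="female", by=1852, age=YOUNG),
            person("mgf", sex="male", by=1851, age=YOUNG),
            person("mgm", sex="female", by=1853, age=YOUNG),
        ]
        persons = [
            person("dad", father="pgf", mother="pgm", sex="male", by=1880, age=OLD),
            person("mum", father="mgf", mother="mgm", sex="female", by=1882, age=YOUNG),
            person("kid", father="dad", mother="mum", sex="male", by=1915, age=40.0),
        ]
        ped = Pedigree("FAM1", persons + extra)
        res = lrc_score(ped, "kid", TABLES)
        assert res.weighted_total == 2.0
        assert res.weighted_longlived == 0.5
        assert res.score == 0.25

    def test_missing_age_relative_excluded_both_sums(self):
        ped = two_parent_pedigree(OLD, None)
        res = lrc_score(ped, "kid", TABLES)
        assert res.score == 1.0
        assert res.weighted_total == 0.5
        assert res.n_relatives_excluded == 1
        reasons = {t.person_id: t.exclusion_reason for t in res.detail if not t.used}
        assert reasons["mum"] == "missing_age"

    def test_zero_usable_relatives_unscorable_not_zero(self):
        ped = two_parent_pedigree(None, None)
        res = lrc_score(ped, "kid", TABLES)
        assert res.score is None
        assert not res.scorable
        assert classify(res) == "unscorable"

    def test_alive_relative_excluded_by_default(self):
        ped = two_parent_pedigree(OLD, OLD)
        ped["mum"].vital_status = "alive"
        res = lrc_score(ped, "kid", TABLES)
        assert res.weighted_total == 0.5

    def test_alive_if_exceeds_counts_past_threshold_only(self):
        cfg = LRCConfig(alive_rule="alive_if_exceeds")
        ped = two_parent_pedigree(OLD, YOUNG)
        ped["dad"].vital_status = "alive"   # already past the threshold age
        ped["mum"].vital_status = "alive"   # below it: excluded entirely
        res = lrc_score(ped, "kid", TABLES, cfg)
        assert res.weighted_total == 0.5
        assert res.score == 1.0

    def test_missing_table_error_names_relative(self):
        tables = flat_tables(years=range(1900, 1951))  # parents' years absent
        ped = two_parent_pedigree(OLD, OLD)
        with pytest.raises(LifeTableError, match="relative dad"):
            lrc_score(ped, "kid", tables)

    def test_deterministic_and_order_invariant(self):
        extra = [person("pgf", sex="male", by=1850, age=OLD),
                 person("pgm", sex="female", by=1852, age=YOUNG)]
        persons = [
            person("dad", father="pgf", mother="pgm", sex="male", by=1880, age=OLD),
            person("mum", sex="female", by=1882, age=YOUNG),
            person("kid", father="dad", mother="mum", sex="male", by=1915, age=40.0),
        ]
        a = lrc_score(Pedigree("FAM1", persons + extra), "kid", TABLES)
        b = lrc_score(Pedigree("FAM1", extra[::-1] + persons), "kid", TABLES)
        assert a.score == b.score == pytest.approx((0.5 + 0.25) / 1.5)

    def test_monotone_in_added_relatives(self):
        def with_grandfather(gp_age):
            return Pedigree("FAM1", [
                person("pgf", sex="male", by=1850, age=gp_age),
                person("dad", father="pgf", sex="male", by=1880, age=OLD),
                person("mum", sex="female", by=1882, age=YOUNG),
                person("kid", father="dad", mother="mum", sex="male", by=1915, age=40.0),
            ])

        base = lrc_score(two_parent_pedigree(OLD, YOUNG), "kid", TABLES)
        assert lrc_score(with_grandfather(OLD), "kid", TABLES).score >= base.score
        assert lrc_score(with_grandfather(YOUNG), "kid", TABLES).score <= base.score

    def test_brute_force_oracle_on_random_pedigrees(self, rng):
        """Score equals a from-scratch recomputation on randomized small
        pedigrees (independent relative walk + direct hazard summation)."""
        from lrckit.pedigree import relationship_coefficient

        hazards = {key: TABLES.get(*key).hazard for key in TABLES.keys()}
        n_match = 0
        for trial in range(1000):
            persons = {}

            def add(pid, father=None, mother=None, sex=None, by=1850, dead=True):
                age = float(rng.uniform(20, 100)) if rng.random() > 0.15 else None
                vital = "dead" if dead and age is not None else "unknown"
                persons[pid] = {
                    "father": father, "mother": mother, "sex": sex,
                    "birth_year": by, "age_end": age, "vital_status": vital,
                }

            add("pgf", sex="male", by=1850)
            add("pgm", sex="female", by=1851)
            add("mgf", sex="male", by=1852)
            add("mgm", sex="female", by=1853)
            add("dad", "pgf", "pgm", "male", 1880)
            add("mum", "mgf", "mgm", "female", 1881)
            for k in range(int(rng.integers(0, 3))):
                side = rng.random() < 0.5
                add(f"au{k}", "pgf" if side else "mgf",
                    "pgm" if side else "mgm",
                    "male" if rng.random() < 0.5 else "female", 1882 + k)
            persons["kid"] = {
                "father": "dad", "mother": "mum", "sex": "male",
                "birth_year": 1915, "age_end": 40.0, "vital_status": "dead",
            }
            ped = Pedigree("FAM1", [
                person(pid, father=rec["father"], mother=rec["mother"],
                       sex=rec["sex"], by=rec["birth_year"], age=rec["age_end"],
                       vital=rec["vital_status"])
                for pid, rec in persons.items()
            ])
            expected, num, den = lrc_brute_force(
                persons, "kid", hazards, 0.10,
                lambda a, b: relationship_coefficient(ped, a, b),
            )
            res = lrc_score(ped, "kid", TABLES)
            assert res.score == (pytest.approx(expected, abs=1e-12) if expected is not None else None)
            assert res.weighted_total == pytest.approx(den, abs=1e-12)
            n_match += 1
        assert n_match == 1000


class TestClassify:
    @pytest.mark.parametrize(
        "score,label",
        [
            (0.0, "family_control"),
            (0.05, "unselected_low"),
            (0.19, "unselected_low"),
            (0.20, "nonclassified"),
            (0.25, "nonclassified"),
            (0.2999, "nonclassified"),
            (0.30, "family_case"),
            (0.75, "family_case"),
            (1.0, "family_case"),
        ],
    )
    def test_boundaries(self, score, label):
        from lrckit.lrc import LRCResult

        res = LRCResult("p", "f", score, score, 1.0, 1, 0)
        assert classify(res) == label


class TestBins:
    def test_examples(self):
        assert bin_label(0.0) == "g1"
        assert bin_label(0.05) == "g2"
        assert bin_label(0.95) == "g9"

    @pytest.mark.parametrize(
        "score,expected",
        [(0.1, "g3"), (0.2, "g4"), (0.3, "g5"), (0.4, "g6"), (0.5, "g7"),
         (0.6, "g8"), (0.7, "g9"), (1.0, "g9")],
    )
    def test_left_closed_edges(self, score, expected):
        assert bin_label(score) == expected

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            bin_label(-0.01)
        with pytest.raises(ValueError):
            bin_label(1.01)

    @settings(max_examples=200, deadline=None)
    @given(score=st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_partition_is_exhaustive(self, score):
        assert bin_label(score) in {f"g{i}" for i in range(1, 10)}

    def test_partition_counts_sum(self, rng):
        from lrckit.lrc import LRCResult

        scores = rng.random(10_000)
        results = [LRCResult(str(i), "f", s, s, 1.0, 1, 0) for i, s in enumerate(scores)]
        results.append(LRCResult("unscorable", "f", None, 0.0, 0.0, 0, 1))
        bins = lrc_bins(results)
        assert sum(len(v) for v in bins.values()) == 10_000
        assert set(bins) == {f"g{i}" for i in range(1, 10)}


class TestConfig:
    def test_invalid_top_fraction(self):
        with pytest.raises(ValueError):
            LRCConfig(top_fraction=0.0)

    def test_band_must_abut_cutoff(self):
        with pytest.raises(ValueError):
            LRCConfig(nonclassified_lower=0.5, case_cutoff=0.3)

    def test_invalid_alive_rule(self):
        with pytest.raises(ValueError):
            LRCConfig(alive_rule="whatever")


class TestScorePedigrees:
    def test_frame_schema(self):
        ped = two_parent_pedigree(OLD, YOUNG)
        df = score_pedigrees([ped], TABLES, focal_role=None)
        assert list(df.columns) == [
            "person_id", "family_id", "score", "weighted_longlived",
            "weighted_total", "n_used", "n_excluded", "label", "bin",
        ]
        assert len(df) == 1
        row = df.iloc[0]
        assert row["score"] == 0.5 and row["bin"] == "g7"
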