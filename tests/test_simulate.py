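import math

import numpy as np
import pandas as pd
import pytest

from lrckit.life_tables import write_life_tables
from lrckit.pedigree import write_pedigree
from lrckit.simulate import (
    MortalityLaw,
    SimScenario,
    SimulationError,
    apply_missingness,
    make_life_tables,
    marginal_lognormal_tables,
    marginal_population_tables,
    simulate_cohort,
    simulate_frailty_records,
    write_sim_output,
)
from lrckit.smr import smr_exact


class TestMortalityLaw:
    def test_makeham_only_flat(self):
        law = MortalityLaw(makeham=0.01, gompertz_b=0.0, gompertz_c=0.0)
        h = law.yearly_hazards(1900, 50)
        assert np.allclose(h, 0.01)

    def test_gompertz_closed_form_cumulative(self):
        b, c = 5e-5, 0.1
        law = MortalityLaw(makeham=0.0, gompertz_b=b, gompertz_c=c)
        h = law.yearly_hazards(1900, 100)
        cum = np.cumsum(h)
        ages = np.arange(1, 102)
        expected = (b / c) * (np.exp(c * ages) - 1.0)
        np.testing.assert_allclose(cum, expected, rtol=1e-12)

    def test_secular_trend_orders_cohorts(self):
        law = MortalityLaw(trend=0.005)
        early = law.yearly_hazards(1860, 100)
        late = law.yearly_hazards(1900, 100)
        assert np.all(late <= early)
        assert np.any(late < early)

    def test_negative_parameters_error(self):
        with pytest.raises(SimulationError):
            MortalityLaw(makeham=-0.1)
        with pytest.raises(SimulationError):
            MortalityLaw(gompertz_b=-1e-5)

    def test_all_zero_error(self):
        with pytest.raises(SimulationError):
            MortalityLaw(makeham=0.0, gompertz_b=0.0)


class TestMakeLifeTables:
    def test_keys_and_dominance(self):
        laws = {
            "female": MortalityLaw(makeham=0.005, gompertz_b=4e-5),
            "male": MortalityLaw(makeham=0.008, gompertz_b=6e-5),
        }
        coll = make_life_tables(laws, range(1900, 1903))
        assert len(coll) == 6
        f = coll.get("female", 1900)
        m = coll.get("male", 1900)
        # configured female advantage: stochastic dominance of survival
        assert all(
            f.survival(t) >= m.survival(t) for t in np.linspace(1, 100, 25)
        )


class TestMarginalTables:
    def test_gamma_mixture_closed_form(self):
        theta = 0.4
        base = make_life_tables({"male": MortalityLaw()}, [1900])
        pop = marginal_population_tables(base, theta)
        H = np.cumsum(base.get("male", 1900).hazard)
        H_pop = np.cumsum(pop.get("male", 1900).hazard)
        np.testing.assert_allclose(H_pop, np.log1p(theta * H) / theta, rtol=1e-12)
        # equivalently S_pop = (1 + theta H)^(-1/theta)
        np.testing.assert_allclose(
            np.exp(-H_pop), (1 + theta * H) ** (-1 / theta), rtol=1e-12
        )

    def test_theta_zero_identity(self):
        base = make_life_tables({"male": MortalityLaw()}, [1900])
        assert marginal_population_tables(base, 0.0) is base
        assert marginal_lognormal_tables(base, 0.0) is base

    def test_heavier_tail_than_base(self):
        base = make_life_tables({"male": MortalityLaw()}, [1900])
        for mixed in (
            marginal_population_tables(base, 0.5),
            marginal_lognormal_tables(base, 0.5),
        ):
            s_base = base.get("male", 1900).survival(95.0)
            s_mix = mixed.get("male", 1900).survival(95.0)
            assert s_mix > s_base

    def test_lognormal_quadrature_matches_monte_carlo(self, rng):
        sigma2 = 0.3
        base = make_life_tables({"male": MortalityLaw()}, [1900])
        mixed = marginal_lognormal_tables(base, sigma2)
        H80 = base.get("male", 1900).cumulative_hazard(80.0)
        u = np.exp(rng.normal(-sigma2 / 2, math.sqrt(sigma2), size=200_000))
        mc = np.mean(np.exp(-u * H80))
        assert mixed.get("male", 1900).survival(80.0) == pytest.approx(mc, rel=2e-3)


class TestSimulateCohort:
    def test_structure_and_roles(self):
        out = simulate_cohort(SimScenario(n_families=20), seed=1)
        pf = out.persons_frame()
        roles = set(pf["role"])
        assert {"IP", "IP_spouse", "F2", "F3"} <= roles
        assert (pf.groupby("family_id")["role"].apply(lambda r: (r == "IP").sum()) == 1).all()

    def test_arm_windows_respected(self):
        sc = SimScenario(n_families=40, p_case=0.5)
        out = simulate_cohort(sc, seed=2)
        ips = out.truth[out.truth["role"] == "IP"]
        ages = ips["true_age"].to_numpy()
        in_case = ages >= 80.0
        in_control = (ages >= 40.0) & (ages < 60.0)
        assert np.all(in_case | in_control)
        assert in_case.any() and in_control.any()

    def test_same_seed_byte_identical_files(self, tmp_path):
        sc = SimScenario(n_families=15, frailty_theta=0.3)
        a = simulate_cohort(sc, seed=7)
        b = simulate_cohort(sc, seed=7)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_pedigree(a.pedigrees, pa)
        write_pedigree(b.pedigrees, pb)
        assert pa.read_bytes() == pb.read_bytes()
        ta, tb = tmp_path / "ta.tsv", tmp_path / "tb.tsv"
        write_life_tables(a.reference_tables, ta)
        write_life_tables(b.reference_tables, tb)
        assert ta.read_bytes() == tb.read_bytes()

    def test_different_seed_differs(self):
        sc = SimScenario(n_families=15)
        a = simulate_cohort(sc, seed=1)
        b = simulate_cohort(sc, seed=2)
        assert not a.truth["true_age"].equals(b.truth["true_age"])

    def test_spouses_not_frail_in_shared_model(self):
        out = simulate_cohort(SimScenario(n_families=30, frailty_theta=0.5), seed=4)
        t = out.truth
        spouses = t[t["role"].str.contains("spouse")]
        assert (spouses["u"] == 1.0).all()
        f3 = t[t["role"] == "F3"]
        per_fam = f3.groupby("family_id")["u"].nunique()
        assert (per_fam == 1).all()
        assert t["u"].var() > 0

    def test_transmission_model_correlations(self):
        sc = SimScenario(
            n_families=800, frailty_theta=0.5, frailty_model="transmission",
            p_case=0.5,
        )
        out = simulate_cohort(sc, seed=11)
        t = out.truth
        f3 = t[t["role"] == "F3"]
        sp = t[t["role"] == "F3_spouse"]
        # spouses are drawn from the population, uncorrelated with the family
        merged = f3.merge(sp[["family_id", "u"]], on="family_id",
                          suffixes=("", "_sp"))
        r = np.corrcoef(np.log(merged["u"]), np.log(merged["u_sp"]))[0, 1]
        assert abs(r) < 0.1
        # parent-child correlation is near 0.5
        f2 = t.set_index("person_id")
        pairs = []
        for ped in out.pedigrees:
            for p in ped:
                if p.role_tag == "F3":
                    for par in ped.parent_ids(p.person_id):
                        if f2.loc[par, "role"] == "F2":
                            pairs.append((math.log(f2.loc[p.person_id, "u"]),
                                          math.log(f2.loc[par, "u"])))
        pairs = np.array(pairs)
        r_pc = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert 0.35 < r_pc < 0.65

    def test_null_population_smr_near_one(self):
        out = simulate_cohort(SimScenario(n_families=400), seed=5)
        pf = out.persons_frame()
        sub = pf[(pf["role"] != "IP") & pf["t"].notna()]
        res = smr_exact(sub, out.reference_tables)
        assert res.smr == pytest.approx(1.0, abs=0.05)

    def test_infeasible_case_arm_error(self):
        laws = {
            "female": MortalityLaw(makeham=5.0, gompertz_b=1e-5),
            "male": MortalityLaw(makeham=5.0, gompertz_b=1e-5),
        }
        sc = SimScenario(n_families=2, p_case=1.0, laws=laws)
        with pytest.raises(SimulationError, match="unattainable|attempts"):
            simulate_cohort(sc, seed=1)

    def test_invalid_scenarios(self):
        with pytest.raises(SimulationError):
            SimScenario(n_families=0)
        with pytest.raises(SimulationError):
            SimScenario(frailty_theta=-0.1)
        with pytest.raises(SimulationError):
            SimScenario(frailty_model="psychic")
        with pytest.raises(SimulationError):
            SimScenario(missing_rates={"F2": 1.5})


class TestMissingness:
    def test_rate_zero_identity(self):
        out = simulate_cohort(SimScenario(n_families=20), seed=6)
        after = apply_missingness(out, {"F2": 0.0}, seed=1)
        a = pd.concat([out.persons_frame()]).fillna(-1)
        b = pd.concat([after.persons_frame()]).fillna(-1)
        pd.testing.assert_frame_equal(a, b)

    def test_rate_one_blanks_all(self):
        out = simulate_cohort(SimScenario(n_families=20), seed=6)
        after = apply_missingness(out, {"F2_spouse": 1.0}, seed=1)
        pf = after.persons_frame()
        assert pf.loc[pf["role"] == "F2_spouse", "t"].isna().all()
        assert pf.loc[pf["role"] == "F2", "t"].notna().all()

    def test_truth_keeps_original_ages(self):
        out = simulate_cohort(SimScenario(n_families=20), seed=6)
        after = apply_missingness(out, {"F3": 1.0}, seed=1)
        assert after.truth["true_age"].notna().all()

    def test_realized_fraction_within_binomial_ci(self):
        out = simulate_cohort(SimScenario(n_families=600), seed=8)
        rate = 0.35
        after = apply_missingness(out, {"F3": rate}, seed=2)
        pf = after.persons_frame()
        f3 = pf[pf["role"] == "F3"]
        n = len(f3)
        assert n > 3000
        frac = f3["t"].isna().mean()
        half = 3 * math.sqrt(rate * (1 - rate) / n)
        assert abs(frac - rate) < half

    def test_scenario_missing_rates_applied(self):
        sc = SimScenario(n_families=30, missing_rates={"F2_spouse": 1.0})
        out = simulate_cohort(sc, seed=9)
        pf = out.persons_frame()
        assert pf.loc[pf["role"] == "F2_spouse", "t"].isna().all()


class TestFrailtyRecords:
    def test_schema_and_determinism(self):
        a = simulate_frailty_records(50, 4, seed=3)
        b = simulate_frailty_records(50, 4, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert list(a.columns) == ["family_id", "group", "t", "event", "entry"]

    def test_censoring(self):
        df = simulate_frailty_records(100, 4, censor_age=70.0, seed=4)
        assert ((df["t"] <= 70.0) | (df["event"] == 1)).all()
        assert (df.loc[df["event"] == 0, "t"] == 70.0).all()

    def test_group_effect_direction(self):
        df = simulate_frailty_records(600, 5, beta_group=math.log(0.5), seed=5)
        assert df.groupby("group")["t"].mean()[1] > df.groupby("group")["t"].mean()[0]


class TestWriteSimOutput:
    def test_files_written(self, tmp_path):
        out = simulate_cohort(SimScenario(n_families=10), seed=1)
        paths = write_sim_output(out, tmp_path)
        for p in paths.values():
            assert p.exists() and p.stat().st_size > 0
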