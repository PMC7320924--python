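import numpy as np
import pandas as pd
import pytest

import stagemap as sm
from stagemap._schema import AGE_GROUPS, SEXES, STAGES
from stagemap.synthetic import UnstageableError, _icar_basis


class TestPopulation:
    def test_area_year_totals_within_band(self, lattice5, pop5):
        totals = pop5.groupby(["area_id", "year"])["person_years"].sum()
        assert totals.between(600, 2600).all()

    def test_all_strata_present(self, pop5):
        counts = pop5.groupby(["area_id", "year"]).size()
        assert (counts == len(AGE_GROUPS) * len(SEXES)).all()
        assert not pop5.duplicated(["area_id", "sex", "age_group", "year"]).any()
        assert (pop5["person_years"] >= 0).all()

    def test_deterministic_for_seed(self, lattice5):
        a = sm.generate_population(lattice5, 1600, 2, seed=7)
        b = sm.generate_population(lattice5, 1600, 2, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_preconditions(self, lattice5):
        with pytest.raises(ValueError):
            sm.generate_population(lattice5, 0.0, 9, seed=1)
        with pytest.raises(ValueError):
            sm.generate_population(lattice5, 1600, 0, seed=1)


class TestSimulateCases:
    def test_zero_rates_give_empty_table(self, lattice5, pop5):
        base = sm.default_baseline_rates({s: 0.0 for s in STAGES})
        cases = sm.simulate_cases(pop5, lattice5,
                                  sm.RiskModelParams(baseline_rates=base, seed=1))
        assert cases.empty

    def test_deterministic_for_seed(self, lattice5, pop5):
        p = sm.RiskModelParams(seed=42)
        a = sm.simulate_cases(pop5, lattice5, p)
        b = sm.simulate_cases(pop5, lattice5, p)
        pd.testing.assert_frame_equal(a, b)

    def test_total_counts_match_poisson_expectation(self):
        """With the random-effect fields switched off, total simulated counts
        are Poisson with mean sum(person_years * rate)."""
        geo = sm.generate_geography(2, 2, 0.0, seed=1)
        pop = sm.generate_population(geo, 1600, 1, seed=2)
        huge = {s: 1e8 for s in STAGES}
        totals = []
        for rep in range(200):
            p = sm.RiskModelParams(tau_u=huge, tau_v=huge, seed=rep)
            totals.append(len(sm.simulate_cases(pop, geo, p)))
        rates = sm.default_baseline_rates().set_index(["sex", "age_group", "stage"])["rate"]
        mu = 0.0
        for _, row in pop.iterrows():  # brute-force aggregation oracle
            for s in STAGES:
                mu += row["person_years"] * rates[(row["sex"], row["age_group"], s)]
        se = np.sqrt(mu / 200)
        assert abs(np.mean(totals) - mu) < 3 * se

    def test_crude_rates_match_stage_baselines(self):
        geo = sm.generate_geography(20, 10, 0.0, seed=3)
        pop = sm.generate_population(geo, 1600, 9, seed=4)
        huge = {s: 1e8 for s in STAGES}
        cases = sm.simulate_cases(pop, geo, sm.RiskModelParams(
            tau_u=huge, tau_v=huge, seed=5))
        py = pop["person_years"].sum()
        nominal = {"I": 20.0, "II": 5.0, "III-IV": 2.0}
        for s in STAGES:
            crude = 1e5 * (cases["stage"] == s).sum() / py
            se = 1e5 * np.sqrt(nominal[s] * py / 1e5) / py
            assert abs(crude - nominal[s]) < 3.5 * se

    def test_exchangeable_with_direct_poisson_sampler(self):
        """Per-area counts from the case simulator agree in mean and variance
        with stratum-by-stratum Poisson sampling at the same intensities."""
        geo = sm.generate_geography(2, 2, 0.0, seed=1)
        pop = sm.generate_population(geo, 1600, 1, seed=2)
        huge = {s: 1e8 for s in STAGES}
        rates = sm.default_baseline_rates().set_index(["sex", "age_group", "stage"])["rate"]
        mu_area = np.zeros(4)
        pos = {a: i for i, a in enumerate(geo.area_ids)}
        for _, row in pop.iterrows():
            for s in STAGES:
                mu_area[pos[row["area_id"]]] += (
                    row["person_years"] * rates[(row["sex"], row["age_group"], s)])
        sim_counts = np.zeros((500, 4))
        for rep in range(500):
            cases = sm.simulate_cases(pop, geo, sm.RiskModelParams(
                tau_u=huge, tau_v=huge, seed=10_000 + rep))
            if not cases.empty:
                c = cases.groupby("area_id").size()
                for a, v in c.items():
                    sim_counts[rep, pos[a]] = v
        rng = np.random.default_rng(99)
        direct = rng.poisson(mu_area, size=(500, 4))
        for j in range(4):
            se = np.sqrt(mu_area[j] / 500)
            assert abs(sim_counts[:, j].mean() - direct[:, j].mean()) < 4 * se
        # Poisson: variance ~= mean
        assert np.allclose(sim_counts.mean(0), sim_counts.var(0), rtol=0.5, atol=1.0)

    def test_quintile_effects_shift_group_rates(self):
        geo = sm.generate_geography(10, 10, 0.0, seed=6)
        pop = sm.generate_population(geo, 1600, 9, seed=7)
        eff = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        huge = {s: 1e8 for s in STAGES}
        cases = sm.simulate_cases(pop, geo, sm.RiskModelParams(
            quintile_log_effects={"I": eff, "II": np.zeros(5), "III-IV": np.zeros(5)},
            tau_u=huge, tau_v=huge, seed=8))
        q = geo.areas["quintile"]
        stage1 = cases[cases["stage"] == "I"]
        counts = stage1["area_id"].map(q).value_counts()
        py = pop.assign(q=pop["area_id"].map(q)).groupby("q")["person_years"].sum()
        rate_q5 = counts["Q5"] / py["Q5"]
        rate_q1 = counts["Q1"] / py["Q1"]
        assert rate_q5 / rate_q1 > 1.8  # exp(1.0) up to noise

    def test_missing_area_and_disconnected_geography_rejected(self, lattice5, pop5):
        bad = pop5.copy()
        bad.loc[0, "area_id"] = "NOWHERE"
        with pytest.raises(ValueError, match="absent"):
            sm.simulate_cases(bad, lattice5, sm.RiskModelParams(seed=1))
        areas = lattice5.areas.copy()
        disconnected = sm.Geography(areas, [])
        with pytest.raises(ValueError, match="connected"):
            sm.simulate_cases(pop5, disconnected, sm.RiskModelParams(seed=1))

    def test_balanced_fields_require_complete_labels(self, lattice5, pop5):
        labels = lattice5.areas["quintile"].iloc[:-1]
        with pytest.raises(ValueError, match="label every area"):
            sm.simulate_cases(pop5, lattice5, sm.RiskModelParams(seed=1),
                              balance_fields_on=labels)
        a = sm.simulate_cases(pop5, lattice5, sm.RiskModelParams(seed=2),
                              balance_fields_on=lattice5.areas["quintile"])
        b = sm.simulate_cases(pop5, lattice5, sm.RiskModelParams(seed=2),
                              balance_fields_on=lattice5.areas["quintile"])
        pd.testing.assert_frame_equal(a, b)

    def test_param_validation(self):
        with pytest.raises(ValueError, match="reference quintile"):
            sm.RiskModelParams(quintile_log_effects={"I": np.array([0.1, 0, 0, 0, 0]),
                                                     "II": np.zeros(5),
                                                     "III-IV": np.zeros(5)})
        with pytest.raises(ValueError, match="positive"):
            sm.RiskModelParams(tau_u={s: 0.0 for s in STAGES})


class TestICAR:
    def test_sum_to_zero_and_determinism(self, lattice5):
        basis = _icar_basis(lattice5.graph, lattice5.area_ids)
        u1 = sm.sample_icar(lattice5.graph, 4.0, np.random.default_rng(5),
                            lattice5.area_ids, basis)
        u2 = sm.sample_icar(lattice5.graph, 4.0, np.random.default_rng(5),
                            lattice5.area_ids, basis)
        assert abs(u1.sum()) < 1e-10
        np.testing.assert_allclose(u1, u2)

    def test_precision_scales_variance(self, lattice5):
        rng = np.random.default_rng(6)
        lo = np.std([sm.sample_icar(lattice5.graph, 1.0, rng) for _ in range(40)])
        hi = np.std([sm.sample_icar(lattice5.graph, 100.0, rng) for _ in range(40)])
        assert lo / hi == pytest.approx(10.0, rel=0.35)


class TestRecodeStage:
    @pytest.mark.parametrize("breslow,ulcer,nodal,expected", [
        (0.8, True, False, "I"),     # thin tumours are stage I even ulcerated
        (1.0, False, False, "I"),    # boundary belongs to stage I
        (1.5, False, False, "I"),    # intermediate, no ulceration
        (1.5, True, False, "II"),    # intermediate with ulceration
        (2.0, False, False, "I"),
        (2.0, True, False, "II"),
        (2.1, False, False, "II"),   # thick tumours are stage II regardless
        (5.0, False, True, "III-IV"),
        (None, False, True, "III-IV"),  # spread stages without thickness
    ])
    def test_staging_rules(self, breslow, ulcer, nodal, expected):
        assert sm.recode_stage(breslow, ulcer, nodal) == expected

    @pytest.mark.parametrize("breslow", [None, float("nan"), 0.0, -1.0])
    def test_unstageable_without_thickness(self, breslow):
        with pytest.raises(UnstageableError):
            sm.recode_stage(breslow, False, False)
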