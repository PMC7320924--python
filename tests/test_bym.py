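import types

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stagemap as sm
from stagemap.bym import PriorSpec

FAST = dict(n_iter=3000, burn_in=1500, thin=3, n_chains=1)


def _sir(O, E, ids=None):
    ids = ids or [str(i) for i in range(len(O))]
    return pd.DataFrame({"O": O, "E": E}, index=ids)


class TestFitBYM:
    def test_single_area_degenerate_graph(self):
        g = nx.Graph()
        g.add_node("0")
        fit = sm.BYMSmoother(n_iter=8000, burn_in=4000, thin=2, n_chains=2,
                             random_state=3).fit(_sir([50], [50.0]), g)
        assert 0.9 <= fit.theta_.iloc[0] <= 1.1
        assert abs(fit.pp_.iloc[0] - 0.5) <= 0.1

    def test_homogeneous_lattice_shrinks_to_one(self, lattice5):
        n = lattice5.n_areas
        fit = sm.BYMSmoother(random_state=1, **FAST).fit(
            _sir([100] * n, [100.0] * n, lattice5.area_ids), lattice5)
        assert fit.theta_.between(0.95, 1.05).all()
        assert fit.pp_.between(0.2, 0.8).all()

    def test_hot_region_detected(self, hot_fit):
        fit, geo, O, E, hot = hot_fit
        cold = [a for a in geo.area_ids if a not in hot]
        assert fit.theta_[hot].mean() > fit.theta_[cold].mean()
        assert (fit.pp_[hot] > 0.80).mean() >= 0.5

    def test_shrinkage_reduces_variance(self, hot_fit):
        fit, geo, O, E, hot = hot_fit
        raw = (O / E).to_numpy()
        assert fit.theta_.to_numpy().var() <= raw.var()

    def test_structured_effects_sum_to_zero(self, hot_fit):
        fit = hot_fit[0]
        assert abs(fit.u_mean_.sum()) < 1e-9

    def test_monotone_shrinkage_at_equal_precision(self):
        """On an exchangeable (complete) graph with equal E, the smoothed
        SIRs preserve the ordering of the raw counts."""
        g = nx.complete_graph(8)
        g = nx.relabel_nodes(g, str)
        O = [2, 5, 8, 11, 14, 17, 20, 23]
        fit = sm.BYMSmoother(random_state=2, **FAST).fit(
            _sir(O, [10.0] * 8), g)
        assert (np.diff(fit.theta_.to_numpy()) > 0).all()

    def test_seed_determinism_and_chain_variation(self, lattice5):
        n = lattice5.n_areas
        tab = _sir([8] * n, [10.0] * n, lattice5.area_ids)
        kw = dict(n_iter=800, burn_in=400, thin=2, n_chains=1)
        a = sm.BYMSmoother(random_state=7, **kw).fit(tab, lattice5)
        b = sm.BYMSmoother(random_state=7, **kw).fit(tab, lattice5)
        c = sm.BYMSmoother(random_state=8, **kw).fit(tab, lattice5)
        np.testing.assert_array_equal(a.theta_draws_, b.theta_draws_)
        assert not np.array_equal(a.theta_draws_, c.theta_draws_)

    def test_prior_robustness(self):
        """Reasonable alternative precision hyperpriors move every smoothed
        SIR by well under 5% relative on a well-identified fixture."""
        geo = sm.generate_geography(10, 10, income_spatial_trend=0.0, seed=21)
        E = pd.Series(20.0, index=geo.area_ids)
        rr = pd.Series(1.0, index=geo.area_ids)
        rr[[a for a in geo.area_ids
            if geo.areas.loc[a, "x"] < 3.5 and geo.areas.loc[a, "y"] < 3.5]] = 2.0
        rng = np.random.default_rng(22)
        O = pd.Series(rng.poisson(E.values * rr.values), index=geo.area_ids)
        sir = _sir(O.tolist(), E.tolist(), geo.area_ids)
        slow = dict(n_iter=12000, burn_in=3000, thin=3, n_chains=2)
        base = sm.BYMSmoother(random_state=30, **slow).fit(sir, geo)
        alt1 = sm.BYMSmoother(priors=PriorSpec(1.0, 0.01, 1.0, 0.01),
                              random_state=31, **slow).fit(sir, geo)
        alt2 = sm.BYMSmoother(priors=PriorSpec(0.1, 0.001, 0.1, 0.001),
                              random_state=32, **slow).fit(sir, geo)
        for alt in (alt1, alt2):
            rel = np.abs(alt.theta_ / base.theta_ - 1.0)
            assert rel.max() < 0.05

    def test_all_zero_counts_warns_but_fits(self, lattice5):
        n = lattice5.n_areas
        with pytest.warns(UserWarning, match="prior-dominated"):
            fit = sm.BYMSmoother(random_state=1, n_iter=600, burn_in=300,
                                 thin=3, n_chains=1).fit(
                _sir([0] * n, [1.0] * n, lattice5.area_ids), lattice5)
        assert np.isfinite(fit.theta_).all()

    def test_island_pinned_with_warning(self):
        g = nx.Graph()
        g.add_edges_from([("0", "1"), ("1", "2"), ("2", "0")])
        g.add_node("3")
        with pytest.warns(UserWarning, match="island"):
            fit = sm.BYMSmoother(random_state=1, n_iter=600, burn_in=300,
                                 thin=3, n_chains=1).fit(
                _sir([5, 5, 5, 5], [5.0] * 4), g)
        assert np.isfinite(fit.theta_).all()
        with pytest.raises(ValueError, match="no neighbours"):
            sm.BYMSmoother(island_policy="error", **FAST).fit(
                _sir([5, 5, 5, 5], [5.0] * 4), g)

    def test_disconnected_graph_rejected(self):
        g = nx.Graph()
        g.add_edges_from([("0", "1"), ("2", "3")])
        with pytest.raises(ValueError, match="disconnected"):
            sm.BYMSmoother(**FAST).fit(_sir([1, 1, 1, 1], [1.0] * 4), g)

    def test_zero_expected_rows_dropped(self, lattice5):
        n = lattice5.n_areas
        E = [10.0] * n
        E[0] = 0.0
        O = [8] * n
        O[0] = 0
        with pytest.warns(UserWarning, match="dropping"):
            fit = sm.BYMSmoother(random_state=1, n_iter=600, burn_in=300,
                                 thin=3, n_chains=1).fit(
                _sir(O, E, lattice5.area_ids), lattice5)
        assert len(fit.theta_) == n - 1


class TestPosteriorSummaries:
    def test_posterior_pp_counting(self):
        draws = np.full((1000, 1), 0.5)
        draws[:873, 0] = 2.0
        post = types.SimpleNamespace(theta_draws_=draws, area_ids_=["a"])
        assert sm.posterior_pp(post).iloc[0] == pytest.approx(0.873)
        post.theta_draws_ = np.full((200, 1), 2.0)
        assert sm.posterior_pp(post).iloc[0] == 1.0
        post.theta_draws_ = np.exp(np.linspace(-1, 1, 201))[:, None]
        assert sm.posterior_pp(post).iloc[0] == pytest.approx(0.5, abs=0.01)
        post.theta_draws_ = np.ones((50, 1))
        with pytest.raises(ValueError, match="100 retained draws"):
            sm.posterior_pp(post)

    def test_variance_fraction_limits(self):
        post = types.SimpleNamespace(frac_draws_=np.ones(100))
        assert sm.variance_fraction(post) == 1.0
        post.frac_draws_ = np.zeros(100)
        assert sm.variance_fraction(post) == 0.0

    def test_variance_fraction_dominated_by_spatial_field(self):
        """Data generated from a strong ICAR field and negligible
        unstructured noise yield a mostly-structured variance share."""
        geo = sm.generate_geography(10, 10, 0.0, seed=41)
        rng = np.random.default_rng(42)
        u = sm.sample_icar(geo.graph, 3.0, rng, geo.area_ids)
        E = np.full(100, 20.0)
        O = rng.poisson(E * np.exp(u))
        fit = sm.BYMSmoother(random_state=43, **FAST).fit(
            _sir(O.tolist(), E.tolist(), geo.area_ids), geo)
        assert sm.variance_fraction(fit) > 0.5

    def test_summary_table_schema(self, hot_fit):
        fit = hot_fit[0]
        tab = fit.summary_table("I")
        assert list(tab.columns) == ["stage", "O", "E", "raw_sir", "smoothed_sir",
                                     "ci_low", "ci_high", "pp"]
        assert (tab["ci_low"] <= tab["smoothed_sir"]).all()
        assert (tab["smoothed_sir"] <= tab["ci_high"]).all()


class TestDIC:
    def test_deviance_matches_closed_form(self):
        fit = sm.BYMSmoother()
        O = np.array([0.0, 3.0, 7.0])
        E = np.array([1.0, 2.0, 5.0])
        theta = np.array([0.5, 1.5, 1.0])
        expected = -2 * stats.poisson.logpmf(O.astype(int), E * theta).sum()
        assert fit._deviance(O, E, theta) == pytest.approx(expected)

    def test_fixed_parameters_give_zero_effective_parameters(self):
        """A posterior degenerate at the true theta has pD exactly 0."""
        fit = sm.BYMSmoother()
        fit.O_ = np.array([4.0, 9.0, 6.0])
        fit.E_ = np.array([5.0, 8.0, 6.0])
        theta = np.array([0.9, 1.1, 1.0])
        fit.theta_draws_ = np.tile(theta, (500, 1))
        fit.deviance_draws_ = np.full(500, fit._deviance(fit.O_, fit.E_, theta))
        d = sm.compute_dic(fit)
        assert d["pD"] == pytest.approx(0.0, abs=1e-9)
        assert d["dic"] == pytest.approx(d["mean_deviance"])

    def test_effective_parameters_small_for_huge_counts(self):
        # huge homogeneous counts force near-complete shrinkage: the model
        # spends roughly one effective parameter (the global level)
        g = nx.relabel_nodes(nx.cycle_graph(4), str)
        fit = sm.BYMSmoother(n_iter=8000, burn_in=4000, thin=2, n_chains=2,
                             random_state=5).fit(
            _sir([100000] * 4, [100000.0] * 4), g)
        assert 0 <= fit.pd_ < 6.0

    def test_dic_parts_consistent(self, hot_fit):
        fit = hot_fit[0]
        d = sm.compute_dic(fit)
        assert d["dic"] == pytest.approx(d["mean_deviance"] + d["pD"])
        assert d["pD"] > 0


class TestZIP:
    def test_structural_zero_fraction_recovered(self):
        geo = sm.generate_geography(5, 10, 0.0, seed=51)
        rng = np.random.default_rng(52)
        E = np.full(50, 5.0)
        z = rng.random(50) < 0.5
        O = np.where(z, 0, rng.poisson(E))
        fit = sm.ZIPBYMSmoother(n_iter=4000, burn_in=2000, thin=2, n_chains=1,
                                random_state=53).fit(
            _sir(O.tolist(), E.tolist(), geo.area_ids), geo)
        assert 0.3 <= fit.pi_ <= 0.7

    def test_degenerate_mixing_prior_reduces_to_poisson(self, hot_lattice):
        geo, O, E, hot = hot_lattice
        sir = _sir(O.tolist(), E.tolist(), geo.area_ids)
        slow = dict(n_iter=8000, burn_in=3000, thin=2, n_chains=1)
        pois = sm.BYMSmoother(random_state=54, **slow).fit(sir, geo)
        zip_ = sm.ZIPBYMSmoother(zip_prior=(1e-3, 1e3), random_state=54,
                                 **slow).fit(sir, geo)
        assert zip_.pi_ < 1e-3
        rel = np.abs(zip_.theta_ / pois.theta_ - 1.0)
        assert rel.mean() < 0.03 and rel.max() < 0.10

    def test_no_zero_counts_gives_small_pi(self, lattice5):
        n = lattice5.n_areas
        fit = sm.ZIPBYMSmoother(random_state=55, **FAST).fit(
            _sir([12] * n, [10.0] * n, lattice5.area_ids), lattice5)
        assert fit.pi_ < 0.1
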