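"""Expected spectra, composite likelihood, AIC machinery, stairway fits."""

import numpy as np
import pytest

from tealgen.demofit import (
    BootstrapCI,
    aic,
    composite_loglik,
    expected_sfs_analytic_1pop,
    expected_sfs_mc,
    fit_model,
    fit_stairway,
    generations_to_years,
    model_selection,
    parametric_bootstrap,
    piecewise_single_pop,
    sample_sfs,
    theta_from_pi,
)
from tealgen.models import build_model
from tealgen.sfs import FoldedSFS

TABLE3 = [
    ("A1", -3777.76, 3),
    ("A2", -3769.52, 4),
    ("A3", -3774.05, 5),
    ("B1", -3776.73, 5),
    ("B2", -3776.78, 6),
    ("B3", -3777.48, 7),
    ("C1", -3777.96, 7),
    ("C2", -3776.91, 8),
    ("C3", -3777.55, 9),
]


class TestAnalyticSfs:
    def test_constant_n_unfolded_ratios(self):
        # E[xi_1]:E[xi_2]:E[xi_3] = 1 : 1/2 : 1/3 for n=4; folded merges 1&3
        e = expected_sfs_analytic_1pop([1e4], [], 4)
        theta = 2 * 1e4  # branch-length scale: 2N per unit 1/i
        assert np.isclose(e.counts[1], theta * (1 + 1 / 3), rtol=1e-8)
        assert np.isclose(e.counts[2], theta * 0.5, rtol=1e-8)

    def test_expansion_gives_singleton_excess(self):
        const = expected_sfs_analytic_1pop([4e4], [], 12)
        expand = expected_sfs_analytic_1pop([4e4, 5e3], [800.0], 12)
        share = lambda e: e.counts[1] / e.counts[~e.mask].sum()
        assert share(expand) > share(const)

    def test_matches_monte_carlo_three_epochs(self):
        sizes, times = [2e4, 5e3, 4e4], [500.0, 3000.0]
        n = 10
        analytic = expected_sfs_analytic_1pop(sizes, times, n)
        model = piecewise_single_pop(sizes, times)
        mc = expected_sfs_mc(model, (n,), 120_000, seed=31)
        pa = analytic.counts[~analytic.mask] / analytic.counts[~analytic.mask].sum()
        pm = mc.counts[~mc.mask]
        # multinomial SE of the MC estimate per cell
        se = np.sqrt(pa * (1 - pa) / 120_000)
        assert (np.abs(pa - pm) < 4 * se + 1e-4).all()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            expected_sfs_analytic_1pop([1e4], [], 1)
        with pytest.raises(ValueError):
            expected_sfs_analytic_1pop([1e4, -1.0], [100.0], 4)


class TestExpectedSfsMc:
    def test_deep_split_concentrates_private_margins(self, study_model):
        from tealgen.models import DemographicModel

        deep = DemographicModel(
            theta_es=5e3, theta_iq=5e3, t_div=1e5, theta_anc=5e3
        )
        s = expected_sfs_mc(deep, (8, 8), 30_000, seed=5)
        grid = s.counts.copy()
        grid[s.mask] = 0.0
        margins = grid[0, :].sum() + grid[:, 0].sum() + grid[-1, :].sum() + grid[:, -1].sum()
        assert margins > 0.98

    def test_symmetric_model_deme_exchangeable(self):
        from tealgen.models import DemographicModel

        sym = DemographicModel(
            theta_es=1e4, theta_iq=1e4, t_div=2000.0, theta_anc=1e4,
            migration=((0.0, 1e-5), (1e-5, 0.0)),
        )
        s = expected_sfs_mc(sym, (6, 6), 100_000, seed=6)
        grid = s.counts.copy()
        grid[s.mask] = 0.0
        asym = np.abs(grid - grid.T)
        # within Monte-Carlo error: compare to binomial noise scale
        noise = 4 * np.sqrt((grid + grid.T) / 2 / 100_000 + 1e-8)
        assert (asym < noise + 2e-3).all()

    def test_probabilities_sum_to_one(self, study_model):
        s = expected_sfs_mc(study_model, (12, 6), 10_000, seed=7)
        assert np.isclose(s.counts[~s.mask].sum(), 1.0)
        assert (s.counts[~s.mask] > 0).all()  # floored, usable under log


class TestCompositeLoglik:
    def test_all_mass_single_cell(self):
        mask = np.array([True, False, False])
        obs = FoldedSFS(counts=np.array([0.0, 5.0, 0.0]), sample_sizes=(4,), mask=mask)
        p = FoldedSFS(counts=np.array([0.0, 1.0, 0.0]), sample_sizes=(4,), mask=mask)
        assert composite_loglik(obs, p) == 0.0

    def test_hand_computed_value(self):
        mask = np.array([True, False, False])
        obs = FoldedSFS(counts=np.array([0.0, 3.0, 1.0]), sample_sizes=(4,), mask=mask)
        p = FoldedSFS(counts=np.array([0.0, 0.75, 0.25]), sample_sizes=(4,), mask=mask)
        assert np.isclose(composite_loglik(obs, p), 3 * np.log(0.75) + np.log(0.25))

    def test_maximised_at_observed_frequencies(self):
        rng = np.random.default_rng(3)
        mask = np.zeros(6, bool)
        mask[0] = True
        m = np.concatenate([[0.0], rng.integers(1, 30, 5).astype(float)])
        obs = FoldedSFS(counts=m, sample_sizes=(10,), mask=mask)
        p_star = m / m.sum()
        best = composite_loglik(
            obs, FoldedSFS(counts=p_star, sample_sizes=(10,), mask=mask)
        )
        for _ in range(200):
            q = rng.dirichlet(np.ones(5))
            probs = np.concatenate([[0.0], q])
            val = composite_loglik(
                obs, FoldedSFS(counts=probs, sample_sizes=(10,), mask=mask)
            )
            assert val <= best + 1e-9

    def test_shape_mismatch_rejected(self):
        a = FoldedSFS(counts=np.array([0.0, 1.0]), sample_sizes=(2,),
                      mask=np.array([True, False]))
        b = FoldedSFS(counts=np.array([0.0, 1.0, 1.0]), sample_sizes=(4,),
                      mask=np.array([True, False, False]))
        with pytest.raises(ValueError):
            composite_loglik(a, b)


class TestAicSelection:
    @pytest.mark.parametrize(
        "lnl,k,expected",
        [(-3774.05, 5, 7558.10), (-3776.73, 5, 7563.46), (0.0, 0, 0.0)],
    )
    def test_aic_values(self, lnl, k, expected):
        assert np.isclose(aic(lnl, k), expected, atol=1e-9)

    def test_published_nine_model_table(self):
        tab = model_selection(TABLE3).set_index("model")
        assert np.isclose(tab.loc["A3", "dAIC"], 11.06, atol=0.02)
        assert np.isclose(tab.loc["C3", "dAIC"], 26.06, atol=0.02)
        assert np.isclose(tab.loc["A2", "AIC"], 7547.04, atol=0.02)
        assert round(tab.loc["A2", "weight"], 2) == 0.99
        assert np.isclose(tab["weight"].sum(), 1.0, atol=1e-12)
        assert tab["dAIC"].min() == 0.0

    def test_single_and_tied_models(self):
        one = model_selection([("A1", -10.0, 2)])
        assert one["dAIC"].iloc[0] == 0.0 and one["weight"].iloc[0] == 1.0
        two = model_selection([("A1", -10.0, 2), ("A2", -9.0, 3)])
        assert np.allclose(two["weight"], 0.5)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            model_selection([("A1", -1.0, 2), ("A1", -2.0, 2)])

    def test_weight_order_inverse_of_daic(self):
        tab = model_selection(TABLE3)
        assert (tab.sort_values("dAIC")["weight"].diff().dropna() <= 1e-12).all()


class TestScalings:
    @pytest.mark.parametrize(
        "t,years", [(407.0, 1628.0), (0.0, 0.0), (450.0, 1800.0), (2109.0, 8436.0)]
    )
    def test_generation_conversion(self, t, years):
        assert generations_to_years(t, 4.0) == years

    def test_theta_from_pi_inverts_published_value(self):
        assert round(theta_from_pi(4.70e-4, 4.83e-9)) == 48654

    def test_theta_scaling_properties(self):
        assert theta_from_pi(0.0, 1e-8) == 0.0
        assert np.isclose(
            theta_from_pi(1e-3, 2e-8), theta_from_pi(1e-3, 1e-8) / 2
        )


@pytest.fixture(scope="module")
def si_observation():
    truth = dict(theta_anc=3225.0, theta_es=16388.0, t_div=407.0)
    model = build_model("A1", truth, theta_iq=48654.0)
    probs = expected_sfs_mc(model, (12, 6), 60_000, seed=41)
    return sample_sfs(probs, 2500, seed=42)


class TestFitting:
    def test_nested_model_dominance(self, si_observation):
        # A1 is A2 at m=0: A2's fitted lnL cannot fall below A1's by more
        # than optimizer/Monte-Carlo tolerance
        f1 = fit_model(si_observation, "A1", 48654.0, n_replicates=2,
                       n_sim_snps=10_000, polish_sim=40_000, seed=1)
        f2 = fit_model(si_observation, "A2", 48654.0, n_replicates=2,
                       n_sim_snps=10_000, polish_sim=40_000, seed=1)
        assert f2.lnL >= f1.lnL - 2.0

    def test_replicate_max_nondecreasing(self, si_observation):
        f1 = fit_model(si_observation, "A1", 48654.0, n_replicates=1,
                       n_sim_snps=10_000, seed=9)
        f3 = fit_model(si_observation, "A1", 48654.0, n_replicates=3,
                       n_sim_snps=10_000, seed=9)
        assert max(f3.replicate_lnls) >= max(f1.replicate_lnls) - 1e-9

    def test_deterministic_under_seed(self, si_observation):
        f1 = fit_model(si_observation, "A1", 48654.0, n_replicates=1,
                       n_sim_snps=10_000, seed=4)
        f2 = fit_model(si_observation, "A1", 48654.0, n_replicates=1,
                       n_sim_snps=10_000, seed=4)
        assert f1.lnL == f2.lnL and f1.params == f2.params


class TestBootstrap:
    def test_toy_bootstrap_bounds_ordered(self):
        truth = dict(theta_anc=3225.0, theta_es=16388.0, t_div=407.0)
        model = build_model("A1", truth, theta_iq=48654.0)
        probs = expected_sfs_mc(model, (8, 4), 30_000, seed=51)
        obs = sample_sfs(probs, 1500, seed=52)
        fit = fit_model(obs, "A1", 48654.0, n_replicates=1, n_sim_snps=10_000,
                        polish_sim=10_000, seed=53)
        ci = parametric_bootstrap(obs, fit, 48654.0, B=2, seed=54,
                                  n_replicates=1, n_sim_snps=10_000,
                                  polish_sim=10_000)
        assert isinstance(ci, BootstrapCI)
        assert (ci.table["lower"] <= ci.table["upper"]).all()


class TestStairway:
    def make_obs(self, sizes, times, n, n_snps, seed):
        e = expected_sfs_analytic_1pop(sizes, times, n)
        p = FoldedSFS(
            counts=np.where(e.mask, 0.0, e.counts), sample_sizes=(n,), mask=e.mask
        )
        return sample_sfs(p, n_snps, seed)

    def test_point_only_when_no_bootstrap(self):
        obs = self.make_obs([2e4], [], 12, 800, seed=61)
        # choose mu*L so the observed S is consistent with theta
        a1 = np.sum(1.0 / np.arange(1, 12))
        mu_L = 800 / (a1 * 2 * 2e4)
        traj = fit_stairway(obs, total_length=mu_L / 4.83e-9, mu=4.83e-9,
                            epoch_breaks=[1000.0], B=0, seed=1)
        assert traj.median is None and traj.n_bootstrap == 0
        assert traj.times_gen.tolist() == [0.0, 1000.0]

    def test_constant_history_recovered(self):
        n, truth = 16, 3e4
        obs = self.make_obs([truth], [], n, 4000, seed=62)
        a1 = np.sum(1.0 / np.arange(1, n))
        mu_L = 4000 / (a1 * 2 * truth)
        traj = fit_stairway(obs, total_length=mu_L / 1e-8, mu=1e-8,
                            epoch_breaks=[2000.0, 20_000.0], B=6, seed=2)
        assert (np.abs(traj.point - truth) / truth < 0.5).all()
        assert (traj.lower <= traj.median).all()
        assert (traj.median <= traj.upper).all()

    def test_underdetermined_schedule_rejected(self):
        obs = self.make_obs([2e4], [], 6, 200, seed=63)
        with pytest.raises(ValueError, match="underdetermined"):
            fit_stairway(obs, 1e6, 4.83e-9, epoch_breaks=[10, 100, 1000, 10000], seed=1)
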