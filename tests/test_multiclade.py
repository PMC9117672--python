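import numpy as np
import pytest

from montane import BDModelSpec, CladeData, CladeSet, fit_bd
from montane.bd import bd_loglik
from montane.multiclade import (compare_shared_vs_specific, fit_shared,
                                joint_loglik, posterior_batch)
from montane.simulate import sim_bd_tree


@pytest.fixture(scope="module")
def pair_tree():
    return sim_bd_tree(lam=0.4, mu=0.05, crown_age=8.0, f=1.0, seed=31)


class TestJointLoglik:
    def test_two_identical_clades_double_the_loglik(self, pair_tree):
        spec = BDModelSpec("BCST_DCST")
        single = bd_loglik(CladeData(tree=pair_tree), spec, [0.4, 0.1])
        cs = CladeSet([CladeData(tree=pair_tree, name="c1"),
                       CladeData(tree=pair_tree, name="c2")])
        assert joint_loglik(cs, spec, [0.4, 0.1]) == pytest.approx(
            2.0 * single, abs=1e-9)

    def test_invariant_to_clade_order(self, pair_tree):
        other = sim_bd_tree(lam=0.4, mu=0.05, crown_age=6.0, f=0.8, seed=32)
        spec = BDModelSpec("BCST_DCST")
        a = joint_loglik(CladeSet([CladeData(tree=pair_tree, name="x"),
                                   CladeData(tree=other, f=0.8, name="y")]),
                         spec, [0.35, 0.05])
        b = joint_loglik(CladeSet([CladeData(tree=other, f=0.8, name="y"),
                                   CladeData(tree=pair_tree, name="x")]),
                         spec, [0.35, 0.05])
        assert a == pytest.approx(b, abs=1e-12)

    def test_clade_names_must_be_unique(self, pair_tree):
        with pytest.raises(ValueError, match="unique"):
            CladeSet([CladeData(tree=pair_tree, name="c"),
                      CladeData(tree=pair_tree, name="c")])


class TestSharedFit:
    def test_aic_consistent_and_lnl_decomposes(self, pair_tree):
        other = sim_bd_tree(lam=0.4, mu=0.05, crown_age=6.0, f=0.9, seed=33)
        cs = CladeSet([CladeData(tree=pair_tree, name="a"),
                       CladeData(tree=other, f=0.9, name="b")])
        fit = fit_shared(cs, BDModelSpec("BCST_DCST"), n_starts=2, seed=0)
        assert fit.aic == pytest.approx(-2.0 * fit.lnl + 2.0 * 2)
        assert sum(fit.clade_lnls.values()) == pytest.approx(fit.lnl, abs=1e-9)

    def test_identical_clades_specific_fits_cost_minus_four(self, pair_tree):
        cs = CladeSet([CladeData(tree=pair_tree, name="c1"),
                       CladeData(tree=pair_tree, name="c2")])
        rec = compare_shared_vs_specific(cs, BDModelSpec("BCST_DCST"),
                                         n_starts=2, seed=0)
        # byte-identical clades: specific fits buy no likelihood, 2 extra params
        assert rec["aicdiff"] == pytest.approx(-4.0, abs=1e-4)
        assert rec["df"] == 2

    def test_df_convention_six_clades_two_params(self):
        trees = [sim_bd_tree(lam=0.4, mu=0.05, crown_age=6.0, f=1.0,
                             seed=40 + i) for i in range(6)]
        cs = CladeSet([CladeData(tree=t, name=f"c{i}")
                       for i, t in enumerate(trees)])
        rec = compare_shared_vs_specific(cs, BDModelSpec("BCST_DCST"),
                                         n_starts=2, seed=0)
        assert rec["df"] == 10
        # shared model is nested in the specific combination
        assert sum(f.lnl for f in rec["specific_fits"].values()) \
            >= rec["shared_fit"].lnl - 1e-6

    def test_heterogeneous_rates_favor_specific_fits(self):
        """Clades simulated with wildly different speciation rates."""
        hits = 0
        for rep in range(10):
            slow = [sim_bd_tree(lam=0.1, mu=0.0, crown_age=20.0, f=1.0,
                                seed=900 + 10 * rep + i) for i in range(2)]
            fast = [sim_bd_tree(lam=1.0, mu=0.0, crown_age=3.5, f=1.0,
                                seed=950 + 10 * rep + i) for i in range(2)]
            cs = CladeSet([CladeData(tree=t, name=f"c{i}")
                           for i, t in enumerate(slow + fast)])
            rec = compare_shared_vs_specific(cs, BDModelSpec("BCST_DCST"),
                                             n_starts=2, seed=rep)
            if rec["aicdiff"] > 0:
                hits += 1
        assert hits >= 9

    def test_pooling_reduces_estimator_rmse(self):
        """Shared-fit lambda is closer to truth than the mean of six
        independent per-clade estimates (25-tip clades)."""
        lam, mu = 0.4, 0.1
        shared_err, mean_err = [], []
        spec = BDModelSpec("BCST_DCST")
        for rep in range(30):
            rng = np.random.default_rng(7000 + rep)
            clades = []
            for i in range(6):
                t = sim_bd_tree(lam=lam, mu=mu, n_tips=25, f=1.0,
                                seed=int(rng.integers(2 ** 31)))
                clades.append(CladeData(tree=t, name=f"c{i}"))
            sf = fit_shared(CladeSet(clades), spec, n_starts=2, seed=rep)
            singles = [fit_bd(c, spec, n_starts=2, seed=rep).params["lambda0"]
                       for c in clades]
            shared_err.append((sf.params["lambda0"] - lam) ** 2)
            mean_err.append((np.mean(singles) - lam) ** 2)
        assert np.sqrt(np.mean(shared_err)) < np.sqrt(np.mean(mean_err))


class TestPosteriorBatch:
    def _draws(self, n_draws, seed0):
        draws = []
        for d in range(n_draws):
            draws.append([sim_bd_tree(lam=0.4, mu=0.05, crown_age=6.0 + i,
                                      f=1.0, seed=seed0 + 10 * d + i)
                          for i in range(3)])
        return draws

    def test_single_draw_reduces_to_one_aicdiff(self):
        draws = self._draws(1, 100)
        batch = posterior_batch(draws, [1.0, 1.0, 1.0],
                                BDModelSpec("BCST_DCST"),
                                BDModelSpec("BTIME_DCST"), n_starts=2, seed=0)
        assert batch.n_draws == 1
        assert batch.median_aicdiff == pytest.approx(
            batch.table["aicdiff"].iloc[0])

    def test_median_invariant_to_draw_order(self):
        draws = self._draws(4, 200)
        a = posterior_batch(draws, [1.0] * 3, BDModelSpec("BCST_DCST"),
                            BDModelSpec("BTIME_DCST"), n_starts=2, seed=0)
        b = posterior_batch(draws[::-1], [1.0] * 3, BDModelSpec("BCST_DCST"),
                            BDModelSpec("BTIME_DCST"), n_starts=2, seed=0)
        assert a.median_aicdiff == pytest.approx(b.median_aicdiff, abs=1e-6)

    def test_null_simulation_median_aicdiff_small(self):
        """Posterior-like replicate draws of a constant-rate truth: the
        time-dependent model should not be preferred (median AICdiff <= 2)."""
        draws = self._draws(20, 300)
        batch = posterior_batch(draws, [1.0] * 3, BDModelSpec("BCST_DCST"),
                                BDModelSpec("BTIME_DCST"), n_starts=2, seed=0)
        assert batch.median_aicdiff <= 2.0
        assert batch.n_failed == 0
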