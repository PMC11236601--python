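import numpy as np
import pandas as pd
import pytest

import heteropool as hp
from heteropool import synthetic as syn
from heteropool import trial_models as tm
from heteropool.synthetic import TruthParams


def _toy_plan(n_hybrids=6, n_parents=6):
    parents = [f"P{i}" for i in range(n_parents)]
    rows = []
    k = 0
    for i in range(n_parents):
        for j in range(i + 1, n_parents):
            if k >= n_hybrids:
                break
            rows.append((f"H{k}", parents[i], parents[j]))
            k += 1
    crosses = pd.DataFrame(rows, columns=["hybrid", "male", "female"])
    return syn.CrossPlan(crosses=crosses,
                         site_hybrids={"S0": list(crosses["hybrid"])},
                         checks=[])


class TestAdditiveDesign:
    def test_rows_have_two_unit_entries(self):
        plan = _toy_plan()
        H = tm.build_hybrid_additive_design(plan)
        assert (H.sum(axis=1) == 2).all()
        assert ((H == 0) | (H == 1)).all().all()

    def test_reciprocal_crosses_identical(self):
        crosses = pd.DataFrame({"hybrid": ["H0", "H1"],
                                "male": ["A", "B"], "female": ["B", "A"]})
        plan = syn.CrossPlan(crosses=crosses,
                             site_hybrids={"S0": ["H0", "H1"]}, checks=[])
        H = tm.build_hybrid_additive_design(plan)
        np.testing.assert_array_equal(H.iloc[0].to_numpy(),
                                      H.iloc[1].to_numpy())

    def test_full_trial_network_dimensions(self):
        # 722 hybrids from 131 pollen parents x 25 female parents
        rng = np.random.default_rng(0)
        males = [f"M{i}" for i in range(131)]
        females = [f"F{i}" for i in range(25)]
        pairs = set()
        while len(pairs) < 722:
            pairs.add((males[rng.integers(131)], females[rng.integers(25)]))
        crosses = pd.DataFrame(
            [(f"H{k}", m, f) for k, (m, f) in enumerate(sorted(pairs))],
            columns=["hybrid", "male", "female"])
        plan = syn.CrossPlan(crosses=crosses, site_hybrids={}, checks=[])
        H = tm.build_hybrid_additive_design(plan, parents=males + females)
        assert H.shape == (722, 156)
        assert (H.sum(axis=1) == 2).all()

    def test_unknown_parent_rejected(self):
        plan = _toy_plan()
        with pytest.raises(ValueError, match="unknown parent"):
            tm.build_hybrid_additive_design(plan, parents=["P0", "P1"])


class TestREMLCore:
    def test_balanced_one_way_matches_anova(self, rng):
        # balanced one-way layout: REML equals the closed-form ANOVA
        # estimators sigma2_e = MSE, sigma2_g = (MSB - MSE) / r
        g, r = 12, 6
        sg, se = 1.2, 0.7
        effects = rng.normal(0, np.sqrt(sg), g)
        y = (np.repeat(effects, r)
             + rng.normal(0, np.sqrt(se), g * r) + 5.0)
        Z = np.kron(np.eye(g), np.ones((r, 1)))
        X = np.ones((g * r, 1))
        term = tm.RandomTerm(name="g", Z=Z,
                             levels=np.array([f"g{i}" for i in range(g)]))
        theta, _, ll, conv, _, P, Py = tm.fit_mixed_model(y, X, [term])
        ybar = y.reshape(g, r).mean(axis=1)
        msb = r * np.sum((ybar - y.mean()) ** 2) / (g - 1)
        mse = np.sum((y.reshape(g, r) - ybar[:, None]) ** 2) / (g * (r - 1))
        assert conv
        assert theta[1] == pytest.approx(mse, rel=1e-4)
        assert theta[0] == pytest.approx((msb - mse) / r, rel=1e-4)

    def test_single_observation_shrinkage_closed_form(self, rng):
        # identity relationship, one record per hybrid, intercept only:
        # BLUP_i = (s2g / (s2g + s2e)) * (y_i - GLS mean)
        n = 30
        y = rng.normal(3.0, 1.0, n)
        Z = np.eye(n)
        X = np.ones((n, 1))
        term = tm.RandomTerm(name="h", Z=Z,
                             levels=np.array([f"h{i}" for i in range(n)]))
        s2g, s2e = 0.8, 0.5
        res = tm._reml_loglik(y, X, [Z @ Z.T], np.eye(n),
                              np.array([s2g, s2e]))
        _, P, Py, _, _ = res
        u = s2g * Z.T @ Py
        shrink = s2g / (s2g + s2e)
        expected = shrink * (y - y.mean())
        np.testing.assert_allclose(u, expected, atol=1e-10)

    def test_null_genetic_signal_shrinks_to_zero(self):
        panel = hp.simulate_founders(K=1, n_per_group=20, n_markers=50,
                                     fst=0.2, seed=3)
        plan = syn.make_cross_plan(panel, n_hybrids=60, sites=["S0"],
                                   hybrids_per_site=50, checks=["C1"], seed=3)
        truth = TruthParams(n_sites=1, sigma2_a=0.0, sigma2_s=0.0,
                            sigma2_e=1.0, sigma2_spatial=0.0)
        pheno, _ = syn.simulate_met(panel, plan, truth, seed=3)
        H = tm.build_hybrid_additive_design(
            plan, parents=list(panel.genotypes.individual_ids))
        fit = tm.reml_fit(pheno, tm.TrialModelSpec(), H=H)
        assert 2 * fit.varcomp["additive"] < 0.05
        assert np.abs(fit.blups["additive"]["blup"]).max() < 0.1

    def test_mixed_model_equation_residual(self, desk, desk_fits):
        # at convergence u_hat = s2 G Z' P y must satisfy the MME: check the
        # equivalent V-form identity  Z'V^-1(y - X b - Z u...) via P algebra
        fits, H = desk_fits
        fit = fits["S01"]
        spec = tm.TrialModelSpec()
        y, X, names, terms, df = tm.build_site_design(
            desk.pheno[desk.pheno.site == "S01"], spec, H=H)
        theta = np.array([fit.varcomp[t.name] for t in terms]
                         + [fit.varcomp["residual"]])
        A_list = [t.Z @ (t.Z.T if t.G is None else t.G @ t.Z.T)
                  for t in terms]
        res = tm._reml_loglik(y, X, A_list, np.eye(len(y)), theta)
        _, P, Py, Vinv, _ = res
        # MME residual: for each term, s2*G*Z'*Vinv*(y - Xb - sum Z u) == u
        beta = fit.beta.to_numpy()
        fitted = X @ beta
        for i, t in enumerate(terms):
            u = fit.blups[t.name]["blup"].to_numpy()
            fitted = fitted + t.Z @ u
        e = y - fitted
        for i, t in enumerate(terms):
            u = fit.blups[t.name]["blup"].to_numpy()
            G = np.eye(t.Z.shape[1]) if t.G is None else t.G
            lhs = theta[i] * G @ t.Z.T @ (e / theta[-1])
            rel = np.linalg.norm(lhs - u) / max(np.linalg.norm(u), 1e-9)
            assert rel < 1e-6

    def test_partitioned_model_nests_hybrid_model(self, desk):
        H = tm.build_hybrid_additive_design(
            desk.plan, parents=list(desk.panel.genotypes.individual_ids))
        site = desk.pheno[desk.pheno.site == "S03"]
        part = tm.reml_fit(site, tm.TrialModelSpec(genetic="additive+sca"),
                           H=H)
        single = tm.reml_fit(site, tm.TrialModelSpec(genetic="hybrid"))
        assert part.loglik >= single.loglik - 1e-4

    def test_reliability_in_unit_interval(self, desk_fits):
        fits, _ = desk_fits
        for fit in fits.values():
            for t in fit.blups.values():
                assert ((t["reliability"] >= 0) & (t["reliability"] <= 1)).all()
            assert all(v >= 0 for v in fit.varcomp.values())

    def test_aliased_fixed_design_reported(self):
        df = pd.DataFrame({
            "site": "S", "row": [1, 1, 2, 2], "col": [1, 2, 1, 2],
            "block": 1, "entry": ["C1", "C1", "C1", "C1"],
            "male": "", "female": "", "is_check": True,
            "yield": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="aliased"):
            tm.reml_fit(df, tm.TrialModelSpec(genetic="hybrid"))


class TestSpatialComparison:
    @staticmethod
    def _simulate(seed, rho_r, rho_c, s2sp):
        panel = hp.simulate_founders(K=1, n_per_group=30, n_markers=30,
                                     fst=0.2, seed=seed)
        plan = syn.make_cross_plan(panel, n_hybrids=60, sites=["S0"],
                                   hybrids_per_site=55, checks=["C1"],
                                   seed=seed)
        truth = TruthParams(n_sites=1, sigma2_a=0.4, sigma2_s=0.0,
                            sigma2_e=0.6, sigma2_spatial=s2sp,
                            rho_row=rho_r, rho_col=rho_c)
        pheno, _ = syn.simulate_met(panel, plan, truth, seed=seed)
        H = tm.build_hybrid_additive_design(
            plan, parents=list(panel.genotypes.individual_ids))
        return pheno, H

    def test_returns_both_fits(self):
        pheno, H = self._simulate(0, 0.5, 0.5, 0.6)
        out = tm.compare_spatial(pheno, tm.TrialModelSpec(), H=H)
        assert {"iid", "ar1xar1", "selected", "fit"} <= set(out)
        assert out["selected"] in ("iid", "ar1xar1")
        assert out["fit"] is out[out["selected"]]

    def test_spatial_data_prefers_ar1_majority(self):
        wins = 0
        n = 5
        for seed in range(n):
            pheno, H = self._simulate(100 + seed, 0.6, 0.4, 1.0)
            out = tm.compare_spatial(pheno, tm.TrialModelSpec(), H=H)
            wins += out["selected"] == "ar1xar1"
        assert wins > n / 2

    def test_iid_data_prefers_iid_majority(self):
        wins = 0
        n = 5
        for seed in range(n):
            pheno, H = self._simulate(200 + seed, 0.0, 0.0, 0.0)
            out = tm.compare_spatial(pheno, tm.TrialModelSpec(), H=H)
            wins += out["selected"] == "iid"
        assert wins > n / 2


class TestMultiSite:
    def test_parent_blup_table_shape_and_sparsity(self, desk, desk_fits):
        fits, _ = desk_fits
        tab = tm.parent_blup_table(fits)
        assert tab.shape == (40, 8)
        # sparse MET: some parents untested at some sites may be NaN; all
        # finite cells come from parents with plots there
        for site, fit in fits.items():
            t = fit.blups["additive"]
            n_obs = t.set_index("level")["n_obs"]
            observed = tab[site].notna()
            assert (n_obs[observed.index][observed] > 0).all()
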