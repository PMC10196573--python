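"""Expression tallies, Poisson GLM machinery, and contingency tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from foragemod.expression import (epoch_contingency_test, fisher_exact_rxc,
                                  interaction_glm_test, per_module_posttests,
                                  poisson_gof_test, tally_module_expression)
from foragemod.validation import poisson_irls_deviance, simulate_count_table


def small_table(rng=None, equal=False):
    rng = rng or np.random.default_rng(0)
    rows = []
    mid = 0
    for geno in ("WT", "KO"):
        for sex in ("M", "F"):
            for _ in range(6):
                mid += 1
                row = {"mouse_id": mid, "sex": sex, "genotype": geno,
                       "phase": "F"}
                for j, m in enumerate(["modA", "modB", "modC"]):
                    lam = 5.0 + j
                    row[m] = 5 + j if equal else rng.poisson(lam)
                rows.append(row)
    return pd.DataFrame(rows)


class TestTally:
    def test_row_sums_conserve_labeled_excursions(self, processed_small):
        excursions, matrix, processed, manifest, truth = processed_small
        from foragemod.module_detection import detect_modules
        from foragemod.excursions import export_excursion_index
        import tempfile, os
        with tempfile.TemporaryDirectory() as d:
            idx = export_excursion_index(excursions, os.path.join(d, "i.csv"))
        catalog, *_ = detect_modules(matrix, manifest, seed=0,
                                     k_range=range(2, 5), n_perm=50)
        counts = tally_module_expression(catalog, idx)
        label_cols = [c for c in counts.columns
                      if c not in ("mouse_id", "sex", "genotype", "phase")]
        total = counts[label_cols].to_numpy().sum()
        n_labeled = sum(1 for v in catalog.labels.values() if v != "0")
        assert total == n_labeled

    def test_epoch_assignment_by_start_time(self):
        from foragemod.module_detection import ModuleCatalog, ReproducibilityResult
        repro = ReproducibilityResult([1], {1: 1.0}, {1: 5}, {1: 0.001},
                                      {1: 0.001}, pi0=1.0)
        labels = {f"m001.e{i:03d}.M.adult.WT.F": "M1" for i in range(1, 4)}
        cat = ModuleCatalog([1], {1: [0.0]}, repro, labels, pc_k=2)
        idx = pd.DataFrame({"cimar": list(labels),
                            "start_time_s": [30.0, 700.0, 700.5]})
        counts = tally_module_expression(cat, idx, epochs=[(0, 10), (10, 30)])
        by_epoch = counts.groupby("epoch")["M1"].sum()
        assert by_epoch[1] == 1 and by_epoch[2] == 2


class TestInteractionGlm:
    def test_identical_counts_give_null_result(self):
        table = small_table(equal=True)
        res = interaction_glm_test(table)
        assert res.lrt_stat == pytest.approx(0.0, abs=1e-8)
        assert res.p > 0.99

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(3)
        table, _ = simulate_count_table(rng)
        res = interaction_glm_test(table)
        assert res.p < 1e-4

    def test_worked_table_deviance_matches_irls_oracle(self):
        rng = np.random.default_rng(5)
        # 2 modules x 2 genotypes x 4 mice worked example
        rows = []
        for mid, (geno, sex) in enumerate(
                [("WT", "M"), ("WT", "F"), ("KO", "M"), ("KO", "F")], 1):
            for m, lam in (("modA", 4), ("modB", 9)):
                rows.append({"mouse_id": mid, "sex": sex, "genotype": geno,
                             "module": m,
                             "count": int(rng.poisson(lam))})
        long = pd.DataFrame(rows)
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        fit = smf.glm("count ~ C(sex) + C(genotype)", data=long,
                      family=sm.families.Poisson()).fit()
        dev_oracle, grad = poisson_irls_deviance(long)
        assert grad < 1e-8  # oracle converged
        assert fit.deviance == pytest.approx(dev_oracle, abs=1e-8)

    def test_lrt_invariant_to_module_relabeling(self):
        table = small_table()
        res1 = interaction_glm_test(table)
        renamed = table.rename(columns={"modA": "zz", "modC": "aa"})
        res2 = interaction_glm_test(renamed)
        assert res1.lrt_stat == pytest.approx(res2.lrt_stat, rel=1e-9)


class TestPosttests:
    def test_zero_variance_module_filtered(self):
        table = small_table()
        table["flat"] = 3
        post = per_module_posttests(table)
        assert "flat" in post.filtered_out
        assert "flat" not in set(post.per_module["module"])

    def test_planted_effects_recovered(self):
        rng = np.random.default_rng(11)
        table, affected = simulate_count_table(rng)
        post = per_module_posttests(table)
        assert set(affected) <= set(post.significant)


class TestGof:
    def test_calibrated_under_true_poisson(self):
        rng = np.random.default_rng(0)
        import statsmodels.api as sm
        ps = []
        for _ in range(200):
            x = rng.integers(0, 2, 60)
            mu = np.exp(2.5 + 0.3 * x)  # moderate means: chi2 asymptotics hold
            y = rng.poisson(mu)
            X = sm.add_constant(x.astype(float))
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            _, _, p = poisson_gof_test(fit)
            ps.append(p)
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_overdispersion_rejected(self):
        rng = np.random.default_rng(1)
        import statsmodels.api as sm
        rejects = 0
        n_sims = 40
        for _ in range(n_sims):
            x = rng.integers(0, 2, 60)
            mu = np.exp(1.5 + 0.3 * x)
            # negative binomial with dispersion ~5
            y = rng.negative_binomial(n=1.0, p=1.0 / (1.0 + mu))
            X = sm.add_constant(x.astype(float))
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            _, _, p = poisson_gof_test(fit)
            rejects += p < 0.05
        assert rejects >= 0.95 * n_sims

    def test_saturated_model_deviance_zero_p_one(self):
        import statsmodels.api as sm
        y = np.array([3.0, 7.0])
        X = np.eye(2)
        fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        dev, df, p = poisson_gof_test(fit)
        assert dev == pytest.approx(0.0, abs=1e-8)
        assert df == 0 and np.isnan(p)


class TestContingency:
    def test_exact_2x2_matches_hypergeometric_enumeration(self):
        # oracle: full enumeration of tables with margins (4,4)/(4,4)
        obs = np.array([[3, 1], [1, 3]])
        rv = hypergeom(8, 4, 4)
        p_obs = rv.pmf(3)
        p_enum = sum(rv.pmf(k) for k in range(5) if rv.pmf(k) <= p_obs + 1e-12)
        assert p_enum == pytest.approx(34 / 70)
        assert fisher_exact_rxc(obs) == pytest.approx(34 / 70)

    def test_monte_carlo_rxc_calibrated_against_chi2(self):
        rng = np.random.default_rng(0)
        tab = rng.poisson(30, size=(4, 3)) + 5
        from scipy.stats import chi2_contingency
        p_mc = fisher_exact_rxc(tab, n_draws=20000, seed=1)
        p_chi = chi2_contingency(tab)[1]
        assert abs(p_mc - p_chi) < 0.12  # large counts: asymptotics agree

    def test_identical_columns_independent(self):
        counts = pd.DataFrame({"g1": [30, 20, 10], "g2": [30, 20, 10]},
                              index=["M1", "M2", "M3"])
        res = epoch_contingency_test(counts)
        assert res.p > 0.99
        if res.method == "chi2":
            assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_planted_genotype_module_dependence_detected(self):
        rng = np.random.default_rng(4)
        base = np.array([40, 30, 20, 10])
        cols = {}
        for g in ("KO_M", "KO_F"):
            cols[g] = rng.poisson(base[::-1] * 2)
        for g in ("WT_M", "WT_F"):
            cols[g] = rng.poisson(base * 2)
        counts = pd.DataFrame(cols, index=[f"M{i}" for i in range(1, 5)])
        res = epoch_contingency_test(counts)
        assert res.p < 0.01
        order = res.column_order
        ko = {order.index("KO_M"), order.index("KO_F")}
        assert ko in ({0, 1}, {2, 3})  # genotypes cluster together

    def test_column_scaling_preserves_rank_order(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.poisson(20, (6, 3)),
                              columns=list("abc"))
        counts.index = [f"M{i}" for i in range(6)]
        res = epoch_contingency_test(counts)
        for c in res.scaled.columns:
            assert (np.argsort(res.scaled[c].to_numpy())
                    == np.argsort(counts.loc[res.scaled.index, c].to_numpy())).all()
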