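import numpy as np
import pandas as pd
import pytest

from hervlink.associate import (
    AssociationConfig,
    fit_condition_model,
    fit_pair_association,
    rank_top_associations,
    transform_expression,
)
from hervlink.de import nb_de_test
from hervlink.filtering import size_factors

from conftest import make_count_matrix, nb_draw
from oracles import ols_oracle

CPM = AssociationConfig(transform="log2_cpm_plus1")


class TestConditionModel:
    def test_constant_feature_has_zero_beta(self):
        x = np.full((1, 8), 64)
        cm = make_count_matrix(x)
        res = fit_condition_model(cm, CPM)
        assert res["beta"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_exact_shift_recovered(self):
        # equal library sizes; case counts 4x control => log2 shift of ~2
        x = np.array([[400, 400, 400, 100, 100, 100], [50, 50, 50, 50, 50, 50]])
        cm = make_count_matrix(x, conditions=["case"] * 3 + ["control"] * 3)
        cfg = AssociationConfig(transform="log2_norm_plus1")
        res = fit_condition_model(cm, cfg)
        expr = transform_expression(cm, cfg)
        shift = expr.loc["F0", ["s0", "s1", "s2"]].mean() - expr.loc["F0", ["s3", "s4", "s5"]].mean()
        assert res["beta"].loc["F0"] == pytest.approx(shift)
        assert res["p_value"].loc["F0"] < 1e-6

    def test_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(21)
        x = rng.poisson(80, size=(5, 6))
        cm = make_count_matrix(x, conditions=["case"] * 3 + ["control"] * 3)
        res = fit_condition_model(cm, CPM)
        expr = transform_expression(cm, CPM)
        design = cm.condition_mask("case").astype(float)
        for fid in cm.feature_ids:
            b, se, p = ols_oracle(expr.loc[fid].to_numpy(), design)
            assert res["beta"].loc[fid] == pytest.approx(b, abs=1e-10)
            assert res["se"].loc[fid] == pytest.approx(se, abs=1e-10)
            assert res["p_value"].loc[fid] == pytest.approx(p, abs=1e-10)

    def test_matches_statsmodels_glm_fit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(33)
        x = rng.poisson(60, size=(4, 10))
        cm = make_count_matrix(x, conditions=["case"] * 5 + ["control"] * 5)
        res = fit_condition_model(cm, CPM)
        expr = transform_expression(cm, CPM)
        design = sm.add_constant(cm.condition_mask("case").astype(float))
        for fid in cm.feature_ids:
            fit = sm.OLS(expr.loc[fid].to_numpy(), design).fit()
            assert res["beta"].loc[fid] == pytest.approx(fit.params[1], abs=1e-10)
            assert res["p_value"].loc[fid] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_too_few_samples_rejected(self):
        cm = make_count_matrix([[1, 2]], conditions=["case", "control"])
        with pytest.raises(ValueError):
            fit_condition_model(cm, CPM)

    def test_betas_track_de_log2fc_on_planted_data(self):
        """Condition betas and the NB test's fold changes rank features the
        same way when effects are strong."""
        rng = np.random.default_rng(14)
        m = 300
        mu = np.exp(rng.normal(5.0, 0.7, m)) + 50
        lfc = np.zeros(m)
        de = rng.choice(m, 40, replace=False)
        lfc[de] = rng.normal(0, 2.0, size=40)
        design = np.array([1.0] * 30 + [0.0] * 30)
        x = nb_draw(rng, mu[:, None] * 2.0 ** (lfc[:, None] * design[None, :]), 0.1)
        cm = make_count_matrix(x, conditions=["case"] * 30 + ["control"] * 30)
        betas = fit_condition_model(cm, CPM)
        de_res = nb_de_test(cm, size_factors(cm))
        rho = pd.concat([betas["beta"], de_res["log2fc"]], axis=1).corr(method="spearman").iloc[0, 1]
        assert rho > 0.9


class TestPairAssociation:
    def test_identical_columns_give_unit_beta_and_rho(self):
        # second constant row keeps library sizes equal across both matrices,
        # so the CPM transform maps the shared first row identically
        x = np.array([[10, 20, 40, 80, 160, 320], [100, 100, 100, 100, 100, 100]])
        cm_g = make_count_matrix(x, feature_ids=["G1", "G2"], conditions=["case"] * 3 + ["control"] * 3)
        cm_h = make_count_matrix(x, feature_ids=["H1", "H2"], conditions=["case"] * 3 + ["control"] * 3)
        res = fit_pair_association(cm_g, cm_h, [("H1", "G1")], CPM)
        assert res["beta"].iloc[0] == pytest.approx(1.0)
        assert res["spearman_rho"].iloc[0] == pytest.approx(1.0)

    def test_sample_mismatch_is_hard_error(self):
        cm_g = make_count_matrix([[1, 2, 3, 4]])
        cm_h = make_count_matrix([[1, 2, 3]], conditions=["case", "case", "control"])
        with pytest.raises(ValueError, match="sample"):
            fit_pair_association(cm_g, cm_h, [], CPM)

    def test_null_pairs_calibrated(self):
        """Independent gene/HERV pairs should reject at roughly the nominal
        rate on raw p-values."""
        rng = np.random.default_rng(6)
        n_pairs, n = 800, 40
        g = rng.poisson(100, size=(n_pairs, n))
        h = rng.poisson(100, size=(n_pairs, n))
        cm_g = make_count_matrix(g, feature_ids=[f"G{i}" for i in range(n_pairs)])
        cm_h = make_count_matrix(h, feature_ids=[f"H{i}" for i in range(n_pairs)])
        res = fit_pair_association(
            cm_g, cm_h, [(f"H{i}", f"G{i}") for i in range(n_pairs)], CPM
        )
        rate = (res["p_value"] < 0.05).mean()
        band = 4 * np.sqrt(0.05 * 0.95 / n_pairs)
        assert abs(rate - 0.05) < band

    def test_planted_shared_effect_detected(self):
        rng = np.random.default_rng(8)
        n = 48
        driver = rng.normal(0, 1, n)
        h = np.round(100 * 2.0 ** (driver + rng.normal(0, 0.2, n))).astype(int)
        g = np.round(80 * 2.0 ** (0.8 * driver + rng.normal(0, 0.2, n))).astype(int)
        noise = rng.poisson(90, size=(20, n))
        cm_h = make_count_matrix(np.vstack([h, noise]), feature_ids=["H0"] + [f"HN{i}" for i in range(20)])
        cm_g = make_count_matrix(np.vstack([g, noise]), feature_ids=["G0"] + [f"GN{i}" for i in range(20)])
        pairs = [("H0", "G0")] + [(f"HN{i}", f"GN{i - 1}" if i else "GN19") for i in range(3)]
        res = fit_pair_association(cm_g, cm_h, pairs, CPM)
        top = res[res["herv_id"] == "H0"].iloc[0]
        assert top["q_value"] < 0.05
        assert top["spearman_rho"] > 0.5

    def test_invariant_to_joint_sample_permutation(self):
        rng = np.random.default_rng(12)
        g = rng.poisson(100, size=(3, 10))
        h = rng.poisson(100, size=(3, 10))
        cm_g = make_count_matrix(g, feature_ids=["Ga", "Gb", "Gc"])
        cm_h = make_count_matrix(h, feature_ids=["Ha", "Hb", "Hc"])
        pairs = [("Ha", "Gb"), ("Hb", "Gc")]
        r1 = fit_pair_association(cm_g, cm_h, pairs, CPM)
        perm = rng.permutation(10)
        cm_g2 = make_count_matrix(
            g[:, perm],
            feature_ids=["Ga", "Gb", "Gc"],
            conditions=[cm_g.sample_meta["condition"].iloc[i] for i in perm],
        )
        cm_h2 = make_count_matrix(
            h[:, perm],
            feature_ids=["Ha", "Hb", "Hc"],
            conditions=[cm_h.sample_meta["condition"].iloc[i] for i in perm],
        )
        r2 = fit_pair_association(cm_g2, cm_h2, pairs, CPM)
        assert r1["beta"].to_numpy() == pytest.approx(r2["beta"].to_numpy())
        assert r1["spearman_rho"].to_numpy() == pytest.approx(r2["spearman_rho"].to_numpy())


class TestRanking:
    def frame(self, rows):
        df = pd.DataFrame(
            rows, columns=["herv_id", "gene_id", "spearman_rho", "q_value"]
        )
        df["significant"] = True
        return df

    def test_sorted_by_absolute_rho(self):
        res = self.frame([("H1", "G1", 0.5, 0.01), ("H2", "G2", -0.9, 0.01)])
        top = rank_top_associations(res, 2)
        assert list(top["herv_id"]) == ["H2", "H1"]

    def test_k_larger_than_list_returns_all(self):
        res = self.frame([("H1", "G1", 0.5, 0.01)])
        assert len(rank_top_associations(res, 10)) == 1

    def test_rho_ties_broken_by_q(self):
        res = self.frame([("H1", "G1", 0.7, 0.01), ("H2", "G2", 0.7, 0.001)])
        top = rank_top_associations(res, 2)
        assert list(top["herv_id"]) == ["H2", "H1"]
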