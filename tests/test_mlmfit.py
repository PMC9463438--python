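"""Multilevel fits, likelihood-ratio tests, sibling FE, twin descriptive."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gnurture import mlmfit, simcohort
from gnurture.mlmfit import (
    ModelFit,
    conditional_wave3_frame,
    falconer_from_correlations,
    falconer_h2,
    fit_gxe,
    fit_lmm,
    lrt,
    ols_r2,
    sibling_fe,
)


def _stub_fit(m2ll, df, names=("Intercept", "x")):
    return ModelFit(
        params=pd.Series(0.0, index=list(names)),
        bse=pd.Series(1.0, index=list(names)),
        varcomp={},
        m2ll=m2ll,
        df_model=df,
        n_obs=10,
        n_persons=10,
        n_families=5,
        ols_r2=0.0,
        method="ml",
        converged=True,
    )


class TestFitLmm:
    def test_degenerate_nesting_reduces_to_ols(self):
        # single-observation clusters: the GLS weighting is scalar, so the
        # multilevel estimates must equal plain least squares
        cfg = simcohort.SimulationConfig(
            n_families=300, sibs_per_family=1, sibship_mix={"singleton": 1.0},
            var_family=0.0, var_person=0.0, n_strata=1, strata_weights=(1.0,),
            stratum_effect=0.0, us_born_effect=0.0, english_home_effect=0.0,
            in_school_effect=0.0, missing_rate=0.0, seed=31,
        )
        sim = simcohort.simulate_cohort(cfg)
        tp = sim.truth.persons.set_index("person_id")
        d = sim.cohort.merge(tp[["z_u", "z_ses"]], left_on="person_id", right_index=True)
        d1 = d[d.wave == 1]
        terms = ["z_u", "z_ses", "age", "female"]
        fit = fit_lmm(d1, "pvt_score", terms, person_col=None)
        ols = sm.OLS(d1["pvt_score"], sm.add_constant(d1[terms])).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params.to_numpy(), atol=1e-6)

    def test_three_level_fit_labels_three_components(self, truth_frame):
        fit = fit_lmm(truth_frame, "pvt_score", ["z_u", "z_ses", "age"])
        assert list(fit.varcomp) == ["family", "person", "wave"]
        assert all(v >= 0 for v in fit.varcomp.values())
        assert np.isfinite(fit.m2ll)
        assert fit.n_obs == len(truth_frame)

    def test_two_level_fit_labels_two_components(self, truth_frame):
        w3 = conditional_wave3_frame(truth_frame)
        fit = fit_lmm(w3, "pvt_score", ["pvt_w1", "z_u"], person_col=None)
        assert list(fit.varcomp) == ["family", "person"]

    def test_ml_likelihood_decreases_with_added_predictor(self, truth_frame):
        small = fit_lmm(truth_frame, "pvt_score", ["z_ses"], method="ml")
        big = fit_lmm(truth_frame, "pvt_score", ["z_ses", "z_u"], method="ml")
        assert big.m2ll <= small.m2ll + 1e-6

    def test_singular_design_names_columns(self, truth_frame):
        d = truth_frame.assign(z_copy=truth_frame["z_u"])
        with pytest.raises(ValueError, match="collinear"):
            fit_lmm(d, "pvt_score", ["z_u", "z_copy"])

    def test_single_person_families_rejected_for_three_level(self):
        cfg = simcohort.SimulationConfig(
            n_families=50, sibs_per_family=1, sibship_mix={"singleton": 1.0}, seed=32
        )
        sim = simcohort.simulate_cohort(cfg)
        with pytest.raises(ValueError, match="person_col=None"):
            fit_lmm(sim.cohort, "pvt_score", ["age"])

    def test_variance_component_recovery(self):
        # parameter-recovery oracle: known variances on a sibling design
        cfg = simcohort.SimulationConfig(
            n_families=800, sibship_mix={"fullsib": 1.0}, missing_rate=0.0, seed=33
        )
        sim = simcohort.simulate_cohort(cfg)
        tp = sim.truth.persons.set_index("person_id")
        d = sim.cohort.merge(tp[["z_u", "z_ses"]], left_on="person_id", right_index=True)
        fit = fit_lmm(
            d, "pvt_score",
            ["z_u", "z_ses", "age", "female", "hispanic", "us_born", "english_home",
             "in_school"],
        )
        for level, truth in (("family", 38.0), ("person", 28.0), ("wave", 25.0)):
            assert fit.varcomp[level] == pytest.approx(truth, rel=0.2)
        for term, truth in (("z_u", 2.5), ("z_ses", 4.2)):
            assert abs(fit.params[term] - truth) < 3 * fit.bse[term]


class TestLrt:
    def test_published_gxe_likelihoods_reject_at_5pct(self):
        reduced = _stub_fit(67_064.0, 22)
        full = _stub_fit(67_058.0, 24)
        res = lrt(reduced, full)
        assert res.statistic == pytest.approx(6.0)
        assert res.df == 2
        from scipy import stats

        assert res.statistic > stats.chi2.ppf(0.95, 2)  # 5.991
        assert res.pvalue < 0.05

    def test_identical_likelihoods_give_p_one(self):
        res = lrt(_stub_fit(100.0, 3), _stub_fit(100.0, 5))
        assert res.statistic == 0
        assert res.pvalue == pytest.approx(1.0)

    def test_worse_full_model_raises(self):
        with pytest.raises(ValueError, match="nesting"):
            lrt(_stub_fit(100.0, 3), _stub_fit(101.0, 5))

    def test_reml_with_differing_fixed_effects_raises(self):
        a = _stub_fit(100.0, 3, names=("Intercept", "x"))
        b = _stub_fit(90.0, 5, names=("Intercept", "x", "y"))
        b.method = "reml"
        with pytest.raises(ValueError, match="REML"):
            lrt(a, b)


class TestOlsR2:
    def test_exact_linear_response(self, rng):
        x = rng.normal(size=200)
        d = pd.DataFrame({"y": 2 + 3 * x, "x": x})
        assert ols_r2(d, "y", ["x"]) == pytest.approx(1.0)

    def test_null_design_explains_nothing(self, rng):
        d = pd.DataFrame({"y": rng.normal(size=10_000), "x": rng.normal(size=10_000)})
        assert ols_r2(d, "y", ["x"]) < 0.01

    def test_predictor_rescaling_invariance(self, rng):
        x = rng.normal(size=300)
        y = x + rng.normal(size=300)
        d = pd.DataFrame({"y": y, "x": x, "x_scaled": 17.3 * x + 2})
        assert ols_r2(d, "y", ["x"]) == pytest.approx(ols_r2(d, "y", ["x_scaled"]))

    def test_zero_response_variance_raises(self):
        d = pd.DataFrame({"y": [1.0, 1.0, 1.0], "x": [1, 2, 3]})
        with pytest.raises(ValueError, match="variance"):
            ols_r2(d, "y", ["x"])

    def test_nested_designs_monotone(self, truth_frame):
        r_small = ols_r2(truth_frame, "pvt_score", ["z_ses"])
        r_big = ols_r2(truth_frame, "pvt_score", ["z_ses", "z_u"])
        assert r_big >= r_small


class TestGxE:
    def test_recentering_leaves_interaction_unchanged(self, truth_frame):
        d = truth_frame.copy()
        g1 = fit_gxe(d, "pvt_score", ["z_u"], "z_ses", controls=["age"])
        d2 = d.assign(z_ses=d.z_ses + 10)
        g2 = fit_gxe(d2, "pvt_score", ["z_u"], "z_ses", controls=["age"])
        assert g1.interaction.params["z_u_x_z_ses"] == pytest.approx(
            g2.interaction.params["z_u_x_z_ses"], abs=1e-6
        )
        # main effects shift by the centering algebra but stay equal here
        # because products are formed from mean-centered inputs
        assert g1.interaction.params["z_u"] == pytest.approx(
            g2.interaction.params["z_u"], abs=1e-6
        )

    def test_interaction_magnitude_recovered(self):
        # generative interaction echoing the printed 0.36 estimate
        cfg = simcohort.SimulationConfig(
            n_families=800, gxe_coef=0.36, missing_rate=0.0, seed=34
        )
        sim = simcohort.simulate_cohort(cfg)
        tp = sim.truth.persons.set_index("person_id")
        d = sim.cohort.merge(tp[["z_u", "z_ses"]], left_on="person_id", right_index=True)
        g = fit_gxe(d, "pvt_score", ["z_u"], "z_ses", controls=["age", "female"])
        est = g.interaction.params["z_u_x_z_ses"]
        se = g.interaction.bse["z_u_x_z_ses"]
        assert abs(est - 0.36) < 3 * se

    def test_null_interaction_coverage(self):
        # with no generative interaction the estimate should sit within 3 SE
        # of zero in nearly all replicates
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            cfg = simcohort.SimulationConfig(
                n_families=120, missing_rate=0.0, seed=5000 + rep
            )
            sim = simcohort.simulate_cohort(cfg)
            tp = sim.truth.persons.set_index("person_id")
            d = sim.cohort.merge(tp[["z_u", "z_ses"]], left_on="person_id",
                                 right_index=True)
            d = d.assign(inter=(d.z_u - d.z_u.mean()) * (d.z_ses - d.z_ses.mean()))
            X = sm.add_constant(d[["z_u", "z_ses", "inter", "age", "female"]])
            res = sm.OLS(d.pvt_score, X).fit(
                cov_type="cluster", cov_kwds={"groups": d.person_id}
            )
            if abs(res.params["inter"]) < 3 * res.bse["inter"]:
                hits += 1
        assert hits >= int(0.94 * n_rep)


class TestSiblingFe:
    def test_family_constant_shift_leaves_estimates_unchanged(self, truth_frame):
        base = sibling_fe(truth_frame, "pvt_score", ["z_u"])
        fam_shift = truth_frame.family_id.map(
            {f: i * 5.0 for i, f in enumerate(truth_frame.family_id.unique())}
        )
        shifted = truth_frame.assign(pvt_score=truth_frame.pvt_score + fam_shift)
        fe2 = sibling_fe(shifted, "pvt_score", ["z_u"])
        assert fe2.params["z_u"] == pytest.approx(base.params["z_u"], abs=1e-10)

    def test_fe_corrects_between_family_confounding(self):
        cfg = simcohort.SimulationConfig(n_families=1200, missing_rate=0.0, seed=35)
        sim = simcohort.simulate_cohort(cfg)
        tp = sim.truth.persons.set_index("person_id")
        d = sim.cohort.merge(tp[["z_u"]], left_on="person_id", right_index=True)
        fe = sibling_fe(d, "pvt_score", ["z_u"])
        pooled = sm.OLS(d.pvt_score, sm.add_constant(d[["z_u"]])).fit().params["z_u"]
        b = cfg.b_child
        assert abs(fe.params["z_u"] - b) < abs(pooled - b)

    def test_identical_pgs_family_contributes_nothing(self):
        d = pd.DataFrame(
            {
                "family_id": ["a"] * 2 + ["b"] * 2,
                "person_id": ["a1", "a2", "b1", "b2"],
                "sibship_type": "fullsib",
                "pgs": [1.0, 1.0, 0.0, 2.0],
                "y": [5.0, 9.0, 1.0, 3.0],
            }
        )
        fit = sibling_fe(d, "y", ["pgs"])
        # only family b identifies the slope: (3-1)/(2-0) = 1
        assert fit.params["pgs"] == pytest.approx(1.0)

    def test_mz_pairs_are_excluded_and_need_variance(self):
        d = pd.DataFrame(
            {
                "family_id": ["a"] * 2,
                "person_id": ["a1", "a2"],
                "sibship_type": "mz",
                "pgs": [1.0, 2.0],
                "y": [5.0, 9.0],
            }
        )
        with pytest.raises(ValueError, match="non-MZ"):
            sibling_fe(d, "y", ["pgs"])

    def test_no_within_family_variance_raises(self):
        d = pd.DataFrame(
            {
                "family_id": ["a"] * 2 + ["b"] * 2,
                "person_id": ["a1", "a2", "b1", "b2"],
                "sibship_type": "fullsib",
                "pgs": [1.0, 1.0, 2.0, 2.0],
                "y": [5.0, 9.0, 1.0, 3.0],
            }
        )
        with pytest.raises(ValueError, match="within-family variance"):
            sibling_fe(d, "y", ["pgs"])


class TestFalconer:
    @pytest.mark.parametrize(
        "r_mz, r_dz, expected",
        [(0.50, 0.31, 0.38), (0.4, 0.4, 0.0), (1.0, 0.5, 1.0), (0.9, 0.1, 1.0)],
    )
    def test_estimator_arithmetic(self, r_mz, r_dz, expected):
        assert falconer_from_correlations(r_mz, r_dz) == pytest.approx(expected)

    def test_invalid_correlation_raises(self):
        with pytest.raises(ValueError):
            falconer_from_correlations(1.2, 0.1)

    def test_cohort_summary(self, small_sim):
        twin = falconer_h2(small_sim.cohort)
        assert twin.n_mz_pairs >= 2 and twin.n_dz_pairs >= 2
        assert -1 <= twin.r_mz <= 1 and -1 <= twin.r_dz <= 1
        assert 0 <= twin.h2 <= 1

    def test_too_few_pairs_raise(self, small_sim):
        no_mz = small_sim.cohort[small_sim.cohort.sibship_type != "mz"]
        with pytest.raises(ValueError, match="MZ"):
            falconer_h2(no_mz)


class TestConditionalFrame:
    def test_persons_lacking_a_wave_are_excluded(self, truth_frame):
        drop_person = truth_frame.person_id.iloc[0]
        d = truth_frame[
            ~((truth_frame.person_id == drop_person) & (truth_frame.wave == 3))
        ]
        w3 = conditional_wave3_frame(d)
        assert drop_person not in set(w3.person_id)
        assert (w3["pvt_w1"].notna()).all()

    def test_one_row_per_person(self, truth_frame):
        w3 = conditional_wave3_frame(truth_frame)
        assert w3.person_id.is_unique
        assert len(w3) == truth_frame.person_id.nunique()
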